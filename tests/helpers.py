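"""Independent oracles used by the tests.

The pair-correlation oracle recomputes g(r) from the binary image by direct
O(n²) pair counting over on-pixels with an analytic rectangle edge
correction — no FFTs — so it shares no code path with the estimator it
checks.
"""

import numpy as np
import pandas as pd

from qsmlm.locio import BinaryImage, LocalizationTable


def pair_correlation_bruteforce(image: BinaryImage, max_r: float = 500.0,
                                bin_width: float = 5.0):
    """Radial pair correlation by explicit pair counting on the pixel grid."""
    ys, xs = np.nonzero(image.pixels)
    ps = image.pixel_size
    H, W = image.pixels.shape
    n = len(xs)
    edges = np.arange(0.0, max_r + bin_width, bin_width)
    n_bins = len(edges) - 1
    num = np.zeros(n_bins)
    for i in range(n):
        rr = ps * np.hypot(xs - xs[i], ys - ys[i])
        rr[i] = -1.0  # self pair
        which = np.digitize(rr, edges) - 1
        ok = (rr > 0) & (which >= 0) & (which < n_bins)
        np.add.at(num, which[ok], 1.0)
    # analytic rectangle-mask autocorrelation, binned over the same lags
    mlag = int(np.ceil(max_r / ps))
    lag = np.arange(-mlag, mlag + 1)
    dy, dx = np.meshgrid(lag, lag, indexing="ij")
    rr = ps * np.hypot(dx, dy)
    c_mask = np.maximum(H - np.abs(dy), 0) * np.maximum(W - np.abs(dx), 0)
    which = np.digitize(rr.ravel(), edges) - 1
    ok = (rr.ravel() > 0) & (which >= 0) & (which < n_bins)
    den = np.bincount(which[ok], weights=c_mask.ravel().astype(float)[ok],
                      minlength=n_bins)
    rho_px = n / (H * W)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(den > 0, num / (rho_px ** 2 * den), 0.0)
    r = 0.5 * (edges[:-1] + edges[1:])
    return r, g, num


def make_table(frame, x, y, photons=None, precision=None,
               field_width=None, field_height=None) -> LocalizationTable:
    """Small LocalizationTable from raw arrays with convenient defaults."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    df = pd.DataFrame({
        "frame": np.asarray(frame, dtype=np.int64),
        "x_nm": x,
        "y_nm": y,
        "photons": np.full(n, 1000.0) if photons is None else np.asarray(photons, float),
        "precision_nm": np.full(n, 10.0) if precision is None else np.asarray(precision, float),
    })
    fw = field_width if field_width is not None else (x.max() if n else 1.0)
    fh = field_height if field_height is not None else (y.max() if n else 1.0)
    return LocalizationTable(df, float(fw), float(fh))
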