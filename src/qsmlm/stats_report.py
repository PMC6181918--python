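"""Study-level statistics: correlations, thresholds, NMI, summaries, fixtures.

Includes the embedded patient summary table (seven breast-tumor touch-prep
patients with FISH HER2 copy numbers and qSMLM densities / cluster
parameters) used for the correlation analyses, and the statistical helpers:
Pearson correlation with Fisher-z confidence interval, least-squares line,
the copy-number-to-density threshold inversion, fraction of ROIs above a
density threshold, normalized mutual information between two result
distributions, and mean/SEM/CV summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import normalized_mutual_info_score


def load_table1() -> pd.DataFrame:
    """Patient summary fixture (P1-P7): FISH copy numbers, qSMLM densities,
    receptors per cluster, cluster radii, clustered fractions, precisions."""
    with resources.files("qsmlm").joinpath("data/table1_patients.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    slope: float
    intercept: float
    r_squared: float
    n: int


def pearson_with_ci(x, y, confidence: float = 0.95) -> CorrelationResult:
    """Pearson correlation with Fisher-z CI, t-test p-value and OLS line.

    The least-squares line regresses y on x, so with y = copy number and
    x = a qSMLM quantity the slope/intercept match a calibration of copy
    number against the imaging readout.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    xm, ym = x - x.mean(), y - y.mean()
    r = float((xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym)))
    n = len(x)
    # Fisher z-transform CI
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    zc = stats.norm.ppf(0.5 + confidence / 2)
    half = zc / np.sqrt(n - 3) if n > 3 else np.inf
    ci_low, ci_high = float(np.tanh(z - half)), float(np.tanh(z + half))
    # two-sided p from the t statistic with n-2 df
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / max(1 - r ** 2, 1e-300))
    p = float(2 * stats.t.sf(abs(t), n - 2))
    slope = float((xm @ ym) / (xm @ xm))
    intercept = float(y.mean() - slope * x.mean())
    return CorrelationResult(r=r, ci_low=ci_low, ci_high=ci_high, p_value=p,
                             slope=slope, intercept=intercept,
                             r_squared=r ** 2, n=n)


def density_threshold_from_fit(fit: CorrelationResult, copy_number: float = 6.0) -> float:
    """Invert the copy-number-on-density line at a clinical copy number.

    With copy = slope * density + intercept, the density corresponding to
    ``copy_number`` is (copy_number - intercept) / slope.  The default of 6
    is the single-probe FISH positivity cutoff.
    """
    if fit.slope == 0:
        raise ValueError("zero slope: threshold undefined")
    return (copy_number - fit.intercept) / fit.slope


def fraction_above_threshold(densities, threshold: float) -> float:
    """Fraction of per-ROI densities strictly above the threshold."""
    densities = np.asarray(densities, dtype=float)
    if len(densities) == 0:
        raise ValueError("empty density list")
    return float((densities > threshold).mean())


def nmi_score(a, b, n_bins: int | None = None) -> float:
    """Normalized mutual information between two result distributions.

    Both samples are paired by quantile rank (each resampled at common
    quantiles when lengths differ), discretized with one shared binning
    (Freedman-Diaconis on the pooled values unless ``n_bins`` is given),
    and scored with mutual information normalized by the arithmetic mean of
    the marginal entropies.  1 means the distributions match bin for bin;
    independent or disjoint samples score near 0.
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    n = min(len(a), len(b))
    q = (np.arange(n) + 0.5) / n
    a_q = np.quantile(a, q)
    b_q = np.quantile(b, q)
    pooled = np.concatenate([a_q, b_q])
    if n_bins is None:
        iqr = np.subtract(*np.percentile(pooled, [75, 25]))
        if iqr <= 0:
            warnings.warn("degenerate pooled distribution: NMI set to 0")
            return 0.0
        width = 2 * iqr / len(pooled) ** (1 / 3)
        n_bins = max(int(np.ceil((pooled.max() - pooled.min()) / width)), 1)
    edges = np.linspace(pooled.min(), pooled.max(), n_bins + 1)
    lab_a = np.clip(np.digitize(a_q, edges) - 1, 0, n_bins - 1)
    lab_b = np.clip(np.digitize(b_q, edges) - 1, 0, n_bins - 1)
    if len(np.unique(lab_a)) < 2 or len(np.unique(lab_b)) < 2:
        warnings.warn("single occupied bin: NMI set to 0")
        return 0.0
    score = normalized_mutual_info_score(lab_a, lab_b, average_method="arithmetic")
    return float(np.clip(score, 0.0, 1.0))


@dataclass(frozen=True)
class Summary:
    mean: float
    sem: float
    cv_percent: float | None
    n: int


def summarize(values) -> Summary:
    """Mean, SEM (sample sd / sqrt(n)) and CV (100 * sd / mean, %)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("summary requires n >= 2")
    sd = float(values.std(ddof=1))
    mean = float(values.mean())
    sem = sd / np.sqrt(len(values))
    if mean == 0:
        warnings.warn("zero mean: CV undefined")
        cv = None
    else:
        cv = 100.0 * sd / mean
    return Summary(mean=mean, sem=sem, cv_percent=cv, n=len(values))


def patient_density_correlation(table: pd.DataFrame | None = None) -> CorrelationResult:
    """Copy number vs detected density over the patients with FISH values."""
    t = load_table1() if table is None else table
    t = t.dropna(subset=["fish_copy_number"])
    return pearson_with_ci(t["density_per_um2"], t["fish_copy_number"])


def patient_per_cluster_correlation(table: pd.DataFrame | None = None) -> CorrelationResult:
    """Copy number vs receptors per cluster over the clustered patients."""
    t = load_table1() if table is None else table
    t = t.dropna(subset=["fish_copy_number", "per_cluster"])
    return pearson_with_ci(t["per_cluster"], t["fish_copy_number"])
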