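"""End-to-end per-ROI analysis composing the individual stages.

Order of operations follows the standard workflow: photon cut, precision
percentile cut, density (artifact) filter, binarization, then density
quantification, pair-correlation fitting and cluster occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import locio, paircorr
from .config import AnalysisConfig
from .density import Roi, RoiDensityResult, detected_density_from_image
from .locio import LocalizationTable
from .occupancy import OccupancyResult, occupancy_pipeline
from .paircorr import PcFit


@dataclass(frozen=True)
class RoiAnalysis:
    """All per-ROI results: filtered table, density, fit, occupancy."""

    table: LocalizationTable
    density: RoiDensityResult
    fit: PcFit
    occupancy: OccupancyResult
    loss_fraction: float


def apply_filters(table: LocalizationTable, config: AnalysisConfig | None = None) -> LocalizationTable:
    """Photon cut -> precision percentile cut -> density filter."""
    config = config or AnalysisConfig()
    table = locio.filter_min_photons(table, config.min_photons)
    if len(table):
        table = locio.filter_precision_percentile(table, config.precision_percentile)
        table = locio.density_filter(table, config.density_filter_radius,
                                     config.density_filter_max_neighbors)
    return table


def analyze_roi(table: LocalizationTable, config: AnalysisConfig | None = None,
                prefiltered: bool = False) -> RoiAnalysis:
    """Run the full analysis on one ROI-sized localization table.

    The ROI is taken to span the table's field.  Returns density (from the
    binarized image, so binning losses are folded in), the pair-correlation
    fit, and — for ROIs with detected clustering — the occupancy result.
    """
    config = config or AnalysisConfig()
    if not prefiltered:
        table = apply_filters(table, config)
    image = locio.binarize(table, config.pixel_size)
    roi = Roi(x0=0.0, y0=0.0, side=table.field_width)
    dens = detected_density_from_image(image, roi, config.alpha)
    corr = paircorr.autocorrelate(image, max_r=config.max_r, bin_width=config.bin_width)
    sigma_bar = float(np.mean(table.precision)) if len(table) else 12.0
    fit = paircorr.fit_protein_correlation(corr, sigma_bar=sigma_bar,
                                           alpha=config.alpha,
                                           deconvolve=config.deconvolve,
                                           r_min=config.r_min)
    occ = occupancy_pipeline(table, fit, precision_mean=sigma_bar,
                             max_dark_frames=config.max_dark_frames,
                             grouping_factor=config.grouping_factor)
    return RoiAnalysis(table=table, density=dens, fit=fit, occupancy=occ,
                       loss_fraction=image.loss_fraction)
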