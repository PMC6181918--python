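"""Cluster occupancy: localizations -> molecules -> clusters -> fraction clustered.

Two grouping scales, both single-linkage (transitive, order-independent):

1. localization -> molecule: spatial distance within a radius tied to the
   localization precision AND frame gap within the maximum fluorophore dark
   time.  Connected components of this spatiotemporal graph are molecules;
   each molecule's position is the centroid of its member localizations.
2. molecule -> cluster: centroids linked at distance <= 2x the cluster
   radius from pair-correlation analysis (the cluster diameter).
   Components with more than two molecules count as clusters.

The headline quantity is the fraction of molecules residing in clusters of
more than two (the fraction of clustered receptors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .density import _spatiotemporal_components
from .locio import LocalizationTable
from .paircorr import PcFit


@dataclass(frozen=True)
class Molecule:
    x: float
    y: float
    n_localizations: int
    first_frame: int
    last_frame: int


@dataclass(frozen=True)
class OccupancyResult:
    molecules: list
    cluster_labels: np.ndarray    # component id per molecule
    cluster_sizes: np.ndarray     # component size per component id
    n_clusters: int               # components with > 2 molecules
    fraction_clustered: float
    skipped: bool = False         # True when the ROI had no detected clustering

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x_nm": [m.x for m in self.molecules],
            "y_nm": [m.y for m in self.molecules],
            "n_locs": [m.n_localizations for m in self.molecules],
            "first_frame": [m.first_frame for m in self.molecules],
            "last_frame": [m.last_frame for m in self.molecules],
            "cluster_id": self.cluster_labels,
        })


def group_localizations(table: LocalizationTable, spatial_radius: float,
                        max_dark_frames: int = 250,
                        return_labels: bool = False):
    """Group localizations into molecules by spatiotemporal single linkage.

    Two localizations are linked when within ``spatial_radius`` AND their
    frame gap is at most ``max_dark_frames``; linkage is transitive.
    Returns the list of :class:`Molecule` (and per-localization labels when
    ``return_labels``).
    """
    if spatial_radius <= 0 or max_dark_frames < 0:
        raise ValueError("grouping parameters must be positive")
    if len(table) == 0:
        return ([], np.empty(0, dtype=int)) if return_labels else []
    labels = _spatiotemporal_components(table.x, table.y, table.frames,
                                        spatial_radius, max_dark_frames)
    order = np.argsort(labels, kind="stable")
    x, y, frames = table.x[order], table.y[order], table.frames[order]
    lab_sorted = labels[order]
    boundaries = np.flatnonzero(np.r_[True, np.diff(lab_sorted) > 0])
    counts = np.diff(np.r_[boundaries, len(lab_sorted)])
    molecules = []
    for start, size in zip(boundaries, counts):
        sl = slice(start, start + size)
        molecules.append(Molecule(
            x=float(x[sl].mean()), y=float(y[sl].mean()),
            n_localizations=int(size),
            first_frame=int(frames[sl].min()), last_frame=int(frames[sl].max())))
    if return_labels:
        return molecules, labels
    return molecules


def assign_clusters(molecules: list, cluster_radius: float) -> OccupancyResult:
    """Single-linkage clustering of molecule centroids.

    Molecules within ``2 * cluster_radius`` of each other (the cluster
    diameter; the linkage distance is inclusive) join the same component.
    Components of three or more molecules are clusters; the fraction
    clustered is the share of molecules living in such components.
    """
    if cluster_radius <= 0:
        raise ValueError("cluster_radius must be > 0")
    if not molecules:
        raise ValueError("assign_clusters requires at least one molecule")
    pts = np.array([[m.x, m.y] for m in molecules])
    n = len(pts)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(2.0 * cluster_radius, output_type="ndarray")
    graph = sparse.coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                              shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    in_cluster = sizes[labels] >= 3
    return OccupancyResult(
        molecules=molecules, cluster_labels=labels, cluster_sizes=sizes,
        n_clusters=int((sizes >= 3).sum()),
        fraction_clustered=float(in_cluster.mean()))


def occupancy_pipeline(table: LocalizationTable, fit: PcFit,
                       precision_mean: float | None = None,
                       max_dark_frames: int = 250,
                       grouping_factor: float = 4.0) -> OccupancyResult:
    """Full occupancy analysis of one ROI given its pair-correlation fit.

    Applied only to ROIs with detected clustering; for a random ROI the
    result carries ``fraction_clustered = 0`` and ``skipped = True``.  The
    localization -> molecule radius is ``grouping_factor`` times the mean
    precision (same-molecule pair distances are Rayleigh with scale
    sqrt(2) sigma, so 4 sigma keeps nearly all of them linked); the
    molecule -> cluster linkage uses the fitted correlation length xi.
    """
    if precision_mean is None:
        precision_mean = float(np.mean(table.precision)) if len(table) else fit.sigma_bar
    if not fit.clustered:
        return OccupancyResult(molecules=[], cluster_labels=np.empty(0, dtype=int),
                               cluster_sizes=np.empty(0, dtype=int), n_clusters=0,
                               fraction_clustered=0.0, skipped=True)
    molecules = group_localizations(table, grouping_factor * precision_mean,
                                    max_dark_frames)
    return assign_clusters(molecules, cluster_radius=fit.xi)
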