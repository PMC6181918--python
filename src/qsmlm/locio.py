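"""Localization tables: data model, CSV I/O, quality filters, binarization.

A localization is one detected appearance of a blinking fluorophore in one
camera frame, with a sub-diffraction position estimate (nm) and a
localization precision sigma (nm).  All downstream analysis (density,
pair correlation, cluster occupancy) consumes the :class:`LocalizationTable`
defined here.

The canonical CSV schema is ``frame,x_nm,y_nm,photons,precision_nm``.
A dialect layer maps other column conventions (e.g. ThunderSTORM exports)
onto it, optionally rescaling positions to nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

CANONICAL_COLUMNS = ("frame", "x_nm", "y_nm", "photons", "precision_nm")

#: Column mapping for CSVs in the canonical schema (identity mapping).
CANONICAL_DIALECT: dict = {c: c for c in CANONICAL_COLUMNS}

#: ThunderSTORM-style export headers mapped onto the canonical schema.
THUNDERSTORM_DIALECT: dict = {
    "frame": "frame",
    "x_nm": "x [nm]",
    "y_nm": "y [nm]",
    "photons": "intensity [photon]",
    "precision_nm": "uncertainty [nm]",
}


class FormatError(ValueError):
    """Input file does not conform to the declared column dialect."""


@dataclass(frozen=True)
class LocalizationTable:
    """Ordered collection of localizations inside a rectangular field.

    Parameters
    ----------
    records
        DataFrame with the canonical columns; row order is meaningful and
        preserved by every operation.
    field_width, field_height
        Field-of-view extent in nm.  All positions lie in
        ``[0, field_width] x [0, field_height]``.
    metadata
        Provenance log.  Every filter appends exactly one entry, so the
        full processing history of a table is auditable.
    """

    records: pd.DataFrame
    field_width: float
    field_height: float
    metadata: tuple = field(default_factory=tuple)

    def __post_init__(self):
        missing = [c for c in CANONICAL_COLUMNS if c not in self.records.columns]
        if missing:
            raise FormatError(f"missing canonical column(s): {missing}")
        r = self.records
        if len(r):
            for col in ("x_nm", "y_nm", "photons", "precision_nm"):
                vals = r[col].to_numpy(float)
                if not np.all(np.isfinite(vals)):
                    raise ValueError(f"non-finite values in column {col!r}")
            if (r["photons"].to_numpy(float) <= 0).any():
                raise ValueError("photons must be > 0")
            if (r["precision_nm"].to_numpy(float) <= 0).any():
                raise ValueError("precision_nm must be > 0")
            x = r["x_nm"].to_numpy(float)
            y = r["y_nm"].to_numpy(float)
            if x.min() < 0 or y.min() < 0 or x.max() > self.field_width or y.max() > self.field_height:
                raise ValueError("localizations outside the field of view")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def x(self) -> np.ndarray:
        return self.records["x_nm"].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return self.records["y_nm"].to_numpy(float)

    @property
    def frames(self) -> np.ndarray:
        return self.records["frame"].to_numpy(np.int64)

    @property
    def photons(self) -> np.ndarray:
        return self.records["photons"].to_numpy(float)

    @property
    def precision(self) -> np.ndarray:
        return self.records["precision_nm"].to_numpy(float)

    def with_records(self, records: pd.DataFrame, log_entry: str) -> "LocalizationTable":
        """Return a copy holding ``records`` with ``log_entry`` appended."""
        return replace(self, records=records.reset_index(drop=True),
                       metadata=self.metadata + (log_entry,))

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


@dataclass(frozen=True)
class BinaryImage:
    """Binary localization image on a square-pixel grid.

    ``pixels[i, j] == 1`` iff at least one localization fell into the pixel
    with row index i (y) and column index j (x); origin (0, 0) coincides
    with the table's coordinate origin.  ``loss_fraction`` is the fraction
    of localizations lost to same-pixel collisions.
    """

    pixels: np.ndarray
    pixel_size: float
    loss_fraction: float

    @property
    def n_on(self) -> int:
        return int(self.pixels.sum())


def read_localizations(path, dialect: dict | None = None,
                       position_scale: float = 1.0,
                       field_width: float | None = None,
                       field_height: float | None = None) -> LocalizationTable:
    """Read a localization CSV into a validated :class:`LocalizationTable`.

    Parameters
    ----------
    path
        CSV file with one header row.
    dialect
        Mapping canonical name -> source column name.  Defaults to the
        canonical schema; :data:`THUNDERSTORM_DIALECT` covers ThunderSTORM
        exports.
    position_scale
        Multiplier applied to x/y to convert them to nm (e.g. 1000 for
        positions stored in µm).
    field_width, field_height
        Field extent in nm; inferred from the data maxima when omitted.
    """
    dialect = dict(dialect or CANONICAL_DIALECT)
    raw = pd.read_csv(path)
    missing = [src for src in dialect.values() if src not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(raw.columns)}")
    df = pd.DataFrame({canon: raw[src] for canon, src in dialect.items()})
    for col in CANONICAL_COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(f"{path}: non-numeric value in column {col!r} at data row {row}")
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise FormatError(f"{path}: missing value in column {col!r} at data row {row}")
        df[col] = numeric
    df["x_nm"] = df["x_nm"] * position_scale
    df["y_nm"] = df["y_nm"] * position_scale
    df["frame"] = df["frame"].astype(np.int64)
    if field_width is None:
        field_width = float(df["x_nm"].max()) if len(df) else 0.0
    if field_height is None:
        field_height = float(df["y_nm"].max()) if len(df) else 0.0
    return LocalizationTable(df, field_width, field_height,
                             metadata=(f"read:{path}",))


def filter_min_photons(table: LocalizationTable, min_photons: float = 700.0) -> LocalizationTable:
    """Keep localizations with at least ``min_photons`` detected photons."""
    if min_photons <= 0:
        raise ValueError("min_photons must be > 0")
    keep = table.photons >= min_photons
    return table.with_records(table.records[keep],
                              f"filter_min_photons:{min_photons}")


def filter_precision_percentile(table: LocalizationTable, percentile: float = 98.0) -> LocalizationTable:
    """Discard localizations whose precision exceeds the table's own quantile.

    The threshold is the ``percentile``-th linear-interpolation quantile of
    the precisions in the *input* table, so the cut is self-referential:
    the worst (100 - percentile)% of localizations are removed.
    """
    if len(table) == 0:
        raise ValueError("precision percentile filter requires a non-empty table")
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    cutoff = np.percentile(table.precision, percentile)  # linear interpolation
    keep = table.precision <= cutoff
    return table.with_records(table.records[keep],
                              f"filter_precision_percentile:{percentile}")


def density_filter(table: LocalizationTable, radius: float = 70.0,
                   max_neighbors: int = 50) -> LocalizationTable:
    """Remove over-dense localizations (artificial-cluster filter).

    A localization is removed when strictly more than ``max_neighbors``
    *other* localizations lie within Euclidean distance ``radius``.
    Neighbor counts are computed on the input table and all removals are
    applied simultaneously (a single pass, not iterated to fixpoint).
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if max_neighbors < 1:
        raise ValueError("max_neighbors must be >= 1")
    if len(table) == 0:
        return table.with_records(table.records, f"density_filter:{radius},{max_neighbors}")
    pts = np.column_stack([table.x, table.y])
    tree = cKDTree(pts)
    # count within radius including self, then subtract self
    counts = tree.query_ball_point(pts, r=radius, return_length=True) - 1
    keep = counts <= max_neighbors
    return table.with_records(table.records[keep],
                              f"density_filter:{radius},{max_neighbors}")


def binarize(table: LocalizationTable, pixel_size: float = 1.6) -> BinaryImage:
    """Bin localizations onto a binary pixel grid.

    Each localization sets pixel ``(floor(y/p), floor(x/p))`` to 1.  Several
    localizations in one pixel collapse to a single on-pixel; the fraction
    lost this way is reported as ``loss_fraction``.  At the 1.6 nm default
    the loss on typical data is ~1% or less.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    w = max(int(np.ceil(table.field_width / pixel_size)), 1)
    h = max(int(np.ceil(table.field_height / pixel_size)), 1)
    pixels = np.zeros((h, w), dtype=np.uint8)
    n = len(table)
    if n:
        ix = np.minimum(np.floor(table.x / pixel_size).astype(np.int64), w - 1)
        iy = np.minimum(np.floor(table.y / pixel_size).astype(np.int64), h - 1)
        pixels[iy, ix] = 1
    n_on = int(pixels.sum())
    loss = 0.0 if n == 0 else (n - n_on) / n
    return BinaryImage(pixels=pixels, pixel_size=float(pixel_size), loss_fraction=loss)
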