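"""Localization table I/O, quality filters and binarization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import qsmlm
from qsmlm.locio import FormatError, THUNDERSTORM_DIALECT
from helpers import make_table

CANONICAL_CSV = "frame,x_nm,y_nm,photons,precision_nm\n1,10.5,20.0,900,11\n2,30.0,40.0,1200,9\n3,50.0,60.0,800,14\n"


class TestReadLocalizations:
    def test_canonical_csv(self, tmp_path):
        p = tmp_path / "locs.csv"
        p.write_text(CANONICAL_CSV)
        table = qsmlm.read_localizations(p)
        assert len(table) == 3
        assert list(table.frames) == [1, 2, 3]
        assert table.x[0] == 10.5

    def test_micron_positions_scaled_to_nm(self, tmp_path):
        p = tmp_path / "locs_um.csv"
        p.write_text("frame,x_nm,y_nm,photons,precision_nm\n1,0.5,1.0,900,11\n")
        table = qsmlm.read_localizations(p, position_scale=1000.0)
        assert table.x[0] == 500.0 and table.y[0] == 1000.0

    def test_thunderstorm_dialect(self, tmp_path):
        p = tmp_path / "ts.csv"
        p.write_text('frame,"x [nm]","y [nm]","intensity [photon]","uncertainty [nm]"\n'
                     "1,10,20,900,11\n")
        table = qsmlm.read_localizations(p, dialect=THUNDERSTORM_DIALECT)
        assert table.photons[0] == 900

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("frame,x_nm,y_nm,precision_nm\n1,10,20,11\n")
        with pytest.raises(FormatError, match="photons"):
            qsmlm.read_localizations(p)

    def test_non_numeric_cell_names_row(self, tmp_path):
        p = tmp_path / "bad2.csv"
        p.write_text("frame,x_nm,y_nm,photons,precision_nm\n1,10,20,900,11\n2,oops,20,900,11\n")
        with pytest.raises(FormatError, match="row 1"):
            qsmlm.read_localizations(p)


class TestFilters:
    def test_photon_threshold_is_inclusive(self):
        t = make_table([0, 1, 2], [1, 2, 3], [1, 2, 3], photons=[650, 700, 701])
        out = qsmlm.filter_min_photons(t, 700)
        assert sorted(out.photons) == [700, 701]

    def test_photon_filter_on_empty_and_identity(self):
        t = make_table([0, 1], [1, 2], [1, 2], photons=[800, 900])
        assert len(qsmlm.filter_min_photons(t, 700)) == 2
        empty = qsmlm.filter_min_photons(t, 1000)
        assert len(qsmlm.filter_min_photons(empty, 700)) == 0

    def test_precision_percentile_integer_sequence(self):
        # sigma = 1..100 at the 98th linear-interpolation percentile:
        # cutoff = 98.02, so exactly sigma in {99, 100} are removed
        t = make_table(np.arange(100), np.arange(100), np.arange(100),
                       precision=np.arange(1, 101))
        out = qsmlm.filter_precision_percentile(t, 98)
        assert len(out) == 98
        assert out.precision.max() == 98

    def test_precision_percentile_two_records(self):
        t = make_table([0, 1], [1, 2], [1, 2], precision=[10, 20])
        out = qsmlm.filter_precision_percentile(t, 50)
        assert list(out.precision) == [10]

    def test_precision_percentile_degenerate_all_equal(self):
        t = make_table([0, 1, 2], [1, 2, 3], [1, 2, 3], precision=[7, 7, 7])
        assert len(qsmlm.filter_precision_percentile(t, 98)) == 3

    def test_precision_percentile_empty_is_error(self):
        t = make_table([], [], [], field_width=1, field_height=1)
        with pytest.raises(ValueError):
            qsmlm.filter_precision_percentile(t)

    def test_density_filter_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 500, 300)
        y = rng.uniform(0, 500, 300)
        t = make_table(np.arange(300), x, y)
        out = qsmlm.density_filter(t, radius=70, max_neighbors=10)
        d2 = (x[:, None] - x) ** 2 + (y[:, None] - y) ** 2
        counts = (d2 <= 70 ** 2).sum(1) - 1
        expected = set(np.flatnonzero(counts <= 10))
        kept = {i for i in range(300)
                if any((out.x == x[i]) & (out.y == y[i]))}
        assert kept == expected

    def test_density_filter_removes_overdense_blob(self):
        rng = np.random.default_rng(1)
        # 60 localizations in a 10 nm disc: each has 59 > 50 neighbors
        t = make_table(np.arange(60), 100 + rng.uniform(0, 10, 60),
                       100 + rng.uniform(0, 10, 60), field_width=200, field_height=200)
        assert len(qsmlm.density_filter(t, 70, 50)) == 0
        # 30 in the same disc: 29 <= 50 neighbors, all retained
        t30 = make_table(np.arange(30), 100 + rng.uniform(0, 10, 30),
                         100 + rng.uniform(0, 10, 30), field_width=200, field_height=200)
        assert len(qsmlm.density_filter(t30, 70, 50)) == 30

    def test_isolated_localization_retained(self):
        t = make_table([0], [500.0], [500.0], field_width=1000, field_height=1000)
        assert len(qsmlm.density_filter(t)) == 1

    def test_metadata_appends_one_entry_per_filter(self):
        t = make_table([0, 1], [1, 2], [1, 2])
        n0 = len(t.metadata)
        t1 = qsmlm.filter_min_photons(t)
        t2 = qsmlm.filter_precision_percentile(t1)
        assert len(t1.metadata) == n0 + 1 and len(t2.metadata) == n0 + 2

    @given(photons=st.lists(st.floats(1, 5000), min_size=1, max_size=40),
           threshold=st.floats(1, 2000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_photon_filter_idempotent_and_order_free(self, photons, threshold):
        n = len(photons)
        t = make_table(np.arange(n), np.arange(n, dtype=float),
                       np.arange(n, dtype=float), photons=photons,
                       field_width=n + 1.0, field_height=n + 1.0)
        once = qsmlm.filter_min_photons(t, threshold)
        twice = qsmlm.filter_min_photons(once, threshold)
        assert once.records[["photons"]].equals(twice.records[["photons"]])
        # permuting rows then filtering keeps the same record multiset
        perm = np.random.default_rng(0).permutation(n)
        t_perm = t.with_records(t.records.iloc[perm], "perm")
        out_perm = qsmlm.filter_min_photons(t_perm, threshold)
        assert sorted(out_perm.photons) == sorted(once.photons)

    def test_density_filter_identity_limits(self):
        rng = np.random.default_rng(2)
        t = make_table(np.arange(50), rng.uniform(0, 1000, 50), rng.uniform(0, 1000, 50))
        assert len(qsmlm.density_filter(t, radius=70, max_neighbors=10 ** 9)) == 50
        assert len(qsmlm.density_filter(t, radius=1e-9, max_neighbors=1)) == 50


class TestBinarize:
    def test_floor_convention(self):
        t = make_table([0], [0.8], [3.3], field_width=10, field_height=10)
        img = qsmlm.binarize(t, pixel_size=1.6)
        assert img.pixels[2, 0] == 1 and img.n_on == 1

    def test_collision_accounting(self):
        t = make_table([0, 1], [0.5, 0.7], [0.5, 0.9], field_width=10, field_height=10)
        img = qsmlm.binarize(t, pixel_size=1.6)
        assert img.n_on == 1 and img.loss_fraction == 0.5

    def test_conservation_on_pixels_plus_collisions(self, bt474_roi):
        table, _ = bt474_roi
        img = qsmlm.binarize(table)
        collisions = len(table) - img.n_on
        assert img.n_on + collisions == len(table)
        assert img.loss_fraction == collisions / len(table)

    def test_simulated_roi_loss_below_two_percent(self, bt474_roi):
        table, _ = bt474_roi
        assert qsmlm.binarize(table).loss_fraction <= 0.02
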