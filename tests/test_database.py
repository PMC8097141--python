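"""Model database: grid sweep, banding and population selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from thetanet.cell import PYR_DEFAULTS
from thetanet.database import (
    FEATURES,
    EmptySelectionError,
    FeatureBands,
    GridSpec,
    ModelDatabase,
    PopulationSpec,
    build_database,
    default_grid,
    derive_bands,
    select_population,
)


class TestBuild:
    def test_singleton_grid_reproduces_base_phenotype(self):
        grid = GridSpec(a=(0.0012,), b=(3.0,), d=(10.0,), k_low=(0.1,))
        db = build_database(grid)
        assert len(db) == 1
        row = db.table.iloc[0]
        assert row.sfa == pytest.approx(0.46, abs=0.02)
        assert row.pir == -5.0
        assert not row.all_undefined

    def test_cartesian_product_cardinality_and_ids(self):
        grid = GridSpec(a=(0.001, 0.002), b=(2.0, 4.0),
                        d=(5.0, 15.0), k_low=(0.08, 0.12))
        db = build_database(grid)
        assert len(db) == 16
        assert list(db.table.model_id) == list(range(16))
        # row parameters enumerate the full product
        combos = {tuple(r) for r in
                  db.table[["a", "b", "d", "k_low"]].itertuples(index=False)}
        assert combos == set(itertools.product(
            (0.001, 0.002), (2.0, 4.0), (5.0, 15.0), (0.08, 0.12)))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(a=(), b=(3.0,), d=(10.0,), k_low=(0.1,))

    def test_default_grid_contains_default_point(self):
        grid = default_grid(10)
        assert grid.size == 10_000
        assert 0.0012 in grid.a and 3.0 in grid.b
        assert 10.0 in grid.d and 0.1 in grid.k_low

    def test_triplets_reproducible_from_parameters(self, small_db):
        from thetanet.features import quantify_features
        row = small_db.table.iloc[40]
        trip = quantify_features(small_db.params_for_row(row))
        assert trip.sfa == row.sfa
        assert trip.rheo == row.rheo
        assert trip.pir == row.pir


class TestHistograms:
    def test_histogram_matches_independent_binning(self, small_db, tmp_path):
        small_db.to_csv(tmp_path / "db.csv")
        exported = pd.read_csv(tmp_path / "db.csv")
        widths = {"sfa": 0.05, "rheo": 0.5, "pir": 0.5}
        for feature, width in widths.items():
            counts, edges = small_db.feature_histogram(feature)
            vals = exported[feature].dropna().to_numpy()
            # oracle: per-bin membership counting by explicit comparison
            oracle = [
                int(np.sum((vals >= lo) & ((vals < hi) if i < len(counts) - 1
                                           else (vals <= hi))))
                for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:]))
            ]
            assert counts.tolist() == oracle
            assert counts.sum() == len(vals)


class TestBands:
    def test_tertile_boundaries_match_sort_based_oracle(self, small_db,
                                                        small_bands):
        def quantile_oracle(sorted_vals, q):
            # order-statistics with linear interpolation
            h = (len(sorted_vals) - 1) * q
            lo, frac = int(np.floor(h)), h - np.floor(h)
            if lo + 1 >= len(sorted_vals):
                return sorted_vals[-1]
            return sorted_vals[lo] * (1 - frac) + sorted_vals[lo + 1] * frac

        for f in FEATURES:
            vals = np.sort(small_db.table[f].dropna().to_numpy())
            (l_lo, l_hi), (m_lo, m_hi), (h_lo, h_hi) = small_bands.lmh[f]
            assert l_lo == vals[0] and h_hi == vals[-1]
            assert l_hi == pytest.approx(quantile_oracle(vals, 1 / 3))
            assert m_hi == pytest.approx(quantile_oracle(vals, 2 / 3))
            assert l_hi == m_lo and m_hi == h_lo  # contiguous, ordered

    def test_narrow_contained_in_broad(self, small_bands):
        for f in FEATURES:
            n_lo, n_hi = small_bands.narrow[f]
            b_lo, b_hi = small_bands.broad[f]
            assert b_lo < n_lo < n_hi < b_hi

    def test_singleton_database_degenerates_to_point_intervals(self):
        grid = GridSpec(a=(0.0012,), b=(3.0,), d=(10.0,), k_low=(0.1,))
        db = build_database(grid)
        row = db.table.iloc[0]
        bands = derive_bands(db)
        for f, val in (("sfa", row.sfa), ("rheo", row.rheo),
                       ("pir", row.pir)):
            for lo, hi in bands.lmh[f]:
                assert lo == hi == val
        spec = PopulationSpec(bands={"sfa": "M", "rheo": "M", "pir": "M"},
                              size=5, seed=0)
        sel = select_population(db, bands, spec)
        assert sel.n_distinct == 1 and len(sel.cells) == 5

    def test_all_undefined_feature_raises_naming_it(self):
        table = pd.DataFrame({
            "model_id": [0], "a": [0.0012], "b": [3.0], "d": [10.0],
            "k_low": [0.1], "sfa": [np.nan], "rheo": [4.0], "pir": [-5.0],
            "all_undefined": [False]})
        with pytest.raises(ValueError, match="sfa"):
            derive_bands(ModelDatabase(table))


class TestSelection:
    def test_every_drawn_cell_satisfies_its_bands(self, small_db,
                                                  small_bands):
        from thetanet.features import quantify_features
        spec = PopulationSpec(bands={"sfa": "M", "rheo": "M", "pir": "M"},
                              size=40, seed=7)
        sel = select_population(small_db, small_bands, spec)
        assert len(sel.cells) == 40
        table = small_db.table.set_index("model_id")
        for mid in np.unique(sel.model_ids):
            row = table.loc[mid]
            for f in FEATURES:
                lo, hi = small_bands.interval(f, "M")
                assert lo <= row[f] <= hi

    def test_distinct_counts_match_bruteforce_filter(self, small_db,
                                                     small_bands, tmp_path):
        small_db.to_csv(tmp_path / "db.csv")
        exported = pd.read_csv(tmp_path / "db.csv")
        for bands_str in ("MMM", "LLL", "HHH"):
            spec = PopulationSpec(bands=dict(zip(FEATURES, bands_str)),
                                  size=200, seed=1)
            try:
                sel = select_population(small_db, small_bands, spec)
            except EmptySelectionError:
                sel = None
            # oracle: row-by-row interval filter over the exported CSV
            keep = []
            for _, row in exported.iterrows():
                ok = all(np.isfinite(row[f])
                         and small_bands.interval(f, bands_str[i])[0]
                         <= row[f]
                         <= small_bands.interval(f, bands_str[i])[1]
                         for i, f in enumerate(FEATURES))
                if ok:
                    keep.append(row.model_id)
            if sel is None:
                assert keep == []
            else:
                assert sorted(sel.qualifying_ids) == sorted(keep)
                assert set(sel.model_ids) <= set(keep)

    def test_selection_reproducible_under_seed(self, small_db, small_bands):
        spec = PopulationSpec(bands={"sfa": "M", "rheo": "M", "pir": "M"},
                              size=30, seed=11)
        s1 = select_population(small_db, small_bands, spec)
        s2 = select_population(small_db, small_bands, spec)
        assert np.array_equal(s1.model_ids, s2.model_ids)
        assert s1.cells == s2.cells

    def test_empty_band_selection_raises(self, small_db, small_bands):
        empty = FeatureBands(
            lmh=small_bands.lmh,
            narrow={f: (1e9, 1e9 + 1) for f in FEATURES},
            broad=small_bands.broad)
        spec = PopulationSpec(bands={"sfa": "N", "rheo": "N", "pir": "N"},
                              size=10, seed=0)
        with pytest.raises(EmptySelectionError):
            select_population(small_db, empty, spec)
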