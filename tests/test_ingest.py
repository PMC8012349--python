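"""I/O round-trips, per-period autoscaling, and period merging."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flavoromics import ingest
from flavoromics.containers import ChemicalMatrix, PanelRatings
from flavoromics.simulate import generate_genotypes


def tiny_ratings_frame():
    return pd.DataFrame(
        {
            "panelist_id": ["p1", "p1", "p2"],
            "session_id": ["s1"] * 3,
            "sample_id": ["A", "B", "A"],
            "attribute": ["liking", "liking", "sweetness"],
            "score": [10.0, -20.0, 55.0],
        }
    )


class TestSensoryIO:
    def test_round_trip_three_rows(self, tmp_path):
        path = tmp_path / "r.csv"
        tiny_ratings_frame().to_csv(path, index=False)
        ratings = ingest.read_sensory(path)
        assert len(ratings.records) == 3
        out = tmp_path / "w.tsv"
        ingest.write_sensory(ratings, out, dialect="tsv")
        again = ingest.read_sensory(out, dialect="tsv")
        pd.testing.assert_frame_equal(ratings.records, again.records)

    def test_out_of_range_intensity_score_cites_row(self, tmp_path):
        df = tiny_ratings_frame()
        df.loc[2, "score"] = 101.0  # sweetness is a [0, 100] scale
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ingest.ParseError, match="row 4"):
            ingest.read_sensory(path)

    def test_non_numeric_score_rejected(self, tmp_path):
        df = tiny_ratings_frame()
        df.loc[1, "score"] = "high"
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ingest.ParseError, match="non-numeric"):
            ingest.read_sensory(path)

    def test_missing_column_rejected(self, tmp_path):
        df = tiny_ratings_frame().drop(columns=["attribute"])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ingest.ParseError, match="attribute"):
            ingest.read_sensory(path)


class TestChemicalIO:
    def test_write_then_read_preserves_values(self, tmp_path, small_chem):
        p, m = tmp_path / "chem.csv", tmp_path / "meta.csv"
        ingest.write_chemicals(small_chem, p, m)
        back = ingest.read_chemicals(p, m)
        assert back.compounds == small_chem.compounds
        np.testing.assert_allclose(
            back.abundance.to_numpy(), small_chem.abundance.to_numpy(),
            rtol=1e-12, atol=1e-12, equal_nan=True,
        )
        pd.testing.assert_series_equal(
            back.period, small_chem.period, check_names=False
        )

    def test_genotype_round_trip(self, tmp_path, small_config, small_truth):
        geno, _ = generate_genotypes(small_config, small_truth)
        p, m = tmp_path / "g.csv", tmp_path / "map.csv"
        ingest.write_genotypes(geno, p, m)
        back = ingest.read_genotypes(p, m)
        pd.testing.assert_frame_equal(back.dosage, geno.dosage, check_names=False)


def _matrix(values: dict, periods: list) -> ChemicalMatrix:
    ab = pd.DataFrame(values, index=[f"s{i}" for i in range(len(periods))])
    return ChemicalMatrix(
        abundance=ab,
        period=pd.Series(periods, index=ab.index),
        compound_class=pd.Series("ester", index=ab.columns),
    )


class TestAutoscale:
    def test_single_period_column_scales_to_unit_z(self):
        m = _matrix({"c": [1.0, 2.0, 3.0]}, ["P1"] * 3)
        scaled = ingest.autoscale_by_period(m)
        np.testing.assert_allclose(scaled.values["c"], [-1.0, 0.0, 1.0])

    def test_constant_column_dropped_with_warning(self):
        m = _matrix({"c": [5.0, 5.0, 5.0], "d": [1.0, 2.0, 4.0]}, ["P1"] * 3)
        with pytest.warns(UserWarning, match="constant"):
            scaled = ingest.autoscale_by_period(m)
        assert scaled.values["c"].isna().all()
        assert ("c", "P1") in scaled.dropped

    def test_retained_columns_have_mean_zero_sd_one(self, small_scaled):
        for p in small_scaled.periods:
            block = small_scaled.values[small_scaled.period == p]
            mu = block.mean()
            sd = block.std(ddof=1)
            defined = block.notna().sum() >= 2
            assert np.allclose(mu[defined], 0.0, atol=1e-9)
            assert np.allclose(sd[defined], 1.0, atol=1e-9)

    def test_autoscaling_is_idempotent(self, small_scaled):
        again = ingest.autoscale_by_period(small_scaled)
        np.testing.assert_allclose(
            again.values.to_numpy(), small_scaled.values.to_numpy(),
            atol=1e-9, equal_nan=True,
        )

    def test_min_z_imputation_fills_sample_gaps(self):
        m = _matrix({"c": [1.0, np.nan, 3.0, 4.0]}, ["P1"] * 4)
        scaled = ingest.autoscale_by_period(m, impute="min_z")
        assert scaled.values["c"].notna().all()
        assert scaled.values.loc["s1", "c"] == scaled.values["c"].min()


class TestMergePeriods:
    def test_identical_compound_lists_keep_everything(self):
        m = _matrix(
            {"a": [1.0, 2, 3, 4], "b": [2.0, 1, 5, 3]}, ["P1", "P1", "P2", "P2"]
        )
        merged, report = ingest.merge_periods(ingest.autoscale_by_period(m))
        assert merged.compounds == ["a", "b"]
        assert report["n_compounds"].sum() == 2

    def test_three_period_masks_intersect_to_single_compound(self):
        ab = pd.DataFrame(
            {
                "A": [1.0, 2, 3, 4, 5, 6],
                "B": [1.0, 2, 3, 4, np.nan, np.nan],
                "C": [1.0, 2, np.nan, np.nan, 5, 6],
            },
            index=[f"s{i}" for i in range(6)],
        )
        m = ChemicalMatrix(
            abundance=ab,
            period=pd.Series(["P1", "P1", "P2", "P2", "P3", "P3"], index=ab.index),
            compound_class=pd.Series("ester", index=ab.columns),
        )
        merged, _ = ingest.merge_periods(ingest.autoscale_by_period(m), "common")
        assert merged.compounds == ["A"]
        union, _ = ingest.merge_periods(ingest.autoscale_by_period(m), "union")
        assert union.compounds == ["A", "B", "C"]

    def test_disjoint_compound_sets_raise_with_diagnostic(self):
        ab = pd.DataFrame(
            {"A": [1.0, 2, np.nan, np.nan], "B": [np.nan, np.nan, 1.0, 2]},
            index=["s0", "s1", "s2", "s3"],
        )
        m = ChemicalMatrix(
            abundance=ab,
            period=pd.Series(["P1", "P1", "P2", "P2"], index=ab.index),
            compound_class=pd.Series("ester", index=ab.columns),
        )
        with pytest.raises(ingest.EmptyIntersectionError):
            ingest.merge_periods(ingest.autoscale_by_period(m), "common")

    @settings(max_examples=25, deadline=None)
    @given(
        masks=st.lists(
            st.lists(st.booleans(), min_size=4, max_size=4),
            min_size=2, max_size=4,
        )
    )
    def test_common_mode_matches_set_intersection(self, masks):
        compounds = ["w", "x", "y", "z"]
        frames, periods = [], []
        for pi, mask in enumerate(masks):
            if not any(mask):
                mask[0] = True  # every period detects something
            block = pd.DataFrame(
                {
                    c: (
                        [pi + 0.1 * i, pi + 0.1 * i + 1.0]
                        if keep else [np.nan, np.nan]
                    )
                    for i, (c, keep) in enumerate(zip(compounds, mask))
                },
                index=[f"p{pi}s0", f"p{pi}s1"],
            )
            frames.append(block)
            periods += [f"P{pi}"] * 2
        ab = pd.concat(frames)
        m = ChemicalMatrix(
            abundance=ab,
            period=pd.Series(periods, index=ab.index),
            compound_class=pd.Series("ester", index=ab.columns),
        )
        scaled = ingest.autoscale_by_period(m)
        expected = set(compounds)
        for mask in masks:
            expected &= {c for c, keep in zip(compounds, mask) if keep}
        if not expected:
            with pytest.raises(ingest.EmptyIntersectionError):
                ingest.merge_periods(scaled, "common")
        else:
            merged, _ = ingest.merge_periods(scaled, "common")
            assert set(merged.compounds) == expected

    def test_default_study_has_59_common_volatiles(self, small_scaled):
        # the generator's always-detected set must survive the merge exactly
        merged, _ = ingest.merge_periods(small_scaled, "common")
        from flavoromics.pls import VOLATILE_CLASSES

        vols = merged.compounds_of_class(*VOLATILE_CLASSES)
        assert len(vols) == 24  # n_common_volatiles of the fixture
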