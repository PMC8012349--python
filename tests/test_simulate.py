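"""Generator behavior: determinism, planted structure, scale bounds."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from flavoromics.containers import (
    HEDONIC_ATTRIBUTES,
    INTENSITY_ATTRIBUTES,
)
from flavoromics.simulate import (
    InvalidConfigError,
    SimConfig,
    generate_chemical_matrix,
    generate_genotypes,
    generate_sensory_panel,
    make_truth,
    sample_truth_table,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_panelists_per_session": 0},
            {"n_samples": 0},
            {"sugar_effect": 0.7, "n_enhancers": 4, "enhancer_effect": 0.1},
            {"allele_freq": 0.0},
            {"allele_freq": 1.2},
            {"qtl_variance": 1.0},
            {"n_latent_pathways": 50, "n_volatiles": 20},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InvalidConfigError):
            make_truth(SimConfig(**kwargs))


class TestDeterminism:
    def test_identical_seed_gives_bitwise_identical_outputs(self, small_config):
        t1, t2 = make_truth(small_config), make_truth(small_config)
        assert t1.to_dict() == t2.to_dict()
        c1 = generate_chemical_matrix(small_config, t1)
        c2 = generate_chemical_matrix(small_config, t2)
        pd.testing.assert_frame_equal(c1.abundance, c2.abundance)
        r1 = generate_sensory_panel(small_config, t1)
        r2 = generate_sensory_panel(small_config, t2)
        pd.testing.assert_frame_equal(r1.records, r2.records)
        g1, p1 = generate_genotypes(small_config, t1)
        g2, p2 = generate_genotypes(small_config, t2)
        pd.testing.assert_frame_equal(g1.dosage, g2.dosage)
        pd.testing.assert_series_equal(p1, p2)

    def test_different_seed_changes_output(self, small_config, small_chem):
        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        chem = generate_chemical_matrix(other, make_truth(other))
        assert not chem.abundance.equals(small_chem.abundance)


class TestSensoryPanel:
    def test_noise_free_means_equal_true_means(self):
        cfg = SimConfig(
            n_samples=24, n_panelists_per_session=5, panelist_sd=0.0,
            rating_noise_sd=0.0, n_volatiles=15, n_common_volatiles=10,
            n_latent_pathways=3, n_enhancers=2, seed=3,
        )
        truth = make_truth(cfg)
        ratings = generate_sensory_panel(cfg, truth)
        table = sample_truth_table(cfg, truth)
        raw = ratings.raw_sample_means()
        for attr in raw.columns:
            expect = table[f"true_{attr}"].clip(
                *((-100, 100) if attr in HEDONIC_ATTRIBUTES else (0, 100))
            )
            np.testing.assert_allclose(
                raw[attr].sort_index(), expect.sort_index(), atol=1e-10
            )

    def test_scores_respect_scale_bounds(self):
        # huge offsets/noise force clipping; bounds must still hold
        cfg = SimConfig(
            n_samples=12, n_panelists_per_session=10, panelist_sd=80.0,
            rating_noise_sd=60.0, n_volatiles=10, n_common_volatiles=6,
            n_latent_pathways=2, n_enhancers=1, seed=5,
        )
        ratings = generate_sensory_panel(cfg, make_truth(cfg))
        rec = ratings.records
        hed = rec[rec["attribute"].isin(HEDONIC_ATTRIBUTES)]["score"]
        inten = rec[rec["attribute"].isin(INTENSITY_ATTRIBUTES)]["score"]
        assert hed.between(-100, 100).all()
        assert inten.between(0, 100).all()
        assert (inten >= 100).any() or (inten <= 0).any()  # clipping occurred

    def test_variance_components_recovered_by_method_of_moments(self):
        # balanced sessions: between/within panelist moments identify the
        # panelist and noise variances
        cfg = SimConfig(
            n_samples=40, samples_per_session=4, n_panelists_per_session=100,
            panelist_sd=10.0, rating_noise_sd=15.0, n_volatiles=12,
            n_common_volatiles=8, n_latent_pathways=3, n_enhancers=1, seed=7,
        )
        ratings = generate_sensory_panel(cfg, make_truth(cfg))
        rec = ratings.records
        sub = rec[rec["attribute"] == "sweetness"].copy()
        # deviations from per-sample means remove the sample effects
        sub["dev"] = sub["score"] - sub.groupby("sample_id")["score"].transform("mean")
        k = cfg.samples_per_session
        pan_mean = sub.groupby("panelist_id")["dev"].mean()
        between = pan_mean.var(ddof=1)          # sigma_p^2 + sigma_e^2 / k
        within = (
            sub.groupby("panelist_id")["dev"].var(ddof=1).mean()
        )                                        # sigma_e^2 (clipping aside)
        sigma_e2 = within
        sigma_p2 = between - sigma_e2 / k
        assert sigma_e2 == pytest.approx(15.0**2, rel=0.2)
        assert sigma_p2 == pytest.approx(10.0**2, rel=0.2)

    def test_planted_slopes_recovered_exactly_from_systematic_means(
        self, small_config, small_truth
    ):
        table = sample_truth_table(small_config, small_truth)
        systematic = (
            table["true_sweetness"]
            - table["resid_sweetness"]
            - small_truth.attribute_intercepts["sweetness"]
            - small_config.temperature_slope * (table["temperature"] - 20.0)
        )
        X = np.column_stack(
            [table["z_sugar"]]
            + [table[f"z_{v}"] for v in small_truth.enhancer_ids]
        )
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(X)), X]), systematic.to_numpy(),
            rcond=None,
        )
        expected = [small_truth.sugar_slope_sweetness] + [
            small_truth.sweetness_slopes[v] for v in small_truth.enhancer_ids
        ]
        np.testing.assert_allclose(coef[1:], expected, atol=1e-6)


class TestChemicalMatrix:
    def test_no_batch_effect_means_periods_agree(self):
        cfg = SimConfig(
            n_samples=900, batch_shift_sd=0.0, n_volatiles=10,
            n_common_volatiles=10, n_latent_pathways=3, n_enhancers=1,
            n_panelists_per_session=2, seed=9,
        )
        chem = generate_chemical_matrix(cfg, make_truth(cfg))
        logs = np.log(chem.abundance)
        vol = chem.compounds_of_class("ester", "aldehyde", "ketone", "other",
                                      "alcohol", "lactone", "terpene", "furan")
        per_period = logs[vol].groupby(chem.period).mean()
        spread = per_period.max() - per_period.min()
        assert (spread < 0.35).all()  # sampling error only at n=300/period

    def test_fold_range_at_least_70_at_defaults(self):
        chem = generate_chemical_matrix(SimConfig(seed=1), make_truth(SimConfig(seed=1)))
        assert chem.fold_ranges().max() >= 70.0

    def test_shared_latent_factor_correlation_matches_closed_form(self):
        # two compounds loading (1, 1) on one factor with residual sd s have
        # log-abundance correlation 1 / (1 + s_tot^2), s_tot^2 = s^2 + tech
        cfg = SimConfig(
            n_samples=4000, n_volatiles=4, n_common_volatiles=4,
            n_latent_pathways=1, n_enhancers=0, batch_shift_sd=0.0,
            n_panelists_per_session=2, seed=13,
        )
        truth = make_truth(cfg)
        a, b = truth.compound_ids[5], truth.compound_ids[6]
        for v in (a, b):
            truth.pathway_of[v] = 0
            truth.pathway_loading[v] = 1.0
            truth.noise_sd[v] = 0.5
        chem = generate_chemical_matrix(cfg, truth)
        r = np.log(chem.abundance[a]).corr(np.log(chem.abundance[b]))
        s_tot2 = 0.5**2 + 0.15**2 / cfg.replicates
        assert r == pytest.approx(1.0 / (1.0 + s_tot2), abs=0.03)

    def test_structural_absence_masks_whole_periods(self, small_chem, small_truth):
        pres = small_chem.period_detection()
        for v, periods in small_truth.period_presence.items():
            assert set(pres.index[pres[v]]) <= set(periods)


class TestGenotypes:
    def test_hardy_weinberg_frequencies_at_half(self):
        cfg = SimConfig(
            allele_freq=0.5, n_genotyped=20_000, n_markers=2,
            n_panelists_per_session=2, seed=17,
        )
        geno, _ = generate_genotypes(cfg, make_truth(cfg))
        freqs = geno.dosage["M001"].value_counts(normalize=True)
        assert freqs[0.0] == pytest.approx(0.25, abs=0.02)
        assert freqs[1.0] == pytest.approx(0.50, abs=0.02)
        assert freqs[2.0] == pytest.approx(0.25, abs=0.02)

    def test_null_qtl_has_no_association(self):
        cfg = SimConfig(
            qtl_variance=0.0, n_genotyped=5000, n_markers=2,
            n_panelists_per_session=2, seed=19,
        )
        geno, pheno = generate_genotypes(cfg, make_truth(cfg))
        r = geno.dosage["M001"].corr(np.log(pheno))
        assert r**2 < 0.01

    def test_planted_qtl_variance_recovered_on_log_scale(self):
        # analytic scaling: marker R^2 = 2p(1-p)a^2 / sigma_tot^2 = q
        r2s = []
        for seed in range(50):
            cfg = SimConfig(
                qtl_variance=0.15, n_genotyped=300, n_markers=2,
                n_panelists_per_session=2, seed=seed,
            )
            geno, pheno = generate_genotypes(cfg, make_truth(cfg))
            r = geno.dosage["M001"].corr(np.log(pheno))
            r2s.append(r**2)
        assert np.mean(r2s) == pytest.approx(0.15, abs=0.03)
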