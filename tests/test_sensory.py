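"""Mixed-model adjusted means, attribute correlations, temperature trends."""

import numpy as np
import pandas as pd
import pytest

from flavoromics import sensory
from flavoromics.containers import PanelRatings
from flavoromics.simulate import SimConfig, make_truth, sample_truth_table


def ratings_from_long(rows):
    df = pd.DataFrame(
        rows, columns=["panelist_id", "sample_id", "score"]
    )
    df["session_id"] = "s1"
    df["attribute"] = "sweetness"
    return PanelRatings(df)


def reml_criterion_dense(y, s_idx, p_idx, ns, npan, theta):
    """Independent dense REML evaluation: -0.5[log|V0| + log|X'V0^-1 X|
    + (n-p) log sigma2_hat + (n-p)], V0 = I + theta ZZ'."""
    n = len(y)
    X = np.zeros((n, ns))
    X[np.arange(n), s_idx] = 1.0
    Z = np.zeros((n, npan))
    Z[np.arange(n), p_idx] = 1.0
    V0 = np.eye(n) + theta * Z @ Z.T
    V0i = np.linalg.inv(V0)
    XtVX = X.T @ V0i @ X
    beta = np.linalg.solve(XtVX, X.T @ V0i @ y)
    r = y - X @ beta
    rss = r @ V0i @ r
    df = n - ns
    sigma2 = rss / df
    _, ld_v = np.linalg.slogdet(V0)
    _, ld_x = np.linalg.slogdet(XtVX)
    return -0.5 * (ld_v + ld_x + df * np.log(sigma2) + df)


class TestPanelistMixedModel:
    def test_single_panelist_gives_raw_means(self):
        ratings = ratings_from_long(
            [("p1", "A", 10.0), ("p1", "B", 30.0), ("p1", "C", 50.0)]
        )
        res = sensory.PanelistMixedModel(ratings, "sweetness").fit()
        np.testing.assert_allclose(res.adjusted_means, [10.0, 30.0, 50.0])

    def test_balanced_design_absorbs_panelist_offsets(self):
        # two panelists with offsets +5/-5, each rating all three samples:
        # adjusted means equal raw sample means, offsets cancel
        base = {"A": 20.0, "B": 40.0, "C": 60.0}
        rows = []
        for pid, off in (("p1", 5.0), ("p2", -5.0)):
            for s, mu in base.items():
                rows.append((pid, s, mu + off))
        res = sensory.PanelistMixedModel(ratings_from_long(rows), "sweetness").fit()
        np.testing.assert_allclose(
            res.adjusted_means, list(base.values()), atol=1e-8
        )

    def test_unbalanced_reml_matches_dense_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        panelists, samples = 4, 4
        rows = []
        offsets = rng.normal(0, 3, panelists)
        mus = rng.normal(40, 8, samples)
        for p in range(panelists):
            for s in range(samples):
                if (p + s) % 4 == 0:
                    continue  # punch holes: unbalanced design
                rows.append(
                    (f"p{p}", f"s{s}", mus[s] + offsets[p] + rng.normal(0, 2))
                )
        ratings = ratings_from_long(rows)
        model = sensory.PanelistMixedModel(ratings, "sweetness")
        res = model.fit()
        # brute-force grid over the variance ratio with the dense formula
        sub = ratings.records
        s_idx = sub["sample_id"].map(
            {s: i for i, s in enumerate(model.samples)}
        ).to_numpy()
        p_idx = sub["panelist_id"].map(
            {p: i for i, p in enumerate(model.panelists)}
        ).to_numpy()
        y = sub["score"].to_numpy()
        grid = np.geomspace(1e-4, 1e3, 4001)
        crits = [
            reml_criterion_dense(y, s_idx, p_idx, 4, 4, t) for t in grid
        ]
        theta_grid = grid[int(np.argmax(crits))]
        theta_fit = res.var_panelist / res.var_residual
        assert np.log(theta_fit + 1e-8) == pytest.approx(
            np.log(theta_grid + 1e-8), abs=1e-2
        )
        # and the criterion value itself agrees tightly at the optimum
        assert model._reml_criterion(theta_fit) == pytest.approx(
            reml_criterion_dense(y, s_idx, p_idx, 4, 4, theta_fit), abs=1e-4
        )

    def test_agrees_with_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(7)
        rows = []
        for p in range(6):
            off = rng.normal(0, 4)
            for s in range(5):
                if (p * 5 + s) % 7 == 0:
                    continue
                rows.append((f"p{p}", f"s{s}", 30 + 5 * s + off + rng.normal(0, 2)))
        ratings = ratings_from_long(rows)
        res = sensory.PanelistMixedModel(ratings, "sweetness").fit()
        df = ratings.records
        sm_res = smf.mixedlm(
            "score ~ 0 + C(sample_id)", df, groups=df["panelist_id"]
        ).fit(reml=True)
        np.testing.assert_allclose(
            res.adjusted_means.to_numpy(), sm_res.fe_params.to_numpy(), atol=1e-4
        )
        assert res.var_panelist == pytest.approx(
            float(sm_res.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-3
        )

    def test_constant_shift_of_one_panelist_only_moves_the_level(self):
        rng = np.random.default_rng(3)
        rows = [
            (f"p{p}", f"s{s}", 30 + 4 * s + rng.normal(0, 2))
            for p in range(4) for s in range(4)
        ]
        shifted = [
            (pid, s, score + (25.0 if pid == "p2" else 0.0))
            for pid, s, score in rows
        ]
        r1 = sensory.PanelistMixedModel(ratings_from_long(rows), "sweetness").fit()
        r2 = sensory.PanelistMixedModel(ratings_from_long(shifted), "sweetness").fit()
        d1 = r1.adjusted_means - r1.adjusted_means.mean()
        d2 = r2.adjusted_means - r2.adjusted_means.mean()
        np.testing.assert_allclose(d1, d2, atol=1e-6)

    def test_fully_confounded_design_raises(self):
        ratings = ratings_from_long(
            [("p1", "A", 10.0), ("p2", "B", 30.0), ("p3", "C", 50.0)]
        )
        with pytest.raises(sensory.EstimabilityError):
            sensory.PanelistMixedModel(ratings, "sweetness")

    def test_single_rater_samples_flagged(self):
        ratings = ratings_from_long(
            [("p1", "A", 10.0), ("p1", "B", 30.0), ("p2", "A", 20.0)]
        )
        with pytest.warns(UserWarning, match="rated once"):
            means = sensory.fit_panelist_adjusted_means(ratings)
        assert means.single_rater_flags["sweetness"] == ["B"]


class TestAttributeCorrelations:
    def _means(self, data):
        df = pd.DataFrame(data)
        df.index = [f"s{i}" for i in range(len(df))]
        return sensory.SampleSensoryMeans(
            means=df, se=df * 0, n_raters=df * 0 + 10
        )

    def test_spearman_hand_example(self):
        m = self._means({
            "liking": [1, 2, 3, 4, 5],
            "sweetness": [2, 1, 4, 3, 5],
        })
        ac = sensory.attribute_correlations(m)
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d^2 = (1,1,1,1,0) -> 1 - 24/120 = 0.8
        assert ac.rho.loc["liking", "sweetness"] == pytest.approx(0.8)
        assert ac.rho.loc["liking", "liking"] == 1.0

    def test_partial_formula_reduces_when_controls_uncorrelated(self):
        assert sensory.partial_correlation_from_r(0.5, 0.0, 0.0) == pytest.approx(0.5)

    def test_partial_of_liking_with_itself_is_one(self):
        m = self._means({
            "liking": [1, 2, 3, 4, 6],
            "sweetness": [2, 1, 4, 3, 5],
            "sourness": [5, 3, 4, 1, 2],
        })
        ac = sensory.attribute_correlations(m)
        assert ac.partial_vs_liking["liking"] == 1.0

    def test_constant_attribute_reported_missing_not_zero(self):
        m = self._means({
            "liking": [1, 2, 3, 4, 5],
            "sweetness": [7, 7, 7, 7, 7],
        })
        ac = sensory.attribute_correlations(m, control="liking")
        assert np.isnan(ac.rho.loc["liking", "sweetness"])


class TestTemperatureTrend:
    def test_flat_response_has_zero_slope(self):
        df = pd.DataFrame({"y": [5.0] * 4, "temperature": [17, 18, 19, 20]})
        tr = sensory.temperature_trend(df, "y", genotype="none")
        assert tr.pooled_slope == pytest.approx(0.0, abs=1e-12)

    def test_hand_ols_example(self):
        df = pd.DataFrame({"y": [30.0, 20.0, 10.0], "temperature": [17, 18, 19]})
        tr = sensory.temperature_trend(df, "y", genotype="none")
        assert tr.pooled_slope == pytest.approx(-10.0)

    def test_single_covariate_value_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "temperature": [18, 18]})
        with pytest.raises(ValueError, match="single"):
            sensory.temperature_trend(df, "y", genotype="none")

    def test_planted_negative_trend_detected_in_most_replicates(self):
        negatives = 0
        for seed in range(100):
            cfg = SimConfig(
                n_samples=60, n_volatiles=10, n_common_volatiles=6,
                n_latent_pathways=2, n_enhancers=1, temperature_slope=-2.0,
                n_panelists_per_session=2, seed=seed,
            )
            table = sample_truth_table(cfg, make_truth(cfg))
            df = table.rename(columns={"true_sweetness": "y"})
            tr = sensory.temperature_trend(df, "y", genotype="none")
            negatives += tr.pooled_slope < 0
        assert negatives >= 95
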