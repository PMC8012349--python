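"""Panelist-adjusted sensory means, attribute correlations, temperature trends.

Consumer panels rate each sample on bounded hedonic/intensity scales, and
panelists differ systematically in scale use.  Sample means are therefore
adjusted with a mixed linear model — sample as a fixed effect, panelist as a
random intercept, fitted by REML — whose fixed-effect estimates are the
least-squares means.  Attribute structure is summarized by Spearman rank
correlations and by rank-based partial correlations controlling sweetness
(to separate hedonic drivers from the dominant sweetness signal).  Seasonal
trends are plain per-genotype linear regressions of a response on the 5-day
mean soil temperature before harvest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from flavoromics.containers import PanelRatings


class EstimabilityError(ValueError):
    """Raised when sample means are confounded with panelist effects."""


@dataclass
class SampleSensoryMeans:
    """Adjusted per-sample sensory means (sample x attribute) with SEs."""

    means: pd.DataFrame
    se: pd.DataFrame
    n_raters: pd.DataFrame
    var_panelist: dict = field(default_factory=dict)   # attribute -> sigma^2_p
    var_residual: dict = field(default_factory=dict)
    single_rater_flags: dict = field(default_factory=dict)

    @property
    def samples(self) -> list:
        return list(self.means.index)

    @property
    def attributes(self) -> list:
        return list(self.means.columns)

    def to_frame(self) -> pd.DataFrame:
        return self.means.copy()


class PanelistMixedModel:
    """Random-intercept model ``score = sample + panelist + error`` for one
    attribute, profiled-REML over the single panelist variance component.

    The REML criterion is profiled analytically over the fixed effects and
    the residual variance, leaving a one-dimensional optimization over the
    variance ratio theta = sigma^2_panelist / sigma^2_error, solved by golden
    section to 1e-8.  With theta known, the GLS normal equations are solved
    by absorbing the panelist blocks (each panelist contributes a rank-one
    correction), so the fit is exact and fast even with hundreds of samples.
    """

    def __init__(self, ratings: PanelRatings, attribute: str):
        rec = ratings.records
        sub = rec[rec["attribute"] == attribute]
        if sub.empty:
            raise ValueError(f"no records for attribute {attribute!r}")
        self.attribute = attribute
        self.samples = sorted(sub["sample_id"].unique())
        self.panelists = sorted(sub["panelist_id"].unique())
        self._s_idx = sub["sample_id"].map(
            {s: i for i, s in enumerate(self.samples)}
        ).to_numpy()
        self._p_idx = sub["panelist_id"].map(
            {p: i for i, p in enumerate(self.panelists)}
        ).to_numpy()
        self._y = sub["score"].to_numpy(dtype=float)
        self._check_estimable()

    def _check_estimable(self) -> None:
        # If every panelist rates a single sample, panelist offsets are
        # confounded with sample means and nothing is estimable.
        df = pd.DataFrame({"p": self._p_idx, "s": self._s_idx})
        per_panelist = df.groupby("p")["s"].nunique()
        if len(self.samples) > 1 and (per_panelist <= 1).all():
            raise EstimabilityError(
                "every panelist rated a single sample; sample means are "
                "confounded with panelist effects"
            )

    # -- REML machinery ----------------------------------------------------
    def _sufficient_stats(self):
        """Per-connected-component sufficient statistics.

        Panelists rate only the samples of their session, so the mixed-model
        equations are block-diagonal over connected components of the
        sample-panelist bipartite graph; solving per block makes each REML
        evaluation cheap even with thousands of panelists.
        """
        if hasattr(self, "_cache"):
            return self._cache
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        ns, np_ = len(self.samples), len(self.panelists)
        si, pi, y = self._s_idx, self._p_idx, self._y
        adj = coo_matrix(
            (np.ones(len(y)), (si, pi + ns)), shape=(ns + np_, ns + np_)
        )
        n_comp, labels = connected_components(adj + adj.T, directed=False)
        comps = []
        for k in range(n_comp):
            s_loc = np.flatnonzero(labels[:ns] == k)
            p_loc = np.flatnonzero(labels[ns:] == k)
            if len(s_loc) == 0:
                continue
            s_map = {g: i for i, g in enumerate(s_loc)}
            p_map = {g: i for i, g in enumerate(p_loc)}
            rows = np.isin(si, s_loc)
            sl = np.array([s_map[v] for v in si[rows]])
            pl = np.array([p_map[v] for v in pi[rows]])
            yl = y[rows]
            M = np.zeros((len(s_loc), len(p_loc)))
            np.add.at(M, (sl, pl), 1.0)
            comps.append({
                "s_glob": s_loc, "p_glob": p_loc,
                "XtX": np.bincount(sl, minlength=len(s_loc)).astype(float),
                "Xty": np.bincount(sl, weights=yl, minlength=len(s_loc)),
                "ZtZ": np.bincount(pl, minlength=len(p_loc)).astype(float),
                "Zty": np.bincount(pl, weights=yl, minlength=len(p_loc)),
                "M": M,
            })
        self._cache = comps
        return comps

    def _gls_solve(self, theta: float, want_cov: bool = False):
        """Mixed-model equations at variance ratio ``theta``, with the
        (diagonal) panelist block absorbed so each component reduces to a
        small Schur-complement solve on its sample effects.

        Returns (beta, u, cov_unscaled, rss, logdet_terms) where
        ``logdet_terms = log|V0| + log|X'V0^-1 X|`` for V0 = I + theta ZZ'.
        """
        comps = self._sufficient_stats()
        ns, np_ = len(self.samples), len(self.panelists)
        beta = np.zeros(ns)
        u = np.zeros(np_)
        logdet = 0.0
        cov = np.zeros((ns, ns)) if want_cov else None
        for c in comps:
            if theta <= 0:
                b = c["Xty"] / c["XtX"]
                beta[c["s_glob"]] = b
                logdet += float(np.log(c["XtX"]).sum())
                if want_cov:
                    cov[np.ix_(c["s_glob"], c["s_glob"])] = np.diag(1.0 / c["XtX"])
                continue
            D = c["ZtZ"] + 1.0 / theta
            S = np.diag(c["XtX"]) - (c["M"] / D) @ c["M"].T
            rhs = c["Xty"] - c["M"] @ (c["Zty"] / D)
            b = np.linalg.solve(S, rhs)
            beta[c["s_glob"]] = b
            u[c["p_glob"]] = (c["Zty"] - c["M"].T @ b) / D
            _, logdetS = np.linalg.slogdet(S)
            logdet += float(np.log(D).sum() + logdetS)
            if want_cov:
                cov[np.ix_(c["s_glob"], c["s_glob"])] = np.linalg.inv(S)
        if theta > 0:
            logdet += np_ * np.log(theta)
        resid = self._y - beta[self._s_idx] - u[self._p_idx]
        rss = float(resid @ resid)
        if theta > 0:
            rss += float(u @ u) / theta
        return beta, u, cov, rss, float(logdet)

    def _reml_criterion(self, theta: float) -> float:
        *_, rss, logdet = self._gls_solve(theta)
        df = len(self._y) - len(self.samples)
        sigma2 = rss / df
        return -0.5 * (logdet + df * np.log(sigma2) + df)

    def fit(self, theta_max: float = 1e4, tol: float = 1e-8) -> "PanelistMixedResults":
        """Profile REML over theta by bracketing grid + golden section."""
        if len(self.panelists) == 1:
            beta, u, cov_un, rss, _ = self._gls_solve(0.0, want_cov=True)
            sigma2 = rss / max(len(self._y) - len(self.samples), 1)
            return self._results(0.0, beta, cov_un, sigma2)
        grid = np.concatenate([[0.0], np.geomspace(1e-6, theta_max, 41)])
        crits = [self._reml_criterion(t) for t in grid]
        k = int(np.argmax(crits))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        if k == 0:
            theta = 0.0
        else:
            invphi = (np.sqrt(5.0) - 1) / 2
            a, b = lo, hi
            c, d = b - invphi * (b - a), a + invphi * (b - a)
            fc, fd = self._reml_criterion(c), self._reml_criterion(d)
            while b - a > tol * max(1.0, b):
                if fc > fd:
                    b, d, fd = d, c, fc
                    c = b - invphi * (b - a)
                    fc = self._reml_criterion(c)
                else:
                    a, c, fc = c, d, fd
                    d = a + invphi * (b - a)
                    fd = self._reml_criterion(d)
            theta = 0.5 * (a + b)
        beta, u, cov_un, rss, _ = self._gls_solve(theta, want_cov=True)
        df = len(self._y) - len(self.samples)
        sigma2 = rss / max(df, 1)
        return self._results(theta, beta, cov_un, sigma2)

    def _results(self, theta, beta, cov_un, sigma2) -> "PanelistMixedResults":
        se = np.sqrt(np.maximum(np.diag(cov_un), 0.0) * sigma2)
        counts = np.bincount(self._s_idx, minlength=len(self.samples))
        return PanelistMixedResults(
            attribute=self.attribute,
            adjusted_means=pd.Series(beta, index=self.samples, name=self.attribute),
            se=pd.Series(se, index=self.samples),
            n_raters=pd.Series(counts, index=self.samples),
            var_panelist=float(theta * sigma2),
            var_residual=float(sigma2),
        )


@dataclass
class PanelistMixedResults:
    """REML fit of the panelist random-intercept model for one attribute."""

    attribute: str
    adjusted_means: pd.Series
    se: pd.Series
    n_raters: pd.Series
    var_panelist: float
    var_residual: float

    def summary(self) -> str:
        lines = [
            f"Panelist mixed model: {self.attribute}",
            f"  samples: {len(self.adjusted_means)}   "
            f"ratings: {int(self.n_raters.sum())}",
            f"  sigma^2 panelist: {self.var_panelist:.4f}   "
            f"sigma^2 residual: {self.var_residual:.4f}",
            f"  grand mean (adjusted): {self.adjusted_means.mean():.3f}",
        ]
        return "\n".join(lines)


def fit_panelist_adjusted_means(
    ratings: PanelRatings, attributes: list | None = None
) -> SampleSensoryMeans:
    """REML-adjusted sample means for every attribute in the ratings.

    Samples rated by a single panelist are flagged; their means are still
    returned (the model's SE for them is correspondingly inflated).
    ``attributes`` restricts the fit to a subset.
    """
    means, ses, counts = {}, {}, {}
    var_p, var_e, flags = {}, {}, {}
    for attr in attributes or ratings.attributes:
        res = PanelistMixedModel(ratings, attr).fit()
        means[attr] = res.adjusted_means
        ses[attr] = res.se
        counts[attr] = res.n_raters
        var_p[attr] = res.var_panelist
        var_e[attr] = res.var_residual
        single = list(res.n_raters.index[res.n_raters == 1])
        flags[attr] = single
        if single:
            warnings.warn(
                f"attribute {attr!r}: samples rated once: {single[:5]}",
                stacklevel=2,
            )
    return SampleSensoryMeans(
        means=pd.DataFrame(means),
        se=pd.DataFrame(ses),
        n_raters=pd.DataFrame(counts),
        var_panelist=var_p,
        var_residual=var_e,
        single_rater_flags=flags,
    )


# -- correlations ----------------------------------------------------------

def partial_correlation_from_r(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation of x, y controlling z."""
    den = np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    if den == 0:
        return np.nan
    return (r_xy - r_xz * r_yz) / den


@dataclass
class AttributeCorrelations:
    """Spearman correlations among attributes, with sweetness-partialled
    correlations against liking."""

    rho: pd.DataFrame
    pvalues: pd.DataFrame
    partial_vs_liking: pd.Series      # controlling sweetness, rank-based
    n: int

    def summary(self) -> str:
        lines = ["Spearman correlations (sample means)", self.rho.round(3).to_string()]
        lines += [
            "",
            "Partial r with liking | sweetness:",
            self.partial_vs_liking.round(3).to_string(),
        ]
        return "\n".join(lines)


def attribute_correlations(
    means: SampleSensoryMeans, control: str = "sweetness"
) -> AttributeCorrelations:
    """All-pairs Spearman rho/p plus partial correlations controlling
    ``control`` (computed on ranks, so Spearman-consistent)."""
    df = means.means
    if len(df) < 4:
        raise ValueError("need >= 4 samples for attribute correlations")
    attrs = list(df.columns)
    const = [a for a in attrs if df[a].nunique() <= 1]
    rho = pd.DataFrame(np.eye(len(attrs)), index=attrs, columns=attrs)
    pv = pd.DataFrame(np.zeros((len(attrs), len(attrs))), index=attrs, columns=attrs)
    for i, a in enumerate(attrs):
        for j, b in enumerate(attrs):
            if j <= i:
                continue
            if a in const or b in const:
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(df[a], df[b])
            rho.loc[a, b] = rho.loc[b, a] = r
            pv.loc[a, b] = pv.loc[b, a] = p
    for a in const:
        rho.loc[a, a] = np.nan

    partial = {}
    if control in attrs:
        ranks = df.rank()
        for a in attrs:
            if a == control:
                continue
            if a == "liking":
                partial[a] = 1.0
                continue
            r_xy = ranks["liking"].corr(ranks[a]) if "liking" in attrs else np.nan
            r_xz = ranks["liking"].corr(ranks[control]) if "liking" in attrs else np.nan
            r_yz = ranks[a].corr(ranks[control])
            partial[a] = partial_correlation_from_r(r_xy, r_xz, r_yz)
    return AttributeCorrelations(
        rho=rho, pvalues=pv,
        partial_vs_liking=pd.Series(partial, name=f"partial | {control}"),
        n=len(df),
    )


# -- temperature trends ----------------------------------------------------

@dataclass
class TemperatureTrend:
    """Per-genotype and pooled OLS fits of a response on temperature."""

    response: str
    per_genotype: pd.DataFrame  # genotype, slope, intercept, n
    pooled_slope: float
    pooled_intercept: float

    def summary(self) -> str:
        lines = [
            f"Temperature trend for {self.response}",
            f"  pooled slope: {self.pooled_slope:.4f} per degree C "
            f"(intercept {self.pooled_intercept:.2f})",
            self.per_genotype.round(4).to_string(index=False),
        ]
        return "\n".join(lines)


def temperature_trend(
    data: pd.DataFrame,
    response: str,
    covariate: str = "temperature",
    genotype: str = "genotype",
) -> TemperatureTrend:
    """Linear regressions of ``response`` on a temperature covariate.

    ``data`` has one row per sample with response, covariate and genotype
    columns.  Each genotype needs >= 2 distinct covariate values; genotypes
    with a single value raise, since their slope is undefined.
    """
    sub = data[[response, covariate] + ([genotype] if genotype in data else [])].dropna()
    if sub[covariate].nunique() < 2:
        raise ValueError(f"covariate {covariate!r} has a single value; slope undefined")
    rows = []
    if genotype in sub:
        for g, grp in sub.groupby(genotype):
            if grp[covariate].nunique() < 2:
                raise ValueError(
                    f"genotype {g!r} has a single {covariate!r} value; slope undefined"
                )
            slope, intercept, *_ = stats.linregress(grp[covariate], grp[response])
            rows.append({"genotype": g, "slope": slope,
                         "intercept": intercept, "n": len(grp)})
    slope, intercept, *_ = stats.linregress(sub[covariate], sub[response])
    return TemperatureTrend(
        response=response,
        per_genotype=pd.DataFrame(rows),
        pooled_slope=float(slope),
        pooled_intercept=float(intercept),
    )
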