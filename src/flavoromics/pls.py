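"""NIPALS partial least squares, VIP scores, cross-period consensus
selection and the sugar-independence test.

The selection procedure identifies volatiles that enhance a sensory response
(sweetness or liking) beyond what sugars explain:

1. one 3-component PLS model per technical period, regressing the
   standardized response on autoscaled compounds plus texture liking;
2. VIP (variable importance in projection) per predictor and period;
3. consensus rule: a volatile is important if VIP exceeds 1.0 in at least
   two of the periods where it was detected;
4. for each consensus volatile, a two-sided t-test on its slope in the
   two-regressor model ``response ~ volatile + total_sugars`` on the merged
   data, Bonferroni-corrected over the volatiles actually tested — volatiles
   surviving at adjusted p < 0.05 enhance the response independently of
   sugars.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from flavoromics.containers import ChemicalMatrix, ScaledMatrix
from flavoromics.sensory import SampleSensoryMeans
from flavoromics.simulate import SUGARS

VOLATILE_CLASSES = ("ester", "aldehyde", "ketone", "lactone", "alcohol",
                    "terpene", "furan", "other")


class ComponentLimitError(ValueError):
    """Requested more PLS components than the predictor rank supports."""


class NotFittedError(RuntimeError):
    pass


class PLSNipals:
    """Univariate-response PLS via NIPALS with X and y deflation.

    Predictors are centered (they normally arrive autoscaled); the response
    is centered and, by default, scaled to unit variance.  Neither choice
    affects VIP (scale-free in y) or R^2.
    """

    def __init__(self, y, X, ncomp: int = 3, scale_y: bool = True):
        X = pd.DataFrame(X)
        y = pd.Series(np.asarray(y, dtype=float), index=X.index)
        if X.isna().any().any() or y.isna().any():
            raise ValueError("missing values must be imputed before PLS")
        sds = X.std(ddof=1)
        zero = list(X.columns[(sds == 0) | sds.isna()])
        if zero:
            raise ValueError(f"zero-variance predictors: {zero[:5]}")
        rank = np.linalg.matrix_rank(X.to_numpy() - X.to_numpy().mean(0))
        if ncomp > rank:
            raise ComponentLimitError(
                f"ncomp={ncomp} exceeds predictor rank {rank}"
            )
        self.ncomp = int(ncomp)
        self.scale_y = scale_y
        self.feature_names = list(X.columns)
        self._X = X
        self._y = y

    def fit(self) -> "PLSResults":
        Xc = self._X.to_numpy(dtype=float)
        y = self._y.to_numpy(dtype=float)
        x_mean = Xc.mean(axis=0)
        y_mean = y.mean()
        y_scale = y.std(ddof=1) if self.scale_y else 1.0
        if y_scale == 0:
            y_scale = 1.0
        E = Xc - x_mean
        f = (y - y_mean) / y_scale

        n, p = E.shape
        A = self.ncomp
        W = np.zeros((p, A))
        T = np.zeros((n, A))
        P = np.zeros((p, A))
        q = np.zeros(A)
        for a in range(A):
            w = E.T @ f
            nw = np.linalg.norm(w)
            if nw < 1e-14:
                raise ComponentLimitError(
                    f"residual covariance vanished at component {a + 1}"
                )
            w /= nw
            t = E @ w
            tt = t @ t
            pa = E.T @ t / tt
            qa = f @ t / tt
            E = E - np.outer(t, pa)
            f = f - qa * t
            W[:, a], T[:, a], P[:, a], q[a] = w, t, pa, qa

        ss = q**2 * (T**2).sum(axis=0)  # explained y-SS per component
        fitted_std = T @ q
        y_std = (y - y_mean) / y_scale
        ss_tot = float(y_std @ y_std)
        resid = y_std - fitted_std
        r2 = 1.0 - float(resid @ resid) / ss_tot
        return PLSResults(
            model=self,
            x_mean=x_mean, y_mean=y_mean, y_scale=y_scale,
            W=W, T=T, P=P, q=q, ss=ss, r2=r2,
            fittedvalues=pd.Series(
                fitted_std * y_scale + y_mean, index=self._X.index
            ),
        )


@dataclass
class PLSResults:
    """Fitted NIPALS decomposition: weights, scores, loadings, y-loadings."""

    model: PLSNipals
    x_mean: np.ndarray
    y_mean: float
    y_scale: float
    W: np.ndarray
    T: np.ndarray
    P: np.ndarray
    q: np.ndarray
    ss: np.ndarray
    r2: float
    fittedvalues: pd.Series

    @property
    def ncomp(self) -> int:
        return len(self.q)

    @property
    def feature_names(self) -> list:
        return self.model.feature_names

    def coef(self) -> pd.Series:
        """Regression coefficients on the original predictor scale."""
        B = self.W @ np.linalg.solve(self.P.T @ self.W, np.diag(np.ones(self.ncomp)))
        b = B @ self.q * self.y_scale
        return pd.Series(b, index=self.feature_names)

    def predict(self, X_new) -> pd.Series:
        X_new = pd.DataFrame(X_new)[self.feature_names]
        E = X_new.to_numpy(dtype=float) - self.x_mean
        R = self.W @ np.linalg.inv(self.P.T @ self.W)
        yhat = (E @ R) @ self.q * self.y_scale + self.y_mean
        return pd.Series(yhat, index=X_new.index)

    def vip(self) -> pd.Series:
        """Wold's VIP: sqrt(p * sum_a SS_a (w_ja/||w_a||)^2 / sum_a SS_a)."""
        p = self.W.shape[0]
        wnorm2 = (self.W**2).sum(axis=0)
        wnorm2[wnorm2 == 0] = 1.0
        frac = (self.W**2) / wnorm2
        v = np.sqrt(p * (frac * self.ss).sum(axis=1) / self.ss.sum())
        return pd.Series(v, index=self.feature_names, name="VIP")

    def summary(self) -> str:
        lines = [
            f"NIPALS PLS: {self.ncomp} components, "
            f"{len(self.feature_names)} predictors, n={len(self.T)}",
            f"  R^2 (training): {self.r2:.4f}",
            "  explained y-SS per component: "
            + ", ".join(f"{s:.4f}" for s in self.ss),
            "  top VIP: "
            + ", ".join(
                f"{k}={v:.2f}" for k, v in self.vip().nlargest(5).items()
            ),
        ]
        return "\n".join(lines)


def vip_scores(results: PLSResults) -> pd.Series:
    """VIP per predictor of a fitted PLS model."""
    if not isinstance(results, PLSResults):
        raise NotFittedError("vip_scores expects a fitted PLSResults")
    return results.vip()


def consensus_selection(
    vips: pd.DataFrame, threshold: float = 1.0, min_periods: int = 2
) -> pd.Series:
    """Boolean consensus flag per variable: VIP > threshold in >=
    ``min_periods`` periods.

    ``vips`` is variables x periods; NaN means the variable was not
    modeled in that period (e.g. compound not detected) and casts no vote.
    """
    if min_periods > vips.shape[1]:
        raise ValueError(
            f"min_periods={min_periods} exceeds the {vips.shape[1]} periods"
        )
    votes = (vips > threshold).sum(axis=1)
    return votes >= min_periods


def sugar_independence_test(
    volatile: pd.Series,
    response: pd.Series,
    total_sugars: pd.Series,
    family_size: int = 1,
) -> dict:
    """t-test on the volatile slope in ``response ~ volatile + total_sugars``.

    Returns beta, t, raw and Bonferroni-adjusted two-sided p, and flags.
    A volatile collinear with total sugars (|r| > 0.999) is reported
    non-identifiable with NaN statistics.
    """
    df = pd.concat(
        {"y": response, "v": volatile, "s": total_sugars}, axis=1
    ).dropna()
    n = len(df)
    if n < 4:
        raise ValueError(f"need >= 4 complete samples, got {n}")
    r_vs = df["v"].corr(df["s"])
    if abs(r_vs) > 0.999:
        return {
            "beta": np.nan, "t": np.nan, "p": np.nan, "p_adj": np.nan,
            "n": n, "identifiable": False,
        }
    X = np.column_stack([np.ones(n), df["v"], df["s"]])
    y = df["y"].to_numpy()
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - 3
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    t = beta[1] / np.sqrt(cov[1, 1])
    p = 2.0 * stats.t.sf(abs(t), dof)
    return {
        "beta": float(beta[1]), "t": float(t), "p": float(p),
        "p_adj": float(min(p * max(family_size, 1), 1.0)),
        "n": n, "identifiable": True,
    }


# -- the full per-period selection procedure --------------------------------

@dataclass
class SelectionReport:
    """Consensus-selected volatiles with per-period VIPs and independence
    tests for one sensory response."""

    response: str
    table: pd.DataFrame        # per volatile: class, VIP per period, flags
    period_r2: dict            # period -> training R^2
    threshold: float
    min_periods: int
    alpha: float

    @property
    def consensus_set(self) -> list:
        return list(self.table.index[self.table["consensus"]])

    @property
    def independent_set(self) -> list:
        return list(self.table.index[self.table["independent"].fillna(False)])

    def summary(self) -> str:
        lines = [
            f"Volatile selection for {self.response}",
            "  per-period PLS R^2: "
            + ", ".join(f"{p}={r:.4f}" for p, r in self.period_r2.items()),
            f"  consensus (VIP > {self.threshold} in >= {self.min_periods} "
            f"periods): {len(self.consensus_set)} volatiles",
            f"  sugar-independent (Bonferroni p < {self.alpha}): "
            f"{len(self.independent_set)} volatiles",
        ]
        return "\n".join(lines)


def fit_period_models(
    scaled: ScaledMatrix,
    means: SampleSensoryMeans,
    response: str,
    ncomp: int = 3,
    include_texture: bool = True,
) -> dict[str, PLSResults]:
    """One PLS per period: response means on that period's detected
    compounds (min-z imputed for sample-level gaps) plus texture liking."""
    out = {}
    for p in scaled.periods:
        rows = scaled.period == p
        block = scaled.values.loc[rows.values]
        present = block.columns[block.notna().any()]
        block = block[present]
        # sample-level gaps within a detected period: impute at the period
        # minimum z (the compound was measurable but near the floor)
        block = block.fillna(block.min())
        y = means.means.loc[block.index, response]
        X = block
        if include_texture and "texture_liking" in means.means.columns:
            tex = means.means.loc[block.index, "texture_liking"]
            tex = (tex - tex.mean()) / tex.std(ddof=1)
            X = block.assign(texture_liking=tex)
        out[p] = PLSNipals(y, X, ncomp=ncomp).fit()
    return out


def select_volatiles(
    scaled: ScaledMatrix,
    means: SampleSensoryMeans,
    chem: ChemicalMatrix,
    response: str = "sweetness",
    ncomp: int = 3,
    threshold: float = 1.0,
    min_periods: int = 2,
    alpha: float = 0.05,
    include_texture: bool = True,
) -> SelectionReport:
    """Full procedure: per-period PLS -> VIP consensus -> sugar-independence.

    Sugars/acids and texture liking take part in the PLS models but only
    volatiles enter the selection report; total sugars for the independence
    test is glucose + fructose + sucrose per sample from the raw matrix.
    """
    models = fit_period_models(scaled, means, response, ncomp, include_texture)
    vips = pd.DataFrame(
        {p: res.vip() for p, res in models.items()}
    ).reindex(scaled.compounds)
    volatiles = [
        c for c in scaled.compounds
        if scaled.compound_class[c] in VOLATILE_CLASSES
    ]
    vol_vips = vips.loc[volatiles]
    consensus = consensus_selection(vol_vips, threshold, min_periods)

    tested = list(consensus.index[consensus])
    total_sugars = chem.abundance[list(SUGARS)].sum(axis=1)
    y = means.means[response]
    rows = []
    for v in consensus.index:
        rec = {"class": scaled.compound_class[v]}
        rec.update({f"vip_{p}": vol_vips.loc[v, p] for p in vips.columns})
        rec["n_pass"] = int((vol_vips.loc[v] > threshold).sum())
        rec["consensus"] = bool(consensus[v])
        if consensus[v]:
            z = scaled.values[v]
            res = sugar_independence_test(
                z, y.reindex(z.index), total_sugars.reindex(z.index),
                family_size=len(tested),
            )
            rec.update(
                beta=res["beta"], t=res["t"], p=res["p"], p_adj=res["p_adj"],
                identifiable=res["identifiable"],
                independent=(res["identifiable"] and res["p_adj"] < alpha),
            )
        else:
            rec.update(beta=np.nan, t=np.nan, p=np.nan, p_adj=np.nan,
                       identifiable=np.nan, independent=False)
        rows.append(pd.Series(rec, name=v))
    table = pd.DataFrame(rows)
    return SelectionReport(
        response=response,
        table=table,
        period_r2={p: res.r2 for p, res in models.items()},
        threshold=threshold,
        min_periods=min_periods,
        alpha=alpha,
    )
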