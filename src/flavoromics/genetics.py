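"""Box-Cox phenotype normalization, single-marker association, and PCA.

Volatile abundances are strongly right-skewed, so phenotypes are normalized
with a Box-Cox power transform (lambda chosen by profile maximum likelihood
on [-2, 2]) before association.  The scan itself is the reported
single-marker analysis: OLS of the normalized phenotype on additive dosage
(0/1/2) per marker, with the marker's variance explained R^2 = model
SS / total SS and BH-FDR control across markers.  PCA of genotype dosages or
chemical values (variables with missing data omitted) summarizes population
and chemical structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from flavoromics.containers import GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class BoxCoxFit:
    """Fitted Box-Cox transform: y = (x^lam - 1)/lam, or log x at lam = 0."""

    lam: float
    transformed: pd.Series
    loglik: float

    def transform(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if abs(self.lam) < 1e-12:
            return np.log(x)
        return (x**self.lam - 1.0) / self.lam


def boxcox_transform(x: pd.Series, interval: tuple = (-2.0, 2.0)) -> BoxCoxFit:
    """Profile-ML Box-Cox fit over ``interval``; all values must be > 0."""
    x = pd.Series(x, dtype=float)
    bad = x.index[(x <= 0) | x.isna()]
    if len(bad):
        raise ValueError(f"non-positive phenotype for sample {bad[0]!r}")
    arr = x.to_numpy()

    def neg_llf(lam):
        return -stats.boxcox_llf(lam, arr)

    res = optimize.minimize_scalar(
        neg_llf, bounds=interval, method="bounded",
        options={"xatol": 1e-6},
    )
    lam = float(res.x)
    fit = BoxCoxFit(lam=lam, transformed=None, loglik=float(-res.fun))
    fit.transformed = pd.Series(fit.transform(arr), index=x.index)
    return fit


@dataclass
class AssociationResult:
    """Per-marker slope, variance explained and FDR-adjusted p-values."""

    table: pd.DataFrame     # marker-indexed: linkage_group, position, slope,
                            # r2, p, p_bh, n
    skipped: list           # monomorphic / under-called markers
    phenotype: str = ""

    def top(self, k: int = 5) -> pd.DataFrame:
        return self.table.nsmallest(k, "p")

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_bh"] < alpha]

    def summary(self) -> str:
        lines = [
            f"Single-marker scan for {self.phenotype or 'phenotype'}: "
            f"{len(self.table)} markers tested, {len(self.skipped)} skipped",
            f"  significant at FDR 0.05: {len(self.significant())}",
            "  top markers:",
            self.top().round(4).to_string(),
        ]
        return "\n".join(lines)


class SingleMarkerScan:
    """Additive single-marker association model for one phenotype.

    Per marker: casewise deletion of missing dosages, skip if fewer than two
    genotype classes remain, OLS of phenotype on dosage, F-test p, and BH
    adjustment across tested markers.  R^2 equals the squared Pearson
    correlation between dosage and phenotype.
    """

    def __init__(self, genotypes: GenotypeMatrix, phenotype: pd.Series):
        self.genotypes = genotypes
        common = genotypes.dosage.index.intersection(phenotype.index)
        if len(common) < 3:
            raise ValueError("need >= 3 samples shared by genotypes and phenotype")
        self.dosage = genotypes.dosage.loc[common]
        self.phenotype = pd.Series(phenotype).loc[common].astype(float)

    def fit(self) -> AssociationResult:
        y_all = self.phenotype.to_numpy()
        rows, skipped = [], []
        for m in self.dosage.columns:
            g = self.dosage[m].to_numpy(dtype=float)
            ok = np.isfinite(g) & np.isfinite(y_all)
            g_ok, y_ok = g[ok], y_all[ok]
            if len(np.unique(g_ok)) < 2:
                skipped.append(m)
                log.info("marker %s monomorphic after deletion; skipped", m)
                continue
            slope, intercept, r, p, _se = stats.linregress(g_ok, y_ok)
            rows.append(
                {"marker": m, "slope": slope, "r2": r**2, "p": p, "n": int(ok.sum())}
            )
        tab = pd.DataFrame(rows).set_index("marker")
        if len(tab):
            tab["p_bh"] = multipletests(tab["p"], method="fdr_bh")[1]
        else:
            tab["p_bh"] = []
        tab = tab.join(self.genotypes.marker_map)
        tab = tab.sort_values(["linkage_group", "position"])
        return AssociationResult(
            table=tab, skipped=skipped,
            phenotype=self.phenotype.name or "",
        )


def single_marker_scan(genotypes: GenotypeMatrix, phenotype: pd.Series) -> AssociationResult:
    """Convenience wrapper around :class:`SingleMarkerScan`."""
    return SingleMarkerScan(genotypes, phenotype).fit()


def genotype_class_report(
    dosage: pd.Series, phenotype: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-genotype-class phenotype means with Tukey-HSD grouping letters.

    Classes sharing a letter are not significantly different at ``alpha``.
    """
    df = pd.concat({"g": dosage, "y": phenotype}, axis=1).dropna()
    classes = sorted(df["g"].unique())
    means = df.groupby("g")["y"].agg(["mean", "std", "count"])
    letters = {c: set() for c in classes}
    if len(classes) >= 2:
        hsd = pairwise_tukeyhsd(df["y"], df["g"], alpha=alpha)
        rej = {}
        for (a, b), r in zip(
            [(i, j) for k, i in enumerate(classes) for j in classes[k + 1:]],
            hsd.reject,
        ):
            rej[(a, b)] = bool(r)
        # compact letter display: greedy insertion
        groups: list[set] = []
        for c in classes:
            placed = False
            for grp in groups:
                if all(not rej.get(tuple(sorted((c, o))), False) for o in grp):
                    grp.add(c)
                    placed = True
            if not placed:
                groups.append({c})
        for i, grp in enumerate(groups):
            for c in grp:
                letters[c].add(chr(ord("a") + i))
    else:
        letters[classes[0]].add("a")
    means["letters"] = ["".join(sorted(letters[c])) for c in means.index]
    return means


@dataclass
class PCAResult:
    scores: pd.DataFrame            # samples x PCs
    percent_variance: pd.Series     # per PC, sums to 100
    loadings: pd.DataFrame
    n_variables_used: int

    def summary(self) -> str:
        pv = self.percent_variance
        return (
            f"PCA on {self.n_variables_used} complete variables; "
            f"PC1+PC2 explain {pv.iloc[:2].sum():.1f}% "
            f"({pv.iloc[0]:.1f} + {pv.iloc[1]:.1f})"
        )


def pca(matrix: pd.DataFrame, autoscale: bool = False, n_components: int | None = None) -> PCAResult:
    """Centered PCA of samples x variables, omitting any variable with
    missing data (the omit-missing rule); ``autoscale=True`` standardizes
    variables first (used for chemical matrices)."""
    complete = matrix.loc[:, matrix.notna().all()]
    complete = complete.loc[:, complete.std(ddof=1) > 0]
    if complete.shape[1] < 2:
        raise ValueError("fewer than 2 complete variables for PCA")
    X = complete.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if autoscale:
        X = X / X.std(axis=0, ddof=1)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s**2 / (len(X) - 1)
    pct = 100.0 * var / var.sum()
    k = n_components or len(s)
    pcs = [f"PC{i + 1}" for i in range(len(s))][:k]
    return PCAResult(
        scores=pd.DataFrame(U[:, :k] * s[:k], index=matrix.index, columns=pcs),
        percent_variance=pd.Series(pct[:k], index=pcs),
        loadings=pd.DataFrame(Vt[:k].T, index=complete.columns, columns=pcs),
        n_variables_used=complete.shape[1],
    )
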