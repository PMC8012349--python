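"""Sensory-chemical correlation tables, the filtered network, and
multiscale-bootstrap hierarchical clustering.

All-pairs Pearson correlations between sensory means and autoscaled
compounds are tabulated with raw, Benjamini-Hochberg and Bonferroni p-values.
The network keeps only pairs surviving Bonferroni correction, weights edges
by |r|, and ranks nodes by authority centrality (principal eigenvector of
A'A, which for an undirected graph coincides with eigenvector centrality).
Cluster support is assessed pvclust-style: hierarchical clustering (legacy
Ward on a correlation dissimilarity) with bootstrap probabilities at several
resample sizes, combined into approximately-unbiased (AU) p-values through
the signed-distance/curvature fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

DEFAULT_SCALES = tuple(np.round(np.linspace(0.5, 1.4, 10), 2))


@dataclass
class CorrelationTable:
    """All-pairs correlation estimates with multiplicity-adjusted p-values."""

    table: pd.DataFrame  # var1, var2, r, n, p, p_bh, p_bonferroni
    variables: list
    excluded_pairs: list = field(default_factory=list)

    def matrix(self, column: str = "r") -> pd.DataFrame:
        """Symmetric matrix form of any table column (diagonal: r=1, p=0)."""
        m = pd.DataFrame(
            np.eye(len(self.variables)) if column == "r" else
            np.zeros((len(self.variables), len(self.variables))),
            index=self.variables, columns=self.variables,
        )
        for _, row in self.table.iterrows():
            m.loc[row["var1"], row["var2"]] = row[column]
            m.loc[row["var2"], row["var1"]] = row[column]
        return m

    def significant(self, alpha: float = 0.01, column: str = "p_bh") -> pd.DataFrame:
        return self.table[self.table[column] < alpha]

    def n_significant(self, alpha: float = 0.01, column: str = "p_bh") -> int:
        return int((self.table[column] < alpha).sum())


def pairwise_correlations(
    data: pd.DataFrame, min_n: int = 5
) -> CorrelationTable:
    """Pearson r and two-sided p for every variable pair, with BH and
    Bonferroni adjustment over all tested pairs.

    ``data`` is samples x variables (sensory means joined to autoscaled
    compounds).  Pairs are computed on pairwise-complete samples; pairs with
    fewer than ``min_n`` shared samples are excluded and logged.
    """
    cols = list(data.columns)
    X = data.to_numpy(dtype=float)
    rows, excluded = [], []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            ok = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
            n = int(ok.sum())
            if n < min_n:
                excluded.append((cols[i], cols[j], n))
                continue
            x, y = X[ok, i], X[ok, j]
            if x.std() == 0 or y.std() == 0:
                excluded.append((cols[i], cols[j], n))
                continue
            r, p = stats.pearsonr(x, y)
            rows.append((cols[i], cols[j], r, n, p))
    if excluded:
        log.info("excluded %d pairs with < %d shared samples", len(excluded), min_n)
    tab = pd.DataFrame(rows, columns=["var1", "var2", "r", "n", "p"])
    if len(tab):
        tab["p_bh"] = multipletests(tab["p"], method="fdr_bh")[1]
        tab["p_bonferroni"] = multipletests(tab["p"], method="bonferroni")[1]
    else:
        tab["p_bh"] = tab["p_bonferroni"] = []
    return CorrelationTable(table=tab, variables=cols, excluded_pairs=excluded)


@dataclass
class ChemNetwork:
    """Bonferroni-filtered correlation network with authority centralities."""

    graph: nx.Graph
    centrality: pd.Series
    alpha: float
    adjust: str

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def to_edgelist(self) -> pd.DataFrame:
        rows = [
            {"var1": u, "var2": v, **d} for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["var1", "var2", "weight", "r", "p_adj"])

    def write_graphml(self, path) -> None:
        g = self.graph.copy()
        nx.set_node_attributes(g, self.centrality.to_dict(), "authority")
        nx.write_graphml(g, path)


def authority_centrality(
    graph: nx.Graph, tol: float = 1e-10, max_iter: int = 10_000
) -> pd.Series:
    """Authority scores: principal eigenvector of A'A per connected
    component, power-iterated from an all-ones start, max-normalized to 1.

    Components are solved independently; each component's unit-norm vector
    is weighted by its principal singular value so denser/stronger
    components dominate, then the whole score vector is scaled to max 1.
    Ties in reporting order are broken by node id.
    """
    nodes = sorted(graph.nodes)
    scores = pd.Series(0.0, index=nodes)
    if not nodes:
        return scores
    for comp in nx.connected_components(graph):
        comp = sorted(comp)
        A = nx.to_numpy_array(graph, nodelist=comp, weight="weight")
        # A is symmetric, so A'A = A^2 shares eigenvectors with A and the
        # authority vector is A's Perron eigenvector; a positive spectral
        # shift removes the +/-lambda degeneracy (e.g. bipartite or path
        # graphs, where the all-ones start is itself an A^2 eigenvector).
        shift = 1.0 + np.abs(A).sum(axis=1).max()
        v = np.ones(len(comp))
        v /= np.linalg.norm(v)
        for _ in range(max_iter):
            w = A @ v + shift * v
            nrm = np.linalg.norm(w)
            if nrm == 0:
                break
            w /= nrm
            if np.linalg.norm(w - v) < tol:
                v = w
                break
            v = w
        v = np.abs(v)
        lam = float(v @ A @ v)  # Perron value of the component
        scores.loc[comp] = v * max(lam, 0.0)
    mx = scores.max()
    if mx > 0:
        scores /= mx
    return scores


def build_network(
    corr: CorrelationTable,
    alpha: float = 0.05,
    adjust: str = "p_bonferroni",
) -> ChemNetwork:
    """Graph of variable pairs significant after the chosen adjustment,
    edge-weighted by |r|, with authority centrality per node.

    An empty edge set yields an empty network, not an error.
    """
    if adjust not in ("p", "p_bh", "p_bonferroni"):
        raise ValueError(f"unknown adjustment column {adjust!r}")
    sig = corr.table[corr.table[adjust] < alpha]
    g = nx.Graph()
    for _, row in sig.iterrows():
        g.add_edge(
            row["var1"], row["var2"],
            weight=float(abs(row["r"])), r=float(row["r"]),
            p_adj=float(row[adjust]),
        )
    cent = authority_centrality(g)
    return ChemNetwork(graph=g, centrality=cent, alpha=alpha, adjust=adjust)


# -- multiscale bootstrap clustering ---------------------------------------

def correlation_distance(data: pd.DataFrame) -> np.ndarray:
    """Condensed 1 - Pearson-r dissimilarity between the columns of
    ``data`` (pairwise-complete)."""
    corr = data.corr(min_periods=2).to_numpy()
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    d = 1.0 - corr
    d[~np.isfinite(d)] = 2.0  # undefined pairs: maximally distant
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return squareform(d, checks=False)


def _ward_linkage(cond: np.ndarray, flavor: str = "ward.D") -> np.ndarray:
    """Legacy Ward (ward.D) on a precomputed dissimilarity.

    SciPy's 'ward' applies the Ward.D2 recurrence, which operates on squared
    input distances; feeding it sqrt(d) and squaring the merge heights
    reproduces the classical Ward.D behavior on d.
    """
    if flavor == "ward.D":
        Z = linkage(np.sqrt(np.maximum(cond, 0.0)), method="ward")
        Z = Z.copy()
        Z[:, 2] **= 2
        return Z
    if flavor == "ward.D2":
        return linkage(cond, method="ward")
    raise ValueError(f"unknown ward flavor {flavor!r}")


def _cluster_sets(Z: np.ndarray, n_leaves: int) -> list[frozenset]:
    """Leaf-index sets of every internal node, in merge order."""
    members = {i: frozenset([i]) for i in range(n_leaves)}
    out = []
    for k, (a, b, *_rest) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n_leaves + k] = merged
        out.append(merged)
    return out


@dataclass
class BootDendrogram:
    """Ward merge tree with AU/BP support per internal node."""

    linkage_matrix: np.ndarray
    labels: list
    clusters: list               # frozensets of leaf indices, merge order
    bp: np.ndarray               # bootstrap probability at scale 1
    au: np.ndarray               # approximately-unbiased p-value
    n_boot: int
    scale_factors: tuple
    bp_by_scale: pd.DataFrame | None = None  # scale x cluster counts/n_boot

    def support_for(self, leaf_labels) -> tuple[float, float] | None:
        """(AU, BP) for the cluster matching a set of labels, if present."""
        want = frozenset(self.labels.index(l) for l in leaf_labels)
        for k, cl in enumerate(self.clusters):
            if cl == want:
                return float(self.au[k]), float(self.bp[k])
        return None

    def to_newick(self) -> str:
        """Newick string with AU/BP as node comments."""
        n = len(self.labels)
        children = {}
        for k, (a, b, h, _c) in enumerate(self.linkage_matrix):
            children[n + k] = (int(a), int(b), float(h))

        def rec(node) -> str:
            if node < n:
                return str(self.labels[node]).replace(" ", "_")
            a, b, h = children[node]
            k = node - n
            return (
                f"({rec(a)},{rec(b)})"
                f"[&&NHX:au={self.au[k]:.3f}:bp={self.bp[k]:.3f}]"
            )

        return rec(n + len(self.linkage_matrix) - 1) + ";"


def bootstrap_cluster(
    data: pd.DataFrame,
    n_boot: int = 1000,
    scale_factors: tuple = DEFAULT_SCALES,
    distance: str = "correlation",
    ward_flavor: str = "ward.D",
    seed: int = 0,
) -> BootDendrogram:
    """Hierarchical clustering of the columns of ``data`` with multiscale
    bootstrap support values.

    BP for a cluster is its appearance frequency among dendrograms of
    bootstrap resamples at the original sample size; the AU p-value corrects
    BP for the curvature of the cluster boundary using the frequencies at
    several resample sizes r*n: ``z_r = Phi^-1(1 - BP_r)`` is regressed on
    ``(sqrt(r), 1/sqrt(r))`` by weighted least squares and
    ``AU = 1 - Phi(v - c)`` for fitted coefficients (v, c).

    The scale grid must include values below and above 1, otherwise the
    signed-distance/curvature decomposition is not identified.
    """
    scales = tuple(float(s) for s in scale_factors)
    if not (min(scales) < 1.0 and max(scales) > 1.0):
        raise ValueError("scale_factors must include values < 1 and > 1")
    if 1.0 not in scales:
        scales = tuple(sorted({*scales, 1.0}))
    if data.shape[1] < 3:
        raise ValueError("need >= 3 variables to cluster")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 per scale")
    if distance != "correlation":
        raise ValueError("only the correlation distance is supported")

    n_samples, n_vars = data.shape
    base_Z = _ward_linkage(correlation_distance(data), ward_flavor)
    base_clusters = _cluster_sets(base_Z, n_vars)
    index = {cl: k for k, cl in enumerate(base_clusters)}

    rng = np.random.default_rng(seed)
    counts = np.zeros((len(scales), len(base_clusters)), dtype=int)
    X = data.to_numpy(dtype=float)
    for si, r in enumerate(scales):
        m = max(3, int(round(n_samples * r)))
        for _ in range(n_boot):
            rows = rng.integers(n_samples, size=m)
            boot = pd.DataFrame(X[rows], columns=data.columns)
            Z = _ward_linkage(correlation_distance(boot), ward_flavor)
            for cl in _cluster_sets(Z, n_vars):
                k = index.get(cl)
                if k is not None:
                    counts[si, k] += 1

    bp_by_scale = counts / n_boot
    r_arr = np.asarray(scales)
    one = int(np.argmin(np.abs(r_arr - 1.0)))
    bp = bp_by_scale[one].copy()
    au = np.empty(len(base_clusters))
    eps = 0.5 / n_boot
    design = np.column_stack([np.sqrt(r_arr), 1.0 / np.sqrt(r_arr)])
    for k in range(len(base_clusters)):
        bpk = np.clip(bp_by_scale[:, k], eps, 1 - eps)
        informative = (bp_by_scale[:, k] > 0) & (bp_by_scale[:, k] < 1)
        if informative.sum() < 2:
            # degenerate support curve: fall back to the plain BP
            au[k] = bp[k]
            continue
        z = stats.norm.ppf(1.0 - bpk)
        w = n_boot * stats.norm.pdf(z) ** 2 / (bpk * (1 - bpk))
        W = np.sqrt(w[informative])
        Xd = design[informative] * W[:, None]
        yz = z[informative] * W
        coef, *_ = np.linalg.lstsq(Xd, yz, rcond=None)
        v, c = coef
        au[k] = 1.0 - stats.norm.cdf(v - c)
    # the root contains every leaf in every resample
    bp[-1] = 1.0
    au[-1] = 1.0
    return BootDendrogram(
        linkage_matrix=base_Z,
        labels=list(data.columns),
        clusters=base_clusters,
        bp=bp,
        au=np.clip(au, 0.0, 1.0),
        n_boot=n_boot,
        scale_factors=scales,
        bp_by_scale=pd.DataFrame(bp_by_scale, index=list(scales)),
    )
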