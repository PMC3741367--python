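"""'Two-color' co-expression network, Markov clustering, GO enrichment.

Nodes of the network are genes colored ``coding`` or ``lincRNA``; an edge
joins two genes whose log2(FPKM+1) profiles across tissues correlate with
|Pearson r| at or above a threshold.  Modules come from the Markov cluster
algorithm (MCL): alternating expansion (matrix squaring — flow spreads) and
inflation (entrywise power + column renormalization — strong flows win) on
the column-stochastic transition matrix of the graph, until the matrix
stops changing.  Clusters are read off the limit matrix's nonzero structure.

lincRNAs carry no functional annotation of their own; a module's coding
genes are tested for GO-term enrichment (hypergeometric upper tail,
Benjamini-Hochberg across terms within the module), and every lincRNA in an
enriched module inherits the module's enriched terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.base import BaseEstimator, ClusterMixin
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def collapse_to_genes(
    expr: pd.DataFrame, id_to_gene: dict[str, str]
) -> pd.DataFrame:
    """Collapse a transcript-level FPKM matrix to gene level (sum of
    isoform FPKM per gene)."""
    genes = [id_to_gene.get(i, i) for i in expr.index]
    return expr.groupby(genes).sum()


def build_graph(
    expr: pd.DataFrame,
    colors: dict[str, str],
    edge_threshold: float = 0.9,
) -> nx.Graph:
    """Co-expression graph over the rows of a (genes x tissues) FPKM matrix.

    Pearson r is computed on log2(FPKM+1); an undirected edge with weight
    |r| (and the sign recorded) joins every pair with |r| >= threshold.
    Constant-expression genes get no edges.  Node attribute ``color`` comes
    from ``colors`` (``coding`` / ``lincRNA``).
    """
    if expr.shape[1] < 3:
        raise ValueError("need >=3 tissues for meaningful correlations")
    X = np.log2(expr.to_numpy(dtype=float) + 1.0)
    genes = list(expr.index)
    sd = X.std(axis=1)
    ok = sd > 0
    G = nx.Graph()
    for g in genes:
        G.add_node(g, color=colors.get(g, "coding"))
    if ok.sum() >= 2:
        with np.errstate(invalid="ignore"):
            R = np.corrcoef(X[ok])
        idx = np.flatnonzero(ok)
        ii, jj = np.triu_indices(len(idx), k=1)
        keep = np.abs(R[ii, jj]) >= edge_threshold
        for a, b in zip(ii[keep], jj[keep]):
            r = float(R[a, b])
            G.add_edge(genes[idx[a]], genes[idx[b]], weight=abs(r), sign=np.sign(r))
    return G


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def _mcl_matrix(
    M: np.ndarray,
    inflation: float,
    expansion: int,
    prune: float,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """Iterate expansion/inflation on a column-stochastic matrix to its limit."""
    for _ in range(max_iter):
        new = np.linalg.matrix_power(M, expansion)
        new = np.power(new, inflation)
        new[new < prune] = 0.0
        colsum = new.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        new /= colsum
        if np.abs(new - M).max() < tol:
            return new
        M = new
    warnings.warn("MCL did not converge within max_iter; using last iterate")
    return M


def mcl(
    graph: nx.Graph,
    inflation: float = 1.8,
    expansion: int = 2,
    prune: float = 1e-5,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> list[set]:
    """Markov clustering of a weighted undirected graph.

    Self-loops of weight 1 are added, columns normalized to a stochastic
    transition matrix, and expansion/inflation iterated to convergence.
    Clusters are the connected components of the limit matrix's nonzero
    entries (attractor systems); a node attracted to several systems is
    assigned to the largest, ties to the lexicographically first.

    Returns clusters sorted by decreasing size then lexicographic member
    order; their union is the node set.
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValueError("graph is empty")
    A = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    np.fill_diagonal(A, 1.0)
    M = A / A.sum(axis=0, keepdims=True)
    limit = _mcl_matrix(M, inflation, expansion, prune, tol, max_iter)
    support = nx.from_numpy_array((limit > 0) | (limit.T > 0))
    comps = [
        {nodes[i] for i in comp}
        for comp in nx.connected_components(support)
    ]
    comps.sort(key=lambda c: (-len(c), sorted(c)))
    return comps


class MarkovClustering(BaseEstimator, ClusterMixin):
    """Scikit-learn estimator interface to MCL on a precomputed affinity.

    ``fit(X)`` expects a symmetric non-negative affinity (adjacency) matrix;
    ``labels_`` assigns each row its cluster index (clusters ordered by
    decreasing size).
    """

    def __init__(
        self,
        inflation: float = 1.8,
        expansion: int = 2,
        prune: float = 1e-5,
        tol: float = 1e-6,
        max_iter: int = 100,
    ):
        self.inflation = inflation
        self.expansion = expansion
        self.prune = prune
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != X.shape[1]:
            raise ValueError("X must be a square affinity matrix")
        if (X < 0).any():
            raise ValueError("affinities must be non-negative")
        G = nx.from_numpy_array(X)
        clusters = mcl(
            G,
            inflation=self.inflation,
            expansion=self.expansion,
            prune=self.prune,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        labels = np.empty(X.shape[0], dtype=int)
        for k, members in enumerate(clusters):
            for i in members:
                labels[i] = k
        self.labels_ = labels
        self.n_clusters_ = len(clusters)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


# ---------------------------------------------------------------------------
# GO enrichment and module annotation
# ---------------------------------------------------------------------------

@dataclass
class EnrichedTerm:
    term: str
    k: int  # term genes in the cluster
    K: int  # term genes in the background
    n: int  # coding genes in the cluster
    N: int  # background size
    p: float
    q: float = 1.0


@dataclass
class Module:
    module_id: int
    genes: set
    colors: dict[str, str]
    enriched: list[EnrichedTerm] = field(default_factory=list)

    @property
    def has_both_colors(self) -> bool:
        cols = {self.colors.get(g, "coding") for g in self.genes}
        return "coding" in cols and "lincRNA" in cols


@dataclass
class ModuleSet:
    modules: list[Module]

    def enriched_modules(self) -> list[Module]:
        return [m for m in self.modules if m.enriched]


def hypergeom_enrichment_p(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric P(X >= k) of drawing k term genes in n
    draws from a background of N genes containing K term genes."""
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def go_enrichment(
    cluster: set,
    go: dict[str, set],
    background: set,
    alpha: float = 0.05,
) -> list[EnrichedTerm]:
    """GO-term enrichment of a cluster's coding genes against a background.

    For every term annotating >=1 cluster gene, the hypergeometric upper
    tail is computed and BH-corrected across the cluster's terms; terms with
    q <= alpha are returned (sorted by p).
    """
    if not background:
        raise ValueError("empty background gene set")
    genes = cluster & background
    N, n = len(background), len(genes)
    term_bg: dict[str, int] = {}
    term_hits: dict[str, int] = {}
    for g in background:
        for term in go.get(g, ()):
            term_bg[term] = term_bg.get(term, 0) + 1
    for g in genes:
        for term in go.get(g, ()):
            term_hits[term] = term_hits.get(term, 0) + 1
    if not term_hits:
        return []
    terms = sorted(term_hits)
    ps = [
        hypergeom_enrichment_p(N, term_bg[t], n, term_hits[t]) for t in terms
    ]
    _, qs, _, _ = multipletests(ps, method="fdr_bh")
    out = [
        EnrichedTerm(t, term_hits[t], term_bg[t], n, N, p, q)
        for t, p, q in zip(terms, ps, qs)
        if q <= alpha
    ]
    out.sort(key=lambda e: (e.p, e.term))
    return out


def make_modules(
    clusters: list[set],
    colors: dict[str, str],
    go: dict[str, set],
    background: set,
    min_module_size: int = 6,
    alpha: float = 0.05,
) -> ModuleSet:
    """Retain clusters of >= min_module_size genes and attach enrichment."""
    modules = []
    for mid, genes in enumerate(c for c in clusters if len(c) >= min_module_size):
        mod = Module(mid, genes, {g: colors.get(g, "coding") for g in genes})
        coding = {g for g in genes if mod.colors[g] == "coding"}
        if coding:
            mod.enriched = go_enrichment(coding, go, background, alpha=alpha)
        modules.append(mod)
    return ModuleSet(modules)


def annotate_lincrnas(modules: ModuleSet) -> dict[str, set]:
    """lincRNAs inherit all enriched terms of their (enriched) module."""
    annotation: dict[str, set] = {}
    for mod in modules.modules:
        if not mod.enriched:
            continue
        terms = {e.term for e in mod.enriched}
        for g in mod.genes:
            if mod.colors.get(g) == "lincRNA":
                annotation[g] = set(terms)
    return annotation


def write_enrichment_tsv(modules: ModuleSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("module_id\tterm\tk\tK\tn\tN\tp\tq\n")
        for mod in modules.modules:
            for e in mod.enriched:
                fh.write(
                    f"{mod.module_id}\t{e.term}\t{e.k}\t{e.K}\t{e.n}\t{e.N}"
                    f"\t{e.p:.6g}\t{e.q:.6g}\n"
                )
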