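"""Co-expression graph, Markov clustering, hypergeometric enrichment."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from lincatlas.coexpression import (
    MarkovClustering,
    _mcl_matrix,
    annotate_lincrnas,
    build_graph,
    collapse_to_genes,
    go_enrichment,
    hypergeom_enrichment_p,
    make_modules,
    mcl,
)
from statsmodels.stats.multitest import multipletests


def clique_pair_graph(k=5, bridge=True):
    G = nx.Graph()
    for base in (0, k):
        for i, j in itertools.combinations(range(k), 2):
            G.add_edge(base + i, base + j, weight=1.0)
    if bridge:
        G.add_edge(0, k, weight=1.0)
    return G


class TestBuildGraph:
    def _expr(self, rows):
        return pd.DataFrame(rows, columns=[f"t{i}" for i in range(6)])

    def test_proportional_profiles_linked(self):
        expr = self._expr({"a": [1, 2, 4, 8, 16, 32],
                           "b": [2, 4, 8, 16, 32, 64]}).T
        expr = pd.DataFrame(
            {"a": [1, 2, 4, 8, 16, 32], "b": [2, 4, 8, 16, 32, 64]}
        ).T
        expr.columns = [f"t{i}" for i in range(6)]
        G = build_graph(expr, {"a": "coding", "b": "lincRNA"})
        assert G.has_edge("a", "b")
        assert G["a"]["b"]["sign"] > 0

    def test_anticorrelated_profiles_linked_with_sign(self):
        expr = pd.DataFrame(
            {"a": [1, 2, 4, 8, 16, 32], "b": [32, 16, 8, 4, 2, 1]}
        ).T
        expr.columns = [f"t{i}" for i in range(6)]
        G = build_graph(expr, {})
        assert G.has_edge("a", "b")
        assert G["a"]["b"]["sign"] < 0
        assert 0 < G["a"]["b"]["weight"] <= 1

    def test_edge_count_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.uniform(0, 50, size=(30, 6)),
                            index=[f"g{i}" for i in range(30)],
                            columns=[f"t{i}" for i in range(6)])
        counts = [
            build_graph(expr, {}, edge_threshold=th).number_of_edges()
            for th in (0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_constant_gene_has_no_edges(self):
        expr = pd.DataFrame(
            {"a": [1, 2, 4, 8, 16, 32], "c": [5, 5, 5, 5, 5, 5]}
        ).T
        expr.columns = [f"t{i}" for i in range(6)]
        G = build_graph(expr, {})
        assert G.degree("c") == 0

    def test_collapse_to_genes_sums_isoforms(self):
        expr = pd.DataFrame({"g1.t1": [1.0, 2.0], "g1.t2": [3.0, 4.0]}).T
        expr.columns = ["a", "b"]
        out = collapse_to_genes(expr, {"g1.t1": "g1", "g1.t2": "g1"})
        assert out.loc["g1"].tolist() == [4.0, 6.0]


class TestMCL:
    def test_disconnected_cliques_recovered(self):
        G = clique_pair_graph(4, bridge=False)
        clusters = mcl(G)
        assert sorted(map(sorted, clusters)) == [[0, 1, 2, 3], [4, 5, 6, 7]]

    def test_bridged_cliques_split(self):
        clusters = mcl(clique_pair_graph(5, bridge=True))
        assert sorted(map(sorted, clusters)) == [[0, 1, 2, 3, 4],
                                                 [5, 6, 7, 8, 9]]

    def test_columns_remain_stochastic_each_iteration(self):
        G = clique_pair_graph(5)
        A = nx.to_numpy_array(G, nodelist=sorted(G), weight="weight")
        np.fill_diagonal(A, 1.0)
        M = A / A.sum(axis=0, keepdims=True)
        import warnings as _warnings

        for _ in range(30):
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")  # single forced iteration
                M = _mcl_matrix(M, inflation=1.8, expansion=2, prune=1e-5,
                                tol=-1.0, max_iter=1)
            assert np.allclose(M.sum(axis=0), 1.0, atol=1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            A = rng.uniform(0, 1, size=(15, 15))
            A = (A + A.T) / 2
            A[A < 0.6] = 0
            np.fill_diagonal(A, 0)
            labels = MarkovClustering().fit_predict(A)
            perm = rng.permutation(15)
            P = np.eye(15)[perm]
            labels_p = MarkovClustering().fit_predict(P @ A @ P.T)
            # same partition after inverting the permutation
            part = {}
            for i, lab in enumerate(labels_p):
                part.setdefault(lab, set()).add(int(perm[i]))
            orig = {}
            for i, lab in enumerate(labels):
                orig.setdefault(lab, set()).add(i)
            assert sorted(map(sorted, part.values())) == sorted(
                map(sorted, orig.values())
            )

    def test_higher_inflation_gives_finer_clustering(self):
        G = nx.path_graph(12)
        nx.set_edge_attributes(G, 1.0, "weight")
        n_fine = len(mcl(G, inflation=10.0))
        n_default = len(mcl(G, inflation=1.8))
        assert n_fine >= n_default

    def test_estimator_contract(self):
        est = MarkovClustering(inflation=2.0)
        clone(est)
        with pytest.raises(ValueError):
            est.fit(np.ones((3, 4)))


class TestHypergeometricEnrichment:
    def test_exact_formula_full_overlap(self):
        # all 5 drawn genes carry the term: p = 1 / C(20,5)
        assert hypergeom_enrichment_p(20, 5, 5, 5) == pytest.approx(
            1 / math.comb(20, 5)
        )

    def test_zero_overlap_p_is_one(self):
        assert hypergeom_enrichment_p(20, 5, 5, 0) == 1.0

    def test_matches_exhaustive_enumeration(self):
        for N in (8, 10, 12):
            pool = list(range(N))
            for K in (2, 4):
                term = set(range(K))
                for n in (3, 5):
                    for k in range(0, min(n, K) + 1):
                        count = sum(
                            1
                            for draw in itertools.combinations(pool, n)
                            if len(term & set(draw)) >= k
                        )
                        expected = count / math.comb(N, n)
                        assert hypergeom_enrichment_p(N, K, n, k) == pytest.approx(
                            expected, rel=1e-9
                        )

    def test_bh_step_up_hand_worked_fixture(self):
        # 10 p-values; BH at alpha=0.05 rejects the first three:
        # largest i with p_(i) <= i/10 * 0.05 is i=3 (0.012 <= 0.015)
        ps = [0.001, 0.008, 0.012, 0.035, 0.04, 0.2, 0.3, 0.5, 0.7, 0.9]
        reject, qs, _, _ = multipletests(ps, alpha=0.05, method="fdr_bh")
        assert reject.tolist() == [True] * 3 + [False] * 7
        # q-values are monotone in p
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))

    def test_go_enrichment_finds_planted_term(self):
        background = {f"g{i}" for i in range(40)}
        go = {f"g{i}": {"T_planted"} if i < 8 else {"T_bg"} for i in range(40)}
        cluster = {f"g{i}" for i in range(8)}
        enriched = go_enrichment(cluster, go, background)
        assert enriched and enriched[0].term == "T_planted"

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            go_enrichment({"a"}, {}, set())


class TestModuleAnnotation:
    def _modules(self, enriched_terms):
        colors = {"c1": "coding", "c2": "coding", "l1": "lincRNA",
                  "l2": "lincRNA", "l3": "lincRNA"}
        go = {"c1": set(enriched_terms), "c2": set(enriched_terms)}
        background = {"c1", "c2"} | {f"bg{i}" for i in range(20)}
        ms = make_modules([set(colors)], colors, go, background,
                          min_module_size=5)
        return ms

    def test_lincrnas_inherit_all_enriched_terms(self):
        ms = self._modules({"T1", "T2"})
        annotation = annotate_lincrnas(ms)
        assert set(annotation) == {"l1", "l2", "l3"}
        assert all(terms == {"T1", "T2"} for terms in annotation.values())

    def test_unenriched_module_annotates_nothing(self):
        colors = {f"g{i}": "lincRNA" for i in range(6)}
        ms = make_modules([set(colors)], colors, {}, {"bg"}, min_module_size=6)
        assert annotate_lincrnas(ms) == {}

    def test_planted_module_terms_recovered_end_to_end(self):
        from lincatlas.synthetic import (
            simulate_annotation,
            simulate_expression,
            simulate_go,
        )

        hits = 0
        total = 0
        for seed in range(5):
            _, truth = simulate_annotation(20 + seed, n_coding=60,
                                           n_novel_linc=30)
            expr = simulate_expression(truth, frac_specific=0.0,
                                       seed=30 + seed, n_modules=4)
            id2g = {
                t.transcript_id: t.gene_id
                for t in truth.all_annotated() + truth.novel
            }
            gexpr = collapse_to_genes(expr, id2g)
            colors = {
                t.gene_id: "coding" if t.biotype == "coding" else "lincRNA"
                for t in truth.all_annotated() + truth.novel
            }
            clusters = mcl(build_graph(gexpr, colors, edge_threshold=0.9))
            go = simulate_go(truth, seed=40 + seed)
            background = {t.gene_id for t in truth.catalogs["coding"]}
            ms = make_modules([c for c in clusters if len(c) >= 6], colors,
                              go, background)
            planted = {}
            for tid, m in truth.planted_modules.items():
                planted.setdefault(m, set()).add(id2g[tid])
            for m, genes in planted.items():
                total += 1
                for mod in ms.modules:
                    if genes <= mod.genes and mod.enriched:
                        if mod.enriched[0].term == truth.module_terms[m]:
                            hits += 1
                        break
        assert hits / total >= 0.95
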