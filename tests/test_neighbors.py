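"""Nearest-neighbor pairing, correlation distributions, GO-sharing null."""

import numpy as np
import pandas as pd
import pytest

from lincatlas.core import AnnotationCatalog
from lincatlas.neighbors import (
    NeighborPair,
    nearest_pairs,
    pair_distributions,
    random_pairs,
    shared_go_test,
    summarize_high_corr,
)
from conftest import make_transcript


def _expr(rows):
    df = pd.DataFrame(rows).T
    df.columns = [f"t{i}" for i in range(df.shape[1])]
    return df


@pytest.fixture()
def simple_locus():
    linc = make_transcript("linc0", gene="linc0",
                           exons=[(10_000, 10_500), (11_000, 11_500)],
                           biotype="lincRNA")
    near = make_transcript("gA", gene="gA", exons=[(8_000, 9_500)],
                           biotype="coding")
    far = make_transcript("gB", gene="gB", exons=[(12_200, 13_000)],
                          biotype="coding")
    return linc, near, far


class TestNearestPairs:
    def test_minimal_gap_wins(self, simple_locus):
        linc, near, far = simple_locus
        expr = _expr({"linc0": [1, 2, 3, 4, 5, 6],
                      "gA": [1, 2, 3, 4, 5, 6],
                      "gB": [6, 5, 4, 3, 2, 1]})
        (pair,) = nearest_pairs([linc], AnnotationCatalog([near, far]), expr)
        assert pair.coding_id == "gA"
        assert pair.gap_bp == 500  # 10_000 - 9_500

    def test_identical_profiles_r_one(self, simple_locus):
        linc, near, _ = simple_locus
        expr = _expr({"linc0": [1, 5, 2, 8, 3, 9], "gA": [1, 5, 2, 8, 3, 9]})
        (pair,) = nearest_pairs([linc], AnnotationCatalog([near]), expr)
        assert pair.r == pytest.approx(1.0)

    def test_constant_profile_flagged_undefined(self, simple_locus):
        linc, near, _ = simple_locus
        expr = _expr({"linc0": [2, 2, 2, 2, 2, 2], "gA": [1, 5, 2, 8, 3, 9]})
        (pair,) = nearest_pairs([linc], AnnotationCatalog([near]), expr)
        assert not pair.r_defined

    def test_no_coding_gene_on_chrom_omitted(self, simple_locus):
        linc, _, _ = simple_locus
        other = make_transcript("gX", gene="gX", chrom="chr2",
                                exons=[(0, 1000)], biotype="coding")
        expr = _expr({"linc0": [1, 2, 3, 4, 5, 6], "gX": [1, 2, 3, 4, 5, 6]})
        assert nearest_pairs([linc], AnnotationCatalog([other]), expr) == []

    def test_order_invariant(self):
        rng = np.random.default_rng(0)
        lincs, coding, rows = [], [], {}
        for i in range(10):
            base = i * 50_000
            coding.append(
                make_transcript(f"c{i}", gene=f"c{i}", exons=[(base, base + 800)],
                                biotype="coding")
            )
            lincs.append(
                make_transcript(f"l{i}", gene=f"l{i}",
                                exons=[(base + 3000, base + 3400),
                                       (base + 4000, base + 4500)],
                                biotype="lincRNA")
            )
            rows[f"c{i}"] = rng.uniform(1, 10, 6)
            rows[f"l{i}"] = rng.uniform(1, 10, 6)
        expr = _expr(rows)
        cat = AnnotationCatalog(coding)
        fwd = nearest_pairs(lincs, cat, expr)
        rev = nearest_pairs(list(reversed(lincs)), cat, expr)
        assert fwd == rev


class TestDistributionsAndNull:
    def test_identical_groups_identical_cdfs(self):
        pairs = [NeighborPair("a", "b", 10, r) for r in (0.1, 0.5, 0.9)]
        dist = pair_distributions(pairs, pairs, pairs)
        assert np.array_equal(dist["linc_coding"]["r_sorted"],
                              dist["random"]["r_sorted"])

    def test_group_sizes_preserved(self):
        p1 = [NeighborPair("a", "b", 1, 0.5)] * 4
        p2 = [NeighborPair("c", "d", 1, 0.2)] * 7
        p3 = [NeighborPair("e", "f", 1, 0.0)] * 3
        dist = pair_distributions(p1, p2, p3)
        assert (dist["linc_coding"]["n"], dist["coding_coding"]["n"],
                dist["random"]["n"]) == (4, 7, 3)

    def test_random_pairs_seeded(self):
        expr = _expr({f"g{i}": np.arange(6) + i for i in range(10)})
        a = random_pairs(list(expr.index), expr, 50, seed=3)
        b = random_pairs(list(expr.index), expr, 50, seed=3)
        assert [(p.lincrna_id, p.coding_id) for p in a] == [
            (p.lincrna_id, p.coding_id) for p in b
        ]

    def test_universal_term_degenerate(self):
        pairs = [NeighborPair("l1", "c1", 1, 0.95),
                 NeighborPair("l2", "c2", 1, 0.9)]
        go = {g: {"T"} for g in ("l1", "l2", "c1", "c2")}
        stats = shared_go_test(pairs, go, n_random=500, seed=1)
        assert stats["frac_shared_among_high"] == 1.0
        assert stats["null_frac"] == 1.0

    def test_disjoint_terms_zero_sharing(self):
        pairs = [NeighborPair("l1", "c1", 1, 0.95)]
        go = {"l1": {"A"}, "c1": {"B"}, "x": {"C"}, "y": {"D"}}
        stats = shared_go_test(pairs, go, n_random=500, seed=2)
        assert stats["frac_shared_among_high"] == 0.0
        assert stats["null_frac"] == 0.0

    def test_null_reproducible_and_varies_across_seeds(self):
        go = {f"g{i}": {f"T{i % 4}"} for i in range(40)}
        pairs = [NeighborPair("g0", "g4", 1, 0.9)]
        a = shared_go_test(pairs, go, n_random=2000, seed=5)
        b = shared_go_test(pairs, go, n_random=2000, seed=5)
        c = shared_go_test(pairs, go, n_random=2000, seed=6)
        assert a["null_frac"] == b["null_frac"]
        assert abs(a["null_frac"] - c["null_frac"]) < 5 * np.sqrt(
            0.25 * 0.75 / 2000
        ) + 1e-9
        assert a["null_frac"] != c["null_frac"]

    def test_planted_cis_pairs_beat_null(self):
        rng = np.random.default_rng(9)
        lincs, coding, rows = [], [], {}
        for i in range(25):
            base = i * 100_000
            coding.append(
                make_transcript(f"cod{i}", gene=f"cod{i}",
                                exons=[(base, base + 1000)], biotype="coding")
            )
            lincs.append(
                make_transcript(f"linc{i}", gene=f"linc{i}",
                                exons=[(base + 4000, base + 4500),
                                       (base + 5000, base + 5600)],
                                biotype="lincRNA")
            )
            prof = rng.uniform(1, 20, 6)
            rows[f"cod{i}"] = prof
            rows[f"linc{i}"] = prof * 0.3 * (1 + rng.normal(0, 0.02, 6))
        expr = _expr(rows)
        pairs = nearest_pairs(lincs, AnnotationCatalog(coding), expr)
        rand = random_pairs(list(expr.index), expr, 300, seed=10)
        dist = pair_distributions(pairs, pairs, rand)
        assert dist["linc_coding"]["median_r"] > dist["random"]["median_r"]
        go = {f"cod{i}": {f"T{i % 5}"} for i in range(25)}
        go.update({f"linc{i}": {f"T{i % 5}"} for i in range(25)})
        stats = shared_go_test(pairs, go, n_random=2000, seed=11)
        assert stats["frac_shared_among_high"] > stats["null_frac"]
        assert stats["empirical_p"] < 0.01


def test_summarize_high_corr_strict_flag():
    pairs = [NeighborPair("a", "b", 1, 0.8), NeighborPair("c", "d", 1, 0.85)]
    assert summarize_high_corr(pairs, 0.8)["n_high_r"] == 2
    assert summarize_high_corr(pairs, 0.8, strict=True)["n_high_r"] == 1
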