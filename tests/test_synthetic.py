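"""Generators: determinism, planted invariants, null behaviours."""

import numpy as np
import pytest

from lincatlas.core import AnnotationCatalog, distance_to_nearest, exonic_overlap_bp
from lincatlas.synthetic import (
    TISSUES,
    simulate_annotation,
    simulate_assemblies,
    simulate_expression,
    simulate_go,
    simulate_histone_tracks,
    simulate_sequence_set,
    simulate_sequences,
)


class TestAnnotation:
    def test_counts(self):
        ann, truth = simulate_annotation(7, n_coding=50, n_known_nc=15,
                                         n_pseudo=5, n_novel_linc=12)
        assert len(truth.catalogs["coding"]) == 50
        assert len(truth.catalogs["known_noncoding"]) == 15
        assert len(truth.catalogs["pseudogene"]) == 5
        assert len(truth.novel) == 12

    def test_same_seed_identical(self):
        a = simulate_annotation(3)[1]
        b = simulate_annotation(3)[1]
        assert a.novel == b.novel
        assert a.catalogs == b.catalogs

    def test_planted_lincrnas_satisfy_catalog_filters(self):
        ann, truth = simulate_annotation(7, n_novel_linc=20)
        coding = AnnotationCatalog(truth.catalogs["coding"])
        for t in truth.novel:
            assert t.exon_count() >= 2
            assert t.length() > 200
            assert distance_to_nearest(t, coding) >= 1000
            for other in truth.all_annotated():
                assert exonic_overlap_bp(t, other) == 0

    def test_lincrna_structure_statistics(self):
        _, truth = simulate_annotation(11, n_coding=0, n_known_nc=0,
                                       n_pseudo=0, n_novel_linc=400,
                                       genome_size=40_000_000)
        n_exons = np.array([t.exon_count() for t in truth.novel])
        exon_lens = np.array(
            [e - s for t in truth.novel for s, e in t.exons]
        )
        assert n_exons.mean() == pytest.approx(2.5, abs=0.15)
        assert exon_lens.mean() == pytest.approx(620, rel=0.1)

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="genome_size"):
            simulate_annotation(1, n_coding=500, genome_size=100_000)


class TestExpression:
    def test_seeded_determinism(self):
        _, t1 = simulate_annotation(5)
        _, t2 = simulate_annotation(5)
        e1 = simulate_expression(t1, seed=9)
        e2 = simulate_expression(t2, seed=9)
        assert e1.equals(e2)

    def test_dimensions_and_nonnegative(self):
        _, truth = simulate_annotation(5, n_coding=30, n_known_nc=10,
                                       n_pseudo=5, n_novel_linc=15)
        expr = simulate_expression(truth, seed=1)
        assert expr.shape == (60, 6)
        assert (expr.to_numpy() >= 0).all()

    def test_planted_specific_argmax_matches(self):
        _, truth = simulate_annotation(5, n_novel_linc=30)
        expr = simulate_expression(truth, frac_specific=1.0, seed=2,
                                   n_modules=0)
        for tid, tissue in truth.planted_specific.items():
            row = expr.loc[tid]
            assert row.idxmax() == tissue
            assert row.max() / row.sum() >= 0.9

    def test_lincrna_median_below_coding(self):
        _, truth = simulate_annotation(6, n_coding=80, n_novel_linc=80,
                                       genome_size=30_000_000)
        expr = simulate_expression(truth, seed=3, n_modules=0)
        lincs = [t.transcript_id for t in truth.novel]
        coding = [t.transcript_id for t in truth.catalogs["coding"]]
        assert (
            expr.loc[lincs].max(axis=1).median()
            < expr.loc[coding].max(axis=1).median()
        )


class TestAssemblies:
    def test_zero_dropout_includes_every_expressed_transcript(self):
        _, truth = simulate_annotation(4, n_novel_linc=10)
        assemblies = simulate_assemblies(truth, dropout=0.0, seed=5)
        ids = {t.transcript_id for t in truth.novel}
        for sample in assemblies.values():
            present = {t.transcript_id for t in sample}
            assert ids <= present

    def test_extreme_dropout_concentrates_low(self):
        _, truth = simulate_annotation(4, n_coding=10, n_novel_linc=50,
                                       genome_size=30_000_000)
        assemblies = simulate_assemblies(truth, dropout=0.98, seed=6,
                                         n_intronic_noise=0,
                                         n_truncation_noise=0)
        from lincatlas.specificity import recurrence

        _, hist = recurrence(truth.novel, assemblies)
        assert sum(hist.get(k, 0) for k in (0, 1)) >= 0.8 * len(truth.novel)

    def test_seeded_reproducibility(self):
        _, t1 = simulate_annotation(4)
        _, t2 = simulate_annotation(4)
        a1 = simulate_assemblies(t1, seed=7)
        a2 = simulate_assemblies(t2, seed=7)
        assert a1 == a2

    def test_noise_artifacts_present(self):
        _, truth = simulate_annotation(4)
        assemblies = simulate_assemblies(truth, seed=8, n_intronic_noise=5,
                                         n_truncation_noise=5)
        sample = assemblies[("heart", 1)]
        intronic = [t for t in sample if t.transcript_id.startswith("noise_intr")]
        trunc = [t for t in sample if t.transcript_id.startswith("noise_trunc")]
        assert len(intronic) == 5 and len(trunc) == 5
        assert all(t.exon_count() == 1 for t in intronic)


class TestSequences:
    def test_zero_bias_classes_indistinguishable(self):
        c, n = simulate_sequence_set(200, 200, bias_strength=0.0, seed=9)
        # compare triplet frequency profiles of the two classes
        def freq(seqs):
            counts = np.zeros(64)
            for s in seqs:
                for i in range(0, len(s) - 2, 3):
                    t = s[i : i + 3]
                    counts["ACGT".index(t[0]) * 16 + "ACGT".index(t[1]) * 4
                           + "ACGT".index(t[2])] += 1
            return counts / counts.sum()

        assert np.abs(freq(c) - freq(n)).max() < 0.01

    def test_gc_content_in_plausible_range(self):
        c, n = simulate_sequence_set(500, 500, bias_strength=1.0, seed=10)
        gc = [
            (s.count("G") + s.count("C")) / len(s) for s in c + n
        ]
        assert 0.3 < np.mean(gc) < 0.7

    def test_lengths_match_transcripts(self):
        _, truth = simulate_annotation(4)
        seqs = simulate_sequences(truth, seed=11)
        for t in truth.novel + truth.all_annotated():
            assert len(seqs[t.transcript_id]) == t.length()

    def test_seeded_determinism(self):
        _, t1 = simulate_annotation(4)
        _, t2 = simulate_annotation(4)
        assert simulate_sequences(t1, seed=12) == simulate_sequences(t2, seed=12)


class TestHistoneTracksAndGO:
    def test_unit_enrichment_is_flat(self):
        _, truth = simulate_annotation(4, n_coding=10, n_novel_linc=5)
        tracks = simulate_histone_tracks(truth, expressed_tss_enrichment=1.0,
                                         noise_cv=0.0, seed=13,
                                         marks=("H3K4me3",), tissues=("heart",))
        track = tracks[("H3K4me3", "heart")]
        vals = {v for ivs in track.intervals.values() for _, _, v in ivs}
        assert vals == {1.0}

    def test_module_genes_share_a_term(self):
        _, truth = simulate_annotation(4, n_coding=40, n_novel_linc=10)
        simulate_expression(truth, seed=14, n_modules=3)
        go = simulate_go(truth, seed=15)
        modules = {}
        for tid, m in truth.planted_modules.items():
            modules.setdefault(m, []).append(tid.rsplit(".", 1)[0])
        for m, genes in modules.items():
            coding = [g for g in genes if g.startswith("cod")]
            shared = set.intersection(*(go[g] for g in coding))
            assert truth.module_terms[m] in shared

    def test_enrichment_below_one_rejected(self):
        _, truth = simulate_annotation(4)
        with pytest.raises(ValueError):
            simulate_histone_tracks(truth, expressed_tss_enrichment=0.5)
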