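"""Seeded generators for every input the pipeline consumes.

The generators emulate the study design the pipeline targets: six mouse
tissues with six biological replicates each, a genome annotation with
coding, known-noncoding and pseudogene loci, planted novel lincRNAs
(multi-exonic, >200 nt spliced, >=1 kb from every coding gene, disjoint
from all catalogs — so they pass the structural and positional filters by
construction), per-sample assemblies with dropout and noise artifacts,
FPKM matrices with planted tissue-specific / ubiquitous / co-expression-
module patterns, nucleotide sequences whose adjoining-triplet statistics
separate coding from noncoding, TSS-enriched histone tracks, and GO labels
aligned with the planted modules.

Every generator is a pure function of its arguments and a seed: the same
call is byte-identical across runs.  Planted ground truth accumulates in a
:class:`SimTruth` so recovery tests can compare pipeline output against
what was actually planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import AnnotationCatalog, Transcript
from .histone import SignalTrack

TISSUES = ("heart", "hippocampus", "liver", "lung", "spleen", "thymus")


@dataclass
class SimTruth:
    """Ground truth of one simulated study."""

    chrom_sizes: dict[str, int]
    catalogs: dict[str, list[Transcript]]  # coding / known_noncoding / pseudogene
    novel: list[Transcript]
    planted_lincrna_ids: set = field(default_factory=set)
    planted_specific: dict[str, str] = field(default_factory=dict)
    expressed_in: dict[str, set] = field(default_factory=dict)
    planted_modules: dict[str, int] = field(default_factory=dict)
    module_terms: dict[int, str] = field(default_factory=dict)
    coverage: dict[str, float] = field(default_factory=dict)
    noise_ids: dict[str, int] = field(default_factory=dict)  # id -> length
    dropout_realizations: dict = field(default_factory=dict)
    triplet_bias: float = 0.0

    def all_annotated(self) -> list[Transcript]:
        return [t for ts in self.catalogs.values() for t in ts]

    def transcripts_by_id(self) -> dict[str, Transcript]:
        out = {t.transcript_id: t for t in self.all_annotated()}
        out.update({t.transcript_id: t for t in self.novel})
        return out


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _make_exons(rng, start: int, n_exons: int, exon_len, intron_len) -> tuple:
    exons = []
    pos = start
    for i in range(n_exons):
        ln = int(exon_len(rng))
        exons.append((pos, pos + ln))
        pos += ln + (int(intron_len(rng)) if i < n_exons - 1 else 0)
    return tuple(exons)


def simulate_annotation(
    seed: int,
    n_coding: int = 50,
    n_known_nc: int = 20,
    n_pseudo: int = 10,
    n_novel_linc: int = 20,
    genome_size: int = 20_000_000,
    n_chroms: int = 2,
    min_locus_gap: int = 1500,
) -> tuple[AnnotationCatalog, SimTruth]:
    """Place annotated and planted loci on a synthetic genome.

    Loci are laid out left-to-right per chromosome with inter-locus gaps of
    at least ``min_locus_gap`` (> 1 kb), so planted novel lincRNAs are
    intergenic with respect to every annotated class by construction.
    Coding genes get 2-12 exons; novel lincRNAs 2-4 exons with 620-nt mean
    exon length and mean exon count 2.5.  Raises when the loci do not fit
    the genome.
    """
    if min(n_coding, n_known_nc, n_pseudo, n_novel_linc) < 0:
        raise ValueError("locus counts must be non-negative")
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    chrom_size = genome_size // n_chroms

    specs = (
        [("coding", f"cod{i}") for i in range(n_coding)]
        + [("known_noncoding", f"nc{i}") for i in range(n_known_nc)]
        + [("pseudogene", f"pseudo{i}") for i in range(n_pseudo)]
        + [("lincRNA", f"linc{i}") for i in range(n_novel_linc)]
    )
    rng.shuffle(specs)

    exon_len = {
        "coding": lambda r: r.integers(100, 400),
        "known_noncoding": lambda r: r.integers(150, 600),
        "pseudogene": lambda r: r.integers(100, 500),
        "lincRNA": lambda r: max(150, int(r.normal(620, 150))),
    }
    n_exons = {
        "coding": lambda r: int(r.integers(2, 13)),
        "known_noncoding": lambda r: int(r.integers(1, 4)),
        "pseudogene": lambda r: int(r.integers(1, 6)),
        "lincRNA": lambda r: int(r.choice([2, 3, 4], p=[0.55, 0.4, 0.05])),
    }
    intron_len = lambda r: r.integers(500, 3000)  # noqa: E731

    cursors = {c: 10_000 for c in chroms}
    catalogs: dict[str, list[Transcript]] = {
        "coding": [], "known_noncoding": [], "pseudogene": []
    }
    novel: list[Transcript] = []
    for biotype, name in specs:
        chrom = chroms[int(rng.integers(0, n_chroms))]
        gap_hi = max(5000, min_locus_gap + 1000)
        start = cursors[chrom] + int(rng.integers(min_locus_gap, gap_hi))
        exons = _make_exons(rng, start, n_exons[biotype](rng),
                            exon_len[biotype], intron_len)
        if exons[-1][1] > chrom_size:
            raise ValueError(
                "loci do not fit: increase genome_size or reduce locus counts"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        t = Transcript(
            transcript_id=f"{name}.t1",
            gene_id=name,
            chrom=chrom,
            strand=strand,
            exons=exons,
            biotype=biotype,
        )
        cursors[chrom] = exons[-1][1]
        if biotype == "lincRNA":
            novel.append(t)
        else:
            catalogs[biotype].append(t)

    truth = SimTruth(
        chrom_sizes={c: chrom_size for c in chroms},
        catalogs=catalogs,
        novel=novel,
        planted_lincrna_ids={t.transcript_id for t in novel},
    )
    annotation = AnnotationCatalog(truth.all_annotated())
    return annotation, truth


def make_disjoint_loci(
    n: int,
    prefix: str,
    chrom: str = "chrU",
    start: int = 0,
    pitch: int = 5000,
) -> list[Transcript]:
    """Deterministic, pairwise-disjoint 2-exon loci (bookkeeping fixtures)."""
    out = []
    for i in range(n):
        s = start + i * pitch
        out.append(
            Transcript(
                transcript_id=f"{prefix}{i}.t1",
                gene_id=f"{prefix}{i}",
                chrom=chrom,
                strand="+",
                exons=((s, s + 400), (s + 1000, s + 1400)),
                biotype="lincRNA",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Expression (with planted specificity and module structure)
# ---------------------------------------------------------------------------

def simulate_expression(
    truth: SimTruth,
    frac_specific: float = 0.5,
    fpkm_scale: float = 10.0,
    seed: int = 0,
    tissues: Sequence[str] = TISSUES,
    coding_frac_specific: float = 0.25,
    n_modules: int = 4,
    module_n_coding: int = 6,
    module_n_linc: int = 2,
) -> pd.DataFrame:
    """FPKM matrix over all planted transcripts with planted patterns.

    ``frac_specific`` of the lincRNAs (and ``coding_frac_specific`` of the
    coding genes) get one dominant tissue carrying >=90% of their expression
    mass; the rest are near-uniform.  lincRNA FPKM is drawn with a lower
    median than coding FPKM.  When ``n_modules`` > 0, disjoint groups of
    coding genes and lincRNAs are planted as co-expression modules: their
    log-expression follows one shared tissue profile, so within-module
    Pearson correlations approach 1.  All planting is recorded in ``truth``.
    """
    if not 0 <= frac_specific <= 1:
        raise ValueError("frac_specific must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    T = len(tissues)
    lincs = [t.transcript_id for t in truth.novel]
    coding = [t.transcript_id for t in truth.catalogs["coding"]]
    others = [
        t.transcript_id
        for cls in ("known_noncoding", "pseudogene")
        for t in truth.catalogs[cls]
    ]

    rows: dict[str, np.ndarray] = {}
    truth.planted_specific = {}
    truth.expressed_in = {}

    def plant_specific(tid: str, scale: float) -> None:
        tissue_idx = int(rng.integers(0, T))
        dominant = max(2.0, rng.lognormal(np.log(scale), 0.5))
        minors = dominant * rng.uniform(0, 1 / 45, size=T)
        v = minors
        v[tissue_idx] = dominant
        rows[tid] = v
        truth.planted_specific[tid] = tissues[tissue_idx]
        truth.expressed_in[tid] = {tissues[tissue_idx]}

    def plant_uniform(tid: str, scale: float) -> None:
        base = max(2.0, rng.lognormal(np.log(scale), 0.5))
        rows[tid] = base * (1.0 + rng.uniform(-0.2, 0.2, size=T))
        truth.expressed_in[tid] = set(tissues)

    # module planting first; module members are excluded from the
    # specific/uniform split so the module profile is not overwritten
    truth.planted_modules = {}
    module_members: set[str] = set()
    n_modules = min(
        n_modules,
        len(coding) // max(module_n_coding, 1) if module_n_coding else n_modules,
        len(lincs) // max(module_n_linc, 1) if module_n_linc else n_modules,
    )
    if n_modules > 0:
        cod_pool = list(rng.permutation(coding))
        linc_pool = list(rng.permutation(lincs))
        for m in range(n_modules):
            members = [cod_pool.pop() for _ in range(module_n_coding)] + [
                linc_pool.pop() for _ in range(module_n_linc)
            ]
            profile = rng.uniform(0, 1, size=T)
            profile = (profile - profile.min()) / max(np.ptp(profile), 1e-9)
            for tid in members:
                a = rng.uniform(1.5, 3.0)  # baseline log2 expression
                x = a + 2.5 * profile + rng.normal(0, 0.05, size=T)
                rows[tid] = np.maximum(2.0 ** x - 1.0, 0.0)
                truth.planted_modules[tid] = m
                truth.expressed_in[tid] = set(tissues)
                module_members.add(tid)

    free_lincs = [t for t in lincs if t not in module_members]
    n_spec = int(round(frac_specific * len(free_lincs)))
    spec_lincs = set(rng.choice(free_lincs, size=n_spec, replace=False)) if n_spec else set()
    for tid in free_lincs:
        if tid in spec_lincs:
            plant_specific(tid, fpkm_scale * 0.3)
        else:
            plant_uniform(tid, fpkm_scale * 0.3)

    free_coding = [t for t in coding if t not in module_members]
    n_spec_c = int(round(coding_frac_specific * len(free_coding)))
    spec_coding = set(rng.choice(free_coding, size=n_spec_c, replace=False)) if n_spec_c else set()
    for tid in free_coding:
        if tid in spec_coding:
            plant_specific(tid, fpkm_scale)
        else:
            plant_uniform(tid, fpkm_scale)

    for tid in others:
        plant_uniform(tid, fpkm_scale * 0.5)

    truth.coverage = {
        tid: float(rng.uniform(5.0, 50.0)) for tid in rows
    }
    index = lincs + coding + others
    df = pd.DataFrame(
        np.vstack([rows[tid] for tid in index]), index=index, columns=list(tissues)
    )
    return df


# ---------------------------------------------------------------------------
# Assemblies
# ---------------------------------------------------------------------------

def simulate_assemblies(
    truth: SimTruth,
    tissues: Sequence[str] = TISSUES,
    replicates: int = 6,
    dropout: float = 0.1,
    n_intronic_noise: int = 20,
    n_truncation_noise: int = 20,
    seed: int = 0,
) -> dict[tuple[str, int], list[Transcript]]:
    """Per-(tissue, replicate) assembled transcript lists.

    Each planted transcript expressed in tissue t (``truth.expressed_in``;
    all tissues when expression has not been simulated) appears in each
    replicate of t with probability 1 - dropout.  Noise artifacts per
    sample: single-exon fragments inside coding-gene introns (pre-mRNA
    contamination) and truncated exon runs of coding transcripts (partial
    assemblies).  Inclusion realizations are recorded in
    ``truth.dropout_realizations``.
    """
    if not 0 <= dropout < 1:
        raise ValueError("dropout must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    all_transcripts = list(truth.novel) + truth.all_annotated()
    multi_exon_coding = [
        t for t in truth.catalogs["coding"] if t.exon_count() >= 2
    ]
    out: dict[tuple[str, int], list[Transcript]] = {}
    truth.dropout_realizations = {}
    truth.noise_ids = {}
    for tissue in tissues:
        for rep in range(1, replicates + 1):
            tag = f"{tissue}_r{rep}"
            sample: list[Transcript] = []
            included = set()
            for t in all_transcripts:
                expressed = truth.expressed_in.get(
                    t.transcript_id, set(tissues)
                )
                if tissue not in expressed:
                    continue
                if rng.random() < dropout:
                    continue
                sample.append(replace(t, source=tag))
                included.add(t.transcript_id)
            for i in range(n_intronic_noise):
                if not multi_exon_coding:
                    break
                host = multi_exon_coding[int(rng.integers(len(multi_exon_coding)))]
                introns = host.introns()
                s, e = introns[int(rng.integers(len(introns)))]
                ln = int(min(rng.integers(200, 800), e - s))
                off = int(rng.integers(0, e - s - ln + 1))
                tid = f"noise_intr_{tag}_{i}"
                sample.append(
                    Transcript(
                        transcript_id=tid,
                        gene_id=tid,
                        chrom=host.chrom,
                        strand=host.strand,
                        exons=((s + off, s + off + ln),),
                        biotype="unannotated",
                        source=tag,
                    )
                )
                truth.noise_ids[tid] = ln
            for i in range(n_truncation_noise):
                if not multi_exon_coding:
                    break
                host = multi_exon_coding[int(rng.integers(len(multi_exon_coding)))]
                k = int(rng.integers(1, host.exon_count()))
                tid = f"noise_trunc_{tag}_{i}"
                exons = host.exons[:k]
                sample.append(
                    Transcript(
                        transcript_id=tid,
                        gene_id=tid,
                        chrom=host.chrom,
                        strand=host.strand,
                        exons=exons,
                        biotype="unannotated",
                        source=tag,
                    )
                )
                truth.noise_ids[tid] = sum(e - s for s, e in exons)
            out[(tissue, rep)] = sample
            truth.dropout_realizations[(tissue, rep)] = included
    return out


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def _triplet_transition_matrix(bias_strength: float, rng) -> np.ndarray:
    """Row-stochastic 64x64 transition matrix, skewness scaling with bias."""
    W = rng.normal(0.0, 1.0, size=(64, 64))
    M = np.exp(bias_strength * W)
    return M / M.sum(axis=1, keepdims=True)


_TRIPLET_STR = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]


def sample_triplet_sequences(
    lengths: Sequence[int], transition: np.ndarray, rng
) -> list[str]:
    """Sequences emitted by a first-order chain over non-overlapping
    triplets, truncated to the requested nucleotide lengths."""
    lengths = np.asarray(lengths, dtype=int)
    n = len(lengths)
    if n == 0:
        return []
    n_trip = np.maximum((lengths + 2) // 3, 1)
    max_trip = int(n_trip.max())
    cum = np.cumsum(transition, axis=1)
    states = np.empty((n, max_trip), dtype=np.int64)
    states[:, 0] = rng.integers(0, 64, size=n)
    for k in range(1, max_trip):
        u = rng.random(n)
        states[:, k] = (cum[states[:, k - 1]] < u[:, None]).sum(axis=1)
    out = []
    for i in range(n):
        seq = "".join(_TRIPLET_STR[s] for s in states[i, : n_trip[i]])
        out.append(seq[: max(int(lengths[i]), 3)])
    return out


def simulate_sequences(
    truth: SimTruth,
    coding_bias_strength: float = 1.0,
    seed: int = 0,
) -> dict[str, str]:
    """id -> sequence for every planted transcript and noise artifact.

    Coding and pseudogene sequences come from a triplet chain with skewed
    transition usage (skew scales with ``coding_bias_strength``); noncoding
    classes and noise come from the uniform chain.  At bias 0 the two
    classes are statistically indistinguishable.  Sequence length equals the
    spliced transcript length.
    """
    if coding_bias_strength < 0:
        raise ValueError("bias strength must be >= 0")
    rng = np.random.default_rng(seed)
    coding_T = _triplet_transition_matrix(coding_bias_strength, rng)
    uniform_T = np.full((64, 64), 1.0 / 64)
    truth.triplet_bias = coding_bias_strength

    coding_ids, noncoding_ids, lengths_c, lengths_n = [], [], [], []
    for t in truth.all_annotated() + truth.novel:
        if t.biotype in ("coding", "pseudogene"):
            coding_ids.append(t.transcript_id)
            lengths_c.append(t.length())
        else:
            noncoding_ids.append(t.transcript_id)
            lengths_n.append(t.length())
    for tid, ln in truth.noise_ids.items():
        noncoding_ids.append(tid)
        lengths_n.append(ln)

    seqs = {}
    for ids, lens, T in (
        (coding_ids, lengths_c, coding_T),
        (noncoding_ids, lengths_n, uniform_T),
    ):
        for tid, seq in zip(ids, sample_triplet_sequences(lens, T, rng)):
            seqs[tid] = seq
    return seqs


def simulate_sequence_set(
    n_coding: int,
    n_noncoding: int,
    bias_strength: float = 1.0,
    mean_length: int = 1500,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Standalone labelled sequence sets for classifier benchmarks."""
    rng = np.random.default_rng(seed)
    coding_T = _triplet_transition_matrix(bias_strength, rng)
    uniform_T = np.full((64, 64), 1.0 / 64)
    lc = rng.integers(mean_length // 2, mean_length * 3 // 2, size=n_coding)
    ln = rng.integers(mean_length // 2, mean_length * 3 // 2, size=n_noncoding)
    return (
        sample_triplet_sequences(lc, coding_T, rng),
        sample_triplet_sequences(ln, uniform_T, rng),
    )


# ---------------------------------------------------------------------------
# Histone tracks and GO labels
# ---------------------------------------------------------------------------

def simulate_histone_tracks(
    truth: SimTruth,
    expressed_tss_enrichment: float = 3.0,
    marks: Sequence[str] = ("H3K4me3", "H3K4me1"),
    tissues: Sequence[str] = TISSUES,
    tile: int = 100,
    tss_halfwidth: int = 1000,
    noise_cv: float = 0.1,
    seed: int = 0,
) -> dict[tuple[str, str], SignalTrack]:
    """(mark, tissue) -> SignalTrack with TSS-proximal enrichment.

    The background is a tiled track with mean 1 and coefficient of variation
    ``noise_cv``; tiles within ``tss_halfwidth`` of the TSS of a gene
    expressed in the tissue are scaled by ``expressed_tss_enrichment``, so
    the mean signal in the TSS window is enrichment x background.
    """
    if expressed_tss_enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    from .histone import tss as _tss

    rng = np.random.default_rng(seed)
    transcripts = truth.all_annotated() + truth.novel
    tracks: dict[tuple[str, str], SignalTrack] = {}
    shape = 1.0 / (noise_cv ** 2) if noise_cv > 0 else None
    for mark in marks:
        for tissue in tissues:
            intervals: dict[str, list[tuple[int, int, float]]] = {}
            for chrom, size in truth.chrom_sizes.items():
                n_tiles = size // tile
                if shape is not None:
                    vals = rng.gamma(shape, 1.0 / shape, size=n_tiles)
                else:
                    vals = np.ones(n_tiles)
                boost = np.ones(n_tiles)
                for t in transcripts:
                    if t.chrom != chrom:
                        continue
                    expressed = truth.expressed_in.get(
                        t.transcript_id, set(tissues)
                    )
                    if tissue not in expressed:
                        continue
                    _, pos, _ = _tss(t)
                    lo = max(0, (pos - tss_halfwidth) // tile)
                    hi = min(n_tiles, -(-(pos + tss_halfwidth) // tile))
                    boost[lo:hi] = expressed_tss_enrichment
                vals = vals * boost
                intervals[chrom] = [
                    (i * tile, (i + 1) * tile, float(v))
                    for i, v in enumerate(vals)
                ]
            tracks[(mark, tissue)] = SignalTrack(intervals)
    return tracks


def simulate_go(
    truth: SimTruth,
    n_terms: int = 50,
    terms_per_gene: int = 2,
    seed: int = 0,
) -> dict[str, set]:
    """Gene -> GO-term-set map whose structure mirrors the planted modules.

    Every coding gene receives ``terms_per_gene`` random background terms;
    coding genes of a planted module additionally all share that module's
    dedicated term (recorded in ``truth.module_terms``), so module-level
    enrichment tests have a planted positive.
    """
    rng = np.random.default_rng(seed)
    background_terms = [f"GO:{i:07d}" for i in range(n_terms)]
    go: dict[str, set] = {}
    for t in truth.catalogs["coding"]:
        gid = t.gene_id
        picks = rng.choice(n_terms, size=min(terms_per_gene, n_terms),
                           replace=False)
        go[gid] = {background_terms[i] for i in picks}
    truth.module_terms = {}
    modules: dict[int, list[str]] = {}
    for tid, m in truth.planted_modules.items():
        modules.setdefault(m, []).append(tid)
    id_to_gene = {
        t.transcript_id: t.gene_id for t in truth.all_annotated() + truth.novel
    }
    coding_genes = {t.gene_id for t in truth.catalogs["coding"]}
    for m, members in sorted(modules.items()):
        term = f"GO:M{m:06d}"
        truth.module_terms[m] = term
        for tid in members:
            gid = id_to_gene.get(tid, tid)
            if gid in coding_genes:
                go.setdefault(gid, set()).add(term)
    return go


# ---------------------------------------------------------------------------
# One-call bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    annotation: AnnotationCatalog
    truth: SimTruth
    expression: pd.DataFrame
    assemblies: dict[tuple[str, int], list[Transcript]]
    sequences: dict[str, str]
    go: dict[str, set]


def simulate_dataset(
    seed: int = 7,
    n_coding: int = 50,
    n_known_nc: int = 20,
    n_pseudo: int = 10,
    n_novel_linc: int = 20,
    genome_size: int = 20_000_000,
    frac_specific: float = 0.5,
    dropout: float = 0.1,
    n_intronic_noise: int = 20,
    n_truncation_noise: int = 20,
    coding_bias_strength: float = 1.0,
    n_modules: int = 4,
) -> SimulatedDataset:
    """Generate a complete coherent input set from one seed.

    Sub-generators receive seeds derived deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]
    annotation, truth = simulate_annotation(
        seeds[0],
        n_coding=n_coding,
        n_known_nc=n_known_nc,
        n_pseudo=n_pseudo,
        n_novel_linc=n_novel_linc,
        genome_size=genome_size,
    )
    expr = simulate_expression(
        truth, frac_specific=frac_specific, seed=seeds[1], n_modules=n_modules
    )
    assemblies = simulate_assemblies(
        truth,
        dropout=dropout,
        n_intronic_noise=n_intronic_noise,
        n_truncation_noise=n_truncation_noise,
        seed=seeds[2],
    )
    sequences = simulate_sequences(
        truth, coding_bias_strength=coding_bias_strength, seed=seeds[3]
    )
    go = simulate_go(truth, seed=seeds[4])
    return SimulatedDataset(annotation, truth, expr, assemblies, sequences, go)
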