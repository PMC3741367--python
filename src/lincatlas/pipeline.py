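"""The five-step novel-lincRNA detection cascade.

Starting from merged assembled transcripts, the cascade keeps a transcript
only if it (1) is reliably expressed (FPKM and read-coverage thresholds),
(2) has no exon overlap with any known coding, noncoding or pseudogene
annotation, (3) is classified noncoding by the triplet coding-potential
model (optionally intersected with an external classifier's labels),
(4) is multi-exonic and longer than 200 nt, and (5) lies in intergenic
space at least 1 kb from every protein-coding gene.  Survivors are merged
into gene loci to form the novel catalog, which can be unioned with a
documented lincRNA catalog.

Every stage records its attrition in a :class:`FilterLedger` whose counts
telescope: the output count of step k is the input count of step k+1, and
every input transcript appears exactly once as surviving or eliminated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .coding import TripletModel, classify
from .core import (
    AnnotationCatalog,
    Transcript,
    distance_to_nearest,
    exonic_overlap_bp,
    merge_transcripts,
)


@dataclass
class LedgerEntry:
    step: str
    n_in: int
    n_out: int
    eliminated: dict[str, str]  # transcript_id -> reason


@dataclass
class FilterLedger:
    entries: list[LedgerEntry] = field(default_factory=list)

    def record(self, step: str, before: Sequence[Transcript],
               after: Sequence[Transcript], reasons: dict[str, str]) -> None:
        self.entries.append(LedgerEntry(step, len(before), len(after), reasons))

    def telescopes(self) -> bool:
        """Counts conserve: out of step k = in of step k+1, and
        in - out = eliminated at every step."""
        for e in self.entries:
            if e.n_in - e.n_out != len(e.eliminated):
                return False
        return all(
            a.n_out == b.n_in for a, b in zip(self.entries, self.entries[1:])
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("step\tn_in\tn_out\tn_eliminated\n")
            for e in self.entries:
                fh.write(f"{e.step}\t{e.n_in}\t{e.n_out}\t{len(e.eliminated)}\n")


@dataclass
class LincRNACatalog:
    """The surviving transcripts grouped into gene loci."""

    transcripts: list[Transcript]
    provenance: dict[str, str] = field(default_factory=dict)  # gene_id -> novel/documented

    @property
    def loci(self) -> dict[str, list[Transcript]]:
        out: dict[str, list[Transcript]] = {}
        for t in self.transcripts:
            out.setdefault(t.gene_id, []).append(t)
        return out

    def n_loci(self) -> int:
        return len({t.gene_id for t in self.transcripts})


# ---------------------------------------------------------------------------
# The five filters
# ---------------------------------------------------------------------------

def filter_expression(
    transcripts: Sequence[Transcript],
    expr: pd.DataFrame,
    coverage: Mapping[str, float],
    min_fpkm: float = 1.0,
    min_coverage: float = 3.0,
) -> tuple[list[Transcript], dict[str, str]]:
    """Step 1: keep reliably expressed transcripts.

    Survivor iff max-over-tissues FPKM >= min_fpkm and read coverage >=
    min_coverage.  Transcripts without an expression row or coverage value
    are treated as 0.
    """
    if min_fpkm < 0 or min_coverage < 0:
        raise ValueError("thresholds must be non-negative")
    survivors, reasons = [], {}
    for t in transcripts:
        fpkm = (
            float(expr.loc[t.transcript_id].max())
            if t.transcript_id in expr.index
            else 0.0
        )
        cov = float(coverage.get(t.transcript_id, 0.0))
        if fpkm >= min_fpkm and cov >= min_coverage:
            survivors.append(t)
        else:
            reasons[t.transcript_id] = (
                "low_fpkm" if fpkm < min_fpkm else "low_coverage"
            )
    return survivors, reasons


_CATALOG_PRIORITY = ("coding", "known_noncoding", "pseudogene")


def filter_annotation_overlap(
    transcripts: Sequence[Transcript],
    catalogs: Mapping[str, AnnotationCatalog],
) -> tuple[list[Transcript], dict[str, str]]:
    """Step 2: eliminate transcripts with >=1 exon overlapping any catalog.

    Overlap is exon-level and strand-blind; a transcript wholly inside an
    annotated gene's intron survives this step.  Eliminated transcripts are
    tagged with the first overlapping catalog class in priority order
    coding > known_noncoding > pseudogene.
    """
    survivors, reasons = [], {}
    for t in transcripts:
        tag = None
        for cls in _CATALOG_PRIORITY:
            cat = catalogs.get(cls)
            if cat is None:
                continue
            hits = [
                h
                for s, e in t.exons
                for h in cat.overlapping(t.chrom, s, e)
                if exonic_overlap_bp(t, h) > 0
            ]
            if hits:
                tag = cls
                break
        if tag is None:
            survivors.append(t)
        else:
            reasons[t.transcript_id] = tag
    return survivors, reasons


def filter_coding_potential(
    transcripts: Sequence[Transcript],
    sequences: Mapping[str, str],
    model: TripletModel,
    cpc_labels: Mapping[str, str] | None = None,
) -> tuple[list[Transcript], dict[str, str]]:
    """Step 3: keep transcripts classified noncoding.

    When external per-transcript labels are provided (``cpc_labels``:
    id -> "coding"/"noncoding"), a survivor must be noncoding by both the
    triplet model and the external labels (intersection).
    """
    missing = [t.transcript_id for t in transcripts
               if t.transcript_id not in sequences]
    if missing:
        raise KeyError(f"missing sequences for transcripts: {missing[:10]}")
    survivors, reasons = [], {}
    for t in transcripts:
        label = classify(sequences[t.transcript_id], model)
        if label == "coding":
            reasons[t.transcript_id] = "coding_potential"
            continue
        if cpc_labels is not None and cpc_labels.get(
            t.transcript_id, "noncoding"
        ) == "coding":
            reasons[t.transcript_id] = "coding_potential_external"
            continue
        survivors.append(t)
    return survivors, reasons


def filter_structure(
    transcripts: Sequence[Transcript],
    min_exons: int = 2,
    min_length: int = 200,
) -> tuple[list[Transcript], dict[str, str]]:
    """Step 4: multi-exon transcripts longer than ``min_length`` nt.

    Exon count uses >= min_exons ("more than one exon"); length is strictly
    greater than min_length ("longer than 200 bases"), so a 200-nt
    transcript is eliminated.
    """
    survivors, reasons = [], {}
    for t in transcripts:
        if t.exon_count() < min_exons:
            reasons[t.transcript_id] = "single_exon"
        elif t.length() <= min_length:
            reasons[t.transcript_id] = "short"
        else:
            survivors.append(t)
    return survivors, reasons


def filter_intergenic(
    transcripts: Sequence[Transcript],
    coding_catalog: AnnotationCatalog,
    min_gap: int = 1000,
) -> tuple[list[Transcript], dict[str, str]]:
    """Step 5: intergenic transcripts at least ``min_gap`` bp from any
    protein-coding gene (span-to-span, strand-blind)."""
    survivors, reasons = [], {}
    for t in transcripts:
        if distance_to_nearest(t, coding_catalog) >= min_gap:
            survivors.append(t)
        else:
            reasons[t.transcript_id] = "near_coding_gene"
    return survivors, reasons


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(
    assembled: Sequence[Transcript],
    expr: pd.DataFrame,
    coverage: Mapping[str, float],
    sequences: Mapping[str, str],
    catalogs: Mapping[str, AnnotationCatalog],
    model: TripletModel,
    config=None,
    cpc_labels: Mapping[str, str] | None = None,
) -> tuple[LincRNACatalog, FilterLedger]:
    """Run the five filters in order and merge survivors into gene loci.

    ``catalogs`` must contain a ``coding`` catalog (used by steps 2 and 5)
    and may contain ``known_noncoding`` and ``pseudogene`` catalogs.
    """
    from .io import RunConfig

    cfg = config or RunConfig()
    ledger = FilterLedger()
    current = list(assembled)

    out, reasons = filter_expression(
        current, expr, coverage, cfg.min_fpkm, cfg.min_coverage
    )
    ledger.record("1_expression", current, out, reasons)
    current = out

    out, reasons = filter_annotation_overlap(current, catalogs)
    ledger.record("2_annotation_overlap", current, out, reasons)
    current = out

    out, reasons = filter_coding_potential(current, sequences, model, cpc_labels)
    ledger.record("3_coding_potential", current, out, reasons)
    current = out

    out, reasons = filter_structure(current, cfg.min_exons, cfg.min_length)
    ledger.record("4_structure", current, out, reasons)
    current = out

    out, reasons = filter_intergenic(
        current, catalogs["coding"], cfg.intergenic_gap
    )
    ledger.record("5_intergenic", current, out, reasons)

    merged = merge_transcripts([out])
    merged = [
        Transcript(
            transcript_id=t.transcript_id,
            gene_id=t.gene_id,
            chrom=t.chrom,
            strand=t.strand,
            exons=t.exons,
            biotype="lincRNA",
            source=t.source,
        )
        for t in merged
    ]
    catalog = LincRNACatalog(
        merged, provenance={t.gene_id: "novel" for t in merged}
    )
    return catalog, ledger


def combine_with_documented(
    novel: LincRNACatalog, documented: Sequence[Transcript]
) -> LincRNACatalog:
    """Union the novel catalog with documented lincRNAs at the gene level.

    A novel locus with >=1 bp exonic overlap to a documented lincRNA is
    deduplicated into the documented entry (the documented annotation wins);
    disjoint loci are concatenated, so disjoint inputs add their gene
    counts.
    """
    doc_catalog = AnnotationCatalog(list(documented))
    doc_ids = {t.gene_id for t in documented}
    kept_novel = []
    for gene_id, transcripts in novel.loci.items():
        dup = any(
            exonic_overlap_bp(t, h) > 0
            for t in transcripts
            for s, e in t.exons
            for h in doc_catalog.overlapping(t.chrom, s, e)
        )
        if not dup:
            kept_novel.extend(transcripts)
    combined = list(documented) + kept_novel
    provenance = {gid: "documented" for gid in doc_ids}
    provenance.update({t.gene_id: "novel" for t in kept_novel})
    return LincRNACatalog(combined, provenance)
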