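"""Genomic data model: transcripts, annotation catalogs, interval arithmetic.

Coordinates are 0-based half-open (BED convention) throughout the in-memory
model; GTF readers/writers convert at the boundary.  A :class:`Transcript` is
the unit that flows through every pipeline stage: a stranded, multi- or
single-exon structure on one chromosome with a biotype label.

Intron-chain identity is the workhorse comparison: two multi-exon transcripts
with identical intron coordinates are considered the same underlying transcript
regardless of how far their terminal exons extend (the cuffcompare ``=`` class
code, terminus-tolerant).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

from intervaltree import IntervalTree

BIOTYPES = ("coding", "known_noncoding", "pseudogene", "unannotated", "lincRNA")


class MatchLevel(Enum):
    """How well a query transcript reproduces a reference transcript."""

    FULL = "full"
    PARTIAL = "partial"
    NONE = "none"

    def __ge__(self, other: "MatchLevel") -> bool:
        order = {"none": 0, "partial": 1, "full": 2}
        return order[self.value] >= order[other.value]


@dataclass(frozen=True)
class Transcript:
    """A stranded exon chain on one chromosome.

    Parameters
    ----------
    transcript_id, gene_id : str
        Stable identifiers; ``gene_id`` groups isoforms of one locus.
    chrom : str
    strand : str
        ``"+"`` or ``"-"``.
    exons : tuple of (int, int)
        Sorted, non-overlapping, 0-based half-open intervals.
    biotype : str
        One of ``coding``, ``known_noncoding``, ``pseudogene``,
        ``unannotated``, ``lincRNA``.
    source : str
        Free-form provenance tag (assembler/sample).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "unannotated"
    source: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not exons:
            raise ValueError("transcript must have at least one exon")
        for s, e in exons:
            if e <= s:
                raise ValueError(f"exon end must exceed start, got ({s}, {e})")
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError("exons must be sorted and non-overlapping")
        object.__setattr__(self, "exons", exons)

    # -- derived structure -------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def length(self) -> int:
        """Mature (spliced) length in nucleotides."""
        return sum(e - s for s, e in self.exons)

    def exon_count(self) -> int:
        return len(self.exons)

    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, 0-based half-open."""
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        )

    def intron_chain_key(self) -> tuple:
        return (self.chrom, self.strand, self.introns())


@dataclass
class AnnotationCatalog:
    """An indexed collection of transcripts supporting interval lookup.

    Two indexes per chromosome: one over individual exons (for the exonic
    overlap filter) and one over whole gene spans (for the intergenic
    distance filter).
    """

    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._exon_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._gene_spans: dict[str, list[tuple[int, int, str]]] = {}
        for t in self.transcripts:
            for s, e in t.exons:
                self._exon_trees[t.chrom].addi(s, e, t)
        spans: dict[tuple[str, str], tuple[int, int]] = {}
        for t in self.transcripts:
            key = (t.chrom, t.gene_id)
            s, e = spans.get(key, (t.start, t.end))
            spans[key] = (min(s, t.start), max(e, t.end))
        by_chrom: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
        for (chrom, gid), (s, e) in spans.items():
            by_chrom[chrom].append((s, e, gid))
        for chrom in by_chrom:
            by_chrom[chrom].sort()
        self._gene_spans = dict(by_chrom)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts)

    def overlapping(
        self,
        chrom: str,
        start: int,
        end: int,
        strand: str | None = None,
    ) -> list[Transcript]:
        """Transcripts with >=1 exon overlapping [start, end) on ``chrom``.

        ``strand=None`` queries strand-blind.
        """
        hits = {
            iv.data.transcript_id: iv.data
            for iv in self._exon_trees.get(chrom, IntervalTree()).overlap(start, end)
            if strand is None or iv.data.strand == strand
        }
        return list(hits.values())

    def gene_spans(self, chrom: str) -> list[tuple[int, int, str]]:
        """Sorted (start, end, gene_id) spans for ``chrom``."""
        return self._gene_spans.get(chrom, [])


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def exonic_overlap_bp(
    a: Transcript, b: Transcript, same_strand_required: bool = False
) -> int:
    """Total bases shared between any exon of ``a`` and any exon of ``b``.

    Returns 0 when chromosomes differ, or when ``same_strand_required`` is set
    and strands differ.  Half-open intervals: abutting exons share 0 bases.
    """
    if a.chrom != b.chrom:
        return 0
    if same_strand_required and a.strand != b.strand:
        return 0
    total = 0
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def match_level(query: Transcript, reference: Transcript) -> MatchLevel:
    """Classify how fully ``query`` reconstructs ``reference``.

    ``FULL``: same chromosome and strand with identical intron chains
    (terminal-exon lengths free to differ); intron-less pairs additionally
    need >=1 bp exonic overlap, since empty chains carry no positional
    information.  ``PARTIAL``: same chromosome/strand with >=1 shared intron
    or >=1 bp exonic overlap.  ``NONE`` otherwise.
    """
    if query.chrom != reference.chrom or query.strand != reference.strand:
        return MatchLevel.NONE
    qi, ri = query.introns(), reference.introns()
    overlap = exonic_overlap_bp(query, reference, same_strand_required=True)
    if qi == ri and (qi or overlap >= 1):
        return MatchLevel.FULL
    if set(qi) & set(ri) or overlap >= 1:
        return MatchLevel.PARTIAL
    return MatchLevel.NONE


# ---------------------------------------------------------------------------
# Merging transcript collections
# ---------------------------------------------------------------------------

def _merge_single_exon(group: list[Transcript]) -> list[Transcript]:
    """Chain same-strand single-exon transcripts by overlap; one rep per chain."""
    group = sorted(group, key=lambda t: t.span)
    out: list[Transcript] = []
    members: list[Transcript] = []
    cur_s, cur_e = group[0].span
    for t in group:
        if t.start < cur_e:  # overlap with the running chain
            cur_e = max(cur_e, t.end)
            members.append(t)
        else:
            out.append(_representative(members, ((cur_s, cur_e),)))
            members, (cur_s, cur_e) = [t], t.span
    out.append(_representative(members, ((cur_s, cur_e),)))
    return out


def _representative(members: list[Transcript], exons: tuple) -> Transcript:
    lead = min(members, key=lambda t: (t.transcript_id,))
    return replace(lead, exons=exons)


def merge_transcripts(
    sets: Iterable[Iterable[Transcript]],
) -> list[Transcript]:
    """Collapse redundant transcripts across assemblies into one combined set.

    Multi-exon transcripts are grouped by (chrom, strand, intron chain); the
    representative's terminal exons extend to the extreme termini observed in
    its group.  Single-exon transcripts are grouped by same-strand overlap
    chaining.  Gene ids are then reassigned by single-linkage clustering of
    representatives sharing >=1 bp of same-strand exonic overlap.

    Idempotent: merging the merged output returns it unchanged.
    """
    multi: dict[tuple, list[Transcript]] = defaultdict(list)
    single: dict[tuple[str, str], list[Transcript]] = defaultdict(list)
    for collection in sets:
        for t in collection:
            if t.exon_count() > 1:
                multi[t.intron_chain_key()].append(t)
            else:
                single[(t.chrom, t.strand)].append(t)

    reps: list[Transcript] = []
    for (chrom, strand, introns), members in multi.items():
        first_start = min(t.start for t in members)
        last_end = max(t.end for t in members)
        bounds = [first_start] + [x for iv in introns for x in iv] + [last_end]
        exons = tuple(
            (bounds[i], bounds[i + 1]) for i in range(0, len(bounds), 2)
        )
        reps.append(_representative(members, exons))
    for members in single.values():
        reps.extend(_merge_single_exon(members))

    _assign_gene_ids(reps)
    reps.sort(key=lambda t: (t.chrom, t.start, t.end, t.transcript_id))
    return reps


def _assign_gene_ids(reps: list[Transcript]) -> None:
    """Single-linkage gene clustering: same-strand exon overlap joins loci."""
    by_key: dict[tuple[str, str], list[int]] = defaultdict(list)
    for i, t in enumerate(reps):
        by_key[(t.chrom, t.strand)].append(i)
    parent = list(range(len(reps)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for idxs in by_key.values():
        # sweep exons; overlap in genomic space on the same strand links loci
        events = sorted(
            (s, e, i) for i in idxs for s, e in reps[i].exons
        )
        active_end, active_i = -1, -1
        for s, e, i in events:
            if s < active_end:
                parent[find(i)] = find(active_i)
                active_end = max(active_end, e)
            else:
                active_end, active_i = e, i
    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(len(reps)):
        groups[find(i)].append(i)
    for members in groups.values():
        gid = min(reps[i].gene_id for i in members)
        for i in members:
            reps[i] = replace(reps[i], gene_id=gid)


def distance_to_nearest(t: Transcript, catalog: AnnotationCatalog) -> float:
    """Minimal span-to-span gap (bp) to any gene of ``catalog`` on t's chrom.

    Strand-blind; 0 when spans overlap; ``math.inf`` when the chromosome is
    empty in the catalog.
    """
    spans = catalog.gene_spans(t.chrom)
    if not spans:
        return math.inf
    best = math.inf
    for s, e, _ in spans:
        if e <= t.start:
            gap = t.start - e
        elif s >= t.end:
            gap = s - t.end
        else:
            return 0
        best = min(best, gap)
    return best
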