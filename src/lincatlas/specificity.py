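"""Tissue-specificity scoring and replicate-recurrence statistics.

The specificity score of an expression pattern p over T tissues is
``max_t 1 - sqrt(JSD(p, delta_t))`` where JSD is the Jensen-Shannon
divergence in bits and delta_t the idealized pattern of exclusive expression
in tissue t.  The score lives in [0, 1]: 1 for perfectly tissue-specific
expression, ~0.19 for uniform expression over six tissues.

Recurrence asks how reproducibly a transcript is re-assembled across
biological replicates: a hit in (tissue, replicate) is any assembled
transcript matching at level >= partial, and the recurrence of a transcript
is the maximum per-tissue hit count.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from .core import Transcript


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def js_divergence(p, q) -> float:
    """Jensen-Shannon divergence in bits: H((p+q)/2) - (H(p)+H(q))/2.

    Both arguments must be probability vectors of equal length (0*log0 = 0).
    The result lies in [0, 1] for base-2 logs.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("probability vectors must be non-negative")
    for v in (p, q):
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("input vectors must each sum to 1")
    m = 0.5 * (p + q)
    return _entropy_bits(m) - 0.5 * (_entropy_bits(p) + _entropy_bits(q))


@dataclass
class SpecificityResult:
    transcript_id: str
    js_score: float
    argmax_tissue: str
    is_specific: bool = False
    defined: bool = True


def specificity_score(
    expr_vector, tissues: list[str] | None = None, transcript_id: str = ""
) -> SpecificityResult:
    """Tissue-specificity score of one expression pattern.

    The pattern is normalized to a probability vector p and scored against
    every extremal pattern delta_t; the score is the best
    ``1 - sqrt(JSD(p, delta_t))`` and the argmax tissue the t achieving it
    (ties broken by tissue order).  All-zero vectors are flagged undefined.
    Scale-invariant: multiplying the pattern by c > 0 changes nothing.
    """
    e = np.asarray(expr_vector, dtype=float)
    if e.ndim != 1 or len(e) < 2:
        raise ValueError("expression vector must be 1-D over >=2 tissues")
    if (e < 0).any():
        raise ValueError("expression must be non-negative")
    names = tissues if tissues is not None else [str(i) for i in range(len(e))]
    total = e.sum()
    if total == 0:
        return SpecificityResult(transcript_id, float("nan"), "", defined=False)
    p = e / total
    best_score, best_t = -1.0, names[0]
    for t in range(len(e)):
        delta = np.zeros(len(e))
        delta[t] = 1.0
        score = 1.0 - np.sqrt(js_divergence(p, delta))
        if score > best_score + 1e-12:
            best_score, best_t = score, names[t]
    return SpecificityResult(transcript_id, float(best_score), best_t)


def score_matrix(expr_df) -> list[SpecificityResult]:
    """Per-row specificity over a (transcripts x tissues) FPKM DataFrame."""
    tissues = list(expr_df.columns)
    return [
        specificity_score(expr_df.loc[tid].to_numpy(), tissues, tid)
        for tid in expr_df.index
    ]


def classify_specific(
    results: list[SpecificityResult],
    cutoff: float = 0.5,
    biotypes: dict[str, str] | None = None,
) -> dict:
    """Mark results with js_score >= cutoff as tissue-specific.

    Mutates ``is_specific`` in place and returns a summary: the overall
    specific fraction (over defined scores), per-biotype fractions when a
    transcript->biotype map is supplied, and the specific id set.
    """
    defined = [r for r in results if r.defined]
    specific_ids = set()
    n_specific = 0
    for r in results:
        r.is_specific = bool(r.defined and r.js_score >= cutoff)
        if r.is_specific:
            n_specific += 1
            specific_ids.add(r.transcript_id)
    frac = n_specific / len(defined) if defined else float("nan")
    summary = {
        "fraction_specific": frac,
        "n_defined": len(defined),
        "n_undefined": len(results) - len(defined),
        "specific_ids": specific_ids,
    }
    if biotypes is not None:
        per: dict[str, list[SpecificityResult]] = defaultdict(list)
        for r in defined:
            per[biotypes.get(r.transcript_id, "unannotated")].append(r)
        summary["fraction_by_biotype"] = {
            bt: sum(r.is_specific for r in rs) / len(rs) for bt, rs in per.items()
        }
    return summary


def write_specificity_tsv(results: list[SpecificityResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tjs_score\targmax_tissue\tis_specific\n")
        for r in results:
            js = f"{r.js_score:.6f}" if r.defined else "NA"
            fh.write(f"{r.transcript_id}\t{js}\t{r.argmax_tissue}\t{int(r.is_specific)}\n")


# ---------------------------------------------------------------------------
# Recurrence
# ---------------------------------------------------------------------------

@dataclass
class RecurrenceResult:
    transcript_id: str
    recurrence: int
    per_tissue: dict[str, int]


class _SampleIndex:
    """Fast match_level >= partial membership test against one assembly."""

    def __init__(self, transcripts: list[Transcript]):
        self.chains = set()
        self.introns = set()
        self.exon_trees: dict[tuple[str, str], IntervalTree] = defaultdict(
            IntervalTree
        )
        for t in transcripts:
            introns = t.introns()
            if introns:
                self.chains.add(t.intron_chain_key())
            for iv in introns:
                self.introns.add((t.chrom, t.strand, iv))
            for s, e in t.exons:
                self.exon_trees[(t.chrom, t.strand)].addi(s, e)

    def hit(self, t: Transcript) -> bool:
        if t.introns() and t.intron_chain_key() in self.chains:
            return True
        for iv in t.introns():
            if (t.chrom, t.strand, iv) in self.introns:
                return True
        tree = self.exon_trees.get((t.chrom, t.strand))
        if tree is None:
            return False
        # half-open overlap of >=1 bp
        return any(tree.overlap(s, e) for s, e in t.exons)


def recurrence(
    novel: list[Transcript],
    assemblies: dict[tuple[str, int], list[Transcript]],
) -> tuple[list[RecurrenceResult], dict[int, int]]:
    """Replicate recurrence of each transcript across assembled samples.

    ``assemblies`` maps (tissue, replicate) to that sample's transcript
    list.  A transcript scores a hit in a sample when any assembled
    transcript there matches it at level partial or better; its recurrence
    is the maximum within-tissue hit count.  Returns per-transcript results
    and the histogram {recurrence value: transcript count} over 0..R.
    """
    indexes = {key: _SampleIndex(ts) for key, ts in assemblies.items()}
    tissues = sorted({t for t, _ in assemblies})
    replicates = sorted({r for _, r in assemblies})
    results = []
    histogram: dict[int, int] = {k: 0 for k in range(len(replicates) + 1)}
    for t in novel:
        per_tissue = {}
        for tissue in tissues:
            hits = sum(
                1
                for rep in replicates
                if (tissue, rep) in indexes and indexes[(tissue, rep)].hit(t)
            )
            per_tissue[tissue] = hits
        rec = max(per_tissue.values()) if per_tissue else 0
        results.append(RecurrenceResult(t.transcript_id, rec, per_tissue))
        histogram[rec] = histogram.get(rec, 0) + 1
    return results, histogram
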