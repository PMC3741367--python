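"""Nearest-coding-neighbor correlation and the GO-sharing randomization null.

If lincRNAs act in cis, their expression should track that of their nearest
protein-coding genes.  For each lincRNA we take the minimal span-gap coding
gene, correlate the two genes' log2(FPKM+1) profiles across tissues, and ask
whether highly correlated pairs (r >= 0.8 by default) share a GO biological
process — comparing the observed sharing fraction against randomly drawn
annotated gene pairs (10,000 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AnnotationCatalog, Transcript


@dataclass
class NeighborPair:
    lincrna_id: str
    coding_id: str
    gap_bp: int
    r: float
    shares_go: bool = False
    r_defined: bool = True


def _log_expr(expr: pd.DataFrame, gid: str) -> np.ndarray | None:
    if gid not in expr.index:
        return None
    return np.log2(expr.loc[gid].to_numpy(dtype=float) + 1.0)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def nearest_pairs(
    lincrnas: list[Transcript],
    coding_catalog: AnnotationCatalog,
    expr: pd.DataFrame,
) -> list[NeighborPair]:
    """One (lincRNA, nearest coding gene) pair per lincRNA locus.

    Distance is span-to-span gap, strand-blind; gap ties break to the
    leftmost gene start.  Pairs whose members lack expression rows are
    dropped; pairs with a constant profile get r = NaN and are flagged.
    Deterministic and independent of input order.
    """
    # collapse lincRNA transcripts to gene spans
    spans: dict[str, tuple[str, int, int]] = {}
    for t in sorted(lincrnas, key=lambda t: t.transcript_id):
        chrom, s, e = spans.get(t.gene_id, (t.chrom, t.start, t.end))
        spans[t.gene_id] = (t.chrom, min(s, t.start), max(e, t.end))
    pairs = []
    for gid in sorted(spans):
        chrom, start, end = spans[gid]
        best_gap, best = math.inf, None
        for gs, ge, coding_id in coding_catalog.gene_spans(chrom):
            gap = max(0, gs - end, start - ge)
            if gap < best_gap or (gap == best_gap and best and gs < best[0]):
                best_gap, best = gap, (gs, coding_id)
        if best is None:
            continue
        x = _log_expr(expr, gid)
        y = _log_expr(expr, best[1])
        if x is None or y is None:
            continue
        r = _pearson(x, y)
        pairs.append(
            NeighborPair(gid, best[1], int(best_gap), r,
                         r_defined=not math.isnan(r))
        )
    return pairs


def coding_coding_pairs(
    coding_catalog: AnnotationCatalog, expr: pd.DataFrame
) -> list[NeighborPair]:
    """Nearest-neighbor pairs among coding genes (the comparison group)."""
    pairs = []
    chroms = sorted({t.chrom for t in coding_catalog.transcripts})
    for chrom in chroms:
        spans = coding_catalog.gene_spans(chrom)
        for i, (s, e, gid) in enumerate(spans):
            best_gap, best_id = math.inf, None
            for j, (s2, e2, gid2) in enumerate(spans):
                if gid2 == gid:
                    continue
                gap = max(0, s2 - e, s - e2)
                if gap < best_gap:
                    best_gap, best_id = gap, gid2
            if best_id is None:
                continue
            x, y = _log_expr(expr, gid), _log_expr(expr, best_id)
            if x is None or y is None:
                continue
            r = _pearson(x, y)
            pairs.append(NeighborPair(gid, best_id, int(best_gap), r,
                                      r_defined=not math.isnan(r)))
    return pairs


def random_pairs(
    gene_ids: list[str], expr: pd.DataFrame, n: int, seed: int
) -> list[NeighborPair]:
    """Uniformly drawn unordered gene pairs with expression rows (seeded)."""
    rng = np.random.default_rng(seed)
    ids = sorted(g for g in gene_ids if g in expr.index)
    if len(ids) < 2:
        raise ValueError("need >=2 genes with expression for random pairs")
    out = []
    for _ in range(n):
        a, b = rng.choice(len(ids), size=2, replace=False)
        x, y = _log_expr(expr, ids[a]), _log_expr(expr, ids[b])
        r = _pearson(x, y)
        out.append(NeighborPair(ids[a], ids[b], -1, r,
                                r_defined=not math.isnan(r)))
    return out


def pair_distributions(
    pairs_linc_coding: list[NeighborPair],
    pairs_coding_coding: list[NeighborPair],
    random: list[NeighborPair],
) -> dict:
    """Empirical r-CDFs and medians for the three pair groups."""
    groups = {
        "linc_coding": pairs_linc_coding,
        "coding_coding": pairs_coding_coding,
        "random": random,
    }
    out = {}
    for name, pairs in groups.items():
        if not pairs:
            raise ValueError(f"empty pair group {name!r}")
        rs = np.sort([p.r for p in pairs if p.r_defined])
        out[name] = {
            "r_sorted": rs,
            "median_r": float(np.median(rs)) if len(rs) else float("nan"),
            "n": len(pairs),
        }
    return out


def summarize_high_corr(
    pairs: list[NeighborPair], r_cutoff: float = 0.8, strict: bool = False
) -> dict:
    """Fractions of highly correlated and GO-sharing pairs.

    frac_high_r = share of pairs with r >= cutoff (or > with ``strict``);
    frac_shared_among_high = share of those that share a GO term.
    """
    n = len(pairs)
    high = [
        p for p in pairs
        if p.r_defined and (p.r > r_cutoff if strict else p.r >= r_cutoff)
    ]
    shared = [p for p in high if p.shares_go]
    return {
        "n_pairs": n,
        "n_high_r": len(high),
        "n_shared": len(shared),
        "frac_high_r": len(high) / n if n else float("nan"),
        "frac_shared_among_high": len(shared) / len(high) if high else float("nan"),
    }


def shared_go_test(
    pairs: list[NeighborPair],
    go: dict[str, set],
    r_cutoff: float = 0.8,
    n_random: int = 10000,
    seed: int = 0,
    strict: bool = False,
) -> dict:
    """Observed vs random GO sharing among highly correlated neighbor pairs.

    ``go`` must cover the coding genes and contain the lincRNAs' inherited
    (module-derived) terms.  A pair shares GO when both members are
    annotated and their term sets intersect.  The null draws ``n_random``
    uniform pairs of annotated genes (seeded) and ``empirical_p`` is the
    binomial upper-tail probability of the observed sharing count under the
    null sharing fraction.
    """
    for p in pairs:
        terms_a = go.get(p.lincrna_id, set())
        terms_b = go.get(p.coding_id, set())
        p.shares_go = bool(terms_a and terms_b and terms_a & terms_b)
    obs = summarize_high_corr(pairs, r_cutoff, strict)

    rng = np.random.default_rng(seed)
    annotated = sorted(g for g in go if go[g])
    if len(annotated) < 2:
        raise ValueError("need >=2 annotated genes for the null")
    null_shared = 0
    idx = rng.integers(0, len(annotated), size=(n_random, 2))
    for a, b in idx:
        if a == b:
            b = (b + 1) % len(annotated)
        if go[annotated[a]] & go[annotated[b]]:
            null_shared += 1
    null_frac = null_shared / n_random

    k, m = obs["n_shared"], obs["n_high_r"]
    if m:
        from scipy.stats import binom

        empirical_p = float(binom.sf(k - 1, m, null_frac)) if k else 1.0
    else:
        empirical_p = float("nan")
    return {
        **obs,
        "null_frac": null_frac,
        "empirical_p": empirical_p,
    }


def write_pairs_tsv(pairs: list[NeighborPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("lincrna_id\tcoding_id\tgap_bp\tr\tshares_go\n")
        for p in pairs:
            r = f"{p.r:.6f}" if p.r_defined else "NA"
            fh.write(f"{p.lincrna_id}\t{p.coding_id}\t{p.gap_bp}\t{r}\t{int(p.shares_go)}\n")
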