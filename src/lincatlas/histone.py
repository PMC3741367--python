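"""TSS-centered metagene profiles from piecewise-constant signal tracks.

A :class:`SignalTrack` is what a bedGraph file describes: disjoint, sorted
intervals per chromosome carrying a float value, implicitly 0 elsewhere.
Queries integrate the track exactly (no interpolation), so a metagene bin
mean is the track integral over the bin divided by the bin width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AnnotationCatalog, Transcript


class SignalTrack:
    """Piecewise-constant genomic signal with exact integral queries."""

    def __init__(self, intervals: dict[str, list[tuple[int, int, float]]]):
        self.intervals = intervals
        self._cum: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, ivs in intervals.items():
            starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
            ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
            vals = np.array([v for _, _, v in ivs], dtype=float)
            cum = np.concatenate([[0.0], np.cumsum(vals * (ends - starts))])
            self._cum[chrom] = (starts, ends, np.concatenate([vals, [0.0]]))
            # cumulative integral up to each interval start
            self._cumint = getattr(self, "_cumint", {})
            self._cumint[chrom] = cum

    def _integral_to(self, chrom: str, pos: int) -> float:
        """Integral of the track over [-inf, pos)."""
        starts, ends, vals = self._cum[chrom]
        cum = self._cumint[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0:
            return 0.0
        partial = vals[i] * max(0, min(pos, ends[i]) - starts[i])
        return float(cum[i] + partial)

    def integral(self, chrom: str, start: int, end: int) -> float:
        """Exact integral of the signal over [start, end)."""
        if end <= start or chrom not in self._cum:
            return 0.0
        return self._integral_to(chrom, end) - self._integral_to(chrom, start)

    def mean(self, chrom: str, start: int, end: int) -> float:
        if end <= start:
            return 0.0
        return self.integral(chrom, start, end) / (end - start)


@dataclass
class MetageneProfile:
    """Average signal in fixed-width bins around a set of anchors.

    ``bin_centers`` are bp offsets relative to the TSS, strand-oriented
    (negative = upstream of transcription).  ``mean`` holds per-bin averages
    over the regions contributing to that bin; ``n_regions`` is the anchor
    count.
    """

    bin_centers: np.ndarray
    mean: np.ndarray
    n_regions: int
    window: int
    bin_size: int

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("bin_center\tmean\tn\n")
            for c, m in zip(self.bin_centers, self.mean):
                fh.write(f"{int(c)}\t{m:.6g}\t{self.n_regions}\n")


def tss(t: Transcript) -> tuple[str, int, str]:
    """5'-most transcribed base: first exon start on '+', last exon end - 1
    on '-'."""
    if t.strand == "+":
        return (t.chrom, t.start, "+")
    return (t.chrom, t.end - 1, "-")


def metagene(
    track: SignalTrack,
    tss_list: list[tuple[str, int, str]],
    window: int = 5000,
    bin_size: int = 100,
) -> MetageneProfile:
    """Strand-oriented metagene profile over [-window, +window) around TSSs.

    Each region contributes the mean track value in each bin; the profile is
    the unweighted mean over regions.  Bins extending past the chromosome
    start (< 0) are excluded for that region only.
    """
    if window % bin_size != 0:
        raise ValueError("window must be a multiple of bin_size")
    if not tss_list:
        raise ValueError("empty TSS list")
    n_bins = 2 * window // bin_size
    offsets = np.arange(-window, window, bin_size)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for chrom, pos, strand in tss_list:
        for k, off in enumerate(offsets):
            if strand == "+":
                s = pos + off
            else:  # mirror around the TSS base: bin [off, off+bin) maps to
                # genomic [pos - off - bin + 1, pos - off + 1)
                s = pos - off - bin_size + 1
            e = s + bin_size
            if s < 0:
                continue
            sums[k] += track.mean(chrom, s, e)
            counts[k] += 1
    mean = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    centers = offsets + bin_size / 2
    return MetageneProfile(
        bin_centers=centers,
        mean=mean,
        n_regions=len(tss_list),
        window=window,
        bin_size=bin_size,
    )


def random_control(
    annotation: AnnotationCatalog,
    n: int,
    seed: int,
    lincrna_tss: list[tuple[str, int, str]] | None = None,
    genome_size: int | None = None,
    min_gap: int = 1000,
) -> list[tuple[str, int, str]]:
    """Random intergenic anchor positions for the control profile.

    Positions are sampled uniformly from intergenic space at least
    ``min_gap`` bp from any coding gene.  When ``lincrna_tss`` is given, the
    per-chromosome counts are matched to its chromosome distribution
    (stratified sampling); otherwise chromosomes are sampled in proportion to
    their intergenic space.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted({t.chrom for t in annotation.transcripts}) or ["chr1"]
    # allowed space per chromosome = complement of coding spans +- min_gap
    allowed: dict[str, list[tuple[int, int]]] = {}
    for chrom in chroms:
        spans = [
            (s, e)
            for s, e, _ in annotation.gene_spans(chrom)
        ]
        size = genome_size or (max(e for _, e in spans) + 10 * min_gap if spans else 10 * min_gap)
        blocked = sorted((max(0, s - min_gap), e + min_gap) for s, e in spans)
        free: list[tuple[int, int]] = []
        cursor = 0
        for s, e in blocked:
            if s > cursor:
                free.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < size:
            free.append((cursor, size))
        allowed[chrom] = free

    def draw(chrom: str, k: int) -> list[tuple[str, int, str]]:
        free = allowed[chrom]
        if not free or k == 0:
            return []
        lens = np.array([e - s for s, e in free], dtype=float)
        probs = lens / lens.sum()
        picks = rng.choice(len(free), size=k, p=probs)
        out = []
        for i in picks:
            s, e = free[i]
            pos = int(rng.integers(s, e))
            strand = "+" if rng.random() < 0.5 else "-"
            out.append((chrom, pos, strand))
        return out

    result: list[tuple[str, int, str]] = []
    if lincrna_tss:
        from collections import Counter

        freq = Counter(c for c, _, _ in lincrna_tss)
        total = sum(freq.values())
        for chrom in sorted(freq):
            k = round(n * freq[chrom] / total)
            result.extend(draw(chrom, k))
        while len(result) < n:
            result.extend(draw(chroms[0], 1))
        result = result[:n]
    else:
        lens = np.array(
            [sum(e - s for s, e in allowed[c]) for c in chroms], dtype=float
        )
        probs = lens / lens.sum()
        counts = rng.multinomial(n, probs)
        for chrom, k in zip(chroms, counts):
            result.extend(draw(chrom, int(k)))
    return result
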