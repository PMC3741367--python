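"""Readers and writers for the standard formats the pipeline consumes.

GTF is read with strict per-line validation: the first structurally invalid
record raises :class:`FormatError` naming the line number, rather than being
silently skipped.  GTF coordinates (1-based inclusive) are converted to the
internal 0-based half-open convention on read and back on write.
"""

from __future__ import annotations


import warnings
from collections import defaultdict
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .core import Transcript


class FormatError(ValueError):
    """A structurally invalid record in an input file."""


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, with the published defaults.

    min_length/min_exons and intergenic_gap implement the "longer than 200
    bases", "more than one exon" and "at least 1 kb from any protein-coding
    gene" rules; js_cutoff, corr_cutoff, mcl_inflation, min_module_size and
    n_random_pairs carry the printed constants of the downstream analyses.
    """

    min_fpkm: float = 1.0
    min_coverage: float = 3.0
    min_length: int = 200
    min_exons: int = 2
    intergenic_gap: int = 1000
    js_cutoff: float = 0.5
    corr_cutoff: float = 0.8
    edge_threshold: float = 0.9
    mcl_inflation: float = 1.8
    min_module_size: int = 6
    n_random_pairs: int = 10000
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        if self.min_fpkm < 0 or self.min_coverage < 0:
            raise ValueError("expression thresholds must be non-negative")
        if not 0 <= self.js_cutoff <= 1:
            raise ValueError("js_cutoff must lie in [0, 1]")
        if not 0 <= self.corr_cutoff <= 1:
            raise ValueError("corr_cutoff must lie in [0, 1]")
        if self.mcl_inflation <= 1:
            raise ValueError("mcl_inflation must exceed 1")
        if self.min_exons < 1 or self.min_length < 0 or self.intergenic_gap < 0:
            raise ValueError("structural thresholds out of range")
        if self.min_module_size < 1 or self.n_random_pairs < 1:
            raise ValueError("module/null sizes must be positive")
        return self

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data).validate()


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _parse_attributes(raw: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise FormatError(f"line {lineno}: malformed attribute {chunk!r}")
        key, value = chunk.split(" ", 1)
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> list[Transcript]:
    """Read exon features of a GTF file into :class:`Transcript` models.

    Non-exon feature rows are ignored.  Raises :class:`FormatError` naming
    the line number of the first malformed record; exon rows missing a
    ``transcript_id`` attribute are malformed.
    """
    exons: dict[str, list[tuple[int, int]]] = defaultdict(list)
    meta: dict[str, tuple[str, str, str, str, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, source, feature, start, end, _score, strand, _frame, raw = fields
            if feature != "exon":
                continue
            try:
                s, e = int(start), int(end)
            except ValueError:
                raise FormatError(f"line {lineno}: non-integer coordinates")
            if e < s or s < 1:
                raise FormatError(f"line {lineno}: invalid interval {start}-{end}")
            if strand not in ("+", "-"):
                raise FormatError(f"line {lineno}: invalid strand {strand!r}")
            attrs = _parse_attributes(raw, lineno)
            if "transcript_id" not in attrs:
                raise FormatError(f"line {lineno}: exon missing transcript_id")
            tid = attrs["transcript_id"]
            gid = attrs.get("gene_id", tid)
            biotype = attrs.get("biotype", "unannotated")
            if tid not in meta:
                meta[tid] = (gid, chrom, strand, biotype,
                             "" if source == "." else source)
                order.append(tid)
            exons[tid].append((s - 1, e))  # 1-based inclusive -> 0-half-open
    out = []
    for tid in order:
        gid, chrom, strand, biotype, source = meta[tid]
        out.append(
            Transcript(
                transcript_id=tid,
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=tuple(sorted(exons[tid])),
                biotype=biotype,
                source=source,
            )
        )
    return out


def write_gtf(transcripts: list[Transcript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            for s, e in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'biotype "{t.biotype}";'
                )
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            t.source or ".",
                            "exon",
                            str(s + 1),
                            str(e),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# BED12
# ---------------------------------------------------------------------------

def write_bed12(transcripts: list[Transcript], path: str | Path) -> None:
    """Write one BED12 row per transcript (catalog output form)."""
    with open(path, "w") as fh:
        for t in transcripts:
            sizes = ",".join(str(e - s) for s, e in t.exons) + ","
            starts = ",".join(str(s - t.start) for s, _ in t.exons) + ","
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        str(t.start),
                        str(t.end),
                        t.transcript_id,
                        "0",
                        t.strand,
                        str(t.start),
                        str(t.end),
                        "0",
                        str(t.exon_count()),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def read_bed12(path: str | Path) -> list[Transcript]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"line {lineno}: expected 12 BED fields")
            chrom, start, _end, name, _score, strand = fields[:6]
            n = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n or len(starts) != n:
                raise FormatError(f"line {lineno}: blockCount mismatch")
            s0 = int(start)
            exons = tuple(
                (s0 + off, s0 + off + sz) for off, sz in zip(starts, sizes)
            )
            out.append(
                Transcript(
                    transcript_id=name,
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Expression matrix / GO / FASTA / bedGraph
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """FPKM matrix, rows = transcripts/genes, columns = tissues.

    Missing cells become 0 (with a warning reporting how many); negative
    values are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        warnings.warn(f"{n_missing} missing expression cells set to 0")
        df = df.fillna(0.0)
    df = df.astype(float)
    if (df.to_numpy() < 0).any():
        raise FormatError("negative FPKM values in expression matrix")
    return df


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA to id->sequence, uppercased; non-ACGT characters are retained
    and reported in a warning."""
    seqs: dict[str, str] = {}
    flagged = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if set(seq) - set("ACGT"):
            flagged += 1
        seqs[rec.id] = seq
    if flagged:
        warnings.warn(f"{flagged} sequences contain non-ACGT characters")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_go_tsv(path: str | Path) -> dict[str, set[str]]:
    """Two-column (gene_id, term_id) TSV to gene -> set-of-terms map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"],
                     dtype=str, comment="#")
    if df.isna().any().any():
        raise FormatError("GO map contains incomplete rows")
    out: dict[str, set[str]] = defaultdict(set)
    for gene, term in zip(df["gene_id"], df["term_id"]):
        out[gene].add(term)
    return dict(out)


def write_go_tsv(go: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(go):
            for term in sorted(go[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_bedgraph(path: str | Path) -> "SignalTrack":
    """Read a bedGraph file into a piecewise-constant SignalTrack.

    Intervals are sorted per chromosome; overlapping intervals are rejected.
    """
    from .histone import SignalTrack

    rows = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    track: dict[str, list[tuple[int, int, float]]] = defaultdict(list)
    for chrom, start, end, value in rows.itertuples(index=False):
        track[chrom].append((int(start), int(end), float(value)))
    for chrom, ivs in track.items():
        ivs.sort()
        for (s0, e0, _), (s1, _, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise FormatError(
                    f"overlapping bedGraph intervals on {chrom} at {s1}"
                )
    return SignalTrack({c: ivs for c, ivs in track.items()})


def write_bedgraph(track: "SignalTrack", path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.intervals):
            for s, e, v in track.intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def fpkm_from_counts(
    counts: pd.DataFrame, lengths: Mapping[str, int]
) -> pd.DataFrame:
    """FPKM = 1e9 * C / (N * L): fragments C on a transcript of length L bp,
    N total mapped fragments per column.  A plumbing surrogate for an
    assembler's abundance estimate when only counts are available."""
    L = np.array([lengths[i] for i in counts.index], dtype=float)
    N = counts.sum(axis=0).to_numpy(dtype=float)
    return counts * 1e9 / np.outer(L, N)
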