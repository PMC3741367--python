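"""Alignment-free coding-potential classification from triplet transitions.

The classifier profiles *adjoining nucleotide triplets*: a sequence read in a
fixed frame is a chain of non-overlapping triplets (codon-style), and coding
sequences show strongly skewed statistics of which triplet follows which,
while noncoding sequences are close to uniform.  Training estimates, per
class, the 64x64 transition probabilities of adjacent triplets and stores
their log2 odds ratio.  Scoring slides over the three forward frames, scores
every adjacent triplet pair, and takes the maximal-scoring contiguous segment
(Kadane) — the most-coding-like stretch — maximized over frames.

The decision threshold is calibrated on the training data (the cut
maximizing balanced accuracy over the training scores); see docs/methods.md
for why a raw zero threshold cannot work for the best-segment statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

_BASE = {"A": 0, "C": 1, "G": 2, "T": 3}
TRIPLETS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
]  # lexicographic AAA..TTT


@dataclass
class TripletModel:
    """64x64 log2-odds table over adjacent non-overlapping triplet pairs.

    Entry (i, j) = log2(P_coding(j | i) / P_noncoding(j | i)), rows/columns
    in lexicographic AAA..TTT order.  ``threshold`` is the decision boundary
    applied to the best-segment score.
    """

    logodds: np.ndarray
    pseudocount: float = 1.0
    threshold: float = 0.0

    def __post_init__(self) -> None:
        self.logodds = np.asarray(self.logodds, dtype=float)
        if self.logodds.shape != (64, 64):
            raise ValueError("logodds table must be 64x64")
        if not np.isfinite(self.logodds).all():
            raise ValueError("logodds entries must be finite")

    def to_tsv(self, path: str | Path) -> None:
        header = "triplet\t" + "\t".join(TRIPLETS)
        lines = [header]
        for i, trip in enumerate(TRIPLETS):
            lines.append(
                trip + "\t" + "\t".join(f"{x:.10g}" for x in self.logodds[i])
            )
        lines.append(f"#pseudocount\t{self.pseudocount:.10g}")
        lines.append(f"#threshold\t{self.threshold:.10g}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TripletModel":
        pseudo, thresh = 1.0, 0.0
        rows = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#pseudocount"):
                pseudo = float(line.split("\t")[1])
            elif line.startswith("#threshold"):
                thresh = float(line.split("\t")[1])
            elif line.startswith("triplet"):
                continue
            else:
                rows.append([float(x) for x in line.split("\t")[1:]])
        return cls(np.array(rows), pseudocount=pseudo, threshold=thresh)


def _triplet_indices(seq: str, frame: int) -> np.ndarray:
    """Indices of non-overlapping triplets of ``seq`` read in ``frame``."""
    usable = seq[frame:]
    n = len(usable) // 3
    if n == 0:
        return np.empty(0, dtype=np.int64)
    arr = np.frombuffer(usable[: 3 * n].encode(), dtype=np.uint8)
    digits = np.full(arr.shape, -1, dtype=np.int64)
    for base, d in _BASE.items():
        digits[arr == ord(base)] = d
    if (digits < 0).any():
        raise ValueError("sequence contains non-ACGT characters")
    digits = digits.reshape(n, 3)
    return digits[:, 0] * 16 + digits[:, 1] * 4 + digits[:, 2]


def _transition_counts(seqs: Iterable[str]) -> tuple[np.ndarray, int]:
    """Frame-0 adjacent-triplet transition counts; returns (counts, skipped)."""
    counts = np.zeros((64, 64), dtype=float)
    skipped = 0
    for seq in seqs:
        seq = seq.upper()
        if len(seq) < 6 or set(seq) - set("ACGT"):
            skipped += 1
            continue
        idx = _triplet_indices(seq, 0)
        if len(idx) < 2:
            skipped += 1
            continue
        np.add.at(counts, (idx[:-1], idx[1:]), 1.0)
    return counts, skipped


def train_triplet_model(
    coding_seqs: Sequence[str],
    noncoding_seqs: Sequence[str],
    pseudocount: float = 1.0,
    calibrate_threshold: bool = True,
) -> TripletModel:
    """Estimate the triplet-transition log-odds table from labelled sequences.

    Transitions are counted in frame 0 only (training sequences are assumed
    in-frame for the coding class); rows are pseudocount-smoothed to
    conditional probabilities before taking log2 odds.  Sequences shorter
    than 6 nt or containing non-ACGT characters are skipped (a warning
    reports how many).

    With ``calibrate_threshold`` the decision boundary is set to the cut
    maximizing balanced accuracy over the training best-segment scores;
    otherwise it stays at 0.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    c_counts, c_skip = _transition_counts(coding_seqs)
    n_counts, n_skip = _transition_counts(noncoding_seqs)
    if c_skip or n_skip:
        warnings.warn(
            f"skipped {c_skip} coding and {n_skip} noncoding training "
            "sequences (too short or non-ACGT)"
        )
    if c_counts.sum() == 0 or n_counts.sum() == 0:
        raise ValueError("no usable training sequences in one of the classes")

    def row_probs(counts: np.ndarray) -> np.ndarray:
        sm = counts + pseudocount
        return sm / sm.sum(axis=1, keepdims=True)

    logodds = np.log2(row_probs(c_counts) / row_probs(n_counts))
    model = TripletModel(logodds, pseudocount=pseudocount, threshold=0.0)
    if calibrate_threshold:
        def scores_of(seqs: Sequence[str]) -> np.ndarray:
            return np.array([
                score_sequence(s, model)[0]
                for s in seqs
                if len(s) >= 9 and not set(s.upper()) - set("ACGT")
            ])

        sc, sn = scores_of(coding_seqs), scores_of(noncoding_seqs)
        if len(sc) and len(sn):
            model.threshold = _balanced_threshold(sc, sn)
    return model


def _balanced_threshold(coding_scores: np.ndarray,
                        noncoding_scores: np.ndarray) -> float:
    """Threshold maximizing balanced accuracy on the training scores.

    Candidates are midpoints between adjacent distinct scores; the lowest
    maximizer is taken for determinism.
    """
    all_scores = np.unique(np.concatenate([coding_scores, noncoding_scores]))
    if len(all_scores) == 1:
        return float(all_scores[0])
    candidates = 0.5 * (all_scores[:-1] + all_scores[1:])
    best_t, best_acc = candidates[0], -1.0
    for t in candidates:
        acc = 0.5 * (
            (coding_scores > t).mean() + (noncoding_scores <= t).mean()
        )
        if acc > best_acc + 1e-12:
            best_acc, best_t = acc, t
    return float(best_t)


def _kadane(scores: np.ndarray) -> tuple[float, tuple[int, int]]:
    """Maximal-sum contiguous subarray, empty segment allowed (0, (0, 0)).

    Returns (best_sum, (start, end)) with half-open step indices; ties go to
    the leftmost, shortest segment.
    """
    best, best_seg = 0.0, (0, 0)
    cur, cur_start = 0.0, 0
    for k, x in enumerate(scores):
        if cur <= 0:
            cur, cur_start = 0.0, k
        cur += x
        if cur > best:
            best, best_seg = cur, (cur_start, k + 1)
    return best, best_seg


def score_sequence(
    seq: str, model: TripletModel
) -> tuple[float, int, tuple[int, int]]:
    """Best-segment coding score of ``seq`` under ``model``.

    For each forward frame, per-step scores s_k = logodds(t_k, t_{k+1}) over
    consecutive non-overlapping triplets; the frame's score is the maximal
    contiguous segment sum (empty segment = 0).  Returns
    (score, best_frame, (segment_start, segment_end)) with the segment in
    step indices of the winning frame; ties break to the lower frame, then
    the leftmost segment.  Trailing bases beyond the last full triplet of a
    frame never affect the score.
    """
    seq = seq.upper()
    if len(seq) < 9:
        raise ValueError("sequence shorter than 9 nt cannot be scored")
    best = (-np.inf, 0, (0, 0))
    for frame in range(3):
        idx = _triplet_indices(seq, frame)
        if len(idx) < 2:
            steps = np.empty(0)
        else:
            steps = model.logodds[idx[:-1], idx[1:]]
        score, seg = _kadane(steps)
        if score > best[0]:
            best = (score, frame, seg)
    return best


def classify(seq: str, model: TripletModel) -> str:
    """``"coding"`` iff the best-segment score exceeds the model threshold."""
    score, _, _ = score_sequence(seq, model)
    return "coding" if score > model.threshold else "noncoding"


class TripletCodingClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn estimator wrapping the triplet log-odds scorer.

    Parameters
    ----------
    pseudocount : float, default 1.0
        Additive smoothing of the transition counts.
    threshold : float or None, default None
        Decision boundary on the best-segment score.  ``None`` calibrates it
        from the training data (midpoint of class median scores).

    Attributes
    ----------
    model_ : TripletModel
    classes_ : ndarray of ["coding", "noncoding"]
    """

    def __init__(self, pseudocount: float = 1.0, threshold: float | None = None):
        self.pseudocount = pseudocount
        self.threshold = threshold

    def fit(self, X: Sequence[str], y: Sequence[str]):
        y = np.asarray(y)
        labels = set(y)
        if not labels <= {"coding", "noncoding"}:
            raise ValueError("labels must be 'coding' or 'noncoding'")
        coding = [s for s, lab in zip(X, y) if lab == "coding"]
        noncoding = [s for s, lab in zip(X, y) if lab == "noncoding"]
        self.model_ = train_triplet_model(
            coding,
            noncoding,
            pseudocount=self.pseudocount,
            calibrate_threshold=self.threshold is None,
        )
        if self.threshold is not None:
            self.model_.threshold = self.threshold
        self.classes_ = np.array(["coding", "noncoding"])
        return self

    def decision_function(self, X: Sequence[str]) -> np.ndarray:
        """Signed distance of the best-segment score from the threshold
        (positive = coding-like)."""
        check_is_fitted(self, "model_")
        return np.array(
            [score_sequence(s, self.model_)[0] - self.model_.threshold for s in X]
        )

    def predict(self, X: Sequence[str]) -> np.ndarray:
        return np.where(self.decision_function(X) > 0, "coding", "noncoding")

    def score_details(self, X: Sequence[str]):
        """Per-sequence (score, frame, segment) tuples."""
        check_is_fitted(self, "model_")
        return [score_sequence(s, self.model_) for s in X]
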