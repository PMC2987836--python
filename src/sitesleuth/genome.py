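"""Non-coding region extraction, negative-example sampling, genome scanning.

Negative training examples are length-L windows drawn uniformly without
replacement from the non-coding complement of the annotated coding
intervals.  Scanning scores every length-L window of every non-coding
region on both strands and keeps the windows the model classifies positive;
reverse-strand hits carry the forward-strand coordinates of the window and
strand '-'.  Window scoring for the linear SVM is done with per-position
k-mer lookup tables folded from the (standardized) weight vector, so a scan
is a handful of integer gathers per position rather than a full
feature-matrix construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from sitesleuth.mapping import (
    FeatureLayout,
    SiteOrigin,
    SiteSequence,
    encode_kmers,
    reverse_complement,
)
from sitesleuth.pwm import AdditiveScorer
from sitesleuth.svm import LinearClassifier
from sitesleuth.tables import FeatureTableBundle

logger = logging.getLogger(__name__)


@dataclass
class GenomeAnnotation:
    """Genome sequences plus coding intervals (0-based, half-open)."""

    sequences: dict[str, str]
    coding: dict[str, list[tuple[int, int]]]
    circular: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for seq_id, intervals in self.coding.items():
            if seq_id not in self.sequences:
                raise ValueError(f"coding intervals reference unknown sequence {seq_id!r}")
            n = len(self.sequences[seq_id])
            for s, e in intervals:
                if not (0 <= s < e <= n):
                    raise ValueError(
                        f"coding interval [{s}, {e}) out of bounds for {seq_id!r} (length {n})")

    def is_circular(self, seq_id: str) -> bool:
        return self.circular.get(seq_id, False)


@dataclass
class NonCodingRegions:
    """Disjoint non-coding intervals per sequence, sorted by start."""

    regions: list[tuple[str, int, int]]

    @property
    def total_length(self) -> int:
        return sum(e - s for _, s, e in self.regions)


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def extract_noncoding(annotation: GenomeAnnotation) -> NonCodingRegions:
    """Complement of the merged coding intervals on every sequence."""
    out: list[tuple[str, int, int]] = []
    for seq_id, seq in annotation.sequences.items():
        n = len(seq)
        pos = 0
        for s, e in _merge(annotation.coding.get(seq_id, [])):
            if s > pos:
                out.append((seq_id, pos, s))
            pos = max(pos, e)
        if pos < n:
            out.append((seq_id, pos, n))
        if not any(r[0] == seq_id for r in out):
            logger.warning("sequence %s is entirely coding; no non-coding regions", seq_id)
    return NonCodingRegions(regions=out)


def eligible_window_starts(annotation: GenomeAnnotation, regions: NonCodingRegions,
                           L: int) -> list[tuple[str, int]]:
    """Starts of length-L windows wholly inside a region with +-1 context.

    Context may come from adjacent genome sequence outside the region; only
    the termini of linear sequences lack context (circular sequences wrap).
    """
    starts: list[tuple[str, int]] = []
    for seq_id, s, e in regions.regions:
        n = len(annotation.sequences[seq_id])
        circ = annotation.is_circular(seq_id)
        for start in range(s, e - L + 1):
            if not circ and (start < 1 or start + L > n - 1):
                continue
            starts.append((seq_id, start))
    return starts


def _window_site(annotation: GenomeAnnotation, seq_id: str, start: int, L: int) -> SiteSequence:
    seq = annotation.sequences[seq_id]
    n = len(seq)
    left = seq[(start - 1) % n] if annotation.is_circular(seq_id) else seq[start - 1]
    right = seq[(start + L) % n] if annotation.is_circular(seq_id) else seq[start + L]
    return SiteSequence(core=seq[start:start + L], left_context=left,
                        right_context=right,
                        origin=SiteOrigin(seq_id, start, start + L, "+"))


def sample_negative_windows(annotation: GenomeAnnotation, regions: NonCodingRegions,
                            L: int, count: int = 10000, seed: int = 0,
                            exclude: Sequence[tuple[str, int, int]] = ()) -> list[SiteSequence]:
    """Uniform sample, without replacement, of eligible non-coding windows.

    ``exclude`` removes windows overlapping the given intervals (used to keep
    planted true sites out of the negative set).  If fewer than ``count``
    windows exist, all are returned with a warning.
    """
    starts = eligible_window_starts(annotation, regions, L)
    if exclude:
        excl = list(exclude)
        starts = [(sid, st) for sid, st in starts
                  if not any(sid == xid and st < xe and st + L > xs
                             for xid, xs, xe in excl)]
    if not starts:
        raise ValueError(f"no eligible length-{L} windows in the non-coding regions")
    rng = np.random.default_rng(seed)
    if len(starts) <= count:
        if len(starts) < count:
            logger.warning("only %d eligible windows (< requested %d); returning all",
                           len(starts), count)
        chosen = list(range(len(starts)))
    else:
        chosen = rng.choice(len(starts), size=count, replace=False)
    return [_window_site(annotation, *starts[i], L) for i in sorted(chosen)]


# ---------------------------------------------------------------------------
# window scorers

class WindowScorer(Protocol):
    """Anything that can score all length-L windows of a sequence stretch."""

    L: int
    context: int  # bases of flanking context needed per side (0 or 1)

    def score_windows(self, ext: str) -> np.ndarray:
        """Scores of the len(ext) - L - 2*context + 1 fully-covered windows."""
        ...

    def is_hit(self, scores: np.ndarray) -> np.ndarray:
        ...


@dataclass
class PwmWindowScorer:
    """Vectorized window scoring for any additive PWM-style model."""

    model: AdditiveScorer
    context: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        self.L = self.model.L

    def score_windows(self, ext: str) -> np.ndarray:
        codes = encode_kmers(ext, 1)  # per-base codes
        n = len(ext) - self.L + 1
        if n <= 0:
            return np.zeros(0)
        scores = np.full(n, self.model.offset, dtype=float)
        M = np.asarray(self.model.matrix, dtype=float)
        for j in range(self.L):
            scores += M[codes[j:j + n], j]
        return scores

    def is_hit(self, scores: np.ndarray) -> np.ndarray:
        from sitesleuth.pwm import QpmemeModel
        if isinstance(self.model, QpmemeModel):
            return scores <= self.model.cutoff
        return scores > self.model.cutoff


@dataclass
class SvmWindowScorer:
    """Window scoring for a linear SVM classifier over mapped features.

    The decision value is linear in the feature vector and every feature is
    a table lookup, so the classifier folds into one 64-entry lookup per
    core position (chemical forward + reverse + base geometry) and one
    256-entry lookup per step, plus a constant.
    """

    clf: LinearClassifier
    tables: FeatureTableBundle
    L: int
    context: int = field(init=False, default=1)

    def __post_init__(self) -> None:
        layout = FeatureLayout(self.L)
        if self.clf.n_features != layout.n_total:
            raise ValueError(
                f"classifier dimension {self.clf.n_features} != {layout.n_total} for L={self.L}")
        chem, base, step = self.tables.arrays()
        v, bias = self.clf.effective_weights()
        # reverse-complement code of every 3-mer, for the other-strand block
        rc3 = np.array([_rc_code(c, 3) for c in range(64)])
        self.pos_tables = np.empty((self.L, 64))
        for j in range(self.L):
            w_fwd = v[layout.chem_fwd_block(j)]
            w_rev = v[layout.chem_rev_block(j)]
            w_base = v[layout.base_block(j)]
            self.pos_tables[j] = chem @ w_fwd + chem[rc3] @ w_rev + base @ w_base
        self.step_tables = np.empty((self.L - 1, 256))
        for s in range(self.L - 1):
            self.step_tables[s] = step @ v[layout.step_block(s)]
        self.bias = bias

    def score_windows(self, ext: str) -> np.ndarray:
        # window g occupies ext[g+1 : g+1+L] with context ext[g] / ext[g+1+L]
        n = len(ext) - self.L - 1
        if n <= 0:
            return np.zeros(0)
        code3 = encode_kmers(ext, 3)  # code3[i] = 3-mer starting at i
        code4 = encode_kmers(ext, 4)
        scores = np.full(n, self.bias)
        for j in range(self.L):
            scores += self.pos_tables[j, code3[j:j + n]]
        for s in range(self.L - 1):
            scores += self.step_tables[s, code4[s:s + n]]
        return scores

    def is_hit(self, scores: np.ndarray) -> np.ndarray:
        return scores > 0


def _rc_code(code: int, k: int) -> int:
    out = 0
    for _ in range(k):
        out = out * 4 + (3 - code % 4)
        code //= 4
    return out


# ---------------------------------------------------------------------------
# scanning

@dataclass
class PredictionSet:
    """Windows classified positive, with coordinates, strand, and score."""

    records: pd.DataFrame  # columns: seq_id, start, end, strand, score, sequence
    L: int
    model_id: str = ""
    skipped_windows: int = 0

    @property
    def n_predictions(self) -> int:
        return len(self.records)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    def to_bed(self, path) -> None:
        bed = self.records[["seq_id", "start", "end"]].copy()
        bed["name"] = [f"{self.model_id or 'hit'}_{i}" for i in range(len(bed))]
        bed["score"] = self.records["score"]
        bed["strand"] = self.records["strand"]
        bed.to_csv(path, sep="\t", index=False, header=False)


_EMPTY_COLUMNS = ["seq_id", "start", "end", "strand", "score", "sequence"]


def scan(scorer: WindowScorer, annotation: GenomeAnnotation,
         regions: NonCodingRegions, model_id: str = "") -> PredictionSet:
    """Score every window of every region on both strands; keep positives.

    Windows needing flanking context that a linear sequence terminus cannot
    provide are skipped and counted in ``skipped_windows``.
    """
    L = scorer.L
    ctx = scorer.context
    rows = []
    skipped = 0
    for seq_id, rs, re_ in regions.regions:
        seq = annotation.sequences[seq_id]
        n = len(seq)
        circ = annotation.is_circular(seq_id)
        lo, hi = rs - ctx, re_ + ctx
        if circ:
            ext = "".join(seq[i % n] for i in range(lo, hi))
            first_start = rs
        else:
            clipped_lo, clipped_hi = max(lo, 0), min(hi, n)
            ext = seq[clipped_lo:clipped_hi]
            first_start = clipped_lo + ctx
            n_windows_nominal = max(0, (re_ - rs) - L + 1)
            n_windows_usable = max(0, (clipped_hi - clipped_lo) - L - 2 * ctx + 1)
            skipped += max(0, n_windows_nominal - n_windows_usable)
        if len(ext) < L + 2 * ctx:
            continue
        fwd = scorer.score_windows(ext)
        rev = scorer.score_windows(reverse_complement(ext))[::-1]
        n_w = len(fwd)
        starts = first_start + np.arange(n_w)
        keep_starts = starts + L <= re_  # window wholly inside the region
        for strand, scores in (("+", fwd), ("-", rev)):
            hits = scorer.is_hit(scores) & keep_starts
            for i in np.flatnonzero(hits):
                start = int(starts[i])
                core = seq[start:start + L]
                rows.append((seq_id, start, start + L, strand,
                             float(scores[i]),
                             core if strand == "+" else reverse_complement(core)))
    df = pd.DataFrame(rows, columns=_EMPTY_COLUMNS)
    return PredictionSet(records=df, L=L, model_id=model_id, skipped_windows=skipped)
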