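"""Classifier evaluation: ROC/AUC with repeated splits, region matching, RP.

AUC is computed as the Mann-Whitney rank statistic (the probability that a
random positive outscores a random negative, ties counting one half), which
equals the area under the tie-grouped ROC sweep.  The repeated-split
experiment retrains a method on a 2/3 sample of the known sites and scores
the held-out third against non-coding background windows, ten times.
Predictions are validated against experimentally determined binding regions
by exact substring containment of the predicted site or its reverse
complement, and the relative-performance statistic compares prediction
counts between methods.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy.stats import rankdata

from sitesleuth.genome import GenomeAnnotation, NonCodingRegions, PredictionSet, sample_negative_windows
from sitesleuth.mapping import reverse_complement


@dataclass
class RocResult:
    """ROC curve points (fpr, tpr) from (0,0) to (1,1), and the AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> RocResult:
    """Rank-based ROC curve and AUC.

    AUC equals the mean over all (positive, negative) pairs of
    1 [pos > neg] + 0.5 [pos == neg]; the curve is a descending-score sweep
    with tied scores grouped into single steps.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    # Mann-Whitney U from the positive rank-sum
    u = ranks[:len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    auc = float(u / (len(pos) * len(neg)))

    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    # count of scores >= t, per threshold, via binary search on sorted arrays
    tpr = (len(pos) - np.searchsorted(pos_sorted, thresholds, side="left")) / len(pos)
    fpr = (len(neg) - np.searchsorted(neg_sorted, thresholds, side="left")) / len(neg)
    return RocResult(fpr=np.concatenate([[0.0], fpr]),
                     tpr=np.concatenate([[0.0], tpr]), auc=auc)


class SiteMethod(Protocol):
    """A trainable scoring method for the repeated-split AUC experiment."""

    def fit(self, positives: list, negatives: list) -> None:
        ...

    def score_sites(self, sites: list) -> np.ndarray:
        ...


@dataclass
class AucExperiment:
    aucs: np.ndarray
    mean: float
    sd: float
    reps: int


def auc_experiment(method: SiteMethod, positives: list,
                   annotation: GenomeAnnotation, regions: NonCodingRegions,
                   L: int, reps: int = 10, seed: int = 0,
                   min_sites: int = 20, negative_cap: int = 1_000_000,
                   n_train_negatives: int = 10000) -> AucExperiment:
    """Repeated 2/3-train / 1/3-test AUC estimation against background windows.

    Requires at least ``min_sites`` known sites (the floor below which the
    AUC estimate is too noisy to report); per repetition the method is
    retrained on the 2/3 split plus sampled negative windows and the AUC is
    computed from the held-out positives versus all eligible non-coding
    windows (a seeded sample of ``negative_cap`` if there are more).
    """
    n = len(positives)
    if n < min_sites:
        raise ValueError(
            f"AUC experiment requires at least {min_sites} known sites, have {n}")
    rng = np.random.default_rng(seed)
    # known sites are not background: exclude their genomic windows
    exclude = [(s.origin.seq_id, s.origin.start, s.origin.end)
               for s in positives if getattr(s, "origin", None) is not None]
    aucs = []
    for _ in range(reps):
        perm = rng.permutation(n)
        n_train = int(round(n * 2 / 3))
        train = [positives[i] for i in perm[:n_train]]
        test = [positives[i] for i in perm[n_train:]]
        train_neg = sample_negative_windows(
            annotation, regions, L, count=n_train_negatives,
            seed=int(rng.integers(2 ** 31)), exclude=exclude)
        method.fit(train, train_neg)
        eval_neg = sample_negative_windows(
            annotation, regions, L, count=negative_cap,
            seed=int(rng.integers(2 ** 31)), exclude=exclude)
        pos_scores = method.score_sites(test)
        neg_scores = method.score_sites(eval_neg)
        aucs.append(roc_auc(pos_scores, neg_scores).auc)
    aucs = np.asarray(aucs)
    return AucExperiment(aucs=aucs, mean=float(aucs.mean()),
                         sd=float(aucs.std(ddof=1)) if reps > 1 else 0.0,
                         reps=reps)


@dataclass
class RegionMatchReport:
    """Predictions validated against experimentally determined regions."""

    total: int
    matched: int

    @property
    def false_positives(self) -> int:
        return self.total - self.matched

    @property
    def fraction_correct(self) -> float:
        if self.total == 0:
            return float("nan")
        return self.matched / self.total


def match_predictions_to_regions(predictions: PredictionSet | Sequence[str],
                                 region_sequences: Sequence[str]) -> RegionMatchReport:
    """Count predictions whose site (or its reverse complement) lies within a region.

    A prediction matches when its full sequence or the reverse complement is
    a substring of any region sequence; a prediction matching several
    regions still counts once.
    """
    if isinstance(predictions, PredictionSet):
        seqs = list(predictions.records["sequence"])
    else:
        seqs = list(predictions)
    matched = 0
    for s in seqs:
        rc = reverse_complement(s)
        if any(s in region or rc in region for region in region_sequences):
            matched += 1
    return RegionMatchReport(total=len(seqs), matched=matched)


def relative_performance(n_other: int, n_sitesleuth: int) -> float:
    """Ratio of another method's prediction count to SiteSleuth's."""
    if n_sitesleuth <= 0:
        raise ValueError("relative performance is undefined without SiteSleuth predictions")
    return n_other / n_sitesleuth
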