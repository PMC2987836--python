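"""Uniform trainable-method adapters over the SVM and the PWM baselines.

The evaluation protocols retrain a method on site subsets and score held-out
sites, so each method is wrapped behind fit(positives, negatives) /
score_sites(sites).  Sites are :class:`~sitesleuth.mapping.SiteSequence`
objects; PWM methods use only the core sequence while the SVM maps cores
with their context through the feature tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from sitesleuth import pwm
from sitesleuth.genome import PwmWindowScorer, SvmWindowScorer
from sitesleuth.mapping import SiteSequence, map_sites_matrix
from sitesleuth.svm import LinearClassifier, PenaltyPair, TrainingSet, decision_values, train_svm
from sitesleuth.tables import FeatureTableBundle


def _cores(sites: list[SiteSequence]) -> list[str]:
    return [s.core for s in sites]


@dataclass
class SvmSiteMethod:
    """SiteSleuth: feature-mapped linear SVM; scores are decision values."""

    tables: FeatureTableBundle
    penalties: PenaltyPair = field(default_factory=lambda: PenaltyPair(1.0, 1.0))
    clf: Optional[LinearClassifier] = None

    def fit(self, positives: list[SiteSequence], negatives: list[SiteSequence]) -> None:
        X = np.vstack([map_sites_matrix(positives, self.tables),
                       map_sites_matrix(negatives, self.tables)])
        y = np.concatenate([np.ones(len(positives)), -np.ones(len(negatives))])
        self.clf = train_svm(TrainingSet(X, y), self.penalties)

    def score_sites(self, sites: list[SiteSequence]) -> np.ndarray:
        if self.clf is None:
            raise RuntimeError("fit before scoring")
        return decision_values(self.clf, map_sites_matrix(sites, self.tables))

    def window_scorer(self, L: int) -> SvmWindowScorer:
        if self.clf is None:
            raise RuntimeError("fit before scanning")
        return SvmWindowScorer(clf=self.clf, tables=self.tables, L=L)


@dataclass
class PwmSiteMethod:
    """One of the PWM baselines behind the common fit/score surface.

    QPMEME scores are negated energies so that, like the other methods,
    larger scores indicate stronger predicted binding (needed for rank-based
    evaluation); classification still uses each method's native cutoff rule.
    """

    name: str  # bvh | match | matrixsearch | qpmeme
    background: pwm.Background = field(default_factory=pwm.Background.uniform)
    model: object = None

    def fit(self, positives: list[SiteSequence], negatives=None) -> None:
        cores = _cores(positives)
        if self.name == "bvh":
            self.model = pwm.bvh_train(cores)
        elif self.name == "match":
            self.model = pwm.match_train(cores)
        elif self.name == "matrixsearch":
            self.model = pwm.matrix_search_train(cores, self.background)
        elif self.name == "qpmeme":
            self.model = pwm.qpmeme_train(cores, self.background)
        else:
            raise ValueError(f"unknown baseline {self.name!r}")

    def score_sites(self, sites: list[SiteSequence]) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("fit before scoring")
        raw = self.model.score_many(_cores(sites))
        return -raw if self.name == "qpmeme" else raw

    def window_scorer(self, L: int) -> PwmWindowScorer:
        if self.model is None:
            raise RuntimeError("fit before scanning")
        if self.model.L != L:
            raise ValueError("model length mismatch")
        return PwmWindowScorer(model=self.model)
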