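"""Class-weighted soft-margin linear SVM training, model selection, prediction.

The classifier solves

    minimize    (1/2)||w||^2 + C+ * sum_{y_k=+1} xi_k + C- * sum_{y_k=-1} xi_k
    subject to  y_k (w.x_k + d) >= 1 - xi_k,   xi_k >= 0

so the penalty for misclassifying the (scarce) positive examples can be set
independently of the penalty for the (abundant) negatives.  Training goes
through libsvm (scikit-learn's SVC with a linear kernel and per-class
weights).  Penalties are selected by maximizing the cross-validated
F-measure over a coarse power-of-two grid followed by progressively finer
local grids.  The decision rule is sign(w.x + d), with 0 counted negative.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.svm import SVC


@dataclass
class TrainingSet:
    """Feature matrix X (N x n) with labels y in {-1, +1}."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise ValueError("X must be (N, n) with one label per row")
        if not np.isfinite(self.X).all():
            raise ValueError("non-finite feature values in training set")
        if not set(np.unique(self.y)) <= {-1, 1}:
            raise ValueError("labels must be -1 or +1")

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.y == 1))

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.y == -1))


@dataclass(frozen=True)
class PenaltyPair:
    c_plus: float
    c_minus: float

    def __post_init__(self) -> None:
        if self.c_plus <= 0 or self.c_minus <= 0:
            raise ValueError("penalties must be positive")


@dataclass
class LinearClassifier:
    """Hyperplane w.x + d = 0 with optional stored feature standardization."""

    w: np.ndarray
    d: float
    penalties: Optional[PenaltyPair] = None
    tol: float = 1e-6
    mean: Optional[np.ndarray] = None
    sd: Optional[np.ndarray] = None

    @property
    def n_features(self) -> int:
        return len(self.w)

    def effective_weights(self) -> tuple[np.ndarray, float]:
        """(v, b) with v.x + b = decision value on *raw* feature space."""
        if self.mean is None:
            return self.w, self.d
        v = self.w / self.sd
        return v, self.d - float(v @ self.mean)

    def to_dict(self) -> dict:
        out = {"n": self.n_features, "w": self.w.tolist(), "d": self.d}
        if self.penalties is not None:
            out["c_plus"] = self.penalties.c_plus
            out["c_minus"] = self.penalties.c_minus
        if self.mean is not None:
            out["standardize"] = {"mean": self.mean.tolist(), "sd": self.sd.tolist()}
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "LinearClassifier":
        pen = None
        if "c_plus" in d:
            pen = PenaltyPair(d["c_plus"], d["c_minus"])
        mean = sd = None
        if "standardize" in d:
            mean = np.asarray(d["standardize"]["mean"], dtype=float)
            sd = np.asarray(d["standardize"]["sd"], dtype=float)
        return cls(w=np.asarray(d["w"], dtype=float), d=float(d["d"]),
                   penalties=pen, mean=mean, sd=sd)


def svm_objective(X: np.ndarray, y: np.ndarray, w: np.ndarray, d: float,
                  penalties: PenaltyPair) -> float:
    """Primal objective value at (w, d) with slacks at their minimal values."""
    margins = y * (X @ w + d)
    xi = np.maximum(0.0, 1.0 - margins)
    c = np.where(y == 1, penalties.c_plus, penalties.c_minus)
    return 0.5 * float(w @ w) + float(c @ xi)


def _kkt_solve(X: np.ndarray, y: np.ndarray, c: np.ndarray,
               F: np.ndarray, U: np.ndarray) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Solve the SVM KKT equations for a hypothesised active-set partition.

    F marks free support vectors (margin exactly 1, 0 < alpha < C); U marks
    bound ones (alpha = C).  The remaining examples have alpha = 0.  Returns
    (w, d, alpha_F, indices of F).
    """
    n = X.shape[1]
    s = (c[U] * y[U]) @ X[U] if U.any() else np.zeros(n)
    t = float((c[U] * y[U]).sum())
    idxF = np.flatnonzero(F)
    k = len(idxF)
    XF, yF = X[idxF], y[idxF]
    A = np.zeros((k + 1, k + 1))
    if k:
        Z = yF[:, None] * XF
        A[:k, :k] = Z @ Z.T
        A[:k, -1] = yF
        A[-1, :k] = yF
    rhs = np.concatenate([1 - yF * (XF @ s), [-t]]) if k else np.array([-t])
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    aF, d = sol[:-1], float(sol[-1])
    w = ((aF * yF) @ XF if k else 0.0) + s
    return w, d, aF, idxF


def _active_set_polish(X: np.ndarray, y: np.ndarray, c: np.ndarray,
                       model: SVC, max_iter: int = 200) -> tuple[np.ndarray, float]:
    """Refine libsvm's solution to an exact KKT point.

    SMO stops at a finite KKT-violation tolerance; starting from its support
    vectors this solves the active-set linear system exactly, moving single
    worst violators between the free / bound / inactive sets until the full
    KKT conditions hold.  The refined solution is kept only if it does not
    increase the primal objective.
    """
    w0 = model.coef_.ravel().astype(float)
    d0 = float(model.intercept_[0])

    def objective(w: np.ndarray, d: float) -> float:
        xi = np.maximum(0.0, 1.0 - y * (X @ w + d))
        return 0.5 * float(w @ w) + float(c @ xi)

    alpha = np.zeros(len(y))
    alpha[model.support_] = np.abs(model.dual_coef_.ravel())
    F = (alpha > 1e-8 * c) & (alpha < c * (1 - 1e-8))
    U = alpha >= c * (1 - 1e-8)
    best_w, best_d, best_obj = w0, d0, objective(w0, d0)
    eps = 1e-10
    for _ in range(max_iter):
        w, d, aF, idxF = _kkt_solve(X, y, c, F, U)
        margins = y * (X @ w + d)
        moved = False
        for j, i in enumerate(idxF):
            if aF[j] < -eps:
                F[i] = False
                moved = True
            elif aF[j] > c[i] + eps:
                F[i] = False
                U[i] = True
                moved = True
        if moved:
            continue
        inactive = ~(F | U)
        viol_Z = inactive & (margins < 1 - 1e-9)
        viol_U = U & (margins > 1 + 1e-9)
        if not viol_Z.any() and not viol_U.any():
            obj = objective(w, d)
            if obj < best_obj:
                best_w, best_d, best_obj = w, d, obj
            break
        candidates = []
        if viol_Z.any():
            i = np.flatnonzero(viol_Z)[np.argmin(margins[viol_Z])]
            candidates.append((1 - margins[i], int(i), "to_free"))
        if viol_U.any():
            i = np.flatnonzero(viol_U)[np.argmax(margins[viol_U])]
            candidates.append((margins[i] - 1, int(i), "unbound"))
        _, i, move = max(candidates)
        if move == "to_free":
            F[i] = True
        else:
            U[i] = False
            F[i] = True
    return best_w, best_d


def train_svm(data: TrainingSet, penalties: PenaltyPair, tol: float = 1e-6,
              standardize: bool = True) -> LinearClassifier:
    """Fit the class-weighted soft-margin linear SVM.

    Training runs libsvm's SMO and then refines the result to an exact KKT
    point by solving the active-set linear system, so the primal objective
    is accurate to numerical precision rather than SMO's stopping tolerance.

    With ``standardize`` (the default), features are scaled to mean 0 / sd 1
    before training and the scaling parameters are stored in the classifier
    and re-applied at prediction; raw feature units (Angstrom, degrees, PCA
    scores) are otherwise arbitrary relative to each other.  Constant
    features get sd treated as 1 (they carry no information either way).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if data.n_positive == 0 or data.n_negative == 0:
        raise ValueError("training requires both classes to be present")
    X = data.X
    mean = sd = None
    if standardize:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        X = (X - mean) / sd
    y = np.asarray(data.y, dtype=float)
    model = SVC(kernel="linear", C=1.0,
                class_weight={1: penalties.c_plus, -1: penalties.c_minus},
                tol=min(tol, 1e-6), shrinking=True, cache_size=500,
                max_iter=20_000_000)
    model.fit(X, data.y)
    c = np.where(y == 1, penalties.c_plus, penalties.c_minus)
    w, d = _active_set_polish(X, y, c, model)
    return LinearClassifier(w=w, d=d, penalties=penalties, tol=tol,
                            mean=mean, sd=sd)


def decision_value(clf: LinearClassifier, x: np.ndarray) -> float:
    """w.x + d, applying the stored standardization to x first if present."""
    x = np.asarray(x, dtype=float)
    if x.shape != (clf.n_features,):
        raise ValueError(f"feature dimension {x.shape} != classifier's ({clf.n_features},)")
    if clf.mean is not None:
        x = (x - clf.mean) / clf.sd
    return float(clf.w @ x + clf.d)


def decision_values(clf: LinearClassifier, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != clf.n_features:
        raise ValueError("feature dimension mismatch")
    if clf.mean is not None:
        X = (X - clf.mean) / clf.sd
    return X @ clf.w + clf.d


def predict(clf: LinearClassifier, x: np.ndarray) -> int:
    """+1 iff the decision value is strictly positive, else -1."""
    return 1 if decision_value(clf, x) > 0 else -1


def f_measure(TP: int, FP: int, FN: int) -> float:
    """Harmonic mean of precision and recall; 0 when there are no true positives."""
    if min(TP, FP, FN) < 0:
        raise ValueError("counts must be non-negative")
    if TP == 0:
        return 0.0
    p = TP / (TP + FP)
    r = TP / (TP + FN)
    return 2 * p * r / (p + r)


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Label-stratified partition into near-equal folds; returns index arrays."""
    assignments = np.empty(len(y), dtype=int)
    for label in (1, -1):
        idx = np.flatnonzero(y == label)
        idx = rng.permutation(idx)
        for f, chunk in enumerate(np.array_split(idx, folds)):
            assignments[chunk] = f
    return [np.flatnonzero(assignments == f) for f in range(folds)]


def _cv_counts(data: TrainingSet, penalties: PenaltyPair, folds: int,
               rng: np.random.Generator, standardize: bool) -> tuple[int, int, int, int]:
    """One stratified k-fold pass; pooled (TP, FP, FN, held-out positives)."""
    parts = _stratified_folds(data.y, folds, rng)
    TP = FP = FN = n_pos = 0
    for f in range(folds):
        test = parts[f]
        train = np.concatenate([parts[g] for g in range(folds) if g != f])
        sub = TrainingSet(data.X[train], data.y[train])
        if sub.n_positive == 0 or sub.n_negative == 0:
            raise ValueError("a training fold lost one class entirely")
        clf = train_svm(sub, penalties, standardize=standardize)
        pred = np.where(decision_values(clf, data.X[test]) > 0, 1, -1)
        yt = data.y[test]
        TP += int(np.sum((pred == 1) & (yt == 1)))
        FP += int(np.sum((pred == 1) & (yt == -1)))
        FN += int(np.sum((pred == -1) & (yt == 1)))
        n_pos += int(np.sum(yt == 1))
    return TP, FP, FN, n_pos


def cross_validate(data: TrainingSet, penalties: PenaltyPair = PenaltyPair(1.0, 1.0),
                   folds: int = 3, reps: int = 10, seed: int = 0,
                   standardize: bool = True) -> dict:
    """Repeated stratified k-fold cross-validation.

    Per repetition the examples are partitioned into ``folds`` near-equal
    label-stratified subsets; each fold is held out once.  V is the fraction
    of held-out positive examples predicted positive, pooled over the folds
    of one repetition.  Returns mean and sd of V over repetitions along with
    the mean pooled F-measure.
    """
    if data.n_positive < folds:
        raise ValueError(f"need at least {folds} positive examples, have {data.n_positive}")
    rng = np.random.default_rng(seed)
    Vs, Fs = [], []
    for _ in range(reps):
        TP, FP, FN, n_pos = _cv_counts(data, penalties, folds, rng, standardize)
        Vs.append(TP / n_pos)
        Fs.append(f_measure(TP, FP, FN))
    Vs = np.asarray(Vs)
    return {"V_mean": float(Vs.mean()),
            "V_sd": float(Vs.std(ddof=1)) if reps > 1 else 0.0,
            "F_mean": float(np.mean(Fs))}


@dataclass
class GridSearchResult:
    best: PenaltyPair
    best_f: float
    trace: dict = field(default_factory=dict)  # (log2 C-, log2 C+) -> F


COARSE_EXPONENTS = tuple(range(-5, 17, 2))  # 2^-5 .. 2^15, 11 values
REFINE_SPACINGS = (1.0, 0.5, 0.25, 0.125)


def grid_search_penalties(data: TrainingSet, folds: int = 3, seed: int = 0,
                          standardize: bool = True,
                          refine_spacings: tuple[float, ...] = REFINE_SPACINGS) -> GridSearchResult:
    """Select (C-, C+) by maximizing cross-validated F over a two-stage grid.

    Coarse stage: the 11 x 11 grid of exponents {-5, -3, ..., 15} for both
    penalties.  Refinement: recentre on the best pair and evaluate a 3 x 3
    neighbourhood with log2-spacing shrinking through ``refine_spacings``.
    One seeded fold partition is reused across all pairs so that F values are
    comparable.  Ties break toward smaller C-, then smaller C+.
    """
    if data.n_positive < folds:
        raise ValueError(f"need at least {folds} positive examples, have {data.n_positive}")
    trace: dict[tuple[float, float], float] = {}

    def evaluate(e_minus: float, e_plus: float) -> float:
        key = (round(e_minus, 6), round(e_plus, 6))
        if key not in trace:
            # fresh generator per pair, same seed: identical partitions
            rng = np.random.default_rng(seed)
            pair = PenaltyPair(c_plus=2.0 ** e_plus, c_minus=2.0 ** e_minus)
            TP, FP, FN, _ = _cv_counts(data, pair, folds, rng, standardize)
            trace[key] = f_measure(TP, FP, FN)
        return trace[key]

    def better(a: tuple[float, float], b: tuple[float, float] | None,
               strict: bool = False) -> bool:
        if b is None:
            return True
        fa, fb = trace[(round(a[0], 6), round(a[1], 6))], trace[(round(b[0], 6), round(b[1], 6))]
        if fa != fb:
            return fa > fb
        return False if strict else a < b  # smaller C- then smaller C+

    best: tuple[float, float] | None = None
    for em, ep in itertools.product(COARSE_EXPONENTS, COARSE_EXPONENTS):
        evaluate(em, ep)
        if better((float(em), float(ep)), best):
            best = (float(em), float(ep))
    assert best is not None
    # refinement recentres only on strict F improvement: on flat plateaus the
    # coarse winner stands rather than drifting one neighbourhood per stage
    for spacing in refine_spacings:
        stage_best = best
        for dm, dp in itertools.product((-spacing, 0.0, spacing), repeat=2):
            cand = (best[0] + dm, best[1] + dp)
            evaluate(*cand)
            if better(cand, stage_best, strict=stage_best == best):
                stage_best = cand
        best = stage_best
    pair = PenaltyPair(c_plus=2.0 ** best[1], c_minus=2.0 ** best[0])
    return GridSearchResult(best=pair, best_f=trace[(round(best[0], 6), round(best[1], 6))],
                            trace=trace)
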