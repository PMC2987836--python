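"""Position-weight-matrix baseline methods: BvH, Match, MATRIX SEARCH, QPMEME.

All four score a length-L sequence S additively over positions.  With
n_{b,j} the count of base b at position j over the N training sites,
f_{b,j} = n_{b,j}/N, and p_b the background base frequency:

* BvH: score(S) = sum_j ln((n_{S_j,j} + 0.5) / (n_{b*,j} + 0.5)) where b* is
  the most common base at j (pseudocount 0.5); cutoff = mean training score.
* Match: an information vector I_j = sum_b f_{b,j} ln(4 f_{b,j}) weights the
  per-position frequencies; the weighted sum is min-max normalized to [0,1];
  cutoff = mean training score.
* MATRIX SEARCH: score(S) = sum_j ln((f_{S_j,j} + 0.01) / p_{S_j})
  (pseudocount 0.01); cutoff = mean training score.
* QPMEME: an energy matrix eps_{b,j} is fit from positive examples only by
  minimizing the variance of the energy of a random background sequence
  subject to every training site scoring at or below the cutoff (-1); a
  sequence is called a site when its energy is <= -1 (lower energy means
  stronger predicted binding).

Classification for the three mean-cutoff methods is strict: score > cutoff.
Natural logarithms throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.optimize

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def _encode_site(site: str, L: int) -> np.ndarray:
    if len(site) != L:
        raise ValueError(f"site length {len(site)} != matrix length {L}")
    try:
        return np.array([_BASE_INDEX[b] for b in site], dtype=int)
    except KeyError as e:
        raise ValueError(f"non-ACGT base {e.args[0]!r} in site") from None


@dataclass
class CountMatrix:
    """Per-position base counts n_{b,j} (rows A, C, G, T) over N sites."""

    counts: np.ndarray  # (4, L) integers
    N: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape[0] != 4:
            raise ValueError("count matrix must have 4 rows (A, C, G, T)")
        sums = self.counts.sum(axis=0)
        if not np.all(sums == self.N):
            raise ValueError("every column of a count matrix must sum to N")

    @property
    def L(self) -> int:
        return self.counts.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.N


@dataclass
class Background:
    """Genome-wide background base frequencies p_b."""

    p: np.ndarray  # length 4, order A, C, G, T

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (4,):
            raise ValueError("background must have 4 entries (A, C, G, T)")
        if not np.isclose(self.p.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")
        if np.any(self.p <= 0):
            raise ValueError("all background frequencies must be positive "
                             "(use smoothing for degenerate inputs)")

    @classmethod
    def uniform(cls) -> "Background":
        return cls(p=np.full(4, 0.25))


def build_count_matrix(sites: Sequence[str]) -> CountMatrix:
    """Tally base counts per position over equal-length ACGT sites."""
    if not sites:
        raise ValueError("no training sites")
    L = len(sites[0])
    counts = np.zeros((4, L), dtype=int)
    for s in sites:
        idx = _encode_site(s, L)
        counts[idx, np.arange(L)] += 1
    return CountMatrix(counts=counts, N=len(sites))


def background_frequencies(sequences: Iterable[str], smoothing: float = 0.0) -> Background:
    """Base frequencies over the concatenation of the supplied sequences.

    ``smoothing`` adds a pseudocount per base, needed only for degenerate
    inputs in which some base never occurs.
    """
    counts = np.zeros(4, dtype=float)
    total = 0
    for seq in sequences:
        for b in seq:
            counts[_BASE_INDEX[b]] += 1
            total += 1
    if total == 0:
        raise ValueError("empty sequence set")
    counts += smoothing
    return Background(p=counts / counts.sum())


class AdditiveScorer:
    """Common machinery: score(S) = sum_j M[S_j, j] + offset."""

    #: (4, L) additive score matrix; subclasses set this
    matrix: np.ndarray
    offset: float = 0.0
    cutoff: float = 0.0

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    def score(self, site: str) -> float:
        idx = _encode_site(site, self.L)
        return float(self.matrix[idx, np.arange(self.L)].sum() + self.offset)

    def score_many(self, sites: Sequence[str]) -> np.ndarray:
        return np.array([self.score(s) for s in sites])


# ---------------------------------------------------------------------------
# BvH

@dataclass
class BvhModel(AdditiveScorer):
    count_matrix: CountMatrix
    cutoff: float = 0.0
    pseudocount: float = 0.5
    matrix: np.ndarray = field(init=False)
    offset: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        n = self.count_matrix.counts
        # modal base per column; np.argmax breaks ties toward A < C < G < T
        modal = n[n.argmax(axis=0), np.arange(self.count_matrix.L)]
        self.matrix = np.log((n + self.pseudocount) / (modal + self.pseudocount))

    def classify(self, site: str) -> bool:
        return self.score(site) > self.cutoff

    def to_dict(self) -> dict:
        return {"method": "bvh", "L": self.L, "N": self.count_matrix.N,
                "counts": self.count_matrix.counts.tolist(),
                "pseudocount": self.pseudocount, "cutoff": self.cutoff}


def bvh_train(sites: Sequence[str]) -> BvhModel:
    cm = build_count_matrix(sites)
    model = BvhModel(count_matrix=cm)
    model.cutoff = float(model.score_many(sites).mean())
    return model


# ---------------------------------------------------------------------------
# Match

@dataclass
class MatchModel(AdditiveScorer):
    count_matrix: CountMatrix
    cutoff: float = 0.0
    matrix: np.ndarray = field(init=False)
    offset: float = field(init=False)
    information: np.ndarray = field(init=False)
    score_min: float = field(init=False)
    score_max: float = field(init=False)

    def __post_init__(self) -> None:
        f = self.count_matrix.frequencies
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(f > 0, f * np.log(4 * f), 0.0)
        self.information = terms.sum(axis=0)  # I_j
        weighted = self.information * f  # (4, L): I_j * f_{b,j}
        self.score_min = float((self.information * f.min(axis=0)).sum())
        self.score_max = float((self.information * f.max(axis=0)).sum())
        if self.score_max <= self.score_min:
            raise ValueError("uninformative matrix: min and max scores coincide")
        span = self.score_max - self.score_min
        self.matrix = weighted / span
        self.offset = -self.score_min / span

    def classify(self, site: str) -> bool:
        return self.score(site) > self.cutoff

    def to_dict(self) -> dict:
        return {"method": "match", "L": self.L, "N": self.count_matrix.N,
                "counts": self.count_matrix.counts.tolist(),
                "information": self.information.tolist(),
                "score_min": self.score_min, "score_max": self.score_max,
                "cutoff": self.cutoff}


def match_train(sites: Sequence[str]) -> MatchModel:
    cm = build_count_matrix(sites)
    model = MatchModel(count_matrix=cm)
    model.cutoff = float(model.score_many(sites).mean())
    return model


def match_score(model: MatchModel, site: str) -> float:
    return model.score(site)


# ---------------------------------------------------------------------------
# MATRIX SEARCH

@dataclass
class MatrixSearchModel(AdditiveScorer):
    count_matrix: CountMatrix
    background: Background
    cutoff: float = 0.0
    pseudocount: float = 0.01
    matrix: np.ndarray = field(init=False)
    offset: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        f = self.count_matrix.frequencies
        self.matrix = np.log((f + self.pseudocount) / self.background.p[:, None])

    def classify(self, site: str) -> bool:
        return self.score(site) > self.cutoff

    def to_dict(self) -> dict:
        return {"method": "matrixsearch", "L": self.L, "N": self.count_matrix.N,
                "counts": self.count_matrix.counts.tolist(),
                "pseudocount": self.pseudocount, "cutoff": self.cutoff,
                "background": self.background.p.tolist()}


def matrix_search_train(sites: Sequence[str], background: Background) -> MatrixSearchModel:
    cm = build_count_matrix(sites)
    model = MatrixSearchModel(count_matrix=cm, background=background)
    model.cutoff = float(model.score_many(sites).mean())
    return model


# ---------------------------------------------------------------------------
# QPMEME

@dataclass
class QpmemeModel(AdditiveScorer):
    epsilon: np.ndarray  # (4, L) energy matrix
    background: Background = field(default_factory=Background.uniform)
    cutoff: float = -1.0
    matrix: np.ndarray = field(init=False)
    offset: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if self.epsilon.shape[0] != 4:
            raise ValueError("energy matrix must have 4 rows")
        self.matrix = self.epsilon

    def classify(self, site: str) -> bool:
        # energies: lower is stronger binding; sites lie at or below the cutoff
        return self.score(site) <= self.cutoff

    def to_dict(self) -> dict:
        return {"method": "qpmeme", "L": self.L, "epsilon": self.epsilon.tolist(),
                "cutoff": self.cutoff, "background": self.background.p.tolist()}


def qpmeme_background_variance(epsilon: np.ndarray, bg: Background) -> float:
    """Variance of sum_j eps_{B_j, j} for B_j drawn i.i.d. from the background."""
    p = bg.p[:, None]
    mean = (p * epsilon).sum(axis=0)
    second = (p * epsilon ** 2).sum(axis=0)
    return float((second - mean ** 2).sum())


def qpmeme_train(sites: Sequence[str], bg: Background | None = None,
                 cutoff: float = -1.0, tol: float = 1e-9) -> QpmemeModel:
    """Fit the QPMEME energy matrix.

    Minimizes the background variance of the energy subject to
    sum_j eps_{S_j, j} <= cutoff for every training site S.  The variance is
    invariant under adding a constant to any column, so the background mean
    energy is gauged to zero per column (sum_b p_b eps_{b,j} = 0); in that
    gauge the objective is the weighted second moment sum_{j,b} p_b eps^2
    and the program is a strictly convex QP.  It is solved exactly through
    its dual (a box-constrained QP in one multiplier per site) followed by
    an active-set polish, so KKT residuals are at numerical precision.
    """
    if not sites:
        raise ValueError("QPMEME needs at least one training site")
    if bg is None:
        bg = Background.uniform()
    L = len(sites[0])
    idx = np.stack([_encode_site(s, L) for s in sites])  # (N, L)
    p = bg.p

    # per-column basis of the gauge subspace {v in R^4 : p.v = 0}, orthonormal
    # under the inner product <u, v> = sum_b p_b u_b v_b
    sqrt_p = np.sqrt(p)
    # in u = sqrt(p) * v coordinates the constraint is sqrt(p).u = 0 and the
    # metric is Euclidean; build an orthonormal basis of that hyperplane
    Q, _ = np.linalg.qr(np.column_stack([sqrt_p, np.eye(4)[:, :3]]))
    U = Q[:, 1:4]  # 4 x 3, orthonormal, each column orthogonal to sqrt_p
    B = U / sqrt_p[:, None]  # columns: gauge-subspace vectors, <B_i, B_j>_p = delta_ij

    # eps[:, j] = B @ c[j]; objective = sum_j |c[j]|^2; constraint rows pick
    # entry (S_j, j): a_row = concat_j B[S_j, :]
    N = len(sites)
    A = np.empty((N, 3 * L))
    for k in range(N):
        A[k] = B[idx[k]].reshape(-1)
    b = np.full(N, float(cutoff))

    # primal: min 1/2 |c|^2  s.t.  A c <= b   (objective scaled by 1/2)
    # dual:   min 1/2 lam' A A' lam + b' lam,  lam >= 0;  c = -A' lam
    M = A @ A.T

    def dual(lam: np.ndarray) -> tuple[float, np.ndarray]:
        g = M @ lam + b
        return 0.5 * float(lam @ (M @ lam)) + float(b @ lam), g

    lam0 = np.ones(N)
    res = scipy.optimize.minimize(dual, lam0, jac=True, method="L-BFGS-B",
                                  bounds=[(0.0, None)] * N,
                                  options={"maxiter": 2000, "ftol": 1e-16,
                                           "gtol": 1e-12})
    lam = res.x
    # active-set polish: constraints with lam above threshold are equalities
    for _ in range(10):
        active = lam > tol * max(1.0, lam.max())
        if not active.any():
            break
        Ma = M[np.ix_(active, active)]
        sol, *_ = np.linalg.lstsq(Ma, -b[active], rcond=None)
        lam_new = np.zeros(N)
        lam_new[active] = sol
        if (lam_new >= -tol).all():
            c = -A.T @ lam_new
            if (A @ c <= b + 1e-8).all():
                lam = np.maximum(lam_new, 0.0)
                break
        lam = np.maximum(lam_new, 0.0)
    c = -A.T @ lam
    if not (A @ c <= b + 1e-8).all():
        raise RuntimeError(
            f"QPMEME solver did not satisfy site constraints "
            f"(max violation {float((A @ c - b).max()):.3g})")
    epsilon = np.empty((4, L))
    for j in range(L):
        epsilon[:, j] = B @ c[3 * j:3 * (j + 1)]
    return QpmemeModel(epsilon=epsilon, background=bg, cutoff=float(cutoff))


# ---------------------------------------------------------------------------
# serialization

def save_model(model, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)


def load_model(path):
    with open(path) as fh:
        d = json.load(fh)
    method = d["method"]
    if method in ("bvh", "match", "matrixsearch"):
        cm = CountMatrix(counts=np.asarray(d["counts"]), N=d["N"])
        if method == "bvh":
            m = BvhModel(count_matrix=cm, pseudocount=d["pseudocount"])
        elif method == "match":
            m = MatchModel(count_matrix=cm)
        else:
            m = MatrixSearchModel(count_matrix=cm,
                                  background=Background(np.asarray(d["background"])),
                                  pseudocount=d["pseudocount"])
        m.cutoff = d["cutoff"]
        return m
    if method == "qpmeme":
        return QpmemeModel(epsilon=np.asarray(d["epsilon"]),
                           background=Background(np.asarray(d["background"])),
                           cutoff=d["cutoff"])
    raise ValueError(f"unknown model method {method!r}")
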