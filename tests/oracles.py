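"""Independent reference computations used to check the implementation.

These deliberately avoid the code paths they validate: the SVM oracle is a
generic dense QP solve of the primal (interior point plus an SQP polish),
the QPMEME oracle solves the gauged variance program in the full epsilon
space with explicit equality constraints, and the AUC oracle is the literal
pairwise comparison.
"""

import numpy as np
import scipy.optimize
from scipy.optimize import Bounds, LinearConstraint

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def svm_primal_qp_oracle(X, y, c_plus, c_minus):
    """Optimal objective of the class-weighted soft-margin SVM primal.

    Variables (w, d, xi); minimize 0.5|w|^2 + sum c_k xi_k subject to
    y_k (w.x_k + d) >= 1 - xi_k and xi_k >= 0, solved with scipy's
    trust-constr interior point and refined with SLSQP; the returned value
    is the objective at the feasible projection (xi = max(0, 1 - margin)).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    N, n = X.shape
    c = np.where(y == 1, c_plus, c_minus)
    nv = n + 1 + N
    H = np.zeros((nv, nv))
    H[:n, :n] = np.eye(n)

    def f(z):
        return 0.5 * z[:n] @ z[:n] + c @ z[n + 1:]

    def grad(z):
        g = np.zeros(nv)
        g[:n] = z[:n]
        g[n + 1:] = c
        return g

    A = np.hstack([y[:, None] * X, y[:, None], np.eye(N)])
    res = scipy.optimize.minimize(
        f, np.zeros(nv), jac=grad, hess=lambda z: H, method="trust-constr",
        constraints=[LinearConstraint(A, 1.0, np.inf)],
        bounds=Bounds(np.concatenate([np.full(n + 1, -np.inf), np.zeros(N)]),
                      np.full(nv, np.inf)),
        options={"gtol": 1e-12, "xtol": 1e-14, "barrier_tol": 1e-12, "maxiter": 2000})
    def feasible_objective(z):
        w, d = z[:n], z[n]
        xi = np.maximum(0.0, 1.0 - y * (X @ w + d))
        return 0.5 * float(w @ w) + float(c @ xi)

    best = feasible_objective(res.x)
    # SLSQP polish from several starts; keep the best feasible objective
    z0_all_slack = np.concatenate([np.zeros(n + 1), np.ones(N)])
    for z0 in (res.x, z0_all_slack):
        res2 = scipy.optimize.minimize(
            f, z0, jac=grad, method="SLSQP",
            constraints=[{"type": "ineq", "fun": lambda z: A @ z - 1.0,
                          "jac": lambda z: A}],
            bounds=[(None, None)] * (n + 1) + [(0, None)] * N,
            options={"maxiter": 1000, "ftol": 1e-14})
        best = min(best, feasible_objective(res2.x))
    return best


def qpmeme_oracle(sites, p, cutoff=-1.0):
    """Optimal background variance for the QPMEME program.

    Full 4L-variable SLSQP solve with the site-score inequality constraints
    and the per-column background-mean-zero equality constraints.
    """
    p = np.asarray(p, dtype=float)
    L = len(sites[0])
    idx = np.stack([[_BASE_INDEX[b] for b in s] for s in sites])

    def variance(e):
        E = e.reshape(4, L)
        mean = (p[:, None] * E).sum(axis=0)
        second = (p[:, None] * E ** 2).sum(axis=0)
        return float((second - mean ** 2).sum())

    cons = [
        {"type": "ineq",
         "fun": lambda e: cutoff - np.array(
             [e.reshape(4, L)[idx[k], np.arange(L)].sum() for k in range(len(sites))])},
        {"type": "eq", "fun": lambda e: p @ e.reshape(4, L)},
    ]
    res = scipy.optimize.minimize(variance, np.zeros(4 * L), constraints=cons,
                                  method="SLSQP",
                                  options={"maxiter": 3000, "ftol": 1e-16})
    return float(res.fun)


def pairwise_auc(pos, neg):
    """AUC by literal enumeration of all (positive, negative) pairs."""
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def naive_region_match(site_seqs, region_seqs):
    """Matched-prediction count by scanning every region position directly."""
    comp = str.maketrans("ACGT", "TGCA")
    matched = 0
    for s in site_seqs:
        rc = s.translate(comp)[::-1]
        hit = False
        for region in region_seqs:
            for i in range(len(region) - len(s) + 1):
                sub = region[i:i + len(s)]
                if sub == s or sub == rc:
                    hit = True
                    break
            if hit:
                break
        matched += hit
    return matched
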