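"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route deliberately different from the
implementation under test: explicit covariance matrices and grid search for
the mixed model, exhaustive enumeration for BH and the hypergeometric tail,
per-base labelling for gene regions.
"""

from __future__ import annotations

from math import comb

import numpy as np


def grid_oracle_loglik(y, X, donors, rounds: int = 4, width: int = 25) -> float:
    """Best ML log-likelihood of the random-intercept model over a refining
    (sigma_donor^2, sigma_e^2) grid, profiling the fixed effects by GLS on
    the explicitly constructed covariance matrix."""
    y = np.asarray(y, float)
    n = len(y)
    donors = np.asarray(donors)
    Z = (donors[:, None] == np.unique(donors)[None, :]).astype(float)
    ZZt = Z @ Z.T

    def ll_at(sd2, se2):
        V = sd2 * ZZt + se2 * np.eye(n)
        sign, logdet = np.linalg.slogdet(V)
        if sign <= 0:
            return -np.inf
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        r = y - X @ beta
        return -0.5 * (n * np.log(2 * np.pi) + logdet + r @ Vi @ r)

    lo_d, hi_d, lo_e, hi_e = 0.0, 10.0, 1e-4, 10.0
    best = (-np.inf, 0.0, 1.0)
    for r_i in range(rounds):
        if r_i == 0:
            ds = np.concatenate([[0.0], np.geomspace(1e-4, hi_d, width)])
            es = np.geomspace(lo_e, hi_e, width)
        else:
            ds = np.linspace(lo_d, hi_d, width)
            es = np.linspace(lo_e, hi_e, width)
        for sd2 in ds:
            for se2 in es:
                v = ll_at(sd2, se2)
                if v > best[0]:
                    best = (v, sd2, se2)
        _, bd, be = best
        sp_d = max((ds[1] - ds[0]) if r_i > 0 else bd, 1e-6)
        sp_e = max((es[1] - es[0]) if r_i > 0 else be, 1e-6)
        lo_d, hi_d = max(bd - 3 * sp_d, 0.0), bd + 3 * sp_d
        lo_e, hi_e = max(be - 3 * sp_e, 1e-6), be + 3 * sp_e
    # simplex polish of the grid optimum on the same 2-D surface
    from scipy.optimize import minimize

    res = minimize(
        lambda p: -ll_at(max(p[0], 0.0), max(p[1], 1e-8)),
        x0=[best[1], best[2]],
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 2000},
    )
    return max(best[0], -res.fun)


def bh_bruteforce(p: np.ndarray) -> np.ndarray:
    """BH q-values from the definition: q_i = min over thresholds t >= p_i of
    n * t / rank(t)."""
    p = np.asarray(p, float)
    n = p.size
    srt = np.sort(p)
    q = np.empty(n)
    for i, pi in enumerate(p):
        cands = []
        for t in srt[srt >= pi - 1e-15]:
            rank = int((srt <= t + 1e-15).sum())
            cands.append(n * t / rank)
        q[i] = min(min(cands), 1.0)
    return q


def hypergeom_upper_enum(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by direct summation of hypergeometric point masses."""
    denom = comb(N, n)
    total = 0
    for x in range(k, min(n, K) + 1):
        if n - x > N - K:
            continue
        total += comb(K, x) * comb(N - K, n - x)
    return total / denom


def label_bases(transcripts) -> dict[str, np.ndarray]:
    """Per-base exonic/intronic labelling for one gene's transcripts.

    Returns boolean arrays over [lo, hi] (1-based closed gene extent) plus
    the offset, keyed 'exonic', 'intronic', 'lo'.
    """
    lo = min(t.span[0] for t in transcripts)
    hi = max(t.span[1] for t in transcripts)
    size = hi - lo + 1
    exonic = np.zeros(size, bool)
    covered = np.zeros(size, bool)
    for t in transcripts:
        s, e = t.span
        covered[s - lo : e - lo + 1] = True
        for xs, xe in t.exons:
            exonic[xs - lo : xe - lo + 1] = True
    return {"exonic": exonic, "intronic": covered & ~exonic, "lo": lo}


def intervals_to_mask(intervals, lo: int, size: int) -> np.ndarray:
    """1-based closed intervals -> boolean base mask over [lo, lo+size)."""
    m = np.zeros(size, bool)
    for s, e in intervals:
        m[s - lo : e - lo + 1] = True
    return m
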