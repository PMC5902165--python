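"""Donor random-intercept harmonic regression and rhythmicity testing.

Per gene and signal layer the model

    y = mu + a*cos(w t) + b*sin(w t) + u_donor + eps,    w = 2*pi/period,
    u_donor ~ N(0, sigma_donor^2),  eps ~ N(0, sigma_e^2)

is fitted by maximum likelihood (not REML: the likelihood-ratio test below
compares models that differ in fixed effects).  For a random-intercept model
the covariance has an analytic block inverse, so for a given variance ratio
lam = sigma_donor^2 / sigma_e^2 the fixed effects are a closed-form GLS step
and sigma_e^2 is profiled out; the fit is a 1-D optimisation over lam >= 0.

Rhythmicity is tested by the likelihood ratio against the null model without
the harmonic terms, referred to a chi-squared distribution with 2 degrees of
freedom (the two harmonic coefficients); for df = 2 the upper tail is
exactly exp(-stat/2).  P-values are adjusted by Benjamini-Hochberg.

Amplitude is reported as the log2 peak-to-trough 2*sqrt(a^2 + b^2); phase is
the time of the fitted peak, (period/2pi)*atan2(b, a) mod period.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

_LRT_SLACK = 1e-8


@dataclass
class HarmonicFit:
    """ML fit of the harmonic mixed model for one gene and layer."""

    mu: float
    a: float
    b: float
    sigma_donor2: float
    sigma_e2: float
    loglik_full: float
    loglik_null: float
    lrt_stat: float
    amplitude: float
    phase_h: float
    n_obs: int
    n_donors: int
    boundary: bool  # donor variance pinned at the zero boundary


def _profile_loglik(lam: float, y, X, group_slices):
    """Profile log-likelihood at variance ratio lam, with GLS beta.

    Uses the Sherman-Morrison form of the random-intercept block inverse:
    (I + lam*J)^-1 = I - lam/(1 + lam*n) * J per donor block.
    """
    n, _ = X.shape
    A = X.T @ X
    bvec = X.T @ y
    q = float(y @ y)
    logdet = 0.0
    for sl in group_slices:
        nd = sl.stop - sl.start
        c = lam / (1.0 + lam * nd)
        sx = X[sl].sum(axis=0)
        sy = float(y[sl].sum())
        A = A - c * np.outer(sx, sx)
        bvec = bvec - c * sx * sy
        q -= c * sy * sy
        logdet += np.log1p(lam * nd)
    beta = np.linalg.solve(A, bvec)
    rss = max(q - float(beta @ bvec), 1e-300)
    s2 = rss / n
    ll = -0.5 * (n * np.log(2.0 * np.pi * s2) + logdet + n)
    return ll, beta, s2


def _fit_ml(y: np.ndarray, X: np.ndarray, group_slices) -> tuple:
    """Maximise the profile likelihood over lam >= 0."""

    def nll(lam):
        return -_profile_loglik(lam, y, X, group_slices)[0]

    grid = np.concatenate([[0.0], np.logspace(-6, 4, 41)])
    vals = np.array([nll(l) for l in grid])
    i = int(np.argmin(vals))
    if i == 0:
        res = optimize.minimize_scalar(
            nll, bounds=(0.0, grid[1]), method="bounded",
            options={"xatol": grid[1] * 1e-9},
        )
    else:
        lo = np.log(grid[max(i - 1, 1)])
        hi = np.log(grid[min(i + 1, len(grid) - 1)])
        res = optimize.minimize_scalar(
            lambda u: nll(np.exp(u)), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        res.x = np.exp(res.x)
    lam = float(res.x) if res.fun <= vals[i] else float(grid[i])
    ll, beta, s2 = _profile_loglik(lam, y, X, group_slices)
    return ll, beta, s2, lam


def amplitude_phase(a: float, b: float, period_h: float = 24.0) -> tuple[float, float]:
    """(log2 peak-to-trough amplitude, peak time in hours in [0, period))."""
    amplitude = 2.0 * float(np.hypot(a, b))
    phase = (period_h / (2.0 * np.pi)) * float(np.arctan2(b, a)) % period_h
    return amplitude, phase


def fit_harmonic_mixed(
    y: np.ndarray,
    times: np.ndarray,
    donors: np.ndarray,
    period_h: float = 24.0,
) -> HarmonicFit:
    """Fit the full and null mixed models on one observation vector.

    Masked samples must already be dropped; requires >= 6 observations,
    >= 2 donors and >= 3 distinct times (identifiability of mu, a, b).
    """
    y = np.asarray(y, float)
    times = np.asarray(times, float)
    donors = np.asarray(donors)
    if y.shape != times.shape or y.shape != donors.shape:
        raise ValueError("y, times and donors must have equal length")
    if np.isnan(y).any():
        raise ValueError("y contains missing values; drop masked samples first")
    n = y.size
    uniq_donors = np.unique(donors)
    if n < 6:
        raise ValueError(f"need >= 6 observations, got {n}")
    if uniq_donors.size < 2:
        raise ValueError("need >= 2 donors for the random-intercept fit")
    if np.unique(times).size < 3:
        raise ValueError("singular design: fewer than 3 distinct times")

    order = np.argsort(donors, kind="stable")
    y = y[order]
    times = times[order]
    donors = donors[order]
    bounds = np.flatnonzero(np.r_[True, donors[1:] != donors[:-1], True])
    slices = [slice(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]

    w = 2.0 * np.pi / period_h
    X = np.column_stack([np.ones(n), np.cos(w * times), np.sin(w * times)])
    X0 = np.ones((n, 1))

    ll_full, beta, s2, lam = _fit_ml(y, X, slices)
    ll_null, _, _, _ = _fit_ml(y, X0, slices)
    lrt = 2.0 * (ll_full - ll_null)
    if lrt < -_LRT_SLACK:
        raise RuntimeError(f"negative LRT statistic {lrt:.3g} beyond numerical slack")
    lrt = max(lrt, 0.0)
    amp, phase = amplitude_phase(beta[1], beta[2], period_h)
    boundary = lam < 1e-8
    if boundary:
        log.debug("donor variance at zero boundary")
    return HarmonicFit(
        mu=float(beta[0]),
        a=float(beta[1]),
        b=float(beta[2]),
        sigma_donor2=lam * s2,
        sigma_e2=s2,
        loglik_full=ll_full,
        loglik_null=ll_null,
        lrt_stat=lrt,
        amplitude=amp,
        phase_h=phase,
        n_obs=n,
        n_donors=uniq_donors.size,
        boundary=boundary,
    )


def lrt_pvalue(lrt_stat: float, df: int = 2) -> float:
    """Upper-tail chi-squared p-value; for df=2 the closed form exp(-stat/2)."""
    if lrt_stat < -_LRT_SLACK:
        raise ValueError(f"negative LRT statistic {lrt_stat}")
    stat = max(float(lrt_stat), 0.0)
    if df == 2:
        return float(np.exp(-stat / 2.0))
    return float(chi2.sf(stat, df))


def adjust_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p propagates NaN q."""
    p = np.asarray(pvals, float)
    if np.nanmin(p, initial=0.0) < 0 or np.nanmax(p, initial=0.0) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum() < ok.size:
        warnings.warn("NaN p-values propagate NaN q-values", stacklevel=2)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def phase_bin(phase_h, width_h: float = 4.0, period_h: float = 24.0):
    """Half-open phase bins [k*w, (k+1)*w); period must be divisible by width."""
    nbins = period_h / width_h
    if abs(nbins - round(nbins)) > 1e-9:
        raise ValueError(f"period {period_h} not divisible by bin width {width_h}")
    phase = np.asarray(phase_h, float)
    if np.any((phase < 0) | (phase >= period_h)):
        raise ValueError("phases must lie in [0, period)")
    bins = np.floor(phase / width_h).astype(int)
    return bins if bins.ndim else int(bins)


def fit_layer(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    period_h: float = 24.0,
    min_obs: int = 6,
) -> pd.DataFrame:
    """Fit every gene of one expression layer; NA rows where unfittable.

    ``samples`` is indexed by sample_id with columns donor_id and time_h.
    Genes with fewer than ``min_obs`` unmasked samples, fewer than 2 donors
    or fewer than 3 distinct times after masking are reported NA for this
    layer (they are not dropped from the other layer).
    """
    samples = samples.loc[expr.columns]
    times_all = samples["time_h"].to_numpy(float)
    donors_all = samples["donor_id"].to_numpy()
    cols = [
        "mu", "a", "b", "sigma_donor2", "sigma_e2", "loglik_full", "loglik_null",
        "lrt_stat", "p", "amplitude", "phase_h", "n_obs", "n_donors", "boundary",
    ]
    values = expr.to_numpy(float)
    rows = []
    for i in range(values.shape[0]):
        y = values[i]
        ok = ~np.isnan(y)
        if ok.sum() < min_obs:
            rows.append([np.nan] * len(cols))
            continue
        try:
            fit = fit_harmonic_mixed(
                y[ok], times_all[ok], donors_all[ok], period_h=period_h
            )
        except ValueError:
            rows.append([np.nan] * len(cols))
            continue
        rows.append(
            [
                fit.mu, fit.a, fit.b, fit.sigma_donor2, fit.sigma_e2,
                fit.loglik_full, fit.loglik_null, fit.lrt_stat,
                lrt_pvalue(fit.lrt_stat), fit.amplitude, fit.phase_h,
                fit.n_obs, fit.n_donors, float(fit.boundary),
            ]
        )
    out = pd.DataFrame(rows, index=expr.index, columns=cols)
    out["q"] = adjust_bh(out["p"].to_numpy())
    return out


def classify_rhythm_groups(
    q_intronic: pd.Series, q_exonic: pd.Series, fdr: float = 0.05
) -> pd.Series:
    """Partition genes into R-I.R-E / R-I / R-E / NR by layer-wise q < fdr.

    A missing layer (NaN q, e.g. masked intronic quantification) counts as
    not significant at that layer, so exonic-only genes land in R-E.
    """
    genes = q_intronic.index.union(q_exonic.index)
    qi = q_intronic.reindex(genes)
    qe = q_exonic.reindex(genes)
    sig_i = (qi < fdr).fillna(False)
    sig_e = (qe < fdr).fillna(False)
    group = pd.Series("NR", index=genes, name="group")
    group[sig_i & sig_e] = "R-I.R-E"
    group[sig_i & ~sig_e] = "R-I"
    group[~sig_i & sig_e] = "R-E"
    return group
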