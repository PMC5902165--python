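"""Semi-supervised classification of dense in-vitro expression time courses.

Each gene x (donor, condition) curve — 25 log2 RPKM values at 2-h spacing
over 48 h after synchronisation — is LOESS-smoothed, summarised by ten shape
measures, and classified into one of four categories (circadian / one_peak /
linear / cloud) by a random forest that is self-trained from a seed set
anchored on eleven core clock genes.  Per gene, the rhythmic/non-rhythmic
status of its four condition-curves defines a 4-bit mask mapped to one of
sixteen models (model 1 = rhythmic in all four, model 16 = in none).

The ten curve measures:

==============  =============================================================
max_slope       largest central-difference slope of the dense smoothed curve
min_slope       smallest such slope (log2 units / h)
extremum1_t     time of the first interior derivative sign change (h);
                sentinel = last time point if absent
extremum2_t     time of the second sign change, same sentinel
minmax_ratio    min/max of the smoothed curve on the linear (2**y) scale
autocorr24      Pearson r of the raw series with itself shifted by 24 h
scattering      median |first difference of raw| / raw range
resid_loess     RMS(raw - smoothed) / SD(raw)
resid_linear    RMS residual of the least-squares line / SD(raw)
period_est      lag in [16, 32] h maximising the smoothed autocorrelation
                (0 if no positive peak)
==============  =============================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks
from sklearn.ensemble import RandomForestClassifier

log = logging.getLogger(__name__)

CLASSES = ("circadian", "one_peak", "linear", "cloud")
UNCLASSIFIED = "unclassified"
FEATURE_NAMES = (
    "max_slope",
    "min_slope",
    "extremum1_t",
    "extremum2_t",
    "minmax_ratio",
    "autocorr24",
    "scattering",
    "resid_loess",
    "resid_linear",
    "period_est",
)

CLOCK_GENES = (
    "ARNTL", "NR1D1", "NR1D2", "PER1", "PER2", "PER3",
    "CRY1", "CRY2", "NPAS2", "TEF", "BHLHE41",
)

DENSE_STEP_H = 0.5


# ---------------------------------------------------------------------------
# LOESS


def loess_matrix(x: np.ndarray, xout: np.ndarray, span: float = 0.3) -> np.ndarray:
    """Linear smoother matrix S with smoothed(xout) = S @ y.

    Locally weighted degree-1 regression with tricube weights over the
    k = floor(span * n) nearest neighbours of each output point.  The
    smoother depends only on x, xout and span, so one matrix smooths every
    curve sharing the grid.
    """
    x = np.asarray(x, float)
    xout = np.asarray(xout, float)
    n = x.size
    k = int(span * n)
    if k < 4:
        raise ValueError(
            f"span {span} gives {k} points per window; need at least 4"
        )
    S = np.zeros((xout.size, n))
    for i, x0 in enumerate(xout):
        d = np.abs(x - x0)
        dmax = np.sort(d)[k - 1]
        if dmax == 0:
            dmax = np.sort(d)[-1]
            if dmax == 0:  # all x identical
                S[i] = 1.0 / n
                continue
        u = np.clip(d / dmax, 0.0, 1.0)
        w = (1.0 - u**3) ** 3
        # weighted linear fit evaluated at x0: hat row of [1, x-x0] regression
        xc = x - x0
        sw = w.sum()
        swx = (w * xc).sum()
        swxx = (w * xc * xc).sum()
        det = sw * swxx - swx * swx
        if det <= 1e-12 * max(sw * swxx, 1e-300):
            S[i] = w / sw
        else:
            S[i] = (swxx * w - swx * w * xc) / det
    return S


def loess_smooth(
    x: np.ndarray, y: np.ndarray, span: float = 0.3, xout: np.ndarray | None = None
) -> np.ndarray:
    """Smooth one curve (or a stack of curves, rows) on ``xout`` (default x)."""
    if xout is None:
        xout = np.asarray(x, float)
    S = loess_matrix(np.asarray(x, float), xout, span)
    return np.asarray(y, float) @ S.T


# ---------------------------------------------------------------------------
# features


def _interior_extrema(dense_t: np.ndarray, deriv: np.ndarray) -> list[float]:
    """Times where the smoothed derivative changes sign (interior extrema)."""
    s = np.sign(deriv)
    # carry the last nonzero sign through exact zeros
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    idx = np.flatnonzero(s[1:] * s[:-1] < 0)
    return [float(0.5 * (dense_t[i] + dense_t[i + 1])) for i in idx]


def extract_features(
    times: np.ndarray,
    raw: np.ndarray,
    smooth_sample: np.ndarray,
    smooth_dense: np.ndarray,
    dense_times: np.ndarray,
    autocorr_lag_h: float = 24.0,
    period_window_h: tuple[float, float] = (16.0, 32.0),
) -> dict[str, float]:
    """Compute the ten curve measures for one curve (see module docstring)."""
    times = np.asarray(times, float)
    raw = np.asarray(raw, float)
    sentinel = float(times[-1])
    out: dict[str, float] = {}

    deriv = np.gradient(smooth_dense, dense_times)
    out["max_slope"] = float(deriv.max())
    out["min_slope"] = float(deriv.min())

    ext = _interior_extrema(dense_times, deriv)
    out["extremum1_t"] = ext[0] if len(ext) >= 1 else sentinel
    out["extremum2_t"] = ext[1] if len(ext) >= 2 else sentinel

    lin = np.exp2(smooth_dense)
    out["minmax_ratio"] = float(lin.min() / lin.max())

    sd_raw = float(raw.std())
    step = float(times[1] - times[0])
    lag = int(round(autocorr_lag_h / step))
    if sd_raw == 0.0:
        log.debug("zero-variance curve: scattering/residuals defined as 0")
        out["autocorr24"] = 0.0
        out["scattering"] = 0.0
        out["resid_loess"] = 0.0
        out["resid_linear"] = 0.0
    else:
        a, b = raw[:-lag], raw[lag:]
        if a.std() == 0 or b.std() == 0:
            out["autocorr24"] = 0.0
        else:
            out["autocorr24"] = float(np.corrcoef(a, b)[0, 1])
        rng = float(raw.max() - raw.min())
        out["scattering"] = float(np.median(np.abs(np.diff(raw)))) / rng
        out["resid_loess"] = float(
            np.sqrt(np.mean((raw - smooth_sample) ** 2)) / sd_raw
        )
        coef = np.polyfit(times, raw, 1)
        out["resid_linear"] = float(
            np.sqrt(np.mean((raw - np.polyval(coef, times)) ** 2)) / sd_raw
        )

    # dominant period: smoothed-curve autocorrelation over the lag window
    dstep = float(dense_times[1] - dense_times[0])
    best_lag, best_r = 0.0, 0.0
    for lag_h in np.arange(period_window_h[0], period_window_h[1] + 1e-9, dstep):
        m = int(round(lag_h / dstep))
        if m >= smooth_dense.size - 2:
            break
        a, b = smooth_dense[:-m], smooth_dense[m:]
        if a.std() == 0 or b.std() == 0:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        if r > best_r:
            best_lag, best_r = float(lag_h), r
    out["period_est"] = best_lag
    return out


# ---------------------------------------------------------------------------
# curve container


@dataclass
class CurveSet:
    """All gene x (donor, condition) curves of one in-vitro experiment."""

    times: np.ndarray
    index: pd.MultiIndex  # (gene_id, donor_id, condition)
    raw: np.ndarray  # (n_curves, n_times)
    smooth_sample: np.ndarray = field(repr=False, default=None)
    smooth_dense: np.ndarray = field(repr=False, default=None)
    dense_times: np.ndarray = field(repr=False, default=None)
    features: pd.DataFrame = None

    @classmethod
    def from_expression(
        cls,
        expr: pd.DataFrame,
        samples: pd.DataFrame,
        span: float = 0.3,
        autocorr_lag_h: float = 24.0,
        period_window_h: tuple[float, float] = (16.0, 32.0),
    ) -> "CurveSet":
        """Assemble curves from an expression matrix and a sample sheet.

        ``samples`` indexed by sample_id with donor_id, condition, time_h
        (replicates already averaged).  Every (donor, condition) must cover
        the same strictly increasing, evenly spaced time grid.
        """
        groups = samples.groupby(["donor_id", "condition"], sort=True)
        times = None
        blocks, keys = [], []
        for (donor, cond), sub in groups:
            sub = sub.sort_values("time_h")
            t = sub["time_h"].to_numpy(float)
            if times is None:
                dt = np.diff(t)
                if t.size < 2 or np.any(dt <= 0) or not np.allclose(dt, dt[0]):
                    raise ValueError("times must be strictly increasing and evenly spaced")
                times = t
            elif not np.array_equal(t, times):
                raise ValueError("condition-curves cover different time grids")
            block = expr[sub.index].to_numpy(float)
            if np.isnan(block).any():
                raise ValueError("missing values in curves; filter/impute first")
            blocks.append(block)
            keys.append((donor, cond))
        raw = np.vstack(blocks)
        index = pd.MultiIndex.from_tuples(
            [(g, d, c) for (d, c) in keys for g in expr.index],
            names=["gene_id", "donor_id", "condition"],
        )
        dense = np.arange(times[0], times[-1] + 1e-9, DENSE_STEP_H)
        S_sample = loess_matrix(times, times, span)
        S_dense = loess_matrix(times, dense, span)
        sm_s = raw @ S_sample.T
        sm_d = raw @ S_dense.T
        feats = pd.DataFrame(
            [
                extract_features(
                    times, raw[i], sm_s[i], sm_d[i], dense,
                    autocorr_lag_h=autocorr_lag_h, period_window_h=period_window_h,
                )
                for i in range(raw.shape[0])
            ],
            index=index,
            columns=list(FEATURE_NAMES),
        )
        return cls(
            times=times, index=index, raw=raw,
            smooth_sample=sm_s, smooth_dense=sm_d, dense_times=dense,
            features=feats,
        )

    @property
    def genes(self) -> pd.Index:
        return self.index.get_level_values("gene_id").unique()


# ---------------------------------------------------------------------------
# seed set and self-training


def seed_training_set(
    curves: CurveSet,
    clock_genes: tuple[str, ...] = CLOCK_GENES,
    n_per_class: int = 11,
    control: str = "siControl",
    seed_donor: str | None = None,
) -> pd.Series:
    """Build the labelled seed set (``n_per_class`` curves per category).

    circadian: the siControl curve of one designated donor (the first donor
    in sorted order by default) for each core clock gene.  one_peak: curves
    with a single interior maximum in [2, 24] h and monotone tails, smoothest
    first.  linear: lowest linear residual among curves with above-median
    |net trend|.  cloud: highest scattering.  Clock genes never seed a
    non-circadian class and the classes are disjoint.
    """
    if len(set(clock_genes)) != len(clock_genes):
        raise ValueError("duplicate gene in clock-gene list")
    feats = curves.features
    idx = feats.index
    missing = [g for g in clock_genes if g not in set(idx.get_level_values("gene_id"))]
    if missing:
        raise ValueError(f"clock genes absent after filtering: {missing}")
    donors = sorted(idx.get_level_values("donor_id").unique())
    donor = seed_donor or donors[0]

    labels: dict[tuple, str] = {}
    for g in clock_genes:
        key = (g, donor, control)
        if key not in idx:
            raise ValueError(f"missing siControl curve for clock gene {g}")
        labels[key] = "circadian"

    clock = set(clock_genes)
    pool_mask = np.array([g not in clock for g in idx.get_level_values("gene_id")])
    pool = feats[pool_mask]

    pos = {key: i for i, key in enumerate(idx)}

    def _single_peak(key) -> bool:
        """One prominent interior maximum in [2, 24] h, tails monotone up to
        smoothing wiggle (extrema below 10% of the curve range ignored)."""
        sd = curves.smooth_dense[pos[key]]
        prom = 0.1 * (sd.max() - sd.min())
        if prom <= 0:
            return False
        maxima, _ = find_peaks(sd, prominence=prom)
        minima, _ = find_peaks(-sd, prominence=prom)
        if len(maxima) != 1 or len(minima) != 0:
            return False
        t_peak = curves.dense_times[maxima[0]]
        return 2.0 <= t_peak <= 24.0 and sd[maxima[0]] > sd[0] and sd[maxima[0]] > sd[-1]

    taken = set(labels)

    one_peak_ok = pool[[_single_peak(k) for k in pool.index]]
    chosen = one_peak_ok.sort_values("resid_loess").index[:n_per_class]
    if len(chosen) < n_per_class:
        raise ValueError(
            f"only {len(chosen)} eligible one_peak seed curves (need {n_per_class})"
        )
    labels.update({k: "one_peak" for k in chosen})
    taken |= set(chosen)

    slopes = np.polyfit(curves.times, curves.raw.T, 1)[0]
    net_trend = pd.Series(
        np.abs(slopes) * (curves.times[-1] - curves.times[0]), index=idx
    )
    lin_ok = pool[(net_trend[pool.index] > net_trend[pool.index].median()).to_numpy()]
    lin_ok = lin_ok[~lin_ok.index.isin(taken)]
    chosen = lin_ok.sort_values("resid_linear").index[:n_per_class]
    if len(chosen) < n_per_class:
        raise ValueError(
            f"only {len(chosen)} eligible linear seed curves (need {n_per_class})"
        )
    labels.update({k: "linear" for k in chosen})
    taken |= set(chosen)

    cloud_ok = pool[~pool.index.isin(taken)]
    chosen = cloud_ok.sort_values("scattering", ascending=False).index[:n_per_class]
    if len(chosen) < n_per_class:
        raise ValueError(
            f"only {len(chosen)} eligible cloud seed curves (need {n_per_class})"
        )
    labels.update({k: "cloud" for k in chosen})

    out = pd.Series(labels, name="label")
    out.index = pd.MultiIndex.from_tuples(out.index, names=idx.names)
    return out


def self_train(
    features: pd.DataFrame,
    seed_labels: pd.Series,
    admit_score: float = 0.9,
    target_per_class: int = 500,
    rng_seed: int = 17,
    n_estimators: int = 500,
    max_iter: int = 50,
) -> tuple[RandomForestClassifier, pd.Series, pd.DataFrame]:
    """Iterative self-training of the four-class random forest.

    Each round trains a forest on the current labelled set, scores the
    unlabelled curves, and permanently admits those whose top class
    probability reaches ``admit_score`` under that label.  ``target_per_class``
    is a per-group quota: a class that holds that many curves stops growing.
    When more curves are eligible than a class has room for, the admitted
    subset is spread evenly across the eligible confidence range rather than
    taken from one extreme — taking only the most confident curves leaves the
    class boundary uncovered, taking only the least confident over-extends
    it.  The loop stops when every class has met its quota or a round admits
    nothing; the last trained model is returned together with the final
    labelled set and a per-iteration class-count history.
    """
    X = features.to_numpy(float)
    index = features.index
    labels = seed_labels.reindex(index)
    history = []
    rf = None
    for it in range(max_iter):
        mask = labels.notna().to_numpy()
        rf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=rng_seed, n_jobs=1
        )
        rf.fit(X[mask], labels[mask].to_numpy())
        counts = labels.value_counts().reindex(CLASSES).fillna(0).astype(int)
        history.append(counts)
        if (counts >= target_per_class).all():
            break
        unl = np.flatnonzero(~mask)
        if unl.size == 0:
            break
        probs = rf.predict_proba(X[unl])
        top = probs.max(axis=1)
        cand = probs.argmax(axis=1)
        grew = False
        for j, cls in enumerate(rf.classes_):
            room = target_per_class - int(counts.get(cls, 0))
            if room <= 0:
                continue
            rows = np.flatnonzero((cand == j) & (top >= admit_score))
            if rows.size == 0:
                continue
            rows = rows[np.argsort(top[rows], kind="stable")]
            if rows.size > room:
                pick = np.unique(
                    np.round(np.linspace(0, rows.size - 1, room)).astype(int)
                )
                rows = rows[pick]
            labels.iloc[unl[rows]] = cls
            grew = True
        if not grew:
            log.warning(
                "self-training stopped without reaching %d per class: %s",
                target_per_class, counts.to_dict(),
            )
            break
    hist = pd.DataFrame(history)
    hist.index.name = "iteration"
    return rf, labels[labels.notna()], hist


def call_category(probs: np.ndarray, classes: list[str], threshold: float = 0.5) -> str:
    """Final call: argmax class iff unique and strictly above the threshold."""
    probs = np.asarray(probs, float)
    top = probs.max()
    if top <= threshold or (probs == top).sum() > 1:
        return UNCLASSIFIED
    return str(classes[int(probs.argmax())])


def classify_curves(
    rf: RandomForestClassifier, features: pd.DataFrame, threshold: float = 0.5
) -> pd.DataFrame:
    """Class probabilities and the final category for every curve."""
    probs = rf.predict_proba(features.to_numpy(float))
    full = pd.DataFrame(0.0, index=features.index, columns=list(CLASSES))
    for j, c in enumerate(rf.classes_):
        full[c] = probs[:, j]
    full["category"] = [
        call_category(row, list(CLASSES), threshold) for row in full[list(CLASSES)].to_numpy()
    ]
    return full


# ---------------------------------------------------------------------------
# 16-model assignment

_ALL_MASKS = [
    (a, b, c, d) for a in (1, 0) for b in (1, 0) for c in (1, 0) for d in (1, 0)
]


def _canonical_model_order() -> dict[tuple[int, int, int, int], int]:
    """Model numbering over the 4-bit rhythmicity mask.

    Bit order: (donorA siControl, donorB siControl, donorA siCLOCK,
    donorB siCLOCK).  Models 1-4 are the fixed patterns 1111, 1110,
    1101, 1100; the remaining nonzero masks follow in order of descending
    number of rhythmic siControl curves then descending binary value;
    model 16 is 0000.
    """
    nonzero = [m for m in _ALL_MASKS if any(m)]
    nonzero.sort(key=lambda m: (-(m[0] + m[1]), -(8 * m[0] + 4 * m[1] + 2 * m[2] + m[3])))
    order = {m: i + 1 for i, m in enumerate(nonzero)}
    order[(0, 0, 0, 0)] = 16
    return order


MODEL_FOR_MASK = _canonical_model_order()


def assign_models(
    calls: pd.DataFrame,
    control: str = "siControl",
    knockdown: str = "siCLOCK",
) -> pd.DataFrame:
    """Map per-curve categories to the per-gene 16-model assignment.

    ``calls`` is indexed by (gene_id, donor_id, condition) with a
    ``category`` column; a curve is rhythmic iff its category is
    ``circadian`` (unclassified counts as non-rhythmic).  Donors are taken
    in sorted order as (donorA, donorB).
    """
    cat = calls["category"]
    donors = sorted(calls.index.get_level_values("donor_id").unique())
    if len(donors) != 2:
        raise ValueError(f"expected 2 donors, got {donors}")
    genes = calls.index.get_level_values("gene_id").unique()
    combos = [(donors[0], control), (donors[1], control), (donors[0], knockdown), (donors[1], knockdown)]
    masks, models = [], []
    for g in genes:
        bits = []
        for donor, cond in combos:
            key = (g, donor, cond)
            if key not in cat.index:
                raise ValueError(f"gene {g}: missing condition-curve {(donor, cond)}")
            bits.append(int(cat[key] == "circadian"))
        mask = tuple(bits)
        masks.append("".join(map(str, mask)))
        models.append(MODEL_FOR_MASK[mask])
    return pd.DataFrame({"mask": masks, "model": models}, index=pd.Index(genes, name="gene_id"))


# ---------------------------------------------------------------------------
# amplitudes


def curve_amplitude(smooth_dense_log2: np.ndarray) -> float:
    """Linear-scale peak-to-trough: max - min of 2**smoothed over the window."""
    lin = np.exp2(np.asarray(smooth_dense_log2, float))
    return float(lin.max() - lin.min())


def condition_amplitudes(curves: CurveSet) -> pd.DataFrame:
    """Per (gene, condition): curve amplitude averaged over donors."""
    amps = pd.Series(
        [curve_amplitude(sd) for sd in curves.smooth_dense], index=curves.index
    )
    return amps.groupby(level=["gene_id", "condition"]).mean().unstack("condition")


@dataclass
class AmplitudeComparison:
    mean_log10_diff: float
    t_stat: float
    p: float
    n_pairs: int
    n_excluded: int


def compare_amplitudes(
    amp_ctrl: pd.Series, amp_kd: pd.Series
) -> AmplitudeComparison:
    """Paired two-sided t-test on log10 amplitudes (knockdown - control).

    Amplitudes are compared on the log10 scale, which brings the right-skewed
    linear amplitudes close to normality.  Pairs with a non-positive
    amplitude are excluded (count reported); fewer than 3 usable pairs is an
    error.
    """
    df = pd.concat({"ctrl": amp_ctrl, "kd": amp_kd}, axis=1).dropna()
    ok = (df["ctrl"] > 0) & (df["kd"] > 0)
    n_excluded = int((~ok).sum())
    if n_excluded:
        log.info("excluded %d gene pairs with zero amplitude", n_excluded)
    df = df[ok]
    if len(df) < 3:
        raise ValueError(f"need >= 3 amplitude pairs, got {len(df)}")
    d = np.log10(df["kd"].to_numpy()) - np.log10(df["ctrl"].to_numpy())
    if np.allclose(d, 0.0):
        return AmplitudeComparison(0.0, 0.0, 1.0, len(df), n_excluded)
    t, p = stats.ttest_rel(np.log10(df["kd"]), np.log10(df["ctrl"]))
    return AmplitudeComparison(float(d.mean()), float(t), float(p), len(df), n_excluded)
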