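"""Synthetic data emulating both study designs, with known ground truth.

In-vivo arm: 10 donors sampled at 4-h intervals over 24 h (clock times
12:00, 16:00, 20:00, 24:00, 04:00, 08:00, encoded as 12..32 h).  Each gene
carries a log2 intronic (pre-mRNA) harmonic signal; its exonic (mRNA) signal
is the steady-state response of first-order degradation at rate
k = ln2 / half_life, which attenuates the oscillation by

    g = k / sqrt(k^2 + w^2)        (w = 2*pi / period)

and delays it by  delta = atan2(w, k) / w  hours, while the baseline gains
the steady-state offset log2(half_life / ln2).  Donor-specific baseline
offsets are shared between the layers.  Counts are drawn negative-binomially
from the RPKM-implied means; the noisy log2 signal matrices are also
returned, since the harmonic mixed model consumes log2 expression.

In-vitro arm: 2 donors x {siControl, siCLOCK} x 25 time points (0..48 h,
2-h spacing), collected in duplicate at every time point.  Four curve
archetypes: damped cosine (circadian; siCLOCK multiplies the amplitude by
``kd_amp_factor``), a single Gaussian bump early in the course (one_peak),
a linear drift (linear), and pure scatter (cloud).  Gaussian log2 noise is
added independently to every replicate measurement.  Eleven designated
clock-gene analogues (named after the core clock genes) are always included
as high-amplitude circadian genes so seed construction is realistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GeneRegions, TranscriptModel, build_gene_regions
from .curves import CLOCK_GENES


def attenuation(half_life_h: float | np.ndarray, period_h: float = 24.0):
    """(gain g, delay delta_h) of first-order degradation on a harmonic drive."""
    k = np.log(2.0) / np.asarray(half_life_h, float)
    w = 2.0 * np.pi / period_h
    g = k / np.hypot(k, w)
    delta = np.arctan2(w, k) / w
    return g, delta


# ---------------------------------------------------------------------------
# in-vivo generator


@dataclass
class InVivoData:
    exonic_counts: pd.DataFrame
    intronic_counts: pd.DataFrame
    exonic_log2: pd.DataFrame  # noisy log2 signal (the mixed model's scale)
    intronic_log2: pd.DataFrame
    exonic_signal: pd.DataFrame  # noise-free log2 signal
    intronic_signal: pd.DataFrame
    samples: pd.DataFrame
    lengths: pd.DataFrame
    truth: pd.DataFrame


def gen_in_vivo(
    n_genes: int,
    n_donors: int = 10,
    times: tuple = (12, 16, 20, 24, 28, 32),
    rhythmic_frac: float = 0.5,
    amp_range: tuple[float, float] = (0.5, 2.0),
    half_life_range: tuple[float, float] = (0.5, 48.0),
    mu_p_range: tuple[float, float] = (0.0, 4.0),
    donor_sd: float = 0.5,
    sigma_e: float = 0.25,
    dispersion: float = 0.05,
    lib_size: float = 2e7,
    period_h: float = 24.0,
    rng_seed: int | None = None,
) -> InVivoData:
    """Simulate the serial-biopsy design (see module docstring).

    ``amp_range`` is the planted intronic log2 peak-to-trough range; pass a
    degenerate range (x, x) to plant one amplitude.  ``sigma_e`` is the
    residual log2 SD, ``donor_sd`` the SD of the per-gene donor intercepts.
    """
    if not 0 <= rhythmic_frac <= 1:
        raise ValueError("rhythmic_frac must lie in [0, 1]")
    if donor_sd < 0 or sigma_e < 0 or dispersion < 0 or lib_size <= 0:
        raise ValueError("invalid noise/library parameters")
    rng = np.random.default_rng(rng_seed)
    times = np.asarray(times, float)
    w = 2.0 * np.pi / period_h

    genes = [f"G{i:05d}" for i in range(n_genes)]
    donors = [f"D{j:02d}" for j in range(n_donors)]
    rhythmic = rng.random(n_genes) < rhythmic_frac
    A = np.where(rhythmic, rng.uniform(*amp_range, n_genes), 0.0)
    phase = rng.uniform(0.0, period_h, n_genes)
    half_life = np.exp(rng.uniform(*np.log(half_life_range), n_genes))
    mu_p = rng.uniform(*mu_p_range, n_genes)
    mu_m = mu_p + np.log2(half_life / np.log(2.0))
    g_att, delta = attenuation(half_life, period_h)

    u = rng.normal(0.0, donor_sd, (n_genes, n_donors))  # per gene x donor

    t_grid = np.tile(times, n_donors)  # samples ordered donor-major
    donor_of_sample = np.repeat(np.arange(n_donors), times.size)
    sample_ids = [
        f"{donors[d]}_T{int(t):02d}" for d, t in zip(donor_of_sample, t_grid)
    ]

    osc_p = (A[:, None] / 2.0) * np.cos(w * (t_grid[None, :] - phase[:, None]))
    osc_m = (A[:, None] * g_att[:, None] / 2.0) * np.cos(
        w * (t_grid[None, :] - phase[:, None] - delta[:, None])
    )
    base = u[:, donor_of_sample]
    sig_p = mu_p[:, None] + osc_p + base
    sig_m = mu_m[:, None] + osc_m + base
    noisy_p = sig_p + rng.normal(0.0, sigma_e, sig_p.shape)
    noisy_m = sig_m + rng.normal(0.0, sigma_e, sig_m.shape)

    len_ex = rng.integers(500, 5000, n_genes)
    len_in = rng.integers(2000, 20000, n_genes)
    libs = lib_size * rng.uniform(0.8, 1.2, len(sample_ids))

    def _counts(log2sig, lengths):
        mean = np.exp2(log2sig) * (lengths[:, None] / 1e3) * (libs[None, :] / 1e6)
        if dispersion > 0:
            r = 1.0 / dispersion
            p = r / (r + mean)
            return rng.negative_binomial(r, p)
        return rng.poisson(mean)

    counts_ex = _counts(noisy_m, len_ex)
    counts_in = _counts(noisy_p, len_in)

    samples = pd.DataFrame(
        {
            "donor_id": [donors[d] for d in donor_of_sample],
            "time_h": t_grid,
            "condition": "none",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    gidx = pd.Index(genes, name="gene_id")
    truth = pd.DataFrame(
        {
            "truth_rhythmic": rhythmic,
            "truth_amp": A,
            "truth_phase": phase % period_h,
            "truth_half_life": half_life,
            "truth_mu_p": mu_p,
            "truth_mu_m": mu_m,
            "truth_attenuation": g_att,
            "truth_delay_h": delta,
        },
        index=gidx,
    )
    lengths = pd.DataFrame(
        {"exonic_length": len_ex, "intronic_length": len_in}, index=gidx
    )
    mk = lambda arr: pd.DataFrame(arr, index=gidx, columns=sample_ids)
    return InVivoData(
        exonic_counts=mk(counts_ex),
        intronic_counts=mk(counts_in),
        exonic_log2=mk(noisy_m),
        intronic_log2=mk(noisy_p),
        exonic_signal=mk(sig_m),
        intronic_signal=mk(sig_p),
        samples=samples,
        lengths=lengths,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# in-vitro generator


@dataclass
class InVitroData:
    expr: pd.DataFrame  # log2 RPKM, genes x samples
    samples: pd.DataFrame
    truth: pd.DataFrame


def gen_in_vitro(
    n_genes: int = 2000,
    donors: tuple[str, str] = ("donorA", "donorB"),
    conditions: tuple[str, str] = ("siControl", "siCLOCK"),
    times: np.ndarray | None = None,
    mix: tuple[float, float, float, float] = (0.10, 0.10, 0.10, 0.70),
    kd_amp_factor: float = 0.4,
    sigma: float = 0.15,
    tau_h: float = 36.0,
    period_h: float = 24.0,
    baseline_range: tuple[float, float] = (2.0, 8.0),
    amp_range: tuple[float, float] = (1.0, 2.5),
    clock_amp_range: tuple[float, float] = (1.5, 2.5),
    donor_baseline_sd: float = 0.3,
    cloud_sd: float = 0.5,
    replicates: int = 2,
    sub_threshold_frac: float = 0.0,
    rng_seed: int | None = None,
) -> InVitroData:
    """Simulate the dense synchronised-myotube design (see module docstring).

    ``mix`` gives the archetype probabilities (circadian, one_peak, linear,
    cloud) for the non-clock genes and must sum to 1.  The eleven clock-gene
    analogues are prepended with amplitudes from ``clock_amp_range``.  With
    ``sub_threshold_frac`` > 0 that fraction of genes is planted below the
    log2 RPKM expression floor (for filter tests).
    """
    if abs(sum(mix) - 1.0) > 1e-9:
        raise ValueError(f"archetype mix must sum to 1, got {sum(mix)}")
    if n_genes < len(CLOCK_GENES):
        raise ValueError(f"n_genes must be >= {len(CLOCK_GENES)}")
    rng = np.random.default_rng(rng_seed)
    if times is None:
        times = np.arange(0.0, 48.0 + 1e-9, 2.0)
    times = np.asarray(times, float)
    w = 2.0 * np.pi / period_h
    classes = ("circadian", "one_peak", "linear", "cloud")

    n_clock = len(CLOCK_GENES)
    genes = list(CLOCK_GENES) + [f"G{i:05d}" for i in range(n_genes - n_clock)]
    archetype = np.array(
        ["circadian"] * n_clock
        + list(rng.choice(classes, size=n_genes - n_clock, p=list(mix)))
    )

    base = rng.uniform(*baseline_range, n_genes)
    if sub_threshold_frac > 0:
        low = rng.random(n_genes) < sub_threshold_frac
        low[:n_clock] = False  # clock genes stay expressed
        base = np.where(low, rng.uniform(-2.0, -0.5, n_genes), base)
    else:
        low = np.zeros(n_genes, bool)
    amp = np.where(
        np.arange(n_genes) < n_clock,
        rng.uniform(*clock_amp_range, n_genes),
        rng.uniform(*amp_range, n_genes),
    )
    phase = rng.uniform(0.0, period_h, n_genes)
    bump_t0 = rng.uniform(4.0, 16.0, n_genes)
    bump_w = rng.uniform(3.0, 6.0, n_genes)
    bump_h = rng.uniform(0.8, 2.0, n_genes)
    slope = rng.uniform(0.02, 0.06, n_genes) * rng.choice([-1.0, 1.0], n_genes)
    donor_off = rng.normal(0.0, donor_baseline_sd, (n_genes, len(donors)))

    env = np.exp(-times / tau_h)

    def _signal(i: int, mult: float) -> np.ndarray:
        a = archetype[i]
        if a == "circadian":
            return (amp[i] * mult / 2.0) * env * np.cos(w * (times - phase[i]))
        if a == "one_peak":
            return bump_h[i] * np.exp(-((times - bump_t0[i]) ** 2) / (2 * bump_w[i] ** 2))
        if a == "linear":
            return slope[i] * times
        return np.zeros_like(times)  # cloud: scatter only

    cols, meta = [], []
    blocks = []
    for di, donor in enumerate(donors):
        for cond in conditions:
            mult = kd_amp_factor if cond == conditions[1] else 1.0
            clean = np.empty((n_genes, times.size))
            for i in range(n_genes):
                clean[i] = base[i] + donor_off[i, di] + _signal(i, mult)
            for r in range(1, replicates + 1):
                block = clean.copy()
                is_cloud = archetype == "cloud"
                if is_cloud.any():
                    block[is_cloud] += rng.normal(
                        0.0, cloud_sd, (int(is_cloud.sum()), times.size)
                    )
                if sigma > 0:
                    block = block + rng.normal(0.0, sigma, block.shape)
                blocks.append(block)
                for t in times:
                    sid = f"{donor}_{cond}_T{t:04.1f}_R{r}"
                    cols.append(sid)
                    meta.append((sid, donor, cond, t, r))
    expr = pd.DataFrame(
        np.hstack(blocks), index=pd.Index(genes, name="gene_id"), columns=cols
    )
    samples = pd.DataFrame(
        meta, columns=["sample_id", "donor_id", "condition", "time_h", "replicate"]
    ).set_index("sample_id")
    truth = pd.DataFrame(
        {
            "truth_archetype": archetype,
            "truth_amp": np.where(archetype == "circadian", amp, 0.0),
            "truth_phase": phase,
            "truth_kd_factor": np.where(archetype == "circadian", kd_amp_factor, 1.0),
            "truth_tau_h": tau_h,
            "truth_sub_threshold": low,
            "truth_clock_gene": np.arange(n_genes) < n_clock,
        },
        index=expr.index,
    )
    return InVitroData(expr=expr, samples=samples, truth=truth)


# ---------------------------------------------------------------------------
# toy annotation


def gen_toy_annotation(
    n_genes: int,
    rng_seed: int | None = None,
    max_transcripts: int = 4,
    max_exons: int = 5,
    span_bp: tuple[int, int] = (1_000, 8_000),
) -> tuple[list[TranscriptModel], dict[str, GeneRegions]]:
    """Random multi-transcript toy genes plus per-base-labelled truth regions.

    The truth is computed by exhaustive per-base labelling (a base is exonic
    if any exon covers it, intronic if some transcript span covers it and no
    exon does), independent of the interval algebra under test.
    """
    rng = np.random.default_rng(rng_seed)
    transcripts: list[TranscriptModel] = []
    truth: dict[str, GeneRegions] = {}
    for gi in range(n_genes):
        gid = f"TG{gi:04d}"
        g0 = gi * 50_000 + 1
        L = int(rng.integers(*span_bp))
        strand = str(rng.choice(["+", "-"]))
        n_tr = int(rng.integers(1, max_transcripts + 1))
        gene_tr = []
        for ti in range(n_tr):
            ne = int(rng.integers(1, max_exons + 1))
            cuts = np.sort(rng.choice(np.arange(L), size=2 * ne, replace=False))
            exons = tuple(
                (g0 + int(cuts[2 * j]), g0 + int(cuts[2 * j + 1]))
                for j in range(ne)
            )
            gene_tr.append(
                TranscriptModel(gid, f"{gid}.T{ti}", "chr1", strand, exons)
            )
        transcripts.extend(gene_tr)

        # independent per-base truth
        hi = max(t.span[1] for t in gene_tr) + 1
        exonic = np.zeros(hi - g0, bool)
        covered = np.zeros(hi - g0, bool)
        for t in gene_tr:
            s, e = t.span
            covered[s - g0 : e - g0 + 1] = True
            for xs, xe in t.exons:
                exonic[xs - g0 : xe - g0 + 1] = True
        intronic = covered & ~exonic

        def _runs(mask: np.ndarray) -> tuple:
            out = []
            idx = np.flatnonzero(mask)
            if idx.size:
                brk = np.flatnonzero(np.diff(idx) > 1)
                starts = np.r_[idx[0], idx[brk + 1]]
                ends = np.r_[idx[brk], idx[-1]]
                out = [(g0 + int(s), g0 + int(e)) for s, e in zip(starts, ends)]
            return tuple(out)

        truth[gid] = GeneRegions(
            gene_id=gid,
            chrom="chr1",
            strand=strand,
            exonic=_runs(exonic),
            intronic=_runs(intronic),
            exonic_length=int(exonic.sum()),
            intronic_length=int(intronic.sum()),
        )
    return transcripts, truth


# ---------------------------------------------------------------------------
# motif memberships


def gen_motif_memberships(
    phases: pd.Series,
    enriched_bin: int,
    p_in: float = 0.8,
    p_out: float = 0.1,
    n_decoys: int = 50,
    decoy_rate: float = 0.15,
    bin_width_h: float = 4.0,
    period_h: float = 24.0,
    rng_seed: int | None = None,
) -> tuple[dict[str, set[str]], dict]:
    """One planted motif concentrated in a phase bin, plus uniform decoys.

    ``phases`` maps gene_id -> phase (h).  The planted term includes genes in
    ``enriched_bin`` with probability ``p_in`` and the rest with ``p_out``;
    each decoy includes every gene with probability ``decoy_rate``.
    """
    if not (0 <= p_out < p_in <= 1) and not (p_in == p_out):
        raise ValueError("need 0 <= p_out < p_in <= 1 (or p_in == p_out for a null)")
    rng = np.random.default_rng(rng_seed)
    nb = int(round(period_h / bin_width_h))
    bins = (np.floor(phases.to_numpy(float) / bin_width_h) % nb).astype(int)
    in_bin = bins == enriched_bin
    prob = np.where(in_bin, p_in, p_out)
    planted = set(phases.index[rng.random(len(phases)) < prob])
    memberships = {"MOTIF_PLANTED": planted}
    for d in range(n_decoys):
        memberships[f"DECOY_{d:03d}"] = set(
            phases.index[rng.random(len(phases)) < decoy_rate]
        )
    truth = {"term": "MOTIF_PLANTED", "bin": enriched_bin, "n_in_bin": int(in_bin.sum())}
    return memberships, truth
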