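"""End-to-end orchestration of the two rhythm-detection arms.

``run_invivo`` normalises the exonic/intronic count matrices, applies the
expression filters, fits the donor random-intercept harmonic model per layer,
groups genes (R-I.R-E / R-I / R-E / NR), computes the exon/intron half-life
proxy, and optionally runs the phase-binned motif enrichment.

``run_invitro`` filters the expression matrix, assembles the four condition-
curves per gene (2 donors x siControl/siCLOCK), extracts the
LOESS shape features, self-trains the random-forest classifier from the
clock-gene seed set, makes the final per-curve calls and the per-gene
16-model assignment, and compares siControl vs siCLOCK amplitudes.

``compare_rhythmic_sets`` mirrors the in-vivo / in-vitro overlap funnel:
genes rhythmic in vitro (selected models) -> subset expressed in vivo ->
subset also rhythmic at the mRNA (exonic) level in vivo.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import curves as cv
from . import enrichment as en
from . import preprocess as pp
from . import rhythm as rh

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable thresholds; defaults are the published analysis settings."""

    period_h: float = 24.0
    fdr: float = 0.05
    min_intronic_reads: float = 2.0
    min_exonic_reads: float = 10.0
    min_exonic_log2rpkm: float = -2.0
    min_intronic_log2rpkm: float = -3.0
    invitro_min_log2rpkm: float = 0.0
    loess_span: float = 0.3
    admit_score: float = 0.9
    target_per_class: int = 500
    n_trees: int = 500
    rf_seed: int = 17
    amp_min: float = 0.5
    enrich_min_genes: int = 5
    enrich_p_max: float = 1e-4
    bin_width_h: float = 4.0
    clock_genes: tuple = field(default_factory=lambda: cv.CLOCK_GENES)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["clock_genes"] = list(d["clock_genes"])
        return d

    @property
    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def run_invivo(
    exonic_counts: pd.DataFrame,
    intronic_counts: pd.DataFrame,
    samples: pd.DataFrame,
    lengths: pd.DataFrame,
    config: PipelineConfig | None = None,
    memberships: dict[str, set[str]] | None = None,
) -> dict:
    """In-vivo arm: normalise, filter, fit both layers, group, proxy, enrich."""
    cfg = config or PipelineConfig()
    libs = pp.exonic_library_sizes(exonic_counts)
    ex_log2 = pp.compute_log2_rpkm(exonic_counts, lengths["exonic_length"], libs)
    in_log2 = pp.compute_log2_rpkm(intronic_counts, lengths["intronic_length"], libs)
    ex_f, in_f, report = pp.filter_in_vivo(
        exonic_counts, intronic_counts, ex_log2, in_log2,
        cfg.min_intronic_reads, cfg.min_exonic_reads,
        cfg.min_exonic_log2rpkm, cfg.min_intronic_log2rpkm,
    )
    if ex_f.empty:
        log.warning("no testable genes after filtering")
        return {"fits": {}, "groups": pd.Series(dtype=object), "filter_report": report,
                "config": cfg, "halflife_proxy": pd.Series(dtype=float)}
    log.info("fitting %d genes on both layers", len(ex_f))
    fit_ex = rh.fit_layer(ex_f, samples, cfg.period_h)
    fit_in = rh.fit_layer(in_f, samples, cfg.period_h)
    groups = rh.classify_rhythm_groups(fit_in["q"], fit_ex["q"], cfg.fdr)
    proxy = pp.exon_intron_ratio(ex_f, in_f)
    out = {
        "fits": {"exonic": fit_ex, "intronic": fit_in},
        "groups": groups,
        "halflife_proxy": proxy,
        "filter_report": report,
        "config": cfg,
        "group_counts": groups.value_counts().to_dict(),
    }
    log.info("rhythm groups: %s", out["group_counts"])
    if memberships is not None:
        fore = en.select_foreground(
            fit_in, cfg.fdr, cfg.amp_min, cfg.bin_width_h, cfg.period_h
        )
        background = set(ex_f.index)
        out["enrichment"] = en.run_enrichment(
            fore, memberships, background, cfg.enrich_min_genes, cfg.enrich_p_max
        )
    return out


def run_invitro(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> dict:
    """In-vitro arm: filter, featurise, self-train, call, assign, compare."""
    cfg = config or PipelineConfig()
    expr_avg, sheet = pp.average_replicates(expr, samples)
    kept = pp.filter_in_vitro(expr_avg, sheet, cfg.invitro_min_log2rpkm)
    if kept.empty:
        raise ValueError("no genes pass the in-vitro expression filter")
    curveset = cv.CurveSet.from_expression(expr_avg.loc[kept], sheet, cfg.loess_span)
    seeds = cv.seed_training_set(curveset, tuple(cfg.clock_genes))
    rf, labels, history = cv.self_train(
        curveset.features, seeds,
        admit_score=cfg.admit_score, target_per_class=cfg.target_per_class,
        rng_seed=cfg.rf_seed, n_estimators=cfg.n_trees,
    )
    calls = cv.classify_curves(rf, curveset.features)
    models = cv.assign_models(calls)
    amps = cv.condition_amplitudes(curveset)
    model_counts = models["model"].value_counts().sort_index()
    assert int(model_counts.sum()) == models.shape[0]
    log.info("model counts: %s", model_counts.to_dict())
    comparison = None
    m1 = models.index[models["model"] == 1]
    if len(m1) >= 3:
        comparison = cv.compare_amplitudes(
            amps.loc[m1, "siControl"], amps.loc[m1, "siCLOCK"]
        )
    return {
        "curves": curveset,
        "seeds": seeds,
        "classifier": rf,
        "training_history": history,
        "calls": calls,
        "models": models,
        "amplitudes": amps,
        "amplitude_comparison": comparison,
        "config": cfg,
        "model_counts": model_counts,
    }


def compare_rhythmic_sets(
    invivo_fit_exonic: pd.DataFrame,
    models: pd.DataFrame,
    model_subset: tuple[int, ...] = (1, 2, 3, 4),
    fdr: float = 0.05,
) -> dict:
    """Overlap funnel between the in-vitro rhythmic genes and the in-vivo arm.

    Returns counts and gene lists for: in-vitro rhythmic (selected models),
    the subset expressed (tested) in vivo, and the subset also rhythmic at
    the exonic (mRNA) level in vivo at q < fdr.
    """
    invitro = set(models.index[models["model"].isin(model_subset)])
    expressed = set(invivo_fit_exonic.index)
    if invitro and expressed and not (invitro & expressed):
        log.warning("in-vitro and in-vivo gene namespaces are disjoint")
    overlap_expr = invitro & expressed
    rhythmic_invivo = set(
        invivo_fit_exonic.index[(invivo_fit_exonic["q"] < fdr).fillna(False)]
    )
    overlap_rhythmic = overlap_expr & rhythmic_invivo
    funnel = {
        "n_invitro_rhythmic": len(invitro),
        "n_expressed_in_vivo": len(overlap_expr),
        "n_rhythmic_in_vivo": len(overlap_rhythmic),
    }
    assert (
        funnel["n_invitro_rhythmic"]
        >= funnel["n_expressed_in_vivo"]
        >= funnel["n_rhythmic_in_vivo"]
    )
    return {
        **funnel,
        "genes_invitro": sorted(invitro),
        "genes_expressed": sorted(overlap_expr),
        "genes_rhythmic": sorted(overlap_rhythmic),
    }


def write_manifest(outdir: str | Path, config: PipelineConfig, extra: dict | None = None):
    """Serialise the full config (and its hash) into the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "config_hash": config.digest}
    if extra:
        manifest.update(extra)
    with open(outdir / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return outdir / "run_manifest.yaml"
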