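"""Normalisation to log2 RPKM, expression filters, and the half-life proxy.

Count matrices are pandas DataFrames (genes x samples, non-negative ints).
Expression matrices are DataFrames of log2 RPKM where masked entries (zero
counts, or an intronic layer failing its expression floor) are NaN — never
silently zero.

The library scaling factor is derived from the exonic layer (column sums of
the exonic count matrix by default) and applied to both layers, so that the
intronic and exonic signals of one sample share a common sequencing-depth
normaliser.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def exonic_library_sizes(exonic_counts: pd.DataFrame) -> pd.Series:
    """Per-sample library size: total exonic mapped counts."""
    sizes = exonic_counts.sum(axis=0).astype(float)
    if (sizes <= 0).any():
        bad = sizes.index[sizes <= 0].tolist()
        raise ValueError(f"zero exonic library size for samples {bad}")
    return sizes


def trimmed_mean_library_sizes(
    exonic_counts: pd.DataFrame, trim: float = 0.3
) -> pd.Series:
    """Optional trimmed-mean-of-ratios scaling (robust alternative).

    Scales each sample's total count by the trimmed mean of per-gene
    log-ratios against the geometric-mean reference sample.
    """
    counts = exonic_counts.to_numpy(float)
    sizes = counts.sum(axis=0)
    cpm = counts / sizes * 1e6
    with np.errstate(divide="ignore"):
        logref = np.log2(cpm).mean(axis=1)
    factors = []
    for j in range(cpm.shape[1]):
        with np.errstate(divide="ignore"):
            m = np.log2(cpm[:, j]) - logref
        m = m[np.isfinite(m)]
        if m.size == 0:
            factors.append(1.0)
            continue
        lo, hi = np.quantile(m, [trim / 2, 1 - trim / 2])
        kept = m[(m >= lo) & (m <= hi)]
        factors.append(2 ** kept.mean() if kept.size else 1.0)
    return pd.Series(sizes * np.asarray(factors), index=exonic_counts.columns)


def compute_log2_rpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """log2( count / (length_kb * library_millions) ); zero counts -> NaN.

    ``lengths`` are region lengths in bp, ``library_sizes`` the (scaled)
    per-sample library sizes.  With ``pseudocount`` > 0 that many reads are
    added to every count before the log (dense log-scale curves for the
    in-vitro arm); otherwise zero counts are masked.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()[:5]
        raise ValueError(f"missing region lengths for genes {missing}")
    if (lengths <= 0).any():
        raise ValueError("region lengths must be positive")
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any() or library_sizes.isna().any():
        raise ValueError("library sizes must be positive for every sample")
    c = counts.to_numpy(float) + pseudocount
    denom = np.outer(lengths.to_numpy(float) / 1e3, library_sizes.to_numpy(float) / 1e6)
    with np.errstate(divide="ignore"):
        vals = np.log2(c / denom)
    vals[~np.isfinite(vals)] = np.nan
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def filter_in_vivo(
    exonic_counts: pd.DataFrame,
    intronic_counts: pd.DataFrame,
    exonic_log2: pd.DataFrame,
    intronic_log2: pd.DataFrame,
    min_intronic_reads: float = 2.0,
    min_exonic_reads: float = 10.0,
    min_exonic_log2rpkm: float = -2.0,
    min_intronic_log2rpkm: float = -3.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Apply the in-vivo expression filters; returns (exonic, intronic, report).

    Rules, applied to per-gene means:
      1. discard genes with mean intronic count < 2 or mean exonic count < 10;
      2. discard genes with mean exonic log2 RPKM < -2 (strict);
      3. genes with mean intronic log2 RPKM < -3 keep their exonic values but
         the whole intronic layer is set missing (NaN).
    Gene means of log2 RPKM are taken over unmasked samples; a gene with all
    samples masked counts as below any floor.
    """
    genes = exonic_counts.index
    if not genes.equals(intronic_counts.index):
        raise ValueError("exonic and intronic matrices must share the gene universe")

    mean_in = intronic_counts.mean(axis=1)
    mean_ex = exonic_counts.mean(axis=1)
    low_counts = (mean_in < min_intronic_reads) | (mean_ex < min_exonic_reads)

    mean_ex_log2 = exonic_log2.mean(axis=1, skipna=True).fillna(-np.inf)
    low_exonic_expr = (mean_ex_log2 < min_exonic_log2rpkm) & ~low_counts

    keep = ~(low_counts | low_exonic_expr)
    kept = genes[keep]

    mean_in_log2 = intronic_log2.loc[kept].mean(axis=1, skipna=True).fillna(-np.inf)
    mask_intronic = mean_in_log2.index[mean_in_log2 < min_intronic_log2rpkm]

    ex_out = exonic_log2.loc[kept]
    in_out = intronic_log2.loc[kept].copy()
    in_out.loc[mask_intronic] = np.nan

    report = pd.DataFrame(
        {
            "rule": [
                "low_mean_counts",
                "low_exonic_log2rpkm",
                "intronic_layer_masked",
            ],
            "genes_removed": [
                int(low_counts.sum()),
                int(low_exonic_expr.sum()),
                int(len(mask_intronic)),
            ],
        }
    )
    log.info(
        "in-vivo filter: %d genes in, %d kept, %d intronic layers masked",
        len(genes),
        len(kept),
        len(mask_intronic),
    )
    return ex_out, in_out, report


def average_replicates(
    expr: pd.DataFrame, samples: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average replicate samples per (donor, condition, time).

    ``samples`` is indexed by sample_id with columns donor_id, condition,
    time_h.  Returns the averaged expression matrix and the collapsed sheet.
    """
    key = ["donor_id", "condition", "time_h"]
    groups = samples.groupby(key, sort=True).groups
    cols, rows = [], []
    for (donor, cond, t), ids in groups.items():
        name = f"{donor}_{cond}_T{float(t):05.1f}"
        cols.append(expr[list(ids)].mean(axis=1).rename(name))
        rows.append((name, donor, cond, t))
    out = pd.concat(cols, axis=1)
    sheet = pd.DataFrame(
        rows, columns=["sample_id", "donor_id", "condition", "time_h"]
    ).set_index("sample_id")
    if len(out.columns) != len(samples):
        log.info("averaged %d samples into %d time points", len(samples), len(out.columns))
    return out, sheet


def filter_in_vitro(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    min_log2rpkm: float = 0.0,
) -> pd.Index:
    """Keep genes whose per-curve mean log2 RPKM exceeds the floor in all four
    condition-curves (2 donors x 2 conditions).

    The threshold is applied to the mean across each curve's time points;
    per-time-point strictness would discard oscillating genes crossing the
    floor.
    """
    curves = samples.groupby(["donor_id", "condition"]).groups
    if len(curves) != 4:
        raise ValueError(
            f"expected 4 condition-curves (2 donors x 2 conditions), got {len(curves)}"
        )
    keep = pd.Series(True, index=expr.index)
    for _, ids in curves.items():
        keep &= expr[list(ids)].mean(axis=1, skipna=True) > min_log2rpkm
    kept = expr.index[keep.fillna(False)]
    log.info("in-vitro filter: %d of %d genes kept", len(kept), len(expr))
    return kept


def exon_intron_ratio(
    exonic_log2: pd.DataFrame, intronic_log2: pd.DataFrame
) -> pd.Series:
    """Half-life proxy: mean exonic log2 RPKM minus mean intronic log2 RPKM.

    At steady state the mature/nascent abundance ratio is inversely
    proportional to the degradation rate, so a higher proxy implies a longer
    inferred mRNA half-life.  Genes with a fully masked intronic layer get
    NaN.
    """
    ex = exonic_log2.mean(axis=1, skipna=True)
    inn = intronic_log2.mean(axis=1, skipna=True)
    return (ex - inn).rename("halflife_proxy")
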