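"""Phase-binned hypergeometric over-representation of gene-set memberships.

Genes rhythmic at the chosen layer (q below the FDR cut) with log2
peak-to-trough amplitude strictly above ``amp_min`` are partitioned into
phase bins; for every (membership term, bin) pair the upper-tail
hypergeometric probability of the observed overlap is computed against the
full expressed background.  No multiple-testing correction is applied to the
reported raw-threshold hits, but a BH column is emitted for transparency.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy.stats import hypergeom

from .rhythm import adjust_bh, phase_bin

log = logging.getLogger(__name__)


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def select_foreground(
    fits: pd.DataFrame,
    fdr: float = 0.05,
    amp_min: float = 0.5,
    bin_width_h: float = 4.0,
    period_h: float = 24.0,
) -> dict[int, set[str]]:
    """Rhythmic genes (q < fdr, amplitude > amp_min) grouped by phase bin.

    ``fits`` is a per-gene table with q, amplitude and phase_h columns (one
    layer).  Amplitude uses the strict inequality; the returned dict maps
    bin index -> gene set and may be empty.
    """
    sel = fits[(fits["q"] < fdr) & (fits["amplitude"] > amp_min)].dropna(
        subset=["phase_h"]
    )
    if sel.empty:
        log.warning("empty enrichment foreground (fdr=%g, amp_min=%g)", fdr, amp_min)
        return {}
    bins = phase_bin(sel["phase_h"].to_numpy(), bin_width_h, period_h)
    out: dict[int, set[str]] = {}
    for gene, b in zip(sel.index, bins):
        out.setdefault(int(b), set()).add(gene)
    return out


def run_enrichment(
    foreground_bins: dict[int, set[str]],
    memberships: dict[str, set[str]],
    background: set[str],
    min_genes: int = 5,
    p_max: float = 1e-4,
) -> pd.DataFrame:
    """Upper-tail test per (term, bin); sorted by p.

    Terms are restricted to the expressed background; a term with no
    background gene is skipped with a log entry.  ``significant`` marks rows
    with at least ``min_genes`` foreground hits and p <= ``p_max``.
    """
    N = len(background)
    rows = []
    for term, members in memberships.items():
        members_bg = members & background
        if not members_bg:
            log.info("term %s absent from background; skipped", term)
            continue
        K = len(members_bg)
        for b, genes in sorted(foreground_bins.items()):
            fg = genes & background
            n = len(fg)
            k = len(fg & members_bg)
            p = hypergeom_test(k, K, n, N)
            rows.append((term, b, k, K, n, N, p))
    out = pd.DataFrame(
        rows, columns=["term", "bin", "k", "K", "n", "N", "p"]
    ).sort_values("p", kind="stable", ignore_index=True)
    out["q_bh"] = adjust_bh(out["p"].to_numpy()) if len(out) else []
    out["significant"] = (out["k"] >= min_genes) & (out["p"] <= p_max)
    return out
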