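"""Half-life proxy and phase-binned motif enrichment on the in-vivo arm.

Verifies on kinetic simulations that (i) the exon/intron log2 ratio tracks
the true mRNA half-life, (ii) genes rhythmic only at the pre-mRNA level have
the longer-half-life proxy, and (iii) a motif planted into one phase bin is
the top enrichment hit against 50 decoys.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr

from circamyo import enrichment as en
from circamyo import preprocess as pp
from circamyo import rhythm as rh
from circamyo import simulate as sim

OUT = Path(__file__).resolve().parents[1] / "results" / "invivo"
OUT.mkdir(parents=True, exist_ok=True)

data = sim.gen_in_vivo(500, rhythmic_frac=1.0, sigma_e=0.25, rng_seed=21)
fit_in = rh.fit_layer(data.intronic_log2, data.samples)
fit_ex = rh.fit_layer(data.exonic_log2, data.samples)
groups = rh.classify_rhythm_groups(fit_in["q"], fit_ex["q"])
proxy = pp.exon_intron_ratio(data.exonic_log2, data.intronic_log2)

rho = spearmanr(proxy, data.truth["truth_half_life"]).statistic
ri, rie = proxy[groups == "R-I"], proxy[groups == "R-I.R-E"]
p = mannwhitneyu(ri, rie, alternative="greater").pvalue
summary = pd.DataFrame(
    {
        "quantity": ["proxy_halflife_spearman", "ri_median_proxy",
                     "rie_median_proxy", "ri_gt_rie_p"],
        "value": [rho, ri.median(), rie.median(), p],
    }
)
summary.to_csv(OUT / "halflife_proxy_summary.tsv", sep="\t", index=False)
print(f"proxy vs true half-life Spearman rho = {rho:.3f}")
print(f"median proxy: R-I {ri.median():.2f} vs R-I.R-E {rie.median():.2f} "
      f"(one-sided p = {p:.2e})")

# planted-motif enrichment against the fitted phases
members, truth_motif = sim.gen_motif_memberships(
    data.truth["truth_phase"], enriched_bin=4, p_in=0.8, p_out=0.1, rng_seed=22
)
fore = en.select_foreground(fit_in)
res = en.run_enrichment(fore, members, set(fit_in.index))
res.head(20).to_csv(OUT / "motif_enrichment_top20.tsv", sep="\t", index=False)
top = res.iloc[0]
print(f"top enrichment hit: {top['term']} in bin {top['bin']} "
      f"(planted: {truth_motif['term']} in bin {truth_motif['bin']}), p = {top['p']:.2e}")
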