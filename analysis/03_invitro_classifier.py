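"""Synchronised-myotube arm: curve classification and 16-model assignment.

Simulates 2000 genes (two donors, siControl/siCLOCK, 25 time points in
duplicate), runs the LOESS-feature + self-trained random-forest classifier,
assigns the 16 models and quantifies siCLOCK amplitude blunting.  Writes the
call, model and amplitude tables under results/ and prints recovery metrics
against the planted truth.
"""

from pathlib import Path

import pandas as pd

from circamyo import pipeline as pl
from circamyo import simulate as sim

OUT = Path(__file__).resolve().parents[1] / "results" / "invitro"
OUT.mkdir(parents=True, exist_ok=True)

data = sim.gen_in_vitro(2000, rng_seed=23)
res = pl.run_invitro(data.expr, data.samples)

res["calls"].to_csv(OUT / "calls.tsv", sep="\t", na_rep="NA")
res["models"].to_csv(OUT / "models.tsv", sep="\t")
res["amplitudes"].to_csv(OUT / "amplitudes.tsv", sep="\t", na_rep="NA")
res["training_history"].to_csv(OUT / "training_history.tsv", sep="\t")
pl.write_manifest(OUT, res["config"],
                  {"model_counts": {int(k): int(v) for k, v in res["model_counts"].items()}})

truth = data.truth["truth_archetype"]
yt = truth.loc[res["calls"].index.get_level_values("gene_id")].to_numpy()
acc = float((res["calls"]["category"].to_numpy() == yt).mean())
circ = truth.index[truth == "circadian"]
m1 = float((res["models"].loc[circ, "model"] == 1).mean())
comp = res["amplitude_comparison"]

print("model counts:", dict(sorted(res["model_counts"].items())))
print(f"curve-call accuracy vs planted archetypes: {acc:.3f}")
print(f"model-1 recovery of genes rhythmic in all four curves: {m1:.3f}")
if comp is not None:
    print(f"siCLOCK amplitude: mean log10 ratio {comp.mean_log10_diff:+.3f} "
          f"(t = {comp.t_stat:.1f}, p = {comp.p:.2e}, n = {comp.n_pairs})")
print(f"tables written to {OUT}")
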