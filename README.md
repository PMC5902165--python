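# circamyo

Rhythm detection for human skeletal-muscle transcriptome time courses, in two
complementary experimental designs:

* **In vivo (serial biopsies).** Bulk RNA-seq of muscle biopsies taken from
  multiple donors every 4 h across 24 h. Reads are quantified separately on
  **intronic** regions (pre-mRNA, a proxy for transcription) and **exonic**
  regions (mature mRNA), and each layer is tested for 24-h rhythmicity with a
  donor random-intercept harmonic model. Comparing the layers separates
  rhythmic transcription from rhythmic mRNA accumulation and yields an
  mRNA half-life proxy.
* **In vitro (synchronised myotubes).** Primary myotubes from two donors,
  transfected with siControl or siCLOCK (clock-disrupting) siRNA,
  synchronised with forskolin and sampled every 2 h for 48 h in duplicate.
  Damped, noisy 25-point curves defeat fixed-period tests, so each
  gene × condition curve is LOESS-smoothed, summarised by ten shape measures
  and classified (circadian / one peak / linear / cloud) by a random forest
  self-trained from eleven core clock genes. Per gene, the rhythmic status of
  the four condition-curves maps to one of 16 models
  (model 1 = rhythmic in all four … model 16 = in none).

A synthetic-data generator emulates both designs with known ground truth, so
every stage is testable without external data.

## Models

**In-vivo rhythmicity.** For gene *g*, layer *l* and donor *d* at clock time
*t* (hours), the log2 RPKM is modelled as

```
y_{d,t} = μ + a·cos(ωt) + b·sin(ωt) + u_d + ε,   ω = 2π/24
u_d ~ N(0, σ_donor²),   ε ~ N(0, σ_e²)
```

fitted by maximum likelihood; rhythmicity is the likelihood-ratio test
against the model without harmonic terms, referred to χ²(df = 2)
(p = exp(−Λ/2)), with Benjamini–Hochberg adjustment across genes. Amplitude
is the log2 peak-to-trough 2√(a²+b²); phase is the fitted peak time
(24/2π)·atan2(b, a) mod 24. Genes are grouped by layer-wise significance:
**R-I.R-E** (both layers), **R-I** (intronic only), **R-E** (exonic only),
**NR**.

**Kinetics.** With first-order mRNA degradation at rate k = ln2/t½, a
harmonic transcription signal reaches the mature layer attenuated by
g = k/√(k²+ω²) and delayed by atan2(ω, k)/ω hours, and the mean
exonic − intronic log2 ratio is a monotone proxy for t½.

**Enrichment.** Rhythmic intronic genes (q < 0.05, amplitude > 0.5 log2)
are split into 4-h phase bins; each motif gene set is tested per bin with an
upper-tail hypergeometric test against all expressed genes.

**In-vitro classification.** Ten measures per curve (extreme slopes, first
and second extremum times, min/max ratio, 24-h autocorrelation, scattering,
LOESS and linear residuals, period estimate), a seed set of 11 curves per
category anchored on ARNTL, NR1D1, NR1D2, PER1-3, CRY1-2, NPAS2, TEF and
BHLHE41, iterative self-training of a 500-tree random forest (admission at
probability ≥ 0.9, target 500 curves per class), and a final call at
probability > 0.5. siCLOCK amplitude blunting is quantified by a paired
t-test on log10 peak-to-trough amplitudes of model-1 genes.

## Worked example

```
$ python analysis/01_invivo_rhythms.py
group counts: {'NR': 374, 'R-I.R-E': 245, 'R-I': 176, 'R-E': 5}
intronic-layer sensitivity on planted rhythms: 0.983
intronic-layer false-call rate on flat genes:  0.026
```

800 simulated genes (half with planted 24-h rhythms) are normalised,
filtered and fitted on both layers: 98% of the planted rhythms are detected
at the pre-mRNA level at FDR 5%, with a 2.6% false-call rate on flat genes.
Genes whose rhythm survives into the mRNA layer (R-I.R-E) are the short
half-life genes; long half-life genes stay intronic-only (R-I), and

```
$ python analysis/02_halflife_and_motifs.py
proxy vs true half-life Spearman rho = 1.000
median proxy: R-I 5.24 vs R-I.R-E 1.89 (one-sided p = 1.25e-52)
top enrichment hit: MOTIF_PLANTED in bin 4 (planted: MOTIF_PLANTED in bin 4), p = 8.45e-36
```

the exon/intron ratio recovers that ordering, and a motif planted into one
phase bin is the top enrichment hit. The in-vitro arm
(`analysis/03_invitro_classifier.py`) classifies 8000 simulated curves,
partitions 2000 genes over the 16 models and detects the siCLOCK amplitude
blunting (mean log10 ratio −0.34, p < 1e-50 on model-1 genes);
`analysis/04_compare_arms.py` reports the cross-design overlap funnel.

The same pipelines run from the shell on TSV inputs:

```
circamyo simulate invivo --n-genes 500 --seed 1 --out data/
circamyo invivo --exonic data/counts_exonic.tsv --intronic data/counts_intronic.tsv \
    --samples data/samples.tsv --lengths data/lengths.tsv --out results/
```

## Layout

```
src/circamyo/     library: annotation, preprocess, rhythm, curves,
                  enrichment, simulate, pipeline, cli
analysis/         numbered narrative drivers writing results/
tests/            pytest suite (unit, property and acceptance tests)
scripts/          acceptance.py
docs/methods.md   modelling assumptions, defaults, limitations
```
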