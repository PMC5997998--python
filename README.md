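# phystate

Physiological state-space embedding of bulk transcriptomes and
early-warning resilience statistics for batch phytoplankton cultures.

## The problem

Diatoms such as *Thalassiosira pseudonana* cycle through four principal
physiological states — light vs dark phase of the diurnal cycle, and
early (nutrient-replete) vs late (nutrient-deplete) phase of batch
growth. A resilient culture reproducibly adopts the internal state
matched to its external environment; losing that correspondence
("relational resilience") precedes population collapse under
accumulating stress. `phystate` quantifies this from data a
stress-test experiment produces: an FPKM expression matrix with sample
labels, cell-count time series, and PAM fluorescence (Fm, Fo) time
series. It is aimed at microbial physiologists running serial-transfer
stress tests who want transcriptome-level and phenotype-level
early-warning statistics from tabular data, without re-running an
alignment pipeline.

## The method

**State descriptors.** Using reference-stage samples, a transcript
qualifies as a descriptor of an axis (light/dark or early/late) when
(1) a two-sided Mann–Whitney U test on log10(FPKM + 1) rejects after
Benjamini–Hochberg adjustment, (2) its per-state medians differ at
least twofold, and (3) that median separation is at least one average
per-state standard deviation in log10 space. Descriptor sets of the
two axes never overlap.

**Position scores.** Each descriptor *i* has two reference
distributions φ_α, φ_β with medians Q₂(φ_α), Q₂(φ_β), extremes
φ_min, φ_max, orientation ε = +1 iff Q₂(φ_α) < Q₂(φ_β), and possibly a
gap θ (centered at θ_c) between them. An observed log10 expression
value κ_i maps to a score λ_i ∈ [−2, 2]:

- inside the gap: λ_i = 2ε(θ_c − κ_i)/θ;
- otherwise, with δ = ±1 selecting the state whose median is closer
  and φ that state's distribution:
  λ_i = 1.5δ + ε|κ_i − Q₂(φ)| / (2|φ_min − Q₂(φ)|) below the median,
  λ_i = 1.5δ − ε|κ_i − Q₂(φ)| / (2|φ_max − Q₂(φ)|) above it, and
  λ_i = 1.5δ at the median; values outside all observed ranges clamp
  to ±2.

A sample's coordinate is the weighted average s_x = Σ ω_i λ_i over the
diurnal descriptors (Σω_i = 1; uniform by default), likewise s_y for
the growth-phase axis. Positive s_x is light-like, positive s_y
early-like; |λ| = 1.5 at a state median, 2 at full commitment, 0 at the
gap center. Reference-stage samples define four circular regions
(centroid + 1.96 × SD of the observed scatter); a sample inside no
region is "non-distinctive".

**Resilience statistics.** Pairwise Spearman correlation of
transcriptomes over genes ≥ 5 FPKM in every sample; Euclidean
distances between replicate positions per sampling time-point, compared
across stages with a two-sided Mann–Whitney U test; coefficient of
variation of Fv/Fm = (Fm − Fo)/Fm across replicates, compared across
stages with a paired two-sided Wilcoxon signed-rank test (exact
p-values at small n). Growth curves are fitted on the log scale with a
lag-logistic model, ln N(t) = ln n₀ + A/(1 + exp(4μ(lag − t)/A + 2))
with A = ln(K/n₀), yielding carrying capacity K, maximum specific
growth rate μ and lag duration; μ is also available directly as the
log-linear regression slope over the exponential phase.

## Worked example

The package ships a synthetic-study generator whose defaults mirror a
three-stage stress test: 3000 genes (60 + 220 planted descriptors with
a 0.6 log10-FPKM state separation), triplicate cultures in two CO₂
conditions, and a final pre-collapse stage with scrambled descriptor
states and doubled replicate jitter. The numbered scripts under
`analysis/` run the full analysis on it:

```sh
python analysis/01_simulate_study.py
python analysis/02_select_descriptors.py
python analysis/03_map_state_space.py
python analysis/04_resilience_stats.py
python analysis/05_growth_fits.py
```

which prints, among other things:

```
selected 60 diurnal and 220 growth-phase descriptors from 24 stage-1 reference transcriptomes
  diurnal: recall 100.0%, 0 false discoveries

classification by stage (fraction of samples):
       correct  nondistinctive
stage
1         1.00            0.00
2         0.96            0.04
3         0.00            1.00

replicate dispersion, stage 3 vs stage 1: median 0.569 vs 0.333; Mann-Whitney U = 172, p = 1.72e-02
Fv/Fm CV, stage 3 vs stage 1 (paired by time, both conditions): W+ = 299, p = 2.38e-07 (exact)

mean fitted parameters per stage (truth: K = 2e6 cells/mL, mu = 0.9 /d, lag = 0.5/1.5/3.0 d):
             K    mu   lag
1     2.01e+06 0.904 0.488
2        2e+06  0.92  1.56
3     1.99e+06 0.892  2.98
```

Reading this: selection recovers every planted descriptor with no
false discoveries; stage-1 and stage-2 samples map to their true
corners of the state space while every dysregulated stage-3 sample
falls into the non-distinctive area; replicate dispersion and the
Fv/Fm CV both shift significantly in the pre-collapse stage (the two
early-warning signals); and the growth fits recover the planted
carrying capacity, growth rate and the stage-wise lengthening lag.

The same pipeline runs end to end from one config file (or on your own
TSV inputs instead of a simulate block):

```sh
phystate run-all --config config.yaml --out out/ --seed 1
```

with subcommands `simulate`, `select-descriptors`, `map-states`,
`resilience-stats` and `growth-fit` for the individual stages. Every
run writes a `manifest.json` with sha256 checksums of all outputs;
reruns with the same seed are byte-identical.

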