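# Methods

## Problem and quantities

Tumor mutational burden (TMB) is the count of somatic coding mutations per
megabase.  The whole-exome (WES) reference value used throughout is

    TMB_WES = n_nonsynonymous / 38 Mb

counting non-synonymous coding base substitutions and indels (missense,
nonsense, nonstop, frame-shift and in-frame indels, translation start site,
splice site); synonymous (`Silent`) calls are tallied separately and never
enter the WES value.  A targeted panel's in-silico TMB is

    TMB_panel = n_mutations_in_panel_genes / panel_size_mb

where membership is by gene symbol and the panel's counting rule decides
whether synonymous calls are included (some commercial assays include them
to reduce sampling noise).  Panel definitions (gene list, captured Mb,
counting rule) are user-supplied config files; vendor gene lists are not
shipped.

Concordance between the two is summarized in two ways: the square of the
Pearson correlation of the raw (untransformed) TMB values, and a suite of
dichotomization metrics — accuracy, false positive rate, false negative
rate, positive and negative percentage agreement — after labelling each
sample TMB-high or TMB-low.

## Rank convention and cutpoints

Every "top f %" statement uses one rule: sort by value descending, break
ties by ascending sample barcode, take the top `floor(f·n)` (at least 1 for
cutpoints).  The WES truth cutpoint is the value of the k-th ranked sample
within each cancer type (default f = 0.20, sweepable 0.10–0.50).  An
interpolated percentile was deliberately avoided: "top 20%" is a rank
statement and interpolation schemes differ across software.

Panel-side classification has two modes:

* **value_transfer** (default for panel evaluation): predicted high when
  the panel TMB reaches the WES cutpoint value.  Because mutation counts
  are integers, panel values exactly equal to the threshold are possible;
  they inherit the same ascending-barcode tie order that defined the truth
  labels (high iff the barcode does not sort after the cutpoint sample's).
  On distinct values this is the plain ≥ rule; with ties it keeps an
  identity panel (panel TMB ≡ WES TMB) reproducing the truth labels
  exactly, which the exome-identity checks require.  This mode reproduces
  the clinically relevant asymmetry: panels enriched in frequently mutated
  genes overestimate TMB and generate an excess of false TMB-high calls
  (FPR > FNR).
* **quantile**: the same rank-top-k rule applied to panel TMB.  By
  construction the predicted and true high sets have equal size, so
  fp = fn — a structural property used in tests to tell the modes apart.

FNR is computed as `1 − (accuracy + FPR)` (within one ulp of fn/n) so the
identity `accuracy + FPR + FNR = 1` is exact in floating point.  PPA/NPA
are reported missing (NaN), not zero, when their denominator is empty.
R² is reported missing with a warning when either axis has zero variance.

## Outlier robustness analyses

`removal_sweep` drops the top `floor(f·n)` samples by WES TMB rank
(f = 0.01…0.05 by default) per cancer type and recomputes R² and the full
metric suite on the remainder, with Δ columns against the f = 0 baseline.
The quantile cutpoint is recomputed on the reduced cohort — "top 20%"
refers to the analyzed set; a frozen-cutpoint variant is available behind
a flag for sensitivity analysis.  Rows that would leave fewer than 10
samples report missing metrics.  `subgroup_correlations` partitions each
cancer type by WES rank into top 5%, top 5–20% and bottom 80% (disjoint,
exhaustive) and reports R² per subgroup and overall; subgroups under 3
samples are missing.

## Random virtual-panel experiment

For each panel size on an ascending grid, genes are drawn uniformly
without replacement from the gene-length universe (1000 draws at full
scale; the shipped analyses and tests use 100 draws — only the Monte-Carlo
error, not the mechanism, depends on the draw count, and the report always
records n_draws).  Each draw's captured size is its summed coding length
in Mb — the defensible proxy for an in-silico panel's footprint, isolated
in `make_virtual_panel` for replacement by measured capture sizes.  The
minimal panel size per cancer type is the first grid point whose mean
accuracy reaches the 90% target, truncated at the grid maximum and flagged
when never reached.  Draw seeds come from a `SeedSequence` spawned per
draw index, so results are deterministic and invariant to batching.

The design experiment classifies by the quantile rule by default.
Transferring an absolute TMB cutpoint onto a small panel's integer count
lattice makes accuracy genuinely non-monotone in panel size at low TMB
(whether the transferred threshold falls just above or below an integer
count per panel Mb is an aliasing artifact of the threshold rule, not a
property of the panel's information content).  The rank rule asks the
question the experiment means — how well does a panel of this size rank
samples within a cancer type — and is scale-free; the mode remains
configurable for sensitivity analysis.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis consumes,
not any particular tumor cohort:

* **Gene universe.**  The universe models the entire coding exome: 18,000
  genes with log-normal coding lengths (median 1.8 kb, log-sd 0.55,
  total ≈ 38 Mb).  Every generated mutation lands in a universe gene, so
  an undersized universe would inflate every panel's TMB by
  `total_length / 38 Mb`; the default is sized to make uniformly random
  panels unbiased.  A 5% "hotspot" subset carries a 5× per-base mutation
  rate enrichment, emulating the mutation-enriched content of cancer gene
  panels — a panel drawn from hotspot genes overestimates TMB, which is
  the mechanism behind panel false-positive TMB-high calls.
* **Per-sample TMB.**  A log-normal body per cancer type
  (`exp(tmb_log_mean)` is the body median, in Mut/Mb) with each sample
  independently promoted to a hypermutator (TMB × `hyper_multiplier`,
  default 30) with probability `hyper_fraction` (default 0.02) — the
  right-skew-plus-ultra-high-tail shape of real per-cancer-type TMB
  distributions.  Counts are `round(TMB × 38)` non-synonymous plus
  Poisson synonymous at `syn_ratio` (default 0.33, the approximate
  synonymous:non-synonymous site availability in coding sequence).
* **Placement.**  Mutations are placed on genes multinomially with
  probability ∝ length × enrichment.  No positional or trinucleotide
  model: gene-level membership is all the pipeline consumes.
* **Outlier injection.**  `inject_outlier` scales one uniformly chosen
  sample's counts by a multiplier, re-drawing the added mutations over the
  universe — the synthetic analogue of a single ultra-hypermutated case.

A low-TMB carcinoma fixture (`paad_like_spec`, n = 177) is calibrated to
median ≈ 0.92 Mut/Mb with IQR ≈ [0.60, 1.23]: the log-sd is the geometric
fit to the quartiles, `(log Q3 − log Q1)/(2·0.6745) ≈ 0.53`.  A single
log-normal cannot match the asymmetric printed quartiles exactly — the
generated Q3 runs ≈ 1.3–1.45 across seeds (the 2% hypermutator tail also
shifts the upper quartile slightly) — so the fixture is a scale
calibration, accurate to ≈ 20% on the quartiles, not a distributional fit.

What passing tests on this generator do show: the estimators, rank rules
and report plumbing are correct, and the outlier-sensitivity of Pearson R²
versus the stability of dichotomous accuracy follows from the distribution
shape alone.  What they do not show: real per-cancer-type parameter
values, mutational-spectrum effects (signatures, hotspot co-occurrence),
or panel-specific capture chemistry — conclusions about a specific assay
still require its real gene list and a real cohort.

## Shipped study conditions

`tmbpanel.examples` freezes two seeded setups used by the documentation,
tests and reproduction script:

* **Outlier demo** — one cancer type, n = 150, body median 2.5 Mut/Mb
  (log-sd 0.5, no background hypermutators), scored with a random
  300-gene panel (≈ 0.6 Mb, the footprint scale of a commercial
  comprehensive genomic profiling assay), plus one injected sample scaled
  500× (≥ 50× the cohort maximum).  The body median sits at the
  pan-cancer scale; at much lower medians the value_transfer threshold
  interacts with the count lattice (see above) and accuracy itself grows
  noisy.
* **Designer demo** — six cancer types, body medians 1, 1.8, 3.3, 6.1,
  11 and 20 Mut/Mb (log-spaced over the range real cancer types span),
  n = 120 each, size grid 150–1000 step 170, 100 draws per size.

## Numerical and degenerate-input choices

* All TMB values are unrounded floats; display rounding happens only at
  report time.
* `floor` (never round/ceil) converts fractions to ranks everywhere.
* Unrecognized MAF variant classifications are retained but flagged and
  never counted; per-category counts are logged so the partition is
  auditable, and the classification table is an editable mapping.
* Samples present in the cancer-type map with no called mutations get a
  profile with TMB 0 — dropping them would bias cutpoints.
* Degenerate all-equal TMB vectors resolve cutpoints by barcode order
  with a logged warning.
* Every output TSV embeds the config SHA-256 and master seed as `#`
  header comments; reports carry no timestamps, so a fixed seed makes
  runs byte-identical.

## Problem sizes

The shipped analyses run at desk scale by choice: cohorts of 90–240
samples per setup, 10 replicate cohorts for the outlier analyses, 100
draws per panel size on a 6-point grid.  The full-scale settings (1000
draws, 150–1000 step 50) are the documented defaults of the library
functions; scaling up changes only Monte-Carlo error.
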