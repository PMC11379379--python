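# Methods

## Model overview

`emsmap` treats EMS mutagenesis as an inhomogeneous Bernoulli process: in one
mutagenized strain, base `i` mutates independently with probability `P_i` per
experiment. `P_i` is modelled as a function of two measurable covariates:

1. **Sequence context.** The 5-mer centred on the base determines a baseline
   event frequency `P0 = C'/C0` (events in the training catalogue per
   occurrence in the reference). 5-mers are taken on the reference forward
   strand and complementary patterns are *not* collapsed — all four central
   bases are modelled, and e.g. `AGGGG` and `CCCCT` are separate rows, since
   strand-resolved catalogues report them separately. `P0` as tabulated is a
   cohort-level frequency; dividing by the training cohort's strain count
   gives the per-strain scale used everywhere downstream.
2. **Chromatin state.** DNA-binding-protein signals (histones, transcription
   factors), smoothed with a centred 100-bp moving average per chromosome,
   proxy local accessibility. Regions depleted of binding signal often
   coincide with "silent regions" where far fewer mutations occur than the
   context model predicts.

A random-forest regressor combines both: each tree groups bases with similar
feature vectors into leaves of at least `min_leaf` bases and predicts the
leaf's mean per-strain event rate; the forest averages the trees. The target
encoding `y_i = (events at base i across the cohort) / n_strains` makes the
forest output directly a per-strain probability, so the training cohort's
effectiveness is `alpha_0 = 1` by construction and another batch is scaled by
`alpha_1 = N1/N0` (ratio of mean events per strain). `P0` enters the trees as
an ordinary feature column (the alternative, using it only as a multiplier on
the output, is not implemented as the default because the forest can learn
non-multiplicative interactions between context and chromatin; the baseline-
only map is available via `baseline_map`).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| smoothing window | 100 bp | moving-average width for protein tracks |
| trees | 600 | forest size at production scale |
| max feature fraction | 0.7 | per-split cap, `floor(0.7 * n_features)` |
| min leaf | 30,000 bases | production-scale overfitting guard |
| desk-scale trees / min leaf | 100 / 200 | defaults for ~1-Mb synthetic work |
| bootstrap fraction | 1.0 (0.5 desk-scale) | per-tree row sample, with replacement |
| depth / AF filter | `> 5`, `> 0.8` (strict) | screen-VCF record quality gate |
| background share | 0.25 | variant removed if carried by ≥ 25 % of pool |
| FDR | 0.05 | Benjamini–Hochberg threshold over tested genes |

The "at most 70 % of features" rule is implemented with standard
random-forest semantics (a fresh random subset at every split);
`per_tree_subset=True` gives the alternative reading in which each tree sees
one fixed feature subset. The per-tree row fraction is exposed because desk-
scale fits are rate-limited by tree construction; halving it roughly halves
training time with little accuracy cost at 10-kb block resolution.

## Statistics

**Expectations.** `P_seq = sum P_i` over a gene territory (union of annotated
intervals; gene body by default, exons optional) and `E = n * P_seq` for a
pool of `n` strains. Both are exactly additive over disjoint intervals and
linear in `alpha`.

**Null counting law.** A gene's count over `n x L` Bernoulli trials is
Poisson-binomial; the package computes it exactly by convolution for small
genes (`method="exact"`) and by the Poisson(E) limit otherwise, which is
indistinguishable at per-base probabilities of 1e-6–1e-4.

**p-values.** Only genes with at least one observed event are tested, so the
default null is *zero-truncated* (conditioned on a positive count) — without
this, short genes with `E ~ 1` are flagged far too often and the null p < 0.05
rate is visibly inflated. The default two-sided p-value is the exact
probability-mass ("minlike") p with a mid-p correction, which keeps the
discrete test's size close to nominal across the 1–15-event expectations
typical of single genes; the classical doubled-tail p and one-sided
enrichment alternatives are available (`tail="doubling"`,
`alternative="greater"`). Multiple testing uses Benjamini–Hochberg.

**Chi-square flank test.** Composition of the four bases at a fixed offset
from mutated sites of one central base, against the genome-wide composition
at that offset around all sites of that base, scaled to the observed total:
Pearson statistic, df = 3, no continuity correction; a zero expected cell is
an error rather than a silent drop.

**Evaluation.** `R^2 = 1 - MSE/Var` with the population variance. Block
validation tiles chromosomes from their first base (positional mode) or sorts
bases by predicted rate and cuts equal-size groups (sorted mode); Pearson r
is computed over blocks and flagged when degenerate. Permutation importance
replaces a feature column by a permutation of itself (exactly preserving the
marginal distribution; an i.i.d. resampling mode is available), recomputes
`R^2` `n` times (default 10) and reports `i_j = R^2 - mean(R^2_perm)` plus a
min-max normalised `V` in [0, 1].

## Synthetic data

The generator emulates the study design so every claim is testable offline:

- **Genome:** i.i.d. bases at 36 % GC (the *C. elegans* genome-wide value),
  default 2 Mb over 2 chromosomes.
- **Tracks:** Gaussian-random-field signals (white noise through three
  cascaded box filters with circular padding, standardised), correlation
  length 5 kb — the long-range structure of ChIP signal without peak-level
  realism.
- **Truth:** `true_p = base_rate * context_multiplier * chromatin_factor`.
  Context multipliers are lognormal across 5-mers with a ~10-fold
  97.5th/2.5th-percentile ratio, occurrence-weighted mean 1. The chromatin
  factor is a smooth monotone function of the first two tracks (track 0
  dominant), mean 1, floored at 1e-4; one silent region per chromosome (5 %
  of its length) has track 0 forced low and the factor capped at 0.01. The
  default `base_rate = 3.6e-6` per base per strain reproduces the ~360
  events per strain of a heavily mutagenized 100-Mb-genome cohort, giving
  ~2,000 events for 300 strains on 2 Mb.
- **Cohorts:** per-base Binomial(n, p) counts with carriers drawn without
  replacement (equivalent to independent per-strain Bernoulli draws); G/C
  alleles follow the EMS transition (G→A, C→T) with probability 0.95.
- **Screens:** each selected strain gets one high-impact mutation at a
  distinct position of the causal gene on top of its passengers; shared
  background variants are injected into a configurable strain fraction.
- **Genes:** non-overlapping single-interval models, lognormal lengths
  around 2.5 kb (0.8–12 kb), exponential gaps — so gene-level expectations
  span ~1–15 events in a 300-strain pool, a realistic heterogeneity for the
  enrichment test.

What the generator does *not* emulate: real chromosome organisation
(arms/centres, repeats), correlated mutation clusters, sequencing error,
annotation errors, or more than one causal gene. Passing tests therefore
demonstrate the statistical machinery and its calibration under the model's
own assumptions, not performance on real WGS data.

## Numerical choices and edge cases

- Internal coordinates are 0-based half-open everywhere; VCF/GFF3/wiggle are
  converted at the parsing boundary only.
- The depth/AF filter uses strict inequalities; AF values from VCF are
  rounded to 6 decimals so float32 storage cannot flip a boundary record.
  Records missing DP/AF are dropped with a warning.
- Moving-average smoothing shrinks its window at chromosome edges; a window
  not smaller than the chromosome returns the global mean.
- Bases whose 5-mer window is incomplete (chromosome edge, N) are excluded
  from the feature matrix; maps fill them with the flagged central-base
  marginal `sum C' / sum C0`.
- Gene-territory probabilities are computed by direct slice summation, not
  cumulative-sum differences, to avoid catastrophic cancellation for
  low-probability regions.
- The Poisson-binomial convolution truncates vanishing tails with a budget
  spread over bases so the accumulated error stays below 1e-12.
- Recurrent events (same site, several strains) count once per event in `C'`;
  InDels are excluded from context counting (ambiguous centre) but retained
  for enrichment and impact profiling, anchored at their VCF position.

## Validation scales

The shipped acceptance checks run desk-scale problems chosen to finish in
minutes on one CPU: enrichment calibration and causal-gene recovery on a
2-Mb genome with 300 training strains and 38-strain screens (5 null
replicates, 20 causal replicates), and random-forest recovery on a 1-Mb
genome with 100 trees, minimum leaf 200 and bootstrap fraction 0.5, scored
as `R^2` between 10-kb block sums of the predicted map and the generating
truth. Production-scale parameters (600 trees, 30,000-base leaves) are the
documented defaults of `train_rf` but are not exercised by the test suite.

## Known limitations

- The map is only as good as the training catalogue's density; single-base
  estimates are noisy and meaningful validation happens at block or gene
  aggregation.
- Calibration of the discrete enrichment test is approximate (mid-p); exact
  nominal size is unattainable for counts with expectations of a few events.
- Screens yielding one or two alleles per gene carry little burden signal;
  the method is designed for pools of dozens of selected strains.
- `alpha` assumes the batches differ only in overall mutagen strength, not in
  context or chromatin preference.
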