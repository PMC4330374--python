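# Methods

This note documents the models, conventions and design choices behind
ribobench, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The folding model

The engine predicts secondary-structure ensembles for short RNA windows
under a deliberately simple, fully specified energy model rather than a
full nearest-neighbour parameter table. A structure is a set of base
pairs (i, j), i < j, in which each base pairs at most once, no two pairs
cross (no pseudoknots), and every hairpin loop contains at least
`min_hairpin_loop` unpaired bases (default 3). The energy of a structure
is the sum of its pair energies plus, optionally, stacking bonuses for
directly adjacent pairs ((i, j) enclosing (i+1, j−1)):

* pair energies (kcal/mol): AU/UA −2, GC/CG −3, GU/UG −1 by default;
  only the six canonical/wobble pair types can have finite energy;
* stacking: off by default; when supplied, keyed by (outer pair type,
  inner pair type);
* `temperature_kT` = 0.6156 kcal/mol (37 °C) converts energies to
  Boltzmann weights.

The rationale: the benchmarking protocol treats folding programs as
interchangeable engines whose output (a BPPM or an MFE structure) feeds
the distance metrics, so correctness is defined against the model itself
rather than against any published parameterisation. A brute-force
enumerator over all legal structures (refusing sequences longer than 20
nt) is the internal oracle: the dynamic programmes must agree with it to
relative 1e−9 on random sequences, and do so at machine precision in the
shipped checks. Real thermodynamic parameters can be plugged in through
`EnergyModel`, and externally computed BPPMs bypass the engine entirely
via the TSV exchange format.

### Recursions

Inside pass (`Q`, `Qb`): `Q[i,j]` sums Boltzmann weights over all
structures of segment [i, j] (1 for an empty segment), decomposed over
whether base i is unpaired or paired to some k; `Qb[i,j]` restricts to
structures closed by the pair (i, j), with the stacking bonus to an
adjacent inner pair handled by the correction
`Q[i+1,j−1] + (σ(i,j) − 1)·Qb[i+1,j−1]`, where σ is the stack's
Boltzmann factor. `Z = Q[1,n]` and `Z ≥ 1` always (the empty structure
contributes 1).

Outside pass: for each legal pair, the exterior weight is decomposed
over the innermost enclosing pair, with an explicit σ−1 correction when
the enclosing pair is directly adjacent (the only configuration in which
an enclosing pair can stack on the scored pair). An auxiliary
per-(h, j) prefix array keeps the whole pass O(n³). Pair probabilities
are `p_ij = Qb[i,j]·Qhat[i,j]/Z`; entries below 1e−12 are dropped from
the sparse BPPM (threshold configurable).

MFE (`F`, `G`, `Eb`): the same decomposition with min-plus algebra.
`G[i,j]` (minimum over structures *not* pairing i with j) exists so that
the stacked and unstacked closures of a pair are scored exactly, without
assuming stacking bonuses are favourable. Traceback tie-breaking is
deterministic: pairing is preferred over leaving a base unpaired, and a
paired base takes its smallest co-minimal partner, so ties resolve
toward pairs at the smallest (i, then j). Ties are detected with an
absolute tolerance of 1e−9 on energies.

Numerics: Boltzmann weights are accumulated in plain float64 without log
scaling; for the ≤101-nt windows this toolkit targets, Z stays far below
overflow (~10^105 at worst under the default model). Very long sequences
with very stable models would need rescaling and are out of scope.

## Windows and categories

Windows take 50 bases either side of the SNV (101 total). An SNV with
fewer than 50 nt between it and the transcription start site is
excluded outright; a window truncated by the transcript 3′ end is kept,
shortened, and flagged (`truncated_3prime`), with an option to drop such
windows instead — the 5′ rule is a hard exclusion because the upstream
flank defines the comparison, while 3′ truncation is recoverable and so
left to the caller. Coordinates are 1-based inclusive in every file
format; 0-based arithmetic appears only in internal string slicing.

Category logic per SNV, from the trio's pairwise structure-difference
calls (a comparison is applicable exactly when the two genotypes
differ): **symmetric** if at least one comparison is applicable and all
applicable ones called a difference; **asymmetric** if calls are mixed;
**non-riboSNitch** if none called a difference; all-identical genotypes
are an error. **Validated** status (allele-specific read mapping) is an
input flag — the toolkit checks the genotype eligibility rule (parents
homozygous different, child heterozygous) and warns on inconsistency but
never recomputes the wet-lab result; **probed** (chemical probing) is
likewise always an input flag. The two flags are treated independently;
nothing requires probed ⊆ validated.

Deduplication collapses windows with identical (ref sequence, alt
sequence, SNV offset); one riboSNitch source suffices to label the
merged window a riboSNitch, categories union, and the merged mean
adjusted P-value is the mean of the sources' means. Windows identical in
ref but differing in alt remain distinct. The operation is idempotent
and label outcomes are order-independent.

## Distance metrics

All four metrics are symmetric, non-negative, zero on identical inputs,
require equal-length inputs (the profile comparison is alignment-free by
construction), and are oriented so that larger always means more
disruption — any future correlation-style metric must be wrapped as
1 − r to keep ROC directions consistent.

* `bppm_profile`: Σ_i [1 − Bhattacharyya coefficient] over the per-base
  (upstream, downstream, unpaired) distributions; bounded by the window
  length and additive over bases.
* `pearson_profile`: 1 − Pearson r between per-base total-pairing
  vectors (1 − p°). Degenerate cases: both vectors constant and equal →
  0; exactly one constant (correlation undefined) → distance 1 with a
  warning, i.e. r treated as 0.
* `relent_profile`: per-base symmetrised Kullback–Leibler (Jeffreys)
  divergence over the 3-category distribution, summed over bases, with
  additive ε = 1e−6 smoothing and renormalisation before the logs
  (ε configurable). This is a documented stand-in for relative-entropy
  scoring between two allele ensembles; no published closed form is
  being reproduced.
* `mfe_bp`: |pairs(s1) Δ pairs(s2)|, the symmetric-difference size
  between MFE base-pair sets. Tree-edit distances between dot-bracket
  strings exist, but the base-pair-set distance is exactly specified,
  standard, and of comparable magnitude; this is a deliberate design
  choice.

## Benchmark protocol

* **Control matching**: for a riboSNitch category of size n, the n
  non-riboSNitches with the *highest* mean FDR-adjusted P-value over
  their applicable trio comparisons are selected — the candidates whose
  PARS comparisons were most confidently unchanged. The direction is a
  genuine judgement call (one could argue for "hardest" controls
  instead), so an `ascending` flag inverts it; ties break on the
  identifier. The lowest-mean-P riboSNitch-subset analysis (top 25%/5%
  most significant riboSNitches, freshly matched controls) is available
  through `run_benchmark(..., ribosnitch_subsets=(25, 5))`.
* **ROC/AUC**: thresholds sweep all distinct scores ("score ≥ threshold"
  calls a riboSNitch); AUC is the Mann–Whitney statistic with ties
  counted one half, verified against an independent rank-sum computation
  and scikit-learn. The curve's best point minimises Euclidean distance
  to (FPR 0, TPR 1); ties take the lowest threshold.
* **DeLong**: s² = var(V10)/m + var(V01)/n over midrank placement
  values; 95% CI = AUC ± 1.96·s, raw values retained (clipping to [0,1]
  is display-only). The estimator matches R pROC's `var(..., 
  method="delong")` to printed precision in the test suite and a
  10,000-replicate bootstrap within sampling error. Curve comparisons
  use the one-tailed normal test on (AUC_a − AUC_b)/SE; pairing is
  auto-detected from window-id overlap (placement-value covariances when
  paired, variance sum when not) and can be overridden.
* **n% tails**: the two score sets are combined; θ_L and θ_H are the
  n/2% and (100 − n/2)% empirical quantiles (linear interpolation
  between order statistics — numpy's default — so the tail mass is split
  symmetrically); scores with s ≤ θ_L or s ≥ θ_H are retained per side.
  Retention is inclusive at the thresholds, so zero-heavy degenerate
  multisets (typical of MFE distances) keep all tied values — which is
  also why tails filtering cannot sharpen such metrics. n = 100 is the
  identity. Retained side sizes need not be equal; asymmetric score
  distributions naturally retain more of one class.
* When raw rather than adjusted P-values are supplied,
  Benjamini–Hochberg adjustment is available (`benjamini_hochberg`),
  checked against statsmodels.

Categories with fewer than two windows per side are reported as NA rows
with an explanatory note, never dropped silently.

## The synthetic-data generator

`simulate_trio_dataset` emulates the *statistical shape* of a trio-PARS
screen, not its biochemistry. Defaults: 200 riboSNitches + 200
non-riboSNitches; 101-nt windows; a 6-bp stem / 4-nt loop hairpin;
50% symmetric riboSNitches; 30% validation-eligible genotype
configurations; 5% probed; comparison P-values from Beta(1, 20) when a
difference was called and Beta(5, 1) when not; `noise_frac` 0. Each SNV
gets its own transcript exactly one window long with the SNV at position
51, so extraction reproduces the generated window with zero exclusions.
One `numpy` generator seeded from `seed` drives every draw; identical
seeds give byte-identical outputs, and the seed is recorded in the SNV
table header.

Sequence design: flanks and loops are drawn from {A, C}, stems from
{G, C} with complementary strands, so the windows contain no U. A
disruptive SNV is a mid-stem G→A (A pairs only with U, so the broken
pair cannot re-form elsewhere); a neutral SNV is a mid-loop A→C. The
hairpin is positioned so the mutated base lands exactly at the window
centre. Flank C's can pair stem G's, giving the ensemble realistic
alternative structure without threatening the stem's dominance.

"Environmental" riboSNitches (`noise_frac`) are windows labelled
riboSNitch — with riboSNitch-consistent diff calls and P-values — whose
SNV is structurally neutral. This models structure changes driven by
cellular context that no thermodynamic predictor can see; it is a
modelling choice, not a published formula. Raising `noise_frac` pulls
the achievable pipeline AUC from ~1 toward 0.5.

What the generator does *not* emulate: raw PARS read counts or nuclease
specificity, mapping artefacts, isoform mixtures within one window,
GC-content and length heterogeneity of real transcripts, or realistic
energy landscapes with multiloops. Passing the end-to-end checks
therefore shows the pipeline's machinery is correct and well-calibrated
on its own terms, not that any particular AUC will be attained on real
variant sets.

## Problem sizes in the shipped checks

The test suite and acceptance script size their simulations to be
decisive yet quick: 200 random sequences (length 5–12) for the
enumeration oracle; 1,000 random score sets for the AUC/rank-sum
identity; a 10,000-replicate bootstrap for the DeLong sd; 1,000
simulations at a known true AUC (binormal model, 60 + 60 scores,
AUC = Φ(1/√2) ≈ 0.76) for CI coverage, expected in the 93–97% band;
10,000 continuous scores for tails retention; 500 + 500 heavy-tailed
(half-Cauchy effect) scores for the tails AUC gain; and a 200 + 200
window pipeline run with a 1,000-permutation label null. These choices
are the package's own defaults for a reproducible demonstration.

## Known limitations

* The energy model is intentionally minimal: no multiloop penalties, no
  dangling ends, no coaxial-stacking geometry beyond adjacent pairs, no
  pseudoknots. Absolute energies and probabilities are not comparable to
  full-parameter folders; only the benchmarking machinery around them is.
* DeLong CIs undercover slightly below nominal at small-to-moderate
  sample sizes (the coverage check sits near 93–94%, consistent with the
  estimator's known small-sample behaviour).
* The Pearson metric is undefined on constant pairing vectors; the
  documented fallback (distance 1 with a warning) is a convention, not a
  statistical statement.
* `match_controls` assumes mean adjusted P-values are comparable across
  candidates with different numbers of applicable comparisons.
* The tails strategy assumes the combined score distribution is
  informative at its extremes; with label noise concentrated at low
  scores (environmental riboSNitches) the bottom tail retains
  confidently wrong positives, and filtering may not help.
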