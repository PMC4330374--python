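# ribobench

A toolkit for predicting and benchmarking **riboSNitches** — single
nucleotide variants (SNVs) that change the secondary structure of the RNA
they sit in. Such variants can rewire post-transcriptional regulation
without touching a protein sequence, and genome-wide structure-probing
screens (e.g. PARS on a parent/parent/child family trio) now detect them
by the thousand. The question this package addresses is the computational
side of that programme: *given only sequence, how well can a thermodynamic
folding prediction tell a structure-changing SNV from a neutral one, and
how should that be measured?*

It is written for computational biologists who want to (a) score candidate
SNVs for structural disruption, (b) benchmark disruption metrics against
labelled variant sets with a rigorous ROC protocol, or (c) stress-test the
whole workflow on synthetic data with known ground truth.

## What it does

1. **Fold** both alleles of an SNV-centred window (default: 50 nt either
   side of the variant, 101 nt total) under a simplified nearest-neighbour
   energy model. The engine computes the partition function
   `Z = Σ_S exp(−E(S)/kT)`, the base-pairing probability matrix (BPPM)
   `p_ij` by an inside–outside dynamic programme, and a minimum free
   energy (MFE) structure — all validated against brute-force enumeration
   of every pseudoknot-free structure on small inputs. Externally computed
   BPPMs (from any folding program) can be injected through a plain TSV
   exchange format instead.

2. **Score** the disruption between the two allele ensembles. The primary
   metric is an alignment-free profile distance between BPPMs: collapse
   each matrix to per-base probabilities of being upstream-paired,
   downstream-paired or unpaired,

   `p_i^( = Σ_{j>i} p_ij`,  `p_i^) = Σ_{j<i} p_ij`,  `p_i^o = 1 − p_i^( − p_i^)`,

   then sum one minus the Bhattacharyya coefficient per base:

   `d = Σ_i [ 1 − ( √(p1_i^( p2_i^() + √(p1_i^) p2_i^)) + √(p1_i^o p2_i^o) ) ]`.

   Also provided: `1 − r` on per-base total-pairing vectors (Pearson),
   a symmetrised relative-entropy profile distance, and the symmetric
   difference between MFE base-pair sets.

3. **Benchmark** scores against labels. Trio SNV tables are turned into a
   non-redundant window set with categories (symmetric / asymmetric /
   validated / probed riboSNitches vs non-riboSNitches); controls are
   matched by mean FDR-adjusted P-value; ROC curves are swept over all
   thresholds with AUC as the Mann–Whitney statistic; confidence
   intervals are `AUC ± 1.96·s` with `s` from DeLong's estimator (verified
   against R's pROC); ROC curves are compared with one-tailed DeLong
   tests; and the **n% tails** opt-out strategy retains only the extreme
   n% of the combined score distribution before re-running the ROC — the
   filter that rescues borderline predictors on noisy genome-wide sets.

4. **Simulate** trio-PARS-style datasets: hairpin windows whose SNV falls
   mid-stem (disruptive) or mid-loop (neutral), trio genotypes realising
   the requested category mixture, Beta-distributed comparison P-values,
   and an adjustable fraction of "environmental" riboSNitches (labelled
   positive but structurally neutral) to probe the limits of thermodynamic
   prediction.

## Worked example

```bash
ribobench simulate --out-dir demo --seed 17
ribobench windows --fasta demo/transcripts.fasta --snvs demo/snvs.tsv \
                  --out-fasta demo/windows.fasta --out-meta demo/meta.tsv
ribobench score --windows demo/windows.fasta --meta demo/meta.tsv \
                --metric bppm_profile --out demo/scores.tsv
ribobench bench --scores demo/scores.tsv --categories demo/meta.tsv \
                --tails 25,5 --out demo/report.tsv
```

The `windows` step prints `400 windows written, 0 SNVs excluded`; the
report then contains one row per category:

```
metric        category    n_pos  n_neg  auc  ci_low  ci_high  best_threshold  best_sens  best_spec
bppm_profile  probed      14     14     1    1       1        1.01099780452   1          1
bppm_profile  validated   58     58     1    1       1        1.00367884499   1          1
bppm_profile  symmetric   114    114    1    1       1        1.00910499597   1          1
bppm_profile  asymmetric  86     86     1    1       1        1.00367884499   1          1
bppm_profile  all         200    200    1    1       1        1.00367884499   1          1
bppm_profile  25% tails   50     50     1    1       1        1.03308323262   1          1
bppm_profile  5% tails    10     10     1    1       1        1.25510903976   1          1
```

`auc` is the area under the ROC curve for separating riboSNitches from
matched non-riboSNitches with the profile distance; `ci_low`/`ci_high`
are the DeLong 95% bounds, and the `best_*` columns describe the operating
point closest to the top-left corner of the curve. At the generator's
default effect sizes the stem-breaking SNVs separate perfectly from the
neutral ones (AUC 1); raising `noise_frac` in the simulation config mixes
in structurally neutral positives and pulls the AUC down toward 0.5.

Library use mirrors the CLI: `simulate_trio_dataset` →
`build_windows` → `score_window` → `run_benchmark`; see the docstrings in
`ribobench.fold`, `ribobench.metrics` and `ribobench.bench`.

## Layout

- `src/ribobench/fold.py` — energy model, enumeration oracle, partition
  function, BPPM, pairing profiles, MFE.
- `src/ribobench/windows.py` — SNV records, window extraction/exclusion,
  category logic, deduplication.
- `src/ribobench/metrics.py` — the four allele-distance metrics.
- `src/ribobench/bench.py` — control matching, ROC/AUC, DeLong, tails.
- `src/ribobench/simulate.py` — synthetic trio-PARS data generator.
- `src/ribobench/io.py`, `cli.py` — text formats and the `ribobench` CLI.
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
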