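# Methods

## The model

lfqpipe analyses label-free quantification (LFQ) data in which protein
abundance is measured as the summed MS1 precursor-ion peak area of a
protein's peptides in one LC-MS/MS run. Three properties of such data
drive the design:

1. **Areas are not comparable across proteins.** A protein's area
   scales with how many tryptic peptides it can contribute inside the
   instrument's preferred length window. Dividing by the *theoretical
   peptide count* (the iBAQ-style denominator) converts areas to a
   per-peptide intensity that is comparable across proteins.
2. **Areas are not comparable across runs.** Total loaded material and
   instrument response drift between runs; rescaling each run to
   fractions of its total removes a global per-run factor.
3. **Missingness is intensity-dependent (MNAR).** Values are missing
   predominantly because a protein's signal fell below the detection
   limit, i.e. the data are left-censored; imputation must therefore
   draw from the low tail, not from the observed distribution's centre.

## Stages and parameters

### In-silico digest (`digest`)

Trypsin cleaves C-terminal to K or R; cleavage is suppressed before
proline (toggleable, on by default — classical trypsin specificity).
Two conventions are exposed because database-search settings and the
counting denominator serve different purposes:

* `SEARCH_PARAMS`: ≤2 missed cleavages, length ≥7 — a typical search
  configuration.
* `COUNTING_PARAMS` (default for normalization): 0 missed cleavages,
  length 7–30 — fully cleaved peptides in the detectable window, the
  established per-peptide-count normalization convention.

The initiator methionine is not specially removed; unknown residues are
rejected with their offset. Proteins whose count is 0 are flagged and
dropped from normalization with a warning.

### Quantification chain (`normalize`)

* **Retention filter**: `unique_peptides ≥ 2` and observed in ≥1 run of
  at least one group. Defaults mirror the "more than one unique
  peptide" retention rule and presence-in-one-replicate depth common in
  multi-replicate LFQ designs.
* **Detection-limit imputation**: per run, missing cells are drawn from
  `N(m − shift·s, (width·s)²)` on the log2 scale with `shift = 1.8`,
  `width = 0.3` (the widely used down-shifted-normal convention,
  per-run statistics, ddof = 1). Implemented as a sklearn-compatible
  transformer (`DetectionLimitImputer`); observed cells are never
  altered (tested bit-wise), provenance is recorded per cell, and draws
  are deterministic under the seed. A run with no observed values is a
  hard error. Imputation runs after filtering and before
  normalization: filtering first avoids imputing rows that are about to
  be dropped; the order is configurable in the library by composing the
  functions differently.
* **Normalization**: `value1 = area / n_theoretical_peptides`,
  `fraction = value1 / Σ value1` per run. Fractions conserve to
  1 ± 1e-9 per run by construction (tested). All downstream statistics
  use log2 fractions — the log2 scale stabilises variance and makes
  fold changes symmetric; zero observed areas are treated as
  non-detections.

### Contrast tests (`contrasts`)

Pooled-variance Student's t (Welch by flag) on log2 fractions, two-sided,
flagged at raw P < 0.05. **No multiple-testing correction by default**:
the selection rule this pipeline reproduces thresholds raw P-values, so
BH-adjusted values are available (`add_bh=True`) but do not drive
selection. Degenerate rows (zero variance in both groups) follow the
convention t = 0, p = 1 when means are equal, p = 0 otherwise. Tests
include imputed values; at default settings an imputed-heavy protein's
contrast is dominated by the down-shift distribution, which is the
intended MNAR interpretation (a non-detection is evidence of low
abundance).

### Trends (`trends`)

Phases span three ordered groups each: injury = first three groups,
repair = last three. Profiles are per-protein group means (the
clustering operates on means, not replicate values). K-means runs on
z-scored profiles so that Euclidean distance measures shape, matching
the intent of Pearson-distance hierarchical clustering, which is also
provided (average linkage, d = 1 − r, undefined correlations of
constant profiles set to distance 1 with a flag). k defaults to 3 for
the injury phase and 4 for the repair phase — the cluster counts the
emulated study reports — with seeded restarts and scipy's deterministic
lowest-index merge order.

The trend rule compares consecutive differences d1, d2 of the three
means against `ε = 0.05 × (max − min)`: both above ε → `up`; both below
−ε → `down`; d1 above/d2 below → `up_down`; the reverse → `down_up`;
otherwise `flat_mixed` (including constant profiles). The relative ε
makes the qualitative cluster descriptions testable. Sign-flipping a
profile provably swaps up↔down and up_down↔down_up (property-tested);
note that *reversing* a profile is not the same operation — a symmetric
biphasic profile reversed is still biphasic.

### Enrichment and funnel (`enrichment`)

`p_hyper = P(X ≥ k)` for the hypergeometric distribution with the
phase's background as population. The background is the set of
proteins quantified (observed in ≥1 run of every group of the phase)
and retained — the "commonly overlapping proteins" role. Raw p < 0.05
drives pathway selection (BH values reported alongside). Common
pathways are those enriched in both phases; the funnel is the
conjunction *significant-in-≥1-contrast ∧ qualifying-trend ∧
extracellular_region ∧ common-pathway-member*, with qualifying trends
monotone (up/down) for the injury phase and biphasic
(up_down/down_up) for the repair phase. Annotations come from offline
GMT fixtures; results are only as current as the supplied term sets.

### Orthogonal validation (`wb_concordance`)

Densitometric mean triples (Sham, MCAO, treated) and label-free group
means are trend-classified with the same rule; concordance = identical
labels. The summary also counts proteins whose MCAO mean strictly
exceeds both the Sham and treated means. On the packaged 12-protein
reference table this rule-based count is 9; note the qualitative
high/low grouping of such tables need not partition cleanly under a
strict-inequality rule (three reference proteins have their *minimum*
in MCAO), which is why the count is reported as a rule, not forced
into a narrative partition.

### Pharmacology statistics (`pharm`)

* **Rank sum**: W = sum of mid-ranks of group a. Exact branch
  enumerates all C(n, n_a) rank assignments (used when both groups have
  ≤8 animals); the normal branch applies the tie-corrected variance and
  a 0.5 continuity correction (matching scipy's asymptotic
  Mann-Whitney). With five-point scores the exact null is lumpy; the
  branches agree within 0.02 for p ≤ 0.1 and within ~0.1 at large p —
  measured by enumeration, and the reason both branches are exposed.
* **ANOVA + Newman-Keuls**: classical one-way ANOVA; SNK sorts group
  means, tests each pair with the studentized-range statistic at its
  span size (harmonic-mean n for unequal groups), stepping down from
  the widest span, and a non-significant span blocks all nested pairs.
  Zero within-group variance with unequal means is flagged
  (F infinite).
* **Infarct volume**: 100·Σinfarct/Σhemisphere over exactly five
  slices; summed areas proxy volume under constant slice thickness.
* **Score-multiset reconstruction**: exhaustive search over integer
  multisets (scores 0–4) whose mean and **population** SD (ddof = 0)
  round to the printed 2-decimal summary — the population formula is
  the one that reproduces the printed score tables exactly. Group size
  n is an input, never assumed.

## The synthetic-data generator

`SyntheticConfig` defaults define the emulated study: 3000 proteins,
4 groups × 3 replicates, base log2 abundance N(20, 2), replicate noise
SD 0.3, differential fraction 0.04 per contrast (~120 proteins, the
scale of the emulated study's per-contrast counts), candidate fraction
0.004 (~12 proteins), effect size 1 log2 unit, left-censoring of the
lowest 25% of each run's intensities (bringing per-run quantification
depth to roughly the observed ~2500-of-3300-retained scale).

Planted effects come in three shapes: *ramps* (0, ±e, ±2e, ±2e —
monotone across the injury phase, differential in the first two
contrasts), *MCAO spikes* (±e in the injured untreated group only —
biphasic repair trend, differential in the second and third contrasts;
these are the planted funnel candidates), and *late steps* (±e in the
treated group only). Spikes are planted in the upper abundance half
because real candidate proteins are drawn from the commonly-quantified
core proteome — a protein censored out of most runs could never be
WB-validated. All planted proteins are drawn from those with ≥2
theoretical peptides so they survive the retention filter.

The linear area is `2^log2_abundance × theoretical_peptide_count`, so
peptide-count normalization is exactly invertible on noise-free data;
this gives the normalization chain an exact oracle (tested: with zero
noise and no censoring, fractions equal true relative abundances to
1e-9).

Annotation fixtures: an `extracellular_region` CC term containing every
planted candidate plus background members at rate 0.1, and WNT/MAPK/AMPK
pathway terms containing each candidate (≥1 of the three), planted
differential proteins at rate 0.4, and background at 0.1 — so pathway
enrichment in both phases is genuinely planted rather than accidental.
A WB-style table is generated for the candidates from their true
repair-phase relative abundances with 5 nominal replicates.

**What the generator does not emulate**: correlated peptide-level
missingness, shared peptides, retention-time effects, batch drift,
protein-protein abundance correlation, or search-engine FDR; passing
tests demonstrate the pipeline's statistical machinery under the
stated generative model, not robustness to those real-data features.

## Numerical and reproducibility choices

* One run seed fans out to per-stage seeds by CRC32 stage-name hashing
  (all below 2^31), so a stage can be re-run independently and the full
  pipeline is byte-deterministic (tested).
* Problem sizes used by the test suite and the acceptance script: digest
  oracle on 1000 sequences, null calibration on 10,000 proteins,
  candidate recovery on ten 3000-protein bundles, end-to-end run at the
  default 3000-protein scale — each completes in seconds on one CPU.
* Degenerate inputs are contracts, not silent behaviour: all-missing
  runs, zero-total runs, k > n clustering, groups with <2 replicates,
  selected-outside-background enrichment, and out-of-scale scores all
  raise with the offending item named.

## Known limitations

* The type-I-error calibration holds for the t-test on observed data;
  under heavy censoring the imputation's low-variance down-shift can
  make imputed-dominated contrasts anticonservative. A flag to exclude
  imputed-dominated proteins is a natural extension.
* Raw-P selection (no FDR) reproduces the emulated selection rule but
  implies ~5% of quantified proteins flagged per contrast under the
  null; the BH column is provided for stricter workflows.
* The funnel's monotone/biphasic trend gate uses group means only;
  within-group variance does not enter the trend decision.
* Hierarchical and K-means clusterings are reported but the funnel's
  trend gate is the rule-based classifier, which is deterministic and
  testable; cluster labels are descriptive output.
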