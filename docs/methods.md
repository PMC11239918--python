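# Methods

This note documents the models, conventions and numerical choices behind
`celtilkit`, in the order of the pipeline.

## CelTIL scoring

The raw score is `-0.8 · cellularity% + 1.3 · TILs%`.  Some descriptions
of the score print the TILs term with an ambiguous sign; the definition
of the score — high values identify immune-infiltrated tumors with
reduced cellularity — forces the positive coefficient, which is what we
implement.  The affine rescaling to 0–100 uses the theoretical raw range
`[-80, 130]` (width 210), so the endpoints of the input square map to
exactly 0 and 100.  Deltas are computed on the scaled score; computing
them on the raw score differs only by the constant factor 100/210 and
would change no response call once cutoffs are expressed on the same
scale.

Response cutoffs follow the convention of the sensitivity set
`(>0, ≥10, ≥20, ≥30, ≥40)`: the zero cutoff is strict, every other
cutoff is inclusive.  Calls are therefore nested — a responder at ≥30 is
a responder at ≥20 and ≥10.

## Expression panel

Counts come from a 192-gene targeted panel containing 185 analysis genes
and 7 housekeeping genes (ACTB, MRPL19, GAPD, PSMC4, PUM1, RPLP0,
SF3A1).  The normalization — `log2(count+1)` minus the per-sample mean
of the log2 housekeeping counts — is the standard convention for such
panels; the exact pipeline used by any given trial lab is typically
unpublished, so this is a package choice.  It is invariant to per-sample
scale factors up to the `+1` pseudocount.

Subtype calls correlate a normalized profile against centroid profiles
over their shared genes and take the argmax.  Spearman correlation is
the default (the common research-based practice, and invariant to
monotone transforms of the profile); Pearson is available.  Exact
correlation ties break deterministically to the first centroid in column
order and are flagged.  Profiles covering less than 90% of the centroid
genes (configurable) are rejected rather than silently scored.

Signature scores are weighted means over the signature genes present in
the profile, with weights renormalized to the present genes; a
single-gene signature (the *ERBB2* mRNA score) reduces to that gene's
normalized value.  The published subtype centroids and signature weights
are proprietary to their assays and are not shipped; the package defines
the file schema and the synthetic generator emits stand-in model files
with the same shape.

Tertile grouping assigns the lowest `ceil(n/3)` reference ranks to
"low", the next `ceil(2n/3) - ceil(n/3)` to "medium" and the rest to
"high" — at n = 77 this gives groups of 26/26/25.  Cutpoints are
midpoints between the boundary order statistics; new samples at or below
a cutpoint go to the lower group, so re-applying the model to its
reference cohort reproduces the fitted group sizes exactly (for
continuous scores).

## Copy-number signatures

SEG records (1-based inclusive; the reader converts BED's half-open
convention for annotations) are mapped to genes by **maximal overlap**:
each gene takes the mean log2-ratio of the segment it overlaps most.  A
length-weighted mean across overlapping segments was considered and
rejected — maximal overlap is deterministic, simpler to audit, and the
two differ only for genes straddling a breakpoint.

Segment signals are arithmetic means of member-gene values.  Signature
scores are plain dot products of the model's coefficient rows with the
segment-signal vector.  Missing segments contribute zero rather than
triggering weight renormalization: renormalizing a linear model with
signed coefficients distorts scores unpredictably, whereas a zero
contribution at the (centered) log2-ratio scale is a neutral value.  A
sample missing more than 20% of segments (configurable) is rejected with
a quality error, and missing segments are reported.

Cluster assignment is Euclidean nearest centroid over the signature
vector.  Whether the original DNA-based classifier standardizes
signature scores before computing distances is not published; the model
file may therefore carry optional per-signature means/SDs, and no
standardization is applied when it does not (the default).  Distance
ties break to the lowest cluster label and are flagged.

## Variant filters

A call survives if it has ≥ 7 reads supporting the alternate allele, a
variant allele fraction of ≥ 5% (SNV) or ≥ 10% (indel), and a population
allele frequency that is missing or ≤ 1e-4.  All thresholds are
inclusive.  The population-frequency rule removes frequent
polymorphisms; the rule is stated in the literature with a contradictory
parenthetical ("removed … (allele frequency ≤ 0.0001)"), which we read
in the only direction that makes biological sense: *keep* rare variants,
remove frequent ones.  Dropped records are attributed to the first rule
they fail, in the order above.  Filtering is idempotent, and tightening
any threshold can only shrink the survivor set.

## Association statistics

- **Fisher exact, 2×2**: two-sided by probability-mass ordering (sum of
  hypergeometric probabilities of all margin-preserving tables no more
  likely than the observed one).  Conventions differ between software
  packages; this is the common definition, and the test suite verifies
  it against explicit enumeration for every margin class with total ≤ 40.
- **Freeman–Halton r×c**: the same ordering, by full recursive
  enumeration of margin-preserving tables; refused above a total of 200
  in favor of a Monte-Carlo approach.
- **Odds ratios**: cross-product with Wald CI on the log scale; a zero
  cell yields a flagged infinite/zero OR, with the Haldane–Anscombe 0.5
  correction available.
- **Logistic regression**: Newton (equivalently IRLS) maximum likelihood
  (tolerance 1e-8, ≤ 100 iterations) via statsmodels; Wald CIs and
  p-values; complete separation or non-convergence is flagged on the
  result rather than raised.
- **ROC AUC**: Mann–Whitney rank statistic with midranks; two-sided
  normal-approximation p with tie correction (the common choice when a
  publication does not state DeLong); Hanley–McNeil CI clipped to [0,1].
- **t tests**: Welch by default (pooled available), two-tailed.
- Contingency and logistic p-values are reported raw; FDR control
  applies only within SAM, mirroring how such trial analyses are
  reported.

## SAM

The two-class unpaired statistic is `d = (mean₂ − mean₁)/(s + s0)` with
the pooled standard error `s` and a fudge factor `s0` chosen over a
5-percentile grid of the `s` distribution to minimize the coefficient of
variation of windowed median-absolute-deviations of `d` across the range
of `s` (the original formulation's recipe).  Expected order statistics
come from full label permutations (default 1000, seeded).  For a
threshold Δ, asymmetric cutoffs are the least/greatest observed d whose
deviation from the expected order statistic reaches ±Δ; the estimated
FDR at Δ is `π̂0 · (mean permuted exceedance count) / (observed calls)`,
with `π̂0` estimated from the share of observed d inside the central 50%
of the permuted distribution.  The reported set uses the smallest Δ with
estimated FDR at or below the target (default 10%); genes also receive
q-values (the smallest FDR at which they would be called).

The *mean* permuted exceedance count follows the method's original
formulation.  Note what this procedure controls: an estimate of
E[false calls]/calls at the chosen cutoffs, not the Benjamini–Hochberg
FDR.  On a fully null dataset each tail's threshold is calibrated near
the nominal rate, so the probability of making *any* (necessarily false)
call on null data is roughly twice nominal; the acceptance script
reports this rate transparently (`sam_null_any_call_rate`).

## Synthetic cohorts

The generator emulates the *shape* of a paired-biopsy trial in HR+/HER2−
early breast cancer, with every latent variable recorded as ground truth:

- **Subtype mixture** (default LumA 0.57, LumB 0.20, HER2-enriched 0.08,
  Basal-like 0.06, Normal-like 0.09) reflecting an HR+/HER2− cohort in
  which basal-like tumors are rare.
- **Expression**: subtype centroid (module-structured over proliferation,
  luminal, basal, HER2-amplicon and immune gene sets) plus a per-sample
  proliferation jitter (SD 0.5) and i.i.d. gene noise (SD 0.5, log2
  scale), exponentiated and rounded to counts over a housekeeping
  baseline of ~2⁶.
- **ERBB2–17q12**: a latent amplicon level drives both normalized ERBB2
  expression and the 17q12 segment signal with loading √ρ each, giving
  Pearson correlation ρ (default 0.55).  ERBB2's subtype-mean is held
  constant — consistent with reports that ERBB2 mRNA is not
  subtype-associated in HER2− cohorts — so the planted correlation is
  not diluted by subtype structure.
- **TP53**: Bernoulli per subtype — Basal-like 1.0 and Luminal A 0.107
  (the two anchored rates), with Luminal B 0.12, HER2-enriched 0.30,
  Normal-like 0.15 chosen once so the cohort-level frequency lands near
  18%.
- **Response**: logistic on standardized proliferation, negative
  standardized ERBB2 level and TP53 status (default βs 0.8, 0.8, ln 6).
  The intercept −1.24 was calibrated analytically-by-simulation to give
  a ~34% marginal response rate under the default mixture.
- **Biopsy dynamics** are parameterized directly on the target scaled
  CelTIL change (responders N(35, 8), non-responders N(4, 8)) rather
  than on a mechanistic tumor-kill model, because the score is the only
  measured quantity; day-21 cellularity/TILs are solved from the target
  delta and clipped to valid percentages, which slightly shrinks extreme
  deltas.
- **Copy number**: four cluster archetypes are block gain/loss patterns
  over the 519 segments; cluster centroids in signature space are the
  exact linear image of those archetypes, so cluster recovery is perfect
  at zero noise and degrades with the per-segment noise SD (default
  0.15).  The 17q12 segment is excluded from the archetype blocks so its
  signal carries only the planted amplicon latent.
- **Model files** (centroids, signature weights, 519-segment definitions
  over a synthetic genome of 3 genes/segment, 150×519 coefficients, 4×150
  cluster centroids) are generated from a fixed model seed (797),
  independent of the cohort seed — the "assay" does not change between
  cohorts.

What the generator does **not** emulate: count overdispersion
(log-normal rather than negative-binomial counts), FFPE segment
dropouts, inter-pathologist scoring noise, subclonal VAF structure, and
any coupling between CN clusters and response.  Tests passing on these
cohorts therefore demonstrate correctness of the pipeline's computations
and recoverability of planted effects, not performance on real assay
noise.

## Problem sizes and determinism

Test and acceptance runs use cohorts of 30–77 patients for end-to-end
stages, n = 500 for correlation recovery, n = 2000 × 20 replicates for
logistic parameter recovery, and 200 genes × 40 samples × 50 replicates
for SAM null calibration — sizes at which every quantity of interest is
estimable with small Monte-Carlo error while the whole suite runs in
well under a minute.  Every stochastic component takes an explicit seed;
identical seeds give byte-identical outputs, including written bundles
(readers use exact float round-tripping).
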