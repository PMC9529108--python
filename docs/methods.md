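# Methods notes

## Model and procedure

The pipeline treats each included publication (or published sub-cohort) as
an independent case-control study reporting genotype counts
(n11, n12, n22) per arm at one VDR polymorphism. All association measures
are odds ratios with the column-22 (mutant, lowercase) allele as the
effect allele and the 11 homozygote as reference. This orientation is the
one that reproduces the published pooled estimates; the source Methods'
literal contrast labels ("F versus f", "BB+Bb versus bb") are written the
other way around, but the published numbers (e.g. the Ferrarezi 1 BsmI
homozygote OR of (86×969)/(154×425) ≈ 1.27, and the Discussion's "Bb and
bb have 22% and 29% increased risk compared to BB") fix the orientation
used here.

Pipeline per SNP:

1. Hardy-Weinberg χ² (df = 1, no continuity correction) on control
   genotype counts; departure at p < 0.05. The plain χ² reproduces the
   published control p-values (0.805, 0.902, …); an exact test does not.
2. Contrast tables under the five genetic models. Studies with a zero
   exposed (or unexposed) count in *both* arms are excluded under that
   model; a single zero cell triggers the 0.5-to-every-cell continuity
   correction for both estimate and variance.
3. Heterogeneity: Cochran Q with inverse-variance weights around the
   inverse-variance mean; I² = max(0,(Q−df)/Q)·100. Pooling is
   Mantel-Haenszel fixed-effect (Robins-Breslow-Greenland variance) iff
   p_het > 0.10 and I² < 50, else DerSimonian-Laird random effects.
   Subgroup analyses (race, HWE status, total sample size ≥/< 500,
   genotyping method) always use random effects.
4. Multiplicity: the family is the five genetic models within one
   (SNP, stratum) cell — Bonferroni multiplies by 5 and caps at 1;
   Benjamini-Hochberg steps up over the same five. Both are reported side
   by side because the published table prints both columns.
5. Publication bias: Egger's unweighted regression of standardized effect
   on precision (t-test on the intercept, df = k−2) and the
   Begg-Mazumdar Kendall-tau test, both on the allelic-model effects.
   The source reports one Egger p per SNP without naming the model; with
   the allelic choice this package obtains 0.423 / 0.283 / 0.398 / 0.977
   for rs2228570 / rs1544410 / rs731236 / rs7975232 against the published
   0.423 / 0.218 / 0.396 / 0.980 — three of four essentially exact, which
   supports (but cannot prove) the allelic assumption.
6. Sensitivity: leave-one-out refits with the auto-selected pooling.
7. TSA on the allelic model: studies accrue by ascending publication year
   (ties broken by author; the source does not state its ordering),
   information is accrued participants, the pooling method is fixed from
   the full set, and boundaries come from the Lan-DeMets
   O'Brien-Fleming-type spending function
   α(t) = 2(1−Φ(z₁₋α/₂/√t)) solved recursively by numerical integration
   of the surviving Brownian-path density. Futility wedges are not
   implemented (the source reports only significance boundaries).

## Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| significance threshold | 0.05 | p | stated design |
| heterogeneity gate | p ≤ 0.10 or I² ≥ 50% | — | stated design |
| continuity correction | 0.5 | added count | zero-cell convention |
| sample-size stratum cut | 500 | persons | stated design (≥500 large) |
| TSA α / power / RRR | 0.05 / 0.80 / 0.20 | — | stated design |
| TSA control event proportion | pooled control effect-allele frequency | proportion | see gap below |
| TSA diversity D² | 0 | proportion | see gap below |

`required_information_size` rounds to the *nearest* integer: the closed
form at pC = 0.5, RRR = 0.2, α = 0.05, power = 0.8 evaluates to 777.04 and
777 is the reference hand value; always rounding up would give 778.

## Known data discrepancies (recorded, not patched)

The transcribed genotype table is internally inconsistent in places; the
genotype columns are treated as authoritative throughout and no digit is
altered:

* rs1544410: Ferrarezi 1 case rows sum to 482 (printed N 483) and control
  rows to 2655 (printed 2654). Derived totals are therefore 4212 cases /
  10005 controls, vs the published prose "4210 and 10004".
* rs731236: Ferrarezi 1-3 case rows sum to 484/466/806 vs printed
  483/465/805, giving 3139 cases vs the published 3136; two control rows
  are also off by one (totals still 9501).
* rs7975232: two case rows and two control rows off by one each
  (errors cancel in the totals 2815/9460→9458).
* Two He 2015 printed HWE p-values (0.955 for rs731236, 0.801 for
  rs7975232) are not reproduced by the χ² on the printed counts (≈0.80 and
  ≈0.66); the test is validated on the rows that do reproduce.
* The published Table 2 block labels for rs7975232/rs731236 are swapped
  relative to Table 1 and the Results text; all outputs here are keyed by
  Table 1's SNP assignment (rs731236 = 11 studies, increased risk 1.19;
  rs7975232 = 9 studies, decreased risk 0.93).

These off-by-ones move pooled odds ratios by < 0.001 and matter only for
exact person totals.

## TSA reproducibility gap

The published information sizes (152472 / 84534 / 42415) cannot be
regenerated from the stated α/power/RRR alone: they additionally depend on
the control event proportion and diversity adjustment the original TSA
software was given, which are not reported. Both are therefore exposed as
configuration (`TSAConfig`), defaulting to the pooled control effect-allele
frequency and D² = 0. At a configuration matched to RIS = 152472 the
rs1544410 final information fraction is ≈ 0.09, where any
O'Brien-Fleming-type boundary is ≈ 6.5 while the final |Z| is ≈ 4.8 — so
the published claim that the rs1544410 Z-curve crosses the monitoring
boundary is not reproducible under alpha-spending arithmetic; the claim
that the rs2228570 White curve crosses 1.96 but not the boundary is
reproduced.

## Synthetic data

The generator draws, per study, a log OR ~ Normal(log OR_true, τ²),
control genotypes multinomially from frequencies
((1−F)p² + Fp, (1−F)2pq, (1−F)q² + Fq) at effect-allele frequency q and
inbreeding F, and case genotypes in Hardy-Weinberg proportions at the
allele frequency implied by the study OR acting on the control allele
odds. Arm totals are fixed (defaults: 10 studies, 100-500 per arm,
q = 0.35, OR 1.15 — the scale of the pooled literature). It emulates the
sampling model the pooling assumes; it does **not** emulate shared control
arms (Hossein-Nezhad 1-3 reuse one control group in the real data),
genotyping error, covariate confounding, or linkage between SNPs — so a
green calibration test certifies the estimator arithmetic, not robustness
to those features. Case genotypes are generated under HWE, so
genotype-model "truths" are derived quantities of (q, F, OR) rather than
free parameters.

## Numerical choices

* Boundary recursion: 601-point grid on ±10 SD of the Brownian-sum scale,
  exact normal-CDF cell increments, first look solved analytically;
  two-look null crossing probability verified by Monte Carlo to ≈ α.
* DL τ² truncated at 0 (statsmodels' untruncated variant is used as a
  cross-check only where τ̂² > 0).
* Begg standardized deviates clip var − var_pooled at 1e-12 to stay
  defined when a study's variance equals the pooled variance.
* Display rounding (2 decimals for ORs/CIs, whole percent for I²) happens
  only at the reporting layer; all internal arithmetic is double
  precision.
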