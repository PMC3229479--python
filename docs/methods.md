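# Methods

## Risk model

Each locus is a biallelic variant characterised by its risk-allele
frequency in the control population, `q`, and a per-allele odds ratio,
`OR`. Under the multiplicative (no-interaction) model the heterozygote
carries odds `OR` and the risk-allele homozygote odds `OR²` relative to
the non-carrier.

Genotype distributions are Hardy-Weinberg within controls at `q` and
within cases at the odds-scaled frequency `q'` with
`q'/(1−q') = OR·q/(1−q)`. This is exact algebra, not an approximation:
multiplying the HWE genotype weights by `OR^g` and renormalising gives
HWE at the odds-scaled allele frequency. The per-genotype likelihood
ratio is then `LR(g) = P(g|case)/P(g|control)`, and the predicted risk
of an individual follows from Bayes' theorem with prior odds
`p/(1−p)`, `p` the baseline lifetime risk (default 0.001), and the
product of the LRs of all their genotypes. Products are accumulated in
log space.

Using the published *control* frequency directly is justified at
`p = 0.001`, where controls are statistically indistinguishable from
the population. A second constructor solves genotype penetrances
numerically (heterozygote OR and homozygote OR² on the odds scale,
marginal risk constrained to `p` to |Δ| < 1e-12) and agrees with the
allele-level route to ~1e-3 in the LRs and < 5e-4 in AUC at
`p = 0.001`; it exists purely as a cross-check.

Assumptions inherited from the model class: independent loci (no LD),
no gene-gene or gene-environment interaction, no covariates. These are
deliberate; panels violating them need a different model.

## AUC computation

Two routes, kept strictly independent so they can check each other:

* **Exact enumeration** (panels ≤ 12 loci): all `3^k` genotype
  combinations are enumerated; the probability of a combination is the
  product of per-locus genotype frequencies under cases and controls
  respectively, and AUC = P(case combo outscores control combo) + ½
  P(tie). Scores are compared on the log-odds scale with an absolute
  tie tolerance of 1e-12; the AUC is invariant to any strictly
  increasing transform of the score.
* **Monte Carlo**: genotypes for N individuals are drawn from the
  control HWE frequencies, disease status is an independent Bernoulli
  draw at each individual's posterior risk, and the AUC is the
  Mann-Whitney rank statistic with midrank ties. Scenario estimates
  average 100 replicates of N = 100,000 (≈ 100 cases each at
  p = 0.001; per-replicate SD ≈ 0.025, so the mean has SE ≈ 0.0025).

Replicate `r`, attempt `a` uses
`SeedSequence(master_seed, spawn_key=(r, a))`; attempts beyond 0 occur
only when a replicate draws a single-class population (re-drawn, at
most 5 times, logged). The whole pipeline is reproducible from one
integer, and two models evaluated under the same master seed share
random draws — the common-random-number device the inverse search
relies on.

## Inverse search

`required_or` brackets the per-allele OR in [1, 20] and bisects on the
mean AUC of the augmented panel (20 replicates per evaluation, common
random numbers, so the objective is monotone in OR up to residual
noise) until the bracket is narrower than 0.05, reporting the midpoint
to one decimal — the printed precision of the original grid. If the
base panel already meets the target the result is 1.0; if OR 20 falls
short an error reports the AUC achieved. Extra variants are
exchangeable and identical within a cell, as the grid design implies.

## Synthetic cohorts

The generator emulates the empirical study's *statistical structure*:
591 cases / 600 controls; genotypes HWE within stratum (controls at
the observed control RAF, cases at the odds-scaled frequency — the
cohort-observed case RAFs then serve as a consistency check only,
since the published ORs are age/sex-adjusted and no crude generator
can match both exactly); ages truncated-normal on [18, 90] with the
reported moments (cases 45 ± 12, controls 49 ± 17); sex Bernoulli
(71% / 55% female); and independent per-genotype missingness at rate
`1 − ((564+581)/(591+600))^(1/6) ≈ 0.0065`, calibrated so the expected
complete-genotype counts match the reported 564 cases / 581 controls.
Age and sex are independent of genotype, so crude and adjusted ORs
coincide in expectation.

What the generator does **not** emulate: population stratification,
relatedness, batch or plate effects, informative (SNP- or
subject-clustered) missingness, and any genotype-demographic
dependence. A green cohort-pipeline test therefore establishes that
the *procedure* is correct (parameter recovery, CI coverage, gradient
direction), not that any particular published cohort estimate is
reproduced — those depend on unavailable patient-level data.

## Cohort pipeline choices

* "Effect size" weights in the risk-allele score are `ln(OR)` from the
  literature panel (additive log-odds, proportional to the model's log
  posterior odds); raw-OR weighting exists behind a flag for
  sensitivity only.
* Allele-count bins follow the reported extremes (0–5 and 10–12 with
  HLA; 8–10 without); interior counts are single-count bins by design
  and are a parameter.
* Bin ORs are reported against the a-priori odds (case/control odds of
  the complete-genotype sample). CIs come from a logistic regression
  with *weighted effect coding* — bin indicators constrained so the
  bin-size-weighted deviations sum to zero, making the intercept the
  weighted-mean bin log-odds — plus age and sex when adjusting. The
  point estimate (crude bin odds over pooled odds) and the regression
  reference (weighted geometric-mean odds) differ by Jensen's gap,
  which is < 2% on realistic cohorts; a reference-like bin therefore
  shows OR ≈ 1, exactly 1 only in symmetric cases.
* Per-SNP associations are binomial GLMs of status on allele count
  (plus age and sex when adjusted) with Wald 95% CIs and a Bonferroni
  flag at 0.05/6 ≈ 0.008 for the default panel. Monomorphic variants
  and separated fits are flagged rather than reported.

## Reproduction of the published values

The panel AUCs computed here are 0.676 (6 SNPs), 0.695 (24) and 0.719
(53); the original report gives 0.64 / 0.66 / 0.69. The difference was
investigated in depth: the enumeration AUC, a closed-form single-locus
computation, the penetrance-route cross-check and a 2-million-sample
direct case/control simulation all agree with each other to < 0.001,
so the implementation is internally consistent. Alternative homozygote
conventions were evaluated — carrier-only ("dominant", hom OR = het
OR) reproduces the published 6- and 24-SNP values almost exactly
(0.643 / 0.658) but not the 53-SNP value (0.671), while an additive
odds convention (hom OR = 2·OR − 1) reproduces none well. No single
convention matches all published numbers, and the multiplicative model
the original text states is the one implemented. Downstream, the
higher 53-SNP baseline (0.719 > 0.70) means no extra variants are
needed to reach AUC 0.70 (required OR 1.0 where the original grid
prints 1.1), and required ORs for higher targets land one rounding
step below the printed ones.

## Numerical notes

* Genotype sampling is `Binomial(2, q)` per locus — identical in law
  to HWE category sampling.
* Posterior risks use the logistic of accumulated log-odds; no
  under/overflow occurs for panels up to hundreds of loci at printed
  OR magnitudes.
* `empirical_auc` uses midranks, so it equals brute-force pair
  counting with ½-credit ties exactly (tested on random instances and
  against an external ROC implementation).
* Degenerate inputs: single-class populations raise an undefined-AUC
  error (scenario replicates are re-drawn instead); empty panels give
  posterior ≡ prior and AUC exactly 0.5; monomorphic variants are
  rejected at panel validation (RAF strictly inside (0,1)).
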