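# Methods

## Models and test statistics

All tests condition on the 2×3 table of genotype counts (cases and
controls over AA, Aa, aa, with `a` the counted effect allele), the
sufficient statistic for a single biallelic SNP in a case/control design.
They are likelihood-ratio (LR) tests of grouped binomial logistic models
with the three genotype classes as covariate patterns:

| term | AA | Aa | aa |
|---|---|---|---|
| additive (`Add`) | 0 | 1 | 2 |
| dominant | 0 | 1 | 1 |
| recessive | 0 | 0 | 1 |
| dominance deviation (`DomDev`) | 0 | 1 | 0 |

* **CAT tests** — single-slope models `logit P = α + βX` with the
  additive, dominant or recessive codes; `β = 0` tested with 1 df.
* **GRM test** — the two-term model `logit P = α + β_Add·Add +
  β_DomDev·DomDev`; `β_Add = β_DomDev = 0` tested with 2 df. The model is
  saturated over three genotype classes, so the LR statistic equals the
  2×3 G-statistic `2·Σ O·ln(O/E)` (with `0·ln 0 ≡ 0`), which is used as a
  closed form and as an independent oracle in the tests.
* **Constraint tests** (model inference) — `β_DomDev = 0`, `β_DomDev =
  β_Add`, `β_DomDev = −β_Add`, each a 1-df LR test of the constrained
  submodel against the full model. Each constraint reduces to a single
  slope on a recoded covariate — (0,1,2), (0,2,2), (0,0,2) — and since
  rescaling a covariate leaves the maximised likelihood unchanged, the
  dominant/recessive constrained fits share their log-likelihood with the
  corresponding CAT fits.

The decision tree runs only when the 2-df test passes the association
threshold (default 1E-5; genome scans use 5E-7 with a 5E-5 suggestive
tier). The additive constraint is tested first at the model-test
threshold (default 0.01, configurable); if it survives, `additive` is
returned without examining the other constraints. Otherwise dominant and
recessive are each tested; exactly one surviving constraint names the
model, and both-or-neither yields `undetermined` with all p-values
exposed — the tie branch is a package decision, since a tree of this
shape does not define it.

### Score and Wald forms

Every classical implementation of these tests reports one of three
asymptotically equivalent statistics, and in moderately sparse tables
they visibly differ in the far tail used by genome-wide thresholds:

* the **score form** of a trend test is the classical Cochran-Armitage
  statistic; it is slightly conservative when the non-zero-coded classes
  are sparse (e.g. a recessive coding at MAF 0.2, where the aa column
  holds ~4% of samples);
* the **Wald form** of the 2-df test shrinks when coefficients are large
  and a homozygote column is sparse (the Hauck-Donner effect), costing
  up to ~0.15 power in recessive settings at MAF 0.2 relative to the LR
  form, and running below nominal size (≈4.9% at the 5% level in our
  null calibration, vs ≈5.0% for the LR form).

The package defaults to the LR form everywhere (`grm_test(...,
statistic="lr")`, `cat_test(..., statistic="lr")`) and exposes
`statistic="wald"` / `statistic="score"`. The simulator tallies all forms
(`power_grm` / `power_grm_wald`, `power_cat_*` / `power_cat_*_score`).
The reference power tables this package reproduces are matched by the
score/Wald columns, not the LR columns — the pattern of their null
calibration (trend tests at nominal, 2-df test below nominal) and of
their sparse-recessive power cells identifies score/Wald-reporting
software — so `scripts/acceptance.py` and the printed-table acceptance
tests compare those columns, while the LR defaults are validated against
closed-form and brute-force oracles.

## Effect estimates

From the saturated two-term fit: `β_Add` and `β_DomDev` with Wald
confidence intervals at a configurable level (default 95%), plus the
homozygote contrast `OR(aa vs AA) = exp(2·β_Add)` with its interval from
the coefficient covariance. On a saturated fit these equal the sample
odds ratios of the table. Intervals are suppressed for non-converged
fits.

## Numerical choices

Fits use Newton-Raphson on the grouped binomial likelihood: relative
log-likelihood tolerance 1e-10, at most 100 iterations, step-halving
(up to 30 halvings) whenever a step decreases the likelihood, and a tiny
ridge (1e-12 of the information trace) keeping the solve defined under
separation or empty classes. The implementation is vectorised over
replicate tables; one batched fit of the additive coding is the only
iterative step per simulated batch, everything else being closed form.

Degenerate inputs: under a monotone likelihood (separation, e.g. a zero
cell on the coded axis) coefficients are capped at ±30 log-odds, the fit
is flagged `converged = False`, and the deviance at the cap — numerically
indistinguishable from the supremum — feeds the LR statistic. A genotype
class with zero total count drops out of the likelihood; the 2-df test
keeps its 2-df reference by convention and the table is flagged. LR
statistics are floored at 0 (roundoff from the closed forms can produce
−1e-14). Wald statistics on tables with empty cells are set to 0:
an infinite-variance Wald test carries no evidence, matching the
non-rejection such tables produce in practice.

## Simulation design

A disease model is (mode of inheritance, risk-allele frequency `p`,
effect size OR, prevalence K). Genotypes follow Hardy-Weinberg
proportions ((1−p)², 2p(1−p), p²); penetrances are genotype relative
risks relative to AA —

* additive: (1, OR, OR²)
* dominant: (1, OR, OR)
* recessive: (1, 1, OR)

— scaled by the baseline `f0 = K / Σ_g HWE(g)·m_g` so the HWE-weighted
mean penetrance equals K exactly. Relative-risk multipliers (rather than
odds multipliers) make power invariant to K to first order, matching the
near-identical results reported for prevalences of 1-10% in studies of
this design; at low prevalence the two parameterisations coincide. Case
and control genotype probabilities follow by Bayes' rule, and replicates
are drawn retrospectively as two multinomials with fixed margins (the
tests condition on the case/control totals). Note that under this
construction the realised case/control genotype odds ratio slightly
exceeds OR at K = 5%; OR is a penetrance ratio, not a sample odds ratio.

Default study conditions: 1000 cases / 1000 controls (2000/2000 for the
sample-size analysis), prevalence 5% (1% and 10% supported), MAF grid
0.1-0.4, OR grid 1.0-3.2 in steps of 0.2, significance thresholds 1E-5
and 1E-7, model-test threshold 0.01. Power and type-I error are the
proportion of replicates with p below threshold, with Monte-Carlo
standard error `sqrt(p(1−p)/R)`. Model retention runs the decision tree
on each significant replicate and reports outcome proportions among
them; it is skipped when association power is below 1% so the tally
never conditions on a handful of extreme replicates. Replicate counts
were set at 20,000 per power cell and 200,000 for null calibration at
the 5%/1% levels — Monte-Carlo SEs of ≤0.0035 and ≤0.0005 respectively,
small against the reproduction tolerances; calibration at a 1E-5
threshold would need ~1E8 replicates and is covered instead by
property-based checks at desk scale. One seeded generator drives each
simulation setting; grid point *i* of a run with seed *s* uses seed
*s + i*, so grids are reproducible row-by-row and a one-point grid
equals a direct `estimate_power` call.

### What the generator does and does not emulate

It emulates single-SNP retrospective case/control sampling under HWE
with a fully penetrance-parameterised effect. It does not model linkage
disequilibrium between markers, population stratification, genotyping
error, covariates, or deviation from HWE in the population — so passing
tests demonstrate the statistical properties of the tests under the
idealised design, not robustness to those real-data complications.
The synthetic VCF fixtures inherit the same limits (independent SNPs,
uniform random MAFs for null markers, optional missingness that is
missing-completely-at-random).

## Genome-scan pipeline

VCF input (biallelic SNPs, GT field) with a `sample_id / status`
phenotype table (1 = control, 2 = case). The effect allele is ALT by
default with a minor-allele re-orientation option; missing calls give
per-SNP complete-case counts (no imputation). QC applies sample filters
first — missingness > 3%, genome-wide heterozygosity outside 23-30% —
then SNP filters computed on retained samples only: call rate < 97%
(a configurable assumption), MAF < 5%, and an exact Hardy-Weinberg test
in controls at p < 5.7E-7. The HWE test enumerates the conditional
distribution of the heterozygote count given allele counts and sums
configurations no more probable than the observed one (no mid-p
adjustment). An optional two-control-group allele-frequency comparison
(off by default) supports designs with two control cohorts. Results are
ranked by the 2-df p-value with significant/suggestive tiers; a scan on
a counts TSV gives exactly the single-table library results.

## Known limitations

* Wald intervals and the normal-approximation CIs degrade in very sparse
  tables; separation is flagged rather than resolved (no Firth
  correction).
* The 2-df reference distribution is asymptotic; at cell expectations
  below ~5 the G-statistic's null calibration drifts, which the QC MAF
  filter largely prevents in scan mode but which simulations at MAF 0.1
  with small samples can expose.
* No covariate adjustment, stratification correction, LD-aware
  multiple-testing, or efficiency-robust (MERT/MAX-type) tests.
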