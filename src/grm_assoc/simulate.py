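"""Monte-Carlo power, type-I error and model-retention estimation.

Case/control genotype counts are simulated under additive, dominant or
recessive disease models parameterised by (risk-allele frequency, genotype
effect size, disease prevalence). The population is assumed in
Hardy-Weinberg equilibrium at the causal SNP; penetrances are genotype
relative risks relative to AA — (1, OR, OR^2) additive, (1, OR, OR)
dominant, (1, 1, OR) recessive — scaled so the HWE-weighted mean
penetrance equals the prevalence. On this construction power is invariant
to the prevalence to first order, matching the near-identical results such
studies report across prevalences of 1-10%; for a rare disease the
multipliers coincide with genotype odds ratios. Cases and controls are
drawn retrospectively as two multinomials with fixed margins, matching the
conditioning of the association tests.

All association tests are evaluated on every replicate with closed forms
where the fitted model is saturated (the 2-df tests and the
dominant/recessive trend tests) and one batched Newton-Raphson fit for the
additive coding, so a grid cell of 20,000 replicates runs in seconds.
Every test is tallied in its likelihood-ratio form (``grm``, ``cat_*``)
and in an alternate form (``grm_wald``; ``cat_*_score``, the classical
Cochran-Armitage statistic). The alternate forms are the ones that
reproduce published power tables computed by software reporting Wald or
score chi-squares; they are slightly conservative in the far tail when a
genotype column is sparse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import trend_score_statistics, wald_grm_statistics
from .counts import CODING_SCHEMES, GenotypeCounts
from .logistic import batch_fit, collapsed_loglik, null_loglik, saturated_loglik

MODELS = ("additive", "dominant", "recessive")
#: LR forms of the four tests, plus the score-form trend statistics and the
#: Wald-form 2-df statistic used when reproducing published power tables.
TESTS = (
    "cat_add", "cat_dom", "cat_rec", "grm",
    "cat_add_score", "cat_dom_score", "cat_rec_score", "grm_wald",
)
OUTCOMES = ("additive", "dominant", "recessive", "undetermined")

_X_ADDITIVE = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]])
#: Merged genotype classes over which the dominant / recessive single-slope
#: fits are saturated (their covariate takes only two distinct values).
_DOM_GROUPS = ((0,), (1, 2))
_REC_GROUPS = ((0, 1), (2,))

#: Retention estimates are skipped below this association power to avoid
#: conditioning on a handful of extreme replicates.
MIN_POWER_FOR_RETENTION = 0.01


@dataclass(frozen=True)
class DiseaseModel:
    """A single-SNP disease model: mode of inheritance, MAF, OR, prevalence.

    ``maf`` is the population frequency of the risk allele ``a`` (assumed
    minor, <= 0.5); ``odds_ratio`` is the per-step genotype effect size,
    applied as a relative risk on the penetrance scale (equal to the
    genotype odds ratio for a rare disease; odds_ratio = 1 is the null
    hypothesis of no association); ``prevalence`` is the population
    disease probability.
    """

    model: str
    maf: float
    odds_ratio: float
    prevalence: float

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        if self.odds_ratio < 1.0:
            raise ValueError("odds_ratio must be >= 1 (code the risk allele)")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")

    @property
    def hwe_frequencies(self) -> np.ndarray:
        """Genotype frequencies ((1-p)^2, 2p(1-p), p^2) for (AA, Aa, aa)."""
        p = self.maf
        return np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])

    @property
    def genotype_risk_multipliers(self) -> np.ndarray:
        """Penetrance multipliers relative to AA for (AA, Aa, aa)."""
        r = self.odds_ratio
        if self.model == "additive":
            return np.array([1.0, r, r**2])
        if self.model == "dominant":
            return np.array([1.0, r, r])
        return np.array([1.0, 1.0, r])


@dataclass(frozen=True)
class GenotypeDistribution:
    """Penetrances and the implied genotype distributions in cases/controls."""

    penetrances: np.ndarray
    case_probs: np.ndarray
    control_probs: np.ndarray


@dataclass(frozen=True)
class SimConfig:
    """One simulation setting: disease model, sample sizes, thresholds, seed."""

    disease: DiseaseModel
    n_cases: int = 1000
    n_controls: int = 1000
    n_replicates: int = 20_000
    significance_threshold: float = 1e-5
    model_test_threshold: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if min(self.n_cases, self.n_controls) < 1:
            raise ValueError("need at least one case and one control")
        for t in (self.significance_threshold, self.model_test_threshold):
            if not 0.0 < t < 1.0:
                raise ValueError("thresholds must lie strictly between 0 and 1")


@dataclass(frozen=True)
class PowerEstimate:
    """Per-test proportion of significant replicates with Monte-Carlo SEs."""

    power: dict[str, float]
    monte_carlo_se: dict[str, float]
    n_replicates: int
    n_nonconverged: int = 0


@dataclass(frozen=True)
class RetentionEstimate:
    """Decision-tree outcome proportions among significant replicates."""

    n_significant: int
    retained_proportions: dict[str, float]
    n_replicates: int
    skipped: bool = False
    skip_reason: str = ""


def solve_penetrances(disease: DiseaseModel) -> GenotypeDistribution:
    """Penetrances consistent with the model's effect sizes and prevalence.

    Penetrances are ``f_g = f0 * m_g`` with relative-risk multipliers
    ``m_g`` fixed by the mode of inheritance and the baseline ``f0``
    scaled so ``sum_g HWE(g) * f_g = prevalence`` exactly. Case and
    control genotype probabilities follow by Bayes' rule.
    """
    hwe = disease.hwe_frequencies
    mult = disease.genotype_risk_multipliers
    K = disease.prevalence

    f = mult * (K / float(hwe @ mult))
    if f[-1] >= 1.0:
        raise ValueError(
            "effect size and prevalence imply a penetrance >= 1; "
            "reduce odds_ratio or prevalence"
        )
    assert abs(hwe @ f - K) < 1e-10

    case_probs = f * hwe / K
    control_probs = (1.0 - f) * hwe / (1.0 - K)
    return GenotypeDistribution(f, case_probs / case_probs.sum(), control_probs / control_probs.sum())


def simulate_counts(
    dist: GenotypeDistribution, n_cases: int, n_controls: int, rng: np.random.Generator
) -> GenotypeCounts:
    """Draw one replicate: two multinomials with fixed case/control margins."""
    cases = rng.multinomial(n_cases, dist.case_probs)
    controls = rng.multinomial(n_controls, dist.control_probs)
    return GenotypeCounts(tuple(cases), tuple(controls))


def simulate_count_batches(
    dist: GenotypeDistribution,
    n_cases: int,
    n_controls: int,
    n_replicates: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (R, 3) case-count and control-count arrays for R replicates."""
    cases = rng.multinomial(n_cases, dist.case_probs, size=n_replicates)
    controls = rng.multinomial(n_controls, dist.control_probs, size=n_replicates)
    return cases, controls


@dataclass(frozen=True)
class ReplicateTests:
    """Vectorised test results over a batch of replicate tables.

    Log-likelihoods are kept so the decision tree can reuse the additive
    fit (identical to the additive trend fit) without re-optimising.
    """

    p_values: dict[str, np.ndarray]
    ll_saturated: np.ndarray
    ll_additive: np.ndarray
    ll_dominant: np.ndarray
    ll_recessive: np.ndarray
    n_nonconverged: int


def batch_association_tests(case_counts: np.ndarray, control_counts: np.ndarray) -> ReplicateTests:
    """All association tests on a stack of 2x3 tables.

    The 2-df statistics (both LR and Wald forms) and the
    dominant/recessive trend statistics are closed-form (the fitted models
    are saturated); only the additive coding needs iterative fitting, done
    in one batched Newton-Raphson pass.
    """
    y = np.asarray(case_counts, dtype=float)
    n = y + np.asarray(control_counts, dtype=float)

    ll_null = null_loglik(y, n)
    ll_sat = saturated_loglik(y, n)
    ll_dom = collapsed_loglik(y, n, _DOM_GROUPS)
    ll_rec = collapsed_loglik(y, n, _REC_GROUPS)
    _, ll_add, conv = batch_fit(y, n, _X_ADDITIVE)

    def lr_p(ll_alt: np.ndarray, df: int) -> np.ndarray:
        return stats.chi2.sf(np.maximum(2.0 * (ll_alt - ll_null), 0.0), df)

    def score_p(coding: str) -> np.ndarray:
        stat = trend_score_statistics(case_counts, control_counts, CODING_SCHEMES[coding])
        return stats.chi2.sf(stat, 1)

    p_values = {
        "cat_add": lr_p(ll_add, 1),
        "cat_dom": lr_p(ll_dom, 1),
        "cat_rec": lr_p(ll_rec, 1),
        "grm": lr_p(ll_sat, 2),
        "cat_add_score": score_p("additive"),
        "cat_dom_score": score_p("dominant"),
        "cat_rec_score": score_p("recessive"),
        "grm_wald": stats.chi2.sf(wald_grm_statistics(case_counts, control_counts), 2),
    }
    return ReplicateTests(p_values, ll_sat, ll_add, ll_dom, ll_rec, int((~conv).sum()))


def batch_model_decisions(tests: ReplicateTests, significant: np.ndarray, model_threshold: float) -> dict[str, int]:
    """Run the decision tree on the significant replicates of a batch.

    Returns outcome counts over additive / dominant / recessive /
    undetermined. The additive constraint is tested first (1-df LR of the
    additive submodel against the saturated two-term model); only when it
    is rejected are the dominant and recessive constraints examined.
    """

    def constraint_p(ll_constrained: np.ndarray) -> np.ndarray:
        stat = np.maximum(2.0 * (tests.ll_saturated - ll_constrained), 0.0)
        return stats.chi2.sf(stat[significant], 1)

    p_add = constraint_p(tests.ll_additive)
    p_dom = constraint_p(tests.ll_dominant)
    p_rec = constraint_p(tests.ll_recessive)

    add_kept = p_add >= model_threshold
    dom_kept = ~add_kept & (p_dom >= model_threshold)
    rec_kept = ~add_kept & (p_rec >= model_threshold)
    return {
        "additive": int(add_kept.sum()),
        "dominant": int((dom_kept & ~rec_kept).sum()),
        "recessive": int((rec_kept & ~dom_kept).sum()),
        "undetermined": int((~add_kept & ~(dom_kept ^ rec_kept)).sum()),
    }


def _run_replicates(config: SimConfig) -> ReplicateTests:
    rng = np.random.default_rng(config.seed)
    dist = solve_penetrances(config.disease)
    cases, controls = simulate_count_batches(
        dist, config.n_cases, config.n_controls, config.n_replicates, rng
    )
    return batch_association_tests(cases, controls)


def _power_from_tests(tests: ReplicateTests, threshold: float, n: int) -> PowerEstimate:
    power, se = {}, {}
    for name in TESTS:
        p = float((tests.p_values[name] < threshold).mean())
        power[name] = p
        se[name] = float(np.sqrt(p * (1.0 - p) / n))
    return PowerEstimate(power, se, n, tests.n_nonconverged)


def estimate_power(config: SimConfig) -> PowerEstimate:
    """Empirical power (or type-I error when OR = 1) for all four tests.

    The estimate is the proportion of replicates with p below
    ``config.significance_threshold``; Monte-Carlo standard errors are
    sqrt(p(1-p)/R). Deterministic given ``config.seed``.
    """
    tests = _run_replicates(config)
    return _power_from_tests(tests, config.significance_threshold, config.n_replicates)


def estimate_model_retention(config: SimConfig) -> tuple[PowerEstimate, RetentionEstimate]:
    """Power plus decision-tree outcome proportions among significant replicates.

    Retention is skipped (flagged empty) when the 2-df test's power is
    below 1%, so the tally never conditions on a handful of extreme
    replicates; it is likewise flagged when no replicate is significant.
    """
    tests = _run_replicates(config)
    power = _power_from_tests(tests, config.significance_threshold, config.n_replicates)

    empty = {k: float("nan") for k in OUTCOMES}
    if power.power["grm"] < MIN_POWER_FOR_RETENTION:
        retention = RetentionEstimate(
            0, empty, config.n_replicates, skipped=True,
            skip_reason="association power below 1%",
        )
        return power, retention

    significant = tests.p_values["grm"] < config.significance_threshold
    n_sig = int(significant.sum())
    if n_sig == 0:
        retention = RetentionEstimate(
            0, empty, config.n_replicates, skipped=True,
            skip_reason="no significant replicates",
        )
        return power, retention

    outcome_counts = batch_model_decisions(tests, significant, config.model_test_threshold)
    proportions = {k: v / n_sig for k, v in outcome_counts.items()}
    return power, RetentionEstimate(n_sig, proportions, config.n_replicates)


GRID_COLUMNS = [
    "model", "maf", "odds_ratio", "prevalence", "n_cases", "n_controls",
    "threshold", "n_replicates",
    "power_cat_add", "power_cat_dom", "power_cat_rec", "power_grm",
    "power_cat_add_score", "power_cat_dom_score", "power_cat_rec_score",
    "power_grm_wald", "se_grm", "n_nonconverged",
    "n_significant", "retained_additive", "retained_dominant",
    "retained_recessive", "retained_undetermined", "retention_skipped",
]


def run_grid(
    diseases: Sequence[DiseaseModel],
    sample_sizes: Sequence[tuple[int, int]] = ((1000, 1000),),
    thresholds: Sequence[float] = (1e-5,),
    n_replicates: int = 20_000,
    seed: int = 0,
    model_test_threshold: float = 0.01,
    retention: bool = True,
    out_tsv: Optional[str] = None,
    log: Optional[callable] = None,
) -> pd.DataFrame:
    """Estimate power (and optionally retention) over a simulation grid.

    One row per (disease, sample size, threshold) combination, in grid
    order; grid point i uses seed ``seed + i`` so runs are deterministic
    per (seed, grid order) and a one-point grid reproduces a direct
    ``estimate_power`` call with the same seed. A failed grid point is
    recorded as a row of NaNs and the run continues.
    """
    rows = []
    point = 0
    for disease in diseases:
        for n_cases, n_controls in sample_sizes:
            for threshold in thresholds:
                config = SimConfig(
                    disease, n_cases, n_controls, n_replicates,
                    threshold, model_test_threshold, seed + point,
                )
                point += 1
                base = {
                    "model": disease.model, "maf": disease.maf,
                    "odds_ratio": disease.odds_ratio,
                    "prevalence": disease.prevalence,
                    "n_cases": n_cases, "n_controls": n_controls,
                    "threshold": threshold, "n_replicates": n_replicates,
                }
                try:
                    if retention:
                        power, ret = estimate_model_retention(config)
                    else:
                        power, ret = estimate_power(config), None
                except Exception as exc:  # pragma: no cover - defensive
                    if log:
                        log(f"grid point {base} failed: {exc}")
                    rows.append(base)
                    continue
                base.update({f"power_{t}": power.power[t] for t in TESTS})
                base["se_grm"] = power.monte_carlo_se["grm"]
                base["n_nonconverged"] = power.n_nonconverged
                if ret is not None:
                    base["n_significant"] = ret.n_significant
                    base.update({f"retained_{k}": ret.retained_proportions[k] for k in OUTCOMES})
                    base["retention_skipped"] = ret.skipped
                if log:
                    log(
                        f"{disease.model} maf={disease.maf} or={disease.odds_ratio} "
                        f"n={n_cases}/{n_controls} thr={threshold:g}: "
                        f"grm={power.power['grm']:.3f} (se {power.monte_carlo_se['grm']:.4f}), "
                        f"cat_add={power.power['cat_add']:.3f}, "
                        f"nonconverged={power.n_nonconverged}"
                    )
                rows.append(base)
    df = pd.DataFrame(rows).reindex(columns=GRID_COLUMNS)
    if out_tsv is not None:
        df.to_csv(out_tsv, sep="\t", index=False)
    return df
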