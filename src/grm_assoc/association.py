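"""Association tests and genetic-model selection on a single 2x3 table.

Four likelihood-ratio association tests are provided:

* three Cochran-Armitage-style trend (CAT) tests, each a single-slope
  logistic model with genotype codes chosen for an assumed mode of
  inheritance — additive (0,1,2), dominant (0,1,1), recessive (0,0,1) —
  tested with 1 df;
* the general regression model (GRM) test, a two-term logistic model
  with an additive code (0,1,2) plus a dominance-deviation code (0,1,0),
  tested jointly with 2 df. The two-term model is saturated over the three
  genotype classes, so its LR statistic equals the 2x3 G-statistic.

Each test is offered in two asymptotically equivalent forms. The trend
tests default to the likelihood-ratio statistic and also provide the
classical score-form Cochran-Armitage statistic. The 2-df test defaults to
the likelihood-ratio statistic (identical to the 2x3 G-statistic) and also
provides the Wald statistic of the two slope coefficients, which is
noticeably conservative when one homozygote column is sparse and the
dominance coefficient is large (the Hauck-Donner effect). The alternate
forms matter when comparing against power tables produced by software that
reports score or Wald chi-squares.

When the GRM test is significant, a decision tree infers the underlying
genetic model by testing the constraints beta_domdev = 0 (additive),
beta_domdev = beta_add (dominant) and beta_domdev = -beta_add (recessive),
each as a 1-df LR test of the constrained submodel against the full model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .counts import CodingScheme, GenotypeCounts
from .logistic import (
    LogisticFit,
    fit_grouped_logistic,
    intercept_only_fit,
    null_loglik,
    saturated_loglik,
)

CAT_MODELS = ("additive", "dominant", "recessive")

#: Recoded single covariate implied by each constraint on the two-term
#: model: beta_domdev = 0 leaves (0,1,2); beta_domdev = beta_add gives
#: Add + DomDev = (0,2,2); beta_domdev = -beta_add gives Add - DomDev =
#: (0,0,2).
CONSTRAINT_CODES = {
    "additive": (0.0, 1.0, 2.0),
    "dominant": (0.0, 2.0, 2.0),
    "recessive": (0.0, 0.0, 2.0),
}


@dataclass(frozen=True)
class TestResult:
    """A likelihood-ratio chi-square test."""

    statistic: float
    df: int
    p_value: float
    converged: bool = True

    @classmethod
    def from_loglik(cls, ll_full: float, ll_null: float, df: int, converged: bool = True) -> "TestResult":
        # tiny negative differences are roundoff from the closed forms
        stat = max(2.0 * (ll_full - ll_null), 0.0)
        return cls(stat, df, float(stats.chi2.sf(stat, df)), converged)


@dataclass(frozen=True)
class ModelDecision:
    """Outcome of the genetic-model decision tree.

    ``outcome`` is ``not_significant`` when the 2-df association test does
    not reach ``assoc_threshold``; otherwise ``additive``, ``dominant``,
    ``recessive``, or ``undetermined`` when the dominant and recessive
    constraint tests are both retained or both rejected.
    """

    outcome: str
    assoc_test: TestResult
    additive_test: Optional[TestResult] = None
    dominant_test: Optional[TestResult] = None
    recessive_test: Optional[TestResult] = None


@dataclass(frozen=True)
class EffectEstimate:
    """Coefficients of the two-term model with Wald intervals.

    All coefficients are on the log-odds scale; ``homozygote_or`` is the
    aa-vs-AA odds ratio exp(2*beta_add) with its interval from the
    coefficient covariance.
    """

    beta_add: float
    beta_domdev: float
    ci_add: tuple[float, float]
    ci_domdev: tuple[float, float]
    homozygote_or: float
    ci_homozygote_or: tuple[float, float]
    ci_level: float
    converged: bool


def trend_score_statistics(
    case_counts: np.ndarray, control_counts: np.ndarray, codes
) -> np.ndarray:
    """Vectorised classical Cochran-Armitage trend statistic on 2x3 tables.

    The score form of the single-slope logistic test: with genotype codes
    ``x``, case counts ``y``, totals ``n``, R cases and N samples overall,
    ``Z^2 = N (N sum(x y) - R sum(x n))^2 /
    (R (N - R) (N sum(x^2 n) - sum(x n)^2))``. Degenerate tables (constant
    covariate among observed classes) get statistic 0.
    """
    y = np.atleast_2d(np.asarray(case_counts, dtype=float))
    c = np.atleast_2d(np.asarray(control_counts, dtype=float))
    n = y + c
    x = np.asarray(codes, dtype=float)
    R, N = y.sum(axis=1), n.sum(axis=1)
    sxy = y @ x
    sxn = n @ x
    sx2n = n @ x**2
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = N * (N * sxy - R * sxn) ** 2 / (R * (N - R) * (N * sx2n - sxn**2))
    return np.where(np.isfinite(stat), stat, 0.0)


def cat_test(counts: GenotypeCounts, model: str, statistic: str = "lr") -> TestResult:
    """Cochran-Armitage-style trend test with 1 df.

    With ``statistic="lr"`` (default), the likelihood-ratio form
    2*(LL(alpha, beta) - LL(alpha)) of the single-slope logistic model with
    the genotype codes of ``model``; with ``statistic="score"``, the
    classical Cochran-Armitage score statistic. The two agree
    asymptotically; the score form is slightly conservative in the far tail
    when the non-zero-coded classes are sparse.
    """
    if model not in CAT_MODELS:
        raise ValueError(f"model must be one of {CAT_MODELS}, got {model!r}")
    if statistic == "lr":
        fit = fit_grouped_logistic(counts, model)
        y, n = counts.as_arrays()
        return TestResult.from_loglik(fit.log_likelihood, float(null_loglik(y, n)), 1, fit.converged)
    if statistic == "score":
        codes = CodingScheme.from_name(model).codes
        cases = np.asarray(counts.case_counts, dtype=float)
        controls = np.asarray(counts.control_counts, dtype=float)
        stat = float(trend_score_statistics(cases[None, :], controls[None, :], codes)[0])
        return TestResult(stat, 1, float(stats.chi2.sf(stat, 1)))
    raise ValueError("statistic must be 'lr' or 'score'")


def wald_grm_statistics(case_counts: np.ndarray, control_counts: np.ndarray) -> np.ndarray:
    """Vectorised 2-df Wald statistic of the two-term model on 2x3 tables.

    The two-term model is saturated, so the slope MLEs are contrasts of
    per-genotype empirical logits and their covariance is the delta-method
    transform of ``1/cases + 1/controls`` per genotype. A table with an
    empty cell has an infinite logit or variance; its statistic is returned
    as 0 (an infinite-variance Wald test carries no evidence), mirroring
    the non-rejection such tables produce in Wald-based software.
    """
    y = np.atleast_2d(np.asarray(case_counts, dtype=float))
    c = np.atleast_2d(np.asarray(control_counts, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        logit = np.log(y) - np.log(c)
        v = 1.0 / y + 1.0 / c
        b_add = (logit[:, 2] - logit[:, 0]) / 2.0
        b_dom = logit[:, 1] - (logit[:, 0] + logit[:, 2]) / 2.0
        c11 = (v[:, 0] + v[:, 2]) / 4.0
        c22 = v[:, 0] / 4.0 + v[:, 1] + v[:, 2] / 4.0
        c12 = (v[:, 0] - v[:, 2]) / 4.0
        det = c11 * c22 - c12**2
        stat = (b_add**2 * c22 - 2.0 * b_add * b_dom * c12 + b_dom**2 * c11) / det
    return np.where(np.isfinite(stat), stat, 0.0)


def grm_test(counts: GenotypeCounts, statistic: str = "lr") -> TestResult:
    """2-df test of the two-term (additive + dominance-deviation) model.

    With ``statistic="lr"`` (default), the likelihood-ratio statistic:
    because the two-term model is saturated over the three genotype
    classes, it equals the G-statistic 2*sum O*ln(O/E) of the 2x3 table and
    the closed form is used directly. With ``statistic="wald"``, the Wald
    statistic of the two slope coefficients, which agrees asymptotically
    but is conservative on tables with a sparse homozygote column. The
    reference distribution is chi-square with 2 df by convention even when
    a genotype class is empty.
    """
    y, n = counts.as_arrays()
    if statistic == "lr":
        return TestResult.from_loglik(float(saturated_loglik(y, n)), float(null_loglik(y, n)), 2)
    if statistic == "wald":
        cases = np.asarray(counts.case_counts, dtype=float)
        controls = np.asarray(counts.control_counts, dtype=float)
        stat = float(wald_grm_statistics(cases[None, :], controls[None, :])[0])
        well_defined = bool(np.all(cases > 0) and np.all(controls > 0))
        return TestResult(stat, 2, float(stats.chi2.sf(stat, 2)), well_defined)
    raise ValueError("statistic must be 'lr' or 'wald'")


def constrained_fit(counts: GenotypeCounts, constraint: str) -> LogisticFit:
    """Fit of the two-term model under a genetic-model constraint.

    The constraint reduces the model to a single slope on a recoded
    covariate (additive (0,1,2); dominant (0,2,2); recessive (0,0,2)).
    Because rescaling a covariate leaves the maximised likelihood
    unchanged, the dominant/recessive constrained log-likelihoods equal
    those of the corresponding trend-test fits.
    """
    if constraint not in CONSTRAINT_CODES:
        raise ValueError(f"constraint must be one of {sorted(CONSTRAINT_CODES)}")
    coding = CodingScheme(f"constrained_{constraint}", CONSTRAINT_CODES[constraint])
    return fit_grouped_logistic(counts, coding)


def model_selection(
    counts: GenotypeCounts,
    assoc_threshold: float = 1e-5,
    model_threshold: float = 0.01,
) -> ModelDecision:
    """Infer the underlying genetic model via the GRM decision tree.

    The genetic model is only examined when the 2-df association test is
    significant at ``assoc_threshold``. The additive constraint
    (beta_domdev = 0) is tested first at ``model_threshold``; if it is not
    rejected the additive model is retained. Otherwise the dominant and
    recessive constraints are each tested against the full model: if
    exactly one is retained that model is selected, and if both or neither
    survive the outcome is ``undetermined`` with all p-values exposed.
    """
    if not (0.0 < assoc_threshold < 1.0 and 0.0 < model_threshold < 1.0):
        raise ValueError("thresholds must lie strictly between 0 and 1")

    assoc = grm_test(counts)
    if assoc.p_value >= assoc_threshold:
        return ModelDecision("not_significant", assoc)

    ll_full = float(saturated_loglik(*counts.as_arrays()))
    add_fit = constrained_fit(counts, "additive")
    add_test = TestResult.from_loglik(ll_full, add_fit.log_likelihood, 1, add_fit.converged)
    if add_test.p_value >= model_threshold:
        return ModelDecision("additive", assoc, add_test)

    dom_fit = constrained_fit(counts, "dominant")
    rec_fit = constrained_fit(counts, "recessive")
    dom_test = TestResult.from_loglik(ll_full, dom_fit.log_likelihood, 1, dom_fit.converged)
    rec_test = TestResult.from_loglik(ll_full, rec_fit.log_likelihood, 1, rec_fit.converged)

    dom_kept = dom_test.p_value >= model_threshold
    rec_kept = rec_test.p_value >= model_threshold
    if dom_kept and not rec_kept:
        outcome = "dominant"
    elif rec_kept and not dom_kept:
        outcome = "recessive"
    else:
        outcome = "undetermined"
    return ModelDecision(outcome, assoc, add_test, dom_test, rec_test)


def effect_estimates(counts: GenotypeCounts, ci_level: float = 0.95) -> EffectEstimate:
    """Point estimates and Wald intervals from the two-term model fit.

    Returns beta_add and beta_domdev with confidence intervals at
    ``ci_level``, plus the homozygote (aa vs AA) odds-ratio contrast
    exp(2*beta_add) with an interval from the coefficient covariance.
    Intervals are suppressed (NaN) when the fit did not converge.
    """
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must lie strictly between 0 and 1")
    fit = fit_grouped_logistic(counts, ["additive", "domdev"])
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    _, b_add, b_dom = fit.coefficients

    if fit.converged and np.all(np.isfinite(fit.standard_errors)):
        se_add, se_dom = fit.standard_errors[1], fit.standard_errors[2]
        ci_add = (b_add - z * se_add, b_add + z * se_add)
        ci_dom = (b_dom - z * se_dom, b_dom + z * se_dom)
        # aa vs AA contrast is 2*beta_add (domdev code is 0 at both homozygotes)
        var_hom = 4.0 * fit.covariance[1, 1]
        se_hom = np.sqrt(var_hom)
        with np.errstate(over="ignore"):  # an unbounded upper limit is inf
            ci_hom = (np.exp(2 * b_add - z * se_hom), np.exp(2 * b_add + z * se_hom))
        return EffectEstimate(
            float(b_add), float(b_dom), ci_add, ci_dom,
            float(np.exp(2 * b_add)), ci_hom, ci_level, True,
        )
    nan_pair = (np.nan, np.nan)
    return EffectEstimate(
        float(b_add), float(b_dom), nan_pair, nan_pair,
        float(np.exp(2 * b_add)), nan_pair, ci_level, False,
    )
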