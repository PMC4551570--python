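"""Hypothesis tests and the interchangeability decision.

Disagreement between two measurement methods can come from three
sources, each tested separately against the full unstructured fit:

* bias — a fixed-effect contrast on the method means (t test);
* between-subject variability — LRT of the CS-constrained D
  (equal between-subject variances) against unstructured D, 1 df;
* within-subject variability (repeatability) — LRT of CS-constrained
  Sigma against unstructured Sigma, 1 df;
* overall variability — LRT constraining both blocks, 2 df.

The constrained (equal-variability) model is the null; minus twice the
log likelihood-ratio is referred to a chi-square with df equal to the
difference in covariance-parameter counts.  The equality constraints
are interior points of the parameter space (variances stay positive
under CS), so no boundary-corrected mixture null is needed.

The decision rule: the methods are interchangeable when the bias is
below a pre-specified threshold and non-significant, and neither the
between- nor the within-subject variabilities differ significantly.
Otherwise the preferred method is the one with the smaller
within-subject variance (the better repeatability).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import MeasurementTable
from .model import (
    MethodComparisonModel,
    MethodComparisonResults,
    ModelSpec,
    _numeric_gradient,
    cov_param_count,
)

logger = logging.getLogger(__name__)

#: the four covariance structures fitted in a full agreement analysis
FULL = ModelSpec("UN", "UN")
EQ_BETWEEN = ModelSpec("CS", "UN")
EQ_WITHIN = ModelSpec("UN", "CS")
EQ_BOTH = ModelSpec("CS", "CS")

_STAT_CLAMP_TOL = 1e-4


def chi2_upper_tail(stat: float, df: int) -> float:
    """Upper tail (survival function) of chi-square(df) at ``stat``."""
    if df < 1 or int(df) != df:
        raise ValueError(f"df must be a positive integer, got {df}")
    if stat < 0:
        raise ValueError(f"statistic must be >= 0, got {stat}")
    return float(stats.chi2.sf(stat, df))


@dataclass(frozen=True)
class LrtResult:
    """Likelihood-ratio test of a constrained covariance structure."""

    stat: float
    df: int
    p_value: float
    deviance_full: float | None = None
    deviance_reduced: float | None = None
    spec_full: ModelSpec | None = None
    spec_reduced: ModelSpec | None = None


def lrt_from_deviances(
    deviance_reduced: float,
    deviance_full: float,
    df: int,
    spec_full: ModelSpec | None = None,
    spec_reduced: ModelSpec | None = None,
) -> LrtResult:
    """LRT from two maximized -2 log-likelihoods of nested models."""
    stat = deviance_reduced - deviance_full
    if stat < -_STAT_CLAMP_TOL:
        raise ValueError(
            f"reduced-model deviance {deviance_reduced:.6g} is below the "
            f"full-model deviance {deviance_full:.6g} by more than the "
            f"optimizer tolerance; refit before testing"
        )
    if stat < 0:
        logger.warning("negative LRT statistic %.3g clamped to 0", stat)
        stat = 0.0
    return LrtResult(
        stat=float(stat),
        df=int(df),
        p_value=chi2_upper_tail(stat, df),
        deviance_full=float(deviance_full),
        deviance_reduced=float(deviance_reduced),
        spec_full=spec_full,
        spec_reduced=spec_reduced,
    )


def lrt(
    fit_full: MethodComparisonResults, fit_reduced: MethodComparisonResults
) -> LrtResult:
    """LRT of ``fit_reduced`` (constrained null) against ``fit_full``."""
    if not fit_reduced.spec.is_nested_in(fit_full.spec):
        raise ValueError(
            f"spec {fit_reduced.spec} is not nested in {fit_full.spec}"
        )
    if fit_full.spec == fit_reduced.spec:
        raise ValueError("specs are identical; nothing to test")
    for f in (fit_full, fit_reduced):
        if not f.converged:
            raise ValueError(f"fit for spec {f.spec} did not converge")
    df = cov_param_count(fit_full.spec) - cov_param_count(fit_reduced.spec)
    return lrt_from_deviances(
        fit_reduced.minus2loglik,
        fit_full.minus2loglik,
        df,
        spec_full=fit_full.spec,
        spec_reduced=fit_reduced.spec,
    )


@dataclass(frozen=True)
class BiasResult:
    """Fixed-effect contrast mu_1 - mu_2 (reference minus new method)."""

    estimate: float
    se: float
    df: float
    t_stat: float
    p_value: float
    df_method: str = "satterthwaite"


def _satterthwaite_df(fit: MethodComparisonResults, contrast: np.ndarray) -> float:
    """Satterthwaite approximation for the contrast's denominator df.

    df = 2 g^2 / (grad g' A grad g) with g(theta) the contrast variance
    c' (sum X' Omega^-1 X)^-1 c and A the asymptotic covariance of the
    covariance parameters.
    """
    model, spec = fit.model, fit.spec

    def g(theta):
        D, S = model._theta_blocks(theta, spec)
        _, _, fixed_cov = model._deviance_blocks(D, S)
        if fixed_cov is None:
            return np.nan
        return float(contrast @ fixed_cov @ contrast)

    g0 = g(fit.theta)
    grad = _numeric_gradient(g, fit.theta)
    A = fit.cov_theta()
    denom = float(grad @ A @ grad)
    if denom <= 0 or not np.isfinite(denom):
        return float(fit.n_subjects - 1)
    df = 2.0 * g0**2 / denom
    # clip to a sane range: at least 1, at most the residual df
    return float(np.clip(df, 1.0, max(fit.n_obs_total - 2, 1)))


def bias_test(
    fit: MethodComparisonResults,
    df_method: str = "satterthwaite",
    force: bool = False,
) -> BiasResult:
    """Two-sided t test of the method-mean difference mu_1 - mu_2."""
    if not fit.converged and not force:
        raise ValueError("fit did not converge; pass force=True to test anyway")
    c = np.array([1.0, -1.0])
    estimate = float(c @ fit.mu)
    var = float(c @ fit.fixed_cov @ c)
    if var <= 0:
        raise ValueError("degenerate data: zero variance for the bias contrast")
    se = math.sqrt(var)
    if df_method == "satterthwaite":
        df = _satterthwaite_df(fit, c)
    elif df_method == "residual":
        df = float(fit.n_obs_total - 2)
    elif df_method == "subjects":
        df = float(fit.n_subjects - 1)
    else:
        raise ValueError(f"unknown df_method {df_method!r}")
    t_stat = estimate / se
    p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    return BiasResult(
        estimate=estimate, se=se, df=df, t_stat=t_stat, p_value=p,
        df_method=df_method,
    )


def _fit_pair(table: MeasurementTable, spec_reduced: ModelSpec, **fit_kw):
    model = MethodComparisonModel(table)
    full = model.fit(FULL, **fit_kw)
    reduced = model.fit(spec_reduced, **fit_kw)
    return lrt(full, reduced)


def test_between(table: MeasurementTable, **fit_kw) -> LrtResult:
    """LRT of equal between-subject variances: (CS,UN) vs (UN,UN), 1 df."""
    return _fit_pair(table, EQ_BETWEEN, **fit_kw)


def test_within(table: MeasurementTable, **fit_kw) -> LrtResult:
    """LRT of equal within-subject variances: (UN,CS) vs (UN,UN), 1 df."""
    return _fit_pair(table, EQ_WITHIN, **fit_kw)


def test_overall(table: MeasurementTable, **fit_kw) -> LrtResult:
    """LRT of equal overall variabilities: (CS,CS) vs (UN,UN), 2 df."""
    return _fit_pair(table, EQ_BOTH, **fit_kw)


def overall_correlation(fit: MethodComparisonResults) -> float:
    """Overall between-method correlation from the (UN,UN) fit:
    (d12 + s12) / sqrt((d11 + s11)(d22 + s22))."""
    omega = fit.omega
    v1, v2 = omega[0, 0], omega[1, 1]
    if v1 <= 0 or v2 <= 0:
        logger.warning("zero overall variance; correlation undefined")
        return float("nan")
    return float(omega[0, 1] / math.sqrt(v1 * v2))


def bonferroni(p: float, n_comparisons: int = 3) -> float:
    """Bonferroni-adjusted p-value (e.g. across the three spatial axes)."""
    return min(1.0, float(p) * n_comparisons)


@dataclass
class AgreementReport:
    """Per-analysis bundle: bias, the three LRTs, variance components,
    and the overall correlation.  ``fits`` carries the four underlying
    fits when the report was produced by :func:`agreement_analysis`;
    a report rebuilt from stored numbers leaves it None."""

    bias: BiasResult
    between_test: LrtResult
    within_test: LrtResult
    overall_test: LrtResult
    between_vars: tuple[float, float]
    within_vars: tuple[float, float]
    overall_vars: tuple[float, float]
    overall_correlation: float
    fits: dict | None = field(default=None, repr=False)
    failures: list[str] = field(default_factory=list)

    def decide(self, bias_threshold: float = 0.1, alpha: float = 0.05) -> "Verdict":
        return decide_interchangeability(self, bias_threshold, alpha)


def agreement_analysis(
    table: MeasurementTable,
    df_method: str = "satterthwaite",
    n_starts: int = 5,
    seed: int = 0,
) -> AgreementReport:
    """Fit the four covariance structures once and assemble the report.

    Deterministic given ``seed`` (multistart jitter only).  A fit that
    fails to converge is recorded in ``report.failures`` and downstream
    quantities are computed from it under protest rather than dropped.
    """
    model = MethodComparisonModel(table)
    fit_kw = dict(n_starts=n_starts, seed=seed)
    fits = {spec: model.fit(spec, **fit_kw)
            for spec in (FULL, EQ_BETWEEN, EQ_WITHIN, EQ_BOTH)}
    failures = [str(s) for s, f in fits.items() if not f.converged]

    full = fits[FULL]

    def safe_lrt(reduced_spec):
        try:
            return lrt(full, fits[reduced_spec])
        except ValueError:
            # non-convergence: report the clamped statistic anyway
            df = cov_param_count(FULL) - cov_param_count(reduced_spec)
            return lrt_from_deviances(
                max(fits[reduced_spec].minus2loglik, full.minus2loglik),
                full.minus2loglik, df,
                spec_full=FULL, spec_reduced=reduced_spec,
            )

    report = AgreementReport(
        bias=bias_test(full, df_method=df_method, force=True),
        between_test=safe_lrt(EQ_BETWEEN),
        within_test=safe_lrt(EQ_WITHIN),
        overall_test=safe_lrt(EQ_BOTH),
        between_vars=(float(full.D_hat[0, 0]), float(full.D_hat[1, 1])),
        within_vars=(float(full.Sigma_hat[0, 0]), float(full.Sigma_hat[1, 1])),
        overall_vars=(
            float(full.D_hat[0, 0] + full.Sigma_hat[0, 0]),
            float(full.D_hat[1, 1] + full.Sigma_hat[1, 1]),
        ),
        overall_correlation=overall_correlation(full),
        fits={str(s): f for s, f in fits.items()},
        failures=failures,
    )
    return report


@dataclass(frozen=True)
class Verdict:
    """Outcome of the interchangeability decision flow."""

    interchangeable: bool
    failed_criteria: tuple[str, ...]
    preferred_method: int | None
    rationale: str


def decide_interchangeability(
    report: AgreementReport,
    bias_threshold: float = 0.1,
    alpha: float = 0.05,
) -> Verdict:
    """Apply the interchangeability criteria to a complete report.

    Interchangeable iff |bias| < bias_threshold AND bias p >= alpha AND
    between-subject p >= alpha AND within-subject p >= alpha.  When any
    criterion fails, the preferred method is the one with the smaller
    within-subject variance (better repeatability); ties go to the
    smaller overall variance, then to the reference method.
    """
    failed = []
    if abs(report.bias.estimate) >= bias_threshold:
        failed.append("bias_threshold")
    if report.bias.p_value < alpha:
        failed.append("bias_significance")
    if report.between_test.p_value < alpha:
        failed.append("between")
    if report.within_test.p_value < alpha:
        failed.append("within")

    if not failed:
        return Verdict(
            interchangeable=True,
            failed_criteria=(),
            preferred_method=None,
            rationale=(
                f"|bias| = {abs(report.bias.estimate):.4g} < {bias_threshold:g}, "
                f"and no test significant at alpha = {alpha:g}: "
                "the two methods are interchangeable."
            ),
        )

    w1, w2 = report.within_vars
    if w1 < w2:
        preferred = 1
    elif w2 < w1:
        preferred = 2
    else:
        o1, o2 = report.overall_vars
        preferred = 1 if o1 <= o2 else 2
    reasons = ", ".join(failed)
    rationale = (
        f"failed criteria: {reasons}; method {preferred} has the smaller "
        f"within-subject variance ({min(w1, w2):.4g} vs {max(w1, w2):.4g}) "
        "and is preferred."
    )
    return Verdict(
        interchangeable=False,
        failed_criteria=tuple(failed),
        preferred_method=preferred,
        rationale=rationale,
    )
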