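"""Synthetic replicated two-method datasets from the generative model.

Draws follow exactly the distributional structure the estimator
assumes: per subject a method-level random effect b_i ~ N2(0, D), per
session an error e_it ~ N2(0, Sigma), response y_it = mu + b_i + e_it.
Missingness, when requested, is applied independently per cell (MCAR)
— the only mechanism compatible with the marginal-likelihood treatment
of unequal replicate counts.  Used for fixtures, parameter-recovery
checks, and test-calibration (type-I error / power) studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import MeasurementTable, MeasurementTableError

logger = logging.getLogger(__name__)

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class SimulationConfig:
    """Generative (mu, D, Sigma) triple plus study-design knobs.

    ``replicates`` is either a fixed per-subject session count p or an
    inclusive (p_min, p_max) range sampled uniformly per subject.
    ``missing`` is a per-method probability in [0, 0.5] that a
    session's cell is unobserved (scalar applies to both methods).
    """

    n_subjects: int = 100
    replicates: int | tuple[int, int] = 3
    mu: tuple[float, float] = (0.0, 0.0)
    D_true: np.ndarray = field(
        default_factory=lambda: np.array([[0.05, 0.02], [0.02, 0.05]])
    )
    Sigma_true: np.ndarray = field(
        default_factory=lambda: np.array([[0.15, 0.05], [0.05, 0.15]])
    )
    missing: float | tuple[float, float] = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        D = np.asarray(self.D_true, dtype=float)
        S = np.asarray(self.Sigma_true, dtype=float)
        for name, M in (("D_true", D), ("Sigma_true", S)):
            if M.shape != (2, 2) or not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric 2x2")
        if np.linalg.eigvalsh(D)[0] < -1e-12:
            raise ValueError("D_true must be positive semidefinite")
        if np.linalg.eigvalsh(S)[0] <= 0:
            raise ValueError("Sigma_true must be positive definite")
        object.__setattr__(self, "D_true", D)
        object.__setattr__(self, "Sigma_true", S)
        m = self.missing
        pair = (m, m) if np.isscalar(m) else tuple(m)
        if not all(0.0 <= q <= 0.5 for q in pair):
            raise ValueError("missing probabilities must lie in [0, 0.5]")
        object.__setattr__(self, "missing", pair)


def _draw_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    D, S = config.D_true, config.Sigma_true
    mu = np.asarray(config.mu, dtype=float)
    rows = []
    for i in range(config.n_subjects):
        if np.isscalar(config.replicates):
            p = int(config.replicates)
        else:
            lo, hi = config.replicates
            p = int(rng.integers(lo, hi + 1))
        b = rng.multivariate_normal(np.zeros(2), D)
        for t in range(1, p + 1):
            e = rng.multivariate_normal(np.zeros(2), S)
            y = mu + b + e
            for m in (1, 2):
                if rng.random() >= config.missing[m - 1]:
                    rows.append((f"S{i + 1:04d}", m, t, y[m - 1]))
    return pd.DataFrame(rows, columns=["subject", "method", "replicate", "value"])


def simulate(config: SimulationConfig) -> MeasurementTable:
    """Draw one dataset; deterministic given ``config.seed``.

    Degenerate draws (e.g. missingness leaving no replicated subject or
    a method unobserved) are re-drawn, up to a bounded retry count.
    """
    rng = np.random.default_rng(config.seed)
    last_err = None
    for _ in range(_MAX_REDRAWS):
        df = _draw_table(config, rng)
        try:
            return MeasurementTable(df)
        except MeasurementTableError as e:
            last_err = e
    raise MeasurementTableError(
        f"could not draw a valid table in {_MAX_REDRAWS} attempts: {last_err}"
    )


def calibration_suite(
    config: SimulationConfig,
    n_reps: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    ci_level: float = 0.99,
    df_method: str = "subjects",
) -> dict:
    """Empirical rejection rates of the four tests over repeated draws.

    Runs the full agreement analysis on ``n_reps`` independent datasets
    drawn under ``config`` and tallies rejections at level ``alpha``,
    with exact (Clopper-Pearson) binomial confidence intervals.  Fit
    failures are counted and reported, never silently dropped.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if n_reps < 100:
        logger.warning("n_reps=%d is small; rates will be noisy", n_reps)
    from .inference import agreement_analysis

    child_seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    rejections = {"bias": 0, "between": 0, "within": 0, "overall": 0}
    n_failures = 0
    n_ok = 0
    for k in range(n_reps):
        cfg = SimulationConfig(
            n_subjects=config.n_subjects,
            replicates=config.replicates,
            mu=config.mu,
            D_true=config.D_true,
            Sigma_true=config.Sigma_true,
            missing=config.missing,
            seed=int(child_seeds[k]),
        )
        try:
            report = agreement_analysis(
                simulate(cfg), df_method=df_method, seed=int(child_seeds[k])
            )
        except Exception as e:  # noqa: BLE001 - tallied, not swallowed
            logger.warning("replicate %d failed: %s", k, e)
            n_failures += 1
            continue
        if report.failures:
            n_failures += 1
        n_ok += 1
        rejections["bias"] += report.bias.p_value < alpha
        rejections["between"] += report.between_test.p_value < alpha
        rejections["within"] += report.within_test.p_value < alpha
        rejections["overall"] += report.overall_test.p_value < alpha

    out = {"n_reps": n_reps, "n_ok": n_ok, "n_failures": n_failures,
           "alpha": alpha, "tests": {}}
    for name, count in rejections.items():
        if n_ok == 0:
            out["tests"][name] = {"rate": float("nan"), "ci": (0.0, 1.0)}
            continue
        ci = stats.binomtest(count, n_ok).proportion_ci(
            confidence_level=ci_level, method="exact"
        )
        out["tests"][name] = {
            "rate": count / n_ok,
            "count": count,
            "ci": (float(ci.low), float(ci.high)),
        }
    return out


def igrt_fixture(seed: int = 0) -> MeasurementTable:
    """Demo dataset shaped like a small head-and-neck IGRT study.

    28 subjects with per-subject session counts drawn to total roughly
    100 paired sessions; the generative triple is chosen qualitatively
    like lateral-axis couch-shift comparisons — a within-subject
    variance ratio of about 3:1 between the two methods and a small
    (below-threshold) bias.  A demonstration fixture, not a
    reproduction of any clinical dataset.
    """
    rng = np.random.default_rng(seed)
    n_subjects = 28
    for _ in range(_MAX_REDRAWS):
        p_list = 2 + rng.binomial(4, 0.39, size=n_subjects)
        if 90 <= int(p_list.sum()) <= 110:
            break
    D = np.array([[0.041, 0.030], [0.030, 0.067]])
    S = np.array([[0.330, 0.060], [0.060, 0.110]])
    mu = np.array([0.03, 0.0])
    rows = []
    for i, p in enumerate(p_list):
        b = rng.multivariate_normal(np.zeros(2), D)
        for t in range(1, int(p) + 1):
            e = rng.multivariate_normal(np.zeros(2), S)
            y = mu + b + e
            rows.append((f"P{i + 1:02d}", 1, t, y[0]))
            rows.append((f"P{i + 1:02d}", 2, t, y[1]))
    return MeasurementTable(
        pd.DataFrame(rows, columns=["subject", "method", "replicate", "value"])
    )
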