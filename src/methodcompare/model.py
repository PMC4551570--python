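"""Doubly-multivariate linear mixed effects model for two-method agreement.

Each subject i contributes paired measurements y_it = (y_it^(1), y_it^(2))
over sessions t = 1..p_i, modelled as

    y_it = mu + b_i + e_it,   b_i ~ N2(0, D),   e_it ~ N2(0, Sigma),

with method-level random effects b_i shared across sessions and
session-level errors e_it independent across sessions.  Stacking the
observed cells session-major (method 1 before method 2 within a session)
gives the marginal covariance

    Omega_i = Z_i D Z_i' + I_{p_i} (x) Sigma

restricted to observed cells: 2x2 session-diagonal blocks D + Sigma and
session-off-diagonal blocks D.  D is the between-subject and Sigma the
within-subject covariance of the two methods; their sum is the overall
between-method covariance.  Either block may be unstructured (UN: two
variances and a covariance) or compound-symmetric (CS: one common
variance and a covariance), which is how equal-variability null models
are expressed.  Estimation is maximum likelihood with the method means
profiled out by GLS, so likelihood-ratio tests between nested structures
are valid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .data import MeasurementTable

logger = logging.getLogger(__name__)

LOG_2PI = math.log(2.0 * math.pi)

_STRUCTURES = ("UN", "CS")


@dataclass(frozen=True)
class ModelSpec:
    """Covariance structure imposed on D (between) and Sigma (within).

    ``UN`` leaves a 2x2 block unstructured (3 free parameters), ``CS``
    imposes compound symmetry: one common variance plus a covariance
    (2 free parameters), i.e. equal variances for the two methods.
    """

    d_structure: str = "UN"
    sigma_structure: str = "UN"

    def __post_init__(self):
        for s in (self.d_structure, self.sigma_structure):
            if s not in _STRUCTURES:
                raise ValueError(f"structure must be one of {_STRUCTURES}, got {s!r}")

    @property
    def n_cov_params(self) -> int:
        return cov_param_count(self)

    def is_nested_in(self, other: "ModelSpec") -> bool:
        """True if self's structures are constraints of other's."""

        def ok(a, b):
            return a == b or (a == "CS" and b == "UN")

        return ok(self.d_structure, other.d_structure) and ok(
            self.sigma_structure, other.sigma_structure
        )

    def __str__(self):
        return f"({self.d_structure},{self.sigma_structure})"


def cov_param_count(spec: ModelSpec) -> int:
    """Number of free covariance parameters: UN block -> 3, CS block -> 2."""
    per = {"UN": 3, "CS": 2}
    return per[spec.d_structure] + per[spec.sigma_structure]


def null_model_lrt_df(spec: ModelSpec) -> int:
    """Covariance parameters minus one, mirroring the null-model LRT df
    reported by standard mixed-model software."""
    return cov_param_count(spec) - 1


@dataclass(frozen=True)
class SubjectDesign:
    """Observed-cell design for one subject.

    Cells are ordered session-major, method-minor over the subject's
    p_i distinct sessions: (session 1: method 1, method 2; session 2: ...).
    A session recorded for only one method leaves the other cell missing.
    """

    subject_id: object
    p_i: int
    observed_mask: np.ndarray  # bool, length 2*p_i
    X_rows: np.ndarray  # n_obs x 2 method indicators (cell-means design)
    Z_rows: np.ndarray  # n_obs x 2 method indicators (random effects)
    values: np.ndarray  # n_obs observed measurements
    methods: np.ndarray  # n_obs method code per observed cell

    @property
    def n_obs(self) -> int:
        return int(self.observed_mask.sum())


def build_subject_designs(table: MeasurementTable) -> list[SubjectDesign]:
    """One design per subject; cells ordered session-major, method-minor."""
    designs = []
    for sid, grp in table.frame.groupby("subject", sort=False):
        if len(grp) == 0:  # pragma: no cover - groupby never yields empty
            logger.warning("subject %r has no records; excluded", sid)
            continue
        sessions = np.sort(grp["replicate"].unique())
        p_i = len(sessions)
        sess_pos = {s: k for k, s in enumerate(sessions)}
        mask = np.zeros(2 * p_i, dtype=bool)
        vals = np.full(2 * p_i, np.nan)
        for _, row in grp.iterrows():
            cell = 2 * sess_pos[row["replicate"]] + (int(row["method"]) - 1)
            mask[cell] = True
            vals[cell] = row["value"]
        methods = np.tile([1, 2], p_i)[mask]
        X = np.zeros((int(mask.sum()), 2))
        X[np.arange(len(methods)), methods - 1] = 1.0
        designs.append(
            SubjectDesign(
                subject_id=sid,
                p_i=p_i,
                observed_mask=mask,
                X_rows=X,
                Z_rows=X.copy(),
                values=vals[mask],
                methods=methods,
            )
        )
    return designs


def marginal_covariance(
    D: np.ndarray, Sigma: np.ndarray, design: SubjectDesign
) -> np.ndarray:
    """Marginal covariance Omega_i restricted to the observed cells.

    The full 2p x 2p grid has session-diagonal blocks D + Sigma and
    session-off-diagonal blocks D; rows/columns of missing cells are
    deleted.  The result must be symmetric positive definite.
    """
    D = np.asarray(D, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    p = design.p_i
    full = np.tile(D, (p, p))
    for t in range(p):
        full[2 * t : 2 * t + 2, 2 * t : 2 * t + 2] += Sigma
    omega = full[np.ix_(design.observed_mask, design.observed_mask)]
    w = np.linalg.eigvalsh(omega)
    if w[0] <= 0:
        raise np.linalg.LinAlgError(
            f"marginal covariance for subject {design.subject_id!r} is not "
            f"positive definite (smallest eigenvalue {w[0]:.3e})"
        )
    return omega


def minus2_loglik(
    mu, D, Sigma, designs: list[SubjectDesign]
) -> float:
    """-2 log marginal likelihood at the given means and covariances.

    Sum over subjects of n_i log(2 pi) + log|Omega_i| + r_i' Omega_i^-1 r_i
    with r_i the observed values minus the corresponding method mean.
    """
    mu = np.asarray(mu, dtype=float)
    total = 0.0
    for d in designs:
        omega = marginal_covariance(D, Sigma, d)
        try:
            c = np.linalg.cholesky(omega)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                f"singular marginal covariance for subject {d.subject_id!r}"
            ) from e
        r = d.values - mu[d.methods - 1]
        z = linalg.solve_triangular(c, r, lower=True)
        total += d.n_obs * LOG_2PI + 2.0 * np.log(np.diag(c)).sum() + z @ z
    return float(total)


def profile_means(D, Sigma, designs: list[SubjectDesign]):
    """GLS estimate of the two method means for given covariances.

    Returns ``(mu, fixed_cov)`` with
    mu = (sum X'Omega^-1 X)^-1 (sum X'Omega^-1 y) and fixed_cov the
    inverse information (sum X'Omega^-1 X)^-1.
    """
    A = np.zeros((2, 2))
    b = np.zeros(2)
    seen = set()
    for d in designs:
        omega = marginal_covariance(D, Sigma, d)
        oi_X = np.linalg.solve(omega, d.X_rows)
        A += d.X_rows.T @ oi_X
        b += oi_X.T @ d.values
        seen.update(d.methods.tolist())
    for m in (1, 2):
        if m not in seen:
            raise ValueError(f"method {m} absent from the data; means not estimable")
    if np.linalg.matrix_rank(A) < 2:
        raise ValueError("rank-deficient fixed-effect information")
    fixed_cov = np.linalg.inv(A)
    return fixed_cov @ b, fixed_cov


# ----------------------------------------------------------------------
# Covariance-block parameterizations (unconstrained optimizer space)
# ----------------------------------------------------------------------
# UN: theta = (a, b, c); L = [[e^a, 0], [b, e^c]]; block = L L'.
# CS: theta = (v, r); block = e^v * [[1, tanh r], [tanh r, 1]].
# Both map all of R^k onto valid (PD up to the floor) blocks.


def _block_from_theta(theta: np.ndarray, structure: str) -> np.ndarray:
    if structure == "UN":
        a, b, c = theta
        l00, l11 = math.exp(a), math.exp(c)
        return np.array(
            [[l00 * l00, b * l00], [b * l00, b * b + l11 * l11]]
        )
    v, r = theta
    var = math.exp(v)
    rho = math.tanh(r)
    return var * np.array([[1.0, rho], [rho, 1.0]])


def _theta_from_block(block: np.ndarray, structure: str, floor: float) -> np.ndarray:
    block = np.asarray(block, dtype=float)
    if structure == "UN":
        b2 = block + floor * np.eye(2)
        L = np.linalg.cholesky(b2)
        return np.array([math.log(L[0, 0]), L[1, 0], math.log(L[1, 1])])
    var = max(0.5 * (block[0, 0] + block[1, 1]), floor)
    rho = float(np.clip(block[0, 1] / var, -0.95, 0.95))
    return np.array([math.log(var), math.atanh(rho)])


def _n_theta(structure: str) -> int:
    return 3 if structure == "UN" else 2


class _PatternGroup:
    """Subjects sharing one observed-cell pattern, stacked for speed."""

    def __init__(self, mask: np.ndarray, p_i: int, X: np.ndarray, methods: np.ndarray):
        self.mask = mask
        self.p_i = p_i
        self.X = X
        self.methods = methods
        self._values = []

    def add(self, values: np.ndarray):
        self._values.append(values)

    def finalize(self):
        self.Y = np.column_stack(self._values)  # n_obs x n_subjects
        self.n_subj = self.Y.shape[1]
        self.n_obs = self.Y.shape[0]

    def omega(self, D, Sigma) -> np.ndarray:
        p = self.p_i
        full = np.tile(D, (p, p))
        for t in range(p):
            full[2 * t : 2 * t + 2, 2 * t : 2 * t + 2] += Sigma
        return full[np.ix_(self.mask, self.mask)]


class MethodComparisonModel:
    """ML estimation of the two-method replicated-measurements LME.

    Parameters
    ----------
    table : MeasurementTable
        Validated long-format data.

    Examples
    --------
    >>> model = MethodComparisonModel(table)
    >>> res = model.fit(ModelSpec("UN", "UN"))
    >>> res.minus2loglik, res.D_hat, res.Sigma_hat  # doctest: +SKIP
    """

    def __init__(self, table: MeasurementTable):
        self.table = table
        self.designs = build_subject_designs(table)
        self.n_obs_total = sum(d.n_obs for d in self.designs)
        self.n_subjects = len(self.designs)
        values = table.frame["value"].to_numpy()
        self._scale = float(np.std(values)) or 1.0
        self._floor = 1e-8 * self._scale**2
        self._groups = self._group_patterns()
        counts = np.bincount(table.frame["method"].to_numpy(), minlength=3)
        if counts[1] == 0 or counts[2] == 0:
            missing = 1 if counts[1] == 0 else 2
            raise ValueError(f"method {missing} absent from the data")

    @classmethod
    def from_dataframe(cls, df) -> "MethodComparisonModel":
        return cls(MeasurementTable.from_dataframe(df))

    def _group_patterns(self):
        groups: dict[tuple, _PatternGroup] = {}
        for d in self.designs:
            key = (d.p_i, tuple(d.observed_mask))
            if key not in groups:
                groups[key] = _PatternGroup(d.observed_mask, d.p_i, d.X_rows, d.methods)
            groups[key].add(d.values)
        for g in groups.values():
            g.finalize()
        return list(groups.values())

    # -- profiled deviance -------------------------------------------

    def _theta_blocks(self, theta: np.ndarray, spec: ModelSpec):
        k = _n_theta(spec.d_structure)
        D = _block_from_theta(theta[:k], spec.d_structure)
        Sigma = _block_from_theta(theta[k:], spec.sigma_structure)
        return D, Sigma

    def profiled_deviance(self, theta: np.ndarray, spec: ModelSpec) -> float:
        """-2 profile log-likelihood: means replaced by their GLS solution."""
        D, Sigma = self._theta_blocks(theta, spec)
        return self._deviance_blocks(D, Sigma)[0]

    def _deviance_blocks(self, D, Sigma):
        A = np.zeros((2, 2))
        b = np.zeros(2)
        quad = 0.0
        logdet = 0.0
        n_tot = 0
        per_group = []
        for g in self._groups:
            omega = g.omega(D, Sigma)
            try:
                c = np.linalg.cholesky(omega)
            except np.linalg.LinAlgError:
                return np.inf, None, None
            XY = np.column_stack([g.X, g.Y])
            W = linalg.cho_solve((c, True), XY)
            WX, WY = W[:, :2], W[:, 2:]
            A += g.n_subj * (g.X.T @ WX)
            b += (g.X.T @ WY).sum(axis=1)
            quad += float(np.sum(g.Y * WY))
            logdet += 2.0 * g.n_subj * float(np.log(np.diag(c)).sum())
            n_tot += g.n_subj * g.n_obs
            per_group.append((g, WX, WY))
        try:
            fixed_cov = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        mu = fixed_cov @ b
        # quad form with profiled means: sum r'O^-1 r = y'O^-1 y - 2 mu'b + mu'A mu
        quad_prof = quad - 2.0 * mu @ b + mu @ A @ mu
        dev = n_tot * LOG_2PI + logdet + quad_prof
        return float(dev), mu, fixed_cov

    # -- starting values ---------------------------------------------

    def _moment_start(self) -> tuple[np.ndarray, np.ndarray]:
        """Moment decomposition into between/within covariance blocks."""
        df = self.table.frame
        piv = df.pivot_table(
            index=["subject", "replicate"], columns="method", values="value"
        )
        # within: covariance of deviations from subject-method means
        centered = df.copy()
        centered["dev"] = df["value"] - df.groupby(["subject", "method"])[
            "value"
        ].transform("mean")
        dev_piv = centered.pivot_table(
            index=["subject", "replicate"], columns="method", values="dev"
        )
        s = self._scale**2
        within = np.full((2, 2), np.nan)
        for i, m in enumerate((1, 2)):
            if m in dev_piv:
                x = dev_piv[m].dropna().to_numpy()
                # ddof adjustment: each subject mean absorbs one df
                n_grp = centered[centered["method"] == m]["subject"].nunique()
                denom = max(len(x) - n_grp, 1)
                within[i, i] = float((x**2).sum()) / denom
        pair = dev_piv.dropna() if set((1, 2)) <= set(dev_piv.columns) else None
        if pair is not None and len(pair) > 2:
            within[0, 1] = within[1, 0] = float(np.cov(pair[1], pair[2])[0, 1])
        else:
            within[0, 1] = within[1, 0] = 0.0
        within = np.nan_to_num(within, nan=0.25 * s)
        w = np.diag(within).copy()
        w[w <= 0] = 0.1 * s
        within[0, 0], within[1, 1] = w
        rho_w = np.clip(within[0, 1] / math.sqrt(w[0] * w[1]), -0.9, 0.9)
        within[0, 1] = within[1, 0] = rho_w * math.sqrt(w[0] * w[1])

        means = df.groupby(["subject", "method"])["value"].mean().unstack()
        nrep = df.groupby(["subject", "method"])["value"].size().unstack()
        between = np.full((2, 2), np.nan)
        pbar = np.ones(2)
        for i, m in enumerate((1, 2)):
            if m in means:
                mi = means[m].dropna()
                pbar[i] = float(nrep[m].dropna().mean()) if m in nrep else 1.0
                if len(mi) > 1:
                    between[i, i] = float(mi.var()) - w[i] / pbar[i]
        both = means.dropna() if set((1, 2)) <= set(means.columns) else None
        if both is not None and len(both) > 1:
            between[0, 1] = float(np.cov(both[1], both[2])[0, 1]) - within[
                0, 1
            ] / max(pbar.mean(), 1.0)
        else:
            between[0, 1] = 0.0
        between = np.nan_to_num(between, nan=0.1 * s)
        d = np.diag(between).copy()
        d[d <= 0] = 0.05 * s
        between[0, 0], between[1, 1] = d
        rho_b = np.clip(between[0, 1] / math.sqrt(d[0] * d[1]), -0.9, 0.9)
        off = rho_b * math.sqrt(d[0] * d[1])
        between[0, 1] = between[1, 0] = off
        return between, within

    def _starts(self, spec: ModelSpec, n_starts: int, seed: int):
        D0, S0 = self._moment_start()
        base = np.concatenate(
            [
                _theta_from_block(D0, spec.d_structure, self._floor),
                _theta_from_block(S0, spec.sigma_structure, self._floor),
            ]
        )
        starts = [base]
        rng = np.random.default_rng(seed)
        for _ in range(n_starts - 1):
            starts.append(base + rng.normal(0.0, 0.4, size=base.size))
        return starts

    # -- fitting ------------------------------------------------------

    def fit(
        self,
        spec: ModelSpec | None = None,
        n_starts: int = 5,
        seed: int = 0,
        tol: float = 1e-8,
        maxiter: int = 500,
    ) -> "MethodComparisonResults":
        """Maximize the profiled marginal likelihood for the given spec.

        Deterministic given ``seed`` (used only to jitter multistart
        points).  The best of ``n_starts`` quasi-Newton runs is polished
        with a derivative-free simplex pass.
        """
        spec = spec or ModelSpec("UN", "UN")
        log_lo = math.log(self._scale) - 14.0
        log_hi = math.log(self._scale) + 8.0
        bounds = []
        for structure in (spec.d_structure, spec.sigma_structure):
            if structure == "UN":
                bounds += [(log_lo, log_hi), (None, None), (log_lo, log_hi)]
            else:
                bounds += [(2 * log_lo, 2 * log_hi), (-7.0, 7.0)]

        best = None
        n_converged = 0
        for k, x0 in enumerate(self._starts(spec, n_starts, seed)):
            with np.errstate(invalid="ignore", over="ignore"):
                res = optimize.minimize(
                    self.profiled_deviance,
                    x0,
                    args=(spec,),
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7},
                )
            logger.debug(
                "start %d spec %s: deviance %.6f success=%s nfev=%d",
                k, spec, res.fun, res.success, res.nfev,
            )
            if best is None or res.fun < best.fun:
                best = res
            n_converged += bool(res.success)
        polish = optimize.minimize(
            self.profiled_deviance,
            best.x,
            args=(spec,),
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": tol * 1e-2, "maxiter": 2000},
        )
        if polish.fun <= best.fun:
            best = polish
        converged = n_converged > 0 or polish.success
        if not converged:
            logger.warning(
                "optimizer did not report convergence for spec %s", spec
            )
        D_hat, Sigma_hat = self._theta_blocks(best.x, spec)
        dev, mu, fixed_cov = self._deviance_blocks(D_hat, Sigma_hat)
        return MethodComparisonResults(
            model=self,
            spec=spec,
            theta=np.asarray(best.x, dtype=float),
            mu=np.asarray(mu),
            D_hat=D_hat,
            Sigma_hat=Sigma_hat,
            minus2loglik=float(dev),
            n_cov_params=cov_param_count(spec),
            fixed_cov=np.asarray(fixed_cov),
            converged=bool(converged),
            n_subjects=self.n_subjects,
            n_obs_total=self.n_obs_total,
        )


@dataclass(frozen=True)
class OverallBlock:
    """Overall (between + within) 2x2 covariance and its correlation."""

    omega: np.ndarray
    corr: np.ndarray


@dataclass
class MethodComparisonResults:
    """ML fit of the two-method LME: estimates, deviance, diagnostics."""

    model: MethodComparisonModel = field(repr=False)
    spec: ModelSpec
    theta: np.ndarray = field(repr=False)
    mu: np.ndarray
    D_hat: np.ndarray
    Sigma_hat: np.ndarray
    minus2loglik: float
    n_cov_params: int
    fixed_cov: np.ndarray
    converged: bool
    n_subjects: int
    n_obs_total: int

    @property
    def omega(self) -> np.ndarray:
        return self.D_hat + self.Sigma_hat

    def overall_block(self) -> OverallBlock:
        return overall_block(self)

    @property
    def overall_correlation(self) -> float:
        return float(self.overall_block().corr[0, 1])

    def cov_theta(self) -> np.ndarray:
        """Asymptotic covariance of the optimizer-space covariance
        parameters: 2 * inverse Hessian of the profiled deviance."""
        H = _numeric_hessian(
            lambda th: self.model.profiled_deviance(th, self.spec), self.theta
        )
        return 2.0 * np.linalg.pinv(H)

    def cov_structure_se(self) -> dict[str, float]:
        """Delta-method standard errors for the natural covariance
        entries (d11, d12, d22, s11, s12, s22)."""
        cov_t = self.cov_theta()

        def natural(th):
            D, S = self.model._theta_blocks(th, self.spec)
            return np.array([D[0, 0], D[0, 1], D[1, 1], S[0, 0], S[0, 1], S[1, 1]])

        J = _numeric_jacobian(natural, self.theta)
        var = np.clip(np.diag(J @ cov_t @ J.T), 0.0, None)
        names = ["d11", "d12", "d22", "s11", "s12", "s22"]
        return dict(zip(names, np.sqrt(var)))

    def summary(self) -> str:
        from .report import results_summary

        return results_summary(self)


def overall_block(fit: MethodComparisonResults) -> OverallBlock:
    """Overall covariance omega = D + Sigma and the implied correlation.

    The overall variance of each method is exactly the sum of its
    between-subject and within-subject variances.  With a zero variance
    on either diagonal the correlation is undefined and reported as NaN.
    """
    omega = fit.D_hat + fit.Sigma_hat
    corr = np.eye(2)
    v1, v2 = omega[0, 0], omega[1, 1]
    if v1 > 0 and v2 > 0:
        corr[0, 1] = corr[1, 0] = omega[0, 1] / math.sqrt(v1 * v2)
    else:
        corr[0, 1] = corr[1, 0] = np.nan
    return OverallBlock(omega=omega, corr=corr)


# ----------------------------------------------------------------------
# small numeric-derivative helpers (used for Satterthwaite df and SEs)
# ----------------------------------------------------------------------


def _numeric_hessian(f, x, rel_step=1e-4):
    x = np.asarray(x, dtype=float)
    n = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def _numeric_jacobian(f, x, rel_step=1e-6):
    x = np.asarray(x, dtype=float)
    h = rel_step * np.maximum(np.abs(x), 1.0)
    cols = []
    for i in range(x.size):
        e = np.zeros(x.size); e[i] = h[i]
        cols.append((np.asarray(f(x + e)) - np.asarray(f(x - e))) / (2 * h[i]))
    return np.column_stack(cols)


def _numeric_gradient(f, x, rel_step=1e-6):
    return _numeric_jacobian(lambda th: np.atleast_1d(f(th)), x, rel_step).ravel()
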