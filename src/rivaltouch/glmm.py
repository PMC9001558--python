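"""Binomial random-intercept mixed models of switch probability.

The model for segment-level switch outcomes is

    y_ij ~ Bernoulli(p_ij),   logit p_ij = x_ij' beta + u_i,
    u_i ~ N(0, sigma^2)   (one random intercept per participant),

with two treatment-coded two-level fixed factors — experimental condition
and visuo-tactile congruency at tactile onset — and optionally their
interaction.  The marginal likelihood integrates the random intercept out
with adaptive Gauss–Hermite quadrature (nodes recentred at each group's
posterior mode and rescaled by its curvature), and is maximised by
quasi-Newton over (beta, log sigma) from several jittered starts.

Inference follows the classical recipe: a 1-df likelihood-ratio test for
the interaction, and follow-up pairwise contrasts of estimated marginal
means on the response (probability) scale with delta-method standard
errors, the random intercept held at its zero population mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

log = logging.getLogger(__name__)

__all__ = [
    "GlmmFit",
    "LrtResult",
    "ContrastResult",
    "fit_switch_model",
    "lrt_interaction",
    "pairwise_contrasts",
]

_SIGMA_FLOOR = 1e-4  # below this the random effect is at the boundary
_SEPARATION_COEF = 15.0


@dataclass
class GlmmFit:
    param_names: list[str]
    coefficients: np.ndarray  # logit scale, order matches param_names
    coef_se: np.ndarray
    z_values: np.ndarray
    random_intercept_var: float
    log_likelihood: float
    n_obs: int
    n_groups: int
    cov: np.ndarray  # covariance of (beta, log sigma)
    include_interaction: bool
    condition_levels: tuple[str, str]
    congruency_levels: tuple[str, str]
    boundary: bool = False
    separation: bool = False

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.param_names.index(name)])


@dataclass(frozen=True)
class LrtResult:
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class ContrastResult:
    level_pair: tuple[str, str]
    within: str  # level of the conditioning factor
    estimate_prob_scale: float
    se: float
    z: float
    p: float
    boundary: bool = False


def _design(
    cond: np.ndarray,
    congr: np.ndarray,
    cond_levels: tuple[str, str],
    congr_levels: tuple[str, str],
    include_interaction: bool,
) -> tuple[np.ndarray, list[str]]:
    a = (cond == cond_levels[1]).astype(float)
    b = (congr == congr_levels[1]).astype(float)
    cols = [np.ones_like(a), a, b]
    names = [
        "intercept",
        f"condition[{cond_levels[1]}]",
        f"congruency[{congr_levels[1]}]",
    ]
    if include_interaction:
        cols.append(a * b)
        names.append(
            f"condition[{cond_levels[1]}]:congruency[{congr_levels[1]}]"
        )
    return np.column_stack(cols), names


class _MarginalLikelihood:
    """Vectorised adaptive-GHQ marginal log-likelihood over groups."""

    def __init__(
        self, X: np.ndarray, y: np.ndarray, group_idx: np.ndarray, n_nodes: int
    ):
        order = np.argsort(group_idx, kind="stable")
        self.X = X[order]
        self.y = y[order].astype(float)
        g = group_idx[order]
        self.n_groups = int(g.max()) + 1
        self.starts = np.searchsorted(g, np.arange(self.n_groups))
        self.group_of_row = g
        nodes, weights = special.roots_hermite(n_nodes)
        self.nodes = nodes
        self.log_weights = np.log(weights) + nodes**2  # e^{x^2} w_k folded in

    def _group_sum(self, v: np.ndarray) -> np.ndarray:
        return np.add.reduceat(v, self.starts)

    def _mode(self, eta0: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mode and curvature of u per group (Newton)."""
        u = np.zeros(self.n_groups)
        inv_var = 1.0 / sigma**2
        for _ in range(60):
            eta = eta0 + u[self.group_of_row]
            p = special.expit(eta)
            grad = self._group_sum(self.y - p) - u * inv_var
            hess = -self._group_sum(p * (1.0 - p)) - inv_var
            step = grad / hess
            u -= step
            if np.max(np.abs(step)) < 1e-10:
                break
        eta = eta0 + u[self.group_of_row]
        p = special.expit(eta)
        hess = -self._group_sum(p * (1.0 - p)) - inv_var
        return u, hess

    def loglik(self, beta: np.ndarray, sigma: float) -> float:
        eta0 = self.X @ beta
        u_hat, hess = self._mode(eta0, sigma)
        tau = 1.0 / np.sqrt(-hess)
        # node positions per group: u_hat + sqrt(2) tau x_k
        z = u_hat[:, None] + np.sqrt(2.0) * tau[:, None] * self.nodes[None, :]
        log_g = np.empty((self.n_groups, len(self.nodes)))
        for k in range(len(self.nodes)):
            eta = eta0 + z[self.group_of_row, k]
            ll_rows = self.y * eta - np.logaddexp(0.0, eta)
            log_g[:, k] = self._group_sum(ll_rows)
        log_prior = (
            -0.5 * (z / sigma) ** 2
            - np.log(sigma)
            - 0.5 * np.log(2.0 * np.pi)
        )
        integrand = log_g + log_prior + self.log_weights[None, :]
        per_group = special.logsumexp(integrand, axis=1) + 0.5 * np.log(
            2.0
        ) + np.log(tau)
        return float(per_group.sum())

    def nll(self, theta: np.ndarray) -> float:
        beta, log_sigma = theta[:-1], theta[-1]
        return -self.loglik(beta, np.exp(log_sigma))


def _pooled_logit_start(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Ridge-stabilised pooled logistic fit used as the optimizer's start."""
    beta = np.zeros(X.shape[1])
    for _ in range(50):
        p = special.expit(X @ beta)
        W = p * (1.0 - p) + 1e-9
        H = X.T @ (X * W[:, None]) + 1e-6 * np.eye(X.shape[1])
        g = X.T @ (y - p) - 1e-6 * beta
        step = np.linalg.solve(H, g)
        beta += step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def _num_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = eps
            ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * eps**2)
    return H


def fit_switch_model(
    segment_table: pd.DataFrame,
    include_interaction: bool = True,
    *,
    n_quad: int = 25,
    n_restarts: int = 3,
    sigma_fixed: float | None = None,
) -> GlmmFit:
    """Fit the switch-probability mixed logistic model.

    ``segment_table`` must hold one row per analysable segment with columns
    ``participant_id``, ``condition`` (two levels), ``congruency_at_onset``
    (congruent / incongruent) and ``switched`` (0 = maintained, 1 = one
    switch); rows are expected to be pre-filtered to single-switch-or-
    maintained, mixed-free segments.
    """
    df = segment_table
    cond_levels = tuple(sorted(df["condition"].unique()))
    congr_levels = tuple(sorted(df["congruency_at_onset"].unique()))
    if len(cond_levels) != 2 or len(congr_levels) != 2:
        raise ValueError("both fixed factors must have exactly two levels")
    X, names = _design(
        df["condition"].to_numpy(),
        df["congruency_at_onset"].to_numpy(),
        cond_levels,
        congr_levels,
        include_interaction,
    )
    y = df["switched"].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("'switched' must be binary")
    groups, group_idx = np.unique(df["participant_id"].to_numpy(), return_inverse=True)

    ml = _MarginalLikelihood(X, y, group_idx, n_quad)
    beta0 = _pooled_logit_start(X, y)
    rng = np.random.default_rng(12345)  # fixed: jittered restarts, reproducible
    starts = [np.concatenate([beta0, [np.log(0.5)]])]
    for _ in range(n_restarts - 1):
        starts.append(
            np.concatenate(
                [beta0 + rng.normal(0, 0.25, len(beta0)), [rng.normal(-0.7, 0.7)]]
            )
        )
    if sigma_fixed is not None:
        ls = np.log(max(sigma_fixed, _SIGMA_FLOOR / 10))
        sigma_bounds = (ls, ls)
        starts = [np.concatenate([s[:-1], [ls]]) for s in starts]
    else:
        sigma_bounds = (np.log(_SIGMA_FLOOR) - 2.0, 3.0)
    bounds = [(-30.0, 30.0)] * X.shape[1] + [sigma_bounds]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            ml.nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    llf = -best.fun
    sigma = float(np.exp(theta[-1]))

    H = _num_hessian(ml.nll, theta)
    p_fix = X.shape[1]
    try:
        cov = np.linalg.inv(H)
        if np.any(np.diag(cov) < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        # variance at its boundary makes H singular in log sigma; fall back
        # to the fixed-effects block with sigma held at its estimate
        cov = np.full((len(theta), len(theta)), np.nan)
        try:
            cov_beta = np.linalg.inv(H[:p_fix, :p_fix])
            if np.any(np.diag(cov_beta) < 0):
                raise np.linalg.LinAlgError
            cov[:p_fix, :p_fix] = cov_beta
        except np.linalg.LinAlgError:
            pass
    se = np.sqrt(np.diag(cov)[:p_fix])

    beta = theta[: X.shape[1]]
    separation = bool(np.any(np.abs(beta) > _SEPARATION_COEF))
    if separation:
        log.warning("possible complete separation: |coefficient| > %g",
                    _SEPARATION_COEF)
    boundary = sigma < _SIGMA_FLOOR * 1.5
    if boundary:
        log.warning("random-intercept variance at boundary (sigma=%.2g)", sigma)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    return GlmmFit(
        param_names=names,
        coefficients=beta,
        coef_se=se,
        z_values=z,
        random_intercept_var=sigma**2,
        log_likelihood=llf,
        n_obs=len(y),
        n_groups=len(groups),
        cov=cov,
        include_interaction=include_interaction,
        condition_levels=cond_levels,
        congruency_levels=congr_levels,
        boundary=boundary,
        separation=separation,
    )


def lrt_interaction(full: GlmmFit, reduced: GlmmFit) -> LrtResult:
    """1-df likelihood-ratio test of the condition × congruency interaction."""
    if not full.include_interaction or reduced.include_interaction:
        raise ValueError("expected a full (interaction) and a reduced model")
    if (
        full.condition_levels != reduced.condition_levels
        or full.congruency_levels != reduced.congruency_levels
        or full.n_obs != reduced.n_obs
    ):
        raise ValueError("models are not nested on the same data")
    chi2 = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    p = float(stats.chi2.sf(chi2, df=1))
    return LrtResult(chi2=chi2, df=1, p=p)


def _cell_row(
    fit: GlmmFit, condition: str, congruency: str
) -> np.ndarray:
    x, _ = _design(
        np.array([condition]),
        np.array([congruency]),
        fit.condition_levels,
        fit.congruency_levels,
        fit.include_interaction,
    )
    return x[0]


def pairwise_contrasts(
    fit: GlmmFit, by: str = "condition"
) -> list[ContrastResult]:
    """Congruency (or condition) contrasts on the probability scale.

    For each level of the conditioning factor, the two levels of the other
    factor are contrasted as a difference of inverse-link estimated
    marginal means (random intercept at zero), with delta-method standard
    errors and two-sided z-tests.  No multiplicity correction is applied.
    """
    if not fit.include_interaction:
        raise ValueError("contrasts require the full (interaction) model")
    if by == "condition":
        outer, inner = fit.condition_levels, fit.congruency_levels
        row = lambda o, i: _cell_row(fit, o, i)  # noqa: E731
    elif by == "congruency":
        outer, inner = fit.congruency_levels, fit.condition_levels
        row = lambda o, i: _cell_row(fit, i, o)  # noqa: E731
    else:
        raise ValueError("by must be 'condition' or 'congruency'")
    beta = fit.coefficients
    cov_beta = fit.cov[: len(beta), : len(beta)]
    results = []
    for level in outer:
        x1, x2 = row(level, inner[0]), row(level, inner[1])
        p1 = special.expit(x1 @ beta)
        p2 = special.expit(x2 @ beta)
        grad = p1 * (1 - p1) * x1 - p2 * (1 - p2) * x2
        var = float(grad @ cov_beta @ grad)
        se = np.sqrt(var) if var > 0 else np.nan
        est = float(p1 - p2)
        if est == 0.0:
            z, p = 0.0, 1.0
        elif np.isfinite(se) and se > 0:
            z = est / se
            p = float(2.0 * stats.norm.sf(abs(z)))
        else:
            z, p = np.nan, np.nan
        results.append(
            ContrastResult(
                level_pair=(inner[0], inner[1]),
                within=level,
                estimate_prob_scale=est,
                se=float(se),
                z=float(z),
                p=p,
                boundary=fit.boundary,
            )
        )
    return results


def fit_table(fit: GlmmFit) -> pd.DataFrame:
    """Coefficient table (estimate, SE, z, p) on the logit scale."""
    p = 2.0 * stats.norm.sf(np.abs(fit.z_values))
    return pd.DataFrame(
        {
            "term": fit.param_names,
            "estimate": fit.coefficients,
            "se": fit.coef_se,
            "z": fit.z_values,
            "p": p,
        }
    )
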