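"""Quasi-variances for reference-free reporting of worth coefficients.

Coefficients identified against a reference category have no standard error
of their own (the reference's is zero by construction) and the errors of
contrasts depend on the full covariance.  Quasi-variances q_i are per-item
surrogates chosen so that q_i + q_j ≈ Var(β̂_i − β̂_j) for every pair, which
lets each item carry its own "quasi-standard error" sqrt(q_i) — including
the reference — and makes any pairwise comparison approximately readable
from per-item error bars alone.

The q are found by least squares on the log scale,

    minimize Σ_{i<j} [log(q_i + q_j) − log Var(β̂_i − β̂_j)]²,

optimized over log q (guaranteeing positivity) with an analytic gradient.
The approximation error is always reported, never hidden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .btmodel import BTFit
from .data_model import DataError, ItemSet

__all__ = ["QuasiVariances", "quasi_variances"]


@dataclass(frozen=True)
class QuasiVariances:
    """Per-item quasi-variances with the worst-pair approximation error."""

    items: ItemSet
    q: dict[str, float]
    worst_relative_error: float

    @property
    def quasi_se(self) -> dict[str, float]:
        return {lab: float(np.sqrt(v)) for lab, v in self.q.items()}

    def comparison_bounds(self, level_multiplier: float = 1.96) -> dict[str, tuple[float, float]]:
        """±multiplier·quasi-SE intervals around 0 width (for error bars)."""
        return {lab: (-level_multiplier * s, level_multiplier * s)
                for lab, s in self.quasi_se.items()}


def _contrast_variances(fit: BTFit) -> np.ndarray:
    m = len(fit.items)
    full = fit.full_beta_covariance()[:m, :m]
    d = np.diag(full)
    return d[:, None] + d[None, :] - 2.0 * full


def quasi_variances(fit: BTFit, tol: float = 1e-10) -> QuasiVariances:
    """Compute quasi-variances for every item of a fitted model.

    The reference item receives a quasi-variance too.  The diagnostic
    ``worst_relative_error`` is max over pairs of
    |(q_i+q_j)/Var(β̂_i−β̂_j) − 1|; q_i + q_j reproduces each contrast
    variance at least that well.
    """
    m = len(fit.items)
    V = _contrast_variances(fit)
    iu = np.triu_indices(m, 1)
    v = V[iu]
    if np.any(v <= 0):
        bad = [(fit.items.items[i], fit.items.items[j])
               for i, j in zip(*iu) if V[i, j] <= 0]
        raise DataError(f"non-positive contrast variance for pairs {bad}")
    log_v = np.log(v)

    def objective(log_q: np.ndarray):
        q = np.exp(log_q)
        s = q[iu[0]] + q[iu[1]]
        r = np.log(s) - log_v
        f = float(np.sum(r * r))
        # d f / d log q_k = sum over pairs containing k of 2 r q_k / s
        coef = 2.0 * r / s
        g = np.zeros(m)
        np.add.at(g, iu[0], coef)
        np.add.at(g, iu[1], coef)
        g *= q
        return f, g

    x0 = np.log(np.full(m, max(np.median(v) / 2.0, 1e-8)))
    res = minimize(objective, x0, jac=True, method="BFGS",
                   options={"gtol": tol, "maxiter": 1000})
    if not res.success and res.status != 2:  # 2 = precision loss at optimum
        raise DataError(f"quasi-variance optimization failed: {res.message}")

    q = np.exp(res.x)
    approx = q[iu[0]] + q[iu[1]]
    worst = float(np.max(np.abs(approx / v - 1.0)))
    return QuasiVariances(
        items=fit.items,
        q={lab: float(qk) for lab, qk in zip(fit.items, q)},
        worst_relative_error=worst,
    )
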