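"""Bradley–Terry worth model: likelihood, fitting and inference.

Each item *i* carries a latent worth π_i > 0; item *i* is preferred over *j*
with probability π_i/(π_i+π_j).  On the log scale with β_i = log π_i this is
a logistic model on worth contrasts, logit(p_ij) = β_i − β_j, optionally
extended by an order term δ — the additive log-odds advantage of the sample
tasted first.  Only contrasts are identifiable; the model is pinned down by
fixing one reference item's coefficient at zero.

Two independent maximum-likelihood fitters are provided: a
minorize–maximize (MM) iteration on the worths and Newton–Raphson on the
contrast design.  Both converge to the same optimum on any dataset whose
win digraph is strongly connected; disconnected or all-win/all-loss data
(separation) make the MLE unbounded and are rejected with a diagnostic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Sequence

import networkx as nx
import numpy as np
from scipy.special import expit
from scipy.stats import chi2, norm

from .data_model import ComparisonRecord, CountMatrices, DataError, ItemSet, aggregate

__all__ = [
    "BTFit",
    "PairwiseTable",
    "LRTResult",
    "SeparationError",
    "ConvergenceError",
    "win_probability",
    "fit",
    "fit_with_order",
    "rereference",
    "pairwise_table",
    "lrt_vs_null",
]

MAX_ABS_COEF = 15.0  # |β| beyond this is numerically indistinguishable from ±∞

ORDER_LABEL = "_first"  # pseudo-label for the order coefficient in covariance


class SeparationError(DataError):
    """The MLE is unbounded (an item never wins/loses, or the win digraph
    is disconnected)."""

    def __init__(self, message: str, items: Sequence[str] = ()):
        super().__init__(message)
        self.items = tuple(items)


class ConvergenceError(RuntimeError):
    """Fitter failed to converge; carries the log-likelihood trace."""

    def __init__(self, message: str, trace: Sequence[float]):
        super().__init__(message)
        self.trace = list(trace)


def win_probability(beta_i: float, beta_j: float, delta: float = 0.0) -> float:
    """P(item i preferred over item j), with i tasted first when δ ≠ 0."""
    return float(expit(beta_i - beta_j + delta))


@dataclass(frozen=True)
class BTFit:
    """A fitted Bradley–Terry model.

    ``beta`` is aligned with ``items`` and satisfies ``beta[reference] == 0``
    exactly.  ``covariance`` covers the free parameters in the order given
    by ``free_labels``: every item except the reference, then the order
    coefficient if present.
    """

    items: ItemSet
    reference: str
    beta: np.ndarray
    covariance: np.ndarray
    loglik: float
    n_obs: int
    order_coef: float | None = None
    algorithm: str = "newton"
    n_iter: int = 0

    @property
    def free_labels(self) -> tuple[str, ...]:
        labels = tuple(x for x in self.items if x != self.reference)
        if self.order_coef is not None:
            labels += (ORDER_LABEL,)
        return labels

    @property
    def beta_dict(self) -> dict[str, float]:
        return {lab: float(b) for lab, b in zip(self.items, self.beta)}

    def full_beta_covariance(self) -> np.ndarray:
        """Covariance of β̂ over all items (+ order term if present), with
        the reference row/column identically zero."""
        m = len(self.items)
        k = m + (1 if self.order_coef is not None else 0)
        full = np.zeros((k, k))
        idx = [self.items.index(lab) if lab != ORDER_LABEL else m
               for lab in self.free_labels]
        full[np.ix_(idx, idx)] = self.covariance
        return full

    def se(self, label: str) -> float:
        """Standard error of β̂ for an item (0 for the reference) or of δ̂."""
        if label == self.reference:
            return 0.0
        pos = self.free_labels.index(label)
        return float(np.sqrt(self.covariance[pos, pos]))

    def wald_p(self, label: str) -> float:
        """Two-sided Wald p-value of a coefficient against zero."""
        se = self.se(label)
        if se == 0.0:
            return 1.0
        est = (self.order_coef if label == ORDER_LABEL
               else self.beta[self.items.index(label)])
        return float(2.0 * norm.sf(abs(est) / se))

    @property
    def order_se(self) -> float | None:
        return None if self.order_coef is None else self.se(ORDER_LABEL)

    @property
    def order_p(self) -> float | None:
        return None if self.order_coef is None else self.wald_p(ORDER_LABEL)

    def contrast_variance(self, label_i: str, label_j: str) -> float:
        """Var(β̂_i − β̂_j) from the fitted covariance."""
        full = self.full_beta_covariance()
        i, j = self.items.index(label_i), self.items.index(label_j)
        return float(full[i, i] + full[j, j] - 2.0 * full[i, j])

    def to_json(self, dest: str | Path | IO[str] | None = None) -> str:
        payload = {
            "items": list(self.items),
            "reference": self.reference,
            "beta": self.beta.tolist(),
            "covariance": self.covariance.tolist(),
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "order_coef": self.order_coef,
            "algorithm": self.algorithm,
            "n_iter": self.n_iter,
        }
        text = json.dumps(payload, indent=2)
        if dest is not None:
            if hasattr(dest, "write"):
                dest.write(text)
            else:
                Path(dest).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path | IO[str]) -> "BTFit":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            p = Path(source)
            payload = json.loads(p.read_text() if p.exists() else str(source))
        return cls(
            items=ItemSet(payload["items"]),
            reference=payload["reference"],
            beta=np.asarray(payload["beta"], dtype=float),
            covariance=np.asarray(payload["covariance"], dtype=float),
            loglik=float(payload["loglik"]),
            n_obs=int(payload["n_obs"]),
            order_coef=payload.get("order_coef"),
            algorithm=payload.get("algorithm", "newton"),
            n_iter=int(payload.get("n_iter", 0)),
        )


@dataclass(frozen=True)
class PairwiseTable:
    """All-pairs contrast estimates and two-sided Wald p-values.

    ``estimates[i, j] = β̂_i − β̂_j`` (antisymmetric); ``p_values`` is
    symmetric with NaN on the diagonal.  Equivalent to refitting with every
    item once as the reference and reading off the coefficient tests.
    """

    items: ItemSet
    estimates: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray

    def p_value(self, label_i: str, label_j: str) -> float:
        return float(self.p_values[self.items.index(label_i),
                                   self.items.index(label_j)])

    def to_frame(self, what: str = "p_values"):
        import pandas as pd

        return pd.DataFrame(getattr(self, what),
                            index=list(self.items), columns=list(self.items))


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of the fitted model against equal worths."""

    statistic: float
    df: int
    p_value: float
    loglik_full: float
    loglik_null: float


# --------------------------------------------------------------------------
# separation diagnostics

def check_separation(counts: CountMatrices) -> None:
    """Raise :class:`SeparationError` unless the win digraph is strongly
    connected (the Ford condition for a finite, unique MLE)."""
    W = counts.wins
    items = counts.items
    never_win = [items.items[k] for k in range(len(items)) if W[k].sum() == 0]
    never_lose = [items.items[k] for k in range(len(items)) if W[:, k].sum() == 0]
    if never_win or never_lose:
        raise SeparationError(
            "separation: item(s) with no wins "
            f"{never_win} / no losses {never_lose}; worth estimates are "
            "unbounded", items=tuple(never_win + never_lose))
    g = nx.DiGraph()
    g.add_nodes_from(range(len(items)))
    g.add_edges_from(zip(*np.nonzero(W)))
    if not nx.is_strongly_connected(g):
        comp = min(nx.strongly_connected_components(g), key=len)
        bad = tuple(items.items[k] for k in sorted(comp))
        raise SeparationError(
            f"separation: win digraph is not strongly connected (e.g. group "
            f"{list(bad)} has no win-path to/from the rest)", items=bad)


# --------------------------------------------------------------------------
# aggregated-count likelihood machinery

def _pair_arrays(counts: CountMatrices):
    """Upper-triangle views: indices (i, j), wins of i over j, pair totals."""
    iu = np.triu_indices(counts.n_items, 1)
    w_ij = counts.wins[iu].astype(float)
    n_ij = counts.pair_totals[iu].astype(float)
    return iu, w_ij, n_ij


def _loglik_counts(beta: np.ndarray, iu, w_ij, n_ij) -> float:
    d = beta[iu[0]] - beta[iu[1]]
    # log p and log(1-p) via logaddexp for numerical safety
    log_p = -np.logaddexp(0.0, -d)
    log_q = -np.logaddexp(0.0, d)
    return float(np.sum(w_ij * log_p + (n_ij - w_ij) * log_q))


def _information_counts(beta: np.ndarray, counts: CountMatrices,
                        ref_idx: int) -> np.ndarray:
    """Observed (= expected) information over the free coefficients."""
    d = beta[:, None] - beta[None, :]
    p = expit(d)
    wgt = counts.pair_totals * p * (1.0 - p)
    free = [k for k in range(counts.n_items) if k != ref_idx]
    H = -wgt[np.ix_(free, free)]
    np.fill_diagonal(H, [wgt[k].sum() for k in free])
    return H


def _fit_newton_counts(counts: CountMatrices, ref_idx: int,
                       max_iter: int, tol: float):
    m = counts.n_items
    iu, w_ij, n_ij = _pair_arrays(counts)
    free = [k for k in range(m) if k != ref_idx]
    wins_total = counts.wins.sum(axis=1).astype(float)

    beta = np.zeros(m)
    ll = _loglik_counts(beta, iu, w_ij, n_ij)
    trace = [ll]
    for it in range(1, max_iter + 1):
        p = expit(beta[:, None] - beta[None, :])
        expected = (counts.pair_totals * p).sum(axis=1)
        grad = (wins_total - expected)[free]
        H = _information_counts(beta, counts, ref_idx)
        step = np.linalg.solve(H, grad)
        # step-halving on non-increase
        scale = 1.0
        for _ in range(50):
            cand = beta.copy()
            cand[free] += scale * step
            ll_new = _loglik_counts(cand, iu, w_ij, n_ij)
            if ll_new >= ll - 1e-14:
                break
            scale *= 0.5
        beta, ll_prev, ll = cand, ll, ll_new
        trace.append(ll)
        if np.max(np.abs(beta)) > MAX_ABS_COEF:
            raise SeparationError(
                "separation: a worth coefficient diverged during fitting",
                items=tuple(counts.items.items[k]
                            for k in free if abs(beta[k]) > MAX_ABS_COEF))
        if abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1e-12):
            return beta, ll, it
    raise ConvergenceError(f"Newton did not converge in {max_iter} iterations",
                           trace)


def _fit_mm_counts(counts: CountMatrices, ref_idx: int,
                   max_iter: int, tol: float):
    """Minorize–maximize on the worths π: the classical update
    π_i ← w_i / Σ_{j≠i} n_ij/(π_i+π_j), renormalized to π_ref = 1."""
    m = counts.n_items
    iu, w_ij, n_ij = _pair_arrays(counts)
    N = counts.pair_totals.astype(float)
    wins_total = counts.wins.sum(axis=1).astype(float)

    pi = np.ones(m)
    ll = _loglik_counts(np.log(pi), iu, w_ij, n_ij)
    trace = [ll]
    for it in range(1, max_iter + 1):
        denom = (N / (pi[:, None] + pi[None, :] +
                      np.eye(m))).sum(axis=1)  # eye avoids 0/0 on diagonal
        pi_new = wins_total / denom
        pi_new = pi_new / pi_new[ref_idx]
        step = np.max(np.abs(np.log(pi_new) - np.log(pi)))
        pi = pi_new
        ll_prev, ll = ll, _loglik_counts(np.log(pi), iu, w_ij, n_ij)
        trace.append(ll)
        if np.max(np.abs(np.log(pi))) > MAX_ABS_COEF:
            raise SeparationError(
                "separation: a worth diverged during MM fitting",
                items=tuple(counts.items.items[k] for k in range(m)
                            if abs(math.log(pi[k])) > MAX_ABS_COEF))
        # MM converges linearly, so the loglik criterion alone can stop
        # while coefficients are still ~1e-4 off; require a stationary
        # parameter vector as well.
        if (abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1e-12)
                and step <= 1e-9):
            return np.log(pi), ll, it
    raise ConvergenceError(f"MM did not converge in {max_iter} iterations",
                           trace)


def fit(
    counts: CountMatrices,
    reference: str | None = None,
    algorithm: str = "newton",
    max_iter: int = 1000,
    tol: float = 1e-10,
    pseudocount: float = 0.0,
) -> BTFit:
    """Maximum-likelihood Bradley–Terry fit to order-aggregated win counts.

    The likelihood is the product over unordered pairs of binomials with
    success probability expit(β_i − β_j); no order term is estimable from
    aggregated counts.  ``algorithm`` selects the MM iteration ("mm") or
    Newton–Raphson ("newton"); both reach the same optimum.  ``pseudocount``
    adds ε fictitious wins in both directions of every compared pair — an
    exploratory regularization for separated data, off by default.

    Raises :class:`SeparationError` when the MLE is unbounded and
    :class:`ConvergenceError` (with trace) after ``max_iter`` iterations.
    """
    items = counts.items
    if reference is None:
        reference = items.items[0]
    ref_idx = items.index(reference)

    if pseudocount > 0.0:
        compared = counts.pair_totals > 0
        wins = counts.wins.astype(float) + pseudocount * compared
        work = _PseudoCounts(items, wins)
    else:
        check_separation(counts)
        work = counts

    if algorithm == "newton":
        beta, ll, n_iter = _fit_newton_counts(work, ref_idx, max_iter, tol)
    elif algorithm == "mm":
        beta, ll, n_iter = _fit_mm_counts(work, ref_idx, max_iter, tol)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")

    beta = beta - beta[ref_idx]  # exact zero at the reference
    H = _information_counts(beta, work, ref_idx)
    covariance = np.linalg.inv(H)
    return BTFit(items=items, reference=reference, beta=beta,
                 covariance=covariance, loglik=ll, n_obs=counts.total,
                 algorithm=algorithm, n_iter=n_iter)


class _PseudoCounts:
    """Duck-typed CountMatrices with fractional (regularized) wins."""

    def __init__(self, items: ItemSet, wins: np.ndarray):
        self.items = items
        self.wins = wins
        self.n_items = len(items)
        self.pair_totals = wins + wins.T
        self.total = int(round(wins.sum()))


# --------------------------------------------------------------------------
# record-level fit with order effect

def fit_with_order(
    records: Sequence[ComparisonRecord],
    reference: str | None = None,
    items: ItemSet | None = None,
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> BTFit:
    """Bradley–Terry fit on judgment-level data with a first-position term.

    The linear predictor for a judgment is β_first − β_second + δ and the
    response is 1 when the first-tasted item was preferred, so positive δ
    is a taste advantage of the first sample.  Estimated by Newton–Raphson
    with step-halving; covariance is the inverse observed information, and
    a two-sided Wald p-value for δ is available as ``fit.order_p``.
    """
    if not records:
        raise DataError("cannot fit on an empty record list")
    counts = aggregate(records, items)
    check_separation(counts)
    items = counts.items
    if reference is None:
        reference = items.items[0]
    ref_idx = items.index(reference)
    m = len(items)
    free = [k for k in range(m) if k != ref_idx]
    col_of = {k: c for c, k in enumerate(free)}
    n_par = m  # m-1 worths + delta

    n = len(records)
    X = np.zeros((n, n_par))
    y = np.zeros(n)
    for r_idx, r in enumerate(records):
        i, j = items.index(r.first), items.index(r.second)
        if i != ref_idx:
            X[r_idx, col_of[i]] = 1.0
        if j != ref_idx:
            X[r_idx, col_of[j]] = -1.0
        X[r_idx, -1] = 1.0  # order dummy: always "first tasted first"
        y[r_idx] = 1.0 if r.winner_was_first else 0.0

    theta = np.zeros(n_par)

    def loglik(t):
        eta = X @ t
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    ll = loglik(theta)
    trace = [ll]
    for it in range(1, max_iter + 1):
        p = expit(X @ theta)
        grad = X.T @ (y - p)
        Wd = p * (1.0 - p)
        H = X.T @ (X * Wd[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "separation: singular information matrix in order-effect fit")
        scale = 1.0
        for _ in range(50):
            cand = theta + scale * step
            ll_new = loglik(cand)
            if ll_new >= ll - 1e-14:
                break
            scale *= 0.5
        theta, ll_prev, ll = cand, ll, ll_new
        trace.append(ll)
        if np.max(np.abs(theta)) > MAX_ABS_COEF:
            raise SeparationError(
                "separation: a coefficient diverged in the order-effect fit")
        if abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1e-12):
            break
    else:
        raise ConvergenceError(
            f"order-effect fit did not converge in {max_iter} iterations",
            trace)

    p = expit(X @ theta)
    Wd = p * (1.0 - p)
    H = X.T @ (X * Wd[:, None])
    covariance = np.linalg.inv(H)
    beta = np.zeros(m)
    for k, c in col_of.items():
        beta[k] = theta[c]
    return BTFit(items=items, reference=reference, beta=beta,
                 covariance=covariance, loglik=ll, n_obs=n,
                 order_coef=float(theta[-1]), algorithm="newton",
                 n_iter=it)


# --------------------------------------------------------------------------
# inference on a fitted model

def rereference(fit_result: BTFit, new_reference: str) -> BTFit:
    """Re-express a fit with a different reference item.

    Pure linear reparametrization: β'_k = β_k − β_new for all k, the
    covariance is mapped by the corresponding contrast matrix, and the
    log-likelihood is unchanged.  Numerically identical to refitting from
    scratch with the new reference.
    """
    items = fit_result.items
    new_idx = items.index(new_reference)  # validates the label
    m = len(items)
    has_order = fit_result.order_coef is not None
    k_full = m + (1 if has_order else 0)

    full_cov = fit_result.full_beta_covariance()
    new_free = [k for k in range(m) if k != new_idx]
    # rows: e_k - e_newref for each new free item; identity row for delta
    A = np.zeros((len(new_free) + (1 if has_order else 0), k_full))
    for r, k in enumerate(new_free):
        A[r, k] = 1.0
        A[r, new_idx] = -1.0
    if has_order:
        A[-1, m] = 1.0
    new_cov = A @ full_cov @ A.T

    new_beta = fit_result.beta - fit_result.beta[new_idx]
    return BTFit(items=items, reference=new_reference, beta=new_beta,
                 covariance=new_cov, loglik=fit_result.loglik,
                 n_obs=fit_result.n_obs, order_coef=fit_result.order_coef,
                 algorithm=fit_result.algorithm, n_iter=fit_result.n_iter)


def pairwise_table(fit_result: BTFit) -> PairwiseTable:
    """Two-sided Wald tests of every worth contrast β_i − β_j.

    The standard error of each contrast comes from the fitted covariance,
    so the table reproduces what one obtains by setting each item in turn
    as the reference category and reading off the coefficient tests.
    """
    items = fit_result.items
    m = len(items)
    full = fit_result.full_beta_covariance()[:m, :m]
    beta = fit_result.beta
    est = beta[:, None] - beta[None, :]
    var = np.diag(full)[:, None] + np.diag(full)[None, :] - 2.0 * full
    se = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * norm.sf(np.abs(z))
    np.fill_diagonal(est, 0.0)
    np.fill_diagonal(se, np.nan)
    np.fill_diagonal(p, np.nan)
    return PairwiseTable(items=items, estimates=est, std_errors=se, p_values=p)


def lrt_vs_null(counts: CountMatrices, reference: str | None = None) -> LRTResult:
    """Global likelihood-ratio test against the equal-worth null.

    Under the null every comparison is a fair coin, so the null
    log-likelihood is N·log(1/2) for N judgments.  The statistic
    2·(ℓ_full − ℓ_null) is referred to χ² with m−1 degrees of freedom.
    """
    fit_result = fit(counts, reference=reference)
    ll_null = counts.total * math.log(0.5)
    stat = max(0.0, 2.0 * (fit_result.loglik - ll_null))
    df = counts.n_items - 1
    return LRTResult(statistic=stat, df=df,
                     p_value=float(chi2.sf(stat, df)),
                     loglik_full=fit_result.loglik, loglik_null=ll_null)
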