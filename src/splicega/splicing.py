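"""Splicing local search with subset-size capping.

The splicing method maintains a partition of the feature indices into an
active set A (selected) and inactive set I, and repeatedly exchanges the
least valuable active features for the most promising inactive ones,
accepting an exchange only when the least-squares loss

    L = (1/2n) * ||Y - X_A beta_A||^2

drops.  Feature value is measured by two filter scores derived from the
change in L:

* backward sacrifice  xi_j  = (X_j'X_j / 2n) * beta_j^2        (cost of
  dropping active feature j),
* forward sacrifice   zeta_j = (X_j'X_j / 2n) * (d_j / (X_j'X_j/n))^2
  with d_j = X_j'(Y - X_A beta_A)/n                            (gain of
  adding inactive feature j).

This module adds the *del/add* cap: whenever |A| exceeds a user budget
``s_max``, the lowest-xi members of A are demoted to I before the swap
search begins, so the returned subset never exceeds ``s_max`` features.
The outer loop repeats swap sweeps until the improvement of one full sweep
falls below the threshold

    tau = tau_const * |A| * log(p) * log(log n) / n   (natural logs),

which shrinks with sample size and grows with dimension, so tiny
improvements on noisy high-dimensional data do not cause endless cycling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._exceptions import ConfigError, DegenerateFeatureError
from .individual import Individual


@dataclass
class SplicingConfig:
    """Tunables of the capped splicing search.

    Parameters
    ----------
    s_max:
        Maximal size of the returned active set (the subset-size budget).
    tau_const:
        Constant in the stopping threshold tau; 0.01 by default.
    k_max:
        Optional cap on the swap size searched per sweep (default: up to
        ``min(|A|, |I|)``).
    ridge_eps:
        Relative ridge penalty used when the active-set Gram matrix is
        singular or |A| >= n; scaled by the mean Gram diagonal.
    max_outer_iters:
        Safety cap on outer sweeps, guarding against threshold cycling
        from floating-point noise.
    standardize:
        Center and unit-scale feature columns (and center Y) internally
        before computing scores and losses; selection is reported on the
        original column indices either way.
    marginal_frac:
        When ``|A| >= marginal_frac * n`` the joint least-squares fit used
        to score the del step is underdetermined; marginal coefficients
        ``beta_j = X_j'Y / X_j'X_j`` are used for that step instead.
    """

    s_max: int
    tau_const: float = 0.01
    k_max: int | None = None
    ridge_eps: float = 1e-8
    max_outer_iters: int = 100
    standardize: bool = True
    marginal_frac: float = 0.9

    def __post_init__(self) -> None:
        if self.s_max < 1:
            raise ConfigError("s_max must be >= 1")
        if self.tau_const <= 0:
            raise ConfigError("tau_const must be > 0")
        if self.max_outer_iters < 1:
            raise ConfigError("max_outer_iters must be >= 1")


def fit_active(X_A: np.ndarray, Y: np.ndarray, ridge_eps: float = 1e-8) -> np.ndarray:
    """Least-squares coefficients for the active-set design X_A.

    Solves the normal equations; when X_A'X_A is singular (or |A| >= n,
    where it necessarily is), falls back to a ridge-stabilized solve with
    penalty ``ridge_eps`` scaled by the mean Gram diagonal.
    """
    X_A = np.asarray(X_A, dtype=float)
    Y = np.asarray(Y, dtype=float).ravel()
    if X_A.ndim != 2 or X_A.shape[1] == 0:
        raise ConfigError("fit_active requires at least one active column")
    n, m = X_A.shape
    gram = X_A.T @ X_A
    rhs = X_A.T @ Y
    if m < n and np.linalg.cond(gram) < 1e12:
        return np.linalg.solve(gram, rhs)
    scale = max(np.trace(gram) / m, 1.0)
    return np.linalg.solve(gram + ridge_eps * scale * np.eye(m), rhs)


def loss(X_A: np.ndarray, beta_A: np.ndarray, Y: np.ndarray, n: int) -> float:
    """Scaled residual sum of squares L = (1/2n)||Y - X_A beta_A||^2."""
    Y = np.asarray(Y, dtype=float).ravel()
    if np.size(beta_A) == 0:
        resid = Y
    else:
        resid = Y - np.asarray(X_A, dtype=float) @ np.asarray(beta_A, dtype=float)
    return float(resid @ resid) / (2.0 * n)


def backward_sacrifice(X_j: np.ndarray, beta_j: float, n: int) -> float:
    """Loss increase attributable to removing active feature j."""
    X_j = np.asarray(X_j, dtype=float).ravel()
    return float(X_j @ X_j) / (2.0 * n) * beta_j**2


def forward_sacrifice(X_j: np.ndarray, d_j: float, n: int) -> float:
    """Loss decrease attributable to adding inactive feature j.

    ``d_j = X_j'(Y - X_A beta_A)/n`` is the scaled residual correlation.
    """
    X_j = np.asarray(X_j, dtype=float).ravel()
    c = float(X_j @ X_j)
    if c <= 0.0:
        raise DegenerateFeatureError("zero-norm feature column")
    return c / (2.0 * n) * (d_j / (c / n)) ** 2


def threshold_tau(active_size: int, p: int, n: int, tau_const: float = 0.01) -> float:
    """Stopping threshold tau = tau_const * |A| log(p) log(log n) / n."""
    if n < 3:
        raise ConfigError("threshold requires n >= 3 so that log(log n) > 0")
    if p < 2:
        raise ConfigError("threshold requires p >= 2")
    if active_size == 0:
        return 0.0
    return tau_const * active_size * math.log(p) * math.log(math.log(n)) / n


def _column_norms2(X: np.ndarray, cols: np.ndarray) -> np.ndarray:
    sub = X[:, cols]
    return np.einsum("ij,ij->j", sub, sub)


def _backward_scores(X: np.ndarray, active: np.ndarray, beta: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    return _column_norms2(X, active) / (2.0 * n) * np.asarray(beta) ** 2


def _forward_scores(X: np.ndarray, inactive: np.ndarray, d: np.ndarray) -> np.ndarray:
    # vectorized forward sacrifice; zero-norm columns score 0 (never added)
    n = X.shape[0]
    c = _column_norms2(X, inactive)
    out = np.zeros_like(c)
    ok = c > 0
    out[ok] = n * np.asarray(d)[ok] ** 2 / (2.0 * c[ok])
    return out


@dataclass
class SplicingState:
    """Partition (A, I) with the fitted quantities the sweep needs.

    ``beta`` are the least-squares coefficients over A, ``d`` the scaled
    residual correlations over I, ``loss_`` the current loss L.
    """

    active: np.ndarray
    inactive: np.ndarray
    beta: np.ndarray
    d: np.ndarray
    loss_: float

    @classmethod
    def from_support(
        cls,
        support: Sequence[int] | np.ndarray,
        X: np.ndarray,
        Y: np.ndarray,
        ridge_eps: float = 1e-8,
    ) -> "SplicingState":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float).ravel()
        n, q = X.shape
        active = np.asarray(sorted(support), dtype=int)
        mask = np.zeros(q, dtype=bool)
        mask[active] = True
        inactive = np.flatnonzero(~mask)
        if active.size:
            beta = fit_active(X[:, active], Y, ridge_eps)
            resid = Y - X[:, active] @ beta
        else:
            beta = np.empty(0)
            resid = Y
        d = X[:, inactive].T @ resid / n
        return cls(active, inactive, beta, d, float(resid @ resid) / (2.0 * n))

    @property
    def loss(self) -> float:
        return self.loss_


def del_add(
    state: SplicingState,
    scores: np.ndarray,
    s_max: int,
    X: np.ndarray,
    Y: np.ndarray,
    ridge_eps: float = 1e-8,
) -> SplicingState:
    """Demote the lowest-scoring active features until ``|A| <= s_max``.

    ``scores`` are backward sacrifices aligned with ``state.active``; ties
    are broken toward demoting the lowest feature index.  Demoted features
    join the inactive set; the fitted quantities are recomputed.
    """
    active = state.active
    if active.size <= s_max:
        return state
    if len(scores) != active.size:
        raise ConfigError("one score per active feature required")
    order = np.lexsort((active, np.asarray(scores, dtype=float)))
    keep = active[order[active.size - s_max :]]
    return SplicingState.from_support(keep, X, Y, ridge_eps)


def splice_sweep(
    state: SplicingState,
    X: np.ndarray,
    Y: np.ndarray,
    k_range: Iterable[int] | None = None,
    ridge_eps: float = 1e-8,
    trace: list[float] | None = None,
) -> SplicingState:
    """One swap sweep over ascending exchange sizes k.

    The sacrifice scores are computed once from the entering state and held
    fixed; for each k the candidate exchanges the k lowest-xi members of
    the entering active set for the k highest-zeta members of the entering
    inactive set, and replaces the current state iff its loss is strictly
    lower.  Values of k exceeding ``min(|A|, |I|)`` are skipped.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float).ravel()
    base_A, base_I = state.active, state.inactive
    limit = min(base_A.size, base_I.size)
    if limit == 0:
        return state
    xi = _backward_scores(X, base_A, state.beta)
    zeta = _forward_scores(X, base_I, state.d)
    low_xi = base_A[np.lexsort((base_A, xi))]          # ascending xi
    high_zeta = base_I[np.lexsort((base_I, -zeta))]    # descending zeta
    ks = range(1, limit + 1) if k_range is None else sorted(set(k_range))
    current = state
    base_set = set(base_A.tolist())
    for k in ks:
        if k < 1 or k > limit:
            continue
        candidate = (base_set - set(low_xi[:k].tolist())) | set(
            high_zeta[:k].tolist()
        )
        cand_state = SplicingState.from_support(candidate, X, Y, ridge_eps)
        if cand_state.loss < current.loss:
            current = cand_state
            if trace is not None:
                trace.append(cand_state.loss)
    return current


@dataclass
class SpliceInfo:
    """Diagnostics of one ``improved_splice`` run."""

    loss: float
    tau: float
    n_sweeps: int
    accepted_losses: list[float] = field(default_factory=list)


def _del_scores(
    X: np.ndarray, Y: np.ndarray, support: np.ndarray, config: SplicingConfig
) -> np.ndarray:
    """Backward sacrifices used by the size cap.

    With very large active sets (|A| close to or above n) the joint fit is
    underdetermined, so marginal coefficients rank the features instead.
    """
    n = X.shape[0]
    c = _column_norms2(X, support)
    if support.size >= config.marginal_frac * n:
        xty = X[:, support].T @ Y
        beta = np.divide(xty, c, out=np.zeros_like(xty), where=c > 0)
    else:
        beta = fit_active(X[:, support], Y, config.ridge_eps)
    return c / (2.0 * n) * beta**2


def improved_splice(
    individual: Individual,
    X: np.ndarray,
    Y: np.ndarray,
    config: SplicingConfig,
    full_output: bool = False,
) -> Individual | tuple[Individual, SpliceInfo]:
    """Improve a feature subset by capped splicing.

    Segments the individual into (A, I); caps A at ``config.s_max`` via the
    del/add step; then repeats swap sweeps until a full sweep improves the
    loss by less than tau (or ``max_outer_iters`` is hit) and merges the
    final partition back into a bit vector.  The output active set never
    exceeds ``s_max`` and its loss never exceeds the capped starting loss.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float).ravel()
    n, q = X.shape
    if individual.q != q:
        raise ConfigError("individual length does not match feature count")
    if config.standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xw = (X - mu) / sd
        Yw = Y - Y.mean()
    else:
        Xw, Yw = X, Y

    support = individual.active
    if support.size > config.s_max:
        scores = _del_scores(Xw, Yw, support, config)
        order = np.lexsort((support, scores))
        support = support[order[support.size - config.s_max :]]
    state = SplicingState.from_support(support, Xw, Yw, config.ridge_eps)

    tau = threshold_tau(state.active.size, q, n, config.tau_const)
    accepted: list[float] = []
    n_sweeps = 0
    if min(state.active.size, state.inactive.size) > 0:
        for _ in range(config.max_outer_iters):
            L0 = state.loss
            k_range = None
            if config.k_max is not None:
                k_range = range(1, config.k_max + 1)
            state = splice_sweep(
                state, Xw, Yw, k_range, config.ridge_eps, trace=accepted
            )
            n_sweeps += 1
            if L0 - state.loss < tau:
                break

    out = Individual.from_support(state.active, q)
    if full_output:
        return out, SpliceInfo(state.loss, tau, n_sweeps, accepted)
    return out


def subset_loss(
    X: np.ndarray, Y: np.ndarray, support: Sequence[int], ridge_eps: float = 1e-8
) -> float:
    """Least-squares loss of an arbitrary support (helper for comparisons)."""
    return SplicingState.from_support(support, X, Y, ridge_eps).loss
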