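"""Similarity fusion by alternating minimization.

The fused similarity matrix is a convex combination ``sum_l alpha_l S_l``
of the per-view similarity matrices, with the weight vector ``alpha``
learned rather than set by hand.  The objective is

    min_{alpha, V, H}  sum_l alpha_l C(P_l || V H^T)  -  eta * H(alpha)
    s.t.  sum(alpha) = 1,  alpha >= 0,  V, H >= 0

where ``P_l`` is the normalized stochastic form of view ``l``,
``C(P||Q) = -sum p log q`` is the cross-entropy, ``H(alpha)`` is the
entropy of the weights, and ``eta > 0`` trades sparseness of the weights
against informativeness: as eta -> 0 all weight concentrates on the
single best-fitting view; as eta -> infinity the weights become uniform.

The two alternating steps are

1. factorization: with alpha fixed, minimize the cross-entropy by a
   rank-k nonnegative factorization Q = V H^T of the weighted average
   matrix P_bar = sum_l alpha_l P_l (cross-entropy is linear in its
   first argument, so sum_l alpha_l C(P_l||Q) = C(P_bar||Q)), via
   multiplicative EM-type updates;
2. weight update: with the per-view cross-entropies ce_l = C(P_l||Q)
   fixed, the entropy-regularized linear program over the simplex has
   the closed-form minimizer alpha_l proportional to exp(-ce_l / eta).

Each step never increases the objective, so the outer trace is
monotone.  The factorization is non-convex in (V, H); ``fuse`` restarts
from several seeded random initializations and keeps the best final
objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .views import SimilarityView

LOG_FLOOR = 1e-12

__all__ = [
    "FusionConfig",
    "FusionWeights",
    "FactorizationModel",
    "FusionResult",
    "cross_entropy",
    "weight_entropy",
    "fit_factorization",
    "optimize_weights",
    "fuse",
]


@dataclass
class FusionConfig:
    """Tunable parameters of the alternating minimization."""

    eta: float = 3.0
    k: int = 6
    max_outer: int = 100
    max_em: int = 1000
    tol_objective: float = 1e-8
    tol_alpha: float = 1e-6
    seed: int = 0
    n_restarts: int = 5

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.k < 1:
            raise ValueError("factorization rank k must be >= 1")
        if self.max_outer < 1 or self.max_em < 1 or self.n_restarts < 1:
            raise ValueError("iteration caps and restart count must be >= 1")


@dataclass
class FusionWeights:
    alpha: np.ndarray
    cross_entropies: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.cross_entropies = np.asarray(self.cross_entropies, dtype=float)
        if self.alpha.min() < 0 or abs(self.alpha.sum() - 1.0) > 1e-12:
            raise ValueError("alpha must be nonnegative and sum to 1")


@dataclass
class FactorizationModel:
    """Rank-k nonnegative factorization Q = V H^T on the probability simplex."""

    V: np.ndarray
    H: np.ndarray
    k: int
    objective_trace: list[float] = field(default_factory=list)

    @property
    def Q(self) -> np.ndarray:
        return self.V @ self.H.T

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]


@dataclass
class FusionResult:
    weights: FusionWeights
    model: FactorizationModel
    view_names: list[str]
    compound_ids: list[str]
    fused_S: np.ndarray
    fused_P: np.ndarray
    trace: list[float]
    converged: bool
    seed: int

    @property
    def alpha(self) -> np.ndarray:
        return self.weights.alpha

    def fused_frame(self):
        import pandas as pd

        return pd.DataFrame(self.fused_S, index=self.compound_ids, columns=self.compound_ids)


def cross_entropy(P: np.ndarray, Q: np.ndarray, eps: float = LOG_FLOOR) -> float:
    """C(P||Q) = -sum p log q, natural log, q floored at eps.

    For P on the probability simplex this is bounded below by the
    entropy of P (Gibbs' inequality), with equality iff Q = P.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {Q.shape}")
    return float(-(P * np.log(np.maximum(Q, eps))).sum())


def weight_entropy(alpha: np.ndarray) -> float:
    """Shannon entropy -sum a log a of a simplex vector (0 log 0 := 0)."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.min() < 0 or abs(alpha.sum() - 1.0) > 1e-9:
        raise ValueError("alpha must be a probability vector")
    pos = alpha[alpha > 0]
    return float(-(pos * np.log(pos)).sum())


def _init_factors(n: int, k: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    V = rng.uniform(0.1, 1.0, size=(n, k))
    H = rng.uniform(0.1, 1.0, size=(n, k))
    s = (V @ H.T).sum()
    V /= s
    return V, H


def fit_factorization(
    P_bar: np.ndarray,
    k: int,
    seed: int | np.random.Generator = 0,
    max_em: int = 1000,
    tol: float = 1e-8,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> FactorizationModel:
    """Minimize C(P_bar || V H^T) over nonnegative rank-k factors.

    Uses the multiplicative updates for the KL-divergence NMF objective;
    after each sweep the product is rescaled onto the probability
    simplex (the exact minimizer along the scaling direction), under
    which minimizing the generalized KL divergence coincides with
    minimizing the cross-entropy.  The recorded objective trace is
    non-increasing up to floating-point error.
    """
    P_bar = np.asarray(P_bar, dtype=float)
    n = P_bar.shape[0]
    if P_bar.ndim != 2 or P_bar.shape[1] != n:
        raise ValueError("P_bar must be square")
    if P_bar.min() < 0 or abs(P_bar.sum() - 1.0) > 1e-6:
        raise ValueError("P_bar must be nonnegative and sum to 1")
    if not 1 <= k <= n:
        raise ValueError(f"rank k={k} must lie in [1, n={n}]")

    if init is not None:
        V, H = np.array(init[0], dtype=float), np.array(init[1], dtype=float)
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        V, H = _init_factors(n, k, rng)

    trace: list[float] = [cross_entropy(P_bar, V @ H.T)]
    for it in range(max_em):
        Q = np.maximum(V @ H.T, LOG_FLOOR)
        V = V * ((P_bar / Q) @ H) / np.maximum(H.sum(axis=0), LOG_FLOOR)
        Q = np.maximum(V @ H.T, LOG_FLOOR)
        H = H * ((P_bar.T / Q.T) @ V) / np.maximum(V.sum(axis=0), LOG_FLOOR)
        s = (V @ H.T).sum()
        V /= s
        obj = cross_entropy(P_bar, V @ H.T)
        if not np.isfinite(obj):
            raise FloatingPointError(f"non-finite objective at EM iteration {it}")
        prev = trace[-1]
        trace.append(obj)
        if abs(prev - obj) <= tol * max(abs(prev), 1.0):
            break
    return FactorizationModel(V=V, H=H, k=k, objective_trace=trace)


def optimize_weights(ce: np.ndarray, eta: float) -> FusionWeights:
    """Exact minimizer of sum_l a_l ce_l - eta H(a) over the simplex.

    The solution is the softmax alpha_l = exp(-ce_l/eta) / sum_m
    exp(-ce_m/eta), computed with the usual max-shift so small eta
    cannot underflow.
    """
    ce = np.asarray(ce, dtype=float)
    if not np.isfinite(ce).all():
        raise ValueError("cross-entropies must be finite")
    if eta <= 0:
        raise ValueError("eta must be positive")
    z = -ce / eta
    z -= z.max()
    w = np.exp(z)
    alpha = w / w.sum()
    return FusionWeights(alpha=alpha, cross_entropies=ce)


def _check_aligned(views: list[SimilarityView]) -> None:
    if len(views) < 2:
        raise ValueError("fusion needs at least 2 views")
    ref = views[0].compound_ids
    for v in views[1:]:
        if v.compound_ids != ref:
            diff = set(v.compound_ids) ^ set(ref)
            if diff:
                raise ValueError(
                    f"views cover different compound sets; symmetric difference: {sorted(diff)}"
                )
            raise ValueError("views list compounds in different orders")


def fuse(views: list[SimilarityView], config: FusionConfig | None = None) -> FusionResult:
    """Learn fusion weights over >=2 views and return the fused matrix.

    Alternates the factorization and weight steps from alpha uniform
    until ``max |delta alpha| < tol_alpha``, the relative objective
    change drops below ``tol_objective``, or ``max_outer`` is reached.
    The factorization warm-starts across outer iterations within one
    restart, which keeps the outer objective trace monotone; the best of
    ``n_restarts`` independent runs (by final objective) is returned.

    ``fused_S`` is the convex combination of the *original* similarity
    matrices; ``fused_P`` combines the normalized forms with the same
    weights.
    """
    if config is None:
        config = FusionConfig()
    _check_aligned(views)
    L = len(views)
    P_list = [v.P for v in views]
    S_list = [v.S for v in views]

    best: tuple[float, FusionWeights, FactorizationModel, list[float], bool] | None = None
    for r in range(config.n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, r]))
        alpha = np.full(L, 1.0 / L)
        model: FactorizationModel | None = None
        trace: list[float] = []
        converged = False
        for _ in range(config.max_outer):
            P_bar = sum(a * P for a, P in zip(alpha, P_list))
            init = (model.V, model.H) if model is not None else None
            model = fit_factorization(
                P_bar,
                config.k,
                seed=rng,
                max_em=config.max_em,
                tol=config.tol_objective,
                init=init,
            )
            Q = model.Q
            ce = np.array([cross_entropy(P, Q) for P in P_list])
            weights = optimize_weights(ce, config.eta)
            new_alpha = weights.alpha
            obj = float(new_alpha @ ce - config.eta * weight_entropy(new_alpha))
            prev_obj = trace[-1] if trace else np.inf
            trace.append(obj)
            delta = float(np.abs(new_alpha - alpha).max())
            alpha = new_alpha
            if delta < config.tol_alpha or (
                np.isfinite(prev_obj)
                and abs(prev_obj - obj) <= config.tol_objective * max(abs(prev_obj), 1.0)
            ):
                converged = True
                break
        assert model is not None
        if best is None or trace[-1] < best[0]:
            best = (trace[-1], weights, model, trace, converged)

    _, weights, model, trace, converged = best
    fused_S = sum(a * S for a, S in zip(weights.alpha, S_list))
    fused_P = sum(a * P for a, P in zip(weights.alpha, P_list))
    return FusionResult(
        weights=weights,
        model=model,
        view_names=[v.name for v in views],
        compound_ids=list(views[0].compound_ids),
        fused_S=np.asarray(fused_S),
        fused_P=np.asarray(fused_P),
        trace=trace,
        converged=converged,
        seed=config.seed,
    )
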