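"""(mu/mu_w, lambda) covariance matrix adaptation evolution strategy.

A self-contained ask/tell implementation of the standard CMA-ES with
log-decreasing recombination weights, cumulative step-size adaptation and
rank-1 + rank-mu covariance updates, using the canonical published default
learning rates as functions of the problem dimension.  Minimization
convention throughout.  Fully deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np


class CmaesError(ValueError):
    pass


@dataclass(frozen=True)
class CmaesConfig:
    """Hyperparameters: sigma0 (initial step size), lam (offspring), mu (parents)."""

    sigma0: float = 0.032
    lam: int = 70
    mu: int = 35
    seed: int = 0
    max_generations: int = 150
    recombination_weights: str = "log"

    def __post_init__(self):
        if self.sigma0 <= 0:
            raise CmaesError(f"sigma0 must be > 0, got {self.sigma0}")
        if self.lam < 2:
            raise CmaesError(f"lam must be >= 2, got {self.lam}")
        if not (1 <= self.mu <= self.lam):
            raise CmaesError(f"mu must be in [1, lam], got {self.mu}")
        if self.recombination_weights not in ("log", "equal"):
            raise CmaesError(
                f"unknown recombination rule {self.recombination_weights!r}"
            )


@dataclass
class CmaesState:
    config: CmaesConfig
    mean: np.ndarray
    sigma: float
    C: np.ndarray
    p_sigma: np.ndarray
    p_c: np.ndarray
    generation: int
    rng: np.random.Generator
    weights: np.ndarray
    mu_eff: float
    c_sigma: float
    d_sigma: float
    c_c: float
    c_1: float
    c_mu: float
    chi_n: float
    best_solution: Optional[np.ndarray] = None
    best_fitness: float = math.inf
    _eig_B: Optional[np.ndarray] = None
    _eig_d: Optional[np.ndarray] = None
    _last_ask: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return self.mean.size


def _recombination_weights(config: CmaesConfig) -> np.ndarray:
    mu = config.mu
    if config.recombination_weights == "equal":
        w = np.full(mu, 1.0 / mu)
    else:
        w = np.log((config.lam + 1) / 2.0) - np.log(np.arange(1, mu + 1))
        w = w / w.sum()
    return w


def cmaes_init(x0: Sequence[float], config: CmaesConfig) -> CmaesState:
    """Initialize the search distribution at x0 with identity covariance."""
    mean = np.asarray(x0, dtype=float).copy()
    if mean.ndim != 1 or mean.size < 1:
        raise CmaesError("x0 must be a non-empty 1-D vector")
    if not np.isfinite(mean).all():
        raise CmaesError("x0 must be finite")
    n = mean.size
    w = _recombination_weights(config)
    mu_eff = 1.0 / float(w @ w)
    c_sigma = (mu_eff + 2) / (n + mu_eff + 5)
    d_sigma = 1 + 2 * max(0.0, math.sqrt((mu_eff - 1) / (n + 1)) - 1) + c_sigma
    c_c = (4 + mu_eff / n) / (n + 4 + 2 * mu_eff / n)
    c_1 = 2 / ((n + 1.3) ** 2 + mu_eff)
    c_mu = min(1 - c_1, 2 * (mu_eff - 2 + 1 / mu_eff) / ((n + 2) ** 2 + mu_eff))
    chi_n = math.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n * n))
    return CmaesState(
        config=config,
        mean=mean,
        sigma=config.sigma0,
        C=np.eye(n),
        p_sigma=np.zeros(n),
        p_c=np.zeros(n),
        generation=0,
        rng=np.random.default_rng(config.seed),
        weights=w,
        mu_eff=mu_eff,
        c_sigma=c_sigma,
        d_sigma=d_sigma,
        c_c=c_c,
        c_1=c_1,
        c_mu=c_mu,
        chi_n=chi_n,
    )


def _eigen(state: CmaesState) -> Tuple[np.ndarray, np.ndarray]:
    if state._eig_B is None:
        C = (state.C + state.C.T) / 2.0
        vals, B = np.linalg.eigh(C)
        floor = 1e-14 * np.trace(C) / state.n
        vals = np.maximum(vals, max(floor, 1e-300))
        if not np.isfinite(vals).all():
            raise CmaesError("covariance eigendecomposition failed")
        state._eig_B = B
        state._eig_d = np.sqrt(vals)
    return state._eig_B, state._eig_d


def cmaes_ask(state: CmaesState) -> List[np.ndarray]:
    """Sample lambda candidates mean + sigma * N(0, C)."""
    B, d = _eigen(state)
    z = state.rng.standard_normal((state.config.lam, state.n))
    y = (z * d) @ B.T
    x = state.mean + state.sigma * y
    state._last_ask = x
    return [x[k].copy() for k in range(state.config.lam)]


def cmaes_tell(
    state: CmaesState,
    candidates: Sequence[np.ndarray],
    fitnesses: Sequence[float],
) -> CmaesState:
    """Rank-and-update step (minimization); mutates and returns the state."""
    lam = state.config.lam
    if len(candidates) != lam or len(fitnesses) != lam:
        raise CmaesError(f"expected {lam} candidates and fitnesses")
    fit = np.asarray(fitnesses, dtype=float)
    if np.isnan(fit).any():
        raise CmaesError(f"NaN fitness for candidate {int(np.argmax(np.isnan(fit)))}")
    xs = np.asarray(candidates, dtype=float)
    order = np.argsort(fit, kind="stable")
    mu = state.config.mu
    w = state.weights
    sel = xs[order[:mu]]

    old_mean = state.mean
    y_sel = (sel - old_mean) / state.sigma
    y_w = w @ y_sel
    new_mean = old_mean + state.sigma * y_w

    B, d = _eigen(state)
    c_inv_sqrt_yw = B @ ((B.T @ y_w) / d)
    g = state.generation + 1
    state.p_sigma = (1 - state.c_sigma) * state.p_sigma + math.sqrt(
        state.c_sigma * (2 - state.c_sigma) * state.mu_eff
    ) * c_inv_sqrt_yw
    ps_norm = float(np.linalg.norm(state.p_sigma))
    h_sigma = ps_norm / math.sqrt(
        1 - (1 - state.c_sigma) ** (2 * g)
    ) < (1.4 + 2 / (state.n + 1)) * state.chi_n
    state.p_c = (1 - state.c_c) * state.p_c + (
        math.sqrt(state.c_c * (2 - state.c_c) * state.mu_eff) * y_w
        if h_sigma
        else 0.0
    )
    rank_mu = (y_sel * w[:, None]).T @ y_sel
    delta_h = (1 - int(h_sigma)) * state.c_c * (2 - state.c_c)
    state.C = (
        (1 - state.c_1 - state.c_mu) * state.C
        + state.c_1 * (np.outer(state.p_c, state.p_c) + delta_h * state.C)
        + state.c_mu * rank_mu
    )
    state.C = (state.C + state.C.T) / 2.0
    state.sigma = state.sigma * math.exp(
        (state.c_sigma / state.d_sigma) * (ps_norm / state.chi_n - 1)
    )
    state.mean = new_mean
    state.generation = g
    state._eig_B = None
    state._eig_d = None

    gen_best = int(order[0])
    if fit[gen_best] < state.best_fitness:
        state.best_fitness = float(fit[gen_best])
        state.best_solution = xs[gen_best].copy()
    return state


@dataclass(frozen=True)
class GenerationRecord:
    generation: int
    best_fitness: float
    median_fitness: float
    sigma: float


def minimize(
    f: Callable[[np.ndarray], float],
    x0: Sequence[float],
    config: CmaesConfig,
    ftarget: Optional[float] = None,
) -> Tuple[np.ndarray, float, List[GenerationRecord]]:
    """Ask/evaluate/tell loop; returns (best solution, best fitness, history)."""
    state = cmaes_init(x0, config)
    history: List[GenerationRecord] = []
    for gen in range(config.max_generations):
        candidates = cmaes_ask(state)
        try:
            fits = [float(f(c)) for c in candidates]
        except Exception as exc:
            raise CmaesError(f"cost evaluation failed at generation {gen}: {exc}") from exc
        cmaes_tell(state, candidates, fits)
        history.append(
            GenerationRecord(
                generation=state.generation,
                best_fitness=float(min(fits)),
                median_fitness=float(np.median(fits)),
                sigma=state.sigma,
            )
        )
        if ftarget is not None and state.best_fitness <= ftarget:
            break
    return state.best_solution, state.best_fitness, history
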