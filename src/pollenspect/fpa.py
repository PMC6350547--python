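"""Flower pollination algorithm (FPA) for per-minibatch learning-rate search.

FPA maintains a population of m candidate learning rates ("pollens") on a
bounded interval.  Each iteration, every pollen performs either

* cross-pollination (with probability P_C): a Lévy-flight move toward the
  global best,    l_i ← l_i + γ·L·(l_best − l_i),   L ~ Lévy(exponent 1.5);
* self-pollination (otherwise): a local move along the difference of two
  random population members,   l_i ← l_i + ε·(l_1 − l_2),   ε ~ U[0, 1].

Candidates are clamped to the bounds and accepted greedily (only when the
fitness — here, the post-update minibatch loss — improves).  Seeding the
initial population with the incumbent learning rate makes the returned rate
provably no worse than the incumbent on the current minibatch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["FPAConfig", "FPAState", "FPAResult", "levy_sample",
           "cross_pollinate", "self_pollinate", "optimize_learning_rate"]


@dataclass
class FPAConfig:
    n_iterations: int = 10
    n_pollen: int = 10
    switch_prob: float = 0.8
    gamma: float = 0.1
    levy_exponent: float = 1.5
    lr_min: float = 1e-4
    lr_max: float = 0.5
    every_k_steps: int = 1

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.n_pollen < 2:
            raise ValueError("n_pollen must be >= 2")
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ValueError("switch_prob must lie in [0, 1]")
        if not 1.0 < self.levy_exponent <= 2.0:
            raise ValueError("levy_exponent must lie in (1, 2]")
        if not 0.0 < self.lr_min < self.lr_max:
            raise ValueError("require 0 < lr_min < lr_max")

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lr_min, self.lr_max)


@dataclass
class FPAState:
    pollens: np.ndarray
    fitnesses: np.ndarray
    l_best: float
    f_best: float


@dataclass
class FPAResult:
    l_best: float
    f_best: float
    trace: list[float] = field(default_factory=list)
    f_incumbent: float | None = None
    n_evaluations: int = 0


def levy_sample(exponent: float, rng: np.random.Generator) -> float:
    """One heavy-tailed step via Mantegna's algorithm.

    L = u / |v|^(1/beta) with u ~ N(0, sigma_u^2), v ~ N(0, 1) and sigma_u the
    Mantegna scale for tail exponent beta.
    """
    if not 1.0 < exponent <= 2.0:
        raise ValueError(f"levy exponent must lie in (1, 2], got {exponent}")
    beta = exponent
    sigma_u = (math.gamma(1 + beta) * math.sin(math.pi * beta / 2)
               / (math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2))) ** (1 / beta)
    u = rng.normal(0.0, sigma_u)
    v = rng.normal(0.0, 1.0)
    return u / abs(v) ** (1.0 / beta)


def _clamp(x: float, bounds: tuple[float, float] | None) -> float:
    if bounds is None:
        return x
    return min(max(x, bounds[0]), bounds[1])


def cross_pollinate(l_i: float, l_best: float, gamma: float, rng: np.random.Generator,
                    bounds: tuple[float, float] | None = None,
                    levy_exponent: float = 1.5) -> float:
    """Global move: l_i + gamma * L * (l_best - l_i), clamped to bounds."""
    if not (math.isfinite(l_i) and math.isfinite(l_best)):
        raise ValueError("learning rates must be finite")
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    step = levy_sample(levy_exponent, rng)
    return _clamp(l_i + gamma * step * (l_best - l_i), bounds)


def self_pollinate(l_i: float, l_1: float, l_2: float, rng: np.random.Generator,
                   bounds: tuple[float, float] | None = None) -> float:
    """Local move: l_i + eps * (l_1 - l_2) with eps ~ U[0, 1], clamped."""
    if not all(map(math.isfinite, (l_i, l_1, l_2))):
        raise ValueError("learning rates must be finite")
    eps = rng.uniform(0.0, 1.0)
    return _clamp(l_i + eps * (l_1 - l_2), bounds)


def optimize_learning_rate(fitness, config: FPAConfig, rng: np.random.Generator,
                           incumbent_lr: float | None = None) -> FPAResult:
    """Minimize ``fitness`` over [lr_min, lr_max] with greedy FPA.

    The population is initialized uniformly on the interval; when an incumbent
    learning rate is supplied it replaces the first pollen, which (with greedy
    acceptance) guarantees f_best <= fitness(incumbent).
    """
    lo, hi = config.bounds
    m = config.n_pollen
    pollens = rng.uniform(lo, hi, size=m)
    if incumbent_lr is not None:
        pollens[0] = _clamp(float(incumbent_lr), config.bounds)

    n_eval = 0

    def safe_fitness(lr: float) -> float:
        nonlocal n_eval
        n_eval += 1
        f = float(fitness(lr))
        if not math.isfinite(f):
            warnings.warn(f"non-finite fitness at learning rate {lr:.3g}; "
                          "candidate rejected", stacklevel=3)
            return math.inf
        return f

    fitnesses = np.array([safe_fitness(l) for l in pollens])
    if not np.any(np.isfinite(fitnesses)):
        raise RuntimeError("fitness is non-finite across the whole initial population")
    f_incumbent = float(fitnesses[0]) if incumbent_lr is not None else None

    best_idx = int(np.argmin(fitnesses))
    l_best, f_best = float(pollens[best_idx]), float(fitnesses[best_idx])
    trace: list[float] = []

    for _ in range(config.n_iterations):
        for i in range(m):
            if rng.uniform() <= config.switch_prob:
                cand = cross_pollinate(pollens[i], l_best, config.gamma, rng,
                                       config.bounds, config.levy_exponent)
            else:
                j, k = rng.integers(m), rng.integers(m)
                cand = self_pollinate(pollens[i], pollens[j], pollens[k], rng,
                                      config.bounds)
            f_cand = safe_fitness(cand)
            if f_cand < fitnesses[i]:  # greedy acceptance
                pollens[i], fitnesses[i] = cand, f_cand
                if f_cand < f_best:
                    l_best, f_best = float(cand), float(f_cand)
        trace.append(f_best)

    return FPAResult(l_best, f_best, trace, f_incumbent, n_eval)
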