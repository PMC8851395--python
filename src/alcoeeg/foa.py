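"""Fruit-fly optimization (FOA) of the SVM hyperparameters (Z, gamma).

Each fly carries one planar position per tuned parameter.  A *smell* phase
perturbs every position by a uniform random step, computes the distance to
the origin ``Dist = sqrt(X^2 + Y^2)`` and the smell concentration judgment
value ``d = 1/Dist``, decodes ``d`` into a parameter value on a log2 scale,
and evaluates the fitness (here: cross-validated classifier accuracy).  A
*vision* phase relocates the whole swarm to the best position found so far
(elitist), so the best-so-far fitness history is non-decreasing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["FOAConfig", "FlySwarm", "FOAResult", "init_swarm", "smell_phase",
           "decode_params", "vision_phase", "optimize"]

logger = logging.getLogger(__name__)

N_PARAMS = 2  # (Z, gamma)


@dataclass
class FOAConfig:
    """Swarm and decode settings.

    The initial windows (ax, bx) and (ay, by) bound the X and Y coordinates
    of every fly (defaults 10, 20, 20, 10 — i.e. both coordinates start in
    [10, 20], giving Dist in [~14, ~28] and d in [~0.035, ~0.07]).  The
    decode maps d to an exponent ``e = clip(kappa d + lam, lo, hi)`` and the
    parameter to ``2^e``; the default exponent range [-10, 10] covers the
    classic 2^-10 .. 2^10 grid for both Z and gamma.
    """

    population: int = 20
    iterations: int = 100
    ax: float = 10.0
    bx: float = 20.0
    ay: float = 20.0
    by: float = 10.0
    step_scale: float = 1.0
    exponent_range: tuple = ((-10.0, 10.0), (-10.0, 10.0))
    kappa: float = 200.0
    lam: float = -10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 1 or self.iterations < 1:
            raise ValueError("population and iterations must be >= 1")
        for lo, hi in self.exponent_range:
            if lo >= hi:
                raise ValueError("exponent_range must have lo < hi")


@dataclass
class FlySwarm:
    positions: np.ndarray  # population x N_PARAMS x 2 (X, Y)
    d: np.ndarray | None = None  # population x N_PARAMS
    params: np.ndarray | None = None  # population x N_PARAMS (Z, gamma)
    fitness: np.ndarray | None = None  # population


@dataclass
class FOAResult:
    best_params: tuple  # (Z, gamma)
    best_fitness: float
    history: list  # per-iteration best-so-far fitness
    evaluations: int


def init_swarm(config: FOAConfig, rng: np.random.Generator | None = None) -> FlySwarm:
    """Positions drawn uniformly from the configured init windows."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    x_lo, x_hi = sorted((config.ax, config.bx))
    y_lo, y_hi = sorted((config.ay, config.by))
    pos = np.empty((config.population, N_PARAMS, 2))
    pos[:, :, 0] = rng.uniform(x_lo, x_hi, size=(config.population, N_PARAMS))
    pos[:, :, 1] = rng.uniform(y_lo, y_hi, size=(config.population, N_PARAMS))
    return FlySwarm(positions=pos)


def decode_params(d_values: np.ndarray, config: FOAConfig) -> tuple:
    """d -> parameter = 2^clip(kappa*d + lam, lo, hi), independently per parameter."""
    out = []
    for j, d in enumerate(np.asarray(d_values, dtype=float)):
        lo, hi = config.exponent_range[j]
        e = min(max(config.kappa * d + config.lam, lo), hi)
        out.append(2.0**e)
    return tuple(out)


def smell_phase(swarm: FlySwarm, config: FOAConfig, rng: np.random.Generator,
                fitness_fn=None) -> FlySwarm:
    """Perturb positions, compute d = 1/Dist, decode, evaluate each fly once."""
    pop = swarm.positions.shape[0]
    step = rng.uniform(-config.step_scale, config.step_scale,
                       size=swarm.positions.shape)
    pos = swarm.positions + step
    dist = np.linalg.norm(pos, axis=2)
    # a fly sitting exactly on the origin has no defined smell value
    for _ in range(100):
        zero = dist == 0
        if not zero.any():
            break
        logger.warning("re-perturbing %d fly position(s) at the origin", zero.sum())
        pos[zero] += rng.uniform(-config.step_scale, config.step_scale,
                                 size=(int(zero.sum()), 2))
        dist = np.linalg.norm(pos, axis=2)
    d = 1.0 / dist
    params = np.array([decode_params(d[i], config) for i in range(pop)])
    fitness = None
    if fitness_fn is not None:
        fitness = np.empty(pop)
        for i in range(pop):
            val = fitness_fn(*params[i])
            if not math.isfinite(val):
                logger.warning("non-finite fitness for params %s; treating as -inf",
                               params[i])
                val = -math.inf
            fitness[i] = val
    return FlySwarm(positions=pos, d=d, params=params, fitness=fitness)


def vision_phase(swarm: FlySwarm, best_so_far: dict | None = None) -> tuple[FlySwarm, dict]:
    """Relocate the swarm to the best position seen so far (elitist).

    Ties in the current swarm go to the lowest fly index; the returned elite
    record ``{positions, params, fitness}`` never worsens.
    """
    if swarm.fitness is None:
        raise ValueError("vision_phase requires an evaluated swarm")
    idx = int(np.argmax(swarm.fitness))  # argmax takes the lowest index on ties
    elite = {
        "positions": swarm.positions[idx].copy(),
        "params": tuple(swarm.params[idx]),
        "fitness": float(swarm.fitness[idx]),
    }
    if best_so_far is not None and best_so_far["fitness"] >= elite["fitness"]:
        elite = best_so_far
    new_pos = np.broadcast_to(elite["positions"], swarm.positions.shape).copy()
    return FlySwarm(positions=new_pos), elite


def optimize(fitness_fn, config: FOAConfig | None = None) -> FOAResult:
    """Run FOA: iterations of smell + vision; returns the elite parameters.

    ``fitness_fn(Z, gamma)`` must return a finite real (higher is better);
    non-finite values are demoted to -inf with a warning.
    """
    config = config or FOAConfig()
    rng = np.random.default_rng(config.seed)
    swarm = init_swarm(config, rng)
    best = None
    history = []
    evaluations = 0
    for _ in range(config.iterations):
        swarm = smell_phase(swarm, config, rng, fitness_fn)
        evaluations += swarm.positions.shape[0]
        swarm, best = vision_phase(swarm, best)
        history.append(best["fitness"])
    return FOAResult(
        best_params=best["params"],
        best_fitness=best["fitness"],
        history=history,
        evaluations=evaluations,
    )
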