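"""Particle swarm optimization of SVR hyperparameters (epsilon, C, phi).

Particles are parameter triples moving in a bounded box. Velocities follow

    v <- q*v + c1*r1*(p_best - x) + c2*r2*(g_best - x)

with per-dimension uniform draws r1, r2 and an inertia factor q decayed
linearly from ``q_max`` to ``q_min`` over the iterations. Velocities are
clamped to ``+-v_max`` and positions to the box. The fitness used for
deconvolution tuning is k-fold gene-holdout reconstruction RMSE.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .deconv_svr import (
    MixtureMatrix,
    SignatureMatrix,
    SvrParams,
    align_and_normalize,
    svr_solve,
)

logger = logging.getLogger(__name__)

FitnessFn = Callable[[np.ndarray], float]

#: default search box for (epsilon, C, phi)
DEFAULT_BOUNDS: tuple[tuple[float, float], ...] = ((0.0, 0.2), (1.0, 100.0), (0.01, 2.0))


@dataclass
class SwarmConfig:
    n_particles: int = 30
    n_iters: int = 100
    c1: float = 2.0
    c2: float = 2.0
    q_max: float = 0.9
    q_min: float = 0.4
    bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS
    v_max: Sequence[float] | None = None  # default 0.2 * (hi - lo) per dim
    seed: int = 0

    def __post_init__(self) -> None:
        if self.q_max < self.q_min:
            raise ValueError("q_max must be >= q_min")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"invalid bound ({lo}, {hi})")

    @property
    def lo(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds])

    @property
    def hi(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])

    @property
    def velocity_cap(self) -> np.ndarray:
        if self.v_max is not None:
            return np.asarray(self.v_max, dtype=float)
        return 0.2 * (self.hi - self.lo)


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    best_position: np.ndarray
    best_fitness: float


@dataclass
class SwarmResult:
    best_position: np.ndarray
    best_fitness: float
    history: list[float] = field(default_factory=list)


def inertia(iteration: int, config: SwarmConfig) -> float:
    """Linear decay of the inertia factor from q_max to q_min."""
    if config.n_iters < 2:
        return config.q_max
    if not 0 <= iteration < config.n_iters:
        raise ValueError(f"iteration {iteration} outside [0, {config.n_iters})")
    span = config.q_max - config.q_min
    return config.q_max - span * iteration / (config.n_iters - 1)


def _init_particle(rng: np.random.Generator, config: SwarmConfig, fitness: FitnessFn) -> Particle:
    pos = rng.uniform(config.lo, config.hi)
    fit = float(fitness(pos))
    return Particle(
        position=pos,
        velocity=np.zeros(len(config.bounds)),
        best_position=pos.copy(),
        best_fitness=fit,
    )


def step(
    swarm: list[Particle],
    g_best: np.ndarray,
    iteration: int,
    config: SwarmConfig,
    rng: np.random.Generator,
    fitness: FitnessFn,
) -> tuple[np.ndarray, float]:
    """One synchronous swarm update; returns the new global best.

    Per particle and dimension, r1 and r2 are fresh U[0,1] draws. Velocities
    are clamped to +-v_max and positions to the bounds, so every visited point
    stays inside the box. Non-finite fitness re-initializes the particle
    uniformly in bounds (logged) instead of poisoning the swarm.
    """
    q = inertia(iteration, config)
    v_cap = config.velocity_cap
    n_dim = len(config.bounds)
    for i, particle in enumerate(swarm):
        r1 = rng.uniform(size=n_dim)
        r2 = rng.uniform(size=n_dim)
        velocity = (
            q * particle.velocity
            + config.c1 * r1 * (particle.best_position - particle.position)
            + config.c2 * r2 * (g_best - particle.position)
        )
        velocity = np.clip(velocity, -v_cap, v_cap)
        position = np.clip(particle.position + velocity, config.lo, config.hi)
        fit = float(fitness(position))
        if not math.isfinite(fit):
            logger.warning("non-finite fitness at %s; re-initializing particle %d", position, i)
            replacement = _init_particle(rng, config, fitness)
            swarm[i] = replacement
            continue
        particle.position = position
        particle.velocity = velocity
        if fit < particle.best_fitness:
            particle.best_fitness = fit
            particle.best_position = position.copy()
    best = min(swarm, key=lambda p: p.best_fitness)
    return best.best_position.copy(), best.best_fitness


def optimize(fitness: FitnessFn, config: SwarmConfig | None = None) -> SwarmResult:
    """Run the swarm for ``n_iters`` iterations and return the global best.

    ``history`` records the best fitness after each iteration and is
    non-increasing. Runs are reproducible for a fixed ``config.seed``.
    """
    config = config or SwarmConfig()
    rng = np.random.default_rng(config.seed)
    swarm = [_init_particle(rng, config, fitness) for _ in range(config.n_particles)]
    best = min(swarm, key=lambda p: p.best_fitness)
    g_best, g_fit = best.best_position.copy(), best.best_fitness
    history: list[float] = []
    for iteration in range(config.n_iters):
        g_best, g_fit = step(swarm, g_best, iteration, config, rng, fitness)
        history.append(g_fit)
    return SwarmResult(best_position=g_best, best_fitness=g_fit, history=history)


def deconv_fitness_factory(
    X: MixtureMatrix,
    S: SignatureMatrix,
    k_folds: int = 5,
    seed: int = 0,
    max_samples: int | None = None,
) -> FitnessFn:
    """Gene-holdout cross-validated reconstruction RMSE as swarm fitness.

    Genes are split into ``k_folds`` shuffled folds (seeded); for each fold an
    SVR is fit per sample on the training genes and the held-out expression is
    reconstructed as S_heldout @ w. The fitness of a parameter triple is the
    RMSE pooled over folds and samples — deterministic for a fixed seed.
    ``max_samples`` caps the number of mixture columns used (speed knob for
    tuning; the first columns are taken, deterministically).
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    X_norm, S_norm = align_and_normalize(X, S)
    if max_samples is not None:
        X_norm = X_norm.iloc[:, :max_samples]
    n_genes, m = S_norm.shape
    if n_genes < k_folds:
        raise ValueError("need at least k_folds genes")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_genes)
    folds = np.array_split(perm, k_folds)
    for fold in folds:
        if len(perm) - len(fold) < m:
            raise ValueError("training fold smaller than the number of cell types")
    S_arr = S_norm.to_numpy()
    X_arr = X_norm.to_numpy()

    def fitness(position: np.ndarray) -> float:
        params = SvrParams(
            epsilon=float(position[0]), C=float(position[1]), phi=float(position[2])
        )
        sq_errors = []
        for fold in folds:
            mask = np.ones(n_genes, dtype=bool)
            mask[fold] = False
            S_train, S_test = S_arr[mask], S_arr[~mask]
            for j in range(X_arr.shape[1]):
                w = svr_solve(X_arr[mask, j], S_train, params)
                resid = X_arr[~mask, j] - S_test @ w
                sq_errors.append(np.mean(resid**2))
        return float(np.sqrt(np.mean(sq_errors)))

    return fitness


def tune_svr_params(
    X: MixtureMatrix,
    S: SignatureMatrix,
    config: SwarmConfig | None = None,
    k_folds: int = 5,
    max_samples: int | None = None,
) -> tuple[SvrParams, float, list[float]]:
    """Swarm-tune (epsilon, C, phi) for deconvolution of X against S.

    The penalty dimension is searched on a log scale internally (its range
    spans orders of magnitude) and reported on the natural scale.
    """
    config = config or SwarmConfig()
    eps_b, c_b, phi_b = config.bounds
    internal = SwarmConfig(
        n_particles=config.n_particles,
        n_iters=config.n_iters,
        c1=config.c1,
        c2=config.c2,
        q_max=config.q_max,
        q_min=config.q_min,
        bounds=(eps_b, (math.log(c_b[0]), math.log(c_b[1])), phi_b),
        v_max=config.v_max,
        seed=config.seed,
    )
    base_fitness = deconv_fitness_factory(
        X, S, k_folds=k_folds, seed=config.seed, max_samples=max_samples
    )

    def fitness(position: np.ndarray) -> float:
        natural = np.array([position[0], math.exp(position[1]), position[2]])
        return base_fitness(natural)

    result = optimize(fitness, internal)
    eps, log_c, phi = result.best_position
    params = SvrParams(epsilon=float(eps), C=float(math.exp(log_c)), phi=float(phi))
    return params, result.best_fitness, result.history
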