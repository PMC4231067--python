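"""Modified Cuckoo Search over the mixed SVM model-selection space.

Cuckoo Search explores with Levy flights — heavy-tailed random steps that mix
many small moves with rare long jumps — over a population of "nests", each
holding one candidate solution.  The Modified variant adds three mechanics:

* the Levy step size decays as A0 / sqrt(G) with generation G, shifting from
  exploration to exploitation;
* the top nests recombine pairwise, placing a new candidate at the golden
  ratio point on the line from the worse toward the better nest;
* a greedy elitist policy: replacements only ever happen when the candidate
  is better, so the generation-best fitness trace is monotone.

The search space is the unit hypercube [0, 1]^d with d = n_features + 3 m:
n_features relaxed binary mask genes (thresholded at 0.5) plus, per
one-against-others classifier, a kernel-kind gene, a kernel-parameter gene
and a penalty gene.  Multiplicative parameters (sigma, C) decode
log-uniformly; the polynomial degree u decodes log-uniformly and rounds to
an integer.  All randomness flows from one seeded generator, so a run is a
pure function of (data, config).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError
from .evaluation import accuracy_fitness, sv_count_fitness
from .genome import (
    C_LOG2_RANGE,
    KERNEL_KINDS,
    SIGMA_LOG2_RANGE,
    U_RANGE,
    ClassifierGenes,
    Genome,
)

GOLDEN_RATIO = (1 + math.sqrt(5)) / 2


@dataclass
class MCSConfig:
    """Search constants; the defaults follow common Modified Cuckoo Search usage."""

    n_nests: int = 25
    discard_fraction: float = 0.25
    top_fraction: float = 0.25
    max_generations: int = 100
    initial_step: float = 1.0  # A0; Levy scale at generation G is A0 / sqrt(G)
    local_step_factor: float = 0.3  # top-nest local walk scale is this * A0 / G
    levy_exponent: float = 1.5
    seed: int = 0
    fitness_mode: str = "accuracy"  # or "sv_count"
    max_evaluations: int | None = None

    def __post_init__(self) -> None:
        if self.n_nests < 4:
            raise ConfigurationError("need at least 4 nests")
        if not 0 < self.discard_fraction < 1:
            raise ConfigurationError("discard_fraction must lie in (0, 1)")
        if not 0 < self.top_fraction < 1:
            raise ConfigurationError("top_fraction must lie in (0, 1)")
        if self.fitness_mode not in ("accuracy", "sv_count"):
            raise ConfigurationError(f"unknown fitness_mode {self.fitness_mode!r}")
        if self.initial_step <= 0 or self.max_generations < 1:
            raise ConfigurationError("initial_step and max_generations must be positive")


@dataclass
class Nest:
    """One candidate: a position in [0,1]^d and its evaluated fitness."""

    position: np.ndarray
    fitness: float


@dataclass
class GenerationRecord:
    generation: int
    best_fitness: float
    mean_fitness: float
    levy_scale: float


def levy_step(
    scale: float, d: int, rng: np.random.Generator, exponent: float = 1.5
) -> np.ndarray:
    """A d-dimensional Levy-flight step via Mantegna's algorithm.

    Per coordinate: step = scale * u / |v|^(1/beta) with u ~ N(0, sigma_u^2),
    v ~ N(0, 1); the resulting magnitudes are heavy-tailed with index beta.
    """
    if scale <= 0:
        raise ConfigurationError("levy scale must be positive")
    beta = exponent
    sigma_u = (
        math.gamma(1 + beta)
        * math.sin(math.pi * beta / 2)
        / (math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2))
    ) ** (1 / beta)
    u = rng.normal(0.0, sigma_u, d)
    v = rng.normal(0.0, 1.0, d)
    return scale * u / np.abs(v) ** (1 / beta)


def decode_genome(position: np.ndarray, m: int, n_features: int = 24) -> Genome:
    """Decode a [0,1]^d position into a Genome (d = n_features + 3 m).

    Mask bit i is set when position[i] >= 0.5.  Per classifier, the kind gene
    maps floor(4 g) onto (linear, quadratic, polynomial, rbf); the parameter
    gene decodes log-uniformly into the kind's range (u rounded to an
    integer); the penalty gene decodes C log-uniformly over [2^-5, 2^15].
    """
    position = np.asarray(position, dtype=np.float64)
    if position.size != n_features + 3 * m:
        raise ConfigurationError(
            f"position has {position.size} genes; expected {n_features} + 3*{m}"
        )
    mask = tuple(bool(b) for b in position[:n_features] >= 0.5)
    classifiers = []
    for i in range(m):
        g_kind, g_param, g_c = position[n_features + 3 * i : n_features + 3 * i + 3]
        kind = KERNEL_KINDS[min(len(KERNEL_KINDS) - 1, int(4 * g_kind))]
        u = None
        sigma = None
        if kind == "polynomial":
            lo, hi = U_RANGE
            u = int(round(lo * (hi / lo) ** g_param))
            u = max(lo, min(hi, u))
        elif kind == "rbf":
            lo, hi = SIGMA_LOG2_RANGE
            sigma = float(2.0 ** (lo + (hi - lo) * g_param))
        lo, hi = C_LOG2_RANGE
        C = float(2.0 ** (lo + (hi - lo) * g_c))
        classifiers.append(ClassifierGenes(kind=kind, u=u, sigma=sigma, C=C))
    return Genome(mask=mask, classifiers=tuple(classifiers))


def optimize(
    objective: Callable[[np.ndarray], float],
    dimension: int,
    cfg: MCSConfig,
    maximize: bool = True,
) -> tuple[np.ndarray, float, list[GenerationRecord]]:
    """Run the Modified Cuckoo Search on [0,1]^dimension.

    Per generation G (1-based): the bottom ``discard_fraction`` of nests are
    abandoned for Levy-flight candidates at scale A0/sqrt(G), kept only if
    better; each top nest recombines with another random top nest at the
    golden-ratio point (or, when paired with itself, takes a short local Levy
    walk at scale local_step_factor * A0 / G, kept only if it improves that
    nest), and the recombined candidate replaces a random nest if better.
    Elitism is structural: nothing is ever overwritten by a worse candidate,
    so the best-fitness trace is monotone.

    Returns (best position, best fitness, per-generation trace).
    """
    rng = np.random.default_rng(cfg.seed)
    sign = 1.0 if maximize else -1.0

    def score(p: np.ndarray) -> float:
        return sign * objective(p)

    n = cfg.n_nests
    positions = rng.random((n, dimension))
    scores = np.array([score(p) for p in positions])
    evaluations = n

    def budget_left() -> bool:
        return cfg.max_evaluations is None or evaluations < cfg.max_evaluations

    trace: list[GenerationRecord] = []
    n_discard = max(1, round(cfg.discard_fraction * n))
    n_top = max(2, round(cfg.top_fraction * n))

    for gen in range(1, cfg.max_generations + 1):
        if not budget_left():
            break
        scale = cfg.initial_step / math.sqrt(gen)
        order = np.argsort(-scores)  # best first

        # abandon the worst nests along Levy flights (keep only improvements)
        for idx in order[n - n_discard :]:
            if not budget_left():
                break
            cand = np.clip(positions[idx] + levy_step(scale, dimension, rng, cfg.levy_exponent), 0.0, 1.0)
            s = score(cand)
            evaluations += 1
            if s > scores[idx]:
                positions[idx], scores[idx] = cand, s

        # golden-ratio recombination among the top nests
        top = order[:n_top]
        for idx in top:
            if not budget_left():
                break
            other = top[rng.integers(n_top)]
            if other == idx or np.allclose(positions[idx], positions[other]):
                local = cfg.local_step_factor * cfg.initial_step / gen
                cand = positions[idx] + levy_step(local, dimension, rng, cfg.levy_exponent)
                s = score(np.clip(cand, 0.0, 1.0))
                evaluations += 1
                if s > scores[idx]:
                    positions[idx], scores[idx] = np.clip(cand, 0.0, 1.0), s
                continue
            better, worse = (idx, other) if scores[idx] >= scores[other] else (other, idx)
            cand = positions[worse] + (positions[better] - positions[worse]) / GOLDEN_RATIO
            cand = np.clip(cand, 0.0, 1.0)
            s = score(cand)
            evaluations += 1
            k = int(rng.integers(n))
            if s > scores[k]:
                positions[k], scores[k] = cand, s

        best = int(np.argmax(scores))
        trace.append(
            GenerationRecord(
                generation=gen,
                best_fitness=sign * scores[best],
                mean_fitness=sign * float(np.mean(scores)),
                levy_scale=scale,
            )
        )

    best = int(np.argmax(scores))
    return positions[best].copy(), sign * scores[best], trace


def init_nests(cfg: MCSConfig, dimension: int, objective: Callable[[np.ndarray], float]) -> list[Nest]:
    """Seeded uniform initial population with evaluated fitness (introspection helper)."""
    rng = np.random.default_rng(cfg.seed)
    positions = rng.random((cfg.n_nests, dimension))
    return [Nest(position=p, fitness=float(objective(p))) for p in positions]


def evolve(
    X: np.ndarray,
    y: Sequence[str],
    cfg: MCSConfig,
) -> tuple[Genome, float, list[GenerationRecord]]:
    """Search for the best genome on a labeled feature matrix.

    Fitness is either the leave-one-out average balanced accuracy (maximized)
    or the full-data support-vector count (minimized), per ``fitness_mode``.
    Fitness values are cached by decoded genome: thresholding makes many
    positions decode identically, and cached and fresh evaluations agree
    exactly because the fitness is deterministic in the genome.
    """
    X = np.asarray(X, dtype=np.float64)
    y = list(y)
    m = len(set(y))
    n_features = X.shape[1]
    dimension = n_features + 3 * m
    maximize = cfg.fitness_mode == "accuracy"
    raw = accuracy_fitness if maximize else sv_count_fitness

    cache: dict[Genome, float] = {}

    def objective(position: np.ndarray) -> float:
        genome = decode_genome(position, m, n_features)
        if genome not in cache:
            cache[genome] = raw(X, y, genome)
        return cache[genome]

    best_position, best_fitness, trace = optimize(objective, dimension, cfg, maximize=maximize)
    return decode_genome(best_position, m, n_features), best_fitness, trace
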