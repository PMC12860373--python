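"""Elitist genetic-algorithm inverse design over coformer space.

The trained suitability classifier acts as the fitness landscape: a
candidate's fitness is its predicted suitability probability minus a
penalty for violating physicochemical/bioactivity box constraints. Two
chromosome representations are supported, because an inverse-design search
can plausibly run either way:

* **discrete** — a chromosome is the bit string of an index into an
  enumerated candidate pool; crossover is one-point on the bits and
  mutation flips each bit at the configured per-gene rate (out-of-pool
  indices are repaired by a uniform re-index);
* **continuous** — a chromosome is a raw descriptor vector inside a box;
  crossover is BLX-alpha blending and mutation is per-gene Gaussian with
  sd proportional to the gene's box span, clipped back into the box.

Selection is tournament (size 3) and the top individuals are carried over
unchanged each generation (elitism), which makes the per-generation best
fitness non-decreasing. Discrete search additionally applies a
no-duplicates policy: a child whose index was already evaluated is
re-drawn (bounded tries), the classic duplicate-avoidance diversity
mechanism. Pool indices carry no neighborhood structure, so without it
neutral drift collapses the population and the search re-evaluates the
same few candidates instead of covering the pool. Everything is driven by
one seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .descriptors import CoformerFeaturizer
from .library import CoformerLibrary, CoformerRecord
from .models import BPClassifier

__all__ = [
    "GAConfig",
    "ConstraintSet",
    "FitnessTrace",
    "GAResult",
    "fitness",
    "run_ga",
    "detect_convergence",
    "map_to_candidate",
]

_SCALAR_FEATURES = ("mw", "hbd", "tpsa", "tyr_inhib")


@dataclass(frozen=True)
class GAConfig:
    """Search hyperparameters; all rates in [0, 1]."""

    population: int = 50
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    generations: int = 100
    elitism: int = 2
    seed: int = 0
    convergence_window: int = 10
    convergence_tol: float = 1e-4
    tournament_size: int = 3
    blend_alpha: float = 0.5
    mutation_sd_frac: float = 0.1

    def __post_init__(self) -> None:
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not 0 <= self.elitism < self.population:
            raise ValueError("elitism must be < population")


@dataclass(frozen=True)
class ConstraintSet:
    """Box bounds on raw descriptors plus a penalty weight.

    ``bounds`` maps a descriptor name (mw, hbd, tpsa, tyr_inhib) to a
    closed interval; a minimum bioactivity requirement is simply a lower
    bound on ``tyr_inhib``. Violations are normalized by the bound's span
    (absolute when the span is zero) and summed; the fitness penalty is
    ``lam`` times that sum, so a feasible candidate's score is exactly the
    model probability.
    """

    bounds: dict = field(default_factory=dict)
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("penalty weight must be >= 0")
        for name, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"bound for {name!r} has lower > upper")

    def violation(self, descriptors: dict) -> float:
        total = 0.0
        for name, (lo, hi) in self.bounds.items():
            x = descriptors[name]
            excess = max(lo - x, 0.0) + max(x - hi, 0.0)
            span = hi - lo
            total += excess / span if span > 0 else excess
        return total

    def is_feasible(self, descriptors: dict) -> bool:
        return self.violation(descriptors) == 0.0


@dataclass
class FitnessTrace:
    """Per-generation best/mean fitness and the best chromosome of each."""

    best: list[float] = field(default_factory=list)
    mean: list[float] = field(default_factory=list)
    best_chromosome: list = field(default_factory=list)
    convergence_generation: int | None = None


@dataclass
class GAResult:
    """Best individual found, its fitness, and the full search trace."""

    best_record: CoformerRecord | None
    best_vector: np.ndarray | None
    best_fitness: float
    best_feasible: bool
    trace: FitnessTrace
    seed: int


def _record_descriptors(rec: CoformerRecord) -> dict:
    return {"mw": rec.mw, "hbd": rec.hbd, "tpsa": rec.tpsa, "tyr_inhib": rec.tyr_inhib}


def fitness(
    probability: float, descriptors: dict, constraints: ConstraintSet
) -> float:
    """Penalized fitness: suitability probability minus weighted violations."""
    return float(probability) - constraints.lam * constraints.violation(descriptors)


class _DiscreteProblem:
    """Pool-indexed search; pool probabilities are cached once up front."""

    def __init__(self, model, featurizer, constraints, pool: CoformerLibrary):
        if len(pool) == 0:
            raise ValueError("candidate pool is empty")
        self.pool = pool
        fm = featurizer.transform(pool)
        probs = model.predict_proba(fm)
        self.scores = np.array(
            [
                fitness(p, _record_descriptors(rec), constraints)
                for p, rec in zip(probs, pool)
            ]
        )
        self.feasible = np.array(
            [constraints.is_feasible(_record_descriptors(rec)) for rec in pool]
        )
        self.n = len(pool)
        self.nbits = max(1, math.ceil(math.log2(self.n))) if self.n > 1 else 1

    def init_population(self, rng, size):
        return rng.integers(self.n, size=size)

    def evaluate(self, population):
        return self.scores[population]

    def crossover(self, rng, a, b):
        if self.nbits < 2:
            return a, b
        cut = int(rng.integers(1, self.nbits))
        mask = (1 << cut) - 1
        c1 = ((a & ~mask) | (b & mask)) % self.n
        c2 = ((b & ~mask) | (a & mask)) % self.n
        return c1, c2

    def mutate(self, rng, ch, rate):
        # per-gene mutation: the genes of the index chromosome are its bits
        out = int(ch)
        for b in range(self.nbits):
            if rng.uniform() < rate:
                out ^= 1 << b
        if out >= self.n:  # repair out-of-pool indices with a uniform reindex
            out = int(rng.integers(self.n))
        return out


class _ContinuousProblem:
    """Box-constrained descriptor-vector search over the model's features."""

    def __init__(self, model, featurizer, constraints, bounds: dict, cfg: GAConfig):
        feats = featurizer.features
        bad = [f for f in feats if f not in _SCALAR_FEATURES]
        if bad:
            raise ValueError(
                f"continuous search requires scalar features only, got {bad}"
            )
        missing = [f for f in feats if f not in bounds]
        if missing:
            raise ValueError(f"missing box bounds for features {missing}")
        self.model = model
        self.featurizer = featurizer
        self.constraints = constraints
        self.features = feats
        self.lo = np.array([bounds[f][0] for f in feats], dtype=float)
        self.hi = np.array([bounds[f][1] for f in feats], dtype=float)
        self.span = self.hi - self.lo
        self.cfg = cfg

    def init_population(self, rng, size):
        return rng.uniform(self.lo, self.hi, size=(size, len(self.features)))

    def evaluate(self, population):
        Z = self.featurizer.transform_raw(population)
        probs = self.model.predict_proba(Z)
        out = np.empty(len(population))
        for i, (p, vec) in enumerate(zip(probs, population)):
            desc = dict(zip(self.features, vec))
            out[i] = fitness(p, desc, self.constraints)
        return out

    def feasible_mask(self, population):
        return np.array(
            [
                self.constraints.is_feasible(dict(zip(self.features, vec)))
                for vec in population
            ]
        )

    def crossover(self, rng, a, b):
        lo_g = np.minimum(a, b)
        hi_g = np.maximum(a, b)
        d = hi_g - lo_g
        alpha = self.cfg.blend_alpha
        c1 = rng.uniform(lo_g - alpha * d, hi_g + alpha * d)
        c2 = rng.uniform(lo_g - alpha * d, hi_g + alpha * d)
        return np.clip(c1, self.lo, self.hi), np.clip(c2, self.lo, self.hi)

    def mutate(self, rng, ch, rate):
        ch = ch.copy()
        for g in range(ch.size):
            if rng.uniform() < rate:
                ch[g] += rng.normal(0.0, self.cfg.mutation_sd_frac * self.span[g])
        return np.clip(ch, self.lo, self.hi)


def _tournament(rng, scores, size):
    idx = rng.integers(len(scores), size=size)
    return idx[np.argmax(scores[idx])]


def run_ga(
    model: BPClassifier,
    featurizer: CoformerFeaturizer,
    constraints: ConstraintSet,
    cfg: GAConfig = GAConfig(),
    pool: CoformerLibrary | None = None,
    bounds: dict | None = None,
) -> GAResult:
    """Run the elitist GA and return the best individual plus its trace.

    Pass ``pool`` for the discrete representation or ``bounds`` (a
    name -> (lo, hi) box over the model's feature spec) for the continuous
    one. Among everything evaluated, a feasible individual is preferred
    over any infeasible one; ties in feasibility resolve by fitness. The
    whole run is deterministic under ``cfg.seed``.
    """
    if (pool is None) == (bounds is None):
        raise ValueError("exactly one of pool/bounds must be given")
    rng = np.random.default_rng(cfg.seed)
    discrete = pool is not None
    problem = (
        _DiscreteProblem(model, featurizer, constraints, pool)
        if discrete
        else _ContinuousProblem(model, featurizer, constraints, bounds, cfg)
    )

    population = problem.init_population(rng, cfg.population)
    scores = problem.evaluate(population)

    def feas(pop):
        if discrete:
            return problem.feasible[pop]
        return problem.feasible_mask(pop)

    trace = FitnessTrace()
    best_ch, best_fit, best_is_feas = None, -np.inf, False
    seen: set[int] = set(int(c) for c in population) if discrete else set()

    def consider(pop, sc):
        nonlocal best_ch, best_fit, best_is_feas
        fmask = feas(pop)
        for ch, s, fe in zip(pop, sc, fmask):
            better = (fe and not best_is_feas) or (
                fe == best_is_feas and s > best_fit
            )
            if better:
                best_ch = ch.copy() if hasattr(ch, "copy") else ch
                best_fit = float(s)
                best_is_feas = bool(fe)

    def log_generation(pop, sc):
        i = int(np.argmax(sc))
        trace.best.append(float(sc[i]))
        trace.mean.append(float(np.mean(sc)))
        ch = pop[i]
        trace.best_chromosome.append(ch.copy() if hasattr(ch, "copy") else ch)

    consider(population, scores)
    log_generation(population, scores)

    for _gen in range(cfg.generations):
        elite_idx = np.argsort(-scores, kind="stable")[: cfg.elitism]
        next_pop = [population[i] for i in elite_idx]
        while len(next_pop) < cfg.population:
            pa = population[_tournament(rng, scores, cfg.tournament_size)]
            pb = population[_tournament(rng, scores, cfg.tournament_size)]
            if rng.uniform() < cfg.crossover_rate:
                ca, cb = problem.crossover(rng, pa, pb)
            else:
                ca, cb = pa, pb
            for child in (ca, cb):
                if len(next_pop) >= cfg.population:
                    break
                child = problem.mutate(rng, child, cfg.mutation_rate)
                if discrete:
                    # no-duplicates policy: avoid re-evaluating known indices
                    for _try in range(20):
                        if int(child) not in seen:
                            break
                        child = int(rng.integers(problem.n))
                next_pop.append(child)
        population = (
            np.array(next_pop) if discrete else np.vstack(next_pop)
        )
        scores = problem.evaluate(population)
        if discrete:
            seen.update(int(c) for c in population)
        consider(population, scores)
        log_generation(population, scores)

    try:
        trace.convergence_generation = detect_convergence(
            trace, cfg.convergence_window, cfg.convergence_tol
        )
    except ValueError:
        trace.convergence_generation = None

    if discrete:
        best_record = problem.pool[int(best_ch)]
        best_vector = None
    else:
        best_record = None
        best_vector = np.asarray(best_ch, dtype=float)
    return GAResult(
        best_record=best_record,
        best_vector=best_vector,
        best_fitness=best_fit,
        best_feasible=best_is_feas,
        trace=trace,
        seed=cfg.seed,
    )


def detect_convergence(
    trace: FitnessTrace | list, window: int, tol: float
) -> int | None:
    """First generation opening a full window whose best-fitness spread <= tol.

    Returns ``None`` when no such window exists; raises when the window is
    longer than the trace.
    """
    best = trace.best if isinstance(trace, FitnessTrace) else list(trace)
    if not best:
        raise ValueError("trace is empty")
    if window > len(best):
        raise ValueError(f"window {window} exceeds trace length {len(best)}")
    arr = np.asarray(best, dtype=float)
    for g in range(len(arr) - window + 1):
        seg = arr[g : g + window]
        if seg.max() - seg.min() <= tol:
            return g
    return None


def map_to_candidate(
    vector: np.ndarray,
    pool: CoformerLibrary,
    featurizer: CoformerFeaturizer,
) -> CoformerRecord:
    """Nearest pool record to a continuous optimum, in normalized space.

    Distances are Euclidean over the featurizer's (scalar) feature columns
    after z-scoring; exact ties resolve to the lexicographically smallest id.
    """
    if len(pool) == 0:
        raise ValueError("candidate pool is empty")
    feats = featurizer.features
    bad = [f for f in feats if f not in _SCALAR_FEATURES]
    if bad:
        raise ValueError(f"mapping requires scalar features only, got {bad}")
    raw_pool = np.array(
        [[getattr(rec, f) for f in feats] for rec in pool], dtype=float
    )
    Zp = featurizer.transform_raw(raw_pool)
    zq = featurizer.transform_raw(np.asarray(vector, dtype=float).reshape(1, -1))[0]
    d = np.linalg.norm(Zp - zq, axis=1)
    dmin = d.min()
    tied = [pool[i].id for i in np.flatnonzero(d == dmin)]
    return pool[min(tied)]
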