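"""Regularized (aging) evolutionary hyperparameter search.

The search space is the discrete 2400-point grid over six hyperparameters
(hidden width, learning rate, epochs, batch size, optimizer, candidate
activation).  Evolution proceeds in cycles over a fixed-size population:

1. sample ``k`` distinct members uniformly and take the fittest as parent
   (tournament selection);
2. mutate the parent by resampling exactly one hyperparameter among its
   other options;
3. evaluate the child, insert it, and remove the *oldest* member —
   aging/regularized evolution, which favours fresh candidates over
   premature convergence on early winners;
4. stop when the best-worst fitness spread of the population falls below
   ``termination_epsilon``, or after ``max_cycles`` cycles.

Because aging can evict the best candidate ever seen, the returned best is
tracked over the full evaluation log, not just the final population.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Hyperparameters", "SearchSpace", "Candidate", "NASConfig", "SearchLog",
    "TABLE1_SPACE", "random_candidate", "mutate", "tournament_select",
    "should_terminate", "evolve", "validation_fitness",
]


@dataclass(frozen=True)
class Hyperparameters:
    """One point of the discrete search grid."""

    n_neurons: int
    learning_rate: float
    n_epochs: int
    batch_size: int
    optimizer: str
    activation: str

    def as_dict(self) -> Dict[str, object]:
        return {
            "n_neurons": self.n_neurons,
            "learning_rate": self.learning_rate,
            "n_epochs": self.n_epochs,
            "batch_size": self.batch_size,
            "optimizer": self.optimizer,
            "activation": self.activation,
        }


class SearchSpace:
    """Ordered option lists per hyperparameter; immutable during a search."""

    def __init__(self, options: Dict[str, Sequence]):
        self._options = {k: tuple(v) for k, v in options.items()}
        for name, opts in self._options.items():
            if len(opts) == 0:
                raise ValueError(f"field {name!r} has no options")

    @property
    def fields(self) -> Tuple[str, ...]:
        return tuple(self._options)

    def options(self, name: str) -> Tuple:
        return self._options[name]

    @property
    def size(self) -> int:
        return int(np.prod([len(v) for v in self._options.values()]))

    def contains(self, hyper: Hyperparameters) -> bool:
        return all(
            getattr(hyper, name) in opts for name, opts in self._options.items()
        )

    def indices(self, hyper: Hyperparameters) -> Tuple[int, ...]:
        return tuple(
            self._options[name].index(getattr(hyper, name)) for name in self.fields
        )

    def enumerate(self):
        """Yield every configuration of the grid (exhaustive oracle use)."""
        import itertools

        names = self.fields
        for combo in itertools.product(*(self._options[n] for n in names)):
            yield Hyperparameters(**dict(zip(names, combo)))


#: the study's hyperparameter grid: 5 x 6 x 5 x 4 x 2 x 2 = 2400 points
TABLE1_SPACE = SearchSpace(
    {
        "n_neurons": (20, 50, 100, 200, 500),
        "learning_rate": (1e-3, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8),
        "n_epochs": (10, 20, 50, 100, 250),
        "batch_size": (32, 64, 128, 256),
        "optimizer": ("Adam", "SGD"),
        "activation": ("tanh", "ReLU"),
    }
)


@dataclass
class Candidate:
    """A configuration with its fitness and insertion-order age proxy."""

    hyper: Hyperparameters
    fitness: Optional[float] = None
    birth_cycle: int = -1


@dataclass(frozen=True)
class NASConfig:
    population_size: int = 16
    sample_size: int = 4
    termination_epsilon: float = 0.01
    max_cycles: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 1 or self.sample_size < 1:
            raise ValueError("population_size and sample_size must be positive")
        if self.sample_size >= self.population_size:
            raise ValueError("sample_size k must be smaller than population_size p")
        if self.termination_epsilon < 0:
            raise ValueError("termination_epsilon must be non-negative")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be positive")


@dataclass
class SearchLog:
    """One record per cycle plus the warm-up evaluations."""

    records: List[Dict] = field(default_factory=list)

    def append(self, **record) -> None:
        self.records.append(record)

    def best_fitness(self) -> float:
        return max(r["fitness"] for r in self.records)

    def to_jsonl(self, path: Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(json.dumps(r) + "\n")


def random_candidate(space: SearchSpace, rng: np.random.Generator) -> Candidate:
    """Draw every field independently and uniformly from its options."""
    values = {
        name: space.options(name)[rng.integers(len(space.options(name)))]
        for name in space.fields
    }
    return Candidate(hyper=Hyperparameters(**values))


def mutate(parent: Candidate, space: SearchSpace, rng: np.random.Generator) -> Candidate:
    """Resample exactly one field uniformly from its *other* options.

    The field is chosen uniformly among fields with more than one option,
    so the child always differs from the parent in exactly one field.
    """
    mutable = [n for n in space.fields if len(space.options(n)) > 1]
    if not mutable:
        raise ValueError("no field has an alternative option to mutate into")
    name = mutable[rng.integers(len(mutable))]
    current = getattr(parent.hyper, name)
    alternatives = [o for o in space.options(name) if o != current]
    new_value = alternatives[rng.integers(len(alternatives))]
    return Candidate(hyper=replace(parent.hyper, **{name: new_value}))


def tournament_select(
    population: Sequence[Candidate], k: int, rng: np.random.Generator
) -> Candidate:
    """Fittest of k members sampled uniformly without replacement.

    Ties are broken by earliest birth_cycle, then by stable population
    index.
    """
    if not 1 <= k <= len(population):
        raise ValueError(f"k={k} must lie in [1, population size {len(population)}]")
    idx = rng.choice(len(population), size=k, replace=False)
    best = None
    for i in sorted(idx):
        cand = population[i]
        if cand.fitness is None:
            raise ValueError("tournament over unevaluated candidates")
        if (
            best is None
            or cand.fitness > best.fitness
            or (cand.fitness == best.fitness and cand.birth_cycle < best.birth_cycle)
        ):
            best = cand
    return best


def should_terminate(population: Sequence[Candidate], epsilon: float) -> bool:
    """Best-worst criterion: stop when max - min fitness < epsilon."""
    fitnesses = [c.fitness for c in population]
    if any(f is None for f in fitnesses):
        raise ValueError("termination check requires a fully evaluated population")
    return (max(fitnesses) - min(fitnesses)) < epsilon


def _evaluate(cand: Candidate, fitness_fn, birth: int) -> Candidate:
    fitness = float(fitness_fn(cand.hyper))
    if not np.isfinite(fitness):
        raise ValueError(f"non-finite fitness for candidate {cand.hyper}")
    cand.fitness = fitness
    cand.birth_cycle = birth
    return cand


def evolve(
    space: SearchSpace,
    config: NASConfig,
    fitness_fn: Callable[[Hyperparameters], float],
) -> Tuple[Candidate, SearchLog]:
    """Run aging evolution and return the best candidate ever evaluated.

    Warm-up fills the population with ``p`` random evaluated candidates
    (no removals); each subsequent cycle inserts one mutated child and
    removes the oldest member, keeping the population size at ``p``.
    """
    rng = np.random.default_rng(config.seed)
    log = SearchLog()
    population: List[Candidate] = []
    birth = 0
    best: Optional[Candidate] = None

    for _ in range(config.population_size):
        cand = _evaluate(random_candidate(space, rng), fitness_fn, birth)
        population.append(cand)
        log.append(
            cycle=None, phase="init", hyper=cand.hyper.as_dict(),
            fitness=cand.fitness, birth_cycle=cand.birth_cycle,
        )
        if best is None or cand.fitness > best.fitness:
            best = cand
        birth += 1

    for cycle in range(config.max_cycles):
        if should_terminate(population, config.termination_epsilon):
            break
        parent = tournament_select(population, config.sample_size, rng)
        child = _evaluate(mutate(parent, space, rng), fitness_fn, birth)
        birth += 1
        population.append(child)
        oldest = min(range(len(population)), key=lambda i: population[i].birth_cycle)
        removed = population.pop(oldest)
        fits = [c.fitness for c in population]
        log.append(
            cycle=cycle, phase="evolve",
            parent=parent.hyper.as_dict(), hyper=child.hyper.as_dict(),
            fitness=child.fitness, birth_cycle=child.birth_cycle,
            removed_birth_cycle=removed.birth_cycle,
            population_size=len(population),
            best=max(fits), worst=min(fits),
        )
        if child.fitness > best.fitness:
            best = child
    return best, log


def validation_fitness(
    X: np.ndarray,
    y: np.ndarray,
    val_frac: float = 0.2,
    cell_mode: str = "standard",
    seed: int = 0,
    max_epochs: Optional[int] = None,
    max_windows: Optional[int] = None,
):
    """Build a fitness function: validation accuracy on a chronological
    hold-out.

    The last ``val_frac`` of the (already chronologically ordered) training
    windows is held out for scoring, so the study's final test partition is
    never touched during the search.  ``max_epochs`` and ``max_windows``
    optionally cap the per-evaluation epoch count and window count during
    the search to bound desk-scale runtimes; the winning configuration is
    retrained at full budget afterwards.
    """
    from emgtremor.bilstm import BiLSTMClassifier

    if max_windows is not None and X.shape[0] > max_windows:
        # evenly thinned subsample keeps chronology and class balance
        keep = np.linspace(0, X.shape[0] - 1, max_windows).astype(int)
        X, y = X[keep], y[keep]
    n = X.shape[0]
    n_fit = int(np.floor(n * (1.0 - val_frac)))
    X_fit, y_fit = X[:n_fit], y[:n_fit]
    X_val, y_val = X[n_fit:], y[n_fit:]

    def fitness(hyper: Hyperparameters) -> float:
        h = hyper.as_dict()
        if max_epochs is not None:
            h["n_epochs"] = min(int(h["n_epochs"]), int(max_epochs))
        h["batch_size"] = min(int(h["batch_size"]), len(X_fit))
        clf = BiLSTMClassifier(cell_mode=cell_mode, random_state=seed, **h)
        clf.fit(X_fit, y_fit)
        return float(np.mean(clf.predict(X_val) == y_val))

    return fitness
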