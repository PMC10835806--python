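"""Genetic-algorithm wrapper feature selection for trait tables.

A candidate trait subset S is a binary chromosome; its fitness is the cost

    Cost(S) = lambda1 * E(S) + lambda2 * N(S)

where E(S) is the cross-validated error rate of the wrapped classifier
(random forest by default) restricted to the traits in S and N(S) is the
subset length.  Lower cost is better: the search favours subsets that are
simultaneously accurate and short.  The weights are calibrated from the data
so the two terms share an order of magnitude (lambda1 = 1, lambda2 = mean
probe error / mean probe length).

The GA uses tournament selection (size 3), single-point crossover, per-bit
mutation and elitism, with a population of 50 evolved for 20 generations by
default.  Elitism makes the best cost per generation non-increasing.
Subset evaluations are memoised by bit pattern, so repeated visits are free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import LabelEncoder

__all__ = [
    "GAConfig",
    "EvalRecord",
    "SubsetEvaluator",
    "GATrace",
    "SelectionResult",
    "cost",
    "calibrate_lambdas",
    "tournament_select",
    "crossover",
    "mutate",
    "run_ga",
    "exhaustive_search",
    "repeat_runs",
]


def cost(E: float, N: int, lambda1: float, lambda2: float) -> float:
    """Evaluation function: lambda1 * error + lambda2 * subset length."""
    if E < 0 or N < 1 or lambda1 < 0 or lambda2 < 0:
        raise ValueError("cost requires E >= 0, N >= 1 and non-negative weights")
    return lambda1 * E + lambda2 * N


@dataclass(frozen=True)
class EvalRecord:
    """One evaluated subset: error rate E, length N."""

    E: float
    N: int


@dataclass
class GAConfig:
    """GA hyperparameters; the defaults are the standard configuration."""

    pop_size: int = 50
    generations: int = 20
    tournament_size: int = 3
    crossover_rate: float = 0.8
    mutation_rate: float | None = None  # per bit; None -> 1/d
    lambda1: float | None = None  # None -> calibrated from probe subsets
    lambda2: float | None = None
    elitism_count: int = 1
    patience: int | None = None  # generations without improvement; None = off
    seed: int = 0


class SubsetEvaluator:
    """Wrapped-classifier evaluator with per-bit-pattern memoisation.

    E(S) is the mean stratified-CV error of the classifier using only the
    columns selected by the chromosome.  The classifier seed is fixed per
    evaluator so a bit pattern always maps to the same record.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        columns: list[str] | None = None,
        cv: int = 3,
        n_estimators: int = 60,
        seed: int = 0,
        estimator_factory=None,
    ):
        self.columns = columns or [c for c in table.columns if c not in ("variety_id", "flower_id")]
        if not self.columns:
            raise ValueError("no trait columns found in the table")
        self.X = table[self.columns].to_numpy(dtype=float)
        self.y = LabelEncoder().fit_transform(table["variety_id"].to_numpy())
        if len(np.unique(self.y)) < 2:
            raise ValueError("need at least two classes")
        self.cv = cv
        self.seed = seed
        if estimator_factory is None:
            estimator_factory = lambda: RandomForestClassifier(  # noqa: E731
                n_estimators=n_estimators, random_state=seed, n_jobs=1
            )
        self._factory = estimator_factory
        # fold indices are fixed per evaluator, so every subset is scored on
        # the same partition and records are reproducible
        skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
        self._folds = list(skf.split(self.X, self.y))
        self._cache: dict[bytes, EvalRecord] = {}
        self.n_evaluations = 0  # classifier fits, excluding cache hits

    @property
    def d(self) -> int:
        return len(self.columns)

    def evaluate(self, bits: np.ndarray) -> EvalRecord:
        bits = np.asarray(bits, dtype=bool)
        if bits.shape != (self.d,):
            raise ValueError(f"chromosome length {bits.size} != {self.d} traits")
        if not bits.any():
            raise ValueError("empty chromosome cannot be evaluated (repair it first)")
        key = np.packbits(bits).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        Xs = self.X[:, bits]
        correct = total = 0
        for tr, te in self._folds:
            model = clone(self._factory())
            model.fit(Xs[tr], self.y[tr])
            correct += int((model.predict(Xs[te]) == self.y[te]).sum())
            total += len(te)
        rec = EvalRecord(E=float(1.0 - correct / total), N=int(bits.sum()))
        self._cache[key] = rec
        self.n_evaluations += 1
        return rec

    def subset_ids(self, bits: np.ndarray) -> list[str]:
        return [c for c, b in zip(self.columns, bits) if b]


def calibrate_lambdas(
    evaluator: SubsetEvaluator, n_probe: int = 20, seed: int = 0
) -> tuple[float, float]:
    """Set the cost weights from random probe subsets.

    lambda1 = 1 and lambda2 = mean probe error / mean probe length, so that
    the two cost terms have comparable magnitude; lambda2 is floored at 1e-4
    (separable data would otherwise make length free) and capped at 1.
    """
    if n_probe < 10:
        raise ValueError("need at least 10 probe subsets")
    rng = np.random.default_rng(seed)
    errors, lengths = [], []
    for _ in range(n_probe):
        bits = _repair(rng.random(evaluator.d) < 0.5, rng)
        rec = evaluator.evaluate(bits)
        errors.append(rec.E)
        lengths.append(rec.N)
    mean_e, mean_n = float(np.mean(errors)), float(np.mean(lengths))
    lam2 = mean_e / mean_n
    if lam2 < 1e-4:
        warnings.warn("probe error rate ~0; lambda2 floored at 1e-4", stacklevel=2)
        lam2 = 1e-4
    return 1.0, float(min(lam2, 1.0))


def _repair(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Ensure at least one selected trait (flip one random bit on if empty)."""
    bits = np.asarray(bits, dtype=bool).copy()
    if not bits.any():
        bits[rng.integers(bits.size)] = True
    return bits


def tournament_select(
    costs: np.ndarray, size: int, rng: np.random.Generator
) -> int:
    """Index of the lowest-cost individual among ``size`` distinct entrants."""
    n = len(costs)
    if size > n:
        raise ValueError(f"tournament size {size} exceeds population {n}")
    entrants = rng.choice(n, size=size, replace=False)
    return int(entrants[np.argmin(np.asarray(costs)[entrants])])


def crossover(
    a: np.ndarray, b: np.ndarray, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Single-point crossover with probability ``rate``; children repaired."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("parents must have equal length")
    if rng.random() < rate and a.size > 1:
        cut = int(rng.integers(1, a.size))
        c1 = np.concatenate([a[:cut], b[cut:]])
        c2 = np.concatenate([b[:cut], a[cut:]])
    else:
        c1, c2 = a.copy(), b.copy()
    return _repair(c1, rng), _repair(c2, rng)


def mutate(bits: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each bit independently with probability ``rate``; repair after."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("mutation rate must lie in [0, 1]")
    bits = np.asarray(bits, dtype=bool)
    flips = rng.random(bits.size) < rate
    return _repair(bits ^ flips, rng)


@dataclass
class GATrace:
    """Per-generation progress: best/mean cost, best subset length and error."""

    frame: pd.DataFrame

    def best_costs(self) -> np.ndarray:
        return self.frame["best_cost"].to_numpy()

    def is_monotone(self) -> bool:
        c = self.best_costs()
        return bool(np.all(np.diff(c) <= 1e-12))


@dataclass
class SelectionResult:
    """Best subset found by one GA run."""

    bits: np.ndarray
    subset: list[str]
    N: int
    error: float
    accuracy: float  # 1 - error, percent
    cost: float
    trace: GATrace
    run_index: int = 0
    lambdas: tuple[float, float] = (1.0, 0.0)


def _resolve_lambdas(
    config: GAConfig, evaluator: SubsetEvaluator
) -> tuple[float, float]:
    if config.lambda1 is not None and config.lambda2 is not None:
        return config.lambda1, config.lambda2
    lam1, lam2 = calibrate_lambdas(evaluator, seed=config.seed)
    return (
        config.lambda1 if config.lambda1 is not None else lam1,
        config.lambda2 if config.lambda2 is not None else lam2,
    )


def run_ga(evaluator: SubsetEvaluator, config: GAConfig | None = None) -> SelectionResult:
    """Evolve trait subsets and return the best ever seen, with its trace.

    Each generation: elitism carries the ``elitism_count`` best individuals
    over unchanged, the rest of the offspring come from tournament selection
    followed by single-point crossover and per-bit mutation.  The run stops
    at ``generations`` (or earlier if the best cost has not improved for
    ``patience`` generations, when set).
    """
    config = config or GAConfig()
    rng = np.random.default_rng(config.seed)
    d = evaluator.d
    mut_rate = config.mutation_rate if config.mutation_rate is not None else 1.0 / d
    lam1, lam2 = _resolve_lambdas(config, evaluator)

    pop = [_repair(rng.random(d) < 0.5, rng) for _ in range(config.pop_size)]

    def eval_pop(pop):
        recs = [evaluator.evaluate(ind) for ind in pop]
        costs = np.array([cost(r.E, r.N, lam1, lam2) for r in recs])
        return recs, costs

    recs, costs = eval_pop(pop)
    best_i = int(np.argmin(costs))
    best_bits, best_rec, best_cost = pop[best_i].copy(), recs[best_i], float(costs[best_i])

    trace_rows = [
        {"generation": 0, "best_cost": best_cost, "mean_cost": float(costs.mean()),
         "best_N": best_rec.N, "best_E": best_rec.E}
    ]
    stall = 0
    for gen in range(1, config.generations + 1):
        elite_idx = np.argsort(costs)[: config.elitism_count]
        new_pop = [pop[i].copy() for i in elite_idx]
        while len(new_pop) < config.pop_size:
            p1 = pop[tournament_select(costs, config.tournament_size, rng)]
            p2 = pop[tournament_select(costs, config.tournament_size, rng)]
            c1, c2 = crossover(p1, p2, config.crossover_rate, rng)
            new_pop.append(mutate(c1, mut_rate, rng))
            if len(new_pop) < config.pop_size:
                new_pop.append(mutate(c2, mut_rate, rng))
        pop = new_pop
        recs, costs = eval_pop(pop)
        gen_best = int(np.argmin(costs))
        if costs[gen_best] < best_cost - 1e-15:
            best_bits, best_rec, best_cost = pop[gen_best].copy(), recs[gen_best], float(costs[gen_best])
            stall = 0
        else:
            stall += 1
        trace_rows.append(
            {"generation": gen, "best_cost": best_cost, "mean_cost": float(costs.mean()),
             "best_N": best_rec.N, "best_E": best_rec.E}
        )
        if config.patience is not None and stall >= config.patience:
            break

    return SelectionResult(
        bits=best_bits,
        subset=evaluator.subset_ids(best_bits),
        N=best_rec.N,
        error=best_rec.E,
        accuracy=100.0 * (1.0 - best_rec.E),
        cost=best_cost,
        trace=GATrace(pd.DataFrame(trace_rows)),
        lambdas=(lam1, lam2),
    )


def exhaustive_search(
    evaluator: SubsetEvaluator, lambda1: float, lambda2: float
) -> tuple[np.ndarray, float]:
    """Minimum-cost subset over all 2^d - 1 non-empty subsets (d <= 20).

    Shares the evaluator's memo cache, so running it after a GA on the same
    evaluator only evaluates the subsets the GA never visited.
    """
    d = evaluator.d
    if d > 20:
        raise ValueError("exhaustive search is limited to d <= 20 traits")
    best_bits, best_cost = None, np.inf
    for code in range(1, 2**d):
        bits = np.array([(code >> i) & 1 for i in range(d)], dtype=bool)
        rec = evaluator.evaluate(bits)
        c = cost(rec.E, rec.N, lambda1, lambda2)
        if c < best_cost:
            best_bits, best_cost = bits, c
    return best_bits, float(best_cost)


def repeat_runs(
    evaluator: SubsetEvaluator,
    config: GAConfig | None = None,
    n_runs: int = 5,
) -> tuple[list[SelectionResult], pd.DataFrame]:
    """Repeat the GA with independent seeds and flag the core feature set.

    Returns every run's result plus a summary table (subset, length,
    accuracy).  The run with the highest accuracy — ties broken toward the
    shorter subset — is flagged ``core``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    config = config or GAConfig()
    seeds = np.random.SeedSequence(config.seed).generate_state(n_runs) % (2**31)
    results = []
    for i, s in enumerate(seeds):
        res = run_ga(evaluator, replace(config, seed=int(s)))
        res.run_index = i + 1
        results.append(res)
    summary = pd.DataFrame(
        {
            "run": [r.run_index for r in results],
            "subset": [", ".join(r.subset) for r in results],
            "length": [r.N for r in results],
            "accuracy": [r.accuracy for r in results],
            "cost": [r.cost for r in results],
        }
    )
    core_idx = summary.sort_values(["accuracy", "length"], ascending=[False, True]).index[0]
    summary["core"] = False
    summary.loc[core_idx, "core"] = True
    return results, summary
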