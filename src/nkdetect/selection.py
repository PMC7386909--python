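"""Genetic-algorithm feature-subset search with a mutual-information mRMR
fitness, plus the repeated-run consensus protocol.

A candidate solution is a set of exactly ``lam`` feature ids; the order of
features within a subset carries no meaning.  Fitness follows the
max-relevance / min-redundancy (mRMR) principle in its difference ("MID")
form:

    fitness(S) = mean_{i in S} I(x_i; y) - mean_{i<j in S} I(x_i; x_j)

with mutual information estimated by the plug-in estimator on
equal-frequency-discretized features.  Because single GA runs are stochastic,
the protocol runs the search many times and reports the run-frequency of each
returned subset; the modal subset is the consensus selection and its relative
frequency rfc = fc / n_runs quantifies stability.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort

__all__ = [
    "GAConfig",
    "ConsensusReport",
    "discretize",
    "mutual_information",
    "mrmr_fitness",
    "mrmr_tables",
    "ga_search",
    "consensus_runs",
    "lambda_sweep",
]


@dataclass
class GAConfig:
    """GA hyperparameters.  ``lam`` is the subset size searched for."""

    lam: int = 4
    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    tournament_size: int = 3
    elitism: int = 2
    mi_bins: int = 4
    seed: int = 0

    def validate(self, m: int) -> None:
        if not (2 <= self.lam <= m):
            raise ValueError(f"subset size {self.lam} infeasible for m={m}")
        if self.mi_bins < 2:
            raise ValueError("mi_bins must be >= 2")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability")


@dataclass
class ConsensusReport:
    """Tally of subsets returned across repeated GA runs.

    ``entries`` are (subset, fc, rfc) sorted by descending frequency;
    rfc = fc / runs.
    """

    lam: int
    runs: int
    entries: list[tuple[tuple[int, ...], int, float]] = field(default_factory=list)

    @property
    def n_distinct(self) -> int:
        return len(self.entries)

    @property
    def modal_subset(self) -> tuple[int, ...]:
        return self.entries[0][0]

    @property
    def modal_rfc_percent(self) -> float:
        return 100.0 * self.entries[0][2]


def discretize(values: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency binning into integer codes 0..bins-1.

    Tied values share a code; for tie-free input the bin occupancies differ
    from n/bins by at most 1.  A constant vector maps to a single code.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    v = np.asarray(values, dtype=float)
    n = v.size
    s = np.sort(v)
    if s[0] == s[-1]:
        return np.zeros(n, dtype=np.int64)
    edges = np.unique(s[[(j * n) // bins for j in range(1, bins)]])
    return np.searchsorted(edges, v, side="right").astype(np.int64)


def mutual_information(x_codes: np.ndarray, y_codes: np.ndarray) -> float:
    """Plug-in mutual information (nats) of two integer-coded variables."""
    x = np.asarray(x_codes, dtype=np.int64)
    y = np.asarray(y_codes, dtype=np.int64)
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    nx, ny = x.max() + 1, y.max() + 1
    joint = np.bincount(x * ny + y, minlength=nx * ny).reshape(nx, ny) / x.size
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (px @ py)[nz])))


def mrmr_tables(
    X: np.ndarray, y: np.ndarray, mi_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Precompute the relevance vector I(x_i; y) and the redundancy matrix
    I(x_i; x_j) so that GA fitness evaluation is a table lookup."""
    X = np.asarray(X, dtype=float)
    m = X.shape[1]
    codes = [discretize(X[:, j], mi_bins) for j in range(m)]
    y_codes = np.asarray(y, dtype=np.int64)
    relevance = np.array([mutual_information(c, y_codes) for c in codes])
    redundancy = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            redundancy[i, j] = redundancy[j, i] = mutual_information(
                codes[i], codes[j]
            )
    return relevance, redundancy


def _fitness_from_tables(
    cols: np.ndarray, relevance: np.ndarray, redundancy: np.ndarray
) -> float:
    rel = relevance[cols].mean()
    k = cols.size
    if k == 1:
        return float(rel)
    red = redundancy[np.ix_(cols, cols)].sum() / (k * (k - 1))
    return float(rel - red)


def mrmr_fitness(
    subset: list[int] | tuple[int, ...],
    cohort_or_X: "Cohort | np.ndarray",
    y: np.ndarray | None = None,
    mi_bins: int = 4,
) -> float:
    """mRMR difference criterion for one subset of feature ids.

    Accepts either a Cohort (ids are registry feature ids) or a raw design
    matrix plus labels (ids are 1-based column indices).
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    if isinstance(cohort_or_X, Cohort):
        X = cohort_or_X.predictor_matrix(subset)
        y = cohort_or_X.labels
        cols = np.arange(len(subset))
        relevance, redundancy = mrmr_tables(X, y, mi_bins)
        return _fitness_from_tables(cols, relevance, redundancy)
    X = np.asarray(cohort_or_X, dtype=float)
    relevance, redundancy = mrmr_tables(X, y, mi_bins)
    return _fitness_from_tables(np.asarray(subset) - 1, relevance, redundancy)


def _tournament(
    rng: np.random.Generator, fitness: np.ndarray, size: int
) -> int:
    contenders = rng.integers(0, fitness.size, size=size)
    return int(contenders[np.argmax(fitness[contenders])])


def _repair(child: np.ndarray, pool: np.ndarray, m: int, lam: int,
            rng: np.random.Generator) -> np.ndarray:
    """Deduplicate a crossover child back to exactly lam distinct ids,
    refilling first from the parents' pool, then globally."""
    uniq = np.unique(child)
    if uniq.size == lam:
        return uniq
    candidates = np.setdiff1d(pool, uniq)
    rng.shuffle(candidates)
    out = np.concatenate([uniq, candidates[: lam - uniq.size]])
    if out.size < lam:
        rest = np.setdiff1d(np.arange(1, m + 1), out)
        out = np.concatenate([out, rng.choice(rest, lam - out.size, replace=False)])
    return np.sort(out)


def ga_search(
    X_or_cohort: "np.ndarray | Cohort",
    y: np.ndarray | None = None,
    config: GAConfig | None = None,
    return_trace: bool = False,
):
    """Evolve fixed-size feature subsets and return the fittest one (sorted
    ids, 1-based).  Tournament selection, uniform crossover with repair,
    single-feature swap mutation, and elitism; reproducible from the seed.

    With ``return_trace`` also returns the best fitness after each
    generation (non-decreasing, by elitism).
    """
    if isinstance(X_or_cohort, Cohort):
        X = X_or_cohort.values
        y = X_or_cohort.labels
    else:
        X = np.asarray(X_or_cohort, dtype=float)
    config = config or GAConfig()
    m = X.shape[1]
    config.validate(m)
    lam = config.lam
    rng = np.random.default_rng(config.seed)

    relevance, redundancy = mrmr_tables(X, y, config.mi_bins)

    def fit(ids: np.ndarray) -> float:
        return _fitness_from_tables(ids - 1, relevance, redundancy)

    if lam == m:
        full = np.arange(1, m + 1)
        trace = [fit(full)] * config.generations
        return (full, trace) if return_trace else full

    pop = np.stack(
        [np.sort(rng.choice(m, lam, replace=False) + 1)
         for _ in range(config.population_size)]
    )
    fitness = np.array([fit(ind) for ind in pop])
    trace = []

    for _ in range(config.generations):
        order = np.argsort(fitness)[::-1]
        next_pop = [pop[i] for i in order[: config.elitism]]
        while len(next_pop) < config.population_size:
            pa = pop[_tournament(rng, fitness, config.tournament_size)]
            pb = pop[_tournament(rng, fitness, config.tournament_size)]
            if rng.random() < config.crossover_rate:
                mask = rng.random(lam) < 0.5
                child = np.where(mask, pa, pb)
                child = _repair(child, np.union1d(pa, pb), m, lam, rng)
            else:
                child = pa.copy()
            if rng.random() < config.mutation_rate:
                pos = rng.integers(lam)
                outside = np.setdiff1d(np.arange(1, m + 1), child)
                child = child.copy()
                child[pos] = rng.choice(outside)
                child = np.sort(child)
            next_pop.append(child)
        pop = np.stack(next_pop)
        fitness = np.array([fit(ind) for ind in pop])
        trace.append(float(fitness.max()))

    best = pop[int(np.argmax(fitness))]
    best = np.sort(best)
    return (best, trace) if return_trace else best


def consensus_runs(
    X_or_cohort: "np.ndarray | Cohort",
    y: np.ndarray | None = None,
    config: GAConfig | None = None,
    runs: int = 30,
) -> ConsensusReport:
    """Repeat the GA ``runs`` times with derived seeds (seed + run index) and
    tally the returned subsets; rfc = fc / runs."""
    if runs < 1:
        raise ValueError("runs must be >= 1")
    config = config or GAConfig()
    tally: dict[tuple[int, ...], int] = {}
    for r in range(runs):
        run_cfg = GAConfig(**{**config.__dict__, "seed": (config.seed + r) % 2**31})
        best = ga_search(X_or_cohort, y, run_cfg)
        key = tuple(int(i) for i in best)
        tally[key] = tally.get(key, 0) + 1
    entries = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    return ConsensusReport(
        lam=config.lam,
        runs=runs,
        entries=[(s, fc, fc / runs) for s, fc in entries],
    )


def lambda_sweep(
    X_or_cohort: "np.ndarray | Cohort",
    y: np.ndarray | None = None,
    lambdas: range | list[int] = range(2, 11),
    runs: int = 30,
    config: GAConfig | None = None,
) -> list[ConsensusReport]:
    """One consensus report per subset size lambda."""
    config = config or GAConfig()
    reports = []
    for lam in lambdas:
        cfg = GAConfig(**{**config.__dict__, "lam": lam})
        reports.append(consensus_runs(X_or_cohort, y, cfg, runs=runs))
    return reports


def exhaustive_best_subset(
    X: np.ndarray, y: np.ndarray, lam: int, mi_bins: int = 4
) -> np.ndarray:
    """Brute-force argmax of the mRMR fitness over all C(m, lam) subsets
    (oracle for small m; exposed for verification)."""
    m = X.shape[1]
    relevance, redundancy = mrmr_tables(X, y, mi_bins)
    best, best_fit = None, -np.inf
    for combo in itertools.combinations(range(m), lam):
        f = _fitness_from_tables(np.asarray(combo), relevance, redundancy)
        if f > best_fit:
            best, best_fit = combo, f
    return np.asarray(best) + 1
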