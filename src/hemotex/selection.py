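"""Feature-subset selection: Inf-FS ranking regularizing a bit-string GA.

Infinite feature selection (Inf-FS) treats features as nodes of a weighted
graph and scores each feature by the summed weight of all paths leaving it,
computed in closed form through the Neumann series

    S = (I - rA)^-1 - I = sum_{l>=1} r^l A^l,

with adjacency A(i,j) mixing pairwise non-redundancy (1 - |spearman rho|)
and marginal dispersion (max of the two rescaled standard deviations), and
r chosen as r_factor / spectral_radius(A) so the series converges.

The genetic algorithm evolves bit-string chromosomes (bit = feature kept)
under a wrapper fitness

    fitness = alpha * gamma + (1 - alpha) * sparsity_reward,

where gamma is hold-out accuracy of a cheap surrogate classifier (1-NN by
default) on the selected columns. Two sparsity terms are available:
``relative`` rewards (n_features - n_selected) / n_selected (unbounded
as subsets shrink) and ``normalized`` (default) rewards
(n_features - n_selected) / n_features, which stays in [0, 1).

The Inf-FS ranking enters twice: initial chromosomes set each bit with a
probability that decreases linearly with Inf-FS rank (0.8 at the top, 0.2
at the bottom), and after the run near-duplicate selected features
(|spearman| > 0.95) are pruned keeping the higher-energy one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats as sstats
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier

from .errors import ParameterError, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureMatrix:
    X: np.ndarray  # (n_samples, n_features)
    y: np.ndarray  # (n_samples,) integer or string labels
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=np.float64)
        y = np.asarray(self.y)
        if X.ndim != 2:
            raise ValidationError("X must be 2D")
        if len(y) != X.shape[0]:
            raise ValidationError("y length must match X rows")
        if not np.isfinite(X).all():
            raise ValidationError("X contains NaN/inf")
        if len(np.unique(y)) < 2:
            raise ValidationError("need at least 2 classes")
        names = self.feature_names or tuple(f"f{i}" for i in range(X.shape[1]))
        if len(names) != X.shape[1]:
            raise ValidationError("feature_names length mismatch")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "feature_names", tuple(names))

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class InfFSRanking:
    energy: np.ndarray  # per-feature path energy
    order: np.ndarray  # indices, descending energy
    r_factor: float


@dataclass
class Chromosome:
    """Bit-string feature subset; repaired to keep at least one bit set."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)


@dataclass
class GAConfig:
    population_size: Optional[int] = None  # default: n_features capped at 200
    generations: int = 100
    crossover_rate: float = 0.80
    mutation_rate: float = 0.10
    elite_count: int = 2
    alpha: float = 0.9
    surrogate: str = "nn1"  # or "gaussian_nb"
    n_eval_splits: int = 3  # hold-out repeats averaged into gamma
    fitness_formula: str = "normalized"  # or "relative"
    mutation_mode: str = "per_chromosome"  # or "per_bit"
    selection_mode: str = "roulette"  # or "tournament"
    redundancy_rho: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("crossover_rate", "mutation_rate", "alpha"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be in [0,1], got {v}")
        if self.fitness_formula not in ("normalized", "relative"):
            raise ParameterError(f"unknown fitness_formula {self.fitness_formula!r}")
        if self.surrogate not in ("nn1", "gaussian_nb"):
            raise ParameterError(f"unknown surrogate {self.surrogate!r}")

    def resolve_population(self, n_features: int) -> int:
        pop = self.population_size or min(n_features, 200)
        if self.elite_count >= pop:
            raise ParameterError("elite_count must be < population_size")
        return pop


@dataclass(frozen=True)
class SelectionResult:
    selected_indices: np.ndarray
    selected_names: tuple[str, ...]
    best_fitness_trace: np.ndarray  # best-so-far per generation
    best_chromosome: Chromosome
    gamma_final: float


def _spearman_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise Spearman correlations with a guaranteed (m, m) shape.

    Rank-transform per column then Pearson; constant columns (undefined
    correlation) are treated as uncorrelated (0).
    """
    ranks = sstats.rankdata(X, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.atleast_2d(np.nan_to_num(np.asarray(rho, dtype=np.float64),
                                      nan=0.0))
    np.fill_diagonal(rho, 1.0)
    return rho


def _adjacency(fm: FeatureMatrix, corr_weight: float) -> np.ndarray:
    rho = _spearman_matrix(fm.X)
    stds = fm.X.std(axis=0)
    smax = stds.max()
    s = stds / smax if smax > 0 else stds
    pair_std = np.maximum.outer(s, s)
    return corr_weight * (1.0 - np.abs(rho)) + (1.0 - corr_weight) * pair_std


def neumann_transform(A: np.ndarray, r: float) -> np.ndarray:
    """S = (I - rA)^-1 - I, the closed form of sum_{l>=1} r^l A^l.

    Requires r * spectral_radius(A) < 1 for the series to converge.
    """
    n = A.shape[0]
    return np.linalg.inv(np.eye(n) - r * A) - np.eye(n)


def infs_rank(
    fm: FeatureMatrix, r_factor: float = 0.5, corr_weight: float = 0.5
) -> InfFSRanking:
    """Closed-form Inf-FS path energy per feature (higher = more relevant)."""
    n = fm.n_features
    if n < 2:
        raise ValidationError("Inf-FS needs at least 2 features "
                              "(pairwise graph undefined)")
    if not (0.0 < r_factor < 1.0):
        raise ParameterError(f"r_factor must be in (0,1), got {r_factor}")
    A = _adjacency(fm, corr_weight)
    radius = float(np.abs(np.linalg.eigvals(A)).max())
    r = r_factor / radius if radius > 0 else r_factor
    S = neumann_transform(A, r)
    energy = S.sum(axis=1)
    order = np.argsort(-energy, kind="stable")
    return InfFSRanking(energy=energy, order=order, r_factor=r_factor)


def _make_surrogate(kind: str):
    if kind == "nn1":
        return KNeighborsClassifier(n_neighbors=1)
    return GaussianNB()


def _holdout_accuracy(
    fm: FeatureMatrix, subset: Chromosome, cfg: GAConfig, split_seed: int
) -> float:
    seed = split_seed % (2**31 - 1)
    for _ in range(10):
        tr, te = train_test_split(
            np.arange(len(fm.y)), test_size=0.3, random_state=seed,
            stratify=fm.y,
        )
        if len(np.unique(fm.y[tr])) == len(np.unique(fm.y)):
            break
        log.warning("class missing from train split; resampling with seed+1")
        seed += 1
    cols = subset.indices
    clf = _make_surrogate(cfg.surrogate)
    clf.fit(fm.X[np.ix_(tr, cols)], fm.y[tr])
    pred = clf.predict(fm.X[np.ix_(te, cols)])
    assert not np.array_equal(np.sort(tr), np.sort(te))  # held-out rows only
    return float(np.mean(pred == fm.y[te]))


def surrogate_accuracy(
    fm: FeatureMatrix, subset: Chromosome, cfg: GAConfig, split_seed: int
) -> float:
    """Stratified 70/30 hold-out accuracy of the cheap surrogate on the
    selected columns, averaged over ``cfg.n_eval_splits`` repeats.

    The split seeds depend only on ``split_seed``, so all chromosomes
    within a GA run are scored on identical held-out rows; averaging a few
    repeats sharpens gamma enough that near-saturated subsets remain
    distinguishable (one noisy hold-out cannot tell 'good' from 'best').
    """
    if subset.n_selected == 0:
        raise ValidationError("subset is empty")
    return float(np.mean([
        _holdout_accuracy(fm, subset, cfg, split_seed + 7001 * j)
        for j in range(max(1, cfg.n_eval_splits))
    ]))


def fitness_value(
    gamma: float, n_features: int, n_selected: int,
    alpha: float, formula: str = "normalized",
) -> float:
    """alpha * gamma + (1 - alpha) * sparsity term (see module docstring)."""
    beta = 1.0 - alpha
    if formula == "relative":
        sparsity = (n_features - n_selected) / n_selected
    elif formula == "normalized":
        sparsity = (n_features - n_selected) / n_features
    else:
        raise ParameterError(f"unknown formula {formula!r}")
    return alpha * gamma + beta * sparsity


def _repair(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not bits.any():
        bits = bits.copy()
        bits[rng.integers(len(bits))] = True
        log.debug("repaired empty chromosome")
    return bits


def ga_fitness(
    chrom: Chromosome, fm: FeatureMatrix, cfg: GAConfig, split_seed: int = 0
) -> float:
    gamma = surrogate_accuracy(fm, chrom, cfg, split_seed)
    return fitness_value(gamma, fm.n_features, chrom.n_selected,
                         cfg.alpha, cfg.fitness_formula)


def initialize_population(
    ranking: InfFSRanking, cfg: GAConfig, n_features: int,
    rng: Optional[np.random.Generator] = None,
) -> list[Chromosome]:
    """Rank-biased initial bit strings: P(bit set) runs linearly from 0.8
    for the top Inf-FS feature to 0.2 for the bottom one; one chromosome is
    forced to exactly the top-50% features."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    pop_size = cfg.resolve_population(n_features)
    p = _rank_bias(ranking, n_features)
    population = []
    top_half = np.zeros(n_features, dtype=bool)
    top_half[ranking.order[: max(1, n_features // 2)]] = True
    population.append(Chromosome(top_half))
    while len(population) < pop_size:
        bits = _repair(rng.random(n_features) < p, rng)
        population.append(Chromosome(bits))
    return population


def _roulette(fitness: np.ndarray, rng: np.random.Generator) -> int:
    shifted = fitness - fitness.min() + 1e-12
    return int(rng.choice(len(fitness), p=shifted / shifted.sum()))


def _tournament(fitness: np.ndarray, rng: np.random.Generator, k: int = 3) -> int:
    cand = rng.integers(0, len(fitness), size=k)
    return int(cand[np.argmax(fitness[cand])])


def _crossover(
    a: np.ndarray, b: np.ndarray, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    if rng.random() < rate and len(a) > 1:
        cut = int(rng.integers(1, len(a)))
        return (np.concatenate([a[:cut], b[cut:]]),
                np.concatenate([b[:cut], a[cut:]]))
    return a.copy(), b.copy()


def _rank_bias(ranking: InfFSRanking, n_features: int) -> np.ndarray:
    """P(bit set) per feature, linear in Inf-FS rank: 0.8 top, 0.2 bottom."""
    rank_of = np.empty(n_features, dtype=int)
    rank_of[ranking.order] = np.arange(n_features)
    return 0.8 - 0.6 * rank_of / max(n_features - 1, 1)


def _mutate(
    bits: np.ndarray, cfg: GAConfig, rng: np.random.Generator,
    bias: Optional[np.ndarray] = None,
) -> np.ndarray:
    if cfg.mutation_mode == "per_chromosome":
        # one guided bit flip: turning ON favors high Inf-FS relevance,
        # turning OFF favors low relevance (uniform when bias is absent)
        if rng.random() < cfg.mutation_rate:
            if bias is None:
                i = int(rng.integers(len(bits)))
            else:
                w = np.where(bits, 1.0 - bias, bias)
                i = int(rng.choice(len(bits), p=w / w.sum()))
            bits[i] = ~bits[i]
    else:  # per_bit: independent flips at the literal rate
        flips = rng.random(len(bits)) < cfg.mutation_rate
        bits ^= flips
    return bits


def _prune_redundant(
    chrom: Chromosome, fm: FeatureMatrix, ranking: InfFSRanking, rho_cut: float
) -> Chromosome:
    """Among selected features, drop one of any |spearman| > rho_cut pair,
    keeping the higher Inf-FS energy."""
    idx = chrom.indices
    if len(idx) < 2:
        return chrom
    rho = np.abs(_spearman_matrix(fm.X[:, idx]))
    keep = np.ones(len(idx), dtype=bool)
    by_energy = np.argsort(-ranking.energy[idx], kind="stable")
    for a_pos in by_energy:
        if not keep[a_pos]:
            continue
        dup = (rho[a_pos] > rho_cut) & keep
        dup[a_pos] = False
        keep[dup] = False
    bits = np.zeros(fm.n_features, dtype=bool)
    bits[idx[keep]] = True
    return Chromosome(bits)


def evolve(fm: FeatureMatrix, cfg: GAConfig) -> SelectionResult:
    """Generational GA with elitism; returns the best-ever subset.

    Parent selection is fitness-proportional (roulette) by default;
    single-point crossover at ``crossover_rate``; mutation per config; the
    ``elite_count`` fittest chromosomes pass unchanged, which makes the
    best-so-far trace non-decreasing.
    """
    rng = np.random.default_rng(cfg.seed)
    split_seed = int(rng.integers(2**31 - 1))
    ranking = infs_rank(fm)
    bias = _rank_bias(ranking, fm.n_features)
    pop = initialize_population(ranking, cfg, fm.n_features, rng)
    pop_size = len(pop)
    select = _roulette if cfg.selection_mode == "roulette" else _tournament

    def score(ch: Chromosome) -> float:
        return ga_fitness(ch, fm, cfg, split_seed)

    fitness = np.array([score(ch) for ch in pop])
    best_i = int(np.argmax(fitness))
    best = Chromosome(pop[best_i].bits.copy())
    best_fit = float(fitness[best_i])
    trace = np.empty(cfg.generations)

    for gen in range(cfg.generations):
        elite_idx = np.argsort(-fitness, kind="stable")[: cfg.elite_count]
        children = [Chromosome(pop[i].bits.copy()) for i in elite_idx]
        while len(children) < pop_size:
            pa = pop[select(fitness, rng)].bits
            pb = pop[select(fitness, rng)].bits
            ca, cb = _crossover(pa, pb, cfg.crossover_rate, rng)
            for bits in (ca, cb):
                if len(children) < pop_size:
                    bits = _repair(_mutate(bits, cfg, rng, bias), rng)
                    children.append(Chromosome(bits))
        pop = children
        fitness = np.array([score(ch) for ch in pop])
        gen_best = int(np.argmax(fitness))
        if fitness[gen_best] > best_fit:
            best_fit = float(fitness[gen_best])
            best = Chromosome(pop[gen_best].bits.copy())
        trace[gen] = best_fit

    pruned = _prune_redundant(best, fm, ranking, cfg.redundancy_rho)
    if pruned.n_selected == 0:
        pruned = best
    gamma = surrogate_accuracy(fm, pruned, cfg, split_seed)
    idx = pruned.indices
    return SelectionResult(
        selected_indices=idx,
        selected_names=tuple(fm.feature_names[i] for i in idx),
        best_fitness_trace=trace,
        best_chromosome=pruned,
        gamma_final=gamma,
    )
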