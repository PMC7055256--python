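"""Splitting founders into two heterotic pools.

Three strategies are implemented, matching how breeders could seed pools at
the very start of a hybrid programme:

* ``random`` — a uniform random balanced bipartition;
* ``genetic_distance`` — rank founders on the first principal component of
  their centered SNP dosage matrix and cut at the median (lowest half to
  pool A), which yields exactly equal pools;
* ``hybrid_performance`` — a genetic algorithm over balanced bipartitions
  maximising the mean F1 TGV of all between-pool crosses, evaluated on the
  full diallel of the founders.

An exhaustive-search oracle over all balanced bipartitions is provided for
small founder sets; the GA is validated against it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .trait_architecture import TraitArchitecture, cross_tgv_matrix

__all__ = [
    "PoolAssignment",
    "DiallelTable",
    "GAParams",
    "f1_hybrid_dosage",
    "full_diallel",
    "split_random",
    "split_genetic_distance",
    "split_hybrid_performance",
    "exhaustive_best_split",
    "between_pool_mean",
    "pc1_scores",
]


@dataclass(frozen=True)
class PoolAssignment:
    """Balanced bipartition of founders into heterotic pools A and B."""

    pool_a: np.ndarray
    pool_b: np.ndarray
    strategy: str

    def __post_init__(self) -> None:
        a, b = np.asarray(self.pool_a), np.asarray(self.pool_b)
        if a.size != b.size:
            raise ValueError("pools must be the same size")
        if np.intersect1d(a, b).size:
            raise ValueError("pools overlap")
        n = a.size + b.size
        if not np.array_equal(np.sort(np.concatenate([a, b])), np.arange(n)):
            raise ValueError("pools must partition founders 0..n-1")

    @property
    def n_founders(self) -> int:
        return self.pool_a.size + self.pool_b.size

    def to_tsv(self) -> str:
        lines = ["founder_id\tpool"]
        pool = {}
        for i in self.pool_a:
            pool[int(i)] = "A"
        for i in self.pool_b:
            pool[int(i)] = "B"
        lines += [f"{i}\t{pool[i]}" for i in sorted(pool)]
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class DiallelTable:
    """F1 TGV for all ordered founder pairs; diagonal entries are the parents.

    For inbred parents a self reproduces the parent genotype, so the diagonal
    holds parental TGV and the matrix is symmetric.
    """

    hybrid_tgv: np.ndarray

    def __post_init__(self) -> None:
        m = self.hybrid_tgv
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("diallel table must be square")
        if not np.allclose(m, m.T):
            raise ValueError("diallel table must be symmetric for inbred parents")

    @property
    def n_founders(self) -> int:
        return self.hybrid_tgv.shape[0]

    def to_tsv(self) -> str:
        ids = [f"F{i:04d}" for i in range(self.n_founders)]
        lines = ["\t".join([""] + ids)]
        for i, row in enumerate(self.hybrid_tgv):
            lines.append("\t".join([ids[i]] + [repr(v) for v in row]))
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class GAParams:
    """Genetic-algorithm configuration for the hybrid-performance split."""

    population_size: int = 200
    n_generations: int = 500
    tournament_size: int = 3
    mutation_rate: float = 0.05  # probability of one A<->B swap per offspring
    stagnation_limit: int = 100  # early stop after this many stale generations
    n_elite: int = 2

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.n_generations < 1:
            raise ValueError("population_size >= 2 and n_generations >= 1 required")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.tournament_size < 1 or self.n_elite < 0:
            raise ValueError("tournament_size >= 1 and n_elite >= 0 required")
        if self.n_elite >= self.population_size:
            raise ValueError("n_elite must be smaller than population_size")


def f1_hybrid_dosage(parent1: np.ndarray, parent2: np.ndarray) -> np.ndarray:
    """Deterministic F1 dosage of two fully inbred parents.

    Per locus: 0x0 -> 0, 0x2 -> 1, 2x2 -> 2, i.e. (d1 + d2) / 2.  Raises for a
    heterozygous parent, whose F1 genotype would require meiotic sampling.
    """
    d1 = np.asarray(parent1)
    d2 = np.asarray(parent2)
    for d in (d1, d2):
        if not np.isin(d, (0, 2)).all():
            raise ValueError("parents must be fully homozygous (dosages in {0, 2})")
    return ((d1 + d2) // 2).astype(np.int8)


def full_diallel(qtn_haplotypes: np.ndarray, arch: TraitArchitecture) -> DiallelTable:
    """Exact F1 TGV for every pair in a full diallel of inbred founders."""
    m = cross_tgv_matrix(qtn_haplotypes, qtn_haplotypes, arch)
    return DiallelTable(hybrid_tgv=(m + m.T) / 2.0)  # symmetrize away float noise


def between_pool_mean(diallel: DiallelTable, assignment: PoolAssignment) -> float:
    """Objective of the hybrid-performance split: mean between-pool F1 TGV."""
    sub = diallel.hybrid_tgv[np.ix_(assignment.pool_a, assignment.pool_b)]
    return float(sub.mean())


def split_random(n_founders: int, seed: int) -> PoolAssignment:
    """Uniform random balanced bipartition."""
    if n_founders % 2:
        raise ValueError("founder count must be even for a balanced split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_founders)
    half = n_founders // 2
    return PoolAssignment(pool_a=np.sort(perm[:half]), pool_b=np.sort(perm[half:]),
                          strategy="random")


def pc1_scores(dosages: np.ndarray) -> np.ndarray:
    """First-principal-component scores of a centered dosage matrix.

    Columns are centered, not variance-scaled (dosages share a scale).  The
    sign is canonicalized so the lowest-index individual with a nonzero score
    scores non-negative, making the split deterministic.
    """
    x = np.asarray(dosages, dtype=np.float64)
    xc = x - x.mean(axis=0)
    if not np.any(xc):
        raise ValueError("all individuals identical at every SNP; PC1 undefined")
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    scores = u[:, 0] * s[0]
    nz = np.flatnonzero(np.abs(scores) > 1e-12 * max(s[0], 1.0))
    if nz.size and scores[nz[0]] < 0:
        scores = -scores
    return scores


def split_genetic_distance(snp_dosages: np.ndarray) -> PoolAssignment:
    """Split founders at the PC1 median of their SNP genotypes.

    Founders are ranked by PC1 score (ties broken by founder index via stable
    sort); the lowest half forms pool A, the highest half pool B, so pools are
    exactly balanced regardless of the score distribution.
    """
    n = snp_dosages.shape[0]
    if n < 2 or n % 2:
        raise ValueError("an even number (>= 2) of founders is required")
    scores = pc1_scores(snp_dosages)
    order = np.argsort(scores, kind="stable")
    half = n // 2
    return PoolAssignment(pool_a=np.sort(order[:half]), pool_b=np.sort(order[half:]),
                          strategy="genetic_distance")


def _masks_to_assignment(mask: np.ndarray, strategy: str) -> PoolAssignment:
    return PoolAssignment(pool_a=np.flatnonzero(mask), pool_b=np.flatnonzero(~mask),
                          strategy=strategy)


def _fitness(pop_masks: np.ndarray, tgv: np.ndarray) -> np.ndarray:
    # mean over A x B cross pairs; pools are balanced so the count is fixed
    n = tgv.shape[0]
    half = n // 2
    m = pop_masks.astype(np.float64)
    cross_sum = np.einsum("ki,ij,kj->k", m, tgv, 1.0 - m)
    return cross_sum / (half * (n - half))


def exhaustive_best_split(diallel: DiallelTable, max_founders: int = 16) -> tuple[PoolAssignment, float]:
    """Exhaustive optimum over all balanced bipartitions (small founder sets).

    Founder 0 is fixed in pool A to skip label-swapped duplicates; the search
    covers C(n-1, n/2 - 1) bipartitions.
    """
    n = diallel.n_founders
    if n % 2:
        raise ValueError("founder count must be even")
    if n > max_founders:
        raise ValueError(f"exhaustive search limited to {max_founders} founders")
    tgv = diallel.hybrid_tgv
    half = n // 2
    best_obj = -np.inf
    best_a: tuple[int, ...] | None = None
    for rest in combinations(range(1, n), half - 1):
        a = (0,) + rest
        mask = np.zeros(n, dtype=bool)
        mask[list(a)] = True
        obj = tgv[np.ix_(mask, ~mask)].mean()
        if obj > best_obj:
            best_obj, best_a = obj, a
    assert best_a is not None
    mask = np.zeros(n, dtype=bool)
    mask[list(best_a)] = True
    return _masks_to_assignment(mask, "hybrid_performance"), float(best_obj)


def split_hybrid_performance(diallel: DiallelTable, ga_params: GAParams | None = None,
                             seed: int = 0) -> tuple[PoolAssignment, float]:
    """GA search for the balanced bipartition maximising mean between-pool F1 TGV.

    Balanced binary encoding with elitism, tournament selection, uniform
    crossover followed by a repair step restoring the 50/50 balance, and swap
    mutation.  Stops early when the best objective has not improved for
    ``stagnation_limit`` generations; if the full generation budget is
    exhausted without stagnating, the best-found split is returned with a
    warning.  Deterministic under ``seed``.

    Returns ``(assignment, objective)``.
    """
    ga = ga_params or GAParams()
    n = diallel.n_founders
    if n % 2:
        raise ValueError("founder count must be even")
    half = n // 2
    tgv = diallel.hybrid_tgv
    rng = np.random.default_rng(seed)
    psize = ga.population_size

    pop = np.zeros((psize, n), dtype=bool)
    for k in range(psize):
        pop[k, rng.permutation(n)[:half]] = True
    fit = _fitness(pop, tgv)

    best_idx = int(np.argmax(fit))
    best_mask, best_fit = pop[best_idx].copy(), float(fit[best_idx])
    stagnant = 0
    converged = False
    for _ in range(ga.n_generations):
        # tournament selection of two parent sets
        cand = rng.integers(psize, size=(2, psize, ga.tournament_size))
        winners = cand[np.arange(2)[:, None], np.arange(psize)[None, :],
                       np.argmax(fit[cand], axis=2)]
        p1, p2 = pop[winners[0]], pop[winners[1]]
        # uniform crossover + repair to exact balance
        take = rng.random((psize, n)) < 0.5
        child = np.where(take, p1, p2)
        for k in range(psize):
            excess = int(child[k].sum()) - half
            if excess > 0:
                on = np.flatnonzero(child[k])
                child[k, rng.choice(on, size=excess, replace=False)] = False
            elif excess < 0:
                off = np.flatnonzero(~child[k])
                child[k, rng.choice(off, size=-excess, replace=False)] = True
        # swap mutation: exchange one A member with one B member
        mutate = np.flatnonzero(rng.random(psize) < ga.mutation_rate)
        for k in mutate:
            on = np.flatnonzero(child[k])
            off = np.flatnonzero(~child[k])
            child[k, rng.choice(on)] = False
            child[k, rng.choice(off)] = True
        # elitism: keep the best masks seen so far
        if ga.n_elite:
            elite_order = np.argsort(fit)[::-1][: ga.n_elite]
            child[: ga.n_elite] = pop[elite_order]
        pop = child
        fit = _fitness(pop, tgv)
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit + 1e-12:
            best_fit = float(fit[gen_best])
            best_mask = pop[gen_best].copy()
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= ga.stagnation_limit:
                converged = True
                break
    if not converged:
        warnings.warn("GA budget exhausted before convergence; returning best-found split",
                      RuntimeWarning, stacklevel=2)
    return _masks_to_assignment(best_mask, "hybrid_performance"), best_fit
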