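"""Meiosis, doubled-haploid production and the recurrent-selection schemes.

Every individual in the forward phase is a doubled haploid (DH), so a line is
represented by a single haplotype over the tracked loci (SNP + QTN) and its
dosage is twice that haplotype.  A cross between two inbreds gives a
deterministic F1; one meiotic gamete is drawn from the F1 (Poisson crossovers
on the genetic map, no interference) and doubled to give the DH progeny.

Two selection schemes are simulated:

* reciprocal recurrent selection on true GCA (RRS-TGV): within each heterotic
  pool, random matings produce DH progeny whose exact general combining
  ability is computed against the opposite pool's current parents; the top
  fraction becomes the next cycle's parents, synchronously in both pools;
* per se selection (control): one undivided population, DH lines ranked on
  their own TGV, with hybrid performance reported on the half-diallel of the
  selected lines (selfs excluded).

Both schemes use the same census (1,000 new DH per cycle at default scale)
and the same 10% selection proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .founder_sim import FounderPopulation, HaplotypePanel, LociAssignment
from .trait_architecture import TraitArchitecture, cross_tgv_matrix, tgv_inbred
from .pool_formation import (
    GAParams,
    PoolAssignment,
    full_diallel,
    split_genetic_distance,
    split_hybrid_performance,
    split_random,
)
from .diversity_metrics import DiversityProjection, fit_diversity_axes, pool_pc1_summary, project_population

__all__ = [
    "GeneticMap",
    "Population",
    "SchemeConfig",
    "CycleRecord",
    "tracked_loci",
    "population_from_founders",
    "sample_crossovers",
    "meiosis_gamete",
    "dh_progeny",
    "random_matings",
    "gca_scores",
    "truncation_select",
    "make_split",
    "run_rrs_cycle",
    "run_perse_scheme",
    "run_scenario",
    "STRATEGIES",
]

STRATEGIES = ("random", "genetic_distance", "hybrid_performance", "control")


@dataclass(frozen=True)
class GeneticMap:
    """Genetic map of the tracked loci (assigned SNP + QTN), flattened.

    ``positions[c]`` holds the map positions (Morgans) of the tracked loci on
    chromosome ``c``; ``lengths[c]`` is the chromosome's genetic length.
    ``snp_cols`` / ``qtn_cols`` index the SNP and QTN columns of the flattened
    (loci concatenated across chromosomes) haplotype matrices.
    """

    positions: tuple[np.ndarray, ...]
    lengths: np.ndarray
    snp_cols: np.ndarray
    qtn_cols: np.ndarray

    @property
    def n_loci(self) -> int:
        return sum(p.size for p in self.positions)

    @property
    def n_chromosomes(self) -> int:
        return len(self.positions)

    @property
    def offsets(self) -> np.ndarray:
        return np.concatenate(([0], np.cumsum([p.size for p in self.positions])))


def tracked_loci(panel: HaplotypePanel, loci: LociAssignment) -> GeneticMap:
    """Build the forward-phase genetic map from the assigned loci.

    Only assigned loci are tracked through breeding cycles; surplus
    segregating sites stay in the panel but are dropped here.
    """
    positions = []
    snp_cols, qtn_cols = [], []
    offset = 0
    for c in range(panel.n_chromosomes):
        sites = np.concatenate([loci.snp_loci[c], loci.qtn_loci[c]])
        is_snp = np.concatenate([np.ones(loci.snp_loci[c].size, bool),
                                 np.zeros(loci.qtn_loci[c].size, bool)])
        order = np.argsort(sites, kind="stable")
        sites, is_snp = sites[order], is_snp[order]
        positions.append(panel.genetic_positions(c)[sites])
        snp_cols.append(offset + np.flatnonzero(is_snp))
        qtn_cols.append(offset + np.flatnonzero(~is_snp))
        offset += sites.size
    return GeneticMap(
        positions=tuple(positions),
        lengths=np.full(panel.n_chromosomes, panel.params.genetic_length),
        snp_cols=np.concatenate(snp_cols),
        qtn_cols=np.concatenate(qtn_cols),
    )


@dataclass
class Population:
    """A set of fully inbred DH lines over the tracked loci.

    ``haplotypes`` is (n, n_tracked_loci) uint8; the genotype dosage of every
    line is exactly twice its haplotype, so homozygosity holds by
    construction.
    """

    haplotypes: np.ndarray
    gmap: GeneticMap
    pool: str = "control"
    cycle: int = 0

    def __post_init__(self) -> None:
        self.haplotypes = np.atleast_2d(np.asarray(self.haplotypes, dtype=np.uint8))
        if self.haplotypes.shape[1] != self.gmap.n_loci:
            raise ValueError("haplotype columns must match the tracked loci count")

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    def dosages(self) -> np.ndarray:
        return (2 * self.haplotypes).astype(np.int8)

    def qtn_haplotypes(self) -> np.ndarray:
        return self.haplotypes[:, self.gmap.qtn_cols]

    def snp_dosages(self) -> np.ndarray:
        return (2 * self.haplotypes[:, self.gmap.snp_cols]).astype(np.int8)

    def tgv(self, arch: TraitArchitecture) -> np.ndarray:
        return tgv_inbred(self.qtn_haplotypes(), arch)

    def subset(self, idx: np.ndarray, pool: str | None = None,
               cycle: int | None = None) -> "Population":
        return Population(
            haplotypes=self.haplotypes[idx].copy(), gmap=self.gmap,
            pool=self.pool if pool is None else pool,
            cycle=self.cycle if cycle is None else cycle,
        )


def population_from_founders(founders: FounderPopulation, loci: LociAssignment,
                             gmap: GeneticMap | None = None, pool: str = "control") -> Population:
    """Restrict founders to the tracked loci, ready for forward simulation."""
    gmap = gmap or tracked_loci(founders.panel, loci)
    blocks = []
    for c in range(founders.panel.n_chromosomes):
        sites = np.sort(np.concatenate([loci.snp_loci[c], loci.qtn_loci[c]]))
        blocks.append(founders.haplotypes[c][:, sites])
    return Population(haplotypes=np.hstack(blocks), gmap=gmap, pool=pool, cycle=0)


@dataclass(frozen=True)
class SchemeConfig:
    """Census and selection bookkeeping shared by both schemes.

    Defaults are the full-scale programme: 500 matings per pool (1,000 new DH
    per cycle between the two pools), 1,000 matings in the undivided control,
    10% truncation selection, 30 cycles.
    """

    n_matings_per_pool: int = 500
    n_matings_control: int = 1000
    selection_proportion: float = 0.10
    n_cycles: int = 30

    def __post_init__(self) -> None:
        if not 0 < self.selection_proportion <= 1:
            raise ValueError("selection_proportion must be in (0, 1]")
        if self.n_matings_per_pool < 1 or self.n_matings_control < 1 or self.n_cycles < 1:
            raise ValueError("counts must be positive")
        for n in (self.n_matings_per_pool, self.n_matings_control):
            k = self.selection_proportion * n
            if abs(k - round(k)) > 1e-9:
                raise ValueError(
                    f"selection_proportion * {n} = {k} is not an integer selected count")
        if self.n_matings_control != 2 * self.n_matings_per_pool:
            raise ValueError(
                "control census must equal the two-pool census "
                "(n_matings_control == 2 * n_matings_per_pool)")

    @property
    def n_selected_per_pool(self) -> int:
        return round(self.selection_proportion * self.n_matings_per_pool)

    @property
    def n_selected_control(self) -> int:
        return round(self.selection_proportion * self.n_matings_control)


@dataclass
class CycleRecord:
    """Per-cycle summary statistics feeding the trajectory figures."""

    cycle: int
    inbred_mean: float
    inbred_var: float
    hybrid_mean: float
    hybrid_var: float
    pool_pc1: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    selected_parent_ids: dict[str, np.ndarray] = field(default_factory=dict)


def sample_crossovers(length_morgans: float, rng: np.random.Generator) -> np.ndarray:
    """Crossover positions for one meiosis on one chromosome.

    Count ~ Poisson(genetic length in Morgans), positions uniform on the map,
    no interference (Haldane's model), no obligate chiasma.
    """
    k = rng.poisson(length_morgans)
    return np.sort(rng.uniform(0.0, length_morgans, size=k))


def meiosis_gamete(hap1: np.ndarray, hap2: np.ndarray, gmap: GeneticMap,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw one recombinant gamete from a phased parent (two haplotypes).

    Crossovers follow :func:`sample_crossovers` per chromosome and the
    starting haplotype is chosen with probability 1/2.
    """
    hap1 = np.asarray(hap1)
    hap2 = np.asarray(hap2)
    gamete = np.empty(gmap.n_loci, dtype=np.uint8)
    off = gmap.offsets
    for c in range(gmap.n_chromosomes):
        sl = slice(off[c], off[c + 1])
        start = rng.integers(2)
        xo = sample_crossovers(gmap.lengths[c], rng)
        if xo.size == 0:
            src = np.full(off[c + 1] - off[c], start)
        else:
            crossings = np.searchsorted(xo, gmap.positions[c], side="right")
            src = (start + crossings) % 2
        gamete[sl] = np.where(src == 0, hap1[sl], hap2[sl])
    return gamete


def dh_progeny(parent1_hap: np.ndarray, parent2_hap: np.ndarray, gmap: GeneticMap,
               rng: np.random.Generator) -> np.ndarray:
    """One doubled-haploid progeny of a cross between two inbred lines.

    The F1 of two inbreds is phased by construction (one haplotype from each
    parent); a single meiotic gamete is drawn from it and doubled.  The
    returned haplotype, carried in duplicate, IS the DH genotype.
    """
    return meiosis_gamete(parent1_hap, parent2_hap, gmap, rng)


def random_matings(n_parents: int, n_matings: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random pairs of two distinct parents; pairs may repeat.

    Selfs are excluded — a self of a DH would be a clone.  Returns an
    (n_matings, 2) index array.
    """
    if n_parents < 2:
        raise ValueError("at least two parents required for matings")
    first = rng.integers(n_parents, size=n_matings)
    second = rng.integers(n_parents - 1, size=n_matings)
    second = second + (second >= first)
    return np.column_stack([first, second])


def _make_progeny(parents: Population, matings: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    haps = parents.haplotypes
    out = np.empty((matings.shape[0], haps.shape[1]), dtype=np.uint8)
    for k, (i, j) in enumerate(matings):
        out[k] = dh_progeny(haps[i], haps[j], parents.gmap, rng)
    return out


def gca_scores(progeny_qtn_hap: np.ndarray, tester_qtn_hap: np.ndarray,
               arch: TraitArchitecture) -> tuple[np.ndarray, np.ndarray]:
    """Exact GCA of each progeny line against a tester set.

    GCA(p) is the mean TGV of the F1s of p with every tester, computed from
    the deterministic F1 genotypes — no field trial, no error term.  Returns
    ``(scores, hybrid_tgv_matrix)`` with the full progeny x tester TGV matrix
    for reporting.
    """
    if np.atleast_2d(tester_qtn_hap).shape[0] == 0:
        raise ValueError("tester set is empty")
    hybrids = cross_tgv_matrix(progeny_qtn_hap, tester_qtn_hap, arch)
    return hybrids.mean(axis=1), hybrids


def truncation_select(scores: np.ndarray, proportion: float) -> np.ndarray:
    """Indices of the top ``proportion`` of scores; ties favour the lower index."""
    scores = np.asarray(scores)
    if scores.size == 0:
        raise ValueError("no scores to select from")
    if not 0 < proportion <= 1:
        raise ValueError("proportion must be in (0, 1]")
    k = round(proportion * scores.size)
    order = np.argsort(-scores, kind="stable")  # stable: equal scores keep index order
    return np.sort(order[:k])


def run_rrs_cycle(pool_a: Population, pool_b: Population, arch: TraitArchitecture,
                  config: SchemeConfig, rng: np.random.Generator,
                  projection: DiversityProjection | None = None,
                  ) -> tuple[Population, Population, CycleRecord]:
    """One synchronous cycle of reciprocal recurrent selection on true GCA.

    Both pools mate, produce DH progeny and are selected against the *same*
    tester generation — the parents that entered the cycle — so the update is
    symmetric.  Inbred and hybrid summaries are computed per pool over all
    progeny / all progeny-x-tester hybrids, then averaged over the two pools.
    """
    cycle = pool_a.cycle + 1
    new_parents: dict[str, Population] = {}
    inbred_stats, hybrid_stats = [], []
    record = CycleRecord(cycle=cycle, inbred_mean=0.0, inbred_var=0.0,
                         hybrid_mean=0.0, hybrid_var=0.0)
    for pool, testers in (("A", pool_b), ("B", pool_a)):
        parents = pool_a if pool == "A" else pool_b
        matings = random_matings(parents.n, config.n_matings_per_pool, rng)
        progeny_hap = _make_progeny(parents, matings, rng)
        progeny = Population(haplotypes=progeny_hap, gmap=parents.gmap,
                             pool=pool, cycle=cycle)
        scores, hybrids = gca_scores(progeny.qtn_haplotypes(),
                                     testers.qtn_haplotypes(), arch)
        sel = truncation_select(scores, config.selection_proportion)
        new_parents[pool] = progeny.subset(sel)
        line_tgv = progeny.tgv(arch)
        inbred_stats.append((line_tgv.mean(), line_tgv.var(ddof=1)))
        hybrid_stats.append((hybrids.mean(), hybrids.var(ddof=1)))
        record.selected_parent_ids[pool] = sel
        if projection is not None:
            scores_pc = project_population(progeny.snp_dosages(), projection)
            record.pool_pc1.update(pool_pc1_summary(scores_pc[:, 0],
                                                    np.full(progeny.n, pool)))
    record.inbred_mean = float(np.mean([s[0] for s in inbred_stats]))
    record.inbred_var = float(np.mean([s[1] for s in inbred_stats]))
    record.hybrid_mean = float(np.mean([s[0] for s in hybrid_stats]))
    record.hybrid_var = float(np.mean([s[1] for s in hybrid_stats]))
    return new_parents["A"], new_parents["B"], record


def run_perse_scheme(founders: Population, arch: TraitArchitecture,
                     config: SchemeConfig, rng: np.random.Generator,
                     projection: DiversityProjection | None = None,
                     ) -> list[CycleRecord]:
    """Per se selection control: one undivided population, selection on line TGV.

    Each cycle makes ``n_matings_control`` random matings among the current
    parents (cycle 1: the founders), ranks the DH progeny on their own TGV and
    promotes the top fraction.  Hybrid performance is reported on the
    half-diallel of the selected lines, selfs excluded.
    """
    parents = founders
    records: list[CycleRecord] = []
    for cycle in range(1, config.n_cycles + 1):
        matings = random_matings(parents.n, config.n_matings_control, rng)
        progeny_hap = _make_progeny(parents, matings, rng)
        progeny = Population(haplotypes=progeny_hap, gmap=parents.gmap,
                             pool="control", cycle=cycle)
        line_tgv = progeny.tgv(arch)
        sel = truncation_select(line_tgv, config.selection_proportion)
        selected = progeny.subset(sel)
        hyb = cross_tgv_matrix(selected.qtn_haplotypes(), selected.qtn_haplotypes(), arch)
        iu = np.triu_indices(selected.n, k=1)  # half-diallel, selfs excluded
        hyb_vals = hyb[iu]
        record = CycleRecord(
            cycle=cycle,
            inbred_mean=float(line_tgv.mean()), inbred_var=float(line_tgv.var(ddof=1)),
            hybrid_mean=float(hyb_vals.mean()), hybrid_var=float(hyb_vals.var(ddof=1)),
            selected_parent_ids={"control": sel},
        )
        if projection is not None:
            scores_pc = project_population(progeny.snp_dosages(), projection)
            record.pool_pc1.update(pool_pc1_summary(scores_pc[:, 0],
                                                    np.full(progeny.n, "control")))
        records.append(record)
        parents = selected
    return records


def make_split(strategy: str, founders_pop: Population, arch: TraitArchitecture,
               seed: int, ga_params: GAParams | None = None) -> PoolAssignment:
    """Dispatch to the pool-formation strategy for an RRS scenario."""
    if strategy == "random":
        return split_random(founders_pop.n, seed)
    if strategy == "genetic_distance":
        return split_genetic_distance(founders_pop.snp_dosages())
    if strategy == "hybrid_performance":
        diallel = full_diallel(founders_pop.qtn_haplotypes(), arch)
        assignment, _ = split_hybrid_performance(diallel, ga_params, seed)
        return assignment
    raise ValueError(f"unknown splitting strategy: {strategy!r}")


def run_scenario(founders: FounderPopulation, loci: LociAssignment,
                 arch: TraitArchitecture, strategy: str, config: SchemeConfig,
                 rng: np.random.Generator | int,
                 ga_params: GAParams | None = None,
                 track_diversity: bool = True) -> list[CycleRecord]:
    """Run one full scenario: split (if RRS) then ``config.n_cycles`` cycles.

    ``strategy`` is one of ``random``, ``genetic_distance``,
    ``hybrid_performance`` (RRS-TGV after the corresponding split) or
    ``control`` (per se selection, no split).  Diversity axes are fitted once
    on the founders and later cycles are projected onto them, keeping PC1
    comparable across cycles.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy: {strategy!r}; expected one of {STRATEGIES}")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    gmap = tracked_loci(founders.panel, loci)
    base = population_from_founders(founders, loci, gmap)
    projection = fit_diversity_axes(base.snp_dosages()) if track_diversity else None
    if strategy == "control":
        return run_perse_scheme(base, arch, config, rng, projection)
    split_seed = int(rng.integers(2**31 - 1))
    assignment = make_split(strategy, base, arch, split_seed, ga_params)
    pool_a = base.subset(assignment.pool_a, pool="A")
    pool_b = base.subset(assignment.pool_b, pool="B")
    records: list[CycleRecord] = []
    for _ in range(config.n_cycles):
        pool_a, pool_b, record = run_rrs_cycle(pool_a, pool_b, arch, config, rng, projection)
        records.append(record)
    return records
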