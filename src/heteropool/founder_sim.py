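"""Coalescent simulation of founder haplotypes and locus panel assignment.

Founders are fully inbred lines obtained by doubling neutral coalescent
haplotypes: chromosome ``c`` of founder ``i`` carries two copies of sampled
haplotype ``i``, so every founder is homozygous at every site.  Segregating
sites are then partitioned, per chromosome, into a neutral SNP panel (used
for diversity metrics and the genetic-distance split) and a QTN panel (which
carries the trait effects).

The coalescent engine is pluggable.  The default engine uses msprime with a
constant-size neutral demography; any callable with the same signature can
substitute, e.g. a simplified drift-forward generator in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "GenomeParams",
    "HaplotypePanel",
    "FounderPopulation",
    "LociAssignment",
    "msprime_engine",
    "simulate_founder_haplotypes",
    "make_inbred_founders",
    "select_loci",
    "write_founders_vcf",
    "read_founders_vcf",
]


@dataclass(frozen=True)
class GenomeParams:
    """Genome model: equal-sized chromosomes with uniform rates.

    Defaults describe a model self-pollinating crop: 10 chromosome pairs of
    1 Morgan / 1e8 bp each, recombination 1e-8 per bp per meiosis, mutation
    2.5e-8 per bp per generation, effective population size 100.
    """

    n_chromosomes: int = 10
    genetic_length: float = 1.0  # Morgans per chromosome
    physical_length: float = 1e8  # bp per chromosome
    recombination_rate: float = 1e-8  # per bp per meiosis
    mutation_rate: float = 2.5e-8  # per bp per generation
    effective_pop_size: int = 100

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        for name in ("genetic_length", "physical_length",
                     "recombination_rate", "mutation_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.effective_pop_size < 2:
            raise ValueError("effective_pop_size must be >= 2")
        expected = self.physical_length * self.recombination_rate
        if not np.isclose(self.genetic_length, expected, rtol=1e-9):
            raise ValueError(
                "genetic_length must equal physical_length * recombination_rate "
                f"({self.genetic_length} != {expected})"
            )


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes over positioned sites, one block per chromosome.

    ``haplotypes[c]`` is an (n_haplotypes, n_sites_c) uint8 matrix of ancestral
    (0) / derived (1) alleles; ``positions[c]`` holds the 1-based bp
    coordinates, strictly increasing.  Every retained site is segregating in
    the panel.
    """

    params: GenomeParams
    positions: list[np.ndarray]  # per chromosome, 1-based bp, int64
    haplotypes: list[np.ndarray]  # per chromosome, (n_hap, n_sites) uint8

    def __post_init__(self) -> None:
        if len(self.positions) != self.params.n_chromosomes:
            raise ValueError("one position array per chromosome required")
        if len(self.haplotypes) != self.params.n_chromosomes:
            raise ValueError("one haplotype matrix per chromosome required")
        n_hap = {h.shape[0] for h in self.haplotypes}
        if len(n_hap) != 1:
            raise ValueError("all chromosomes must carry the same haplotype count")
        for c, (pos, hap) in enumerate(zip(self.positions, self.haplotypes)):
            if hap.shape[1] != pos.shape[0]:
                raise ValueError(f"chromosome {c}: sites/positions mismatch")
            if pos.size and (np.any(np.diff(pos) <= 0) or pos[0] < 1):
                raise ValueError(f"chromosome {c}: positions must be 1-based, strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes[0].shape[0]

    @property
    def n_chromosomes(self) -> int:
        return self.params.n_chromosomes

    def n_sites(self, chromosome: int | None = None) -> int:
        if chromosome is None:
            return sum(h.shape[1] for h in self.haplotypes)
        return self.haplotypes[chromosome].shape[1]

    def genetic_positions(self, chromosome: int) -> np.ndarray:
        """Map positions in Morgans (bp * recombination rate)."""
        return self.positions[chromosome] * self.params.recombination_rate

    def allele_frequencies(self, chromosome: int) -> np.ndarray:
        return self.haplotypes[chromosome].mean(axis=0)


@dataclass
class FounderPopulation:
    """Fully inbred founders: one haplotype each, carried in duplicate.

    ``haplotypes[c]`` is (n_founders, n_sites_c) uint8; dosage at any site is
    ``2 * haplotype``, so every founder is homozygous everywhere.
    """

    panel: HaplotypePanel
    haplotypes: list[np.ndarray] = field(default_factory=list)

    @property
    def n_founders(self) -> int:
        return self.haplotypes[0].shape[0]

    def dosages(self, chromosome: int) -> np.ndarray:
        return (2 * self.haplotypes[chromosome]).astype(np.int8)

    def dosages_at(self, loci: "LociAssignment", which: str = "snp") -> np.ndarray:
        """Founder dosage matrix restricted to the SNP or QTN panel."""
        idx = loci.snp_loci if which == "snp" else loci.qtn_loci
        return np.hstack([self.dosages(c)[:, idx[c]] for c in range(len(self.haplotypes))])

    def haplotypes_at(self, loci: "LociAssignment", which: str = "qtn") -> np.ndarray:
        idx = loci.snp_loci if which == "snp" else loci.qtn_loci
        return np.hstack([self.haplotypes[c][:, idx[c]] for c in range(len(self.haplotypes))])


@dataclass
class LociAssignment:
    """Disjoint per-chromosome SNP and QTN site indices, equal counts per chromosome."""

    snp_loci: list[np.ndarray]
    qtn_loci: list[np.ndarray]
    n_snp_total: int
    n_qtn_total: int

    def __post_init__(self) -> None:
        n_chrom = len(self.snp_loci)
        if len(self.qtn_loci) != n_chrom:
            raise ValueError("snp_loci and qtn_loci must cover the same chromosomes")
        snp_counts = {a.size for a in self.snp_loci}
        qtn_counts = {a.size for a in self.qtn_loci}
        if len(snp_counts) != 1 or len(qtn_counts) != 1:
            raise ValueError("equal SNP and QTN counts per chromosome required")
        if sum(a.size for a in self.snp_loci) != self.n_snp_total:
            raise ValueError("n_snp_total does not match assigned loci")
        if sum(a.size for a in self.qtn_loci) != self.n_qtn_total:
            raise ValueError("n_qtn_total does not match assigned loci")
        for c, (s, q) in enumerate(zip(self.snp_loci, self.qtn_loci)):
            if np.intersect1d(s, q).size:
                raise ValueError(f"chromosome {c}: SNP and QTN loci overlap")


def msprime_engine(params: GenomeParams, n_haplotypes: int, seed: int) -> tuple[
        list[np.ndarray], list[np.ndarray]]:
    """Neutral coalescent with recombination via msprime, one run per chromosome.

    Returns per-chromosome (positions, haplotype matrix).  Alleles are coded
    ancestral=0 / derived=1 under an infinite-sites binary mutation model;
    multi-mutation sites are discarded to keep every site strictly biallelic.
    """
    import msprime

    positions: list[np.ndarray] = []
    haplotypes: list[np.ndarray] = []
    for c in range(params.n_chromosomes):
        # independent chromosomes: separate tree sequences, distinct seeds
        anc_seed = (seed * 1_000_003 + 2 * c) % (2**31 - 2) + 1
        mut_seed = (seed * 1_000_003 + 2 * c + 1) % (2**31 - 2) + 1
        # ploidy-1 samples on the diploid timescale: with haploid ploidy msprime
        # coalesces pairs at rate 1/population_size, so 2*Ne restores the
        # standard diploid theta = 4*Ne*mu*L.
        ts = msprime.sim_ancestry(
            samples=n_haplotypes,
            ploidy=1,
            population_size=2 * params.effective_pop_size,
            sequence_length=params.physical_length,
            recombination_rate=params.recombination_rate,
            discrete_genome=True,
            random_seed=anc_seed,
        )
        mts = msprime.sim_mutations(
            ts,
            rate=params.mutation_rate,
            model=msprime.BinaryMutationModel(),
            random_seed=mut_seed,
        )
        pos: list[int] = []
        rows: list[np.ndarray] = []
        for var in mts.variants():
            if len(var.alleles) != 2:
                continue  # recurrent mutation at the site; drop
            geno = var.genotypes.astype(np.uint8)
            f = geno.mean()
            if f <= 0 or f >= 1:
                continue
            pos.append(int(var.site.position) + 1)  # 1-based bp
            rows.append(geno)
        if rows:
            p = np.asarray(pos, dtype=np.int64)
            h = np.asarray(rows, dtype=np.uint8).T
            # discrete_genome can place two mutations on one bp; keep the first
            keep = np.concatenate(([True], np.diff(p) > 0))
            positions.append(p[keep])
            haplotypes.append(np.ascontiguousarray(h[:, keep]))
        else:
            positions.append(np.empty(0, dtype=np.int64))
            haplotypes.append(np.empty((n_haplotypes, 0), dtype=np.uint8))
    return positions, haplotypes


def simulate_founder_haplotypes(
    params: GenomeParams,
    n_haplotypes: int,
    seed: int,
    min_sites_per_chromosome: int = 0,
    engine: Callable[[GenomeParams, int, int], tuple[list[np.ndarray], list[np.ndarray]]] = msprime_engine,
    max_attempts: int = 10,
) -> HaplotypePanel:
    """Simulate founder haplotypes under the neutral coalescent.

    Parameters
    ----------
    min_sites_per_chromosome
        Minimum segregating sites required on every chromosome (e.g. the
        per-chromosome SNP + QTN demand).  If a run falls short the simulation
        is re-run with a derived seed, up to ``max_attempts`` times, then an
        error naming required versus obtained counts is raised.  The retry is
        deterministic: attempt ``k`` uses seed ``seed + k * 7919``.
    engine
        Coalescent backend; default :func:`msprime_engine`.
    """
    if n_haplotypes < 2:
        raise ValueError("n_haplotypes must be >= 2")
    last_counts: list[int] = []
    for attempt in range(max_attempts):
        attempt_seed = (seed + attempt * 7919) % (2**31 - 1)
        positions, haplotypes = engine(params, n_haplotypes, attempt_seed)
        panel = HaplotypePanel(params=params, positions=positions, haplotypes=haplotypes)
        last_counts = [panel.n_sites(c) for c in range(params.n_chromosomes)]
        if all(n >= min_sites_per_chromosome for n in last_counts):
            return panel
    raise RuntimeError(
        f"coalescent yielded too few segregating sites after {max_attempts} attempts: "
        f"required >= {min_sites_per_chromosome} per chromosome, obtained {last_counts}"
    )


def make_inbred_founders(panel: HaplotypePanel, n_founders: int | None = None) -> FounderPopulation:
    """Double the first ``n_founders`` haplotypes into fully inbred founders."""
    if n_founders is None:
        n_founders = panel.n_haplotypes
    if panel.n_haplotypes < n_founders:
        raise ValueError(
            f"panel holds {panel.n_haplotypes} haplotypes, {n_founders} founders requested"
        )
    haps = [h[:n_founders].copy() for h in panel.haplotypes]
    return FounderPopulation(panel=panel, haplotypes=haps)


def select_loci(panel: HaplotypePanel, n_snp: int, n_qtn: int, seed: int) -> LociAssignment:
    """Randomly partition segregating sites into SNP and QTN panels.

    Equal counts per chromosome; SNP and QTN sets are disjoint within each
    chromosome.  Deterministic under ``seed``.
    """
    n_chrom = panel.n_chromosomes
    if n_snp % n_chrom or n_qtn % n_chrom:
        raise ValueError("n_snp and n_qtn must be divisible by the chromosome count")
    snp_per, qtn_per = n_snp // n_chrom, n_qtn // n_chrom
    rng = np.random.default_rng(seed)
    snp_loci, qtn_loci = [], []
    for c in range(n_chrom):
        avail = panel.n_sites(c)
        if avail < snp_per + qtn_per:
            raise ValueError(
                f"chromosome {c}: {avail} segregating sites, "
                f"{snp_per + qtn_per} required ({snp_per} SNP + {qtn_per} QTN)"
            )
        draw = rng.choice(avail, size=snp_per + qtn_per, replace=False)
        snp_loci.append(np.sort(draw[:snp_per]))
        qtn_loci.append(np.sort(draw[snp_per:]))
    return LociAssignment(snp_loci=snp_loci, qtn_loci=qtn_loci,
                          n_snp_total=n_snp, n_qtn_total=n_qtn)


def write_founders_vcf(founders: FounderPopulation, loci: LociAssignment | None,
                       path: str) -> None:
    """Export founder genotypes as VCF v4.2 (one sample per founder).

    Contigs are named chr1..chrN; the INFO field PANEL marks each site as
    SNP, QTN or NONE (unassigned surplus site).
    """
    panel = founders.panel
    n = founders.n_founders
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=PANEL,Number=1,Type=String,'
                 'Description="Locus panel assignment (SNP/QTN/NONE)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in range(panel.n_chromosomes):
            fh.write(f"##contig=<ID=chr{c + 1},length={int(panel.params.physical_length)}>\n")
        samples = "\t".join(f"F{i:04d}" for i in range(n))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for c in range(panel.n_chromosomes):
            tag = np.full(panel.n_sites(c), "NONE", dtype=object)
            if loci is not None:
                tag[loci.snp_loci[c]] = "SNP"
                tag[loci.qtn_loci[c]] = "QTN"
            haps = founders.haplotypes[c]
            for j, pos in enumerate(panel.positions[c]):
                gts = "\t".join("1|1" if a else "0|0" for a in haps[:, j])
                fh.write(f"chr{c + 1}\t{pos}\t.\tA\tT\t.\tPASS\tPANEL={tag[j]}\tGT\t{gts}\n")


def read_founders_vcf(path: str, params: GenomeParams) -> tuple[FounderPopulation, LociAssignment | None]:
    """Import founder genotypes and panel assignment from a VCF written by this package."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    n = len(vcf.samples)
    positions: dict[int, list[int]] = {c: [] for c in range(params.n_chromosomes)}
    rows: dict[int, list[np.ndarray]] = {c: [] for c in range(params.n_chromosomes)}
    tags: dict[int, list[str]] = {c: [] for c in range(params.n_chromosomes)}
    for rec in vcf:
        c = int(rec.CHROM.removeprefix("chr")) - 1
        dos = np.array([g[0] for g in rec.genotypes], dtype=np.uint8)
        positions[c].append(rec.POS)
        rows[c].append(dos)
        tags[c].append(rec.INFO.get("PANEL") or "NONE")
    pos_arrays, hap_arrays, snp_loci, qtn_loci = [], [], [], []
    for c in range(params.n_chromosomes):
        pos_arrays.append(np.asarray(positions[c], dtype=np.int64))
        hap_arrays.append(
            np.asarray(rows[c], dtype=np.uint8).T if rows[c] else np.empty((n, 0), np.uint8))
        t = np.asarray(tags[c], dtype=object)
        snp_loci.append(np.flatnonzero(t == "SNP"))
        qtn_loci.append(np.flatnonzero(t == "QTN"))
    panel = HaplotypePanel(params=params, positions=pos_arrays, haplotypes=hap_arrays)
    founders = FounderPopulation(panel=panel, haplotypes=[h.copy() for h in hap_arrays])
    n_snp = sum(a.size for a in snp_loci)
    n_qtn = sum(a.size for a in qtn_loci)
    loci = None
    if n_snp or n_qtn:
        loci = LociAssignment(snp_loci=snp_loci, qtn_loci=qtn_loci,
                              n_snp_total=n_snp, n_qtn_total=n_qtn)
    return founders, loci
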