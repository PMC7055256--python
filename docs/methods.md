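# Methods

## The simulated programme

`heteropool` models the first decades of a hybrid breeding programme in a
self-pollinating crop as a closed stochastic system with four stages:

1. **Founders.** 100 fully inbred, genetically diverse lines are created by
   simulating neutral coalescent haplotypes (msprime, constant effective
   population size, recombination and mutation at uniform per-bp rates) and
   doubling each haplotype. Chromosomes are independent; each is 1 Morgan and
   10^8 bp, with recombination 10^-8 /bp and mutation 2.5x10^-8 /bp, Ne = 100.
   Segregating sites are partitioned per chromosome into 10,000 SNP (neutral,
   used only for diversity metrics and the genetic-distance split) and 500,
   2,000 or 8,000 QTN (trait-bearing), in equal numbers per chromosome and
   disjoint from each other. Surplus segregating sites are left unassigned
   and are not tracked forward.
2. **Trait.** Additive effects `a ~ N(0,1)`, dominance degrees
   `delta ~ N(mu, 0.2)` with `mu` in {0.2, 0.4, 0.8}, dominance effects
   `d = delta |a|`. Locus contribution to TGV is `a (x-1) + d 1{x=1}` on
   dosage `x`. A single linear calibration (scale on all effects plus an
   intercept) puts founder TGV at mean 100, variance 10.
3. **Pool formation.** Random balanced bipartition; PC1 rank split of the
   centered SNP dosage matrix; or GA maximisation of mean between-pool F1 TGV
   over the full founder diallel.
4. **Selection.** 30 cycles of RRS-TGV (500 within-pool matings per pool, one
   DH per mating, GCA of every progeny computed exactly against the opposite
   pool's 50 parents, top 10% promoted, both pools updated synchronously
   against the same tester generation), or per se selection (1,000 matings in
   one population, top 10% on line TGV, hybrids reported on the selections'
   half-diallel, selfs excluded). Both schemes make 1,000 new DH per cycle
   and select 10%.

All genetic values are exact: there is no environmental error, no estimation,
no genotype-by-environment interaction. Consequently any difference between
strategies is purely genetic, which is the point of the design.

## Assumptions and key modelling choices

- **Coalescent timescale.** Founder haplotypes are sampled as ploidy-1
  lineages on the diploid timescale (pairwise coalescence rate 1/(2Ne)), so
  the expected number of segregating sites follows Watterson's formula with
  theta = 4 Ne mu L; the test suite verifies this against the closed form.
  The demography is constant-size Ne = 100; a different recent history can be
  substituted by plugging another engine callable into
  `simulate_founder_haplotypes`.
- **Meiosis.** Crossover counts are Poisson with mean equal to the map length
  in Morgans, positions uniform, no interference and no obligate chiasma
  (Haldane's model); the two-locus recombination fraction therefore follows
  Haldane's map function, which the tests check by simulation. F1s of inbreds
  are phased by construction, so a DH progeny is a single recombinant gamete
  carried in duplicate.
- **Dominance degrees are not truncated** by default, although the model is
  motivated by incomplete dominance: N(0.8, 0.2) has visible mass above 1 and
  truncation would silently change the sampled distribution. A
  `truncate_degrees` switch (clip to [-1, 1]) is available.
- **Degenerate dominance is allowed.** `DominanceConfig(0.0, 0.0)` makes
  every degree exactly zero. This purely additive null model is used heavily
  in testing because it has exact consequences: every hybrid is its midparent
  mean, GCA ranks coincide with line ranks, and the pool-split objective is
  partition-invariant.
- **Random matings** draw unordered pairs of two *distinct* parents uniformly
  with replacement across matings. Selfs are excluded because a self of a DH
  is a clone; repeats are allowed because 500 pairs from 50 parents forces
  reuse.
- **Hybrid reporting for RRS** uses all progeny-by-tester hybrids (500 x 50
  per pool), and inbred reporting all 500 DH per pool, with the two pools'
  summaries averaged. The control reports hybrids among its selected lines.
  These are different populations of hybrids, and under a purely additive
  trait the control's figure is higher by roughly half a selection
  differential; the comparison between schemes is therefore made at replicate
  standard-error resolution, where the two coincide at low dominance / low
  QTN and RRS dominates at high dominance / high QTN.
- **Variance denominators** are n-1 (sample) everywhere: founder calibration,
  per-cycle variances, and replicate SDs. At n = 100 founders the choice
  moves the calibration scale by under 1%; it is configurable in
  `calibrate_trait`.
- **Ties** in truncation selection are broken by original index (lower index
  wins, via a stable sort). Ties are measure-zero for a continuous trait but
  arise in degenerate tests, and the rule keeps every run bit-reproducible.
- **PC1 conventions.** Dosage columns are centered, not variance-scaled, and
  the axis sign is canonicalized so the lowest-index individual with a
  nonzero score is non-negative. The genetic-distance split is a rank split
  (lowest 50 scores to pool A), which guarantees balanced pools regardless of
  the score distribution. Diversity axes are fitted once on the founders and
  all later cycles are projected onto those fixed axes — per-cycle refitting
  would make scores incomparable across cycles.
- **The GA** for the hybrid-performance split encodes a balanced bipartition
  as a boolean mask, with tournament selection (size 3), uniform crossover
  followed by a repair step restoring balance, one-swap mutation (rate 0.05
  per offspring), elitism (2), population 200 and up to 500 generations with
  early stop after 100 stagnant generations. It is validated against an
  exhaustive oracle on all balanced bipartitions of up to 12 founders. With
  100 founders convergence to the global optimum is not guaranteed (the
  search space is ~5x10^28); exhausting the budget without stagnating returns
  the best-found split with a warning.

## Seeding

Every stochastic operation takes an explicit seed or `numpy.random.Generator`;
the package never touches global RNG state. Grid runs derive sub-seeds from a
master seed via `numpy.random.SeedSequence(master_seed, spawn_key=...)`:
founders depend only on the replicate index, loci on (replicate, n_qtn),
trait effects on (replicate, n_qtn, dominance mean), and forward cycles on
all of those plus the strategy. Within one (qtn, dom, replicate) cell all
four strategies therefore share the identical founders and trait — strategy
comparisons are paired, as in the original experimental design.

## Scale profiles

The full profile — 3 QTN levels x 3 dominance levels x 4 strategies
x 20 replicates x 30 cycles with 1,000 DH per cycle — is supported but takes
hours of CPU. The `desk` profile is the package's reduced standard for tests
and development: 2 chromosomes of 2.5x10^7 bp (kept at 1 Morgan by raising
recombination to 4x10^-8 /bp), 1,000 SNP, QTN levels {100, 400}, 40 founders,
200 matings per pool (400 in the control), 10 cycles, 5 replicates. The
choices preserve the structural invariants: equal loci per chromosome, 10%
selection with the selected count equal to the pool parent count, identical
census between schemes, and enough expected segregating sites (Watterson
expectation ~1,060 per chromosome at n = 40) to fill the loci panels with
margin. If a coalescent run still falls short, it is re-run with a derived
seed a bounded number of times before erroring.

## What the synthetic data does and does not show

The generator *is* the study system — there is no external data — but the
desk profile differs from the full programme in genome size, founder count
and census, so desk-scale results are qualitative reproductions of the
trajectory patterns (hybrid superiority of RRS at high dominance/QTN,
control's superior inbreds, hybrid-variance ordering, pool divergence and
within-pool diversity collapse), not quantitative predictions of the
full-scale trajectories. Nothing here models environmental error, selection
on estimated rather than true values, genotype-by-environment interaction,
overlapping generations, or a finite breeding budget; conclusions transfer to
real programmes only insofar as those omissions are tolerable, which is the
same caveat the underlying experimental design carries.

## Known limitations

- The coalescent founder stage treats chromosomes as independent and sites as
  strictly biallelic (multi-mutation sites are discarded).
- PC1-based diversity summarises a high-dimensional divergence process on one
  fixed axis; pools can diverge in allele frequency while their founder-axis
  PC1 means move little, so the frequency-divergence statistic is the primary
  divergence measure and PC1 range the within-pool diversity measure.
- The GA is stochastic; its optimality is proven only against small
  exhaustive instances.
- `run_grid` parallelism is deliberately absent (cells are cheap to shard
  externally; the resumable per-cell CSV layout exists for exactly that).
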