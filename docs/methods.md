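# Methods

This note documents the models behind `dmiscan`, the parameters that
matter, the numerical conventions, and what the synthetic-data generator
does and does not emulate.

## Two-locus statistics

All statistics derive from the four haplotype frequencies
g_ab, g_Ab, g_aB, g_AB of a pair of biallelic loci. `summarize_pair`
computes, per pair:

- allele frequencies and single-locus heterozygosities
  h_A = 1 − p_a² − p_A², h_B likewise;
- the expected variance of the two-locus heterozygote count K under
  independent loci, σ²_exp = h_A + h_B − h_A² − h_B²;
- the deviation Δ₂ = 2 Σ_ik (g_ik² − p_i² p_k²) and its normalized form
  X(2) = Δ₂ / σ²_exp;
- linkage disequilibrium D = g_AB·g_ab − g_aB·g_Ab and D′ = D/|D_max|,
  with D_max = max(−p_A p_B, −p_a p_b) for D < 0 and
  min(p_A p_b, p_a p_B) for D > 0;
- the per-haplotype imbalance D2_ik = g_ik² − p_i² p_k² and
  ΔD2 = D2_ab − D2_AB.

Two algebraic identities are used as internal cross-checks and enforced
by tests at 1e-10: Δ₂ = 4D(2g_ab + 2g_AB − 2D − 1), and, when D < 0,
(D2_ab − D2_AB)/Σ|D2_ik| = −(1 − p_A − p_B). `var_K_by_enumeration`
recomputes Var(K) by brute-force enumeration of all ten unordered
haplotype pairs and serves as the independent oracle for
σ²_exp + Δ₂.

Orientation. D as defined above is *repulsion-oriented*: it is negative
while the two parental haplotypes (Ab, aB) are in excess. ΔD2 is
reported as D2_ab − D2_AB (positive when the AB recombinant is the
deficient one). Which of the two mixed-ancestry haplotypes is called
"AB" is a labelling choice; relabelling the parents leaves X(2) and D′
unchanged and flips the sign of ΔD2, so candidate calls do not depend
on it. The summary exposes D2 for all four haplotypes so callers can
choose the recombinant pair explicitly.

Degenerate inputs. σ²_exp = 0 (both loci monomorphic) makes X(2)
undefined; it is reported as NaN and flagged, never raised. A single
monomorphic locus yields Δ₂ = 0 and X(2) = 0. D = 0 is mapped to
D′ = 0. Haplotype-frequency vectors are validated as a simplex at
tolerance 1e-12 and renormalized on read.

Estimators are plug-in (no small-sample correction): phased counts are
divided by their total; pseudo-phased estimation uses only individuals
homozygous at both loci, two identical haplotypes each, and flags a pair
unusable below a minimum of 50 haplotypes. The G test of independence
(2×2 allele table, marginal expectations, df = 1, 0·ln 0 = 0) is
included purely as the comparison baseline for unlinked pairs; it is
computed on the same haplotype estimates as the scan statistics.

## Deterministic dynamics

The haploid toy model follows haplotype frequencies in an infinite
panmictic hybrid population with fitnesses w_ab = 1, w_Ab = 1+α,
w_aB = 1+β, w_AB = (1+α)(1+β)(1+γ), founded as a fraction f of aB
individuals and 1−f of Ab. One generation applies, in order:
selection, recombination (D of the selected pool decays by c·D), and
migration (a fraction m1 of aB and m2 of Ab haplotypes replaces the
resident pool). Migrants enter after selection; the acceptance of this
ordering matters only at a ±1-generation level for window boundaries.

Generation indexing: the founding admixed population is generation 1,
so recombinants first appear at generation 2. Trajectories are recorded
only while both loci are polymorphic (minor allele frequency ≥ 0.005 by
default); the first generation breaching the threshold terminates the
run and is not recorded. Under these conventions the reference
strong-DMI trajectory (α = 0.001, β = 0.002, γ = −0.5, c = 0.1,
f = 0.5, no migration) has its negative-X(2) window at generations
25–509 with the minimum at generation 58, which the test suite pins
exactly.

The diploid recursion tracks the gamete pool of a random-mating
population: random union of gametes, genotype fitness
(1+α)^nA (1+β)^nB (1+γ)^e(nA,nB), meiosis with recombination
probability c. The epistasis exponent e encodes dominance of the
incompatibility: *codominant* e = nA·nB; *recessive* the same except
e(1,1) = 0 (double heterozygotes escape); *homo_homo* e = 4 only for
the double homozygote. Higher dominance exposes the DMI earlier:
deterministic windows order codominant < recessive < homo_homo in both
onset and persistence.

`parameter_grid` runs one trajectory per cell of a cartesian parameter
grid and reports the detection window, the minimum X(2) and minimum ΔD2
with their generations. Two robust orderings, enforced as tests: the
depth |min X(2)| is unimodal in c (peaking at low-to-intermediate
recombination) and non-increasing as f departs 0.5, with no negative
window at strongly skewed admixture (f ≲ 0.3 without migration).

## Forward-time simulator

Individual-based, diploid, ancestry-labelled: each marker on each
haplotype records the parental population of origin (1 = the aB parent,
0 = the Ab parent). Mutation is ignored; ancestry labels are the only
alleles. Default population size N = 5000.

- **Founding**: each of N individuals is pure parent-1 with probability
  f, else pure parent-2 (binomial founding, not exact proportions).
- **Fitness**: per DMI pair, the incompatible allele A is parent-2
  ancestry at the first locus and B parent-1 ancestry at the second
  (parental haplotypes are compatible by construction); genotype
  fitness uses the dominance-aware exponent above, and multiple DMIs
  multiply. Default dominance is recessive.
- **Reproduction (WF)**: both parents of every offspring are drawn
  fitness-proportionally with replacement (fecundity-style viability
  weighting; selfing is not excluded). The whole generation is
  replaced. An optional exponential expansion N(t) = round(N₀(1+r)^t)
  runs for a configured number of generations (default examples use a
  5% rate over 35 generations).
- **Reproduction (Moran)**: deaths are drawn per individual from the
  age-specific schedule (0.2, 0.2, 0, 0, 0, 0, 0.25, 0.5, 0.75, 1.0)
  for ages 0–9; the dead are replaced by juveniles bred
  fitness-proportionally from the survivors; survivors age by one. One
  time step is counted as one generation when aligning with WF runs;
  founders start at age 0.
- **Meiosis**: one crossover decision per marker interval with
  probability min(d_cM/100, 0.5), independent intervals (no
  interference), free recombination (0.5) between chromosomes.
- **Migration**: after selection/birth, expected m·N individuals
  (stochastically rounded) are replaced by pure parental juveniles —
  m1 from the aB parent, m2 from the Ab parent.
- **Sampling**: individuals whose minor-parent genome fraction is below
  the hybrid-exclusion threshold (default 10%) are excluded; a uniform
  sample without replacement of the configured size is returned as
  phased haplotypes plus the 0/1/2 dosage matrix. If fewer hybrids are
  eligible than requested, all are returned with a flag. For two-marker
  genomes the genome fraction is too coarse for the exclusion rule to
  be meaningful, so focal-pair experiments set the threshold to 0.

Randomness: a single master seed feeds a `SeedSequence`; the simulation
and sampling streams are spawned separately so checkpoint sampling does
not perturb the trajectory. Identical configuration and seed give
bit-identical populations.

`random_architecture` draws the validation genomes: four DMI-designated
plus two neutral chromosomes, 100 markers each at 1 cM spacing (1 Mb per
cM for bp coordinates); DMI loci fall uniformly on the DMI chromosomes
(pairs may be inter- or intrachromosomal), with α, β ~ Exp(mean 0.001)
and γ ~ U[−1, −0.001]. A hub option makes two pairs share one locus
(the three-locus interaction model).

What the generator emulates: pulse admixture with optional continuous
unidirectional or bidirectional migration, drift, age structure,
expansion, and arbitrary pairwise DMI architectures over a marker map.
What it does not: mutation, ancestry-call errors or missing data (real
hard-call panels have both; the scan handles missingness but simulated
fixtures are complete), recombination-map error, more than two source
populations, sex chromosomes, and selection other than the DMI scheme.
Passing validation here therefore demonstrates the statistical behavior
of the method under its own model assumptions, not robustness to
upstream ancestry-inference error.

## Genome scan

Pipeline order: locus filters → LD thinning → marker subsample →
pairwise statistics → candidate calls → 1-Mb binning → bootstrap
support.

- **Locus filters**: keep markers with each homozygote class above 5%
  and heterozygous-or-missing below 60%, frequencies over all retained
  individuals ("or heterozygous" is read as the union of the two
  categories).
- **LD thinning**: one deterministic forward pass in genomic order;
  within a 10-kb window the later marker of any pair with dosage
  r² > 0.9 is dropped (pairwise-complete individuals; the earlier
  marker always wins). Correlation is on the ancestry-dosage scale.
- **Marker subsample**: up to 700 markers drawn uniformly (seeded) from
  the thinned set, not stratified by chromosome.
- **Statistics**: every unordered pair gets X(2), D′, ΔD2 and the
  haplotype frequencies, from phased haplotypes or the homozygote-only
  pseudo-phased estimator (minimum 50 haplotypes). Candidates satisfy
  X(2) < −0.005 and D′ < 0.
- **Binning**: 0-based half-open 1-Mb bins; a bin pair is a putative
  DMI if it contains at least one candidate marker pair; same-bin pairs
  are excluded.
- **Bootstrap support**: the scan is repeated on (default) 20
  independent marker samples from the fixed thinned set. p_bin is the
  median candidate fraction among tested bin pairs. A candidate bin
  pair observed x times is scored with the exact binomial upper tail
  P(X ≥ x | n, p_bin); the support threshold k is the smallest count
  whose p-value beats the FDR-style cutoff
  (#bins retained at that count)/(total candidate bins over all
  bootstraps) × 0.001. "Total significant pairs" is counted in bin
  pairs summed over bootstraps; counting marker pairs instead is a
  defensible alternative the code keeps localized in one place.
  p_bin = 0 degenerates to k = 1 with a warning.

## Evaluation harness

Detection of a truth pair means the candidate flag at the exact true
marker pair; flags at linked flanking markers count as false positives
in the rate tables (deliberately — hitchhiking signal is real but is
scored as error). Sensitivity/specificity come with 95% Wald intervals
p̂ ± 1.96·√(p̂(1−p̂)/n), clipped to [0, 1]. False/true positive rates are
stratified by chromosome class (both markers on neutral chromosomes vs
any marker on a DMI chromosome) and X(2) threshold, with confidence
intervals from resampling 2000 pairs 1000 times out of the pooled
per-pair outcomes. The distance profile reports the candidate fraction
among pairs spanning windows of increasing cM radius around the two
true loci, with the genome-wide fraction as the reference.

## Problem sizes

The validation experiments use the full population size N = 5000 with
50 replicates for the neutral null (two-marker genomes, checkpoints
every 10 generations to 150) and 30 replicates for the two-DMI
six-chromosome genomes (600 markers, sampled at generation 30, 200
individuals, phased). Stochastic ordering checks (Moran vs WF onset,
migration swamping vs rescue) use N = 1000 with 20 paired seeds; these
are rank comparisons, for which the smaller population only widens the
variance without biasing the order.

## Known limitations

- The statistics assume a single pulse of admixture between two
  sources; continuous admixture from a third source violates the
  recombinant-balance null.
- Pseudo-phased estimation is biased when homozygosity correlates with
  ancestry (e.g., strong inbreeding), and its 50-haplotype floor makes
  pairs undersampled in young or small samples silently unusable —
  the scan reports them as skipped rather than guessing.
- The negative-X(2) window is transient: populations sampled before
  recombinant imbalance accumulates, or after the incompatible alleles
  are purged, show nothing. The deterministic module exists precisely
  to compute that window for a hypothesized demography.
- Weak incompatibilities (|γ| close to 0) produce signals inside the
  sampling noise floor at realistic sample sizes; the evaluation
  harness quantifies this rather than the scan compensating for it.
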