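# dmiscan

Detection of Dobzhansky–Muller incompatibilities (DMIs) in hybrid
genomes from the variance in two-locus heterozygosity.

## The problem

When two diverged populations hybridize, negative epistasis between
alleles that evolved in different lineages (a DMI) is exposed in the
hybrids. Classical mapping of DMIs needs crosses and large panels, and
LD-based genome scans cannot separate excess linkage caused by selection
from the physical linkage of parental haplotypes — which makes DMIs
*within* a chromosome nearly invisible to them.

`dmiscan` implements a pair of statistics that target the one pattern
physical linkage cannot produce: **imbalance between the two recombinant
haplotypes**. In a hybrid population founded from parents fixed for
haplotypes *Ab* and *aB*, the recombinants *ab* and *AB* are generated
at equal rates; selection against the incompatible combination *A*–*B*
depletes *AB* specifically. The package provides the statistics, a
deterministic model of their dynamics, a forward-time simulator for
validation and power analysis, and a genome-scan pipeline for real
ancestry data. It is written for population geneticists analysing hybrid
zones or admixed populations with marker-level local-ancestry calls.

## The statistics

For two biallelic loci with haplotype frequencies *g<sub>ik</sub>* and
allele frequencies *p<sub>i</sub>*, let *K* ∈ {0, 1, 2} be the number of
heterozygous loci in an individual formed by random union of haplotypes.
With heterozygosities *h*<sub>A</sub> = 1 − *p<sub>a</sub>*² −
*p<sub>A</sub>*² (and *h*<sub>B</sub> likewise):

- expected variance under independence:
  σ²<sub>exp</sub> = *h*<sub>A</sub> + *h*<sub>B</sub> − *h*<sub>A</sub>² − *h*<sub>B</sub>²
- observed deviation:
  Δ₂ = 2 Σ<sub>ik</sub> (*g<sub>ik</sub>*² − *p<sub>i</sub>*² *p<sub>k</sub>*²)
- **X(2) = Δ₂ / σ²<sub>exp</sub>**, and
  **ΔD2 = D2<sub>ab</sub> − D2<sub>AB</sub>** with
  D2<sub>ik</sub> = *g<sub>ik</sub>*² − *p<sub>i</sub>*² *p<sub>k</sub>*².

Residual linkage of parental haplotypes makes X(2) positive; recombinant
imbalance makes it negative. A marker pair is a candidate DMI when
X(2) < −0.005 **and** D′ < 0 (the deficient haplotype is a recombinant,
not a parental type). ΔD2 identifies which recombinant is depleted.
Because the statistics never reference the recombination rate, the same
scan covers inter- and intrachromosomal pairs.

## Worked example

Deterministic dynamics of a strong DMI (α = 0.001, β = 0.002,
γ = −0.5, recombination c = 0.1, even admixture):

```sh
dmiscan trajectory --alpha 0.001 --beta 0.002 --gamma -0.5 \
    --c 0.1 --f 0.5 --out-dir traj
cat traj/window.json
```

```json
{
  "first_negative_generation": 25,
  "last_negative_generation": 509,
  "argmin_generation": 58,
  "min_X2": -0.09015356895781122,
  ...
}
```

X(2) at the DMI pair is negative from generation 25 to 509 with the
strongest signal (X(2) ≈ −0.090) at generation 58: the detection window
for this demography.

Simulate a hybrid population and scan it:

```sh
dmiscan simulate --seed 7 --n 2000 --f 0.5 --n-generations 30 \
    --sample-size 300 --n-dmi-pairs 1 --dmi-chromosomes 2 \
    --neutral-chromosomes 1 --markers-per-chromosome 50 \
    --write-phased --out-dir sim
dmiscan scan --input sim/ancestry.tsv --phased-input sim/phased.tsv \
    --mode phased --max-markers 100 --seed 1 --bootstrap 10 \
    --out-dir scan
cat scan/summary.json
```

```json
{
  "n_markers_after_filters": 142,
  "n_pairs": 4950,
  "n_usable_pairs": 4950,
  "n_candidate_pairs": 71,
  "n_candidate_bin_pairs": 71,
  "k": 3,
  "p_bin": 0.009595959595959595,
  "n_supported_bin_pairs": 93
}
```

The manifest records the drawn incompatibility (here chr1:33 Mb ×
chr2:22 Mb, γ ≈ −0.13). Of 4950 marker pairs, 71 (1.4%) are candidates,
and the strongest sit at and around the true pair — e.g. the top
candidates by X(2) span chr1:31–36 Mb × chr2:22–32 Mb, showing how the
signal of a DMI propagates into linked flanking regions. `k` is the
bootstrap support threshold calibrated from the binomial null: a 1-Mb
bin pair must recur in at least `k` of the bootstrap marker samples to
be retained.

For real data the input is a tab-separated ancestry-call table (rows =
markers; columns `chrom`, `pos`, then one 0/1/2/NA dosage of parent-1
ancestry per individual). Without phased haplotypes, use
`--mode pseudo_phased`: only individuals homozygous at both loci carry
phase information, each contributing two haplotypes, with pairs below 50
such haplotypes skipped.

## Library surface

Everything the CLI does is a thin layer over the library:
`dmiscan.corestats` (statistics and estimators),
`dmiscan.dynamics` (deterministic recursions, detection windows,
parameter grids), `dmiscan.simulator` (Wright–Fisher and Moran
forward simulation), `dmiscan.scan` (filters, LD thinning, pairwise
scan, binning, bootstrap support) and `dmiscan.evaluate`
(sensitivity/specificity, false/true positive rates, distance
profiles). See `docs/methods.md` for the model details and design
choices.

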