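"""Forward-time, individual-based simulator of an admixed diploid population.

Individuals carry ancestry-labelled chromosomes: every marker on each of
the two haplotypes records which parental population (1 = the "aB" parent,
0 = the "Ab" parent) the local genome segment derives from.  The
population is founded by a single admixture pulse (fraction ``f`` of
parent-1 individuals), evolves under Wright-Fisher (non-overlapping) or
Moran (overlapping, age-structured) reproduction with fitness-weighted
parent sampling, per-interval recombination derived from the cM map, free
recombination between chromosomes, and optional juvenile-stage migration
from either parent.  Mutation is ignored: ancestry labels are the only
alleles.

One or more Dobzhansky-Muller incompatibilities (DMIs) can be placed on
the map.  At a DMI pair the incompatible allele A is the parent-2 ancestry
at the first locus and B is the parent-1 ancestry at the second locus, so
the parental haplotypes are Ab and aB and the deleterious recombinant AB
carries parent-2 ancestry at the first locus together with parent-1
ancestry at the second.  Genotype fitness is
(1+alpha)^nA (1+beta)^nB (1+gamma)^e(nA, nB), multiplicative across DMIs,
with the dominance-aware exponent ``e`` shared with
:mod:`dmiscan.dynamics` ("recessive" by default: double heterozygotes do
not suffer from the incompatibility).

This module is also the package's fixture generator: sampled populations
convert directly to the ancestry matrices consumed by :mod:`dmiscan.scan`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import DOMINANCE_MODES, epistasis_exponent

__all__ = [
    "GenomeArchitecture",
    "DMIPair",
    "DMIArchitecture",
    "SimConfig",
    "Population",
    "SampledPopulation",
    "RandomArchitecture",
    "DEFAULT_MORTALITY_SCHEDULE",
    "build_population",
    "fitness",
    "step",
    "sample",
    "run_simulation",
    "random_architecture",
]

#: per-age death probabilities of the Moran model, ages 0..9
DEFAULT_MORTALITY_SCHEDULE = (0.2, 0.2, 0.0, 0.0, 0.0, 0.0, 0.25, 0.5, 0.75, 1.0)


class GenomeArchitecture:
    """Marker map: chromosomes with cM and bp positions.

    Recombination probability between adjacent markers is
    ``min(d_cM / 100, 0.5)`` (no interference, independent intervals);
    markers on different chromosomes recombine freely (0.5).
    """

    def __init__(self, chromosomes):
        """``chromosomes``: iterable of (name, cm_positions, bp_positions)."""
        names, chrom_idx, cms, bps = [], [], [], []
        for ci, (name, cm, bp) in enumerate(chromosomes):
            cm = np.asarray(cm, dtype=float)
            bp = np.asarray(bp, dtype=np.int64)
            if cm.shape != bp.shape or cm.ndim != 1 or len(cm) == 0:
                raise ValueError(f"chromosome {name!r}: bad marker positions")
            if np.any(np.diff(cm) <= 0) or np.any(np.diff(bp) <= 0):
                raise ValueError(
                    f"chromosome {name!r}: positions must be strictly increasing"
                )
            names.append(str(name))
            chrom_idx.append(np.full(len(cm), ci))
            cms.append(cm)
            bps.append(bp)
        self.chrom_names: list[str] = names
        self.marker_chrom = np.concatenate(chrom_idx)
        self.cm = np.concatenate(cms)
        self.bp = np.concatenate(bps)
        # probability that the source haplotype switches between marker
        # j-1 and j during meiosis; 0.5 at chromosome starts makes the
        # first marker of each chromosome an independent coin flip
        switch = np.empty(len(self.cm))
        switch[0] = 0.5
        d = np.diff(self.cm) / 100.0
        switch[1:] = np.minimum(d, 0.5)
        switch[1:][np.diff(self.marker_chrom) != 0] = 0.5
        self.switch_prob = switch

    @property
    def n_markers(self) -> int:
        return len(self.cm)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_names)

    @classmethod
    def uniform(
        cls,
        n_chromosomes: int,
        markers_per_chromosome: int = 100,
        spacing_cm: float = 1.0,
        bp_per_cm: float = 1e6,
        names=None,
    ) -> "GenomeArchitecture":
        """Evenly spaced markers (1 cM apart by default, 1 Mb per cM)."""
        if names is None:
            names = [f"chr{i + 1}" for i in range(n_chromosomes)]
        cm = (np.arange(markers_per_chromosome) + 1) * spacing_cm
        bp = np.round(cm * bp_per_cm).astype(np.int64)
        return cls([(name, cm, bp) for name in names])

    def markers_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [self.chrom_names[c] for c in self.marker_chrom],
                "pos": self.bp,
                "cm": self.cm,
            }
        )


@dataclass(frozen=True)
class DMIPair:
    """One pairwise incompatibility between two marker loci."""

    locus_a: int
    locus_b: int
    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = -0.5
    dominance_mode: str = "recessive"

    def __post_init__(self) -> None:
        if self.gamma > 0:
            raise ValueError("a DMI requires gamma <= 0")
        if self.dominance_mode not in DOMINANCE_MODES or self.dominance_mode == "haploid":
            raise ValueError(f"bad diploid dominance mode {self.dominance_mode!r}")
        if self.locus_a == self.locus_b:
            raise ValueError("DMI loci must be distinct markers")


@dataclass
class DMIArchitecture:
    """A set of pairwise DMIs; fitness is multiplicative across pairs.

    Interaction hubs (one locus shared by two pairs) are expressed simply
    as two pairs sharing a marker index.
    """

    pairs: list[DMIPair] = field(default_factory=list)

    def validate(self, arch: GenomeArchitecture) -> None:
        for p in self.pairs:
            for locus in (p.locus_a, p.locus_b):
                if not 0 <= locus < arch.n_markers:
                    raise ValueError(f"DMI locus {locus} not on the marker map")

    @property
    def loci(self) -> list[int]:
        return sorted({l for p in self.pairs for l in (p.locus_a, p.locus_b)})


@dataclass(frozen=True)
class SimConfig:
    """Demography and sampling settings of one simulation run."""

    N: int = 5000
    f: float = 0.5
    m1: float = 0.0
    m2: float = 0.0
    model: str = "WF"
    mortality_schedule: tuple = DEFAULT_MORTALITY_SCHEDULE
    growth_rate: float = 0.0
    growth_duration: int = 0
    n_generations: int = 50
    sample_size: int = 300
    hybrid_exclusion_threshold: float = 0.10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("population size must be at least 2")
        for name in ("f", "m1", "m2"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.model not in ("WF", "Moran"):
            raise ValueError("model must be 'WF' or 'Moran'")
        if self.sample_size > self.N:
            raise ValueError("sample_size cannot exceed N")


@dataclass
class Population:
    """Current state: phased ancestry labels, ages and the generation index.

    ``haplotypes`` has shape (2N, M); rows 2i and 2i+1 belong to
    individual i.  Founders are generation 1.
    """

    haplotypes: np.ndarray
    ages: np.ndarray
    generation: int
    founding_size: int

    @property
    def size(self) -> int:
        return len(self.ages)


def _rngs_from_config(cfg: SimConfig):
    ss = np.random.SeedSequence(cfg.seed)
    sim, samp = ss.spawn(2)
    return np.random.default_rng(sim), np.random.default_rng(samp)


def build_population(
    arch: GenomeArchitecture, cfg: SimConfig, rng: np.random.Generator | None = None
) -> Population:
    """Found the hybrid population: each individual is pure parent-1
    (probability ``f``) or pure parent-2."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    origin = rng.random(cfg.N) < cfg.f
    hap = np.repeat(origin, 2).astype(np.uint8)[:, None] * np.ones(
        arch.n_markers, dtype=np.uint8
    )
    return Population(hap, np.zeros(cfg.N, dtype=np.int64), 1, cfg.N)


def _exponent_table(mode: str) -> np.ndarray:
    t = np.empty((3, 3), dtype=np.int64)
    for nA in range(3):
        for nB in range(3):
            t[nA, nB] = epistasis_exponent(nA, nB, mode)
    return t


def fitness(pop: Population, dmis: DMIArchitecture) -> np.ndarray:
    """Per-individual fitness, multiplicative over DMI pairs."""
    w = np.ones(pop.size)
    if not dmis.pairs:
        return w
    dosage1 = pop.haplotypes[0::2] + pop.haplotypes[1::2]  # parent-1 copies
    for p in dmis.pairs:
        nA = 2 - dosage1[:, p.locus_a].astype(np.int64)
        nB = dosage1[:, p.locus_b].astype(np.int64)
        e = _exponent_table(p.dominance_mode)[nA, nB]
        w = w * (1 + p.alpha) ** nA * (1 + p.beta) ** nB * (1 + p.gamma) ** e
    return w


def _meiosis(
    haplotypes: np.ndarray,
    parent_idx: np.ndarray,
    arch: GenomeArchitecture,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete per parent: crossover per marker interval, free
    recombination between chromosomes, no interference."""
    n = len(parent_idx)
    switches = rng.random((n, arch.n_markers)) < arch.switch_prob
    which = np.cumsum(switches, axis=1, dtype=np.int64) & 1
    rows = 2 * parent_idx[:, None] + which
    return haplotypes[rows, np.arange(arch.n_markers)[None, :]]


def _target_size(pop: Population, cfg: SimConfig) -> int:
    t = min(pop.generation, cfg.growth_duration)
    return int(round(pop.founding_size * (1.0 + cfg.growth_rate) ** t))


def _stochastic_round(x: float, rng: np.random.Generator) -> int:
    base = int(np.floor(x))
    return base + int(rng.random() < (x - base))


def _apply_migration(
    hap: np.ndarray, ages: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> None:
    """Replace random individuals with pure parental juveniles, in place."""
    n = len(ages)
    n1 = _stochastic_round(cfg.m1 * n, rng)
    n2 = _stochastic_round(cfg.m2 * n, rng)
    if n1 + n2 == 0:
        return
    idx = rng.choice(n, size=min(n1 + n2, n), replace=False)
    for label, ind in ((1, idx[:n1]), (0, idx[n1:])):
        hap[2 * ind] = label
        hap[2 * ind + 1] = label
        ages[ind] = 0


def _reproduce(
    pop: Population,
    arch: GenomeArchitecture,
    dmis: DMIArchitecture,
    cfg: SimConfig,
    rng: np.random.Generator,
    n_offspring: int,
    parent_pool: np.ndarray | None = None,
) -> np.ndarray:
    """Fitness-proportional parent sampling and meiosis for both gametes."""
    w = fitness(pop, dmis)
    if parent_pool is not None:
        mask = np.zeros(pop.size, dtype=bool)
        mask[parent_pool] = True
        w = np.where(mask, w, 0.0)
    total = w.sum()
    if total <= 0:
        raise RuntimeError("no viable parents (total fitness is zero)")
    prob = w / total
    mothers = rng.choice(pop.size, size=n_offspring, p=prob)
    fathers = rng.choice(pop.size, size=n_offspring, p=prob)
    hap = np.empty((2 * n_offspring, arch.n_markers), dtype=np.uint8)
    hap[0::2] = _meiosis(pop.haplotypes, mothers, arch, rng)
    hap[1::2] = _meiosis(pop.haplotypes, fathers, arch, rng)
    return hap


def step(
    pop: Population,
    arch: GenomeArchitecture,
    dmis: DMIArchitecture,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> Population:
    """Advance one generation (one discrete time step for Moran)."""
    if cfg.model == "WF":
        n_next = _target_size(pop, cfg)
        hap = _reproduce(pop, arch, dmis, cfg, rng, n_next)
        ages = np.zeros(n_next, dtype=np.int64)
    else:
        schedule = np.asarray(cfg.mortality_schedule)
        death_p = schedule[np.minimum(pop.ages, len(schedule) - 1)]
        dead = rng.random(pop.size) < death_p
        survivors = np.flatnonzero(~dead)
        if len(survivors) == 0:
            survivors = np.arange(pop.size)  # degenerate: everyone died
        n_dead = pop.size - len(survivors)
        hap = pop.haplotypes.copy()
        ages = pop.ages.copy()
        if n_dead > 0:
            juveniles = _reproduce(
                pop, arch, dmis, cfg, rng, n_dead, parent_pool=survivors
            )
            dead_idx = np.flatnonzero(dead)
            hap[2 * dead_idx] = juveniles[0::2]
            hap[2 * dead_idx + 1] = juveniles[1::2]
        ages[~dead] += 1
        ages[dead] = 0
    _apply_migration(hap, ages, cfg, rng)
    return Population(hap, ages, pop.generation + 1, pop.founding_size)


@dataclass
class SampledPopulation:
    """A phased sample of hybrid individuals at one generation."""

    haplotypes: np.ndarray  # (2n, M) ancestry labels
    generation: int
    ancestry_fraction: np.ndarray  # parent-1 genome fraction per individual
    short_sample: bool = False  # fewer eligible hybrids than requested

    @property
    def dosage(self) -> np.ndarray:
        """Parent-1 ancestry dosage (0/1/2) per individual and marker."""
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)

    @property
    def n_individuals(self) -> int:
        return len(self.haplotypes) // 2

    def to_ancestry_matrix(self, arch: GenomeArchitecture):
        from .scan import AncestryMatrix

        return AncestryMatrix(
            dosage=self.dosage,
            markers=arch.markers_frame(),
            individuals=[f"ind{i}" for i in range(self.n_individuals)],
            haplotypes=self.haplotypes.copy(),
        )


def sample(
    pop: Population, cfg: SimConfig, rng: np.random.Generator | None = None
) -> SampledPopulation:
    """Uniform sample of hybrids, excluding nearly pure parental
    individuals (minor-parent genome fraction below the threshold)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    frac1 = (pop.haplotypes[0::2].mean(axis=1) + pop.haplotypes[1::2].mean(axis=1)) / 2
    minor = np.minimum(frac1, 1.0 - frac1)
    eligible = np.flatnonzero(minor >= cfg.hybrid_exclusion_threshold)
    short = len(eligible) < cfg.sample_size
    if short:
        warnings.warn(
            f"only {len(eligible)} eligible hybrids for a sample of "
            f"{cfg.sample_size}; returning all eligible individuals"
        )
        chosen = eligible
    else:
        chosen = rng.choice(eligible, size=cfg.sample_size, replace=False)
    chosen = np.sort(chosen)
    rows = np.empty(2 * len(chosen), dtype=np.int64)
    rows[0::2] = 2 * chosen
    rows[1::2] = 2 * chosen + 1
    return SampledPopulation(
        pop.haplotypes[rows].copy(), pop.generation, frac1[chosen], short
    )


def run_simulation(
    arch: GenomeArchitecture,
    dmis: DMIArchitecture,
    cfg: SimConfig,
    checkpoints=None,
):
    """Run the simulation; return (samples, final population).

    ``samples`` maps each checkpoint generation (default: the last one,
    ``cfg.n_generations``) to a :class:`SampledPopulation`.  The sampling
    RNG stream is separate from the simulation stream, so the checkpoint
    list does not perturb the trajectory.
    """
    dmis.validate(arch)
    sim_rng, sample_rng = _rngs_from_config(cfg)
    if checkpoints is None:
        checkpoints = [cfg.n_generations]
    checkpoints = sorted(set(int(c) for c in checkpoints))
    pop = build_population(arch, cfg, sim_rng)
    samples: dict[int, SampledPopulation] = {}
    if pop.generation in checkpoints:
        samples[pop.generation] = sample(pop, cfg, sample_rng)
    while pop.generation < cfg.n_generations:
        pop = step(pop, arch, dmis, cfg, sim_rng)
        if pop.generation in checkpoints:
            samples[pop.generation] = sample(pop, cfg, sample_rng)
    return samples, pop


@dataclass
class RandomArchitecture:
    """A randomly drawn genome + DMI architecture and its chromosome plan."""

    arch: GenomeArchitecture
    dmis: DMIArchitecture
    dmi_chromosomes: list[str]
    neutral_chromosomes: list[str]


def random_architecture(
    n_dmi_pairs: int,
    n_dmi_chromosomes: int = 4,
    n_neutral_chromosomes: int = 2,
    markers_per_chromosome: int = 100,
    spacing_cm: float = 1.0,
    alpha_mean: float = 0.001,
    gamma_range: tuple = (-1.0, -0.001),
    dominance_mode: str = "recessive",
    hub: bool = False,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> RandomArchitecture:
    """Draw a multi-chromosome genome with randomly placed DMIs.

    DMI loci fall uniformly on the designated DMI chromosomes (so pairs
    may be inter- or intrachromosomal); alpha and beta are exponential
    with mean ``alpha_mean`` and gamma uniform on ``gamma_range``.  With
    ``hub=True`` and ``n_dmi_pairs=2`` the two pairs share one locus
    (three distinct loci: A-C and B-C interactions).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    arch = GenomeArchitecture.uniform(
        n_dmi_chromosomes + n_neutral_chromosomes, markers_per_chromosome, spacing_cm
    )
    dmi_chroms = arch.chrom_names[:n_dmi_chromosomes]
    neutral_chroms = arch.chrom_names[n_dmi_chromosomes:]
    dmi_markers = np.flatnonzero(arch.marker_chrom < n_dmi_chromosomes)
    pairs = []
    if n_dmi_pairs > 0:
        n_loci = n_dmi_pairs + 1 if hub else 2 * n_dmi_pairs
        loci = rng.choice(dmi_markers, size=n_loci, replace=False)
        if hub:
            hub_locus = loci[-1]
            combos = [(loci[i], hub_locus) for i in range(n_dmi_pairs)]
        else:
            combos = [(loci[2 * i], loci[2 * i + 1]) for i in range(n_dmi_pairs)]
        for la, lb in combos:
            pairs.append(
                DMIPair(
                    locus_a=int(la),
                    locus_b=int(lb),
                    alpha=float(rng.exponential(alpha_mean)),
                    beta=float(rng.exponential(alpha_mean)),
                    gamma=float(rng.uniform(gamma_range[0], gamma_range[1])),
                    dominance_mode=dominance_mode,
                )
            )
    return RandomArchitecture(arch, DMIArchitecture(pairs), dmi_chroms, neutral_chroms)
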