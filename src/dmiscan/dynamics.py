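"""Deterministic two-locus DMI dynamics in a hybrid population.

Models a panmictic hybrid population founded by mixing two parental
populations fixed for haplotypes aB (fraction ``f``) and Ab (fraction
``1 - f``).  Alleles A and B are weakly beneficial individually
(coefficients ``alpha``, ``beta`` > 0) but negatively epistatic together
(``gamma`` <= 0), the classic Dobzhansky-Muller configuration.  Haplotype
frequencies evolve under selection, recombination (probability ``c``) and
optional one-way migration from either parent, with no genetic drift.

The haploid recursion tracks the four haplotype frequencies directly
(selection acting on the gamete pool); the diploid recursion tracks the
gamete pool of a random-mating diploid population in which the epistatic
penalty depends on the dominance of the incompatibility (recessive,
homozygote-homozygote only, or codominant).

Life cycle per generation: selection -> recombination -> migration
(migrants enter as juveniles after selection).  The founding admixed
population is generation 1, so recombinant haplotypes first appear at
generation 2.  Trajectories are recorded only while both loci are
polymorphic (minor allele frequency >= ``maf_stop``); the first generation
that breaches the threshold is not recorded.  Under these conventions the
standard strong-DMI example (alpha = 0.001, beta = 0.002, gamma = -0.5,
c = 0.1, f = 0.5, no migration) yields a negative-X(2) window spanning
generations 25-509 with the strongest signal at generation 58.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corestats import (
    HaplotypeDistribution,
    TwoLocusSummary,
    summarize_pair,
)

__all__ = [
    "SelectionParams",
    "Demography",
    "Trajectory",
    "DetectionWindow",
    "DOMINANCE_MODES",
    "haploid_step",
    "diploid_step",
    "run_trajectory",
    "detection_window",
    "parameter_grid",
    "genotype_fitness_matrix",
    "epistasis_exponent",
]

DOMINANCE_MODES = ("haploid", "recessive", "homo_homo", "codominant")


@dataclass(frozen=True)
class SelectionParams:
    """Direct selection (alpha for A, beta for B) and epistasis gamma.

    gamma <= 0 gives a DMI; gamma = 0 switches epistasis off.  The
    dominance mode controls how the epistatic penalty scales with the
    number of incompatible allele copies in a diploid genotype.
    """

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    dominance_mode: str = "haploid"

    def __post_init__(self) -> None:
        if self.dominance_mode not in DOMINANCE_MODES:
            raise ValueError(f"unknown dominance mode {self.dominance_mode!r}")
        if 1 + self.alpha <= 0 or 1 + self.beta <= 0 or 1 + self.gamma < 0:
            raise ValueError("fitness coefficients give non-positive fitness")

    def haplotype_fitness(self) -> np.ndarray:
        """(w_ab, w_Ab, w_aB, w_AB) of the haploid scheme."""
        a, b, g = self.alpha, self.beta, self.gamma
        return np.array([1.0, 1 + a, 1 + b, (1 + a) * (1 + b) * (1 + g)])


@dataclass(frozen=True)
class Demography:
    """Admixture proportion, recombination and migration rates.

    ``f`` is the founding fraction of the aB parental population; ``m1``
    and ``m2`` are per-generation migrant fractions from the aB and Ab
    parents respectively.
    """

    f: float = 0.5
    c: float = 0.5
    m1: float = 0.0
    m2: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must be in [0, 1]")
        if not 0.0 <= self.c <= 0.5:
            raise ValueError("recombination probability c must be in [0, 0.5]")
        if self.m1 < 0 or self.m2 < 0 or self.m1 + self.m2 > 1:
            raise ValueError("migration rates must be >= 0 with m1 + m2 <= 1")

    def founding_distribution(self) -> HaplotypeDistribution:
        return HaplotypeDistribution(0.0, 1.0 - self.f, self.f, 0.0)


def _migrate(g: np.ndarray, dem: Demography) -> np.ndarray:
    if dem.m1 == 0 and dem.m2 == 0:
        return g
    out = (1.0 - dem.m1 - dem.m2) * g
    out[2] += dem.m1  # aB immigrants
    out[1] += dem.m2  # Ab immigrants
    return out


def haploid_step(
    g: HaplotypeDistribution, sel: SelectionParams, dem: Demography
) -> HaplotypeDistribution:
    """One generation of the haploid recursion: selection, recombination,
    migration, in that order."""
    freqs = g.as_array()
    w = sel.haplotype_fitness()
    gsel = w * freqs
    gsel /= gsel.sum()
    D = gsel[3] * gsel[0] - gsel[1] * gsel[2]
    grec = gsel + dem.c * D * np.array([-1.0, 1.0, 1.0, -1.0])
    return HaplotypeDistribution.from_array(_migrate(grec, dem))


def epistasis_exponent(nA: int, nB: int, dominance_mode: str) -> int:
    """Exponent of (1 + gamma) for a genotype with nA, nB incompatible
    allele copies."""
    if dominance_mode == "codominant":
        return nA * nB
    if dominance_mode == "recessive":
        # single-copy carriers of both alleles escape the incompatibility
        return 0 if (nA == 1 and nB == 1) else nA * nB
    if dominance_mode == "homo_homo":
        return 4 if (nA == 2 and nB == 2) else 0
    raise ValueError(f"no epistasis exponent for mode {dominance_mode!r}")


# haplotype index order (ab, Ab, aB, AB)
_HAP_A = np.array([0, 1, 0, 1])
_HAP_B = np.array([0, 0, 1, 1])


def genotype_fitness_matrix(sel: SelectionParams) -> np.ndarray:
    """4x4 fitness of ordered haplotype pairs under the diploid scheme."""
    w = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            nA = int(_HAP_A[i] + _HAP_A[j])
            nB = int(_HAP_B[i] + _HAP_B[j])
            e = epistasis_exponent(nA, nB, sel.dominance_mode)
            w[i, j] = (
                (1 + sel.alpha) ** nA * (1 + sel.beta) ** nB * (1 + sel.gamma) ** e
            )
    return w


def diploid_step(
    g: HaplotypeDistribution, sel: SelectionParams, dem: Demography
) -> HaplotypeDistribution:
    """One generation of the diploid gamete-pool recursion.

    Random union of gametes forms diploid genotypes, selection reweights
    them with a dominance-aware epistatic penalty, and meiosis with
    recombination probability ``c`` returns the next gamete pool.
    """
    if sel.dominance_mode == "haploid":
        raise ValueError("diploid_step requires a diploid dominance mode")
    freqs = g.as_array()
    W = genotype_fitness_matrix(sel)
    geno = W * np.outer(freqs, freqs)
    geno /= geno.sum()
    # meiosis: with prob 1-c transmit one parental haplotype, with prob c a
    # recombinant mixing the locus-A allele of one with the locus-B allele
    # of the other
    gam = np.zeros(4)
    c = dem.c
    for i in range(4):
        for j in range(4):
            p = geno[i, j]
            if p == 0:
                continue
            gam[i] += p * (1 - c) / 2
            gam[j] += p * (1 - c) / 2
            r1 = 2 * _HAP_B[j] + _HAP_A[i]  # index of (A-allele i, B-allele j)
            r2 = 2 * _HAP_B[i] + _HAP_A[j]
            gam[r1] += p * c / 2
            gam[r2] += p * c / 2
    return HaplotypeDistribution.from_array(_migrate(gam, dem))


@dataclass
class Trajectory:
    """Per-generation record of a deterministic run.

    ``generations[k]`` is the generation index (founders = 1) of
    ``distributions[k]`` / ``summaries[k]``.
    """

    generations: list[int] = field(default_factory=list)
    distributions: list[HaplotypeDistribution] = field(default_factory=list)
    summaries: list[TwoLocusSummary] = field(default_factory=list)
    termination: str = "generation_cap"

    def __len__(self) -> int:
        return len(self.generations)

    def x2(self) -> np.ndarray:
        return np.array([s.X2 for s in self.summaries])

    def to_frame(self) -> pd.DataFrame:
        """Tidy table (one row per generation) of the trajectory."""
        rows = []
        for gen, g, s in zip(self.generations, self.distributions, self.summaries):
            rows.append(
                {
                    "generation": gen,
                    "g_ab": g.g_ab, "g_Ab": g.g_Ab, "g_aB": g.g_aB, "g_AB": g.g_AB,
                    "p_A": s.p_A, "p_B": s.p_B,
                    "D": s.D, "Dprime": s.Dprime, "X2": s.X2, "deltaD2": s.deltaD2,
                }
            )
        return pd.DataFrame(rows)


def run_trajectory(
    sel: SelectionParams,
    dem: Demography,
    maf_stop: float = 0.005,
    max_generations: int = 10000,
) -> Trajectory:
    """Iterate the deterministic recursion from the founding admixture.

    Generations are recorded while both loci are polymorphic (minor allele
    frequency >= ``maf_stop``); iteration stops when a locus breaches the
    threshold (that generation is not recorded) or at ``max_generations``.
    """
    step = haploid_step if sel.dominance_mode == "haploid" else diploid_step
    traj = Trajectory()
    g = dem.founding_distribution()
    for gen in range(1, max_generations + 1):
        s = summarize_pair(g)
        if min(s.p_a, s.p_A, s.p_b, s.p_B) < maf_stop:
            traj.termination = "near_fixation"
            break
        traj.generations.append(gen)
        traj.distributions.append(g)
        traj.summaries.append(s)
        g = step(g, sel, dem)
    else:
        traj.termination = "generation_cap"
    return traj


@dataclass(frozen=True)
class DetectionWindow:
    """Span of generations with X(2) below a threshold."""

    first_negative_generation: int | None
    last_negative_generation: int | None
    argmin_generation: int | None
    min_X2: float
    empty: bool


def detection_window(traj: Trajectory, threshold: float = 0.0) -> DetectionWindow:
    """First/last generation with X(2) < ``threshold`` and the argmin."""
    gens = np.array(traj.generations)
    x2 = traj.x2()
    ok = np.isfinite(x2)
    neg = ok & (x2 < threshold)
    if not neg.any():
        mn = float(np.nanmin(x2)) if ok.any() else float("nan")
        return DetectionWindow(None, None, None, mn, True)
    idx = np.flatnonzero(neg)
    argmin = idx[np.argmin(x2[idx])]
    return DetectionWindow(
        int(gens[idx[0]]),
        int(gens[idx[-1]]),
        int(gens[argmin]),
        float(x2[argmin]),
        False,
    )


def parameter_grid(
    sel: SelectionParams,
    dem: Demography,
    *,
    maf_stop: float = 0.005,
    max_generations: int = 10000,
    x2_threshold: float = 0.0,
    **grids,
) -> pd.DataFrame:
    """Detection windows and extreme X(2)/dD2 over a parameter grid.

    Keyword grids name SelectionParams or Demography fields (e.g.
    ``c=[0.01, 0.1, 0.5]``, ``f=np.linspace(0.05, 0.5, 10)``); one
    trajectory is run per cell of their cartesian product.
    """
    sel_fields = {"alpha", "beta", "gamma", "dominance_mode"}
    dem_fields = {"f", "c", "m1", "m2"}
    names = list(grids)
    for name in names:
        if name not in sel_fields | dem_fields:
            raise ValueError(f"unknown grid parameter {name!r}")
    rows = []
    for combo in itertools.product(*(grids[n] for n in names)):
        override = dict(zip(names, combo))
        cell_sel = SelectionParams(
            alpha=override.get("alpha", sel.alpha),
            beta=override.get("beta", sel.beta),
            gamma=override.get("gamma", sel.gamma),
            dominance_mode=override.get("dominance_mode", sel.dominance_mode),
        )
        cell_dem = Demography(
            f=override.get("f", dem.f),
            c=override.get("c", dem.c),
            m1=override.get("m1", dem.m1),
            m2=override.get("m2", dem.m2),
        )
        traj = run_trajectory(cell_sel, cell_dem, maf_stop, max_generations)
        win = detection_window(traj, x2_threshold)
        dd2 = np.array([s.deltaD2 for s in traj.summaries])
        x2 = traj.x2()
        row = dict(override)
        row.update(
            n_generations=len(traj),
            termination=traj.termination,
            first_negative=win.first_negative_generation,
            last_negative=win.last_negative_generation,
            argmin_generation=win.argmin_generation,
            min_X2=win.min_X2,
            min_deltaD2=float(dd2.min()) if len(dd2) else float("nan"),
            argmin_deltaD2_generation=(
                int(traj.generations[int(dd2.argmin())]) if len(dd2) else None
            ),
        )
        rows.append(row)
    return pd.DataFrame(rows)
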