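"""Closed-form two-locus statistics for DMI detection.

A two-locus system with alleles a/A at locus **A** and b/B at locus **B**
has four haplotypes ab, Ab, aB, AB with frequencies ``g_ik``.  In a hybrid
population founded from parental populations fixed for Ab and aB, the two
recombinant haplotypes ab and AB are generated at equal rates; negative
epistasis between A and B (a Dobzhansky-Muller incompatibility) depletes AB
and leaves an imbalance between the recombinants.

Two statistics capture this signal:

* ``X2`` -- the deviation of the variance in two-locus heterozygosity
  Var(K), K in {0, 1, 2}, from its expectation under independent loci,
  normalized by that expectation.  X(2) < 0 indicates recombinant
  imbalance, which physical linkage alone cannot produce.
* ``deltaD2`` -- D2_ab - D2_AB where D2_ik = g_ik^2 - p_i^2 p_k^2, an
  explicit measure of which recombinant is deficient.

The module also provides plug-in estimators from phased haplotype counts
and from "pseudo-phased" diploid ancestry genotypes (only individuals
homozygous at both loci carry phase information), and the classical G test
of two-locus independence used as a comparison baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "HaplotypeDistribution",
    "TwoLocusSummary",
    "TwoLocusGenotypeCounts",
    "PseudoPhasedEstimate",
    "GTestResult",
    "summarize_pair",
    "pair_statistics",
    "var_K_by_enumeration",
    "estimate_phased",
    "estimate_from_homozygotes",
    "g_test",
    "DEFAULT_MIN_HAPLOTYPES",
]

#: frequencies must sum to 1 within this tolerance; renormalized on read
SIMPLEX_TOL = 1e-12

#: minimum number of homozygous-homozygous haplotypes for a usable
#: pseudo-phased estimate
DEFAULT_MIN_HAPLOTYPES = 50


@dataclass(frozen=True)
class HaplotypeDistribution:
    """Frequencies of the four two-locus haplotypes (ab, Ab, aB, AB)."""

    g_ab: float
    g_Ab: float
    g_aB: float
    g_AB: float

    def __post_init__(self) -> None:
        g = np.array([self.g_ab, self.g_Ab, self.g_aB, self.g_AB], dtype=float)
        if np.any(g < -SIMPLEX_TOL) or np.any(g > 1 + SIMPLEX_TOL):
            raise ValueError(f"haplotype frequencies outside [0, 1]: {g}")
        total = g.sum()
        if abs(total - 1.0) > SIMPLEX_TOL:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")
        g = np.clip(g, 0.0, 1.0) / np.clip(g, 0.0, 1.0).sum()
        for name, value in zip(("g_ab", "g_Ab", "g_aB", "g_AB"), g):
            object.__setattr__(self, name, float(value))

    @classmethod
    def from_array(cls, g) -> "HaplotypeDistribution":
        g = np.asarray(g, dtype=float)
        return cls(g[0], g[1], g[2], g[3])

    def as_array(self) -> np.ndarray:
        """Frequencies in the fixed order (ab, Ab, aB, AB)."""
        return np.array([self.g_ab, self.g_Ab, self.g_aB, self.g_AB])


@dataclass(frozen=True)
class TwoLocusSummary:
    """All derived statistics for one locus pair.

    ``X2`` is NaN (and ``x2_defined`` False) when a locus is monomorphic,
    i.e. the expected variance is zero and the normalization is undefined.
    """

    p_a: float
    p_A: float
    p_b: float
    p_B: float
    h_A: float
    h_B: float
    var_expected: float
    delta2: float
    X2: float
    D: float
    Dprime: float
    D2_ab: float
    D2_Ab: float
    D2_aB: float
    D2_AB: float
    deltaD2: float

    @property
    def x2_defined(self) -> bool:
        return not math.isnan(self.X2)


def pair_statistics(g_ab, g_Ab, g_aB, g_AB):
    """Vectorized two-locus statistics from haplotype frequencies.

    All arguments broadcast against each other; returns a dict of arrays
    (scalars in, scalars out via 0-d arrays).  Where ``var_expected`` is 0
    (a monomorphic locus) ``X2`` is NaN.
    """
    g_ab, g_Ab, g_aB, g_AB = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (g_ab, g_Ab, g_aB, g_AB))
    )
    p_A = g_Ab + g_AB
    p_a = g_ab + g_aB
    p_B = g_aB + g_AB
    p_b = g_ab + g_Ab
    h_A = 1.0 - p_a**2 - p_A**2
    h_B = 1.0 - p_b**2 - p_B**2
    var_expected = h_A + h_B - h_A**2 - h_B**2

    D2_ab = g_ab**2 - p_a**2 * p_b**2
    D2_Ab = g_Ab**2 - p_A**2 * p_b**2
    D2_aB = g_aB**2 - p_a**2 * p_B**2
    D2_AB = g_AB**2 - p_A**2 * p_B**2
    delta2 = 2.0 * (D2_ab + D2_Ab + D2_aB + D2_AB)

    with np.errstate(divide="ignore", invalid="ignore"):
        X2 = np.where(var_expected > 0, delta2 / np.where(var_expected > 0, var_expected, 1.0), np.nan)

    D = g_AB * g_ab - g_aB * g_Ab
    # D' normalization: Dmax depends on the sign of D; D = 0 -> D' = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        dmax_neg = np.abs(np.maximum(-p_A * p_B, -p_a * p_b))
        dmax_pos = np.minimum(p_A * p_b, p_a * p_B)
        Dprime = np.where(
            D < 0,
            np.where(dmax_neg > 0, D / np.where(dmax_neg > 0, dmax_neg, 1.0), 0.0),
            np.where(
                (D > 0) & (dmax_pos > 0), D / np.where(dmax_pos > 0, dmax_pos, 1.0), 0.0
            ),
        )

    return {
        "p_a": p_a, "p_A": p_A, "p_b": p_b, "p_B": p_B,
        "h_A": h_A, "h_B": h_B,
        "var_expected": var_expected, "delta2": delta2, "X2": X2,
        "D": D, "Dprime": Dprime,
        "D2_ab": D2_ab, "D2_Ab": D2_Ab, "D2_aB": D2_aB, "D2_AB": D2_AB,
        "deltaD2": D2_ab - D2_AB,
    }


def summarize_pair(g: HaplotypeDistribution) -> TwoLocusSummary:
    """Compute every two-locus statistic for one haplotype distribution."""
    s = pair_statistics(g.g_ab, g.g_Ab, g.g_aB, g.g_AB)
    return TwoLocusSummary(**{k: float(v) for k, v in s.items()})


# haplotype index order (ab, Ab, aB, AB): allele at locus A, allele at locus B
_HAP_A = np.array([0, 1, 0, 1])
_HAP_B = np.array([0, 0, 1, 1])


def var_K_by_enumeration(g: HaplotypeDistribution) -> float:
    """Brute-force Var(K) by enumerating all unordered haplotype pairs.

    K is the number of heterozygous loci (0, 1 or 2) in an individual built
    from two haplotypes drawn independently from ``g``.  This is the
    independent oracle for ``var_expected + delta2`` of `summarize_pair`.
    """
    freqs = g.as_array()
    mean_K = 0.0
    var_terms = []
    for i in range(4):
        for j in range(4):
            p = freqs[i] * freqs[j]
            K = int(_HAP_A[i] != _HAP_A[j]) + int(_HAP_B[i] != _HAP_B[j])
            mean_K += p * K
            var_terms.append((p, K))
    return float(sum(p * (K - mean_K) ** 2 for p, K in var_terms))


def estimate_phased(counts) -> HaplotypeDistribution:
    """Plug-in haplotype frequencies from phased counts (ab, Ab, aB, AB)."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (4,):
        raise ValueError("expected four haplotype counts (ab, Ab, aB, AB)")
    if np.any(counts < 0):
        raise ValueError("haplotype counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("no observations")
    return HaplotypeDistribution.from_array(counts / total)


@dataclass
class TwoLocusGenotypeCounts:
    """3x3 table of diploid ancestry genotypes at two loci.

    ``table[i, j]`` counts individuals with genotype ``i`` at the first
    locus and ``j`` at the second, where 0 = homozygous for the first
    allele (a resp. b), 1 = heterozygous, 2 = homozygous for the second
    allele (A resp. B).  ``n_missing`` counts individuals missing at either
    locus.
    """

    table: np.ndarray
    n_missing: int = 0

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table)
        if self.table.shape != (3, 3):
            raise ValueError("genotype table must be 3x3")
        if np.any(self.table < 0) or self.n_missing < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class PseudoPhasedEstimate:
    """Homozygote-only haplotype estimate with its effective sample size."""

    distribution: HaplotypeDistribution | None
    n_haplotypes: int
    usable: bool


def estimate_from_homozygotes(
    counts: TwoLocusGenotypeCounts, min_haplotypes: int = DEFAULT_MIN_HAPLOTYPES
) -> PseudoPhasedEstimate:
    """Estimate haplotype frequencies from homozygous-homozygous genotypes.

    Only individuals homozygous at both loci carry unambiguous phase; each
    contributes two identical two-locus haplotypes.  If fewer than
    ``min_haplotypes`` haplotypes result, the pair is flagged unusable.
    """
    t = counts.table
    # cells (0,0)->ab, (2,0)->Ab, (0,2)->aB, (2,2)->AB; two haplotypes each
    hap_counts = 2 * np.array([t[0, 0], t[2, 0], t[0, 2], t[2, 2]], dtype=float)
    n = int(hap_counts.sum())
    if n == 0 or n < min_haplotypes:
        return PseudoPhasedEstimate(None, n, False)
    return PseudoPhasedEstimate(
        HaplotypeDistribution.from_array(hap_counts / n), n, True
    )


@dataclass(frozen=True)
class GTestResult:
    G: float
    df: int
    p_value: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.p_value)


def g_test(counts) -> GTestResult:
    """Likelihood-ratio (G) test of two-locus independence.

    ``counts`` are the four haplotype counts (ab, Ab, aB, AB) forming a
    2x2 allele-by-allele table; expected counts come from the marginal
    products, df = 1, with the convention 0*ln(0) = 0.  If either margin is
    monomorphic the p-value is NaN (test undefined).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (4,):
        raise ValueError("expected four haplotype counts (ab, Ab, aB, AB)")
    if np.any(counts < 0):
        raise ValueError("haplotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("no observations")
    table = counts.reshape(2, 2, order="F")  # rows: a/A, cols: b/B
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        return GTestResult(math.nan, 1, math.nan)
    expected = np.outer(row, col) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    G = float(2.0 * terms.sum())
    return GTestResult(G, 1, float(sps.chi2.sf(G, 1)))
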