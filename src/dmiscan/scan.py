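"""Genome-scan pipeline for candidate DMI pairs.

Input is a per-individual, per-marker diploid ancestry matrix (dosage of
parent-1 ancestry: 0, 1, 2, or missing), the hard-call product of
upstream local-ancestry inference.  The pipeline mirrors a typical hybrid
population scan:

1. locus filtering (both homozygote classes > 5%, heterozygous-or-missing
   < 60%),
2. LD thinning (drop the later of any marker pair with dosage r^2 > 0.9
   within 10 kb),
3. sampling up to 700 markers and computing X(2), D', dD2 for every pair
   (phased haplotypes, or "pseudo-phased": only individuals homozygous at
   both loci contribute haplotypes, two each, requiring at least 50),
4. flagging candidates with X(2) < -0.005 and D' < 0,
5. assigning candidates to 1-Mb bin pairs, and
6. bootstrap support: the scan is repeated on independent marker samples
   and a binomial calibration determines the minimum number of
   occurrences k at which a bin pair is retained.

Haplotype labelling: for a marker pair, the incompatible allele A is the
parent-2 ancestry at the first marker and B the parent-1 ancestry at the
second, so the parental (founder) haplotypes are Ab (parent-2/parent-2)
and aB (parent-1/parent-1) and the recombinants ab/AB are the
mixed-ancestry haplotypes.  D < 0 then means parental excess, and the
candidate rule X(2) < threshold with D' < 0 targets a deficit of one
recombinant specifically.  Swapping the parent labels globally leaves X(2)
and D' unchanged and flips the sign of dD2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .corestats import DEFAULT_MIN_HAPLOTYPES, pair_statistics

__all__ = [
    "AncestryMatrix",
    "BootstrapResult",
    "filter_loci",
    "ld_thin",
    "pairwise_scan",
    "g_test_scan",
    "bin_pairs",
    "bootstrap_support",
    "DEFAULT_X2_THRESHOLD",
]

DEFAULT_X2_THRESHOLD = -0.005
MISSING = -1


@dataclass
class AncestryMatrix:
    """Individuals x markers parent-1 ancestry dosages with marker metadata.

    ``dosage`` is int8 with -1 for missing; ``markers`` is a DataFrame
    with columns ``chrom`` and ``pos`` (bp), optionally ``cm``.  Phased
    haplotypes (2n x M, 0/1 labels) may be attached when available.
    """

    dosage: np.ndarray
    markers: pd.DataFrame
    individuals: list[str]
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be individuals x markers")
        bad = ~np.isin(self.dosage, [MISSING, 0, 1, 2])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {self.dosage[i, j]} for individual "
                f"{self.individuals[i]!r} at marker row {j}"
            )
        self.markers = self.markers.reset_index(drop=True)
        if {"chrom", "pos"} - set(self.markers.columns):
            raise ValueError("markers must have 'chrom' and 'pos' columns")
        if len(self.markers) != self.dosage.shape[1]:
            raise ValueError("marker table does not match dosage matrix width")
        if len(self.individuals) != self.dosage.shape[0]:
            raise ValueError("individual list does not match dosage matrix height")
        if self.markers.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate (chrom, pos) marker entries")
        order = self.markers.sort_values(
            ["chrom", "pos"], kind="stable"
        ).index.to_numpy()
        if not np.array_equal(order, np.arange(len(order))):
            warnings.warn("markers were not sorted by (chrom, pos); sorting")
            self._reorder(order)
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
            if self.haplotypes.shape != (2 * self.dosage.shape[0], self.dosage.shape[1]):
                raise ValueError("haplotypes must have shape (2n, M)")

    def _reorder(self, order: np.ndarray) -> None:
        self.markers = self.markers.iloc[order].reset_index(drop=True)
        self.dosage = self.dosage[:, order]
        if self.haplotypes is not None:
            self.haplotypes = self.haplotypes[:, order]

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def ancestry_fraction(self) -> np.ndarray:
        """Genome-wide parent-1 fraction per individual (missing ignored)."""
        d = np.ma.masked_equal(self.dosage, MISSING)
        return (d.mean(axis=1) / 2.0).filled(np.nan)

    def subset_markers(self, idx) -> "AncestryMatrix":
        idx = np.asarray(idx)
        return AncestryMatrix(
            dosage=self.dosage[:, idx],
            markers=self.markers.iloc[idx].reset_index(drop=True),
            individuals=list(self.individuals),
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, idx],
        )


def filter_loci(matrix: AncestryMatrix, hom_freq_min: float = 0.05,
                het_missing_max: float = 0.60) -> AncestryMatrix:
    """Keep markers with both homozygote frequencies above ``hom_freq_min``
    and a heterozygous-or-missing fraction below ``het_missing_max``,
    computed over all individuals."""
    d = matrix.dosage
    n = d.shape[0]
    f0 = (d == 0).sum(axis=0) / n
    f2 = (d == 2).sum(axis=0) / n
    fhm = ((d == 1) | (d == MISSING)).sum(axis=0) / n
    keep = (f0 > hom_freq_min) & (f2 > hom_freq_min) & (fhm < het_missing_max)
    if not keep.any():
        warnings.warn("no markers pass the locus filters")
    return matrix.subset_markers(np.flatnonzero(keep))


def _dosage_r2(d: np.ndarray, i: int, j: int) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete
    individuals; 0 when undefined (fewer than 2 points or zero variance)."""
    di, dj = d[:, i], d[:, j]
    ok = (di != MISSING) & (dj != MISSING)
    if ok.sum() < 2:
        return 0.0
    x = di[ok].astype(float)
    y = dj[ok].astype(float)
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return 0.0
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def ld_thin(
    matrix: AncestryMatrix, r2_threshold: float = 0.9, window_bp: int = 10_000
) -> AncestryMatrix:
    """One deterministic forward pass in genomic order: for each kept
    marker, drop any later marker within ``window_bp`` whose dosage r^2
    exceeds the threshold (the earlier marker wins)."""
    chrom = matrix.markers["chrom"].to_numpy()
    pos = matrix.markers["pos"].to_numpy()
    M = matrix.n_markers
    dropped = np.zeros(M, dtype=bool)
    for i in range(M):
        if dropped[i]:
            continue
        j = i + 1
        while j < M and chrom[j] == chrom[i] and pos[j] - pos[i] <= window_bp:
            if not dropped[j] and _dosage_r2(matrix.dosage, i, j) > r2_threshold:
                dropped[j] = True
            j += 1
    return matrix.subset_markers(np.flatnonzero(~dropped))


def _pair_haplotype_freqs(matrix: AncestryMatrix, idx: np.ndarray, mode: str,
                          min_haplotypes: int):
    """Haplotype frequencies (ab, Ab, aB, AB) for all unordered marker
    pairs among ``idx``, as flat upper-triangle arrays.

    Returns (iu, ju, g_ab, g_Ab, g_aB, g_AB, n_hap, usable) where iu/ju
    index into ``idx``.
    """
    k = len(idx)
    iu, ju = np.triu_indices(k, 1)
    if mode == "phased":
        if matrix.haplotypes is None:
            raise ValueError("phased mode requires attached haplotypes")
        H = matrix.haplotypes[:, idx].astype(np.float64)
        n2 = H.shape[0]
        c11 = H.T @ H
        c10 = H.T @ (1.0 - H)
        c00 = n2 - c11 - c10 - c10.T
        # A = parent-2 at the first marker, B = parent-1 at the second:
        # ab=(1,0), Ab=(0,0), aB=(1,1), AB=(0,1) in parent-1 labels
        n_ab = c10[iu, ju]
        n_Ab = c00[iu, ju]
        n_aB = c11[iu, ju]
        n_AB = c10.T[iu, ju]
        n_hap = np.full(len(iu), float(n2))
        usable = np.ones(len(iu), dtype=bool)
    elif mode == "pseudo_phased":
        d = matrix.dosage[:, idx]
        I0 = (d == 0).astype(np.float64)
        I2 = (d == 2).astype(np.float64)
        # homozygote-homozygote individuals contribute 2 haplotypes each
        n_ab = 2.0 * (I2.T @ I0)[iu, ju]  # (dos 2, dos 0)
        n_Ab = 2.0 * (I0.T @ I0)[iu, ju]
        n_aB = 2.0 * (I2.T @ I2)[iu, ju]
        n_AB = 2.0 * (I0.T @ I2)[iu, ju]
        n_hap = n_ab + n_Ab + n_aB + n_AB
        usable = n_hap >= max(min_haplotypes, 1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.where(n_hap > 0, n_hap, 1.0)
        freqs = [n_ab / denom, n_Ab / denom, n_aB / denom, n_AB / denom]
    return iu, ju, *freqs, n_hap, usable


def _select_markers(matrix: AncestryMatrix, max_markers, rng) -> np.ndarray:
    if max_markers is not None and matrix.n_markers > max_markers:
        if rng is None:
            rng = np.random.default_rng()
        return np.sort(rng.choice(matrix.n_markers, size=max_markers, replace=False))
    return np.arange(matrix.n_markers)


def pairwise_scan(
    matrix: AncestryMatrix,
    mode: str = "pseudo_phased",
    max_markers: int | None = 700,
    x2_threshold: float = DEFAULT_X2_THRESHOLD,
    min_haplotypes: int = DEFAULT_MIN_HAPLOTYPES,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """All-pairs X(2)/D'/dD2 scan over a (sampled) marker set.

    Returns one row per unordered marker pair with the haplotype
    frequencies, statistics, a usability flag (enough phase-informative
    haplotypes, both loci polymorphic) and the candidate flag
    (X(2) < ``x2_threshold`` and D' < 0).
    """
    if rng is None and seed is not None:
        rng = np.random.default_rng(seed)
    idx = _select_markers(matrix, max_markers, rng)
    if len(idx) < 2:
        return _empty_scan_frame()
    iu, ju, g_ab, g_Ab, g_aB, g_AB, n_hap, usable = _pair_haplotype_freqs(
        matrix, idx, mode, min_haplotypes
    )
    s = pair_statistics(g_ab, g_Ab, g_aB, g_AB)
    enough = usable
    usable = usable & np.isfinite(s["X2"])
    skip_reason = np.where(
        usable, "", np.where(enough, "monomorphic", "too_few_haplotypes")
    )
    candidate = usable & (s["X2"] < x2_threshold) & (s["Dprime"] < 0)
    m = matrix.markers
    mi, mj = idx[iu], idx[ju]
    out = pd.DataFrame(
        {
            "m1": mi,
            "m2": mj,
            "chrom1": m["chrom"].to_numpy()[mi],
            "pos1": m["pos"].to_numpy()[mi],
            "chrom2": m["chrom"].to_numpy()[mj],
            "pos2": m["pos"].to_numpy()[mj],
            "n_hap": n_hap,
            "g_ab": g_ab,
            "g_Ab": g_Ab,
            "g_aB": g_aB,
            "g_AB": g_AB,
            "X2": s["X2"],
            "Dprime": s["Dprime"],
            "deltaD2": s["deltaD2"],
            "usable": usable,
            "candidate": candidate,
            "skip_reason": skip_reason,
        }
    )
    if "cm" in m.columns:
        out["cm1"] = m["cm"].to_numpy()[mi]
        out["cm2"] = m["cm"].to_numpy()[mj]
    return out


def _empty_scan_frame() -> pd.DataFrame:
    cols = [
        "m1", "m2", "chrom1", "pos1", "chrom2", "pos2", "n_hap",
        "g_ab", "g_Ab", "g_aB", "g_AB", "X2", "Dprime", "deltaD2",
        "usable", "candidate", "skip_reason",
    ]
    return pd.DataFrame({c: [] for c in cols})


def g_test_scan(
    matrix: AncestryMatrix,
    mode: str = "pseudo_phased",
    max_markers: int | None = 700,
    min_haplotypes: int = DEFAULT_MIN_HAPLOTYPES,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-pair G test of two-locus independence on the same haplotype
    estimates as `pairwise_scan` (comparison baseline; meaningful for
    unlinked pairs)."""
    if rng is None and seed is not None:
        rng = np.random.default_rng(seed)
    idx = _select_markers(matrix, max_markers, rng)
    if len(idx) < 2:
        return pd.DataFrame({c: [] for c in ["m1", "m2", "G", "p_G", "usable"]})
    iu, ju, g_ab, g_Ab, g_aB, g_AB, n_hap, usable = _pair_haplotype_freqs(
        matrix, idx, mode, min_haplotypes
    )
    # observed 2x2 counts (rows a/A, cols b/B) and marginal expectations
    O = np.stack([g_ab, g_aB, g_Ab, g_AB], axis=-1) * n_hap[..., None]
    row_a = O[..., 0] + O[..., 1]
    row_A = O[..., 2] + O[..., 3]
    col_b = O[..., 0] + O[..., 2]
    col_B = O[..., 1] + O[..., 3]
    n = np.where(n_hap > 0, n_hap, 1.0)
    E = np.stack(
        [row_a * col_b, row_a * col_B, row_A * col_b, row_A * col_B], axis=-1
    ) / n[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(O > 0, O * np.log(O / E), 0.0)
    G = 2.0 * terms.sum(axis=-1)
    poly = (row_a > 0) & (row_A > 0) & (col_b > 0) & (col_B > 0)
    usable = usable & poly
    p = np.where(usable, sps.chi2.sf(np.where(usable, G, 0.0), 1), np.nan)
    G = np.where(usable, G, np.nan)
    return pd.DataFrame(
        {"m1": idx[iu], "m2": idx[ju], "G": G, "p_G": p, "usable": usable}
    )


def bin_pairs(results: pd.DataFrame, bin_size_bp: int = 1_000_000) -> pd.DataFrame:
    """Aggregate usable marker pairs into chromosome x 1-Mb bin pairs.

    Bins are 0-based half-open multiples of ``bin_size_bp``.  Pairs whose
    two markers fall in the same bin are excluded.  A bin pair is a
    putative DMI (``candidate`` True) if at least one contained marker
    pair is a candidate.
    """
    r = results[results["usable"].astype(bool)].copy()
    if len(r) == 0:
        return pd.DataFrame(
            {c: [] for c in
             ["chrom1", "bin1", "chrom2", "bin2", "n_pairs", "n_candidate_pairs",
              "candidate"]}
        )
    b1 = (r["pos1"].to_numpy() // bin_size_bp).astype(np.int64)
    b2 = (r["pos2"].to_numpy() // bin_size_bp).astype(np.int64)
    c1 = r["chrom1"].astype(str).to_numpy()
    c2 = r["chrom2"].astype(str).to_numpy()
    # canonical order within each pair so (x, y) == (y, x)
    flip = (c1 > c2) | ((c1 == c2) & (b1 > b2))
    k1c = np.where(flip, c2, c1)
    k1b = np.where(flip, b2, b1)
    k2c = np.where(flip, c1, c2)
    k2b = np.where(flip, b1, b2)
    same = (k1c == k2c) & (k1b == k2b)
    df = pd.DataFrame(
        {
            "chrom1": k1c[~same],
            "bin1": k1b[~same],
            "chrom2": k2c[~same],
            "bin2": k2b[~same],
            "is_candidate": r["candidate"].to_numpy()[~same],
        }
    )
    out = (
        df.groupby(["chrom1", "bin1", "chrom2", "bin2"], as_index=False)
        .agg(n_pairs=("is_candidate", "size"), n_candidate_pairs=("is_candidate", "sum"))
    )
    out["candidate"] = out["n_candidate_pairs"] > 0
    return out


@dataclass
class BootstrapResult:
    """Outcome of the bootstrap support calibration."""

    supported: pd.DataFrame  # bin pairs with occurrence count >= k
    counts: pd.DataFrame  # all candidate bin pairs with occurrence counts
    k: int
    p_bin: float
    n_bootstrap: int
    per_bootstrap: pd.DataFrame = field(default_factory=pd.DataFrame)


def bootstrap_support(
    matrix: AncestryMatrix,
    mode: str = "pseudo_phased",
    n_bootstrap: int = 20,
    markers_per_bootstrap: int = 700,
    fdr: float = 0.001,
    x2_threshold: float = DEFAULT_X2_THRESHOLD,
    min_haplotypes: int = DEFAULT_MIN_HAPLOTYPES,
    bin_size_bp: int = 1_000_000,
    seed: int | None = None,
) -> BootstrapResult:
    """Bootstrap the marker sampling and calibrate a support threshold k.

    Each bootstrap draws an independent marker sample from the (thinned)
    matrix, scans it, and bins candidates.  ``p_bin`` is the median over
    bootstraps of the candidate fraction among tested bin pairs.  The
    occurrence count of a candidate bin pair across bootstraps is compared
    with Binomial(n_bootstrap, p_bin): k is the smallest count whose
    upper-tail p-value passes the Benjamini-Hochberg-style criterion
    p < (number of bin pairs retained at that count) /
    (total candidate bin pairs over all bootstraps) * fdr.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_bootstrap)
    frac_rows = []
    occurrence: dict[tuple, int] = {}
    total_significant = 0
    for b, child in enumerate(children):
        rng = np.random.default_rng(child)
        res = pairwise_scan(
            matrix,
            mode=mode,
            max_markers=markers_per_bootstrap,
            x2_threshold=x2_threshold,
            min_haplotypes=min_haplotypes,
            rng=rng,
        )
        bins = bin_pairs(res, bin_size_bp)
        n_tested = len(bins)
        n_cand = int(bins["candidate"].sum()) if n_tested else 0
        total_significant += n_cand
        frac_rows.append(
            {"bootstrap": b, "n_tested_bins": n_tested, "n_candidate_bins": n_cand,
             "candidate_fraction": n_cand / n_tested if n_tested else np.nan}
        )
        for _, row in bins[bins["candidate"]].iterrows():
            key = (row["chrom1"], row["bin1"], row["chrom2"], row["bin2"])
            occurrence[key] = occurrence.get(key, 0) + 1
    per_bootstrap = pd.DataFrame(frac_rows)
    p_bin = float(np.nanmedian(per_bootstrap["candidate_fraction"]))
    counts = pd.DataFrame(
        [
            {"chrom1": k[0], "bin1": k[1], "chrom2": k[2], "bin2": k[3], "count": v}
            for k, v in sorted(occurrence.items())
        ]
    )
    if np.isnan(p_bin) or p_bin == 0 or total_significant == 0:
        if occurrence:
            warnings.warn("baseline candidate fraction is zero; using k = 1")
        k = 1
    else:
        k = n_bootstrap + 1  # sentinel: nothing passes
        count_values = counts["count"].to_numpy() if len(counts) else np.array([])
        for c in range(1, n_bootstrap + 1):
            pval = float(sps.binom.sf(c - 1, n_bootstrap, p_bin))
            n_at = int((count_values >= c).sum())
            if n_at == 0:
                break
            if pval < (n_at / total_significant) * fdr:
                k = c
                break
    if len(counts):
        supported = counts[counts["count"] >= k].reset_index(drop=True)
    else:
        supported = counts
    return BootstrapResult(supported, counts, k, p_bin, n_bootstrap, per_bootstrap)
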