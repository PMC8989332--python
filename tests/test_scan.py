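"""Tests of the genome-scan pipeline: filters, thinning, pairwise
statistics, binning and bootstrap support."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dmiscan import simulator as sim
from dmiscan.corestats import g_test
from dmiscan.scan import (
    AncestryMatrix,
    bin_pairs,
    bootstrap_support,
    filter_loci,
    g_test_scan,
    ld_thin,
    pairwise_scan,
)


def make_matrix(dosage, positions=None, chrom="chr1", haplotypes=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if positions is None:
        positions = (np.arange(m) + 1) * 1000
    markers = pd.DataFrame({"chrom": [chrom] * m, "pos": positions})
    return AncestryMatrix(
        dosage=dosage,
        markers=markers,
        individuals=[f"i{k}" for k in range(n)],
        haplotypes=haplotypes,
    )


class TestAncestryMatrix:
    def test_rejects_invalid_dosage(self):
        with pytest.raises(ValueError, match="invalid dosage"):
            make_matrix([[0, 3], [1, 2]])

    def test_rejects_duplicate_markers(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_matrix([[0, 1], [1, 2]], positions=[100, 100])

    def test_sorts_unsorted_markers_with_warning(self):
        with pytest.warns(UserWarning, match="sort"):
            am = make_matrix([[0, 1], [2, 1]], positions=[2000, 1000])
        assert list(am.markers["pos"]) == [1000, 2000]
        assert list(am.dosage[0]) == [1, 0]

    def test_ancestry_fraction_ignores_missing(self):
        am = make_matrix([[2, -1], [0, 2]])
        assert am.ancestry_fraction() == pytest.approx([1.0, 0.5])


class TestFilterLoci:
    def test_rare_homozygote_dropped(self):
        # marker 0: hom0 at 4%, marker 1 fine
        n = 100
        col0 = np.array([0] * 4 + [2] * 70 + [1] * 26)
        col1 = np.array([0] * 20 + [2] * 30 + [1] * 50)
        am = make_matrix(np.column_stack([col0, col1]))
        out = filter_loci(am)
        assert out.n_markers == 1
        assert out.markers["pos"].iloc[0] == 2000

    def test_heterozygous_or_missing_excess_dropped(self):
        col0 = np.array([1] * 50 + [-1] * 15 + [0] * 17 + [2] * 18)  # 65%
        col1 = np.array([1] * 50 + [0] * 25 + [2] * 25)  # 50%
        am = make_matrix(np.column_stack([col0, col1]))
        out = filter_loci(am)
        assert list(out.markers["pos"]) == [2000]

    def test_balanced_marker_retained(self):
        col = np.array([0] * 20 + [1] * 50 + [2] * 30)
        am = make_matrix(col[:, None])
        assert filter_loci(am).n_markers == 1


class TestLdThin:
    def test_identical_close_markers_thinned(self, rng):
        col = rng.integers(0, 3, size=200).astype(np.int8)
        am = make_matrix(np.column_stack([col, col]), positions=[1000, 6000])
        out = ld_thin(am)
        assert list(out.markers["pos"]) == [1000]

    def test_identical_distant_markers_kept(self, rng):
        col = rng.integers(0, 3, size=200).astype(np.int8)
        am = make_matrix(np.column_stack([col, col]), positions=[1000, 51000])
        assert ld_thin(am).n_markers == 2

    def test_independent_markers_kept(self, rng):
        d = rng.integers(0, 3, size=(300, 5)).astype(np.int8)
        am = make_matrix(d, positions=[1000, 2000, 3000, 4000, 5000])
        assert ld_thin(am).n_markers == 5

    def test_chain_thinning_keeps_earliest(self, rng):
        col = rng.integers(0, 3, size=200).astype(np.int8)
        am = make_matrix(np.column_stack([col, col, col]),
                         positions=[1000, 6000, 11000])
        out = ld_thin(am)
        # 1000 drops 6000; 11000 is inside 1000's window too
        assert list(out.markers["pos"]) == [1000]


class TestPairwiseScan:
    def test_dmi_pair_flagged_phased(self, dmi_sample_gen30):
        res = pairwise_scan(dmi_sample_gen30, mode="phased", max_markers=None)
        assert len(res) == 1
        row = res.iloc[0]
        assert row["usable"]
        assert row["X2"] < -0.005 and row["Dprime"] < 0
        assert bool(row["candidate"])

    def test_pseudo_phased_close_to_phased(self, dmi_sample_gen30):
        phased = pairwise_scan(dmi_sample_gen30, mode="phased", max_markers=None)
        pseudo = pairwise_scan(dmi_sample_gen30, mode="pseudo_phased",
                               max_markers=None)
        assert pseudo.iloc[0]["usable"]
        assert pseudo.iloc[0]["n_hap"] >= 50
        assert np.sign(pseudo.iloc[0]["X2"]) == np.sign(phased.iloc[0]["X2"])

    def test_candidate_requires_negative_dprime(self):
        # a one-locus label swap of an imbalanced configuration: X2 < 0
        # (label-invariant) but D > 0, so D' > 0 blocks the candidate call.
        # Haplotype counts: (1,0) x80, (0,0) x200, (1,1) x0, (0,1) x120
        # -> scan-orientation frequencies (ab, Ab, aB, AB) = (.2, .5, 0, .3)
        blocks = [(1, 0)] * 80 + [(0, 0)] * 200 + [(0, 1)] * 120
        H = np.array(blocks, dtype=np.uint8)
        dosage = (H[0::2] + H[1::2]).astype(np.int8)
        am = make_matrix(dosage, haplotypes=H)
        res = pairwise_scan(am, mode="phased", max_markers=None)
        assert res.iloc[0]["X2"] < -0.005
        assert res.iloc[0]["Dprime"] > 0
        assert not bool(res.iloc[0]["candidate"])

    def test_min_haplotype_rule_marks_unusable(self):
        # all individuals heterozygous at marker 0: no homo-homo pairs
        d = np.column_stack([
            np.ones(100, dtype=np.int8),
            np.array([0] * 50 + [2] * 50, dtype=np.int8),
        ])
        am = make_matrix(d)
        res = pairwise_scan(am, mode="pseudo_phased", max_markers=None)
        assert not bool(res.iloc[0]["usable"])
        assert not bool(res.iloc[0]["candidate"])
        assert res.iloc[0]["skip_reason"] == "too_few_haplotypes"

    def test_marker_subsample_is_seeded(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(50, 30)).astype(np.int8)
        am = make_matrix(d)
        r1 = pairwise_scan(am, mode="pseudo_phased", max_markers=10, seed=5,
                           min_haplotypes=1)
        r2 = pairwise_scan(am, mode="pseudo_phased", max_markers=10, seed=5,
                           min_haplotypes=1)
        assert r1.equals(r2)

    def test_parent_relabeling_invariance(self, dmi_sample_gen30):
        am = dmi_sample_gen30
        flipped = AncestryMatrix(
            dosage=np.where(am.dosage == -1, -1, 2 - am.dosage).astype(np.int8),
            markers=am.markers.copy(),
            individuals=list(am.individuals),
            haplotypes=(1 - am.haplotypes).astype(np.uint8),
        )
        a = pairwise_scan(am, mode="phased", max_markers=None)
        b = pairwise_scan(flipped, mode="phased", max_markers=None)
        assert b["X2"].to_numpy() == pytest.approx(a["X2"].to_numpy(), abs=1e-12)
        assert b["Dprime"].to_numpy() == pytest.approx(
            a["Dprime"].to_numpy(), abs=1e-12
        )
        assert b["deltaD2"].to_numpy() == pytest.approx(
            -a["deltaD2"].to_numpy(), abs=1e-12
        )
        assert (b["candidate"] == a["candidate"]).all()


class TestGTestScan:
    def test_matches_single_pair_g_test(self, dmi_sample_gen30):
        res = g_test_scan(dmi_sample_gen30, mode="phased", max_markers=None)
        H = dmi_sample_gen30.haplotypes.astype(float)
        h1, h2 = H[:, 0], H[:, 1]
        counts = [
            int((h1 * (1 - h2)).sum()),       # ab
            int(((1 - h1) * (1 - h2)).sum()),  # Ab
            int((h1 * h2).sum()),             # aB
            int(((1 - h1) * h2).sum()),       # AB
        ]
        ref = g_test(counts)
        assert res.iloc[0]["G"] == pytest.approx(ref.G, abs=1e-9)
        assert res.iloc[0]["p_G"] == pytest.approx(ref.p_value, abs=1e-12)

    def test_independent_table_large_p(self, rng):
        n = 400
        H = rng.integers(0, 2, size=(2 * n, 2)).astype(np.uint8)
        dosage = (H[0::2] + H[1::2]).astype(np.int8)
        am = make_matrix(dosage, haplotypes=H)
        res = g_test_scan(am, mode="phased", max_markers=None)
        assert res.iloc[0]["p_G"] > 0.01


class TestBinPairs:
    def _frame(self, rows):
        base = dict(n_hap=100.0, g_ab=0.25, g_Ab=0.25, g_aB=0.25, g_AB=0.25,
                    X2=0.0, Dprime=0.0, deltaD2=0.0, usable=True)
        recs = []
        for (c1, p1, c2, p2, cand) in rows:
            recs.append(dict(m1=0, m2=1, chrom1=c1, pos1=p1, chrom2=c2, pos2=p2,
                             candidate=cand, **base))
        return pd.DataFrame(recs)

    def test_coordinate_arithmetic(self):
        out = bin_pairs(self._frame([("chr1", 500_000, "chr2", 1_500_000, True)]))
        row = out.iloc[0]
        assert (row["chrom1"], row["bin1"], row["chrom2"], row["bin2"]) == (
            "chr1", 0, "chr2", 1
        )
        assert bool(row["candidate"])

    def test_deduplicates_pairs_in_same_bins(self):
        out = bin_pairs(self._frame([
            ("chr1", 100_000, "chr2", 1_200_000, True),
            ("chr1", 900_000, "chr2", 1_800_000, True),
        ]))
        assert len(out) == 1
        assert out.iloc[0]["n_candidate_pairs"] == 2

    def test_self_bin_pairs_excluded(self):
        out = bin_pairs(self._frame([("chr1", 100_000, "chr1", 900_000, True)]))
        assert len(out) == 0

    def test_canonical_order_merges_reversed_pairs(self):
        out = bin_pairs(self._frame([
            ("chr2", 1_500_000, "chr1", 500_000, True),
            ("chr1", 500_000, "chr2", 1_500_000, False),
        ]))
        assert len(out) == 1
        assert out.iloc[0]["n_pairs"] == 2


@pytest.fixture(scope="module")
def genome_matrix():
    """Small two-DMI genome for bootstrap machinery tests."""
    ra = sim.random_architecture(2, n_dmi_chromosomes=2,
                                 n_neutral_chromosomes=1,
                                 markers_per_chromosome=40, seed=21)
    cfg = sim.SimConfig(N=800, f=0.5, n_generations=25, sample_size=150,
                        seed=21)
    samples, _ = sim.run_simulation(ra.arch, ra.dmis, cfg)
    return samples[25].to_ancestry_matrix(ra.arch)


class TestBootstrapSupport:
    def test_k_respects_binomial_oracle(self, genome_matrix):
        """The calibrated k is the smallest count whose exact binomial
        upper-tail probability beats the BH-style cutoff (recomputed here
        independently by summing pmf terms)."""
        boot = bootstrap_support(genome_matrix, mode="phased", n_bootstrap=10,
                                 markers_per_bootstrap=60, seed=3)
        if boot.p_bin == 0 or len(boot.counts) == 0:
            pytest.skip("no candidates produced by this genome")

        def upper_tail(x, n, p):
            return sum(
                sps.binom.pmf(i, n, p) for i in range(x, n + 1)
            )

        total = int(boot.per_bootstrap["n_candidate_bins"].sum())
        expected_k = boot.n_bootstrap + 1
        for c in range(1, boot.n_bootstrap + 1):
            n_at = int((boot.counts["count"] >= c).sum())
            if n_at == 0:
                break
            if upper_tail(c, boot.n_bootstrap, boot.p_bin) < n_at / total * 0.001:
                expected_k = c
                break
        assert boot.k == expected_k
        assert (boot.supported["count"] >= boot.k).all()

    def test_deterministic_under_seed(self, genome_matrix):
        b1 = bootstrap_support(genome_matrix, mode="phased", n_bootstrap=5,
                               markers_per_bootstrap=50, seed=9)
        b2 = bootstrap_support(genome_matrix, mode="phased", n_bootstrap=5,
                               markers_per_bootstrap=50, seed=9)
        assert b1.k == b2.k
        assert b1.counts.equals(b2.counts)

    def test_zero_baseline_gives_k_one(self):
        # independent random dosages: no candidates anywhere
        local_rng = np.random.default_rng(123)
        d = local_rng.integers(0, 3, size=(120, 40)).astype(np.int8)
        markers = pd.DataFrame({
            "chrom": ["chr1"] * 20 + ["chr2"] * 20,
            "pos": list((np.arange(20) + 1) * 2_000_000) * 2,
        })
        am = AncestryMatrix(dosage=d, markers=markers,
                            individuals=[f"i{k}" for k in range(120)])
        boot = bootstrap_support(am, mode="pseudo_phased", n_bootstrap=5,
                                 markers_per_bootstrap=30, min_haplotypes=10,
                                 seed=2)
        assert boot.k == 1
        assert len(boot.supported) == 0
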