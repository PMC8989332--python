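import numpy as np
import pytest

from dmiscan import simulator as sim


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture(scope="session")
def random_simplices(rng):
    """1000 random valid haplotype-frequency vectors (Dirichlet draws,
    including sparse corners)."""
    dense = rng.dirichlet(np.ones(4), size=700)
    spiky = rng.dirichlet(0.2 * np.ones(4), size=300)
    return np.vstack([dense, spiky])


@pytest.fixture(scope="session")
def two_marker_dmi_arch():
    """Two markers 10 cM apart on one chromosome (c = 0.1)."""
    return sim.GenomeArchitecture(
        [("chr1", [10.0, 20.0], [10_000_000, 20_000_000])]
    )


@pytest.fixture(scope="session")
def unlinked_pair_arch():
    """One marker on each of two chromosomes (c = 0.5)."""
    return sim.GenomeArchitecture(
        [("chr1", [10.0], [10_000_000]), ("chr2", [10.0], [10_000_000])]
    )


@pytest.fixture(scope="session")
def strong_dmi():
    return sim.DMIArchitecture(
        [sim.DMIPair(0, 1, alpha=0.001, beta=0.002, gamma=-0.5)]
    )


@pytest.fixture(scope="session")
def dmi_sample_gen30(two_marker_dmi_arch, strong_dmi):
    """A phased 300-individual sample at generation 30 of a strong
    intrachromosomal DMI (N = 1000)."""
    cfg = sim.SimConfig(
        N=1000, f=0.5, n_generations=30, sample_size=300,
        hybrid_exclusion_threshold=0.0, seed=7,
    )
    samples, _ = sim.run_simulation(two_marker_dmi_arch, strong_dmi, cfg)
    return samples[30].to_ancestry_matrix(two_marker_dmi_arch)
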