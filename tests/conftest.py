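import numpy as np
import pytest

from adipoepi.simulate import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_cfg():
    """A reduced fixture configuration for fast end-to-end tests."""
    return SimConfig(
        seed=7,
        chrom_lengths={"chr1": 4_000_000, "chr2": 4_000_000},
        n_genes=400,
        n_lncrnas=80,
        n_mirnas=50,
        n_stage_specific_per_stage=10,
        n_ba_specific=8,
        n_wa_specific=8,
        n_common=8,
        n_bmp7_transient=5,
        n_lnc_stage_specific_per_stage=6,
        n_lnc_ba_specific=10,
        n_lnc_wa_specific=10,
        n_mirna_stage_specific_per_stage=3,
        n_stage_enhancers_per_stage=20,
        n_constitutive_enhancers=50,
        n_se=6,
        n_weak_se=4,
        reads_per_stage=40_000,
        n_tf_peaks=600,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    from adipoepi.simulate import simulate_expression

    return simulate_expression(small_cfg)


@pytest.fixture(scope="session")
def small_epi(small_cfg, small_sim):
    from adipoepi.simulate import simulate_epigenome

    return simulate_epigenome(small_cfg, small_sim)
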