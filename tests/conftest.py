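import numpy as np
import pytest

import illusionet as il


@pytest.fixture(scope="session")
def baseline_config():
    """The committed calibrated configuration."""
    return il.resolve_config()


@pytest.fixture(scope="session")
def baseline_network(baseline_config):
    return il.build_network(baseline_config)


@pytest.fixture(scope="session")
def baseline_frequency_profile(baseline_config):
    """Phi across the standard 10-frequency grid at baseline (reused)."""
    rows, peak_freq, peak_phi = il.run_am(baseline_config)
    return rows, peak_freq, peak_phi


@pytest.fixture(scope="session")
def phenotype_table(baseline_config):
    """The six-phenotype classification table (expensive, reused)."""
    return il.classify_phenotypes(baseline_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def tiny_layer(A=0.5, B=1.0, C=1.0, h_ex=0.02, h_inh=0.01,
               sigma_ex=2.0, sigma_inh=4.0, normalize=True):
    """Small-kernel layer for fast dynamics tests."""
    from illusionet import KernelSpec, make_subfields
    from illusionet.dynamics import LayerParams

    g_ex, g_inh = make_subfields(
        KernelSpec(h=h_ex, sigma=sigma_ex),
        KernelSpec(h=h_inh, sigma=sigma_inh),
        B, C, normalize=normalize,
    )
    return LayerParams(A=A, B=B, C=C, g_ex=g_ex, g_inh=g_inh)
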