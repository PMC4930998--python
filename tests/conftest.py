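"""Shared fixtures: small simulated datasets and their on-disk trio."""

import numpy as np
import pytest

from newtflow.simulate import SimulationConfig, simulate_dataset, write_dataset


@pytest.fixture(scope="session")
def sc_config():
    """Small secondary-contact simulation, mutation rate raised so the tiny
    locus panel still carries a usable number of SNPs."""
    return SimulationConfig(
        model="SC", params=(1.0, 0.4, 0.4, 0.4, 1.5, 0.5),
        N_A=20_000, mu=1e-7, n_loci=40, locus_length=300,
        outgroup_divergence=0.03, seed=20_160_609)


@pytest.fixture(scope="session")
def sc_dataset(sc_config):
    return simulate_dataset(sc_config)


@pytest.fixture(scope="session")
def sc_trio(sc_dataset, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("trio")
    return write_dataset(sc_dataset, outdir)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
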