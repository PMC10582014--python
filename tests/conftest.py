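"""Shared fixtures: small deterministic communities and read sets."""

import numpy as np
import pytest

from pedna import core, simulate


@pytest.fixture(scope="session")
def small_mech_community():
    """Six hosts, two per mechanism, no free viruses."""
    return simulate.build_community(
        6,
        0,
        mechanism_counts={"EV_producer": 2, "GTA_producer": 2, "transducer": 2},
        seed=5,
    )


@pytest.fixture(scope="session")
def small_mech_reads(small_mech_community):
    mix = simulate.default_pedna_mix(small_mech_community, induction=10.0)
    return simulate.sample_pedna_reads(
        small_mech_community, mix, 12_000, seed=6, induction=10.0
    )


@pytest.fixture(scope="session")
def virion_ev_community():
    """Three EV hosts plus three free viruses (split-stage test bed)."""
    return simulate.build_community(
        3, 3, mechanism_counts={"EV_producer": 3}, seed=9
    )


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
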