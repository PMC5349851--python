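import logging

import numpy as np
import pytest

from csikit.selex import BindingProfile, ReadSet, compute_csi

logging.getLogger("csikit").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20170210)


def make_profile(csi_values: np.ndarray, k: int, strand_mode: str = "forward") -> BindingProfile:
    """Profile with prescribed csi values (counts/expected filled trivially)."""
    n = 4**k
    csi = np.asarray(csi_values, dtype=float)
    assert csi.shape == (n,)
    return BindingProfile(
        dimer_id="toy",
        k=k,
        strand_mode=strand_mode,
        counts=np.zeros(n),
        expected=np.ones(n),
        enrichment=csi.copy(),
        csi=csi,
    )


def random_profile(k: int, rng: np.random.Generator, strand_mode: str = "forward") -> BindingProfile:
    """Profile from random Poisson counts vs a uniform expectation."""
    n = 4**k
    observed = rng.poisson(5.0, size=n).astype(float)
    expected = np.full(n, 5.0)
    return compute_csi(observed, expected, strand_mode=strand_mode, dimer_id=f"rand{k}")


@pytest.fixture
def toy_readset():
    return ReadSet.from_sequences("toy", 3, ["ACGTACGTACGTACGTACGT"])
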