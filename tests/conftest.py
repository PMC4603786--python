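import numpy as np
import pytest

from drugcast import synth
from drugcast.chem import Fingerprint


ZERO_NOISE = dict(
    fp_bitflip_rate=0.0,
    remote_bitflip_rate=0.0,
    se_noise_rate=0.0,
    se_dropout_rate=0.0,
)

# structured regime in which the intersection rule is provably exact:
# disjoint latent sets and no drug pair sharing more than one target
RECOVERY_PARAMS = synth.WorldParams(
    n_targets=30,
    n_drugs=20,
    n_decoy_compounds=40,
    se_catalog_size=300,
    disjoint_latent=True,
    pair_share_cap=1,
    serious_rate=0.0,
    **ZERO_NOISE,
)

TINY_PARAMS = synth.WorldParams(n_targets=12, n_drugs=8, n_decoy_compounds=20)


@pytest.fixture(scope="session")
def tiny_world():
    return synth.make_world(TINY_PARAMS, seed=7)


@pytest.fixture(scope="session")
def zero_noise_world():
    return synth.make_world(RECOVERY_PARAMS, seed=11)


def random_fp(rng: np.random.Generator, popcount: int | None = None) -> Fingerprint:
    if popcount is None:
        popcount = int(rng.integers(1, 400))
    on = rng.choice(1024, size=popcount, replace=False)
    return Fingerprint.from_on_bits(on.tolist())
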