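import numpy as np
import pytest

from cytoval import (EventTable, default_gate_config, default_profile,
                     simulate_matrix)


@pytest.fixture(scope="session")
def pb_profile():
    return default_profile("PB")


@pytest.fixture(scope="session")
def bm_profile():
    return default_profile("BM")


@pytest.fixture(scope="session")
def ln_profile():
    return default_profile("LN")


@pytest.fixture(scope="session")
def gates():
    return default_gate_config()


@pytest.fixture(scope="session")
def ln_blank(ln_profile):
    """One moderately sized labeled blank lymph-node table, reused read-only."""
    return simulate_matrix(ln_profile, 60_000, seed=424242)


@pytest.fixture()
def tiny_events():
    """Three hand-written events spanning the gate regions."""
    return EventTable(
        fsc=np.array([500.0, 10.0, 800.0]),
        ssc=np.array([300.0, 5.0, 900.0]),
        fl1_ige=np.array([10.0, 1.0, 2000.0]),
        fl2_cd117=np.array([12.0, 1.0, 3000.0]),
        fl3_7aad=np.array([3.0, 2.0, 4.0]),
        label=np.array(["lymphocyte", "debris", "mast_cell"], dtype=object),
    )


def random_events(n: int, seed: int, labeled: bool = False) -> EventTable:
    rng = np.random.default_rng(seed)
    cols = 10.0 ** rng.uniform(0, 4, size=(n, 5))
    label = None
    if labeled:
        label = rng.choice(["lymphocyte", "monocyte", "other"], size=n).astype(object)
    return EventTable(*(cols[:, i] for i in range(5)), label=label)
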