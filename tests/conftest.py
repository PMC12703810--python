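import numpy as np
import pytest

from mrfkit.dictionary import GridSpec, build_dictionary, compress
from mrfkit.sequence import default_schedule

TABLE1 = {
    "0% PVP": (2872.0, 1217.0),
    "10% PVP": (2151.0, 1245.0),
    "25% PVP": (1304.0, 962.0),
    "40% PVP": (656.0, 472.0),
    "FBG": (1321.0, 41.0),
}


def brute_force_match(signal: np.ndarray, atoms: np.ndarray) -> int:
    """Independent exhaustive oracle: argmax_i |<atom_i, signal>| with the
    signal L2-normalized, computed directly from definitions."""
    s = np.asarray(signal, dtype=complex)
    s = s / np.linalg.norm(s)
    scores = np.abs(np.conj(atoms) @ s)
    return int(np.argmax(scores))


@pytest.fixture(scope="session")
def schedule300():
    return default_schedule(300)


@pytest.fixture(scope="session")
def tiny_grid():
    return GridSpec(
        t1_segments=((100.0, 1000.0, 100.0), (1000.0, 3000.0, 500.0)),
        t2_segments=((20.0, 100.0, 20.0), (100.0, 500.0, 100.0)),
        b1_values=np.array([0.9, 1.0, 1.1]),
    )


@pytest.fixture(scope="session")
def tiny_dict(tiny_grid, schedule300):
    return build_dictionary(tiny_grid, schedule300)


@pytest.fixture(scope="session")
def tiny_dict_b1_1(tiny_grid, schedule300):
    return build_dictionary(tiny_grid, schedule300, b1_subset=[1.0])


@pytest.fixture(scope="session")
def tiny_compressed(tiny_dict):
    return compress(tiny_dict, rank=30)
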