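import numpy as np
import pytest

from plantcc.ensemble import fixture_networks
from plantcc.network import load_cc_model


@pytest.fixture(scope="session")
def cc():
    return load_cc_model()


@pytest.fixture(scope="session")
def fixtures():
    return fixture_networks()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def brute_force_attractors(net):
    """Independent oracle: walk the trajectory of every initial state.

    Pure-python per-state walk with no shared machinery with the
    pointer-doubling enumeration it is used to check.
    """
    from plantcc.dynamics import successor

    n = net.n
    basins: dict[tuple, int] = {}
    for s0 in range(1 << n):
        seen = {}
        path = []
        s = s0
        while s not in seen:
            seen[s] = len(path)
            path.append(s)
            s = successor(net, s)
        cyc = path[seen[s]:]
        m = cyc.index(min(cyc))
        canon = tuple(cyc[m:] + cyc[:m])
        basins[canon] = basins.get(canon, 0) + 1
    return basins
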