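import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from stiffkmc import build_benchmark_network, make_toy_network  # noqa: E402


@pytest.fixture(scope="session")
def benchmark_zeta10():
    return build_benchmark_network(zeta=10.0)


@pytest.fixture(scope="session")
def benchmark_zeta100():
    return build_benchmark_network(zeta=100.0)


@pytest.fixture()
def birth_death():
    return make_toy_network("birth-death", lam=10.0, mu=1.0)


@pytest.fixture()
def fast_pair():
    return make_toy_network("fast-pair-slow-sink", kf=1e3, kr=1e3, ks=1.0,
                            n0=20)
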