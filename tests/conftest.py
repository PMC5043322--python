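import numpy as np
import pytest

from labsim import Lab, Literature, SimulationParameters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    """Baseline parameters: N=100, b=0.1, W=0.8, e=75, eta=0.2."""
    return SimulationParameters()


@pytest.fixture
def small_literature(rng):
    """Literature holding 200 published positive novel records (half true)."""
    lit = Literature(capacity=10_000)
    from labsim import PublicationRecord

    for i in range(200):
        hyp = lit.new_hypothesis(is_true=(i % 2 == 0), originator=i % 10, step=0)
        lit.add_record(
            PublicationRecord(hyp.hyp_id, i % 10, 0, "positive", "novel", hyp.is_true)
        )
    return lit


@pytest.fixture
def lab():
    return Lab(lab_id=0, power=0.8, effort=75.0, replication_rate=0.0)
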