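import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

from mirtarget import MiRNA, RuleConfig, Transcript

BASES = np.array(list("ACGU"))


def random_mirna(rng, mid="m", length=None):
    L = int(rng.integers(18, 25)) if length is None else length
    return MiRNA(mid, "".join(rng.choice(BASES, L)))


def random_transcript(rng, tid="t", length=None):
    L = int(rng.integers(200, 2001)) if length is None else length
    return Transcript(tid, "".join(rng.choice(BASES, L)))


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture
def default_rules():
    return RuleConfig()


@pytest.fixture
def gu_rich_mirna():
    # 21 nt, G/U at enough positions for wobble constructions (incl. pos 11)
    return MiRNA("mir-test", "UGUGGUAGUAGGUUGUAUAGU")
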