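import numpy as np
import pytest

from myokin.params import S1_WT, S1_R453C, ACTO_S1_WT, ACTO_S1_R453C
from myokin.synth import InstrumentModel


@pytest.fixture
def s1_wt():
    return S1_WT


@pytest.fixture
def s1_mut():
    return S1_R453C


@pytest.fixture
def acto_wt():
    return ACTO_S1_WT


@pytest.fixture
def acto_mut():
    return ACTO_S1_R453C


@pytest.fixture
def noiseless():
    return InstrumentModel(noise_sd_pct=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20130453)


def biexp_trace(t, amps_pct, rates, baseline=None, noise_sd_pct=0.0, rng=None,
                meta=None):
    """Synthetic rise: signal = baseline - sum(a/100 * exp(-k t)).

    ``baseline`` defaults to 1 + total amplitude (pre-mix level 1).
    """
    from myokin.trace import FluorescenceTrace
    amps = np.asarray(amps_pct, dtype=float) / 100.0
    rates = np.asarray(rates, dtype=float)
    if baseline is None:
        baseline = 1.0 + amps.sum()
    y = baseline - sum(a * np.exp(-k * t) for a, k in zip(amps, rates))
    if noise_sd_pct:
        y = y + (rng or np.random.default_rng(0)).normal(
            0, noise_sd_pct / 100.0, t.size)
    return FluorescenceTrace(t, y, meta or {})
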