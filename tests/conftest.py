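import numpy as np
import pytest

from psirt1 import SequenceParams, TissueState


@pytest.fixture
def protocol_seq() -> SequenceParams:
    """In-vivo post-contrast PSIR protocol at 60 bpm."""
    return SequenceParams(
        rr_ms=1000.0, t_inv_ms=300.0, tr_ms=9.4, flip_deg=18.0, tfe_factor=23
    )


@pytest.fixture
def fig1_seq() -> SequenceParams:
    """Illustration parameters: TR 10 ms, flip 15 deg, 19 readout pulses."""
    return SequenceParams(
        rr_ms=1000.0, t_inv_ms=300.0, tr_ms=10.0, flip_deg=15.0, tfe_factor=19
    )


@pytest.fixture
def ll_seq() -> SequenceParams:
    """Look-Locker protocol: continuous readout, flip 15 deg, TR 25 ms."""
    return SequenceParams(
        rr_ms=1000.0, t_inv_ms=0.0, tr_ms=25.0, flip_deg=15.0, tfe_factor=40, kernel_rr=1
    )


@pytest.fixture
def tissue_400() -> TissueState:
    return TissueState(t1_ms=400.0)


def discrete_readout_steady_state(t1_ms: float, m0: float, tr_ms: float, flip_deg: float) -> float:
    """Independent oracle: fixed point of the pulse recursion m -> (m cos a) E + m0 (1 - E).

    Iterated numerically rather than solved, so it shares no algebra with the
    closed-form apparent relaxation.
    """
    e = np.exp(-tr_ms / t1_ms)
    cosa = np.cos(np.radians(flip_deg))
    m = m0
    for _ in range(200_000):
        m_next = m * cosa * e + m0 * (1.0 - e)
        if abs(m_next - m) < 1e-15:
            return m_next
        m = m_next
    return m
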