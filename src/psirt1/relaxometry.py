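"""Closed-form longitudinal magnetization evolution for inversion-recovery
spoiled-gradient-echo kernels.

The repeating unit ("kernel") of a phase-sensitive inversion recovery (PSIR)
acquisition spans two cardiac RR intervals and contains six magnetization
checkpoints:

    M_A  just after the inversion pulse,
    M_B  at the start of the first readout train (after the inversion delay),
    M_C  at the end of the first readout train,
    M_D  at the start of the second readout train (same cardiac phase, next
         beat),
    M_E  at the end of the second readout train,
    M_F  just before the next inversion pulse.

Between readouts the magnetization relaxes freely toward ``m0`` with time
constant ``t1``.  During a readout train of ``n`` spoiled RF pulses of flip
angle alpha repeated every TR the magnetization relaxes toward a *saturated*
steady state ``m0_star`` with a shortened apparent time constant ``t1_star``.
With a low-high k-space profile order the image intensity reflects M_B and
M_D, the magnetization at the start of each readout.

A single-RR kernel (``kernel_rr=1``) models a conventional IR-TFE (inversion
every heart beat, one readout) and, with a readout filling the whole RR, the
Look-Locker sequence.

All times are in milliseconds; magnetization is in units of ``m0``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SequenceParams",
    "TissueState",
    "ApparentRelaxation",
    "MagnetizationKernel",
    "apparent_relaxation",
    "relax_toward",
    "propagate_kernel",
    "steady_state_kernel",
    "look_locker_signal",
    "look_locker_null_time",
]

_TIME_EPS = 1e-9  # slack for "readout fills the RR" configurations (Look-Locker)


@dataclass(frozen=True)
class SequenceParams:
    """Timing and RF parameters of one PSIR / IR-TFE / Look-Locker kernel.

    Parameters
    ----------
    rr_ms : float
        Duration of one cardiac RR interval.
    t_inv_ms : float
        Inversion delay: time from the inversion pulse to the start of the
        first readout train.  May be 0 (continuous acquisition).
    tr_ms : float
        Repetition time of the readout pulses.
    flip_deg : float
        Readout flip angle alpha in degrees, ``0 <= flip_deg < 90``.
        0 is admitted as the unsaturated limit.
    tfe_factor : int
        Number ``n`` of readout pulses per acquisition block; the block lasts
        ``t_acq_ms = tfe_factor * tr_ms``.
    inversion_deg : float
        Inversion pulse angle in degrees, ``90 < inversion_deg <= 180``.
    kernel_rr : int
        RR intervals per kernel: 2 for PSIR, 1 for IR-TFE / Look-Locker.
    """

    rr_ms: float
    t_inv_ms: float
    tr_ms: float
    flip_deg: float
    tfe_factor: int
    inversion_deg: float = 180.0
    kernel_rr: int = 2

    def __post_init__(self) -> None:
        if self.rr_ms <= 0:
            raise ValueError(f"rr_ms must be positive, got {self.rr_ms}")
        if self.tr_ms <= 0:
            raise ValueError(f"tr_ms must be positive, got {self.tr_ms}")
        if self.t_inv_ms < 0:
            raise ValueError(f"t_inv_ms must be non-negative, got {self.t_inv_ms}")
        if not 0.0 <= self.flip_deg < 90.0:
            raise ValueError(f"flip_deg must be in [0, 90), got {self.flip_deg}")
        if not 90.0 < self.inversion_deg <= 180.0:
            raise ValueError(
                f"inversion_deg must be in (90, 180], got {self.inversion_deg}"
            )
        if int(self.tfe_factor) != self.tfe_factor or self.tfe_factor < 1:
            raise ValueError(f"tfe_factor must be a positive integer, got {self.tfe_factor}")
        if self.kernel_rr not in (1, 2):
            raise ValueError(f"kernel_rr must be 1 or 2, got {self.kernel_rr}")
        if self.t_inv_ms + self.t_acq_ms > self.rr_ms + _TIME_EPS:
            raise ValueError(
                "readout must end within the RR interval: "
                f"t_inv_ms + tfe_factor*tr_ms = {self.t_inv_ms + self.t_acq_ms:.3f} "
                f"> rr_ms = {self.rr_ms:.3f}"
            )

    @property
    def t_acq_ms(self) -> float:
        """Duration of one readout train, ``tfe_factor * tr_ms``."""
        return self.tfe_factor * self.tr_ms

    @property
    def kernel_ms(self) -> float:
        """Total kernel duration, ``kernel_rr * rr_ms``."""
        return self.kernel_rr * self.rr_ms

    @property
    def cos_flip(self) -> float:
        return float(np.cos(np.radians(self.flip_deg)))

    @property
    def cos_inversion(self) -> float:
        return float(np.cos(np.radians(self.inversion_deg)))

    def replace(self, **changes) -> "SequenceParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class TissueState:
    """Ground-truth or fitted (T1, M0) pair for one tissue or voxel."""

    t1_ms: float
    m0: float = 1.0

    def __post_init__(self) -> None:
        if self.t1_ms <= 0:
            raise ValueError(f"t1_ms must be positive, got {self.t1_ms}")
        if self.m0 <= 0:
            raise ValueError(f"m0 must be positive, got {self.m0}")

    @property
    def r1_per_s(self) -> float:
        """Relaxation rate R1 = 1000 / t1_ms, in 1/s."""
        return 1000.0 / self.t1_ms


@dataclass(frozen=True)
class ApparentRelaxation:
    """Apparent relaxation during a spoiled readout train.

    ``t1_star_ms <= t1_ms`` and ``m0_star <= m0``, with equality only for
    flip angle 0.
    """

    t1_star_ms: float
    m0_star: float


@dataclass(frozen=True)
class MagnetizationKernel:
    """Magnetization at the six checkpoints of one two-RR PSIR kernel."""

    m_a: float
    m_b: float
    m_c: float
    m_d: float
    m_e: float
    m_f: float

    def as_array(self) -> np.ndarray:
        return np.array([self.m_a, self.m_b, self.m_c, self.m_d, self.m_e, self.m_f])


# ---------------------------------------------------------------------------
# array-friendly primitives (used by the voxelwise fitter and the simulator)
# ---------------------------------------------------------------------------

def apparent_relaxation_arrays(t1_ms, m0, seq: SequenceParams):
    """Vectorized apparent relaxation (t1_star, m0_star) for a readout train.

    The readout applies flip alpha then TR of free relaxation, per pulse.
    Eliminating the pulse structure gives an exponential approach at the
    pulse instants with

        1/t1_star = 1/t1 - ln(cos alpha)/TR
        m0_star   = m0 * (1 - E) / (1 - E cos alpha),   E = exp(-TR/t1)

    which is exact at multiples of TR (not the thin-pulse continuum
    approximation ``m0 * t1_star / t1``), so the closed-form kernel agrees
    with a pulse-by-pulse simulation to machine precision.
    """
    t1_ms = np.asarray(t1_ms, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    cosa = seq.cos_flip
    if seq.flip_deg == 0.0:
        return t1_ms + 0.0, m0 + 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        r1_star = 1.0 / t1_ms - np.log(cosa) / seq.tr_ms
        t1_star = 1.0 / r1_star
        e_tr = np.exp(-seq.tr_ms / t1_ms)
        m0_star = m0 * (1.0 - e_tr) / (1.0 - e_tr * cosa)
    return t1_star, m0_star


def relax_toward(m_start, m_target, duration_ms, tau_ms):
    """Exponential approach of the longitudinal magnetization.

    Returns ``m_target + (m_start - m_target) * exp(-duration_ms / tau_ms)``.
    Accepts scalars or broadcastable arrays.
    """
    if np.any(np.asarray(tau_ms) <= 0):
        raise ValueError("tau_ms must be positive")
    if np.any(np.asarray(duration_ms) < 0):
        raise ValueError("duration_ms must be non-negative")
    return m_target + (m_start - m_target) * np.exp(
        -np.asarray(duration_ms, dtype=float) / tau_ms
    )


def _kernel_segments(t1_ms, m0, seq: SequenceParams):
    """The free/saturated relaxation segments of one kernel.

    Each segment is (duration, target, tau); checkpoints fall at segment
    boundaries.  For ``kernel_rr=2`` the boundaries are M_B..M_F; for
    ``kernel_rr=1`` they are M_B, M_C (end of readout) and the pre-inversion
    magnetization.
    """
    t1_star, m0_star = apparent_relaxation_arrays(t1_ms, m0, seq)
    ti, ta, rr = seq.t_inv_ms, seq.t_acq_ms, seq.rr_ms
    if seq.kernel_rr == 2:
        return [
            (ti, m0, t1_ms),
            (ta, m0_star, t1_star),
            (rr - ta, m0, t1_ms),
            (ta, m0_star, t1_star),
            (max(rr - ti - ta, 0.0), m0, t1_ms),
        ]
    return [
        (ti, m0, t1_ms),
        (ta, m0_star, t1_star),
        (max(rr - ti - ta, 0.0), m0, t1_ms),
    ]


def propagate_checkpoints(t1_ms, m0, seq: SequenceParams, m_a):
    """Chain the kernel segments from a given post-inversion magnetization.

    Returns the magnetization after each segment (length 5 for PSIR kernels,
    3 for single-RR kernels), vectorized over broadcastable inputs.
    """
    m = np.asarray(m_a, dtype=float)
    out = []
    for duration, target, tau in _kernel_segments(t1_ms, m0, seq):
        m = relax_toward(m, target, duration, tau)
        out.append(m)
    return out


def steady_state_m_a(t1_ms, m0, seq: SequenceParams):
    """Post-inversion steady-state magnetization M_A of the repeated kernel.

    Each segment is an affine map of its entry magnetization, so one kernel
    maps ``m -> A m + B`` with ``0 < A < 1``; the inversion contributes
    ``cos(inversion_deg)``.  The steady state is the fixed point

        m_a = B c / (1 - A c),   c = cos(inversion_deg).
    """
    t1_ms = np.asarray(t1_ms, dtype=float)
    segs = _kernel_segments(t1_ms, m0, seq)
    a = np.ones_like(t1_ms, dtype=float)
    b = np.zeros_like(t1_ms, dtype=float)
    for duration, target, tau in segs:
        g = np.exp(-np.asarray(duration, dtype=float) / tau)
        a = g * a
        b = g * b + target * (1.0 - g)
    c = seq.cos_inversion
    return b * c / (1.0 - a * c)


def steady_state_readout(t1_ms, m0, seq: SequenceParams):
    """Steady-state signal at the readout starts, vectorized.

    For ``kernel_rr=2`` returns ``(m_b, m_d)``; for ``kernel_rr=1`` returns
    the single readout-start magnetization ``m_b``.
    """
    m_a = steady_state_m_a(t1_ms, m0, seq)
    cps = propagate_checkpoints(t1_ms, m0, seq, m_a)
    if seq.kernel_rr == 2:
        return cps[0], cps[2]
    return cps[0]


# ---------------------------------------------------------------------------
# scalar, typed surface
# ---------------------------------------------------------------------------

def apparent_relaxation(tissue: TissueState, seq: SequenceParams) -> ApparentRelaxation:
    """Apparent relaxation (T1*, M0*) during the spoiled readout train."""
    if seq.flip_deg >= 90.0:
        raise ValueError("flip_deg must be below 90 degrees")
    t1_star, m0_star = apparent_relaxation_arrays(tissue.t1_ms, tissue.m0, seq)
    return ApparentRelaxation(float(t1_star), float(m0_star))


def propagate_kernel(tissue: TissueState, seq: SequenceParams, m_a: float) -> MagnetizationKernel:
    """Propagate one full PSIR kernel from post-inversion magnetization m_a."""
    if seq.kernel_rr != 2:
        raise ValueError("propagate_kernel requires a two-RR (PSIR) kernel")
    cps = propagate_checkpoints(tissue.t1_ms, tissue.m0, seq, m_a)
    return MagnetizationKernel(float(m_a), *(float(c) for c in cps))


def steady_state_kernel(
    tissue: TissueState, seq: SequenceParams, method: str = "closed_form"
) -> MagnetizationKernel:
    """Steady-state checkpoints of the repeated PSIR kernel.

    With a perfect inversion the steady state satisfies ``m_a = -m_f`` and
    ``|m_a| < m0``; with an imperfect inversion ``m_a = m_f cos(inv)``.

    ``method='iterate'`` repeats kernel propagation to convergence instead of
    using the affine fixed point; both agree and the iterative route is kept
    as an internal cross-check.
    """
    if seq.kernel_rr != 2:
        raise ValueError("steady_state_kernel requires a two-RR (PSIR) kernel")
    if method == "closed_form":
        m_a = float(steady_state_m_a(tissue.t1_ms, tissue.m0, seq))
    elif method == "iterate":
        m_a = -tissue.m0
        for _ in range(100_000):
            cps = propagate_checkpoints(tissue.t1_ms, tissue.m0, seq, m_a)
            m_a_next = float(cps[-1]) * seq.cos_inversion
            if abs(m_a_next - m_a) < 1e-14 * tissue.m0:
                m_a = m_a_next
                break
            m_a = m_a_next
    else:
        raise ValueError(f"unknown method {method!r}")
    return propagate_kernel(tissue, seq, m_a)


def look_locker_signal(t_ms, tissue: TissueState, seq: SequenceParams):
    """Steady-state Look-Locker signal at time ``t_ms`` after inversion.

    The Look-Locker sequence inverts every RR interval and reads out
    continuously, so the whole interval relaxes toward ``m0_star`` with
    ``t1_star`` and the signal is

        M(t) = m0_star * (1 - (2 / (1 + e)) * exp(-t / t1_star)),
        e = exp(-rr / t1_star).

    ``t_ms`` may be a scalar or an array in ``[0, rr_ms)``.
    """
    if seq.kernel_rr != 1:
        raise ValueError("look_locker_signal requires a single-RR kernel")
    t = np.asarray(t_ms, dtype=float)
    if np.any(t < 0) or np.any(t >= seq.rr_ms):
        raise ValueError("t_ms must lie in [0, rr_ms)")
    t1_star, m0_star = apparent_relaxation_arrays(tissue.t1_ms, tissue.m0, seq)
    e = np.exp(-seq.rr_ms / t1_star)
    out = m0_star * (1.0 - (2.0 / (1.0 + e)) * np.exp(-t / t1_star))
    return float(out) if np.isscalar(t_ms) else out


def look_locker_null_time(tissue: TissueState, seq: SequenceParams) -> float:
    """Zero crossing of the steady-state Look-Locker signal after inversion.

    ``t_null = t1_star * ln(2 / (1 + e))`` with ``e = exp(-rr/t1_star)``.
    In general this does NOT coincide with the PSIR zero crossing of the
    same tissue: the continuous readout shortens the relaxation to t1_star
    and shifts the steady state.
    """
    t1_star, _ = apparent_relaxation_arrays(tissue.t1_ms, tissue.m0, seq)
    e = np.exp(-seq.rr_ms / float(t1_star))
    return float(t1_star) * float(np.log(2.0 / (1.0 + e)))
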