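"""Extended phase graph (EPG) engine for spoiled gradient-echo trains.

State is kept in the usual configuration basis: transverse orders
``F+(k), F-(k)`` (with ``F-(k) = conj(F(-k))``) and longitudinal orders
``Z(k)`` for k >= 0. Gradient spoiling shifts transverse orders by one;
RF pulses mix the three components order-by-order; relaxation scales F by
exp(-t/T2) and Z by exp(-t/T1) with recovery of Z(0) toward the proton
density.

The conventions (rotation handedness, signal demodulation) match the
isochromat simulator in :mod:`b1sandwich.bloch`, which serves as an
independent oracle in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TissueParams",
    "EPGState",
    "epg_rf",
    "epg_relax_recover",
    "epg_grad_spoil",
    "flash_train",
]


@dataclass
class TissueParams:
    """Relaxation parameters of one tissue/voxel.

    t1, t2 in seconds; pd is the relative proton density (equilibrium
    magnetization). Physical tissue has t2 <= t1; violations only warn.
    """

    t1: float
    t2: float = 0.05
    pd: float = 1.0

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("t1 and t2 must be positive")
        if self.pd < 0:
            raise ValueError("pd must be >= 0")
        if self.t2 > self.t1:
            warnings.warn("t2 > t1 is unphysical for tissue", stacklevel=2)


@dataclass
class EPGState:
    """Configuration-state amplitudes up to ``max_order``."""

    fp: np.ndarray  # F+(k), complex, k = 0..max_order
    fm: np.ndarray  # conj(F(-k)), complex
    z: np.ndarray  # Z(k), complex
    pd: float = 1.0

    @classmethod
    def equilibrium(cls, max_order: int, pd: float = 1.0) -> "EPGState":
        n = max_order + 1
        z = np.zeros(n, dtype=complex)
        z[0] = pd
        return cls(np.zeros(n, dtype=complex), np.zeros(n, dtype=complex), z, pd)

    @property
    def max_order(self) -> int:
        return self.fp.size - 1

    def copy(self) -> "EPGState":
        return EPGState(self.fp.copy(), self.fm.copy(), self.z.copy(), self.pd)

    def total_magnetization(self) -> float:
        """Root sum of squared configuration amplitudes (norm bound <= pd)."""
        return float(
            np.sqrt(
                np.abs(self.fp[0]) ** 2
                + 2 * np.sum(np.abs(self.fp[1:]) ** 2)
                + np.abs(self.z[0]) ** 2
                + 2 * np.sum(np.abs(self.z[1:]) ** 2)
            )
        )


def epg_rf(state: EPGState, flip_deg: float, phase_deg: float = 0.0) -> EPGState:
    """Apply an instantaneous RF rotation of given flip and phase."""
    a = np.deg2rad(flip_deg)
    p = np.deg2rad(phase_deg)
    ca2 = np.cos(a / 2.0) ** 2
    sa2 = np.sin(a / 2.0) ** 2
    sa = np.sin(a)
    eip = np.exp(1j * p)
    fp = ca2 * state.fp + sa2 * eip**2 * state.fm - 1j * eip * sa * state.z
    fm = sa2 / eip**2 * state.fp + ca2 * state.fm + 1j / eip * sa * state.z
    z = -0.5j / eip * sa * state.fp + 0.5j * eip * sa * state.fm + np.cos(a) * state.z
    return EPGState(fp, fm, z, state.pd)


def epg_relax_recover(state: EPGState, t_s: float, tissue: TissueParams) -> EPGState:
    """Free relaxation/recovery over ``t_s`` seconds."""
    if t_s < 0:
        raise ValueError("t_s must be >= 0")
    e1 = np.exp(-t_s / tissue.t1)
    e2 = np.exp(-t_s / tissue.t2)
    z = state.z * e1
    z[0] += tissue.pd * (1.0 - e1)
    return EPGState(state.fp * e2, state.fm * e2, z, state.pd)


def epg_grad_spoil(state: EPGState, truncation_tol: float = 1e-6) -> EPGState:
    """One unit of gradient dephasing: shift transverse orders by one.

    The highest order is discarded; if it carried more than
    ``truncation_tol`` of amplitude a warning is raised so callers can grow
    ``max_order``.
    """
    if np.abs(state.fp[-1]) > truncation_tol:
        warnings.warn(
            f"EPG truncation discarded |F+|={np.abs(state.fp[-1]):.2e} at max_order",
            stacklevel=2,
        )
    fp = np.empty_like(state.fp)
    fm = np.empty_like(state.fm)
    fp[1:] = state.fp[:-1]
    fm[:-1] = state.fm[1:]
    fm[-1] = 0.0
    fp[0] = np.conj(fm[0])
    return EPGState(fp, fm, state.z.copy(), state.pd)


def flash_train(
    state: EPGState,
    n_echoes: int,
    flip_deg: float,
    tr_flash_s: float,
    tissue: TissueParams,
    rf_spoil_increment_deg: float = 50.0,
    te_s: float = 0.0,
    t2_decay_to_te: bool = True,
    truncation_tol: float = 1e-6,
) -> tuple[np.ndarray, EPGState]:
    """Spoiled gradient-echo readout train.

    Per echo: RF pulse with quadratic RF-spoiling phase, echo sampled at the
    excitation instant (optionally decayed to TE by exp(-TE/T2)), relaxation
    over TR_FLASH, one gradient-spoiler shift. Echoes are demodulated by the
    transmit phase so an ideally spoiled train returns real positive
    ``Mz_k sin(flip)``.
    """
    if n_echoes < 1:
        raise ValueError("n_echoes must be >= 1")
    ete = np.exp(-te_s / tissue.t2) if (te_s and t2_decay_to_te) else 1.0
    echoes = np.empty(n_echoes, dtype=complex)
    for j in range(n_echoes):
        phi = rf_spoil_increment_deg * j * (j + 1) / 2.0
        state = epg_rf(state, flip_deg, phi)
        echoes[j] = 1j * state.fp[0] * np.exp(-1j * np.deg2rad(phi)) * ete
        state = epg_relax_recover(state, tr_flash_s, tissue)
        state = epg_grad_spoil(state, truncation_tol)
    return echoes, state
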