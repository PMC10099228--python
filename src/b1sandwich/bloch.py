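"""Numerical Bloch simulation primitives.

Everything here works in the rotating frame with hard-pulse (piecewise-constant)
RF. Amplitudes are expressed as the instantaneous nutation frequency
``f1 = gamma * B1 / (2 pi)`` in Hz, so a constant pulse of amplitude ``f1``
and duration ``T`` rotates the magnetization by ``360 * f1 * T`` degrees on
resonance. Relaxation is neglected during RF pulses (pulse durations of a few
milliseconds are far shorter than the T1/T2 of interest here).

Conventions (shared with :mod:`b1sandwich.epg`):

* an on-resonance pulse of flip ``a`` and phase ``p`` applies the rotation
  ``Rz(p) @ Rx(a) @ Rz(-p)`` with right-handed rotation matrices;
* the complex signal is ``1j * (Mx + 1j My) * exp(-1j p)`` so that exciting
  equilibrium magnetization yields a real, positive signal ``sin(a)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "rotate",
    "hard_pulse_matrix",
    "simulate_pulse_mz",
    "isochromat_flash_train",
    "ideal_spoiled_train",
]


def rotate(m: np.ndarray, axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rodrigues rotation of magnetization vectors.

    Parameters
    ----------
    m : (..., 3) array
    axis : (..., 3) array, unit vectors (unnormalized axes are normalized here)
    angle : (...) array, radians, right-handed about ``axis``
    """
    m = np.asarray(m, dtype=float)
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis, axis=-1, keepdims=True)
    # zero axis -> identity
    safe = np.where(norm == 0.0, 1.0, norm)
    n = axis / safe
    ang = np.asarray(angle, dtype=float)[..., None]
    cos = np.cos(ang)
    sin = np.sin(ang)
    ndotm = np.sum(n * m, axis=-1, keepdims=True)
    out = m * cos + np.cross(n, m) * sin + n * ndotm * (1.0 - cos)
    return np.where(norm == 0.0, m, out)


def hard_pulse_matrix(f1_hz: complex, offset_hz: float, dt_s: float) -> np.ndarray:
    """Closed-form 3x3 rotation for one piecewise-constant RF step.

    ``f1_hz`` is the complex RF amplitude (magnitude = nutation frequency in
    Hz, argument = RF phase); ``offset_hz`` the off-resonance frequency.
    """
    wx = 2.0 * np.pi * np.real(f1_hz)
    wy = 2.0 * np.pi * np.imag(f1_hz)
    wz = 2.0 * np.pi * offset_hz
    w = np.array([wx, wy, wz])
    wmag = np.linalg.norm(w)
    if wmag == 0.0:
        return np.eye(3)
    basis = np.eye(3)
    cols = [rotate(basis[i], w, wmag * dt_s) for i in range(3)]
    return np.stack(cols, axis=-1)


def simulate_pulse_mz(
    samples_hz: np.ndarray,
    dt_s: float,
    b1_scales: np.ndarray,
    b0_offsets_hz: np.ndarray,
) -> np.ndarray:
    """Residual Mz after an RF pulse, starting from equilibrium.

    Integrates the Bloch equation (no relaxation) by composing hard-pulse
    rotations for each waveform sample, vectorized over a grid of relative
    transmit amplitudes and off-resonance frequencies.

    Returns
    -------
    mz : (n_scales, n_offsets) array
    """
    samples = np.asarray(samples_hz, dtype=complex)
    scales = np.atleast_1d(np.asarray(b1_scales, dtype=float))
    offsets = np.atleast_1d(np.asarray(b0_offsets_hz, dtype=float))
    ns, no = scales.size, offsets.size

    m = np.zeros((ns, no, 3))
    m[..., 2] = 1.0
    wz = 2.0 * np.pi * offsets[None, :]  # (1, no)
    for s in samples:
        wx = 2.0 * np.pi * scales[:, None] * s.real  # (ns, 1)
        wy = 2.0 * np.pi * scales[:, None] * s.imag
        axis = np.empty((ns, no, 3))
        axis[..., 0] = wx
        axis[..., 1] = wy
        axis[..., 2] = wz
        wmag = np.sqrt(axis[..., 0] ** 2 + axis[..., 1] ** 2 + axis[..., 2] ** 2)
        m = rotate(m, axis, wmag * dt_s)
    return m[..., 2]


def _rf_matrix(flip_deg: float, phase_deg: float) -> np.ndarray:
    a = np.deg2rad(flip_deg)
    p = np.deg2rad(phase_deg)
    ca, sa = np.cos(a), np.sin(a)
    cp, sp = np.cos(p), np.sin(p)
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]], dtype=float)
    rz = np.array([[cp, -sp, 0], [sp, cp, 0], [0, 0, 1]], dtype=float)
    rzm = np.array([[cp, sp, 0], [-sp, cp, 0], [0, 0, 1]], dtype=float)
    return rz @ rx @ rzm


def isochromat_flash_train(
    n_echoes: int,
    flip_deg: float,
    tr_flash_s: float,
    t1_s: float,
    t2_s: float,
    rf_spoil_increment_deg: float = 50.0,
    n_spins: int = 512,
    te_s: float = 0.0,
    m0: float = 1.0,
    initial_mz: float | None = None,
) -> np.ndarray:
    """Spoiled gradient-echo train simulated on a ring of isochromats.

    Independent dephasing oracle for the EPG engine: ``n_spins`` isochromats
    acquire one full cycle (2 pi) of gradient dephasing per TR, exactly
    emulating the configuration-order shift of the phase graph. Echo ``j`` is
    sampled immediately after the RF pulse and demodulated by the quadratic
    RF-spoiling transmit phase.
    """
    m = np.zeros((n_spins, 3))
    m[:, 2] = m0 if initial_mz is None else initial_mz
    dphi = 2.0 * np.pi * (np.arange(n_spins) + 0.5) / n_spins
    cg, sg = np.cos(dphi), np.sin(dphi)
    e1 = np.exp(-tr_flash_s / t1_s)
    e2 = np.exp(-tr_flash_s / t2_s)
    ete = np.exp(-te_s / t2_s) if te_s else 1.0

    echoes = np.empty(n_echoes, dtype=complex)
    for j in range(n_echoes):
        phi = rf_spoil_increment_deg * j * (j + 1) / 2.0
        m = m @ _rf_matrix(flip_deg, phi).T
        sig = np.mean(m[:, 0] + 1j * m[:, 1])
        echoes[j] = 1j * sig * np.exp(-1j * np.deg2rad(phi)) * ete
        # relaxation over TR_FLASH
        m[:, 0] *= e2
        m[:, 1] *= e2
        m[:, 2] = m[:, 2] * e1 + m0 * (1.0 - e1)
        # gradient spoiling: one dephasing cycle across the ring
        x = m[:, 0] * cg - m[:, 1] * sg
        y = m[:, 0] * sg + m[:, 1] * cg
        m[:, 0], m[:, 1] = x, y
    return echoes


def ideal_spoiled_train(
    n_echoes: int,
    flip_deg: float,
    tr_flash_s: float,
    t1_s: float,
    m0: float = 1.0,
    initial_mz: float | None = None,
) -> np.ndarray:
    """Closed-form perfectly-spoiled FLASH recursion.

    ``Mz_{k+1} = (Mz_k cos b) E1 + (1 - E1)`` with echo ``Mz_k sin b`` —
    the T2 -> 0 limit of the phase-graph train.
    """
    b = np.deg2rad(flip_deg)
    e1 = np.exp(-tr_flash_s / t1_s)
    mz = m0 if initial_mz is None else initial_mz
    echoes = np.empty(n_echoes)
    for k in range(n_echoes):
        echoes[k] = mz * np.sin(b)
        mz = (mz * np.cos(b)) * e1 + m0 * (1.0 - e1)
    return echoes
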