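"""RF pulse design for the preparation module: rect, apodized sinc, and HS8.

The HS8 (order-8 stretched hyperbolic secant) preparation pulse is an
amplitude- and frequency-modulated broadband pulse operated *below* the
adiabatic limit, so its saturation response still encodes the transmit
amplitude. Its flip-vs-amplitude response is nonlinear at high flip angles,
which is handled downstream by a monotone lookup table
(:class:`LookupTable`) inverting the Bloch-simulated Mz response.

Amplitudes are stored as complex nutation frequencies in Hz (see
:mod:`b1sandwich.bloch`); magnitude is real-nonnegative with the frequency
modulation carried in the phase.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .bloch import simulate_pulse_mz

__all__ = [
    "PulseWaveform",
    "PulseResponse",
    "LookupTable",
    "make_rect",
    "make_hs8",
    "make_sinc",
    "simulate_pulse_response",
    "pulse_energy",
    "build_lookup",
]

#: integration step ceiling: < 0.1 deg rotation error at a few kHz offset
MAX_DT_S = 5e-6


@dataclass
class PulseWaveform:
    """Sampled complex RF envelope.

    samples : complex nutation frequency per time step (Hz); |samples| is the
        envelope, the argument the phase/frequency modulation.
    dt : seconds per sample.
    nominal_flip_deg : on-resonance flip achieved at relative amplitude 1.0.
    family : "rect", "sinc" or "hs8".
    tbp : time-bandwidth product (sinc/hs8 only).
    """

    samples: np.ndarray
    dt: float
    nominal_flip_deg: float
    family: str
    tbp: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.samples.size * self.dt

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.samples)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.samples)

    @property
    def peak_hz(self) -> float:
        return float(np.max(np.abs(self.samples)))

    def on_resonance_mz(self, b1_scale: float = 1.0) -> float:
        return float(simulate_pulse_mz(self.samples, self.dt, [b1_scale], [0.0])[0, 0])

    def to_csv(self, path: str | Path) -> None:
        """Write time_s, amp, phase_rad columns plus a JSON metadata sidecar."""
        path = Path(path)
        t = np.arange(self.samples.size) * self.dt
        arr = np.column_stack([t, np.abs(self.samples), np.angle(self.samples)])
        np.savetxt(path, arr, delimiter=",", header="time_s,amp,phase_rad", comments="")
        meta = {
            "family": self.family,
            "dt": self.dt,
            "nominal_flip_deg": self.nominal_flip_deg,
            "tbp": self.tbp,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "PulseWaveform":
        path = Path(path)
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        meta = json.loads(path.with_suffix(".json").read_text())
        samples = arr[:, 1] * np.exp(1j * arr[:, 2])
        return cls(
            samples=samples,
            dt=float(meta["dt"]),
            nominal_flip_deg=float(meta["nominal_flip_deg"]),
            family=meta["family"],
            tbp=meta.get("tbp"),
        )


@dataclass
class PulseResponse:
    """Bloch-simulated saturation response of a pulse over (B1 scale, B0) grids."""

    b1_scales: np.ndarray
    b0_offsets: np.ndarray
    mz: np.ndarray  # (n_scales, n_offsets)
    nominal_flip_deg: float

    @property
    def effective_flip_deg(self) -> np.ndarray:
        return np.degrees(np.arccos(np.clip(self.mz, -1.0, 1.0)))


@dataclass
class LookupTable:
    """Monotone table of apparent ratio (Mz after prep) vs nominal flip.

    ``apparent_ratio[i]`` is the longitudinal magnetization left by the
    preparation pulse when the transmit amplitude corresponds to a *nominal*
    (linearly-scaled) flip of ``nominal_flip_deg[i]``. For a rect pulse this
    is exactly ``cos``; for the HS8 it deviates above ~90 deg and remains
    invertible up to roughly 200 deg.
    """

    nominal_flip_deg: np.ndarray
    apparent_ratio: np.ndarray
    valid_range_deg: tuple[float, float]

    def forward(self, flip_deg):
        """Nominal flip (deg) -> apparent ratio (Mz), linear interpolation."""
        return np.interp(flip_deg, self.nominal_flip_deg, self.apparent_ratio)

    def invert(self, ratio, clamp: bool = True):
        """Apparent ratio -> nominal flip (deg) over the invertible range.

        Ratios outside the monotone branch are clamped to the range edge
        (ties broken toward the lower flip). Returns (flip, clipped_mask)
        when ``clamp`` is True and the input is an array; scalar input
        returns a float.
        """
        ratio = np.asarray(ratio, dtype=float)
        lo, hi = self.valid_range_deg
        sel = (self.nominal_flip_deg >= lo) & (self.nominal_flip_deg <= hi)
        flips = self.nominal_flip_deg[sel]
        ratios = self.apparent_ratio[sel]
        # np.interp needs increasing x; ratio decreases with flip
        clipped = (ratio > ratios[0]) | (ratio < ratios[-1])
        out = np.interp(ratio, ratios[::-1], flips[::-1])
        if not clamp and np.any(clipped):
            raise ValueError("ratio outside invertible lookup range")
        if out.ndim == 0:
            return float(out)
        return out

    def to_csv(self, path: str | Path) -> None:
        arr = np.column_stack([self.nominal_flip_deg, self.apparent_ratio])
        np.savetxt(
            path, arr, delimiter=",", header="nominal_flip_deg,apparent_ratio", comments=""
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "LookupTable":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return build_lookup_from_table(arr[:, 0], arr[:, 1])

    @classmethod
    def ideal_arccos(cls, max_deg: float = 360.0, step_deg: float = 0.5) -> "LookupTable":
        """The exact arccos relation of a linear (rect) preparation pulse."""
        flips = np.arange(0.0, max_deg + step_deg / 2, step_deg)
        return build_lookup_from_table(flips, np.cos(np.deg2rad(flips)))


def _resample_dt(duration_s: float, n_min: int = 64) -> tuple[int, float]:
    n = max(n_min, int(np.ceil(duration_s / MAX_DT_S)))
    return n, duration_s / n


def make_rect(duration_s: float, nominal_flip_deg: float, dt_s: float | None = None) -> PulseWaveform:
    """Constant-amplitude (hard) pulse.

    The amplitude is set analytically: flip = 360 * f1 * duration, so a
    0.5 ms 90 deg pulse has f1 = 500 Hz.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if nominal_flip_deg < 0:
        raise ValueError("nominal_flip_deg must be >= 0")
    n, dt = _resample_dt(duration_s) if dt_s is None else (int(round(duration_s / dt_s)), dt_s)
    f1 = nominal_flip_deg / (360.0 * duration_s)
    samples = np.full(n, f1, dtype=complex)
    return PulseWaveform(samples, dt, nominal_flip_deg, "rect")


def _calibrate(samples: np.ndarray, dt: float, nominal_flip_deg: float) -> np.ndarray:
    """Scale a unit-peak envelope so the on-resonance flip equals nominal.

    Uses Bloch simulation and root finding on Mz(amplitude) = cos(nominal);
    valid for nominal flips in (0, 180) where the response is decreasing.
    """
    if nominal_flip_deg == 0:
        return np.zeros_like(samples)
    if not 0 < nominal_flip_deg <= 180.0:
        raise ValueError("calibration requires 0 <= nominal_flip_deg <= 180")
    target = np.cos(np.deg2rad(nominal_flip_deg))

    def f(peak_hz: float) -> float:
        return float(simulate_pulse_mz(samples * peak_hz, dt, [1.0], [0.0])[0, 0]) - target

    # Mz(amplitude) is oscillatory beyond 180 deg of rotation; scan upward
    # from zero and bracket the *first* crossing of the target.
    area = np.sum(np.abs(samples)) * dt
    guess = nominal_flip_deg / (360.0 * area)  # small-tip upper-bound estimate
    hi = 3.0 * guess
    for _ in range(8):  # frequency-modulated pulses need far more amplitude
        scan = np.linspace(0.0, hi, 241)[1:]
        mz = simulate_pulse_mz(samples, dt, scan, [0.0])[:, 0]
        below = np.nonzero(mz <= target)[0]
        if below.size:
            break
        hi *= 2.0
    else:
        raise RuntimeError("pulse calibration failed to bracket the target flip")
    i = below[0]
    lo = scan[i - 1] if i > 0 else scan[0] * 1e-3
    peak = brentq(f, lo, scan[i], xtol=1e-7 * guess)
    return samples * peak


def make_hs8(
    duration_s: float,
    tbp: float,
    nominal_flip_deg: float,
    truncation: float = 0.01,
    dt_s: float | None = None,
) -> PulseWaveform:
    """Order-8 stretched hyperbolic-secant (HS8) pulse.

    Amplitude ``A(tau) = sech(beta tau^8)`` on tau in [-1, 1], with beta set
    so the endpoint amplitude equals ``truncation`` times the peak. The
    frequency sweep is proportional to the running integral of
    ``sech^2(beta tau^8)`` and normalized so the total sweep equals
    ``tbp / duration`` Hz (a 5 ms, TBP-15 pulse sweeps +-1.5 kHz).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if tbp <= 0:
        raise ValueError("tbp must be positive")
    if not 0.0 < truncation < 1.0:
        raise ValueError("truncation must be in (0, 1)")
    n, dt = _resample_dt(duration_s) if dt_s is None else (int(round(duration_s / dt_s)), dt_s)
    bandwidth_hz = tbp / duration_s
    if bandwidth_hz / 2.0 >= 0.5 / dt:
        raise ValueError("frequency sweep exceeds the Nyquist limit of the sampling step")

    beta = np.arccosh(1.0 / truncation)
    tau = np.linspace(-1.0, 1.0, n, endpoint=False) + 1.0 / n  # midpoints
    amp = 1.0 / np.cosh(beta * tau**8)
    sweep = 1.0 / np.cosh(beta * tau**8) ** 2
    cum = np.cumsum(sweep)
    cum = cum - cum[-1] / 2.0  # symmetric sweep through zero at pulse center
    freq_hz = bandwidth_hz * cum / np.sum(sweep)  # total sweep = bandwidth
    phase = 2.0 * np.pi * np.cumsum(freq_hz) * dt
    envelope = amp * np.exp(1j * phase)
    samples = _calibrate(envelope, dt, nominal_flip_deg)
    return PulseWaveform(samples, dt, nominal_flip_deg, "hs8", tbp=tbp, meta={"truncation": truncation})


def make_sinc(
    duration_s: float,
    bandwidth_hz: float,
    nominal_flip_deg: float,
    n_lobes: int | None = None,
    apodization: str = "hanning",
    dt_s: float | None = None,
) -> PulseWaveform:
    """Apodized sinc pulse with main-lobe bandwidth ``bandwidth_hz``.

    The envelope is ``sinc(bandwidth * t)`` (zero crossings every
    1/bandwidth), Hanning-apodized by default; the lobe count follows from
    the duration unless given explicitly.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if bandwidth_hz <= 0:
        raise ValueError("bandwidth_hz must be positive")
    n, dt = _resample_dt(duration_s) if dt_s is None else (int(round(duration_s / dt_s)), dt_s)
    if 1.0 / bandwidth_hz < 2 * dt:
        raise ValueError("bandwidth not representable at the sampling step")
    if n_lobes is not None:
        half_span = n_lobes / bandwidth_hz
        if 2 * half_span > duration_s + 1e-12:
            raise ValueError("n_lobes does not fit in duration at this bandwidth")
    t = (np.arange(n) + 0.5) * dt - duration_s / 2.0
    env = np.sinc(bandwidth_hz * t)
    if apodization == "hanning":
        env = env * (0.5 + 0.5 * np.cos(2.0 * np.pi * t / duration_s))
    elif apodization not in (None, "none"):
        raise ValueError(f"unknown apodization {apodization!r}")
    samples = _calibrate(env.astype(complex), dt, nominal_flip_deg)
    tbp = bandwidth_hz * duration_s
    return PulseWaveform(samples, dt, nominal_flip_deg, "sinc", tbp=tbp)


def simulate_pulse_response(
    pulse: PulseWaveform,
    b1_scales,
    b0_offsets_hz=(0.0,),
) -> PulseResponse:
    """Bloch-simulate the residual Mz over B1-scale and off-resonance grids."""
    scales = np.atleast_1d(np.asarray(b1_scales, dtype=float))
    offsets = np.atleast_1d(np.asarray(b0_offsets_hz, dtype=float))
    if scales.size == 0 or offsets.size == 0:
        raise ValueError("grids must be non-empty")
    if np.any(scales < 0):
        raise ValueError("b1_scales must be >= 0")
    mz = simulate_pulse_mz(pulse.samples, pulse.dt, scales, offsets)
    return PulseResponse(scales, offsets, mz, pulse.nominal_flip_deg)


def pulse_energy(pulse: PulseWaveform) -> float:
    """Relative RF energy: integral of |amplitude|^2 dt (Hz^2 s)."""
    return float(np.sum(np.abs(pulse.samples) ** 2) * pulse.dt)


def build_lookup_from_table(nominal_flip_deg: np.ndarray, ratio: np.ndarray) -> LookupTable:
    """Identify the maximal invertible branch of a sampled Mz-vs-flip curve."""
    flips = np.asarray(nominal_flip_deg, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    if flips.size < 3 or np.any(np.diff(flips) <= 0):
        raise ValueError("nominal flip grid must be strictly increasing with >= 3 points")
    dec = np.diff(ratio) < 0
    end = int(np.argmin(dec)) if not dec.all() else dec.size
    if end == 0 and not dec[0]:
        raise ValueError("response is not decreasing at the origin; no invertible range")
    valid = (float(flips[0]), float(flips[end]))
    if valid[1] - valid[0] < 10.0:
        raise ValueError("no monotone interval of at least 10 degrees")
    return LookupTable(flips, ratio, valid)


def build_lookup(response: PulseResponse, offset_index: int = 0) -> LookupTable:
    """Lookup table from a response sampled on a monotone B1-scale grid at B0 = 0.

    The nominal-flip axis is ``b1_scale * nominal_flip_deg`` of the pulse —
    the flip a perfectly linear pulse would produce at that amplitude.
    """
    scales = response.b1_scales
    if np.any(np.diff(scales) <= 0):
        raise ValueError("b1_scales must be strictly increasing")
    if response.nominal_flip_deg <= 0:
        raise ValueError("response must come from a pulse with positive nominal flip")
    if abs(response.b0_offsets[offset_index]) > 1e-9:
        warnings.warn("lookup built from a nonzero off-resonance column")
    flips = scales * response.nominal_flip_deg
    return build_lookup_from_table(flips, response.mz[:, offset_index])
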