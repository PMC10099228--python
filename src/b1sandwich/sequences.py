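"""Timing and signal models of the three presaturation-TurboFLASH schemes.

Three schemes are modeled, named after their timing structure:

``satTFL``
    Reference image train (S0), long delay TD (~5 T1) for full recovery,
    preparation pulse, prepared train (S1), dead time TR_fill. One TR per
    segment/partition.
``shortTR_satTFL``
    Same per-image structure but with TD ~ 1 s and TR ~ 2 s; all S0
    segments are acquired first, then all S1 segments, at a per-image
    period of TR/2.
``sandwich``
    TD = 0: S0 train, preparation pulse and S1 train are played
    back-to-back within each TR (1 s), so S0 and S1 share the same T1
    contrast; two dummy TRs precede data acquisition.

The measured preparation flip is recovered downstream from the S0/S1 pair
as arccos(S1/S0) (with a lookup correction for nonlinear preparation
pulses); everything in this module produces the complex echo trains and the
exact scan durations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from .epg import EPGState, TissueParams, epg_relax_recover, flash_train
from .pulses import (
    LookupTable,
    PulseWaveform,
    make_hs8,
    make_rect,
    make_sinc,
    pulse_energy,
    simulate_pulse_response,
    build_lookup,
)

__all__ = [
    "PulseSpec",
    "ProtocolConfig",
    "SignalTrains",
    "PRESETS",
    "get_preset",
    "scan_duration",
    "encode_order",
    "simulate_acquisition",
    "average_power_ratio",
    "prep_lookup",
    "build_prep_pulse",
]


@dataclass
class PulseSpec:
    """Lightweight description of an RF pulse; realized lazily as a waveform."""

    family: str = "rect"  # rect | sinc | hs8
    duration_s: float = 0.5e-3
    tbp: float | None = None
    truncation: float = 0.01
    bandwidth_hz: float | None = None


@dataclass
class ProtocolConfig:
    """Full description of one B1+ mapping protocol.

    Times are seconds, angles degrees. ``tr_s`` is the period of one
    S0/S1 cycle (one TR), ``td_s`` the delay between the S0 train and the
    preparation pulse, ``tr_fill_s`` the dead time completing the TR
    (derived if omitted). 3D protocols acquire one partition per TR.
    """

    scheme: str  # satTFL | shortTR_satTFL | sandwich
    dims: int = 2
    n_lines_per_shot: int = 9  # N'
    n_segments: int = 1
    n_partitions: int = 1
    td_s: float = 0.0
    tr_s: float = 1.0
    tr_flash_s: float = 4.2e-3
    te_s: float = 1.78e-3
    alpha_nom_deg: float = 90.0
    beta_nom_deg: float = 9.0
    prep_pulse: PulseSpec = field(default_factory=PulseSpec)
    excitation_pulse: PulseSpec = field(default_factory=lambda: PulseSpec("rect", 1.0e-4))
    n_dummy_tr: int = 0
    centric: bool = True
    gated: bool = False
    rf_spoil_increment_deg: float = 50.0
    tr_fill_s: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.scheme not in ("satTFL", "shortTR_satTFL", "sandwich"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if self.n_lines_per_shot < 1 or self.n_segments < 1 or self.n_partitions < 1:
            raise ValueError("segmentation counts must be >= 1")
        if self.scheme == "sandwich" and self.td_s != 0.0:
            raise ValueError("sandwich scheme has td_s = 0 by definition")
        readout = 2 * self.n_lines_per_shot * self.tr_flash_s
        if self.tr_s < self.td_s + readout:
            raise ValueError("tr_s shorter than td_s plus both readout trains")
        if self.tr_fill_s is None:
            self.tr_fill_s = self.tr_s - self.td_s - readout - self.prep_pulse.duration_s

    @property
    def ratio(self) -> float:
        """Preparation-to-excitation flip ratio alpha:beta."""
        return self.alpha_nom_deg / self.beta_nom_deg

    @property
    def n_total_lines(self) -> int:
        return self.n_segments * self.n_lines_per_shot

    @property
    def n_shots(self) -> int:
        return self.n_segments * (self.n_partitions if self.dims == 3 else 1)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolConfig":
        d = dict(d)
        for key in ("prep_pulse", "excitation_pulse"):
            if isinstance(d.get(key), dict):
                d[key] = PulseSpec(**d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProtocolConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class SignalTrains:
    """Per-shot, per-echo complex amplitudes of the S0 and S1 trains."""

    s0_echoes: np.ndarray  # (n_shots, N')
    s1_echoes: np.ndarray
    segment_order: np.ndarray  # (n_segments, N') k-line index per echo
    b1_scale: float
    protocol: ProtocolConfig


# ---------------------------------------------------------------------------
# presets (paper protocols)
# ---------------------------------------------------------------------------

_RECT_PREP = PulseSpec("rect", 0.5e-3)
_HS8_PREP = PulseSpec("hs8", 5.0e-3, tbp=15.0)


def _preset_dict() -> dict[str, ProtocolConfig]:
    p: dict[str, ProtocolConfig] = {}
    p["2d-sattfl"] = ProtocolConfig(
        "satTFL", 2, 36, 1, 1, td_s=9.85, tr_s=20.0, alpha_nom_deg=90, beta_nom_deg=9,
        prep_pulse=_RECT_PREP, name="2d-sattfl",
    )
    p["2d-shorttr"] = ProtocolConfig(
        "shortTR_satTFL", 2, 9, 4, 1, td_s=0.96, tr_s=2.0, alpha_nom_deg=90, beta_nom_deg=9,
        prep_pulse=_RECT_PREP, name="2d-shorttr",
    )
    p["2d-sandwich"] = ProtocolConfig(
        "sandwich", 2, 9, 4, 1, td_s=0.0, tr_s=1.0, alpha_nom_deg=90, beta_nom_deg=9,
        prep_pulse=_RECT_PREP, n_dummy_tr=2, name="2d-sandwich",
    )
    p["2d-ref-sattfl"] = ProtocolConfig(
        "satTFL", 2, 9, 4, 1, td_s=9.96, tr_s=20.0, alpha_nom_deg=90, beta_nom_deg=9,
        prep_pulse=_RECT_PREP, name="2d-ref-sattfl",
    )
    p["2d-ptx-sandwich"] = ProtocolConfig(
        "sandwich", 2, 36, 1, 1, td_s=0.0, tr_s=1.0, alpha_nom_deg=130, beta_nom_deg=6.5,
        prep_pulse=_HS8_PREP, tr_flash_s=4.2e-3, name="2d-ptx-sandwich",
    )
    p["brain3d-sattfl"] = ProtocolConfig(
        "satTFL", 3, 36, 1, 18, td_s=9.9, tr_s=20.0, tr_flash_s=2.7e-3, te_s=0.87e-3,
        alpha_nom_deg=130, beta_nom_deg=6.5, prep_pulse=_HS8_PREP, name="brain3d-sattfl",
    )
    p["brain3d-shorttr"] = ProtocolConfig(
        "shortTR_satTFL", 3, 36, 1, 18, td_s=0.9, tr_s=2.0, tr_flash_s=2.7e-3, te_s=0.87e-3,
        alpha_nom_deg=130, beta_nom_deg=6.5, prep_pulse=_HS8_PREP, name="brain3d-shorttr",
    )
    p["brain3d-sandwich"] = ProtocolConfig(
        "sandwich", 3, 36, 1, 18, td_s=0.0, tr_s=1.0, tr_flash_s=2.7e-3, te_s=0.87e-3,
        alpha_nom_deg=130, beta_nom_deg=6.5, prep_pulse=_HS8_PREP, n_dummy_tr=2,
        name="brain3d-sandwich",
    )
    p["heart3d-sandwich"] = ProtocolConfig(
        "sandwich", 3, 36, 1, 24, td_s=0.0, tr_s=1.0, tr_flash_s=2.7e-3, te_s=0.87e-3,
        alpha_nom_deg=130, beta_nom_deg=6.5, prep_pulse=_HS8_PREP, n_dummy_tr=2,
        gated=True, name="heart3d-sandwich",
    )
    return p


PRESETS: dict[str, ProtocolConfig] = _preset_dict()


def get_preset(name: str) -> ProtocolConfig:
    try:
        return replace(PRESETS[name])
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


# ---------------------------------------------------------------------------
# timing
# ---------------------------------------------------------------------------

def scan_duration(protocol: ProtocolConfig) -> float:
    """Total acquisition time in seconds (or heartbeats when gated).

    One TR per segment (2D) or per partition (3D), plus dummy TRs. Gated
    protocols play one TR per heartbeat, so the count is returned directly.
    """
    n_tr = protocol.n_shots + protocol.n_dummy_tr
    if protocol.gated:
        return float(n_tr)
    return float(n_tr * protocol.tr_s)


def encode_order(n_total_lines: int, n_segments: int, centric: bool = True) -> np.ndarray:
    """Phase-encode line index per (segment, echo).

    Centric ordering ranks lines by distance from the k-space center (DC at
    index ``n//2``) and deals them round-robin across segments, so echo 1 of
    every shot carries the lowest-|k| line of that shot and the very center
    lands on echo 1 of segment 1. Linear ordering assigns contiguous blocks
    starting at the k-space edge.
    """
    if n_total_lines % n_segments:
        raise ValueError("n_total_lines must be divisible by n_segments")
    n = n_total_lines
    if centric:
        c = n // 2
        # center first, then outward, positive-k side before negative at ties
        keys = sorted(range(n), key=lambda k: (abs(k - c), k < c))
        order = np.asarray(keys)
    else:
        order = np.arange(n)
    n_prime = n // n_segments
    table = np.empty((n_segments, n_prime), dtype=int)
    for rank, line in enumerate(order):
        if centric:
            table[rank % n_segments, rank // n_segments] = line
        else:
            table[rank // n_prime, rank % n_prime] = line
    return table


# ---------------------------------------------------------------------------
# pulse realization
# ---------------------------------------------------------------------------

def build_prep_pulse(protocol: ProtocolConfig) -> PulseWaveform:
    """Materialize the protocol's preparation pulse at its nominal flip."""
    spec = protocol.prep_pulse
    flip = protocol.alpha_nom_deg
    if spec.family == "rect":
        return make_rect(spec.duration_s, flip)
    if spec.family == "hs8":
        return make_hs8(spec.duration_s, spec.tbp or 15.0, flip, spec.truncation)
    if spec.family == "sinc":
        bw = spec.bandwidth_hz or (spec.tbp or 15.0) / spec.duration_s
        return make_sinc(spec.duration_s, bw, flip)
    raise ValueError(f"unknown pulse family {spec.family!r}")


def prep_lookup(
    protocol: ProtocolConfig,
    max_scale: float = 2.5,
    n_scales: int = 501,
) -> LookupTable:
    """Bloch-derived lookup table for the protocol's preparation pulse.

    For a rect pulse this reduces to the exact arccos relation; for the HS8
    it captures the sub-linear response and its invertible range (~200 deg).
    """
    if protocol.alpha_nom_deg == 0:
        return LookupTable.ideal_arccos()
    if protocol.prep_pulse.family == "rect":
        # analytic: flip linear in B1, ratio = cos(flip)
        flips = np.linspace(0.0, max_scale * protocol.alpha_nom_deg, n_scales)
        from .pulses import build_lookup_from_table

        return build_lookup_from_table(flips, np.cos(np.deg2rad(flips)))
    pulse = build_prep_pulse(protocol)
    scales = np.linspace(0.0, max_scale, n_scales)
    resp = simulate_pulse_response(pulse, scales, [0.0])
    return build_lookup(resp)


def _prep_effective_flip(lookup: LookupTable, nominal_flip_deg: float) -> float:
    """Effective saturation flip (deg) whose cosine equals the prep's Mz."""
    ratio = float(np.clip(lookup.forward(nominal_flip_deg), -1.0, 1.0))
    return float(np.degrees(np.arccos(ratio)))


# ---------------------------------------------------------------------------
# acquisition simulation
# ---------------------------------------------------------------------------

def _train(state, protocol, tissue, flip_deg, truncation_tol=1e-3):
    return flash_train(
        state,
        protocol.n_lines_per_shot,
        flip_deg,
        protocol.tr_flash_s,
        tissue,
        rf_spoil_increment_deg=protocol.rf_spoil_increment_deg,
        te_s=protocol.te_s,
        truncation_tol=truncation_tol,
    )


def simulate_acquisition(
    protocol: ProtocolConfig,
    tissue: TissueParams,
    b1_scale: float = 1.0,
    prep_lookup_table: LookupTable | None = None,
    max_order: int | None = None,
    steady_state_tol: float = 1e-1,
    truncation_tol: float = 1e-3,
) -> SignalTrains:
    """EPG simulation of a full acquisition in temporal order.

    The true relative transmit amplitude ``b1_scale`` scales the nominal
    excitation flip linearly and drives the preparation pulse through its
    (possibly nonlinear) Bloch response, supplied as ``prep_lookup_table``
    (built from the protocol's prep pulse if omitted; exact arccos for a
    rect pulse).

    The simulation starts from thermal equilibrium and executes the
    protocol's dummy TRs before data retention. A warning is issued when the
    magnetization has visibly not reached a cyclic steady state by the end
    of the dummy TRs.
    """
    if b1_scale < 0:
        raise ValueError("b1_scale must be >= 0")
    lookup = prep_lookup_table if prep_lookup_table is not None else prep_lookup(protocol)
    alpha_eff = (
        0.0
        if protocol.alpha_nom_deg == 0
        else _prep_effective_flip(lookup, b1_scale * protocol.alpha_nom_deg)
    )
    beta = b1_scale * protocol.beta_nom_deg
    n_prime = protocol.n_lines_per_shot
    if max_order is None:
        # one TR holds up to 2 N' + 1 spoiler shifts (S0 train, prep, S1 train)
        max_order = 2 * n_prime + 4
    state = EPGState.equilibrium(max_order, tissue.pd)

    def prep(state):
        # Saturation operator: the preparation pulse is flanked by strong
        # crusher gradients, so transverse configurations neither survive it
        # nor refocus later; longitudinal orders are scaled by cos(alpha_eff).
        z = state.z * np.cos(np.deg2rad(alpha_eff))
        return EPGState(
            np.zeros_like(state.fp), np.zeros_like(state.fm), z, state.pd
        )

    s0_list: list[np.ndarray] = []
    s1_list: list[np.ndarray] = []
    dummy_first: list[complex] = []

    scheme = protocol.scheme
    n_shots = protocol.n_shots

    if scheme in ("satTFL", "sandwich"):
        fill = protocol.tr_fill_s
        for shot in range(protocol.n_dummy_tr + n_shots):
            s0, state = _train(state, protocol, tissue, beta, truncation_tol)
            if scheme == "satTFL":
                state = epg_relax_recover(state, protocol.td_s, tissue)
            state = prep(state)
            s1, state = _train(state, protocol, tissue, beta, truncation_tol)
            state = epg_relax_recover(state, fill, tissue)
            if shot < protocol.n_dummy_tr:
                dummy_first.append(s0[0])
            else:
                s0_list.append(s0)
                s1_list.append(s1)
    elif scheme == "shortTR_satTFL":
        # two passes at period TR/2: all S0 shots first, then all S1 shots
        half = protocol.tr_s / 2.0
        train_dur = n_prime * protocol.tr_flash_s
        fill0 = half - train_dur
        fill1 = half - train_dur - protocol.prep_pulse.duration_s
        for _ in range(n_shots):
            s0, state = _train(state, protocol, tissue, beta, truncation_tol)
            state = epg_relax_recover(state, fill0, tissue)
            s0_list.append(s0)
        for _ in range(n_shots):
            state = prep(state)
            s1, state = _train(state, protocol, tissue, beta, truncation_tol)
            state = epg_relax_recover(state, max(fill1, 0.0), tissue)
            s1_list.append(s1)
    else:  # pragma: no cover - guarded by ProtocolConfig
        raise ValueError(scheme)

    s0_arr = np.asarray(s0_list)
    s1_arr = np.asarray(s1_list)
    if protocol.n_dummy_tr and dummy_first:
        ref = np.abs(s0_arr[0, 0])
        if ref > 0 and abs(dummy_first[-1] - s0_arr[0, 0]) / ref > steady_state_tol:
            warnings.warn(
                "magnetization not in cyclic steady state after the configured dummy TRs",
                stacklevel=2,
            )
    order = encode_order(protocol.n_total_lines, protocol.n_segments, protocol.centric)
    return SignalTrains(s0_arr, s1_arr, order, b1_scale, protocol)


# ---------------------------------------------------------------------------
# RF energy bookkeeping
# ---------------------------------------------------------------------------

def _protocol_energy(protocol: ProtocolConfig) -> float:
    """Total RF energy of one acquisition (prep + excitation, incl. dummies)."""
    spec = protocol.excitation_pulse
    exc = make_rect(spec.duration_s, protocol.beta_nom_deg) if spec.family == "rect" else None
    if exc is None:
        bw = spec.bandwidth_hz or 4.0 / spec.duration_s
        exc = make_sinc(spec.duration_s, bw, protocol.beta_nom_deg)
    e_exc = pulse_energy(exc)
    e_prep = pulse_energy(build_prep_pulse(protocol)) if protocol.alpha_nom_deg > 0 else 0.0
    n_tr = protocol.n_shots + protocol.n_dummy_tr
    n_exc = n_tr * 2 * protocol.n_lines_per_shot
    return n_tr * e_prep + n_exc * e_exc


def average_power_ratio(protocol_a: ProtocolConfig, protocol_b: ProtocolConfig) -> float:
    """Ratio of time-averaged RF power of protocol A over protocol B."""
    rr_s = 1.0  # gated TRs modeled at the default 1 s RR interval
    dur_a = scan_duration(protocol_a) * (rr_s if protocol_a.gated else 1.0)
    dur_b = scan_duration(protocol_b) * (rr_s if protocol_b.gated else 1.0)
    if dur_a <= 0 or dur_b <= 0:
        raise ValueError("zero-duration protocol")
    return (_protocol_energy(protocol_a) / dur_a) / (_protocol_energy(protocol_b) / dur_b)
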