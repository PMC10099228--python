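# Methods

## Physical model

All sequence signals come from an extended-phase-graph (EPG) simulation of
RF-spoiled FLASH readouts. The state holds transverse configuration orders
F+(k), F-(k) and longitudinal orders Z(k); an RF pulse mixes the three
components order-by-order, free evolution scales F by exp(-t/T2) and Z by
exp(-t/T1) with recovery of Z(0) toward the proton density, and each
per-line spoiler gradient shifts the transverse orders by one. Echoes are
sampled at the excitation instant, demodulated by the quadratic RF-spoiling
transmit phase (default increment 50°, vendor-typical; exposed as a
parameter), and decayed to TE by exp(-TE/T2). Relaxation during RF pulses is
neglected (pulse durations ≤ 5 ms are far below the T1/T2 of interest).

The engine is cross-validated two ways in the test suite: against an
isochromat ensemble (512 spins acquiring one full dephasing cycle per TR),
which reproduces the EPG train to better than 1e-3 over 72 echoes, and
against the closed-form perfectly-spoiled recursion
`Mz_{k+1} = (Mz_k cos β) E1 + (1 - E1)`, which the EPG train matches to 1e-4
in the T2 → 0 limit.

### Scheme timing

One TR holds one S0/S1 pair of one k-space segment (2D) or one partition
(3D, fully sampled in the partition direction, one partition per TR):

* **satTFL** — S0 train, delay TD (≈ 5 T1), preparation pulse, S1 train,
  dead time TR_fill completing the TR.
* **short-TR satTFL** — two passes at period TR/2: all S0 segments first,
  then (prep + S1 segment) × n. With TR = 2 s and a 37.8 ms train this
  reproduces the stated TD ≈ 0.96 s between consecutive images.
* **sandwich** — S0 train, preparation pulse, S1 train back-to-back, then
  TR_fill (0.92 s at TR = 1 s); two dummy TRs precede data retention so the
  magnetization approaches its cyclic steady state.

Simulations start from thermal equilibrium (a one-off scanner acquisition),
execute the dummy TRs, and retain every shot. Scan durations are exact TR
counts; gated protocols count heartbeats (RR fixed at 1 s for power
bookkeeping).

### Preparation pulse operator

The preparation pulse is flanked by strong crusher gradients on the scanner.
Modeling it instead as a plain EPG rotation at a fixed phase lets
configuration states stored during the S0 train refocus coherently into the
S1 train — a 1024-isochromat full-sequence simulation confirms the effect
(S1 k-center up to 3× the ideal-spoiling value), and it would destroy the
sandwich scheme's accuracy in a way that contradicts its demonstrated
performance. The prep is therefore applied as a saturation operator on the
configuration basis: all transverse orders are zeroed and every Z order is
scaled by cos(α_eff), where α_eff is the effective saturation flip from the
pulse's Bloch response at the voxel's transmit amplitude. For a rect pulse
α_eff is linear in B1; for the HS8 it comes from the lookup table.

### Measured flip extraction

Simulated "measured flip" values follow the reconstruction chain the scanner
uses: the per-echo signals of one image are mapped to their k-space lines by
the centric segmented encode order, weighted by the Hanning recon window,
and summed — the reconstruction of a point-like object. This folds
relaxation during the readout train into the measurement; it is what makes
the conventional scheme T1-sensitive at high flip angles (spread ≈ 6° at
120° across T1 0.5–3 s; ≈ 13° for the short-TR variant) while the sandwich
scheme, whose S0 and S1 share one T1 contrast, stays below 2°. The bare
k-center echo is available as `method="kcenter"`; it is exact in the
fully-relaxed single-line limit and is used for those identity checks.

The sandwich scheme departs from the arccos relation at large flip angles
(bias ≈ -5° at 120°, growing beyond; the measured-vs-nominal curve flattens
near 160°, which defines its dynamic range). Within 40–120° the departure is
small and the scheme tracks the conventional one; a sequence-level lookup
could correct the residual curvature but is deliberately not applied, so the
reported curves show the raw behavior.

## Pulses

* **rect** — constant amplitude, flip = 360·f1·T exactly; amplitude set
  analytically.
* **HS8** — amplitude sech(β τ⁸) on τ ∈ [-1, 1] with β = arccosh(1/trunc)
  (truncation 1% of peak by default); frequency modulation proportional to
  the running integral of sech²(β τ⁸), normalized so the total sweep is
  TBP/duration (±1.5 kHz for 5 ms, TBP 15). Amplitude is calibrated by root
  finding on the Bloch-simulated on-resonance Mz, bracketing the *first*
  crossing (the response is oscillatory at higher amplitude). Operated below
  the adiabatic limit the in-band response still ripples with off-resonance
  (~0.2 in Mz over ±1 kHz, verified against an independent ODE integration),
  but far less than it changes over a 20% transmit variation — the ordering
  that matters for B0 robustness.
* **sinc** — envelope sinc(B·t) (zero crossings every 1/B), Hanning-apodized,
  Bloch-calibrated. The HS8-vs-sinc comparison uses the matched-bandwidth
  convention of ±3 kHz: the HS8 then needs ~18% of the sinc's peak amplitude
  at comparable RF energy (ratio ≈ 0.8; the exact energy ratio depends on the
  sinc apodization and lobe convention, which has no single standard).

The **lookup table** samples the prep pulse's Mz over a monotone B1-scale
grid (step 0.005 scale units), identifies the maximal strictly-decreasing
branch from 0° (rect: 180°; HS8: ~230° nominal), and inverts by monotone
piecewise-linear interpolation with out-of-range ratios clamped toward the
lower flip.

## Noise model

Monte-Carlo analysis adds i.i.d. complex Gaussian noise to every echo sample
(one k-space line). The default noise SD is anchored so the conventional
satTFL S0 k-center line has SNR 50 at T1 = 2 s and β = 9° (≈ 0.003 in units
of the equilibrium magnetization); the absolute level only scales the SD
maps, so conclusions are stated as orderings (sandwich SD > satTFL SD at
matched noise, SD growing with the α:β ratio). Each grid point draws from a
generator seeded by (seed, i, j), so grids are reproducible under any
evaluation order.

## Synthetic phantoms and reconstruction

Digital phantoms supply proton density, T1/T2 and a smooth center-brightened
complex transmit field (magnitude ≈ 0.45–1.2, emulating a CP-mode head coil
at 7 T; an 8-channel variant places Gaussian channel fields around the
periphery). The brain-like phantom includes a long-T1 (4 s) CSF-like
compartment. Per-voxel echo trains are cached over (T1, T2, |B1|) quantized
to 0.01, each k-line is the 2D spectrum of its echo's signal image, and the
reconstruction applies the Hanning window over the acquired extent,
zero-fills to 64×64 (partial Fourier, when enabled, is zero-filled — no
homodyne), and inverse-FFTs. Masks threshold |S0| at 10% of its 99th
percentile and erode by one voxel.

These phantoms emulate the T1/B1 structure that drives the mapping errors;
they do not model chemical shift, flow, motion, B0-induced distortions, or
realistic coil sensitivities (the recon assumes a single uniform receiver).
Passing phantom tests therefore validates the signal model and recon chain,
not in-vivo robustness. Map accuracy near object boundaries is limited by
Gibbs ringing interacting with the spatially varying flip (interior median
error < 1° for an ideal acquisition; a few degrees within ~4 voxels of the
rim), which is why voxel-wise comparisons erode the mask.

The point-spread-function metric assigns the train's modulation to the
phase-encode axis via the encode order, applies the Hanning window,
zero-pads 128× and reports the FWHM of the transform modulus in native
pixels (flat-train baseline 1.95 px; scheme values stay within a few percent
of it, i.e. intervoxel blurring is low).

## Default parameters

| parameter | default | note |
|---|---|---|
| T1 grid | 0.5–3.0 s, step 0.25 | range of interest at 7 T |
| T2 | 50 ms | train decay scale; not critical to the ratio |
| RF-spoil increment | 50° | exposed on `ProtocolConfig` |
| EPG max order | 2 N′ + 4 | one TR holds ≤ 2 N′ + 1 spoiler shifts |
| Bloch step | ≤ 5 µs | < 0.1° rotation error at 3 kHz offset |
| CoV α range | 40–120°, step 5° | the schemes' common linear range |
| monotonicity tol | 0.05 deg/deg | dynamic-range slope threshold |
| mask threshold | 10% of p99(|S0|), erode 1 | intensity mask |
| MC repeats / noise SD | 1000 / SNR-50 anchor | reduced repeats in unit tests |

Problem sizes in the shipped analyses: forward curves use 2° flip spacing
(91 points), T1 spreads an 11-point T1 grid, phantom demonstrations 50×36 or
48×36 matrices zero-padded to 64×64, and Monte-Carlo unit checks 200–1000
repeats. All headline quantities recomputed by `scripts/acceptance.py` are
deterministic.

## Known limitations

* The EPG prep operator discards coherence pathways through the preparation
  pulse entirely; sequences with weak prep crushers would behave worse than
  simulated.
* 2D excitation slice profiles are not resolved (nonselective excitation is
  assumed; maps are interpreted at slice center).
* Off-resonance during the readout is not modeled; B0 sensitivity enters
  only through the preparation pulse's response.
* The sinc reference pulse convention (apodization, lobe count) is not
  standardized; peak and energy comparisons to the HS8 shift by tens of
  percent across reasonable conventions.
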