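"""Synthetic RF pulse-sequence renderer.

Generates ground-truth pulse trains — shaped complex envelopes placed on a
timeline with per-pulse frequency offsets and phases — and renders them into
an :class:`~pulsescope.iq_io.IQRecording` with the impairments a cheap SDR
dongle adds when eavesdropping on a scanner: a residual carrier offset
(scanner Larmor frequency vs. SDR demodulation frequency), additive complex
Gaussian noise, and limited dynamic range through 8-bit quantisation.

Flip angles are represented through envelope *area* (small-tip-angle
proportionality, angle ∝ ∫B1 dt): a 180° pulse of a given shape carries twice
the area of a 90° pulse of the same shape.  The packaged fixtures encode five
clinical sequences — a 7-echo 5-slice spin echo, a TurboFLASH B1-mapping
scan with a preconditioning pulse, a STIR + water-excitation spin-echo EPI,
and three 3D turbo-spin-echo (SPACE) variants — with their characteristic
timings as ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
import numpy as np

from .errors import ClippingError, FixtureLookupError, ResolutionError
from .iq_io import IQRecording

__all__ = [
    "PulseShapeSpec",
    "PulseEventSpec",
    "SequenceScript",
    "RenderConfig",
    "make_shape",
    "shape_area",
    "render",
    "fixture",
    "FIXTURE_NAMES",
    "script_to_json",
    "script_from_json",
]

SHAPE_KINDS = ("rect", "sinc", "hypsec", "binomial121")
ROLES = (
    "excitation",
    "refocusing",
    "inversion",
    "preconditioning",
    "restoration",
    "readout",
    "water_excitation",
)

#: Shape parameters used when none are given (also the classifier templates).
DEFAULT_SHAPE_PARAMS = {
    "rect": {},
    "sinc": {"n_lobes": 3, "apodization": "hann"},
    "hypsec": {"mu": 4.9, "truncation_frac": 0.1},
    "binomial121": {"sub_duration_s": 4e-4, "spacing_s": 2.38e-3},
}


@dataclass
class PulseShapeSpec:
    """One RF envelope shape.

    ``kind`` selects the family; ``params`` the family-specific knobs:

    - ``sinc``: ``n_lobes`` (zero-crossing pairs per side), ``apodization``
      (``none`` or ``hann``);
    - ``hypsec``: ``beta_rad_per_s`` (sweep rate, derived from
      ``truncation_frac`` when absent), ``mu`` (dimensionless phase factor),
      ``truncation_frac`` (envelope value at the edges, fraction of peak);
    - ``binomial121``: ``sub_duration_s`` and centre-to-centre ``spacing_s``
      of the three 1:2:1-weighted rectangular sub-pulses.
    """

    kind: str
    duration_s: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in SHAPE_KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}; choose from {SHAPE_KINDS}")
        merged = dict(DEFAULT_SHAPE_PARAMS[self.kind])
        merged.update(self.params)
        self.params = merged
        if self.kind == "binomial121":
            if not self.params["spacing_s"] > self.params["sub_duration_s"]:
                raise ValueError("binomial121 spacing_s must exceed sub_duration_s")
            # support must hold all three sub-pulses
            need = 2 * self.params["spacing_s"] + self.params["sub_duration_s"]
            if self.duration_s < need:
                self.duration_s = need
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if self.kind == "hypsec":
            tf = self.params["truncation_frac"]
            if not 0 < tf < 0.5:
                raise ValueError("hypsec truncation_frac must lie in (0, 0.5)")


@dataclass
class PulseEventSpec:
    """A shaped pulse placed on the timeline.

    ``onset_s`` is the start of the envelope support; symmetric shapes peak at
    ``onset_s + shape.duration_s / 2``.  ``freq_offset_hz`` is the pulse's
    transmit offset relative to the scanner centre (slice-select offsets),
    ``phase_rad`` its RF phase.
    """

    onset_s: float
    shape: PulseShapeSpec
    peak_amplitude: float = 1.0
    freq_offset_hz: float = 0.0
    phase_rad: float = 0.0
    role: str | None = None
    slice_index: int | None = None

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")
        if not self.peak_amplitude > 0:
            raise ValueError("peak_amplitude must be positive")
        if self.role is not None and self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.shape.duration_s

    @property
    def nominal_peak_s(self) -> float:
        """Ground-truth peak time (centre of the symmetric envelope)."""
        return self.onset_s + self.shape.duration_s / 2


@dataclass
class SequenceScript:
    """Ordered pulse events plus nominal sequence-level timings.

    ``expected_timings`` carries the nominal quantities the sequence was built
    with (slice TR, echo spacing, ...) in seconds, and serves as the ground
    truth for decoder round-trip checks.
    """

    name: str
    events: list
    total_duration_s: float
    expected_timings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.onset_s)
        last_end = max((e.end_s for e in self.events), default=0.0)
        if self.total_duration_s < last_end:
            raise ValueError("total_duration_s must cover the last event")

    def nominal_peak_times(self) -> np.ndarray:
        return np.array([e.nominal_peak_s for e in self.events])


@dataclass
class RenderConfig:
    """Receiver-chain impairments applied when rendering.

    Defaults emulate the capture conditions of a NESDR-class dongle feeding a
    192 kHz stereo WAV: a 1.2 kHz residual carrier offset, additive complex
    Gaussian noise at 1e-3 full scale per component, and 8-bit quantisation.
    ``gain`` scales the summed signal (noise included) before quantisation.
    """

    sample_rate_hz: float = 192_000.0
    carrier_offset_hz: float = 1_200.0
    noise_sigma: float = 1e-3
    quantization_bits: int | None = 8
    gain: float = 0.9
    seed: int = 0
    center_frequency_hz: float = 63_640_000.0

    def __post_init__(self) -> None:
        if self.quantization_bits not in (None, 8, 12, 16):
            raise ValueError("quantization_bits must be one of None, 8, 12, 16")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")


# ---------------------------------------------------------------------------
# Shapes
# ---------------------------------------------------------------------------

def make_shape(spec: PulseShapeSpec, sample_rate_hz: float) -> np.ndarray:
    """Sample one unit-peak complex envelope.

    Returns ``round(duration_s * fs)`` complex samples centred on the shape's
    symmetry axis.  Peak modulus is 1 at the centre for every kind (for
    ``binomial121`` the middle sub-pulse is the unit peak; the outer two have
    amplitude 1/2).
    """
    n = int(round(spec.duration_s * sample_rate_hz))
    if n < 2:
        raise ResolutionError(
            f"{spec.kind} of {spec.duration_s * 1e3:.4f} ms spans {n} sample(s) "
            f"at {sample_rate_hz:g} Hz; need at least 2"
        )
    t = (np.arange(n) - (n - 1) / 2) / sample_rate_hz

    if spec.kind == "rect":
        return np.ones(n, dtype=np.complex128)

    if spec.kind == "sinc":
        n_lobes = int(spec.params["n_lobes"])
        env = np.sinc(2.0 * n_lobes * t / spec.duration_s)
        if spec.params.get("apodization", "none") == "hann":
            env = env * np.hanning(n)
        return env.astype(np.complex128)

    if spec.kind == "hypsec":
        tf = spec.params["truncation_frac"]
        beta = spec.params.get("beta_rad_per_s")
        if beta is None:
            # edge value sech(beta*T/2) = truncation_frac
            beta = math.acosh(1.0 / tf) / (spec.duration_s / 2)
        mu = spec.params["mu"]
        sech = 1.0 / np.cosh(beta * t)
        return sech * np.exp(1j * mu * np.log(sech))

    # binomial121: three rects, amplitude 1/2, 1, 1/2, centres spacing_s apart
    sub_n = int(round(spec.params["sub_duration_s"] * sample_rate_hz))
    if sub_n < 2:
        raise ResolutionError("binomial121 sub-pulse shorter than 2 samples")
    env = np.zeros(n, dtype=np.complex128)
    centre = (n - 1) / 2
    spacing_n = spec.params["spacing_s"] * sample_rate_hz
    for k, amp in zip((-1, 0, 1), (0.5, 1.0, 0.5)):
        c = centre + k * spacing_n
        i0 = int(round(c - (sub_n - 1) / 2))
        env[i0 : i0 + sub_n] = amp
    return env


def shape_area(spec: PulseShapeSpec, sample_rate_hz: float) -> float:
    """Envelope-modulus area ∫|env| dt of a unit-peak shape, in seconds."""
    env = make_shape(spec, sample_rate_hz)
    return float(np.trapezoid(np.abs(env))) / sample_rate_hz


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render(script: SequenceScript, config: RenderConfig | None = None) -> IQRecording:
    """Render a script into a complex baseband recording.

    The noiseless signal is the superposition over events of
    ``amp * envelope(t - onset) * exp(i*(2π (f_offset + carrier_offset) t + φ))``;
    complex Gaussian noise (``noise_sigma`` per component, seeded) is added,
    the whole is scaled by ``gain`` and optionally quantised.  Deterministic
    for a fixed (script, config) pair.
    """
    config = config or RenderConfig()
    fs = config.sample_rate_hz
    n_total = int(round(script.total_duration_s * fs))
    sig = np.zeros(n_total, dtype=np.complex128)

    peak = 0.0
    for ev in script.events:
        env = make_shape(ev.shape, fs) * ev.peak_amplitude
        i0 = int(round(ev.onset_s * fs))
        if i0 + env.size > n_total:
            raise ValueError(f"event at {ev.onset_s:.6f} s extends past total_duration_s")
        t = (i0 + np.arange(env.size)) / fs
        f = ev.freq_offset_hz + config.carrier_offset_hz
        sig[i0 : i0 + env.size] += env * np.exp(1j * (2 * np.pi * f * t + ev.phase_rad))

    peak = float(np.max(np.abs(sig))) if n_total else 0.0
    if peak * config.gain > 1.0 + 1e-12:
        worst = max(script.events, key=lambda e: e.peak_amplitude)
        raise ClippingError(
            f"gain {config.gain} drives peak modulus to {peak * config.gain:.3f} > 1; "
            f"largest event at onset {worst.onset_s:.6f} s (amplitude {worst.peak_amplitude})"
        )

    rng = np.random.default_rng(config.seed)
    if config.noise_sigma > 0:
        sig = sig + config.noise_sigma * (
            rng.standard_normal(n_total) + 1j * rng.standard_normal(n_total)
        )
    sig *= config.gain

    if config.quantization_bits is not None:
        full = 2 ** (config.quantization_bits - 1)
        re = np.clip(np.round(sig.real * full), -full, full - 1) / full
        im = np.clip(np.round(sig.imag * full), -full, full - 1) / full
        sig = re + 1j * im

    return IQRecording(
        samples=sig,
        sample_rate_hz=fs,
        center_frequency_hz=config.center_frequency_hz,
        source_bit_depth=config.quantization_bits,
        label=script.name,
    )


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

#: Slice-select frequency offsets (Hz) for the 5-slice 2D fixtures, by
#: spatial position, and the even–odd interleaved temporal acquisition order
#: (spatial indices, 0-based: all even positions first, then the odd ones).
SLICE_OFFSETS_HZ = (-2000.0, -1000.0, 0.0, 1000.0, 2000.0)
INTERLEAVED_ORDER = (0, 2, 4, 1, 3)

_SINC = lambda dur: PulseShapeSpec("sinc", dur, {"n_lobes": 3, "apodization": "hann"})


def _semc() -> tuple[SequenceScript, RenderConfig]:
    """5-slice 7-echo spin echo: 90° then 7×180°, slice TR 80 ms, spacing 9.9 ms."""
    slice_tr = 0.080
    first_gap = 0.00495          # excitation -> first refocusing peak
    echo_spacing = 0.0099
    dur = 2.56e-3
    lead = 0.005
    events = []
    for g, spatial in enumerate(INTERLEAVED_ORDER):
        t0 = lead + g * slice_tr
        f = SLICE_OFFSETS_HZ[spatial]
        events.append(PulseEventSpec(t0 - dur / 2, _SINC(dur), 0.5, f,
                                     role="excitation", slice_index=spatial))
        for k in range(7):
            tp = t0 + first_gap + k * echo_spacing
            events.append(PulseEventSpec(tp - dur / 2, _SINC(dur), 1.0, f,
                                         role="refocusing", slice_index=spatial))
    script = SequenceScript(
        "semc", events, total_duration_s=5 * slice_tr,
        expected_timings={
            "slice_tr_s": slice_tr,
            "echo_spacing_s": echo_spacing,
            "echo_time_s": 2 * first_gap,
        },
    )
    return script, RenderConfig()


def _b1map() -> tuple[SequenceScript, RenderConfig]:
    """Two 64-pulse TurboFLASH trains 247 ms apart, in-train spacing 3.04 ms;
    the second train is preceded by a sinc preconditioning pulse whose area is
    8× the 10° readout pulse area (hence an 80° flip)."""
    fs = 192_000.0
    slice_tr = 0.247
    train_tr = 0.00304
    n_read = 64
    read_dur = 5e-4
    read_amp = 0.12
    read_area = read_amp * read_dur          # rect: amp × duration
    precond_shape = _SINC(2.56e-3)
    precond_amp = 8.0 * read_area / shape_area(precond_shape, fs)
    t_train1 = 0.010
    t_train2 = t_train1 + slice_tr
    t_precond = t_train2 - 0.020

    events = []
    for t_start in (t_train1, t_train2):
        for k in range(n_read):
            tp = t_start + k * train_tr
            events.append(PulseEventSpec(tp - read_dur / 2,
                                         PulseShapeSpec("rect", read_dur),
                                         read_amp, 0.0, role="readout"))
    events.append(PulseEventSpec(t_precond - precond_shape.duration_s / 2,
                                 precond_shape, precond_amp, 0.0,
                                 role="preconditioning"))
    script = SequenceScript(
        "b1map", events, total_duration_s=0.46,
        expected_timings={
            "slice_tr_s": slice_tr,
            "readout_spacing_s": train_tr,
            "preconditioning_area_ratio": 8.0,
            "readout_flip_deg": 10.0,
        },
    )
    return script, RenderConfig()


def _se_epi() -> tuple[SequenceScript, RenderConfig]:
    """STIR + water-excitation diffusion EPI: per slice a 10 ms adiabatic
    inversion, a binomial 1-2-1 composite 156 ms later, and a refocusing pulse
    24 ms after the composite centre; slice TR 356 ms, 5 slices.

    The timings are the sequence's measured values (inversion delay 156 ms,
    half-echo 24 ms, slice TR 356 ms) rather than the console-prescribed
    160/360 ms, so a decode round trip reproduces the measured numbers.
    """
    slice_tr = 0.356
    ti = 0.156
    half_echo = 0.024
    inv_shape = PulseShapeSpec("hypsec", 0.010, {"mu": 4.9, "truncation_frac": 0.1})
    wexc_shape = PulseShapeSpec("binomial121", 0.0,
                                {"sub_duration_s": 4e-4, "spacing_s": 2.38e-3})
    # binomial areas: (0.5 + 1 + 0.5)·amp·sub_dur; amp 0.5 -> 90°-equivalent 4e-4·amp·2
    wexc_amp = 0.5
    a90 = 2.0 * wexc_amp * 4e-4
    refoc_dur = 1.6e-3
    refoc_amp = 2.0 * a90 / refoc_dur        # rect area = 2 × 90° area
    lead = 0.010
    events = []
    for g, spatial in enumerate(INTERLEAVED_ORDER):
        t_inv = lead + g * slice_tr
        f = SLICE_OFFSETS_HZ[spatial]
        events.append(PulseEventSpec(t_inv - inv_shape.duration_s / 2, inv_shape,
                                     1.0, f, role="inversion", slice_index=spatial))
        t_wexc = t_inv + ti
        events.append(PulseEventSpec(t_wexc - wexc_shape.duration_s / 2, wexc_shape,
                                     wexc_amp, f, role="water_excitation",
                                     slice_index=spatial))
        t_ref = t_wexc + half_echo
        events.append(PulseEventSpec(t_ref - refoc_dur / 2,
                                     PulseShapeSpec("rect", refoc_dur),
                                     refoc_amp, f, role="refocusing",
                                     slice_index=spatial))
    script = SequenceScript(
        "se_epi", events, total_duration_s=1.8,
        expected_timings={
            "slice_tr_s": slice_tr,
            "inversion_delay_s": ti,
            "half_echo_s": half_echo,
            "echo_time_s": 2 * half_echo,
            "composite_spacing_s": 2.38e-3,
            "inversion_duration_s": inv_shape.duration_s,
        },
    )
    return script, RenderConfig()


def _space(variant: str) -> tuple[SequenceScript, RenderConfig]:
    """3D SPACE stand-in: sinc excitation then 40 rectangular refocusing
    pulses at 5 ms spacing (the echo-train length and spacing are desk-scale
    stand-ins, not vendor values).  Variants add a restoration pulse after the
    train or a smooth variable-flip-angle schedule (min 25% of max)."""
    fs = 192_000.0
    n_refoc = 40
    spacing = 0.005
    exc_shape = _SINC(2.56e-3)
    exc_amp = 0.8
    a90 = exc_amp * shape_area(exc_shape, fs)
    refoc_dur = 1.0e-3
    refoc_area = (120.0 / 90.0) * a90        # constant 120° train
    refoc_amp = refoc_area / refoc_dur

    if variant == "varfa":
        i = np.arange(n_refoc)
        sched = np.where(
            i < 10,
            0.625 + 0.375 * np.cos(np.pi * i / 9),          # 1.00 -> 0.25
            0.25 + 0.65 * ((i - 9) / (n_refoc - 10)) ** 2,  # 0.25 -> 0.90
        )
    else:
        sched = np.ones(n_refoc)

    lead = 0.005
    events = [PulseEventSpec(lead - exc_shape.duration_s / 2, exc_shape, exc_amp,
                             0.0, role="excitation")]
    for k in range(n_refoc):
        tp = lead + spacing / 2 + k * spacing
        events.append(PulseEventSpec(tp - refoc_dur / 2,
                                     PulseShapeSpec("rect", refoc_dur),
                                     refoc_amp * sched[k], 0.0, role="refocusing"))
    timings = {"echo_spacing_s": spacing, "echo_time_s": spacing}
    total = lead + spacing / 2 + n_refoc * spacing + 0.02
    if variant == "restore":
        t_rest = lead + spacing / 2 + (n_refoc - 1) * spacing + 2 * spacing
        rest_amp = a90 / refoc_dur
        events.append(PulseEventSpec(t_rest - refoc_dur / 2,
                                     PulseShapeSpec("rect", refoc_dur),
                                     rest_amp, 0.0, role="restoration"))
        total = t_rest + 0.02
    if variant == "varfa":
        timings["train_profile"] = sched.tolist()
    script = SequenceScript(f"space_{variant}", events, total_duration_s=total,
                            expected_timings=timings)
    cfg = RenderConfig(center_frequency_hz=123_600_000.0)
    return script, cfg


_FIXTURES = {
    "semc": _semc,
    "b1map": _b1map,
    "se_epi": _se_epi,
    "space_const": lambda: _space("const"),
    "space_restore": lambda: _space("restore"),
    "space_varfa": lambda: _space("varfa"),
}

FIXTURE_NAMES = tuple(_FIXTURES)


def fixture(name: str) -> tuple[SequenceScript, RenderConfig]:
    """Return the packaged ground-truth (script, render defaults) for ``name``."""
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; valid fixtures: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return builder()


# ---------------------------------------------------------------------------
# Script (de)serialisation
# ---------------------------------------------------------------------------

def script_to_json(script: SequenceScript) -> str:
    d = {
        "name": script.name,
        "total_duration_s": script.total_duration_s,
        "expected_timings": script.expected_timings,
        "events": [
            {
                "onset_s": e.onset_s,
                "shape": {"kind": e.shape.kind, "duration_s": e.shape.duration_s,
                          "params": e.shape.params},
                "peak_amplitude": e.peak_amplitude,
                "freq_offset_hz": e.freq_offset_hz,
                "phase_rad": e.phase_rad,
                "role": e.role,
                "slice_index": e.slice_index,
            }
            for e in script.events
        ],
    }
    return json.dumps(d, indent=2, sort_keys=True)


def script_from_json(text: str) -> SequenceScript:
    d = json.loads(text)
    for key in ("name", "events", "total_duration_s"):
        if key not in d:
            raise ValueError(f"sequence script JSON missing required key {key!r}")
    events = []
    for ed in d["events"]:
        sd = ed["shape"]
        events.append(PulseEventSpec(
            onset_s=float(ed["onset_s"]),
            shape=PulseShapeSpec(sd["kind"], float(sd["duration_s"]),
                                 dict(sd.get("params", {}))),
            peak_amplitude=float(ed.get("peak_amplitude", 1.0)),
            freq_offset_hz=float(ed.get("freq_offset_hz", 0.0)),
            phase_rad=float(ed.get("phase_rad", 0.0)),
            role=ed.get("role"),
            slice_index=ed.get("slice_index"),
        ))
    return SequenceScript(d["name"], events, float(d["total_duration_s"]),
                          dict(d.get("expected_timings", {})))
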