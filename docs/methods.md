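# Methods

This note records the models, conventions and parameter choices behind
`pulsescope`, in the spirit of a package's statistical/numerical appendix:
what is computed, under which assumptions, and where the design was
genuinely open.

## Signal model and units

A recording is a complex baseband stream in dimensionless full-scale units
(each component in [-1, 1)). The renderer produces

    s[n] = gain · ( Σ_k a_k e_k(t_n − t_k) exp(i(2π(f_k + Δf) t_n + φ_k)) + ν[n] )

with `e_k` a unit-peak envelope, `a_k` the pulse amplitude (full scale),
`f_k` the pulse's transmit offset in Hz (slice selection), `Δf` the residual
carrier offset in Hz, `φ_k` the RF phase in radians, and `ν` complex
Gaussian noise with `noise_sigma` per component. The sum is then quantised
to `quantization_bits` by rounding to `2^(bits−1)` levels per component.
Defaults (192 kHz sampling, Δf = 1.2 kHz, σ = 1e-3, 8 bits, gain 0.9,
seed 0) emulate an inexpensive RTL-based dongle feeding a 192 kHz stereo WAV
at high but realistic SNR, with every impairment active.

Flip angles are carried by envelope *area*: in the small-tip regime
α ∝ ∫B₁ dt, so a 180° pulse of a given shape has exactly twice the area of a
90° pulse of the same shape, and ratios of areas are ratios of angles. The
adiabatic inversion pulse is the one place this proportionality does not
hold physically (adiabatic passage is amplitude-insensitive above
threshold); its fixture amplitude is therefore a free choice (1.0, the
largest pulse in its record).

## Pulse shapes

- **rect** — constant 1.
- **sinc** — `sinc(2·n_lobes·t/T)`, optionally Hann-apodised. Zeros fall at
  `k·T/(2·n_lobes)`; the outermost pair coincides with the support edge, so
  `n_lobes = 3` shows 4 interior sign changes. Default `n_lobes 3`, Hann.
- **hypsec** — `sech(βt)·exp(iμ·ln sech(βt))`, the standard adiabatic
  full-passage pulse; its instantaneous frequency is `−μβ·tanh(βt)`. When
  `beta_rad_per_s` is not given, β is derived from `truncation_frac` (the
  envelope value at the support edges): β = arcsech(f)/(T/2). Defaults
  μ = 4.9 and truncation 0.1 — a modest truncation so the rendered support
  visually matches its nominal duration.
- **binomial121** — three rectangular sub-pulses with 1:2:1 amplitudes
  (middle = unit peak), centres `spacing_s` apart. Default sub-pulse
  duration 0.4 ms (not a published value; a plausible hard-pulse width) and
  spacing 2.38 ms (the fat–water π interval at 1.5 T).

## Packaged fixtures

The fixtures encode the *measured* timing structure of five clinical
sequences as ground truth, at desk scale:

| fixture | structure | key timings |
|---|---|---|
| `semc` | 5 slices × (90° sinc + 7×180° sinc) | slice TR 80 ms, echo spacing 9.9 ms, first echo at 4.95 ms |
| `b1map` | 2 TurboFLASH trains of 64 rect readouts; sinc preconditioning before train 2 | trains 247 ms apart, in-train 3.04 ms, preconditioning area = 8× readout (80° vs 10°) |
| `se_epi` | 5 slices × (hypsec inversion 10 ms + binomial 1-2-1 + rect refocusing) | inversion delay 156 ms, half-echo 24 ms, slice TR 356 ms |
| `space_const` | sinc excitation + 40 rect refocusing | echo spacing 5 ms |
| `space_restore` | as above + restoration pulse after the train | restoration 2 spacings after the last echo |
| `space_varfa` | as `space_const` with a smooth amplitude schedule | min 25% of max, decrease then quadratic ramp-up |

Choices where no published value exists, fixed once: the 2D multi-slice
fixtures use slice offsets −2…+2 kHz in 1 kHz steps, acquired in the order
(0, 2, 4, 1, 3) — all even spatial positions, then the odd ones — to realise
an even–odd interleave; the SPACE echo train is 40 pulses at 5 ms spacing (a
desk-scale stand-in, not a vendor echo-train length; real 3D acquisitions
run far longer); the variable-flip schedule is a generic smooth
decrease-then-ramp curve, not a claim about any vendor's pattern; readout
pulses are 0.5 ms rects at amplitude 0.12 so they sit comfortably above the
detection threshold set by the larger preconditioning pulse. The
`expected_timings` attached to each script are the construction parameters
and serve as round-trip oracles; they are not measured values baked into the
decoder.

## Decoder conventions and numerics

**Carrier offset.** The estimator takes the strongest burst (contiguous
envelope region above 25% of the global peak, or a user window), finds the
spectrum peak of the Hann-windowed segment with 8× zero padding and
parabolic interpolation of the log magnitude, then refines by a weighted
linear fit to the unwrapped phase of the *squared* derotated segment.
Squaring removes the π phase flips at negative envelope lobes; weighting by
squared magnitude suppresses the noisy phase near envelope zeros. The
parabolic stage alone is not reliable to ±5 Hz on millisecond bursts (bins
are hundreds of Hz); the phase-slope stage is. On records with several
slice offsets, "the" carrier offset is by convention the offset of the
strongest burst; per-pulse frequencies are relative to it, and all
slice-order conclusions depend only on frequency differences.

**Detection.** Noise floor = median(envelope)/0.6745 (Rayleigh-consistent,
immune to the pulses dominating the record); opening threshold
max(8·floor, 0.02·max); closing at half the threshold (hysteresis); gaps
below 0.1 ms merged (this re-joins the envelope nulls between sinc lobes);
events under 50 µs dropped. With a quantised record the off-pulse envelope
is mostly exactly zero, so the max-fraction term dominates.

**Peak time.** The centroid of (envelope − level) over the contiguous
region above level = half the event maximum. For any symmetric pulse this
is the symmetry axis — the plateau midpoint of a rect, the apex of a smooth
lobe — and because it averages over the whole top it is robust where a bare
argmax or a 3-point parabola is not: an 8-bit-quantised flat top carries
ripple of about one LSB, which sends the argmax wandering across the
plateau (~±0.4 ms on a 1 ms readout pulse). The centroid keeps every
fixture pulse within ±0.3 samples (±1.6 µs at 192 kHz) of its rendered
envelope centre. A 3-point parabola remains as fallback for sub-3-sample
tops. All sequence timings are differences of these peak times
(separation-of-maxima convention).

**Duration** is the threshold-crossing span. This matches what one reads
off a time-domain plot but under-reports the tails of sech/sinc envelopes;
with the default 10% hypsec truncation, the detected span of the 10 ms
inversion pulse is the full 10 ms because the envelope edge (10% of peak)
sits well above the 2% detection threshold.

**Composite grouping.** Runs of 2–5 consecutive events, each shorter than
1.5 ms, with end-to-start gaps under 5 ms, fuse into one composite whose
area is the member sum and whose peak is the largest member's peak (the "2"
of 1–2–1, so composite timing is peak-to-peak like everything else). The
duration and run-length gates are what keep a spin-echo pair (millisecond
envelopes 2.4 ms apart edge-to-edge) and a 64-pulse readout train (0.5 ms
pulses 2.5 ms apart) from being mistaken for composites: real composite
sub-pulses are sub-millisecond and come in small groups.

**Per-slice repetition time.** Gap-based grouping cannot separate these
sequences' inter-group gaps from their in-group intervals (for the EPI
fixture they differ by 13%). Instead the slice TR is found as the smallest
lag P under which the event pattern maps onto itself: every event with room
for a partner one lag later (t ≤ t_last − P) must find one within 0.2 ms, at
least two such events must exist, and the record must span at least 1.1
lags. Shorter internal periodicities (echo or readout spacings) never map
the *complete* structure — some eligible event (the first excitation, the
train tail, the preconditioning pulse) is left without a partner — so they
are rejected. The returned value is the median of the matched differences
(sub-sample precision). Single-repetition records (the SPACE fixtures)
correctly raise a structure error and report no slice TR.

**Roles.** Inferred from structure: regular runs of ≥ 8 pulses are trains —
readout when their median area is under half the leading pulse's (the
leader then becomes the preconditioning pulse if ≥ 2× the readout area),
refocusing otherwise; the first event of a periodic group with ≥ 100 ms to
the next event is an inversion; composites are water excitations; the first
remaining pulse per group is the excitation and later pulses with 1.5–2.5×
its area are refocusing pulses; a pulse trailing a refocusing train by
> 1.5 spacings is a restoration candidate. Run detection is global, not
per group, because the preconditioning pulse of a two-train B1 map falls in
the first train's period window while belonging to the second train.

**Echo timing.** Echo time = 2 × (excitation → first refocusing peak);
echo spacing = median refocusing-to-refocusing interval (they coincide for
CPMG-timed trains). Both are reported; a composite excitation contributes
its middle-sub-pulse peak.

**Slice frequencies.** One representative frequency per periodic group
(median of the group's per-pulse `f_center`); spatial index = ascending
rank; acquisition order = spatial indices in temporal order; the even–odd
flag is true when one parity class (0-based) is exhausted before the other
begins, in either order. Frequencies within 50 Hz of one another are
declared degenerate and the order undefined.

**Flip angles.** `deduced = reference × (target area / reference area)`,
exact by construction. Time-domain area is the primary estimator; it equals
the on-resonance spectral amplitude by the Fourier zero-frequency identity,
so it matches an amplitude ratio read in the frequency domain. The deduced
preconditioning angle comes out ~79.7° against the 8.0× construction ratio:
the detection threshold crops the apodised sinc's outer tails (~0.4% of its
area) while the rect readout loses essentially nothing. Reference pulse: the
median-area readout event.

**Shape classification.** The envelope on a window of twice the event
duration centred on the refined peak is correlated (normalised inner
product, 256-point grid) against rect/sinc/hypsec templates. Each
template's support duration is set by matching its full width at half
maximum to the observed one — the detected span is threshold-dependent (a
Hann-apodised sinc loses its tails), so duration-matched templates
misclassify cropped sincs as sech-like; width-matched templates do not.
Templates are centred on the centroid peak, not the raw argmax, for the
same flat-top reason as above. Label = argmax score, `unknown` below 0.9.
Composites with three rect sub-pulses whose areas fit 1:2:1 within 10% are
labelled `binomial121`.

## What the synthetic data does and does not show

The renderer reproduces the aspects of a real capture that the decoder's
logic depends on: shaped complex envelopes, per-slice offsets, a carrier
offset, noise, and coarse quantisation. It does **not** model: Bloch
dynamics or slice profiles (areas stand in for flip angles), gradient
activity, receiver filtering/decimation inside the SDR software, oscillator
drift (ppm-scale over long records), amplifier droop or nonlinearity, or
interference in an imperfectly shielded room. Passing round trips therefore
validate the decoding chain's correctness and its quoted precision (~0.07%
worst-case timing error at default impairments, against the ~1% the
measurement principle is credited with) — not robustness to every artefact
of a hospital installation. Real captures may need the `--swap-iq` flag
(the I/Q channel order of SDR WAV writers is not standardised), a manual
estimation window on sparse records, or custom detection thresholds.

## Degenerate inputs and tie-breaks

All-zero or all-noise records decode to an empty event list with a warning,
never an exception. A flat-top argmax tie is resolved by the centroid rule
(first maximal sample only seeds the region search). Events at the record
boundary fall back from centroid/parabolic refinement to the raw argmax.
Binomial sub-pulse grids are placed by rounding centre positions, so
sub-pulse spacings are exact to half a sample.

## Problem sizes

Each fixture renders 0.2–1.8 s of 192 kHz complex baseband (43k–346k
samples) and decodes in well under a second; the full acceptance run covers
all six fixtures. These sizes were chosen to exercise every code path with
comfortable statistical margin, not as a performance ceiling.
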