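"""Sequence-level quantities from detected pulse events.

Turns a list of measured pulses into the numbers an MR physicist reads off a
pulse-sequence diagram: per-slice repetition time, echo spacing and echo
time, inversion delay, per-slice frequencies and interleave order, flip-angle
ratios, pulse-shape labels and variable-flip-angle train profiles.

Timing works peak-to-peak (differences of refined envelope maxima).  The
per-slice repetition time is found as the smallest lag under which the event
pattern is shift-invariant: every event that has room for a partner one lag
later must find one within tolerance, and the record must span more than one
lag.  This periodicity criterion separates the whole-pattern repetition from
shorter internal periodicities (echo trains, readout trains), which never map
the complete structure onto itself.

Flip angles are compared through envelope areas: in the small-tip regime the
flip angle is proportional to ∫B1 dt, so the ratio of two pulse areas equals
the ratio of their flip angles (the time-domain area equals the on-resonance
spectral amplitude by the Fourier zero-frequency identity, so this matches an
amplitude ratio taken in the frequency domain).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .demodulation import BasebandSignal, estimate_carrier_offset, fine_demodulate
from .errors import ClassificationError, EstimationError, StructureError
from .iq_io import IQRecording
from .pulse_detection import DetectConfig, PulseEvent, detect_pulses, group_composites
from .rf_synth import DEFAULT_SHAPE_PARAMS, PulseShapeSpec, make_shape

__all__ = [
    "FlipAngleEstimate", "SequenceReport", "peak_intervals", "find_period",
    "split_groups", "estimate_slice_tr", "estimate_echo_timing", "infer_roles",
    "inversion_delay", "slice_frequency_analysis", "flip_angle_from_ratio",
    "classify_shape", "train_flip_profile", "decode", "report_to_dict",
    "report_to_json",
]

#: roles that act as "the excitation" for spin-echo timing purposes
_EXCITATION_ROLES = ("excitation", "water_excitation")


@dataclass
class FlipAngleEstimate:
    """Deduced flip angle from an area ratio against a reference pulse."""

    reference_angle_deg: float
    area_ratio: float
    deduced_angle_deg: float = field(init=False)

    def __post_init__(self) -> None:
        if self.reference_angle_deg <= 0 or self.area_ratio <= 0:
            raise ValueError("reference angle and area ratio must be positive")
        self.deduced_angle_deg = self.reference_angle_deg * self.area_ratio


@dataclass
class SequenceReport:
    """Derived sequence-level quantities; inapplicable fields stay None."""

    events: list
    peak_intervals_s: list | None = None
    slice_tr_s: float | None = None
    echo_spacing_s: float | None = None
    echo_time_s: float | None = None
    inversion_delay_s: float | None = None
    readout_spacing_s: float | None = None
    composite_spacing_s: float | None = None
    slice_frequencies_hz: list | None = None
    acquisition_order: list | None = None
    interleave_even_odd: bool | None = None
    flip_estimates: list = field(default_factory=list)
    train_profile: list | None = None
    applied_offset_hz: float | None = None
    warnings: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Timing
# ---------------------------------------------------------------------------

def peak_intervals(events: list[PulseEvent]) -> list[float]:
    """Successive differences of event peak times, in order."""
    if len(events) < 2:
        raise StructureError("need at least 2 events for peak intervals")
    t = np.array([e.t_peak_s for e in sorted(events, key=lambda e: e.t_peak_s)])
    return np.diff(t).tolist()


def find_period(events: list[PulseEvent], tol_s: float = 2e-4,
                min_cycles: float = 1.1) -> float:
    """Smallest lag under which the event pattern maps onto itself.

    Candidates are the clustered pairwise peak differences; a lag P is
    accepted when every event with ``t <= t_last - P`` has a partner at
    ``t + P`` within ``tol_s`` (at least two such events) and the record
    spans at least ``min_cycles`` lags.  The returned value is the median of
    the matched differences, so it carries sub-sample precision.
    """
    t = np.sort(np.array([e.t_peak_s for e in events]))
    n = t.size
    if n < 3:
        raise StructureError("need >= 3 events to search for a repetition period")
    span = t[-1] - t[0]
    diffs = np.sort((t[None, :] - t[:, None])[np.triu_indices(n, 1)])
    # cluster to candidate lags
    cands: list[float] = []
    i = 0
    while i < diffs.size:
        j = i
        while j + 1 < diffs.size and diffs[j + 1] - diffs[i] <= tol_s:
            j += 1
        cands.append(float(np.median(diffs[i : j + 1])))
        i = j + 1
    for P in cands:
        if P < 2 * tol_s or span < min_cycles * P:
            continue
        eligible = t[t <= t[-1] - P + tol_s]
        if eligible.size < 2:
            continue
        target = eligible + P
        idx = np.clip(np.searchsorted(t, target), 1, n - 1)
        near = np.minimum(np.abs(t[idx] - target), np.abs(t[idx - 1] - target))
        if np.all(near <= tol_s):
            best = np.where(np.abs(t[idx] - target) <= np.abs(t[idx - 1] - target),
                            t[idx], t[idx - 1])
            return float(np.median(best - eligible))
    raise StructureError("no repetition period found (fewer than 2 repeating groups?)")


def split_groups(events: list[PulseEvent], period_s: float,
                 tol_s: float = 2e-4) -> list[list[PulseEvent]]:
    """Partition events into period windows anchored at the first peak."""
    ev = sorted(events, key=lambda e: e.t_peak_s)
    t0 = ev[0].t_peak_s
    groups: dict[int, list[PulseEvent]] = {}
    for e in ev:
        g = int(np.floor((e.t_peak_s - t0 + tol_s) / period_s))
        groups.setdefault(g, []).append(e)
    return [groups[k] for k in sorted(groups)]


def estimate_slice_tr(events: list[PulseEvent]) -> float:
    """Per-slice repetition time: the fundamental period of the event pattern."""
    return find_period(events)


def estimate_echo_timing(group: list[PulseEvent]) -> tuple[float | None, float]:
    """(echo_spacing_s, echo_time_s) of one repetition.

    Echo time is twice the excitation-to-first-refocusing peak interval; the
    echo spacing is the median interval between successive refocusing peaks
    (None with a single refocusing pulse).  Roles must already be inferred.
    """
    exc = [e for e in group if e.role_guess in _EXCITATION_ROLES]
    ref = [e for e in group if e.role_guess == "refocusing"]
    if not exc or not ref:
        raise StructureError("group lacks excitation and/or refocusing events")
    e0 = min(exc, key=lambda e: e.t_peak_s)
    ref = sorted((r for r in ref if r.t_peak_s > e0.t_peak_s), key=lambda r: r.t_peak_s)
    if not ref:
        raise StructureError("no refocusing event follows the excitation")
    echo_time = 2.0 * (ref[0].t_peak_s - e0.t_peak_s)
    spacing = None
    if len(ref) >= 2:
        spacing = float(np.median(np.diff([r.t_peak_s for r in ref])))
    return spacing, float(echo_time)


def inversion_delay(group: list[PulseEvent]) -> float:
    """Peak-to-peak delay from the inversion pulse to the excitation."""
    inv = [e for e in group if e.role_guess == "inversion"]
    exc = [e for e in group if e.role_guess in _EXCITATION_ROLES]
    if not inv or not exc:
        raise StructureError("group lacks inversion and/or excitation events")
    return float(min(exc, key=lambda e: e.t_peak_s).t_peak_s
                 - min(inv, key=lambda e: e.t_peak_s).t_peak_s)


# ---------------------------------------------------------------------------
# Roles
# ---------------------------------------------------------------------------

def _find_runs(events: list[PulseEvent], min_len: int = 8,
               spacing_tol: float = 0.25) -> list[tuple[int, int]]:
    """Maximal stretches of >= min_len events with regular peak spacing."""
    n = len(events)
    if n < min_len:
        return []
    t = np.array([e.t_peak_s for e in events])
    iv = np.diff(t)
    runs = []
    i = 0
    while i < iv.size:
        ref = iv[i]
        j = i
        while j + 1 < iv.size and abs(iv[j + 1] - ref) <= spacing_tol * ref:
            j += 1
        if (j - i + 2) >= min_len:
            runs.append((i, j + 1))  # event index range [i, j+1] inclusive
        i = j + 1
    return runs


def infer_roles(events: list[PulseEvent],
                group_ids: list[int] | None = None) -> list[PulseEvent]:
    """Set ``role_guess`` in place (and return the list).

    Heuristics: regular runs of >= 8 pulses are trains — readout when much
    smaller than their leading pulse (which then becomes the preconditioning
    pulse), refocusing otherwise; the first event of a periodic group with
    >= 100 ms to the next event is an inversion; composites are water
    excitations; the first remaining pulse of a group is the excitation, and
    later pulses with about twice its area are refocusing pulses; a pulse
    trailing a refocusing train after a longer-than-normal gap is a
    restoration candidate.
    """
    ev = sorted(events, key=lambda e: e.t_peak_s)
    n = len(ev)
    if group_ids is None:
        group_ids = [0] * n
    for e in ev:
        e.role_guess = None

    in_run = [False] * n
    runs = _find_runs(ev)
    for a, b in runs:
        members = ev[a : b + 1]
        med_area = float(np.median([m.area for m in members]))
        spacing = float(np.median(np.diff([m.t_peak_s for m in members])))
        leader = ev[a - 1] if a > 0 else None
        is_readout = False
        if leader is not None and not (ev[a].t_peak_s - leader.t_peak_s < 20 * spacing):
            leader = None
        if leader is None:
            is_readout = True                      # bare train of small pulses
        elif med_area < 0.5 * leader.area:
            is_readout = True
            if leader.area >= 2 * med_area:
                leader.role_guess = "preconditioning"
        role = "readout" if is_readout else "refocusing"
        for k in range(a, b + 1):
            ev[k].role_guess = role
            in_run[k] = True
        # restoration candidate after a refocusing train
        if role == "refocusing" and b + 1 < n and group_ids[b + 1] == group_ids[b]:
            gap = ev[b + 1].t_peak_s - ev[b].t_peak_s
            if gap > 1.5 * spacing and ev[b + 1].role_guess is None:
                ev[b + 1].role_guess = "restoration"

    # composites are water-excitation pulses
    for e in ev:
        if e.role_guess is None and e.n_sub >= 2:
            e.role_guess = "water_excitation"

    # per group: inversion, excitation, refocusing by area ratio
    for g in sorted(set(group_ids)):
        members = [ev[k] for k in range(n) if group_ids[k] == g]
        if not members:
            continue
        first = members[0]
        k_first = ev.index(first)
        if (first.role_guess is None and k_first + 1 < n
                and ev[k_first + 1].t_peak_s - first.t_peak_s >= 0.1):
            first.role_guess = "inversion"
        exc = next((m for m in members if m.role_guess in _EXCITATION_ROLES), None)
        if exc is None:
            exc = next((m for m in members if m.role_guess is None), None)
            if exc is not None:
                exc.role_guess = "excitation"
        if exc is None:
            continue
        for m in members:
            if m.role_guess is None and m.t_peak_s > exc.t_peak_s:
                if 1.5 * exc.area <= m.area <= 2.5 * exc.area:
                    m.role_guess = "refocusing"
    return ev


# ---------------------------------------------------------------------------
# Frequencies & slices
# ---------------------------------------------------------------------------

def slice_frequency_analysis(
    events: list[PulseEvent],
    period_s: float | None = None,
    freq_tol_hz: float = 50.0,
) -> tuple[list[float], list[int], bool]:
    """Per-group centre frequencies, acquisition order and interleave flag.

    Each periodic group gets one representative frequency (median of its
    events' ``f_center_hz``); the spatial slice index is the rank of that
    frequency sorted ascending, and the acquisition order lists spatial
    indices in temporal order.  ``interleave_even_odd`` is True when all even
    spatial indices (0-based) are visited before all odd ones, or vice versa.
    """
    if period_s is None:
        period_s = find_period(events)
    groups = split_groups(events, period_s)
    freqs = [float(np.median([e.f_center_hz for e in g])) for g in groups]
    if len(freqs) < 2 or (max(freqs) - min(freqs)) < freq_tol_hz:
        warnings.warn("slice frequencies are degenerate; acquisition order undefined",
                      UserWarning, stacklevel=2)
        return freqs, list(range(len(freqs))), False
    order = np.argsort(np.argsort(freqs)).tolist()  # rank of each group's freq
    parities = [o % 2 for o in order]
    k = parities.index(1 - parities[0]) if (1 - parities[0]) in parities else len(parities)
    interleaved = (
        len(set(parities[:k])) == 1
        and len(set(parities[k:])) <= 1
        and 0 < k < len(parities)
    )
    return freqs, order, bool(interleaved)


# ---------------------------------------------------------------------------
# Amplitudes & shapes
# ---------------------------------------------------------------------------

def flip_angle_from_ratio(reference: PulseEvent, reference_angle_deg: float,
                          target: PulseEvent) -> FlipAngleEstimate:
    """Deduce the target's flip angle from the envelope-area ratio."""
    if reference.area <= 0:
        raise ZeroDivisionError("reference pulse has zero area")
    return FlipAngleEstimate(
        reference_angle_deg=reference_angle_deg,
        area_ratio=target.area / reference.area,
    )


def _resampled_env(env: np.ndarray, n_points: int = 256) -> np.ndarray:
    x = np.linspace(0.0, 1.0, n_points)
    xi = np.linspace(0.0, 1.0, env.size)
    out = np.interp(x, xi, env)
    peak = out.max()
    return out / peak if peak > 0 else out


def _fwhm_samples(env: np.ndarray) -> float:
    """Full width at half maximum (in samples) of the lobe around the argmax,
    with linear interpolation of the crossings."""
    k = int(np.argmax(env))
    half = 0.5 * env[k]
    lo = k
    while lo > 0 and env[lo - 1] >= half:
        lo -= 1
    hi = k
    while hi < env.size - 1 and env[hi + 1] >= half:
        hi += 1
    left = float(lo)
    if lo > 0 and env[lo] > env[lo - 1]:
        left = lo - 1 + (half - env[lo - 1]) / (env[lo] - env[lo - 1])
    right = float(hi)
    if hi < env.size - 1 and env[hi] > env[hi + 1]:
        right = hi + (env[hi] - half) / (env[hi] - env[hi + 1])
    return max(right - left, 1.0)


@lru_cache(maxsize=None)
def _template_fwhm_frac(kind: str) -> float:
    """FWHM of the unit template as a fraction of its support duration."""
    spec = PulseShapeSpec(kind, 1.0, dict(DEFAULT_SHAPE_PARAMS[kind]))
    env = np.abs(make_shape(spec, 4096.0))
    return _fwhm_samples(env) / env.size


def classify_shape(event: PulseEvent, bb: BasebandSignal,
                   min_score: float = 0.9) -> tuple[str, float]:
    """Label the event's envelope as rect / sinc / hypsec / unknown.

    The envelope on a window of twice the event duration centred on the peak
    is resampled to 256 points, peak-normalised and correlated (normalised
    inner product) against unit templates of each candidate generated with
    default parameters.  Each template's support duration is set by matching
    its full width at half maximum to the observed one, which makes the
    comparison insensitive to how much of the pulse's tails the detection
    threshold kept.  The label is the argmax score, or ``unknown`` below
    ``min_score``.  Composites are classified per sub-event and labelled
    ``binomial121`` when the three sub-areas fit 1:2:1 within 10%.
    """
    if event.sub_events:
        subs = event.sub_events
        labels = [classify_shape(s, bb, min_score)[0] for s in subs]
        if len(subs) == 3 and all(l == "rect" for l in labels):
            areas = np.array([s.area for s in subs])
            ratios = areas / areas[1]
            if np.all(np.abs(ratios - [0.5, 1.0, 0.5]) <= 0.1 * np.array([0.5, 1.0, 0.5])):
                return "binomial121", 1.0
        return "unknown", 0.0

    fs = bb.sample_rate_hz
    half_w = event.duration_s
    i0 = max(int(round((event.t_peak_s - half_w) * fs)), 0)
    i1 = min(int(round((event.t_peak_s + half_w) * fs)), bb.samples.size)
    if i1 - i0 < 16:
        raise ClassificationError("event spans fewer than 16 samples")
    obs = np.abs(bb.samples[i0:i1])
    fwhm_s = _fwhm_samples(obs) / fs
    # centre templates on the refined (centroid) peak, not the raw argmax,
    # which wanders across flat tops under noise
    k_peak = int(round(event.t_peak_s * fs)) - i0

    obs_n = _resampled_env(obs)
    best_label, best_score = "unknown", 0.0
    for kind in ("rect", "sinc", "hypsec"):
        dur = fwhm_s / _template_fwhm_frac(kind)
        spec = PulseShapeSpec(kind, dur, dict(DEFAULT_SHAPE_PARAMS[kind]))
        try:
            tmpl = np.abs(make_shape(spec, fs))
        except Exception:
            continue
        # embed the template in the observation window, centred on the peak
        win = np.zeros(obs.size)
        t0 = k_peak - tmpl.size // 2
        a, b = max(t0, 0), min(t0 + tmpl.size, obs.size)
        win[a:b] = tmpl[a - t0 : b - t0]
        tmpl_n = _resampled_env(win)
        denom = np.linalg.norm(obs_n) * np.linalg.norm(tmpl_n)
        if denom == 0:
            continue
        score = float(np.dot(obs_n, tmpl_n) / denom)
        if score > best_score:
            best_label, best_score = kind, score
    if best_score < min_score:
        return "unknown", best_score
    return best_label, best_score


def train_flip_profile(events: list[PulseEvent]) -> list[float]:
    """Refocusing areas normalised by the maximum, in temporal order."""
    ref = sorted((e for e in events if e.role_guess == "refocusing"),
                 key=lambda e: e.t_peak_s)
    if len(ref) < 3:
        raise StructureError("need >= 3 refocusing events for a train profile")
    areas = np.array([e.area for e in ref])
    return (areas / areas.max()).tolist()


# ---------------------------------------------------------------------------
# Full decode chain
# ---------------------------------------------------------------------------

def decode(
    rec: IQRecording | BasebandSignal,
    detect_cfg: DetectConfig | None = None,
    offset_hz: float | None = None,
    reference_flip_deg: float | None = None,
    classify: bool = True,
) -> SequenceReport:
    """Run the whole chain on a recording and return a :class:`SequenceReport`.

    Offset estimation (unless ``offset_hz`` is given), fine demodulation,
    detection, composite grouping, role inference, then every applicable
    derived quantity; fields the record does not support stay ``None``.
    ``reference_flip_deg`` is the known readout flip angle used to deduce the
    preconditioning flip angle, when such a pulse is present.
    """
    detect_cfg = detect_cfg or DetectConfig()
    warns: list[str] = []

    if offset_hz is None:
        try:
            est = estimate_carrier_offset(rec)
            offset_hz = est.offset_hz
        except EstimationError as exc:
            warns.append(str(exc))
            offset_hz = 0.0
    bb = fine_demodulate(rec, offset_hz)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        raw = detect_pulses(bb, detect_cfg)
        warns.extend(str(c.message) for c in caught)
    if not raw:
        return SequenceReport(events=[], applied_offset_hz=offset_hz, warnings=warns)

    events = group_composites(
        raw,
        composite_max_gap_s=detect_cfg.composite_max_gap_s,
        member_max_duration_s=detect_cfg.composite_member_max_duration_s,
        max_members=detect_cfg.composite_max_members,
    )

    report = SequenceReport(events=events, applied_offset_hz=offset_hz, warnings=warns)
    if len(events) >= 2:
        report.peak_intervals_s = peak_intervals(events)

    period = None
    try:
        period = find_period(events)
        report.slice_tr_s = period
    except StructureError as exc:
        warns.append(f"slice TR: {exc}")

    if period is not None:
        t0 = min(e.t_peak_s for e in events)
        group_ids = [int(np.floor((e.t_peak_s - t0 + 2e-4) / period)) for e in events]
    else:
        group_ids = [0] * len(events)
    infer_roles(events, group_ids)
    groups = [
        [e for e, g in zip(events, group_ids) if g == gid]
        for gid in sorted(set(group_ids))
    ]

    for group in groups:
        try:
            spacing, echo_time = estimate_echo_timing(group)
            report.echo_spacing_s = spacing
            report.echo_time_s = echo_time
            break
        except StructureError:
            continue
    for group in groups:
        try:
            report.inversion_delay_s = inversion_delay(group)
            break
        except StructureError:
            continue

    readout_iv = []
    for a, b in _find_runs(events):
        if events[a].role_guess == "readout":
            readout_iv.extend(np.diff([e.t_peak_s for e in events[a : b + 1]]))
    if readout_iv:
        report.readout_spacing_s = float(np.median(readout_iv))

    comp_spacing = []
    for e in events:
        if e.role_guess == "water_excitation" and e.n_sub >= 2:
            comp_spacing.extend(np.diff([s.t_peak_s for s in e.sub_events]))
    if comp_spacing:
        report.composite_spacing_s = float(np.median(comp_spacing))

    if period is not None and len(groups) >= 2:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            freqs, order, interleaved = slice_frequency_analysis(events, period)
            if caught:
                warns.extend(str(c.message) for c in caught)
            else:
                report.slice_frequencies_hz = freqs
                report.acquisition_order = order
                report.interleave_even_odd = interleaved

    if reference_flip_deg is not None:
        precond = [e for e in events if e.role_guess == "preconditioning"]
        readouts = sorted((e for e in events if e.role_guess == "readout"),
                          key=lambda e: e.area)
        if precond and readouts:
            ref = readouts[len(readouts) // 2]  # median-area readout pulse
            report.flip_estimates.append(
                flip_angle_from_ratio(ref, reference_flip_deg, precond[0])
            )

    try:
        report.train_profile = train_flip_profile(events)
    except StructureError:
        pass

    if classify:
        for e in events:
            try:
                e.shape_label = classify_shape(e, bb)[0]
            except ClassificationError:
                e.shape_label = None

    return report


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def report_to_dict(report: SequenceReport, include_events: bool = True) -> dict:
    d = {
        "n_events": len(report.events),
        "slice_tr_s": report.slice_tr_s,
        "echo_spacing_s": report.echo_spacing_s,
        "echo_time_s": report.echo_time_s,
        "inversion_delay_s": report.inversion_delay_s,
        "readout_spacing_s": report.readout_spacing_s,
        "composite_spacing_s": report.composite_spacing_s,
        "slice_frequencies_hz": report.slice_frequencies_hz,
        "acquisition_order": report.acquisition_order,
        "interleave_even_odd": report.interleave_even_odd,
        "flip_estimates": [
            {"reference_angle_deg": f.reference_angle_deg,
             "area_ratio": f.area_ratio,
             "deduced_angle_deg": f.deduced_angle_deg}
            for f in report.flip_estimates
        ],
        "train_profile": report.train_profile,
        "applied_offset_hz": report.applied_offset_hz,
        "warnings": report.warnings,
    }
    if include_events:
        d["events"] = [
            {"t_start_s": e.t_start_s, "t_peak_s": e.t_peak_s, "t_end_s": e.t_end_s,
             "duration_s": e.duration_s, "peak_amplitude": e.peak_amplitude,
             "area": e.area, "f_center_hz": e.f_center_hz,
             "phase_at_peak_rad": e.phase_at_peak_rad, "n_sub": e.n_sub,
             "shape_label": e.shape_label, "role_guess": e.role_guess}
            for e in report.events
        ]
    return d


def report_to_json(report: SequenceReport, include_events: bool = True) -> str:
    return json.dumps(report_to_dict(report, include_events), indent=2, sort_keys=True)
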