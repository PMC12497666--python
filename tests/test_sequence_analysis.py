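"""Sequence-level decoding: timings, roles, slices, flip angles, shapes."""

import dataclasses

import numpy as np
import pytest

import pulsescope as ps
from pulsescope.errors import StructureError
from pulsescope.pulse_detection import PulseEvent
from pulsescope.sequence_analysis import find_period, report_to_json

FS = 192_000.0


def _ev(tp, area=1.0, dur=1e-3, role=None, f=0.0, n_sub=0):
    e = PulseEvent(t_start_s=tp - dur / 2, t_end_s=tp + dur / 2, t_peak_s=tp,
                   peak_amplitude=1.0, area=area, f_center_hz=f, role_guess=role)
    if n_sub:
        e.sub_events = [dataclasses.replace(e, sub_events=None) for _ in range(n_sub)]
    return e


class TestPeakIntervals:
    def test_two_events_give_the_echo_time(self):
        assert ps.peak_intervals([_ev(0.1), _ev(0.148)]) == pytest.approx([0.048])

    def test_constant_spacing(self):
        events = [_ev(0.01 + k * 0.005) for k in range(6)]
        assert ps.peak_intervals(events) == pytest.approx([0.005] * 5)

    def test_order_invariance(self):
        events = [_ev(0.03), _ev(0.01), _ev(0.02)]
        assert ps.peak_intervals(events) == pytest.approx([0.01, 0.01])

    def test_single_event_raises(self):
        with pytest.raises(StructureError):
            ps.peak_intervals([_ev(0.1)])


class TestSliceTR:
    def test_two_identical_groups_exact(self):
        g = [0.0, 0.005, 0.0149]  # irregular internal structure
        events = [_ev(0.01 + t) for t in g] + [_ev(0.01 + 0.0832 + t) for t in g]
        assert ps.estimate_slice_tr(events) == pytest.approx(0.0832, abs=1e-12)

    def test_semc_80ms(self, decoded):
        _, _, r = decoded("semc")
        assert r.slice_tr_s == pytest.approx(0.080, rel=1e-3)

    def test_se_epi_356ms(self, decoded):
        _, _, r = decoded("se_epi")
        assert r.slice_tr_s == pytest.approx(0.356, rel=1e-3)

    def test_b1map_247ms(self, decoded):
        _, _, r = decoded("b1map")
        assert r.slice_tr_s == pytest.approx(0.247, rel=1e-3)

    def test_single_group_raises(self, rendered):
        _, cfg, rec = rendered("space_const")
        bb = ps.fine_demodulate(rec, cfg.carrier_offset_hz)
        with pytest.raises(StructureError):
            ps.estimate_slice_tr(ps.detect_pulses(bb))

    def test_in_train_period_is_rejected(self, decoded):
        """The 3.04 ms readout period must not masquerade as the slice TR."""
        _, _, r = decoded("b1map")
        assert r.slice_tr_s > 0.2


class TestEchoTiming:
    def test_exact_doubling(self):
        group = [_ev(0.010, area=1.0, role="excitation"),
                 _ev(0.017, area=2.0, role="refocusing")]
        spacing, te = ps.estimate_echo_timing(group)
        assert te == pytest.approx(0.014, abs=1e-12)
        assert spacing is None

    def test_semc_spacing(self, decoded):
        _, _, r = decoded("semc")
        assert r.echo_spacing_s == pytest.approx(9.9e-3, rel=5e-3)
        assert round(r.echo_spacing_s * 1e3) == 10

    def test_se_epi_echo_time_48ms(self, decoded):
        _, _, r = decoded("se_epi")
        assert r.echo_time_s == pytest.approx(0.048, abs=5e-4)

    def test_missing_refocusing_raises(self):
        with pytest.raises(StructureError):
            ps.estimate_echo_timing([_ev(0.01, role="excitation")])


class TestRoles:
    def test_semc_group_roles_and_area_ratio(self, decoded):
        _, _, r = decoded("semc")
        first_group = r.events[:8]
        roles = [e.role_guess for e in first_group]
        assert roles == ["excitation"] + ["refocusing"] * 7
        exc = first_group[0]
        for ref in first_group[1:]:
            assert ref.area / exc.area == pytest.approx(2.0, abs=0.05)

    def test_se_epi_inversion_tagged(self, decoded):
        _, _, r = decoded("se_epi")
        assert r.events[0].role_guess == "inversion"
        assert r.events[1].role_guess == "water_excitation"

    def test_b1map_preconditioning_and_readouts(self, decoded):
        _, _, r = decoded("b1map", reference_flip_deg=10.0)
        roles = [e.role_guess for e in r.events]
        assert roles.count("readout") == 128
        assert roles.count("preconditioning") == 1

    def test_single_pulse_defaults_to_excitation(self):
        events = [_ev(0.01)]
        ps.infer_roles(events)
        assert events[0].role_guess == "excitation"


class TestInversionDelay:
    def test_se_epi_156ms(self, decoded):
        _, _, r = decoded("se_epi")
        assert r.inversion_delay_s == pytest.approx(0.156, abs=5e-4)

    def test_synthetic_stir_delay(self):
        """A 120 ms inversion->excitation delay is recovered to the sample."""
        inv = ps.PulseEventSpec(0.005, ps.PulseShapeSpec("hypsec", 0.010), 1.0,
                                role="inversion")
        exc = ps.PulseEventSpec(0.130 - 1.28e-3, ps.PulseShapeSpec("sinc", 2.56e-3),
                                0.5, role="excitation")
        ref = ps.PulseEventSpec(0.150 - 0.8e-3, ps.PulseShapeSpec("rect", 1.6e-3),
                                0.62, role="refocusing")
        script = ps.SequenceScript("stir", [inv, exc, ref], 0.4)
        # two repetitions so the group structure is detectable
        script2 = ps.SequenceScript("stir2", script.events + [
            dataclasses.replace(e, onset_s=e.onset_s + 0.2) for e in script.events
        ], 0.4)
        rec = ps.render(script2, ps.RenderConfig())
        r = ps.decode(rec)
        assert r.inversion_delay_s == pytest.approx(0.120, abs=2e-5)

    def test_missing_roles_raise(self):
        with pytest.raises(StructureError):
            ps.inversion_delay([_ev(0.01, role="excitation")])


class TestSliceFrequencies:
    def test_semc_even_odd_interleave(self, decoded):
        _, _, r = decoded("semc")
        assert r.acquisition_order == [0, 2, 4, 1, 3]
        assert r.interleave_even_odd is True
        assert len(r.slice_frequencies_hz) == 5
        # relative spacing of slice frequencies: 1 kHz steps
        f = np.sort(r.slice_frequencies_hz)
        assert np.allclose(np.diff(f), 1000.0, atol=10.0)

    def test_sequential_order_not_interleaved(self):
        events = []
        for g in range(4):
            events += [_ev(0.01 + g * 0.05 + k * 0.005, f=1000.0 * g)
                       for k in range(3)]
        freqs, order, interleaved = ps.slice_frequency_analysis(events)
        assert order == [0, 1, 2, 3]
        assert interleaved is False

    def test_rank_recovery_is_exact(self, decoded):
        """Frequency ranks are exact for offsets far above the ~5 Hz accuracy."""
        script, _, r = decoded("semc")
        spatial_by_time = [e.slice_index for e in script.events[::8]]
        assert r.acquisition_order == spatial_by_time


class TestFlipAngles:
    def test_identity(self):
        e = _ev(0.01, area=0.5)
        fe = ps.flip_angle_from_ratio(e, 10.0, e)
        assert fe.area_ratio == 1.0
        assert fe.deduced_angle_deg == 10.0

    def test_closed_form_rect_areas(self):
        a = _ev(0.01, area=0.5 * 1e-3)   # rect 1 ms, amplitude 0.5
        b = _ev(0.02, area=0.5 * 2e-3)   # rect 2 ms, amplitude 0.5
        assert ps.flip_angle_from_ratio(a, 30.0, b).deduced_angle_deg == pytest.approx(60.0)

    def test_b1map_preconditioning_angle_80deg(self, decoded):
        _, _, r = decoded("b1map", reference_flip_deg=10.0)
        assert len(r.flip_estimates) == 1
        assert r.flip_estimates[0].deduced_angle_deg == pytest.approx(80.0, abs=2.0)

    def test_deduced_is_reference_times_ratio(self, decoded):
        _, _, r = decoded("b1map", reference_flip_deg=10.0)
        fe = r.flip_estimates[0]
        assert fe.deduced_angle_deg == fe.reference_angle_deg * fe.area_ratio

    def test_zero_reference_area_raises(self):
        bad = _ev(0.01, area=0.0)
        with pytest.raises(ZeroDivisionError):
            ps.flip_angle_from_ratio(bad, 10.0, _ev(0.02))


class TestShapeClassification:
    def test_space_first_sinc_then_rect(self, decoded):
        _, _, r = decoded("space_const")
        assert r.events[0].shape_label == "sinc"
        assert all(e.shape_label == "rect" for e in r.events[1:])

    def test_se_epi_inversion_is_hypsec(self, decoded):
        _, _, r = decoded("se_epi")
        assert r.events[0].shape_label == "hypsec"

    def test_water_excitation_is_binomial(self, decoded):
        _, _, r = decoded("se_epi")
        assert r.events[1].shape_label == "binomial121"

    def test_classification_scores_high(self, rendered):
        _, cfg, rec = rendered("space_const")
        bb = ps.fine_demodulate(rec, cfg.carrier_offset_hz)
        events = ps.detect_pulses(bb)
        for e in events[:3]:
            label, score = ps.classify_shape(e, bb)
            assert score >= 0.97

    def test_noise_is_unknown(self):
        rng = np.random.default_rng(0)
        x = 1e-3 * (rng.standard_normal(4000) + 1j * rng.standard_normal(4000))
        bb = ps.BasebandSignal(x, FS)
        ev = ps.measure_pulse(bb, 0.005, 0.015)
        label, score = ps.classify_shape(ev, bb)
        assert label == "unknown"
        assert score < 0.9

    @pytest.mark.parametrize("kind,params", [
        ("rect", {}),
        ("sinc", {"n_lobes": 3, "apodization": "hann"}),
        ("hypsec", {"mu": 4.9, "truncation_frac": 0.1}),
    ])
    def test_self_consistency_render_classify(self, kind, params):
        """make_shape -> render -> classify returns the generating label."""
        shape = ps.PulseShapeSpec(kind, 4e-3, params)
        ev = ps.PulseEventSpec(3e-3, shape, 0.8)
        rec = ps.render(ps.SequenceScript("k", [ev], 12e-3),
                        ps.RenderConfig(noise_sigma=5e-4))  # SNR > 30 dB
        r = ps.decode(rec)
        assert len(r.events) == 1
        assert r.events[0].shape_label == kind


class TestTrainProfile:
    def test_space_const_flat_within_1pct(self, decoded):
        _, _, r = decoded("space_const")
        assert np.allclose(r.train_profile, 1.0, atol=0.01)

    def test_space_varfa_matches_schedule(self, decoded):
        script, _, r = decoded("space_varfa")
        sched = np.array(script.expected_timings["train_profile"])
        prof = np.array(r.train_profile)
        assert prof.size == sched.size == 40
        assert np.max(np.abs(prof - sched / sched.max())) < 0.02

    def test_identical_pulses_exactly_constant_without_noise(self):
        script, cfg = ps.fixture("space_const")
        cfg = dataclasses.replace(cfg, noise_sigma=0.0, quantization_bits=None)
        r = ps.decode(ps.render(script, cfg), offset_hz=cfg.carrier_offset_hz)
        assert np.max(r.train_profile) - np.min(r.train_profile) < 1e-9

    def test_too_few_refocusing_raises(self):
        with pytest.raises(StructureError):
            ps.train_flip_profile([_ev(0.01, role="refocusing")])


class TestDecode:
    def test_semc_end_to_end(self, decoded):
        _, _, r = decoded("semc")
        assert r.slice_tr_s == pytest.approx(0.080, rel=1e-3)
        assert r.echo_spacing_s == pytest.approx(9.9e-3, rel=5e-3)
        assert r.interleave_even_odd is True

    def test_zero_recording(self):
        rec = ps.IQRecording(samples=np.zeros(10_000, dtype=complex),
                             sample_rate_hz=FS)
        r = ps.decode(rec)
        assert r.events == []
        assert r.slice_tr_s is None
        assert r.warnings

    def test_decode_is_deterministic(self, rendered):
        _, _, rec = rendered("semc")
        a = report_to_json(ps.decode(rec))
        b = report_to_json(ps.decode(rec))
        assert a == b

    def test_restoration_pulse_found(self, decoded):
        _, _, r = decoded("space_restore")
        assert r.events[-1].role_guess == "restoration"

    def test_offset_override_is_echoed(self, rendered):
        _, _, rec = rendered("space_const")
        r = ps.decode(rec, offset_hz=1_199.0)
        assert r.applied_offset_hz == 1_199.0

    def test_roundtrip_intervals_within_1pct(self, rendered):
        """Every recovered interval agrees with the script ground truth to 1%."""
        keys = ("slice_tr_s", "echo_spacing_s", "echo_time_s",
                "inversion_delay_s", "readout_spacing_s", "composite_spacing_s")
        checked = 0
        for name in ps.FIXTURE_NAMES:
            script, cfg, rec = rendered(name)
            r = ps.decode(rec)
            for k in keys:
                truth, got = script.expected_timings.get(k), getattr(r, k)
                if truth and got:
                    assert got == pytest.approx(truth, rel=0.01), (name, k)
                    checked += 1
        assert checked >= 10
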