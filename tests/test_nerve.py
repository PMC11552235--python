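"""Envelope filtering, response quantification, thresholds, and heatmaps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sandplume.nerve import (
    DoseResponseSeries,
    NerveTrace,
    ResponseQuant,
    classify_kinetics,
    envelope,
    estimate_threshold,
    quantify,
    response_heatmap,
)


def make_trace(samples, fs=1000.0, stimuli=None):
    return NerveTrace(fs=fs, samples=np.asarray(samples, float),
                      stimuli=stimuli or [], species="test")


class TestEnvelope:
    def test_zero_trace_gives_zero_envelope(self):
        env = envelope(make_trace(np.zeros(5000)))
        assert np.all(env == 0.0)

    def test_unity_dc_gain(self):
        env = envelope(make_trace(np.full(5000, -0.25)))
        assert env[1000:4000] == pytest.approx(0.25, rel=1e-9)

    def test_minus_3db_at_25hz(self):
        # ride a small ripple on a positive pedestal so |.| is the identity
        fs = 2000.0
        t = np.arange(int(20 * fs)) / fs
        for f, gain in [(1.0, 1.0), (25.0, 1.0 / np.sqrt(2.0))]:
            env = envelope(make_trace(1.0 + 0.1 * np.sin(2 * np.pi * f * t), fs=fs))
            mid = env[int(5 * fs):int(15 * fs)]
            ripple = (mid.max() - mid.min()) / 2.0
            assert ripple == pytest.approx(0.1 * gain, rel=0.02)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            envelope(make_trace(np.zeros(100), fs=50.0))

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="short"):
            envelope(make_trace(np.zeros(10), fs=10_000.0))


def alpha_trace(amp=1.0, tau=2.0, fs=1000.0, onset=10.0, dur=40.0):
    """Deterministic non-negative alpha-function 'envelope' as a raw trace."""
    t = np.arange(int(dur * fs)) / fs
    tau_r = np.clip(t - onset, 0.0, None)
    sig = amp * (tau_r / tau) * np.exp(1.0 - tau_r / tau)
    return NerveTrace(fs=fs, samples=sig,
                      stimuli=[("stim", onset, onset + 20.0)], species="test")


class TestQuantify:
    def test_flat_trace_scores_zero_area_and_no_kinetics(self):
        tr = make_trace(np.zeros(30_000), fs=1000.0,
                        stimuli=[("stim", 10.0, 20.0)])
        q = quantify(tr, "stim")
        assert q.area == 0.0
        assert q.kinetics_class == "none"

    def test_alpha_function_area_recovered_within_5pc(self):
        # integral of A*(tau/taud)*e^(1-tau/taud) over [0, W] has a closed form
        amp, tau, W = 0.5, 2.0, 20.0 + 9.99
        tr = alpha_trace(amp=amp, tau=tau)
        analytic = amp * np.e * (tau - np.exp(-W / tau) * (W + tau))
        q = quantify(tr, "stim", pre_window=5.0, tail=10.0)
        assert q.area == pytest.approx(analytic, rel=0.05)

    @settings(deadline=None, derandomize=True)
    @given(offset=st.floats(0.0, 0.5))
    def test_area_invariant_to_dc_offset(self, offset):
        # baseline subtraction removes any electrode DC pedestal
        base = alpha_trace(amp=0.5)
        shifted = NerveTrace(fs=base.fs, samples=base.samples + offset,
                             stimuli=base.stimuli, species="test")
        q0 = quantify(base, "stim", pre_window=5.0, tail=10.0)
        q1 = quantify(shifted, "stim", pre_window=5.0, tail=10.0)
        assert q1.area == pytest.approx(q0.area, rel=1e-6, abs=1e-6)

    def test_missing_stimulus_label(self):
        with pytest.raises(KeyError):
            quantify(alpha_trace(), "nope")

    def test_requires_5s_pre_window(self):
        tr = make_trace(np.zeros(30_000), fs=1000.0, stimuli=[("stim", 2.0, 10.0)])
        with pytest.raises(ValueError, match="pre-stimulus"):
            quantify(tr, "stim")


class TestClassifyKinetics:
    def make_quant(self, peak=1.0, ttp=2.0, decay=0.1, noise=0.01):
        return ResponseQuant(stimulus="s", baseline=0.0, area=1.0, peak=peak,
                             time_to_peak=ttp, decay_fraction=decay,
                             kinetics_class="none", baseline_sd=noise)

    def test_subnoise_response_is_none(self):
        assert classify_kinetics(self.make_quant(peak=0.02, noise=0.01)) == "none"

    def test_fast_needs_early_peak_and_full_decay(self):
        assert classify_kinetics(self.make_quant(ttp=2.0, decay=0.1)) == "fast_transient"

    def test_late_peak_or_sustained_tail_is_slow(self):
        assert classify_kinetics(self.make_quant(ttp=25.0, decay=0.1)) == "slow_sustained"
        assert classify_kinetics(self.make_quant(ttp=2.0, decay=0.8)) == "slow_sustained"

    def test_ambiguous_mid_band_is_not_fast(self):
        assert classify_kinetics(self.make_quant(ttp=2.0, decay=0.45)) == "slow_sustained"


def hill_series(rng, thresh_idx=3, n_doses=7, n_reps=4, blank_sd=0.05):
    doses = np.geomspace(0.01, 10.0, n_doses)
    k = doses[thresh_idx]
    blanks = rng.normal(1.0, blank_sd, n_reps)
    responses = [
        rng.normal(1.0, blank_sd, n_reps)
        + 10.0 * d**4 / (d**4 + k**4) * (d >= k)
        for d in doses
    ]
    return DoseResponseSeries(compound="l-ala", species="x", doses=doses,
                              responses=responses, blanks=blanks)


class TestEstimateThreshold:
    def test_flat_series_has_no_threshold(self, rng):
        doses = np.geomspace(0.01, 10.0, 5)
        s = DoseResponseSeries(
            compound="c", species="s", doses=doses,
            responses=[rng.normal(1.0, 0.05, 4) for _ in doses],
            blanks=rng.normal(1.0, 0.05, 4),
        )
        thr, flags = estimate_threshold(s)
        assert thr is None
        assert not flags.any()

    def test_hill_series_threshold_at_fourth_dose(self, rng):
        s = hill_series(rng, thresh_idx=3)
        thr, flags = estimate_threshold(s)
        assert thr == pytest.approx(s.doses[3])
        assert flags[3]

    def test_unsorted_doses_rejected(self, rng):
        s = hill_series(rng)
        s.doses = s.doses[::-1].copy()
        with pytest.raises(ValueError, match="ascending"):
            estimate_threshold(s)

    def test_threshold_not_raised_by_quieter_blanks(self, rng):
        noisy = hill_series(rng, thresh_idx=3, blank_sd=0.3)
        quiet = DoseResponseSeries(
            compound=noisy.compound, species=noisy.species, doses=noisy.doses,
            responses=noisy.responses, blanks=(noisy.blanks - 1.0) * 0.1 + 1.0,
        )
        thr_noisy, _ = estimate_threshold(noisy)
        thr_quiet, _ = estimate_threshold(quiet)
        if thr_noisy is not None:
            assert thr_quiet is not None
            assert thr_quiet <= thr_noisy


class TestResponseHeatmap:
    def test_single_leg_single_compound(self):
        m = response_heatmap(pd.DataFrame({"ala": [2.5]}, index=["leg1"]))
        assert m["ala"] == pytest.approx(1.0)

    def test_invariant_to_per_leg_gain(self, rng):
        areas = pd.DataFrame(rng.uniform(0.1, 1.0, (4, 3)),
                             index=list("abcd"), columns=["x", "y", "z"])
        scaled = areas.copy()
        scaled.loc["b"] *= 10.0
        pd.testing.assert_series_equal(response_heatmap(areas),
                                       response_heatmap(scaled))

    def test_known_relative_magnitudes_recovered(self):
        rel = np.array([1.0, 0.5, 0.25])
        areas = pd.DataFrame([rel * g for g in (1.0, 3.0, 0.2)],
                             columns=["a", "b", "c"])
        m = response_heatmap(areas)
        assert np.allclose(m.to_numpy(), rel, rtol=1e-12)

    def test_dead_leg_excluded_with_warning(self):
        areas = pd.DataFrame([[1.0, 0.5], [0.0, 0.0]], index=["ok", "dead"],
                             columns=["a", "b"])
        with pytest.warns(UserWarning, match="dead"):
            m = response_heatmap(areas)
        assert m["a"] == pytest.approx(1.0)
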