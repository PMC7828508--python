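"""Snippet geometry and construction of the averaged online decoder."""

import numpy as np
import pytest

from oaad.decoder import LagGrid, build_lagged_matrix, fit_ridge_decoder
from oaad.errors import BalanceError, InvalidInputError
from oaad.online_model import (
    AttentionSchedule,
    TrialData,
    WindowSpec,
    fit_biased_decoders,
    fit_online_decoder,
    snippet_bounds,
    snippet_count,
    snippet_weight_matrix,
)
from oaad.preprocessing import EegSegment, EnvelopeSignal
from oaad.synthetic import ForwardModel, generate_envelope, simulate_trial

GRID = LagGrid.from_n_lags(3)


def _make_trial(rng, side="left", n_ch=2, T=20.0, rate=64.0, trial_id="t",
                same_envelopes=False):
    n = int(T * rate)
    env_l = EnvelopeSignal(rng.standard_normal(n), rate, side="left")
    env_r = EnvelopeSignal(env_l.values.copy() if same_envelopes else rng.standard_normal(n),
                           rate, side="right")
    eeg = EegSegment(rng.standard_normal((n_ch, n)), rate)
    return TrialData(eeg, env_l, env_r, AttentionSchedule.fixed(side, T), trial_id)


class TestSnippetGeometry:
    def test_first_window_bounds(self):
        spec = WindowSpec(15, 1, 60)
        assert snippet_bounds(spec, 1) == (0, 960)
        assert snippet_bounds(spec, 2) == (64, 1024)

    def test_snippet_count_default_geometry(self):
        spec = WindowSpec(15, 1, 60)
        assert snippet_count(spec) == 46
        assert 16 * snippet_count(spec) == 736
        assert 12 * snippet_count(spec) == 552

    def test_full_trial_window_gives_single_snippet(self):
        assert snippet_count(WindowSpec(60, 7, 60)) == 1

    def test_window_exceeding_trial_rejected(self):
        with pytest.raises(InvalidInputError):
            WindowSpec(61, 1, 60)

    def test_out_of_range_snippet_index(self):
        spec = WindowSpec(15, 1, 60)
        with pytest.raises(IndexError):
            snippet_bounds(spec, 47)
        with pytest.raises(IndexError):
            snippet_bounds(spec, 0)

    def test_detection_timestamp(self):
        spec = WindowSpec(15, 1, 60)
        assert spec.detection_time_s(1) == 15.0
        assert spec.detection_time_s(46) == 60.0


class TestOnlineConstruction:
    def test_mean_of_identical_trials_equals_single_decoder(self, rng):
        trial = _make_trial(rng, T=20.0)
        spec = WindowSpec(20, 1, 20)
        one = fit_online_decoder([trial], spec, GRID, 1.0)
        three = fit_online_decoder([trial, trial, trial], spec, GRID, 1.0)
        assert np.allclose(one.weights, three.weights, atol=1e-12)

    def test_full_window_equals_mean_of_per_trial_ridge_fits(self, rng):
        trials = [_make_trial(rng, side=s, trial_id=f"t{i}")
                  for i, s in enumerate(["left", "right", "left"])]
        spec = WindowSpec(20, 1, 20)
        online = fit_online_decoder(trials, spec, GRID, 10.0)
        per_trial = []
        for t in trials:
            X = build_lagged_matrix(t.eeg.data, GRID)
            side = t.schedule.segments[0][2]
            per_trial.append(fit_ridge_decoder(X, t.envelope(side).values, 10.0, GRID, 2).weights)
        assert np.allclose(online.weights, np.mean(per_trial, axis=0), atol=1e-12)

    def test_switching_trial_rejected_for_construction(self, rng):
        trial = _make_trial(rng)
        trial.schedule = AttentionSchedule.switching("left", 20.0, 10.0)
        with pytest.raises(InvalidInputError, match="switching"):
            fit_online_decoder([trial], WindowSpec(10, 1, 20), GRID)

    def test_averaging_conservation(self, rng):
        trials = [_make_trial(rng, trial_id=f"t{i}") for i in range(2)]
        spec = WindowSpec(5, 5, 20)
        online = fit_online_decoder(trials, spec, GRID, 10.0)
        J = snippet_count(spec)
        snippets = [
            snippet_weight_matrix(t, spec, j, GRID, 10.0, "left")
            for t in trials for j in range(1, J + 1)
        ]
        assert np.allclose(online.weights, np.mean(snippets, axis=0), atol=1e-12)

    def test_trial_order_does_not_matter(self, rng):
        trials = [_make_trial(rng, trial_id=f"t{i}") for i in range(4)]
        spec = WindowSpec(10, 2, 20)
        a = fit_online_decoder(trials, spec, GRID, 10.0)
        b = fit_online_decoder(trials[::-1], spec, GRID, 10.0)
        assert np.allclose(a.weights, b.weights, atol=1e-10)


class TestBiasedConstruction:
    def test_seven_per_side_partition(self, rng):
        trials = [
            _make_trial(rng, side="left" if i % 2 == 0 else "right", trial_id=f"t{i}")
            for i in range(14)
        ]
        spec = WindowSpec(10, 5, 20)
        d_l, d_r = fit_biased_decoders(trials, spec, GRID, 10.0)
        assert d_l.meta["n_trials"] == 7 and d_r.meta["n_trials"] == 7
        assert d_l.meta["bias"] == "left" and d_r.meta["bias"] == "right"

    def test_identical_data_alternating_sides_gives_equal_decoders(self, rng):
        base = _make_trial(rng, side="left", same_envelopes=True)
        trials = []
        for i, side in enumerate(["left", "right"] * 2):
            t = TrialData(base.eeg, base.env_left, base.env_right,
                          AttentionSchedule.fixed(side, 20.0), f"t{i}")
            trials.append(t)
        d_l, d_r = fit_biased_decoders(trials, WindowSpec(10, 5, 20), GRID, 10.0)
        assert np.allclose(d_l.weights, d_r.weights, atol=1e-12)

    def test_missing_side_is_named(self, rng):
        trials = [_make_trial(rng, side="left", trial_id=f"t{i}") for i in range(4)]
        with pytest.raises(BalanceError, match="right"):
            fit_biased_decoders(trials, WindowSpec(10, 5, 20), GRID)

    def test_matched_side_evaluation_beats_mismatched_with_spatial_effect(self):
        # forward model where left- vs right-attended states differ in topography
        rng = np.random.default_rng(5)
        fwd = ForwardModel.default(n_channels=8, rng=5, spatial=True, noise_sd=20.0)
        spec = WindowSpec(15, 3, 60)
        T, rate = 60.0, 64.0

        def trial(side, tid):
            e_l = generate_envelope(T, rate, rng, side="left")
            e_r = generate_envelope(T, rate, rng, side="right")
            return simulate_trial(e_l, e_r, AttentionSchedule.fixed(side, T), fwd, rng, tid)

        constr = [trial(s, f"c{i}") for i, s in enumerate(["left", "right"] * 3)]
        test = [trial(s, f"t{i}") for i, s in enumerate(["left", "right"] * 3)]
        d_l, d_r = fit_biased_decoders(constr, spec, LagGrid(rate_hz=rate), 10.0)
        from oaad.streaming import detect_trial

        def accuracy(decoder_for):
            recs = []
            for t in test:
                side = t.schedule.segments[0][2]
                recs.extend(detect_trial(t, {"m": decoder_for(side)}, spec, ks=(1,)))
            return float(np.mean([r.correct for r in recs]))

        matched = accuracy(lambda s: d_l if s == "left" else d_r)
        mismatched = accuracy(lambda s: d_r if s == "left" else d_l)
        assert matched >= mismatched
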