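"""The forward-model generator: envelopes, EEG, schedules and sessions."""

import numpy as np
import pytest

from oaad.errors import BalanceError, InvalidInputError
from oaad.online_model import AttentionSchedule, WindowSpec
from oaad.preprocessing import zscore
from oaad.streaming import SessionPlan, run_online_session
from oaad.synthetic import (
    ForwardModel,
    generate_envelope,
    generate_session,
    simulate_eeg,
    simulate_trial,
)


class TestGenerateEnvelope:
    def test_contract_length_and_normalization(self):
        env = generate_envelope(60.0, 64.0, rng=0)
        assert len(env) == 3840
        assert abs(env.values.mean()) < 1e-9
        assert abs(env.values.std() - 1.0) < 1e-9

    def test_independent_seeds_are_uncorrelated(self):
        rs = []
        for seed in range(100):
            a = generate_envelope(60.0, 64.0, rng=seed).values
            b = generate_envelope(60.0, 64.0, rng=1000 + seed).values
            rs.append(abs(np.corrcoef(a, b)[0, 1]))
        assert max(rs) < 0.2

    def test_spectral_centroid_in_speech_modulation_band(self):
        env = generate_envelope(60.0, 64.0, rng=2)
        spec = np.abs(np.fft.rfft(env.values)) ** 2
        freqs = np.fft.rfftfreq(len(env), d=1 / 64.0)
        centroid = np.sum(freqs[1:] * spec[1:]) / np.sum(spec[1:])
        assert 2.0 <= centroid <= 8.0

    def test_invalid_duration(self):
        with pytest.raises(InvalidInputError):
            generate_envelope(0.0)


class TestSimulateEeg:
    def test_single_lag_kernel_gives_shifted_copy(self):
        env = generate_envelope(10.0, 64.0, rng=3)
        kernel = np.zeros((1, 4))
        kernel[0, 3] = 1.0
        fwd = ForwardModel(kernel, np.zeros((1, 4)), gain_att=1.0, gain_ign=0.0, noise_sd=0.0)
        eeg = simulate_eeg(env, generate_envelope(10.0, 64.0, rng=4), fwd)
        # channel is the envelope delayed by 3 samples (up to z-score normalization)
        assert np.allclose(zscore(eeg.data[0, 3:]), zscore(env.values[:-3]), atol=1e-9)

    def test_kernel_span_limited_to_250ms(self):
        too_long = np.zeros((1, 30))  # > 17 lags at 64 Hz
        with pytest.raises(InvalidInputError, match="250"):
            ForwardModel(too_long, too_long)

    def test_gain_ordering_enforced(self):
        k = np.zeros((1, 4))
        with pytest.raises(InvalidInputError):
            ForwardModel(k, k, gain_att=0.2, gain_ign=0.5)


class TestGenerateSession:
    def test_default_trial_structure(self):
        plan = SessionPlan()
        session = generate_session(plan, ForwardModel.default(rng=0), rng_seed=0)
        assert len(session.trials) == 30
        assert session.roles.count("construction") == 14
        assert session.roles.count("test_fixed") == 12
        assert session.roles.count("test_switching") == 4
        constr_sides = [t.schedule.segments[0][2] for t in session.trials[:14]]
        assert constr_sides.count("left") == 7

    def test_same_seed_is_reproducible(self):
        plan = SessionPlan(n_construction=2, n_test_fixed=2, n_test_switching=0,
                           spec=WindowSpec(5, 1, 10))
        fwd = ForwardModel.default(n_channels=4, rng=1)
        a = generate_session(plan, fwd, rng_seed=42)
        b = generate_session(plan, fwd, rng_seed=42)
        for ta, tb in zip(a.trials, b.trials):
            assert np.array_equal(ta.eeg.data, tb.eeg.data)
            assert np.array_equal(ta.env_left.values, tb.env_left.values)

    def test_odd_construction_count_with_balance_required(self):
        plan = SessionPlan(n_construction=3, n_test_fixed=2, n_test_switching=0,
                           spec=WindowSpec(5, 1, 10))
        with pytest.raises(BalanceError):
            generate_session(plan, ForwardModel.default(n_channels=4, rng=0),
                             rng_seed=0, require_balanced_construction=True)

    def test_switching_trial_follows_schedule(self):
        # noiseless, delta kernel: EEG tracks whichever stream is attended
        rng = np.random.default_rng(8)
        env_l = generate_envelope(20.0, 64.0, rng, side="left")
        env_r = generate_envelope(20.0, 64.0, rng, side="right")
        kernel = np.zeros((1, 1))
        kernel[0, 0] = 1.0
        fwd = ForwardModel(kernel, kernel, gain_att=1.0, gain_ign=0.0, noise_sd=0.0)
        sched = AttentionSchedule.switching("left", 20.0, 10.0)
        trial = simulate_trial(env_l, env_r, sched, fwd, rng)
        first, second = trial.eeg.data[0, :640], trial.eeg.data[0, 640:]
        assert np.corrcoef(first, env_l.values[:640])[0, 1] > 0.99
        assert np.corrcoef(second, env_r.values[640:])[0, 1] > 0.99


class TestEndToEnd:
    def test_accuracy_monotone_in_attended_ignored_gain_ratio(self):
        spec = WindowSpec(15, 3, 60)
        plan = SessionPlan(n_construction=6, n_test_fixed=6, n_test_switching=0, spec=spec)
        mean_acc = []
        for gain_ign in (0.9, 0.4, 0.1):  # decreasing => easier
            accs = []
            for seed in range(5):
                base = ForwardModel.default(n_channels=8, rng=seed, gain_ign=gain_ign)
                # mirrored kernels: separation governed purely by the gain ratio
                fwd = ForwardModel(base.kernels_att, base.kernels_att.copy(),
                                   gain_att=1.0, gain_ign=gain_ign,
                                   noise_sd=base.noise_sd)
                session = generate_session(plan, fwd, rng_seed=seed)
                res = run_online_session(plan, session.trials, ks=(1,), build_biased=False)
                accs.append(100.0 * res.records["correct"].mean())
            mean_acc.append(np.mean(accs))
        assert mean_acc[2] > mean_acc[0]
        for lo, hi in zip(mean_acc, mean_acc[1:]):
            assert hi >= lo - 2.0  # non-decreasing up to sampling error

    def test_default_session_beats_chance(self, experiment_session, experiment_result):
        from oaad.detection import binomial_chance_level, evaluate_accuracy

        df = experiment_result.records
        single = df[(df.model == "single") & (df.k == 1)]
        assert evaluate_accuracy(single) > binomial_chance_level(len(single), 0.5)
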