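"""Synthetic dichotic-listening sessions with a known forward model.

EEG is generated as a lagged linear response to the attended speech
envelope (strong gain) plus the ignored envelope (weak gain) plus noise,
embodying the premise that attended speech is represented more strongly in
cortex than ignored speech. Envelopes are speech-like 2-8 Hz amplitude
modulations; sessions follow the online-experiment trial structure
(attention-fixed construction trials, then fixed and mid-trial-switching
test trials) or the 30-trial simulation layout. Everything is reproducible
from a seed, so decoder construction, streaming and detection are testable
end-to-end without real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import BalanceError, InvalidInputError
from .online_model import AttentionSchedule, TrialData
from .preprocessing import EegSegment, EnvelopeSignal, resample, zscore
from .streaming import SessionPlan

__all__ = [
    "ForwardModel",
    "SimulatedSession",
    "generate_envelope",
    "simulate_eeg",
    "simulate_trial",
    "generate_session",
    "to_raw_rate",
]

MAX_KERNEL_MS = 250.0


@dataclass
class ForwardModel:
    """Lagged linear envelope-to-EEG generative model.

    Each channel responds to the attended envelope through
    ``gain_att * kernels_att[n]`` and to the ignored envelope through
    ``gain_ign * kernels_ign[n]`` (causal convolution over lags within
    0-250 ms), plus white Gaussian noise of ``noise_sd``. Channels are
    z-scored afterwards. ``spatial_gain`` optionally scales each channel's
    attended response by a side-specific topography, giving left- and
    right-attended states distinguishable spatial patterns (the premise
    behind direction-biased decoders).
    """

    kernels_att: np.ndarray
    kernels_ign: np.ndarray
    gain_att: float = 1.0
    gain_ign: float = 0.4
    noise_sd: float = 300.0
    rate_hz: float = 64.0
    spatial_gain: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.kernels_att = np.atleast_2d(np.asarray(self.kernels_att, dtype=float))
        self.kernels_ign = np.atleast_2d(np.asarray(self.kernels_ign, dtype=float))
        if self.kernels_att.shape != self.kernels_ign.shape:
            raise InvalidInputError("attended and ignored kernel shapes differ")
        max_lags = int(np.floor(MAX_KERNEL_MS * self.rate_hz / 1000.0)) + 1
        if self.kernels_att.shape[1] > max_lags:
            raise InvalidInputError(
                f"kernel span {self.kernels_att.shape[1]} lags exceeds "
                f"{MAX_KERNEL_MS} ms ({max_lags} lags at {self.rate_hz} Hz)"
            )
        if not self.gain_att >= self.gain_ign >= 0:
            raise InvalidInputError("gains must satisfy gain_att >= gain_ign >= 0")

    @property
    def n_channels(self) -> int:
        return self.kernels_att.shape[0]

    @classmethod
    def default(
        cls,
        n_channels: int = 16,
        rng: np.random.Generator | int | None = 0,
        rate_hz: float = 64.0,
        spatial: bool = False,
        latency_jitter_s: float = 0.04,
        **overrides,
    ) -> "ForwardModel":
        """Tri-phasic envelope-following kernels with channel-varying gain.

        Each channel's kernel is a P1-N1-P2-like succession of Gaussian
        components near 50, 100 and 180 ms (dominant deflection near
        100 ms), with per-channel random amplitude, polarity and latency
        jitter (sd ``latency_jitter_s``) emulating the spread of response
        latencies across the scalp. The resulting multichannel response is
        broadband over the 2-8 Hz envelope band, so a lag-limited backward
        decoder can invert it. With ``spatial=True`` the attended response
        additionally carries a side-dependent channel topography (two
        half-montage gain profiles), so left- and right-attended trials
        differ spatially.
        """
        rng = np.random.default_rng(rng)
        n_lags = int(np.floor(MAX_KERNEL_MS * rate_hz / 1000.0)) + 1
        t = np.arange(n_lags) / rate_hz

        def channel_kernels() -> np.ndarray:
            ks = []
            for _ in range(n_channels):
                j = rng.normal(0.0, latency_jitter_s)
                amp = rng.normal(1.0, 0.3) * rng.choice([-1, 1])

                def bump(mu: float, sd: float) -> np.ndarray:
                    return np.exp(-0.5 * ((t - mu - j) / sd) ** 2)

                ks.append(
                    amp
                    * (0.6 * bump(0.05, 0.02) - 1.0 * bump(0.10, 0.025) + 0.5 * bump(0.18, 0.03))
                )
            return np.array(ks)

        spatial_gain = None
        if spatial:
            half = n_channels // 2
            left = np.ones(n_channels)
            right = np.ones(n_channels)
            left[:half] *= 1.6
            left[half:] *= 0.4
            right[:half] *= 0.4
            right[half:] *= 1.6
            spatial_gain = {"left": left, "right": right}
        return cls(
            kernels_att=channel_kernels(),
            kernels_ign=channel_kernels(),
            rate_hz=rate_hz,
            spatial_gain=spatial_gain,
            **overrides,
        )


def generate_envelope(
    duration_s: float,
    rate_hz: float = 64.0,
    rng: np.random.Generator | int | None = None,
    side: str | None = None,
    trial_id: str | None = None,
) -> EnvelopeSignal:
    """Speech-like envelope: rectified low-passed noise, band-limited to 2-8 Hz.

    Gaussian noise is low-pass filtered at 8 Hz, full-wave rectified (speech
    envelopes are non-negative power signals), band-passed to 2-8 Hz so the
    modulation content matches preprocessed speech envelopes, and z-scored.
    """
    if duration_s <= 0:
        raise InvalidInputError("duration must be positive")
    rng = np.random.default_rng(rng)
    n = int(round(duration_s * rate_hz))
    x = rng.standard_normal(n)
    sos_lp = signal.butter(4, 8.0, btype="lowpass", fs=rate_hz, output="sos")
    x = signal.sosfiltfilt(sos_lp, x)
    x = np.abs(x)
    # steep band edges keep sub-2 Hz leakage negligible
    sos_bp = signal.butter(8, [2.0, 8.0], btype="bandpass", fs=rate_hz, output="sos")
    x = signal.sosfiltfilt(sos_bp, x)
    return EnvelopeSignal(values=zscore(x), env_rate_hz=rate_hz, side=side, trial_id=trial_id)


def _convolve_channels(env: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Causal per-channel convolution of one envelope, truncated to its length."""
    n = env.size
    return np.stack([np.convolve(env, k)[:n] for k in kernels])


def simulate_eeg(
    env_att: EnvelopeSignal,
    env_ign: EnvelopeSignal,
    forward: ForwardModel,
    rng: np.random.Generator | int | None = None,
    att_side: np.ndarray | str | None = None,
    trial_id: str | None = None,
) -> EegSegment:
    """Generate one trial's EEG from attended and ignored envelopes.

    ``att_side`` (a side name, or a per-sample array of sides for
    attention-switching trials) selects the spatial topography applied to
    the attended response when the forward model has one.
    """
    if len(env_att) != len(env_ign):
        raise InvalidInputError("attended and ignored envelopes differ in length")
    rng = np.random.default_rng(rng)
    att = _convolve_channels(env_att.values, forward.kernels_att)
    ign = _convolve_channels(env_ign.values, forward.kernels_ign)
    if forward.spatial_gain is not None and att_side is not None:
        if isinstance(att_side, str):
            att = forward.spatial_gain[att_side][:, None] * att
        else:
            gain = np.stack([forward.spatial_gain[s] for s in att_side], axis=1)
            att = gain * att
    data = forward.gain_att * att + forward.gain_ign * ign
    if forward.noise_sd > 0:
        data = data + forward.noise_sd * rng.standard_normal(data.shape)
    return EegSegment(
        data=zscore(data, axis=1),
        rate_hz=forward.rate_hz,
        eog_mask=np.zeros(forward.n_channels, dtype=bool),
        trial_id=trial_id,
    )


def simulate_trial(
    env_left: EnvelopeSignal,
    env_right: EnvelopeSignal,
    schedule: AttentionSchedule,
    forward: ForwardModel,
    rng: np.random.Generator | int | None = None,
    trial_id: str = "",
) -> TrialData:
    """Assemble a trial whose attended stream follows the schedule.

    For switching schedules the attended/ignored composite envelopes swap
    roles at the transition before convolution, so the EEG tracks whichever
    stream is currently attended.
    """
    n = len(env_left)
    rate = env_left.env_rate_hz
    times = np.arange(n) / rate
    sides = np.array([schedule.side_at(t) for t in times])
    left_attended = sides == "left"
    att = np.where(left_attended, env_left.values, env_right.values)
    ign = np.where(left_attended, env_right.values, env_left.values)
    eeg = simulate_eeg(
        EnvelopeSignal(att, rate),
        EnvelopeSignal(ign, rate),
        forward,
        rng,
        att_side=sides if not schedule.is_fixed else sides[0],
        trial_id=trial_id,
    )
    return TrialData(eeg=eeg, env_left=env_left, env_right=env_right, schedule=schedule, trial_id=trial_id)


@dataclass
class SimulatedSession:
    """A full synthetic session plus the generative ground truth."""

    plan: SessionPlan
    trials: list[TrialData]
    forward: ForwardModel
    seed: int | None = None
    roles: list[str] = field(default_factory=list)


def _balanced_sides(n: int, rng: np.random.Generator) -> list[str]:
    sides = ["left", "right"] * (n // 2)
    if n % 2:
        sides.append(str(rng.choice(["left", "right"])))
    perm = rng.permutation(len(sides))
    return [sides[i] for i in perm]


def generate_session(
    plan: SessionPlan,
    forward: ForwardModel,
    rng_seed: int | None = 0,
    require_balanced_construction: bool = False,
) -> SimulatedSession:
    """Generate a reproducible session following the plan's trial structure.

    Construction trials are attention-fixed with balanced sides when their
    count is even; an odd construction count is an error when balance is
    required, as it is for direction-biased models. Test sides are
    balanced; switching trials change sides at ``plan.transition_s``.
    """
    rng = np.random.default_rng(rng_seed)
    spec = plan.spec
    T = spec.trial_len_s
    if require_balanced_construction and plan.n_construction % 2:
        raise BalanceError(
            f"{plan.n_construction} construction trials cannot balance left/right "
            "for direction-biased models"
        )
    constr_sides = _balanced_sides(plan.n_construction, rng)
    fixed_sides = _balanced_sides(plan.n_test_fixed, rng)
    switch_sides = _balanced_sides(plan.n_test_switching, rng)

    trials: list[TrialData] = []
    roles: list[str] = []

    def make_trial(trial_id: str, schedule: AttentionSchedule) -> TrialData:
        env_l = generate_envelope(T, spec.rate_hz, rng, side="left", trial_id=trial_id)
        env_r = generate_envelope(T, spec.rate_hz, rng, side="right", trial_id=trial_id)
        return simulate_trial(env_l, env_r, schedule, forward, rng, trial_id=trial_id)

    for i, side in enumerate(constr_sides):
        trials.append(make_trial(f"c{i + 1:02d}", AttentionSchedule.fixed(side, T)))
        roles.append("construction")
    for i, side in enumerate(fixed_sides):
        trials.append(make_trial(f"t{i + 1:02d}", AttentionSchedule.fixed(side, T)))
        roles.append("test_fixed")
    for i, side in enumerate(switch_sides):
        sched = AttentionSchedule.switching(side, T, plan.transition_s)
        trials.append(make_trial(f"s{i + 1:02d}", sched))
        roles.append("test_switching")

    return SimulatedSession(plan=plan, trials=trials, forward=forward, seed=rng_seed, roles=roles)


def to_raw_rate(
    eeg: EegSegment,
    raw_rate_hz: float = 1000.0,
    rng: np.random.Generator | int | None = None,
    broadband_noise_sd: float = 0.0,
) -> EegSegment:
    """Upsample a 64 Hz synthetic trial to an acquisition rate.

    Used to exercise the causal online preprocessing chain (CAR, FIR
    band-pass, downsampling) on synthetic data; optional broadband noise
    emulates out-of-band acquisition content the chain must reject.
    """
    data = resample(eeg.data, eeg.rate_hz, raw_rate_hz, axis=1)
    if broadband_noise_sd > 0:
        rng = np.random.default_rng(rng)
        data = data + broadband_noise_sd * rng.standard_normal(data.shape)
    return EegSegment(
        data=data,
        rate_hz=raw_rate_hz,
        channel_labels=list(eeg.channel_labels),
        eog_mask=eeg.eog_mask.copy(),
        trial_id=eeg.trial_id,
    )
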