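"""Sliding-window online decoder construction.

A trial of length T seconds is cut into J = floor((T - W + 1) / M)
overlapping snippets of W seconds hopped by M seconds. One ridge decoder
is fitted per snippet against the attended envelope, and the online model
is the unweighted mean of all I * J snippet decoders over the I
construction trials. Direction-biased models average only the trials on
which attention was held to one fixed side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decoder import Decoder, LagGrid, build_lagged_matrix, ridge_solve
from .errors import BalanceError, InvalidInputError
from .preprocessing import EegSegment, EnvelopeSignal

__all__ = [
    "WindowSpec",
    "AttentionSchedule",
    "TrialData",
    "snippet_bounds",
    "snippet_count",
    "fit_online_decoder",
    "fit_biased_decoders",
]

_EPS = 1e-9  # guards float jitter in seconds-domain window arithmetic


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: window W, hop M and trial length T in seconds."""

    window_s: float = 15.0
    hop_s: float = 1.0
    trial_len_s: float = 60.0
    rate_hz: float = 64.0

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.hop_s <= 0 or self.trial_len_s <= 0:
            raise InvalidInputError("window, hop and trial length must be positive")
        if self.window_s > self.trial_len_s:
            raise InvalidInputError("window size W exceeds trial length T")
        for name, secs in (("window_s", self.window_s), ("hop_s", self.hop_s)):
            n = secs * self.rate_hz
            if abs(n - round(n)) > _EPS:
                raise InvalidInputError(f"{name}={secs} s is not an integer sample count")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_s * self.rate_hz))

    @property
    def hop_samples(self) -> int:
        return int(round(self.hop_s * self.rate_hz))

    @property
    def n_snippets(self) -> int:
        return snippet_count(self)

    def detection_time_s(self, j: int) -> float:
        """Timestamp (j - 1) * M + W at which snippet j's decision is emitted."""
        return (j - 1) * self.hop_s + self.window_s


def snippet_count(spec: WindowSpec) -> int:
    """Number of W-second windows hopped by M that fit in a T-second trial.

    J = floor((T - W) / M) + 1, in the seconds domain: the count of start
    positions (j - 1) * M with (j - 1) * M + W <= T. At M = 1 this equals
    floor(T - W + 1) (46 snippets for T=60, W=15), and W = T gives J = 1
    for any hop.
    """
    return int(np.floor((spec.trial_len_s - spec.window_s + _EPS) / spec.hop_s)) + 1


def snippet_bounds(spec: WindowSpec, j: int) -> tuple[int, int]:
    """Half-open 0-based sample interval of the j-th (1-based) snippet."""
    J = snippet_count(spec)
    if not 1 <= j <= J:
        raise IndexError(f"snippet index {j} outside 1..{J}")
    start = (j - 1) * spec.hop_samples
    return start, start + spec.window_samples


@dataclass
class AttentionSchedule:
    """Attended side as a step function of trial time.

    ``segments`` is a list of (start_s, end_s, side) covering [0, T]
    contiguously; attention-fixed trials have one segment, switching trials
    two with the boundary near the trial midpoint.
    """

    segments: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        if not self.segments:
            raise InvalidInputError("schedule has no segments")
        prev_end = None
        for start, end, side in self.segments:
            if side not in ("left", "right"):
                raise InvalidInputError(f"unknown side {side!r}")
            if end <= start:
                raise InvalidInputError("segment end must exceed start")
            if prev_end is not None and abs(start - prev_end) > _EPS:
                raise InvalidInputError("segments must be contiguous")
            prev_end = end

    @classmethod
    def fixed(cls, side: str, trial_len_s: float = 60.0) -> "AttentionSchedule":
        return cls([(0.0, trial_len_s, side)])

    @classmethod
    def switching(
        cls, first_side: str, trial_len_s: float = 60.0, transition_s: float = 30.0
    ) -> "AttentionSchedule":
        other = "right" if first_side == "left" else "left"
        return cls([(0.0, transition_s, first_side), (transition_s, trial_len_s, other)])

    @property
    def is_fixed(self) -> bool:
        return len(self.segments) == 1

    @property
    def start_s(self) -> float:
        return self.segments[0][0]

    @property
    def end_s(self) -> float:
        return self.segments[-1][1]

    def side_at(self, t_s: float) -> str:
        """Scheduled side at time t (segments are closed-open, last closed)."""
        for start, end, side in self.segments:
            if start - _EPS <= t_s < end - _EPS:
                return side
        if abs(t_s - self.end_s) <= 1e-6 or t_s >= self.end_s:
            return self.segments[-1][2]
        raise InvalidInputError(f"time {t_s} s outside schedule [{self.start_s}, {self.end_s}]")


@dataclass
class TrialData:
    """One trial: EEG at 64 Hz, both speech envelopes, and the ground truth."""

    eeg: EegSegment
    env_left: EnvelopeSignal
    env_right: EnvelopeSignal
    schedule: AttentionSchedule
    trial_id: str = ""

    def __post_init__(self) -> None:
        n = self.eeg.n_samples
        if len(self.env_left) != n or len(self.env_right) != n:
            raise InvalidInputError("EEG and envelope lengths differ")

    @property
    def n_samples(self) -> int:
        return self.eeg.n_samples

    def envelope(self, side: str) -> EnvelopeSignal:
        return self.env_left if side == "left" else self.env_right


def snippet_weight_matrix(
    trial: TrialData,
    spec: WindowSpec,
    j: int,
    lag_grid: LagGrid,
    lambda_reg: float,
    target_side: str,
) -> np.ndarray:
    """Fit the j-th snippet's decoder weights (lags x channels) for one trial."""
    start, stop = snippet_bounds(spec, j)
    X = build_lagged_matrix(trial.eeg.data[:, start:stop], lag_grid)
    s = trial.envelope(target_side).values[start:stop]
    w = ridge_solve(X, s, lambda_reg)
    return w.reshape(lag_grid.n_lags, trial.eeg.n_channels)


def _attended_side(trial: TrialData) -> str:
    if not trial.schedule.is_fixed:
        raise InvalidInputError(
            f"trial {trial.trial_id!r} is attention-switching; construction "
            "requires a single attended side per trial"
        )
    return trial.schedule.segments[0][2]


def fit_online_decoder(
    trials: list[TrialData],
    spec: WindowSpec,
    lag_grid: LagGrid | None = None,
    lambda_reg: float = 10.0,
    bias: str = "none",
) -> Decoder:
    """Average the I * J per-snippet ridge decoders of attention-fixed trials.

    Each snippet decoder regresses the attended envelope on the lag-expanded
    EEG of its window; the online model is their unweighted arithmetic mean,
    accumulated as a running sum so storage stays O(1) in J.
    """
    if not trials:
        raise InvalidInputError("at least one construction trial required")
    lag_grid = lag_grid or LagGrid(rate_hz=spec.rate_hz)
    J = snippet_count(spec)
    total = np.zeros((lag_grid.n_lags, trials[0].eeg.n_channels))
    for trial in trials:
        side = _attended_side(trial)
        for j in range(1, J + 1):
            total += snippet_weight_matrix(trial, spec, j, lag_grid, lambda_reg, side)
    n = len(trials) * J
    return Decoder(
        weights=total / n,
        lag_grid=lag_grid,
        lambda_reg=lambda_reg,
        n_channels=trials[0].eeg.n_channels,
        meta={"n_trials": len(trials), "n_snippets_per_trial": J, "bias": bias},
    )


def fit_biased_decoders(
    trials: list[TrialData],
    spec: WindowSpec,
    lag_grid: LagGrid | None = None,
    lambda_reg: float = 10.0,
) -> tuple[Decoder, Decoder]:
    """Left- and right-biased decoders from the side-partitioned trials.

    Each biased model averages snippet decoders from trials attended to one
    side only, so the pair together uses the same total trial count as the
    single model.
    """
    left = [t for t in trials if _attended_side(t) == "left"]
    right = [t for t in trials if _attended_side(t) == "right"]
    missing = [s for s, grp in (("left", left), ("right", right)) if not grp]
    if missing:
        raise BalanceError(f"no construction trials attended to the {missing[0]} side")
    d_left = fit_online_decoder(left, spec, lag_grid, lambda_reg, bias="left")
    d_right = fit_online_decoder(right, spec, lag_grid, lambda_reg, bias="right")
    return d_left, d_right
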