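"""Emulation of the online dichotic-listening session.

EEG arrives in M-second blocks and accumulates in a per-trial buffer. The
first phase of the session streams attention-fixed construction trials and
fits each snippet decoder as soon as its window of data is available,
accumulating the running sums that define the single and direction-biased
online models. The test phase then emits one detection per hop for every
model and smoothing width. Wall-clock time is virtual: arrival timestamps
are bookkeeping, so runs are deterministic and the streamed outputs are
bit-identical to a batch execution on the same data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .decoder import Decoder, LagGrid, build_lagged_matrix
from .detection import (
    DetectionRecord,
    decide_series,
    correlate_snippet,
    records_to_frame,
    smooth_correlations,
)
from .errors import BalanceError, InvalidInputError, SessionOrderError
from .online_model import (
    TrialData,
    WindowSpec,
    fit_biased_decoders,
    fit_online_decoder,
    snippet_bounds,
    snippet_count,
    snippet_weight_matrix,
)
from .preprocessing import EegSegment

__all__ = [
    "SessionPlan",
    "StreamBuffer",
    "SessionResult",
    "stream_blocks",
    "detect_trial",
    "run_online_session",
]


@dataclass(frozen=True)
class SessionPlan:
    """Trial roles and geometry of one online session.

    The experiment layout is 14 attention-fixed construction trials
    (balanced 7 left / 7 right for the biased models) followed by 12
    attention-fixed and 4 attention-switching test trials with sides
    balanced 8/8. ``simulation()`` gives the offline-simulation layout of
    30 attention-fixed trials with up to 15 used for construction.
    """

    n_construction: int = 14
    n_test_fixed: int = 12
    n_test_switching: int = 4
    spec: WindowSpec = field(default_factory=WindowSpec)
    block_s: float | None = None
    transition_s: float = 30.0

    @property
    def n_trials(self) -> int:
        return self.n_construction + self.n_test_fixed + self.n_test_switching

    @property
    def block_seconds(self) -> float:
        return self.spec.hop_s if self.block_s is None else self.block_s

    @classmethod
    def simulation(cls, n_construction: int = 15, n_test: int = 15, **kw) -> "SessionPlan":
        return cls(n_construction=n_construction, n_test_fixed=n_test, n_test_switching=0, **kw)


class StreamBuffer:
    """Accumulates raw blocks for the current trial; resets at trial onset."""

    def __init__(self, rate_hz: float) -> None:
        self.rate_hz = rate_hz
        self._blocks: list[np.ndarray] = []
        self.clock_s = 0.0

    def append(self, block: np.ndarray, arrival_s: float) -> None:
        self._blocks.append(np.atleast_2d(block))
        self.clock_s = arrival_s

    @property
    def n_samples(self) -> int:
        return sum(b.shape[1] for b in self._blocks)

    @property
    def data(self) -> np.ndarray:
        return np.concatenate(self._blocks, axis=1)

    def reset(self) -> None:
        self._blocks.clear()
        self.clock_s = 0.0


def stream_blocks(
    eeg: EegSegment | TrialData, block_s: float
) -> Iterator[tuple[float, np.ndarray]]:
    """Yield consecutive non-overlapping M-second blocks with arrival times.

    The arrival timestamp of a block is the trial time at which its last
    sample exists. A final partial block (trial length not a multiple of
    the block size) is dropped with a warning.
    """
    seg = eeg.eeg if isinstance(eeg, TrialData) else eeg
    n_block = int(round(block_s * seg.rate_hz))
    n_full = seg.n_samples // n_block
    if seg.n_samples % n_block:
        warnings.warn("trial length is not a multiple of the block size; final partial block dropped")
    for b in range(n_full):
        yield (b + 1) * block_s, seg.data[:, b * n_block : (b + 1) * n_block]


@dataclass
class SessionResult:
    """Decoders and detection records produced by one session run."""

    single: Decoder
    biased_left: Decoder | None
    biased_right: Decoder | None
    records: pd.DataFrame


def _trial_type(trial: TrialData) -> str:
    return "fixed" if trial.schedule.is_fixed else "switching"


def detect_trial(
    trial: TrialData,
    models: dict[str, Decoder | dict[str, Decoder]],
    spec: WindowSpec,
    ks: tuple[int, ...] = (1, 3, 5, 7),
) -> list[DetectionRecord]:
    """Per-snippet detections on one test trial for every model and width k.

    ``models`` maps a model name to either a single decoder or a
    {"left", "right"} pair of direction-biased decoders; a biased pair is
    evaluated matched-side, i.e. each snippet uses the decoder whose bias
    equals the scheduled attended side at the detection timestamp.
    """
    J = snippet_count(spec)
    t_type = _trial_type(trial)
    records: list[DetectionRecord] = []
    for name, model in models.items():
        r_l = np.empty(J)
        r_r = np.empty(J)
        truths: list[str] = []
        for j in range(1, J + 1):
            start, stop = snippet_bounds(spec, j)
            truth = trial.schedule.side_at(spec.detection_time_s(j))
            truths.append(truth)
            dec = model[truth] if isinstance(model, dict) else model
            X = build_lagged_matrix(trial.eeg.data[:, start:stop], dec.lag_grid)
            s_hat = dec.flat_weights @ X
            r_l[j - 1] = correlate_snippet(s_hat, trial.env_left.values[start:stop])
            r_r[j - 1] = correlate_snippet(s_hat, trial.env_right.values[start:stop])
        for k in ks:
            sl = smooth_correlations(r_l, k)
            sr = smooth_correlations(r_r, k)
            decisions = decide_series(sl, sr)
            for j in range(1, J + 1):
                records.append(
                    DetectionRecord(
                        trial_id=trial.trial_id,
                        j=j,
                        time_s=spec.detection_time_s(j),
                        r_left=r_l[j - 1],
                        r_right=r_r[j - 1],
                        r_left_smooth=sl[j - 1],
                        r_right_smooth=sr[j - 1],
                        decided_side=decisions[j - 1],
                        truth_side=truths[j - 1],
                        correct=decisions[j - 1] == truths[j - 1],
                        model=name,
                        k=k,
                        trial_type=t_type,
                    )
                )
    return records


def _streamed_construction(
    trials: list[TrialData],
    spec: WindowSpec,
    lag_grid: LagGrid,
    lambda_reg: float,
    build_biased: bool,
) -> tuple[Decoder, Decoder | None, Decoder | None]:
    """Fit construction-phase decoders incrementally from streamed blocks."""
    J = snippet_count(spec)
    n_ch = trials[0].eeg.n_channels
    shape = (lag_grid.n_lags, n_ch)
    total = np.zeros(shape)
    side_totals = {"left": np.zeros(shape), "right": np.zeros(shape)}
    side_counts = {"left": 0, "right": 0}
    for trial in trials:
        side = trial.schedule.segments[0][2]
        side_counts[side] += 1
        buffer = StreamBuffer(spec.rate_hz)
        next_j = 1
        for arrival_s, block in stream_blocks(trial, spec.hop_s):
            buffer.append(block, arrival_s)
            while next_j <= J and snippet_bounds(spec, next_j)[1] <= buffer.n_samples:
                w = snippet_weight_matrix(trial, spec, next_j, lag_grid, lambda_reg, side)
                total += w
                side_totals[side] += w
                next_j += 1
    single = Decoder(
        weights=total / (len(trials) * J),
        lag_grid=lag_grid,
        lambda_reg=lambda_reg,
        n_channels=n_ch,
        meta={"n_trials": len(trials), "n_snippets_per_trial": J, "bias": "none"},
    )
    if not build_biased:
        return single, None, None
    missing = [s for s in ("left", "right") if side_counts[s] == 0]
    if missing:
        raise BalanceError(f"no construction trials attended to the {missing[0]} side")
    biased = {
        s: Decoder(
            weights=side_totals[s] / (side_counts[s] * J),
            lag_grid=lag_grid,
            lambda_reg=lambda_reg,
            n_channels=n_ch,
            meta={"n_trials": side_counts[s], "n_snippets_per_trial": J, "bias": s},
        )
        for s in ("left", "right")
    }
    return single, biased["left"], biased["right"]


def run_online_session(
    plan: SessionPlan,
    trials: list[TrialData],
    lag_grid: LagGrid | None = None,
    lambda_reg: float = 10.0,
    ks: tuple[int, ...] = (1, 3, 5, 7),
    build_biased: bool = True,
    streamed: bool = True,
) -> SessionResult:
    """Run one full session: construction on streamed blocks, then testing.

    With ``streamed=False`` the decoders are fitted in one batch pass; the
    two paths execute the same snippet fits in the same order and produce
    bit-identical decoders and records.
    """
    if len(trials) != plan.n_trials:
        raise InvalidInputError(f"plan expects {plan.n_trials} trials, got {len(trials)}")
    construction = trials[: plan.n_construction]
    test = trials[plan.n_construction :]
    if not construction:
        raise SessionOrderError("session has no construction trials before testing")
    for t in construction:
        if not t.schedule.is_fixed:
            raise SessionOrderError(
                f"construction trial {t.trial_id!r} is attention-switching; "
                "the construction phase must precede all switching trials"
            )
    spec = plan.spec
    lag_grid = lag_grid or LagGrid(rate_hz=spec.rate_hz)

    if streamed:
        single, d_left, d_right = _streamed_construction(
            construction, spec, lag_grid, lambda_reg, build_biased
        )
    else:
        single = fit_online_decoder(construction, spec, lag_grid, lambda_reg)
        d_left = d_right = None
        if build_biased:
            d_left, d_right = fit_biased_decoders(construction, spec, lag_grid, lambda_reg)

    models: dict[str, Decoder | dict[str, Decoder]] = {"single": single}
    if build_biased:
        models["biased"] = {"left": d_left, "right": d_right}

    records: list[DetectionRecord] = []
    for trial in test:
        records.extend(detect_trial(trial, models, spec, ks))
    return SessionResult(
        single=single,
        biased_left=d_left,
        biased_right=d_right,
        records=records_to_frame(records),
    )
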