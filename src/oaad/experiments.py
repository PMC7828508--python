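"""Parameter-grid evaluation of the online decoder.

Reproduces the simulation protocol: for every combination of window size W,
hop M and construction-trial count I, an online model is built on the
first I trials of each session and evaluated on all remaining trials, for
each correlation-smoothing width k and model type. Overlapping grid cells
share per-snippet decoder fits through a (W, window-start, trial) cache,
and smoothing widths are applied post hoc to the stored correlation
series, so the grid costs far less than naive per-cell refitting while
producing identical numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decoder import LagGrid, build_lagged_matrix, ridge_solve
from .detection import correlate_snippet, decide_series, smooth_correlations
from .errors import InvalidInputError
from .online_model import TrialData, WindowSpec, snippet_bounds, snippet_count
from .synthetic import SimulatedSession

__all__ = ["GridSpec", "grid_search", "summarize", "marginal"]


@dataclass(frozen=True)
class GridSpec:
    """Joint parameter space searched by the simulation protocol."""

    W_set: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0)
    M_set: tuple[float, ...] = (1.0, 3.0, 5.0, 7.0, 9.0)
    I_set: tuple[int, ...] = (1, 5, 10, 15)
    k_set: tuple[int, ...] = (1, 3, 5, 7)
    model_types: tuple[str, ...] = ("single",)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in (*self.W_set, *self.M_set, *self.I_set, *self.k_set)):
            raise InvalidInputError("all grid values must be positive")
        if "biased" in self.model_types and any(i % 2 for i in self.I_set):
            raise InvalidInputError(
                "direction-biased models need an even construction-trial count I "
                "to balance left and right trials"
            )


def _attended(trial: TrialData) -> str:
    return trial.schedule.segments[0][2]


def _session_trials(session) -> tuple[list[TrialData], int | None, int]:
    """Return (trials, subject label, construction trials available)."""
    if isinstance(session, SimulatedSession):
        label = session.seed
        return session.trials, label, session.plan.n_construction
    trials = list(session)
    return trials, None, len(trials) - 1


def grid_search(
    sessions: list,
    grid: GridSpec | None = None,
    lag_grid: LagGrid | None = None,
    lambda_reg: float = 10.0,
    stratify_trial_types: bool = False,
) -> pd.DataFrame:
    """Accuracy table over the {W, M, I} x {k} x {model type} grid.

    One row per session (subject), grid cell, smoothing width and model
    type, with columns (subject, W, M, I, k, model_type, trial_type,
    accuracy, n_records). With ``stratify_trial_types`` an extra row per
    trial type present is emitted alongside the pooled ``"all"`` row.
    Construction uses the first I trials in session order; evaluation uses
    every remaining trial.
    """
    grid = grid or GridSpec()
    rows: list[dict] = []
    for s_idx, session in enumerate(sessions):
        trials, label, n_avail = _session_trials(session)
        subject = label if label is not None else s_idx
        rate = trials[0].eeg.rate_hz
        T = trials[0].n_samples / rate
        lg = lag_grid or LagGrid(rate_hz=rate)
        n_ch = trials[0].eeg.n_channels

        cache: dict[tuple[float, int, int], np.ndarray] = {}

        def snippet_w(ti: int, W: float, start: int, stop: int) -> np.ndarray:
            key = (W, start, ti)
            if key not in cache:
                trial = trials[ti]
                X = build_lagged_matrix(trial.eeg.data[:, start:stop], lg)
                s = trial.envelope(_attended(trial)).values[start:stop]
                cache[key] = ridge_solve(X, s, lambda_reg)
            return cache[key]

        valid_I = []
        for I in grid.I_set:
            if I > n_avail:
                warnings.warn(f"I={I} exceeds the {n_avail} available construction trials; skipped")
            else:
                valid_I.append(I)
        if not valid_I:
            continue

        for W in grid.W_set:
            for M in grid.M_set:
                spec = WindowSpec(W, M, T, rate)
                J = snippet_count(spec)
                bounds = [snippet_bounds(spec, j) for j in range(1, J + 1)]
                trial_sums = np.stack(
                    [
                        np.sum([snippet_w(ti, W, a, b) for a, b in bounds], axis=0)
                        for ti in range(max(valid_I))
                    ]
                )
                prefix = np.cumsum(trial_sums, axis=0)
                for I in valid_I:
                    models: dict[str, np.ndarray | dict[str, np.ndarray]] = {}
                    if "single" in grid.model_types:
                        models["single"] = prefix[I - 1] / (I * J)
                    if "biased" in grid.model_types:
                        by_side: dict[str, list[int]] = {"left": [], "right": []}
                        for ti in range(I):
                            by_side[_attended(trials[ti])].append(ti)
                        if all(by_side.values()):
                            models["biased"] = {
                                s: trial_sums[ix].sum(axis=0) / (len(ix) * J)
                                for s, ix in by_side.items()
                            }
                        else:
                            warnings.warn(
                                f"I={I}: one attention side absent; biased cell skipped"
                            )
                    rows.extend(
                        _evaluate_cell(
                            trials[I:], models, spec, lg, grid.k_set,
                            subject, W, M, I, stratify_trial_types,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=["subject", "W", "M", "I", "k", "model_type", "trial_type", "accuracy", "n_records"],
    )


def _evaluate_cell(
    test_trials: list[TrialData],
    models: dict,
    spec: WindowSpec,
    lag_grid: LagGrid,
    k_set: tuple[int, ...],
    subject,
    W: float,
    M: float,
    I: int,
    stratify: bool,
) -> list[dict]:
    J = snippet_count(spec)
    # raw correlation series per (model, trial), smoothed per k afterwards
    per_model: dict[str, list[tuple[str, list[str], np.ndarray, np.ndarray]]] = {
        m: [] for m in models
    }
    for trial in test_trials:
        t_type = "fixed" if trial.schedule.is_fixed else "switching"
        truths = [trial.schedule.side_at(spec.detection_time_s(j)) for j in range(1, J + 1)]
        rs = {m: (np.empty(J), np.empty(J)) for m in models}
        for j in range(1, J + 1):
            start, stop = snippet_bounds(spec, j)
            X = build_lagged_matrix(trial.eeg.data[:, start:stop], lag_grid)
            env_l = trial.env_left.values[start:stop]
            env_r = trial.env_right.values[start:stop]
            for m, w in models.items():
                w_flat = (w[truths[j - 1]] if isinstance(w, dict) else w).reshape(-1)
                s_hat = w_flat @ X
                rs[m][0][j - 1] = correlate_snippet(s_hat, env_l)
                rs[m][1][j - 1] = correlate_snippet(s_hat, env_r)
        for m in models:
            per_model[m].append((t_type, truths, rs[m][0], rs[m][1]))

    rows = []
    for m, trial_results in per_model.items():
        for k in k_set:
            correct: dict[str, list[bool]] = {}
            for t_type, truths, r_l, r_r in trial_results:
                decisions = decide_series(smooth_correlations(r_l, k), smooth_correlations(r_r, k))
                correct.setdefault("all", []).extend(d == t for d, t in zip(decisions, truths))
                if stratify:
                    correct.setdefault(t_type, []).extend(
                        d == t for d, t in zip(decisions, truths)
                    )
            for t_type, flags in correct.items():
                rows.append(
                    dict(
                        subject=subject, W=W, M=M, I=I, k=k, model_type=m,
                        trial_type=t_type,
                        accuracy=100.0 * float(np.mean(flags)),
                        n_records=len(flags),
                    )
                )
    return rows


def summarize(
    table: pd.DataFrame,
    by: tuple[str, ...] = ("W", "M", "I", "k", "model_type", "trial_type"),
) -> pd.DataFrame:
    """Per-cell mean and sd of accuracy across subjects (sd with n-1 denominator)."""
    if len(table) == 0:
        raise InvalidInputError("empty result table")
    g = table.groupby(list(by), observed=True)["accuracy"]
    out = g.agg(accuracy_mean="mean", accuracy_sd=lambda a: a.std(ddof=1) if len(a) > 1 else 0.0)
    out["n_cells"] = g.size()
    return out.reset_index()


def marginal(table: pd.DataFrame, param: str) -> pd.DataFrame:
    """Accuracy collapsed onto one parameter (boxplot-style marginal)."""
    g = table.groupby(param, observed=True)["accuracy"]
    return g.agg(accuracy_mean="mean", accuracy_sd=lambda a: a.std(ddof=1) if len(a) > 1 else 0.0).reset_index()
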