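"""Backward (stimulus-reconstruction) ridge decoder.

A linear decoder D(tau, n) maps multichannel EEG R at post-stimulus lags
tau in [0, 250] ms back to the speech envelope S:

    S_hat(t) = sum_n sum_tau D(tau, n) R(t + tau, n)

Because cortical activity follows the stimulus, reconstruction of S(t)
uses EEG *after* t; lags are therefore applied as forward shifts of the
EEG, the standard backward-model convention. The weights are the ridge
(L2-regularised least squares) solution on the lag-expanded design matrix,

    D = (R R^T + lambda I)^(-1) R S^T

computed on the raw (unnormalised) covariance of z-scored data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .errors import InvalidInputError
from .preprocessing import EegSegment, EnvelopeSignal

__all__ = ["LagGrid", "Decoder", "build_lagged_matrix", "fit_ridge_decoder", "reconstruct"]


@dataclass(frozen=True)
class LagGrid:
    """Decoder lag range in milliseconds at a given sampling rate."""

    tau_min_ms: float = 0.0
    tau_max_ms: float = 250.0
    rate_hz: float = 64.0

    def __post_init__(self) -> None:
        if self.tau_max_ms < self.tau_min_ms:
            raise InvalidInputError("tau_max_ms < tau_min_ms")
        if self.rate_hz <= 0:
            raise InvalidInputError("rate_hz must be positive")

    @property
    def lags_samples(self) -> np.ndarray:
        lo = int(np.floor(self.tau_min_ms * self.rate_hz / 1000.0))
        hi = int(np.floor(self.tau_max_ms * self.rate_hz / 1000.0))
        return np.arange(lo, hi + 1)

    @property
    def n_lags(self) -> int:
        return self.lags_samples.size

    @classmethod
    def from_n_lags(cls, n_lags: int, rate_hz: float = 64.0) -> "LagGrid":
        """Grid of ``n_lags`` consecutive sample lags starting at zero."""
        return cls(0.0, (n_lags - 1) * 1000.0 / rate_hz, rate_hz)


@dataclass
class Decoder:
    """Fitted decoder weights, shape (n_lags, n_channels), with provenance."""

    weights: np.ndarray
    lag_grid: LagGrid
    lambda_reg: float
    n_channels: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.lag_grid.n_lags, self.n_channels):
            raise InvalidInputError(
                f"weights shape {self.weights.shape} != "
                f"({self.lag_grid.n_lags}, {self.n_channels})"
            )
        if self.lambda_reg < 0:
            raise InvalidInputError("lambda_reg must be >= 0")

    @property
    def flat_weights(self) -> np.ndarray:
        """Weights flattened lag-major, matching build_lagged_matrix rows."""
        return self.weights.reshape(-1)


def _as_channel_matrix(eeg: EegSegment | np.ndarray) -> np.ndarray:
    if isinstance(eeg, EegSegment):
        return eeg.data
    return np.atleast_2d(np.asarray(eeg, dtype=float))


def build_lagged_matrix(eeg: EegSegment | np.ndarray, lag_grid: LagGrid) -> np.ndarray:
    """Lag-expanded design matrix, shape (n_lags * n_channels, n_samples).

    Row (k, n) at column t holds R(t + tau_k, n): the EEG shifted so that
    each stimulus sample is regressed on the EEG that follows it. Samples
    shifted past the segment end are zero-padded. Rows are ordered
    lag-major: row index = k * n_channels + n.
    """
    data = _as_channel_matrix(eeg)
    n_ch, n_t = data.shape
    lags = lag_grid.lags_samples
    if n_t < lag_grid.n_lags:
        raise InvalidInputError(f"segment of {n_t} samples shorter than {lag_grid.n_lags} lags")
    out = np.zeros((lags.size * n_ch, n_t))
    for k, tau in enumerate(lags):
        block = out[k * n_ch : (k + 1) * n_ch]
        if tau == 0:
            block[:, :] = data
        elif tau > 0:
            block[:, : n_t - tau] = data[:, tau:]
        else:  # negative lag: shift the other way, pad at the start
            block[:, -tau:] = data[:, : n_t + tau]
    return out


def fit_ridge_decoder(
    design: np.ndarray,
    envelope: EnvelopeSignal | np.ndarray,
    lambda_reg: float = 10.0,
    lag_grid: LagGrid | None = None,
    n_channels: int | None = None,
    meta: dict | None = None,
) -> Decoder:
    """Ridge solution D = (X X^T + lambda I)^(-1) X s on a lagged design.

    ``lag_grid``/``n_channels`` describe how the design rows factor into
    (lag, channel); when omitted each row is treated as one channel at a
    single zero lag.
    """
    X = np.atleast_2d(np.asarray(design, dtype=float))
    s = envelope.values if isinstance(envelope, EnvelopeSignal) else np.asarray(envelope, float)
    s = np.ravel(s)
    if X.shape[1] != s.size:
        raise InvalidInputError(f"design has {X.shape[1]} columns, envelope {s.size} samples")
    if lag_grid is None:
        lag_grid = LagGrid.from_n_lags(1, rate_hz=64.0)
    if n_channels is None:
        n_channels = X.shape[0] // lag_grid.n_lags
    if lag_grid.n_lags * n_channels != X.shape[0]:
        raise InvalidInputError("n_lags * n_channels != design row count")

    w = ridge_solve(X, s, lambda_reg)
    return Decoder(
        weights=w.reshape(lag_grid.n_lags, n_channels),
        lag_grid=lag_grid,
        lambda_reg=lambda_reg,
        n_channels=n_channels,
        meta=meta or {},
    )


def ridge_solve(X: np.ndarray, s: np.ndarray, lambda_reg: float) -> np.ndarray:
    """Solve (X X^T + lambda I) w = X s; falls back to pseudo-inverse when singular."""
    G = X @ X.T
    if lambda_reg > 0:
        G = G + lambda_reg * np.eye(G.shape[0])
    b = X @ s
    try:
        w = linalg.solve(G, b, assume_a="sym")
        if not np.all(np.isfinite(w)):
            raise linalg.LinAlgError("non-finite solution")
    except (linalg.LinAlgError, ValueError):
        warnings.warn("singular normal equations; using pseudo-inverse solution")
        w = linalg.pinv(G) @ b
    return w


def reconstruct(decoder: Decoder, eeg: EegSegment | np.ndarray) -> EnvelopeSignal:
    """Reconstruct the envelope estimate S_hat from EEG with a fitted decoder.

    Uses the same lag and zero-padding conventions as build_lagged_matrix;
    the output is not re-z-scored.
    """
    data = _as_channel_matrix(eeg)
    if data.shape[0] != decoder.n_channels:
        raise InvalidInputError(
            f"EEG has {data.shape[0]} channels, decoder expects {decoder.n_channels}"
        )
    X = build_lagged_matrix(data, decoder.lag_grid)
    rate = eeg.rate_hz if isinstance(eeg, EegSegment) else decoder.lag_grid.rate_hz
    return EnvelopeSignal(values=decoder.flat_weights @ X, env_rate_hz=rate)
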