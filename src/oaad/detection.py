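"""Direction detection from reconstructed envelopes.

For each snippet the reconstructed envelope is Pearson-correlated with the
left and right speech envelopes; the larger (optionally causally smoothed)
coefficient decides the attended side, timestamped at the window end
(j - 1) * M + W. Accuracy is scored against the attention schedule, and
statistical chance level comes from the exact binomial test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError
from .preprocessing import EnvelopeSignal

__all__ = [
    "SmoothingSpec",
    "DetectionRecord",
    "correlate_snippet",
    "smooth_correlations",
    "decide_direction",
    "decide_series",
    "records_to_frame",
    "evaluate_accuracy",
    "binomial_chance_level",
]


@dataclass(frozen=True)
class SmoothingSpec:
    """Width k of the causal moving-average filter on correlation series."""

    k: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise InvalidInputError("smoothing width k must be >= 1")


@dataclass
class DetectionRecord:
    """One snippet's detection output for one model and smoothing width."""

    trial_id: str
    j: int
    time_s: float
    r_left: float
    r_right: float
    r_left_smooth: float
    r_right_smooth: float
    decided_side: str
    truth_side: str
    correct: bool
    model: str = "single"
    k: int = 1
    trial_type: str = "fixed"


def correlate_snippet(
    reconstructed: EnvelopeSignal | np.ndarray, actual: EnvelopeSignal | np.ndarray
) -> float:
    """Sample Pearson correlation; zero-variance input yields r = 0."""
    x = np.ravel(reconstructed.values if isinstance(reconstructed, EnvelopeSignal) else reconstructed)
    y = np.ravel(actual.values if isinstance(actual, EnvelopeSignal) else actual)
    if x.size != y.size:
        raise InvalidInputError("snippet lengths differ")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero-variance snippet; correlation defined as 0")
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def smooth_correlations(series: Sequence[float], spec: SmoothingSpec | int) -> np.ndarray:
    """Causal moving average over the trailing k values, current included.

    output[t] = mean(series[max(0, t - k + 1) .. t]); early samples with
    fewer than k predecessors average whatever is available, and smoothing
    never crosses trial boundaries (callers pass one trial's series).
    k = 1 is the identity.
    """
    k = spec.k if isinstance(spec, SmoothingSpec) else SmoothingSpec(spec).k
    x = np.asarray(series, dtype=float)
    if k == 1 or x.size == 0:
        return x.copy()
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(x.size)
    lo = np.maximum(0, idx - k + 1)
    return (csum[idx + 1] - csum[lo]) / (idx + 1 - lo)


def decide_direction(r_left: float, r_right: float, previous: str | None = None) -> str:
    """Larger correlation wins; exact tie repeats the previous decision, else left."""
    if r_left > r_right:
        return "left"
    if r_right > r_left:
        return "right"
    return previous if previous is not None else "left"


def decide_series(r_left: Iterable[float], r_right: Iterable[float]) -> list[str]:
    """Apply the decision rule along one trial's chronological snippet series."""
    out: list[str] = []
    prev: str | None = None
    for rl, rr in zip(r_left, r_right):
        prev = decide_direction(rl, rr, prev)
        out.append(prev)
    return out


def records_to_frame(records: Iterable[DetectionRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def evaluate_accuracy(
    records: pd.DataFrame | Iterable[DetectionRecord],
    by: Sequence[str] | None = None,
) -> float | pd.DataFrame:
    """Detection accuracy in percent, overall or stratified.

    With ``by=None`` returns 100 * #correct / #records over all rows;
    otherwise a DataFrame with accuracy and record counts per group (for
    example ``by=("model", "k", "trial_type")``).
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if len(df) == 0:
        raise InvalidInputError("no detection records; accuracy undefined")
    if by is None:
        return float(100.0 * df["correct"].mean())
    grouped = df.groupby(list(by), observed=True)["correct"]
    out = grouped.agg(accuracy=lambda c: 100.0 * c.mean(), n_records="size")
    return out.reset_index()


def binomial_chance_level(n: int, p: float = 0.5, alpha: float = 0.05) -> float:
    """Minimum accuracy (%) significantly above guessing by the exact binomial test.

    Returns 100 * k* / n where k* is the smallest success count whose exact
    binomial CDF reaches 1 - alpha (one-sided; no normal approximation).
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if not 0 < p < 1:
        raise InvalidInputError("p must lie in (0, 1)")
    if not 0 < alpha < 1:
        raise InvalidInputError("alpha must lie in (0, 1)")
    k = np.arange(n + 1)
    cdf = stats.binom.cdf(k, n, p)
    k_star = int(k[np.argmax(cdf >= 1 - alpha)])
    return 100.0 * k_star / n
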