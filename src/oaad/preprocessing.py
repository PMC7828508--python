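"""Audio and EEG preprocessing for envelope-based attention decoding.

Two chains are provided. The *offline* chain mirrors how recorded datasets
are conditioned after acquisition: high-pass, mains notch, common average
reference (CAR) excluding electro-oculogram (EOG) channels, zero-phase
2-8 Hz band-pass, anti-aliased resampling to 64 Hz and per-channel
z-scoring. The *online* chain is the minimal causal variant used when EEG
arrives in blocks: CAR, a causal 1650th-order linear-phase FIR band-pass
whose group delay (order/2 samples) is compensated by a timestamp shift,
resampling and z-scoring.

Speech envelopes are the power (squared magnitude) of the analytic signal
obtained by the Hilbert transform, resampled to 64 Hz and z-scored, which
keeps the 2-8 Hz amplitude modulations that cortical activity entrains to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "AudioSegment",
    "EnvelopeSignal",
    "EegSegment",
    "zscore",
    "common_average_reference",
    "extract_envelope",
    "preprocess_eeg_offline",
    "preprocess_eeg_online_block",
]


@dataclass
class AudioSegment:
    """A raw mono audio segment (speech stimulus)."""

    samples: np.ndarray
    rate_hz: float = 44100.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise InvalidInputError("audio segment is empty")
        if self.rate_hz <= 0:
            raise InvalidInputError("audio sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz


@dataclass
class EnvelopeSignal:
    """A preprocessed speech envelope (z-scored, 64 Hz by default)."""

    values: np.ndarray
    env_rate_hz: float = 64.0
    side: str | None = None
    trial_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class EegSegment:
    """Multichannel EEG: a channels x samples matrix plus metadata.

    ``eog_mask`` flags V/HEOG channels, which are excluded from the common
    average reference and normally dropped before decoding.
    """

    data: np.ndarray
    rate_hz: float
    channel_labels: list[str] = field(default_factory=list)
    eog_mask: np.ndarray | None = None
    trial_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        n_ch = self.data.shape[0]
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(n_ch)]
        if len(self.channel_labels) != n_ch:
            raise InvalidInputError("channel label count != channel count")
        if self.eog_mask is None:
            self.eog_mask = np.zeros(n_ch, dtype=bool)
        self.eog_mask = np.asarray(self.eog_mask, dtype=bool)
        if self.eog_mask.size != n_ch:
            raise InvalidInputError("eog_mask length != channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def drop_eog(self) -> "EegSegment":
        """Return a copy with EOG channels removed."""
        keep = ~self.eog_mask
        return EegSegment(
            data=self.data[keep].copy(),
            rate_hz=self.rate_hz,
            channel_labels=[l for l, k in zip(self.channel_labels, keep) if k],
            eog_mask=np.zeros(int(keep.sum()), dtype=bool),
            trial_id=self.trial_id,
        )


def zscore(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Z-score along ``axis``; zero-variance slices are returned as zeros."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    out = x - mu
    nonzero = sd > 0
    if not np.all(nonzero):
        warnings.warn("zero-variance slice in z-score; returned as zeros")
        sd = np.where(nonzero, sd, 1.0)
    return out / sd


def _resample_fraction(rate_in: float, rate_out: float) -> tuple[int, int]:
    frac = Fraction(rate_out / rate_in).limit_denominator(10000)
    return frac.numerator, frac.denominator


def resample(x: np.ndarray, rate_in: float, rate_out: float, axis: int = -1) -> np.ndarray:
    """Polyphase anti-aliased resampling by the rational factor rate_out/rate_in."""
    up, down = _resample_fraction(rate_in, rate_out)
    return signal.resample_poly(x, up, down, axis=axis)


def common_average_reference(eeg: EegSegment) -> EegSegment:
    """Re-reference every channel to the mean of the non-EOG channels."""
    keep = ~eeg.eog_mask
    if not np.any(keep):
        raise InvalidInputError("all channels flagged as EOG; no reference channels")
    ref = eeg.data[keep].mean(axis=0, keepdims=True)
    return EegSegment(
        data=eeg.data - ref,
        rate_hz=eeg.rate_hz,
        channel_labels=list(eeg.channel_labels),
        eog_mask=eeg.eog_mask.copy(),
        trial_id=eeg.trial_id,
    )


def extract_envelope(
    audio: AudioSegment,
    target_rate_hz: float = 64.0,
    *,
    power: bool = True,
    normalize: bool = True,
) -> EnvelopeSignal:
    """Hilbert-transform envelope of a speech segment, resampled and z-scored.

    Parameters
    ----------
    audio
        Raw speech segment.
    target_rate_hz
        Output envelope rate (64 Hz by default).
    power
        If True (default), use the squared magnitude (power) of the analytic
        signal; if False, the magnitude.
    normalize
        If True (default), z-score the resampled envelope over the segment.
    """
    if target_rate_hz >= audio.rate_hz:
        raise InvalidInputError(
            f"target rate {target_rate_hz} Hz must be below the audio rate {audio.rate_hz} Hz"
        )
    analytic = signal.hilbert(audio.samples)
    env = np.abs(analytic)
    if power:
        env = env**2
    env = resample(env, audio.rate_hz, target_rate_hz)
    if normalize:
        env = zscore(env)
    return EnvelopeSignal(values=env, env_rate_hz=target_rate_hz)


def preprocess_eeg_offline(
    eeg: EegSegment,
    band_lo_hz: float = 2.0,
    band_hi_hz: float = 8.0,
    notch_hz: tuple[float, ...] = (60.0, 120.0),
    hp_hz: float = 0.5,
    target_rate_hz: float = 64.0,
) -> EegSegment:
    """Offline EEG conditioning chain (zero-phase filtering).

    High-pass at ``hp_hz``, notch filters at mains harmonics, CAR over the
    non-EOG channels, zero-phase 2-8 Hz band-pass, polyphase resampling to
    ``target_rate_hz`` and per-channel z-scoring over the segment.
    """
    data = np.asarray(eeg.data, dtype=float)
    fs = eeg.rate_hz

    sos_hp = signal.butter(4, hp_hz, btype="highpass", fs=fs, output="sos")
    data = signal.sosfiltfilt(sos_hp, data, axis=1)

    for f0 in notch_hz:
        if f0 < fs / 2:
            b, a = signal.iirnotch(f0, Q=30.0, fs=fs)
            data = signal.filtfilt(b, a, data, axis=1)

    referenced = common_average_reference(
        EegSegment(data, fs, list(eeg.channel_labels), eeg.eog_mask, eeg.trial_id)
    )
    data = referenced.data

    sos_bp = signal.butter(4, [band_lo_hz, band_hi_hz], btype="bandpass", fs=fs, output="sos")
    data = signal.sosfiltfilt(sos_bp, data, axis=1)

    data = resample(data, fs, target_rate_hz, axis=1)
    data = zscore(data, axis=1)
    return EegSegment(
        data=data,
        rate_hz=target_rate_hz,
        channel_labels=list(eeg.channel_labels),
        eog_mask=eeg.eog_mask.copy(),
        trial_id=eeg.trial_id,
    )


def design_online_fir(
    fir_order: int = 1650,
    band: tuple[float, float] = (2.0, 8.0),
    rate_hz: float = 1000.0,
) -> np.ndarray:
    """Linear-phase windowed-sinc (Hamming) band-pass taps of the given order."""
    return signal.firwin(
        fir_order + 1, list(band), pass_zero=False, window="hamming", fs=rate_hz
    )


def preprocess_eeg_online_block(
    buffer: EegSegment,
    fir_order: int = 1650,
    band: tuple[float, float] = (2.0, 8.0),
    target_rate_hz: float = 64.0,
) -> EegSegment:
    """Minimal causal preprocessing of the EEG accumulated so far in a trial.

    The buffer is copied, re-referenced (CAR over non-EOG channels) and
    band-passed with a causal linear-phase FIR filter. A linear-phase FIR of
    even order delays its output by exactly ``fir_order / 2`` samples; that
    delay is compensated by discarding the first ``fir_order / 2`` output
    samples so that output sample ``t`` is aligned with input time ``t``
    before pairing with the (undelayed) speech envelopes. The aligned data
    are then resampled to ``target_rate_hz`` and z-scored per channel over
    the processed span.

    Raises
    ------
    InsufficientDataError
        If the buffer holds no more samples than the FIR order, in which
        case no aligned output exists yet.
    """
    if buffer.n_samples <= fir_order:
        raise InsufficientDataError(
            f"buffer has {buffer.n_samples} samples; > {fir_order} required"
        )
    referenced = common_average_reference(buffer)
    taps = design_online_fir(fir_order, band, buffer.rate_hz)
    filtered = signal.lfilter(taps, 1.0, referenced.data, axis=1)
    delay = fir_order // 2
    aligned = filtered[:, delay:]
    data = resample(aligned, buffer.rate_hz, target_rate_hz, axis=1)
    data = zscore(data, axis=1)
    return EegSegment(
        data=data,
        rate_hz=target_rate_hz,
        channel_labels=list(buffer.channel_labels),
        eog_mask=buffer.eog_mask.copy(),
        trial_id=buffer.trial_id,
    )
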