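"""Continuous EEG -> clean epoch sets.

The chain mirrors standard event-related practice for a 500 Hz, 10-20
montage recording: zero-phase FIR band-pass (0.1-30 Hz), re-reference to
the averaged mastoids (TP9/TP10), epoching around stimulus onsets
(-200..1000 ms, half-open sample grid), baseline correction to the
pre-stimulus mean, amplitude-based trial rejection (mean + 3 SD of the
per-trial max-abs statistic) and reduction to a sparse 27-electrode array
for network analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, MontageError, ParameterError, PipelineError

logger = logging.getLogger(__name__)

#: Sparse 27-electrode 10-20 array used for the time-varying network
#: analysis: a symmetric frontal/central/temporal/parietal/occipital cover.
DEFAULT_NETWORK_MONTAGE = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2",
)


@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts.

    data: (channels, samples); events: list of (sample_index, label).
    """

    data: np.ndarray
    rate: float
    channel_labels: tuple
    events: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 2:
            raise DataError("recording data must be (channels, samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise DataError("channel_labels length != number of channels")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise DataError("channel labels must be unique")
        for s, _ in self.events:
            if not (0 <= s < self.data.shape[1]):
                raise DataError(f"event sample {s} outside recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise MontageError(f"channel {label!r} not in montage") from None


@dataclass
class EpochSet:
    """Stimulus-locked trials: (trials, channels, samples), microvolts."""

    data: np.ndarray
    window_ms: tuple
    rate: float
    condition: np.ndarray        # per-trial string label
    channel_labels: tuple
    baseline_window_ms: Optional[tuple] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        self.condition = np.asarray(self.condition, dtype=object)
        if self.data.ndim != 3:
            raise DataError("epoch data must be (trials, channels, samples)")
        if len(self.condition) != self.data.shape[0]:
            raise DataError("one condition label per trial required")
        expected = n_window_samples(self.window_ms, self.rate)
        if self.data.shape[2] != expected:
            raise DataError(
                f"samples {self.data.shape[2]} != window/rate grid {expected}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times, half-open [start, end): onset (0 ms) is on the grid."""
        n = self.data.shape[2]
        return self.window_ms[0] + 1000.0 * np.arange(n) / self.rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise MontageError(f"channel {label!r} not in montage") from None

    def select_condition(self, condition: str) -> np.ndarray:
        return self.data[self.condition == condition]


def n_window_samples(window_ms: Sequence[float], rate: float) -> int:
    start, end = window_ms
    return int(round((end - start) * rate / 1000.0))


def bandpass_fir(rec: Recording, low_hz: float = 0.1, high_hz: float = 30.0,
                 l_trans_hz: float = 0.1, h_trans_hz: float = 7.5) -> Recording:
    """Zero-phase (group-delay-compensated) Hamming windowed-sinc band-pass.

    Transition widths default to 0.1 Hz at the low edge and 7.5 Hz at the
    high edge; stopband attenuation of the Hamming design is ~53 dB.
    """
    if not (0 < low_hz < high_hz < rec.rate / 2):
        raise ParameterError(
            f"band ({low_hz}, {high_hz}) must satisfy 0 < low < high < Nyquist")
    from mne.filter import filter_data

    out = filter_data(
        rec.data, sfreq=rec.rate, l_freq=low_hz, h_freq=high_hz,
        l_trans_bandwidth=l_trans_hz, h_trans_bandwidth=h_trans_hz,
        fir_design="firwin", fir_window="hamming", phase="zero",
        verbose="error",
    )
    return replace(rec, data=out)


def notch_filter(rec: Recording, freq_hz: float = 50.0) -> Recording:
    """Optional mains notch; off by default in the pipeline (the target
    acquisition already notched 50 Hz)."""
    from mne.filter import notch_filter as _notch

    out = _notch(rec.data, Fs=rec.rate, freqs=freq_hz, verbose="error")
    return replace(rec, data=out)


def rereference(rec: Recording, ref_labels: Sequence[str] = ("TP9", "TP10")) -> Recording:
    """Subtract the instantaneous mean of the reference channels everywhere."""
    idx = [rec.channel_index(l) for l in ref_labels]
    ref = rec.data[idx].mean(axis=0, keepdims=True)
    return replace(rec, data=rec.data - ref)


def epoch(rec: Recording, window_ms: Sequence[float] = (-200.0, 1000.0)) -> EpochSet:
    """Cut one trial per event on the half-open [start, end) sample grid.

    At 500 Hz a (-200, 1000) ms window yields 600 samples with stimulus
    onset at index 100.  Events whose window does not fit inside the
    recording are dropped with a logged warning.
    """
    n = n_window_samples(window_ms, rec.rate)
    if n < 1:
        raise ParameterError("empty epoch window")
    off = int(round(window_ms[0] * rec.rate / 1000.0))
    trials, labels, dropped = [], [], 0
    for sample, label in rec.events:
        a = sample + off
        b = a + n
        if a < 0 or b > rec.n_samples:
            dropped += 1
            continue
        trials.append(rec.data[:, a:b])
        labels.append(label)
    if dropped:
        logger.warning("epoch: dropped %d event(s) too close to an edge", dropped)
    data = np.stack(trials) if trials else np.empty((0, rec.n_channels, n))
    return EpochSet(data=data, window_ms=tuple(window_ms), rate=rec.rate,
                    condition=np.array(labels, dtype=object),
                    channel_labels=rec.channel_labels)


def _window_slice(ep: EpochSet, window_ms: Sequence[float], half_open: bool = True) -> np.ndarray:
    t = ep.times_ms
    lo, hi = window_ms
    return (t >= lo - 1e-9) & ((t < hi - 1e-9) if half_open else (t <= hi + 1e-9))


def baseline_correct(ep: EpochSet, baseline_ms: Sequence[float] = (-200.0, 0.0)) -> EpochSet:
    """Subtract, per trial and channel, the mean over the baseline window."""
    lo, hi = baseline_ms
    if not (ep.window_ms[0] <= lo < hi <= ep.window_ms[1]):
        raise ParameterError("baseline window must lie inside the epoch window")
    mask = _window_slice(ep, baseline_ms)
    if not mask.any():
        raise ParameterError("baseline window contains no samples")
    base = ep.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(ep, data=ep.data - base, baseline_window_ms=tuple(baseline_ms))


def reject_amplitude(ep: EpochSet, k: float = 3.0, stat: str = "max_abs"):
    """Drop trials whose amplitude statistic exceeds mean + k*SD over trials.

    The per-trial statistic is the max over channels and samples of the
    absolute voltage (``max_abs``, default) or the largest per-channel
    peak-to-peak range (``peak_to_peak``).  Rejection uses a strict
    inequality, so identical trials (SD = 0) are all kept.  Returns the
    reduced :class:`EpochSet` and a per-trial log DataFrame.
    """
    if ep.n_trials < 3:
        raise ParameterError("amplitude rejection needs at least 3 trials")
    if stat == "max_abs":
        s = np.abs(ep.data).max(axis=(1, 2))
    elif stat == "peak_to_peak":
        s = (ep.data.max(axis=2) - ep.data.min(axis=2)).max(axis=1)
    else:
        raise ParameterError(f"unknown rejection statistic {stat!r}")
    mu, sd = s.mean(), s.std(ddof=1)
    thresh = mu + k * sd if np.isfinite(k) else np.inf
    keep = ~(s > thresh)
    log = pd.DataFrame({
        "trial": np.arange(ep.n_trials),
        "condition": ep.condition,
        "statistic": s,
        "threshold": thresh,
        "kept": keep,
    })
    if not keep.any():
        raise PipelineError("preprocess", "all_trials_rejected",
                            "amplitude rejection removed every trial")
    out = replace(ep, data=ep.data[keep], condition=ep.condition[keep])
    n_rej = int((~keep).sum())
    if n_rej:
        logger.info("reject_amplitude: removed %d/%d trials", n_rej, ep.n_trials)
    return out, log


def select_channels(ep: EpochSet, montage_subset: Sequence[str] = DEFAULT_NETWORK_MONTAGE) -> EpochSet:
    """Reduce and reorder the channel axis to the requested subset."""
    subset = list(montage_subset)
    if len(set(subset)) != len(subset):
        raise ParameterError("montage subset contains duplicate labels")
    idx = [ep.channel_index(l) for l in subset]
    return replace(ep, data=ep.data[:, idx, :], channel_labels=tuple(subset))


def preprocess_recording(rec: Recording, *, band=(0.1, 30.0),
                         ref_labels=("TP9", "TP10"),
                         window_ms=(-200.0, 1000.0),
                         baseline_ms=(-200.0, 0.0),
                         reject_k: float = 3.0,
                         montage_subset: Optional[Sequence[str]] = None,
                         l_trans_hz: float = 0.1, h_trans_hz: float = 7.5):
    """Full continuous-to-epochs chain; returns (EpochSet, rejection log)."""
    rec = rereference(rec, ref_labels)
    rec = bandpass_fir(rec, band[0], band[1], l_trans_hz=l_trans_hz,
                       h_trans_hz=h_trans_hz)
    ep = epoch(rec, window_ms)
    ep = baseline_correct(ep, baseline_ms)
    ep, log = reject_amplitude(ep, k=reject_k)
    if montage_subset is not None:
        ep = select_channels(ep, montage_subset)
    return ep, log
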