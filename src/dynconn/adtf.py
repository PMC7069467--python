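"""Adaptive directed transfer function (ADTF) networks.

From the time-varying VAR coefficients A_k(t), the frequency-domain
coefficient matrix is

    Abar(f, t) = I - sum_{k=1..p} A_k(t) * exp(-i 2 pi f k / rate)

and H(f, t) = Abar(f, t)^{-1} is the time-varying transfer matrix.  The
ADTF is the sink-normalized squared magnitude

    gamma2_ij(f, t) = |H_ij|^2 / sum_m |H_im|^2

(the share of inflow into channel i originating from channel j), and the
band-integrated network weight is the ratio of band sums

    theta2_ij(t) = sum_f |H_ij|^2 / sum_f sum_m |H_im|^2,

which keeps every sink row summing to one after integration.  Per-trial
networks are averaged trial by trial into a subject-level time-varying
network; averaging suppresses noise-driven fluctuations while keeping the
genuine time course.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .errors import AggregationError, ParameterError
from .mvaar import TVMVARModel

logger = logging.getLogger(__name__)

#: 1-30 Hz at 1 Hz steps: the broad band of a 0.1-30 Hz-filtered epoch at
#: the spectral resolution a 1.2 s trial supports.
DEFAULT_FREQS_HZ = np.arange(1.0, 31.0)
DEFAULT_BAND_HZ = (1.0, 30.0)


@dataclass
class TransferFunction:
    values: np.ndarray           # (time, freq, n, n) complex
    freqs_hz: np.ndarray
    rate: float
    times: np.ndarray            # sample indices
    n_regularized: int = 0


@dataclass
class ADTFMatrix:
    values: np.ndarray           # (time, freq, n, n) in [0, 1]
    freqs_hz: np.ndarray
    rate: float
    times: np.ndarray


@dataclass
class TimeVaryingNetwork:
    """Directed weighted adjacency over time; w[t, i, j] = flow j -> i."""

    w: np.ndarray                # (time, n, n), nonnegative
    times_ms: np.ndarray
    band_hz: tuple
    channel_labels: Optional[tuple]
    n_trials_averaged: int = 1

    @property
    def n_channels(self) -> int:
        return self.w.shape[1]

    def at_time(self, time_ms: float) -> np.ndarray:
        """Weight matrix at the nearest grid latency."""
        i = int(np.argmin(np.abs(self.times_ms - time_ms)))
        return self.w[i]


def _batched_inverse(Abar: np.ndarray):
    """Invert a (..., n, n) stack; regularize singular items with jitter."""
    n_reg = 0
    try:
        H = np.linalg.inv(Abar)
        if np.all(np.isfinite(H)):
            return H, 0
    except np.linalg.LinAlgError:
        pass
    flat = Abar.reshape(-1, *Abar.shape[-2:]).copy()
    H = np.empty_like(flat)
    eye = np.eye(Abar.shape[-1])
    for i, M in enumerate(flat):
        try:
            Hi = np.linalg.inv(M)
            if not np.all(np.isfinite(Hi)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            Hi = np.linalg.inv(M + 1e-8 * eye)
            n_reg += 1
        H[i] = Hi
    logger.warning("transfer_function: regularized %d singular point(s)", n_reg)
    return H.reshape(Abar.shape), n_reg


def transfer_function(model: TVMVARModel,
                      freqs_hz: Sequence[float] = DEFAULT_FREQS_HZ) -> TransferFunction:
    """Time-varying transfer matrix H(f, t) on the given frequency grid."""
    f = np.asarray(freqs_hz, dtype=float)
    if np.any(f <= 0) or np.any(f >= model.rate / 2):
        raise ParameterError("frequencies must lie in (0, rate/2)")
    A = model.coeffs                                    # (nt, p, n, n)
    p, n = model.order, A.shape[2]
    k = np.arange(1, p + 1)
    z = np.exp(-2j * np.pi * np.outer(f, k) / model.rate)   # (nf, p)
    Abar = np.eye(n) - np.einsum("fk,tkij->tfij", z, A)
    H, n_reg = _batched_inverse(Abar)
    return TransferFunction(values=H, freqs_hz=f, rate=model.rate,
                            times=model.times, n_regularized=n_reg)


def normalize_adtf(H: TransferFunction) -> ADTFMatrix:
    """Sink-row normalization: each row of gamma2 sums to 1 at every (t, f)."""
    mag = np.abs(H.values) ** 2
    denom = mag.sum(axis=-1, keepdims=True)
    zero = denom[..., 0] == 0
    if zero.any():
        logger.warning("normalize_adtf: %d zero row(s) set uniform", int(zero.sum()))
        n = mag.shape[-1]
        mag[zero] = 1.0 / n
        denom = mag.sum(axis=-1, keepdims=True)
    return ADTFMatrix(values=mag / denom, freqs_hz=H.freqs_hz, rate=H.rate,
                      times=H.times)


def integrate_band(obj: Union[TransferFunction, ADTFMatrix],
                   band_hz: Sequence[float] = DEFAULT_BAND_HZ,
                   method: str = "ratio") -> np.ndarray:
    """Integrate over a frequency band -> (time, n, n) weights.

    ``ratio`` (default, on a :class:`TransferFunction`) divides band-summed
    |H|^2 by its row sum, preserving per-sink normalization; ``mean``
    averages per-frequency gamma2 over the band.  On an
    :class:`ADTFMatrix` the two coincide.
    """
    lo, hi = band_hz
    sel = (obj.freqs_hz >= lo - 1e-9) & (obj.freqs_hz <= hi + 1e-9)
    if not sel.any():
        raise ParameterError(f"band {band_hz} contains no grid frequencies")
    if isinstance(obj, ADTFMatrix):
        return obj.values[:, sel].mean(axis=1)
    if method == "ratio":
        num = (np.abs(obj.values[:, sel]) ** 2).sum(axis=1)
        denom = num.sum(axis=-1, keepdims=True)
        denom[denom == 0] = 1.0
        return num / denom
    if method == "mean":
        return integrate_band(normalize_adtf(obj), band_hz)
    raise ParameterError(f"unknown integration method {method!r}")


def _times_ms(model: TVMVARModel, window_start_ms: float) -> np.ndarray:
    return window_start_ms + 1000.0 * model.times / model.rate


def trial_network(model: TVMVARModel,
                  freqs_hz: Sequence[float] = DEFAULT_FREQS_HZ,
                  band_hz: Sequence[float] = DEFAULT_BAND_HZ,
                  window_start_ms: float = -200.0,
                  method: str = "ratio") -> TimeVaryingNetwork:
    """Band-integrated ADTF network of a single trial."""
    H = transfer_function(model, freqs_hz)
    w = integrate_band(H, band_hz, method=method)
    return TimeVaryingNetwork(w=w, times_ms=_times_ms(model, window_start_ms),
                              band_hz=tuple(band_hz),
                              channel_labels=model.channel_labels,
                              n_trials_averaged=1)


def trial_networks(models: Sequence[TVMVARModel],
                   freqs_hz: Sequence[float] = DEFAULT_FREQS_HZ,
                   band_hz: Sequence[float] = DEFAULT_BAND_HZ,
                   window_start_ms: float = -200.0):
    """Band-integrated ADTF networks of many same-shape trials.

    Inversions are batched over trials x time and accumulated one
    frequency at a time, so memory stays at O(trials x time x n^2).
    """
    if not models:
        return []
    f = np.asarray(freqs_hz, dtype=float)
    lo, hi = band_hz
    f = f[(f >= lo - 1e-9) & (f <= hi + 1e-9)]
    if f.size == 0:
        raise ParameterError(f"band {band_hz} contains no grid frequencies")
    ref = models[0]
    A = np.stack([m.coeffs for m in models])            # (M, nt, p, n, n)
    M, nt, p, n, _ = A.shape
    k = np.arange(1, p + 1)
    eye = np.eye(n)
    acc = np.zeros((M, nt, n, n))
    for fi in f:
        z = np.exp(-2j * np.pi * fi * k / ref.rate)
        Abar = eye - np.einsum("k,mtkij->mtij", z, A)
        H, _ = _batched_inverse(Abar)
        acc += np.abs(H) ** 2
    denom = acc.sum(axis=-1, keepdims=True)
    denom[denom == 0] = 1.0
    acc /= denom
    times_ms = _times_ms(ref, window_start_ms)
    return [TimeVaryingNetwork(w=acc[i], times_ms=times_ms, band_hz=(lo, hi),
                               channel_labels=ref.channel_labels,
                               n_trials_averaged=1)
            for i in range(M)]


def average_trials(nets: Sequence[TimeVaryingNetwork]) -> TimeVaryingNetwork:
    """Entrywise mean over per-trial networks -> subject-level network."""
    if not nets:
        raise AggregationError("no networks to average")
    ref = nets[0]
    for net in nets[1:]:
        if net.w.shape != ref.w.shape or net.band_hz != ref.band_hz \
                or net.channel_labels != ref.channel_labels:
            raise AggregationError("networks differ in shape, band or montage")
        if not np.allclose(net.times_ms, ref.times_ms):
            raise AggregationError("networks differ in time grid")
    total = sum(net.n_trials_averaged for net in nets)
    w = np.mean([net.w for net in nets], axis=0)
    return TimeVaryingNetwork(w=w, times_ms=ref.times_ms.copy(),
                              band_hz=ref.band_hz,
                              channel_labels=ref.channel_labels,
                              n_trials_averaged=total)
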