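"""Condition-average ERPs, component measurement and mass-univariate tests.

Components follow the auditory emotional-oddball literature: N1 (negative,
100-200 ms, frontal), P3a (positive, ~300 ms, frontal) and the late
positive potential LPP (positive, 400-1000 ms, centroparietal).  Condition
and group contrasts are run as a pointwise two-tailed t-test at every
channel and time point in 0-1000 ms, with Benjamini-Hochberg FDR control
pooled jointly over channels and time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import MontageError, ParameterError, SelectionError, StatisticsError
from .preprocessing import EpochSet

logger = logging.getLogger(__name__)


@dataclass
class ERPWaveform:
    data: np.ndarray             # (channels, samples), microvolts
    rate: float
    window_ms: tuple
    condition: str
    channel_labels: tuple
    n_trials_averaged: int = 1

    @property
    def times_ms(self) -> np.ndarray:
        return self.window_ms[0] + 1000.0 * np.arange(self.data.shape[1]) / self.rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise MontageError(f"channel {label!r} not in montage") from None


@dataclass(frozen=True)
class ComponentDefinition:
    name: str
    window_ms: tuple
    electrodes: tuple
    polarity: str                # "negative" | "positive"


#: Default component windows/sites for the emotional oddball paradigm.
N1 = ComponentDefinition("N1", (100.0, 200.0), ("Fz",), "negative")
P3A = ComponentDefinition("P3a", (250.0, 350.0), ("Fz",), "positive")
LPP = ComponentDefinition("LPP", (400.0, 1000.0),
                          ("Cz", "CP1", "CP2", "Pz", "P3", "P4"), "positive")
DEFAULT_COMPONENTS = (N1, P3A, LPP)


@dataclass
class MassUnivariateResult:
    t_values: np.ndarray         # (channels, samples)
    p_values: np.ndarray
    fdr_mask: np.ndarray         # boolean, same shape
    q: float
    test_window_ms: tuple
    times_ms: np.ndarray
    channel_labels: tuple


def average_erp(ep: EpochSet, condition: str) -> ERPWaveform:
    """Arithmetic mean over all trials carrying the given condition label."""
    trials = ep.select_condition(condition)
    if trials.shape[0] == 0:
        raise SelectionError(f"no trials with condition {condition!r}")
    return ERPWaveform(data=trials.mean(axis=0), rate=ep.rate,
                       window_ms=ep.window_ms, condition=condition,
                       channel_labels=ep.channel_labels,
                       n_trials_averaged=trials.shape[0])


def _stack(waves: Sequence[ERPWaveform]) -> np.ndarray:
    ref = waves[0]
    for w in waves[1:]:
        if w.data.shape != ref.data.shape or w.channel_labels != ref.channel_labels:
            raise StatisticsError("waveforms differ in shape or montage")
    return np.stack([w.data for w in waves])


def mass_univariate_ttest(a: Sequence[ERPWaveform], b: Sequence[ERPWaveform],
                          paired: bool = True,
                          window_ms: Sequence[float] = (0.0, 1000.0),
                          q: float = 0.05) -> MassUnivariateResult:
    """Pointwise two-tailed t-test at every channel/time in the window.

    ``a`` and ``b`` are per-subject waveforms.  Paired tests use
    within-subject differences (condition contrasts); unpaired tests use
    Welch's t (between-group contrasts).  Time points with zero variance
    yield t = 0, p = 1 with a logged warning rather than NaN.
    """
    if paired:
        if len(a) != len(b):
            raise StatisticsError("paired test requires matched subject lists")
        if len(a) < 2:
            raise StatisticsError("paired test requires n >= 2 subjects")
    elif min(len(a), len(b)) < 2:
        raise StatisticsError("unpaired test requires n >= 2 per group")

    A, B = _stack(a), _stack(b)
    ref = a[0]
    t_axis = ref.times_ms
    sel = (t_axis >= window_ms[0] - 1e-9) & (t_axis <= window_ms[1] + 1e-9)
    A, B = A[:, :, sel], B[:, :, sel]

    with np.errstate(divide="ignore", invalid="ignore"):
        if paired:
            t, p = stats.ttest_rel(A, B, axis=0)
        else:
            t, p = stats.ttest_ind(A, B, axis=0, equal_var=False)
    bad = ~np.isfinite(t)
    if bad.any():
        logger.warning("mass_univariate_ttest: %d zero-variance point(s) set to p=1",
                       int(bad.sum()))
        t = np.where(bad, 0.0, t)
        p = np.where(bad, 1.0, p)

    mask = fdr_correct(p, q=q)
    return MassUnivariateResult(t_values=t, p_values=p, fdr_mask=mask, q=q,
                                test_window_ms=tuple(window_ms),
                                times_ms=t_axis[sel],
                                channel_labels=ref.channel_labels)


def fdr_correct(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up over all supplied p-values jointly.

    Channels x time are pooled into one family; the returned boolean mask
    has the input's shape and is true for ranks <= k* where
    k* = max{i : p_(i) <= i*q/m}.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros_like(p, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    reject = multipletests(p.ravel(), alpha=q, method="fdr_bh")[0]
    return reject.reshape(p.shape)


def measure_component(erp: ERPWaveform, comp: ComponentDefinition) -> float:
    """Signed mean amplitude over the component window and electrodes (uV).

    The window mean (rather than the peak) is used; polarity only labels
    the expected direction.
    """
    lo, hi = comp.window_ms
    if not (erp.window_ms[0] <= lo < hi <= erp.window_ms[1]):
        raise ParameterError(f"{comp.name} window outside the ERP window")
    idx = [erp.channel_index(e) for e in comp.electrodes]
    t = erp.times_ms
    sel = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    return float(erp.data[np.ix_(idx, np.flatnonzero(sel))].mean())
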