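"""Time-varying multivariate adaptive autoregressive (MVAAR) estimation.

Each trial y(t) (n channels) is modelled as a VAR(p) whose coefficient
matrices A_1(t)..A_p(t) evolve as a random walk and are tracked with a
Kalman filter:

    state   x(t) = x(t-1) + w(t),        w ~ N(0, uc * I)
    obs     y(t) = [A_1(t)..A_p(t)] phi(t) + e(t)

where phi(t) stacks the p lagged sample vectors.  Because every output
channel shares the same regressor phi(t), the state covariance factorises
as I_n (x) P with P of size (n*p, n*p) when the observation noise is
isotropic; the recursion below tracks that factor, which makes a 600-step,
27-channel pass cheap.  The observation-noise level is adapted online by
exponential smoothing of the squared innovations.

The update coefficient ``uc`` trades tracking speed against estimation
variance; 1e-3 is a conventional default for 500 Hz event-related epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DataError, ParameterError

_EPS = 1e-12


@dataclass(frozen=True)
class KalmanConfig:
    order: int = 5                  # model order p
    uc: float = 1e-3                # random-walk process-noise level
    init_state_cov: float = 1.0     # scale of the initial state covariance
    obs_noise_init: float = 1.0     # initial observation-noise variance
    noise_smoothing: float = 0.02   # EWMA factor for innovation variance

    def __post_init__(self):
        if self.order < 1:
            raise ParameterError("model order must be >= 1")
        if self.uc < 0:
            raise ParameterError("uc must be >= 0")
        if not (0 < self.noise_smoothing <= 1):
            raise ParameterError("noise_smoothing must be in (0, 1]")


@dataclass
class TVMVARModel:
    """Time-resolved VAR coefficients for one trial.

    ``coeffs[t, k, i, j]`` is the influence of channel j at lag k+1 on
    channel i, evaluated at ``times[t]`` (sample index within the trial).
    """

    order: int
    coeffs: np.ndarray           # (n_times, p, n, n)
    times: np.ndarray            # sample indices the coefficients refer to
    residual_cov: np.ndarray     # (n, n), pooled innovation covariance
    uc: float
    rate: float
    channel_labels: Optional[tuple] = None

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[2]


def fit_kalman_mvaar(trial: np.ndarray, cfg: KalmanConfig = KalmanConfig(),
                     rate: float = 500.0, store_every: int = 1,
                     channel_labels: Optional[Sequence[str]] = None) -> TVMVARModel:
    """Fit one trial (channels x samples); see :func:`fit_kalman_mvaar_trials`."""
    return fit_kalman_mvaar_trials(np.asarray(trial)[None], cfg, rate=rate,
                                   store_every=store_every,
                                   channel_labels=channel_labels)[0]


def fit_kalman_mvaar_trials(trials: np.ndarray, cfg: KalmanConfig = KalmanConfig(),
                            rate: float = 500.0, store_every: int = 1,
                            channel_labels: Optional[Sequence[str]] = None):
    """Kalman-filter MVAAR fit, vectorized over independent trials.

    Parameters
    ----------
    trials : (n_trials, n_channels, n_samples)
        One independent filter pass is run per trial (no concatenation).
    store_every : int
        Keep coefficient snapshots on the decimated grid
        ``0, store_every, 2*store_every, ...``; snapshots earlier than the
        first estimable time (t = p) are back-filled with the first
        estimate so downstream time grids align with the epoch.

    Returns
    -------
    list of :class:`TVMVARModel`, one per trial.
    """
    y = np.asarray(trials, dtype=float)
    if y.ndim != 3:
        raise DataError("trials must be (n_trials, n_channels, n_samples)")
    if not np.all(np.isfinite(y)):
        raise DataError("non-finite samples in input")
    T, n, s = y.shape
    p = cfg.order
    if s <= p:
        raise ParameterError(f"need more than order={p} samples, got {s}")
    d = n * p

    store_idx = np.arange(0, s, max(int(store_every), 1))
    store_mask = np.zeros(s, dtype=bool)
    store_mask[store_idx] = True
    pos = {t: i for i, t in enumerate(store_idx)}

    X = np.zeros((T, d, n))
    P = np.broadcast_to(np.eye(d), (T, d, d)).copy() * cfg.init_state_cov
    r = np.full(T, float(cfg.obs_noise_init))
    E = np.broadcast_to(np.eye(n), (T, n, n)).copy() * cfg.obs_noise_init
    g = cfg.noise_smoothing
    uc = cfg.uc
    diag = np.arange(d)

    out = np.empty((T, len(store_idx), d, n))
    first = None  # first estimated X, for back-filling t < p

    # lagged regressor phi(t) = [y(t-1); ...; y(t-p)] stacked channelwise
    for t in range(p, s):
        phi = np.concatenate([y[:, :, t - k] for k in range(1, p + 1)], axis=1)
        # predict: random-walk state, P <- P + uc*I
        P[:, diag, diag] += uc
        err = y[:, :, t] - np.einsum("tdn,td->tn", X, phi)
        Pphi = np.einsum("tij,tj->ti", P, phi)
        S = np.einsum("ti,ti->t", phi, Pphi) + r
        S = np.maximum(S, _EPS)
        K = Pphi / S[:, None]
        X += K[:, :, None] * err[:, None, :]
        P -= K[:, :, None] * Pphi[:, None, :]
        if (t - p) % 32 == 31:  # curb asymmetry drift from the rank-1 update
            P += np.transpose(P, (0, 2, 1))
            P *= 0.5
        e2 = (err ** 2).mean(axis=1)
        r = np.maximum((1.0 - g) * r + g * e2, _EPS)
        E = (1.0 - g) * E + g * err[:, :, None] * err[:, None, :]
        if first is None:
            first = X.copy()
        if store_mask[t]:
            out[:, pos[t]] = X
    # back-fill stored grid points before the first estimable time
    for t in store_idx[store_idx < p]:
        out[:, pos[t]] = first
    # any stored index >= p is always visited, so `out` is fully written

    labels = tuple(channel_labels) if channel_labels is not None else None
    models = []
    for i in range(T):
        # (n_times, d, n) -> (n_times, p, n_src, n_sink) -> (n_times, p, sink, src)
        A = out[i].reshape(len(store_idx), p, n, n).transpose(0, 1, 3, 2)
        models.append(TVMVARModel(order=p, coeffs=np.ascontiguousarray(A),
                                  times=store_idx.copy(), residual_cov=E[i],
                                  uc=uc, rate=rate, channel_labels=labels))
    return models


def companion_matrix(A: np.ndarray) -> np.ndarray:
    """Companion form of stacked lag matrices A (p, n, n) -> (np, np)."""
    A = np.asarray(A, dtype=float)
    p, n, _ = A.shape
    top = A.transpose(1, 0, 2).reshape(n, p * n)
    comp = np.zeros((p * n, p * n))
    comp[:n] = top
    if p > 1:
        comp[n:, : (p - 1) * n] = np.eye((p - 1) * n)
    return comp


def spectral_radius(A: np.ndarray) -> float:
    return float(np.abs(np.linalg.eigvals(companion_matrix(A))).max())


def stability_check(A: np.ndarray) -> bool:
    """True iff the VAR defined by lag matrices A (p, n, n) is stable
    (companion-matrix spectral radius < 1)."""
    return spectral_radius(A) < 1.0


def ols_var_fit(trial: np.ndarray, order: int) -> np.ndarray:
    """Ordinary least-squares VAR(p) fit of one stationary trial.

    Returns lag matrices (p, n, n).  Used as the stationary reference the
    adaptive estimates should converge to, and as the coefficient source
    for the static (non-adaptive) transfer function.
    """
    y = np.asarray(trial, dtype=float)
    n, s = y.shape
    if s <= order:
        raise ParameterError("trial shorter than the model order")
    Y = y[:, order:].T                                      # (s-p, n)
    Z = np.concatenate([y[:, order - k: s - k] for k in range(1, order + 1)],
                       axis=0).T                            # (s-p, n*p)
    B, *_ = np.linalg.lstsq(Z, Y, rcond=None)               # (n*p, n)
    return B.reshape(order, n, n).transpose(0, 2, 1)


def select_order(trials: np.ndarray, candidates=range(1, 11)) -> int:
    """Optional helper: BIC-minimizing VAR order over pooled OLS fits."""
    y = np.asarray(trials, dtype=float)
    if y.ndim == 2:
        y = y[None]
    best, best_bic = None, np.inf
    for p in candidates:
        n_obs, rss_logdet = 0, 0.0
        cov = None
        resid_all = []
        for trial in y:
            n, s = trial.shape
            if s <= p:
                continue
            A = ols_var_fit(trial, p)
            Y = trial[:, p:].T
            Z = np.concatenate([trial[:, p - k: s - k] for k in range(1, p + 1)], axis=0).T
            pred = Z @ A.transpose(0, 2, 1).reshape(p * n, n)
            resid_all.append(Y - pred)
        if not resid_all:
            continue
        R = np.concatenate(resid_all)
        m, n = R.shape
        sigma = (R.T @ R) / m
        sign, logdet = np.linalg.slogdet(sigma + _EPS * np.eye(n))
        bic = logdet + (np.log(m) * p * n * n) / m
        if bic < best_bic:
            best, best_bic = p, bic
    if best is None:
        raise ParameterError("no candidate order is estimable on these trials")
    return best
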