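"""Stimulus-reconstruction decoding of the speech envelope.

A backward multiple linear regression predicts the speech envelope from
band-limited EEG amplitude at distributed lags (-300..300 ms in 50-ms
steps).  Accuracy is assessed with 10-fold cross-validation over
consecutive segments; per-fold Pearson correlations between predicted
and actual envelope are pooled through the Fisher z-transform, giving
the oscillation tracking index.

Positive lag means the EEG sample follows the envelope sample it
predicts (the brain lags the stimulus).
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import signal, stats

from .containers import TrackingResult

DEFAULT_LAGS_MS = tuple(float(v) for v in range(-300, 301, 50))


def band_amplitude(data: np.ndarray, rate: float, band: tuple[float, float]) -> np.ndarray:
    """Band-limited instantaneous amplitude: zero-phase band-pass then |Hilbert|.

    ``data`` is (..., samples); filtering and the analytic signal are
    applied along the last axis.
    """
    lo, hi = band
    if not 0 < lo < hi < rate / 2:
        raise ValueError(f"band {band} invalid for rate {rate} Hz")
    sos = signal.butter(4, band, btype="bandpass", fs=rate, output="sos")
    filtered = signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)
    return np.abs(signal.hilbert(filtered, axis=-1))


def build_lagged_design(
    amplitude: np.ndarray, rate: float, lags_ms: tuple[float, ...] = DEFAULT_LAGS_MS
) -> tuple[np.ndarray, np.ndarray]:
    """Time-lagged design matrix from (channels, time) amplitude.

    Column ``(c, l)`` holds channel ``c`` shifted so that row ``t``
    contains the EEG amplitude at ``t + lag_l``.  Boundary rows where any
    lag falls outside the data, and rows with any missing predictor, are
    trimmed.  Returns ``(X, valid_rows)`` where ``valid_rows`` indexes
    the retained target samples.
    """
    amp = np.atleast_2d(np.asarray(amplitude, dtype=float))
    n_ch, n_t = amp.shape
    shifts = np.array([int(round(l * rate / 1000.0)) for l in lags_ms])
    lo, hi = -int(shifts.min()), int(shifts.max())
    rows = np.arange(max(0, -shifts.min()), n_t - max(0, shifts.max()))
    X = np.empty((len(rows), n_ch * len(shifts)))
    for ci in range(n_ch):
        for li, s in enumerate(shifts):
            X[:, ci * len(shifts) + li] = amp[ci, rows + s]
    finite = np.all(np.isfinite(X), axis=1)
    return X[finite], rows[finite]


def fisher_pool(r_list: np.ndarray | list[float]) -> float:
    """Pool correlations via the inverse Fisher transform of the mean z.

    ``tanh(mean(atanh(r_k)))``; raises for |r| = 1 (infinite z).
    """
    r = np.asarray(r_list, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("cannot Fisher-pool correlations with |r| >= 1")
    return float(np.tanh(np.mean(np.arctanh(r))))


def _consecutive_folds(n: int, n_folds: int) -> list[np.ndarray]:
    """n consecutive, contiguous, equal-length segments; remainder to the last."""
    base = n // n_folds
    bounds = [k * base for k in range(n_folds)] + [n]
    return [np.arange(bounds[k], bounds[k + 1]) for k in range(n_folds)]


def reconstruct_envelope_cv(
    amplitude: np.ndarray,
    envelope: np.ndarray,
    rate: float,
    lags_ms: tuple[float, ...] = DEFAULT_LAGS_MS,
    n_folds: int = 10,
    participant: str = "",
    band: str = "",
    scope: str = "all",
) -> TrackingResult:
    """Cross-validated envelope reconstruction from lagged EEG amplitude.

    ``amplitude`` is (channels, time) band amplitude over the
    concatenated speech chunks and ``envelope`` the aligned stimulus
    envelope.  Each fold fits ordinary least squares (with intercept) on
    the remaining nine segments and correlates the prediction with the
    actual envelope on the held-out segment.
    """
    env = np.asarray(envelope, dtype=float)
    X, rows = build_lagged_design(amplitude, rate, lags_ms)
    y = env[rows]
    keep = np.isfinite(y)
    X, y = X[keep], y[keep]
    if len(y) < n_folds * 2:
        raise ValueError(f"{len(y)} samples cannot support {n_folds} folds")

    Xd = np.column_stack([np.ones(len(y)), X])
    folds = _consecutive_folds(len(y), n_folds)
    r_k = np.empty(n_folds)
    for k, test in enumerate(folds):
        train = np.setdiff1d(np.arange(len(y)), test, assume_unique=True)
        beta, _, rank, _ = np.linalg.lstsq(Xd[train], y[train], rcond=None)
        if rank < Xd.shape[1]:
            warnings.warn("rank-deficient design; minimum-norm solution used")
        pred = Xd[test] @ beta
        r_k[k] = stats.pearsonr(pred, y[test]).statistic
    return TrackingResult(
        participant=participant,
        band=band,
        scope=scope,
        fold_r=r_k,
        pooled_r=fisher_pool(r_k),
        n_folds=n_folds,
    )


def epoch_tracking_data(
    epochs,
    envelope,
    band: tuple[float, float],
    edge_ms: float = 300.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Aligned (band amplitude, envelope) over concatenated speech windows.

    Band amplitude is computed on the full epoch (so the pre-onset
    padding absorbs the left filter transient) and the interior of each
    speech window — ``[edge_ms, duration - edge_ms)`` relative to onset —
    is concatenated across trials, excluding the onset and offset
    transients of the per-epoch filter and analytic signal.  Returns
    ``(amplitude (channels, time), envelope (time,))``.
    """
    amp = band_amplitude(epochs.data, epochs.rate, band)
    dur = float(epochs.trials["duration_ms"].min())
    t = epochs.times_ms
    sel = (t >= edge_ms) & (t < dur - edge_ms)
    if not sel.any():
        raise ValueError("speech window shorter than twice the edge margin")
    off = int(round(edge_ms * epochs.rate / 1000.0))
    n_sel = int(sel.sum())
    amp_cat = np.concatenate(list(amp[:, :, sel]), axis=-1)
    env_cat = np.concatenate(
        [
            envelope.samples[
                int(round(o * epochs.rate / 1000.0)) + off :
                int(round(o * epochs.rate / 1000.0)) + off + n_sel
            ]
            for o in epochs.trials["onset_ms"]
        ]
    )
    return amp_cat, env_cat


def single_channel_tracking(
    amplitude: np.ndarray,
    envelope: np.ndarray,
    rate: float,
    ch_names: list[str],
    **kwargs,
) -> list[TrackingResult]:
    """One reconstruction model per channel (per-electrode tracking maps)."""
    return [
        reconstruct_envelope_cv(
            amplitude[ci : ci + 1], envelope, rate, scope=ch_names[ci], **kwargs
        )
        for ci in range(amplitude.shape[0])
    ]
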