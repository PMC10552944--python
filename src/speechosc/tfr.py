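"""Morlet time-frequency decomposition and decibel baseline normalization.

Power is computed with 5-cycle Morlet wavelets on the padded epoch,
averaged across trials, and expressed in dB relative to the mean power in
a pre-onset baseline window.  Band power is the mean dB value over a
band x window rectangle (0-1000 ms post-onset by default).

The wavelets use MNE's L2 (energy) normalization.  Artifact samples are
zero-filled before the convolution and every output sample whose wavelet
support overlaps an artifact is re-masked to NaN, so missing data are
excluded from (rather than diluted into) the trial and time averages.
"""
from __future__ import annotations

import numpy as np
from mne.time_frequency import tfr_array_morlet

from .containers import EpochedEEG, TimeFrequencyPower

N_CYCLES = 5.0


def morlet_tfr(
    epochs: EpochedEEG,
    freqs: np.ndarray | None = None,
    n_cycles: float = N_CYCLES,
    crop_ms: tuple[float, float] = (-1000.0, 1000.0),
) -> TimeFrequencyPower:
    """Trial-averaged Morlet wavelet power, cropped to ``crop_ms``.

    The default frequency grid is 1-50 Hz in 1-Hz steps.  The epoch must
    extend at least half a wavelet beyond the cropped window at the
    lowest frequency, otherwise edge effects would leak into the output.
    """
    if freqs is None:
        freqs = np.arange(1.0, 51.0)
    freqs = np.asarray(freqs, dtype=float)
    rate = epochs.rate
    half_support = n_cycles / freqs.min() / 2.0 * 1000.0  # ms
    times = epochs.times_ms
    if times[0] > crop_ms[0] - half_support + 1e-6 or (
        times[-1] < crop_ms[1] + half_support - 1000.0 / rate - 1e-6
    ):
        raise ValueError(
            f"epoch ({times[0]:.0f}..{times[-1]:.0f} ms) too short for "
            f"{n_cycles} cycles at {freqs.min()} Hz around {crop_ms}"
        )

    data = epochs.data
    nan_mask = ~np.isfinite(data)
    filled = np.where(nan_mask, 0.0, data)
    power = tfr_array_morlet(
        filled, sfreq=rate, freqs=freqs, n_cycles=n_cycles,
        output="power", zero_mean=True, verbose="error",
    )  # (n_trials, n_ch, n_freq, n_times)

    if nan_mask.any():
        # dilate the artifact mask by half the wavelet support per frequency
        for fi, f in enumerate(freqs):
            half = int(np.ceil(n_cycles / f / 2.0 * rate))
            kernel = np.ones(2 * half + 1, dtype=bool)
            for tr, ch in zip(*np.nonzero(nan_mask.any(axis=2))):
                bad = np.convolve(nan_mask[tr, ch], kernel, mode="same") > 0
                power[tr, ch, fi, bad] = np.nan

    avg = np.nanmean(power, axis=0)  # trials averaged before dB conversion
    keep = (times >= crop_ms[0]) & (times < crop_ms[1])
    return TimeFrequencyPower(
        power=avg[:, :, keep], frequencies=freqs, times_ms=times[keep], is_db=False
    )


def baseline_normalize_db(
    tfr: TimeFrequencyPower, baseline_ms: tuple[float, float] = (-1000.0, 0.0)
) -> TimeFrequencyPower:
    """Convert power to dB relative to the mean baseline power.

    Per channel x frequency: ``10 * log10(power / mean baseline power)``.
    Scale-invariant: rescaling the raw signal leaves the output unchanged.
    """
    if tfr.is_db:
        raise ValueError("input is already dB-normalized")
    win = tfr.window(*baseline_ms)
    if not win.any():
        raise ValueError(f"baseline window {baseline_ms} outside the epoch")
    base = np.nanmean(tfr.power[:, :, win], axis=2, keepdims=True)
    if np.any(~np.isfinite(base)) or np.any(base <= 0):
        raise ValueError("baseline power is zero or undefined for some channel/frequency")
    return TimeFrequencyPower(
        power=10.0 * np.log10(tfr.power / base),
        frequencies=tfr.frequencies,
        times_ms=tfr.times_ms,
        is_db=True,
        baseline_ms=baseline_ms,
    )


def band_power(
    tfr: TimeFrequencyPower,
    band: tuple[float, float],
    window_ms: tuple[float, float] = (0.0, 1000.0),
) -> np.ndarray:
    """Mean dB over a frequency band and time window, per channel.

    Band limits are inclusive on the frequency grid; the time window is
    half-open.  Missing samples are excluded from the mean.
    """
    fsel = (tfr.frequencies >= band[0]) & (tfr.frequencies <= band[1])
    tsel = tfr.window(*window_ms)
    if not fsel.any() or not tsel.any():
        raise ValueError(f"band {band} / window {window_ms} do not intersect the grid")
    return np.nanmean(tfr.power[:, fsel][:, :, tsel], axis=(1, 2))
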