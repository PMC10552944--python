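"""Phase-amplitude coupling via the Kullback-Leibler modulation index.

Coupling between a slow phase-giving rhythm (f_p) and a fast
amplitude-giving rhythm (f_a) is quantified by binning the instantaneous
phase of the f_p-filtered signal into 18 equal bins on [-pi, pi), taking
the mean f_a amplitude per bin, normalizing the bin means to a
distribution P, and computing

    MI = D_KL(P, Q) / log(N_bin),    Q uniform,

so MI = 0 for amplitude independent of phase and MI = 1 when all
amplitude concentrates in a single bin.  Filter bandwidths follow the
variable-bandwidth rule: f_p is filtered at center +/- 1 Hz (narrow, to
keep the waveform near-sinusoidal) and f_a at center +/- f_p, wide
enough to capture the modulation sidebands.

Comodulograms are evaluated on a phase grid of 2-15 Hz (1-Hz steps) by
an amplitude grid of 16-50 Hz (2-Hz steps), separately for a 0-1000 ms
post-onset speech window and a -1000-0 ms baseline window.  Per-trial MI
values are averaged, then normalized against 200 surrogates built by
pairing the amplitude of each trial with the phase of a different,
randomly chosen trial (destroying the within-trial phase-amplitude
dependency while keeping both marginals).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import Comodulogram, EpochedEEG

N_BINS = 18
PHASE_FREQS = np.arange(2.0, 16.0, 1.0)
AMP_FREQS = np.arange(16.0, 51.0, 2.0)


@dataclass
class BandPair:
    """A phase-frequency / amplitude-frequency filter pair.

    The phase band is ``fp_center +/- fp_half`` (default +/- 1 Hz); the
    amplitude band is ``fa_center +/- fa_half`` where ``fa_half``
    defaults to ``fp_center`` (the variable-bandwidth rule).
    """

    fp_center: float
    fa_center: float
    fp_half: float = 1.0
    fa_half: float | None = None

    def __post_init__(self) -> None:
        if self.fa_half is None:
            self.fa_half = self.fp_center
        if self.fa_center - self.fa_half <= 0:
            raise ValueError(
                f"amplitude band lower edge {self.fa_center - self.fa_half} Hz <= 0"
            )
        if self.fa_center - self.fa_half <= self.fp_center + self.fp_half:
            raise ValueError(
                f"amplitude band ({self.fa_center} +/- {self.fa_half} Hz) must lie "
                f"above the phase band ({self.fp_center} +/- {self.fp_half} Hz)"
            )

    @property
    def phase_band(self) -> tuple[float, float]:
        return (self.fp_center - self.fp_half, self.fp_center + self.fp_half)

    @property
    def amp_band(self) -> tuple[float, float]:
        return (self.fa_center - self.fa_half, self.fa_center + self.fa_half)


def _bandpass(x: np.ndarray, rate: float, band: tuple[float, float], order: int = 3) -> np.ndarray:
    hi = min(band[1], rate / 2 * 0.99)
    sos = signal.butter(order, (band[0], hi), btype="bandpass", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def extract_phase_amp(
    x: np.ndarray, rate: float, pair: BandPair
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous phase and amplitude for a band pair.

    Phase is the angle of the analytic signal of the f_p-filtered data;
    amplitude is the magnitude of the analytic signal of the f_a-filtered
    data (variable bandwidth).  ``x`` is (..., samples).
    """
    x = np.asarray(x, dtype=float)
    phase = np.angle(signal.hilbert(_bandpass(x, rate, pair.phase_band), axis=-1))
    amp = np.abs(signal.hilbert(_bandpass(x, rate, pair.amp_band), axis=-1))
    return phase, amp


def modulation_index(
    phase: np.ndarray, amplitude: np.ndarray, n_bins: int = N_BINS
) -> float:
    """KL modulation index of one phase/amplitude series pair.

    Empty bins contribute 0 to the divergence (the 0*log(0) limit); a
    warning is raised when more than 2 bins are empty, since the series
    is then too short to sample the phase circle.
    """
    phase = np.asarray(phase, dtype=float).ravel()
    amplitude = np.asarray(amplitude, dtype=float).ravel()
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must have equal length")
    if np.any(amplitude < 0):
        raise ValueError("amplitude must be nonnegative")
    bins = phase_bin_indices(phase, n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    sums = np.bincount(bins, weights=amplitude, minlength=n_bins)
    if np.sum(counts == 0) > 2:
        warnings.warn(f"{np.sum(counts == 0)} of {n_bins} phase bins are empty")
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return _mi_from_bin_means(means[None, :])[0]


def phase_bin_indices(phase: np.ndarray, n_bins: int = N_BINS) -> np.ndarray:
    """Left-closed equal phase bins on [-pi, pi); bin 0 starts at -pi."""
    wrapped = np.mod(phase + np.pi, 2 * np.pi)  # [0, 2pi)
    idx = np.floor(wrapped / (2 * np.pi) * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def _mi_from_bin_means(means: np.ndarray) -> np.ndarray:
    """MI for rows of per-bin mean amplitudes (rows sum-normalized to P)."""
    means = np.asarray(means, dtype=float)
    n_bins = means.shape[-1]
    totals = means.sum(axis=-1, keepdims=True)
    safe = np.where(totals > 0, totals, 1.0)
    p = means / safe
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p * n_bins), 0.0)
    mi = terms.sum(axis=-1) / np.log(n_bins)
    return np.where(totals[..., 0] > 0, mi, 0.0)


def mi_analytic_profile(depth: float, n_bins: int = N_BINS) -> float:
    """MI of the analytic amplitude profile ``1 + depth * cos(phase)``.

    Brute-force oracle: the phase is uniform, so the mean amplitude in
    bin i is the average of the profile over the bin, computed here in
    closed form from the integral of cos over the bin edges.
    """
    edges = -np.pi + 2 * np.pi * np.arange(n_bins + 1) / n_bins
    width = 2 * np.pi / n_bins
    means = 1.0 + depth * (np.sin(edges[1:]) - np.sin(edges[:-1])) / width
    return float(_mi_from_bin_means(means[None, :])[0])


# ---------------------------------------------------------------------------
# trial-wise MI with surrogate normalization
# ---------------------------------------------------------------------------

def _pairwise_bin_means(
    phase: np.ndarray, amp: np.ndarray, n_bins: int = N_BINS
) -> np.ndarray:
    """Mean amplitude per bin for every (phase trial i, amplitude trial j).

    Returns an (n_trials, n_trials, n_bins) array M where ``M[i, j]`` is
    the binned-mean profile obtained by pairing the phase of trial i with
    the amplitude of trial j; the diagonal holds the observed pairings.
    """
    n, T = phase.shape
    bins = phase_bin_indices(phase, n_bins)
    M = np.zeros((n, n, n_bins))
    for i in range(n):
        onehot = np.zeros((T, n_bins))
        onehot[np.arange(T), bins[i]] = 1.0
        counts = onehot.sum(axis=0)
        sums = amp @ onehot  # (n_trials, n_bins)
        M[i] = sums / np.maximum(counts, 1.0)
        M[i][:, counts == 0] = 0.0
    return M


def trial_mi_with_surrogates(
    phase: np.ndarray,
    amp: np.ndarray,
    n_surrogates: int = 200,
    rng: np.random.Generator | None = None,
    n_bins: int = N_BINS,
) -> tuple[float, float, float, float]:
    """Observed trial-averaged MI and its surrogate normalization.

    ``phase`` and ``amp`` are (n_trials, n_samples).  The observed value
    averages per-trial MI.  Each surrogate pairs the amplitude of every
    trial with the phase of a random *different* trial and averages the
    mismatched MIs.  Returns ``(mi_obs, z, surr_mean, surr_sd)``.
    """
    if phase.shape[0] < 2:
        raise ValueError("surrogate normalization needs at least 2 trials")
    rng = np.random.default_rng() if rng is None else rng
    n = phase.shape[0]
    M = _pairwise_bin_means(phase, amp, n_bins)
    mi_pair = _mi_from_bin_means(M.reshape(n * n, n_bins)).reshape(n, n)
    mi_obs = float(np.mean(np.diag(mi_pair)))

    surr = np.empty(n_surrogates)
    for s in range(n_surrogates):
        # phase trial for each amplitude trial j: random i != j
        i = rng.integers(0, n - 1, size=n)
        i += i >= np.arange(n)
        surr[s] = mi_pair[i, np.arange(n)].mean()
    mu, sd = float(surr.mean()), float(surr.std(ddof=1))
    z = (mi_obs - mu) / sd if sd > 0 else np.nan
    return mi_obs, z, mu, sd


def screen_phase_spectrum(
    trials: np.ndarray, rate: float, phase_freqs: np.ndarray, tol_hz: float = 1.0
) -> np.ndarray:
    """Automated check that the power spectrum has a local peak or trough
    near each candidate phase frequency.

    Replaces the visual peak/trough inspection of the modulating-band
    spectrum: the trial-averaged Welch spectrum must contain a local
    extremum within ``tol_hz`` of the candidate frequency.  Frequencies
    failing the check are flagged (cells are never dropped).
    """
    finite = np.where(np.isfinite(trials), trials, 0.0)
    nper = min(trials.shape[-1], int(rate * 2))
    f, pxx = signal.welch(finite, fs=rate, nperseg=nper, axis=-1)
    spec = pxx.mean(axis=0) if pxx.ndim > 1 else pxx
    d = np.diff(np.log(spec + 1e-300))
    extrema = f[1:-1][np.sign(d[:-1]) != np.sign(d[1:])]
    return np.array(
        [np.any(np.abs(extrema - fp) <= tol_hz) for fp in phase_freqs], dtype=bool
    )


def comodulogram(
    trials: np.ndarray,
    rate: float,
    phase_freqs: np.ndarray = PHASE_FREQS,
    amp_freqs: np.ndarray = AMP_FREQS,
    n_surrogates: int = 200,
    rng: np.random.Generator | None = None,
    condition: str = "speech",
    cluster: str = "all",
    min_trials: int = 10,
) -> Comodulogram:
    """Surrogate-normalized comodulogram of a set of trials.

    ``trials`` is (n_trials, n_samples): one representative time course
    per trial (for an electrode cluster, the signal averaged across the
    cluster's electrodes).  Cells whose amplitude band would not clear
    the phase band, or whose band edges exceed Nyquist, are left NaN.
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    if trials.shape[0] < min_trials:
        raise ValueError(f"need >= {min_trials} trials, got {trials.shape[0]}")
    rng = np.random.default_rng() if rng is None else rng
    finite = np.where(np.isfinite(trials), trials, 0.0)

    nf_p, nf_a = len(phase_freqs), len(amp_freqs)
    mi = np.full((nf_p, nf_a), np.nan)
    z = np.full((nf_p, nf_a), np.nan)
    smu = np.full((nf_p, nf_a), np.nan)
    ssd = np.full((nf_p, nf_a), np.nan)
    screening = screen_phase_spectrum(trials, rate, np.asarray(phase_freqs))

    for pi, fp in enumerate(phase_freqs):
        phase = np.angle(
            signal.hilbert(_bandpass(finite, rate, (fp - 1.0, fp + 1.0)), axis=-1)
        )
        for ai, fa in enumerate(amp_freqs):
            lo, hi = fa - fp, fa + fp
            if lo <= fp + 1.0 or hi >= rate / 2:
                continue
            amp = np.abs(signal.hilbert(_bandpass(finite, rate, (lo, hi)), axis=-1))
            obs, zc, mu, sd = trial_mi_with_surrogates(
                phase, amp, n_surrogates=n_surrogates, rng=rng
            )
            mi[pi, ai], z[pi, ai], smu[pi, ai], ssd[pi, ai] = obs, zc, mu, sd

    return Comodulogram(
        phase_freqs=np.asarray(phase_freqs, float),
        amp_freqs=np.asarray(amp_freqs, float),
        mi=np.clip(mi, 0.0, 1.0),
        surrogate_mean=smu,
        surrogate_sd=ssd,
        z=z,
        condition=condition,
        cluster=cluster,
        screening=screening,
    )


def comodulogram_conditions(
    epochs: EpochedEEG,
    channels: list[str] | None = None,
    windows: dict[str, tuple[float, float]] | None = None,
    cluster: str = "all",
    **kwargs,
) -> dict[str, Comodulogram]:
    """Comodulograms for the speech (0-1000 ms) and baseline (-1000-0 ms)
    windows of an epoched recording.

    The signals of the requested channels are averaged into one
    representative time course per trial before phase/amplitude
    extraction.
    """
    if windows is None:
        windows = {"speech": (0.0, 1000.0), "baseline": (-1000.0, 0.0)}
    if channels is None:
        channels = epochs.ch_names
    idx = [epochs.ch_names.index(ch) for ch in channels]
    mean_ts = np.nanmean(epochs.data[:, idx, :], axis=1)  # (trials, samples)
    out = {}
    for name, (t0, t1) in windows.items():
        sel = epochs.time_window(t0, t1)
        out[name] = comodulogram(
            mean_ts[:, sel], epochs.rate, condition=name, cluster=cluster, **kwargs
        )
    return out
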