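"""Shared in-memory containers for the analysis pipeline.

The pipeline's time convention is milliseconds relative to speech-chunk
onset: sample index 0 corresponds to onset, intervals are half-open
``[start, end)``.  Artifact samples are carried as NaN and propagate as
"missing" through downstream averages.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpeechEnvelope",
    "EnvelopeSpectrum",
    "EpochedEEG",
    "TimeFrequencyPower",
    "TrackingResult",
    "Comodulogram",
    "GazeDensityMap",
    "GazeDistanceResult",
    "ClusterResult",
    "GroupComparison",
    "PredictionResult",
]


@dataclass
class SpeechEnvelope:
    """Amplitude-modulation time series of an audio stimulus.

    Parameters
    ----------
    samples : ndarray, shape (n,)
        Nonnegative envelope amplitude.
    rate : float
        Sampling rate in Hz (1000 after the standard processing chain).
    chunks : ndarray, shape (n_chunks, 2)
        Speech-chunk annotations as (onset_ms, offset_ms) rows, sorted and
        non-overlapping, half-open.
    """

    samples: np.ndarray
    rate: float
    chunks: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.chunks = np.asarray(self.chunks, dtype=float).reshape(-1, 2)
        if self.samples.ndim != 1:
            raise ValueError("envelope samples must be one-dimensional")
        if np.any(self.samples < 0):
            raise ValueError("envelope samples must be nonnegative")
        if len(self.chunks):
            if np.any(np.diff(self.chunks[:, 0]) < 0):
                raise ValueError("chunks must be sorted by onset")
            if np.any(self.chunks[:, 1] <= self.chunks[:, 0]):
                raise ValueError("chunk offsets must exceed onsets")
            if np.any(self.chunks[1:, 0] < self.chunks[:-1, 1]):
                raise ValueError("chunks must not overlap")

    @property
    def duration_ms(self) -> float:
        return len(self.samples) / self.rate * 1000.0

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.rate * 1000.0


@dataclass
class EnvelopeSpectrum:
    """One-sided power spectrum of a speech envelope with detected peaks."""

    frequencies: np.ndarray
    power: np.ndarray
    peaks: pd.DataFrame  # columns: frequency, height

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly ascending")


@dataclass
class EpochedEEG:
    """Trials x channels x samples EEG with montage and trial annotations.

    ``data`` holds amplitude in microvolts; artifact samples are NaN.
    ``tmin_ms`` gives the time of sample 0 relative to chunk onset (so a
    (-1000, +1000) ms epoch around onset has ``tmin_ms = -1000``).
    """

    data: np.ndarray
    rate: float
    ch_names: list[str]
    montage: dict[str, np.ndarray]
    trials: pd.DataFrame  # columns: onset_ms, duration_ms, condition
    tmin_ms: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError(
                f"channel count {self.data.shape[1]} does not match "
                f"{len(self.ch_names)} channel names"
            )
        missing = [ch for ch in self.ch_names if ch not in self.montage]
        if missing:
            raise ValueError(f"montage lacks positions for {missing[:5]}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        return self.tmin_ms + np.arange(self.data.shape[2]) / self.rate * 1000.0

    def positions(self) -> np.ndarray:
        """Sensor positions as an (n_channels, ndim) array in montage order."""
        return np.array([self.montage[ch] for ch in self.ch_names], dtype=float)

    def time_window(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """Boolean sample mask for the half-open window [start_ms, stop_ms)."""
        t = self.times_ms
        return (t >= start_ms) & (t < stop_ms)


@dataclass
class TimeFrequencyPower:
    """Trial-averaged wavelet power, channels x frequencies x time."""

    power: np.ndarray
    frequencies: np.ndarray
    times_ms: np.ndarray
    is_db: bool = False
    baseline_ms: tuple[float, float] | None = None

    def window(self, start_ms: float, stop_ms: float) -> np.ndarray:
        return (self.times_ms >= start_ms) & (self.times_ms < stop_ms)


@dataclass
class TrackingResult:
    """Stimulus-reconstruction accuracy for one participant / band / scope."""

    participant: str
    band: str
    scope: str  # "all" or a channel label
    fold_r: np.ndarray
    pooled_r: float
    n_folds: int


@dataclass
class Comodulogram:
    """Modulation-index grid over (phase frequency, amplitude frequency).

    ``mi`` is the raw trial-averaged modulation index; ``z`` the
    surrogate-normalized score.  ``screening`` flags phase frequencies at
    which the low-frequency power spectrum shows no local peak/trough
    (cells are flagged, never dropped).
    """

    phase_freqs: np.ndarray
    amp_freqs: np.ndarray
    mi: np.ndarray
    surrogate_mean: np.ndarray | None = None
    surrogate_sd: np.ndarray | None = None
    z: np.ndarray | None = None
    condition: str = "speech"
    cluster: str = "all"
    screening: np.ndarray | None = None  # bool per phase frequency

    def __post_init__(self) -> None:
        expected = (len(self.phase_freqs), len(self.amp_freqs))
        if self.mi.shape != expected:
            raise ValueError(f"mi grid shape {self.mi.shape} != {expected}")
        if np.any(self.mi < -1e-12) or np.any(self.mi > 1 + 1e-12):
            raise ValueError("modulation index must lie in [0, 1]")

    def argmax_cell(self, use_z: bool = True) -> tuple[float, float]:
        grid = self.z if (use_z and self.z is not None) else self.mi
        i, j = np.unravel_index(np.nanargmax(grid), grid.shape)
        return float(self.phase_freqs[i]), float(self.amp_freqs[j])

    def coupling_centroid(self, z_threshold: float = 2.0) -> tuple[float, float]:
        """Coupling location as the z-weighted centroid of the significant blob.

        Because the variable-bandwidth rule makes adjacent amplitude
        cells within +/- f_p of a true coupling carry nearly identical
        information, the raw grid argmax jitters across the blob; the
        centroid of cells with z above ``z_threshold``, snapped to the
        nearest grid cell, is the stable location estimate.
        """
        z = np.where(np.isfinite(self.z), self.z, 0.0) if self.z is not None else self.mi
        w = np.where(z > z_threshold, z, 0.0)
        if w.sum() == 0:
            return (np.nan, np.nan)
        fp = float(w.sum(axis=1) @ self.phase_freqs) / w.sum()
        fa = float(w.sum(axis=0) @ self.amp_freqs) / w.sum()
        return (
            float(self.phase_freqs[np.argmin(np.abs(self.phase_freqs - fp))]),
            float(self.amp_freqs[np.argmin(np.abs(self.amp_freqs - fa))]),
        )


@dataclass
class GazeDensityMap:
    """Kernel density of gaze points on a pixel grid (unit mass)."""

    xs: np.ndarray  # grid cell-center x coordinates, pixels
    ys: np.ndarray
    density: np.ndarray  # shape (len(ys), len(xs))
    scope: str = ""

    @property
    def cell_area(self) -> float:
        dx = self.xs[1] - self.xs[0] if len(self.xs) > 1 else 1.0
        dy = self.ys[1] - self.ys[0] if len(self.ys) > 1 else 1.0
        return float(dx * dy)

    def mass(self) -> float:
        return float(self.density.sum() * self.cell_area)


@dataclass
class GazeDistanceResult:
    """Observed EMD ranked within a label-permutation null distribution."""

    observed: float
    null: np.ndarray
    rank: int  # 1 + number of null values strictly below observed, in [1, n+1]
    significant: bool
    n_permutations: int

    def p_value(self) -> float:
        """One-tailed Monte-Carlo p with the standard +1 correction."""
        return (1 + np.sum(self.null >= self.observed)) / (self.n_permutations + 1)


@dataclass
class ClusterResult:
    """Clusters of adjacent suprathreshold elements with permutation p-values."""

    clusters: list[dict]  # members, stat (max |t|), p
    n_permutations: int
    alpha: float
    test: str  # "independent" or "dependent"
    covariate_used: bool = False
    t_obs: np.ndarray | None = None

    def significant(self) -> list[dict]:
        return [c for c in self.clusters if c["p"] < self.alpha]


@dataclass
class GroupComparison:
    """Two-group scalar comparison (pooled t or Kolmogorov-Smirnov)."""

    variable: str
    mean_x: float
    sd_x: float
    n_x: int
    mean_y: float
    sd_y: float
    n_y: int
    statistic: float
    df: int | None
    p: float
    eta_sq: float | None = None
    kind: str = "t"


@dataclass
class PredictionResult:
    """Nested cross-validation outcome for one feature set and target."""

    task: str  # "severity-3-class" or "score-regression"
    fold_metric: np.ndarray
    metric: float  # pooled accuracy (%) or mean R^2
    chance_threshold: float | None = None
    coefficients: dict | None = None
    feature_names: list[str] | None = None
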