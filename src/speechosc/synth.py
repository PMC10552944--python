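"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:
speech envelopes with a handful of discrete modulation peaks in the
1-7 Hz range; EEG epochs made of 1/f (pink) background noise carrying a
lag-embedded band-filtered copy of the envelope at a controllable SNR
and a phase-amplitude-coupled oscillation pair of controllable
(f_p, f_a, depth); two-group gaze point clouds drawn from Gaussian
mixtures of controllable divergence; and a two-group cohort with ADOS
severity grades and correlated cognitive scores.

Every generator is a pure function of its spec (the seed lives in the
spec); each dataset ships a ground-truth registry so recovery tests can
score themselves automatically.

Default cohort parameters mirror the study population: 31 affected and
33 typically developing participants, mean ages near 3 years, and the
group means / SDs of the published behavioral summary.  Default signal
parameters are 1000 Hz sampling, 50 trials of ~2.4 s, 110 channels,
theta-band envelope embedding at a 100-ms lag, and a (6 Hz, 36 Hz)
coupling at depth 0.8.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EpochedEEG, SpeechEnvelope
from .io import severity_from_ados
from .preprocess import make_synthetic_montage

# Behavioral summary statistics of the reference cohort (mean, sd) per group.
COHORT_SCORE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "age": {"ASD": (3.09, 0.91), "TD": (2.92, 1.30)},
    "mullen_vr_dq": {"ASD": (87.18, 26.37), "TD": (126.13, 27.28)},
    "mullen_fm_dq": {"ASD": (82.42, 21.29), "TD": (103.22, 12.01)},
    "mullen_el_dq": {"ASD": (58.52, 31.69), "TD": (104.77, 24.08)},
    "mullen_rl_dq": {"ASD": (62.12, 33.37), "TD": (117.62, 18.98)},
    "vineland_el": {"ASD": (10.94, 3.55), "TD": (17.15, 2.14)},
    "vineland_rl": {"ASD": (11.00, 2.80), "TD": (16.27, 2.11)},
}


@dataclass
class PacSpec:
    f_p: float = 6.0
    f_a: float = 36.0
    depth: float = 0.8
    channels: tuple[str, ...] = ()
    slow_amp: float = 1.0
    fast_amp: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError("coupling depth must lie in [0, 1]")
        if self.f_a - self.f_p <= 2.0:
            raise ValueError(
                f"f_a ({self.f_a}) must exceed f_p ({self.f_p}) by more than "
                "the 2-Hz analysis bandwidth"
            )


@dataclass
class GazeGroupSpec:
    """Per-group Gaussian mixture over screen coordinates."""

    means: tuple[tuple[float, float], ...] = ((760.0, 560.0), (1160.0, 640.0))
    sds: tuple[float, ...] = (150.0, 150.0)
    weights: tuple[float, ...] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")


@dataclass
class SimulationSpec:
    n_per_group: tuple[int, int] = (31, 33)  # (ASD, TD)
    n_trials: int = 50
    trial_ms: float = 2400.0
    pre_ms: float = 1000.0
    rate: float = 1000.0
    n_channels: int = 110
    # envelope
    envelope_peaks: tuple[float, ...] = (1.2, 3.3, 4.7)
    envelope_depth: float = 0.5
    # tracking embedding
    embed_lag_ms: float = 100.0
    embed_band: tuple[float, float] = (4.0, 8.0)
    snr: float = 1.0
    embed_channels: tuple[str, ...] = ("E1",)
    # phase-amplitude coupling (default: a 6-electrode cluster, matching how
    # coupling is analyzed — one representative time course per cluster)
    pac: tuple[PacSpec, ...] = (
        PacSpec(channels=("E1", "E2", "E3", "E4", "E5", "E6")),
    )
    # gaze
    n_frames: int = 20
    points_per_frame: int = 5
    screen: tuple[float, float] = (1920.0, 1200.0)
    gaze_groups: dict = field(
        default_factory=lambda: {"ASD": GazeGroupSpec(), "TD": GazeGroupSpec()}
    )
    # cohort
    score_params: dict = field(default_factory=lambda: dict(COHORT_SCORE_PARAMS))
    score_correlation: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), default=list, indent=1))


def _rng(spec: SimulationSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n: int) -> np.ndarray:
    """1/f-amplitude noise along the last axis, unit variance."""
    white = rng.standard_normal(shape + (n,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    with np.errstate(divide="ignore"):
        scale = np.where(freqs > 0, 1.0 / np.sqrt(np.maximum(freqs, 1e-300)), 0.0)
    pink = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = pink.std(axis=-1, keepdims=True)
    return pink / np.where(sd > 0, sd, 1.0)


# ---------------------------------------------------------------------------
# envelope
# ---------------------------------------------------------------------------

def gen_envelope(spec: SimulationSpec) -> SpeechEnvelope:
    """Nonnegative envelope with discrete modulation peaks and chunk table.

    Built as ``1 + depth * sum_k cos(2 pi f_k t + phi_k) / K`` plus a
    touch of slow noise, clipped at zero.  Chunks tile the signal with
    200-ms silent gaps, one chunk per trial.
    """
    if spec.trial_ms < 2000.0 and spec.n_trials * spec.trial_ms < 2000.0:
        raise ValueError("total envelope duration must be at least 2 s")
    rng = _rng(spec, 1)
    gap_ms = 200.0
    total_ms = spec.n_trials * (spec.trial_ms + gap_ms) + gap_ms
    n = int(round(total_ms * spec.rate / 1000.0))
    t = np.arange(n) / spec.rate
    peaks = np.asarray(spec.envelope_peaks, dtype=float)
    env = np.ones(n)
    if len(peaks) and spec.envelope_depth > 0:
        phases = rng.uniform(0, 2 * np.pi, size=len(peaks))
        mod = np.sum(
            [np.cos(2 * np.pi * f * t + ph) for f, ph in zip(peaks, phases)], axis=0
        )
        env += spec.envelope_depth * mod / len(peaks)
        env += 0.02 * _pink_noise(rng, (), n)
    env = np.clip(env, 0.0, None)
    onsets = gap_ms + np.arange(spec.n_trials) * (spec.trial_ms + gap_ms)
    chunks = np.column_stack([onsets, onsets + spec.trial_ms])
    return SpeechEnvelope(samples=env, rate=spec.rate, chunks=chunks)


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def gen_eeg(
    spec: SimulationSpec, envelope: SpeechEnvelope, participant_stream: int = 0
) -> tuple[EpochedEEG, dict]:
    """Epoched EEG: pink background + lagged envelope embedding + coupling.

    Each trial spans ``[-pre_ms, trial_ms)`` around a chunk onset.  The
    pre-onset baseline holds background noise only.  On the embedding
    channels the band-filtered, z-scored envelope chunk is added from
    onset on, delayed by ``embed_lag_ms`` and scaled to ``snr`` (amplitude
    ratio against the unit-variance background).  On the coupling
    channels a slow narrowband oscillation at f_p (filtered noise, so its
    phase is stochastic) is added together with a fast component
    ``fast_amp * (1 + depth cos(phi_p)) * cos(2 pi f_a t)``.
    """
    if envelope.duration_ms < spec.n_trials * spec.trial_ms:
        raise ValueError("envelope does not cover the requested trials")
    for pac in spec.pac:
        _ = PacSpec(pac.f_p, pac.f_a, pac.depth)  # re-validate bandwidth rule
    rng = _rng(spec, 1000 + participant_stream)
    rate = spec.rate
    n_pre = int(round(spec.pre_ms * rate / 1000.0))
    n_post = int(round(spec.trial_ms * rate / 1000.0))
    n_samp = n_pre + n_post
    montage = make_synthetic_montage(spec.n_channels)
    ch_names = list(montage)
    data = _pink_noise(rng, (spec.n_trials, spec.n_channels), n_samp)

    # envelope embedding: the envelope amplitude-modulates a carrier at the
    # band center.  Because a band of half-width w can only carry amplitude
    # modulation below w, the modulator is the envelope low-passed at the
    # half-width — the band amplitude then tracks exactly the envelope
    # content that band could physically represent.
    f_lo, f_hi = spec.embed_band
    half_width = (f_hi - f_lo) / 2.0
    f_center = (f_hi + f_lo) / 2.0
    sos = signal.butter(4, half_width, btype="low", fs=rate, output="sos")
    mod_env = np.clip(signal.sosfiltfilt(sos, envelope.samples), 0.0, None)
    lag = int(round(spec.embed_lag_ms * rate / 1000.0))
    embed_idx = [ch_names.index(ch) for ch in spec.embed_channels]
    t_carrier = np.arange(n_post) / rate
    for k, (onset, offset) in enumerate(envelope.chunks[: spec.n_trials]):
        i0 = int(round(onset * rate / 1000.0))
        seg = mod_env[i0 - lag : i0 - lag + n_post] if i0 >= lag else None
        if seg is None or len(seg) < n_post:
            continue
        sd = seg.std()
        carrier = np.cos(2 * np.pi * f_center * t_carrier + rng.uniform(0, 2 * np.pi))
        for ci in embed_idx:
            data[k, ci, n_pre:] += spec.snr * (seg / (sd if sd > 0 else 1.0)) * carrier

    # phase-amplitude coupling components (post-onset only)
    t_post = np.arange(n_post) / rate
    for pac in spec.pac:
        idx = [ch_names.index(ch) for ch in pac.channels] or embed_idx
        carrier = _pink_noise(rng, (spec.n_trials,), n_post)
        sos_p = signal.butter(
            3, (pac.f_p - 1.0, pac.f_p + 1.0), btype="bandpass", fs=rate, output="sos"
        )
        slow = signal.sosfiltfilt(sos_p, carrier, axis=-1)
        slow /= slow.std(axis=-1, keepdims=True)
        phi = np.angle(signal.hilbert(slow, axis=-1))
        fast = (
            pac.fast_amp
            * (1.0 + pac.depth * np.cos(phi))
            * np.cos(2 * np.pi * pac.f_a * t_post)[None, :]
        )
        for ci in idx:
            data[:, ci, n_pre:] += pac.slow_amp * slow + fast

    trials = pd.DataFrame(
        {
            "onset_ms": envelope.chunks[: spec.n_trials, 0],
            "duration_ms": spec.trial_ms,
            "condition": "speech",
        }
    )
    epochs = EpochedEEG(
        data=data,
        rate=rate,
        ch_names=ch_names,
        montage=montage,
        trials=trials,
        tmin_ms=-spec.pre_ms,
    )
    truth = {
        "embed_lag_ms": spec.embed_lag_ms,
        "embed_band": list(spec.embed_band),
        "snr": spec.snr,
        "embed_channels": list(spec.embed_channels),
        "pac": [
            {
                "f_p": p.f_p,
                "f_a": p.f_a,
                "depth": p.depth,
                "channels": list(p.channels) or list(spec.embed_channels),
            }
            for p in spec.pac
        ],
    }
    return epochs, truth


# ---------------------------------------------------------------------------
# gaze
# ---------------------------------------------------------------------------

def gen_gaze(spec: SimulationSpec) -> tuple[pd.DataFrame, dict]:
    """Two-group gaze streams drawn from per-group Gaussian mixtures.

    Every participant contributes ``points_per_frame`` fixation points
    per frame, clipped to the screen.
    """
    if spec.n_frames < 1:
        raise ValueError("need at least one frame")
    if spec.screen[0] <= 0 or spec.screen[1] <= 0:
        raise ValueError("screen bounds must be positive")
    rng = _rng(spec, 2)
    rows = []
    frame_dt = 1000.0 / 30.0
    for gi, (group, n_grp) in enumerate(zip(("ASD", "TD"), spec.n_per_group)):
        mix: GazeGroupSpec = spec.gaze_groups[group]
        means = np.asarray(mix.means, dtype=float)
        sds = np.asarray(mix.sds, dtype=float)
        weights = np.asarray(mix.weights, dtype=float)
        for p in range(n_grp):
            pid = f"{group}{p + 1:02d}"
            for fr in range(spec.n_frames):
                comp = rng.choice(len(weights), size=spec.points_per_frame, p=weights)
                pts = means[comp] + rng.standard_normal(
                    (spec.points_per_frame, 2)
                ) * sds[comp][:, None]
                pts[:, 0] = np.clip(pts[:, 0], 0, spec.screen[0])
                pts[:, 1] = np.clip(pts[:, 1], 0, spec.screen[1])
                for t_i, (x, y) in enumerate(pts):
                    rows.append(
                        {
                            "participant": pid,
                            "frame": fr,
                            "t_ms": fr * frame_dt + t_i,
                            "x_px": x,
                            "y_px": y,
                        }
                    )
    truth = {
        group: asdict(spec.gaze_groups[group]) for group in ("ASD", "TD")
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

_ADOS_WEIGHTS = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 3.0, 3.0])  # totals 3..10


def gen_cohort(spec: SimulationSpec) -> tuple[pd.DataFrame, dict]:
    """Two-group cohort with severity grades and correlated scores.

    Scores are drawn per group from the configured (mean, sd) with a
    shared latent factor inducing correlation ``score_correlation``
    across scores within a participant.  ADOS totals are 1 for the
    typical group and drawn over 3-10 for the affected group; severity
    grades follow the 3-4 / 5-7 / 8-10 mapping.  ``missing_rate``
    removes score cells at random (explicit NaN, never zero).
    """
    rng = _rng(spec, 3)
    rho = spec.score_correlation
    score_names = [k for k in spec.score_params if k != "age"]
    rows = []
    for group, n_grp in zip(("ASD", "TD"), spec.n_per_group):
        for p in range(n_grp):
            latent = rng.standard_normal()
            age_mu, age_sd = spec.score_params["age"][group]
            age = max(1.0, rng.normal(age_mu, age_sd))
            if group == "ASD":
                total = int(rng.choice(np.arange(3, 11), p=_ADOS_WEIGHTS / _ADOS_WEIGHTS.sum()))
            else:
                total = 1
            rec = {
                "participant": f"{group}{p + 1:02d}",
                "group": group,
                "gender": "F" if rng.random() < 0.27 else "M",
                "age": age,
                "ados_total": total,
                "severity": severity_from_ados(total),
            }
            for name in score_names:
                mu, sd = spec.score_params[name][group]
                z = np.sqrt(rho) * latent + np.sqrt(1 - rho) * rng.standard_normal()
                val = mu + sd * z
                if spec.missing_rate > 0 and rng.random() < spec.missing_rate:
                    val = np.nan
                rec[name] = val
            rows.append(rec)
    truth = {
        "score_params": {
            k: {g: list(v) for g, v in d.items()} for k, d in spec.score_params.items()
        },
        "score_correlation": rho,
    }
    return pd.DataFrame(rows), truth
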