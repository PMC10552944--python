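"""Run configuration: frequency bands, analysis grids, and fixed constants.

Defaults encode the analysis constants used throughout the pipeline:
bands delta 1-3, theta 4-8, alpha 8-12, beta 12-20 and low-gamma 25-35 Hz;
reconstruction lags -300..300 ms in 50-ms steps; comodulogram grid with
phase frequencies 2-15 Hz (1-Hz steps) and amplitude frequencies 16-50 Hz
(2-Hz steps); 200 surrogates; 1000 permutations; alpha = 0.05.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 20.0),
    "low_gamma": (25.0, 35.0),
}


def _default_lags() -> list[float]:
    return [float(v) for v in range(-300, 301, 50)]


def _default_phase_freqs() -> list[float]:
    return [float(v) for v in range(2, 16)]


def _default_amp_freqs() -> list[float]:
    return [float(v) for v in range(16, 51, 2)]


@dataclass
class Config:
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    lags_ms: list[float] = field(default_factory=_default_lags)
    pac_phase_freqs: list[float] = field(default_factory=_default_phase_freqs)
    pac_amp_freqs: list[float] = field(default_factory=_default_amp_freqs)
    n_surrogates: int = 200
    n_permutations: int = 1000
    alpha: float = 0.05
    random_seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bands = {k: (float(lo), float(hi)) for k, (lo, hi) in self.bands.items()}
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name!r}: low {lo} must be < high {hi}")
        lags = np.asarray(self.lags_ms, dtype=float)
        if not np.allclose(np.sort(lags), np.sort(-lags)):
            raise ValueError("lag grid must be symmetric about 0 ms")
        for attr in ("n_surrogates", "n_permutations"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = {k: list(v) for k, v in d["bands"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        d = dict(d)
        if "bands" in d:
            d["bands"] = {k: tuple(v) for k, v in d["bands"].items()}
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        """Stable digest of the resolved configuration, for run logs."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
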