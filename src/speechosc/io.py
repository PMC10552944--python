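"""Readers and writers for the pipeline's external formats.

Covers the psychometric cohort CSV, the plain-array EEG fixture format
(flat float32 binary + JSON sidecar), EDF and EEGLAB ``.set`` epoch
reading (via MNE), the gaze CSV and WAV audio.

Every reader/writer pair round-trips bit-identically on fixture data.
Missing psychometric values are explicit NaN, never silent zeros.
"""
from __future__ import annotations

import csv
import importlib.resources
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .containers import EpochedEEG

COHORT_COLUMNS = [
    "group", "gender", "age", "ados_total", "ados_sa", "ados_rrb", "severity",
    "mullen_vr_dq", "mullen_vr_raw", "mullen_vr_t",
    "mullen_fm_dq", "mullen_fm_raw", "mullen_fm_t",
    "mullen_el_dq", "mullen_el_raw", "mullen_el_t",
    "mullen_rl_dq", "mullen_rl_raw", "mullen_rl_t",
    "vineland_rl", "vineland_el",
]
_NUMERIC_COHORT = [c for c in COHORT_COLUMNS if c not in ("group", "gender", "severity")]
GAZE_COLUMNS = ["participant", "frame", "t_ms", "x_px", "y_px"]


def severity_from_ados(total: float) -> str:
    """Map an ADOS calibrated severity score to a symptom grade.

    Scores 3-4 map to "low", 5-7 to "moderate", 8-10 to "high"; scores
    below 3 (non-spectrum) map to "none".
    """
    if np.isnan(total):
        return "none"
    if total < 3:
        return "none"
    if total <= 4:
        return "low"
    if total <= 7:
        return "moderate"
    if total <= 10:
        return "high"
    raise ValueError(f"ADOS total {total} outside the 1-10 calibrated range")


# ---------------------------------------------------------------------------
# cohort table
# ---------------------------------------------------------------------------

def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read a per-participant psychometric CSV.

    Cells containing "/" (or left empty) are parsed as missing.  The
    severity grade of each row is checked against the ADOS mapping; a
    malformed row raises an error naming its line number.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, not an empty table") from None
        if [h.strip() for h in header] != COHORT_COLUMNS:
            raise ValueError(f"{path}: unexpected column header {header[:4]}...")
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(COHORT_COLUMNS):
                raise ValueError(
                    f"{path} line {lineno}: expected {len(COHORT_COLUMNS)} "
                    f"fields, got {len(row)}"
                )
            rec = dict(zip(COHORT_COLUMNS, (c.strip() for c in row)))
            if rec["group"] not in ("ASD", "TD"):
                raise ValueError(
                    f"{path} line {lineno}: unknown group label {rec['group']!r}"
                )
            for col in _NUMERIC_COHORT:
                val = rec[col]
                rec[col] = np.nan if val in ("/", "") else float(val)
            if rec["severity"] in ("/", ""):
                rec["severity"] = "none"
            rows.append(rec)
    if not rows:
        raise ValueError(f"{path}: no participant rows")
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    if np.any(df["age"] <= 0):
        raise ValueError(f"{path}: ages must be positive")
    expected = df["ados_total"].map(severity_from_ados)
    bad = df.index[df["severity"] != expected]
    if len(bad):
        raise ValueError(
            f"{path} line {bad[0] + 2}: severity grade "
            f"{df.loc[bad[0], 'severity']!r} inconsistent with ADOS total "
            f"{df.loc[bad[0], 'ados_total']}"
        )
    df.attrs["group_counts"] = df["group"].value_counts().to_dict()
    return df


def load_reference_cohort() -> pd.DataFrame:
    """Load the packaged per-participant psychometric table (31 ASD, 33 TD)."""
    ref = importlib.resources.files("speechosc.data") / "cohort_psychometrics.csv"
    with importlib.resources.as_file(ref) as path:
        return read_cohort_table(path)


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df[COHORT_COLUMNS].copy()
    out.to_csv(path, index=False, na_rep="/")


# ---------------------------------------------------------------------------
# fixture EEG format: flat float32 binary + JSON sidecar
# ---------------------------------------------------------------------------

def write_eeg_fixture(epochs: EpochedEEG, prefix: str | Path) -> None:
    """Write an EpochedEEG as ``<prefix>.bin`` (float32, C order) + ``<prefix>.json``."""
    prefix = Path(prefix)
    data = np.ascontiguousarray(epochs.data, dtype=np.float32)
    prefix.with_suffix(".bin").write_bytes(data.tobytes())
    sidecar = {
        "shape": list(data.shape),
        "rate": epochs.rate,
        "tmin_ms": epochs.tmin_ms,
        "ch_names": epochs.ch_names,
        "montage": {ch: list(map(float, p)) for ch, p in epochs.montage.items()},
        "trials": epochs.trials.to_dict(orient="list"),
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_eeg_fixture(prefix: str | Path) -> EpochedEEG:
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    shape = tuple(sidecar["shape"])
    raw = np.frombuffer(prefix.with_suffix(".bin").read_bytes(), dtype=np.float32)
    data = raw.reshape(shape).astype(float)
    trials = pd.DataFrame(sidecar["trials"])
    if trials.empty:
        raise ValueError(f"{prefix}: no trial annotations")
    return EpochedEEG(
        data=data,
        rate=sidecar["rate"],
        ch_names=list(sidecar["ch_names"]),
        montage={ch: np.asarray(p, float) for ch, p in sidecar["montage"].items()},
        trials=trials,
        tmin_ms=sidecar["tmin_ms"],
    )


# ---------------------------------------------------------------------------
# EDF (continuous multichannel) + events sidecar
# ---------------------------------------------------------------------------

def write_edf(
    data: np.ndarray,
    rate: float,
    ch_names: list[str],
    path: str | Path,
    events: pd.DataFrame | None = None,
) -> None:
    """Write continuous (channels x samples) data to a minimal EDF file.

    Samples are scaled to the 16-bit integer range per channel.  Trial
    events, if given, go to a ``<path>.events.json`` sidecar (onset_ms,
    duration_ms, condition), which :func:`read_eeg` picks up.
    """
    path = Path(path)
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    spr = int(round(rate))  # one-second data records
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = np.nan_to_num(data)

    phys_min = padded.min(axis=1)
    phys_max = padded.max(axis=1)
    span = np.where(phys_max - phys_min < 1e-9, 1.0, phys_max - phys_min)
    dig = np.round(
        (padded - phys_min[:, None]) / span[:, None] * 65534 - 32767
    ).astype("<i2")

    def f(text: str, width: int) -> bytes:
        return text.ljust(width)[:width].encode("ascii")

    header = b"".join([
        f("0", 8), f("X X X X", 80), f("Startdate X X X X", 80),
        f("01.01.00", 8), f("00.00.00", 8),
        f(str(256 * (n_ch + 1)), 8), f("", 44),
        f(str(n_rec), 8), f("1", 8), f(str(n_ch), 4),
    ])
    sig = b"".join(f(ch, 16) for ch in ch_names)
    sig += b"".join(f("AgAgCl", 80) for _ in range(n_ch))
    sig += b"".join(f("uV", 8) for _ in range(n_ch))
    sig += b"".join(f(f"{phys_min[i]:.1f}", 8) for i in range(n_ch))
    sig += b"".join(f(f"{phys_min[i] + span[i]:.1f}", 8) for i in range(n_ch))
    sig += b"".join(f("-32767", 8) for _ in range(n_ch))
    sig += b"".join(f("32767", 8) for _ in range(n_ch))
    sig += b"".join(f("", 80) for _ in range(n_ch))
    sig += b"".join(f(str(spr), 8) for _ in range(n_ch))
    sig += f("", 32 * n_ch)

    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            block = dig[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())
    if events is not None:
        Path(str(path) + ".events.json").write_text(
            json.dumps(events.to_dict(orient="list"))
        )


def _read_edf_continuous(path: Path) -> tuple[np.ndarray, float, list[str]]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


def _read_set_epochs(path: Path) -> tuple[np.ndarray, float, list[str]]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ep = mne.io.read_epochs_eeglab(path, verbose="error")
    return ep.get_data(copy=True) * 1e6, float(ep.info["sfreq"]), list(ep.ch_names)


def read_eeg(
    path: str | Path,
    dialect: str,
    montage: dict[str, np.ndarray] | None = None,
    tmin_ms: float = 0.0,
) -> EpochedEEG:
    """Read epoched EEG from ``fixture``, ``edf`` or ``set`` sources.

    EDF input is continuous; it is cut into trials using the
    ``<path>.events.json`` sidecar (raising "no trial annotations" when
    absent).  A montage must be supplied for EDF/.set input, keyed by
    channel label, and must cover every data channel.
    """
    path = Path(path)
    if dialect == "fixture":
        return read_eeg_fixture(path)
    if dialect not in ("edf", "set"):
        raise ValueError(f"unsupported dialect {dialect!r}")
    if montage is None:
        raise ValueError(f"{dialect} input requires an explicit montage")

    if dialect == "set":
        data, rate, ch_names = _read_set_epochs(path)
        trials = pd.DataFrame(
            {
                "onset_ms": np.zeros(data.shape[0]),
                "duration_ms": np.full(data.shape[0], data.shape[2] / rate * 1e3),
                "condition": "speech",
            }
        )
    else:
        cont, rate, ch_names = _read_edf_continuous(path)
        events_path = Path(str(path) + ".events.json")
        if not events_path.exists():
            raise ValueError(f"{path}: no trial annotations")
        trials = pd.DataFrame(json.loads(events_path.read_text()))
        if trials.empty:
            raise ValueError(f"{path}: no trial annotations")
        n_samp = int(round(trials["duration_ms"].max() * rate / 1000.0))
        data = np.full((len(trials), cont.shape[0], n_samp), np.nan)
        for k, row in trials.reset_index(drop=True).iterrows():
            start = int(round(row["onset_ms"] * rate / 1000.0))
            stop = min(start + n_samp, cont.shape[1])
            data[k, :, : stop - start] = cont[:, start:stop]

    missing = [ch for ch in ch_names if ch not in montage]
    if missing:
        raise ValueError(f"montage mismatch: no position for {missing[:5]}")
    return EpochedEEG(
        data=data,
        rate=rate,
        ch_names=ch_names,
        montage=montage,
        trials=trials,
        tmin_ms=tmin_ms,
    )


# ---------------------------------------------------------------------------
# gaze CSV and WAV audio
# ---------------------------------------------------------------------------

def read_gaze_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: gaze CSV lacks columns {missing}")
    return df[GAZE_COLUMNS]


def write_gaze_csv(df: pd.DataFrame, path: str | Path) -> None:
    df[GAZE_COLUMNS].to_csv(path, index=False)


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read mono WAV audio as float in [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        raise ValueError(f"{path}: expected mono audio, got {data.shape[1]} channels")
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return np.asarray(data, dtype=float), float(rate)


def write_wav(samples: np.ndarray, rate: float, path: str | Path) -> None:
    peak = np.max(np.abs(samples)) or 1.0
    scaled = np.round(samples / peak * 32767).astype(np.int16)
    wavfile.write(path, int(rate), scaled)
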