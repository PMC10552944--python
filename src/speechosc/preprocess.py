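"""Continuous-EEG preprocessing: filtering, spatial smoothing,
re-referencing, and trial epoching.

The pipeline order is fixed: band-pass + notch filter, instantaneous
spatial smoothing, common average reference, epoching around speech-chunk
onsets.  Operator-interactive cleaning (ICA component rejection,
spline interpolation of bad channels) is out of scope; the functions here
accept pre-cleaned input in which artifact periods are marked, and those
samples are carried as NaN through every later stage.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal
from scipy.sparse import csr_matrix
from scipy.spatial import Delaunay

from .containers import EpochedEEG

BANDPASS_HZ = (0.1, 70.0)
NOTCH_HZ = 50.0


def filter_continuous(
    data: np.ndarray,
    rate: float,
    band: tuple[float, float] = BANDPASS_HZ,
    notch: float | None = NOTCH_HZ,
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass plus notch filter.

    ``data`` is (channels, samples).  Requires rate >= 2 x the upper band
    edge (and in practice >= 250 Hz for the default 0.1-70 Hz band).
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if rate < 2 * band[1]:
        raise ValueError(f"rate {rate} Hz < 2 x upper band edge {band[1]} Hz")
    sos = signal.butter(4, band, btype="bandpass", fs=rate, output="sos")
    out = signal.sosfiltfilt(sos, data, axis=-1)
    if notch is not None:
        b, a = signal.iirnotch(notch, Q=30.0, fs=rate)
        out = signal.filtfilt(b, a, out, axis=-1)
    return out


def _neighbor_table(
    positions: np.ndarray, ch_names: list[str], k: int = 6
) -> tuple[np.ndarray, np.ndarray]:
    """Indices and inverse-distance weights of the k nearest neighbors.

    Distances use the full (2-D or 3-D) sensor coordinates; ties are
    broken by channel-label order, which the lexicographic argsort of
    (distance, label rank) implements.
    """
    n = len(positions)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} channels, got {n}")
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    label_rank = np.argsort(np.argsort(ch_names))
    neighbors = np.empty((n, k), dtype=int)
    weights = np.empty((n, k))
    for i in range(n):
        order = sorted(
            (j for j in range(n) if j != i), key=lambda j: (d[i, j], label_rank[j])
        )
        neighbors[i] = order[:k]
        if np.any(d[i, neighbors[i]] == 0):
            raise ValueError("coincident sensor positions in montage")
        weights[i] = 1.0 / d[i, neighbors[i]]
    return neighbors, weights


def spatial_smooth(
    data: np.ndarray, positions: np.ndarray, ch_names: list[str] | None = None
) -> np.ndarray:
    """Instantaneous trimmed inverse-distance spatial smoothing.

    Per channel and sample: collect the 6 nearest neighbors plus the
    channel itself (self weight 1, neighbor weights proportional to
    inverse distance), sort the 7 values, drop the minimum and maximum,
    and average the remaining 5 with their weights.  Removes local
    outliers without changing the topography of smooth maps.
    """
    data = np.asarray(data, dtype=float)
    squeeze = data.ndim == 1
    data = np.atleast_2d(data)
    n_ch, n_samp = data.shape
    if positions.shape[0] != n_ch:
        raise ValueError("montage position count does not match channel count")
    if ch_names is None:
        ch_names = [f"E{i}" for i in range(n_ch)]
    neighbors, nbr_w = _neighbor_table(positions, ch_names, k=6)

    # stack: (7, n_ch, n_samp) values with matching weights (7, n_ch)
    vals = np.concatenate(
        [data[None, :, :], data[neighbors].transpose(1, 0, 2)], axis=0
    )
    w = np.concatenate([np.ones((1, n_ch)), nbr_w.T], axis=0)

    order = np.argsort(vals, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(vals, order, axis=0)
    sorted_w = np.take_along_axis(
        np.broadcast_to(w[:, :, None], vals.shape), order, axis=0
    )
    core_v = sorted_vals[1:-1]  # drop min and max
    core_w = sorted_w[1:-1]
    out = np.sum(core_v * core_w, axis=0) / np.sum(core_w, axis=0)
    return out[0] if squeeze else out


def rereference_average(data: np.ndarray) -> np.ndarray:
    """Common average reference: subtract the cross-channel mean per sample."""
    data = np.asarray(data, dtype=float)
    if data.shape[-2] < 2:
        raise ValueError("common average reference needs at least 2 channels")
    return data - np.nanmean(data, axis=-2, keepdims=True)


def epoch_trials(
    cont: np.ndarray,
    rate: float,
    chunks: np.ndarray,
    ch_names: list[str],
    montage: dict[str, np.ndarray],
    pre_ms: float = 0.0,
    post_ms: float = 0.0,
    artifact_mask: np.ndarray | None = None,
) -> EpochedEEG:
    """Cut continuous data into one trial per speech chunk.

    Each trial spans ``[onset - pre_ms, offset + post_ms)``; sample 0 of
    the output corresponds to ``onset - pre_ms`` (``tmin_ms = -pre_ms``).
    Artifact-masked samples become NaN.  Chunks extending past the
    recording end are dropped with a warning; chunks that lie entirely
    inside an artifact span are excluded and the retained-trial count
    decremented.
    """
    cont = np.atleast_2d(np.asarray(cont, dtype=float))
    chunks = np.asarray(chunks, dtype=float).reshape(-1, 2)
    n_samp_total = cont.shape[1]
    if artifact_mask is not None:
        artifact_mask = np.asarray(artifact_mask, dtype=bool)
        cont = cont.copy()
        cont[:, artifact_mask] = np.nan

    rows, segs = [], []
    for onset, offset in chunks:
        i0 = int(round((onset - pre_ms) * rate / 1000.0))
        i1 = int(round((offset + post_ms) * rate / 1000.0))
        if i0 < 0 or i1 > n_samp_total:
            warnings.warn(
                f"chunk ({onset:.0f}, {offset:.0f}) ms exceeds the recording; "
                "trial dropped"
            )
            continue
        c0 = int(round(onset * rate / 1000.0))
        c1 = int(round(offset * rate / 1000.0))
        if artifact_mask is not None and artifact_mask[c0:c1].all():
            continue  # chunk fully inside an artifact span
        rows.append(
            {"onset_ms": onset, "duration_ms": offset - onset, "condition": "speech"}
        )
        segs.append(cont[:, i0:i1])

    if not rows:
        raise ValueError("no trials survived epoching")
    max_len = max(s.shape[1] for s in segs)
    data = np.full((len(segs), cont.shape[0], max_len), np.nan)
    for k, seg in enumerate(segs):
        data[k, :, : seg.shape[1]] = seg
    trials = pd.DataFrame(rows)
    trials.attrs["n_retained"] = len(rows)
    trials.attrs["n_total"] = len(chunks)
    return EpochedEEG(
        data=data,
        rate=rate,
        ch_names=ch_names,
        montage=montage,
        trials=trials,
        tmin_ms=-pre_ms,
    )


# ---------------------------------------------------------------------------
# montage helpers
# ---------------------------------------------------------------------------

def make_synthetic_montage(n_channels: int, radius: float = 0.09) -> dict[str, np.ndarray]:
    """Sensor positions on a spherical cap (sunflower layout), labelled E1..En."""
    k = np.arange(1, n_channels + 1)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    r = radius * np.sqrt(k / n_channels)
    th = k * golden
    x, y = r * np.cos(th), r * np.sin(th)
    z = np.sqrt(np.maximum(radius**2 * 1.2**2 - x**2 - y**2, 0.0))
    return {f"E{i}": np.array([x[i - 1], y[i - 1], z[i - 1]]) for i in k}


def montage_adjacency(
    positions: np.ndarray, prune_factor: float = 1.5
) -> csr_matrix:
    """Electrode adjacency from a Delaunay triangulation of the 2-D projection.

    Edges longer than ``prune_factor`` x the median edge length are
    removed so that the rim of the cap does not produce spurious
    long-range neighbors.
    """
    pts2d = np.asarray(positions, dtype=float)[:, :2]
    tri = Delaunay(pts2d)
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = sorted((simplex[a], simplex[(a + 1) % 3]))
            edges.add((i, j))
    edges = np.array(sorted(edges))
    lengths = np.linalg.norm(pts2d[edges[:, 0]] - pts2d[edges[:, 1]], axis=1)
    keep = lengths <= prune_factor * np.median(lengths)
    edges = edges[keep]
    n = len(pts2d)
    adj = np.zeros((n, n), dtype=bool)
    adj[edges[:, 0], edges[:, 1]] = True
    adj[edges[:, 1], edges[:, 0]] = True
    return csr_matrix(adj)
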