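"""File formats: tracks/truth/estimates/classifications CSV, TIFF volume
series, and JSON summaries.

All CSVs are comma-separated UTF-8 with '.' decimals and a mandatory
header.  Lengths are micrometres on disk (``z_um`` increases downward,
frames are 0-based) and SI metres in memory.  Volume series are one
multi-page 16-bit TIFF per time point, named ``t{index:05d}.tif``.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .classify import ClassificationResult
from .estimation import PopulationSummary, TrackEstimate
from .tracking import Track

__all__ = [
    "write_tracks_csv", "read_tracks_csv",
    "write_truth_csv", "read_truth_csv",
    "write_estimates_csv", "read_estimates_csv",
    "write_classifications_csv",
    "write_volume_series", "read_volume_series",
    "write_summary_json",
]

_TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um", "z_um"]


class FormatError(ValueError):
    """A file does not match the documented dialect."""


def write_tracks_csv(tracks: list[Track], path) -> None:
    """Write tracks in the documented dialect (one row per observation)."""
    rows = []
    for tr in tracks:
        for i, f in enumerate(tr.frames):
            rows.append({
                "track_id": tr.track_id,
                "frame": int(f),
                "t_s": float(f) * tr.dt,
                "x_um": tr.x[i] * 1e6,
                "y_um": tr.y[i] * 1e6 if tr.y is not None else math.nan,
                "z_um": tr.z[i] * 1e6 if tr.z is not None else math.nan,
            })
    pd.DataFrame(rows, columns=_TRACK_COLUMNS).to_csv(path, index=False)


def read_tracks_csv(path, z_down: bool = True) -> list[Track]:
    """Read a tracks CSV back into :class:`Track` objects.

    ``z_down=False`` flips the axial sign for tables whose z axis
    increases upward, so sinking stays positive internally.
    """
    df = pd.read_csv(path)
    missing = [c for c in _TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: tracks CSV missing columns {missing}")
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy(dtype=int)
        if len(frames) > 1:
            dts = np.diff(g["t_s"].to_numpy()) / np.diff(frames)
            dt = float(np.median(dts))
        else:
            dt = float(g["t_s"].iloc[0] / frames[0]) if frames[0] else 1.0
        y = g["y_um"].to_numpy() * 1e-6
        z = g["z_um"].to_numpy() * 1e-6
        if not z_down:
            z = -z
        tracks.append(Track(
            track_id=int(tid), frames=frames, dt=dt,
            x=g["x_um"].to_numpy() * 1e-6,
            y=None if np.all(np.isnan(y)) else y,
            z=None if np.all(np.isnan(z)) else z))
    return tracks


def write_truth_csv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)


def read_truth_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"particle_id", "radius_um", "density_kg_m3", "v_stokes_um_s"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: truth CSV missing columns {sorted(missing)}")
    return df


def write_estimates_csv(estimates: list[TrackEstimate], path) -> None:
    from .estimation import estimates_frame
    estimates_frame(estimates).to_csv(path, index=False)


def read_estimates_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "track_id" not in df.columns or "vz_um_s" not in df.columns:
        raise FormatError(f"{path}: not an estimates CSV")
    return df


def write_classifications_csv(results: list[ClassificationResult], path) -> None:
    pd.DataFrame([{
        "track_id": r.track_id,
        "rho_hat_kg_m3": r.rho_hat,
        "call": r.call,
        "regime": r.regime,
        "note": r.note,
    } for r in results]).to_csv(path, index=False)


def write_volume_series(volumes: np.ndarray, directory) -> list[Path]:
    """Write a (t, z, y, x) series as one multi-page TIFF per time point."""
    volumes = np.asarray(volumes)
    if volumes.ndim != 4:
        raise FormatError(f"expected (t, z, y, x) series, got {volumes.shape}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, vol in enumerate(volumes):
        p = directory / f"t{i:05d}.tif"
        tifffile.imwrite(p, vol.astype(np.uint16), photometric="minisblack")
        paths.append(p)
    return paths


def read_volume_series(directory) -> np.ndarray:
    """Read a ``t*.tif`` series back into a (t, z, y, x) array."""
    paths = sorted(Path(directory).glob("t*.tif"))
    if not paths:
        raise FormatError(f"no t*.tif volumes found in {directory}")
    vols = [tifffile.imread(p) for p in paths]
    shapes = {v.shape for v in vols}
    if len(shapes) != 1:
        raise FormatError(f"inconsistent volume shapes in {directory}: {shapes}")
    return np.stack(vols)


def write_summary_json(summaries: dict[str, PopulationSummary], path) -> None:
    """Serialize population summaries (micrometre-scaled where relevant)."""
    scale = {"D": 1e12, "r": 1e6, "v_z": 1e6}
    payload = {}
    for name, s in summaries.items():
        k = scale.get(s.quantity, 1.0)
        payload[name] = {
            "quantity": s.quantity,
            "mean": s.mean * k,
            "median": s.median * k,
            "ci95_half_width": s.ci95_half_width * k,
            "n": s.n,
            "bin_edges": (s.bin_edges * k).tolist(),
            "counts": s.counts.tolist(),
        }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
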