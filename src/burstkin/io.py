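"""File I/O: spot/track tables (CSV), label masks (16-bit TIFF), movies
(multi-page TIFF + YAML sidecar) and run configuration.

All tables carry a header-comment line with the config hash and package
version so any output can be traced to the exact run that produced it.
Readers accept externally produced tables in the same schema; extra
columns are preserved.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .core import Movie, RigidTransformSeries, SpotRecord, Track, tracks_from_arrays

__all__ = [
    "SPOT_COLUMNS",
    "TRACK_COLUMNS",
    "config_hash",
    "load_config",
    "save_config",
    "write_spot_table",
    "read_spot_table",
    "write_track_table",
    "read_track_table",
    "write_transforms",
    "read_transforms",
    "write_mask",
    "read_mask",
    "write_movie",
    "read_movie",
]

SPOT_COLUMNS = ["channel", "frame", "x_um", "y_um", "peak_intensity",
                "dog_value", "nucleus_label"]
TRACK_COLUMNS = ["track_id", "channel", "frame", "x_um", "y_um", "intensity",
                 "nucleus_label", "gap_flag"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a mapping")
    return cfg


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def _header(cfg_hash: str | None) -> str:
    tag = cfg_hash or "unconfigured"
    return f"# burstkin v{__version__} config={tag}\n"


def _write_csv(df: pd.DataFrame, path, cfg_hash: str | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(cfg_hash))
        df.to_csv(fh, index=False)


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


# ---------------------------------------------------------------------------
# spot and track tables
# ---------------------------------------------------------------------------

def write_spot_table(spots: list[SpotRecord], path,
                     cfg_hash: str | None = None) -> None:
    df = pd.DataFrame(
        [
            {"channel": s.channel, "frame": s.frame, "x_um": s.x_um,
             "y_um": s.y_um, "peak_intensity": s.peak_intensity,
             "dog_value": s.dog_value, "nucleus_label": s.nucleus_label}
            for s in spots
        ],
        columns=SPOT_COLUMNS,
    )
    _write_csv(df, path, cfg_hash)


def read_spot_table(path) -> list[SpotRecord]:
    df = _read_csv(path, ["frame", "x_um", "y_um"])
    return [
        SpotRecord(
            x_um=float(r.x_um), y_um=float(r.y_um), frame=int(r.frame),
            peak_intensity=float(getattr(r, "peak_intensity", 0.0) or 0.0),
            dog_value=float(getattr(r, "dog_value", 0.0) or 0.0),
            nucleus_label=int(getattr(r, "nucleus_label", 0) or 0),
            channel=str(getattr(r, "channel", "smt")),
        )
        for r in df.itertuples(index=False)
    ]


def write_track_table(tracks: list[Track], path,
                      cfg_hash: str | None = None) -> None:
    rows = []
    for t in tracks:
        gaps = set(t.gaps)
        for i, f in enumerate(t.frames):
            rows.append(
                {"track_id": t.track_id, "channel": t.channel, "frame": int(f),
                 "x_um": t.xy_um[i, 0], "y_um": t.xy_um[i, 1],
                 "intensity": (float(t.intensity[i])
                               if t.intensity is not None else np.nan),
                 "nucleus_label": t.nucleus_label,
                 "gap_flag": int(int(f) + 1 in gaps)}
            )
    _write_csv(pd.DataFrame(rows, columns=TRACK_COLUMNS), path, cfg_hash)


def read_track_table(path) -> list[Track]:
    df = _read_csv(path, ["track_id", "frame", "x_um", "y_um"])
    tracks = tracks_from_arrays(
        df["track_id"].to_numpy(), df["frame"].to_numpy(),
        df["x_um"].to_numpy(), df["y_um"].to_numpy(),
        intensity=df["intensity"].to_numpy() if "intensity" in df else None,
    )
    if "nucleus_label" in df or "channel" in df or "condition" in df:
        meta = df.drop_duplicates("track_id").set_index("track_id")
        for t in tracks:
            if "nucleus_label" in meta:
                t.nucleus_label = int(meta.loc[t.track_id, "nucleus_label"])
            if "channel" in meta:
                t.channel = str(meta.loc[t.track_id, "channel"])
            if "condition" in meta:
                t.condition = str(meta.loc[t.track_id, "condition"])
    return tracks


def write_transforms(series: RigidTransformSeries, path,
                     cfg_hash: str | None = None) -> None:
    df = pd.DataFrame({
        "frame": np.arange(len(series)),
        "dx_px": series.dx_px, "dy_px": series.dy_px,
        "dtheta_deg": series.dtheta_deg,
    })
    _write_csv(df, path, cfg_hash)


def read_transforms(path, center_px: tuple[float, float]) -> RigidTransformSeries:
    df = _read_csv(path, ["frame", "dx_px", "dy_px", "dtheta_deg"])
    df = df.sort_values("frame")
    return RigidTransformSeries(
        dx_px=df["dx_px"].to_numpy(dtype=float),
        dy_px=df["dy_px"].to_numpy(dtype=float),
        dtheta_deg=df["dtheta_deg"].to_numpy(dtype=float),
        center_px=center_px,
    )


# ---------------------------------------------------------------------------
# masks and movies
# ---------------------------------------------------------------------------

def write_mask(mask: np.ndarray, path) -> None:
    """Label or binary mask as 16-bit TIFF."""
    arr = np.asarray(mask)
    if arr.dtype == bool:
        arr = arr.astype(np.uint16)
    if arr.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("label values exceed 16-bit range")
    tifffile.imwrite(str(path), arr.astype(np.uint16))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_movie(movie: Movie, path) -> None:
    """Movie as multi-page TIFF (TCYX) with a YAML calibration sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), movie.data.astype(np.float32),
                     photometric="minisblack", metadata={"axes": "TCYX"})
    sidecar = path.with_suffix(path.suffix + ".yaml")
    save_config(
        {
            "channels": list(movie.channels),
            "pixel_size_um": float(movie.pixel_size_um),
            "frame_interval_s": float(movie.frame_interval_s),
        },
        sidecar,
    )


def read_movie(path) -> Movie:
    path = Path(path)
    data = tifffile.imread(str(path))
    meta = load_config(path.with_suffix(path.suffix + ".yaml"))
    if data.ndim == 3:  # single channel
        data = data[:, None]
    return Movie(data=np.asarray(data, dtype=float),
                 channels=tuple(meta["channels"]),
                 pixel_size_um=float(meta["pixel_size_um"]),
                 frame_interval_s=float(meta["frame_interval_s"]))
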