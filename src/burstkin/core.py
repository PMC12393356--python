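"""Core data structures shared across the pipeline.

Conventions
-----------
* Image arrays are indexed ``(row, col)``; ``x`` maps to columns and ``y``
  to rows. Spot and track coordinates are stored in micrometres (µm),
  converted from pixels with ``pixel_size_um``.
* Time is carried as integer frame indices plus a frame interval in
  seconds; derived quantities (durations, diffusion coefficients) are in
  seconds and µm²/s.
* Movies are ``(T, C, H, W)`` float arrays with a named channel axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SimulationConfig",
    "WalkerSpec",
    "BurstSchedule",
    "SpotRecord",
    "Track",
    "BurstEvent",
    "MSDCurve",
    "TrackFeatures",
    "NucleusMask",
    "OrganelleMask",
    "SignedDistanceRecord",
    "Movie",
    "GroundTruth",
    "RigidTransformSeries",
]


# ---------------------------------------------------------------------------
# simulation configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition and rendering constants for synthetic data.

    Defaults follow the high-speed single-molecule regime (5 ms interval);
    locus-tracking movies use 15–30 s intervals instead.
    """

    pixel_size_um: float = 0.1
    frame_interval_s: float = 0.005
    n_frames: int = 100
    image_shape: tuple[int, int] = (128, 128)
    rng_seed: int = 0
    localization_noise_um: float = 0.02
    psf_sigma_px: float = 1.2
    background_level: float = 100.0
    snr: float = 10.0
    read_noise: float = 2.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")

    @property
    def noise_sigma(self) -> float:
        """Std-dev of background noise (Poisson shot + read noise)."""
        return float(np.sqrt(self.background_level + self.read_noise**2))


@dataclass(frozen=True)
class WalkerSpec:
    """Generative parameters for one simulated walker.

    ``model`` is one of ``brownian`` (free diffusion), ``confined``
    (Brownian steps reflected at a disc of radius ``Rc_um``) or ``fbm``
    (fractional Brownian motion with anomalous exponent ``alpha``).
    """

    model: str = "brownian"
    D_um2_s: float = 0.1
    alpha: float = 1.0
    Rc_um: float = 0.25
    start_xy_um: tuple[float, float] = (0.0, 0.0)
    lifetime_frames: int = 50
    start_frame: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("brownian", "confined", "fbm"):
            raise ValueError(f"unknown motion model {self.model!r}")
        if self.D_um2_s < 0:
            raise ValueError("D_um2_s must be non-negative")
        if self.model == "fbm" and not (0 < self.alpha <= 2):
            raise ValueError("alpha must lie in (0, 2] for fbm walkers")
        if self.model == "confined" and self.Rc_um <= 0:
            raise ValueError("Rc_um must be positive for confined walkers")
        if self.lifetime_frames < 1:
            raise ValueError("lifetime_frames must be positive")


@dataclass
class BurstSchedule:
    """Ground-truth on/off schedule of an MS2 focus in one nucleus."""

    nucleus_id: int
    on_intervals: list[tuple[int, int]]  # half-open [start, end)
    focus_track: int | None = None       # index of the locus walker
    on_intensity: float = 1.0
    off_intensity: float = 0.0

    def validate(self, n_frames: int) -> None:
        prev_end = 0
        for start, end in self.on_intervals:
            if not (0 <= start < end <= n_frames):
                raise ValueError(f"interval ({start}, {end}) outside [0, {n_frames})")
            if start < prev_end:
                raise ValueError("on_intervals must be disjoint and sorted")
            prev_end = end

    def is_on(self, frame: int) -> bool:
        return any(s <= frame < e for s, e in self.on_intervals)


# ---------------------------------------------------------------------------
# spots, tracks, bursts
# ---------------------------------------------------------------------------

@dataclass
class SpotRecord:
    """A localized fluorescent punctum in one frame."""

    x_um: float
    y_um: float
    frame: int
    peak_intensity: float = 0.0
    dog_value: float = 0.0
    nucleus_label: int = 0
    channel: str = "smt"


@dataclass
class Track:
    """Time-ordered chain of localizations sharing one identity.

    ``frames`` is strictly increasing; missing frames between the first
    and the last are gaps (closed during linking but never interpolated).
    """

    track_id: int
    frames: np.ndarray
    xy_um: np.ndarray
    intensity: np.ndarray | None = None
    channel: str = "smt"
    nucleus_label: int = 0
    condition: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy_um = np.asarray(self.xy_um, dtype=float)
        if self.xy_um.ndim != 2 or self.xy_um.shape[1] != 2:
            raise ValueError("xy_um must be (n, 2)")
        if len(self.frames) != len(self.xy_um):
            raise ValueError("frames and xy_um length mismatch")
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def gaps(self) -> list[int]:
        """Frame indices missing between the first and last observation."""
        if len(self.frames) < 2:
            return []
        full = set(range(int(self.frames[0]), int(self.frames[-1]) + 1))
        return sorted(full - set(self.frames.tolist()))

    def slice_frames(self, start: int, end: int, new_id: int | None = None) -> "Track":
        """Sub-track restricted to frames in the half-open [start, end)."""
        keep = (self.frames >= start) & (self.frames < end)
        return replace(
            self,
            track_id=self.track_id if new_id is None else new_id,
            frames=self.frames[keep],
            xy_um=self.xy_um[keep],
            intensity=None if self.intensity is None else np.asarray(self.intensity)[keep],
        )


@dataclass
class BurstEvent:
    """A contiguous interval of above-threshold RNA focus signal."""

    nucleus_id: int
    start_frame: int
    end_frame: int          # half-open
    frame_interval_s: float
    mean_intensity: float = float("nan")
    frames_observed: int = 0

    @property
    def duration_s(self) -> float:
        return (self.end_frame - self.start_frame) * self.frame_interval_s

    def contains(self, frame: int) -> bool:
        return self.start_frame <= frame < self.end_frame


# ---------------------------------------------------------------------------
# biophysics
# ---------------------------------------------------------------------------

@dataclass
class MSDCurve:
    """Time-averaged mean squared displacement of one track.

    Only lags with at least ``min_pairs`` (default 3) averaged
    displacements are retained.
    """

    dt_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray

    def __len__(self) -> int:
        return len(self.dt_s)


@dataclass
class TrackFeatures:
    """The per-track biophysical parameter set used for state clustering."""

    track_id: int
    D_um2_s: float = float("nan")
    alpha: float = float("nan")
    Rc_um: float = float("nan")
    Dr_um2_s: float = float("nan")
    msd_dt1_um2: float = float("nan")
    res_025_s: float = float("nan")
    res_050_s: float = float("nan")
    disp_frame_um: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_spots: int = 0
    condition: str = ""
    qc_flags: str = ""

    CLUSTER_FEATURES = (
        "D_um2_s", "alpha", "Rc_um", "Dr_um2_s", "msd_dt1_um2", "res_025_s",
    )

    @property
    def complete(self) -> bool:
        vals = [getattr(self, f) for f in self.CLUSTER_FEATURES]
        return bool(np.all(np.isfinite(vals)))


# ---------------------------------------------------------------------------
# segmentation products
# ---------------------------------------------------------------------------

@dataclass
class NucleusMask:
    """Integer-labelled nuclei of one frame with per-label statistics."""

    frame: int
    label_image: np.ndarray
    median_intensity: dict[int, float]
    area_px: dict[int, int]

    @property
    def labels(self) -> list[int]:
        return sorted(self.median_intensity)


@dataclass
class OrganelleMask:
    """Binary organelle mask plus internal/external distance transforms (µm).

    ``internal_dist`` is positive strictly inside the mask (distance to the
    nearest outside pixel); ``external_dist`` is positive strictly outside
    (distance to the nearest inside pixel). They are never both positive.
    """

    frame: int
    mask: np.ndarray
    internal_dist: np.ndarray
    external_dist: np.ndarray
    pixel_size_um: float = 0.1


@dataclass
class SignedDistanceRecord:
    """Signed distance of a spot to an organelle edge.

    Positive means further outside the organelle, negative further inside.
    """

    spot_id: int
    organelle: str
    signed_dist_um: float
    frame: int
    condition: str = ""


# ---------------------------------------------------------------------------
# movies and ground truth
# ---------------------------------------------------------------------------

@dataclass
class Movie:
    """Calibrated multi-channel time-lapse stack, shape (T, C, H, W)."""

    data: np.ndarray
    channels: tuple[str, ...]
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("movie data must be (T, C, H, W)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel axis does not match channel names")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, self.channels.index(name)]


@dataclass
class GroundTruth:
    """Everything a synthetic movie knows about itself."""

    tracks: list[Track] = field(default_factory=list)
    bursts: list[BurstSchedule] = field(default_factory=list)
    nuclei_mask: np.ndarray | None = None      # label image (H, W)
    organelle_mask: np.ndarray | None = None   # binary (H, W)
    drift: np.ndarray | None = None            # (T, 3): dx_px, dy_px, dtheta_deg
    track_nucleus: dict[int, int] = field(default_factory=dict)


@dataclass
class RigidTransformSeries:
    """Per-frame rigid transforms mapping each frame onto the reference.

    Applying rotation ``dtheta_deg`` about the image centre followed by
    translation ``(dx_px, dy_px)`` maps coordinates observed in frame *t*
    into the reference frame.
    """

    dx_px: np.ndarray
    dy_px: np.ndarray
    dtheta_deg: np.ndarray
    center_px: tuple[float, float]  # (row, col)

    def __len__(self) -> int:
        return len(self.dx_px)

    def transform_points(self, frame: int, xy_px: np.ndarray) -> np.ndarray:
        """Map pixel coordinates (x, y) from ``frame`` onto the reference."""
        xy = np.atleast_2d(np.asarray(xy_px, dtype=float))
        cy, cx = self.center_px
        th = np.deg2rad(self.dtheta_deg[frame])
        c, s = np.cos(th), np.sin(th)
        dx = xy[:, 0] - cx
        dy = xy[:, 1] - cy
        # image-convention rotation: positive angle rotates counter-clockwise
        # with the y-axis pointing down, matching skimage.transform.rotate
        xr = c * dx + s * dy + cx + self.dx_px[frame]
        yr = -s * dx + c * dy + cy + self.dy_px[frame]
        return np.column_stack([xr, yr])


def tracks_from_arrays(
    track_ids: Sequence[int],
    frames: Sequence[int],
    x_um: Sequence[float],
    y_um: Sequence[float],
    intensity: Sequence[float] | None = None,
    **meta,
) -> list[Track]:
    """Assemble Track objects from flat columnar data (CSV-shaped)."""
    track_ids = np.asarray(track_ids)
    frames = np.asarray(frames)
    xy = np.column_stack([np.asarray(x_um, float), np.asarray(y_um, float)])
    inten = None if intensity is None else np.asarray(intensity, float)
    out: list[Track] = []
    for tid in np.unique(track_ids):
        sel = np.flatnonzero(track_ids == tid)
        sel = sel[np.argsort(frames[sel], kind="stable")]
        out.append(
            Track(
                track_id=int(tid),
                frames=frames[sel],
                xy_um=xy[sel],
                intensity=None if inten is None else inten[sel],
                **meta,
            )
        )
    return out
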