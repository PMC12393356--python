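"""Spot linking, burst-event assembly, burst statistics and drift correction.

Linking follows the two-pass linear-assignment scheme used throughout the
single-particle-tracking literature: optimal bipartite assignment between
consecutive frames (Hungarian algorithm on squared displacement, gated at
the maximum linking distance), followed by a gap-closing pass that joins
track ends to later track starts when the frame gap and closing distance
allow. No splitting or merging. Defaults mirror the original acquisition
settings: max linking distance 0.4 µm, max frame gap 3, max closing
distance 0.6 µm, minimum 5 spots per track; single-molecule movies also
drop spots before a settling frame (500) where photobleaching has not yet
sparsified the field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import linear_sum_assignment
from scipy.stats import rankdata  # noqa: F401  (kept for report helpers)
from skimage import transform as sktransform
from skimage.registration import phase_cross_correlation

from .core import (
    BurstEvent,
    Movie,
    NucleusMask,
    RigidTransformSeries,
    SpotRecord,
    Track,
)
from .segmentation import SegmentationParams, auto_threshold

__all__ = [
    "LinkingParams",
    "link_spots",
    "assemble_bursts",
    "burst_statistics",
    "correct_drift",
    "apply_transforms_to_tracks",
]


@dataclass(frozen=True)
class LinkingParams:
    """Linker settings (single-molecule defaults)."""

    max_link_um: float = 0.4
    max_gap_frames: int = 3
    max_close_um: float = 0.6
    min_spots: int = 5
    min_frame: int | None = None  # e.g. 500 for SMT movies


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def _assign(prev_xy: np.ndarray, next_xy: np.ndarray, max_dist: float
            ) -> list[tuple[int, int]]:
    """Gated optimal assignment between two point sets (squared distances)."""
    if len(prev_xy) == 0 or len(next_xy) == 0:
        return []
    d2 = ((prev_xy[:, None, :] - next_xy[None, :, :]) ** 2).sum(axis=2)
    gate = max_dist**2
    big = 1e12
    cost = np.where(d2 <= gate, d2, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if d2[r, c] <= gate]


def link_spots(
    spots: list[SpotRecord],
    max_link_um: float = 0.4,
    max_gap_frames: int = 3,
    max_close_um: float = 0.6,
    min_spots: int = 5,
    min_frame: int | None = None,
) -> list[Track]:
    """Link localizations into tracks with gap closing.

    Pass 1 assigns spots of frame f to frame f+1 minimizing total squared
    displacement subject to the gate ``max_link_um``. Pass 2 joins a
    segment's last spot to a later segment's first spot when
    ``1 ≤ frame gap ≤ max_gap_frames`` missing frames separate them and the
    end-to-start distance is ≤ ``max_close_um`` (candidates greedily
    consumed in (gap, distance) order). Tracks with fewer than
    ``min_spots`` localizations are dropped.
    """
    if min_frame is not None:
        spots = [s for s in spots if s.frame >= min_frame]
    if not spots:
        return []
    order = np.argsort([s.frame for s in spots], kind="stable")
    spots = [spots[i] for i in order]
    by_frame: dict[int, list[int]] = {}
    for i, s in enumerate(spots):
        by_frame.setdefault(int(s.frame), []).append(i)
    xy = np.array([[s.x_um, s.y_um] for s in spots])

    # pass 1: frame-to-frame segments
    segments: list[list[int]] = []
    open_by_spot: dict[int, int] = {}  # spot index -> segment index
    frames_sorted = sorted(by_frame)
    for f in frames_sorted:
        idx_here = by_frame[f]
        idx_prev = by_frame.get(f - 1, [])
        linked_here: set[int] = set()
        if idx_prev:
            pairs = _assign(xy[idx_prev], xy[idx_here], max_link_um)
            for r, c in pairs:
                sp_prev, sp_here = idx_prev[r], idx_here[c]
                seg = open_by_spot.get(sp_prev)
                if seg is None:
                    segments.append([sp_prev])
                    seg = len(segments) - 1
                segments[seg].append(sp_here)
                open_by_spot[sp_here] = seg
                linked_here.add(sp_here)
        for i in idx_here:
            if i not in linked_here and i not in open_by_spot:
                segments.append([i])
                open_by_spot[i] = len(segments) - 1

    # pass 2: gap closing between segment ends and later segment starts
    ends = [(seg[-1], k) for k, seg in enumerate(segments)]
    starts = [(seg[0], k) for k, seg in enumerate(segments)]
    candidates = []
    for (e_spot, ke) in ends:
        fe = spots[e_spot].frame
        for (s_spot, ks) in starts:
            if ks == ke:
                continue
            gap = spots[s_spot].frame - fe - 1
            if not (1 <= gap <= max_gap_frames):
                continue
            dist = float(np.hypot(*(xy[s_spot] - xy[e_spot])))
            if dist <= max_close_um:
                candidates.append((gap, dist, ke, ks))
    candidates.sort(key=lambda c: (c[0], c[1]))
    successor: dict[int, int] = {}
    used_starts: set[int] = set()
    used_ends: set[int] = set()
    for gap, dist, ke, ks in candidates:
        if ke in used_ends or ks in used_starts:
            continue
        successor[ke] = ks
        used_ends.add(ke)
        used_starts.add(ks)

    merged: list[list[int]] = []
    heads = [k for k in range(len(segments)) if k not in used_starts]
    for k in heads:
        chain = list(segments[k])
        nxt = successor.get(k)
        while nxt is not None:
            chain.extend(segments[nxt])
            nxt = successor.get(nxt)
        merged.append(chain)

    tracks: list[Track] = []
    tid = 0
    for chain in merged:
        if len(chain) < min_spots:
            continue
        members = [spots[i] for i in chain]
        labels = [m.nucleus_label for m in members]
        majority = max(set(labels), key=labels.count)
        tracks.append(
            Track(
                track_id=tid,
                frames=np.array([m.frame for m in members]),
                xy_um=np.array([[m.x_um, m.y_um] for m in members]),
                intensity=np.array([m.peak_intensity for m in members]),
                channel=members[0].channel,
                nucleus_label=majority,
            )
        )
        tid += 1
    return tracks


# ---------------------------------------------------------------------------
# bursts
# ---------------------------------------------------------------------------

def assemble_bursts(rna_tracks: list[Track], frame_interval_s: float
                    ) -> list[BurstEvent]:
    """Each linked RNA-focus track becomes one burst event.

    The event spans the track's first to last frame (half-open end); its
    nucleus is the majority spot label (mixed-label tracks are assigned to
    the majority).
    """
    events = []
    for t in rna_tracks:
        inten = (float(np.mean(t.intensity))
                 if t.intensity is not None and len(t.intensity) else float("nan"))
        events.append(
            BurstEvent(
                nucleus_id=t.nucleus_label,
                start_frame=int(t.frames[0]),
                end_frame=int(t.frames[-1]) + 1,
                frame_interval_s=frame_interval_s,
                mean_intensity=inten,
                frames_observed=len(t),
            )
        )
    return events


def burst_statistics(
    events: list[BurstEvent],
    phase_windows: dict[str, tuple[float, float]] | None = None,
    frame_interval_s: float | None = None,
    n_nuclei: int | None = None,
    observed_frames: int | None = None,
    t0_frame: int = 0,
) -> dict[str, dict[str, float | None]]:
    """Per-phase burst rate and mean on/off durations.

    ``phase_windows`` maps phase name to a (start_s, end_s) window relative
    to the stimulation frame ``t0_frame``; omit it to pool everything into
    one ``all`` phase. Events are assigned to the phase containing their
    start. Off-durations are the spans between consecutive events of the
    same nucleus within a phase. Rates are events per nucleus per hour of
    observed phase time. Phases with no events report ``None`` (missing,
    never zero).
    """
    if frame_interval_s is None:
        frame_interval_s = events[0].frame_interval_s if events else 1.0
    nuclei = {e.nucleus_id for e in events}
    if n_nuclei is None:
        n_nuclei = max(len(nuclei), 1)
    if observed_frames is None:
        observed_frames = max((e.end_frame for e in events), default=0)
    total_span_s = observed_frames * frame_interval_s
    if phase_windows is None:
        phase_windows = {"all": (-np.inf, np.inf)}

    out: dict[str, dict[str, float | None]] = {}
    for phase, (a, b) in phase_windows.items():
        phase_events = [
            e for e in events
            if a <= (e.start_frame - t0_frame) * frame_interval_s < b
        ]
        if not phase_events:
            out[phase] = {"burst_rate_per_nucleus_hour": None,
                          "mean_on_duration_s": None,
                          "mean_off_duration_s": None,
                          "n_events": 0}
            continue
        lo = max(a, (0 - t0_frame) * frame_interval_s)
        hi = min(b, (observed_frames - t0_frame) * frame_interval_s)
        window_s = max(hi - lo, frame_interval_s)
        offs: list[float] = []
        for nuc in {e.nucleus_id for e in phase_events}:
            evs = sorted((e for e in phase_events if e.nucleus_id == nuc),
                         key=lambda e: e.start_frame)
            for prev, nxt in zip(evs, evs[1:]):
                offs.append((nxt.start_frame - prev.end_frame) * frame_interval_s)
        out[phase] = {
            "burst_rate_per_nucleus_hour":
                len(phase_events) / n_nuclei / (window_s / 3600.0),
            "mean_on_duration_s":
                float(np.mean([e.duration_s for e in phase_events])),
            "mean_off_duration_s": float(np.mean(offs)) if offs else None,
            "n_events": len(phase_events),
        }
    return out


# ---------------------------------------------------------------------------
# drift correction
# ---------------------------------------------------------------------------

def _prepare_template(frame: np.ndarray, blur_sigma: float = 4.0) -> np.ndarray:
    """Contrast-enhanced nuclear silhouette for registration.

    The nucleus is segmented (Gaussian blur + Huang-family threshold), its
    bounds dilated, and outlier pixels moderated toward the region medians
    so focal spots inside the nucleus cannot bias the rigid registration.
    """
    img = np.asarray(frame, dtype=float)
    sm = ndi.gaussian_filter(img, blur_sigma)
    thr = auto_threshold(sm, "huang")
    mask = sm > thr
    mask = ndi.binary_fill_holes(mask)
    mask = ndi.binary_dilation(mask, iterations=2)
    # the registration target is the (near noise-free) nuclear silhouette
    # plus a faint, heavily smoothed copy of real structure: focal signal
    # inside the nucleus is flattened away and per-frame shot noise cannot
    # bias the angular search
    out = ndi.gaussian_filter(mask.astype(float), 2.0)
    texture = ndi.gaussian_filter(img, 4.0)
    t_lo, t_hi = texture.min(), texture.max()
    if t_hi > t_lo:
        out += 0.15 * (texture - t_lo) / (t_hi - t_lo)
    lo, hi = out.min(), out.max()
    return (out - lo) / (hi - lo) if hi > lo else out * 0.0


def _register_frame(ref: np.ndarray, moving: np.ndarray,
                    max_rotation_deg: float, coarse_step: float,
                    fine_step: float, upsample: int
                    ) -> tuple[float, float, float]:
    """Estimate (dx, dy, dtheta) mapping ``moving`` onto ``ref``.

    1D angular search (coarse then fine) over rotations about the image
    centre; translation by phase correlation at each candidate angle.
    """
    def try_angle(theta: float) -> tuple[float, np.ndarray]:
        if theta != 0.0:
            unrot = sktransform.rotate(moving, theta, preserve_range=True,
                                       mode="edge")
        else:
            unrot = moving
        shift, error, _ = phase_cross_correlation(ref, unrot,
                                                  upsample_factor=upsample,
                                                  normalization=None)
        return float(error), shift

    if max_rotation_deg <= 0:
        err, shift = try_angle(0.0)
        return float(shift[1]), float(shift[0]), 0.0

    def search(angles: np.ndarray, rel_margin: float = 5e-2
               ) -> tuple[float, float, np.ndarray]:
        # evaluate by increasing |theta|; a larger rotation must beat the
        # incumbent by a relative margin, so a flat (rotation-free) error
        # landscape resolves to theta = 0 instead of chasing noise
        best_th, (best_err, best_shift) = float(angles[0]), try_angle(float(angles[0]))
        for th in angles[1:]:
            err, shift = try_angle(float(th))
            if err < best_err * (1.0 - rel_margin):
                best_th, best_err, best_shift = float(th), err, shift
        return best_th, best_err, best_shift

    coarse = np.arange(-max_rotation_deg, max_rotation_deg + 1e-9, coarse_step)
    coarse = coarse[np.argsort(np.abs(coarse), kind="stable")]
    best, _, _ = search(coarse)
    fine = np.arange(best - coarse_step, best + coarse_step + 1e-9, fine_step)
    fine = fine[np.argsort(np.abs(fine - best), kind="stable")]
    theta, _, shift = search(fine)
    return float(shift[1]), float(shift[0]), float(theta)


def correct_drift(
    movie: Movie,
    template_channel: int | str = "dna",
    max_rotation_deg: float = 2.0,
    coarse_step_deg: float = 0.2,
    fine_step_deg: float = 0.05,
    upsample: int = 20,
    reference_frame: int = 0,
    resample_movie: bool = True,
) -> tuple[Movie, RigidTransformSeries]:
    """Rigid-body drift correction against a nuclear-silhouette template.

    Each frame's preprocessed template channel is registered onto the
    reference frame (rotation by 1D search within ±``max_rotation_deg``,
    translation by upsampled phase correlation). Set
    ``max_rotation_deg=0`` for translation-only registration. The returned
    transforms map frame coordinates onto the reference frame and should be
    applied to spot coordinates with :func:`apply_transforms_to_tracks`
    (coordinate correction avoids interpolation blur); the corrected movie
    is also emitted for visual inspection unless ``resample_movie=False``.
    """
    ci = (movie.channels.index(template_channel)
          if isinstance(template_channel, str) else template_channel)
    h, w = movie.shape
    center_rc = ((h - 1) / 2.0, (w - 1) / 2.0)
    templates = [_prepare_template(movie.data[f, ci])
                 for f in range(movie.n_frames)]
    ref = templates[reference_frame]
    dx = np.zeros(movie.n_frames)
    dy = np.zeros(movie.n_frames)
    dth = np.zeros(movie.n_frames)
    for f in range(movie.n_frames):
        if f == reference_frame:
            continue
        dx[f], dy[f], dth[f] = _register_frame(
            ref, templates[f], max_rotation_deg, coarse_step_deg,
            fine_step_deg, upsample)
        if not np.isfinite([dx[f], dy[f], dth[f]]).all():
            raise RuntimeError(f"registration failed at frame {f}")
    series = RigidTransformSeries(dx_px=dx, dy_px=dy, dtheta_deg=dth,
                                  center_px=center_rc)

    if not resample_movie:
        return movie, series
    out = np.empty_like(movie.data)
    center_xy = np.array([center_rc[1], center_rc[0]])
    for f in range(movie.n_frames):
        tf = (
            sktransform.SimilarityTransform(translation=-center_xy)
            + sktransform.SimilarityTransform(rotation=np.deg2rad(-dth[f]))
            + sktransform.SimilarityTransform(
                translation=center_xy + [dx[f], dy[f]])
        )
        for c in range(movie.data.shape[1]):
            if dx[f] == 0 and dy[f] == 0 and dth[f] == 0:
                out[f, c] = movie.data[f, c]
            else:
                out[f, c] = sktransform.warp(movie.data[f, c], tf.inverse,
                                             order=3, mode="edge",
                                             preserve_range=True)
    corrected = Movie(data=out, channels=movie.channels,
                      pixel_size_um=movie.pixel_size_um,
                      frame_interval_s=movie.frame_interval_s)
    return corrected, series


def apply_transforms_to_tracks(tracks: list[Track],
                               series: RigidTransformSeries,
                               pixel_size_um: float) -> list[Track]:
    """Map track coordinates onto the reference frame (no resampling)."""
    out = []
    for t in tracks:
        xy_px = t.xy_um / pixel_size_um
        new = np.empty_like(xy_px)
        for i, f in enumerate(t.frames):
            new[i] = series.transform_points(int(f), xy_px[i])[0]
        out.append(Track(track_id=t.track_id, frames=t.frames.copy(),
                         xy_um=new * pixel_size_um,
                         intensity=None if t.intensity is None else t.intensity.copy(),
                         channel=t.channel, nucleus_label=t.nucleus_label,
                         condition=t.condition))
    return out
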