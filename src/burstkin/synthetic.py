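"""Ground-truth generators: walker ensembles, burst schedules, rendered movies.

Everything downstream of this module is tested against the schedules,
positions and masks produced here. All randomness flows through a single
``numpy.random.Generator`` seeded from ``SimulationConfig.rng_seed``, so a
fixed config reproduces every array bit-for-bit.

Motion models
-------------
brownian   independent Gaussian steps per axis, Var = 2·D·dt.
confined   Brownian steps reflected at the disc of radius Rc about the
           start point (reflection applied before localization noise).
fbm        fractional Brownian motion with stationary increments and
           E[MSD(dT)] = 4·D·dT^alpha (2D convention), sampled exactly via
           Cholesky factorization of the fractional-Gaussian-noise
           covariance.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import ndimage as ndi
from skimage import transform as sktransform

from .core import (
    BurstSchedule,
    GroundTruth,
    Movie,
    SimulationConfig,
    Track,
    WalkerSpec,
)

__all__ = [
    "simulate_tracks",
    "telegraph_intervals",
    "EllipseNucleus",
    "BlobOrganelle",
    "render_movie",
    "inject_drift",
    "make_burst_movie",
    "simulate_state_modulated_locus",
]


# ---------------------------------------------------------------------------
# walker simulation
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _fgn_cholesky(n_steps: int, alpha: float) -> np.ndarray:
    """Cholesky factor of the unit fGn covariance for ``n_steps`` increments.

    rho(k) = 0.5*(|k+1|^a - 2|k|^a + |k-1|^a) is the autocovariance of
    unit-variance fractional Gaussian noise with Hurst H = alpha/2.
    """
    k = np.arange(n_steps, dtype=float)
    rho = 0.5 * (np.abs(k + 1) ** alpha - 2 * np.abs(k) ** alpha + np.abs(k - 1) ** alpha)
    cov = rho[np.abs(np.subtract.outer(np.arange(n_steps), np.arange(n_steps)))]
    # tiny jitter guards against numerically semi-definite cases at alpha→2
    return np.linalg.cholesky(cov + 1e-12 * np.eye(n_steps))


def _brownian_steps(n: int, D: float, dt: float, rng: np.random.Generator) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n, 2))


def _fbm_positions(n: int, D: float, alpha: float, dt: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Positions (n+1, 2) of an fBm walk starting at the origin."""
    if abs(alpha - 1.0) < 1e-12:
        steps = _brownian_steps(n, D, dt, rng)
    else:
        L = _fgn_cholesky(n, float(alpha))
        z = rng.standard_normal((n, 2))
        scale = np.sqrt(2.0 * D * dt**alpha)  # per-axis Var of one increment
        steps = scale * (L @ z)
    pos = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
    return pos


def _reflect_disc(pos: np.ndarray, center: np.ndarray, Rc: float) -> np.ndarray:
    """Mirror a point across the circle of radius Rc until it is inside."""
    p = pos.copy()
    for _ in range(64):
        d = np.hypot(*(p - center))
        if d <= Rc:
            return p
        p = center + (p - center) * ((2.0 * Rc - d) / d)
    # pathological step size; clamp to the boundary
    d = np.hypot(*(p - center))
    return center + (p - center) * (Rc / d)


def simulate_tracks(specs: list[WalkerSpec], cfg: SimulationConfig) -> list[Track]:
    """Simulate walker trajectories at the configured frame interval.

    Positions are in µm. Gaussian localization error of std
    ``cfg.localization_noise_um`` is added independently per frame and axis
    after the motion model (it represents camera error, not motion, so
    confined walkers respect the hard Rc bound before noise).
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    rng = np.random.default_rng(cfg.rng_seed)
    dt = cfg.frame_interval_s
    tracks: list[Track] = []
    for tid, spec in enumerate(specs):
        n_pos = spec.lifetime_frames
        n_steps = n_pos - 1
        start = np.asarray(spec.start_xy_um, dtype=float)
        if spec.model == "fbm":
            pos = start + _fbm_positions(n_steps, spec.D_um2_s, spec.alpha, dt, rng)
        elif spec.model == "brownian":
            steps = _brownian_steps(n_steps, spec.D_um2_s, dt, rng)
            pos = start + np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
        else:  # confined
            steps = _brownian_steps(n_steps, spec.D_um2_s, dt, rng)
            pos = np.empty((n_pos, 2))
            pos[0] = start
            for i in range(n_steps):
                pos[i + 1] = _reflect_disc(pos[i] + steps[i], start, spec.Rc_um)
        if cfg.localization_noise_um > 0:
            pos = pos + rng.normal(0.0, cfg.localization_noise_um, size=pos.shape)
        frames = np.arange(spec.start_frame, spec.start_frame + n_pos)
        tracks.append(Track(track_id=tid, frames=frames, xy_um=pos))
    return tracks


# ---------------------------------------------------------------------------
# burst schedules (telegraph process)
# ---------------------------------------------------------------------------

def telegraph_intervals(
    n_frames: int,
    mean_on_frames: float,
    mean_off_frames: float,
    rng: np.random.Generator,
    start_frame: int = 0,
) -> list[tuple[int, int]]:
    """Sample half-open on-intervals of a two-state telegraph process.

    Dwell times are exponential with the given means (in frames); the
    process starts in the off state at ``start_frame``.
    """
    intervals: list[tuple[int, int]] = []
    t = float(start_frame)
    while t < n_frames:
        t += rng.exponential(mean_off_frames)
        on_start = int(np.ceil(t))
        t += rng.exponential(mean_on_frames)
        on_end = int(np.ceil(t))
        if on_start >= n_frames:
            break
        on_end = min(on_end, n_frames)
        if on_end <= on_start:
            continue
        if intervals and on_start <= intervals[-1][1]:
            # off dwell shorter than one frame: indistinguishable from a
            # continuous burst at this sampling, so merge
            intervals[-1] = (intervals[-1][0], on_end)
        else:
            intervals.append((on_start, on_end))
    return intervals


# ---------------------------------------------------------------------------
# movie rendering
# ---------------------------------------------------------------------------

class EllipseNucleus:
    """Elliptical nucleus footprint (pixel units)."""

    def __init__(self, center_px: tuple[float, float], axes_px: tuple[float, float],
                 angle_deg: float = 0.0, label: int = 1):
        self.center_px = center_px  # (row, col)
        self.axes_px = axes_px      # (semi-axis row, semi-axis col)
        self.angle_deg = angle_deg
        self.label = label

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        dr = rr - self.center_px[0]
        dc = cc - self.center_px[1]
        th = np.deg2rad(self.angle_deg)
        u = np.cos(th) * dr + np.sin(th) * dc
        v = -np.sin(th) * dr + np.cos(th) * dc
        return (u / self.axes_px[0]) ** 2 + (v / self.axes_px[1]) ** 2 <= 1.0


class BlobOrganelle:
    """Speckle-like organelle: a union of discs around a centre."""

    def __init__(self, center_px: tuple[float, float], radius_px: float,
                 n_lobes: int = 1, lobe_jitter_px: float = 0.0, seed: int = 0):
        self.center_px = center_px
        self.radius_px = radius_px
        self.n_lobes = n_lobes
        self.lobe_jitter_px = lobe_jitter_px
        self.seed = seed

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        out = np.zeros(shape, dtype=bool)
        centers = [self.center_px]
        for _ in range(self.n_lobes - 1):
            centers.append(
                (
                    self.center_px[0] + rng.normal(0, self.lobe_jitter_px),
                    self.center_px[1] + rng.normal(0, self.lobe_jitter_px),
                )
            )
        for cr, ccen in centers:
            out |= (rr - cr) ** 2 + (cc - ccen) ** 2 <= self.radius_px**2
        return out


def _render_gaussian_spot(img: np.ndarray, row: float, col: float,
                          amplitude: float, sigma: float) -> None:
    """Add a 2D Gaussian of given peak amplitude in place."""
    h, w = img.shape
    half = int(np.ceil(4 * sigma))
    r0, r1 = max(0, int(row) - half), min(h, int(row) + half + 1)
    c0, c1 = max(0, int(col) - half), min(w, int(col) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    img[r0:r1, c0:c1] += amplitude * np.exp(
        -((rr - row) ** 2 + (cc - col) ** 2) / (2 * sigma**2)
    )


CHANNELS = ("rna", "dna", "organelle", "nuclear")


def render_movie(
    tracks: list[Track],
    bursts: list[BurstSchedule],
    nuclei: list[EllipseNucleus],
    organelles: list[BlobOrganelle] | None,
    cfg: SimulationConfig,
    track_nucleus: dict[int, int] | None = None,
    nuclear_level_factor: float = 1.0,
) -> tuple[Movie, GroundTruth]:
    """Render walker tracks and burst schedules into a noisy 4-channel movie.

    Channels: ``rna`` (burst foci, visible only during on-intervals),
    ``dna`` (locus tag, always visible), ``organelle`` and ``nuclear``.
    Spots are Gaussians of width ``psf_sigma_px`` and peak amplitude
    ``snr * noise_sigma`` over the nuclear background; noise is Poisson
    shot noise plus Gaussian read noise.
    """
    h, w = cfg.image_shape
    rng = np.random.default_rng(cfg.rng_seed + 1)

    nuclei_label = np.zeros((h, w), dtype=np.int32)
    for nuc in nuclei:
        m = nuc.mask((h, w))
        if np.any(nuclei_label[m] != 0):
            raise ValueError("nuclei overlap")
        nuclei_label[m] = nuc.label

    org_mask = np.zeros((h, w), dtype=bool)
    for org in organelles or []:
        org_mask |= org.mask((h, w))

    # static smooth texture inside nuclei (zero-median multiplicative field)
    texture = ndi.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), 6.0)
    texture -= np.median(texture)
    texture *= 0.05 / max(texture.std(), 1e-12)

    nuc_bg = cfg.background_level * nuclear_level_factor * (1.0 + texture)
    outside_bg = 0.2 * cfg.background_level
    base = np.where(nuclei_label > 0, nuc_bg, outside_bg)

    amp = cfg.snr * cfg.noise_sigma
    px = cfg.pixel_size_um
    track_by_id = {t.track_id: t for t in tracks}

    for t in tracks:
        pos_px = t.xy_um / px
        if np.any(pos_px < 0) or np.any(pos_px[:, 0] >= w) or np.any(pos_px[:, 1] >= h):
            raise ValueError(f"track {t.track_id} exits the image")

    data = np.empty((cfg.n_frames, len(CHANNELS), h, w), dtype=float)
    for f in range(cfg.n_frames):
        frame = {name: base.copy() for name in CHANNELS}
        frame["organelle"] = base + np.where(org_mask, amp, 0.0)
        # dna channel: every track's locus spot
        for t in tracks:
            idx = np.searchsorted(t.frames, f)
            if idx < len(t.frames) and t.frames[idx] == f:
                x, y = t.xy_um[idx] / px
                _render_gaussian_spot(frame["dna"], y, x, amp, cfg.psf_sigma_px)
        # rna channel: burst focus only while on
        for b in bursts:
            if not b.is_on(f):
                continue
            ft = track_by_id.get(b.focus_track)
            if ft is None:
                continue
            idx = np.searchsorted(ft.frames, f)
            if idx < len(ft.frames) and ft.frames[idx] == f:
                x, y = ft.xy_um[idx] / px
                _render_gaussian_spot(frame["rna"], y, x, amp * b.on_intensity,
                                      cfg.psf_sigma_px)
        for ci, name in enumerate(CHANNELS):
            noisy = rng.poisson(np.clip(frame[name], 0, None)).astype(float)
            noisy += rng.normal(0.0, cfg.read_noise, (h, w))
            data[f, ci] = noisy

    movie = Movie(data=data, channels=CHANNELS, pixel_size_um=px,
                  frame_interval_s=cfg.frame_interval_s)
    gt = GroundTruth(
        tracks=tracks,
        bursts=bursts,
        nuclei_mask=nuclei_label,
        organelle_mask=org_mask,
        track_nucleus=dict(track_nucleus or {}),
    )
    return movie, gt


# ---------------------------------------------------------------------------
# drift injection
# ---------------------------------------------------------------------------

def inject_drift(
    movie: Movie,
    drift: np.ndarray,
    ground_truth: GroundTruth | None = None,
) -> Movie:
    """Apply per-frame rigid-body drift (dx_px, dy_px, dtheta_deg).

    Each frame is rotated about the image centre by ``dtheta_deg`` and then
    translated by ``(dx_px, dy_px)`` (x = columns, y = rows), emulating
    stage drift and slow cell rotation. If ``ground_truth`` is given its
    ``drift`` field records the applied transforms.
    """
    drift = np.asarray(drift, dtype=float)
    if drift.shape != (movie.n_frames, 3):
        raise ValueError("drift must be (n_frames, 3)")
    h, w = movie.shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])  # (x, y)
    out = np.empty_like(movie.data)
    for f in range(movie.n_frames):
        dx, dy, dth = drift[f]
        tf = (
            sktransform.SimilarityTransform(translation=-center)
            + sktransform.SimilarityTransform(rotation=np.deg2rad(dth))
            + sktransform.SimilarityTransform(translation=center + [dx, dy])
        )
        for c in range(movie.data.shape[1]):
            if dx == 0 and dy == 0 and dth == 0:
                out[f, c] = movie.data[f, c]
            else:
                out[f, c] = sktransform.warp(
                    movie.data[f, c], tf.inverse, order=3, mode="edge",
                    preserve_range=True,
                )
    if ground_truth is not None:
        ground_truth.drift = drift.copy()
    return Movie(data=out, channels=movie.channels,
                 pixel_size_um=movie.pixel_size_um,
                 frame_interval_s=movie.frame_interval_s)


def drift_point_forward(xy_px: np.ndarray, drift_row: np.ndarray,
                        shape: tuple[int, int]) -> np.ndarray:
    """Where a point of the undrifted frame lands after drift (x, y in px)."""
    h, w = shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    dx, dy, dth = drift_row
    th = np.deg2rad(dth)
    xy = np.atleast_2d(np.asarray(xy_px, float))
    u = xy[:, 0] - cx
    v = xy[:, 1] - cy
    xr = np.cos(th) * u - np.sin(th) * v + cx + dx
    yr = np.sin(th) * u + np.cos(th) * v + cy + dy
    return np.column_stack([xr, yr])


# ---------------------------------------------------------------------------
# higher-level study designs
# ---------------------------------------------------------------------------

def make_burst_movie(
    cfg: SimulationConfig,
    n_nuclei: int = 20,
    mean_on_frames: float = 8.0,
    mean_off_frames: float = 20.0,
    locus_D_um2_s: float = 0.005,
    locus_Rc_um: float = 0.4,
    nucleus_radius_px: float | None = None,
    on_intensity: float = 3.0,
) -> tuple[Movie, GroundTruth]:
    """Telegraph-bursting nuclei on a grid: the burst-calling fixture.

    Each nucleus holds one confined locus walker whose position carries the
    MS2 focus; the focus is rendered only during the nucleus's on-intervals.
    The focus is ``on_intensity`` times brighter than the single-spot SNR
    reference (an MS2 focus aggregates tens of stem-loop-bound coat
    proteins over multiple nascent transcripts, so it dominates the diffuse
    nucleoplasmic reporter background).
    """
    h, w = cfg.image_shape
    rng = np.random.default_rng(cfg.rng_seed + 2)
    n_cols = int(np.ceil(np.sqrt(n_nuclei)))
    n_rows = int(np.ceil(n_nuclei / n_cols))
    cell_h, cell_w = h / n_rows, w / n_cols
    if nucleus_radius_px is None:
        nucleus_radius_px = 0.32 * min(cell_h, cell_w)

    nuclei: list[EllipseNucleus] = []
    specs: list[WalkerSpec] = []
    schedules: list[BurstSchedule] = []
    track_nucleus: dict[int, int] = {}
    for i in range(n_nuclei):
        r = (i // n_cols + 0.5) * cell_h
        c = (i % n_cols + 0.5) * cell_w
        ax = nucleus_radius_px * rng.uniform(0.85, 1.0)
        ay = nucleus_radius_px * rng.uniform(0.85, 1.0)
        label = i + 1
        nuclei.append(EllipseNucleus((r, c), (ax, ay), label=label))
        start_um = (c * cfg.pixel_size_um, r * cfg.pixel_size_um)
        specs.append(
            WalkerSpec(
                model="confined",
                D_um2_s=locus_D_um2_s,
                Rc_um=min(locus_Rc_um, 0.5 * min(ax, ay) * cfg.pixel_size_um),
                start_xy_um=start_um,
                lifetime_frames=cfg.n_frames,
            )
        )
        intervals = telegraph_intervals(cfg.n_frames, mean_on_frames,
                                        mean_off_frames, rng)
        schedules.append(BurstSchedule(nucleus_id=label, on_intervals=intervals,
                                       focus_track=i, on_intensity=on_intensity))
        track_nucleus[i] = label

    tracks = simulate_tracks(specs, cfg)
    for t in tracks:
        t.nucleus_label = track_nucleus[t.track_id]
    return render_movie(tracks, schedules, nuclei, None, cfg,
                        track_nucleus=track_nucleus)


def simulate_state_modulated_locus(
    cfg: SimulationConfig,
    n_cells: int = 20,
    D_by_state: dict[str, float] | None = None,
    t0_frame: int = 0,
    phase_frames: dict[str, tuple[int, int]] | None = None,
    mean_on_frames: float = 10.0,
    mean_off_frames: float = 25.0,
    seed_offset: int = 0,
) -> tuple[list[Track], list[BurstSchedule]]:
    """Loci whose instantaneous D depends on transcriptional state.

    Ground truth for the burst-mobility analysis: within each cell a single
    locus performs Brownian motion whose per-frame step variance switches
    with the burst schedule (and, if ``phase_frames`` is given, with the
    stimulation phase). Returns one Track and one BurstSchedule per cell;
    track_id doubles as nucleus/cell id.
    """
    if D_by_state is None:
        D_by_state = {"pre": 0.002, "burst": 0.004, "nonburst": 0.008}
    rng = np.random.default_rng(cfg.rng_seed + 3 + seed_offset)
    dt = cfg.frame_interval_s
    tracks: list[Track] = []
    schedules: list[BurstSchedule] = []
    for cell in range(n_cells):
        intervals = telegraph_intervals(cfg.n_frames, mean_on_frames,
                                        mean_off_frames, rng,
                                        start_frame=t0_frame)
        sched = BurstSchedule(nucleus_id=cell, on_intervals=intervals,
                              focus_track=cell)
        pos = np.empty((cfg.n_frames, 2))
        pos[0] = rng.uniform(2.0, 8.0, 2)
        for f in range(1, cfg.n_frames):
            if f <= t0_frame:
                state = "pre"
            elif sched.is_on(f):
                state = "burst"
            else:
                state = "nonburst"
            if phase_frames is not None:
                for name, (a, b) in phase_frames.items():
                    if a <= f < b and name in D_by_state:
                        state = name
            step_sd = np.sqrt(2.0 * D_by_state[state] * dt)
            pos[f] = pos[f - 1] + rng.normal(0.0, step_sd, 2)
        if cfg.localization_noise_um > 0:
            pos = pos + rng.normal(0.0, cfg.localization_noise_um, pos.shape)
        tracks.append(
            Track(track_id=cell, frames=np.arange(cfg.n_frames), xy_um=pos,
                  nucleus_label=cell)
        )
        schedules.append(sched)
    return tracks, schedules
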