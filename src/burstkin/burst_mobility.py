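"""Burst- and phase-resolved locus mobility.

DNA-locus tracks are cut into segments by transcriptional state — a frame
is burst-labelled iff it falls inside an on-interval of a burst event of
the same nucleus — or by stimulation phase (pre / acute / chronic relative
to hormone addition). Mobility is then compared between states with
per-cell mean single-frame displacements and two-tailed t-tests, paired
across cells whenever both states were observed in the same cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .biophysics import compute_track_features, single_frame_displacements
from .core import BurstEvent, Track

__all__ = [
    "PhaseWindows",
    "TrackSegment",
    "segment_by_bursts",
    "segment_by_phase",
    "compare_mobility",
    "normalized_displacement_timecourse",
    "significance_stars",
]


@dataclass(frozen=True)
class PhaseWindows:
    """Stimulation-phase windows in seconds relative to hormone addition.

    Defaults: pre-stimulation before t=0, acute 0–120 min, chronic from
    160 min on (frames between 120 and 160 min are deliberately unlabeled).
    An alternative preset anchored on the observed bursting peak (acute
    24–132 min) is available via :meth:`bursting_peak_preset`.
    """

    pre: tuple[float, float] = (-np.inf, 0.0)
    acute: tuple[float, float] = (0.0, 120.0 * 60.0)
    chronic: tuple[float, float] = (160.0 * 60.0, np.inf)

    @classmethod
    def bursting_peak_preset(cls) -> "PhaseWindows":
        return cls(acute=(24.0 * 60.0, 132.0 * 60.0))

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {"pre": self.pre, "acute": self.acute, "chronic": self.chronic}

    def label(self, t_s: float) -> str | None:
        for name, (a, b) in self.as_dict().items():
            if a <= t_s < b:
                return name
        return None


@dataclass
class TrackSegment:
    """A maximal run of equal state within one track."""

    track_id: int
    state: str
    start_frame: int
    end_frame: int  # half-open
    nucleus_label: int
    displacements: np.ndarray = field(default_factory=lambda: np.empty(0))
    alpha: float = float("nan")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame

    @property
    def mean_disp_um(self) -> float:
        return float(np.mean(self.displacements)) if len(self.displacements) else float("nan")


def _runs(labels: list[str | None]) -> list[tuple[int, int, str]]:
    """Maximal runs of equal non-None label as (start, end, label)."""
    runs = []
    start = None
    for i, lab in enumerate(labels + [None]):
        if start is not None and (lab != labels[start]):
            if labels[start] is not None:
                runs.append((start, i, labels[start]))
            start = i if lab is not None else None
        elif start is None and lab is not None:
            start = i
    return runs


def _segments_from_labels(
    track: Track,
    frame_labels: list[str | None],
    frame_interval_s: float,
    min_segment_frames: int,
    feature_min_frames: int = 10,
) -> list[TrackSegment]:
    segs: list[TrackSegment] = []
    for i0, i1, state in _runs(frame_labels):
        sub_frames = track.frames[i0:i1]
        if len(sub_frames) < min_segment_frames:
            continue
        sub = track.slice_frames(int(sub_frames[0]), int(sub_frames[-1]) + 1)
        alpha = float("nan")
        if len(sub) >= feature_min_frames:
            alpha = compute_track_features(sub, frame_interval_s).alpha
        segs.append(
            TrackSegment(
                track_id=track.track_id, state=state,
                start_frame=int(sub_frames[0]),
                end_frame=int(sub_frames[-1]) + 1,
                nucleus_label=track.nucleus_label,
                displacements=single_frame_displacements(sub),
                alpha=alpha,
            )
        )
    return segs


def segment_by_bursts(
    dna_tracks: list[Track],
    bursts: list[BurstEvent],
    frame_interval_s: float,
    min_segment_frames: int = 3,
) -> list[TrackSegment]:
    """Cut DNA tracks into burst / non-burst segments.

    A frame is burst-labelled iff it lies inside an on-interval of a burst
    event of the same nucleus (frame-level containment, so within-track
    transitions are preserved). Segments shorter than
    ``min_segment_frames`` are dropped from displacement statistics.
    Tracks whose nucleus has no burst events at all still yield their
    non-burst segments.
    """
    by_nucleus: dict[int, list[BurstEvent]] = {}
    for b in bursts:
        by_nucleus.setdefault(b.nucleus_id, []).append(b)
    segments: list[TrackSegment] = []
    for t in dna_tracks:
        evs = by_nucleus.get(t.nucleus_label, [])
        labels: list[str | None] = [
            "burst" if any(e.contains(int(f)) for e in evs) else "nonburst"
            for f in t.frames
        ]
        segments.extend(_segments_from_labels(t, labels, frame_interval_s,
                                              min_segment_frames))
    return segments


def segment_by_phase(
    tracks: list[Track],
    windows: PhaseWindows,
    t0_frame: int,
    frame_interval_s: float,
    min_segment_frames: int = 3,
) -> list[TrackSegment]:
    """Cut tracks into pre / acute / chronic segments relative to t0.

    Frames falling in no window (e.g. the 120–160 min transition) stay
    unlabeled and break segments.
    """
    segments: list[TrackSegment] = []
    for t in tracks:
        labels = [windows.label((int(f) - t0_frame) * frame_interval_s)
                  for f in t.frames]
        segments.extend(_segments_from_labels(t, labels, frame_interval_s,
                                              min_segment_frames))
    return segments


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return "n/a"
    for thr, mark in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < thr:
            return mark
    return "ns"


def compare_mobility(
    segments: list[TrackSegment],
    grouping: str | list[str] = "burst_vs_nonburst",
    compare_alpha: bool = False,
) -> dict:
    """Per-cell mobility comparison between states.

    Cells (nuclei) are the statistical unit: each cell contributes its mean
    single-frame displacement per state. For two groups the test is a
    paired two-tailed t-test across cells observed in both states, falling
    back to an unpaired test otherwise; with three phases all pairwise
    comparisons are reported. Set ``compare_alpha`` to also test
    per-segment anomalous exponents (used for the
    transcription-inhibition analysis).
    """
    if grouping == "burst_vs_nonburst":
        states = ["burst", "nonburst"]
    elif grouping == "phase":
        states = ["pre", "acute", "chronic"]
    elif isinstance(grouping, (list, tuple)) and len(grouping) >= 2:
        states = list(grouping)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    per_cell: dict[str, dict[int, float]] = {s: {} for s in states}
    alpha_by_state: dict[str, list[float]] = {s: [] for s in states}
    for s in states:
        cells: dict[int, list[float]] = {}
        for seg in segments:
            if seg.state != s:
                continue
            if len(seg.displacements):
                cells.setdefault(seg.nucleus_label, []).extend(
                    seg.displacements.tolist())
            if np.isfinite(seg.alpha):
                alpha_by_state[s].append(seg.alpha)
        per_cell[s] = {c: float(np.mean(v)) for c, v in cells.items()}

    observed = [s for s in states if per_cell[s]]
    if len(observed) < 2:
        raise ValueError("need at least two observed groups to compare")

    comparisons = []
    for i in range(len(observed)):
        for j in range(i + 1, len(observed)):
            a, b = observed[i], observed[j]
            shared = sorted(set(per_cell[a]) & set(per_cell[b]))
            if len(shared) >= 2:
                va = [per_cell[a][c] for c in shared]
                vb = [per_cell[b][c] for c in shared]
                res = stats.ttest_rel(va, vb)
                paired, n = True, len(shared)
            else:
                va = list(per_cell[a].values())
                vb = list(per_cell[b].values())
                if len(va) < 2 or len(vb) < 2:
                    continue
                res = stats.ttest_ind(va, vb)
                paired, n = False, min(len(va), len(vb))
            comp = {
                "group_a": a, "group_b": b,
                "mean_a_um": float(np.mean(va)),
                "mean_b_um": float(np.mean(vb)),
                "t": float(res.statistic), "p": float(res.pvalue),
                "paired": paired, "n_cells": n,
                "stars": significance_stars(float(res.pvalue)),
            }
            if compare_alpha and alpha_by_state[a] and alpha_by_state[b]:
                ares = stats.ttest_ind(alpha_by_state[a], alpha_by_state[b])
                comp["median_alpha_a"] = float(np.median(alpha_by_state[a]))
                comp["median_alpha_b"] = float(np.median(alpha_by_state[b]))
                comp["alpha_p"] = float(ares.pvalue)
            comparisons.append(comp)

    return {
        "grouping": grouping,
        "per_cell_mean_disp_um": {s: per_cell[s] for s in observed},
        "group_means_um": {s: float(np.mean(list(per_cell[s].values())))
                           for s in observed},
        "comparisons": comparisons,
    }


def normalized_displacement_timecourse(
    tracks: list[Track],
    t0_frame: int,
    frame_interval_s: float,
    bin_s: float,
    anchor: str = "pre",
    min_loci_per_bin: int = 3,
) -> pd.DataFrame:
    """Mean single-frame displacement over time, normalized to baseline.

    Displacements are assigned to time bins by their midpoint relative to
    t0; each bin's mean over loci is divided by the pre-stimulation mean
    (``anchor='pre'``) or the first bin (``anchor='first'``). Bins with
    fewer loci than ``min_loci_per_bin`` are flagged.
    """
    times, disps, loci = [], [], []
    for t in tracks:
        consecutive = np.diff(t.frames) == 1
        d = np.diff(t.xy_um, axis=0)[consecutive]
        mid = (t.frames[:-1][consecutive] + 0.5 - t0_frame) * frame_interval_s
        times.append(mid)
        disps.append(np.hypot(d[:, 0], d[:, 1]))
        loci.append(np.full(len(mid), t.track_id))
    times = np.concatenate(times) if times else np.empty(0)
    disps = np.concatenate(disps) if disps else np.empty(0)
    loci = np.concatenate(loci) if loci else np.empty(0)

    if anchor == "pre":
        pre = disps[times < 0]
        if pre.size == 0:
            raise ValueError(
                "no pre-stimulation displacements; use anchor='first'")
        norm = float(pre.mean())
    elif anchor == "first":
        norm = None  # set after binning
    else:
        raise ValueError(f"unknown anchor {anchor!r}")

    lo = np.floor(times.min() / bin_s) * bin_s if times.size else 0.0
    hi = np.ceil(times.max() / bin_s) * bin_s if times.size else bin_s
    edges = np.arange(lo, hi + bin_s, bin_s)
    rows = []
    for a, b in zip(edges[:-1], edges[1:]):
        sel = (times >= a) & (times < b)
        n_loci = len(np.unique(loci[sel]))
        rows.append({
            "t_mid_s": (a + b) / 2,
            "mean_disp_um": float(disps[sel].mean()) if sel.any() else np.nan,
            "n_loci": n_loci,
            "flagged": n_loci < min_loci_per_bin,
        })
    df = pd.DataFrame(rows)
    if anchor == "first":
        first = df["mean_disp_um"].dropna()
        norm = float(first.iloc[0]) if len(first) else np.nan
    df["normalized_disp"] = df["mean_disp_um"] / norm if norm else np.nan
    return df
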