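"""Crossover-peak detection, refinement and frame-to-frame linking.

The crossover points of the two-start actin helix appear as height maxima
along the filament. Peaks are found semi-automatically: a backbone is
traced through the filament (or approximate points are supplied manually),
local maxima of the height profile along the backbone are picked, and each
is refined by the two-step rule used throughout the analysis — the maximum
pixel of a 5x5 window, then the height-weighted center of mass of the 5x5
window around that maximum (weights are heights minus the window minimum,
which makes the estimate invariant to a height offset).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage.morphology import skeletonize

from .frames import HeightFrame

__all__ = [
    "FilamentTrace",
    "PeakRecord",
    "PeakTrack",
    "trace_backbone",
    "trace_all",
    "sample_profile",
    "refine_peak",
    "detect_peaks_along_trace",
    "link_peaks",
]


@dataclass
class FilamentTrace:
    """Ordered backbone polyline with arc-length coordinates.

    ``points`` is (N, 2) in nm as (x, y); ``arc_coords`` the cumulative
    arc length per point. Polarity is carried as annotation
    (``pointed_at_start`` / ``pointed_at_end`` / ``unknown``) — it cannot
    be read off a topograph without a polarity marker.
    """

    points: np.ndarray
    polarity: str = "unknown"
    arc_coords: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 2 or self.points.shape[1] != 2:
            raise ValueError("trace needs >= 2 (x, y) points")
        if self.arc_coords is None:
            seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            self.arc_coords = np.concatenate(([0.0], np.cumsum(seg)))
        self.arc_coords = np.asarray(self.arc_coords, dtype=float)
        if np.any(np.diff(self.arc_coords) <= 0):
            raise ValueError("arc coordinates must be strictly increasing")

    @property
    def length_nm(self) -> float:
        return float(self.arc_coords[-1])

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class PeakRecord:
    """One refined crossover peak."""

    frame_index: int
    position_nm: tuple[float, float]
    arc_nm: float
    height_nm: float
    track_id: Optional[int] = None
    degenerate: bool = False


@dataclass
class PeakTrack:
    """Time-ordered records of one peak followed across frames."""

    track_id: int
    records: list[PeakRecord] = field(default_factory=list)

    @property
    def heights(self) -> np.ndarray:
        return np.array([r.height_nm for r in self.records])

    @property
    def frames(self) -> np.ndarray:
        return np.array([r.frame_index for r in self.records])

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# backbone tracing
# ---------------------------------------------------------------------------

_EIGHT = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]


def _longest_skeleton_path(skel: np.ndarray) -> list[tuple[int, int]]:
    """Ordered pixel path between the two farthest skeleton endpoints.

    Double breadth-first search (tree-diameter heuristic); also prunes
    short side spurs the skeletonization may leave at filament ends.
    """
    pixels = set(zip(*np.nonzero(skel)))

    def bfs(start):
        dist = {start: 0}
        parent = {start: None}
        queue = deque([start])
        far = start
        while queue:
            p = queue.popleft()
            for dy, dx in _EIGHT:
                q = (p[0] + dy, p[1] + dx)
                if q in pixels and q not in dist:
                    dist[q] = dist[p] + 1
                    parent[q] = p
                    queue.append(q)
                    if dist[q] > dist[far]:
                        far = q
        return far, parent

    start = next(iter(pixels))
    a, _ = bfs(start)
    b, parent = bfs(a)
    path = []
    node = b
    while node is not None:
        path.append(node)
        node = parent[node]
    return path


def trace_backbone(
    frame: HeightFrame,
    seed_point_nm: tuple[float, float],
    height_floor_nm: float = 4.0,
    min_length_nm: float = 40.0,
    polarity: str = "unknown",
) -> FilamentTrace:
    """Ridge-following backbone through the filament containing a seed.

    The connected region above ``height_floor_nm`` that contains the seed
    is skeletonized; the longest path through the skeleton is lightly
    smoothed and resampled at 1-pixel arc steps, ordered from the end
    with the smaller x (then y).

    Raises
    ------
    ValueError
        If the seed lies on background or the traced region is shorter
        than ``min_length_nm`` (roughly two half helices).
    """
    px = frame.pixel_size_nm
    col = int(round(seed_point_nm[0] / px))
    row = int(round(seed_point_nm[1] / px))
    mask = frame.grid >= height_floor_nm
    if not (0 <= row < mask.shape[0] and 0 <= col < mask.shape[1]) or not mask[row, col]:
        raise ValueError("seed point lies below the height floor")
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3)))
    comp = labels == labels[row, col]
    trace = _trace_component(comp, px, polarity, frame, height_floor_nm)
    if trace.length_nm < min_length_nm:
        raise ValueError(
            f"traced region is {trace.length_nm:.1f} nm, shorter than {min_length_nm} nm"
        )
    return trace


def _trace_component(
    comp: np.ndarray,
    px: float,
    polarity: str,
    frame: Optional[HeightFrame] = None,
    height_floor_nm: float = 4.0,
) -> FilamentTrace:
    skel = skeletonize(comp)
    if skel.sum() < 2:
        raise ValueError("region too small to trace")
    path = _longest_skeleton_path(skel)
    pts = np.array([(c, r) for r, c in path], dtype=float) * px  # (x, y) nm
    if len(pts) < 2:
        raise ValueError("region too small to trace")
    # orient deterministically: start at smaller x (then smaller y)
    if tuple(pts[0]) > tuple(pts[-1]):
        pts = pts[::-1]
    # light smoothing tames pixel staircase before arc-length resampling
    if len(pts) >= 5:
        pts = np.column_stack(
            [ndimage.uniform_filter1d(pts[:, i], size=5, mode="nearest") for i in range(2)]
        )
    if frame is not None:
        # center on the ridge, re-smoothing each pass so per-point noise in
        # the snap does not zig-zag the polyline (which would inflate arcs)
        for _ in range(2):
            pts = _snap_to_ridge(pts, frame)
            pts = np.column_stack(
                [ndimage.uniform_filter1d(pts[:, i], size=7, mode="nearest") for i in range(2)]
            )
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate(([0.0], np.cumsum(seg)))
    keep = np.concatenate(([True], np.diff(arc) > 1e-9))
    pts, arc = pts[keep], arc[keep]
    s = np.arange(0.0, arc[-1], px)
    resampled = np.column_stack([np.interp(s, arc, pts[:, 0]), np.interp(s, arc, pts[:, 1])])
    if frame is not None:
        resampled = _extend_to_floor(resampled, frame, height_floor_nm, px)
    seg = np.linalg.norm(np.diff(resampled, axis=0), axis=1)
    arcs = np.concatenate(([0.0], np.cumsum(seg)))
    return FilamentTrace(resampled, polarity=polarity, arc_coords=arcs)


def _snap_to_ridge(pts: np.ndarray, frame: HeightFrame, reach_px: float = 3.0) -> np.ndarray:
    """Center trace points on the filament ridge.

    Each point moves along its local perpendicular to the height-weighted
    centroid of the profile sampled within ``reach_px`` pixels, which
    corrects the off-axis wander skeletonization leaves near filament
    ends.
    """
    px = frame.pixel_size_nm
    tangents = np.gradient(pts, axis=0)
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tangents /= norms
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    offsets = np.linspace(-reach_px * px, reach_px * px, 2 * int(reach_px) * 2 + 1)
    # sample a (n_points, n_offsets) sheet of heights
    sample = pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    coords = np.stack([sample[..., 1].ravel() / px, sample[..., 0].ravel() / px])
    h = ndimage.map_coordinates(frame.grid, coords, order=1, mode="nearest").reshape(
        len(pts), len(offsets)
    )
    w = h - h.min(axis=1, keepdims=True)
    wsum = w.sum(axis=1)
    wsum[wsum == 0] = 1.0
    shift = (w * offsets[None, :]).sum(axis=1) / wsum
    return pts + shift[:, None] * normals


def _extend_to_floor(
    pts: np.ndarray, frame: HeightFrame, floor: float, step_nm: float, max_steps: int = 20
) -> np.ndarray:
    """Extend a trace past the skeleton ends along the end tangents.

    Skeletonization retracts from the rounded filament tips by roughly
    the filament half-width, which would drop the terminal crossover
    peaks; the trace is continued in 1-px steps while the interpolated
    height stays above the floor (and inside the frame).
    """
    px = frame.pixel_size_nm
    h, w = frame.grid.shape

    def height_at(p):
        if not (0 <= p[0] < (w - 1) * px and 0 <= p[1] < (h - 1) * px):
            return -np.inf
        return float(
            ndimage.map_coordinates(
                frame.grid, [[p[1] / px], [p[0] / px]], order=1, mode="nearest"
            )[0]
        )

    k = min(5, len(pts) - 1)
    for end in (0, -1):
        anchor = pts[0] if end == 0 else pts[-1]
        inner = pts[k] if end == 0 else pts[-1 - k]
        tangent = anchor - inner
        norm = np.linalg.norm(tangent)
        if norm == 0:
            continue
        tangent = tangent / norm * step_nm
        ext = []
        p = anchor.copy()
        for _ in range(max_steps):
            p = p + tangent
            if height_at(p) < floor:
                break
            ext.append(p.copy())
        if ext:
            if end == 0:
                pts = np.vstack([ext[::-1], pts])
            else:
                pts = np.vstack([pts, ext])
    return pts


def trace_all(
    frame: HeightFrame,
    height_floor_nm: float = 4.0,
    min_length_nm: float = 40.0,
) -> list[FilamentTrace]:
    """Trace every sufficiently long filament in a frame.

    Connected regions above the floor are traced independently; regions
    shorter than ``min_length_nm`` are skipped. Traces are ordered by
    their mean y (top to bottom).
    """
    mask = frame.grid >= height_floor_nm
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    traces = []
    for lab in range(1, n + 1):
        comp = labels == lab
        if comp.sum() < 10:
            continue
        try:
            trace = _trace_component(comp, frame.pixel_size_nm, "unknown", frame, height_floor_nm)
        except ValueError:
            continue
        if trace.length_nm >= min_length_nm:
            traces.append(trace)
    traces.sort(key=lambda t: t.centroid[1])
    return traces


def sample_profile(frame: HeightFrame, trace: FilamentTrace) -> np.ndarray:
    """Bilinearly interpolated height profile along a trace."""
    px = frame.pixel_size_nm
    coords = np.vstack([trace.points[:, 1] / px, trace.points[:, 0] / px])
    return ndimage.map_coordinates(frame.grid, coords, order=1, mode="nearest")


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------


def refine_peak(
    frame: HeightFrame,
    approx_point_nm: tuple[float, float],
    window_px: int = 5,
    interpolate: bool = True,
    frame_index: int = 0,
) -> PeakRecord:
    """Two-step peak refinement inside a ``window_px`` square window.

    Step 1 locates the maximum pixel of the window centered on the
    approximate point (ties broken toward the smallest row, then column).
    Step 2 replaces the position by the height-weighted center of mass of
    the window re-centered on that maximum, with weights equal to heights
    minus the window minimum. The reported height is the bilinearly
    interpolated height at the refined position (or the maximum-pixel
    height with ``interpolate=False``).

    Raises ``ValueError`` if either window would extend outside the
    frame. A perfectly flat window is returned with ``degenerate=True``
    at the tie-break pixel.
    """
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window_px must be an odd integer >= 3")
    px = frame.pixel_size_nm
    grid = frame.grid
    r = window_px // 2

    def window_around(row, col):
        if row - r < 0 or col - r < 0 or row + r >= grid.shape[0] or col + r >= grid.shape[1]:
            raise ValueError("refinement window extends outside the frame")
        return grid[row - r : row + r + 1, col - r : col + r + 1]

    row0 = int(round(approx_point_nm[1] / px))
    col0 = int(round(approx_point_nm[0] / px))
    win = window_around(row0, col0)
    k = int(np.argmax(win))  # row-major: smallest row then column on ties
    mrow, mcol = row0 - r + k // window_px, col0 - r + k % window_px

    win = window_around(mrow, mcol)
    w = win - win.min()
    degenerate = bool(np.all(w <= 0))
    if degenerate:
        ref_row, ref_col = float(mrow), float(mcol)
    else:
        dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
        ref_row = mrow + float((w * dy).sum() / w.sum())
        ref_col = mcol + float((w * dx).sum() / w.sum())

    if interpolate:
        height = float(
            ndimage.map_coordinates(grid, [[ref_row], [ref_col]], order=1, mode="nearest")[0]
        )
    else:
        height = float(grid[mrow, mcol])
    return PeakRecord(
        frame_index=frame_index,
        position_nm=(ref_col * px, ref_row * px),
        arc_nm=float("nan"),
        height_nm=height,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# detection along a trace
# ---------------------------------------------------------------------------


def _project_arc(trace: FilamentTrace, idx: int, point_nm: np.ndarray) -> float:
    """Arc coordinate of a point near trace sample ``idx`` (tangent projection)."""
    lo, hi = max(idx - 3, 0), min(idx + 4, len(trace.points))
    local = trace.points[lo:hi]
    j = lo + int(np.argmin(np.linalg.norm(local - point_nm, axis=1)))
    j0, j1 = max(j - 1, 0), min(j + 1, len(trace.points) - 1)
    tangent = trace.points[j1] - trace.points[j0]
    norm = np.linalg.norm(tangent)
    if norm == 0:
        return float(trace.arc_coords[j])
    tangent /= norm
    return float(trace.arc_coords[j] + np.dot(point_nm - trace.points[j], tangent))


def detect_peaks_along_trace(
    frame: HeightFrame,
    trace: FilamentTrace,
    min_separation_nm: float = 15.0,
    height_floor_nm: float = 4.0,
    prominence_nm: float = 0.4,
    window_px: int = 5,
    frame_index: int = 0,
    interpolate: bool = True,
    smooth_sigma_px: float = 2.0,
) -> list[PeakRecord]:
    """Crossover peaks along a traced filament, ordered by arc coordinate.

    Candidate maxima are picked on a Gaussian-smoothed copy of the height
    profile (the smoothing suppresses the subunit-scale corrugation and
    pixel noise, leaving the half-helix periodicity), kept if separated
    by at least ``min_separation_nm`` (about half of the shortest
    decorated pitch) and prominent by ``prominence_nm`` over the
    inter-peak dip, then each is refined on the *raw* frame with
    :func:`refine_peak`. Peaks whose refinement window would leave the
    frame keep their profile position unrefined.
    """
    px = frame.pixel_size_nm
    profile = sample_profile(frame, trace)
    smooth = ndimage.gaussian_filter1d(profile, sigma=smooth_sigma_px) if smooth_sigma_px else profile
    distance = max(int(round(min_separation_nm / px)), 1)
    idxs, _ = find_peaks(
        smooth, distance=distance, height=height_floor_nm, prominence=prominence_nm
    )
    records: list[PeakRecord] = []
    for i in idxs:
        approx = trace.points[i]
        try:
            rec = refine_peak(frame, tuple(approx), window_px, interpolate, frame_index)
        except ValueError:
            rec = PeakRecord(
                frame_index, tuple(approx), float("nan"), float(profile[i])
            )
        rec.arc_nm = _project_arc(trace, i, np.asarray(rec.position_nm))
        records.append(rec)
    records.sort(key=lambda rec: rec.arc_nm)
    deduped: list[PeakRecord] = []
    for rec in records:
        if deduped and rec.arc_nm - deduped[-1].arc_nm < px / 2:
            continue
        deduped.append(rec)
    deduped = _recover_gap_peaks(
        frame, trace, smooth, deduped, distance, window_px, interpolate, frame_index,
        height_floor_nm,
    )
    return deduped


def _recover_gap_peaks(
    frame: HeightFrame,
    trace: FilamentTrace,
    smooth: np.ndarray,
    records: list[PeakRecord],
    distance: int,
    window_px: int,
    interpolate: bool,
    frame_index: int,
    height_floor_nm: float,
) -> list[PeakRecord]:
    """Second detection pass inside implausibly long inter-peak gaps.

    A spacing beyond ~1.7x the trace's median pitch almost always means a
    low-drawn peak slipped under the prominence cut; the gap interior is
    re-searched for a genuine local maximum (mirroring the manual click
    the semi-automatic procedure allows for ambiguous peaks).
    """
    if len(records) < 4:
        return records
    arcs = np.array([r.arc_nm for r in records])
    med = float(np.median(np.diff(arcs)))
    trigger = max(1.7 * med, 40.0)
    added: list[PeakRecord] = []
    margin = max(distance // 2, 2)
    for a, b in zip(records, records[1:]):
        if b.arc_nm - a.arc_nm <= trigger:
            continue
        ia = int(np.searchsorted(trace.arc_coords, a.arc_nm)) + margin
        ib = int(np.searchsorted(trace.arc_coords, b.arc_nm)) - margin
        if ib - ia < 3:
            continue
        seg = smooth[ia:ib]
        cands, _ = find_peaks(seg)  # any interior local maximum
        if len(cands) == 0:
            continue
        j = ia + int(cands[np.argmax(seg[cands])])
        if smooth[j] < height_floor_nm:
            continue
        try:
            rec = refine_peak(frame, tuple(trace.points[j]), window_px, interpolate, frame_index)
        except ValueError:
            continue
        rec.arc_nm = _project_arc(trace, j, np.asarray(rec.position_nm))
        if a.arc_nm + 2 < rec.arc_nm < b.arc_nm - 2:
            added.append(rec)
    if added:
        records = sorted(records + added, key=lambda r: r.arc_nm)
    return records


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------


def link_peaks(
    per_frame_peaks: Sequence[Sequence[PeakRecord]],
    max_displacement_nm: float = 10.0,
) -> list[PeakTrack]:
    """Greedy nearest-neighbor linking of peaks across consecutive frames.

    For each consecutive frame pair, candidate links are considered in
    order of increasing displacement and accepted one-to-one; any peak
    left without a partner within ``max_displacement_nm`` starts a new
    track (no teleporting assignments).
    """
    tracks: list[PeakTrack] = []
    active: dict[int, PeakTrack] = {}  # index into previous frame -> track

    for f, peaks in enumerate(per_frame_peaks):
        peaks = list(peaks)
        if f == 0 or not active:
            new_active = {}
            for j, rec in enumerate(peaks):
                track = PeakTrack(track_id=len(tracks))
                rec.track_id = track.track_id
                track.records.append(rec)
                tracks.append(track)
                new_active[j] = track
            active = new_active
            continue

        prev_tracks = list(active.values())
        prev_pos = np.array([t.records[-1].position_nm for t in prev_tracks])
        cand = []
        for i, _ in enumerate(prev_tracks):
            for j, rec in enumerate(peaks):
                d = float(np.linalg.norm(prev_pos[i] - np.asarray(rec.position_nm)))
                if d <= max_displacement_nm:
                    cand.append((d, i, j))
        cand.sort()
        used_i: set[int] = set()
        used_j: set[int] = set()
        new_active = {}
        for d, i, j in cand:
            if i in used_i or j in used_j:
                continue
            used_i.add(i)
            used_j.add(j)
            track = prev_tracks[i]
            peaks[j].track_id = track.track_id
            track.records.append(peaks[j])
            new_active[j] = track
        for j, rec in enumerate(peaks):
            if j not in used_j:
                track = PeakTrack(track_id=len(tracks))
                rec.track_id = track.track_id
                track.records.append(rec)
                tracks.append(track)
                new_active[j] = track
        active = new_active
    return tracks
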