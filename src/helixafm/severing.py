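"""Filament severing: break detection and site classification.

Severing sites are classified at half-helix resolution into four
categories relative to cofilin clusters:

- ``far_bare``      — bare half helix not adjacent to any cluster,
- ``neighbor_bare`` — bare half helix immediately neighboring a cluster,
- ``end_cluster``   — decorated half helix at a cluster end (adjacent to a
  bare zone, or at the physical filament end),
- ``inner_cluster`` — decorated half helix in the cluster interior.

The boundary-proximal pool (``neighbor_bare`` + ``end_cluster``) captures
events within one half helix of a cluster/bare-zone boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import STATE_DECORATED

__all__ = [
    "CATEGORIES",
    "SeveringEvent",
    "severing_category",
    "classify_severing",
    "detect_breaks",
    "tally_severing",
    "half_helix_of_arc",
]

CATEGORIES = ("far_bare", "neighbor_bare", "end_cluster", "inner_cluster")


@dataclass
class SeveringEvent:
    """A localized filament break.

    ``frame_index`` is the first frame in which the gap is visible; the
    decoration states used for classification are those of the frame
    before (post-break retraction corrupts them). A decorated half helix
    at the physical filament end is classified ``end_cluster`` (a missing
    neighbor counts like a bare boundary); ``at_filament_end`` flags
    those cases separately.
    """

    frame_index: int
    arc_nm: float
    half_helix_index: Optional[int] = None
    category: Optional[str] = None
    at_filament_end: bool = False
    filament_id: int = 0


def severing_category(states: Sequence[str], index: int) -> str:
    """Category of a break in half helix ``index`` given decoration states.

    ``states`` may use any labels; only equality with ``"decorated"``
    matters (neighbor/bare/paracrystal labels all count as bare).
    """
    n = len(states)
    if not 0 <= index < n:
        raise IndexError("half-helix index out of range")
    dec = [s == STATE_DECORATED for s in states]
    if dec[index]:
        left_boundary = index == 0 or not dec[index - 1]
        right_boundary = index == n - 1 or not dec[index + 1]
        return "end_cluster" if (left_boundary or right_boundary) else "inner_cluster"
    left_dec = index > 0 and dec[index - 1]
    right_dec = index < n - 1 and dec[index + 1]
    return "neighbor_bare" if (left_dec or right_dec) else "far_bare"


def half_helix_of_arc(peak_arcs: Sequence[float], arc_nm: float) -> int:
    """Index of the half helix containing an arc coordinate.

    ``peak_arcs`` are the ordered crossover-peak arcs; interval i spans
    [peak i, peak i+1). A coordinate exactly on an interior peak goes to
    the pointed-side (lower-index) interval; coordinates outside the
    peak range clip to the terminal intervals.
    """
    arcs = np.asarray(peak_arcs, dtype=float)
    if len(arcs) < 2:
        raise ValueError("need at least two peaks to define a half helix")
    idx = int(np.searchsorted(arcs, arc_nm, side="left")) - 1
    return int(np.clip(idx, 0, len(arcs) - 2))


def classify_severing(
    event: SeveringEvent,
    states: Sequence[str],
    peak_arcs: Optional[Sequence[float]] = None,
) -> SeveringEvent:
    """Fill in the half-helix index and category of a break.

    ``states`` are the decoration states at the event frame (the frame
    before the break); ``peak_arcs`` locate the half helices along the
    filament (omit if ``event.half_helix_index`` is already set).
    """
    if event.half_helix_index is None:
        if peak_arcs is None:
            raise ValueError("need peak_arcs to localize the break")
        event.half_helix_index = half_helix_of_arc(peak_arcs, event.arc_nm)
    i = event.half_helix_index
    event.category = severing_category(states, i)
    is_dec = states[i] == STATE_DECORATED
    event.at_filament_end = is_dec and (i == 0 or i == len(states) - 1)
    return event


def detect_breaks(
    movie,
    traces,
    gap_threshold_nm: float = 10.0,
    persistence_frames: int = 2,
    height_floor_nm: float = 4.0,
) -> list[SeveringEvent]:
    """Detect new persistent gaps along previously continuous filaments.

    For every reference trace (typically traced on the first frame, while
    the filament is intact) the height profile is re-sampled along the
    same path in each frame. A break is reported at the first frame where
    an interior run of below-floor samples at least ``gap_threshold_nm``
    long appears and persists for ``persistence_frames`` consecutive
    frames; its arc is the gap midpoint in the reference (pre-break)
    coordinates.

    Parameters
    ----------
    movie : Movie
    traces : FilamentTrace or list of FilamentTrace
        Reference backbones, one per filament, traced before any break.

    Returns
    -------
    list of SeveringEvent with frame and arc filled in (classification is
    a separate step, see :func:`classify_severing`).
    """
    from .peaktrack import FilamentTrace, sample_profile

    if isinstance(traces, FilamentTrace):
        traces = [traces]
    events: list[SeveringEvent] = []
    for fid, trace in enumerate(traces):
        n_frames = len(movie)
        # per frame: list of (start_arc, end_arc) interior gap runs
        runs_by_frame = []
        for frame in movie:
            prof = sample_profile(frame, trace)
            low = prof < height_floor_nm
            runs = []
            start = None
            for j, flag in enumerate(np.concatenate([low, [False]])):
                if flag and start is None:
                    start = j
                elif not flag and start is not None:
                    if start > 0 and j < len(low):  # interior runs only
                        a0, a1 = trace.arc_coords[start], trace.arc_coords[j - 1]
                        if a1 - a0 >= gap_threshold_nm:
                            runs.append((a0, a1))
                    start = None
            runs_by_frame.append(runs)

        reported: list[float] = []
        for f, runs in enumerate(runs_by_frame):
            for a0, a1 in runs:
                mid = 0.5 * (a0 + a1)
                if any(abs(mid - m) < gap_threshold_nm for m in reported):
                    continue
                persist = all(
                    any(r0 <= mid <= r1 for r0, r1 in runs_by_frame[g])
                    for g in range(f, min(f + persistence_frames, n_frames))
                )
                if persist and f + persistence_frames <= n_frames:
                    events.append(SeveringEvent(frame_index=f, arc_nm=mid, filament_id=fid))
                    reported.append(mid)
    return events


def tally_severing(events: Sequence[SeveringEvent]) -> dict:
    """Counts and fractions per category, plus the boundary-proximal pool.

    The boundary-proximal pool (``neighbor_bare`` + ``end_cluster``)
    counts events within one half helix of a bare-zone/cluster boundary.
    """
    if len(events) == 0:
        raise ValueError("no severing events to tally")
    counts = {cat: 0 for cat in CATEGORIES}
    for ev in events:
        if ev.category not in counts:
            raise ValueError(f"event with unknown or missing category: {ev.category!r}")
        counts[ev.category] += 1
    n = len(events)
    fractions = {cat: round(100.0 * c / n) / 100.0 for cat, c in counts.items()}
    boundary = counts["neighbor_bare"] + counts["end_cluster"]
    return {
        "n": n,
        "counts": counts,
        "fractions": fractions,
        "boundary_proximal_count": boundary,
        "boundary_proximal_fraction": round(100.0 * boundary / n) / 100.0,
        "inside_cluster_count": counts["end_cluster"] + counts["inner_cluster"],
        "inside_cluster_fraction": round(
            100.0 * (counts["end_cluster"] + counts["inner_cluster"]) / n
        )
        / 100.0,
    }
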