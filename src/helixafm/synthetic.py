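"""Synthetic HS-AFM movie generator for helical actin filaments.

Ground-truth filament models are built as ordered lists of half helices
(the interval between two consecutive crossover points of the two-start
helix), each carrying a true pitch, a decoration state and a true peak
height. Models are rendered into calibrated height rasters by

1. placing the crossover peaks at their true arc positions plus an
   orientation-dependent offset and per-frame Gaussian localization
   jitter (the measurement error the paracrystal calibration quantifies),
2. sweeping a periodic axial envelope that peaks at each crossover and
   dips to a configurable fraction of the peak height in between,
3. giving the filament a hemi-elliptical cross-section,
4. dilating the surface with a spherical AFM tip (grayscale dilation), and
5. adding i.i.d. per-pixel height noise.

Dynamics (cofilin cluster growth with a pointed-end bias, and
category-dependent severing) are simulated on the model and every true
event is written to a ground-truth log, so each analysis stage can be
validated against exactly known inputs.

Polarity convention: the pointed end of every model is at half-helix
index 0 (lower arc coordinate).
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .config import (
    GeneratorConfig,
    STATE_BARE,
    STATE_DECORATED,
    STATE_P_NEIGHBOR,
    STATE_B_NEIGHBOR,
    STATE_PARACRYSTAL,
)
from .frames import HeightFrame, Movie
from .severing import severing_category

__all__ = [
    "HalfHelixModel",
    "FilamentModel",
    "GroundTruthLog",
    "FilamentTruth",
    "FrameTruth",
    "GrowthEventTruth",
    "SeveringEventTruth",
    "build_filament_model",
    "render_frame",
    "simulate_dynamics",
    "make_paracrystal_field",
    "render_field_movie",
    "make_arc_backbone",
    "PITCH_TRUNCATION_NM",
    "END_TAPER_NM",
    "ARC_MARGIN_NM",
    "BAND_ROWS",
]

#: Pitches are redrawn until above this floor; > 8 sigma below every state
#: mean, so the truncation never distorts the sampled distributions while
#: guarding against nonphysical non-positive pitches.
PITCH_TRUNCATION_NM = 10.0

#: Axial distance over which the envelope rolls off beyond the terminal
#: crossovers (cosine taper to the background).
END_TAPER_NM = 10.0

#: Arc coordinate of the first crossover / margin beyond the last one.
ARC_MARGIN_NM = 18.0

#: Rows of the raster band allotted to one rendered filament.
BAND_ROWS = 25

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclass
class HalfHelixModel:
    """One half helix of the ground-truth model."""

    pitch_true_nm: float
    state: str
    peak_height_true_nm: float


@dataclass
class FilamentModel:
    """Ordered half helices plus backbone geometry.

    The pointed end sits at index 0. ``backbone_points`` is an optional
    dense arc-parameterized polyline (N, 2) in nm; ``None`` renders a
    straight filament along +x.
    """

    half_helices: list[HalfHelixModel]
    polarity: str = "pointed_at_start"
    backbone_points: Optional[np.ndarray] = None
    terminal_height_true_nm: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.half_helices) < 1:
            raise ValueError("a filament needs at least one half helix")
        if any(h.pitch_true_nm <= 0 for h in self.half_helices):
            raise ValueError("pitches must be > 0")

    @property
    def n(self) -> int:
        return len(self.half_helices)

    @property
    def pitches(self) -> np.ndarray:
        return np.array([h.pitch_true_nm for h in self.half_helices])

    @property
    def states(self) -> list[str]:
        return [h.state for h in self.half_helices]

    @property
    def heights(self) -> np.ndarray:
        return np.array([h.peak_height_true_nm for h in self.half_helices])

    @property
    def crossover_arcs_true(self) -> np.ndarray:
        """Arc coordinates of the n+1 true crossover points."""
        return ARC_MARGIN_NM + np.concatenate(([0.0], np.cumsum(self.pitches)))

    @property
    def total_arc_nm(self) -> float:
        return float(2 * ARC_MARGIN_NM + self.pitches.sum())

    def cluster_spans(self) -> list[tuple[int, int]]:
        """Maximal runs of decorated half helices, inclusive index spans."""
        spans = []
        start = None
        for i, st in enumerate(self.states + [STATE_BARE]):
            if st == STATE_DECORATED and start is None:
                start = i
            elif st != STATE_DECORATED and start is not None:
                spans.append((start, i - 1))
                start = None
        return spans

    def rendered_peak_heights(self) -> np.ndarray:
        """Heights of the n+1 rendered crossover peaks.

        Each half helix owns its pointed-side peak (peak k takes the
        height drawn for half helix k), so pooled peak heights reproduce
        the per-state height SDs. A peak whose barbed-side neighbor half
        helix is decorated takes that decorated height instead — the
        boundary crossover belongs to the cluster — and the barbed-most
        peak uses the model's terminal draw.
        """
        st = self.states
        h = self.heights
        n = self.n
        out = np.empty(n + 1)
        for k in range(n + 1):
            if k < n and st[k] == STATE_DECORATED:
                out[k] = h[k]
            elif k > 0 and st[k - 1] == STATE_DECORATED:
                out[k] = h[k - 1]
            elif k < n:
                out[k] = h[k]
            else:
                out[k] = (
                    self.terminal_height_true_nm
                    if self.terminal_height_true_nm is not None
                    else h[n - 1]
                )
        return out


def _draw_pitch(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0.0:
        return mean
    for _ in range(100):
        p = rng.normal(mean, sd)
        if p > PITCH_TRUNCATION_NM:
            return float(p)
    raise RuntimeError("pitch sampling failed; check state parameters")


def _assign_neighbor_states(states: list[str]) -> list[str]:
    """Return states with neighbor labels recomputed next to decorated runs.

    The first non-decorated half helix on the pointed-end side of a run
    becomes ``p_neighbor`` and on the barbed side ``b_neighbor``; a half
    helix squeezed between two runs gets the pointed-side label (the
    supertwist propagates toward the pointed end). Former neighbors no
    longer adjacent to a run revert to bare. Paracrystal labels are left
    untouched.
    """
    n = len(states)
    out = []
    for i, st in enumerate(states):
        if st in (STATE_DECORATED, STATE_PARACRYSTAL):
            out.append(st)
            continue
        barbed_of_run = i > 0 and states[i - 1] == STATE_DECORATED
        pointed_of_run = i < n - 1 and states[i + 1] == STATE_DECORATED
        if pointed_of_run:
            out.append(STATE_P_NEIGHBOR)
        elif barbed_of_run:
            out.append(STATE_B_NEIGHBOR)
        else:
            out.append(STATE_BARE)
    return out


def make_arc_backbone(length_nm: float, radius_nm: float, step_nm: float = 0.75) -> np.ndarray:
    """Circular-arc polyline of a given arc length and curvature radius."""
    if radius_nm <= 0 or length_nm <= 0:
        raise ValueError("length and radius must be > 0")
    s = np.arange(0.0, length_nm + step_nm, step_nm)
    theta = s / radius_nm
    x = radius_nm * np.sin(theta)
    y = radius_nm * (1.0 - np.cos(theta))
    return np.column_stack([x, y])


def build_filament_model(
    config: GeneratorConfig,
    n_half_helices: int,
    cluster_spec: Sequence[tuple[int, int]] = (),
    rng: Optional[np.random.Generator] = None,
    base_state: str = STATE_BARE,
    backbone_points: Optional[np.ndarray] = None,
) -> FilamentModel:
    """Sample a ground-truth filament model.

    Parameters
    ----------
    n_half_helices : int
        Number of half helices (>= 1).
    cluster_spec : sequence of (first, last)
        Inclusive index intervals to decorate with cofilin. Must lie in
        range and not overlap. Neighbor states are assigned automatically
        on either side of each decorated run.
    base_state : str
        State of undecorated half helices (``"bare"`` or
        ``"paracrystal"`` for the calibration preset).

    True pitches are drawn independently per half helix from the state's
    (mean, structural SD) normal truncated at > 10 nm; true peak heights
    from the state's height normal. Measurement error is *not* added
    here — it enters at render time as localization jitter.
    """
    if n_half_helices < 1:
        raise ValueError("n_half_helices must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    spans = sorted(tuple(s) for s in cluster_spec)
    for a, b in spans:
        if not (0 <= a <= b <= n_half_helices - 1):
            raise ValueError(f"cluster interval ({a}, {b}) out of range")
    for (_, b0), (a1, _) in zip(spans, spans[1:]):
        if a1 <= b0:
            raise ValueError("cluster intervals must not overlap")

    states = [base_state] * n_half_helices
    for a, b in spans:
        for i in range(a, b + 1):
            states[i] = STATE_DECORATED
    states = _assign_neighbor_states(states)

    helices = []
    for st in states:
        sp = config.states[st]
        pitch = _draw_pitch(rng, sp.pitch_mean_nm, sp.pitch_sd_struct_nm)
        height = float(rng.normal(sp.peak_height_mean_nm, sp.peak_height_sd_nm))
        height = max(height, 1.0)
        helices.append(HalfHelixModel(pitch, st, height))
    sp_last = config.states[states[-1]]
    terminal = max(
        float(rng.normal(sp_last.peak_height_mean_nm, sp_last.peak_height_sd_nm)), 1.0
    )
    return FilamentModel(helices, backbone_points=backbone_points, terminal_height_true_nm=terminal)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _peak_offsets(n_peaks: int, config: GeneratorConfig) -> np.ndarray:
    """Deterministic orientation-dependent axial offsets, one per peak.

    Offsets are spread uniformly over [-range, +range] by a golden-ratio
    phase sequence seeded by the filament azimuth, emulating the
    registration mismatch between the apparent peak (the highest subunit)
    and the true crossover point.
    """
    if config.offset_range_nm == 0.0:
        return np.zeros(n_peaks)
    phase0 = config.orientation_phase_deg / 360.0
    frac = np.mod(phase0 + _GOLDEN * np.arange(n_peaks), 1.0)
    return config.offset_range_nm * (2.0 * frac - 1.0)


def observed_crossover_arcs(
    model: FilamentModel, config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """True crossover arcs plus orientation offset plus per-peak jitter."""
    arcs = model.crossover_arcs_true + _peak_offsets(model.n + 1, config)
    if config.localization_jitter_nm > 0:
        arcs = arcs + rng.normal(0.0, config.localization_jitter_nm, model.n + 1)
    # jitter is ~10x smaller than any pitch; enforce ordering defensively
    return np.maximum.accumulate(arcs)


def _axial_envelope(
    s: np.ndarray,
    obs_arcs: np.ndarray,
    peak_heights: np.ndarray,
    floor: float,
    break_arcs: Sequence[float] = (),
    ripple_nm: float = 0.0,
    ripple_period_nm: float = 5.5,
) -> np.ndarray:
    """Height of the backbone ridge line as a function of arc coordinate."""
    o = obs_arcs
    h = peak_heights
    env = np.zeros_like(s, dtype=float)

    inside = (s >= o[0]) & (s <= o[-1])
    if np.any(inside):
        si = s[inside]
        k = np.clip(np.searchsorted(o, si, side="right") - 1, 0, len(o) - 2)
        u = (si - o[k]) / (o[k + 1] - o[k])
        f = floor + (1.0 - floor) * 0.5 * (1.0 + np.cos(2.0 * np.pi * u))
        # smoothstep height blend: zero slope at the nodes keeps the
        # rendered apex exactly on the (jittered) crossover arc even when
        # neighboring peaks differ in height
        blend = u * u * (3.0 - 2.0 * u)
        env[inside] = f * ((1.0 - blend) * h[k] + blend * h[k + 1])

    left = (s < o[0]) & (s > o[0] - END_TAPER_NM)
    env[left] = h[0] * np.cos(np.pi * (o[0] - s[left]) / (2.0 * END_TAPER_NM)) ** 2
    right = (s > o[-1]) & (s < o[-1] + END_TAPER_NM)
    env[right] = h[-1] * np.cos(np.pi * (s[right] - o[-1]) / (2.0 * END_TAPER_NM)) ** 2

    if ripple_nm > 0:
        # subunit corrugation, phase-anchored at the nearest crossover so
        # every apex keeps its exact height and position
        d_nearest = np.min(np.abs(s[:, None] - o[None, :]), axis=1)
        dip = 0.5 * ripple_nm * (1.0 - np.cos(2.0 * np.pi * d_nearest / ripple_period_nm))
        env = np.clip(env - dip, 0.0, None)

    for b in break_arcs:
        gap = np.abs(s - b)
        env[gap < 7.5] = 0.0
        ramp = (gap >= 7.5) & (gap < 11.5)
        env[ramp] *= np.sin(np.pi * (gap[ramp] - 7.5) / (2.0 * 4.0)) ** 2
    return env


def _cross_section(env_row: np.ndarray, d_nm: np.ndarray) -> np.ndarray:
    """Hemi-elliptical cross-section: height env, half-width env/2."""
    half_w = np.maximum(env_row[None, :] * 0.5, 1e-9)
    ratio = d_nm[:, None] / half_w
    return env_row[None, :] * np.sqrt(np.clip(1.0 - ratio**2, 0.0, None))


def _tip_structure(tip_radius_nm: float, pixel_size_nm: float) -> np.ndarray:
    r = tip_radius_nm
    R = int(np.ceil(r / pixel_size_nm))
    yy, xx = np.mgrid[-R : R + 1, -R : R + 1]
    rho2 = (yy**2 + xx**2) * pixel_size_nm**2
    ball = np.sqrt(np.clip(r**2 - rho2, 0.0, None)) - r
    ball[rho2 > r**2] = -1e9  # outside the tip footprint: never selected
    return ball


def dilate_with_tip(grid: np.ndarray, tip_radius_nm: float, pixel_size_nm: float) -> np.ndarray:
    """Grayscale dilation of a height map by a spherical tip."""
    if tip_radius_nm <= 0:
        return grid
    return ndimage.grey_dilation(grid, structure=_tip_structure(tip_radius_nm, pixel_size_nm))


def _render_band(
    model: FilamentModel,
    config: GeneratorConfig,
    obs_arcs: np.ndarray,
    rng: Optional[np.random.Generator],
    break_arcs: Sequence[float] = (),
    n_cols: Optional[int] = None,
    n_rows: int = BAND_ROWS,
) -> np.ndarray:
    """Render one filament into its raster band (no noise if rng is None)."""
    px = config.pixel_size_nm
    heights = model.rendered_peak_heights()
    if n_cols is None:
        n_cols = int(math.ceil(model.total_arc_nm / px)) + 1

    if model.backbone_points is None:
        cy = (n_rows // 2) * px
        s = np.arange(n_cols) * px
        d = np.arange(n_rows) * px - cy
        env = _axial_envelope(
            s, obs_arcs, heights, config.envelope_floor, break_arcs,
            config.subunit_ripple_nm, config.subunit_spacing_nm,
        )
        grid = _cross_section(env, d)
    else:
        bb = np.asarray(model.backbone_points, dtype=float)
        seg = np.linalg.norm(np.diff(bb, axis=0), axis=1)
        arcs_bb = np.concatenate(([0.0], np.cumsum(seg)))
        if arcs_bb[-1] < model.total_arc_nm - 1e-6:
            raise ValueError("backbone polyline shorter than the filament")
        from scipy.spatial import cKDTree

        pad = ARC_MARGIN_NM
        x0, y0 = bb.min(axis=0) - pad
        bb_shift = bb - [x0, y0]
        x1, y1 = bb_shift.max(axis=0) + pad
        n_cols = int(math.ceil(x1 / px)) + 1
        n_rows = int(math.ceil(y1 / px)) + 1
        tree = cKDTree(bb_shift)
        yy, xx = np.mgrid[0:n_rows, 0:n_cols]
        pts = np.column_stack([xx.ravel() * px, yy.ravel() * px])
        dist, idx = tree.query(pts, workers=-1)
        env = _axial_envelope(
            arcs_bb[idx], obs_arcs, heights, config.envelope_floor, break_arcs,
            config.subunit_ripple_nm, config.subunit_spacing_nm,
        )
        half_w = np.maximum(env * 0.5, 1e-9)
        z = env * np.sqrt(np.clip(1.0 - (dist / half_w) ** 2, 0.0, None))
        grid = z.reshape(n_rows, n_cols)

    grid = dilate_with_tip(grid, config.tip_radius_nm, px)
    if rng is not None and config.noise_sd_nm > 0:
        grid = grid + rng.normal(0.0, config.noise_sd_nm, grid.shape)
    return grid


def render_frame(
    model: FilamentModel,
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
    t_s: float = 0.0,
    break_arcs: Sequence[float] = (),
) -> HeightFrame:
    """Render a single filament model into a height frame.

    Deterministic given (model, config, seed): when ``rng`` is omitted it
    is seeded from ``config.seed``. The raster is sized to the model with
    an 18 nm margin on every side.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    obs = observed_crossover_arcs(model, config, rng)
    grid = _render_band(model, config, obs, rng, break_arcs)
    return HeightFrame(grid, config.pixel_size_nm, t_s)


# ---------------------------------------------------------------------------
# ground truth log
# ---------------------------------------------------------------------------


@dataclass
class GrowthEventTruth:
    frame_index: int
    cluster_id: int
    direction: str  # "pointed" | "barbed"
    half_helix_index: int


@dataclass
class SeveringEventTruth:
    frame_index: int
    half_helix_index: int
    arc_nm: float
    category: str


@dataclass
class FrameTruth:
    states: list[str]
    crossover_arcs_true: list[float]
    crossover_arcs_observed: list[float]
    peak_heights: list[float]
    cluster_spans: list[tuple[int, int]]
    break_arcs: list[float]


@dataclass
class FilamentTruth:
    polarity: str
    y_offset_nm: float
    frames: list[FrameTruth] = field(default_factory=list)
    growth_events: list[GrowthEventTruth] = field(default_factory=list)
    severing_events: list[SeveringEventTruth] = field(default_factory=list)


@dataclass
class GroundTruthLog:
    """Everything the generator knows, for validating the analysis."""

    pixel_size_nm: float
    frame_interval_s: float
    filaments: list[FilamentTruth] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @property
    def growth_events(self) -> list[GrowthEventTruth]:
        return [ev for fil in self.filaments for ev in fil.growth_events]

    @property
    def severing_events(self) -> list[SeveringEventTruth]:
        return [ev for fil in self.filaments for ev in fil.severing_events]


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def _frame_truth(model: FilamentModel, obs: np.ndarray, breaks: Sequence[float]) -> FrameTruth:
    return FrameTruth(
        states=list(model.states),
        crossover_arcs_true=[float(v) for v in model.crossover_arcs_true],
        crossover_arcs_observed=[float(v) for v in obs],
        peak_heights=[float(v) for v in model.rendered_peak_heights()],
        cluster_spans=model.cluster_spans(),
        break_arcs=[float(b) for b in breaks],
    )


def _redraw(helix: HalfHelixModel, new_state: str, config: GeneratorConfig, rng) -> None:
    sp = config.states[new_state]
    helix.state = new_state
    helix.pitch_true_nm = _draw_pitch(rng, sp.pitch_mean_nm, sp.pitch_sd_struct_nm)
    helix.peak_height_true_nm = max(float(rng.normal(sp.peak_height_mean_nm, sp.peak_height_sd_nm)), 1.0)


def _refresh_neighbors(model: FilamentModel, config: GeneratorConfig, rng) -> None:
    new_states = _assign_neighbor_states(model.states)
    for helix, st in zip(model.half_helices, new_states):
        if helix.state != st:
            _redraw(helix, st, config, rng)


def simulate_dynamics(
    model: FilamentModel,
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[Movie, GroundTruthLog]:
    """Simulate cluster growth and severing on a model and render the movie.

    Per frame, each cofilin cluster gains one half helix with probability
    ``growth_rate_per_s * frame_interval_s``, extending toward the pointed
    end with probability ``growth_bias_pointed`` (else barbed). A growth
    step whose target half helix does not exist (filament end) or is
    already decorated is dropped, not redirected, so the logged direction
    fractions stay at the configured bias. Newly decorated half helices
    redraw pitch and height from the decorated distributions, and the
    neighbor states are re-assigned around every run.

    Severing is drawn per half helix per frame with the category-dependent
    rates (the category evaluated on the true states); a break removes
    ~15 nm of filament around a point inside that half helix in all later
    frames.

    Returns the rendered movie plus a ground-truth log recording every
    growth event (direction, frame) and severing event (half-helix index,
    category), along with the per-frame states and crossover positions.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    model = copy.deepcopy(model)
    dt = config.frame_interval_s
    p_grow = config.growth_rate_per_s * dt

    spans = model.cluster_spans()
    breaks: list[float] = []
    truth = FilamentTruth(polarity=model.polarity, y_offset_nm=0.0)
    grids = []

    for f in range(config.n_frames):
        if f > 0:
            # growth, one attempt per cluster per frame
            for cid, (a, b) in enumerate(list(spans)):
                if p_grow > 0 and rng.random() < p_grow:
                    pointed = rng.random() < config.growth_bias_pointed
                    target = a - 1 if pointed else b + 1
                    if 0 <= target < model.n and model.states[target] != STATE_DECORATED:
                        _redraw(model.half_helices[target], STATE_DECORATED, config, rng)
                        spans[cid] = (min(a, target), max(b, target))
                        truth.growth_events.append(
                            GrowthEventTruth(
                                frame_index=f,
                                cluster_id=cid,
                                direction="pointed" if pointed else "barbed",
                                half_helix_index=target,
                            )
                        )
            _refresh_neighbors(model, config, rng)
            # severing
            if any(r > 0 for r in config.severing_rates.values()):
                states = model.states
                arcs = model.crossover_arcs_true
                for i in range(model.n):
                    cat = severing_category(states, i)
                    if rng.random() < config.severing_rates[cat] * dt:
                        width = arcs[i + 1] - arcs[i]
                        arc = float(rng.uniform(arcs[i] + 0.3 * width, arcs[i] + 0.7 * width))
                        truth.severing_events.append(
                            SeveringEventTruth(f, i, arc, cat)
                        )
                        breaks.append(arc)
        obs = observed_crossover_arcs(model, config, rng)
        truth.frames.append(_frame_truth(model, obs, breaks))
        grids.append(_render_band(model, config, obs, rng, breaks))

    n_cols = max(g.shape[1] for g in grids)
    grids = [np.pad(g, ((0, 0), (0, n_cols - g.shape[1]))) for g in grids]
    movie = Movie.from_arrays(grids, config.pixel_size_nm, dt)
    log = GroundTruthLog(
        pixel_size_nm=config.pixel_size_nm,
        frame_interval_s=dt,
        filaments=[truth],
        config=config.to_dict(),
    )
    return movie, log


# ---------------------------------------------------------------------------
# multi-filament fields
# ---------------------------------------------------------------------------


def render_field_movie(
    models: Sequence[FilamentModel],
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[Movie, GroundTruthLog]:
    """Render several static filaments stacked into one movie.

    Each filament occupies its own horizontal band (band pitch
    ``BAND_ROWS`` rows); localization jitter and pixel noise are redrawn
    every frame, so repeated frames give independent pitch measurements
    of the same underlying structures.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    px = config.pixel_size_nm
    n_cols = max(int(math.ceil(m.total_arc_nm / px)) + 1 for m in models)
    truths = [
        FilamentTruth(polarity=m.polarity, y_offset_nm=i * BAND_ROWS * px)
        for i, m in enumerate(models)
    ]
    grids = []
    for f in range(config.n_frames):
        bands = []
        for m, tr in zip(models, truths):
            obs = observed_crossover_arcs(m, config, rng)
            tr.frames.append(_frame_truth(m, obs, ()))
            bands.append(_render_band(m, config, obs, rng, n_cols=n_cols))
        grids.append(np.vstack(bands))
    movie = Movie.from_arrays(grids, px, config.frame_interval_s)
    log = GroundTruthLog(px, config.frame_interval_s, truths, config.to_dict())
    return movie, log


def make_paracrystal_field(
    config: GeneratorConfig,
    n_filaments: int,
    n_half_helices: int = 20,
    rng: Optional[np.random.Generator] = None,
) -> tuple[Movie, GroundTruthLog]:
    """Parallel calibration filaments with zero structural pitch variation.

    Every half helix uses the ``paracrystal`` state (pitch exactly its
    36.5 nm mean); all apparent pitch variance in the rendered movie comes
    from localization jitter, tip convolution and pixel noise, which is
    what makes the field a measurement-error standard.
    """
    if n_filaments < 1:
        raise ValueError("n_filaments must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    models = [
        build_filament_model(
            config, n_half_helices, cluster_spec=(), rng=rng, base_state=STATE_PARACRYSTAL
        )
        for _ in range(n_filaments)
    ]
    return render_field_movie(models, config, rng)
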