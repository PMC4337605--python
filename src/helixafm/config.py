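"""Generator configuration.

The defaults encode the published statistics of actin filaments imaged by
HS-AFM on a supported lipid bilayer: bare filaments with crossover peaks of
8.6 +/- 0.8 nm and half-helical pitch 36.8 nm (structural SD 3.1 nm after
removing the 3.0 nm measurement error calibrated on paracrystals), fully
cofilin-decorated segments ~2 nm taller with a 27% shorter pitch
(26.9 nm, structural SD 2.3 nm), and the asymmetric bare neighbors of a
cofilin cluster: supertwisted on the pointed-end side (28.8 nm), slightly
overtwisted on the barbed-end side (37.3 nm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

__all__ = [
    "StateParams",
    "GeneratorConfig",
    "STATE_BARE",
    "STATE_DECORATED",
    "STATE_P_NEIGHBOR",
    "STATE_B_NEIGHBOR",
    "STATE_PARACRYSTAL",
    "default_states",
]

STATE_BARE = "bare"
STATE_DECORATED = "decorated"
STATE_P_NEIGHBOR = "p_neighbor"
STATE_B_NEIGHBOR = "b_neighbor"
STATE_PARACRYSTAL = "paracrystal"

#: Categories a severing site can fall into (shared with :mod:`helixafm.severing`).
SEVERING_CATEGORIES = ("far_bare", "neighbor_bare", "end_cluster", "inner_cluster")


@dataclass
class StateParams:
    """Per-decoration-state half-helix statistics.

    ``pitch_sd_struct_nm`` is the *structural* SD: what remains of the
    observed pitch SD after subtracting the measurement error in
    quadrature. The generator samples true pitches from this, and
    measurement error is added only at render time (peak localization
    jitter), so the generate->render->measure loop reproduces the observed
    SD by quadrature composition.
    """

    pitch_mean_nm: float
    pitch_sd_struct_nm: float
    peak_height_mean_nm: float
    peak_height_sd_nm: float


def default_states() -> dict[str, StateParams]:
    # Neighbor structural SDs are quadrature residuals of the observed
    # 4.5 / 4.6 nm SDs against the 3.0 nm error calibration.
    return {
        STATE_BARE: StateParams(36.8, 3.1, 8.6, 0.8),
        STATE_DECORATED: StateParams(26.9, 2.3, 10.6, 1.0),
        STATE_P_NEIGHBOR: StateParams(28.8, 3.4, 9.2, 1.0),
        STATE_B_NEIGHBOR: StateParams(37.3, 3.5, 9.0, 0.9),
        STATE_PARACRYSTAL: StateParams(36.5, 0.0, 8.6, 0.8),
    }


def _default_severing_rates() -> dict[str, float]:
    return {cat: 0.0 for cat in SEVERING_CATEGORIES}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic AFM movie generator.

    Attributes
    ----------
    pixel_size_nm : float
        Square pixel edge, nm (default 1.5 so that a 5x5 analysis window
        spans 7.5 x 7.5 nm^2).
    frame_interval_s : float
        Time between frames (default 0.5 s, i.e. 2 frames/s imaging).
    n_frames : int
        Frames to simulate.
    states : dict[str, StateParams]
        Per-state pitch/height distributions, see :func:`default_states`.
    localization_jitter_nm : float
        Per-peak, per-frame axial localization error SD sigma_p. The
        default 3.0/sqrt(2) makes the pitch-level error (difference of two
        independent jitters) match the 3.0 nm paracrystal calibration.
    offset_range_nm, orientation_phase_deg : float
        Optional deterministic axial peak offset emulating the
        orientation-dependent mismatch between the apparent peak and the
        true crossover (up to +/-2.5 nm depending on filament azimuth).
        Disabled by default (range 0); when enabled, per-peak offsets are
        spread uniformly over ``[-range, +range]`` with the phase setting
        the sequence origin.
    tip_radius_nm : float
        Spherical tip radius for grayscale dilation (0 disables).
    noise_sd_nm : float
        i.i.d. per-pixel height noise SD added after tip dilation.
    envelope_floor : float
        Inter-peak minimum of the axial height envelope as a fraction of
        the local peak height.
    subunit_ripple_nm, subunit_spacing_nm : float
        Amplitude and period of the axial corrugation from individual
        actin subunits (~5.5 nm monomer spacing along one strand),
        phase-anchored at each crossover. The corrugation is what makes
        the apparent peak sharp enough for pixel-level localization.
    growth_bias_pointed : float
        Probability beta that a cluster growth step extends toward the
        pointed end (default 0.8, the published preference).
    growth_rate_per_s : float
        Per-cluster probability rate of gaining one half helix.
    severing_rates : dict[str, float]
        Per-category severing rate (per eligible half helix per second).
    seed : int
        Base seed; rendering and simulation are deterministic given
        (model, config, seed).
    """

    pixel_size_nm: float = 1.5
    frame_interval_s: float = 0.5
    n_frames: int = 1
    states: dict[str, StateParams] = field(default_factory=default_states)
    localization_jitter_nm: float = 3.0 / math.sqrt(2.0)
    offset_range_nm: float = 0.0
    orientation_phase_deg: float = 0.0
    tip_radius_nm: float = 2.0
    noise_sd_nm: float = 0.15
    envelope_floor: float = 0.75
    subunit_ripple_nm: float = 0.4
    subunit_spacing_nm: float = 5.5
    growth_bias_pointed: float = 0.8
    growth_rate_per_s: float = 0.05
    severing_rates: dict[str, float] = field(default_factory=_default_severing_rates)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0.0 <= self.growth_bias_pointed <= 1.0:
            raise ValueError("growth_bias_pointed must lie in [0, 1]")
        if self.localization_jitter_nm < 0 or self.offset_range_nm < 0:
            raise ValueError("jitter and offset range must be >= 0")
        if self.tip_radius_nm < 0 or self.noise_sd_nm < 0:
            raise ValueError("tip radius and noise SD must be >= 0")
        if not 0.0 < self.envelope_floor <= 1.0:
            raise ValueError("envelope_floor must lie in (0, 1]")
        if self.subunit_ripple_nm < 0 or self.subunit_spacing_nm <= 0:
            raise ValueError("subunit ripple must be >= 0 and spacing > 0")
        if self.growth_rate_per_s < 0:
            raise ValueError("growth_rate_per_s must be >= 0")
        for name, sp in self.states.items():
            if sp.pitch_mean_nm <= 0 or sp.peak_height_mean_nm <= 0:
                raise ValueError(f"state {name!r}: means must be > 0")
            if sp.pitch_sd_struct_nm < 0 or sp.peak_height_sd_nm < 0:
                raise ValueError(f"state {name!r}: SDs must be >= 0")
        for cat, rate in self.severing_rates.items():
            if cat not in SEVERING_CATEGORIES:
                raise ValueError(f"unknown severing category {cat!r}")
            if rate < 0:
                raise ValueError("severing rates must be >= 0")

    @classmethod
    def paracrystal_preset(cls, **overrides) -> "GeneratorConfig":
        """Calibration-field preset: zero structural pitch variation.

        All apparent pitch variance then comes from localization jitter
        (and pixelation), mirroring the role of actin paracrystals as the
        measurement-error standard.
        """
        cfg = cls(**overrides)
        sp = cfg.states[STATE_PARACRYSTAL]
        if sp.pitch_sd_struct_nm != 0.0:
            raise ValueError("paracrystal preset requires pitch_sd_struct_nm == 0")
        return cfg

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["states"] = {k: asdict(v) for k, v in self.states.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "states" in d:
            d["states"] = {k: StateParams(**v) for k, v in d["states"].items()}
        return cls(**d)
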