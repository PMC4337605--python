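"""File formats: TIFF movies, JSON ground truth, YAML configs, CSV tables.

Heights are stored as 32-bit float nanometres in multi-page TIFF, with
the calibration (pixel size, frame interval) embedded as JSON in the
image description and mirrored in an optional sidecar. Calibration is
never guessed: reading a movie without a pixel size is an error.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .config import GeneratorConfig
from .frames import HeightFrame, Movie
from .synthetic import (
    FilamentTruth,
    FrameTruth,
    GroundTruthLog,
    GrowthEventTruth,
    SeveringEventTruth,
)

__all__ = [
    "write_movie",
    "read_movie",
    "write_ground_truth",
    "read_ground_truth",
    "load_config",
    "save_config",
    "config_hash",
    "write_table",
    "read_table",
]


def write_movie(movie: Movie, path) -> None:
    """Write a movie as multi-page 32-bit float TIFF (heights in nm).

    Pixel size and frame timestamps are embedded as JSON in the TIFF
    image description, so the file round-trips without a sidecar.
    """
    path = Path(path)
    stack = np.stack([f.grid for f in movie]).astype(np.float32)
    meta = {
        "pixel_size_nm": movie.pixel_size_nm,
        "timestamps_s": [f.t_s for f in movie],
        "units": "nm",
    }
    tifffile.imwrite(path, stack, description=json.dumps(meta))


def _meta_from_description(desc: Optional[str]) -> dict:
    if not desc:
        return {}
    try:
        meta = json.loads(desc)
        return meta if isinstance(meta, dict) else {}
    except (json.JSONDecodeError, TypeError):
        return {}


def read_movie(
    path,
    pixel_size_nm: Optional[float] = None,
    frame_interval_s: Optional[float] = None,
) -> Movie:
    """Read a movie from multi-page TIFF or a directory of TIFFs.

    Calibration resolution order: explicit arguments, then embedded
    description JSON, then a ``metadata.json`` next to the file (or in
    the directory). A missing pixel size raises — it is never guessed.
    """
    path = Path(path)
    if path.is_dir():
        tiffs = sorted(path.glob("*.tif")) + sorted(path.glob("*.tiff"))
        if not tiffs:
            raise ValueError(f"no TIFF files in {path}")
        grids = [tifffile.imread(p).astype(float) for p in tiffs]
        grids = [g[0] if g.ndim == 3 else g for g in grids]
        meta = {}
        sidecar = path / "metadata.json"
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
    else:
        with tifffile.TiffFile(path) as tf:
            stack = tf.asarray().astype(float)
            meta = _meta_from_description(tf.pages[0].description)
        grids = [stack] if stack.ndim == 2 else list(stack)
        sidecar = path.with_suffix(".json")
        if not meta and sidecar.exists():
            meta = json.loads(sidecar.read_text())

    px = pixel_size_nm if pixel_size_nm is not None else meta.get("pixel_size_nm")
    if px is None:
        raise ValueError(
            "pixel size not found: pass pixel_size_nm or provide metadata "
            "(embedded description or metadata.json)"
        )
    times = meta.get("timestamps_s")
    if times is None or len(times) != len(grids):
        dt = frame_interval_s if frame_interval_s is not None else meta.get(
            "frame_interval_s", 0.5
        )
        times = [i * dt for i in range(len(grids))]
    frames = [HeightFrame(g, float(px), float(t)) for g, t in zip(grids, times)]
    return Movie(frames)


# ---------------------------------------------------------------------------
# ground truth and config
# ---------------------------------------------------------------------------


def write_ground_truth(log: GroundTruthLog, path) -> None:
    log.to_json(path)


def read_ground_truth(path) -> GroundTruthLog:
    with open(path) as fh:
        d = json.load(fh)
    filaments = []
    for fd in d.get("filaments", []):
        filaments.append(
            FilamentTruth(
                polarity=fd["polarity"],
                y_offset_nm=fd["y_offset_nm"],
                frames=[
                    FrameTruth(
                        states=fr["states"],
                        crossover_arcs_true=fr["crossover_arcs_true"],
                        crossover_arcs_observed=fr["crossover_arcs_observed"],
                        peak_heights=fr["peak_heights"],
                        cluster_spans=[tuple(s) for s in fr["cluster_spans"]],
                        break_arcs=fr["break_arcs"],
                    )
                    for fr in fd["frames"]
                ],
                growth_events=[GrowthEventTruth(**ev) for ev in fd["growth_events"]],
                severing_events=[SeveringEventTruth(**ev) for ev in fd["severing_events"]],
            )
        )
    return GroundTruthLog(
        pixel_size_nm=d["pixel_size_nm"],
        frame_interval_s=d["frame_interval_s"],
        filaments=filaments,
        config=d.get("config", {}),
    )


def save_config(config: GeneratorConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def load_config(path) -> GeneratorConfig:
    with open(path) as fh:
        return GeneratorConfig.from_dict(yaml.safe_load(fh))


def config_hash(config: GeneratorConfig) -> str:
    """Short stable hash of a configuration (for output provenance stamps)."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# stamped CSV tables
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path, stamp: Optional[dict] = None) -> None:
    """CSV with a leading ``#`` provenance comment (config hash, seed)."""
    path = Path(path)
    with open(path, "w") as fh:
        if stamp:
            fh.write("# " + json.dumps(stamp, sort_keys=True) + "\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
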