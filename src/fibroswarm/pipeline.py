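"""Reproducible multi-stage runs with provenance records.

A run config (YAML or dict) selects stages and carries one parameter
block per stage, mirroring the config dataclasses of the underlying
modules.  Stages execute in dependency order::

    simulate -> render -> piv
    simulate -> kinematics | similarity | landmarks

Every artefact is written with a JSON provenance sidecar (tool version,
config hash, input hashes, seed, timestamp); identical config and seed
produce byte-identical CSV artefacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import PlanError
from .io import write_image_stack, write_tracks
from .piv import PIVConfig, field_summary, run_piv
from .synth import RenderConfig, SwarmConfig, render_movie, simulate_tracks
from .tracks import landmark_displacement, movement_similarity, step_kinematics

logger = logging.getLogger(__name__)

STAGES = ("simulate", "render", "piv", "kinematics", "similarity", "landmarks")
_DEPS = {
    "render": "simulate",
    "piv": "render",
    "kinematics": "simulate",
    "similarity": "simulate",
    "landmarks": "simulate",
}


def config_hash(config: dict) -> str:
    """Stable hash of a config dict (invariant under key reordering)."""
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def file_hash(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@dataclass
class ProvenanceRecord:
    """What produced an artefact: version, config hash, inputs, seed, time."""

    tool_version: str
    config_hash: str
    input_hashes: dict
    seed: int
    timestamp: str

    def write(self, artefact_path: Path) -> Path:
        side = Path(str(artefact_path) + ".provenance.json")
        side.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return side


@dataclass
class RunConfig:
    """Parsed run configuration: stages, per-stage blocks, paths, seed."""

    stages: list
    out_dir: Path
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)
    render: dict = field(default_factory=dict)
    piv: dict = field(default_factory=dict)
    kinematics: dict = field(default_factory=dict)
    similarity: dict = field(default_factory=dict)
    landmarks: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)} - {"raw"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        unknown = set(raw) - known
        if unknown:
            raise PlanError(f"unknown config keys: {sorted(unknown)}")
        if "stages" not in kwargs or not kwargs["stages"]:
            raise PlanError("config must select at least one stage")
        bad = [s for s in kwargs["stages"] if s not in STAGES]
        if bad:
            raise PlanError(f"unknown stages {bad}; available: {STAGES}")
        kwargs["out_dir"] = Path(kwargs.get("out_dir", "fibroswarm_out"))
        return cls(raw=raw, **kwargs)


def _plan(stages: list) -> list:
    """Validate dependencies and return stages in execution order."""
    selected = set(stages)
    for s in selected:
        dep = _DEPS.get(s)
        if dep and dep not in selected:
            raise PlanError(f"stage {s!r} requires stage {dep!r} in the same run")
    return [s for s in STAGES if s in selected]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages and write artefacts with provenance.

    Returns a dict mapping stage name to its primary in-memory result
    (track table, ImageStack, VectorField / summary, tables).
    """
    order = _plan(config.stages)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config.raw)
    logger.info("run %s: stages=%s seed=%d", chash, order, config.seed)
    results: dict = {}
    artefacts: dict = {}

    def provenance() -> ProvenanceRecord:
        return ProvenanceRecord(
            tool_version=__version__,
            config_hash=chash,
            input_hashes={k: file_hash(v) for k, v in artefacts.items()},
            seed=config.seed,
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )

    for stage in order:
        t0 = time.perf_counter()
        if stage == "simulate":
            cfg = SwarmConfig(**{"seed": config.seed, **config.simulate})
            tracks = simulate_tracks(cfg)
            path = out / "tracks.csv"
            write_tracks(tracks, path)
            provenance().write(path)
            artefacts["tracks"] = path
            results["simulate"] = tracks
        elif stage == "render":
            rc = dict(config.render)
            if "channel_map" in rc:
                rc["channel_map"] = {int(k): int(v) for k, v in rc["channel_map"].items()}
            if "image_shape" in rc:
                rc["image_shape"] = tuple(rc["image_shape"])
            rc.setdefault("origin", "center")  # simulated tracks are arena-centred
            cfg = RenderConfig(**{"seed": config.seed, **rc})
            movie = render_movie(results["simulate"], cfg)
            path = out / "movie.tif"
            write_image_stack(movie, path)
            provenance().write(path)
            artefacts["movie"] = path
            results["render"] = movie
        elif stage == "piv":
            opts = dict(config.piv)
            pair = (opts.pop("frame_a", 0), opts.pop("frame_b", 1))
            channel = opts.pop("channel", 0)
            dt = opts.pop("interval_min", results["render"].frame_interval)
            cfg = PIVConfig(**opts)
            movie = results["render"]
            fld = run_piv(movie.frame(pair[0], channel), movie.frame(pair[1], channel), cfg)
            import pandas as pd

            pts = fld.points()
            table = pd.DataFrame(
                {
                    "x": pts[:, 0],
                    "y": pts[:, 1],
                    "u": fld.u.ravel(),
                    "v": fld.v.ravel(),
                    "valid": fld.valid.ravel().astype(int),
                }
            )
            path = out / "piv.csv"
            table.to_csv(path, index=False, float_format="%.6g")
            provenance().write(path)
            artefacts["piv"] = path
            results["piv"] = (fld, field_summary(fld, dt=dt))
        elif stage == "kinematics":
            kin, curve = step_kinematics(results["simulate"], **config.kinematics)
            path = out / "kinematics.csv"
            kin.to_csv(path, index=False, float_format="%.6g")
            curve.to_csv(out / "velocity_curve.csv", index=False, float_format="%.6g")
            provenance().write(path)
            results["kinematics"] = (kin, curve)
        elif stage == "similarity":
            sim = movement_similarity(results["simulate"], **config.similarity)
            path = out / "similarity.csv"
            sim.per_cell.to_csv(path, index=False, float_format="%.6g")
            provenance().write(path)
            (out / "similarity_global.json").write_text(
                json.dumps({"global_score_deg": sim.global_score})
            )
            results["similarity"] = sim
        elif stage == "landmarks":
            opts = dict(config.landmarks)
            ids = opts.pop("track_ids", None)
            tracks = results["simulate"]
            if ids is None:
                ids = sorted(tracks["track_id"].unique())[:5]
            lm = tracks[tracks["track_id"].isin(ids)]
            table = landmark_displacement(lm, **opts)
            path = out / "landmarks.csv"
            table.to_csv(path, index=False, float_format="%.6g")
            provenance().write(path)
            results["landmarks"] = table
        logger.info("stage %s done in %.2f s", stage, time.perf_counter() - t0)
    return results
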