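"""Run configuration and the end-to-end pipeline.

A :class:`RunConfig` gathers the window, network, training and simulation
settings plus output paths and one global seed in a YAML-friendly structure.
Per-stage seeds (simulation, training) are derived deterministically from
the global seed with `numpy.random.SeedSequence`, so each stage is
reproducible in isolation as well as inside the full pipeline.

:func:`run_pipeline` executes simulate -> train -> segment -> evaluate,
echoes the resolved configuration into the output directory and writes a
manifest listing every produced file with its SHA-256 checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .exceptions import ConfigurationError
from .io import write_trajectories
from .simulate import MotionParams, SimulationConfig, simulate_dataset, dataset_summary
from .train import TrainConfig
from .unet import UNetConfig
from .windows import WindowSpec

logger = logging.getLogger("trajseg")

__all__ = ["RunConfig", "run_pipeline", "derive_seed", "load_run_config"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministically derive a per-stage seed below 2**31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _build_section(cls, values: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - names
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in section {section!r}: {sorted(unknown)}"
        )
    return cls(**values)


@dataclass
class RunConfig:
    """Everything a full pipeline run needs; every field has a default."""

    seed: int = 0
    n_test_tracks: int = 50
    out_dir: str = "trajseg_run"
    window: WindowSpec = field(default_factory=WindowSpec)
    unet: UNetConfig = field(default_factory=UNetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration key(s): {sorted(unknown)}")
        kwargs: dict = {}
        for scalar in ("seed", "n_test_tracks", "out_dir"):
            if scalar in d:
                kwargs[scalar] = d.pop(scalar)
        if "window" in d:
            kwargs["window"] = _build_section(WindowSpec, d.pop("window"), "window")
        if "unet" in d:
            kwargs["unet"] = _build_section(UNetConfig, d.pop("unet"), "unet")
        if "train" in d:
            kwargs["train"] = _build_section(TrainConfig, d.pop("train"), "train")
        if "simulation" in d:
            sim = dict(d.pop("simulation"))
            if "states" in sim:
                sim["states"] = tuple(sim["states"])
            if "motion" in sim:
                sim["motion"] = _build_section(
                    MotionParams, sim["motion"], "simulation.motion"
                )
            kwargs["simulation"] = _build_section(
                SimulationConfig, sim, "simulation"
            )
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_test_tracks": self.n_test_tracks,
            "out_dir": self.out_dir,
            "window": self.window.to_dict(),
            "unet": self.unet.to_dict(),
            "train": self.train.to_dict(),
            "simulation": {
                **{
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in dataclasses.asdict(self.simulation).items()
                    if k != "motion"
                },
                "motion": dataclasses.asdict(self.simulation.motion),
            },
        }


def load_run_config(path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected by name."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"configuration file {path} is not a mapping")
    return RunConfig.from_dict(data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate -> train -> segment -> evaluate end to end.

    Returns the manifest dict (also written to ``manifest.json`` in the
    output directory).  Any stage failure propagates with the stage named.
    """
    from dataclasses import replace

    from .infer import write_segmented_csv
    from .model import TrajectorySegmenter

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    produced: list[Path] = []

    cfg_path = out / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    produced.append(cfg_path)

    stage = "simulate"
    try:
        sim_cfg = replace(config.simulation, seed=derive_seed(config.seed, "simulate"))
        train_trajs, test_trajs = simulate_dataset(sim_cfg, n_test=config.n_test_tracks)
        logger.info(
            "simulate: %d train / %d test tracks (%s)",
            len(train_trajs), len(test_trajs), dataset_summary(train_trajs),
        )
        train_path, test_path = out / "train.csv", out / "test.csv"
        write_trajectories(train_trajs, train_path)
        write_trajectories(test_trajs, test_path)
        produced += [train_path, test_path]

        stage = "train"
        model = TrajectorySegmenter(
            train_trajs,
            window_spec=config.window,
            coord_system=config.train.coord_system,
            unet_config=config.unet,
        )
        logger.info("train: %d trajectories -> %d windows",
                    len(train_trajs), model.n_windows)
        res = model.fit(
            learning_rate=config.train.learning_rate,
            epochs=config.train.epochs,
            batch_size=config.train.batch_size,
            seed=derive_seed(config.seed, "train"),
            include_padded_points_in_loss=config.train.include_padded_points_in_loss,
        )
        ckpt = out / "model.ckpt.npz"
        res.save(ckpt)
        produced.append(ckpt)
        logger.info("train: final loss %.4f", res.loss_history[-1])

        stage = "segment"
        preds = res.segment_all(test_trajs)
        seg_path = out / "segmented.csv"
        write_segmented_csv(test_trajs, preds, seg_path)
        produced.append(seg_path)

        stage = "evaluate"
        report = res.evaluate(test_trajs)
        logger.info("evaluate: accuracy %.4f on %d points",
                    report.accuracy, report.n_scored)
        report_path = out / "report.json"
        report_path.write_text(json.dumps(report.to_dict(), indent=2))
        produced.append(report_path)
    except Exception as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "files": {p.name: _sha256(p) for p in produced},
        "accuracy": report.accuracy,
        "n_scored": report.n_scored,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
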