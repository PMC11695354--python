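"""Experiment orchestration: configs, run directories, manifests, exports.

A run is driven by a YAML config that fully determines it (together with
the seed): data generation, network and training settings, and which
stages to execute.  Every run directory receives a manifest (config
snapshot, seeds, package version, stage outputs, timestamps) sufficient to
re-run it bit-compatibly on the same platform.

Artifact conventions: CSV for tabular outputs, ``.npz`` for tensors and
checkpoints, plain-text key/value for Moran results.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kernels import SigmaSchedule
from .network import NetworkConfig, SpikingDelayNet
from .receptive_fields import all_receptive_fields
from .spatial import MoranResult, compare_morans_distributions, max_permuted_morans, queen_weights
from .structure import RewirePolicy
from .synthetic import (
    ClassPatternConfig,
    ClassPatternTask,
    make_class_pattern_task,
    make_planted_structure_task,
)
from .training import TrainConfig, train

__all__ = [
    "load_config",
    "run_experiment",
    "save_checkpoint",
    "load_checkpoint",
    "export_receptive_fields",
]

_STAGES = ("synth", "train", "rf", "morans", "compare")


def load_config(path: str | Path) -> dict:
    """Parse and validate a YAML experiment config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping, got {type(cfg).__name__}")
    bad = [s for s in cfg.get("stages", []) if s not in _STAGES]
    if bad:
        raise ValueError(f"unknown stages {bad}; valid stages are {list(_STAGES)}")
    for key in ("data", "network", "train", "morans"):
        if key in cfg and not isinstance(cfg[key], dict):
            raise ValueError(f"config section {key!r} must be a mapping")
    return cfg


def _build_dataset(cfg: dict, seed: int) -> ClassPatternTask:
    data_cfg = dict(cfg.get("data", {}))
    kind = data_cfg.pop("kind", "class_pattern")
    ccfg = ClassPatternConfig(**data_cfg)
    rng = np.random.default_rng(seed)
    if kind == "class_pattern":
        return make_class_pattern_task(ccfg, rng)
    if kind == "planted_structure":
        return make_planted_structure_task(ccfg, rng)
    raise ValueError(f"unknown data kind {kind!r}")


def _network_config(cfg: dict, task: ClassPatternTask) -> NetworkConfig:
    net = dict(cfg.get("network", {}))
    net.setdefault("n_inputs", task.config.n_channels)
    net.setdefault("n_outputs", task.config.n_classes)
    net.setdefault("T", task.config.T)
    return NetworkConfig(**net)


def _train_config(cfg: dict, seed: int) -> TrainConfig:
    tr = dict(cfg.get("train", {}))
    rewire = tr.pop("rewire", None)
    sigma = tr.pop("sigma", None)
    tr.setdefault("seed", seed)
    tcfg = TrainConfig(**tr)
    if rewire:
        tcfg = dataclasses.replace(tcfg, rewire=RewirePolicy(**rewire))
    if sigma:
        tcfg = dataclasses.replace(tcfg, sigma_schedule=SigmaSchedule(**sigma))
    return tcfg


def save_checkpoint(model: SpikingDelayNet, path: str | Path) -> None:
    """Write a model checkpoint (config as JSON + named parameter arrays)."""
    state = model.state_dict()
    state["config_json"] = np.array(json.dumps(dataclasses.asdict(model.cfg)))
    np.savez_compressed(path, **state)


def load_checkpoint(path: str | Path) -> SpikingDelayNet:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint {path} not found")
    with np.load(path, allow_pickle=False) as data:
        state = {k: data[k] for k in data.files}
    cfg = NetworkConfig(**json.loads(str(state.pop("config_json"))))
    model = SpikingDelayNet(cfg, np.random.default_rng(0))
    model.load_state_dict(state)
    return model


def export_receptive_fields(
    model_or_checkpoint, out_dir: str | Path, tag: str = "trained", magnitude: bool = False
) -> list[Path]:
    """Write one CSV matrix per output class; filenames encode class and tag."""
    model = (
        model_or_checkpoint
        if isinstance(model_or_checkpoint, SpikingDelayNet)
        else load_checkpoint(model_or_checkpoint)
    )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rf in all_receptive_fields(model, magnitude=magnitude):
        p = out_dir / f"rf_class{rf.class_id:02d}_{tag}.csv"
        np.savetxt(p, rf.matrix, delimiter=",")
        paths.append(p)
    return paths


def _write_moran(result: MoranResult, path: Path) -> None:
    with open(path, "w") as fh:
        for key in ("i_value", "i_max_permuted", "n_permutations", "null_baseline", "seed"):
            fh.write(f"{key} = {getattr(result, key)}\n")


def run_experiment(config_path: str | Path, out_dir: str | Path | None = None) -> Path:
    """Execute the stage chain requested by a config; returns the run directory.

    Stages (any prefix of ``synth -> train -> rf -> morans -> compare``):
    dataset generation, training, receptive-field export, per-class
    permutation-maximized Moran's I, and the trained-vs-untrained
    Mann-Whitney comparison.
    """
    cfg = load_config(config_path)
    seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages", list(_STAGES))
    run_dir = Path(out_dir or cfg.get("out", "runs/run"))
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg,
        "seed": seed,
        "version": __version__,
        "started": datetime.datetime.now().isoformat(),
        "outputs": {},
    }

    task = _build_dataset(cfg, seed)
    if "synth" in stages:
        ds_path = run_dir / "dataset.npz"
        np.savez_compressed(
            ds_path,
            inputs=task.inputs,
            labels=task.labels,
            idx_train=task.idx_train,
            idx_test=task.idx_test,
        )
        manifest["outputs"]["dataset"] = str(ds_path)

    model = untrained_state = None
    if "train" in stages:
        net_cfg = _network_config(cfg, task)
        tcfg = _train_config(cfg, seed)
        model = SpikingDelayNet(net_cfg, np.random.default_rng(seed))
        untrained_state = model.state_dict()
        model, history = train(model, task, tcfg)
        history.to_csv(run_dir / "metrics.csv", index=False)
        save_checkpoint(model, run_dir / "checkpoint.npz")
        manifest["outputs"]["metrics"] = str(run_dir / "metrics.csv")
        manifest["outputs"]["checkpoint"] = str(run_dir / "checkpoint.npz")

    if "rf" in stages and model is not None:
        paths = export_receptive_fields(model, run_dir / "rf", tag="trained")
        manifest["outputs"]["rf"] = [str(p) for p in paths]

    moran_trained: list[float] = []
    if "morans" in stages and model is not None:
        n_perm = int(cfg.get("morans", {}).get("n_perm", 2000))
        rfs = all_receptive_fields(model)
        w = queen_weights(*rfs[0].matrix.shape)
        moran_dir = run_dir / "morans"
        moran_dir.mkdir(exist_ok=True)
        for rf in rfs:
            res = max_permuted_morans(rf.matrix, w, n_perm=n_perm, rng=seed + rf.class_id)
            moran_trained.append(res.i_max_permuted)
            _write_moran(res, moran_dir / f"moran_class{rf.class_id:02d}_trained.txt")
        manifest["outputs"]["morans"] = str(moran_dir)

    if "compare" in stages and model is not None and moran_trained:
        n_perm = int(cfg.get("morans", {}).get("n_perm", 2000))
        ref = SpikingDelayNet(model.cfg, np.random.default_rng(seed))
        ref.load_state_dict(untrained_state)
        rfs0 = all_receptive_fields(ref)
        w = queen_weights(*rfs0[0].matrix.shape)
        moran_untrained = [
            max_permuted_morans(rf.matrix, w, n_perm=n_perm, rng=seed + 10_000 + rf.class_id).i_max_permuted
            for rf in rfs0
        ]
        U, p = compare_morans_distributions(np.array(moran_trained), np.array(moran_untrained))
        comp = pd.DataFrame(
            [
                {
                    "U_trained": U,
                    "p_value": p,
                    "mean_trained": np.mean(moran_trained),
                    "mean_untrained": np.mean(moran_untrained),
                }
            ]
        )
        comp.to_csv(run_dir / "compare.csv", index=False)
        manifest["outputs"]["compare"] = str(run_dir / "compare.csv")

    manifest["finished"] = datetime.datetime.now().isoformat()
    with open(run_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return run_dir
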