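"""Experiment configuration and staged pipeline runner.

An ``ExperimentConfig`` fully describes a run (grid, coil, noise,
kernel, network, split, seeds, output paths); its canonical-JSON hash
identifies the run, and every stochastic stage draws its seed from the
master seed.  ``run_pipeline`` executes a subset of the stages

    simulate -> corrupt -> hept -> train -> predict -> evaluate

writing artifacts plus a manifest (config hash, seeds, artifact
checksums) into the output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as dio
from .cgan import (DatasetSplit, NetworkConfig, assemble_dataset, predict,
                   train)
from .em_forward import CoilConfig, make_acquisition, solve_fields
from .evaluate import roi_statistics
from .hept import build_noise_robust_kernel, hept_reconstruct
from .models import (build_head_model, build_phantom_library)
from .noise import NoiseSpec, corrupt_acquisition

__all__ = ["ExperimentConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("dlept")

STAGES = ("simulate", "corrupt", "hept", "train", "predict", "evaluate")


@dataclass
class ExperimentConfig:
    grid_shape: tuple = (64, 64)
    spacing: float = 0.004
    n_phantoms: int = 6
    n_heads: int = 0
    slices_per_model: int = 2
    coil: dict = field(default_factory=dict)
    noise: dict = field(default_factory=lambda: {"snr_mag": 90.0,
                                                 "phase_sd": 9e-3})
    kernel_support: tuple = (7, 7)
    network: dict = field(default_factory=dict)
    split: dict = field(default_factory=dict)
    master_seed: int = 0
    out_dir: str = "runs/demo"

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        kw = {f.name: data[f.name] for f in dataclasses.fields(cls)
              if f.name in data}
        for key in ("grid_shape", "kernel_support"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: ExperimentConfig, stages=("simulate",)) -> dict:
    """Execute pipeline stages in canonical order; returns the manifest."""
    stages = [s for s in STAGES if s in set(stages)]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.config_hash(),
                "master_seed": config.master_seed,
                "stages": stages, "artifacts": {}, "timing_s": {}}
    rng = np.random.default_rng(config.master_seed)
    seeds = {s: int(rng.integers(2 ** 31)) for s in STAGES}
    manifest["seeds"] = seeds

    models = build_phantom_library(
        max(config.n_phantoms, 1), seed=seeds["simulate"],
        grid_shape=config.grid_shape, spacing=config.spacing)[
            :config.n_phantoms]
    models += [build_head_model(seed=seeds["simulate"] + i,
                                grid_shape=config.grid_shape,
                                spacing=config.spacing)
               for i in range(config.n_heads)]
    coil = CoilConfig(**config.coil)
    noise = NoiseSpec(seed=seeds["corrupt"], **config.noise)
    sols, acqs = {}, {}

    def artifact(name, path):
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha(path)}

    for stage in stages:
        t0 = time.time()
        log.info("stage %s starting", stage)
        if stage == "simulate":
            for i, m in enumerate(models):
                sols[i] = solve_fields(m, coil)
            p = out / "solutions.h5"
            if p.exists():
                p.unlink()
            for i, s in sols.items():
                dio.write_solution(p, s, key=f"solution{i:03d}")
            dio.write_model_library(out / "models.h5", models)
            artifact("solutions", p)
            artifact("models", out / "models.h5")
        elif stage == "corrupt":
            _need(sols, "simulate", stage)
            p = out / "acquisitions.h5"
            if p.exists():
                p.unlink()
            for i, m in enumerate(models):
                clean = make_acquisition(sols[i], m, aux="mask")
                spec = dataclasses.replace(noise, seed=noise.seed + i)
                acqs[i] = corrupt_acquisition(clean, spec)
                dio.write_acquisition(p, acqs[i], key=f"acq{i:03d}")
            artifact("acquisitions", p)
        elif stage == "hept":
            _need(acqs, "corrupt", stage)
            kernel = build_noise_robust_kernel(config.kernel_support,
                                               config.spacing)
            maps = hept_reconstruct(acqs[0], kernel)
            dio.write_eps_maps(out / "hept_sigma.nii.gz",
                               out / "hept_epsr.nii.gz", maps, config.spacing)
            artifact("hept_sigma", out / "hept_sigma.nii.gz")
            artifact("hept_epsr", out / "hept_epsr.nii.gz")
        elif stage == "train":
            _need(sols, "simulate", stage)
            ids = list(range(len(models)))
            split = DatasetSplit(train=ids[:-1] or ids, test=ids[-1:]
                                 if len(ids) > 1 else [])
            net_cfg = NetworkConfig(seed=seeds["train"], **config.network)
            ds = assemble_dataset(models, split, noise,
                                  aux=net_cfg.aux, target=net_cfg.target,
                                  slices_per_model=config.slices_per_model,
                                  solutions=sols)
            trained = train(ds, net_cfg)
            manifest["trained"] = {"final_l1": trained.history["l1"][-1]}
            dio.save_checkpoint(out / "checkpoint", trained)
            artifact("checkpoint", out / "checkpoint.npz")
        elif stage == "predict":
            ckpt = out / "checkpoint.npz"
            if not ckpt.exists():
                raise FileNotFoundError(
                    "predict requires a checkpoint; run the train stage first")
            _need(acqs, "corrupt", stage)
            trained = dio.load_checkpoint(out / "checkpoint")
            maps = predict(trained, acqs[len(models) - 1])
            dio.write_eps_maps(out / "dl_sigma.nii.gz", out / "dl_epsr.nii.gz",
                               maps, config.spacing)
            artifact("dl_sigma", out / "dl_sigma.nii.gz")
        elif stage == "evaluate":
            _need(acqs, "corrupt", stage)
            kernel = build_noise_robust_kernel(config.kernel_support,
                                               config.spacing)
            report = {}
            for i, m in enumerate(models):
                maps = hept_reconstruct(acqs[i], kernel)
                report[f"model{i:03d}"] = roi_statistics(maps, m.label_grid)
            dio.write_report(out / "report", report)
            artifact("report", out / "report.json")
        manifest["timing_s"][stage] = round(time.time() - t0, 3)
        log.info("stage %s done in %.1fs", stage, manifest["timing_s"][stage])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _need(store, producer, stage):
    if not store:
        raise RuntimeError(
            f"stage {stage!r} requires artifacts from {producer!r}; "
            f"include {producer!r} in the stage list")
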