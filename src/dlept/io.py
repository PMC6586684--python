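"""Readers and writers: NIfTI maps, HDF5 containers, checkpoints, reports.

Conventions: 0-based voxel indices, axis order (row = y, column = x),
spacing in meters everywhere in memory; the NIfTI affine carries the
voxel size (in mm, the format's convention).  Complex arrays are stored
in HDF5 as real/imag pairs.  All round-trips are lossless.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .cgan import NetworkConfig, TrainedModel, UNet
from .em_forward import Acquisition, FieldSolution
from .hept import EpsMaps
from .models import TissueModel

__all__ = ["write_nifti_map", "read_nifti_map", "write_model", "read_model",
           "write_model_library", "read_model_library", "write_solution",
           "read_solution", "write_acquisition", "read_acquisition",
           "write_eps_maps", "read_eps_maps", "save_checkpoint",
           "load_checkpoint", "write_report"]


# ----------------------------------------------------------------------
# NIfTI
# ----------------------------------------------------------------------

def _affine(spacing_m: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = spacing_m * 1000.0  # mm
    return aff

def write_nifti_map(path, data: np.ndarray, spacing: float,
                    description: str = "") -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64)[..., None],
                          _affine(spacing))
    img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))


def read_nifti_map(path):
    """Returns (2D array, spacing in meters, description)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)[..., 0]
    spacing = float(img.header.get_zooms()[0]) / 1000.0
    descr = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode()
    return data, spacing, descr


# ----------------------------------------------------------------------
# HDF5: tissue models, field solutions, acquisitions
# ----------------------------------------------------------------------

def _write_model_group(g, model: TissueModel):
    g.create_dataset("label_grid", data=model.label_grid)
    g.create_dataset("sigma_map", data=model.sigma_map)
    g.create_dataset("epsr_map", data=model.epsr_map)
    g.attrs["spacing"] = model.spacing
    props = {str(k): v for k, v in model.region_properties.items()}
    g.attrs["region_properties"] = json.dumps(props)


def _read_model_group(g) -> TissueModel:
    props = {int(k): tuple(v) for k, v in
             json.loads(g.attrs["region_properties"]).items()}
    return TissueModel(label_grid=g["label_grid"][()],
                       sigma_map=g["sigma_map"][()],
                       epsr_map=g["epsr_map"][()],
                       spacing=float(g.attrs["spacing"]),
                       region_properties=props)


def write_model(path, model: TissueModel) -> None:
    with h5py.File(path, "w") as f:
        _write_model_group(f.create_group("model"), model)


def read_model(path) -> TissueModel:
    with h5py.File(path, "r") as f:
        return _read_model_group(f["model"])


def write_model_library(path, models) -> None:
    """One group per model, keyed model000, model001, ..."""
    with h5py.File(path, "w") as f:
        for i, m in enumerate(models):
            _write_model_group(f.create_group(f"model{i:03d}"), m)


def read_model_library(path):
    with h5py.File(path, "r") as f:
        return [_read_model_group(f[k]) for k in sorted(f.keys())]


def _write_complex(g, name, arr):
    g.create_dataset(f"{name}_real", data=arr.real)
    g.create_dataset(f"{name}_imag", data=arr.imag)


def _read_complex(g, name):
    return g[f"{name}_real"][()] + 1j * g[f"{name}_imag"][()]


def write_solution(path, sol: FieldSolution, key: str = "solution") -> None:
    with h5py.File(path, "a") as f:
        if key in f:
            del f[key]
        g = f.create_group(key)
        for name, arr in (("Ez", sol.Ez), ("B1p", sol.B1p), ("B1m", sol.B1m)):
            _write_complex(g, name, arr)
        g.attrs["omega"] = sol.omega
        g.attrs["spacing"] = sol.spacing


def read_solution(path, key: str = "solution") -> FieldSolution:
    with h5py.File(path, "r") as f:
        g = f[key]
        return FieldSolution(Ez=_read_complex(g, "Ez"),
                             B1p=_read_complex(g, "B1p"),
                             B1m=_read_complex(g, "B1m"),
                             omega=float(g.attrs["omega"]),
                             spacing=float(g.attrs["spacing"]))


def write_acquisition(path, acq: Acquisition, key: str = "acquisition") -> None:
    with h5py.File(path, "a") as f:
        if key in f:
            del f[key]
        g = f.create_group(key)
        for name in ("magnitude", "phase", "aux"):
            g.create_dataset(name, data=getattr(acq, name))
        g.create_dataset("mask", data=acq.mask.astype(np.uint8))
        for name in ("clean_magnitude", "clean_phase"):
            arr = getattr(acq, name)
            if arr is not None:
                g.create_dataset(name, data=arr)
        g.attrs.update({"spacing": acq.spacing, "aux_kind": acq.aux_kind,
                        "snr": acq.snr, "phase_sd": acq.phase_sd})


def read_acquisition(path, key: str = "acquisition") -> Acquisition:
    with h5py.File(path, "r") as f:
        g = f[key]
        kw = {name: g[name][()] for name in ("magnitude", "phase", "aux")}
        kw["mask"] = g["mask"][()].astype(bool)
        for name in ("clean_magnitude", "clean_phase"):
            kw[name] = g[name][()] if name in g else None
        return Acquisition(spacing=float(g.attrs["spacing"]),
                           aux_kind=str(g.attrs["aux_kind"]),
                           snr=float(g.attrs["snr"]),
                           phase_sd=float(g.attrs["phase_sd"]), **kw)


def write_eps_maps(path_sigma, path_epsr, maps: EpsMaps,
                   spacing: float) -> None:
    write_nifti_map(path_sigma, maps.sigma_map, spacing,
                    description=f"{maps.method} sigma [S/m]")
    write_nifti_map(path_epsr, maps.epsr_map, spacing,
                    description=f"{maps.method} epsr [-]")


def read_eps_maps(path_sigma, path_epsr) -> EpsMaps:
    sig, sp, descr = read_nifti_map(path_sigma)
    eps, _, _ = read_nifti_map(path_epsr)
    method = descr.split()[0] if descr else "unknown"
    return EpsMaps(sigma_map=sig, epsr_map=eps, method=method,
                   valid_mask=np.isfinite(sig))


# ----------------------------------------------------------------------
# Checkpoints
# ----------------------------------------------------------------------

def save_checkpoint(path, model: TrainedModel) -> None:
    """Generator weights as .npz plus a JSON sidecar with config/history."""
    path = Path(path)
    arrays = {f"p{i:03d}": p for i, (p, _) in enumerate(model.generator.params)}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {"config": dataclasses.asdict(model.config),
               "history": model.history,
               "base_channels": model.config.base_channels}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path) -> TrainedModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfgd = sidecar["config"]
    for key in ("sigma_range", "epsr_range"):
        cfgd[key] = tuple(cfgd[key])
    config = NetworkConfig(**cfgd)
    G = UNet(cin=3, base=config.base_channels,
             rng=np.random.default_rng(config.seed))
    data = np.load(path.with_suffix(".npz"))
    for i, (p, _) in enumerate(G.params):
        p[...] = data[f"p{i:03d}"]
    return TrainedModel(config=config, generator=G,
                        history=sidecar.get("history", {}))


def write_report(path, report: dict) -> None:
    """JSON report plus a flat CSV with one row per (tissue, metric)."""
    path = Path(path)
    path.with_suffix(".json").write_text(json.dumps(report, indent=1,
                                                    default=float))
    lines = ["section,key,value"]

    def flatten(prefix, obj):
        if isinstance(obj, dict):
            for k, v in obj.items():
                flatten(f"{prefix}.{k}" if prefix else str(k), v)
        elif isinstance(obj, (list, tuple)):
            lines.append(f"{prefix},list,\"{obj}\"")
        else:
            lines.append(f"{prefix.rsplit('.', 1)[0] if '.' in prefix else ''},"
                         f"{prefix.rsplit('.', 1)[-1]},{obj}")
    flatten("", report)
    path.with_suffix(".csv").write_text("\n".join(lines) + "\n")
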