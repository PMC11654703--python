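"""HDF5/JSON serialization for tensors and model parameters.

Arrays go to HDF5 datasets; structural metadata (task grid, model class)
travels as JSON strings in attributes.  Loaders re-validate invariants by
reconstructing the dataclasses through their constructors.  TFR indicator
tensors are rebuilt on load, never serialized.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .lds_core import InputModel, LDSParams, ModelClassSpec
from .synthetic_task import ResponseTensor
from .task_grid import TaskGrid
from .tfr_core import TFRParams


def save_response_tensor(path: str | Path, data: ResponseTensor) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("Y", data=data.Y)
        f.attrs["grid"] = data.grid.to_json()
        f.attrs["bin_ms"] = data.bin_ms
        if data.zscore_mean is not None:
            f.create_dataset("zscore_mean", data=data.zscore_mean)
            f.create_dataset("zscore_sd", data=data.zscore_sd)


def load_response_tensor(path: str | Path) -> ResponseTensor:
    with h5py.File(path, "r") as f:
        grid = TaskGrid.from_json(f.attrs["grid"])
        mean = f["zscore_mean"][:] if "zscore_mean" in f else None
        sd = f["zscore_sd"][:] if "zscore_sd" in f else None
        return ResponseTensor(
            Y=f["Y"][:], grid=grid, bin_ms=float(f.attrs["bin_ms"]),
            zscore_mean=mean, zscore_sd=sd,
        )


def _class_spec_json(cs: ModelClassSpec) -> str:
    return json.dumps(
        {
            "dynamics_context_dependent": cs.dynamics_context_dependent,
            "inputs_context_dependent": cs.inputs_context_dependent,
            "latent_dim": cs.latent_dim,
            "input_dim_motion": cs.input_dim_motion,
            "input_dim_color": cs.input_dim_color,
            "inputs_time_varying": cs.inputs_time_varying,
        }
    )


def save_lds_params(path: str | Path, params: LDSParams) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["class_spec"] = _class_spec_json(params.class_spec)
        f.attrs["is_orthonormalized"] = params.is_orthonormalized
        for k in ("A", "B_mot", "B_col", "x0", "C_load", "d"):
            f.create_dataset(k, data=getattr(params, k))
        g = f.create_group("inputs")
        g.create_dataset("courses_motion", data=params.inputs.courses_motion)
        g.create_dataset("courses_color", data=params.inputs.courses_color)
        g.create_dataset("scalars_motion", data=params.inputs.scalars_motion)
        g.create_dataset("scalars_color", data=params.inputs.scalars_color)


def load_lds_params(path: str | Path) -> LDSParams:
    with h5py.File(path, "r") as f:
        cs = ModelClassSpec(**json.loads(f.attrs["class_spec"]))
        inputs = InputModel(
            f["inputs/courses_motion"][:],
            f["inputs/courses_color"][:],
            f["inputs/scalars_motion"][:],
            f["inputs/scalars_color"][:],
            time_varying=cs.inputs_time_varying,
        )
        return LDSParams(
            class_spec=cs, A=f["A"][:], B_mot=f["B_mot"][:], B_col=f["B_col"][:],
            x0=f["x0"][:], C_load=f["C_load"][:], d=f["d"][:], inputs=inputs,
            is_orthonormalized=bool(f.attrs["is_orthonormalized"]),
        )


def save_tfr_params(path: str | Path, params: TFRParams) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["input_dims"] = json.dumps(list(params.input_dims))
        f.create_dataset("loading", data=params.loading)
        f.create_dataset("core", data=params.core)
        f.create_dataset("dir_courses", data=params.dir_courses)
        f.create_dataset("coh_scalars", data=params.coh_scalars)


def load_tfr_params(path: str | Path) -> TFRParams:
    with h5py.File(path, "r") as f:
        return TFRParams(
            loading=f["loading"][:], core=f["core"][:],
            dir_courses=f["dir_courses"][:], coh_scalars=f["coh_scalars"][:],
            input_dims=tuple(json.loads(f.attrs["input_dims"])),
        )
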