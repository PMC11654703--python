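"""Simulated causal perturbation experiments and pipeline reporting.

State perturbations displace the latent state once, along the latent image
(through C^T, norm preserving for orthonormal loadings) of an
observation-space direction — typically a principal component of the data,
which is computable without fitting any model.  Input perturbations
transiently switch off one modality's inferred input.  Because the model is
linear, the effect (perturbed minus unperturbed trajectory) is identical
across conditions for state perturbations and scales linearly with the
perturbation norm; whether the effect norm transiently grows above its
onset value discriminates non-normal (dynamics-switching) from near-normal
(input-switching) mechanisms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import dynamics as dyn
from . import fit_select, lds_core
from .errors import ConfigError, ShapeError
from .lds_core import LDSParams, N_CONTEXTS
from .synthetic_task import GroundTruthSpec, ResponseTensor, generate_dataset
from .task_grid import TaskGrid


# ---------------------------------------------------------------------------
# principal components of the data


def pca_dimensions(
    data: ResponseTensor, context: int, n_components: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Principal directions of one context's activity, model free.

    The tensor is unfolded to neurons x (time*condition) samples and
    centered; returns (components, explained_variance) with orthonormal
    components in columns of a (N, n_components) matrix, ordered by
    variance.
    """
    Y = data.Y[:, :, :, context]
    X = Y.reshape(Y.shape[0], -1)
    Xc = X - X.mean(axis=1, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / Xc.shape[1]
    if n_components is not None:
        U, var = U[:, :n_components], var[:n_components]
    return U, var


# ---------------------------------------------------------------------------
# perturbations


@dataclass(frozen=True)
class PerturbationSpec:
    """One perturbation experiment.

    ``kind``: 'state' (single-bin latent displacement of norm ``norm``
    along ``direction``, an observation-space unit vector) or 'input'
    (zero one ``modality``'s input over ``duration`` bins from ``onset``).
    ``onset`` is the 1-based bin at which the perturbation is applied
    (default: the first analyzed bin).
    """

    kind: str = "state"
    direction: np.ndarray | None = None
    norm: float = 10.0
    onset: int = 1
    duration: int = 2
    modality: str = "motion"
    contexts: tuple[int, ...] = (0, 1)
    conditions: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("state", "input"):
            raise ConfigError("kind must be 'state' or 'input'")
        if self.kind == "input" and self.modality not in ("motion", "color"):
            raise ConfigError("modality must be 'motion' or 'color'")


@dataclass
class PerturbationResult:
    """Per-context effect of a perturbation.

    ``effect``[cx] is the (N, T) observation-space difference trajectory
    (identical across probed conditions for state perturbations — asserted);
    ``effect_norm``[cx] its norm over time; ``amplifying``[cx] is True when
    the norm transiently rises above its onset value before decaying.
    """

    spec: PerturbationSpec
    baseline: dict
    perturbed: dict
    effect: dict
    effect_norm: dict
    projections: dict
    amplifying: dict


def perturb(
    params: LDSParams,
    spec: PerturbationSpec,
    grid: TaskGrid,
    axes: np.ndarray | None = None,
) -> PerturbationResult:
    """Run paired (unperturbed, perturbed) simulations and take differences.

    ``axes`` (N, m), optional: named observation-space dimensions the effect
    is projected onto (e.g. a decision axis).
    """
    T = params.inputs.n_bins
    if not 1 <= spec.onset <= T:
        raise ConfigError(f"onset bin {spec.onset} outside trial of {T} bins")
    conds = list(spec.conditions) if spec.conditions is not None else list(range(grid.K))
    C = params.C_load
    result = PerturbationResult(
        spec=spec, baseline={}, perturbed={}, effect={}, effect_norm={},
        projections={}, amplifying={},
    )
    for cx in spec.contexts:
        drive = lds_core.condition_drive(params, grid, cx)[:, :, conds]
        A = params.A_ctx(cx)
        Xb = lds_core._simulate_from_drive(A, params.x0[cx], drive)
        if spec.kind == "state":
            if spec.direction is None:
                raise ConfigError("state perturbation requires a direction")
            v = np.asarray(spec.direction, dtype=float)
            if v.shape[0] == C.shape[0]:
                v_lat = C.T @ v
            elif v.shape[0] == C.shape[1]:
                v_lat = v
            else:
                raise ShapeError("direction must live in observation or latent space")
            drive_p = drive.copy()
            drive_p[:, spec.onset - 1, :] += (spec.norm * v_lat)[:, None]
        else:
            drive_p = _switched_off_drive(params, grid, cx, spec, conds)
        Xp = lds_core._simulate_from_drive(A, params.x0[cx], drive_p)
        Yb = np.einsum("nl,ltk->ntk", C, Xb[:, 1:, :]) + params.d[:, None, None]
        Yp = np.einsum("nl,ltk->ntk", C, Xp[:, 1:, :]) + params.d[:, None, None]
        eff = Yp - Yb
        if spec.kind == "state":
            # linear dynamics: the effect cannot depend on the condition
            assert np.allclose(eff, eff[:, :, :1], atol=1e-9)
            eff_tk = eff[:, :, 0]
        else:
            eff_tk = eff.mean(axis=2)
        norm_t = np.linalg.norm(eff_tk, axis=0)
        onset_norm = norm_t[spec.onset - 1]
        later = norm_t[spec.onset :]
        result.baseline[cx] = Yb
        result.perturbed[cx] = Yp
        result.effect[cx] = eff
        result.effect_norm[cx] = norm_t
        result.amplifying[cx] = bool(later.size and later.max() > onset_norm * (1 + 1e-9))
        if axes is not None:
            result.projections[cx] = np.einsum("nm,ntk->mtk", np.asarray(axes), eff)
    return result


def _switched_off_drive(params, grid, cx, spec, conds):
    """Drive with one modality's input zeroed over the switch-off window."""
    lev_m = params.inputs.level_series("motion", grid)
    lev_c = params.inputs.level_series("color", grid)
    um = lev_m[grid.motion_index][conds]  # (K', Um, T)
    uc = lev_c[grid.color_index][conds]
    w = slice(spec.onset - 1, spec.onset - 1 + spec.duration)
    if spec.modality == "motion":
        um = um.copy()
        um[:, :, w] = 0.0
    else:
        uc = uc.copy()
        uc[:, :, w] = 0.0
    Bm, Bc = params.B_mot_ctx(cx), params.B_col_ctx(cx)
    return np.einsum("lu,kut->ltk", Bm, um) + np.einsum("lu,kut->ltk", Bc, uc)


def classify_amplification(
    params: LDSParams,
    data: ResponseTensor,
    n_pcs: int | None = None,
    norm: float = 10.0,
) -> bool:
    """True if any top-PC state perturbation is transiently amplified.

    PCs are computed per context from the data alone; a normal system can
    never amplify (||A^t v|| <= max|lambda|^t for normal A), so amplification
    along any PC flags non-normal recurrent dynamics.
    """
    n = n_pcs if n_pcs is not None else params.latent_dim
    for cx in range(N_CONTEXTS):
        pcs, _ = pca_dimensions(data, cx, n_components=n)
        for j in range(pcs.shape[1]):
            spec = PerturbationSpec(
                kind="state", direction=pcs[:, j], norm=norm, contexts=(cx,),
                conditions=(0,),
            )
            res = perturb(params, spec, data.grid)
            if res.amplifying[cx]:
                return True
    return False


# ---------------------------------------------------------------------------
# task-subspace projections


@dataclass
class SubspaceProjection:
    projections: np.ndarray  # (m, T, K, CX)
    basis: np.ndarray  # (N, m) orthonormal, first axis direction preserved
    pre_orthogonalization_angles_deg: np.ndarray  # (m, m)


def task_subspace_projection(
    trajectories: np.ndarray,
    axes: np.ndarray,
    subtract_condition_mean: bool = False,
) -> SubspaceProjection:
    """Project trajectories onto an ordered, QR-orthogonalized axis set.

    ``axes``: (N, m) unit-norm columns in priority order; the first axis is
    unchanged by the orthogonalization.  Pairwise angles between the raw
    axes are recorded before the QR step.  ``trajectories``: (N, T, K, CX).
    """
    A = np.asarray(axes, dtype=float)
    if A.ndim != 2:
        raise ShapeError("axes must be a (N, m) matrix")
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ShapeError("axis set is rank deficient (linearly dependent axes)")
    dots = np.clip(np.abs(A.T @ A), 0.0, 1.0)
    angles = np.degrees(np.arccos(dots))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))[None, :]  # keep each axis's original orientation
    traj = np.asarray(trajectories, dtype=float)
    if subtract_condition_mean:
        traj = traj - traj.mean(axis=2, keepdims=True)
    proj = np.einsum("nm,ntkc->mtkc", Q, traj)
    return SubspaceProjection(
        projections=proj, basis=Q, pre_orthogonalization_angles_deg=angles
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Generate (or load) a tensor, fit, characterize, perturb, and report.

    ``config`` is a dict or path to a JSON file; see the README for the
    schema.  Stages run in order with per-stage failure isolation: a
    failing stage is recorded in the error manifest and later stages that
    depend on it are skipped.  Deterministic given the seeds in the config.
    Returns the JSON-serializable summary (also written to summary.json
    when ``outdir`` is given).
    """
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    out: dict = {"config": config, "errors": {}, "stages": {}}
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    data = gt = None
    try:
        synth = config.get("synthetic", {})
        spec = GroundTruthSpec(**synth)
        data, gt = generate_dataset(spec)
        out["stages"]["synth"] = {
            "n_neurons": data.n_neurons, "n_bins": data.n_bins,
            "K": data.grid.K, "seed": spec.seed, "context_mode": spec.context_mode,
        }
        if outdir is not None:
            from . import io as ctxio

            ctxio.save_response_tensor(outdir / "tensor.h5", data)
    except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
        out["errors"]["synth"] = repr(exc)
        return _finish(out, outdir)

    fits = {}
    try:
        fc = config.get("fit", {})
        cfg = fit_select.FitConfig(**fc.get("config", {}))
        for cls in fc.get("classes", ["{A,Bcx}"]):
            cs = class_spec_from_name(
                cls,
                latent_dim=fc.get("latent_dim", gt.latent_dim),
                input_dim=fc.get("input_dim", gt.class_spec.input_dim_motion),
            )
            results = fit_select.multi_restart(data, cs, cfg, fc.get("n_restarts", 1))
            fits[cls] = results
            out["stages"].setdefault("fit", {})[cls] = fit_select.summarize_restarts(results)
            if outdir is not None:
                from . import io as ctxio

                ctxio.save_lds_params(
                    outdir / f"fit_{_slug(cls)}.h5", results[0].params
                )
    except Exception as exc:  # noqa: BLE001
        out["errors"]["fit"] = repr(exc)

    try:
        rows = []
        for cls, results in fits.items():
            best = results[0].params
            for cx in range(N_CONTEXTS):
                modes = dyn.eigenmodes(best.A_ctx(cx))
                for i in range(modes.n_modes):
                    rows.append(
                        {
                            "model": cls, "context": cx, "mode": i,
                            "eig_norm": float(np.abs(modes.eigvals[i])),
                            "tau_ms": float(modes.tau_ms[i]),
                            "freq_hz": float(modes.freq_hz[i]),
                            "slow": bool(modes.slow[i]),
                            "henrici": dyn.henrici_index(best.A_ctx(cx)),
                        }
                    )
        out["stages"]["dynamics"] = {"n_modes": len(rows)}
        if outdir is not None and rows:
            import pandas as pd

            pd.DataFrame(rows).to_csv(outdir / "modes.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        out["errors"]["dynamics"] = repr(exc)

    try:
        pcfg = config.get("perturb", {})
        if pcfg.get("enabled", True) and gt is not None:
            amp = classify_amplification(gt, data, norm=pcfg.get("norm", 10.0))
            out["stages"]["perturb"] = {"ground_truth_amplifying": bool(amp)}
    except Exception as exc:  # noqa: BLE001
        out["errors"]["perturb"] = repr(exc)

    return _finish(out, outdir)


def _finish(out: dict, outdir: Path | None) -> dict:
    if outdir is not None:
        (outdir / "summary.json").write_text(json.dumps(out, indent=2, default=str))
    return out


def _slug(name: str) -> str:
    return name.strip("{}").replace(",", "_")


def class_spec_from_name(
    name: str, latent_dim: int, input_dim: int, inputs_time_varying: bool = True
):
    """Parse a class name like '{Acx,B}' into a ModelClassSpec."""
    from .lds_core import ModelClassSpec

    inner = name.strip("{} ").split(",")
    if len(inner) != 2:
        raise ConfigError(f"cannot parse model class name {name!r}")
    return ModelClassSpec(
        dynamics_context_dependent=inner[0].strip() == "Acx",
        inputs_context_dependent=inner[1].strip() == "Bcx",
        latent_dim=latent_dim,
        input_dim_motion=input_dim,
        input_dim_color=input_dim,
        inputs_time_varying=inputs_time_varying,
    )
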