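"""Gradient-based fitting, multi-restart protocol and LOOCV model selection.

The objective is the reconstruction MSE plus an input-norm penalty
(weight ``lambda_inp``), minimized with ADAM.  The model is a linear
recurrence, so the gradients are computed exactly by backpropagation
through time (closed form, no autodiff dependency); they are validated
against finite differences in the test suite.

Model selection uses leave-one-condition-out cross-validation: one
(motion, color) condition is removed from both contexts, the model is
refitted on the remaining conditions, and the held-out condition is
forward-generated from the refit initial conditions and the coherence
inputs identified from the other conditions sharing its levels (on the
6x6 grid each level appears in 5 other conditions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import lds_core, tfr_core
from .errors import ConfigError, DivergenceError, ShapeError
from .lds_core import (
    InputModel,
    LDSParams,
    ModelClassSpec,
    N_CONTEXTS,
    constant_courses,
    orthonormalize,
)
from .synthetic_task import ResponseTensor
from .task_grid import TaskGrid

# ---------------------------------------------------------------------------
# configuration and result containers


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings.  Defaults are the reference protocol's values:
    ADAM learning rate 0.009, input penalty 1e-5, Gaussian init SD 0.01,
    convergence when the cost changes by < 1e-5 after at least 5,000
    iterations, hard cap 10,000 iterations."""

    learning_rate: float = 0.009
    lambda_inp: float = 1e-5
    init_sd: float = 0.01
    convergence_dcost: float = 1e-5
    max_iter: int = 10_000
    min_iter: int = 5_000
    n_restarts: int = 1
    seed: int = 0
    lambda_dyn: float = 0.0
    loocv_restarts: int = 1

    def __post_init__(self) -> None:
        if self.lambda_inp < 0 or self.lambda_dyn < 0:
            raise ConfigError("penalty weights must be >= 0")
        if self.max_iter < self.min_iter:
            raise ConfigError("max_iter must be >= min_iter")
        if self.learning_rate <= 0 or self.init_sd <= 0:
            raise ConfigError("learning_rate and init_sd must be positive")


@dataclass
class FitResult:
    """One converged model: orthonormalized parameters plus bookkeeping."""

    params: LDSParams
    class_spec: ModelClassSpec
    train_mse: float
    cost_trace: np.ndarray
    seed: int
    converged: bool
    n_iter: int
    error: str | None = None


@dataclass
class LOOCVPoint:
    """LOOCV summary for one (class, dimensionality) grid point."""

    class_name: str
    latent_dim: int
    input_dim: int
    fold_conditions: np.ndarray
    fold_mse: np.ndarray
    skipped: list[int]

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_mse))

    @property
    def sem(self) -> float:
        n = self.fold_mse.size
        return float(np.std(self.fold_mse, ddof=1) / np.sqrt(n)) if n > 1 else 0.0


@dataclass
class LOOCVReport:
    points: list[LOOCVPoint]

    @property
    def best(self) -> LOOCVPoint:
        return min(self.points, key=lambda p: p.mean)


# ---------------------------------------------------------------------------
# internal parameter vector, forward/backward pass


def _dir_of(levels) -> np.ndarray:
    return (np.asarray(levels) > 0).astype(int)


class _Problem:
    """Precomputed index structure for one training set."""

    def __init__(self, grid: TaskGrid, conditions: np.ndarray):
        self.grid = grid
        self.conditions = np.asarray(conditions, dtype=int)
        self.m_idx = grid.motion_index[self.conditions]
        self.c_idx = grid.color_index[self.conditions]
        self.m_dir = _dir_of(grid.motion_levels)
        self.c_dir = _dir_of(grid.color_levels)
        self.n_lev_m = len(grid.motion_levels)
        self.n_lev_c = len(grid.color_levels)
        # one-hot level membership for gradient accumulation
        self.M_onehot = np.eye(self.n_lev_m)[self.m_idx].T  # (n_lev, K)
        self.C_onehot = np.eye(self.n_lev_c)[self.c_idx].T


def _init_theta(
    class_spec: ModelClassSpec, n_neurons: int, n_bins: int, problem: _Problem,
    init_sd: float, rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    L = class_spec.latent_dim
    Um, Uc = class_spec.input_dim_motion, class_spec.input_dim_color
    th = {
        "A": init_sd * rng.standard_normal((class_spec.n_dynamics, L, L)),
        "Bm": init_sd * rng.standard_normal((class_spec.n_input_maps, L, Um)),
        "Bc": init_sd * rng.standard_normal((class_spec.n_input_maps, L, Uc)),
        "x0": init_sd * rng.standard_normal((N_CONTEXTS, L)),
        "C": init_sd * rng.standard_normal((n_neurons, L)),
        "d": init_sd * rng.standard_normal(n_neurons),
        "sm": init_sd * rng.standard_normal((Um, problem.n_lev_m)),
        "sc": init_sd * rng.standard_normal((Uc, problem.n_lev_c)),
    }
    if class_spec.inputs_time_varying:
        th["cm"] = init_sd * rng.standard_normal((Um, 2, n_bins))
        th["cc"] = init_sd * rng.standard_normal((Uc, 2, n_bins))
    else:
        th["cm"] = constant_courses(Um, n_bins)
        th["cc"] = constant_courses(Uc, n_bins)
    return th


def _level_drive(courses, scalars, dirs):
    """(n_levels, U, T) input traces for each signed level."""
    return courses[:, dirs, :].transpose(1, 0, 2) * scalars.T[:, :, None]


def _cost_and_grads(
    th: dict[str, np.ndarray],
    Y: np.ndarray,
    class_spec: ModelClassSpec,
    problem: _Problem,
    lambda_inp: float,
    lambda_dyn: float = 0.0,
    frozen: frozenset = frozenset(),
) -> tuple[float, dict[str, np.ndarray]]:
    """Exact objective and gradients via backprop through time.

    Y: (N, T, K, 2) training tensor (K = len(problem.conditions)).
    """
    N, T, K, _ = Y.shape
    L = class_spec.latent_dim
    nA, nB = th["A"].shape[0], th["Bm"].shape[0]
    denom = N * T * K * N_CONTEXTS

    ulev_m = _level_drive(th["cm"], th["sm"], problem.m_dir)  # (n_lev, Um, T)
    ulev_c = _level_drive(th["cc"], th["sc"], problem.c_dir)
    um = ulev_m[problem.m_idx]  # (K, Um, T)
    uc = ulev_c[problem.c_idx]

    g = {k: np.zeros_like(v) for k, v in th.items()}
    cost = 0.0
    gum_total = np.zeros((um.shape[1], T, K))
    guc_total = np.zeros((uc.shape[1], T, K))

    for cx in range(N_CONTEXTS):
        ia, ib = min(cx, nA - 1), min(cx, nB - 1)
        A, Bm, Bc = th["A"][ia], th["Bm"][ib], th["Bc"][ib]
        drive = np.einsum("lu,kut->ltk", Bm, um) + np.einsum("lu,kut->ltk", Bc, uc)
        X = np.empty((L, T + 1, K))
        X[:, 0, :] = th["x0"][cx][:, None]
        for t in range(1, T + 1):
            X[:, t, :] = A @ X[:, t - 1, :] + drive[:, t - 1, :]
        pred = np.einsum("nl,ltk->ntk", th["C"], X[:, 1:, :]) + th["d"][:, None, None]
        resid = pred - Y[:, :, :, cx]
        cost += float(np.sum(resid**2)) / denom
        cost += lambda_inp * float(np.sum(drive**2))

        dpred = (2.0 / denom) * resid
        g["C"] += np.einsum("ntk,ltk->nl", dpred, X[:, 1:, :])
        g["d"] += dpred.sum(axis=(1, 2))

        # backward recursion for dL/dx(t)
        gX = np.empty((L, T + 1, K))
        Cd = np.einsum("nl,ntk->ltk", th["C"], dpred)  # (L, T, K)
        gX[:, T, :] = Cd[:, T - 1, :]
        At = A.T
        for t in range(T - 1, 0, -1):
            gX[:, t, :] = Cd[:, t - 1, :] + At @ gX[:, t + 1, :]
        gX[:, 0, :] = At @ gX[:, 1, :]

        g["A"][ia] += np.einsum("ltk,mtk->lm", gX[:, 1:, :], X[:, :-1, :])
        g["x0"][cx] += gX[:, 0, :].sum(axis=1)
        gdrive = gX[:, 1:, :] + 2.0 * lambda_inp * drive
        g["Bm"][ib] += np.einsum("ltk,kut->lu", gdrive, um)
        g["Bc"][ib] += np.einsum("ltk,kut->lu", gdrive, uc)
        gum_total += np.einsum("lu,ltk->utk", Bm, gdrive)
        guc_total += np.einsum("lu,ltk->utk", Bc, gdrive)

    # chain input-trace gradients to courses and coherence scalars
    for nm, gu, onehot, dirs, ck, sk in (
        ("m", gum_total, problem.M_onehot, problem.m_dir, "cm", "sm"),
        ("c", guc_total, problem.C_onehot, problem.c_dir, "cc", "sc"),
    ):
        if gu.shape[0] == 0:
            continue
        gu_lev = np.einsum("jk,utk->jut", onehot, gu)  # (n_lev, U, T)
        for j in range(gu_lev.shape[0]):
            dj = dirs[j]
            if class_spec.inputs_time_varying:
                g[ck][:, dj, :] += gu_lev[j] * th[sk][:, j][:, None]
            g[sk][:, j] += np.sum(gu_lev[j] * th[ck][:, dj, :], axis=1)

    if lambda_dyn > 0.0:
        for ia in range(nA):
            A = th["A"][ia]
            P = A @ A.T - A.T @ A
            cost += lambda_dyn * float(np.sum(P**2))
            g["A"][ia] += lambda_dyn * 4.0 * (P @ A - A @ P)

    if not class_spec.inputs_time_varying:
        g["cm"][:] = 0.0
        g["cc"][:] = 0.0
    for k in frozen:
        g[k][:] = 0.0
    return cost, g


_DCOST_WINDOW = 100


def _converged(trace: np.ndarray, it: int, dcost: float) -> bool:
    """Cost-change stopping rule, evaluated over a 100-iteration window.

    Successive-iteration differences under ADAM are noisy (transient
    plateaus), so the criterion compares the cost against its value 100
    iterations earlier.
    """
    if it <= _DCOST_WINDOW:
        return False
    return abs(trace[it - 1 - _DCOST_WINDOW] - trace[it - 1]) < dcost


class _Adam:
    """Plain ADAM with the standard defaults (beta1=0.9, beta2=0.999)."""

    def __init__(self, theta: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in theta.items()}
        self.v = {k: np.zeros_like(v) for k, v in theta.items()}
        self.t = 0

    def step(self, theta: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for k, gk in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk**2
            theta[k] -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)


def _theta_to_params(th: dict[str, np.ndarray], class_spec: ModelClassSpec) -> LDSParams:
    inputs = InputModel(
        th["cm"].copy(), th["cc"].copy(), th["sm"].copy(), th["sc"].copy(),
        time_varying=class_spec.inputs_time_varying,
    )
    return LDSParams(
        class_spec=class_spec,
        A=th["A"].copy(), B_mot=th["Bm"].copy(), B_col=th["Bc"].copy(),
        x0=th["x0"].copy(), C_load=th["C"].copy(), d=th["d"].copy(), inputs=inputs,
    )


# ---------------------------------------------------------------------------
# public fitting API


def fit(
    data: ResponseTensor,
    class_spec: ModelClassSpec,
    config: FitConfig,
    conditions: np.ndarray | None = None,
    freeze_C: np.ndarray | None = None,
) -> FitResult:
    """Fit one model by ADAM on the penalized reconstruction objective.

    ``conditions`` restricts training to a subset of condition ids (used by
    LOOCV); the returned parameters are orthonormalized post hoc.
    ``freeze_C`` fixes the loading map (used with the normal-dynamics
    penalty) and excludes it from the gradient updates.
    """
    grid = data.grid
    if conditions is None:
        conditions = np.arange(grid.K)
    conditions = np.asarray(conditions, dtype=int)
    Y = data.Y[:, :, conditions, :]
    if not np.all(np.isfinite(Y)):
        raise ShapeError("training data contains non-finite entries")
    problem = _Problem(grid, conditions)
    rng = np.random.default_rng(config.seed)
    th = _init_theta(class_spec, data.n_neurons, data.n_bins, problem, config.init_sd, rng)
    frozen = frozenset()
    if freeze_C is not None:
        th["C"] = np.array(freeze_C, dtype=float)
        frozen = frozenset({"C"})

    opt = _Adam(th, config.learning_rate)
    trace = np.empty(config.max_iter)
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        c, grads = _cost_and_grads(
            th, Y, class_spec, problem, config.lambda_inp, config.lambda_dyn, frozen
        )
        if not np.isfinite(c):
            raise DivergenceError(f"non-finite cost at iteration {it}")
        trace[it - 1] = c
        opt.step(th, grads)
        if it >= config.min_iter and _converged(trace, it, config.convergence_dcost):
            converged = True
            break

    params = orthonormalize(_theta_to_params(th, class_spec))
    pred = lds_core.reconstruct(params, grid)[:, :, conditions, :]
    return FitResult(
        params=params,
        class_spec=class_spec,
        train_mse=lds_core.mse(Y, pred),
        cost_trace=trace[:it].copy(),
        seed=config.seed,
        converged=converged,
        n_iter=it,
    )


def restart_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-restart seeds derived from a master seed."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def multi_restart(
    data: ResponseTensor,
    class_spec: ModelClassSpec,
    config: FitConfig,
    n_restarts: int | None = None,
    **fit_kwargs,
) -> list[FitResult]:
    """Independent seeded restarts, sorted by training MSE (best first).

    Per-restart failures are flagged on the result (``error`` set, params
    None) without aborting the batch.
    """
    n = config.n_restarts if n_restarts is None else n_restarts
    if n < 1:
        raise ConfigError("n_restarts must be >= 1")
    results: list[FitResult] = []
    for s in restart_seeds(config.seed, n):
        cfg = replace(config, seed=int(s))
        try:
            results.append(fit(data, class_spec, cfg, **fit_kwargs))
        except DivergenceError as exc:  # pragma: no cover - rare at defaults
            results.append(
                FitResult(
                    params=None, class_spec=class_spec, train_mse=np.inf,
                    cost_trace=np.empty(0), seed=int(s), converged=False,
                    n_iter=0, error=str(exc),
                )
            )
    results.sort(key=lambda r: r.train_mse)
    return results


def summarize_restarts(results: list[FitResult]) -> dict[str, float]:
    """Mean/SD/SEM of training MSE across successful restarts."""
    m = np.array([r.train_mse for r in results if r.error is None])
    return {
        "n": int(m.size),
        "mean": float(m.mean()),
        "sd": float(m.std(ddof=1)) if m.size > 1 else 0.0,
        "sem": float(m.std(ddof=1) / np.sqrt(m.size)) if m.size > 1 else 0.0,
        "best": float(m.min()),
    }


# ---------------------------------------------------------------------------
# leave-one-condition-out cross-validation


def held_out_mse(result_params: LDSParams, data: ResponseTensor, condition: int) -> float:
    """Forward-generate one condition from the fitted parameters and score it.

    Uses only the refit initial conditions and the coherence inputs shared
    with the training conditions; never the held-out observations.
    """
    pred = lds_core.reconstruct(result_params, data.grid)[:, :, condition, :]
    return lds_core.mse(data.Y[:, :, condition, :], pred)


def loocv(
    data: ResponseTensor,
    class_spec: ModelClassSpec,
    config: FitConfig,
    dims_grid: list[tuple[int, int]] | None = None,
    folds: np.ndarray | None = None,
) -> LOOCVReport:
    """Leave-one-condition-out cross-validation over a dimensionality grid.

    ``dims_grid`` lists (latent_dim, input_dim_per_modality) pairs; None
    evaluates the class at its own dimensions.  A fold removes one
    condition from both contexts; folds whose motion or color level would
    vanish from the training set are skipped with a warning.
    """
    grid = data.grid
    if folds is None:
        folds = np.arange(grid.K)
    if dims_grid is None:
        dims_grid = [(class_spec.latent_dim, class_spec.input_dim_motion)]
    points: list[LOOCVPoint] = []
    for latent, u_in in dims_grid:
        cs = replace(
            class_spec, latent_dim=latent, input_dim_motion=u_in, input_dim_color=u_in
        )
        fold_mse, used, skipped = [], [], []
        for k in folds:
            keep = np.setdiff1d(np.arange(grid.K), [k])
            if (
                grid.motion_index[k] not in grid.motion_index[keep]
                or grid.color_index[k] not in grid.color_index[keep]
            ):
                warnings.warn(f"fold {k}: coherence level unique to held-out condition; skipped")
                skipped.append(int(k))
                continue
            best = None
            for s in restart_seeds(config.seed + 17 * (int(k) + 1), config.loocv_restarts):
                r = fit(data, cs, replace(config, seed=int(s)), conditions=keep)
                if best is None or r.train_mse < best.train_mse:
                    best = r
            fold_mse.append(held_out_mse(best.params, data, int(k)))
            used.append(int(k))
        points.append(
            LOOCVPoint(
                class_name=cs.name, latent_dim=latent, input_dim=u_in,
                fold_conditions=np.array(used), fold_mse=np.array(fold_mse),
                skipped=skipped,
            )
        )
    return LOOCVReport(points=points)


# ---------------------------------------------------------------------------
# normal-dynamics penalty


def normal_penalty(A: np.ndarray) -> float:
    """Squared Frobenius norm of the commutator A A^T - A^T A.

    Zero iff A is normal (orthogonally diagonalizable); added to the cost
    with weight ``lambda_dyn`` when fitting normal-dynamics variants.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ShapeError("A must be square")
    P = A @ A.T - A.T @ A
    return float(np.sum(P**2))


# ---------------------------------------------------------------------------
# TFR fitting (gradient route, plus an alternating reference solver)


@dataclass
class TFRFitResult:
    params: tfr_core.TFRParams
    train_mse: float
    cost_trace: np.ndarray
    seed: int
    converged: bool
    n_iter: int


def _tfr_indices(grid: TaskGrid, input_dims: tuple[int, int]):
    Um, Uc = input_dims
    U = Um + Uc
    K = grid.K
    cidx = np.empty((U + 1, K), dtype=int)
    didx = np.empty((U + 1, K), dtype=int)
    m_dir = _dir_of(grid.motion_levels)
    c_dir = _dir_of(grid.color_levels)
    for i in range(Um):
        cidx[i] = tfr_core.N_COH * i + grid.motion_index
        didx[i] = tfr_core.N_DIR * i + m_dir[grid.motion_index]
    for i in range(Uc):
        u = Um + i
        cidx[u] = tfr_core.N_COH * u + grid.color_index
        didx[u] = tfr_core.N_DIR * u + c_dir[grid.color_index]
    cidx[U] = tfr_core.N_COH * U
    didx[U] = tfr_core.N_DIR * U
    return cidx, didx


def _tfr_cost_and_grads(th, Y, cidx, didx, context_dependent_core: bool):
    N, T, K, _ = Y.shape
    denom = Y.size
    C, core, R, P = th["C"], th["core"], th["R"], th["P"]
    ncore = core.shape[0]
    drive = P[cidx][:, :, None] * R[didx]  # (U+1, K, T)
    g = {k: np.zeros_like(v) for k, v in th.items()}
    gdrive = np.zeros_like(drive)
    cost = 0.0
    for cx in range(N_CONTEXTS):
        cc = core[min(cx, ncore - 1)]
        G = np.zeros((cc.shape[0], T, K))
        for lag in range(T):
            G[:, lag:, :] += np.einsum("lu,ukt->ltk", cc[:, lag, :], drive[:, :, : T - lag])
        pred = np.einsum("nl,ltk->ntk", C, G)
        resid = pred - Y[:, :, :, cx]
        cost += float(np.sum(resid**2)) / denom
        dpred = (2.0 / denom) * resid
        g["C"] += np.einsum("ntk,ltk->nl", dpred, G)
        dG = np.einsum("nl,ntk->ltk", C, dpred)
        ic = min(cx, ncore - 1)
        for lag in range(T):
            g["core"][ic][:, lag, :] += np.einsum(
                "ltk,ukt->lu", dG[:, lag:, :], drive[:, :, : T - lag]
            )
            gdrive[:, :, : T - lag] += np.einsum("lu,ltk->ukt", cc[:, lag, :], dG[:, lag:, :])
    g["P"] = np.zeros_like(P)
    np.add.at(g["P"], cidx, np.sum(gdrive * R[didx], axis=2))
    g["R"] = np.zeros_like(R)
    np.add.at(g["R"], didx.ravel(), (gdrive * P[cidx][:, :, None]).reshape(-1, T))
    return cost, g


def fit_tfr(
    data: ResponseTensor,
    latent_dim: int,
    input_dims: tuple[int, int],
    config: FitConfig,
    context_dependent_core: bool = True,
) -> TFRFitResult:
    """Fit the TFR by ADAM on the reconstruction MSE (same protocol as the
    LDS fits); the loading is orthonormalized post hoc via SVD."""
    grid = data.grid
    U = sum(input_dims)
    T = data.n_bins
    rng = np.random.default_rng(config.seed)
    sd = config.init_sd
    th = {
        "C": sd * rng.standard_normal((data.n_neurons, latent_dim)),
        "core": sd * rng.standard_normal(
            (N_CONTEXTS if context_dependent_core else 1, latent_dim, T, U + 1)
        ),
        "R": sd * rng.standard_normal((tfr_core.N_DIR * U + 1, T)),
        "P": sd * rng.standard_normal(tfr_core.N_COH * U + 1),
    }
    cidx, didx = _tfr_indices(grid, input_dims)
    opt = _Adam(th, config.learning_rate)
    trace = np.empty(config.max_iter)
    converged, it = False, 0
    for it in range(1, config.max_iter + 1):
        c, grads = _tfr_cost_and_grads(th, data.Y, cidx, didx, context_dependent_core)
        if not np.isfinite(c):
            raise DivergenceError(f"non-finite cost at iteration {it}")
        trace[it - 1] = c
        opt.step(th, grads)
        if it >= config.min_iter and _converged(trace, it, config.convergence_dcost):
            converged = True
            break

    Uu, s, Vt = np.linalg.svd(th["C"], full_matrices=False)
    Tmat = s[:, None] * Vt
    core = np.einsum("ij,cjtu->citu", Tmat, th["core"])
    params = tfr_core.TFRParams(
        loading=Uu, core=core, dir_courses=th["R"].copy(), coh_scalars=th["P"].copy(),
        input_dims=tuple(input_dims),
    )
    pred = tfr_core.tfr_predict(params, grid)
    return TFRFitResult(
        params=params, train_mse=lds_core.mse(data.Y, pred),
        cost_trace=trace[:it].copy(), seed=config.seed, converged=converged, n_iter=it,
    )


def fit_tfr_als(
    data: ResponseTensor,
    latent_dim: int,
    input_dims: tuple[int, int],
    n_outer: int = 10,
    seed: int = 0,
    ridge: float = 1e-8,
) -> TFRFitResult:
    """Alternating estimation of W = C*core (reduced-rank regression) and of
    the input factors P, R (linear least squares each).

    Reference solver for small problems, used to cross-check the gradient
    route; the core is always context dependent here.
    """
    grid = data.grid
    U = sum(input_dims)
    N, T, K, _ = data.Y.shape
    rng = np.random.default_rng(seed)
    R = rng.standard_normal((tfr_core.N_DIR * U + 1, T))
    P = rng.standard_normal(tfr_core.N_COH * U + 1)
    cidx, didx = _tfr_indices(grid, input_dims)
    C = None
    core = None
    trace = []
    for _ in range(n_outer):
        drive = P[cidx][:, :, None] * R[didx]  # (U+1, K, T)
        # design: pred[n,t,k] = sum_{lag,u} W[n,lag,u] * drive[u,k,t-lag]
        D = np.zeros((T, U + 1, T, K))  # (lag, u, t, k)
        for lag in range(T):
            D[lag, :, lag:, :] = drive.transpose(0, 2, 1)[None, :, : T - lag, :]
        Dm = D.reshape(T * (U + 1), T * K)
        gram = Dm @ Dm.T + ridge * np.eye(Dm.shape[0])
        Ws = []
        for cx in range(N_CONTEXTS):
            Ycx = data.Y[:, :, :, cx].reshape(N, T * K)
            Ws.append(np.linalg.solve(gram, Dm @ Ycx.T).T)  # (N, T*(U+1))
        Wall = np.concatenate(Ws, axis=1)
        Uu, s, Vt = np.linalg.svd(Wall, full_matrices=False)
        C = Uu[:, :latent_dim]
        core = np.stack(
            [(C.T @ W).reshape(latent_dim, T, U + 1) for W in Ws]
        )
        params = tfr_core.TFRParams(C, core, R, P, tuple(input_dims))
        trace.append(lds_core.mse(data.Y, tfr_core.tfr_predict(params, grid)))

        # P-step: prediction is linear in P given R, core, C
        Mu = _unit_scalar_basis(core, C, R, didx, T, K)  # (U+1, N, T, K, 2)
        nP = P.size
        Phi = np.zeros((nP, N * T * K * N_CONTEXTS))
        for u in range(U + 1):
            for c in np.unique(cidx[u]):
                sel = cidx[u] == c
                contrib = np.zeros((N, T, K, N_CONTEXTS))
                contrib[:, :, sel, :] = Mu[u][:, :, sel, :]
                Phi[c] += contrib.ravel()
        y = data.Y.ravel()
        P = np.linalg.lstsq(Phi.T, y, rcond=None)[0]

        # R-step: prediction is linear in R given P, core, C
        nR = R.size
        Psi = np.zeros((nR, N * T * K * N_CONTEXTS))
        for d in range(R.shape[0]):
            for tp in range(T):
                contrib = np.zeros((N, T, K, N_CONTEXTS))
                for u in range(U + 1):
                    sel = didx[u] == d
                    if not np.any(sel):
                        continue
                    w = P[cidx[u, sel]]  # (n_sel,)
                    for cx in range(N_CONTEXTS):
                        cc = core[min(cx, core.shape[0] - 1)]
                        Cc = C @ cc[:, : T - tp, u]  # (N, lags)
                        contrib[:, tp:, :, cx][:, :, sel] += (
                            Cc[:, :, None] * w[None, None, :]
                        )
                Psi[d * T + tp] = contrib.ravel()
        R = np.linalg.lstsq(Psi.T, y, rcond=None)[0].reshape(R.shape)

    params = tfr_core.TFRParams(C, core, R, P, tuple(input_dims))
    final = lds_core.mse(data.Y, tfr_core.tfr_predict(params, grid))
    trace.append(final)
    return TFRFitResult(
        params=params, train_mse=final, cost_trace=np.array(trace), seed=seed,
        converged=True, n_iter=n_outer,
    )


def _unit_scalar_basis(core, C, R, didx, T, K):
    """Per-channel prediction with the channel's scalar set to 1."""
    U1 = didx.shape[0]
    N = C.shape[0]
    out = np.zeros((U1, N, T, K, N_CONTEXTS))
    for u in range(U1):
        Ru = R[didx[u]]  # (K, T)
        for cx in range(N_CONTEXTS):
            cc = core[min(cx, core.shape[0] - 1)]
            G = np.zeros((cc.shape[0], T, K))
            for lag in range(T):
                G[:, lag:, :] += cc[:, lag, u][:, None, None] * Ru[:, : T - lag].T[None]
            out[u, :, :, :, cx] = np.einsum("nl,ltk->ntk", C, G)
    return out
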