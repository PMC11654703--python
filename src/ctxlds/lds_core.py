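"""Constrained linear dynamical system (LDS) for condition-averaged responses.

The model is the non-probabilistic state-space model

    x_k(t) = A_cx x_k(t-1) + B_cx^m u^m_k(t) + B_cx^c u^c_k(t)
    y_k(t) = C x_k(t) + d

fitted jointly to the response tensors of the two task contexts (attend-motion
and attend-color).  Which parameters may differ across contexts defines the
model class: {A,B} (fully tied), {A,Bcx} (context-dependent inputs),
{Acx,B} (context-dependent dynamics) and {Acx,Bcx}.  The initial condition
x0 is always learned per context; the loading map C (orthonormal columns
after :func:`orthonormalize`), the bias d, the input time courses and the
coherence scalars are always shared.

Inputs follow the task structure: per input dimension there is one time
course per evidence direction (toward / away from the response field) and
six learned coherence scalars, so the drive for a condition with signed
coherence level j is ``u_i(t) = course[i, dir(j), t] * scalar[i, j]``.
Conditions that share a coherence level share its input trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, DegenerateLoadingError, ShapeError, SimulationOverflowError
from .task_grid import TaskGrid

N_CONTEXTS = 2
N_COH_LEVELS = 6


# ---------------------------------------------------------------------------
# model classes


@dataclass(frozen=True)
class ModelClassSpec:
    """Which parameter blocks are context dependent, and the dimensionalities.

    The four (dynamics, inputs) context-dependence combinations are exactly
    the model classes {A,B}, {A,Bcx}, {Acx,B}, {Acx,Bcx}.
    """

    dynamics_context_dependent: bool
    inputs_context_dependent: bool
    latent_dim: int
    input_dim_motion: int
    input_dim_color: int
    inputs_time_varying: bool = True

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ShapeError("latent_dim must be >= 1")
        if self.input_dim_motion < 0 or self.input_dim_color < 0:
            raise ShapeError("input dimensions must be >= 0")

    @property
    def name(self) -> str:
        a = "Acx" if self.dynamics_context_dependent else "A"
        b = "Bcx" if self.inputs_context_dependent else "B"
        return "{%s,%s}" % (a, b)

    @property
    def n_dynamics(self) -> int:
        return N_CONTEXTS if self.dynamics_context_dependent else 1

    @property
    def n_input_maps(self) -> int:
        return N_CONTEXTS if self.inputs_context_dependent else 1


# ---------------------------------------------------------------------------
# inputs


@dataclass
class InputModel:
    """Learned external input signals.

    ``courses_*`` have shape (input_dim, 2, T): one time course per evidence
    direction (index 0: negative/away, index 1: positive/toward), shared by
    the three coherence strengths of that direction.  ``scalars_*`` have
    shape (input_dim, 6): one learned signed scalar per coherence level, in
    the task grid's ascending level order.  When ``time_varying`` is False
    the courses are fixed to 1 and are not free parameters.
    """

    courses_motion: np.ndarray
    courses_color: np.ndarray
    scalars_motion: np.ndarray
    scalars_color: np.ndarray
    time_varying: bool = True

    def __post_init__(self) -> None:
        for c, s, nm in (
            (self.courses_motion, self.scalars_motion, "motion"),
            (self.courses_color, self.scalars_color, "color"),
        ):
            if c.ndim != 3 or c.shape[1] != 2:
                raise ShapeError(f"{nm} courses must have shape (dim, 2, T)")
            if s.ndim != 2 or s.shape[0] != c.shape[0]:
                raise ShapeError(f"{nm} scalars must have shape (dim, n_levels)")
        if not self.time_varying:
            if not (np.all(self.courses_motion == 1.0) and np.all(self.courses_color == 1.0)):
                raise ShapeError("time_varying=False requires unit courses")

    @property
    def n_bins(self) -> int:
        return self.courses_motion.shape[2]

    def series(self, modality: str, level_index: int, grid: TaskGrid) -> np.ndarray:
        """Input coordinates u(t), shape (input_dim, T), for one signed level."""
        if modality == "motion":
            courses, scalars = self.courses_motion, self.scalars_motion
            levels = grid.motion_levels
        elif modality == "color":
            courses, scalars = self.courses_color, self.scalars_color
            levels = grid.color_levels
        else:
            raise ValueError(f"unknown modality {modality!r}")
        d = 1 if levels[level_index] > 0 else 0
        return courses[:, d, :] * scalars[:, level_index][:, None]

    def level_series(self, modality: str, grid: TaskGrid) -> np.ndarray:
        """All level traces stacked, shape (n_levels, input_dim, T)."""
        n_levels = len(grid.motion_levels if modality == "motion" else grid.color_levels)
        return np.stack(
            [self.series(modality, j, grid) for j in range(n_levels)], axis=0
        )


def constant_courses(input_dim: int, n_bins: int) -> np.ndarray:
    return np.ones((input_dim, 2, n_bins))


# ---------------------------------------------------------------------------
# parameters


@dataclass
class LDSParams:
    """Full parameter set Theta = (A, B_mot, B_col, x0, C_load, d, inputs).

    Context-shared blocks are stored once: ``A`` has leading dimension 1 when
    shared and 2 when context dependent (likewise ``B_*``); ``x0`` is always
    (2, L).  Use :meth:`A_ctx` / :meth:`B_mot_ctx` / :meth:`B_col_ctx` to
    resolve the block for a given context.
    """

    class_spec: ModelClassSpec
    A: np.ndarray  # (nA, L, L)
    B_mot: np.ndarray  # (nB, L, Um)
    B_col: np.ndarray  # (nB, L, Uc)
    x0: np.ndarray  # (2, L)
    C_load: np.ndarray  # (N, L)
    d: np.ndarray  # (N,)
    inputs: InputModel
    is_orthonormalized: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        cs = self.class_spec
        L = cs.latent_dim
        if self.A.shape != (cs.n_dynamics, L, L):
            raise ShapeError(f"A has shape {self.A.shape}, expected ({cs.n_dynamics},{L},{L})")
        if self.B_mot.shape != (cs.n_input_maps, L, cs.input_dim_motion):
            raise ShapeError("B_mot shape inconsistent with class spec")
        if self.B_col.shape != (cs.n_input_maps, L, cs.input_dim_color):
            raise ShapeError("B_col shape inconsistent with class spec")
        if self.x0.shape != (N_CONTEXTS, L):
            raise ShapeError("x0 must have shape (2, L)")
        if self.C_load.ndim != 2 or self.C_load.shape[1] != L:
            raise ShapeError("C_load must have shape (N, L)")
        if self.d.shape != (self.C_load.shape[0],):
            raise ShapeError("d must have shape (N,)")
        if self.inputs.courses_motion.shape[0] != cs.input_dim_motion:
            raise ShapeError("inputs.courses_motion inconsistent with class spec")
        if self.inputs.courses_color.shape[0] != cs.input_dim_color:
            raise ShapeError("inputs.courses_color inconsistent with class spec")
        if self.inputs.time_varying != cs.inputs_time_varying:
            raise ShapeError("inputs.time_varying inconsistent with class spec")

    @property
    def n_neurons(self) -> int:
        return self.C_load.shape[0]

    @property
    def latent_dim(self) -> int:
        return self.class_spec.latent_dim

    def A_ctx(self, cx: int) -> np.ndarray:
        return self.A[min(cx, self.A.shape[0] - 1)]

    def B_mot_ctx(self, cx: int) -> np.ndarray:
        return self.B_mot[min(cx, self.B_mot.shape[0] - 1)]

    def B_col_ctx(self, cx: int) -> np.ndarray:
        return self.B_col[min(cx, self.B_col.shape[0] - 1)]

    def copy(self) -> "LDSParams":
        return replace(
            self,
            A=self.A.copy(),
            B_mot=self.B_mot.copy(),
            B_col=self.B_col.copy(),
            x0=self.x0.copy(),
            C_load=self.C_load.copy(),
            d=self.d.copy(),
            inputs=InputModel(
                self.inputs.courses_motion.copy(),
                self.inputs.courses_color.copy(),
                self.inputs.scalars_motion.copy(),
                self.inputs.scalars_color.copy(),
                self.inputs.time_varying,
            ),
        )


# ---------------------------------------------------------------------------
# forward computations


def condition_drive(params: LDSParams, grid: TaskGrid, context: int) -> np.ndarray:
    """Combined latent input vectors B*u(t) for every condition.

    Returns shape (L, T, K) where entry [:, t-1, k] is
    ``B^m_cx u^m_k(t) + B^c_cx u^c_k(t)`` (time steps t = 1..T).
    """
    T = params.inputs.n_bins
    lev_m = params.inputs.level_series("motion", grid)  # (6, Um, T)
    lev_c = params.inputs.level_series("color", grid)
    um = lev_m[grid.motion_index]  # (K, Um, T)
    uc = lev_c[grid.color_index]
    Bm, Bc = params.B_mot_ctx(context), params.B_col_ctx(context)
    drive = np.einsum("lu,kut->ltk", Bm, um) + np.einsum("lu,kut->ltk", Bc, uc)
    assert drive.shape == (params.latent_dim, T, grid.K)
    return drive


def simulate_latents(
    params: LDSParams, grid: TaskGrid, condition: int, context: int
) -> np.ndarray:
    """Latent trajectory x(0..T) for one condition/context, shape (T+1, L).

    x(0) = x0[context]; x(t) = A_cx x(t-1) + B_cx u(t).  Pure function of the
    parameters: the deterministic unrolling of the model's state equation.
    """
    if not 0 <= condition < grid.K:
        raise ShapeError(f"condition {condition} outside grid with K={grid.K}")
    X = _simulate_all(params, grid, context)
    return X[:, :, condition].T


def _simulate_from_drive(A: np.ndarray, x0: np.ndarray, drive: np.ndarray) -> np.ndarray:
    """Roll the state equation forward.  drive: (L, T, K) -> X: (L, T+1, K)."""
    L, T, K = drive.shape
    X = np.empty((L, T + 1, K))
    X[:, 0, :] = x0[:, None]
    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(1, T + 1):
            X[:, t, :] = A @ X[:, t - 1, :] + drive[:, t - 1, :]
    if not np.all(np.isfinite(X)):
        norms = np.abs(np.linalg.eigvals(A))
        raise SimulationOverflowError(
            f"non-finite latents; largest |eigenvalue| of A is {norms.max():.4g}"
        )
    return X


def _simulate_all(params: LDSParams, grid: TaskGrid, context: int) -> np.ndarray:
    drive = condition_drive(params, grid, context)
    return _simulate_from_drive(params.A_ctx(context), params.x0[context], drive)


def latents(params: LDSParams, grid: TaskGrid) -> np.ndarray:
    """Latent trajectories for all conditions/contexts, shape (L, T+1, K, 2)."""
    return np.stack(
        [_simulate_all(params, grid, cx) for cx in range(N_CONTEXTS)], axis=-1
    )


def reconstruct(params: LDSParams, grid: TaskGrid) -> np.ndarray:
    """Predicted response tensor (raw scale), shape (N, T, K, 2).

    y_k(t) = C x_k(t) + d for t = 1..T; x(0) is not observed.
    """
    X = latents(params, grid)[:, 1:, :, :]
    Y = np.einsum("nl,ltkc->ntkc", params.C_load, X) + params.d[:, None, None, None]
    return Y


def mse(data: np.ndarray, pred: np.ndarray) -> float:
    """Mean squared error per tensor entry.

    Averages ||y - yhat||^2 over neurons, time bins, conditions and contexts.
    On z-scored data this is the fraction of unexplained variance.
    """
    data = np.asarray(data, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if data.shape != pred.shape:
        raise ShapeError(f"shape mismatch: data {data.shape} vs prediction {pred.shape}")
    return float(np.mean((data - pred) ** 2))


def input_penalty(params: LDSParams, grid: TaskGrid) -> float:
    """Sum over (t, k, cx) of ||B_cx u_{t,k,cx}||^2 (the learned-input norm)."""
    total = 0.0
    for cx in range(N_CONTEXTS):
        drive = condition_drive(params, grid, cx)
        total += float(np.sum(drive**2))
    return total


def cost(params: LDSParams, data: np.ndarray, grid: TaskGrid, lambda_inp: float) -> float:
    """Objective: reconstruction MSE plus the input-norm penalty.

    ``lambda_inp`` (default 1e-5 in fitting) discourages explaining
    integration signals with large inputs rather than with the dynamics.
    """
    if lambda_inp < 0:
        raise ConfigError("lambda_inp must be >= 0")
    return mse(data, reconstruct(params, grid)) + lambda_inp * input_penalty(params, grid)


# ---------------------------------------------------------------------------
# orthonormalization


def orthonormalize(params: LDSParams) -> LDSParams:
    """Similarity-transform the parameters so C has orthonormal columns.

    With C = U S V^T and T = S V^T, returns
    Theta~ = (T A T^-1, T B, T x0, C T^-1 = U, d, u).  The predicted
    observations and the eigenvalues of A are invariant (similarity), so all
    downstream dynamics analyses can be read in an isometric latent basis.
    """
    C = params.C_load
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    if s[-1] <= s[0] * 1e-12 or s[0] == 0.0:
        raise DegenerateLoadingError("C_load is (numerically) rank deficient")
    T = s[:, None] * Vt
    Tinv = Vt.T / s[None, :]
    out = params.copy()
    out.A = np.stack([T @ a @ Tinv for a in params.A])
    out.B_mot = np.stack([T @ b for b in params.B_mot])
    out.B_col = np.stack([T @ b for b in params.B_col])
    out.x0 = params.x0 @ T.T
    out.C_load = U
    out.is_orthonormalized = True
    return out


# ---------------------------------------------------------------------------
# bookkeeping


def count_parameters(
    class_spec: ModelClassSpec, n_neurons: int, n_bins: int, n_levels: int = N_COH_LEVELS
) -> int:
    """Exact number of learnable scalars for a model class.

    Per block: A contributes L^2 (shared) or 2 L^2; each B contributes
    L*U (shared) or 2 L*U; C contributes N*L; d contributes N; x0 contributes
    2L.  Each input dimension contributes 2T time-course values when courses
    are time varying (none otherwise) plus its 6 coherence scalars (one per
    signed level of the standard grid).
    """
    L = class_spec.latent_dim
    U_in = class_spec.input_dim_motion + class_spec.input_dim_color
    n = class_spec.n_dynamics * L * L
    n += class_spec.n_input_maps * L * U_in
    n += n_neurons * L  # loading
    n += n_neurons  # bias
    n += N_CONTEXTS * L  # initial conditions
    per_dim = (2 * n_bins if class_spec.inputs_time_varying else 0) + n_levels
    n += U_in * per_dim
    return n


def count_parameters_from_instance(params: LDSParams) -> int:
    """Brute-force flatten-and-count of an instantiated parameter container."""
    n = params.A.size + params.B_mot.size + params.B_col.size
    n += params.x0.size + params.C_load.size + params.d.size
    if params.inputs.time_varying:
        n += params.inputs.courses_motion.size + params.inputs.courses_color.size
    n += params.inputs.scalars_motion.size + params.inputs.scalars_color.size
    return n


def data_point_count(n_neurons: int, n_bins: int, n_conditions: int) -> int:
    """Number of fitted data points N*T*K*(number of contexts)."""
    return n_neurons * n_bins * n_conditions * N_CONTEXTS
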