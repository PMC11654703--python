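"""Tensor factor regression (TFR): a low-rank factorization that nests the LDS.

The response tensor is approximated by the multilinear contraction

    Y[n,t,k] ~= C[n,l] * core[l,t'',u] * T_ind[t,t',t''] * Q_ind[u,k,c,d]
                * P[c] * R_dir[d,t']

per context.  ``C`` is an orthonormal loading map; the per-context core
tensor plays the role of the lag-indexed maps A^{t''} B of an LDS but each
lag entry is free; ``T_ind`` is the fixed causal-convolution indicator
(nonzero iff t - t' = t'' with t >= t'); ``Q_ind`` routes each condition to
its motion coherence cell, color coherence cell and the shared baseline
cell; ``P`` holds the coherence scalars (6 per real input dimension plus
one baseline) and ``R_dir`` the direction time courses (2 per input
dimension plus one baseline).  Because the core's lag structure is free,
the TFR sets an upper bound on the goodness of fit achievable by any LDS
of the same rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ShapeError
from .lds_core import N_CONTEXTS
from .task_grid import TaskGrid

N_COH = 6  # coherence cells per input dimension
N_DIR = 2  # direction courses per input dimension


@dataclass
class TFRParams:
    """Learnable TFR factors (indicator tensors are rebuilt, never stored).

    Shapes, with l latents, U real input dimensions, T bins, N neurons:
    ``loading`` (N, l); ``core`` (n_core_contexts, l, T, U+1) — last channel
    is the baseline; ``dir_courses`` (2U+1, T); ``coh_scalars`` (6U+1,).
    The baseline channel uses the last direction-course row and the last
    scalar, shared by every condition (it carries condition-independent
    structure).
    """

    loading: np.ndarray
    core: np.ndarray
    dir_courses: np.ndarray
    coh_scalars: np.ndarray
    input_dims: tuple[int, int]  # (motion, color)

    def __post_init__(self) -> None:
        U = sum(self.input_dims)
        ncx, l, T, nchan = self.core.shape
        if ncx not in (1, N_CONTEXTS):
            raise ShapeError("core leading dim must be 1 (shared) or 2 (per context)")
        if nchan != U + 1:
            raise ShapeError(f"core must have {U + 1} channels (inputs + baseline)")
        if self.loading.ndim != 2 or self.loading.shape[1] != l:
            raise ShapeError("loading must have shape (N, l)")
        if self.dir_courses.shape != (N_DIR * U + 1, T):
            raise ShapeError(f"dir_courses must have shape ({N_DIR * U + 1}, {T})")
        if self.coh_scalars.shape != (N_COH * U + 1,):
            raise ShapeError(f"coh_scalars must have shape ({N_COH * U + 1},)")

    @property
    def n_bins(self) -> int:
        return self.core.shape[2]

    @property
    def latent_dim(self) -> int:
        return self.core.shape[1]

    def core_ctx(self, cx: int) -> np.ndarray:
        return self.core[min(cx, self.core.shape[0] - 1)]


# ---------------------------------------------------------------------------
# indicator tensors


def build_indicators(n_bins: int, grid: TaskGrid, input_dims: tuple[int, int]):
    """Fixed routing tensors (data independent).

    ``T_ind`` has shape (T, T, T) over (t, t', lag t''), 1 iff t - t' = t''
    with t >= t' (1-based observation times, 0-based lags): the causal
    convolution layout.  ``Q_ind`` has shape (U+1, K, 6U+1, 2U+1) and, for
    channel u and condition k, selects the coherence-scalar cell c and
    direction-course row d that drive that channel: motion/color channels
    point at their dimension's cell for k's coherence level and direction;
    the baseline channel points at the shared last cells for every k.
    """
    T = n_bins
    T_ind = np.zeros((T, T, T))
    for t in range(1, T + 1):
        for tp in range(1, t + 1):
            T_ind[t - 1, tp - 1, t - tp] = 1.0

    Um, Uc = input_dims
    U = Um + Uc
    K = grid.K
    Q_ind = np.zeros((U + 1, K, N_COH * U + 1, N_DIR * U + 1))
    m_idx, c_idx = grid.motion_index, grid.color_index
    m_lvls = np.asarray(grid.motion_levels)
    c_lvls = np.asarray(grid.color_levels)
    for k in range(K):
        jm, jc = m_idx[k], c_idx[k]
        dm = 1 if m_lvls[jm] > 0 else 0
        dc = 1 if c_lvls[jc] > 0 else 0
        for i in range(Um):
            Q_ind[i, k, N_COH * i + jm, N_DIR * i + dm] = 1.0
        for i in range(Uc):
            u = Um + i
            Q_ind[u, k, N_COH * u + jc, N_DIR * u + dc] = 1.0
        Q_ind[U, k, N_COH * U, N_DIR * U] = 1.0  # baseline cell
    return T_ind, Q_ind


def channel_drive(params: TFRParams, grid: TaskGrid) -> np.ndarray:
    """Per-channel drive P[c(u,k)] * R[d(u,k), t'], shape (U+1, K, T).

    Equivalent to contracting Q_ind with P and R, computed by direct
    indexing for speed.
    """
    Um, Uc = params.input_dims
    U = Um + Uc
    K, T = grid.K, params.n_bins
    drive = np.empty((U + 1, K, T))
    m_idx, c_idx = grid.motion_index, grid.color_index
    m_dir = (np.asarray(grid.motion_levels) > 0).astype(int)
    c_dir = (np.asarray(grid.color_levels) > 0).astype(int)
    P, R = params.coh_scalars, params.dir_courses
    for i in range(Um):
        drive[i] = P[N_COH * i + m_idx][:, None] * R[N_DIR * i + m_dir[m_idx]]
    for i in range(Uc):
        u = Um + i
        drive[u] = P[N_COH * u + c_idx][:, None] * R[N_DIR * u + c_dir[c_idx]]
    drive[U] = P[N_COH * U] * R[N_DIR * U][None, :]
    return drive


# ---------------------------------------------------------------------------
# prediction


def _latent_course(core_cx: np.ndarray, drive: np.ndarray) -> np.ndarray:
    """Causal convolution of the core with the drive: (l, T, K).

    G[l,t,k] = sum_{t'<=t} core[l, t-t', u] * drive[u, k, t'].
    """
    l, T, nchan = core_cx.shape
    K = drive.shape[1]
    G = np.zeros((l, T, K))
    for lag in range(T):
        # contribution of lag t''=lag couples drive at t' with output at t'+lag
        # core[:, lag, :] @ drive[:, :, t'] accumulated into G[:, t'+lag, :]
        contrib = np.einsum("lu,ukt->ltk", core_cx[:, lag, :], drive[:, :, : T - lag])
        G[:, lag:, :] += contrib
    return G


def tfr_predict(params: TFRParams, grid: TaskGrid) -> np.ndarray:
    """Full multilinear prediction, shape (N, T, K, 2); linear in each factor."""
    drive = channel_drive(params, grid)
    out = []
    for cx in range(N_CONTEXTS):
        G = _latent_course(params.core_ctx(cx), drive)
        out.append(np.einsum("nl,ltk->ntk", params.loading, G))
    return np.stack(out, axis=-1)


def tfr_predict_dense(params: TFRParams, grid: TaskGrid) -> np.ndarray:
    """Same prediction via explicit contraction with the indicator tensors.

    Slower reference path used for validation: contracts
    C * core * T_ind * Q_ind * P * R with einsum.
    """
    T_ind, Q_ind = build_indicators(params.n_bins, grid, params.input_dims)
    out = []
    for cx in range(N_CONTEXTS):
        Y = np.einsum(
            "nl,lsu,tps,ukcd,c,dp->ntk",
            params.loading,
            params.core_ctx(cx),
            T_ind,
            Q_ind,
            params.coh_scalars,
            params.dir_courses,
            optimize=True,
        )
        out.append(Y)
    return np.stack(out, axis=-1)


# ---------------------------------------------------------------------------
# LDS nesting


def lds_to_core(A: np.ndarray, B: np.ndarray, x0: np.ndarray, n_bins: int) -> np.ndarray:
    """Core tensor realizing an LDS exactly: core[:, t'', u] = (A^{t''} B)[:, u].

    The appended baseline channel carries the homogeneous term A^t x0
    (paired with a delta-at-first-bin baseline course, see
    :func:`lds_to_tfr`), so the TFR prediction with this core matches the
    LDS latent trajectory contribution C x(t) for every condition.
    """
    L, U = B.shape
    core = np.empty((L, n_bins, U + 1))
    Apow_B = B.copy()
    Apow_x0 = A @ x0
    for lag in range(n_bins):
        core[:, lag, :U] = Apow_B
        core[:, lag, U] = Apow_x0
        Apow_B = A @ Apow_B
        Apow_x0 = A @ Apow_x0
    return core


def lds_to_tfr(params, grid: TaskGrid) -> TFRParams:
    """Embed an LDS parameter set in the TFR parameterization exactly.

    Requires the LDS input structure (courses/scalars) shared across
    dimensions of a modality in the grid's level order, which is how
    :class:`~ctxlds.lds_core.InputModel` stores them.  The per-neuron bias d
    is not representable in the TFR (which has no bias term) and is ignored;
    callers comparing predictions should add it back on the TFR side.
    """
    from .lds_core import LDSParams  # local import to avoid cycle at import time

    assert isinstance(params, LDSParams)
    cs = params.class_spec
    Um, Uc = cs.input_dim_motion, cs.input_dim_color
    U = Um + Uc
    T = params.inputs.n_bins
    if len(grid.motion_levels) != N_COH or len(grid.color_levels) != N_COH:
        raise ShapeError("lds_to_tfr requires the 6-level coherence grid")

    cores = []
    for cx in range(N_CONTEXTS):
        B = np.concatenate([params.B_mot_ctx(cx), params.B_col_ctx(cx)], axis=1)
        cores.append(lds_to_core(params.A_ctx(cx), B, params.x0[cx], T))
    ncx = 1 if (cores[0] == cores[1]).all() else N_CONTEXTS
    core = np.stack(cores[:ncx])

    dir_courses = np.zeros((N_DIR * U + 1, T))
    coh_scalars = np.zeros(N_COH * U + 1)
    for i in range(Um):
        dir_courses[N_DIR * i : N_DIR * i + 2] = params.inputs.courses_motion[i]
        coh_scalars[N_COH * i : N_COH * i + 6] = params.inputs.scalars_motion[i]
    for i in range(Uc):
        u = Um + i
        dir_courses[N_DIR * u : N_DIR * u + 2] = params.inputs.courses_color[i]
        coh_scalars[N_COH * u : N_COH * u + 6] = params.inputs.scalars_color[i]
    dir_courses[N_DIR * U, 0] = 1.0  # baseline: delta at the first bin
    coh_scalars[N_COH * U] = 1.0
    return TFRParams(
        loading=params.C_load.copy(),
        core=core,
        dir_courses=dir_courses,
        coh_scalars=coh_scalars,
        input_dims=(Um, Uc),
    )


# ---------------------------------------------------------------------------
# bookkeeping


def count_parameters_tfr(
    latent: int,
    input_dims: tuple[int, int] | int,
    n_neurons: int,
    n_bins: int,
    context_dependent_core: bool = True,
) -> int:
    """Exact learnable-scalar count for the TFR model.

    loading N*l + core (2 if context dependent, else 1)*l*T*(U+1)
    + direction courses (2U+1)*T + coherence scalars 6U+1, with U the real
    input dimensionality (baseline channel counted once in the core).
    """
    U = sum(input_dims) if isinstance(input_dims, tuple) else int(input_dims)
    n = n_neurons * latent
    n += (N_CONTEXTS if context_dependent_core else 1) * latent * n_bins * (U + 1)
    n += (N_DIR * U + 1) * n_bins
    n += N_COH * U + 1
    return n
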