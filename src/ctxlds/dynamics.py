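"""Post-fit characterization of linear dynamics.

Eigenmode decomposition A = R Lam L (L = R^-1), decay time constants and
rotation frequencies in physical units (50-ms bins -> 20 Hz sampling),
Henrici's departure from normality, input loads (non-normalized projections
of the input vectors onto left eigenvectors), impulse responses, the
observability Gramian and most-amplifying modes, condition-dependent /
condition-independent (CD/CI) decomposition, mode alignments and the
coherence-demixing plane.

All scalar summaries are similarity invariant, so they can be read in the
orthonormalized latent basis without loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import DegeneratePlaneError, ShapeError, StabilityError
from .lds_core import LDSParams, N_CONTEXTS
from .synthetic_task import ResponseTensor
from .task_grid import TaskGrid

BIN_MS = 50.0
BIN_HZ = 20.0
SLOW_NORM = 0.8  # |lambda| above this -> slow mode (tau > 224 ms)

#: rotation-frequency histogram edges (Hz) used for mode categorization
FREQ_BIN_EDGES = (0.25, 1.0)


# ---------------------------------------------------------------------------
# eigenmodes


@dataclass
class EigenModeSet:
    """Eigenmodes of a dynamics matrix, ordered by descending |lambda|.

    ``R`` holds unit-norm right eigenvectors in columns; ``L = R^-1`` holds
    the (non-normalized) left eigenvectors in rows, so L R = I and the mode
    decomposition Sum_l r_l l_l^T resolves the identity.  ``pair_id`` is -1
    for real modes and a shared nonnegative id for the two members of a
    complex-conjugate pair.  ``tau_ms`` is the decay time constant and
    ``freq_hz`` the rotation frequency (identical within a pair).
    """

    eigvals: np.ndarray
    R: np.ndarray
    L: np.ndarray
    pair_id: np.ndarray
    tau_ms: np.ndarray
    freq_hz: np.ndarray
    slow: np.ndarray
    cond_R: float

    @property
    def n_modes(self) -> int:
        return self.eigvals.size

    def group_indices(self) -> list[np.ndarray]:
        """Indices grouped so each conjugate pair appears once."""
        seen: set[int] = set()
        groups: list[np.ndarray] = []
        for i in range(self.n_modes):
            if i in seen:
                continue
            if self.pair_id[i] >= 0:
                j = [j for j in range(self.n_modes) if self.pair_id[j] == self.pair_id[i]]
                seen.update(j)
                groups.append(np.array(j))
            else:
                seen.add(i)
                groups.append(np.array([i]))
        return groups


def time_constant(eig_norm: float, bin_ms: float = BIN_MS) -> float:
    """Decay time constant tau = bin / (-ln |lambda|) in ms.

    The time at which a state along the mode has decayed to 1/e (37%).
    |lambda| = 1 returns +inf (an integration mode); |lambda| > 1 returns
    the negative growth constant (flagging expansion).
    """
    if eig_norm <= 0:
        raise ValueError("eigenvalue norm must be positive")
    if eig_norm == 1.0:
        return np.inf
    return bin_ms / (-np.log(eig_norm))


def rotation_frequency(lam: complex, bin_hz: float = BIN_HZ) -> float:
    """Rotation frequency f = bin_hz * omega / (2*pi) in Hz.

    omega is the nonnegative phase of the eigenvalue (the positive-imaginary
    member of a conjugate pair).  Real positive eigenvalues rotate at 0 Hz;
    real negative eigenvalues alternate sign every bin, i.e. rotate at the
    Nyquist frequency bin_hz/2.
    """
    lam = complex(lam)
    if lam == 0:
        raise ValueError("rotation frequency undefined for a zero eigenvalue")
    omega = abs(np.arctan2(lam.imag, lam.real))
    return bin_hz * omega / (2.0 * np.pi)


def eigenmodes(
    A: np.ndarray, bin_ms: float = BIN_MS, cond_warn: float = 1e8
) -> EigenModeSet:
    """Full eigenmode set of a dynamics matrix.

    Ordering is deterministic: descending |lambda|, ties broken by
    descending rotation frequency, then by the sign of the imaginary part
    (positive first).  Warns when the eigenvector matrix is ill conditioned
    (near-defective A).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ShapeError("A must be square")
    w, V = np.linalg.eig(A)
    V = V / np.linalg.norm(V, axis=0, keepdims=True)
    freqs = np.array([rotation_frequency(l) if l != 0 else 0.0 for l in w])
    order = np.lexsort((-np.sign(w.imag), -freqs, -np.abs(w)))
    w, V, freqs = w[order], V[:, order], freqs[order]
    cond = float(np.linalg.cond(V))
    if cond > cond_warn:
        warnings.warn(
            f"eigenvector matrix condition number {cond:.3g}: A is near defective"
        )
    L = np.linalg.inv(V)

    pair_id = np.full(w.size, -1, dtype=int)
    next_id = 0
    for i in range(w.size):
        if pair_id[i] >= 0 or abs(w[i].imag) < 1e-12:
            continue
        for j in range(i + 1, w.size):
            if pair_id[j] < 0 and abs(w[j] - np.conj(w[i])) < 1e-8 * max(1.0, abs(w[i])):
                pair_id[i] = pair_id[j] = next_id
                next_id += 1
                break

    norms = np.abs(w)
    taus = np.array([time_constant(n, bin_ms) if n > 0 else 0.0 for n in norms])
    return EigenModeSet(
        eigvals=w, R=V, L=L, pair_id=pair_id, tau_ms=taus, freq_hz=freqs,
        slow=norms > SLOW_NORM, cond_R=cond,
    )


def henrici_index(A: np.ndarray) -> float:
    """Henrici's departure from normality, normalized to [0, 1].

    sqrt(||A||_F^2 - sum |lambda_i|^2) / ||A||_F; 0 iff A is normal.  The
    radicand is a difference of equal-magnitude sums, so roundoff of order
    machine epsilon survives the square root as ~1e-8: relative radicands
    below 1e-12 are floored to exactly 0.
    """
    A = np.asarray(A, dtype=float)
    fro2 = float(np.sum(A**2))
    if fro2 == 0.0:
        raise ValueError("Henrici index undefined for the zero matrix")
    w = np.linalg.eigvals(A)
    val = (fro2 - float(np.sum(np.abs(w) ** 2))) / fro2
    if val < 1e-12:
        return 0.0
    return float(np.sqrt(min(val, 1.0)))


def freq_category(freq_hz: float) -> str:
    """Histogram bin of a rotation frequency: '<0.25', '0.25-1' or '>1' Hz."""
    lo, hi = FREQ_BIN_EDGES
    if freq_hz < lo:
        return "<0.25"
    return "0.25-1" if freq_hz <= hi else ">1"


# ---------------------------------------------------------------------------
# input loads


def input_loads(modes: EigenModeSet, bu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-mode input loads for a drive time series B*u(t).

    ``bu``: (L, T) in the same latent basis as the modes.  Returns
    (loads, contributions): ``loads`` has shape (n_modes, T) with conjugate
    pairs sharing one value, 2*||Re{l^T Bu} Re{r} - Im{l^T Bu} Im{r}|| for
    pairs and |l^T Bu| for real modes; ``contributions`` has shape
    (n_groups, L, T) and sums exactly to B*u(t) (each pair counted once).
    """
    bu = np.asarray(bu, dtype=float)
    if bu.ndim != 2 or bu.shape[0] != modes.n_modes:
        raise ShapeError("bu must have shape (latent_dim, T) in the modes' basis")
    alpha = modes.L @ bu  # (L, T) complex: l_l^T Bu(t)
    groups = modes.group_indices()
    loads = np.zeros((modes.n_modes, bu.shape[1]))
    contribs = np.zeros((len(groups), modes.n_modes, bu.shape[1]))
    for gi, g in enumerate(groups):
        i = g[0]
        r = modes.R[:, i]
        if g.size == 1:
            contrib = np.real(np.outer(r, alpha[i]))
            loads[i] = np.abs(np.real(alpha[i])) * np.linalg.norm(np.real(r))
        else:
            vec = (
                np.real(alpha[i])[None, :] * np.real(r)[:, None]
                - np.imag(alpha[i])[None, :] * np.imag(r)[:, None]
            )
            contrib = 2.0 * vec
            loads[g] = 2.0 * np.linalg.norm(vec, axis=0)
        contribs[gi] = contrib
    return loads, contribs


def model_input_loads(
    params: LDSParams,
    grid: TaskGrid,
    modality: str = "motion",
    level_index: int | None = None,
    context: int = 0,
    time_slice: slice = slice(None),
) -> np.ndarray:
    """Time-averaged coherence input loads of a fitted model.

    Uses the modality's drive B*u(t) for one coherence level (default the
    strongest positive level) in the requested context, and averages the
    per-mode load trace over the trial (window configurable via
    ``time_slice``).  Returns one value per mode of that context's dynamics
    matrix.
    """
    modes = eigenmodes(params.A_ctx(context))
    lev = params.inputs.level_series(modality, grid)
    if level_index is None:
        level_index = lev.shape[0] - 1  # strongest positive coherence
    B = params.B_mot_ctx(context) if modality == "motion" else params.B_col_ctx(context)
    bu = B @ lev[level_index]  # (L, T)
    loads, _ = input_loads(modes, bu)
    return loads[:, time_slice].mean(axis=1)


# ---------------------------------------------------------------------------
# impulse responses and Gramians


def impulse_response(A: np.ndarray, directions: np.ndarray, horizon: int) -> np.ndarray:
    """State-norm traces ||x(t)||, x(0) = v, x(t) = A x(t-1).

    ``directions``: (m, L) unit vectors; returns (m, horizon+1) traces.
    """
    A = np.asarray(A, dtype=float)
    V = np.atleast_2d(np.asarray(directions, dtype=float))
    norms = np.linalg.norm(V, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-8):
        raise ShapeError("perturbation directions must be unit norm")
    out = np.empty((V.shape[0], horizon + 1))
    X = V.T.copy()
    for t in range(horizon + 1):
        out[:, t] = np.linalg.norm(X, axis=0)
        X = A @ X
    return out


def random_directions(latent_dim: int, n: int, seed: int = 0) -> np.ndarray:
    """Uniform random unit vectors on the sphere, shape (n, L)."""
    rng = np.random.default_rng(seed)
    V = rng.standard_normal((n, latent_dim))
    return V / np.linalg.norm(V, axis=1, keepdims=True)


@dataclass
class GramianResult:
    Q: np.ndarray
    eigvals: np.ndarray  # descending
    eigvecs: np.ndarray  # columns, most amplifying first
    residual: float


def observability_gramian(A: np.ndarray, C_load: np.ndarray) -> GramianResult:
    """Observability Gramian: solve A^T Q A - Q + C^T C = 0.

    Requires spectral radius < 1 (only stable systems have a finite
    Gramian).  The eigenvectors with the largest eigenvalues of Q are the
    most-amplifying state directions for the readout.
    """
    A = np.asarray(A, dtype=float)
    C = np.asarray(C_load, dtype=float)
    rho = float(np.max(np.abs(np.linalg.eigvals(A))))
    if rho >= 1.0:
        raise StabilityError(f"unstable dynamics: max |eigenvalue| = {rho:.4f} >= 1")
    Q = scipy.linalg.solve_discrete_lyapunov(A.T, C.T @ C)
    Q = 0.5 * (Q + Q.T)
    residual = float(np.linalg.norm(A.T @ Q @ A - Q + C.T @ C, "fro"))
    w, V = np.linalg.eigh(Q)
    order = np.argsort(w)[::-1]
    return GramianResult(Q=Q, eigvals=w[order], eigvecs=V[:, order], residual=residual)


@dataclass
class ControllabilityReport:
    rank: int
    latent_dim: int

    @property
    def controllable(self) -> bool:
        return self.rank == self.latent_dim


def controllability_check(A: np.ndarray, B: np.ndarray) -> ControllabilityReport:
    """Rank of the controllability matrix [B, AB, ..., A^{L-1} B]."""
    A = np.asarray(A, dtype=float)
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if B.shape[0] != A.shape[0]:
        B = B.T
    blocks = [B]
    for _ in range(A.shape[0] - 1):
        blocks.append(A @ blocks[-1])
    rank = int(np.linalg.matrix_rank(np.hstack(blocks)))
    return ControllabilityReport(rank=rank, latent_dim=A.shape[0])


# ---------------------------------------------------------------------------
# CD/CI decomposition and alignments


@dataclass
class CDCIDecomp:
    """Condition-dependent / condition-independent split of a tensor.

    CI[n,t,cx] is the across-condition mean; CD = data - CI averages to
    zero over conditions at every (neuron, time, context) and CD + CI
    reconstructs the data exactly.  ``cd_axes``[:, t, cx] is the leading
    singular vector of the (neuron x condition) CD slice at time t;
    ``ci_axes`` is the unit-normalized CI vector.
    """

    CD: np.ndarray  # (N, T, K, 2)
    CI: np.ndarray  # (N, T, 2)
    cd_axes: np.ndarray  # (N, T, 2)
    ci_axes: np.ndarray  # (N, T, 2)


def cd_ci_decompose(data: ResponseTensor | np.ndarray) -> CDCIDecomp:
    Y = data.Y if isinstance(data, ResponseTensor) else np.asarray(data, dtype=float)
    if Y.ndim != 4:
        raise ShapeError("expected a (N, T, K, contexts) tensor")
    if Y.shape[2] < 2:
        raise ShapeError("CD/CI decomposition requires >= 2 conditions")
    CI = Y.mean(axis=2)
    CD = Y - CI[:, :, None, :]
    N, T, _, CX = Y.shape
    cd_axes = np.zeros((N, T, CX))
    ci_axes = np.zeros((N, T, CX))
    for cx in range(CX):
        for t in range(T):
            u, _, _ = np.linalg.svd(CD[:, t, :, cx], full_matrices=False)
            cd_axes[:, t, cx] = u[:, 0]
            v = CI[:, t, cx]
            nv = np.linalg.norm(v)
            ci_axes[:, t, cx] = v / nv if nv > 0 else 0.0
    return CDCIDecomp(CD=CD, CI=CI, cd_axes=cd_axes, ci_axes=ci_axes)


def mode_alignment(
    vector: np.ndarray, modes: EigenModeSet, C_load: np.ndarray | None = None
) -> np.ndarray:
    """Alignment of a vector with each eigenmode, in [0, 1].

    For real modes, the absolute dot product with the unit right
    eigenvector; for a conjugate pair, the cosine of the minimum principal
    angle between the vector and the plane spanned by the real and
    imaginary parts of the right eigenvector (pair members share the
    value).  A neuron-space vector is mapped to the latent basis through
    C_load^T first.
    """
    v = np.asarray(vector, dtype=float)
    if C_load is not None and v.shape[0] == C_load.shape[0]:
        v = C_load.T @ v
    if v.shape != (modes.n_modes,):
        raise ShapeError("vector dimensionality does not match the mode set")
    nv = np.linalg.norm(v)
    if nv == 0:
        raise ValueError("alignment undefined for the zero vector")
    v = v / nv
    out = np.zeros(modes.n_modes)
    for g in modes.group_indices():
        i = g[0]
        if g.size == 1:
            r = np.real(modes.R[:, i])
            out[i] = abs(float(v @ (r / np.linalg.norm(r))))
        else:
            plane = np.stack([np.real(modes.R[:, i]), np.imag(modes.R[:, i])], axis=1)
            Qp, _ = np.linalg.qr(plane)
            angles = scipy.linalg.subspace_angles(Qp, v[:, None])
            out[g] = float(np.cos(np.min(angles)))
    return out


# ---------------------------------------------------------------------------
# coherence demixing plane


@dataclass
class DemixPlane:
    """Orthonormal (coh, |coh|) basis from regressing inputs on coherence."""

    basis: np.ndarray  # (L, 2) or (L, 1) if collapsed
    coef_coh: np.ndarray
    coef_abs: np.ndarray
    collapsed: bool


def demix_input_plane(
    input_vectors: np.ndarray, coherences: np.ndarray, collapse_tol: float = 1e-6
) -> DemixPlane:
    """Regress per-coherence input vectors on (coh, |coh|, 1).

    ``input_vectors``: (n_levels, L) — e.g. B*u at a fixed time for each
    signed coherence.  The coherence-slope and magnitude-slope coefficient
    vectors are orthonormalized (coherence first) to give the demixed 2D
    plane; if the magnitude coefficient is (numerically) collinear or zero,
    the plane collapses to 1D and is flagged.
    """
    V = np.asarray(input_vectors, dtype=float)
    coh = np.asarray(coherences, dtype=float)
    if V.shape[0] != coh.size:
        raise ShapeError("one input vector per coherence level required")
    X = np.stack([coh, np.abs(coh), np.ones_like(coh)], axis=1)
    if np.linalg.matrix_rank(X) < 3:
        raise DegeneratePlaneError(
            "regressors (coh, |coh|, 1) are rank deficient; need >= 2 strengths "
            "in both directions"
        )
    coefs, *_ = np.linalg.lstsq(X, V, rcond=None)
    b_coh, b_abs = coefs[0], coefs[1]
    n1 = np.linalg.norm(b_coh)
    if n1 == 0:
        raise DegeneratePlaneError("coherence coefficient vector is zero")
    e1 = b_coh / n1
    resid = b_abs - (e1 @ b_abs) * e1
    if np.linalg.norm(resid) < collapse_tol * max(n1, 1.0):
        return DemixPlane(basis=e1[:, None], coef_coh=b_coh, coef_abs=b_abs, collapsed=True)
    e2 = resid / np.linalg.norm(resid)
    return DemixPlane(
        basis=np.stack([e1, e2], axis=1), coef_coh=b_coh, coef_abs=b_abs, collapsed=False
    )


def plane_angle_deg(basis_a: np.ndarray, basis_b: np.ndarray) -> float:
    """Largest principal angle between two subspaces, in degrees."""
    return float(np.degrees(np.max(scipy.linalg.subspace_angles(basis_a, basis_b))))


# ---------------------------------------------------------------------------
# summary norms


@dataclass
class NormTraces:
    """Input-norm and output-norm traces, per modality and context.

    ``input_norm[mod][cx]``: (n_levels, T) traces of ||B u(t)|| per
    coherence level; ``output_norm[mod][cx]``: (n_levels, T) traces of
    ||x(t)|| when the system is driven by that modality alone from x0 = 0.
    """

    input_norm: dict
    output_norm: dict
    mean_subtracted: bool


def summary_norms(
    params: LDSParams, grid: TaskGrid, subtract_condition_mean: bool = False
) -> NormTraces:
    T = params.inputs.n_bins
    input_norm: dict = {}
    output_norm: dict = {}
    for mod in ("motion", "color"):
        lev = params.inputs.level_series(mod, grid)  # (n_lev, U, T)
        input_norm[mod] = []
        output_norm[mod] = []
        for cx in range(N_CONTEXTS):
            B = params.B_mot_ctx(cx) if mod == "motion" else params.B_col_ctx(cx)
            bu = np.einsum("lu,jut->jlt", B, lev)  # (n_lev, L, T)
            if subtract_condition_mean:
                bu = bu - bu.mean(axis=0, keepdims=True)
            input_norm[mod].append(np.linalg.norm(bu, axis=1))
            A = params.A_ctx(cx)
            X = np.zeros((lev.shape[0], A.shape[0], T + 1))
            for t in range(1, T + 1):
                X[:, :, t] = (A @ X[:, :, t - 1].T).T + bu[:, :, t - 1]
            output_norm[mod].append(np.linalg.norm(X[:, :, 1:], axis=1))
    return NormTraces(
        input_norm=input_norm, output_norm=output_norm,
        mean_subtracted=subtract_condition_mean,
    )


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (statistic, p-value)."""
    from scipy.stats import ranksums

    res = ranksums(np.asarray(a), np.asarray(b))
    return float(res.statistic), float(res.pvalue)
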