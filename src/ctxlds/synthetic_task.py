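"""Ground-truth LDS generator emulating the contextual random-dots dataset.

Produces response tensors with the statistical shape of the pseudo-population
recordings: N neurons x T bins (50 ms) x K conditions (motion x color
coherence pairs) x 2 contexts, z-scored per neuron, generated from a known
linear dynamical system with additive Gaussian noise.  The generator spans
the mechanistic regimes contrasted by the model classes: contextual
modulation of the inputs (input switching), of the recurrent dynamics
(dynamics switching), both, or neither, with a knob for the degree of
non-normality of the dynamics.

The ground truth is returned as an ordinary :class:`~ctxlds.lds_core.LDSParams`,
so every downstream stage (fitting, LOOCV, dynamics characterization,
perturbations) can be validated against known parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import lds_core
from .errors import DegenerateZScoreError, EigenPlanError, ShapeError
from .lds_core import InputModel, LDSParams, ModelClassSpec, N_CONTEXTS
from .task_grid import TaskGrid, make_task_grid

CONTEXT_MODES = ("none", "input-switching", "dynamics-switching", "both")

#: eigenvalue targets used by default: one near-integrator mode, slow and
#: intermediate rotational pairs, and faster decaying real modes (8 latents).
DEFAULT_EIGEN_PLAN = (
    0.98,
    0.9 * np.exp(0.25j),
    0.9 * np.exp(-0.25j),
    0.85,
    0.7 * np.exp(0.6j),
    0.7 * np.exp(-0.6j),
    0.6,
    0.4,
)


@dataclass(frozen=True)
class GroundTruthSpec:
    """Recipe for a synthetic ground-truth system and dataset.

    Defaults are desk scale: 60 neurons, 8 latents, 2+2 input dimensions,
    15 bins of 50 ms, the 6x6 coherence grid (K=36) and 2 contexts — large
    enough to exercise every analysis, small enough for seconds-scale fits.
    ``non_normality`` >= 0 skews the eigenbasis (0 gives a normal dynamics
    matrix); ``context_mode`` selects which generative blocks differ across
    contexts; ``input_gain_irrelevant`` scales the irrelevant modality's
    input subspace in each context when inputs switch.
    """

    n_neurons: int = 60
    n_bins: int = 15
    latent_dim: int = 8
    input_dim_motion: int = 2
    input_dim_color: int = 2
    eigen_plan: tuple[complex, ...] = DEFAULT_EIGEN_PLAN
    non_normality: float = 0.0
    context_mode: str = "none"
    input_gain_irrelevant: float = 0.3
    noise_sd: float = 0.1
    seed: int = 0
    bin_ms: float = 50.0
    input_scale: float = 1.5

    def __post_init__(self) -> None:
        if self.context_mode not in CONTEXT_MODES:
            raise ShapeError(f"context_mode must be one of {CONTEXT_MODES}")
        if self.latent_dim < max(self.input_dim_motion, self.input_dim_color):
            raise ShapeError("latent_dim must be >= each input dimensionality")
        if self.non_normality < 0:
            raise ShapeError("non_normality must be >= 0")
        if not 0.0 <= self.input_gain_irrelevant <= 1.0:
            raise ShapeError("input_gain_irrelevant must lie in [0, 1]")

    @property
    def class_spec(self) -> ModelClassSpec:
        return ModelClassSpec(
            dynamics_context_dependent=self.context_mode in ("dynamics-switching", "both"),
            inputs_context_dependent=self.context_mode in ("input-switching", "both"),
            latent_dim=self.latent_dim,
            input_dim_motion=self.input_dim_motion,
            input_dim_color=self.input_dim_color,
        )


@dataclass
class ResponseTensor:
    """Z-scored condition-averaged response tensor plus its task table.

    ``Y`` has shape (n_neurons, n_bins, K, 2).  ``zscore_mean``/``zscore_sd``
    are the per-neuron statistics applied (population SD over all bins,
    conditions and contexts jointly), so ``Y * sd + mean`` restores the raw
    simulated rates.
    """

    Y: np.ndarray
    grid: TaskGrid
    bin_ms: float = 50.0
    zscore_mean: np.ndarray | None = None
    zscore_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.Y.ndim != 4 or self.Y.shape[2] != self.grid.K or self.Y.shape[3] != N_CONTEXTS:
            raise ShapeError(
                f"Y must have shape (N, T, K={self.grid.K}, {N_CONTEXTS}); got {self.Y.shape}"
            )
        if not np.all(np.isfinite(self.Y)):
            raise ShapeError("response tensor contains non-finite entries")

    @property
    def n_neurons(self) -> int:
        return self.Y.shape[0]

    @property
    def n_bins(self) -> int:
        return self.Y.shape[1]

    @property
    def raw(self) -> np.ndarray:
        if self.zscore_mean is None or self.zscore_sd is None:
            return self.Y
        return self.Y * self.zscore_sd[:, None, None, None] + self.zscore_mean[:, None, None, None]

    def subset_conditions(self, keep: np.ndarray) -> "ResponseTensor":
        """View of the tensor restricted to a condition subset (for LOOCV).

        The grid is kept whole; callers track which condition ids survive.
        """
        out = ResponseTensor.__new__(ResponseTensor)
        out.Y = self.Y[:, :, keep, :]
        out.grid = self.grid
        out.bin_ms = self.bin_ms
        out.zscore_mean = self.zscore_mean
        out.zscore_sd = self.zscore_sd
        return out


# ---------------------------------------------------------------------------
# ground-truth construction


def _real_block_form(plan: np.ndarray) -> np.ndarray:
    """Real block-diagonal matrix with the planned eigenvalues.

    Real targets become scalar diagonal entries; conjugate pairs become
    2x2 scaled-rotation blocks |lambda| [[cos w, -sin w], [sin w, cos w]].
    """
    used = np.zeros(len(plan), dtype=bool)
    blocks: list[np.ndarray] = []
    for i, lam in enumerate(plan):
        if used[i]:
            continue
        used[i] = True
        if abs(lam.imag) < 1e-12:
            blocks.append(np.array([[lam.real]]))
            continue
        partner = None
        for j in range(i + 1, len(plan)):
            if not used[j] and abs(plan[j] - np.conj(lam)) < 1e-9:
                partner = j
                break
        if partner is None:
            raise EigenPlanError(f"complex target {lam} lacks a conjugate partner")
        used[partner] = True
        r, w = abs(lam), abs(np.angle(lam))
        blocks.append(r * np.array([[np.cos(w), -np.sin(w)], [np.sin(w), np.cos(w)]]))
    n = sum(b.shape[0] for b in blocks)
    out = np.zeros((n, n))
    pos = 0
    for b in blocks:
        m = b.shape[0]
        out[pos : pos + m, pos : pos + m] = b
        pos += m
    return out


def _basis(rng: np.random.Generator, L: int, non_normality: float) -> np.ndarray:
    """Eigenbasis: orthonormal when non_normality=0, sheared otherwise."""
    Q, _ = np.linalg.qr(rng.standard_normal((L, L)))
    if non_normality == 0.0:
        return Q
    G = np.triu(rng.standard_normal((L, L)), k=1) / np.sqrt(L)
    return Q @ (np.eye(L) + non_normality * G)


def _planned_dynamics(
    rng: np.random.Generator, spec: GroundTruthSpec
) -> tuple[np.ndarray, np.ndarray]:
    plan = np.asarray(spec.eigen_plan, dtype=complex)
    if plan.size > spec.latent_dim:
        raise EigenPlanError(
            f"eigen_plan has {plan.size} targets but latent_dim={spec.latent_dim}"
        )
    norms = np.abs(plan)
    if np.any(norms <= 0) or np.any(norms > 1.05):
        raise EigenPlanError("eigen_plan norms must lie in (0, 1.05]")
    if plan.size < spec.latent_dim:
        fill = rng.uniform(0.2, 0.6, size=spec.latent_dim - plan.size)
        plan = np.concatenate([plan, fill.astype(complex)])
    Lam = _real_block_form(plan)
    return plan, Lam


def sample_ground_truth(spec: GroundTruthSpec) -> LDSParams:
    """Draw a ground-truth LDS realizing the spec's eigenvalue plan exactly.

    A = R Lam R^-1 with R orthonormal (``non_normality`` = 0) or sheared;
    the loading map has orthonormal columns; input courses are smooth
    transient bumps whose amplitude is linear in signed coherence.  In the
    input-switching regimes, the irrelevant modality's input map is scaled
    by ``input_gain_irrelevant`` in each context; in the dynamics-switching
    regimes, each context gets an independently realigned eigenbasis (same
    eigenvalue plan).
    """
    rng = np.random.default_rng(spec.seed)
    L, T = spec.latent_dim, spec.n_bins
    cs = spec.class_spec

    _, Lam = _planned_dynamics(rng, spec)
    if cs.dynamics_context_dependent:
        A = np.stack(
            [_mk_A(_basis(rng, L, spec.non_normality), Lam) for _ in range(N_CONTEXTS)]
        )
    else:
        A = _mk_A(_basis(rng, L, spec.non_normality), Lam)[None]

    # shared base input maps with orthonormal columns
    Bm0 = np.linalg.qr(rng.standard_normal((L, spec.input_dim_motion)))[0]
    Bc0 = np.linalg.qr(rng.standard_normal((L, spec.input_dim_color)))[0]
    if cs.inputs_context_dependent:
        g = spec.input_gain_irrelevant
        B_mot = np.stack([Bm0, g * Bm0])  # motion irrelevant in color context (cx=1)
        B_col = np.stack([g * Bc0, Bc0])  # color irrelevant in motion context (cx=0)
    else:
        B_mot, B_col = Bm0[None], Bc0[None]

    grid = make_task_grid()  # canonical 6-level grid defines scalar count
    courses_m = _bump_courses(spec.input_dim_motion, T)
    courses_c = _bump_courses(spec.input_dim_color, T)
    scalars_m = _coh_scalars(grid.motion_levels, spec.input_dim_motion, spec.input_scale)
    scalars_c = _coh_scalars(grid.color_levels, spec.input_dim_color, spec.input_scale)
    inputs = InputModel(courses_m, courses_c, scalars_m, scalars_c)

    x0 = 0.5 * rng.standard_normal((N_CONTEXTS, L))
    C = np.linalg.qr(rng.standard_normal((spec.n_neurons, L)))[0]
    d = 0.3 * rng.standard_normal(spec.n_neurons)
    return LDSParams(
        class_spec=cs, A=A, B_mot=B_mot, B_col=B_col, x0=x0, C_load=C, d=d, inputs=inputs
    )


def _mk_A(R: np.ndarray, Lam: np.ndarray) -> np.ndarray:
    return R @ Lam @ np.linalg.inv(R)


def _bump_courses(input_dim: int, n_bins: int) -> np.ndarray:
    """Smooth transient courses, strong early in the trial then decaying.

    Each input dimension gets a slightly later/wider bump so the per-modality
    drive genuinely spans its dimensionality over time.
    """
    t = np.arange(1, n_bins + 1, dtype=float)
    out = np.empty((input_dim, 2, n_bins))
    for i in range(input_dim):
        peak = 3.0 + 1.5 * i
        bump = (t / peak) * np.exp(1.0 - t / peak)
        out[i, :, :] = bump / bump.max()
    return out


def _coh_scalars(levels, input_dim: int, scale: float) -> np.ndarray:
    """Coherence scalars per input dimension.

    Even dimensions code signed coherence (evidence direction + strength);
    odd dimensions code centered coherence magnitude (|coh| minus its mean,
    identical for the two directions of a strength) — the signed/magnitude
    mixture the coh-|coh| demixing analysis expects.  The distinct profiles
    also make the level series span the full input dimensionality.
    """
    lv = np.asarray(levels, dtype=float)
    mag = np.abs(lv) - np.abs(lv).mean()
    out = np.empty((input_dim, lv.size))
    for i in range(input_dim):
        profile = lv if i % 2 == 0 else mag
        out[i] = scale * profile / (1.0 + i // 2)
    return out


# ---------------------------------------------------------------------------
# observation generation


def zscore(Y_raw: np.ndarray, on_degenerate: str = "raise") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-neuron z-scoring over all bins, conditions and contexts jointly.

    Returns (Y_z, mean, sd) using the population SD (ddof=0), so each
    neuron's pooled entries have exactly mean 0 and SD 1 afterwards.
    ``on_degenerate``: 'raise' (default) or 'drop' neurons with SD 0.
    """
    mean = Y_raw.mean(axis=(1, 2, 3))
    sd = Y_raw.std(axis=(1, 2, 3))
    # constant neurons can carry O(eps) summation residue in their SD
    bad = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    if np.any(bad):
        if on_degenerate == "drop":
            keep = ~bad
            Y_raw, mean, sd = Y_raw[keep], mean[keep], sd[keep]
        else:
            idx = np.flatnonzero(bad)
            raise DegenerateZScoreError(
                f"neurons {idx.tolist()} have zero variance; z-scoring undefined"
            )
    Yz = (Y_raw - mean[:, None, None, None]) / sd[:, None, None, None]
    return Yz, mean, sd


def generate_observations(
    gt: LDSParams,
    grid: TaskGrid,
    noise_sd: float,
    seed: int,
    bin_ms: float = 50.0,
    on_degenerate: str = "raise",
) -> ResponseTensor:
    """Simulate the ground truth, add i.i.d. Gaussian noise, z-score.

    Deterministic given (gt, grid, noise_sd, seed): identical seeds yield
    bit-identical tensors.
    """
    if noise_sd < 0:
        raise ShapeError("noise_sd must be >= 0")
    Y_raw = lds_core.reconstruct(gt, grid)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        Y_raw = Y_raw + noise_sd * rng.standard_normal(Y_raw.shape)
    Yz, mean, sd = zscore(Y_raw, on_degenerate=on_degenerate)
    return ResponseTensor(Y=Yz, grid=grid, bin_ms=bin_ms, zscore_mean=mean, zscore_sd=sd)


def generate_dataset(
    spec: GroundTruthSpec, grid: TaskGrid | None = None
) -> tuple[ResponseTensor, LDSParams]:
    """Convenience: ground truth plus observations from a single spec/seed."""
    if grid is None:
        grid = make_task_grid()
    gt = sample_ground_truth(spec)
    data = generate_observations(gt, grid, spec.noise_sd, seed=spec.seed + 1, bin_ms=spec.bin_ms)
    return data, gt
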