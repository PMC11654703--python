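import numpy as np
import pytest

from ctxlds.fit_select import FitConfig
from ctxlds.lds_core import InputModel, LDSParams, ModelClassSpec, constant_courses
from ctxlds.synthetic_task import GroundTruthSpec, generate_dataset, sample_ground_truth
from ctxlds.task_grid import make_task_grid


@pytest.fixture(scope="session")
def grid():
    return make_task_grid()


@pytest.fixture(scope="session")
def tiny_spec():
    """Small system for fast fitting tests: 20 neurons, 3 latents, 1+1 inputs."""
    return GroundTruthSpec(
        n_neurons=20, latent_dim=3, input_dim_motion=1, input_dim_color=1,
        eigen_plan=(0.9, 0.7, 0.5), non_normality=0.3,
        context_mode="input-switching", noise_sd=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def tiny_data(tiny_spec):
    return generate_dataset(tiny_spec)


@pytest.fixture(scope="session")
def desk_gt(grid):
    """Default desk-scale ground truth (60 neurons, 8 latents, 2+2 inputs)."""
    return sample_ground_truth(
        GroundTruthSpec(context_mode="input-switching", non_normality=0.5, seed=3)
    )


@pytest.fixture
def quick_config():
    return FitConfig(max_iter=300, min_iter=100, convergence_dcost=1e-6, seed=0)


def random_lds(
    rng,
    n_neurons=7,
    latent_dim=3,
    input_dims=(1, 1),
    dynamics_ctx=False,
    inputs_ctx=False,
    n_bins=5,
    stable_scale=0.6,
    zero_bias=False,
):
    """Random well-conditioned LDS parameter set for invariance tests."""
    Um, Uc = input_dims
    cs = ModelClassSpec(dynamics_ctx, inputs_ctx, latent_dim, Um, Uc)
    L = latent_dim
    A = stable_scale * rng.standard_normal((cs.n_dynamics, L, L)) / np.sqrt(L)
    inputs = InputModel(
        rng.standard_normal((Um, 2, n_bins)),
        rng.standard_normal((Uc, 2, n_bins)),
        rng.standard_normal((Um, 6)),
        rng.standard_normal((Uc, 6)),
    )
    return LDSParams(
        class_spec=cs,
        A=A,
        B_mot=rng.standard_normal((cs.n_input_maps, L, Um)),
        B_col=rng.standard_normal((cs.n_input_maps, L, Uc)),
        x0=rng.standard_normal((2, L)),
        C_load=rng.standard_normal((n_neurons, L)),
        d=np.zeros(n_neurons) if zero_bias else rng.standard_normal(n_neurons),
        inputs=inputs,
    )
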