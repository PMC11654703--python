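import numpy as np
import pytest
import scipy.linalg as sla
from hypothesis import given, settings
from hypothesis import strategies as st

from ctxlds import lds_core
from ctxlds.dynamics import (
    cd_ci_decompose,
    controllability_check,
    demix_input_plane,
    eigenmodes,
    freq_category,
    henrici_index,
    impulse_response,
    input_loads,
    mode_alignment,
    model_input_loads,
    observability_gramian,
    plane_angle_deg,
    random_directions,
    rotation_frequency,
    summary_norms,
    time_constant,
)
from ctxlds.errors import DegeneratePlaneError, ShapeError, StabilityError
from ctxlds.synthetic_task import GroundTruthSpec, generate_observations, sample_ground_truth

from conftest import random_lds


def rotation(theta, scale=1.0):
    return scale * np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )


class TestEigenmodes:
    def test_diagonal_matrix(self):
        m = eigenmodes(np.diag([0.9, 0.5]))
        assert np.allclose(m.eigvals, [0.9, 0.5])
        assert np.allclose(np.abs(m.R), np.eye(2))
        assert np.allclose(np.abs(m.L), np.eye(2))
        assert list(m.pair_id) == [-1, -1]

    def test_scaled_rotation_is_conjugate_pair(self):
        m = eigenmodes(rotation(0.4, scale=0.8))
        assert np.allclose(np.abs(m.eigvals), 0.8)
        assert m.pair_id[0] == m.pair_id[1] == 0
        assert m.tau_ms[0] == m.tau_ms[1]
        assert m.freq_hz[0] == m.freq_hz[1]

    def test_reconstruction_oracle_random_6x6(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((6, 6)) * 0.4
        m = eigenmodes(A)
        back = np.real(m.R @ np.diag(m.eigvals) @ m.L)
        assert np.abs(back - A).max() < 1e-8
        assert np.abs(m.L @ m.R - np.eye(6)).max() < 1e-8
        # eigenvector/eigenvalue consistency
        for i in range(6):
            assert np.abs(A @ m.R[:, i] - m.eigvals[i] * m.R[:, i]).max() < 1e-8
            assert np.abs(m.L[i] @ A - m.eigvals[i] * m.L[i]).max() < 1e-8

    def test_ordering_deterministic_by_norm_then_freq(self):
        A = sla.block_diag(rotation(0.9, 0.7), rotation(0.2, 0.7), np.diag([0.95]))
        m = eigenmodes(A)
        assert abs(m.eigvals[0]) == pytest.approx(0.95)
        # among the |lambda|=0.7 modes the faster rotation comes first
        assert m.freq_hz[1] >= m.freq_hz[3]
        assert m.eigvals[1].imag > 0  # positive-imaginary member first

    def test_slow_flag_threshold(self):
        m = eigenmodes(np.diag([0.95, 0.81, 0.8, 0.3]))
        assert list(m.slow) == [True, True, False, False]

    def test_near_defective_warns(self):
        A = np.array([[0.5, 1e8], [0.0, 0.5 + 1e-12]])
        with pytest.warns(UserWarning, match="near defective"):
            eigenmodes(A)


class TestTimeConstant:
    @pytest.mark.parametrize(
        "norm,tau_ms", [(0.7, 140), (0.8, 224), (0.9, 475)]
    )
    def test_printed_conversions_nearest_ms(self, norm, tau_ms):
        assert round(time_constant(norm)) == tau_ms

    def test_near_unity_mode_two_sig_figs_seconds(self):
        assert time_constant(0.98) / 1000 == pytest.approx(2.5, abs=0.05)

    def test_integration_mode_is_infinite(self):
        assert time_constant(1.0) == np.inf

    def test_growth_flagged_negative(self):
        assert time_constant(1.05) < 0

    def test_domain_error(self):
        with pytest.raises(ValueError):
            time_constant(0.0)


class TestRotationFrequency:
    def test_real_positive_is_zero(self):
        assert rotation_frequency(0.7) == 0.0

    def test_quarter_turn_is_five_hz(self):
        assert rotation_frequency(0.8j) == pytest.approx(5.0)

    def test_negative_real_is_nyquist(self):
        # brute force: a 1D signed sequence x(t) = (-0.5)^t alternates every
        # bin -> period 2 bins = 100 ms -> 10 Hz
        x = np.array([(-0.5) ** t for t in range(8)])
        signs = np.sign(x)
        period_bins = 2 * np.mean(np.diff(np.flatnonzero(signs[:-1] != signs[1:])))
        assert rotation_frequency(-0.5) == pytest.approx(20.0 / period_bins)
        assert rotation_frequency(-0.5) == pytest.approx(10.0)

    def test_zero_eigenvalue_undefined(self):
        with pytest.raises(ValueError):
            rotation_frequency(0.0)

    def test_frequency_categories(self):
        assert freq_category(0.1) == "<0.25"
        assert freq_category(0.5) == "0.25-1"
        assert freq_category(2.0) == ">1"


class TestHenrici:
    def test_symmetric_is_normal(self):
        rng = np.random.default_rng(1)
        S = rng.standard_normal((5, 5))
        assert henrici_index(S + S.T) < 1e-10

    def test_nilpotent_is_maximal(self):
        for c in (0.5, 3.0):
            assert henrici_index(np.array([[0.0, c], [0.0, 0.0]])) == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_bounded_on_random_matrices(self, seed):
        A = np.random.default_rng(seed).standard_normal((4, 4))
        assert 0.0 <= henrici_index(A) <= 1.0

    def test_zero_matrix_undefined(self):
        with pytest.raises(ValueError):
            henrici_index(np.zeros((3, 3)))


class TestInputLoads:
    def test_diagonal_system_unit_drive(self):
        m = eigenmodes(np.diag([0.9, 0.5, 0.2]))
        bu = np.zeros((3, 4))
        bu[0, :] = 1.0  # drive along the first eigenvector only
        loads, contribs = input_loads(m, bu)
        assert np.allclose(loads[0], 1.0)
        assert np.allclose(loads[1:], 0.0)
        assert np.allclose(contribs.sum(axis=0), bu, atol=1e-12)

    def test_orthogonal_drive_loads_zero(self):
        rng = np.random.default_rng(2)
        A = 0.5 * rng.standard_normal((4, 4))
        m = eigenmodes(A)
        # drive orthogonal to left eigenvector 0 (real part and imag part)
        l0 = m.L[0]
        basis = np.linalg.svd(np.stack([np.real(l0), np.imag(l0)]))[2]
        v = basis[-1]  # in the null space of both components
        loads, _ = input_loads(m, v[:, None])
        assert loads[0, 0] < 1e-10

    @pytest.mark.parametrize("dim", [5, 7, 10])
    def test_reconstruction_identity(self, dim):
        """Per-mode contributions (pairs counted once) must sum to B*u(t)
        exactly, including complex pairs."""
        rng = np.random.default_rng(dim)
        A = 0.6 * rng.standard_normal((dim, dim))
        m = eigenmodes(A)
        bu = rng.standard_normal((dim, 9))
        loads, contribs = input_loads(m, bu)
        assert np.abs(contribs.sum(axis=0) - bu).max() < 1e-9
        # pair members share a single load value
        for pid in set(m.pair_id[m.pair_id >= 0]):
            i, j = np.flatnonzero(m.pair_id == pid)
            assert np.array_equal(loads[i], loads[j])

    def test_model_loads_use_strongest_positive_coherence(self, grid, desk_gt):
        loads = model_input_loads(lds_core.orthonormalize(desk_gt), grid)
        assert loads.shape == (8,)
        assert np.all(loads >= 0)

    def test_dimension_mismatch_rejected(self):
        m = eigenmodes(np.diag([0.5, 0.4]))
        with pytest.raises(ShapeError):
            input_loads(m, np.zeros((3, 4)))


class TestImpulseResponse:
    def test_normal_dynamics_never_amplifies(self):
        rng = np.random.default_rng(3)
        Q = np.linalg.qr(rng.standard_normal((5, 5)))[0]
        A = Q @ np.diag([0.9, 0.8, 0.5, 0.3, 0.1]) @ Q.T
        V = random_directions(5, 12, seed=0)
        traces = impulse_response(A, V, 10)
        bound = 0.9 ** np.arange(11)
        assert np.all(traces <= bound[None, :] + 1e-12)
        assert np.all(np.diff(traces, axis=1) <= 1e-12)

    def test_shear_amplifies_single_step(self):
        A = np.array([[0.9, 5.0], [0.0, 0.9]])
        tr = impulse_response(A, np.array([[0.0, 1.0]]), 3)
        assert tr[0, 1] == pytest.approx(np.sqrt(25.0 + 0.81))
        assert tr[0, 1] > 1.0

    def test_eigenvector_direction_decays_geometrically(self):
        rng = np.random.default_rng(4)
        A = 0.7 * rng.standard_normal((4, 4))
        m = eigenmodes(A)
        real = np.flatnonzero(m.pair_id < 0)
        i = real[0]
        v = np.real(m.R[:, i])
        v = v / np.linalg.norm(v)
        tr = impulse_response(A, v[None], 6)[0]
        lam = abs(m.eigvals[i])
        assert np.allclose(tr, lam ** np.arange(7), atol=1e-10)

    def test_non_unit_directions_rejected(self):
        with pytest.raises(ShapeError):
            impulse_response(np.eye(2), np.array([[2.0, 0.0]]), 3)


class TestGramian:
    def test_zero_dynamics_gives_ctc(self):
        rng = np.random.default_rng(5)
        C = rng.standard_normal((6, 3))
        g = observability_gramian(np.zeros((3, 3)), C)
        assert np.allclose(g.Q, C.T @ C, atol=1e-12)

    def test_scalar_geometric_series(self):
        g = observability_gramian(np.array([[0.5]]), np.array([[1.0]]))
        assert g.Q[0, 0] == pytest.approx(4.0 / 3.0)

    def test_matches_truncated_series_oracle(self):
        rng = np.random.default_rng(6)
        A = 0.35 * rng.standard_normal((5, 5))  # spectral radius ~0.8
        C = rng.standard_normal((8, 5))
        g = observability_gramian(A, C)
        series = np.zeros((5, 5))
        Ap = np.eye(5)
        for _ in range(201):
            series += Ap.T @ (C.T @ C) @ Ap
            Ap = A @ Ap
        assert np.abs(g.Q - series).max() < 1e-6
        assert g.residual < 1e-8
        assert np.all(np.diff(g.eigvals) <= 1e-12)

    def test_unstable_dynamics_refused_with_report(self):
        with pytest.raises(StabilityError, match="1.05"):
            observability_gramian(np.diag([1.05, 0.2]), np.eye(2))


class TestControllability:
    def test_identity_dynamics_single_input_not_controllable(self):
        rep = controllability_check(np.eye(2), np.array([1.0, 0.0]))
        assert rep.rank == 1 and not rep.controllable

    def test_shift_matrix_krylov_chain(self):
        L = 4
        A = np.diag(np.ones(L - 1), k=-1)  # shift: e_i -> e_{i+1}
        B = np.zeros((L, 1))
        B[0, 0] = 1.0
        rep = controllability_check(A, B)
        assert rep.rank == L and rep.controllable

    def test_generic_pair_controllable(self):
        rng = np.random.default_rng(7)
        rep = controllability_check(rng.standard_normal((5, 5)),
                                    rng.standard_normal((5, 2)))
        assert rep.controllable


class TestCDCI:
    def test_identical_conditions_have_zero_cd(self, grid):
        Y = np.tile(np.random.default_rng(8).standard_normal((5, 4, 1, 2)),
                    (1, 1, grid.K, 1))
        dec = cd_ci_decompose(Y)
        assert np.abs(dec.CD).max() < 1e-12

    def test_decomposition_identities(self, grid):
        rng = np.random.default_rng(9)
        Y = rng.standard_normal((6, 5, grid.K, 2))
        dec = cd_ci_decompose(Y)
        assert np.abs(dec.CD.mean(axis=2)).max() < 1e-12
        assert np.abs(dec.CD + dec.CI[:, :, None, :] - Y).max() < 1e-12
        # leading CD axis is unit norm and captures max variance at each time
        assert np.allclose(np.linalg.norm(dec.cd_axes, axis=0), 1.0)

    def test_requires_two_conditions(self):
        with pytest.raises(ShapeError):
            cd_ci_decompose(np.zeros((3, 4, 1, 2)))


class TestModeAlignment:
    def test_eigenvector_aligns_perfectly(self):
        rng = np.random.default_rng(10)
        A = 0.5 * rng.standard_normal((4, 4))
        m = eigenmodes(A)
        real = np.flatnonzero(m.pair_id < 0)
        v = np.real(m.R[:, real[0]])
        a = mode_alignment(v / np.linalg.norm(v), m)
        assert a[real[0]] == pytest.approx(1.0, abs=1e-9)

    def test_vector_orthogonal_to_pair_plane(self):
        A = sla.block_diag(rotation(0.5, 0.8), np.diag([0.3, 0.2]))
        m = eigenmodes(A)
        pair = np.flatnonzero(m.pair_id == 0)
        v = np.zeros(4)
        v[2] = 1.0  # orthogonal to the rotation plane (dims 0,1)
        a = mode_alignment(v, m)
        assert a[pair[0]] == pytest.approx(0.0, abs=1e-10)

    def test_matches_grid_search_oracle(self):
        """Pair alignment equals brute-force maximization of |cos| over the
        unit circle of the pair's plane."""
        rng = np.random.default_rng(11)
        A = 0.6 * rng.standard_normal((5, 5))
        m = eigenmodes(A)
        pid = m.pair_id.max()
        i = int(np.flatnonzero(m.pair_id == pid)[0])
        plane = np.linalg.qr(
            np.stack([np.real(m.R[:, i]), np.imag(m.R[:, i])], axis=1)
        )[0]
        v = rng.standard_normal(5)
        v /= np.linalg.norm(v)
        thetas = np.linspace(0, np.pi, 200_000)
        dirs = plane @ np.stack([np.cos(thetas), np.sin(thetas)])
        brute = np.abs(dirs.T @ v).max()
        assert mode_alignment(v, m)[i] == pytest.approx(brute, abs=1e-9)

    def test_neuron_space_vector_mapped_through_loading(self, desk_gt):
        p = lds_core.orthonormalize(desk_gt)
        m = eigenmodes(p.A_ctx(0))
        v = p.C_load @ np.real(m.R[:, 0])
        a = mode_alignment(v / np.linalg.norm(v), m, C_load=p.C_load)
        assert a.max() <= 1.0 + 1e-9

    def test_zero_vector_rejected(self):
        m = eigenmodes(np.diag([0.5, 0.3]))
        with pytest.raises(ValueError):
            mode_alignment(np.zeros(2), m)


class TestDemixPlane:
    COH = np.array([-0.5, -0.15, -0.05, 0.05, 0.15, 0.5])

    def test_purely_linear_inputs_collapse_to_1d(self):
        v = np.array([1.0, 2.0, 0.0, 0.0])
        vectors = np.outer(self.COH, v)
        plane = demix_input_plane(vectors, self.COH)
        assert plane.collapsed and plane.basis.shape[1] == 1

    def test_constructed_truth_recovery_within_one_degree(self):
        rng = np.random.default_rng(12)
        v1, v2 = np.linalg.qr(rng.standard_normal((6, 2)))[0].T
        vectors = np.outer(self.COH, v1) + np.outer(np.abs(self.COH), v2)
        plane = demix_input_plane(vectors, self.COH)
        truth = np.stack([v1, v2], axis=1)
        assert plane_angle_deg(plane.basis, truth) < 1.0

    def test_context_shared_input_model_has_zero_plane_angle(self, grid):
        gt = sample_ground_truth(GroundTruthSpec(context_mode="none", seed=14))
        planes = []
        for cx in range(2):
            lev = gt.inputs.level_series("motion", grid)
            bu = np.einsum("lu,jut->jlt", gt.B_mot_ctx(cx), lev)[:, :, 2]
            planes.append(demix_input_plane(bu, np.asarray(grid.motion_levels)))
        assert plane_angle_deg(planes[0].basis, planes[1].basis) < 1e-6

    def test_single_strength_rank_deficient(self):
        coh = np.array([-0.3, 0.3])
        with pytest.raises(DegeneratePlaneError):
            demix_input_plane(np.random.default_rng(0).standard_normal((2, 4)), coh)


class TestSummaryNorms:
    def test_zero_inputs_zero_traces(self, grid):
        p = random_lds(np.random.default_rng(13))
        p.inputs.scalars_motion[:] = 0.0
        p.inputs.scalars_color[:] = 0.0
        tr = summary_norms(p, grid, subtract_condition_mean=True)
        assert np.abs(tr.input_norm["motion"][0]).max() == 0.0
        assert np.abs(tr.output_norm["color"][1]).max() == 0.0

    def test_context_shared_inputs_identical_across_contexts(self, grid):
        gt = sample_ground_truth(GroundTruthSpec(context_mode="none", seed=15))
        tr = summary_norms(gt, grid)
        for mod in ("motion", "color"):
            assert np.allclose(tr.input_norm[mod][0], tr.input_norm[mod][1])

    def test_input_switching_gain_visible_in_norm_ratio(self, grid):
        gt = sample_ground_truth(
            GroundTruthSpec(context_mode="input-switching",
                            input_gain_irrelevant=0.6, seed=16)
        )
        tr = summary_norms(gt, grid)
        rel = tr.input_norm["motion"][0][-1]  # motion relevant in context 0
        irr = tr.input_norm["motion"][1][-1]
        ratio = irr[rel > 1e-12] / rel[rel > 1e-12]
        assert np.allclose(ratio, 0.6, atol=1e-9)


class TestSimilarityInvariance:
    def test_eigen_summaries_invariant_under_any_similarity(self):
        p = random_lds(np.random.default_rng(17), n_neurons=9, latent_dim=4,
                       stable_scale=0.5)
        q = lds_core.orthonormalize(p)
        ma, mb = eigenmodes(p.A_ctx(0)), eigenmodes(q.A_ctx(0))
        assert np.allclose(np.abs(ma.eigvals), np.abs(mb.eigvals), atol=1e-8)
        assert np.allclose(ma.tau_ms, mb.tau_ms, atol=1e-6)
        assert np.allclose(ma.freq_hz, mb.freq_hz, atol=1e-8)

    def test_basis_dependent_summaries_invariant_once_orthonormalized(self):
        """Once the loading is orthonormal, re-orthonormalizing is a pure
        rotation: Henrici, Gramian spectrum and impulse norms are unchanged."""
        p = lds_core.orthonormalize(
            random_lds(np.random.default_rng(18), n_neurons=9, latent_dim=4,
                       stable_scale=0.5)
        )
        q = lds_core.orthonormalize(p)
        a, b = p.A_ctx(0), q.A_ctx(0)
        assert henrici_index(a) == pytest.approx(henrici_index(b), abs=1e-8)
        ga = observability_gramian(a, p.C_load)
        gb = observability_gramian(b, q.C_load)
        assert np.allclose(ga.eigvals, gb.eigvals, atol=1e-8 * max(1, ga.eigvals[0]))
        tr_a = impulse_response(a, np.eye(4)[:1], 6)
        # the perturbation direction must rotate with the basis
        R = q.C_load.T @ p.C_load
        v = R @ np.eye(4)[0]
        tr_b = impulse_response(b, (v / np.linalg.norm(v))[None], 6)
        assert np.allclose(tr_a, tr_b, atol=1e-8)
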