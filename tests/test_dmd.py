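import numpy as np
import pytest

from obsight import dmd
from obsight.preprocess import FoldChangeState, standardize

from conftest import random_stable_system, trajectory


def make_state(z, m, r):
    return FoldChangeState(
        zbar=z, mu=np.zeros(z.shape[0]), sigma=np.ones(z.shape[0]),
        raw_z=z, gene_ids=[f"g{i}" for i in range(z.shape[0])],
        n_timepoints=m, n_replicates=r,
    )


class TestShiftMatrices:
    def test_single_replicate_layout(self):
        z = np.array([[1.0, 2.0, 3.0]])
        zp, zf = dmd.build_shift_matrices(z, 3, 1)
        np.testing.assert_array_equal(zp, [[1.0, 2.0]])
        np.testing.assert_array_equal(zf, [[2.0, 3.0]])

    def test_no_pair_crosses_replicate_boundary(self):
        # replicate 1: a b c ; replicate 2: d e f
        z = np.array([[1.0, 2.0, 3.0, 10.0, 20.0, 30.0]])
        zp, zf = dmd.build_shift_matrices(z, 3, 2)
        assert zp.shape == (1, 4)
        np.testing.assert_array_equal(zp, [[1.0, 2.0, 10.0, 20.0]])
        np.testing.assert_array_equal(zf, [[2.0, 3.0, 20.0, 30.0]])

    def test_exact_linear_relation(self):
        K, _, z0 = random_stable_system(8, 4, seed=5)
        Z = trajectory(K, z0, 10)
        zp, zf = dmd.build_shift_matrices(Z, 10, 1)
        np.testing.assert_allclose(zf, K @ zp, atol=1e-12)

    def test_rejects_single_time_point(self):
        with pytest.raises(ValueError):
            dmd.build_shift_matrices(np.ones((3, 1)), 1, 1)


class TestFitExactDMD:
    def test_single_decaying_mode(self):
        v = np.array([1.0, 2.0, -1.0])
        Z = np.column_stack([v * 0.5**t for t in range(6)])
        zp, zf = dmd.build_shift_matrices(Z, 6, 1)
        model = dmd.fit_exact_dmd(zp, zf, 1)
        assert model.eigenvalues[0] == pytest.approx(0.5, abs=1e-10)

    def test_spectrum_matches_dense_eig_oracle(self):
        rng = np.random.default_rng(7)
        # dense diagonalizable stable 5x5 operator
        P = rng.normal(size=(5, 5))
        eigs = rng.uniform(0.3, 0.9, 5)
        K = P @ np.diag(eigs) @ np.linalg.inv(P)
        Z = trajectory(K, rng.normal(size=5), 20)
        zp, zf = dmd.build_shift_matrices(Z, 20, 1)
        model = dmd.fit_exact_dmd(zp, zf, 5)
        oracle = np.sort(np.linalg.eigvals(K).real)
        np.testing.assert_allclose(
            np.sort(model.eigenvalues.real), oracle, atol=1e-8
        )
        assert np.max(np.abs(model.eigenvalues.imag)) < 1e-8

    def test_planar_rotation_spectrum(self):
        theta = 0.7
        K = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        Z = trajectory(K, np.array([1.0, 0.3]), 12)
        zp, zf = dmd.build_shift_matrices(Z, 12, 1)
        model = dmd.fit_exact_dmd(zp, zf, 2)
        expected = np.exp(1j * np.array([theta, -theta]))
        np.testing.assert_allclose(
            sorted(model.eigenvalues, key=lambda z: z.imag),
            sorted(expected, key=lambda z: z.imag),
            atol=1e-8,
        )

    def test_conjugate_pairs_for_real_data(self):
        rng = np.random.default_rng(11)
        Z = rng.normal(size=(10, 9))
        zp, zf = dmd.build_shift_matrices(Z, 9, 1)
        model = dmd.fit_exact_dmd(zp, zf, 6)
        complex_eigs = model.eigenvalues[np.abs(model.eigenvalues.imag) > 1e-10]
        # multiset of conjugates equals the multiset itself
        np.testing.assert_allclose(
            np.sort_complex(complex_eigs), np.sort_complex(np.conj(complex_eigs)),
            atol=1e-10,
        )

    def test_rank_exceeding_numerical_rank_rejected(self):
        Z = np.outer(np.arange(1.0, 5.0), np.ones(6))  # rank-1 data
        zp, zf = dmd.build_shift_matrices(Z, 6, 1)
        with pytest.raises(ValueError, match="numerical rank"):
            dmd.fit_exact_dmd(zp, zf, 3)

    def test_basis_orthonormal_and_similarity(self):
        K, _, z0 = random_stable_system(12, 4, seed=2)
        Z = trajectory(K, z0, 15)
        zp, zf = dmd.build_shift_matrices(Z, 15, 1)
        model = dmd.fit_exact_dmd(zp, zf, 4)
        np.testing.assert_allclose(
            model.basis_U.T @ model.basis_U, np.eye(4), atol=1e-10
        )
        np.testing.assert_allclose(
            np.sort_complex(np.linalg.eigvals(model.reduced_K)),
            np.sort_complex(model.eigenvalues),
            atol=1e-10,
        )

    def test_serialization_roundtrip(self, tmp_path):
        K, _, z0 = random_stable_system(6, 3, seed=9)
        Z = trajectory(K, z0, 8)
        zp, zf = dmd.build_shift_matrices(Z, 8, 1)
        model = dmd.fit_exact_dmd(zp, zf, 3, gene_ids=[f"g{i}" for i in range(6)])
        path = tmp_path / "model.json"
        model.save(path)
        back = dmd.DMDModel.load(path)
        np.testing.assert_allclose(back.modes_V, model.modes_V)
        np.testing.assert_allclose(back.eigenvalues, model.eigenvalues)
        assert back.gene_ids == model.gene_ids


class TestPredict:
    def test_step0_is_rank_r_projection(self):
        K, _, z0 = random_stable_system(10, 3, seed=3)
        Z = trajectory(K, z0, 12)
        zp, zf = dmd.build_shift_matrices(Z, 12, 1)
        model = dmd.fit_exact_dmd(zp, zf, 3)
        pred = dmd.predict(model, z0, 0)
        proj = model.modes_V @ (np.linalg.pinv(model.modes_V) @ z0)
        np.testing.assert_allclose(pred[:, 0], proj.real, atol=1e-10)

    def test_reproduces_noiseless_trajectory(self):
        K, _, z0 = random_stable_system(10, 4, seed=4)
        Z = trajectory(K, z0, 12)
        zp, zf = dmd.build_shift_matrices(Z, 12, 1)
        model = dmd.fit_exact_dmd(zp, zf, 4)
        pred = dmd.predict(model, z0, 11)
        np.testing.assert_allclose(pred, Z, atol=1e-8)

    def test_unstable_mode_grows(self):
        v = np.array([1.0, 1.0])
        Z = np.column_stack([v * 1.3**t for t in range(6)])
        zp, zf = dmd.build_shift_matrices(Z, 6, 1)
        model = dmd.fit_exact_dmd(zp, zf, 1)
        pred = dmd.predict(model, v, 10)
        norms = np.linalg.norm(pred, axis=0)
        assert np.all(np.diff(norms) > 0)


class TestRSquared:
    def test_perfect_and_mean_baselines(self):
        actual = np.random.default_rng(0).normal(size=(5, 8))
        assert dmd.r_squared(actual, actual) == pytest.approx(1.0)
        mean_pred = np.tile(actual.mean(axis=1, keepdims=True), (1, 8))
        assert dmd.r_squared(mean_pred, actual) == pytest.approx(0.0)

    def test_zero_deviation_rejected(self):
        with pytest.raises(ValueError):
            dmd.r_squared(np.ones((2, 3)), np.ones((2, 3)))


class TestRankScan:
    def test_r2_one_at_true_rank_and_monotone(self):
        K, _, _ = random_stable_system(15, 3, seed=6)
        rng = np.random.default_rng(6)
        blocks = [trajectory(K, K @ rng.normal(size=15), 9) for _ in range(2)]
        state = make_state(np.hstack(blocks), 9, 2)
        table = dmd.rank_scan(state, [1, 2, 3])
        r2 = table["r2"].to_numpy()
        assert r2[-1] == pytest.approx(1.0, abs=1e-8)
        assert r2[0] < 1.0
        assert np.all(np.diff(r2) >= -1e-9)


class TestModeClassification:
    @pytest.mark.parametrize(
        "lam, stability, oscillatory",
        [
            (0.9 + 0j, "stable", False),
            (0.5 + 0.5j, "stable", True),
            (1.01 + 0j, "unstable", False),
            (1.0 + 0j, "marginal", False),
        ],
    )
    def test_labels(self, lam, stability, oscillatory):
        model = dmd.DMDModel(
            rank_r=1, basis_U=np.ones((1, 1)), reduced_K=np.ones((1, 1)),
            modes_V=np.ones((1, 1), complex), eigenvalues=np.array([lam]),
            amplitudes_b=np.ones(1, complex), singular_values=np.ones(1),
        )
        (label,) = dmd.classify_modes(model)
        assert label.stability == stability
        assert label.oscillatory == oscillatory


class TestClusterByMode:
    def test_concentrated_loading_ranks_first(self):
        V = np.zeros((5, 2), complex)
        V[3, 0] = 2.0
        V[:, 1] = 0.1
        model = dmd.DMDModel(
            rank_r=2, basis_U=np.eye(5)[:, :2], reduced_K=np.eye(2),
            modes_V=V, eigenvalues=np.array([0.5, 0.4], complex),
            amplitudes_b=np.ones(2, complex), singular_values=np.ones(2),
        )
        assert dmd.cluster_by_mode(model, 0, 1) == [3]
        assert sorted(dmd.cluster_by_mode(model, 1, 5)) == [0, 1, 2, 3, 4]

    def test_block_system_modes_stay_in_blocks(self):
        # two decoupled blocks with distinct eigenvalues
        rng = np.random.default_rng(8)
        K = np.zeros((8, 8))
        K[:4, :4] = 0.9 * np.eye(4) + 0.02 * rng.normal(size=(4, 4))
        K[4:, 4:] = 0.4 * np.eye(4) + 0.02 * rng.normal(size=(4, 4))
        z0 = rng.normal(size=8)
        Z = trajectory(K, z0, 20)
        zp, zf = dmd.build_shift_matrices(Z, 20, 1)
        model = dmd.fit_exact_dmd(zp, zf, 8)
        # leading-|lambda| mode belongs to the 0.9 block -> genes 0..3
        top = dmd.cluster_by_mode(model, 0, 4)
        assert set(top) == {0, 1, 2, 3}
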