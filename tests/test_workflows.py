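"""All-vs-all comparison, bootstrap, convergence, sparsification, projection."""

import numpy as np
import pytest

import ensemblecmp as ec
from ensemblecmp.ces import LN2
from ensemblecmp.exceptions import InputError, TopologyError
from ensemblecmp.workflows import _smacof, _stress


def _copies(ens, k):
    return [ens.subset(np.arange(ens.n_frames), label=f"c{i}") for i in range(k)]


class TestCompareAll:
    def test_identical_ensembles_score_zero_everywhere(self, lowrank_ensemble):
        small = lowrank_ensemble.subset(np.arange(100))
        trio = _copies(small, 3)
        hes = ec.compare_all(trio, method="hes")
        ces = ec.compare_all(trio, method="ces", seed=0)
        dres = ec.compare_all(trio, method="dres", seed=0)
        off = ~np.eye(3, dtype=bool)
        assert hes.values[off].max() <= 1e-6
        assert ces.values[off].max() <= 1e-6
        assert dres.values[off].max() <= 0.02

    def test_block_structure_two_states(self, tight_ensemble, far_ensemble):
        a1 = tight_ensemble.subset(np.arange(50), label="A1")
        a2 = tight_ensemble.subset(np.arange(50, 100), label="A2")
        b = far_ensemble.subset(np.arange(50), label="B")
        sm = ec.compare_all([a1, a2, b], method="ces", seed=0)
        assert sm.values[0, 1] <= 0.05
        assert sm.values[0, 2] == pytest.approx(LN2, abs=1e-6)
        assert sm.values[1, 2] == pytest.approx(LN2, abs=1e-6)

    @pytest.mark.parametrize("method", ["hes", "ces"])
    def test_input_order_permutes_rows_without_changing_values(
        self, method, tight_ensemble, far_ensemble
    ):
        a = tight_ensemble.subset(np.arange(60), label="A")
        b = far_ensemble.subset(np.arange(60), label="B")
        c = tight_ensemble.subset(np.arange(60, 120), label="C")
        sm = ec.compare_all([a, b, c], method=method, seed=0)
        perm = ec.compare_all([c, a, b], method=method, seed=0)
        order = [perm.labels.index(lbl) for lbl in sm.labels]
        reordered = perm.values[np.ix_(order, order)]
        # HES values are O(1e4); allow float-summation-order noise there
        tol = {"hes": dict(rtol=1e-9), "ces": dict(atol=1e-12)}[method]
        np.testing.assert_allclose(reordered, sm.values, **tol)

    def test_symmetry_and_zero_diagonal(self, tight_ensemble, far_ensemble):
        sm = ec.compare_all(
            [tight_ensemble.subset(np.arange(40)), far_ensemble.subset(np.arange(40))],
            method="ces", seed=0,
        )
        assert np.array_equal(sm.values, sm.values.T)
        assert np.diagonal(sm.values).max() == 0.0
        assert sm.values.max() <= LN2

    def test_preloaded_matrix_reproduces_fresh_result_bit_exactly(
        self, tight_ensemble, far_ensemble
    ):
        pair = [
            tight_ensemble.subset(np.arange(50)),
            far_ensemble.subset(np.arange(50)),
        ]
        matrix = ec.rmsd_matrix(pair)
        fresh = ec.compare_all(pair, method="ces", seed=0)
        cached = ec.compare_all(pair, method="ces", matrix=matrix, seed=0)
        assert np.array_equal(fresh.values, cached.values)

    def test_mixed_atom_counts_raise(self, tight_ensemble):
        other = ec.Ensemble("o", np.random.default_rng(0).normal(size=(5, 7, 3)))
        with pytest.raises(TopologyError):
            ec.compare_all([tight_ensemble, other], method="ces")

    def test_single_ensemble_raises(self, tight_ensemble):
        with pytest.raises(InputError):
            ec.compare_all([tight_ensemble], method="ces")


class TestBootstrap:
    def test_null_case_small_mean_and_std(self, chain_center, far_center):
        third = ec.displaced_center(chain_center, 20.0, seed=61)
        states = [(chain_center, 0.5, 0.4), (far_center, 0.5, 0.35), (third, 0.5, 0.25)]
        ens, _ = ec.make_multistate_ensemble(
            ec.SyntheticSpec(20, states, 120, seed=62, label="m")
        )
        copy = ens.subset(np.arange(120), label="c")
        report = ec.bootstrap_uncertainty(
            ens, copy, method="ces", n_replicates=50, seed=0
        )
        assert report.mean <= 0.05
        assert report.std <= 0.05

    def test_minimal_two_replicates_populate_fields(self, tight_ensemble, far_ensemble):
        report = ec.bootstrap_uncertainty(
            tight_ensemble.subset(np.arange(30)),
            far_ensemble.subset(np.arange(30)),
            method="ces", n_replicates=2, seed=1,
        )
        assert report.n_replicates == len(report.replicates) == 2
        assert report.std >= 0
        assert report.point_estimate == pytest.approx(LN2, abs=1e-6)

    def test_deterministic_given_seed(self, tight_ensemble, far_ensemble):
        args = (
            tight_ensemble.subset(np.arange(25)),
            far_ensemble.subset(np.arange(25)),
        )
        r1 = ec.bootstrap_uncertainty(*args, method="hes", n_replicates=5, seed=7)
        r2 = ec.bootstrap_uncertainty(*args, method="hes", n_replicates=5, seed=7)
        assert np.array_equal(r1.replicates, r2.replicates)

    def test_invalid_replicate_count_raises(self, tight_ensemble):
        with pytest.raises(InputError):
            ec.bootstrap_uncertainty(
                tight_ensemble, tight_ensemble, n_replicates=1
            )


class TestConvergenceProfile:
    def test_full_window_gives_exact_zero(self, lowrank_ensemble):
        small = lowrank_ensemble.subset(np.arange(80))
        profile = ec.convergence_profile(
            small, window_lengths=[80], method="ces", seed=0
        )
        assert profile.divergences[0] == 0.0

    def test_change_point_keeps_profile_at_analytic_plateau(
        self, chain_center, far_center
    ):
        """A trajectory that switches state half-way: every pre-switch prefix
        contains only state A, so its divergence from the (50/50) full
        ensemble is the analytic JS((1,0),(0.5,0.5)) ~= 0.216."""
        ea = ec.make_harmonic_ensemble(
            ec.SyntheticSpec(20, [(chain_center, 0.5, 1.0)], 100, seed=51)
        )
        eb = ec.make_harmonic_ensemble(
            ec.SyntheticSpec(20, [(far_center, 0.5, 1.0)], 100, seed=52)
        )
        switch = ec.Ensemble("switch", np.concatenate([ea.coords, eb.coords]))
        profile = ec.convergence_profile(
            switch, window_lengths=[50, 100, 150, 200], method="ces", seed=0
        )
        plateau = ec.js_divergence_discrete([1.0, 0.0], [0.5, 0.5])
        # small windows carry some extra-cluster small-sample bias
        assert profile.divergences[0] == pytest.approx(plateau, abs=0.06)
        assert profile.divergences[1] == pytest.approx(plateau, abs=0.02)
        assert profile.divergences[2] < 0.1  # window past the switch point
        assert profile.divergences[-1] == 0.0

    def test_bad_windows_raise(self, tight_ensemble):
        with pytest.raises(InputError):
            ec.convergence_profile(tight_ensemble, window_lengths=[])
        with pytest.raises(InputError):
            ec.convergence_profile(tight_ensemble, window_lengths=[50, 50])
        with pytest.raises(InputError):
            ec.convergence_profile(tight_ensemble, window_lengths=[100, 500])


class TestSparsify:
    def test_keep_every_one_is_identity(self, tight_ensemble):
        out = ec.sparsify_ensemble(tight_ensemble, 1)
        assert np.array_equal(out.coords, tight_ensemble.coords)

    @pytest.mark.parametrize("n,k", [(200, 3), (200, 7), (17, 5)])
    def test_frame_count_is_ceil_n_over_k(self, tight_ensemble, n, k):
        ens = tight_ensemble.subset(np.arange(n))
        assert ec.sparsify_ensemble(ens, k).n_frames == -(-n // k)

    def test_decimation_to_too_few_frames_raises(self, tight_ensemble):
        with pytest.raises(InputError):
            ec.sparsify_ensemble(tight_ensemble.subset(np.arange(4)), 4)

    def test_curve_reports_small_divergence_for_well_mixed_fixture(
        self, lowrank_ensemble
    ):
        curve = ec.sparsification_curve(
            lowrank_ensemble, method="ces", keep_every=(2, 4), seed=0
        )
        assert curve.n_frames.tolist() == [100, 50]
        assert curve.divergences.max() <= 0.1


class TestProjection2d:
    def test_two_points_separated_by_their_divergence(self):
        sm = ec.SimilarityMatrix(
            "ces", ["a", "b"], np.array([[0.0, 0.42], [0.42, 0.0]])
        )
        coords = ec.project_similarity_2d(sm, seed=0)
        assert np.linalg.norm(coords[0] - coords[1]) == pytest.approx(0.42, abs=1e-9)
        np.testing.assert_allclose(coords.mean(axis=0), 0.0, atol=1e-9)

    def test_valid_triangle_is_reproduced_exactly(self):
        d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        sm = ec.SimilarityMatrix("ces", list("abc"), d)
        coords = ec.project_similarity_2d(sm, seed=0)
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(
                    d[i, j], abs=1e-6
                )

    def test_random_matrix_stress_competitive_with_restart_oracle(self):
        rng = np.random.default_rng(12)
        raw = rng.uniform(0.1, 1.0, size=(4, 4))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0.0)
        sm = ec.SimilarityMatrix("ces", list("abcd"), d)
        ours = _stress(ec.project_similarity_2d(sm, seed=0), d)
        # brute-force oracle: many independent majorization runs from
        # random starts
        best = np.inf
        for trial in range(20):
            start = rng.uniform(-1, 1, size=(4, 2))
            best = min(best, _stress(_smacof(d, start, n_iter=500), d))
        assert ours <= best * 1.05 + 1e-12

    def test_too_small_matrix_raises(self):
        sm = ec.SimilarityMatrix("ces", ["a"], np.zeros((1, 1)))
        with pytest.raises(InputError):
            ec.project_similarity_2d(sm)
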