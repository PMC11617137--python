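"""Second moments, variational ReML fitting, and component evidence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vrsa.components import build_components, component_matrices
from vrsa.core import (
    FitResult,
    component_evidence,
    component_evidence_refit,
    fit_components,
    fit_gram_batch,
    group_evidence,
    second_moment,
)
from vrsa.synth import GenerativeSpec, generate_patterns


def _draw(weights, n_voxels, seed, noise_var=1.0):
    spec = GenerativeSpec(weights=weights, noise_var=noise_var, n_voxels=n_voxels,
                          n_subjects=1, n_runs=1, rng_seed=seed)
    return generate_patterns(spec).patterns[(0, 0)].values


class TestSecondMoment:
    def test_zero_patterns_give_zero_matrix(self):
        np.testing.assert_array_equal(second_moment(np.zeros((8, 5))).G, 0.0)

    def test_hand_computed_outer_product(self):
        U = np.array([[1.0, 2.0], [3.0, 4.0]])
        S = second_moment(U, center=False, normalize=False)
        np.testing.assert_allclose(S.G, [[5.0, 11.0], [11.0, 25.0]])

    def test_orthonormal_rows_give_identity(self):
        U = np.eye(8)
        S = second_moment(U, center=False, normalize=False)
        np.testing.assert_allclose(S.G, np.eye(8))

    def test_centering_removes_shared_voxel_means(self, rng):
        U = rng.normal(size=(8, 100)) + 7.0 * rng.normal(size=100)
        G = second_moment(U, center=True).G
        # the all-ones direction carries no energy after centering
        ones = np.ones(8) / np.sqrt(8)
        assert ones @ G @ ones == pytest.approx(0.0, abs=1e-10)

    def test_non_finite_input_rejected(self):
        U = np.zeros((8, 3))
        U[0, 0] = np.inf
        with pytest.raises(ValueError):
            second_moment(U)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_spectrum_invariant_under_condition_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        U = rng.normal(size=(8, 30))
        G = second_moment(U).G
        perm = rng.permutation(8)
        G_perm = second_moment(U[perm]).G
        np.testing.assert_allclose(
            np.linalg.eigvalsh(G), np.linalg.eigvalsh(G_perm), atol=1e-10
        )
        assert np.trace(G_perm) == pytest.approx(np.trace(G))


class TestFitComponents:
    def test_pure_noise_recovers_unit_noise_and_no_components(self):
        U = _draw({}, 10000, seed=1)
        res = fit_components(U)
        w = res.weights
        assert w["noise"] == pytest.approx(1.0, rel=0.05)
        for name in component_matrices():
            assert w[name] < 0.05
        assert res.converged

    def test_planted_component_recovered_within_ten_percent(self):
        U = _draw({"ET_dist": 2.0}, 10000, seed=2)
        res = fit_components(U)
        assert res.weights["ET_dist"] == pytest.approx(2.0, rel=0.10)
        assert res.weights["noise"] == pytest.approx(1.0, rel=0.10)

    def test_recovery_error_decreases_with_voxel_count(self):
        sizes = (500, 2000, 10000)
        rmse = []
        for n_vox in sizes:
            errs = [
                fit_components(_draw({"ET_dist": 2.0}, n_vox, seed=100 + r)).weights[
                    "ET_dist"
                ]
                - 2.0
                for r in range(6)
            ]
            rmse.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert rmse[0] > rmse[1] > rmse[2]

    def test_penalized_objective_ascends_across_iterations(self):
        # J(h) = loglik - prior quadratic must be non-decreasing in max_iter.
        from vrsa.core import PRIOR_MEAN, PRIOR_VAR, _prepare_problem

        U = _draw({"T_dir": 1.0}, 500, seed=5)
        S = second_moment(U)
        Sp, Q, _ = _prepare_problem(S.G, build_components(), True)
        m = Q.shape[0]
        pm = np.full(m, PRIOR_MEAN)
        pv = np.full(m, PRIOR_VAR)
        Js = []
        for k in (1, 2, 4, 8, 64):
            h, C, F, ll, iters, conv = fit_gram_batch(
                Sp[None], S.n_voxels, Q, pm[None], pv[None], max_iter=k
            )
            quad = 0.5 * np.sum((h[0] - pm) ** 2 / pv)
            Js.append(ll[0] - quad)
        assert all(b >= a - 1e-6 for a, b in zip(Js, Js[1:]))

    def test_loglik_matches_closed_form_mle_with_flat_prior(self):
        # Noise-only model: MLE sigma^2 = tr(S)/d, with an analytic maximum.
        rng = np.random.default_rng(3)
        U = rng.normal(size=(8, 400)) * 1.3
        res = fit_components(U, components=[], center=False,
                             prior_mean=-32.0, prior_var=1e6)
        d, n = 8, 400
        S = second_moment(U, center=False).G
        s2 = np.trace(S) / d
        L_max = -0.5 * n * (d * np.log(2 * np.pi) + d * np.log(s2) + d)
        assert res.weights["noise"] == pytest.approx(s2, rel=1e-3)
        assert res.loglik == pytest.approx(L_max, abs=0.5)

    def test_raw_matrix_requires_voxel_count(self):
        with pytest.raises(ValueError, match="n_voxels"):
            from vrsa.core import fit_gram

            fit_gram(np.eye(8), build_components(), center=False)


class TestComponentEvidence:
    def test_absent_components_cost_little_to_remove(self):
        res = fit_components(_draw({}, 10000, seed=1))
        dF = component_evidence(res)
        # removing an unsupported component changes the evidence by at most a
        # few nats (an Occam bonus when a weight has drifted slightly positive)
        assert max(abs(v) for v in dF.values()) < 5.0

    def test_strongly_planted_component_has_large_negative_evidence(self):
        res = fit_components(_draw({"ET_dist": 4.0}, 10000, seed=6))
        dF = component_evidence(res)
        assert dF["ET_dist"] < -10.0
        others = [v for k, v in dF.items() if k != "ET_dist"]
        assert all(v > dF["ET_dist"] / 100 for v in others)

    def test_bmr_agrees_with_refit_for_unsupported_components(self):
        res = fit_components(_draw({}, 2000, seed=7))
        bmr = component_evidence(res, method="bmr")
        refit = component_evidence(res, method="refit")
        for name, w in res.weights.items():
            if name != "noise" and w < 1e-6:  # posterior collapsed onto the pin
                assert bmr[name] == pytest.approx(refit[name], abs=1.0)

    def test_bmr_overstates_evidence_for_supported_components(self):
        # Documented divergence: the Gaussian identity extrapolates the
        # quadratic posterior down to the pin and overshoots the exact refit.
        res = fit_components(_draw({"ET_dist": 4.0}, 10000, seed=6))
        bmr = component_evidence(res, method="bmr")
        refit = component_evidence(res, method="refit")
        assert bmr["ET_dist"] < refit["ET_dist"] < -10.0

    def test_unknown_method_rejected(self):
        res = fit_components(_draw({}, 200, seed=1))
        with pytest.raises(ValueError):
            component_evidence(res, method="exhaustive")

    def test_refit_wrapper_matches_fit_then_score(self):
        U = _draw({"T_dir": 2.0}, 1000, seed=9)
        direct = component_evidence_refit(U)
        via_fit = component_evidence(fit_components(U))
        assert direct == pytest.approx(via_fit)


class TestGroupEvidence:
    def test_single_subject_is_identity(self):
        d = {"ET_dist": -3.0}
        assert group_evidence([d]) == d

    def test_two_identical_subjects_double_the_evidence(self):
        d = {"ET_dist": -3.0, "T_dir": 1.0}
        assert group_evidence([d, d]) == {"ET_dist": -6.0, "T_dir": 2.0}

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_evidence([])

    def test_group_evidence_beats_every_subject_for_strong_planting(
        self, tiny_strong_dataset
    ):
        from vrsa.glm import assemble_U

        per_subject = []
        for s in tiny_strong_dataset.subjects:
            U = assemble_U(tiny_strong_dataset.runs(s))
            per_subject.append(component_evidence(fit_components(U.values)))
        grp = group_evidence(per_subject)
        assert all(grp["ET_dist"] < d["ET_dist"] for d in per_subject)
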