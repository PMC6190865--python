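"""Random-effects group BMS: Dirichlet fixed point, PPM/EPM, FFX ops."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bmsmaps import (
    DataError,
    DirichletPosterior,
    bayes_factor_to_posterior,
    exceedance_probabilities,
    group_bayes_factor,
    posterior_model_probabilities,
    rfx_update,
    voxelwise_bms,
)
from conftest import exact_rfx_posterior_mean_k2


class TestRfxUpdate:
    def test_identical_rows_force_symmetric_counts(self):
        """Zero-information rows split counts evenly: alpha = alpha0 + N/K."""
        dp, sp = rfx_update(np.zeros((10, 2)))
        np.testing.assert_allclose(dp.alpha, [6.0, 6.0])
        np.testing.assert_allclose(
            posterior_model_probabilities(dp), [0.5, 0.5]
        )
        np.testing.assert_allclose(sp.u_normalised, 0.5)

    def test_decisive_rows_reduce_to_counting(self):
        """Three subjects favouring model 1 by 10 nats: alpha ~ [4, 1]."""
        lev = np.column_stack([np.full(3, 10.0), np.zeros(3)])
        dp, sp = rfx_update(lev)
        np.testing.assert_allclose(dp.alpha, [4.0, 1.0], atol=1e-3)
        np.testing.assert_allclose(sp.u_normalised[:, 0], 1.0, atol=1e-3)

    def test_row_shift_invariance(self, rng):
        lev = rng.normal(0, 2, size=(6, 3))
        shifts = rng.normal(0, 50, size=6)
        dp1, sp1 = rfx_update(lev)
        dp2, sp2 = rfx_update(lev + shifts[:, None])
        np.testing.assert_allclose(dp1.alpha, dp2.alpha, atol=1e-9)
        np.testing.assert_allclose(sp1.u_normalised, sp2.u_normalised, atol=1e-9)

    def test_count_conservation(self, rng):
        for _ in range(5):
            N, K = int(rng.integers(1, 30)), int(rng.integers(2, 5))
            lev = rng.normal(0, 3, size=(N, K))
            dp, _ = rfx_update(lev)
            assert dp.alpha.sum() == pytest.approx(dp.alpha0.sum() + N, abs=1e-6)
            assert (dp.alpha >= dp.alpha0 - 1e-9).all()

    def test_monotone_in_evidence(self):
        """Raising one subject's evidence for model 1 never lowers alpha_1."""
        base = np.array([[1.0, 0.0], [0.0, 2.0], [0.5, 0.0]])
        alphas = []
        for bump in [0.0, 1.0, 3.0, 10.0]:
            lev = base.copy()
            lev[0, 0] += bump
            dp, _ = rfx_update(lev)
            alphas.append(dp.alpha[0])
        assert np.all(np.diff(alphas) >= -1e-9)

    def test_input_validation(self):
        with pytest.raises(DataError):
            rfx_update(np.array([[1.0, np.inf]]))
        with pytest.raises(DataError):
            rfx_update(np.zeros((3, 1)))
        with pytest.raises(DataError):
            rfx_update(np.zeros((3, 2)), alpha0=[1.0, 0.0])

    def test_matches_exact_hierarchy_inversion_on_decisive_groups(self):
        """Brute-force quadrature of the Dirichlet hierarchy agrees with the
        fixed point when per-subject evidence is decisive or flat."""
        cases = [
            [[10.0, 0.0]],
            [[10.0, 0.0], [0.0, 10.0]],
            [[12.0, 0.0], [9.0, 0.0], [0.0, 11.0]],
            [[10.0, 0.0], [15.0, 0.0], [8.0, 0.0], [0.0, 10.0]],
            [[10.0, 0.0], [0.0, 10.0], [0.0, 0.0]],
        ]
        for lev in cases:
            lev = np.asarray(lev)
            dp, _ = rfx_update(lev)
            vb = posterior_model_probabilities(dp)[0]
            exact = exact_rfx_posterior_mean_k2(lev)
            assert vb == pytest.approx(exact, abs=0.02)


class TestPosteriorProbabilities:
    @pytest.mark.parametrize(
        "alpha,expected",
        [([4, 1], [0.8, 0.2]), ([1, 1, 1], [1 / 3, 1 / 3, 1 / 3])],
    )
    def test_direct_ratio(self, alpha, expected):
        dp = DirichletPosterior(
            alpha=alpha, alpha0=np.ones(len(alpha)), beta=np.asarray(alpha) - 1,
            n_subjects=int(sum(alpha) - len(alpha)),
        )
        np.testing.assert_allclose(posterior_model_probabilities(dp), expected)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.floats(0.1, 50), min_size=2, max_size=6))
    def test_normalised_and_open_interval(self, alpha):
        dp = DirichletPosterior(
            alpha=alpha, alpha0=np.full(len(alpha), 0.1),
            beta=np.asarray(alpha) - 0.1, n_subjects=1,
        )
        r = posterior_model_probabilities(dp)
        assert r.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all((r > 0) & (r < 1))


class TestExceedance:
    def _dp(self, alpha):
        a = np.asarray(alpha, float)
        return DirichletPosterior(
            alpha=a, alpha0=np.ones(a.size), beta=a - 1.0,
            n_subjects=int(a.sum() - a.size),
        )

    @pytest.mark.parametrize(
        "alpha,phi1",
        [([1, 1], 0.5), ([3, 1], 0.875), ([4, 1], 0.9375)],
    )
    def test_two_model_closed_form(self, alpha, phi1):
        # phi_1 = P(Beta(a1, a2) > 1/2): e.g. 1 - 0.5^3 = 0.875 for (3, 1)
        phi = exceedance_probabilities(self._dp(alpha))
        assert phi[0] == pytest.approx(phi1, abs=1e-12)
        assert phi.sum() == pytest.approx(1.0)

    def test_monte_carlo_agrees_with_closed_form(self):
        n = 1_000_000
        rng = np.random.default_rng(77)
        draws = rng.dirichlet([3.0, 1.0], size=n)
        mc = np.mean(draws[:, 0] > draws[:, 1])
        se = np.sqrt(mc * (1 - mc) / n)
        assert abs(mc - 0.875) <= 3 * se

    def test_three_model_mc_matches_integral_identity(self):
        # exchangeable alpha: every model exceeds with probability 1/K
        dp = self._dp([2.0, 2.0, 2.0])
        phi = exceedance_probabilities(dp, n_samples=200_000, seed=5)
        np.testing.assert_allclose(phi, 1 / 3, atol=0.01)
        assert phi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning, match="small"):
            exceedance_probabilities(self._dp([2, 1, 1]), n_samples=100, seed=0)


class TestFfx:
    def test_bf20_landmark_and_complementarity(self):
        assert bayes_factor_to_posterior(20.0) == pytest.approx(20 / 21)
        assert bayes_factor_to_posterior(20.0) > 0.95
        assert bayes_factor_to_posterior(1.0) == 0.5
        for b in [0.2, 1.0, 7.5]:
            assert bayes_factor_to_posterior(b) + bayes_factor_to_posterior(
                1 / b
            ) == pytest.approx(1.0)
        with pytest.raises(DataError):
            bayes_factor_to_posterior(0.0)

    def test_group_bayes_factor_additivity_and_identity(self):
        lev = np.array([[1.0, 0.0], [2.0, 0.0]])
        assert group_bayes_factor(lev, 0, 1) == pytest.approx(3.0)
        assert group_bayes_factor(lev, 1, 1) == 0.0

    def test_rfx_robust_to_outlier_where_ffx_is_not(self):
        """Nine subjects at +1 nat, one at -50: log GBF = -41 flips the FFX
        verdict, while the RFX frequency estimate stays above 0.5."""
        lev = np.zeros((10, 2))
        lev[:9, 0] = 1.0
        lev[9, 0] = -50.0
        assert group_bayes_factor(lev, 0, 1) == pytest.approx(-41.0)
        dp, _ = rfx_update(lev)
        assert posterior_model_probabilities(dp)[0] > 0.5


class TestVoxelwise:
    def test_constant_evidence_rows_give_spatially_constant_ppm(self, rng):
        from bmsmaps import GridMeta, LogEvidenceMaps

        row = rng.normal(0, 2, size=(5, 2))
        mask = np.ones((3, 4, 2), bool)
        mask[0, 0, 0] = False
        ev = np.repeat(row[:, :, None], mask.size, axis=2)
        ev[:, :, ~mask.ravel()] = np.nan
        maps = LogEvidenceMaps(
            evidences=ev, mask=mask, grid_meta=GridMeta((1, 1, 1)),
            model_names=["a", "b"], subject_ids=[f"s{i}" for i in range(5)],
        )
        res = voxelwise_bms(maps, seed=0)
        in_ppm = res.ppm[0][mask]
        assert np.ptp(in_ppm) < 1e-9
        assert np.isnan(res.ppm[0][0, 0, 0])
        dp, _ = rfx_update(row)
        assert in_ppm[0] == pytest.approx(posterior_model_probabilities(dp)[0])

    def test_model_permutation_permutes_maps(self, small_maps):
        res = voxelwise_bms(small_maps, seed=1)
        flipped = type(small_maps)(
            evidences=small_maps.evidences[:, ::-1],
            mask=small_maps.mask,
            grid_meta=small_maps.grid_meta,
            model_names=list(small_maps.model_names[::-1]),
            subject_ids=list(small_maps.subject_ids),
        )
        res_f = voxelwise_bms(flipped, seed=1)
        np.testing.assert_allclose(res.ppm[0], res_f.ppm[1], atol=1e-9, equal_nan=True)
        np.testing.assert_allclose(res.epm[1], res_f.epm[0], atol=1e-9, equal_nan=True)

    def test_ppm_normalisation_and_count_conservation(self, small_result):
        mask = small_result.mask
        total = small_result.ppm.sum(axis=0)[mask]
        np.testing.assert_allclose(total, 1.0, atol=1e-9)
        alpha_sum = small_result.alpha.sum(axis=0)[mask]
        np.testing.assert_allclose(
            alpha_sum, small_result.alpha0.sum() + small_result.n_subjects, atol=1e-5
        )
        epm_sum = small_result.epm.sum(axis=0)[mask]
        np.testing.assert_allclose(epm_sum, 1.0, atol=1e-9)  # K=2 closed form

    def test_masked_evidence_is_an_error(self, small_maps):
        broken = type(small_maps)(
            evidences=small_maps.evidences.copy(),
            mask=small_maps.mask,
            grid_meta=small_maps.grid_meta,
            model_names=list(small_maps.model_names),
            subject_ids=list(small_maps.subject_ids),
        )
        col = np.flatnonzero(broken.mask.ravel())[0]
        broken.evidences[0, 0, col] = np.nan
        with pytest.raises(DataError, match="non-finite"):
            voxelwise_bms(broken, seed=0)

    def test_result_round_trip(self, small_result, tmp_path):
        from bmsmaps import read_bms_result, write_bms_result

        write_bms_result(small_result, tmp_path, run_info={"seed": 3})
        back = read_bms_result(tmp_path)
        assert back.model_names == small_result.model_names
        np.testing.assert_allclose(
            back.ppm[:, back.mask], small_result.ppm[:, small_result.mask],
            rtol=2e-6, atol=1e-6,
        )
        np.testing.assert_array_equal(back.mask, small_result.mask)
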