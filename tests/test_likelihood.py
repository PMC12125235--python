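import itertools
import math

import numpy as np
import pytest

from conftest import censored_jdf_batch, ordered_window_integral
from omelrrss import GEDParams, SchemeConfig
from omelrrss.ged import krecord_cdf, krecord_pdf, krecord_sf, RecordSpec
from omelrrss.likelihood import (TruncationPolicy, build_dist_matrix,
                                 likelihood_permanent, likelihood_series,
                                 loglik, mle_theta, permanent, series_terms)
from omelrrss.sampling import (CensoredSample, SampleSizeModel, SchemeConfig,
                               sample_melrrss_marginal)


class TestPermanent:
    def test_two_by_two(self):
        assert permanent([[1.0, 2.0], [3.0, 4.0]]) == pytest.approx(10.0)

    @pytest.mark.parametrize("n", [2, 4, 6])
    def test_identity(self, n):
        assert permanent(np.eye(n)) == pytest.approx(1.0)

    def test_matches_brute_force_5x5(self, rng):
        M = rng.uniform(size=(5, 5))
        brute = sum(math.prod(M[i, p[i]] for i in range(5))
                    for p in itertools.permutations(range(5)))
        assert permanent(M) == pytest.approx(brute, rel=1e-12)

    def test_batched_equals_scalar(self, rng):
        M = rng.uniform(size=(7, 4, 4))
        batch = permanent(M)
        for j in range(7):
            assert batch[j] == pytest.approx(permanent(M[j]), rel=1e-12)

    def test_rejects_non_square(self):
        with pytest.raises(ValueError):
            permanent(np.ones((2, 3)))


class TestDistMatrix:
    def test_structure_and_ranges(self):
        scheme = SchemeConfig(1, 3, 1)
        p = GEDParams(1.2, 1.0)
        vals = np.array([0.2, 0.5, 0.9, 1.4])
        dm = build_dist_matrix(CensoredSample(vals, 2, 3, "ascending"),
                               scheme, p)
        assert dm.entries.shape == (4, 4)
        # censor rows are probabilities
        assert np.all((dm.entries[0] >= 0) & (dm.entries[0] <= 1))
        assert np.all((dm.entries[3] >= 0) & (dm.entries[3] <= 1))

    def test_complete_sample_all_density_rows(self):
        scheme = SchemeConfig(1, 2, 0)
        p = GEDParams(1.2, 1.0)
        vals = np.array([0.3, 0.8])
        dm = build_dist_matrix(CensoredSample(vals, 1, 2, "ascending"),
                               scheme, p)
        for row, z in enumerate(vals):
            for col, i in enumerate(scheme.record_indices):
                assert dm.entries[row, col] == pytest.approx(
                    krecord_pdf(z, RecordSpec(i, 1), p), rel=1e-10)


class TestNormalizationAndOrientation:
    @pytest.mark.parametrize("m1,m2,k,r,s", [
        (1, 0, 1, 1, 1), (1, 1, 1, 1, 2), (2, 0, 2, 1, 2),
        (2, 1, 1, 1, 3), (3, 0, 1, 1, 3)])
    def test_uncensored_jdf_integrates_to_one(self, m1, m2, k, r, s):
        val = ordered_window_integral(SchemeConfig(k, m1, m2),
                                      GEDParams(1.3, 1.0), r, s, nodes=72)
        assert val == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("m1,m2,r,s", [(2, 1, 2, 3), (2, 1, 2, 2),
                                           (1, 1, 2, 2), (2, 1, 1, 2)])
    def test_censored_jdf_integrates_to_one(self, m1, m2, r, s):
        """Censoring blocks present: this discriminates the censor-tail
        orientation (the swapped assignment integrates to != 1)."""
        val = ordered_window_integral(SchemeConfig(1, m1, m2),
                                      GEDParams(1.3, 1.0), r, s, nodes=72)
        assert val == pytest.approx(1.0, abs=1e-4)

    def test_swapped_orientation_fails_normalization(self):
        """One left-censor row plus a two-point window discriminates the
        censor-tail assignment: the correct one integrates to 1, the swapped
        one to sum_perms P(slot is the minimum) = 2."""
        scheme = SchemeConfig(1, 2, 1)
        p = GEDParams(1.3, 1.0)
        nodes = 72
        x, w = np.polynomial.legendre.leggauss(nodes)
        x = 0.5 * (x + 1.0)
        w = 0.5 * w
        zmax = 15.0
        z3 = zmax * x
        z2 = np.multiply.outer(z3, x)                       # z2 < z3
        W = np.multiply.outer(zmax * w * z3, w).ravel()
        Z2, Z3 = z2.ravel(), np.broadcast_to(z3[:, None], z2.shape).ravel()
        M = np.empty((Z2.size, 3, 3))
        for col, i in enumerate(scheme.record_indices):
            rs = RecordSpec(i, 1)
            M[:, 0, col] = krecord_sf(Z2, rs, p)    # swapped: P(W > z_r)
            M[:, 1, col] = krecord_pdf(Z2, rs, p)
            M[:, 2, col] = krecord_pdf(Z3, rs, p)
        val = float(np.sum(W * permanent(M)))       # /(r-1)! = /1
        assert val == pytest.approx(2.0, abs=1e-3)

    def test_permanent_form_matches_direct_assembly(self, rng):
        scheme = SchemeConfig(2, 2, 1)
        p = GEDParams(0.8, 1.5)
        Z = np.sort(rng.uniform(0.1, 2.0, size=(5, 2)), axis=1)
        direct = censored_jdf_batch(Z, scheme, p, 2, 3)
        for row, z in enumerate(Z):
            sample = CensoredSample(np.array([z[0] / 2, z[0], z[1]]), 2, 3,
                                    "ascending")
            assert likelihood_permanent(0.8, 1.5, sample, scheme) == \
                pytest.approx(direct[row], rel=1e-10)


class TestSeriesForm:
    def test_series_matches_permanent_random_designs(self, rng):
        worst = 0.0
        for _ in range(50):
            m1 = int(rng.integers(1, 4))
            m2 = int(rng.integers(0, m1 + 1))
            n = m1 + m2
            if n < 2:
                continue
            k = int(rng.choice([1, 2, 3]))
            scheme = SchemeConfig(k, m1, m2)
            th = float(rng.uniform(0.3, 3.0))
            lam = float(rng.uniform(0.5, 2.5))
            vals = np.sort(sample_melrrss_marginal(scheme,
                                                   GEDParams(th, lam), rng))
            r = int(rng.integers(1, n))
            s = int(rng.integers(r + 1, n + 1))
            sample = CensoredSample(vals, r, s, "ascending")
            lp = likelihood_permanent(th, lam, sample, scheme)
            ls = likelihood_series(th, lam, sample, scheme)
            worst = max(worst, abs(ls - lp) / lp)
        assert worst < 1e-6

    def test_series_terms_reconstruct_one_permutation(self, rng):
        """Summing theta^eta e^{-theta W} D V over the censor multi-indices of
        one permutation reproduces that permutation's product of record
        pdf/cdf/sf factors."""
        scheme = SchemeConfig(2, 2, 1)
        p = GEDParams(1.4, 1.1)
        vals = np.sort(sample_melrrss_marginal(scheme, p, rng))
        sample = CensoredSample(vals, 2, 2, "ascending")
        desc = sample.as_descending()
        perm = (2, 1, 1)
        direct = (krecord_sf(desc.values[desc.r - 1], RecordSpec(perm[0], 2), p)
                  * krecord_pdf(desc.values[1], RecordSpec(perm[1], 2), p)
                  * krecord_cdf(desc.values[desc.s - 1], RecordSpec(perm[2], 2), p))
        tot = 0.0
        for l0 in range(perm[0], 80):
            for nu in range(perm[2]):
                st = series_terms((l0,), (nu,), perm, sample, 1.1, 2)
                tot += st.D * st.V * p.theta ** st.eta * math.exp(-p.theta * st.W)
        assert tot == pytest.approx(direct, rel=1e-10)

    def test_series_terms_validates_index_ranges(self, rng):
        scheme = SchemeConfig(1, 2, 1)
        vals = np.sort(sample_melrrss_marginal(scheme, GEDParams(1, 1), rng))
        sample = CensoredSample(vals, 2, 2, "ascending")
        with pytest.raises(ValueError):
            series_terms((0,), (0,), (2, 1, 1), sample, 1.0, 1)  # l < i
        with pytest.raises(ValueError):
            series_terms((2,), (1,), (2, 1, 1), sample, 1.0, 1)  # nu > i-1

    def test_degenerate_uniform_size_equals_fixed(self, rng):
        scheme = SchemeConfig(1, 3, 2)
        p = GEDParams(1.0, 1.5)
        vals = np.sort(sample_melrrss_marginal(scheme, p, rng))
        sample = CensoredSample(vals, 2, 4, "ascending")
        fixed = likelihood_series(1.0, 1.5, sample, scheme)
        degen = likelihood_series(1.0, 1.5, sample, scheme,
                                  SampleSizeModel.uniform(5, 5))
        assert degen == pytest.approx(fixed, rel=1e-12)


class TestMLE:
    def test_worked_example_consistency(self):
        # the Newton path and the bounded fallback agree
        vals = np.array([0.01, 0.01, 0.02, 0.05, 0.08, 0.12, 0.59])
        scheme = SchemeConfig(1, 5, 2)
        sample = CensoredSample(vals, 3, 5, "ascending")
        res = mle_theta(sample, scheme, 1.5)
        assert res.converged
        # stationarity of the log-likelihood at the estimate
        th = np.array([res.theta * 0.995, res.theta, res.theta * 1.005])
        ll = loglik(th, sample, scheme, 1.5)
        assert ll[1] >= ll[0] and ll[1] >= ll[2]

    def test_parameter_recovery_complete_samples(self, rng):
        scheme = SchemeConfig(1, 5, 2)
        est = []
        for _ in range(200):
            vals = np.sort(sample_melrrss_marginal(scheme,
                                                   GEDParams(2.0, 1.5), rng))
            est.append(mle_theta(CensoredSample(vals, 1, 7, "ascending"),
                                 scheme, 1.5).theta)
        assert abs(np.mean(est) - 2.0) / 2.0 < 0.15

    def test_scale_equivariance(self, rng):
        scheme = SchemeConfig(1, 3, 1)
        vals = np.sort(sample_melrrss_marginal(scheme, GEDParams(1.5, 1.0), rng))
        s1 = CensoredSample(vals, 2, 3, "ascending")
        s2 = CensoredSample(vals * 3.0, 2, 3, "ascending")
        t1 = mle_theta(s1, scheme, 1.0).theta
        t2 = mle_theta(s2, scheme, 1.0 / 3.0).theta
        assert t1 == pytest.approx(t2, rel=1e-5)

    def test_random_size_mixture_runs(self, rng):
        scheme = SchemeConfig(1, 5, 2)
        vals = np.sort(sample_melrrss_marginal(scheme, GEDParams(1.0, 1.5), rng))
        sample = CensoredSample(vals, 3, 4, "ascending")
        res = mle_theta(sample, scheme, 1.5, SampleSizeModel.uniform(2, 7))
        assert res.theta > 0 and res.converged
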