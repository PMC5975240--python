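"""Random-effects BMS: Dirichlet updates, exceedance probabilities against
the exact beta oracle, family-level aggregation and the omnibus risk."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from speechdcm import bms
from speechdcm import model_space as ms
from speechdcm.bms import DirichletPosterior, LogEvidenceMatrix


def make_L(values):
    values = np.asarray(values, float)
    n, k = values.shape
    return LogEvidenceMatrix(values, [f"s{i}" for i in range(n)], list(range(1, k + 1)))


class TestRfxBms:
    def test_uninformative_evidence_gives_symmetric_counts(self):
        post = bms.rfx_bms(np.zeros((6, 3)))
        assert np.allclose(post.alpha, 1 + 6 / 3, atol=1e-6)

    def test_single_decisive_subject(self):
        post = bms.rfx_bms(np.array([[50.0, -50.0]]))
        assert np.allclose(post.alpha, [2.0, 1.0], atol=1e-6)
        assert np.allclose(post.u, [[1.0, 0.0]], atol=1e-9)

    def test_row_constant_shift_invariance(self, rng):
        L = rng.normal(size=(8, 5))
        shifted = L + rng.normal(size=(8, 1)) * 10
        a = bms.rfx_bms(L).alpha
        b = bms.rfx_bms(shifted).alpha
        assert np.allclose(a, b, atol=1e-6)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_dirichlet_mass_conservation(self, seed):
        g = np.random.default_rng(seed)
        n, k = int(g.integers(2, 20)), int(g.integers(2, 12))
        post = bms.rfx_bms(g.normal(scale=3, size=(n, k)))
        assert abs((post.alpha - post.alpha0).sum() - n) < 1e-6
        assert np.all(post.alpha >= post.alpha0)
        assert np.allclose(post.u.sum(axis=1), 1.0, atol=1e-9)

    def test_rejects_nonfinite_and_bad_alpha0(self):
        with pytest.raises(ValueError):
            bms.rfx_bms(np.array([[np.nan, 0.0]]))
        with pytest.raises(ValueError):
            bms.rfx_bms(np.zeros((2, 2)), alpha0=0.0)


class TestExpectedProbs:
    @pytest.mark.parametrize(
        "alpha,expected", [((1.0, 1.0), (0.5, 0.5)), ((3.0, 1.0), (0.75, 0.25))]
    )
    def test_ratio(self, alpha, expected):
        post = DirichletPosterior(np.array(alpha), np.ones(2), np.zeros((1, 2)), 1, True, 0.0)
        assert np.allclose(bms.expected_probs(post), expected)

    def test_normalised_for_random_alpha(self, rng):
        post = DirichletPosterior(rng.uniform(0.5, 9, 7), np.ones(7), np.zeros((1, 7)), 1, True, 0.0)
        assert bms.expected_probs(post).sum() == pytest.approx(1.0)


class TestExceedance:
    def _post(self, alpha):
        alpha = np.asarray(alpha, float)
        return DirichletPosterior(alpha, np.ones_like(alpha), np.zeros((1, len(alpha))), 1, True, 0.0)

    def test_symmetric_alpha_near_half(self):
        xp = bms.exceedance_probs(self._post([5.0, 5.0]), n_samples=200_000, seed=0)
        assert np.allclose(xp, 0.5, atol=0.01)

    def test_sums_to_one_exactly(self):
        xp = bms.exceedance_probs(self._post([3.0, 1.0, 2.0]), n_samples=50_000, seed=1)
        assert xp.sum() == 1.0  # counts partition the samples

    def test_k2_monte_carlo_matches_beta_integral(self):
        post = self._post([8.0, 4.0])
        exact = bms.exceedance_exact_k2(post)
        # independent oracle: numerical integration of the Beta(8, 4) density
        dens, _ = integrate.quad(lambda x: stats.beta.pdf(x, 8, 4), 0.5, 1.0)
        assert exact[0] == pytest.approx(dens, abs=1e-9)
        mc = bms.exceedance_probs(post, n_samples=1_000_000, seed=2)
        assert np.abs(mc - exact).max() < 0.01

    def test_minimum_sample_count_enforced(self):
        with pytest.raises(ValueError):
            bms.exceedance_probs(self._post([1.0, 1.0]), n_samples=100)


class TestFamilyBms:
    def test_prior_equalisation_with_unequal_family_sizes(self):
        # 2 + 6 models, no information: family probabilities should be ~1/2
        L = make_L(np.zeros((10, 8)))
        part = ms.FamilyPartition("custom", {"small": [1, 2], "big": [3, 4, 5, 6, 7, 8]})
        res = bms.family_bms(L, part, n_samples=200_000, seed=3)
        assert np.allclose(res.expected_probs, 0.5, atol=0.02)
        assert np.allclose(res.exceedance_probs, 0.5, atol=0.02)

    def test_strong_uniform_evidence_for_one_family(self, rng):
        vals = rng.normal(scale=0.5, size=(12, 6))
        vals[:, :3] += 6.0  # every subject favours family A's models
        L = make_L(vals)
        part = ms.FamilyPartition("custom", {"A": [1, 2, 3], "B": [4, 5, 6]})
        res = bms.family_bms(L, part, n_samples=200_000, seed=4)
        assert res.exceedance_probs[0] > 0.99

    def test_singleton_families_reduce_to_model_level(self, rng):
        # one model per family: family inference must agree with the
        # model-level comparison under the same uniform prior
        L = make_L(rng.normal(size=(9, 3)))
        part = ms.FamilyPartition("custom", {"A": [1], "B": [2], "C": [3]})
        fam = bms.family_bms(L, part, n_samples=50_000, seed=5)
        mod = bms.model_bms(L, n_samples=50_000, seed=5)
        assert np.allclose(fam.expected_probs, mod.expected_probs, atol=1e-9)
        assert np.allclose(fam.exceedance_probs, mod.exceedance_probs, atol=1e-9)
        assert fam.bor == pytest.approx(mod.bor)

    def test_family_evidence_marginalisation_oracle(self, rng):
        vals = rng.normal(size=(4, 5))
        L = make_L(vals)
        part = ms.FamilyPartition("custom", {"A": [1, 2, 3], "B": [4, 5]})
        Lfam, names = bms.family_evidence(L, part)
        from scipy.special import logsumexp

        assert names == ["A", "B"]
        expect_a = logsumexp(vals[:, :3], axis=1) - np.log(3)
        assert np.allclose(Lfam.values[:, 0], expect_a)

    def test_partition_must_match_columns(self):
        L = make_L(np.zeros((3, 4)))
        part = ms.FamilyPartition("custom", {"A": [1, 2], "B": [3, 9]})
        with pytest.raises(ValueError):
            bms.family_bms(L, part)

    def test_merged_scheme_restricts_to_non_null_models(self):
        # full 96-column matrix: the merged schemes must use 88 columns
        L = make_L(np.zeros((3, 96)))
        part = ms.get_partition("arcuate_vs_arcaslant")
        res = bms.family_bms(L, part, n_samples=50_000, seed=6)
        assert res.n_models_used == 88
        assert len(res.posterior.alpha) == 2  # arcuate vs arcuate-aslant


class TestBor:
    def test_identical_evidences_favour_null(self):
        L = make_L(np.zeros((10, 4)))
        post = bms.rfx_bms(L)
        bor = bms.bayesian_omnibus_risk(L, post)
        assert 0.5 <= bor < 1.0
        # oracle: direct evaluation of the two bounds
        f0 = bms._free_energy_h0(L.values)
        f1 = bms._free_energy_h1(L.values, post)
        assert bor == pytest.approx(1.0 / (1.0 + np.exp(f1 - f0)))

    def test_dominant_model_yields_tiny_risk(self):
        vals = np.zeros((20, 4))
        vals[:, 1] = 5.0
        L = make_L(vals)
        bor = bms.bayesian_omnibus_risk(L, bms.rfx_bms(L))
        assert bor < 0.05

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_bounded_between_zero_and_one(self, seed):
        g = np.random.default_rng(seed)
        L = make_L(g.normal(scale=2, size=(6, 5)))
        bor = bms.bayesian_omnibus_risk(L, bms.rfx_bms(L))
        assert 0.0 < bor < 1.0


class TestResultPlumbing:
    def test_model_bms_summary_and_protected_ep(self, rng):
        L = make_L(rng.normal(size=(6, 4)))
        res = bms.model_bms(L, n_samples=50_000, seed=7)
        assert res.expected_probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert res.exceedance_probs.sum() == pytest.approx(1.0, abs=1e-6)
        expected_pep = (1 - res.bor) * res.exceedance_probs + res.bor / 4
        assert np.allclose(res.protected_exceedance_probs, expected_pep)
        assert set(res.summary().columns) >= {"name", "expected_prob", "exceedance_prob"}

    def test_evidence_matrix_csv_round_trip(self, tmp_path, rng):
        L = make_L(rng.normal(size=(3, 5)))
        path = tmp_path / "L.csv"
        L.to_csv(str(path))
        back = LogEvidenceMatrix.from_csv(str(path))
        assert np.allclose(back.values, L.values)
        assert back.model_ids == L.model_ids

    def test_nonfinite_matrix_rejected(self):
        with pytest.raises(ValueError):
            make_L(np.array([[0.0, np.inf]]))

    def test_fixed_effects_debug_output(self, rng):
        L = make_L(rng.normal(size=(4, 3)))
        gbf = bms.fixed_effects_log_group_bayes_factor(L)
        assert gbf.max() == 0.0 and np.all(gbf <= 0)
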