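import math

import numpy as np
import pytest
from scipy import stats

from zinbda.exceptions import ConfigurationError, ValidationError
from zinbda.model import (PriorConfig, ZINBParams, build_design, log_posterior,
                          log_prior, nb_log_pmf, zinb_log_likelihood)
from zinbda.table_io import CountTable

from conftest import make_metadata


def random_instance(seed, max_cells=20):
    """Random small table + valid parameters + design, for oracle checks."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 6))
    d = int(rng.integers(1, max_cells // n + 1))
    counts = rng.integers(0, 30, (d, n))
    table = CountTable(counts, [f"f{j}" for j in range(d)], [f"s{i}" for i in range(n)])
    diets = rng.choice(["A", "B"], n).tolist()
    diets[0] = "A"  # keep the reference level present
    meta = make_metadata(table.sample_ids, diets, rng.choice(["c1", "c2"], n))
    design = build_design(meta, "A")
    params = ZINBParams(
        beta=rng.normal(0, 1, (design.n_covariates, d)),
        u=rng.normal(0, 1, (design.n_cages, d)),
        pi=rng.uniform(0, 1, d), phi=rng.uniform(0.1, 10, d))
    depths = rng.uniform(10, 1e4, n)
    return table, params, design, depths


def enumeration_loglik(table, params, design, depths):
    """Independent oracle: per-cell sum over the structural-zero indicator."""
    log_eta = design.x @ params.beta + design.z @ params.u + np.log(depths)[:, None]
    mu = np.exp(log_eta)
    total = 0.0
    for i in range(table.n_samples):
        for j in range(table.n_features):
            y = table.counts[j, i]
            nb = stats.nbinom.pmf(y, params.phi[j],
                                  params.phi[j] / (params.phi[j] + mu[i, j]))
            total += math.log(params.pi[j] * (y == 0) + (1 - params.pi[j]) * nb)
    return total


class TestNBLogPmf:
    def test_geometric_case(self):
        # phi=1 is geometric: P(0) = phi/(phi+mu) = 1/3
        assert nb_log_pmf(0, 2.0, 1.0) == pytest.approx(math.log(1 / 3), abs=1e-12)

    def test_matches_scipy_parameterization(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 40, 50)
        mu = rng.uniform(0.01, 50, 50)
        phi = rng.uniform(0.05, 20, 50)
        ref = stats.nbinom.logpmf(y, phi, phi / (phi + mu))
        np.testing.assert_allclose(nb_log_pmf(y, mu, phi), ref, atol=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            nb_log_pmf(1, -2.0, 1.0)
        with pytest.raises(ValidationError):
            nb_log_pmf(1, np.inf, 1.0)


class TestZINBLikelihood:
    def single_cell(self, y, pi, mu, phi):
        table = CountTable(np.array([[y]]), ["f"], ["s"])
        meta = make_metadata(["s"], ["A"], ["c"])
        design = build_design(meta, "A")
        params = ZINBParams(beta=np.array([[math.log(mu)]]), u=np.zeros((1, 1)),
                            pi=[pi], phi=[phi])
        return zinb_log_likelihood(table, params, design, depths=[1.0])

    def test_single_zero_cell_mixture(self):
        # pi + (1-pi) * NB(0 | 2, 1) = 0.5 + 0.5/3 = 2/3
        got = self.single_cell(0, 0.5, 2.0, 1.0)
        assert got == pytest.approx(math.log(2 / 3), abs=1e-12)

    def test_no_inflation_collapses_to_nb(self):
        table, params, design, depths = random_instance(3)
        params.pi[:] = 0.0
        mu = np.exp(design.x @ params.beta + design.z @ params.u
                    + np.log(depths)[:, None])
        plain = stats.nbinom.logpmf(table.counts.T, params.phi,
                                    params.phi / (params.phi + mu)).sum()
        got = zinb_log_likelihood(table, params, design, depths=depths)
        assert got == pytest.approx(plain, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle(self, seed):
        table, params, design, depths = random_instance(seed)
        got = zinb_log_likelihood(table, params, design, depths=depths)
        assert got == pytest.approx(enumeration_loglik(table, params, design, depths),
                                    abs=1e-10)

    def test_invariant_under_sample_permutation(self):
        table, params, design, depths = random_instance(8)
        base = zinb_log_likelihood(table, params, design, depths=depths)
        rng = np.random.default_rng(0)
        perm = rng.permutation(table.n_samples)
        ptable = CountTable(table.counts[:, perm], table.feature_ids,
                            [table.sample_ids[i] for i in perm])
        design.x = design.x[perm]
        design.z = design.z[perm]
        got = zinb_log_likelihood(ptable, params, design, depths=depths[perm])
        assert got == pytest.approx(base, rel=1e-12)

    def test_zero_depth_rejected(self, toy_table, toy_metadata):
        design = build_design(toy_metadata, "A")
        params = ZINBParams(beta=np.zeros((design.n_covariates, 2)),
                            u=np.zeros((design.n_cages, 2)), pi=[0, 0], phi=[1, 1])
        with pytest.raises(ValidationError):
            zinb_log_likelihood(toy_table, params, design, depths=[0.0, 5.0])


class TestLogPrior:
    def test_hand_computed_value(self):
        # single feature, beta=(0,), u absent, pi=0.5, phi=1:
        #   Beta(1.5,1.5) at 0.5: B(1.5,1.5) = pi/8, density = sqrt(.25)/(pi/8) = 4/pi
        #   half-Cauchy(3) at 1/phi=1: 2/(3*pi*(1+1/9)) = 3/(5*pi); Jacobian log(1)=0
        #   Normal(0, sd 5) at 0: -log(5*sqrt(2*pi))
        params = ZINBParams(beta=np.zeros((1, 1)), u=None, pi=[0.5], phi=[1.0])
        expected = (math.log(4 / math.pi) + math.log(3 / (5 * math.pi))
                    - math.log(5 * math.sqrt(2 * math.pi)))
        assert log_prior(params, PriorConfig()) == pytest.approx(expected, abs=1e-12)

    def test_normal_terms_at_mode(self):
        # at beta = u = 0 every Normal term contributes -log(sd * sqrt(2 pi))
        params = ZINBParams(beta=np.zeros((2, 3)), u=np.zeros((2, 3)),
                            pi=np.full(3, 0.5), phi=np.ones(3))
        expected = (3 * math.log(4 / math.pi)
                    + 3 * math.log(3 / (5 * math.pi))
                    - 6 * math.log(5 * math.sqrt(2 * math.pi))
                    - 6 * math.log(2 * math.sqrt(2 * math.pi)))
        assert log_prior(params) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("pi,phi", [(0.5, -1.0), (1.5, 1.0), (-0.1, 1.0)])
    def test_out_of_support_is_minus_inf(self, pi, phi):
        params = ZINBParams(beta=np.zeros((1, 1)), u=None, pi=[pi], phi=[phi])
        assert log_prior(params) == -np.inf


class TestLogPosterior:
    def test_additivity(self):
        table, params, design, depths = random_instance(5)
        priors = PriorConfig()
        total = log_posterior(table, params, design, priors, depths=depths)
        parts = (log_prior(params, priors)
                 + zinb_log_likelihood(table, params, design, depths=depths))
        assert total == pytest.approx(parts, rel=1e-12)

    def test_minus_inf_propagates(self):
        table, params, design, depths = random_instance(6)
        params.phi[0] = -1.0
        assert log_posterior(table, params, design, depths=depths) == -np.inf

    def test_finite_on_random_draw(self):
        table, params, design, depths = random_instance(7)
        assert np.isfinite(log_posterior(table, params, design, depths=depths))


class TestBuildDesign:
    def test_dummy_coding_four_levels(self):
        meta = make_metadata([f"s{i}" for i in range(8)],
                             ["LFD", "LFD", "HFD", "HFD", "A", "A", "B", "B"],
                             [f"c{i // 2}" for i in range(8)])
        design = build_design(meta, "LFD")
        assert design.x.shape == (8, 4)
        assert design.covariate_names[0] == "intercept"
        assert "diet[LFD]" not in design.covariate_names

    def test_cage_one_hot_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        cages = rng.choice([f"c{i}" for i in range(8)], 40)
        meta = make_metadata([f"s{i}" for i in range(40)], ["A"] * 40, cages)
        design = build_design(meta, "A")
        assert design.z.shape[1] == len(np.unique(cages))
        np.testing.assert_array_equal(design.z.sum(axis=1), 1.0)

    def test_unknown_reference_rejected(self, toy_metadata):
        with pytest.raises(ConfigurationError, match="XYZ"):
            build_design(toy_metadata, "XYZ")
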