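import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zinbda.exceptions import (ConfigurationError, DegeneratePartitionError,
                               ValidationError)
from zinbda.inference import DifferentialAbundanceResult
from zinbda.pathways import (compare_groups_lsd, complete_incomplete_log_ratio,
                             compute_completeness, correlate_completeness_with_beta,
                             spearman)
from zinbda.synthetic import SimulationConfig, generate_truth, simulate_genome_annotations
from zinbda.table_io import CountTable


def result_from_means(feature_ids, covariate, means):
    """Build a summary object directly from given CLR means (no sampling)."""
    frame = pd.DataFrame({
        "feature_id": feature_ids, "covariate": covariate,
        "clr_mean": means, "clr_sd": 1.0, "lo": np.asarray(means) - 1,
        "hi": np.asarray(means) + 1})
    return DifferentialAbundanceResult(frame=frame, level=0.95,
                                       reference_feature=feature_ids[0])


class TestCompleteness:
    def test_proportion(self):
        ann = {"g1": {"r1", "r2", "r3"}}
        defs = {"pw": {"r1", "r2", "r3", "r4"}}
        comp = compute_completeness(ann, defs)
        assert comp.frame.loc["g1", "pw"] == 0.75

    def test_complete_classification(self):
        ann = {"g1": {"r1", "r2"}}
        comp = compute_completeness(ann, {"pw": {"r1", "r2"}})
        assert comp.complete_genomes("pw") == {"g1"}

    def test_unannotated_genome_scores_zero(self):
        comp = compute_completeness({"g1": {"r1"}}, {"pw": {"r1"}},
                                    genomes=["g1", "g2"])
        assert comp.frame.loc["g2", "pw"] == 0.0

    def test_recovers_generator_record(self):
        cfg = SimulationConfig(n_features=15, seed=50)
        truth = generate_truth(cfg)
        ann = simulate_genome_annotations(truth, cfg, n_pathways=4,
                                          reactions_per_pathway=5,
                                          complete_fraction=0.4)
        genomes = [f"G{j + 1:04d}" for j in range(15)]
        comp = compute_completeness(ann.annotations, ann.pathway_definitions,
                                    genomes=genomes)
        for p in ann.pathway_definitions:
            assert comp.complete_genomes(p) == ann.complete_genomes[p]


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3], [10, 20, 30])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1])[0] == pytest.approx(-1.0)

    def test_tie_corrected_value(self):
        # average ranks: x -> (1, 2.5, 2.5, 4), y -> (1, 3, 2, 4);
        # Pearson on those ranks = 4.5 / sqrt(22.5)
        rho, _ = spearman([1, 2, 2, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(4.5 / math.sqrt(22.5), abs=1e-10)

    def test_exact_permutation_matches_enumeration(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        rho, p = spearman(x, y, p_method="exact")
        # independent enumeration over all 120 permutations via scipy's rho
        rho_ref = stats.spearmanr(x, y).statistic
        count = 0
        for perm in itertools.permutations(y):
            r = stats.spearmanr(x, perm).statistic
            if abs(r) >= abs(rho_ref) - 1e-12:
                count += 1
        assert rho == pytest.approx(rho_ref, abs=1e-12)
        assert p == count / 120

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_undefined(self):
        rho, p = spearman([1, 1, 1], [1, 2, 3])
        assert np.isnan(rho) and np.isnan(p)

    @pytest.mark.parametrize("transform", [np.exp, lambda v: 3 * v + 1, np.cbrt])
    def test_invariant_under_monotone_transform(self, transform):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=12), rng.normal(size=12)
        base = spearman(x, y)[0]
        assert spearman(transform(x), y)[0] == pytest.approx(base, abs=1e-12)


class TestCorrelateCompleteness:
    def test_planted_signal_ranks_first(self):
        cfg = SimulationConfig(n_features=20, seed=51)
        truth = generate_truth(cfg)
        ann = simulate_genome_annotations(truth, cfg, n_pathways=5,
                                          reactions_per_pathway=4,
                                          complete_fraction=0.4, planted_effect=0)
        genomes = [f"G{j + 1:04d}" for j in range(20)]
        comp = compute_completeness(ann.annotations, ann.pathway_definitions,
                                    genomes=genomes)
        effect = truth.beta_true[0] - truth.beta_true[0].mean()  # CLR of the truth
        result = result_from_means(genomes, "diet[x]", effect)
        corr = correlate_completeness_with_beta(comp, result, "diet[x]")
        assert corr.iloc[0]["pathway"] == "PWY001"
        assert corr.iloc[0]["rho"] > 0

    def test_constant_completeness_undefined(self):
        comp = compute_completeness({"g1": {"r1"}, "g2": {"r1"}, "g3": {"r1"}},
                                    {"pw": {"r1"}})
        result = result_from_means(["g1", "g2", "g3"], "c", [1.0, 2.0, 3.0])
        corr = correlate_completeness_with_beta(comp, result, "c")
        assert np.isnan(corr.iloc[0]["rho"])

    def test_shuffled_labels_lose_signal(self):
        rng = np.random.default_rng(52)
        n = 30
        genomes = [f"g{j}" for j in range(n)]
        values = np.linspace(0, 1, n)
        comp = compute_completeness(
            {g: set() for g in genomes}, {"pw": {"r1"}}, genomes=genomes)
        comp.frame["pw"] = values
        effect = values + rng.normal(0, 0.01, n)  # strong signal when aligned
        insignificant = 0
        for _ in range(100):
            perm = rng.permutation(n)
            result = result_from_means(genomes, "c", effect[perm])
            corr = correlate_completeness_with_beta(comp, result, "c")
            if corr.iloc[0]["p"] > 0.05:
                insignificant += 1
        assert insignificant >= 90


class TestLogRatio:
    def make_table(self, complete_counts, incomplete_counts):
        counts = np.array([complete_counts, incomplete_counts])
        table = CountTable(counts, ["gc", "gi"], ["s1"] if counts.shape[1] == 1
                           else [f"s{i}" for i in range(counts.shape[1])])
        comp = compute_completeness({"gc": {"r1"}, "gi": set()}, {"pw": {"r1"}},
                                    genomes=["gc", "gi"])
        return table, comp

    def test_worked_arithmetic(self):
        table, comp = self.make_table([90], [10])
        series = complete_incomplete_log_ratio(table, comp, "pw", pseudocount=1.0)
        assert series.values.iloc[0] == pytest.approx(math.log(91 / 11), abs=1e-6)

    def test_equal_sums_zero(self):
        table, comp = self.make_table([25], [25])
        series = complete_incomplete_log_ratio(table, comp, "pw", pseudocount=0.0)
        assert series.values.iloc[0] == 0.0

    def test_antisymmetric_under_set_swap(self):
        table, comp = self.make_table([70, 12], [30, 44])
        fwd = complete_incomplete_log_ratio(table, comp, "pw", pseudocount=0.0)
        swapped = comp.frame.copy()
        swapped["pw"] = 1.0 - swapped["pw"]  # complete <-> incomplete
        comp.frame = swapped
        rev = complete_incomplete_log_ratio(table, comp, "pw", pseudocount=0.0)
        np.testing.assert_allclose(rev.values, -fwd.values, atol=1e-12)

    def test_degenerate_partition_rejected(self):
        table = CountTable(np.array([[5], [5]]), ["g1", "g2"], ["s1"])
        comp = compute_completeness({"g1": {"r1"}, "g2": {"r1"}}, {"pw": {"r1"}},
                                    genomes=["g1", "g2"])
        with pytest.raises(DegeneratePartitionError):
            complete_incomplete_log_ratio(table, comp, "pw")

    def test_unknown_pathway_rejected(self):
        table, comp = self.make_table([1], [1])
        with pytest.raises(ConfigurationError):
            complete_incomplete_log_ratio(table, comp, "nope")


class TestFisherLSD:
    def test_textbook_case(self):
        values = np.array([1, 2, 1, 2, 10, 11], dtype=float)
        groups = np.array(["A", "A", "B", "B", "C", "C"])
        f_stat, pairs = compare_groups_lsd(values, groups)
        pairs = pairs.set_index(["group_a", "group_b"])
        assert pairs.loc[("A", "B"), "p"] > 0.5
        assert pairs.loc[("A", "C"), "p"] < 0.01
        assert f_stat > 10

    def test_two_groups_equals_pooled_t_test(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 8)
        _, pairs = compare_groups_lsd(np.concatenate([a, b]),
                                      np.array(["A"] * 6 + ["B"] * 8))
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert pairs.iloc[0]["t"] == pytest.approx(ref.statistic, abs=1e-12)
        assert pairs.iloc[0]["p"] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_all_equal_undefined(self):
        f_stat, pairs = compare_groups_lsd(np.ones(6), np.array(list("AABBCC")))
        assert np.isnan(f_stat)
        assert pairs["p"].isna().all()

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups_lsd(np.arange(3.0), np.array(["A", "A", "B"]))
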