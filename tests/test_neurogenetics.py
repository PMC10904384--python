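import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from gammasfc import (
    GeneMatchError,
    GeneSetCollection,
    InsufficientDataError,
    NodeLabeling,
    ParameterError,
    Partition,
    SyntheticSpec,
    ValidationError,
    aggregate_samples,
    disorder_scores,
    generate_expression,
    group_scores,
)


def expr_from(values, modules, genes):
    frame = pd.DataFrame(values, index=pd.Index(modules, name="module"), columns=genes)
    labeling = NodeLabeling(node_ids=[f"s{m}" for m in modules], labels=list(modules))
    samples = frame.copy()
    samples.index = [f"s{m}" for m in modules]
    return aggregate_samples(samples, labeling)


class TestAggregateSamples:
    def test_one_sample_per_module_is_identity(self):
        expr = expr_from([[1.0, 2.0], [3.0, 4.0]], ["M1", "M2"], ["GA", "GB"])
        assert expr.values.loc["M1", "GA"] == 1.0
        assert expr.values.loc["M2", "GB"] == 4.0

    def test_two_samples_average(self):
        samples = pd.DataFrame({"GA": [1.0, 3.0]}, index=["s1", "s2"])
        lab = NodeLabeling(node_ids=["s1", "s2"], labels=["M1", "M1"])
        expr = aggregate_samples(samples, lab)
        assert expr.values.loc["M1", "GA"] == 2.0
        assert expr.n_samples_per_module["M1"] == 2

    def test_matches_groupby_mean_oracle(self):
        rng = np.random.default_rng(4)
        samples = pd.DataFrame(
            rng.normal(size=(12, 5)),
            index=[f"s{i}" for i in range(12)],
            columns=[f"G{i}" for i in range(5)],
        )
        labels = [f"M{i % 3}" for i in range(12)]
        lab = NodeLabeling(node_ids=list(samples.index), labels=labels)
        expr = aggregate_samples(samples, lab)
        for mod in set(labels):
            rows = [i for i, l in enumerate(labels) if l == mod]
            manual = samples.iloc[rows].to_numpy().mean(axis=0)
            np.testing.assert_allclose(expr.values.loc[mod].to_numpy(), manual, atol=1e-12)

    def test_unlabeled_sample_rejected(self):
        samples = pd.DataFrame({"GA": [1.0]}, index=["s1"])
        lab = NodeLabeling(node_ids=["sX"], labels=["M1"])
        with pytest.raises(ValidationError):
            aggregate_samples(samples, lab)

    def test_empty_expression_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_samples(pd.DataFrame(), NodeLabeling(node_ids=["s"], labels=["M"]))


class TestDisorderScores:
    def test_three_module_hand_example(self):
        expr = expr_from([[1.0], [2.0], [3.0]], ["M1", "M2", "M3"], ["GA"])
        sets = GeneSetCollection(sets={"D1": ["GA"]})
        table = disorder_scores(expr, sets).table
        z = table.set_index("module")["z"]
        # sample sd of (1,2,3) is exactly 1
        assert z["M1"] == pytest.approx(-1.0)
        assert z["M2"] == pytest.approx(0.0, abs=1e-12)
        assert z["M3"] == pytest.approx(1.0)

    def test_z_mean_zero_sd_one_across_modules(self):
        rng = np.random.default_rng(9)
        expr = expr_from(
            rng.normal(size=(8, 6)), [f"M{i}" for i in range(8)],
            [f"G{i}" for i in range(6)],
        )
        sets = GeneSetCollection(sets={"D1": ["G0", "G1", "G2"]})
        z = disorder_scores(expr, sets).table["z"]
        assert z.mean() == pytest.approx(0.0, abs=1e-10)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_zero_variance_gives_nan_and_no_flags(self):
        expr = expr_from([[2.0], [2.0], [2.0]], ["M1", "M2", "M3"], ["GA"])
        sets = GeneSetCollection(sets={"D1": ["GA"]})
        table = disorder_scores(expr, sets).table
        assert table["z"].isna().all()
        assert (table["flag"] == "none").all()

    def test_case_insensitive_matching(self):
        expr = expr_from([[1.0], [2.0], [3.0]], ["M1", "M2", "M3"], ["BdNf"])
        sets = GeneSetCollection(sets={"D1": ["bdnf"]})
        scores = disorder_scores(expr, sets)
        assert scores.n_genes_matched["D1"] == 1

    def test_unmatched_set_rejected(self):
        expr = expr_from([[1.0], [2.0]], ["M1", "M2"], ["GA"])
        sets = GeneSetCollection(sets={"D9": ["NOPE"]})
        with pytest.raises(GeneMatchError, match="D9"):
            disorder_scores(expr, sets)

    def test_single_module_rejected(self):
        expr = expr_from([[1.0]], ["M1"], ["GA"])
        sets = GeneSetCollection(sets={"D1": ["GA"]})
        with pytest.raises(InsufficientDataError):
            disorder_scores(expr, sets)

    def test_planted_overexpression_is_flagged_high(self):
        spec = SyntheticSpec(
            seed=5, n_nodes=8, module_sizes=(1,) * 8,
            planted=((3, "DisorderX", 4.0),), n_genes=40,
        )
        samples, labeling, sets = generate_expression(spec, spec.ground_truth())
        expr = aggregate_samples(samples, labeling)
        table = disorder_scores(expr, sets).table
        flagged = table[table["flag"] == "high"]
        assert list(flagged["module"]) == [3]

    @given(
        a=st.floats(min_value=0.01, max_value=100.0),
        b=st.floats(min_value=-50.0, max_value=50.0),
    )
    def test_z_invariant_under_affine_rescaling(self, a, b):
        rng = np.random.default_rng(77)
        raw = rng.normal(size=(6, 4))
        genes = [f"G{i}" for i in range(4)]
        modules = [f"M{i}" for i in range(6)]
        sets = GeneSetCollection(sets={"D1": genes[:2]})
        z0 = disorder_scores(expr_from(raw, modules, genes), sets).table["z"]
        z1 = disorder_scores(expr_from(a * raw + b, modules, genes), sets).table["z"]
        np.testing.assert_allclose(z0, z1, atol=1e-8)

    def test_median_center_option(self):
        expr = expr_from(
            [[1.0, 10.0], [2.0, 2.0], [3.0, 3.0]], ["M1", "M2", "M3"], ["GA", "GB"]
        )
        sets = GeneSetCollection(sets={"D1": ["GA", "GB"]})
        mean_t = disorder_scores(expr, sets, center="mean").table
        med_t = disorder_scores(expr, sets, center="median").table
        assert mean_t.loc[0, "mean_expression"] == pytest.approx(5.5)
        assert med_t.loc[0, "mean_expression"] == pytest.approx(5.5)
        assert mean_t.loc[1, "mean_expression"] == pytest.approx(2.0)


class TestGroupScores:
    def test_single_disorder_group_identical_to_disorder(self):
        rng = np.random.default_rng(10)
        expr = expr_from(
            rng.normal(size=(5, 4)), [f"M{i}" for i in range(5)],
            ["GA", "GB", "GC", "GD"],
        )
        sets = GeneSetCollection(sets={"D1": ["GA", "GB"]}, group={"D1": "G1"})
        d = disorder_scores(expr, sets).table
        g = group_scores(expr, sets).table
        np.testing.assert_allclose(d["z"], g["z"], atol=1e-12)

    def test_disjoint_union_pooling(self):
        rng = np.random.default_rng(11)
        values = rng.normal(size=(5, 4))
        genes = ["GA", "GB", "GC", "GD"]
        expr = expr_from(values, [f"M{i}" for i in range(5)], genes)
        sets = GeneSetCollection(
            sets={"D1": ["GA", "GB"], "D2": ["GC", "GD"]},
            group={"D1": "G1", "D2": "G1"},
        )
        g = group_scores(expr, sets)
        assert g.n_genes_matched["G1"] == 4
        pooled_mean = expr.values[genes].mean(axis=1)
        got = g.table.set_index("module")["mean_expression"]
        np.testing.assert_allclose(got[pooled_mean.index], pooled_mean, atol=1e-12)

    def test_shared_gene_counts_once(self):
        expr = expr_from([[1.0, 5.0], [2.0, 6.0], [0.0, 1.0]],
                         ["M1", "M2", "M3"], ["GA", "GB"])
        sets = GeneSetCollection(
            sets={"D1": ["GA", "GB"], "D2": ["GA"]}, group={"D1": "G1", "D2": "G1"}
        )
        g = group_scores(expr, sets)
        assert g.n_genes_matched["G1"] == 2

    def test_seven_groups_yield_seven_sets_of_rows(self):
        spec = SyntheticSpec(
            seed=6, n_nodes=10, module_sizes=(1,) * 10,
            n_null_sets=40, n_groups=7, n_genes=400,
        )
        samples, labeling, sets = generate_expression(spec, spec.ground_truth())
        expr = aggregate_samples(samples, labeling)
        assert len(sets.sets) == 40
        g = group_scores(expr, sets)
        assert g.table["set"].nunique() == 7
        assert len(g.table) == 7 * 10

    def test_missing_group_mapping_rejected(self):
        expr = expr_from([[1.0], [2.0]], ["M1", "M2"], ["GA"])
        sets = GeneSetCollection(sets={"D1": ["GA"]})
        with pytest.raises(ParameterError):
            group_scores(expr, sets)
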