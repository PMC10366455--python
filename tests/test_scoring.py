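import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neutropipe.io import GeneSetCollection, SampleTable
from neutropipe.scoring import (
    BETA_CAP,
    GeneScaling,
    fit_gene_scaling,
    fit_scalings,
    pathway_scores,
    scale_expression,
    score_group_test,
)


class TestScaleExpression:
    def test_zero_at_center(self):
        s = GeneScaling("g", beta=3.7, center=1.2)
        assert scale_expression(1.2, s) == 0.0

    def test_logistic_closed_form(self):
        # beta = 1, x - center = ln 3: 2/(1 + 1/3) - 1 = 1/2
        s = GeneScaling("g", beta=1.0, center=0.0)
        assert scale_expression(np.log(3.0), s) == pytest.approx(0.5, abs=1e-12)

    def test_flat_when_beta_zero(self):
        s = GeneScaling("g", beta=0.0, center=5.0)
        assert np.all(scale_expression(np.array([-100.0, 0.0, 100.0]), s) == 0.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(-50, 50), st.floats(0, 30), st.floats(-20, 20))
    def test_tanh_identity_and_bounds(self, x, beta, center):
        s = GeneScaling("g", beta=beta, center=center)
        v = scale_expression(x, s)
        logistic = 2.0 / (1.0 + np.exp(-beta * (x - center))) - 1.0
        assert v == pytest.approx(logistic, abs=1e-12)
        assert -1.0 <= v <= 1.0

    def test_monotone_in_x(self):
        s = GeneScaling("g", beta=2.0, center=0.0)
        xs = np.linspace(-5, 5, 101)
        assert np.all(np.diff(scale_expression(xs, s)) > 0)


class TestFitGeneScaling:
    def test_zero_variance_gene(self):
        s = fit_gene_scaling(np.full(10, 3.3), np.array([0] * 5 + [1] * 5))
        assert s.beta == 0.0
        assert s.center == pytest.approx(3.3)

    def test_independent_labels_give_small_beta(self, rng):
        expr = rng.normal(size=2000)
        labels = rng.integers(0, 2, size=2000)
        s = fit_gene_scaling(expr, labels)
        assert s.beta < 0.1

    def test_complete_separation_hits_cap(self, rng):
        expr = rng.normal(size=200)
        labels = (expr > np.median(expr)).astype(int)
        s = fit_gene_scaling(expr, labels)
        # beta is reported per expression unit; undo the standardization
        sd = np.std(expr)
        assert s.beta * sd == pytest.approx(BETA_CAP)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="two classes"):
            fit_gene_scaling(np.arange(5.0), np.zeros(5))

    def test_balanced_weights_equalize_class_contributions(self, rng):
        # center = balanced weighted mean: midpoint of class means even with 4:1 sizes
        expr = np.concatenate([np.full(80, 1.0), np.full(20, 3.0)])
        labels = np.array([0] * 80 + [1] * 20)
        s = fit_gene_scaling(expr + rng.normal(scale=1e-6, size=100), labels)
        assert s.center == pytest.approx(2.0, abs=1e-3)


class TestPathwayScores:
    def make_inputs(self, rng):
        genes = [f"g{i}" for i in range(6)]
        samples = [f"s{i}" for i in range(8)]
        expr = pd.DataFrame(rng.normal(5, 1, size=(6, 8)), index=genes, columns=samples)
        scalings = pd.DataFrame({
            "gene_id": genes,
            "beta": [1.0, 2.0, 0.5, 1.5, 0.0, 3.0],
            "center": expr.mean(axis=1).to_numpy(),
        })
        return expr, scalings

    def test_singleton_pathway_equals_scaled_gene(self, rng):
        expr, scalings = self.make_inputs(rng)
        sets = GeneSetCollection({"one": ("", ["g2"])})
        psm = pathway_scores(expr, scalings, sets)
        s = GeneScaling("g2", 0.5, scalings.set_index("gene_id").loc["g2", "center"])
        expected = scale_expression(expr.loc["g2"].to_numpy(), s)
        assert psm.scores.loc["one"].to_numpy() == pytest.approx(expected, abs=1e-12)

    def test_zero_betas_give_zero_scores(self, rng):
        expr, scalings = self.make_inputs(rng)
        scalings["beta"] = 0.0
        sets = GeneSetCollection({"all": ("", list(expr.index))})
        psm = pathway_scores(expr, scalings, sets)
        assert np.all(psm.scores.to_numpy() == 0.0)

    def test_mean_of_member_genes(self):
        expr = pd.DataFrame([[1.0], [2.0]], index=["a", "b"], columns=["s"])
        # choose beta/center so scaled values are exactly 0.5 and -0.1
        b_a = 2 * np.arctanh(0.5)
        b_b = 2 * np.arctanh(0.1)
        scalings = pd.DataFrame({"gene_id": ["a", "b"], "beta": [b_a, b_b],
                                 "center": [0.0, 3.0]})
        sets = GeneSetCollection({"p": ("", ["a", "b"])})
        psm = pathway_scores(expr, scalings, sets)
        assert psm.scores.loc["p", "s"] == pytest.approx(0.2, abs=1e-12)
        assert psm.n_genes_used["p"] == 2

    def test_unmeasured_genes_dropped_and_counted(self, rng):
        expr, scalings = self.make_inputs(rng)
        sets = GeneSetCollection({"p": ("", ["g0", "ghost1", "ghost2"])})
        psm = pathway_scores(expr, scalings, sets)
        assert psm.n_genes_used["p"] == 1

    def test_monotone_response_to_expression_bump(self, rng):
        expr, scalings = self.make_inputs(rng)
        sets = GeneSetCollection({"p": ("", ["g0", "g1", "g3"])})
        base = pathway_scores(expr, scalings, sets).scores.loc["p", "s3"]
        expr2 = expr.copy()
        expr2.loc["g1", "s3"] += 1.0
        bumped = pathway_scores(expr2, scalings, sets).scores.loc["p", "s3"]
        assert bumped >= base

    def test_no_overlap_errors(self, rng):
        expr, scalings = self.make_inputs(rng)
        sets = GeneSetCollection({"p": ("", ["nope"])})
        with pytest.raises(ValueError, match="no gene set overlaps"):
            pathway_scores(expr, scalings, sets)


class TestFitScalings:
    def test_recovery_samples_never_enter_the_fit(self, small_cohort):
        from neutropipe.diffexpr import log_norm_expression

        expr = log_norm_expression(small_cohort.counts).iloc[:100]
        full = fit_scalings(expr, small_cohort.samples)
        no_rec = [s for s in expr.columns
                  if small_cohort.samples.group_of(s) != "cap_recovery"]
        dropped = fit_scalings(expr[no_rec], small_cohort.samples)
        pd.testing.assert_frame_equal(full, dropped)


class TestScoreGroupTest:
    def frame(self, a, b):
        vals = np.array([a + b])
        cols = [f"x{i}" for i in range(len(a))] + [f"y{i}" for i in range(len(b))]
        scores = pd.DataFrame(vals, index=["p"], columns=cols)
        samples = SampleTable(pd.DataFrame({
            "sample_id": cols,
            "group": ["cap_admission"] * len(a) + ["control"] * len(b),
        }))
        return scores, samples

    def test_exact_two_sided_p(self):
        scores, samples = self.frame([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        out = score_group_test(scores, samples)
        assert out["p_value"].iloc[0] == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        scores, samples = self.frame([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        out = score_group_test(scores, samples)
        assert out["p_value"].iloc[0] == 1.0

    def test_label_swap_symmetric(self):
        scores, samples = self.frame([0.9, 0.1, 0.4], [0.2, 0.8, 0.3])
        p1 = score_group_test(scores, samples, ("cap_admission", "control"))["p_value"].iloc[0]
        p2 = score_group_test(scores, samples, ("control", "cap_admission"))["p_value"].iloc[0]
        assert p1 == p2
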