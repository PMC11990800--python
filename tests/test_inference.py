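"""ABC engine mechanics, guards, and the Beta length-model fit."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from karyosim.fixtures import default_arm_model, default_driver_model, default_wgd_model
from karyosim.inference import (
    PosteriorTable,
    Prior,
    PriorSpec,
    abc_posterior,
    build_reference_table,
    fit_beta_lengths,
    infer_arm_selection,
    infer_driver_selection,
    infer_wgd,
    label_driver_genes,
)


def linear_simulator(params, rng):
    """Cheap analytic stand-in: summary = theta + Gaussian noise."""
    return np.array([params["theta"] + rng.normal(0, 0.1),
                     rng.normal()])  # second channel is pure noise


@pytest.fixture(scope="module")
def linear_table():
    spec = PriorSpec([Prior("theta", 0.0, 1.0)])
    params, summ = build_reference_table(
        spec, linear_simulator, 1500, np.random.default_rng(0)
    )
    return spec, params, summ


class TestEngine:
    @pytest.mark.parametrize("engine", ["rf", "rejection"])
    def test_posterior_concentrates_on_truth(self, linear_table, engine):
        spec, params, summ = linear_table
        post = abc_posterior(params, summ, [0.5, 0.0], prior=spec, engine=engine)
        assert abs(post.mean("theta") - 0.5) < 0.1
        assert abs(post.map_estimate("theta") - 0.5) < 0.12
        lo, hi = post.credible_interval("theta", 0.9)
        assert lo <= 0.5 <= hi

    def test_posterior_support_within_prior(self, linear_table):
        spec, params, summ = linear_table
        post = abc_posterior(params, summ, [0.9, 0.0], prior=spec, engine="rejection")
        v, w = post.draws["theta"]
        assert v[w > 0].min() >= 0.0 and v[w > 0].max() <= 1.0

    def test_flat_response_recovers_prior(self):
        """A summary carrying no information leaves the posterior ~ prior."""
        spec = PriorSpec([Prior("theta", 0.0, 1.0)])
        params, summ = build_reference_table(
            spec, lambda p, r: np.array([r.normal()]), 1500,
            np.random.default_rng(1),
        )
        post = abc_posterior(params, summ, [0.0], prior=spec)
        # mean near the prior mean (effective leaf sample is small, so the
        # band is loose) and interval close to the prior's width
        assert abs(post.mean("theta") - 0.5) < 0.15
        lo, hi = post.credible_interval("theta", 0.9)
        assert hi - lo > 0.6  # wide, prior-like

    def test_dimension_mismatch_rejected(self, linear_table):
        spec, params, summ = linear_table
        with pytest.raises(ValueError):
            abc_posterior(params, summ, [0.5], prior=spec)

    def test_coverage_calibration_reduced(self):
        """90% intervals should contain the truth in most repeated trials."""
        spec = PriorSpec([Prior("theta", 0.0, 1.0)])
        params, summ = build_reference_table(
            spec, linear_simulator, 800, np.random.default_rng(2)
        )
        rng = np.random.default_rng(3)
        hits = 0
        trials = 25
        for _ in range(trials):
            truth = rng.uniform(0.1, 0.9)
            obs = [truth + rng.normal(0, 0.1), rng.normal()]
            post = abc_posterior(params, summ, obs, prior=spec)
            lo, hi = post.credible_interval("theta", 0.9)
            hits += lo <= truth <= hi
        assert hits >= int(0.7 * trials)

    def test_reference_table_deterministic(self):
        spec = PriorSpec([Prior("theta", 0.0, 1.0)])
        p1, s1 = build_reference_table(spec, linear_simulator, 50, 7)
        p2, s2 = build_reference_table(spec, linear_simulator, 50, 7)
        pd.testing.assert_frame_equal(p1, p2)
        np.testing.assert_array_equal(s1, s2)


class TestGuards:
    def test_small_cohort_refused(self):
        model = default_arm_model(cohort_size=9)
        freq = pd.DataFrame(
            {"arm": model.genome.arm_labels, "fr_gain": 0.3, "fr_loss": 0.0}
        )
        with pytest.raises(ValueError, match="below the minimum"):
            infer_arm_selection(freq, model, 0)

    def test_no_arm_passes_filter(self):
        model = default_arm_model()
        freq = pd.DataFrame(
            {"arm": model.genome.arm_labels, "fr_gain": 0.05, "fr_loss": 0.02}
        )
        with pytest.warns(UserWarning):
            res = infer_arm_selection(freq, model, 0)
        assert res["posterior"] is None
        assert res["inferred_arms"] == []

    def test_low_wgd_proportion_refused(self):
        with pytest.raises(ValueError, match="not analyzed"):
            infer_wgd((0.05, 0.2), default_wgd_model(), 0)

    def test_missing_gene_warned_and_excluded(self):
        model = default_driver_model(cohort_size=10)
        obs = pd.DataFrame(
            {"gene": ["TSG1", "OG1"], "fr_mut": [0.4, 0.1],
             "fr_gain": [0.0, 0.1], "fr_loss": [0.1, 0.0]}
        )
        with pytest.warns(UserWarning, match="excluded"):
            res = infer_driver_selection(
                obs, model, 0, n_sims=30, n_trees=50
            )
        assert res["genes"] == ["TSG1", "OG1"]


class TestLabelDriverGenes:
    def test_loss_dominated_is_tsg(self):
        df = pd.DataFrame({"gene": ["a"], "fr_gain": [0.1], "fr_loss": [0.3]})
        assert label_driver_genes(df) == {"a": "TSG"}

    def test_gain_dominated_is_og(self):
        df = pd.DataFrame({"gene": ["a"], "fr_gain": [0.3], "fr_loss": [0.1]})
        assert label_driver_genes(df) == {"a": "OG"}

    def test_tie_uses_fallback_or_drops(self):
        df = pd.DataFrame({"gene": ["a", "b"], "fr_gain": [0.2, 0.2],
                           "fr_loss": [0.2, 0.2]})
        with pytest.warns(UserWarning, match="dropped"):
            roles = label_driver_genes(df, fallback={"a": "OG"})
        assert roles == {"a": "OG"}


class TestBetaFit:
    def test_recovers_parameters_within_ten_percent(self):
        rng = np.random.default_rng(42)
        ratios = rng.beta(2.0, 5.0, size=10_000)
        a, b = fit_beta_lengths(ratios)
        assert a == pytest.approx(2.0, rel=0.1)
        assert b == pytest.approx(5.0, rel=0.1)

    def test_constant_ratios_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_beta_lengths(np.full(100, 0.3))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="lie in"):
            fit_beta_lengths([0.2, 1.4])


class TestSelfConsistency:
    def test_observed_row_parameters_in_credible_interval(self):
        """Using a table row's own summaries as the observation must place
        that row's parameter inside a wide credible interval."""
        spec = PriorSpec([Prior("theta", 0.0, 1.0)])
        params, summ = build_reference_table(
            spec, linear_simulator, 1000, np.random.default_rng(9)
        )
        idx = 123
        post = abc_posterior(params, summ, summ[idx], prior=spec)
        lo, hi = post.credible_interval("theta", 0.95)
        assert lo - 0.05 <= params["theta"].iloc[idx] <= hi + 0.05
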