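import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methtrio import (
    BetaMatrix,
    SimulationConfig,
    TrioDesign,
    TrioSubject,
    bh_adjust,
    estimate_prior,
    generate_cohort,
    moderated_t,
    paired_differences,
    run_pairwise_dmp,
)
from methtrio.dmp import ModeratedFitParams, trigamma_inverse
from methtrio.errors import ConfigError, DataError


def brute_force_bh(p):
    """Independent step-up oracle: q_(i) = min_{j>=i} m*p_(j)/j, clipped."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q[order[rank - 1]] = min(running, 1.0)
    return q


class TestPairedDifferences:
    def _matrix(self, per_subject):
        """per_subject: dict subject -> (buffy, pmn, lymph) scalars; 1 probe."""
        cols, subs = {}, []
        for sid, (b, p, l) in per_subject.items():
            cols[f"{sid}_b"], cols[f"{sid}_p"], cols[f"{sid}_l"] = [b], [p], [l]
            subs.append(TrioSubject(sid, f"{sid}_b", f"{sid}_p", f"{sid}_l"))
        values = pd.DataFrame(cols, index=["cg1"])
        return BetaMatrix(values), TrioDesign(tuple(subs))

    def test_identical_fractions_give_zero(self):
        matrix, design = self._matrix({"A": (0.5, 0.5, 0.5), "B": (0.3, 0.3, 0.3)})
        out = paired_differences(matrix, design, "BP")
        assert out.loc["cg1", "mean"] == 0.0
        assert out.loc["cg1", "var"] == 0.0

    def test_hand_arithmetic(self):
        matrix, design = self._matrix(
            {"A": (0.6, 0.5, 0.0), "B": (0.7, 0.5, 0.0), "C": (0.8, 0.5, 0.0)}
        )
        out = paired_differences(matrix, design, "BP")
        assert out.loc["cg1", "mean"] == pytest.approx(0.2)
        assert out.loc["cg1", "var"] == pytest.approx(0.01)
        assert out.loc["cg1", "n"] == 3

    def test_orientation_is_first_minus_second(self):
        matrix, design = self._matrix({"A": (0.9, 0.2, 0.1), "B": (0.9, 0.2, 0.1)})
        assert paired_differences(matrix, design, "BP").loc["cg1", "mean"] == pytest.approx(0.7)
        assert paired_differences(matrix, design, "BL").loc["cg1", "mean"] == pytest.approx(0.8)
        assert paired_differences(matrix, design, "PL").loc["cg1", "mean"] == pytest.approx(0.1)

    def test_untestable_probe_marked(self):
        matrix, design = self._matrix({"A": (0.5, 0.4, 0.3), "B": (0.5, np.nan, 0.3)})
        out = paired_differences(matrix, design, "BP")
        assert out.loc["cg1", "n"] == 1
        assert np.isnan(out.loc["cg1", "mean"])

    def test_unknown_comparison_rejected(self, tiny_matrix, tiny_design):
        with pytest.raises(ConfigError):
            paired_differences(tiny_matrix, tiny_design, "XY")

    def test_synthetic_true_dmp_effect_recovered(self, clean_cohort):
        out = paired_differences(clean_cohort.beta, clean_cohort.design, "PL")
        truth = clean_cohort.truth
        true_delta = truth.true_pmn_beta - truth.true_lymph_beta
        dmp_probes = true_delta.index[true_delta.abs() > 0.25]
        err = (out.loc[dmp_probes, "mean"] - true_delta[dmp_probes]).abs()
        assert err.max() < 0.03  # within noise of the generating effect


class TestPriorEstimation:
    def test_equal_variances_give_infinite_prior_df(self):
        params = estimate_prior(np.full(100, 0.04), d=28)
        assert np.isinf(params.d0)
        # the moment estimator corrects for E[log chi2_d/d]: the fitted prior
        # is the common value times exp(log(d/2) - digamma(d/2)) ~ 1 + 1/d
        from scipy.special import digamma

        expected = 0.04 * np.exp(np.log(14) - digamma(14.0))
        assert params.s0_sq == pytest.approx(expected, rel=1e-9)
        assert params.s0_sq == pytest.approx(0.04, rel=0.05)

    def test_recovers_generating_prior(self, rng):
        d0, s0, d, G = 4.0, 0.04, 28.0, 10_000
        s2 = s0 * (rng.chisquare(d, G) / d) / (rng.chisquare(d0, G) / d0)
        params = estimate_prior(s2, d)
        assert params.d0 == pytest.approx(d0, rel=0.15)
        assert params.s0_sq == pytest.approx(s0, rel=0.05)

    def test_heavy_tails_give_small_finite_prior_df(self, rng):
        # log-variance dispersion far above trigamma(d/2): tiny d0
        s2 = np.exp(rng.normal(0, 4, size=2000))
        params = estimate_prior(s2, d=28)
        assert 0 < params.d0 < 2

    def test_too_few_variances_rejected(self):
        with pytest.raises(DataError):
            estimate_prior(np.array([0.1] * 5), d=5)

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma

        for x in (0.1, 1.0, 7.3, 150.0):
            assert trigamma_inverse(float(polygamma(1, x))) == pytest.approx(x, rel=1e-6)

    def test_matches_bioconductor_squeezevar(self, rng, tmp_path):
        """Independent oracle: limma::squeezeVar on the same variances."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the cross-check oracle")
        d0, s0, d, G = 4.0, 0.04, 28.0, 400
        s2 = s0 * (rng.chisquare(d, G) / d) / (rng.chisquare(d0, G) / d0)
        path = tmp_path / "vars.txt"
        np.savetxt(path, s2)
        script = (
            "suppressMessages(library(limma));"
            f'x <- scan("{path}", quiet=TRUE);'
            "sv <- squeezeVar(x, df=28);"
            'cat(sv$df.prior, sv$var.prior, sv$var.post[1:3], sep="\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        r_d0, r_s0, *r_post = map(float, out.stdout.split())
        params = estimate_prior(s2, d)
        assert params.d0 == pytest.approx(r_d0, rel=1e-4)
        assert params.s0_sq == pytest.approx(r_s0, rel=1e-4)
        post = (params.d0 * params.s0_sq + d * s2[:3]) / (params.d0 + d)
        np.testing.assert_allclose(post, r_post, rtol=1e-4)


class TestModeratedT:
    def test_no_moderation_limit_equals_ordinary_paired_t(self, rng):
        diffs = rng.normal(0.05, 0.03, size=(200, 8))
        mean, var, n = diffs.mean(1), diffs.var(1, ddof=1), 8
        params = ModeratedFitParams(d=7, d0=0.0, s0_sq=1.0)
        t, p, df = moderated_t(mean, var, np.full(200, n), params)
        t_ref, p_ref = stats.ttest_1samp(diffs, 0.0, axis=1).statistic, stats.ttest_1samp(diffs, 0.0, axis=1).pvalue
        np.testing.assert_allclose(t, t_ref, rtol=1e-12)
        np.testing.assert_allclose(p, p_ref, rtol=1e-9)
        assert df == 7

    def test_zero_mean_gives_t_zero_p_one(self):
        params = ModeratedFitParams(d=2, d0=2.0, s0_sq=0.02)
        t, p, _ = moderated_t(0.0, 0.01, 3, params)
        assert t == 0.0 and p == 1.0

    def test_hand_computed_example(self):
        # s2_post = (2*0.02 + 2*0.01)/4 = 0.015; t = 0.2/sqrt(0.015/3); df = 4
        params = ModeratedFitParams(d=2, d0=2.0, s0_sq=0.02)
        t, p, df = moderated_t(0.2, 0.01, 3, params)
        assert t == pytest.approx(0.2 / np.sqrt(0.015 / 3), rel=1e-12)
        assert t == pytest.approx(2.828, abs=5e-3)
        assert df == 4
        assert p == pytest.approx(2 * stats.t.sf(2.8284271, 4), rel=1e-6)

    def test_posterior_variance_is_convex_combination(self, rng):
        var = rng.uniform(0.001, 0.1, size=100)
        params = ModeratedFitParams(d=9, d0=4.0, s0_sq=0.02)
        s2_post = (params.d0 * params.s0_sq + 9 * var) / (params.d0 + 9)
        lo = np.minimum(var, params.s0_sq)
        hi = np.maximum(var, params.s0_sq)
        assert ((s2_post >= lo - 1e-15) & (s2_post <= hi + 1e-15)).all()

    def test_infinite_prior_df_uses_prior_variance_only(self):
        params = ModeratedFitParams(d=9, d0=np.inf, s0_sq=0.04)
        t, p, df = moderated_t(0.2, 0.5, 10, params)
        assert t == pytest.approx(0.2 / np.sqrt(0.04 / 10))
        assert df == 1e6

    def test_zero_posterior_variance_warns_and_maps_to_p_zero(self):
        params = ModeratedFitParams(d=2, d0=0.0, s0_sq=1.0)
        with pytest.warns(UserWarning, match="zero posterior"):
            t, p, _ = moderated_t(0.2, 0.0, 3, params)
        assert np.isinf(t) and p == 0.0


class TestBH:
    def test_single_p(self):
        np.testing.assert_allclose(bh_adjust([0.04]), [0.04])

    def test_ladder_collapses_to_common_q(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_nan_passthrough(self):
        q = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], brute_force_bh([0.01, 0.02]))

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False, allow_subnormal=False),
            min_size=1, max_size=60,
        )
    )
    def test_matches_brute_force_step_up(self, pvals):
        np.testing.assert_allclose(bh_adjust(pvals), brute_force_bh(pvals), rtol=1e-12)

    def test_monotone_in_p_rank(self, rng):
        p = rng.uniform(size=500)
        q = bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestPairwiseDMP:
    def test_recall_and_fdr_on_true_pl_dmps(self):
        recalls, fdrs = [], []
        for seed in range(10):
            cohort = generate_cohort(SimulationConfig(seed=seed, n_discordant_probes=0))
            results = run_pairwise_dmp(cohort.beta, cohort.design, comparisons=("PL",))
            called = set(results.tables["PL"].index[results.tables["PL"]["significant_p"]])
            true = set(cohort.truth.true_dmp.index[cohort.truth.true_dmp["PL"]])
            recalls.append(len(called & true) / len(true))
            fdrs.append(len(called - true) / max(len(called), 1))
        assert np.mean(recalls) >= 0.8
        assert np.mean(fdrs) <= 0.1

    def test_global_null_yields_almost_no_calls(self):
        cohort = generate_cohort(
            SimulationConfig(seed=3, frac_dmp_pl=0.0, n_discordant_probes=0)
        )
        results = run_pairwise_dmp(cohort.beta, cohort.design)
        for label, tab in results.tables.items():
            assert tab["significant_p"].mean() <= 0.001

    def test_significant_db_set_is_subset_of_significant(self, default_cohort):
        results = run_pairwise_dmp(default_cohort.beta, default_cohort.design)
        for tab in results.tables.values():
            assert (tab["significant_p_db"] <= tab["significant_p"]).all()

    def test_antisymmetry_under_orientation_swap(self, clean_cohort):
        """Swapping the compared fractions negates delta-beta and t but
        leaves p and q unchanged."""
        design = clean_cohort.design
        swapped = TrioDesign(
            tuple(
                TrioSubject(s.subject_id, s.buffy, s.lymphocyte, s.pmn)
                for s in design.subjects
            )
        )
        a = run_pairwise_dmp(clean_cohort.beta, design, comparisons=("PL",)).tables["PL"]
        b = run_pairwise_dmp(clean_cohort.beta, swapped, comparisons=("PL",)).tables["PL"]
        np.testing.assert_allclose(a["delta_beta"], -b["delta_beta"], atol=1e-12)
        np.testing.assert_allclose(a["t"], -b["t"], rtol=1e-9)
        np.testing.assert_allclose(a["p"], b["p"], rtol=1e-9)

    def test_count_table_percentages(self, default_cohort):
        results = run_pairwise_dmp(default_cohort.beta, default_cohort.design)
        counts = results.counts()
        row = counts.loc["PL"]
        assert row["pct_significant_q"] == pytest.approx(
            100 * row["n_significant_q"] / row["n_tested"], abs=0.005
        )
        assert "PL" in results.summary()
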