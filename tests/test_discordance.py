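import numpy as np
import pandas as pd
import pytest

from methtrio import (
    BetaMatrix,
    SimulationConfig,
    TrioDesign,
    TrioSubject,
    bonferroni_z_cutoff,
    classify_peak_probes,
    compute_residuals,
    fit_cohort,
    remove_discordant,
    simulate_cohort,
    standardize_and_flag,
)
from methtrio.deconvolution import MixtureFit
from methtrio.discordance import DiscordancePartition, ResidualMatrix, residual_histogram
from methtrio.errors import ConfigError, DegenerateDistributionError, DesignError


def _fit(subject_id, w_pmn, w_lymph):
    return MixtureFit(subject_id, w_pmn, w_lymph, 0.0, 2)


def _single_trio_matrix(buffy, pmn, lymph):
    values = pd.DataFrame(
        {"A_buffy": [buffy, 0.5], "A_pmn": [pmn, 0.5], "A_lymphocyte": [lymph, 0.5]},
        index=["cg1", "cg2"],
    )
    design = TrioDesign((TrioSubject("A", "A_buffy", "A_pmn", "A_lymphocyte"),))
    return BetaMatrix(values), design


class TestBonferroniCutoff:
    @pytest.mark.parametrize(
        "n_tests,expected",
        [(412_481, 5.29), (1, 1.96), (100, 3.48)],
    )
    def test_two_sided_normal_critical_values(self, n_tests, expected):
        assert bonferroni_z_cutoff(0.05, n_tests) == pytest.approx(expected, abs=0.005)

    def test_invalid_inputs(self):
        with pytest.raises(ConfigError):
            bonferroni_z_cutoff(0.0, 10)
        with pytest.raises(ConfigError):
            bonferroni_z_cutoff(0.05, 0)


class TestResiduals:
    @pytest.mark.parametrize(
        "buffy,pmn,lymph,expected",
        [
            (0.0, 1.0, 1.0, -1.0),  # fractions methylated, buffy not
            (1.0, 1.0, 0.0, 0.4),  # buffy and pmn methylated, lymph not
            (0.62, 0.7, 0.5, 0.0),  # exact weighted sum: 0.6*0.7+0.4*0.5
        ],
    )
    def test_hand_computed_trio_residuals(self, buffy, pmn, lymph, expected):
        matrix, design = _single_trio_matrix(buffy, pmn, lymph)
        rm = compute_residuals(matrix, design, [_fit("A", 0.6, 0.4)])
        assert rm.residuals.loc["cg1", "A"] == pytest.approx(expected, abs=1e-12)

    def test_missing_fit_raises(self):
        matrix, design = _single_trio_matrix(0.5, 0.5, 0.5)
        with pytest.raises(DesignError, match="A"):
            compute_residuals(matrix, design, [_fit("Z", 0.6, 0.4)])

    def test_missing_beta_gives_missing_residual(self):
        matrix, design = _single_trio_matrix(0.5, 0.5, 0.5)
        matrix.values.loc["cg1", "A_pmn"] = np.nan
        rm = compute_residuals(matrix, design, [_fit("A", 0.6, 0.4)])
        assert np.isnan(rm.residuals.loc["cg1", "A"])

    def test_residual_bounds_under_unit_weights(self, default_cohort):
        results = fit_cohort(default_cohort.beta, default_cohort.design)
        rm = results.residuals()
        arr = rm.residuals.to_numpy()
        assert np.nanmin(arr) >= -1.01 and np.nanmax(arr) <= 1.0


class TestStandardizeAndFlag:
    def _null_residuals(self, rng, n_probes=20_000, n_subjects=29, sd=0.02):
        res = pd.DataFrame(
            rng.normal(0.0, sd, size=(n_probes, n_subjects)),
            index=[f"cg{i}" for i in range(n_probes)],
            columns=[f"S{j}" for j in range(n_subjects)],
        )
        return ResidualMatrix(res)

    def test_zscores_have_mean_zero_sd_one(self, rng):
        rm = self._null_residuals(rng, 500, 5).standardize()
        z = rm.zscores.to_numpy().ravel()
        assert np.mean(z) == pytest.approx(0.0, abs=1e-12)
        assert np.std(z, ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_family_wise_control_under_null(self, rng):
        rm = self._null_residuals(rng)
        part = standardize_and_flag(rm, alpha=0.05)
        frac = part.n_discordant_trios / (20_000 * 29)
        assert frac <= 0.0005

    def test_single_gross_outlier_is_the_only_flag(self, rng):
        rm = self._null_residuals(rng, 100, 3, sd=0.01)
        rm.residuals.iloc[7, 1] = -1.0
        part = standardize_and_flag(rm)
        assert part.discordant_trios == {(rm.residuals.index[7], rm.residuals.columns[1])}
        assert list(part.discordant_probes) == [rm.residuals.index[7]]

    def test_partition_is_exhaustive_and_disjoint(self, default_cohort):
        results = fit_cohort(default_cohort.beta, default_cohort.design)
        part = standardize_and_flag(results.residuals())
        disc, conc = set(part.discordant_probes), set(part.concordant_probes)
        assert disc.isdisjoint(conc)
        assert disc | conc == set(default_cohort.beta.probe_ids)
        assert part.n_probes == len(disc) + len(conc)

    def test_zero_spread_is_degenerate(self):
        rm = ResidualMatrix(pd.DataFrame(np.zeros((5, 3))))
        with pytest.raises(DegenerateDistributionError):
            standardize_and_flag(rm)

    def test_robust_standardization_resists_outliers(self, rng):
        rm = self._null_residuals(rng, 2000, 10)
        rm.residuals.iloc[:50, :] = -0.9  # gross contamination inflates plain sigma
        plain = ResidualMatrix(rm.residuals.copy()).standardize(robust=False)
        robust = ResidualMatrix(rm.residuals.copy()).standardize(robust=True)
        assert robust.sigma < plain.sigma


class TestInjectedRecovery:
    def test_injected_probes_recovered_with_few_false_flags(self, default_cohort):
        results = fit_cohort(default_cohort.beta, default_cohort.design)
        part = standardize_and_flag(results.residuals())
        injected = set(default_cohort.truth.injected_probe_ids)
        flagged = set(part.discordant_probes)
        recall = len(injected & flagged) / len(injected)
        assert recall >= 0.95
        false_flags = flagged - injected
        assert len(false_flags) / max(len(flagged), 1) <= 0.05

    def test_sensitivity_specificity_across_seeds(self):
        """Multi-seed average of recall and false discovery under defaults."""
        recalls, fdrs = [], []
        for seed in range(50):
            cohort = simulate_cohort(SimulationConfig(seed=seed))
            results = fit_cohort(cohort.beta, cohort.design)
            part = standardize_and_flag(results.residuals())
            injected = set(cohort.truth.injected_probe_ids)
            flagged = set(part.discordant_probes)
            recalls.append(len(injected & flagged) / len(injected))
            fdrs.append(len(flagged - injected) / max(len(flagged), 1))
        assert np.mean(recalls) >= 0.95
        assert np.mean(fdrs) <= 0.05

    def test_gain_only_injection_gives_one_sided_negative_peak(self, default_cohort):
        results = fit_cohort(default_cohort.beta, default_cohort.design)
        part = standardize_and_flag(results.residuals())
        assert part.n_negative_flagged >= 10 * max(part.n_positive_flagged, 1)


class TestPeakProbes:
    def test_injected_probes_populate_the_peak(self, default_cohort):
        results = fit_cohort(default_cohort.beta, default_cohort.design)
        rm = results.residuals()
        peak = set(classify_peak_probes(rm, -0.6))
        injected = set(default_cohort.truth.injected_probe_ids)
        assert len(injected & peak) / len(injected) >= 0.95

    def test_quiet_probe_not_in_peak(self, rng):
        res = pd.DataFrame(rng.uniform(-0.1, 0.1, size=(100, 5)))
        assert len(classify_peak_probes(ResidualMatrix(res), -0.6)) == 0

    def test_threshold_nesting(self, default_cohort):
        results = fit_cohort(default_cohort.beta, default_cohort.design)
        rm = results.residuals()
        tight = set(classify_peak_probes(rm, -0.8))
        loose = set(classify_peak_probes(rm, -0.6))
        assert tight <= loose


class TestRemoveDiscordant:
    def _partition(self, discordant, all_probes):
        discordant = pd.Index(discordant)
        return DiscordancePartition(
            discordant_trios=set(),
            discordant_probes=discordant,
            peak_probes=pd.Index([]),
            concordant_probes=pd.Index(all_probes).difference(discordant),
            z_cutoff=5.29,
            n_tests=len(all_probes),
            n_probes=len(all_probes),
            n_subjects=29,
            n_positive_flagged=0,
            n_negative_flagged=0,
        )

    def test_empty_discordant_set_is_identity(self, tiny_matrix):
        part = self._partition([], tiny_matrix.probe_ids)
        out = remove_discordant(tiny_matrix, part)
        assert list(out.probe_ids) == list(tiny_matrix.probe_ids)

    def test_injected_probes_absent_from_filtered_matrix(self, default_cohort):
        results = fit_cohort(default_cohort.beta, default_cohort.design)
        part = standardize_and_flag(results.residuals())
        out = remove_discordant(default_cohort.beta, part)
        assert not set(default_cohort.truth.injected_probe_ids) & set(out.probe_ids)
        assert out.n_probes == default_cohort.beta.n_probes - len(part.discordant_probes)


class TestHistogram:
    def test_fixed_bin_width(self, rng):
        rm = ResidualMatrix(pd.DataFrame(rng.normal(0, 0.05, size=(200, 4))))
        hist = residual_histogram(rm)
        assert hist["bin_width"] == 0.001
        assert sum(hist["counts"]) == 800
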