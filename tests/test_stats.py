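"""Split-plot mixed ANOVA, Tukey post-hocs, simple effects, correlations."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import vowelvar as vv
from vowelvar.stats import (DegenerateDataError, UnbalancedDesignError,
                            anova_report, fit_mixed_anova, posthoc_pairwise,
                            simple_effects_condition_within_group)


class TestDesignDf:
    def test_default_design_strata_dfs(self, balanced_table):
        fit = fit_mixed_anova(balanced_table)
        assert fit.effects["group"].df_den == 22
        for name in ("condition", "vowel", "group:condition", "group:vowel",
                     "condition:vowel", "group:condition:vowel"):
            assert fit.effects[name].df_den == 154
        assert fit.effects["vowel"].df_num == 3

    def test_small_design_strata_dfs(self):
        tab = vv.simulate_log_ttv_table(n_per_group=3, rng=0)
        fit = fit_mixed_anova(tab)
        assert fit.effects["group"].df_den == 4       # 6 participants - 2
        assert fit.effects["vowel"].df_den == 6 * 7 - 14

    def test_df_invariant_to_response_values(self):
        dfs = set()
        for seed in range(5):
            tab = vv.simulate_log_ttv_table(n_per_group=4, rng=seed)
            fit = fit_mixed_anova(tab)
            dfs.add(tuple(e.df_den for e in fit.effects.values()))
        assert len(dfs) == 1


class TestFitCorrectness:
    def test_sum_of_squares_decomposition(self, balanced_table):
        fit = fit_mixed_anova(balanced_table)
        y = balanced_table["log_ttv"].to_numpy()
        ss_total = np.sum((y - y.mean()) ** 2)
        ss_effects = sum(e.ss for e in fit.effects.values())
        ss_subj = fit.ms_subject * fit.df_subject
        ss_resid = fit.ms_residual * fit.df_residual
        assert ss_effects + ss_subj + ss_resid == pytest.approx(ss_total, abs=1e-8)

    def test_matches_lmer_satterthwaite_reference(self, tmp_path):
        """From-scratch F/df/p and variance components equal a REML mixed
        model with Satterthwaite df fitted by lmerTest."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; reference comparison impossible")
        tab = vv.simulate_log_ttv_table(n_per_group=4, rng=17)
        csv = tmp_path / "tab.csv"
        tab.to_csv(csv, index=False)
        rcode = f"""
        options(contrasts = c("contr.sum", "contr.poly"))
        suppressMessages(library(lmerTest))
        d <- read.csv("{csv}")
        for (f in c("group", "condition", "vowel")) d[[f]] <- factor(d[[f]])
        m <- lmer(log_ttv ~ group * condition * vowel + (1 | participant), data = d)
        a <- anova(m)
        vc <- as.data.frame(VarCorr(m))
        out <- list(effects = lapply(rownames(a), function(r) {{
            list(name = r, F = a[r, "F value"], df_num = a[r, "NumDF"],
                 df_den = a[r, "DenDF"], p = a[r, "Pr(>F)"])
        }}), sigma2_participant = vc$vcov[1], sigma2_residual = vc$vcov[2])
        cat(jsonlite::toJSON(out, auto_unbox = TRUE, digits = 12))
        """
        res = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        ref = json.loads(res.stdout)
        fit = fit_mixed_anova(tab)
        name_map = {"group": "group", "condition": "condition", "vowel": "vowel",
                    "group:condition": "group:condition",
                    "group:vowel": "group:vowel",
                    "condition:vowel": "condition:vowel",
                    "group:condition:vowel": "group:condition:vowel"}
        for entry in ref["effects"]:
            eff = fit.effects[name_map[entry["name"]]]
            # rel: lmer's iterative REML stops at a finite convergence
            # tolerance, so its F agrees with the closed form to ~1e-7 rel
            assert eff.F == pytest.approx(entry["F"], rel=1e-6)
            # lmerTest computes Satterthwaite df by numeric differentiation;
            # it agrees with the exact stratum df only to ~1e-5
            assert eff.df_den == pytest.approx(entry["df_den"], abs=1e-4)
            assert eff.p == pytest.approx(entry["p"], abs=1e-6)
        assert fit.sigma2_participant == pytest.approx(
            ref["sigma2_participant"], abs=1e-6)
        assert fit.sigma2_residual == pytest.approx(
            ref["sigma2_residual"], abs=1e-6)

    def test_constant_response_flagged_degenerate(self, balanced_table):
        tab = balanced_table.copy()
        tab["log_ttv"] = 1.0
        with pytest.raises(DegenerateDataError):
            fit_mixed_anova(tab)

    def test_unbalanced_input_refused(self, balanced_table):
        with pytest.raises(UnbalancedDesignError):
            fit_mixed_anova(balanced_table.iloc[:-1])

    def test_negative_participant_variance_truncated(self):
        tab = vv.simulate_log_ttv_table(n_per_group=3, participant_sd=0.0,
                                        residual_sd=1.0, rng=23)
        fit = fit_mixed_anova(tab)
        assert fit.sigma2_participant >= 0.0


class TestPosthocs:
    def test_vowel_family_has_six_contrasts(self, balanced_table):
        fit = fit_mixed_anova(balanced_table)
        results = posthoc_pairwise(fit, "vowel")
        assert len(results) == 6
        assert all(r.p_adjusted >= r.p_unadjusted - 1e-12 for r in results)

    def test_identical_level_means_give_p_near_one(self, balanced_table):
        tab = balanced_table.copy()
        # force all vowel marginal means equal
        vmeans = tab.groupby("vowel")["log_ttv"].transform("mean")
        tab["log_ttv"] = tab["log_ttv"] - vmeans
        fit = fit_mixed_anova(tab)
        for r in posthoc_pairwise(fit, "vowel"):
            assert abs(r.estimate) < 1e-10
            assert r.p_adjusted == pytest.approx(1.0, abs=1e-9)

    def test_group_condition_cells_strata(self, balanced_table):
        fit = fit_mixed_anova(balanced_table)
        results = posthoc_pairwise(fit, "group:condition")
        assert len(results) == 6
        for r in results:
            spans_groups = r.contrast.count("ANS") == 1
            assert r.df == (fit.df_subject if spans_groups else fit.df_residual)

    def test_simple_effect_estimates_are_cell_mean_differences(self, balanced_table):
        fit = fit_mixed_anova(balanced_table)
        cells = balanced_table.groupby(["group", "condition"])["log_ttv"].mean()
        for r in simple_effects_condition_within_group(fit):
            grp = r.contrast.split(":")[0]
            assert r.estimate == pytest.approx(
                cells[(grp, "DAF")] - cells[(grp, "NAF")], abs=1e-12)

    def test_crossover_recovered_with_correct_signs(self, balanced_table):
        fit = fit_mixed_anova(balanced_table)
        simple = {r.contrast.split(":")[0]: r
                  for r in simple_effects_condition_within_group(fit)}
        assert simple["ANS"].estimate > 0 and simple["AWS"].estimate < 0
        assert fit.effects["group:condition"].p < 0.05


class TestCorrelation:
    @staticmethod
    def _cells(x, y):
        rows = []
        for i, (xi, yi) in enumerate(zip(x, y)):
            rows.append({"participant": f"P{i:02d}", "group": "ANS",
                         "condition": "NAF", "log_wtv": xi, "log_ttv": yi})
        return pd.DataFrame(rows)

    def test_perfect_line_gives_r_one(self):
        x = np.arange(8.0)
        r, p = vv.correlate_wtv_ttv(self._cells(x, x), "ANS", "NAF")
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_matches_closed_form_on_hand_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 7.0])
        r, _ = vv.correlate_wtv_ttv(self._cells(x, y), "ANS", "NAF")
        closed = (np.sum((x - x.mean()) * (y - y.mean()))
                  / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        assert r == pytest.approx(closed, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            vv.correlate_wtv_ttv(self._cells(np.ones(5), np.arange(5.0)),
                                 "ANS", "NAF")

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            vv.correlate_wtv_ttv(self._cells([1, 2], [3, 4]), "ANS", "NAF")

    def test_null_rejection_rate_calibrated(self):
        """Independent wtv/ttv at n=12: the t-test rejects ~5% of the time."""
        rng = np.random.default_rng(6)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            x, y = rng.standard_normal(12), rng.standard_normal(12)
            _, p = vv.correlate_wtv_ttv(self._cells(x, y), "ANS", "NAF")
            rejections += p < 0.05
        assert 0.035 <= rejections / reps <= 0.065


class TestPowerMonotonicity:
    def test_interaction_rejection_rate_non_decreasing(self):
        rates = []
        for magnitude in (0.0, 0.125, 0.3):
            rng = np.random.default_rng(9)
            hits = 0
            for _ in range(50):
                tab = vv.simulate_log_ttv_table(group_shift=0.0,
                                                daf_shift=magnitude, rng=rng)
                hits += fit_mixed_anova(tab).effects["group:condition"].p < 0.05
            rates.append(hits / 50)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[0] < 0.2 and rates[2] > 0.8


def test_anova_report_structure(balanced_table):
    tab = balanced_table.copy()
    rng = np.random.default_rng(4)
    tab["log_wtv"] = tab["log_ttv"] * 0.1 + rng.normal(0, 0.2, len(tab))
    report = anova_report(tab)
    assert set(report["responses"]) == {"log_ttv", "log_wtv"}
    entry = report["responses"]["log_ttv"]
    assert set(entry["anova"]) == set(vv.stats.EFFECTS)
    assert len(entry["posthoc_vowel"]) == 6
    assert len(entry["simple_effects"]) == 2
    assert set(report["wtv_ttv_correlations"]) == {
        "ANS:NAF", "ANS:DAF", "AWS:NAF", "AWS:DAF"}
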