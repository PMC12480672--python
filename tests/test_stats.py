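"""Mixed-effects screen, VIF pruning, interaction design, moderation."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from copdmon import stats as S
from copdmon.synth.cohort import CohortSpec, gen_cohort


def brute_force_vif_prune(design: pd.DataFrame, terms, cutoff=20.0):
    """Independent greedy oracle: recompute every VIF from scratch each
    round with plain numpy regressions."""
    current = list(terms)
    removed = []
    while len(current) >= 2:
        vifs = {}
        for t in current:
            X = np.column_stack([np.ones(len(design))]
                                + [design[o].to_numpy()
                                   for o in current if o != t])
            y = design[t].to_numpy()
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            ss_res = np.sum((y - X @ beta) ** 2)
            ss_tot = np.sum((y - y.mean()) ** 2)
            r2 = 1 - ss_res / ss_tot
            vifs[t] = np.inf if r2 >= 1 else 1 / (1 - r2)
        worst = max(vifs.values())
        if worst < cutoff:
            break
        victim = sorted(t for t, v in vifs.items() if v == worst)[-1]
        current.remove(victim)
        removed.append(victim)
    return current, removed


class TestZscore:
    def test_hand_example(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out = S.zscore(df, ["x"])
        assert out["x"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_idempotent_up_to_reestimation(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.standard_normal(500)})
        once = S.zscore(df, ["x"])
        twice = S.zscore(once, ["x"])
        assert np.allclose(once["x"], twice["x"], atol=1e-12)

    def test_constant_column_error_names_column(self):
        df = pd.DataFrame({"flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="flat"):
            S.zscore(df, ["flat"])

    def test_missing_entries_untouched(self):
        df = pd.DataFrame({"x": [1.0, np.nan, 3.0, 5.0]})
        out = S.zscore(df, ["x"])
        assert np.isnan(out["x"].iloc[1])
        assert out["x"].std(ddof=1) == pytest.approx(1.0)


class TestSignificanceStars:
    @pytest.mark.parametrize("p,stars", [
        (0.049, "*"), (0.051, ""), (0.009, "**"), (0.0009, "***"),
        (0.05, ""), (np.nan, ""),
    ])
    def test_tiers(self, p, stars):
        assert S.significance_stars(p) == stars


class TestVifPrune:
    def test_duplicate_column_removed_once(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.standard_normal(200)})
        df["b"] = df["a"]
        df["c"] = rng.standard_normal(200)
        kept, log = S.vif_prune(df, ["a", "b", "c"])
        assert kept == ["a", "c"]  # lexicographically last of the tie goes
        assert log["removed"].tolist() == ["b"]

    def test_orthogonal_columns_all_retained(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((500, 4)),
                          columns=list("abcd"))
        kept, log = S.vif_prune(df, list("abcd"))
        assert kept == list("abcd")
        assert log.empty

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, k = 150, int(rng.integers(4, 9))
        df = pd.DataFrame(rng.standard_normal((n, k)),
                          columns=[f"x{i}" for i in range(k)])
        # plant collinear structures
        df["x1"] = df["x0"] + 0.05 * rng.standard_normal(n)
        if k > 4:
            df["x3"] = df["x0"] + df["x2"] + 0.1 * rng.standard_normal(n)
        terms = list(df.columns)
        kept, log = S.vif_prune(df, terms)
        kept_oracle, removed_oracle = brute_force_vif_prune(df, terms)
        assert kept == kept_oracle
        assert log["removed"].tolist() == removed_oracle

    def test_retained_set_satisfies_cutoff(self):
        rng = np.random.default_rng(2)
        n = 200
        df = pd.DataFrame(rng.standard_normal((n, 3)), columns=list("abc"))
        df["d"] = df["a"] + df["b"] + 0.01 * rng.standard_normal(n)
        kept, log = S.vif_prune(df, list("abcd"))
        assert S._vifs(df[kept]).max() < 20
        assert len(log) <= 3


class TestInteractionDesign:
    def test_single_feature_term_structure(self):
        terms = S.build_interaction_design(["jitter"])
        assert len(terms) == 15
        assert "jitter:hrv_pnn20" in terms
        assert "jitter:hrv_pnn20:pa_steps" in terms
        assert "hrv_mean_nn:pa_steps" in terms
        assert sum(":" not in t for t in terms) == 5  # mains

    def test_no_features_degenerate(self):
        terms = S.build_interaction_design([])
        assert terms == ["hrv_mean_nn", "hrv_sdnn", "hrv_pnn20", "pa_steps",
                         "hrv_mean_nn:pa_steps", "hrv_sdnn:pa_steps",
                         "hrv_pnn20:pa_steps"]

    def test_display_names_use_colon_convention(self):
        r = S.ModelResult("absolute_jitter:hrv_pnn20:pa_steps", 1.0, 0.5,
                          1.5, 0.2)
        assert r.display == "absolute jitter:HRV(pNN20):PA(steps)"


class TestUnivariate:
    def test_planted_effect_recovered(self, planted_cohort):
        table, _ = planted_cohort
        zt = S.zscore(table, ["jitter"])
        r = S.fit_univariate(zt, "jitter", "score")
        assert r.estimate < 0
        assert r.ci_high < 0
        assert r.p_value < 0.01
        assert r.scale == "beta"

    def test_ci_brackets_estimate(self, planted_cohort):
        table, _ = planted_cohort
        zt = S.zscore(table, ["jitter", "shimmer"])
        for feat in ("jitter", "shimmer"):
            r = S.fit_univariate(zt, feat, "score")
            assert r.ci_low <= r.estimate <= r.ci_high

    def test_exacerbation_outcome_reports_odds_ratio(self, planted_cohort):
        table, _ = planted_cohort
        zt = S.zscore(table, ["jitter"])
        r = S.fit_univariate(zt, "jitter", "exacerbation")
        assert r.scale == "or"
        assert r.estimate > 0
        assert r.ci_low <= r.estimate <= r.ci_high
        assert r.estimate < 1  # planted negative effect -> protective OR

    def test_row_order_invariance(self, planted_cohort):
        table, _ = planted_cohort
        zt = S.zscore(table, ["jitter"])
        r1 = S.fit_univariate(zt, "jitter", "score")
        shuffled = zt.sample(frac=1.0, random_state=7)
        r2 = S.fit_univariate(shuffled, "jitter", "score")
        assert r2.estimate == pytest.approx(r1.estimate, rel=1e-6)
        assert r2.p_value == pytest.approx(r1.p_value, rel=1e-4, abs=1e-12)

    def test_screen_flags_failures_not_omits(self):
        table, _ = gen_cohort(CohortSpec(n_participants=4, n_days=10, seed=9))
        table["broken"] = table["jitter"]
        table.loc[:, "broken"] = np.nan
        out = S.univariate_screen(table, ["jitter", "broken"], "score")
        assert len(out) == 2
        row = out.set_index("term").loc["broken"]
        assert not row["converged"]
        assert np.isnan(row["estimate"])

    def test_confounder_independence(self):
        # adding an independent confounder barely moves the estimate
        spec = CohortSpec(n_participants=20, n_days=100,
                          fixed_effects={"jitter": -0.4},
                          confounder_effects={}, seed=10)
        table, _ = gen_cohort(spec)
        zt = S.zscore(table, ["jitter"])
        with_conf = S.fit_univariate(zt, "jitter", "score")
        without = S.fit_univariate(zt, "jitter", "score", confounders=())
        se = (with_conf.ci_high - with_conf.ci_low) / (2 * 1.96)
        assert abs(with_conf.estimate - without.estimate) < 2 * se


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
class TestLme4CrossCheck:
    def test_linear_mixed_model_matches_lmer(self, tmp_path, planted_cohort):
        """Independent oracle: the same REML model fitted by R lme4."""
        table, _ = planted_cohort
        zt = S.zscore(table, ["jitter"])
        cols = ["participant", "daily_score", "jitter", "age", "sex",
                "smoking"]
        data = zt[cols].dropna()
        csv = tmp_path / "cohort.csv"
        data.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            'd <- read.csv("%s")\n'
            "library(lme4)\n"
            "m <- lmer(daily_score ~ jitter + age + factor(sex) + "
            "factor(smoking) + (1|participant), data = d, REML = TRUE)\n"
            'cat(fixef(m)["jitter"])\n' % csv)
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        beta_r = float(out.stdout.strip().split()[-1])
        r = S.fit_univariate(zt, "jitter", "score")
        assert r.estimate == pytest.approx(beta_r, rel=2e-3)


class TestModeration:
    def test_stratum_occupancy_for_normal_moderator(self):
        rng = np.random.default_rng(3)
        table, _ = gen_cohort(CohortSpec(n_participants=30, n_days=100,
                                         seed=11))
        zt = S.zscore(table, ["jitter", "hrv_pnn20"])
        strata = S.moderation_stratify(zt, "jitter", "hrv_pnn20", "score")
        occ = np.array([s.n_rows for s in strata], dtype=float)
        occ /= occ.sum()
        assert occ == pytest.approx([0.159, 0.341, 0.341, 0.159], abs=0.03)

    def test_planted_moderation_flips_sign(self, planted_cohort):
        table, _ = planted_cohort
        zt = S.zscore(table, ["jitter", "hrv_pnn20"])
        strata = S.moderation_stratify(zt, "jitter", "hrv_pnn20", "score")
        occupied = [s for s in strata if not s.empty]
        assert len(occupied) >= 2
        low, high = occupied[0], occupied[-1]
        assert low.result.estimate * high.result.estimate < 0

    def test_sparse_stratum_reported_empty(self, planted_cohort):
        table, _ = planted_cohort
        zt = S.zscore(table, ["jitter", "hrv_pnn20"])
        sub = zt[zt["hrv_pnn20"] > -1.0]  # empty the lowest stratum
        # recompute strata on a moderator whose low tail is cut off: the
        # boundaries shift, but a tiny stratum must be data, not an error
        strata = S.moderation_stratify(sub.head(60), "jitter", "hrv_pnn20",
                                       "score", min_rows=25)
        assert any(s.empty for s in strata) or all(not s.empty
                                                   for s in strata)

    def test_constant_moderator_rejected(self, planted_cohort):
        table, _ = planted_cohort
        t = table.copy()
        t["flat"] = 1.0
        with pytest.raises(ValueError):
            S.moderation_stratify(t, "jitter", "flat", "score")


class TestMultivariateAndReports:
    def test_planted_interaction_recovered(self, planted_cohort):
        table, _ = planted_cohort
        zt = S.zscore(table, ["jitter", "hrv_mean_nn", "hrv_sdnn",
                              "hrv_pnn20", "pa_steps"])
        terms = S.build_interaction_design(["jitter"])
        kept, _ = S.vif_prune(zt, terms)
        assert "jitter:hrv_pnn20" in kept
        res = S.fit_multivariate(zt, kept, "score")
        r = res["jitter:hrv_pnn20"]
        assert r.estimate > 0 and r.ci_low > 0

    def test_rank_deficient_terms_error_lists_alias(self, planted_cohort):
        table, _ = planted_cohort
        zt = S.zscore(table, ["jitter"])
        zt["jitter_copy"] = zt["jitter"]
        with pytest.raises(ValueError, match="alias"):
            S.fit_multivariate(zt, ["jitter", "jitter_copy"], "score")

    def test_permuted_labels_destroy_recovery(self, planted_cohort):
        table, _ = planted_cohort
        zt = S.zscore(table, ["jitter"])
        rng = np.random.default_rng(0)
        broken = zt.copy()
        broken["jitter"] = rng.permutation(broken["jitter"].to_numpy())
        r = S.fit_univariate(broken, "jitter", "score")
        assert r.p_value > 0.01 or abs(r.estimate) < 0.1

    def test_summary_and_report_formatting(self, planted_cohort):
        table, _ = planted_cohort
        zt = S.zscore(table, ["jitter"])
        model = S.MixedAssociation.from_dataframe(zt, "daily_score",
                                                  ["jitter"])
        res = model.fit()
        text = res.summary()
        assert "jitter" in text and "[" in text
        df, report = S.render_reports(res, title="Univariate screen")
        assert set(df.columns) >= {"term", "estimate", "ci_low", "ci_high",
                                   "p_value", "stars"}
        assert "* p <.05" in report

    def test_or_rows_print_exponentiated_bounds(self, planted_cohort):
        table, _ = planted_cohort
        zt = S.zscore(table, ["jitter"])
        r = S.fit_univariate(zt, "jitter", "exacerbation")
        assert r.ci_low > 0  # OR scale bounds are positive
        assert f"{r.estimate:.2f}" in r.formatted()
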