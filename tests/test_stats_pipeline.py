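"""Mixed-model inference chain: fits, selection, contrasts, R², LRT,
repeated-measures ANOVA, and the small preliminary tests."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from abrstab.stats_pipeline import (
    StatsError,
    corr_test,
    delta_r2,
    emmeans_contrasts,
    fit_lmm,
    fit_nested_models,
    fit_subscale_models,
    r2_decomposition,
    rmanova_gg,
    select_model,
    subscale_lrt,
    tukey_p,
    vif,
    welch_t,
)
from abrstab.synthetic_abr import DEFAULT_COMPONENT_OFFSETS, CohortSpec, simulate_cohort


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(CohortSpec(n_participants=80, seed=101))


@pytest.fixture(scope="module")
def m1_fit(cohort):
    stab, traits = cohort
    return fit_lmm("M1", stab, traits)


class TestFitLmm:
    def test_recovers_injected_coefficients(self, m1_fit):
        coef = m1_fit.coefficients.set_index("term")
        truth = {"intercept": 0.43, "aq_total": -0.023,
                 "full_sabr": -0.38, "onset": 0.24, "ffr": -0.15, "offset": -0.47}
        for term, val in truth.items():
            lo, hi = coef.loc[term, ["ci_low", "ci_high"]]
            assert lo < val < hi, term

    def test_zero_variance_random_intercept(self):
        stab, traits = simulate_cohort(CohortSpec(n_participants=60, seed=3, participant_sd=0.0))
        fit = fit_lmm("M1", stab, traits)
        r2m, r2c = r2_decomposition(fit)
        assert abs(r2c - r2m) < 1e-6

    def test_coding_invariance_of_likelihood(self, cohort):
        stab, traits = cohort
        fe = fit_lmm("M1", stab, traits, coding="effects")
        ft = fit_lmm("M1", stab, traits, coding="treatment")
        assert fe.loglik == pytest.approx(ft.loglik, abs=1e-6)
        assert fe.bic == pytest.approx(ft.bic, abs=1e-6)

    def test_component_effects_sum_to_zero(self, m1_fit):
        effects = m1_fit.component_effects()
        assert len(effects) == 5
        assert sum(effects.values()) == pytest.approx(0.0, abs=1e-10)

    def test_bic_identity(self, m1_fit):
        assert m1_fit.bic == pytest.approx(
            -2 * m1_fit.loglik + m1_fit.n_params * np.log(m1_fit.n_obs))

    def test_rank_deficiency_rejected(self, cohort):
        stab, traits = cohort
        traits = traits.copy()
        traits["vci"] = traits["age"] * 2.0  # exactly collinear in M3
        with pytest.raises(StatsError, match="rank"):
            fit_lmm("M3", stab, traits)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
class TestAgainstLmerTest:
    def test_matches_lmertest_satterthwaite(self, tmp_path, cohort):
        """Coefficients, SEs, Satterthwaite dfs, and BIC agree with lme4/lmerTest."""
        stab, traits = cohort
        fit = fit_lmm("M1", stab, traits)
        stab.to_csv(tmp_path / "stab.csv", index=False)
        traits.to_csv(tmp_path / "traits.csv", index=False)
        script = f"""
        suppressMessages({{library(lme4); library(lmerTest)}})
        stab <- read.csv("{tmp_path}/stab.csv"); tr <- read.csv("{tmp_path}/traits.csv")
        d <- merge(stab, tr, by="participant_id")
        d$component <- factor(d$component,
            levels=c("click","full_sabr","onset","ffr","offset"))
        contrasts(d$component) <- contr.sum(5)
        m <- lmer(Zr ~ component + aq_total + (1|participant_id), data=d, REML=FALSE)
        co <- coef(summary(m))
        out <- data.frame(term=rownames(co), est=co[,1], se=co[,2], df=co[,3])
        write.csv(out, "{tmp_path}/r_out.csv", row.names=FALSE)
        cat(BIC(m), file="{tmp_path}/bic.txt")
        """
        (tmp_path / "fit.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "fit.R")], check=True,
                       capture_output=True, timeout=300)
        r = pd.read_csv(tmp_path / "r_out.csv").set_index("term")
        mine = fit.coefficients.set_index("term")
        # R's contr.sum shows levels 1..4 = click..ffr; ours shows 2..5
        pairs = {"(Intercept)": "intercept", "component2": "full_sabr",
                 "component3": "onset", "component4": "ffr", "aq_total": "aq_total"}
        for rterm, term in pairs.items():
            assert mine.loc[term, "estimate"] == pytest.approx(r.loc[rterm, "est"], abs=1e-5)
            assert mine.loc[term, "se"] == pytest.approx(r.loc[rterm, "se"], abs=1e-5)
            assert mine.loc[term, "df"] == pytest.approx(r.loc[rterm, "df"], rel=0.02)
        r_bic = float((tmp_path / "bic.txt").read_text())
        assert fit.bic == pytest.approx(r_bic, abs=0.01)


class TestSelectModel:
    def test_null_cohort_prefers_component_only_model(self):
        wins = 0
        n_seeds = 12
        for seed in range(n_seeds):
            stab, traits = simulate_cohort(
                CohortSpec(n_participants=50, seed=200 + seed, beta_trait=0.0))
            best, _ = select_model(fit_nested_models(stab, traits))
            wins += best == "M0"
        assert wins >= 0.6 * n_seeds

    def test_strong_trait_effect_selects_trait_model(self):
        wins = 0
        n_seeds = 12
        for seed in range(n_seeds):
            stab, traits = simulate_cohort(
                CohortSpec(n_participants=80, seed=300 + seed, beta_trait=-0.023))
            best, _ = select_model(fit_nested_models(stab, traits))
            wins += best in ("M1", "M2", "M3")
        assert wins >= 0.9 * n_seeds

    def test_single_fit_delta_zero(self, m1_fit):
        best, table = select_model({"M1": m1_fit})
        assert best == "M1" and table["delta_bic"].iloc[0] == 0.0

    def test_delta_table_has_exactly_one_zero(self, cohort):
        stab, traits = cohort
        _, table = select_model(fit_nested_models(stab, traits))
        assert (table["delta_bic"] == 0.0).sum() == 1

    def test_differing_observations_rejected(self, cohort, m1_fit):
        stab, traits = cohort
        other = fit_lmm("M1", stab[stab["component"] != "ffr"], traits)
        with pytest.raises(StatsError, match="differing"):
            select_model({"a": m1_fit, "b": other})


class TestContrasts:
    def test_all_ten_pairs_present(self, m1_fit):
        table = emmeans_contrasts(m1_fit)
        assert len(table) == 10

    def test_adjusted_never_below_unadjusted(self, m1_fit):
        table = emmeans_contrasts(m1_fit)
        assert (table["p_tukey"] >= table["p_unadjusted"] - 1e-12).all()

    def test_click_differs_from_all_other_components(self):
        offs = {"click": 0.5, "full_sabr": -0.125, "onset": -0.125,
                "ffr": -0.125, "offset": -0.125}
        stab, traits = simulate_cohort(CohortSpec(
            n_participants=60, seed=77, component_offsets=offs,
            beta_trait=0.0, participant_sd=0.1, residual_sd=0.1))
        fit = fit_lmm("M0", stab, traits)
        table = emmeans_contrasts(fit)
        click_rows = table[table["contrast"].str.startswith("click")]
        assert len(click_rows) == 4
        assert (click_rows["p_tukey"] < 0.05).all()

    def test_equal_offsets_rarely_significant(self):
        offs = {c: 0.0 for c in DEFAULT_COMPONENT_OFFSETS}
        clean = 0
        n_seeds = 10
        for seed in range(n_seeds):
            stab, traits = simulate_cohort(CohortSpec(
                n_participants=50, seed=400 + seed, component_offsets=offs, beta_trait=0.0))
            fit = fit_lmm("M0", stab, traits)
            clean += (emmeans_contrasts(fit)["p_tukey"] >= 0.05).all()
        assert clean >= n_seeds - 2

    def test_two_level_tukey_reduces_to_t(self):
        offs = {"onset": 0.2, "offset": -0.2}
        stab, traits = simulate_cohort(CohortSpec(
            n_participants=40, seed=9, component_offsets=offs, beta_trait=0.0))
        fit = fit_lmm("M0", stab, traits)
        table = emmeans_contrasts(fit)
        assert len(table) == 1
        row = table.iloc[0]
        t_p = 2 * sps.t.sf(abs(row["t"]), row["df"])
        assert row["p_tukey"] == pytest.approx(t_p, abs=1e-6)

    def test_tukey_q_consistent_with_scipy_for_k2(self):
        # the analytic two-level reduction must agree with the q-distribution
        q_based = float(sps.studentized_range.sf(2.2 * np.sqrt(2.0), 2, 60))
        assert tukey_p(2.2, 2, 60.0) == pytest.approx(q_based, abs=1e-5)


class TestR2:
    def test_identical_models_delta_zero(self, m1_fit):
        assert delta_r2(m1_fit, m1_fit) == 0.0

    def test_pure_fixed_effect_data(self):
        stab, traits = simulate_cohort(CohortSpec(
            n_participants=40, seed=8, participant_sd=0.0, residual_sd=1e-6))
        fit = fit_lmm("M1", stab, traits)
        assert fit.r2_marginal > 0.999

    def test_r2_matches_plugin_variance_oracle(self):
        spec = CohortSpec(n_participants=400, seed=21)
        stab, traits = simulate_cohort(spec)
        fit = fit_lmm("M1", stab, traits)
        df = stab.merge(traits, on="participant_id")
        fixed = df["component"].map(spec.component_offsets) + spec.beta_trait * df["aq_total"]
        sf2 = np.var(fixed)
        total = sf2 + spec.participant_sd**2 + spec.residual_sd**2
        assert fit.r2_marginal == pytest.approx(sf2 / total, abs=0.03)
        assert fit.r2_conditional == pytest.approx((sf2 + spec.participant_sd**2) / total, abs=0.03)

    def test_aq_unique_variance_is_positive(self, cohort):
        stab, traits = cohort
        fits = fit_nested_models(stab, traits)
        assert delta_r2(fits["M1"], fits["M0"]) > 0.0

    def test_non_nested_pair_rejected(self, cohort, m1_fit):
        stab, traits = cohort
        other = fit_lmm("M1", stab[stab["component"] != "ffr"], traits)
        with pytest.raises(StatsError):
            delta_r2(m1_fit, other)


class TestSubscaleLrt:
    def test_identical_models_chi2_zero(self, m1_fit):
        chi2, df, p = subscale_lrt(m1_fit, m1_fit)
        assert chi2 == 0.0 and df == 0 and p == 1.0

    def test_null_subscale_lrt_distribution(self):
        """Under no subscale effect the LRT statistic follows χ²(1)."""
        chi2s = []
        for seed in range(40):
            stab, traits = simulate_cohort(CohortSpec(n_participants=40, seed=500 + seed))
            full, reduced = fit_subscale_models(stab, traits, "aq_imagination")
            chi2, df, _ = subscale_lrt(full, reduced)
            assert df == 1
            chi2s.append(chi2)
        ks = sps.ks_1samp(chi2s, sps.chi2(1).cdf)
        assert ks.pvalue > 0.01

    def test_strong_subscale_effect_detected(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            stab, traits = simulate_cohort(CohortSpec(n_participants=60, seed=600 + seed))
            df = stab.merge(traits, on="participant_id")
            stab = stab.copy()
            stab["Zr"] = stab["Zr"].to_numpy() - 0.08 * df["aq_imagination"].to_numpy()
            full, reduced = fit_subscale_models(stab, traits, "aq_imagination")
            _, _, p = subscale_lrt(full, reduced)
            hits += p < 0.05
        assert hits >= 0.9 * n_seeds


def rm_long(Y, factor_names=("A",)):
    n = Y.shape[0]
    rows = []
    if Y.ndim == 2:
        for i in range(n):
            for j in range(Y.shape[1]):
                rows.append({"s": i, factor_names[0]: j, "y": Y[i, j]})
    return pd.DataFrame(rows)


class TestRmanova:
    def test_two_level_factor_epsilon_is_one(self):
        rng = np.random.default_rng(0)
        df = rm_long(rng.standard_normal((12, 2)))
        eff = rmanova_gg(df, "y", ["A"], "s").effects["A"]
        assert eff.gg_epsilon == 1.0 and not eff.corrected

    def test_compound_symmetric_epsilon_near_one(self):
        eps = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            Y = rng.standard_normal((45, 1)) * 1.0 + rng.standard_normal((45, 5)) * 0.8
            eps.append(rmanova_gg(rm_long(Y), "y", ["A"], "s").effects["A"].gg_epsilon)
        assert 0.85 <= np.mean(eps) <= 1.0

    def test_maximally_nonspherical_epsilon_near_lower_bound(self):
        rng = np.random.default_rng(1)
        w = np.array([1.0, -1.0, 0.5, -0.5, 0.0])
        Y = np.outer(rng.standard_normal(30), w) + 1e-3 * rng.standard_normal((30, 5))
        eff = rmanova_gg(rm_long(Y), "y", ["A"], "s").effects["A"]
        assert eff.gg_epsilon < 0.30  # bound is 1/(k−1) = 0.25
        assert eff.corrected

    def test_matches_pingouin_one_way(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        Y = rng.standard_normal((20, 1)) + rng.standard_normal((20, 5)) * np.array(
            [0.3, 0.5, 1.0, 1.8, 2.5])
        df = rm_long(Y)
        eff = rmanova_gg(df, "y", ["A"], "s").effects["A"]
        table = pg.rm_anova(data=df, dv="y", within="A", subject="s", correction=True)
        assert eff.F == pytest.approx(float(table["F"].iloc[0]), abs=1e-8)
        assert eff.gg_epsilon == pytest.approx(float(table["eps"].iloc[0]), abs=1e-8)
        spher = pg.sphericity(data=df, dv="y", within="A", subject="s")
        assert eff.mauchly_chi2 == pytest.approx(float(spher.chi2), abs=1e-8)
        assert eff.p == pytest.approx(float(table["p_GG_corr"].iloc[0]), abs=1e-8)

    def test_two_way_f_matches_anovarm(self):
        from statsmodels.stats.anova import AnovaRM
        rng = np.random.default_rng(5)
        rows = []
        for i in range(15):
            s = rng.standard_normal() * 0.8
            for j in range(2):
                for k in range(5):
                    rows.append({"s": i, "ear": j, "comp": k,
                                 "y": s + 0.2 * j + 0.3 * k + rng.standard_normal() * 0.7})
        df = pd.DataFrame(rows)
        res = rmanova_gg(df, "y", ["ear", "comp"], "s")
        ref = AnovaRM(df, "y", "s", within=["ear", "comp"]).fit().anova_table
        assert res.effects["ear"].F == pytest.approx(ref.loc["ear", "F Value"], abs=1e-8)
        assert res.effects["comp"].F == pytest.approx(ref.loc["comp", "F Value"], abs=1e-8)
        assert res.effects["ear:comp"].F == pytest.approx(ref.loc["ear:comp", "F Value"], abs=1e-8)
        assert res.effects["ear"].gg_epsilon == 1.0

    def test_incomplete_cells_rejected(self):
        df = rm_long(np.random.default_rng(0).standard_normal((10, 3)))
        with pytest.raises(StatsError, match="incomplete"):
            rmanova_gg(df.iloc[:-1], "y", ["A"], "s")


class TestVifAndSmallTests:
    def test_orthogonal_predictors_vif_one(self):
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.standard_normal((50, 3)))
        q -= q.mean(axis=0)
        out = vif(pd.DataFrame(q, columns=list("abc")))
        assert np.allclose(out, 1.0, atol=1e-2)

    def test_two_correlated_predictors_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(200)
        z = rng.standard_normal(200)
        # orthonormalize so the empirical correlation is exactly r
        x = (x - x.mean()) / np.std(x)
        z = z - z.mean() - x * np.dot(z - z.mean(), x) / np.dot(x, x)
        z /= np.std(z)
        r = 0.6
        y = r * x + np.sqrt(1 - r**2) * z
        out = vif(pd.DataFrame({"x": x, "y": y}))
        assert out["x"] == pytest.approx(1.0 / (1.0 - r**2), abs=1e-9)

    def test_duplicated_column_infinite(self):
        x = np.arange(20.0)
        out = vif(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(out).all()

    def test_welch_identical_groups(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_welch_p_matches_permutation(self):
        rng = np.random.default_rng(7)
        a = np.array([4.1, 5.3, 6.0, 4.8, 5.5, 6.2, 5.0, 4.4])
        b = np.array([5.9, 6.4, 7.1, 6.8, 5.7, 7.3, 6.6])
        t_obs, _, p = welch_t(a, b)
        pooled = np.concatenate([a, b])
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            t_perm, _, _ = welch_t(perm[:len(a)], perm[len(a):])
            count += abs(t_perm) >= abs(t_obs)
        assert p == pytest.approx(count / n_perm, abs=0.02)

    def test_corr_perfect(self):
        x = np.arange(10.0)
        r, p = corr_test(x, x)
        assert r == pytest.approx(1.0)

    def test_corr_constant_input_rejected(self):
        with pytest.raises(StatsError):
            corr_test(np.ones(5), np.arange(5.0))
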