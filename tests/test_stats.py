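import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from blinkpipe.stats import (
    LMESpec,
    MixedEffectsComparison,
    compare_fits,
    fit_lme,
    holm_adjust,
    per_day_contrasts,
)
from oracles import brute_holm


def grip_like_table(rng, n_std=11, n_enr=16, group_effect=0.0, mouse_sd=10.0,
                    noise_sd=7.0, n_per_mouse=8):
    rows = []
    for g, n, eff in (("standard", n_std, 0.0), ("enriched", n_enr, group_effect)):
        for m in range(n):
            mouse = f"{g[:3]}{m:02d}"
            off = rng.normal(0, mouse_sd)
            for t in range(n_per_mouse):
                rows.append(
                    {
                        "mouse_id": mouse,
                        "group": g,
                        "trial_or_run": t + 1,
                        "value": 90.0 + eff + off + rng.normal(0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)


def day_table(rng, n_days=4, group_effect_by_day=None, mouse_sd=10.0, noise_sd=15.0):
    effects = group_effect_by_day or {}
    rows = []
    for g, n in (("standard", 11), ("enriched", 16)):
        for m in range(n):
            mouse = f"{g[:3]}{m:02d}"
            off = rng.normal(0, mouse_sd)
            for d in range(1, n_days + 1):
                eff = effects.get(d, 0.0) if g == "enriched" else 0.0
                for t in range(1, 5):
                    rows.append(
                        {
                            "mouse_id": mouse,
                            "group": g,
                            "day": d,
                            "trial_or_run": t,
                            "value": 100.0 + eff + off + rng.normal(0, noise_sd),
                        }
                    )
    return pd.DataFrame(rows)


class TestHolm:
    def test_worked_example(self):
        adj = holm_adjust([0.01, 0.02, 0.04])
        assert np.allclose(adj, [0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.3]) == pytest.approx([0.3])

    def test_all_ones(self):
        assert np.allclose(holm_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20),
    )
    def test_matches_brute_force(self, pvals):
        ours = holm_adjust(pvals)
        theirs = brute_holm(pvals)
        assert np.allclose(ours, theirs)
        assert np.all(ours >= np.asarray(pvals) - 1e-12)
        assert np.all(ours <= 1.0)


class TestFitLME:
    def test_group_test_agrees_with_mouse_mean_comparison(self, rng):
        from scipy import stats as sps

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = grip_like_table(rng, group_effect=9.0, n_per_mouse=1)
            res = fit_lme(table, LMESpec(outcome="value"))
        means = table.groupby(["mouse_id", "group"])["value"].mean().reset_index()
        t, p = sps.ttest_ind(
            means.loc[means.group == "enriched", "value"],
            means.loc[means.group == "standard", "value"],
        )
        # one observation per mouse: the group test must agree in
        # direction with the two-sample comparison of mouse means (the
        # tau2/sigma2 split is unidentified here, so only the total
        # variance -- and hence direction and rough magnitude -- is pinned)
        row = res.terms.set_index("term").loc["group"]
        assert row["df2"] == 25
        diff = (
            means.loc[means.group == "enriched", "value"].mean()
            - means.loc[means.group == "standard", "value"].mean()
        )
        group_coef = [v for k, v in res.fe_params.items() if "group" in k][0]
        assert np.sign(group_coef) == np.sign(diff)
        assert row["p"] == pytest.approx(p, abs=0.15)

    def test_recovers_injected_group_difference(self, rng):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = grip_like_table(rng, group_effect=60.0, mouse_sd=15)
            res = fit_lme(table, LMESpec(outcome="value"))
        est = [v for k, v in res.fe_params.items() if "group" in k]
        assert len(est) == 1
        # sum coding: the group column carries half the group difference
        assert 2 * abs(est[0]) == pytest.approx(60.0, abs=15.0)

    def test_constant_outcome_rejected(self):
        table = pd.DataFrame(
            {
                "mouse_id": list("aabb"),
                "group": ["standard", "standard", "enriched", "enriched"],
                "value": [1.0, 1.0, 1.0, 1.0],
            }
        )
        with pytest.raises(ValueError, match="zero variance"):
            fit_lme(table, LMESpec(outcome="value"))

    def test_single_group_rejected(self, rng):
        table = grip_like_table(rng)
        table = table[table.group == "standard"]
        with pytest.raises(ValueError, match="2 levels"):
            fit_lme(table, LMESpec(outcome="value"))

    def test_residuals_cover_every_row(self, rng):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = grip_like_table(rng)
            res = fit_lme(table, LMESpec(outcome="value"))
        assert res.residuals.shape[0] == res.n_obs == len(table)
        assert res.fitted.shape[0] == len(table)

    def test_containment_dfs_on_balanced_eyeblink_design(self, rng):
        table = day_table(rng, n_days=10)
        per_day = (
            table.groupby(["mouse_id", "group", "day"], as_index=False)["value"].mean()
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_lme(
                per_day,
                LMESpec(outcome="value", fixed_effects=("group", "day", "group:day")),
            )
        t = res.terms.set_index("term")
        assert t.loc["group", "df2"] == 25  # 27 mice - 2 between params
        assert t.loc["day", "df2"] == 270 - 27 - 18
        assert t.loc["group:day", "df1"] == 9


class TestContrasts:
    def test_single_day_reduces_to_two_group_comparison(self, rng):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = day_table(rng, n_days=1, group_effect_by_day={1: 30.0})
            out = per_day_contrasts(
                table,
                LMESpec(outcome="value", fixed_effects=("group", "day", "group:day")),
            )
        assert len(out) == 1
        assert out.loc[0, "p_adj"] == pytest.approx(out.loc[0, "p_raw"])
        assert out.loc[0, "contrast"] == "standard - enriched"
        assert out.loc[0, "estimate"] == pytest.approx(-30.0, abs=15.0)

    def test_mid_phase_effect_flags_those_days(self, rng):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = day_table(
                rng, n_days=6,
                group_effect_by_day={3: 40.0, 4: 40.0},
                mouse_sd=8.0, noise_sd=12.0,
            )
            out = per_day_contrasts(
                table,
                LMESpec(outcome="value", fixed_effects=("group", "day", "group:day")),
            ).set_index("day")
        assert out.loc[3, "significant"] and out.loc[4, "significant"]
        assert not out.loc[[1, 2, 5, 6], "significant"].any()

    def test_adjusted_never_flags_more_than_raw(self, rng):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = day_table(rng, n_days=5, group_effect_by_day={2: 25.0})
            out = per_day_contrasts(
                table,
                LMESpec(outcome="value", fixed_effects=("group", "day", "group:day")),
            )
        assert (out["p_adj"] >= out["p_raw"] - 1e-12).all()
        assert out["significant"].sum() <= (out["p_raw"] < 0.05).sum()


class TestCompareFits:
    def _fits(self, rng):
        table = day_table(rng, n_days=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            small = fit_lme(table, LMESpec(outcome="value", fixed_effects=("group",)))
            big = fit_lme(
                table, LMESpec(outcome="value", fixed_effects=("group", "day"))
            )
        return table, small, big

    def test_duplicate_model_zero_delta(self, rng):
        _, small, _ = self._fits(rng)
        out = compare_fits([small, small])
        assert np.allclose(out["delta_aic"], 0.0)

    def test_pure_noise_term_penalized_by_bic(self, rng):
        _, small, big = self._fits(rng)
        out = compare_fits([small, big]).set_index("model")
        # day carries no signal here: BIC must prefer the smaller model
        assert out.loc[1, "bic"] > out.loc[0, "bic"]
        # and the LR test against the nested model is reported
        assert out.loc[1, "lr_vs_model"] == 0
        assert out.loc[1, "lr_df"] == 3

    def test_non_nested_pair_marked_na(self, rng):
        table = day_table(rng, n_days=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_lme(table, LMESpec(outcome="value", fixed_effects=("group",)))
            b = fit_lme(table, LMESpec(outcome="value", fixed_effects=("day",)))
        out = compare_fits([a, b])
        assert out["lr_stat"].isna().all()

    def test_mismatched_tables_rejected(self, rng):
        table = day_table(rng, n_days=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_lme(table, LMESpec(outcome="value", fixed_effects=("group",)))
            b = fit_lme(
                table.iloc[: len(table) // 2],
                LMESpec(outcome="value", fixed_effects=("group",)),
            )
        with pytest.raises(ValueError, match="share"):
            compare_fits([a, b])


class TestEstimatorAPI:
    def test_get_set_params_round_trip(self):
        est = MixedEffectsComparison(outcome="value", alpha=0.01)
        params = est.get_params()
        assert params["alpha"] == 0.01
        est2 = MixedEffectsComparison().set_params(**params)
        assert est2.alpha == 0.01

    def test_fit_exposes_fitted_attributes(self, rng):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = MixedEffectsComparison(outcome="value").fit(
                grip_like_table(rng, group_effect=20.0)
            )
        assert hasattr(est, "result_")
        assert est.anova_.iloc[0]["term"] == "group"
        assert np.isfinite(est.aic_) and np.isfinite(est.bic_)


@pytest.mark.parametrize("reml", [True])
def test_fixed_effects_match_lme4(tmp_path, rng, reml):
    """Independent cross-check of the mixed-model fit against R's lme4."""
    table = grip_like_table(rng, group_effect=12.0, n_per_mouse=4)
    csv = tmp_path / "table.csv"
    table.to_csv(csv, index=False)
    rscript = tmp_path / "fit.R"
    rscript.write_text(
        """
        suppressMessages(library(lme4))
        d <- read.csv(commandArgs(TRUE)[1])
        d$group <- factor(d$group)
        contrasts(d$group) <- contr.sum(2)
        m <- lmer(value ~ group + (1|mouse_id), data=d, REML=TRUE)
        fe <- fixef(m)
        vc <- as.data.frame(VarCorr(m))
        cat(sprintf("%.8f %.8f %.8f %.8f\\n",
            fe[1], fe[2], vc$vcov[1], vc$vcov[2]))
        """
    )
    proc = subprocess.run(
        ["Rscript", str(rscript), str(csv)],
        capture_output=True,
        text=True,
        timeout=120,
    )
    assert proc.returncode == 0, proc.stderr
    r_int, r_group, r_mouse_var, r_resid_var = map(float, proc.stdout.split())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = fit_lme(table, LMESpec(outcome="value"))
    ours = res.fe_params.to_numpy()
    assert ours[0] == pytest.approx(r_int, abs=1e-4)
    # R's contr.sum puts +1 on the first level (enriched), as patsy's Sum does
    assert ours[1] == pytest.approx(r_group, abs=1e-4)
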