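"""Mixed-model layer: LME fitting, elimination, R², repeatability."""

import warnings

import numpy as np
import pandas as pd
import pytest

from airbreath import mixed_stats as ms
from airbreath import simulate as sim
from airbreath.errors import UndefinedStatisticError, UnidentifiableError

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="module")
def trait_table():
    return sim.simulate_trait_table(seed=314, v_id=0.3, v_group=0.1, v_resid=0.6)


@pytest.fixture(scope="module")
def analysis_table():
    return sim.simulate_analysis_table(seed=2718)


class TestFitLME:
    def test_pure_noise_slopes_within_3se_of_zero(self):
        df = sim.simulate_trait_table(seed=1, v_id=0.0, v_group=0.0, v_resid=1.0)
        rng = np.random.default_rng(2)
        df["x"] = rng.normal(size=len(df))
        fit = ms.fit_lme(ms.ModelSpec("y", ["x"]), df)
        t = fit.tvalues()["x"]
        assert abs(t) < 3.0

    def test_known_slope_recovered(self):
        # attacks -> breaths slope designed into the generator
        recovered = 0
        for s in range(30):
            df = sim.simulate_analysis_table(seed=1000 + s)
            fit = ms.fit_lme(
                ms.ModelSpec("breaths", ["activity_log", "attacks_log"]), df
            )
            est = fit.fe_params["attacks_log"]
            se = fit.result.bse_fe["attacks_log"]
            if abs(est - 1.687) <= 1.96 * se:
                recovered += 1
        assert recovered >= 27  # >= 90% CI coverage of the design value

    def test_zero_id_variance_estimated_at_boundary(self):
        df = sim.simulate_trait_table(seed=3, v_id=0.0, v_group=0.2, v_resid=0.8)
        fit = ms.fit_lme(ms.ModelSpec("y", []), df)
        assert fit.variance_components().v_id < 0.05

    def test_too_few_grouping_levels(self):
        df = sim.simulate_trait_table(seed=4, n_groups=1)
        with pytest.raises(Exception):
            ms.fit_lme(ms.ModelSpec("y", [], random="group"), df)


class TestCompareRandomStructures:
    def test_no_heterogeneity_prefers_intercepts(self):
        chosen = 0
        for s in range(20):
            df = sim.simulate_trait_table(seed=100 + s)
            out = ms.compare_random_structures(
                ms.ModelSpec("y", ["C(oxygen_level)"]), df, "oxygen_num"
            )
            chosen += out["choice"] == "intercept"
        assert chosen >= 19  # intercept-only in >= 95% of runs

    def test_strong_slopes_detected(self):
        df = sim.simulate_trait_table(seed=9, v_slope=2.0, v_resid=0.2)
        out = ms.compare_random_structures(
            ms.ModelSpec("y", ["C(oxygen_level)"]), df, "oxygen_num"
        )
        assert out["choice"] == "slope"

    def test_equal_likelihood_ties_to_intercept(self):
        # if the slope model cannot improve the likelihood, parsimony wins
        df = sim.simulate_trait_table(seed=10, v_slope=0.0)
        out = ms.compare_random_structures(
            ms.ModelSpec("y", []), df, "oxygen_num"
        )
        stat = out["table"]["lrt_stat"].iloc[1]
        if stat <= 0:
            assert out["choice"] == "intercept"


class TestBackwardElimination:
    def test_irrelevant_covariate_dropped(self):
        df = sim.simulate_trait_table(seed=21, v_resid=1.0)
        rng = np.random.default_rng(22)
        df["junk"] = rng.normal(size=len(df))
        final, trail = ms.backward_eliminate(ms.ModelSpec("y", ["junk"]), df)
        assert "junk" not in final.spec.fixed_terms
        assert trail.iloc[0]["decision"] == "dropped"

    def test_alpha_one_keeps_full_model(self, analysis_table):
        terms = ["smr_log", "activity_log", "attacks_log"]
        final, trail = ms.backward_eliminate(
            ms.ModelSpec("breaths", terms), analysis_table, alpha=1.0
        )
        assert final.spec.fixed_terms == terms
        assert (trail["decision"] == "kept").all()

    def test_interaction_protects_main_effect(self, analysis_table):
        terms = ["attacks_log", "C(oxygen_level)", "attacks_log:C(oxygen_level)"]
        _, trail = ms.backward_eliminate(
            ms.ModelSpec("breaths", terms), analysis_table, alpha=1.0
        )
        # with alpha=1 nothing is dropped, and the only candidate ever
        # offered is the interaction (main effects are protected)
        assert set(trail["term"]) == {"attacks_log:C(oxygen_level)"}

    def test_true_effects_retained_nulls_dropped(self, analysis_table):
        terms = ["smr_log", "mass_log", "pct_air", "activity_log",
                 "attacks_log", "C(oxygen_level)"]
        final, trail = ms.backward_eliminate(
            ms.ModelSpec("breaths", terms), analysis_table, alpha=0.05
        )
        assert "activity_log" in final.spec.fixed_terms
        assert "attacks_log" in final.spec.fixed_terms

    def test_trail_replays_deterministically(self, analysis_table):
        spec = ms.ModelSpec("breaths", ["smr_log", "activity_log", "attacks_log"])
        _, t1 = ms.backward_eliminate(spec, analysis_table)
        _, t2 = ms.backward_eliminate(spec, analysis_table)
        pd.testing.assert_frame_equal(t1, t2)


class TestR2Nakagawa:
    def test_variance_ratio_formulas(self, trait_table):
        fit = ms.fit_lme(ms.ModelSpec("y", ["C(oxygen_level)"]), trait_table)
        vc = fit.variance_components()
        r2 = ms.r2_nakagawa(fit)
        assert r2.r2_marginal == pytest.approx(vc.v_fixed / vc.total)
        assert r2.r2_conditional == pytest.approx(
            (vc.v_fixed + vc.v_id + vc.v_group) / vc.total
        )
        assert 0.0 <= r2.r2_marginal <= r2.r2_conditional <= 1.0

    def test_null_fixed_effects_with_equal_id_resid(self):
        df = sim.simulate_trait_table(
            seed=31, v_id=0.5, v_group=0.0, v_resid=0.5,
            n_groups=30, n_obs=6,
        )
        fit = ms.fit_lme(ms.ModelSpec("y", []), df)
        r2 = ms.r2_nakagawa(fit)
        assert r2.r2_marginal == pytest.approx(0.0, abs=0.02)
        assert r2.r2_conditional == pytest.approx(0.5, abs=0.12)

    def test_component_mix_recovered(self):
        # v_fixed comes from designed level effects; estimates land within
        # 0.05 of the generator's variance shares at the study's n
        effs = np.array([-0.6, -0.3, 0.0, 0.3, 0.6])
        true_vf = float(np.var(np.repeat(effs, 44), ddof=1))
        r2m, r2c = [], []
        for s in range(10):
            df = sim.simulate_trait_table(
                seed=400 + s, v_id=0.3, v_group=0.1, v_resid=0.6,
                obs_effects=effs,
            )
            fit = ms.fit_lme(ms.ModelSpec("y", ["C(oxygen_level)"]), df)
            r2 = ms.r2_nakagawa(fit)
            r2m.append(r2.r2_marginal)
            r2c.append(r2.r2_conditional)
        tot = true_vf + 1.0
        assert np.median(r2m) == pytest.approx(true_vf / tot, abs=0.05)
        assert np.median(r2c) == pytest.approx((true_vf + 0.4) / tot, abs=0.05)

    def test_affine_rescaling_invariance(self, trait_table):
        spec = ms.ModelSpec("y", ["C(oxygen_level)"])
        r2a = ms.r2_nakagawa(ms.fit_lme(spec, trait_table))
        scaled = trait_table.copy()
        scaled["y"] = 3.0 * scaled["y"] + 7.0
        r2b = ms.r2_nakagawa(ms.fit_lme(spec, scaled))
        assert r2a.r2_marginal == pytest.approx(r2b.r2_marginal, abs=1e-4)
        assert r2a.r2_conditional == pytest.approx(r2b.r2_conditional, abs=1e-4)


class TestRepeatability:
    def test_seed_mandatory(self, trait_table):
        with pytest.raises(ValueError, match="seed"):
            ms.repeatability(trait_table, "y", n_boot=10)

    def test_zero_truth_gives_near_zero_with_ci_including_zero(self):
        df = sim.simulate_trait_table(seed=51, v_id=0.0, v_group=0.1, v_resid=0.9)
        est = ms.repeatability(df, "y", adjust_terms=["C(oxygen_level)"],
                               n_boot=50, seed=1)
        assert est.r < 0.1
        assert est.ci_low == pytest.approx(0.0, abs=0.02)

    def test_duplicate_observations_drive_r_to_one(self):
        rng = np.random.default_rng(6)
        rows = []
        for g in range(6):
            for i in range(4):
                y = rng.normal()
                for k in range(2):
                    rows.append({
                        "group_id": f"g{g}", "fish_id": f"g{g}f{i}",
                        "oxygen_level": str(k), "y": y,
                    })
        df = pd.DataFrame(rows)
        est = ms.repeatability(df, "y", random="id", n_boot=10, seed=2)
        assert est.r > 0.98

    def test_point_recovery_at_study_size(self):
        # truth v_id=0.3, v_group=0.1, v_resid=0.6 -> r = 0.3
        rs = []
        for s in range(11):
            df = sim.simulate_trait_table(seed=600 + s)
            est = ms.repeatability(df, "y", adjust_terms=["C(oxygen_level)"],
                                   n_boot=0, seed=1)
            rs.append(est.r)
        assert np.median(rs) == pytest.approx(0.3, abs=0.05)

    def test_shift_and_label_invariance(self, trait_table):
        base = ms.repeatability(trait_table, "y", n_boot=0, seed=5)
        shifted = trait_table.copy()
        shifted["y"] = shifted["y"] + 100.0
        est2 = ms.repeatability(shifted, "y", n_boot=0, seed=5)
        assert est2.r == pytest.approx(base.r, abs=1e-5)
        relabeled = trait_table.copy()
        mapping = {f: f"zz_{i}" for i, f in
                   enumerate(sorted(relabeled["fish_id"].unique(), reverse=True))}
        relabeled["fish_id"] = relabeled["fish_id"].map(mapping)
        est3 = ms.repeatability(relabeled, "y", n_boot=0, seed=5)
        assert est3.r == pytest.approx(base.r, abs=1e-4)

    def test_single_observation_per_id_unidentifiable(self):
        df = sim.simulate_trait_table(seed=61, n_obs=1)
        with pytest.raises(UnidentifiableError):
            ms.repeatability(df, "y", n_boot=10, seed=1)

    def test_ci_brackets_estimate_and_p_small_for_real_variance(self, trait_table):
        est = ms.repeatability(trait_table, "y",
                               adjust_terms=["C(oxygen_level)"],
                               n_boot=60, seed=9)
        assert 0.0 <= est.ci_low <= est.r <= est.ci_high <= 1.0
        assert est.p < 0.05
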