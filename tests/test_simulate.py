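"""Synthetic-data generator: backbones, noise, Loewe null, CT round trips."""

import numpy as np
import pandas as pd
import pytest

from synergyci import (
    ConstantRatioDesign,
    CtSimParams,
    DesignError,
    DomainError,
    MedianEffectFit,
    SimulationSpec,
    additive_mixture_fit,
    ci_profile,
    combination_index_at_fa,
    effect_at_dose,
    fit_median_effect,
    loewe_additive_total_dose,
    simulate_combination,
    simulate_ct_dataset,
    simulate_ct_table,
    simulate_single_agent,
)
from synergyci.readout import reductions_from_ct_table


class TestSingleAgent:
    def test_noise_free_points_lie_on_curve(self):
        spec = SimulationSpec(noise_scale=0.0)
        s = simulate_single_agent(spec, 1)
        fit = MedianEffectFit(*spec.true_fit1)
        assert s.effects == pytest.approx(effect_at_dose(fit, s.doses), abs=1e-15)

    @pytest.mark.parametrize("which,truth", [(1, (14.28, 1.835)), (2, (91.2, 2.005))])
    def test_generation_refit_round_trip(self, which, truth):
        spec = SimulationSpec(noise_scale=0.0)
        fit = fit_median_effect(simulate_single_agent(spec, which))
        assert fit.dm == pytest.approx(truth[0], rel=1e-6)
        assert fit.m == pytest.approx(truth[1], rel=1e-6)

    def test_seeded_runs_are_bit_identical(self):
        spec = SimulationSpec(noise_scale=0.05, n_replicates=3, seed=42)
        a = simulate_single_agent(spec, 1)
        b = simulate_single_agent(spec, 1)
        assert np.array_equal(a.effects, b.effects)
        c = simulate_combination(spec)
        d = simulate_combination(spec)
        assert np.array_equal(c.effects, d.effects)

    def test_different_seeds_differ(self):
        a = simulate_single_agent(SimulationSpec(noise_scale=0.05, seed=1), 1)
        b = simulate_single_agent(SimulationSpec(noise_scale=0.05, seed=2), 1)
        assert not np.array_equal(a.effects, b.effects)

    def test_noise_keeps_effects_in_unit_interval(self):
        spec = SimulationSpec(noise_scale=0.5, n_replicates=10, seed=7)
        s = simulate_single_agent(spec, 1)
        assert np.all((s.effects >= 0.0) & (s.effects <= 1.0))

    def test_multiplicative_fold_noise_model(self):
        spec = SimulationSpec(noise_model="multiplicative-fold", noise_scale=0.1,
                              n_replicates=4, seed=11)
        s = simulate_single_agent(spec, 1)
        assert np.all((s.effects >= 0.0) & (s.effects <= 1.0))
        assert not np.allclose(s.effects[:5], s.effects[5:10])

    def test_invalid_dose_grid_rejected(self):
        with pytest.raises(DesignError):
            SimulationSpec(dose_grid1=(4.0, 2.0, 1.0))
        with pytest.raises(DesignError):
            SimulationSpec(dose_grid1=(0.0, 1.0))


class TestAdditiveMixture:
    def test_identical_agents_keep_their_median(self):
        fit = (12.0, 1.5)
        add = additive_mixture_fit(fit, fit, (3.0, 11.0))
        assert add.dm == pytest.approx(12.0, rel=1e-12)

    def test_harmonic_combination_hand_arithmetic(self):
        add = additive_mixture_fit((10.0, 2.0), (100.0, 2.0), (1.0, 1.0))
        assert add.dm == pytest.approx(2.0 / (0.1 + 0.01), rel=1e-12)  # ~18.18
        assert add.m == 2.0

    def test_additive_mixture_yields_unit_ci_everywhere(self):
        f1, f2 = MedianEffectFit(10.0, 2.0), MedianEffectFit(100.0, 2.0)
        add = additive_mixture_fit(f1, f2, (1.0, 1.0))
        design = ConstantRatioDesign(fit1=f1, fit2=f2, fit12=add, ratio=(1.0, 1.0))
        assert ci_profile(design).ci == pytest.approx(np.ones(11), abs=1e-9)

    def test_unequal_slopes_refuse_closed_form(self):
        with pytest.raises(DesignError, match="numeric"):
            additive_mixture_fit((10.0, 1.0), (100.0, 2.0), (1.0, 1.0))

    def test_numeric_additive_curve_satisfies_loewe_identity(self):
        # any slopes: the ratio-split components of D_add(fa) exhaust the isobole
        f1, f2 = MedianEffectFit(13.57, 1.38), MedianEffectFit(48.93, 0.88)
        for fa in (0.1, 0.5, 0.9):
            d = float(loewe_additive_total_dose(f1, f2, (1.0, 3.6), fa))
            d1, d2 = d * 1.0 / 4.6, d * 3.6 / 4.6
            assert d1 / f1.dose_at(fa) + d2 / f2.dose_at(fa) == pytest.approx(1.0, abs=1e-12)


class TestCombinationSimulation:
    def test_loewe_null_gives_unit_ci_downstream(self):
        spec = SimulationSpec(true_fit1=(10.0, 2.0), true_fit2=(100.0, 2.0),
                              ratio=(1.0, 1.0), interaction_kappa=1.0)
        fits = [fit_median_effect(simulate_single_agent(spec, w)) for w in (1, 2)]
        fit12 = fit_median_effect(simulate_combination(spec))
        design = ConstantRatioDesign(fit1=fits[0], fit2=fits[1], fit12=fit12,
                                     ratio=spec.ratio)
        assert ci_profile(design).ci == pytest.approx(np.ones(11), abs=1e-9)

    @pytest.mark.parametrize("kappa", [0.47, 0.5, 2.0])
    def test_planted_kappa_is_flat_ci_with_equal_slopes(self, kappa):
        spec = SimulationSpec(true_fit1=(15.0, 2.0), true_fit2=(90.0, 2.0),
                              ratio=(1.0, 7.3), interaction_kappa=kappa)
        fit12 = fit_median_effect(simulate_combination(spec))
        design = ConstantRatioDesign(
            fit1=MedianEffectFit(15.0, 2.0), fit2=MedianEffectFit(90.0, 2.0),
            fit12=fit12, ratio=spec.ratio)
        assert ci_profile(design).ci == pytest.approx(np.full(11, kappa), rel=1e-6)

    def test_unequal_slope_mixture_backbone_is_loewe_consistent(self):
        spec = SimulationSpec(true_fit1=(13.57, 1.38), true_fit2=(48.93, 0.88),
                              ratio=(1.0, 3.6), interaction_kappa=1.0)
        s = simulate_combination(spec)
        f1, f2 = MedianEffectFit(13.57, 1.38), MedianEffectFit(48.93, 0.88)
        for d, fa in zip(s.doses, s.effects):
            assert d == pytest.approx(float(loewe_additive_total_dose(f1, f2, spec.ratio, fa)),
                                      rel=1e-9)

    def test_explicit_mixture_fit_overrides_construction(self):
        spec = SimulationSpec(true_mixture=(28.28, 1.73))
        fit12 = fit_median_effect(simulate_combination(spec))
        assert fit12.dm == pytest.approx(28.28, rel=1e-6)
        assert fit12.m == pytest.approx(1.73, rel=1e-6)


class TestParameterRecoveryUnderNoise:
    def test_slope_recovery_rate_at_five_percent_noise(self):
        # frozen calibration: 5-dose ladder spanning dm/4..4dm, 2 replicates,
        # additive fa-noise sigma 0.05, steep slope m=1.835 -> the refitted
        # slope lands within 15% of truth in ~75% of runs (the boundary doses
        # carry most of the logit-scale noise); regression bound 70%
        truth_m = 1.835
        ok = 0
        n_runs = 500
        for seed in range(n_runs):
            spec = SimulationSpec(noise_scale=0.05, n_replicates=2, seed=seed)
            fit = fit_median_effect(simulate_single_agent(spec, 1))
            if abs(fit.m - truth_m) / truth_m <= 0.15:
                ok += 1
        assert ok / n_runs >= 0.70
        # the median fitted slope itself is close to truth
        ms = []
        for seed in range(100):
            spec = SimulationSpec(noise_scale=0.05, n_replicates=2, seed=seed)
            ms.append(fit_median_effect(simulate_single_agent(spec, 1)).m)
        assert np.median(ms) == pytest.approx(truth_m, rel=0.10)


class TestCtSimulation:
    def test_zero_target_matches_calibrator_delta_ct(self):
        df = simulate_ct_table({"d1": 0.0}, calibrator_condition="stimulated")
        wide = df.pivot_table(index=["sample", "condition"], columns="gene", values="ct")
        dct = (wide["IL1B"] - wide["ACTB"]).reset_index(drop=True)
        assert dct.nunique() == 1

    def test_fifty_percent_target_is_one_cycle(self):
        df = simulate_ct_table({"d1": 50.0})
        wide = df.pivot_table(index="condition", columns="gene", values="ct")
        ddct = (wide.loc["d1", "IL1B"] - wide.loc["d1", "ACTB"]) - (
            wide.loc["control", "IL1B"] - wide.loc["control", "ACTB"])
        assert ddct == pytest.approx(1.0, abs=1e-12)

    def test_round_trip_through_readout(self):
        targets = {"a": 20.0, "b": 50.0, "c": 90.0}
        df = simulate_ct_table(targets, n_replicates=2)
        out = reductions_from_ct_table(df, "ACTB", "control")
        got = out.groupby("condition")["pct_reduction"].mean()
        for cond, pct in targets.items():
            assert got[cond] == pytest.approx(pct, abs=1e-9)

    def test_saturating_target_rejected(self):
        with pytest.raises(DomainError):
            simulate_ct_table({"d": 100.0})

    def test_full_ct_dataset_recovers_planted_interaction(self):
        spec = SimulationSpec(true_fit1=(15.0, 2.0), true_fit2=(90.0, 2.0),
                              ratio=(1.0, 7.3), interaction_kappa=0.5,
                              n_replicates=2, noise_scale=0.0)
        ct, meta = simulate_ct_dataset(spec)
        per_sample = reductions_from_ct_table(ct, "ACTB", "stimulated")
        merged = per_sample.merge(meta.assign(
            sample=lambda d: d["condition"] + "_r" + d["replicate"].astype(str)),
            on=["sample", "condition"])
        fits = {}
        from synergyci import DoseEffectSeries
        for agent, sub in merged.groupby("agent"):
            fa = np.clip(sub["pct_reduction"] / 100.0, 0.0, 1.0)
            fits[agent] = fit_median_effect(
                DoseEffectSeries.from_arrays(agent, sub["dose"], fa))
        design = ConstantRatioDesign(
            fit1=fits[spec.agent1], fit2=fits[spec.agent2],
            fit12=fits[spec.mixture_label], ratio=spec.ratio)
        ci = combination_index_at_fa(design, 0.5).ci
        assert ci == pytest.approx(0.5, abs=0.05)
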