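import dataclasses

import numpy as np
import pytest

from nsclc_cea import (
    HazardRatio,
    HrDerivedEndpoint,
    LogLogisticParams,
    SurvivalCurve,
    ValidationError,
    apply_override,
    life_years,
    loglogistic_survival,
    n_cycles,
    run_cohort,
)
from nsclc_cea.engine import (
    discontinuation_prob,
    end_stage_death_prob,
    pd_exit_probs,
    pfs_exit_probs,
    resolve_curves,
)

STATE_COLS = ("pfs_on", "pfs_off", "pd", "end_stage", "death")


def tislelizumab(config):
    return config.strategy("tislelizumab")


class TestTransitionBuildingBlocks:
    def test_pfs_exit_split(self, config):
        os_c, pfs_c = resolve_curves(tislelizumab(config))
        p_death, p_prog = pfs_exit_probs(os_c, pfs_c, 1)
        assert p_death == pytest.approx(1 - 1 / 1.00927, rel=1e-9)
        assert p_prog == pytest.approx((1 - 1 / 1.09158) - (1 - 1 / 1.00927), rel=1e-9)
        assert p_death + p_prog <= 1

    def test_progression_clipped_when_pfs_equals_os(self, config):
        tis = tislelizumab(config)
        same = dataclasses.replace(tis, pfs=tis.os)
        os_c, pfs_c = resolve_curves(same)
        for t in (1, 10, 100):
            assert pfs_exit_probs(os_c, pfs_c, t)[1] == 0.0

    def test_discontinuation_probs_are_constant(self, config):
        assert discontinuation_prob(tislelizumab(config)) == 0.004499
        assert discontinuation_prob(config.strategy("docetaxel")) == 0.007759
        assert discontinuation_prob(config.strategy("nivolumab"), t=100) == 0.003408

    def test_pd_exit_probs(self, settings):
        p_death, p_to_end = pd_exit_probs(settings, 1)
        assert p_death == pytest.approx(1 - 1 / 1.01184, rel=1e-9)  # 0.011701
        assert p_to_end >= 0

    def test_end_stage_death_prob_modes(self, settings):
        anl_os = SurvivalCurve.loglogistic(settings.anlotinib.os)
        assert end_stage_death_prob(settings, 10) == pytest.approx(
            float(anl_os.transition_prob(10))
        )
        fixed = dataclasses.replace(
            settings, end_stage_mortality_mode="fixed", end_stage_fixed_prob=1.0
        )
        assert end_stage_death_prob(fixed, 10) == 1.0
        with pytest.raises(ValidationError, match="transient"):
            dataclasses.replace(
                settings, end_stage_mortality_mode="fixed", end_stage_fixed_prob=0.0
            )


@pytest.fixture(scope="module", params=["docetaxel", "tislelizumab", "nivolumab"])
def trace(config, request):
    return run_cohort(
        config.settings, config.strategy(request.param), config.strategies
    )


class TestCohortTrace:
    def test_starts_fully_on_therapy(self, trace):
        assert trace.pfs_on[0] == 1.0 and trace.death[0] == 0.0

    def test_mass_conserved_every_cycle(self, trace):
        assert np.abs(trace.row_sums() - 1.0).max() < 1e-9

    def test_death_monotone_nondecreasing(self, trace):
        assert np.all(np.diff(trace.death) >= -1e-15)

    def test_occupancies_are_fractions(self, trace):
        for col in STATE_COLS:
            occ = getattr(trace, col)
            assert np.all((occ >= -1e-15) & (occ <= 1 + 1e-12))

    def test_convolution_and_iterative_paths_agree(self, config):
        for name in ("tislelizumab", "nivolumab"):
            a = run_cohort(config.settings, config.strategy(name),
                           config.strategies, method="convolution")
            b = run_cohort(config.settings, config.strategy(name),
                           config.strategies, method="iterative")
            for col in STATE_COLS + ("pd_entries", "end_entries", "end_deaths"):
                np.testing.assert_allclose(
                    getattr(a, col), getattr(b, col), atol=1e-12, err_msg=col
                )


class TestStructuralLimits:
    def test_zero_discontinuation_never_populates_pfs_off(self, config):
        cfg = apply_override(config, "tislelizumab.discontinuation_prob", 0.0)
        trace = run_cohort(cfg.settings, cfg.strategy("tislelizumab"), cfg.strategies)
        assert np.all(trace.pfs_off == 0.0)

    def test_cumulative_death_telescopes_when_pfs_equals_os(self, config):
        """With the PFS curve set equal to OS, nobody progresses and the
        death column must reproduce 1 - S_OS(t) exactly at every cycle."""
        tis = tislelizumab(config)
        strat = dataclasses.replace(tis, pfs=tis.os)
        trace = run_cohort(config.settings, strat, config.strategies)
        t = np.arange(trace.n_cycles + 1)
        np.testing.assert_allclose(
            trace.death, 1 - loglogistic_survival(tis.os, t), atol=1e-9
        )
        assert np.all(trace.pd == 0)

    def test_near_certain_death_absorbs_cohort_immediately(self, config):
        tis = tislelizumab(config)
        lethal = LogLogisticParams(theta=1e9, kappa=1.0)
        strat = dataclasses.replace(tis, os=lethal, pfs=lethal)
        trace = run_cohort(config.settings, strat, config.strategies)
        assert trace.death[1] > 1 - 1e-6
        assert trace.death[-1] > 1 - 1e-6

    def test_negligible_hazards_keep_cohort_in_pfs(self, config):
        tis = tislelizumab(config)
        inert = LogLogisticParams(theta=1e-12, kappa=1.0)
        strat = dataclasses.replace(
            tis,
            os=inert,
            pfs=inert,
            discontinuation_prob_per_cycle=dataclasses.replace(
                tis.discontinuation_prob_per_cycle, mean=0.0, low=0.0
            ),
        )
        trace = run_cohort(config.settings, strat, config.strategies)
        assert trace.pfs_on[-1] > 1 - 1e-8

    def test_fixed_end_stage_prob_one_empties_in_one_cycle(self, config):
        settings = dataclasses.replace(
            config.settings,
            end_stage_mortality_mode="fixed",
            end_stage_fixed_prob=1.0,
        )
        trace = run_cohort(settings, tislelizumab(config), config.strategies)
        # occupancy each cycle is exactly that cycle's inflow
        np.testing.assert_allclose(trace.end_stage, trace.end_entries, atol=1e-12)


class TestClockModes:
    def test_model_time_clock_changes_the_trace(self, config):
        fast = run_cohort(config.settings, tislelizumab(config), config.strategies)
        settings_mt = dataclasses.replace(config.settings, pd_clock_mode="model_time")
        mt = run_cohort(settings_mt, tislelizumab(config), config.strategies)
        assert not np.allclose(fast.pd, mt.pd)
        assert np.abs(mt.row_sums() - 1.0).max() < 1e-9

    def test_convolution_requires_state_entry_clock(self, config):
        settings_mt = dataclasses.replace(config.settings, pd_clock_mode="model_time")
        with pytest.raises(ValidationError, match="state_entry"):
            run_cohort(settings_mt, tislelizumab(config), config.strategies,
                       method="convolution")


class TestLifeYears:
    def test_rectangular_trace(self, config):
        trace = run_cohort(config.settings, tislelizumab(config), config.strategies)
        k = 20
        rect = dataclasses.replace(
            trace,
            pfs_on=np.where(np.arange(trace.n_cycles + 1) < k, 1.0, 0.0),
            pfs_off=np.zeros(trace.n_cycles + 1),
            pd=np.zeros(trace.n_cycles + 1),
            end_stage=np.zeros(trace.n_cycles + 1),
        )
        assert life_years(rect, config.settings) == pytest.approx(k * 21 / 365.25)

    def test_higher_death_hazard_never_gains_life_years(self, config):
        tis = tislelizumab(config)
        base = run_cohort(config.settings, tis, config.strategies)
        worse = dataclasses.replace(
            tis,
            os=HrDerivedEndpoint(
                reference="tislelizumab", endpoint="os",
                hr=HazardRatio(mean=1.5, ci_low=1.5, ci_high=1.5),
            ),
            name="worse",
        )
        trace_w = run_cohort(config.settings, worse, config.strategies)
        assert life_years(trace_w, config.settings) <= life_years(base, config.settings)

    def test_half_cycle_correction_bounded_by_one_cycle(self, config):
        trace = run_cohort(config.settings, tislelizumab(config), config.strategies)
        on = life_years(trace, dataclasses.replace(config.settings,
                                                   half_cycle_correction=True))
        off = life_years(trace, config.settings)
        assert abs(on - off) <= 21 / 365.25


def test_hr_derived_strategy_requires_reference(config):
    niv = config.strategy("nivolumab")
    with pytest.raises(ValidationError, match="reference"):
        run_cohort(config.settings, niv, strategies=None)


def test_horizon_sets_trace_length(config):
    settings = dataclasses.replace(config.settings, horizon_years=1)
    trace = run_cohort(settings, tislelizumab(config), config.strategies)
    assert trace.n_cycles == n_cycles(settings) == 17
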