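import numpy as np
import pandas as pd
import pytest

from swanstage import (ArrivalSchedule, ModelParams, Patch, ValidationError,
                       WaterLevelSeries, generate_arrivals, run_simulation,
                       summarize_replicates)
from swanstage.engine import ARRIVAL_HOUR, SimulationState, derive_seed


def flat_levels(days, level=-0.93, start="2005-10-01"):
    return WaterLevelSeries(start=pd.Timestamp(start),
                            levels=np.full(days * 24, level))


def sandy_patch(density, area=2.5e6):
    return Patch("A", "sand", "shallow", area_m2=area, tuber_density_g_m2=density)


def small_schedule(total=200, peak1="2005-10-03"):
    return ArrivalSchedule(peak1_date=peak1, total_swans=total)


class TestArrivals:
    def test_two_one_split(self):
        sched = ArrivalSchedule(peak1_date="2005-10-19", total_swans=3000)
        assert sched.n_super_individuals == 150
        assert sched.n_peak1 == 100
        arrivals = generate_arrivals(sched, "2005-10-01", 61 * 24,
                                     np.random.default_rng(0))
        assert len(arrivals) == 150
        assert sum(1 for _, pk in arrivals if pk == 1) == 100

    def test_divisibility_enforced(self):
        with pytest.raises(ValidationError):
            ArrivalSchedule(peak1_date="2005-10-19", total_swans=3010)

    def test_degenerate_sd_hits_peaks_exactly(self):
        sched = ArrivalSchedule(peak1_date="2005-10-19", total_swans=600, sd_days=0.0)
        arrivals = generate_arrivals(sched, "2005-10-01", 61 * 24,
                                     np.random.default_rng(0))
        steps = {step for step, _ in arrivals}
        assert steps == {18 * 24 + ARRIVAL_HOUR, 32 * 24 + ARRIVAL_HOUR}

    def test_seed_reproducibility(self):
        sched = small_schedule()
        a1 = generate_arrivals(sched, "2005-10-01", 61 * 24, np.random.default_rng(42))
        a2 = generate_arrivals(sched, "2005-10-01", 61 * 24, np.random.default_rng(42))
        assert a1 == a2


class TestRun:
    def test_no_swans_leaves_world_untouched(self):
        res = run_simulation(ModelParams(), [sandy_patch(13.2)], flat_levels(10),
                             ArrivalSchedule(peak1_date="2005-10-03", total_swans=0),
                             seed=1)
        assert res.bird_days == 0 and res.peak_number == 0
        assert res.final_densities.iloc[0] == 13.2

    def test_foodless_lake_expels_every_arrival(self):
        res = run_simulation(ModelParams(), [sandy_patch(0.0)], flat_levels(10),
                             small_schedule(), seed=1)
        arrived = res.individuals[res.individuals["arrival_step"].notna()]
        assert (arrived["reason"] == "emigrated_to_fields").all()
        assert (arrived["duration_days"] == 0).all()
        assert res.bird_days == 0

    def test_abundant_food_matches_refuel_time_prediction(self):
        p = ModelParams()
        res = run_simulation(p, [sandy_patch(1e6, area=1e8)], flat_levels(10),
                             ArrivalSchedule(peak1_date="2005-10-02",
                                             total_swans=20, sd_days=0.0), seed=1)
        ind = res.individuals.iloc[0]
        assert ind["reason"] == "target_reached"
        # closed-form refuelling time at the saturated intake rate
        sat = p.f * p.b * p.phi_sand / p.h
        net = p.q * p.e * sat - (p.f * p.c_f_sandy_shallow
                                 + (1 - p.f) * (p.c_r + p.c_p) / 2)
        predicted_days = (p.target_store_J - p.initial_store_J) / (net * 86400)
        assert abs(ind["duration_days"] - predicted_days) < 1.0

    def test_mass_balance(self, params, patches_2005, lake_2005):
        res = run_simulation(params, patches_2005, lake_2005,
                             small_schedule(total=3000, peak1="2005-10-19"), seed=3)
        init = np.array([p.tuber_density_g_m2 for p in patches_2005])
        areas = np.array([p.area_m2 for p in patches_2005])
        removed = float(((init - res.final_densities.to_numpy()) * areas).sum())
        assert removed == pytest.approx(res.total_ingested_g, rel=1e-6)
        assert np.all(res.final_densities.to_numpy() <= init + 1e-12)

    def test_departure_reasons_account_for_everyone(self, params, patches_2005,
                                                    lake_2005, schedule_2005):
        res = run_simulation(params, patches_2005, lake_2005, schedule_2005, seed=5)
        assert res.individuals["reason"].notna().all()
        arrived = res.individuals["arrival_step"].notna()
        assert (res.individuals.loc[~arrived, "reason"] == "never_arrived").all()
        assert len(res.individuals) == schedule_2005.n_super_individuals

    def test_bird_days_equals_count_sum_and_peak_is_max(self, params, patches_2005,
                                                        lake_2005, schedule_2005):
        res = run_simulation(params, patches_2005, lake_2005, schedule_2005, seed=5)
        assert res.bird_days == res.daily_counts.sum()
        assert res.peak_number == res.daily_counts.max()

    def test_same_seed_is_bit_identical(self, params, patches_2005, lake_2005,
                                        schedule_2005):
        r1 = run_simulation(params, patches_2005, lake_2005, schedule_2005, seed=11)
        r2 = run_simulation(params, patches_2005, lake_2005, schedule_2005, seed=11)
        pd.testing.assert_series_equal(r1.daily_counts, r2.daily_counts)
        pd.testing.assert_series_equal(r1.final_densities, r2.final_densities)
        pd.testing.assert_frame_equal(r1.individuals, r2.individuals)
        assert r1.total_ingested_g == r2.total_ingested_g

    def test_short_level_series_rejected(self, params):
        with pytest.raises(ValidationError):
            run_simulation(params, [sandy_patch(10.0)],
                           WaterLevelSeries(start="2005-10-01", levels=[-0.93] * 3),
                           small_schedule(), seed=1)


class TestEmergentResponses:
    def test_higher_emigration_threshold_cannot_raise_bird_days(self, patches_2005,
                                                                lake_2005):
        sched = small_schedule(total=1000, peak1="2005-10-19")
        base = ModelParams()
        greedy = base.replace(p=0.9)  # beet fields more attractive
        bd_base = run_simulation(base, patches_2005, lake_2005, sched, seed=7).bird_days
        bd_greedy = run_simulation(greedy, patches_2005, lake_2005, sched,
                                   seed=7).bird_days
        assert bd_greedy <= bd_base

    def test_doubling_patch_area_cannot_reduce_bird_days(self, params, lake_2005):
        sched = small_schedule(total=2000, peak1="2005-10-19")
        small = [sandy_patch(13.2, area=1.0e6)]
        big = [sandy_patch(13.2, area=2.0e6)]
        bd_small = run_simulation(params, small, lake_2005, sched, seed=7).bird_days
        bd_big = run_simulation(params, big, lake_2005, sched, seed=7).bird_days
        assert bd_big >= bd_small


class TestExpectedGain:
    def _state(self, params, n_patches=2):
        patches = [sandy_patch(13.2) for _ in range(n_patches)]
        levels = flat_levels(2)
        return SimulationState(params, patches, levels, arrivals=[],
                               rng=np.random.default_rng(0))

    def test_candidate_counts_itself(self, params):
        state = self._state(params)
        from swanstage.params import SuperIndividual
        si = SuperIndividual(id=0, arrival_step=0, store_J=params.initial_store_J)
        gains = state._net_gains(si, state.occupancy(), [0.33, 0.33])
        from swanstage import gain_rate
        expected = gain_rate(13.2, "sand", "shallow", 0.33,
                             20 / 2.5e6, params).net_J_s
        assert gains[0] == pytest.approx(expected)

    def test_crowded_patch_is_less_attractive(self, params):
        state = self._state(params)
        from swanstage.params import SuperIndividual
        for k in range(10):
            crowd = SuperIndividual(id=100 + k, arrival_step=0, location=1,
                                    store_J=params.initial_store_J)
            state.present.append(crowd)
        si = SuperIndividual(id=0, arrival_step=0, store_J=params.initial_store_J)
        gains = state._net_gains(si, state.occupancy(), [0.33, 0.33])
        assert gains[1] < gains[0]


class TestSummaries:
    def test_replicate_sd_uses_sample_convention(self, params, patches_2005,
                                                 lake_2005):
        sched = small_schedule(total=600, peak1="2005-10-19")
        runs = [run_simulation(params, patches_2005, lake_2005, sched,
                               seed=derive_seed(1, 0, r)) for r in range(4)]
        s = summarize_replicates(runs)
        bdays = [r.bird_days for r in runs]
        assert s.bird_days_mean == pytest.approx(np.mean(bdays))
        assert s.bird_days_sd == pytest.approx(np.std(bdays, ddof=1))
        identical = summarize_replicates([runs[0], runs[0]])
        assert identical.bird_days_sd == 0.0

    def test_two_replicate_sd_arithmetic(self, params, patches_2005, lake_2005):
        sched = small_schedule(total=600, peak1="2005-10-19")
        runs = [run_simulation(params, patches_2005, lake_2005, sched,
                               seed=derive_seed(2, 0, r)) for r in range(2)]
        s = summarize_replicates(runs)
        b0, b1 = runs[0].bird_days, runs[1].bird_days
        assert s.bird_days_sd == pytest.approx(abs(b1 - b0) / np.sqrt(2))
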