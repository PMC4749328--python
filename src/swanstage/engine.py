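"""Hourly time-stepped individual-based stopover simulation.

Super-individuals (flocks of 20 swans) arrive in two peaks, choose patches by
net-gain-rate maximization with perfect knowledge, deplete tubers, accumulate
energy stores, and leave either when their store reaches the target or when
the best obtainable gain rate drops below the emigration threshold set by the
surrounding beet fields.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import energetics
from .params import (ModelParams, Patch, SuperIndividual, ValidationError,
                     WaterLevelSeries)
from .hydrology import actual_depth

#: Hour of day at which newly arrived flocks enter the lake.
ARRIVAL_HOUR = 6
#: Hour of day of the daily census (daytime telescope counts).
CENSUS_HOUR = 12
#: Mean distance (m) between inlets, used as the flight distance whenever a
#: move crosses inlets; within-inlet moves are treated as distance 0.
INTER_INLET_DISTANCE_M = 3317.0


@dataclass(frozen=True)
class ArrivalSchedule:
    """Two-peaked arrival schedule (non-breeders then breeders).

    The second peak follows the first by 14 days and holds half as many
    birds; arrival dates are normally distributed around each peak with a
    3-day standard deviation.
    """

    peak1_date: pd.Timestamp
    total_swans: int
    sd_days: float = 3.0
    peak_separation_days: int = 14
    super_individual_size: int = 20

    def __post_init__(self) -> None:
        object.__setattr__(self, "peak1_date", pd.Timestamp(self.peak1_date))
        if self.total_swans % self.super_individual_size != 0:
            raise ValidationError(
                f"total_swans ({self.total_swans}) must be divisible by "
                f"{self.super_individual_size}")
        if self.sd_days < 0:
            raise ValidationError("sd_days must be >= 0")

    @property
    def peak2_date(self) -> pd.Timestamp:
        return self.peak1_date + pd.Timedelta(days=self.peak_separation_days)

    @property
    def n_super_individuals(self) -> int:
        return self.total_swans // self.super_individual_size

    @property
    def n_peak1(self) -> int:
        """Two thirds of the flocks belong to the first (larger) peak."""
        return round(2 / 3 * self.n_super_individuals)


def generate_arrivals(schedule: ArrivalSchedule, window_start: pd.Timestamp,
                      window_hours: int,
                      rng: np.random.Generator) -> list[tuple[Optional[int], int]]:
    """Draw per-flock arrival steps (hour index) and peak membership.

    Arrival dates are drawn Normal(peak, sd_days), rounded to whole days, and
    clipped to the start of the simulation window; flocks whose date falls
    after the window never arrive (step ``None``).  Arrival hour of day is
    fixed at :data:`ARRIVAL_HOUR` so arrivals are on the lake at census time.
    """
    window_start = pd.Timestamp(window_start)
    n1 = schedule.n_peak1
    n2 = schedule.n_super_individuals - n1
    out: list[tuple[Optional[int], int]] = []
    n_days = window_hours // 24
    for peak_no, peak_date, n in ((1, schedule.peak1_date, n1),
                                  (2, schedule.peak2_date, n2)):
        peak_day = (peak_date - window_start) / pd.Timedelta(days=1)
        offsets = np.rint(rng.normal(peak_day, schedule.sd_days, size=n)).astype(int)
        for day in offsets:
            day = max(day, 0)
            if day >= n_days:
                out.append((None, peak_no))
            else:
                out.append((int(day) * 24 + ARRIVAL_HOUR, peak_no))
    return out


@dataclass
class SimulationResult:
    """Outputs of one replicate run."""

    daily_counts: pd.Series          # swans present at the census hour, per day
    final_densities: pd.Series       # g m^-2 per patch (index: patch label)
    individuals: pd.DataFrame        # one row per super-individual
    total_ingested_g: float
    seed: Optional[int] = None

    @property
    def bird_days(self) -> float:
        return float(self.daily_counts.sum())

    @property
    def peak_number(self) -> float:
        return float(self.daily_counts.max()) if len(self.daily_counts) else 0.0


class SimulationState:
    """Mutable state advanced one hour at a time by :func:`step`."""

    def __init__(self, params: ModelParams, patches: Sequence[Patch],
                 levels: WaterLevelSeries,
                 arrivals: Sequence[tuple[Optional[int], int]],
                 rng: np.random.Generator,
                 census_hour: int = CENSUS_HOUR):
        self.params = params
        self.patches = [copy.deepcopy(p) for p in patches]
        self.levels = levels
        self.rng = rng
        self.census_hour = census_hour
        self.t = 0
        self.threshold = energetics.emigration_threshold(params)
        self.total_ingested_g = 0.0
        size = params.super_individual_size
        self.individuals = [
            SuperIndividual(id=i, n_swans=size, arrival_step=step,
                            arrival_peak=peak, store_J=params.initial_store_J,
                            departure_reason=None if step is not None else "never_arrived")
            for i, (step, peak) in enumerate(arrivals)]
        self.present: list[SuperIndividual] = []
        self._pending = sorted(
            (si for si in self.individuals if si.arrival_step is not None),
            key=lambda si: si.arrival_step)
        self._pending_i = 0
        # static per-patch quantities
        self._cost = [energetics.cost_rate(p.sediment, p.depth_class, self.params)
                      for p in self.patches]
        self._inlet = [p.inlet_id for p in self.patches]
        self.daily_records: list[int] = []
        self.flew_this_step: set[int] = set()

    # -- helpers ------------------------------------------------------------

    def occupancy(self) -> list[int]:
        occ = [0] * len(self.patches)
        for si in self.present:
            if si.location is not None:
                occ[si.location] += 1
        return occ

    def _net_gains(self, si: SuperIndividual, occ: list[int],
                   depths: list[float]) -> list[float]:
        """Expected net gain per patch with the candidate's own flock included
        in the patch density; far patches are charged the flight cost
        amortized over the hour."""
        p = self.params
        size = p.super_individual_size
        cur = si.location
        cur_inlet = self._inlet[cur] if cur is not None else None
        gains = []
        for j, patch in enumerate(self.patches):
            n_si = occ[j] + (1 if j != cur else 0)
            N = size * n_si / patch.area_m2
            g = energetics.gain_rate(patch.tuber_density_g_m2, patch.sediment,
                                     patch.depth_class, depths[j], N, p)
            net = g.net_J_s
            if cur is not None and j != cur and self._inlet[j] != cur_inlet:
                cost, _ = energetics.flight_cost_and_time(INTER_INLET_DISTANCE_M, p)
                net -= cost / p.timestep_s
            gains.append(net)
        return gains

    def _depart(self, si: SuperIndividual, reason: str) -> None:
        si.departure_step = self.t
        si.departure_reason = reason
        si.location = None
        self.present.remove(si)

    # -- one hour -----------------------------------------------------------

    def step(self) -> None:
        if self.t >= len(self.levels):
            raise ValidationError("level series exhausted")
        p = self.params
        lake = self.levels.levels[self.t]
        depths = [actual_depth(patch, lake, p.target_level_m) for patch in self.patches]

        # admit this hour's arrivals
        while (self._pending_i < len(self._pending)
               and self._pending[self._pending_i].arrival_step == self.t):
            si = self._pending[self._pending_i]
            self.present.append(si)
            self._pending_i += 1

        # decision phase, randomized order, occupancy updated between movers
        self.flew_this_step = set()
        deciders = list(self.present)
        self.rng.shuffle(deciders)
        occ = self.occupancy()
        for si in deciders:
            if si.store_J >= p.target_store_J:
                occ_idx = si.location
                self._depart(si, "target_reached")
                if occ_idx is not None:
                    occ[occ_idx] -= 1
                continue
            gains = self._net_gains(si, occ, depths)
            best = max(gains)
            if best < self.threshold:
                occ_idx = si.location
                self._depart(si, "emigrated_to_fields")
                if occ_idx is not None:
                    occ[occ_idx] -= 1
                continue
            cur = si.location
            if cur is not None and gains[cur] >= best:
                continue  # staying ties or beats moving
            dest = gains.index(best)  # lowest index among maxima
            if cur is not None:
                occ[cur] -= 1
                if self._inlet[dest] != self._inlet[cur]:
                    _, steps = energetics.flight_cost_and_time(
                        INTER_INLET_DISTANCE_M, p)
                    if steps > 0:
                        self.flew_this_step.add(si.id)
            si.location = dest
            occ[dest] += 1

        # foraging, depletion, store dynamics
        size = p.super_individual_size
        by_patch: dict[int, list[SuperIndividual]] = {}
        for si in self.present:
            if si.id in self.flew_this_step:
                si.store_J -= p.flight_cost_J  # flight hour: no foraging
            elif si.location is not None:
                by_patch.setdefault(si.location, []).append(si)
        for j, flocks in by_patch.items():
            patch = self.patches[j]
            n_swans = size * len(flocks)
            N = n_swans / patch.area_m2
            I = energetics.intake_rate(patch.tuber_density_g_m2, patch.sediment,
                                       depths[j], N, p)
            want_g = I * p.timestep_s * n_swans
            avail_g = patch.tuber_density_g_m2 * patch.area_m2
            taken_g = min(want_g, avail_g)  # cannot eat more than is there
            grams_per_swan = taken_g / n_swans
            patch.tuber_density_g_m2 -= taken_g / patch.area_m2
            self.total_ingested_g += taken_g
            delta = p.q * p.e * grams_per_swan - self._cost[j] * p.timestep_s
            for si in flocks:
                si.store_J += delta
        for si in list(self.present):
            if si.store_J <= 0.0:
                si.store_J = 0.0
                self._depart(si, "emigrated_to_fields")  # forced by starvation
            elif si.store_J >= p.target_store_J:
                self._depart(si, "target_reached")

        if self.t % 24 == self.census_hour:
            self.daily_records.append(size * len(self.present))
        self.t += 1


def run_simulation(params: ModelParams, patches: Sequence[Patch],
                   levels: WaterLevelSeries, schedule: ArrivalSchedule,
                   seed: int, census_hour: int = CENSUS_HOUR) -> SimulationResult:
    """Run one replicate over the full level-series window."""
    n_hours = len(levels)
    if n_hours < 24:
        raise ValidationError("level series must cover at least one day")
    rng = np.random.default_rng(seed)
    arrivals = generate_arrivals(schedule, levels.start, n_hours, rng)
    state = SimulationState(params, patches, levels, arrivals, rng,
                            census_hour=census_hour)
    for _ in range(n_hours):
        state.step()

    dates = pd.date_range(levels.start.normalize(), periods=len(state.daily_records),
                          freq="D")
    daily = pd.Series(state.daily_records, index=dates, name="count")
    labels = [f"{p.inlet_id}:{p.patch_type}" for p in state.patches]
    final = pd.Series([p.tuber_density_g_m2 for p in state.patches], index=labels,
                      name="tuber_density_g_m2")
    rows = []
    for si in state.individuals:
        if si.arrival_step is not None and si.departure_step is None:
            # still on the lake when the window closed
            si.departure_step = state.t - 1
            si.departure_reason = "season_end"
        duration = (np.nan if si.arrival_step is None
                    else (si.departure_step - si.arrival_step) / 24.0)
        rows.append({"id": si.id, "peak": si.arrival_peak,
                     "arrival_step": si.arrival_step,
                     "departure_step": si.departure_step,
                     "reason": si.departure_reason,
                     "duration_days": duration,
                     "final_store_pct": 100.0 * si.store_J / params.target_store_J})
    individuals = pd.DataFrame(rows)
    return SimulationResult(daily_counts=daily, final_densities=final,
                            individuals=individuals,
                            total_ingested_g=state.total_ingested_g, seed=seed)


@dataclass
class ReplicateSummary:
    n: int
    peak_mean: float
    peak_sd: float
    bird_days_mean: float
    bird_days_sd: float
    duration_by_peak: pd.DataFrame   # rows: peak 1/2; mean, sd of staging days
    store_pct_by_peak: pd.DataFrame  # rows: peak 1/2; mean, sd of % target store


def summarize_replicates(results: Sequence[SimulationResult]) -> ReplicateSummary:
    """Means and sample SDs (n-1 denominator) across replicate runs."""
    if len(results) < 2:
        raise ValidationError("need at least 2 replicates to summarize")
    peaks = np.array([r.peak_number for r in results])
    bdays = np.array([r.bird_days for r in results])

    def by_peak(col: str) -> pd.DataFrame:
        per_rep = []
        for r in results:
            arrived = r.individuals[r.individuals["arrival_step"].notna()]
            per_rep.append(arrived.groupby("peak")[col].mean())
        df = pd.DataFrame(per_rep)
        return pd.DataFrame({"mean": df.mean(axis=0), "sd": df.std(axis=0, ddof=1)})

    return ReplicateSummary(
        n=len(results),
        peak_mean=float(peaks.mean()), peak_sd=float(peaks.std(ddof=1)),
        bird_days_mean=float(bdays.mean()), bird_days_sd=float(bdays.std(ddof=1)),
        duration_by_peak=by_peak("duration_days"),
        store_pct_by_peak=by_peak("final_store_pct"))


def derive_seed(base_seed: int, *streams: int) -> int:
    """Deterministic child seed below 2^31 for replicate/scenario isolation."""
    mask = (1 << 64) - 1
    x = (int(base_seed) * 2654435761) & mask
    for s in streams:
        x = ((x ^ (int(s) + 1)) * 2246822519) & mask
    return x % (2 ** 31)
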