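"""Foraging energetics: accessibility, interference, intake, net gain,
and the emigration threshold.

All functions are pure and operate on scalars, so the simulation engine and
any audit script can call them directly.  Tuber intake follows a type II
functional response, scaled by the proportion of accessible (reachable)
tubers at the current water depth, by interference competition between
swans, and by the swans' time budget.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .params import ARRIVAL_MASS_G, TARGET_MASS_G, ModelParams


@dataclass(frozen=True)
class GainComponents:
    """Breakdown of the net gain rate on a patch (per swan)."""

    intake_g_s: float         # tuber intake rate I
    metabolizable_J_s: float  # q * e * I
    cost_J_s: float           # f*c_f + (1-f)*(c_r+c_p)/2
    net_J_s: float            # metabolizable - cost


def accessible_fraction(d: float, sediment: str, params: ModelParams) -> float:
    """Fraction of buried tubers reachable at water depth ``d`` (m).

    Below the head-dipping limit everything is reachable; beyond the maximum
    up-ending reach nothing is.  In between, the reachable fraction falls off
    quadratically with depth through a sediment-specific burial-depth shape
    factor, clamped to at most 1.  Water shallower than the minimum foraging
    depth makes the patch unusable (fraction 0) rather than removing it from
    the model, because levels fluctuate hourly.
    """
    if d < params.depth_min or d > params.depth_reach_max:
        return 0.0
    if d <= params.depth_headdip_max:
        return 1.0
    beta = params.beta_sand if sediment == "sand" else params.beta_clay
    return min(1.0, beta * ((params.depth_reach_max - d) * 100.0) ** 2)


#: Quartic fitted to relative intake against swan density (swans per m^2).
_INTERFERENCE_COEFFS = (-530344.0, 60100.0, -1976.3, -0.7284, 1.0)


def interference_factor(N: float) -> float:
    """Relative intake rate at swan density ``N`` (swans m^-2), in [0, 1].

    A fitted quartic polynomial; values are clamped to [0, 1] because the
    polynomial diverges outside the density range it was fitted on.
    """
    if N < 0:
        raise ValueError(f"swan density must be >= 0, got {N}")
    c4, c3, c2, c1, c0 = _INTERFERENCE_COEFFS
    raw = (((c4 * N + c3) * N + c2) * N + c1) * N + c0
    return min(1.0, max(0.0, raw))


def intake_rate(D: float, sediment: str, d: float, N: float,
                params: ModelParams) -> float:
    """Tuber intake rate I (g s^-1) per swan.

    Type II functional response on the accessible tuber density A(d)*D, with
    the attack rate and time underwater depending on sediment, scaled by the
    foraging time budget f, the area-restricted-search benefit b, and the
    interference factor i(N).
    """
    if D < 0:
        raise ValueError(f"tuber density must be >= 0, got {D}")
    A = accessible_fraction(d, sediment, params)
    if A == 0.0 or D == 0.0:
        return 0.0
    if sediment == "sand":
        a, phi = params.a_sand, params.phi_sand
    else:
        a, phi = params.a_clay, params.phi_clay
    avail = a * A * D
    return params.f * params.b * interference_factor(N) * phi * avail / (
        1.0 + avail * params.h)


def nonforaging_cost(params: ModelParams) -> float:
    """Mean of resting and preening costs (J s^-1), the non-foraging budget."""
    return (params.c_r + params.c_p) / 2.0


def cost_rate(sediment: str, depth_class: str, params: ModelParams) -> float:
    """Time-budget-weighted metabolic rate on a patch type (J s^-1)."""
    return params.f * params.foraging_cost(sediment, depth_class) + \
        (1.0 - params.f) * nonforaging_cost(params)


def gain_rate(D: float, sediment: str, depth_class: str, d: float, N: float,
              params: ModelParams) -> GainComponents:
    """Net energy gain rate G_t (J s^-1) per swan, with components."""
    I = intake_rate(D, sediment, d, N, params)
    metab = params.q * params.e * I
    cost = cost_rate(sediment, depth_class, params)
    return GainComponents(intake_g_s=I, metabolizable_J_s=metab,
                          cost_J_s=cost, net_J_s=metab - cost)


def emigration_threshold(params: ModelParams) -> float:
    """Gain rate (J s^-1) below which swans leave for the beet fields.

    The alternative habitat offers a daily surplus MEI_b - DEE_b, discounted
    by the fraction p that reflects its perceived higher predation risk.
    """
    if params.MEI_b < params.DEE_b:
        warnings.warn("MEI_b < DEE_b: emigration threshold is negative",
                      stacklevel=2)
    return params.p * (params.MEI_b - params.DEE_b) / 86400.0


def flight_cost_and_time(distance_m: float, params: ModelParams) -> tuple[float, int]:
    """(energy J, timesteps) to move a given distance between patches.

    Moves below the travel threshold (within-inlet) are free and instant;
    longer moves cost one fixed mean between-inlet flight and one time step
    (including settling).  The cost is not distance-proportional.
    """
    if distance_m < 0:
        raise ValueError(f"distance must be >= 0, got {distance_m}")
    if distance_m <= params.travel_threshold_m:
        return 0.0, 0
    return params.flight_cost_J, 1


def energy_store_from_mass(mass_g: float, params: ModelParams) -> float:
    """Energy store (J) of a swan of given body mass: fat above lean mass."""
    return (mass_g - params.lean_mass_g) * params.store_energy_density_J_per_g


def arrival_store_J(params: ModelParams) -> float:
    """Store implied by the arrival body condition (abdominal profile 2)."""
    return energy_store_from_mass(ARRIVAL_MASS_G, params)


def target_store_from_condition(params: ModelParams) -> float:
    """Store implied by the departure body condition (abdominal profile 5)."""
    return energy_store_from_mass(TARGET_MASS_G, params)
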