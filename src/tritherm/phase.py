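"""Sweep drivers: phase diagrams over (T, K) and thermal-mismatch sweeps.

Community structure at any point of the environment plane follows
deterministically from the threshold curves:

====================  =================================
productivity           community
====================  =================================
K < K_C                R (resource only)
K_C ≤ K < K_A          CR (consumer–resource)
K_A ≤ K < K_P          PCR/CR (alternative stable states)
K ≥ K_P                PCR (trophic chain)
====================  =================================

with the predator columns collapsing to CR whenever the predator
thresholds do not exist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import isfinite
from typing import Callable, Literal

import numpy as np

from .equilibrium import (
    EquilibriumState,
    K_MAX_DEFAULT,
    ThresholdCurve,
    Thresholds,
    cr_equilibrium,
    pcr_state_at_K,
    thresholds,
)
from .params import ConfigurationError, ModelParameters
from .scenarios import ScenarioSpec, scenario_parameterization

logger = logging.getLogger(__name__)

REGION_TAGS = ("R", "CR", "PCR/CR", "PCR")


@dataclass
class PhaseDiagram:
    """Classified community structure over an environment × productivity grid."""

    scenario_id: int
    axis: str
    axis_grid: np.ndarray
    k_grid: np.ndarray
    region: np.ndarray  # shape (len(k_grid), len(axis_grid)), dtype object
    thresholds: ThresholdCurve


def classify(
    K: float,
    T: float,
    params: ModelParameters,
    scenario: ScenarioSpec,
    tsr_reference: str = "fixed",
    with_states: bool = False,
):
    """Community tag at one (K, T) point, optionally with the equilibria.

    In the bistable band both coexisting states are returned: the CR
    attractor and the stable trophic-chain state from the PCR branch.
    """
    th = thresholds(T, params, scenario, tsr_reference)
    tag = classify_from_thresholds(K, th)
    if not with_states:
        return tag
    states: list[EquilibriumState] = []
    if tag in ("CR", "PCR/CR"):
        states.append(cr_equilibrium(K, T, params, scenario, tsr_reference))
    if tag in ("PCR", "PCR/CR"):
        pcr = pcr_state_at_K(K, T, params, scenario, tsr_reference)
        if pcr is not None:
            states.append(pcr)
    if tag == "R":
        states.append(EquilibriumState(community="R", R_tilde=K))
    return tag, states


def classify_from_thresholds(K: float, th: Thresholds) -> str:
    """Deterministic region tag from a threshold triple."""
    if K < th.K_C:
        return "R"
    if not isfinite(th.K_P):
        return "CR"
    if K >= th.K_P:
        return "PCR"
    if K >= th.K_A:
        return "PCR/CR"
    return "CR"


def temperature_sweep(
    scenario_id: int,
    t_grid: np.ndarray | None = None,
    params: ModelParameters | None = None,
    tsr_reference: str = "fixed",
) -> ThresholdCurve:
    """Threshold curves K_C(T), K_P(T), K_A(T) for one scenario."""
    params = params or ModelParameters()
    scenario = scenario_parameterization(scenario_id)
    if t_grid is None:
        t_grid = np.arange(5.0, 25.0 + 1e-9, 0.25)
    curve = ThresholdCurve(axis="T")
    for T in t_grid:
        th = thresholds(float(T), params, scenario, tsr_reference)
        curve.append(float(T), th.K_C, th.K_P, th.K_A)
    return curve


def phase_diagram(
    scenario_id: int,
    t_grid: np.ndarray | None = None,
    k_grid: np.ndarray | None = None,
    params: ModelParameters | None = None,
    tsr_reference: str = "fixed",
) -> PhaseDiagram:
    """Figure-2-style phase diagram over the (T, K) plane."""
    params = params or ModelParameters()
    if t_grid is None:
        t_grid = np.arange(5.0, 25.0 + 1e-9, 0.25)
    if k_grid is None:
        k_grid = np.logspace(-5, -2, 60)
    curve = temperature_sweep(scenario_id, t_grid, params, tsr_reference)
    region = np.empty((len(k_grid), len(t_grid)), dtype=object)
    for j, (_, k_c, k_p, k_a) in enumerate(curve.values):
        th = Thresholds(k_c, k_p, k_a)
        for i, K in enumerate(k_grid):
            region[i, j] = classify_from_thresholds(float(K), th)
    return PhaseDiagram(
        scenario_id=scenario_id,
        axis="T",
        axis_grid=np.asarray(t_grid, dtype=float),
        k_grid=np.asarray(k_grid, dtype=float),
        region=region,
        thresholds=curve,
    )


# ---------------------------------------------------------------------------
# thermal-niche mismatch sweeps (scenarios 11 and 12)


@dataclass
class MismatchSweep:
    """Result of a thermal-niche-mismatch sweep at fixed temperature.

    ``persistence_window`` bounds the shift interval within which the
    trophic chain can persist at some productivity K ≤ k_max (None when
    the predator persists nowhere).  For predator sweeps,
    ``analytic_existence_shift`` is the exact shift at which the
    environmental temperature meets the predator's shifted upper thermal
    limit (the functional response vanishes below it).
    ``coincidence_shift`` reports the smallest shift at which K_P and K_C
    coincide within ``coincidence_rtol`` (None when the two thresholds
    never meet, which is the generic outcome: the invasion threshold
    exceeds K_C by Cv*·θ_I/(ρ·θ_v) > 0).
    """

    species: str
    T_env: float
    curve: ThresholdCurve
    k_max: float
    persistence_window: tuple[float, float] | None = None
    analytic_existence_shift: float | None = None
    coincidence_shift: float | None = None
    coincidence_rtol: float = 1e-3


def _sweep_scenario(species: str, delta: float) -> ScenarioSpec:
    if species == "consumer":
        return scenario_parameterization(11, consumer_shift=delta)
    if species == "predator":
        return scenario_parameterization(12, predator_shift=delta)
    raise ConfigurationError(f"species must be 'consumer' or 'predator', got {species!r}")


def mismatch_sweep(
    T_env: float,
    species: Literal["consumer", "predator"],
    delta_grid: np.ndarray | None = None,
    params: ModelParameters | None = None,
    k_max: float = K_MAX_DEFAULT,
    refine: float = 0.01,
    tsr_reference: str = "fixed",
    coincidence_rtol: float = 1e-3,
) -> MismatchSweep:
    """Sweep the thermal-niche shift ΔTPC of one species at fixed T_env.

    For each shift Δ the full threshold triple is computed with the
    scenario-10 temperature machinery active and the focal species' niche
    displaced by Δ.  Persistence-window boundaries (smallest/largest Δ at
    which the trophic chain exists for some K ≤ k_max) are refined by
    bisection to ``refine`` °C.

    Parameters
    ----------
    T_env : float
        Environmental temperature (°C).
    species : {"consumer", "predator"}
        Which species' niche is shifted (scenario 11 or 12).
    delta_grid : array, optional
        Shift grid (°C); defaults to ±16 °C at 0.1 °C resolution.
    k_max : float
        Productivity ceiling for declaring a threshold non-existent.
    refine : float
        Bisection resolution for boundary shifts (°C).
    """
    params = params or ModelParameters()
    if delta_grid is None:
        delta_grid = np.arange(-16.0, 16.0 + 1e-9, 0.1)
    delta_grid = np.asarray(delta_grid, dtype=float)

    def triple(delta: float) -> Thresholds:
        return thresholds(T_env, params, _sweep_scenario(species, delta), tsr_reference)

    curve = ThresholdCurve(axis="dTPC")
    table: dict[float, Thresholds] = {}
    for d in delta_grid:
        th = triple(float(d))
        table[float(d)] = th
        curve.append(float(d), th.K_C, th.K_P, th.K_A)

    def persists(delta: float) -> bool:
        th = table.get(delta) or triple(delta)
        return th.K_A <= k_max

    window = _existence_window(persists, delta_grid, refine)

    analytic = None
    if species == "predator":
        # f_T = 0 once T_env >= shifted Tmax: exact lower existence boundary
        analytic = T_env - params.predator_niche.tmax

    coincidence = _coincidence_shift(table, delta_grid, triple, refine, coincidence_rtol)

    return MismatchSweep(
        species=species,
        T_env=T_env,
        curve=curve,
        k_max=k_max,
        persistence_window=window,
        analytic_existence_shift=analytic,
        coincidence_shift=coincidence,
        coincidence_rtol=coincidence_rtol,
    )


def _existence_window(
    persists: Callable[[float], bool], delta_grid: np.ndarray, refine: float
) -> tuple[float, float] | None:
    flags = [persists(float(d)) for d in delta_grid]
    if not any(flags):
        return None
    i_first = flags.index(True)
    i_last = len(flags) - 1 - flags[::-1].index(True)
    lower = float(delta_grid[i_first])
    upper = float(delta_grid[i_last])
    if i_first > 0:
        lower = _bisect_boundary(persists, float(delta_grid[i_first - 1]), lower, refine)
    if i_last < len(flags) - 1:
        upper = _bisect_boundary(
            persists, float(delta_grid[i_last + 1]), upper, refine
        )
    return lower, upper


def _bisect_boundary(
    persists: Callable[[float], bool], outside: float, inside: float, refine: float
) -> float:
    while abs(inside - outside) > refine:
        mid = 0.5 * (inside + outside)
        if persists(mid):
            inside = mid
        else:
            outside = mid
    return 0.5 * (inside + outside)


def _coincidence_shift(
    table: dict[float, Thresholds],
    delta_grid: np.ndarray,
    triple: Callable[[float], Thresholds],
    refine: float,
    rtol: float,
) -> float | None:
    def coincides(delta: float) -> bool:
        th = table.get(delta) or triple(delta)
        if not (isfinite(th.K_C) and isfinite(th.K_P)):
            return False
        return (th.K_P - th.K_C) <= rtol * th.K_C

    flags = [coincides(float(d)) for d in delta_grid]
    if not any(flags):
        return None
    i_first = flags.index(True)
    first = float(delta_grid[i_first])
    if i_first > 0:
        first = _bisect_boundary(coincides, float(delta_grid[i_first - 1]), first, refine)
    return first


def bistability_temperature_window(
    scenario_id: int = 10,
    t_grid: np.ndarray | None = None,
    params: ModelParameters | None = None,
    rtol: float = 1e-6,
    tsr_reference: str = "fixed",
) -> tuple[float, float] | None:
    """Temperature interval over which the emergent Allee effect exists.

    Scans the temperature grid for K_A < K_P (strictly, beyond the solver
    tolerance ``rtol``) and returns the first and last such temperature,
    or None when the bistable band is empty everywhere.
    """
    params = params or ModelParameters()
    scenario = scenario_parameterization(scenario_id)
    if t_grid is None:
        t_grid = np.arange(5.0, 25.0 + 1e-9, 0.1)
    bistable = []
    for T in t_grid:
        th = thresholds(float(T), params, scenario, tsr_reference)
        if isfinite(th.K_P) and (th.K_P - th.K_A) > rtol * th.K_P:
            bistable.append(float(T))
    if not bistable:
        return None
    return bistable[0], bistable[-1]
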