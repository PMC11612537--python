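"""Community equilibria and productivity thresholds at fixed temperature.

The model admits three community states — resource only (R), consumer–
resource (CR) and the full trophic chain (PCR) — separated along the
productivity axis K by three thresholds:

* ``K_C``: smallest carrying capacity at which a consumer can establish
  (R0 = 1 at R̃ = K without predation);
* ``K_P``: smallest K at which the predator invades the CR equilibrium
  (vulnerable consumer biomass reaches the break-even density Cv*);
* ``K_A``: smallest K at which an established predator can persist — the
  fold of the trophic-chain equilibrium branch.  K_A < K_P signals an
  emergent Allee effect with alternative stable states (PCR/CR) in
  between.

The trophic-chain branch is parameterised by predation pressure p: the
predator's biomass balance pins Cv = Cv* in closed form, leaving a single
scalar root R̃(p) from R0(R̃, p) = 1, after which every other equilibrium
quantity is explicit algebra.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from math import exp, inf, isfinite, log
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .life_history import CohortStatistics, Environment, per_recruit_integrals
from .params import ModelParameters
from .scenarios import ScenarioSpec
from .thermal import RateBundle, effective_rates

logger = logging.getLogger(__name__)

#: relative tolerance of the R̃ and K root solves
ROOT_RTOL = 1e-9
#: default ceiling above which a threshold is declared non-existent in sweeps
K_MAX_DEFAULT = 1e-2
#: default predation-pressure scan grid for the fold search (day⁻¹)
P_GRID_DEFAULT = np.logspace(-4, 2, 60)


@dataclass(frozen=True)
class EquilibriumState:
    """One community equilibrium.

    ``community`` is "R", "CR" or "PCR"; ``b`` is the consumer birth-rate
    flux (newborns·L⁻¹·day⁻¹), ``P`` the predator biomass, ``Cv`` the
    vulnerable consumer biomass and ``p`` the per-capita predation
    pressure on vulnerable juveniles.  ``stage_biomass`` holds the
    (vulnerable, juvenile, adult) consumer biomasses.
    """

    community: str
    R_tilde: float
    b: float = 0.0
    P: float = 0.0
    Cv: float = 0.0
    p: float = 0.0
    stage_biomass: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def consumer_biomass(self) -> float:
        return sum(self.stage_biomass)

    @property
    def juvenile_adult_ratio(self) -> float:
        bv, bj, ba = self.stage_biomass
        return (bv + bj) / ba if ba > 0 else inf if (bv + bj) > 0 else 0.0


@dataclass(frozen=True)
class BranchPoint:
    """One point of the trophic-chain (PCR) equilibrium branch."""

    p: float
    K: float
    state: EquilibriumState
    stable: bool | None = None


@dataclass
class ThresholdCurve:
    """Threshold triples along an environmental axis (T or ΔTPC)."""

    axis: str
    values: list[tuple[float, float, float, float]] = field(default_factory=list)

    def append(self, x: float, k_c: float, k_p: float, k_a: float) -> None:
        self.values.append((x, k_c, k_p, k_a))

    def column(self, name: str) -> np.ndarray:
        idx = {"axis": 0, "K_C": 1, "K_P": 2, "K_A": 3}[name]
        return np.array([v[idx] for v in self.values])

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow([self.axis, "K_C", "K_P", "K_A"])
            for row in self.values:
                writer.writerow(["inf" if v == inf else repr(v) for v in row])

    @classmethod
    def from_csv(cls, path) -> "ThresholdCurve":
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            curve = cls(axis=header[0])
            for row in reader:
                curve.values.append(tuple(float(v) for v in row))
        return curve


# ---------------------------------------------------------------------------
# scalar building blocks


def _cohort(R: float, p: float, rates: RateBundle, params: ModelParameters) -> CohortStatistics:
    return per_recruit_integrals(Environment(R_tilde=R, p=p), rates, params.Rh, params.omega)


def _r0(R: float, p: float, rates: RateBundle, params: ModelParameters) -> float:
    return _cohort(R, p, rates, params).R0


def solve_resource_density(
    p: float,
    rates: RateBundle,
    params: ModelParameters,
    r_cap: float = 1e3,
) -> float | None:
    """Resource density R̃ solving R0(R̃, p) = 1, or None if unreachable.

    R0 is strictly increasing in R̃ (more food, faster growth, higher
    fecundity), so a bracketing bisection from the maturation limit
    upwards is globally convergent.
    """
    if rates.G_T <= 0 or rates.B_T <= 0:
        return None
    sigma_min = rates.lmat_T / rates.linf_T
    if sigma_min >= 1:
        return None
    r_lo = params.Rh * sigma_min / (1 - sigma_min)
    if _r0(r_cap, p, rates, params) <= 1.0:
        return None  # consumer cannot offset mortality at any resource level
    hi = r_lo * 1.01
    while _r0(hi, p, rates, params) < 1.0:
        hi *= 2.0
        if hi >= r_cap:
            hi = r_cap
            break
    lo = r_lo * (1 + 1e-13)
    return brentq(
        lambda R: _r0(R, p, rates, params) - 1.0,
        lo,
        hi,
        xtol=1e-300,
        rtol=ROOT_RTOL * 1e-3,
    )


def critical_vulnerable_biomass(rates: RateBundle, params: ModelParameters) -> float:
    """Break-even vulnerable biomass Cv* for predator growth (g·L⁻¹).

    Solves ε·f_T·a·Cv/(1 + a·h·Cv) = μ_P; +inf when no vulnerable biomass
    can sustain the predator (ε·f_T ≤ h·μ_P or f_T = 0).
    """
    denom = params.attack * (params.eps * rates.f_T - params.handling * rates.mu_P)
    if rates.f_T <= 0 or denom <= 0:
        return inf
    return rates.mu_P / denom


# ---------------------------------------------------------------------------
# thresholds and equilibria


def consumer_invasion_K(
    T: float,
    params: ModelParameters,
    scenario: ScenarioSpec,
    tsr_reference: str = "fixed",
) -> float:
    """Productivity threshold K_C for consumer establishment; +inf if none.

    Equals the resource density at which R0 = 1 without predation: at
    invasion the resource sits at carrying capacity, so K_C is independent
    of everything downstream of the consumer.
    """
    rates = effective_rates(T, params, scenario, tsr_reference)
    R = solve_resource_density(0.0, rates, params)
    return inf if R is None else R


def cr_equilibrium(
    K: float,
    T: float,
    params: ModelParameters,
    scenario: ScenarioSpec,
    tsr_reference: str = "fixed",
) -> EquilibriumState:
    """Consumer–resource equilibrium at carrying capacity K.

    R̃ is pinned by R0(R̃, 0) = 1 (independent of K); the birth-rate flux
    follows from the resource balance b·θ_I = ρ(K − R̃), and stage
    biomasses are b·θ_*.  Returns the resource-only state when K < K_C.
    """
    rates = effective_rates(T, params, scenario, tsr_reference)
    R = solve_resource_density(0.0, rates, params)
    if R is None or K <= R:
        return EquilibriumState(community="R", R_tilde=K)
    stats = _cohort(R, 0.0, rates, params)
    b = params.rho * (K - R) / stats.theta_I
    return EquilibriumState(
        community="CR",
        R_tilde=R,
        b=b,
        Cv=b * stats.theta_v,
        stage_biomass=(b * stats.theta_v, b * stats.theta_j, b * stats.theta_a),
    )


def predator_invasion_K(
    T: float,
    params: ModelParameters,
    scenario: ScenarioSpec,
    tsr_reference: str = "fixed",
) -> float:
    """Productivity threshold K_P for predator invasion of CR; +inf if none.

    Vulnerable biomass grows linearly with K along the CR branch, so the
    invasion point Cv_CR(K) = Cv* is explicit:
    K_P = R̃* + Cv*·θ_I/(ρ·θ_v).
    """
    rates = effective_rates(T, params, scenario, tsr_reference)
    R = solve_resource_density(0.0, rates, params)
    if R is None:
        return inf
    cv_star = critical_vulnerable_biomass(rates, params)
    if not isfinite(cv_star):
        return inf
    stats = _cohort(R, 0.0, rates, params)
    if stats.theta_v <= 0:
        return inf
    return R + cv_star * stats.theta_I / (params.rho * stats.theta_v)


def _branch_point(
    p: float,
    rates: RateBundle,
    params: ModelParameters,
    cv_star: float,
) -> BranchPoint | None:
    R = solve_resource_density(p, rates, params)
    if R is None:
        return None
    stats = _cohort(R, p, rates, params)
    if stats.theta_v <= 0:
        return None
    b = cv_star / stats.theta_v
    P = p * (1 + params.attack * params.handling * cv_star) / (rates.f_T * params.attack)
    K = R + b * stats.theta_I / params.rho
    state = EquilibriumState(
        community="PCR",
        R_tilde=R,
        b=b,
        P=P,
        Cv=cv_star,
        p=p,
        stage_biomass=(b * stats.theta_v, b * stats.theta_j, b * stats.theta_a),
    )
    return BranchPoint(p=p, K=K, state=state)


def pcr_branch(
    T: float,
    params: ModelParameters,
    scenario: ScenarioSpec,
    p_grid: Sequence[float] | None = None,
    tsr_reference: str = "fixed",
) -> list[BranchPoint]:
    """Trophic-chain equilibrium branch parameterised by predation pressure.

    For each p the predator balance fixes Cv = Cv*, R̃(p) solves
    R0(R̃, p) = 1, and the supporting productivity is
    K(p) = R̃ + b·θ_I/ρ with b = Cv*/θ_v.  K(0) coincides with K_P.  The
    branch terminates where the consumer can no longer offset predation.
    Points before the fold (K decreasing in p) are labelled unstable
    (saddle), points beyond it stable, following the structural stability
    assignment of the source bifurcation analysis.
    """
    rates = effective_rates(T, params, scenario, tsr_reference)
    cv_star = critical_vulnerable_biomass(rates, params)
    if not isfinite(cv_star):
        return []
    if p_grid is None:
        p_grid = P_GRID_DEFAULT
    points: list[BranchPoint] = []
    for p in p_grid:
        bp = _branch_point(float(p), rates, params, cv_star)
        if bp is None:
            logger.debug("PCR branch terminates at p=%.3g (T=%.2f)", p, T)
            break
        points.append(bp)
    if points:
        # structural stability labels: the low-p side of the fold is the saddle
        i_fold = min(range(len(points)), key=lambda i: points[i].K)
        points = [
            BranchPoint(bp.p, bp.K, bp.state, stable=i >= i_fold)
            for i, bp in enumerate(points)
        ]
    return points


def predator_persistence_K(
    T: float,
    params: ModelParameters,
    scenario: ScenarioSpec,
    p_grid: Sequence[float] | None = None,
    tsr_reference: str = "fixed",
) -> float:
    """Predator persistence threshold K_A — the fold of the PCR branch.

    K_A = min over p ≥ 0 of K(p); equals K_P when the branch leaves the
    invasion point with non-decreasing K (no emergent Allee effect) and
    +inf when no branch exists.  A coarse log-spaced p scan brackets the
    fold, bounded scalar minimisation refines it.
    """
    rates = effective_rates(T, params, scenario, tsr_reference)
    cv_star = critical_vulnerable_biomass(rates, params)
    k_p = predator_invasion_K(T, params, scenario, tsr_reference)
    if not isfinite(cv_star) or not isfinite(k_p):
        return inf
    if p_grid is None:
        p_grid = P_GRID_DEFAULT

    def k_of_p(p: float) -> float:
        bp = _branch_point(p, rates, params, cv_star)
        return bp.K if bp is not None else inf

    ks = [k_of_p(float(p)) for p in p_grid]
    finite = [(p, k) for p, k in zip(p_grid, ks) if isfinite(k)]
    if not finite:
        return k_p
    i_min = min(range(len(finite)), key=lambda i: finite[i][1])
    if finite[i_min][1] >= k_p:
        return k_p
    lo = finite[max(0, i_min - 1)][0]
    hi = finite[min(len(finite) - 1, i_min + 1)][0]
    res = minimize_scalar(
        lambda x: k_of_p(exp(x)),
        bounds=(log(lo), log(hi)),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return min(k_p, float(res.fun), finite[i_min][1])


def pcr_state_at_K(
    K: float,
    T: float,
    params: ModelParameters,
    scenario: ScenarioSpec,
    tsr_reference: str = "fixed",
) -> EquilibriumState | None:
    """Stable trophic-chain equilibrium supported at productivity K.

    Solves K(p) = K on the stable (high-p) side of the fold of the PCR
    branch; None when K lies below the persistence threshold or no branch
    exists.
    """
    rates = effective_rates(T, params, scenario, tsr_reference)
    cv_star = critical_vulnerable_biomass(rates, params)
    if not isfinite(cv_star):
        return None
    branch = pcr_branch(T, params, scenario, tsr_reference=tsr_reference)
    stable = [bp for bp in branch if bp.stable]
    if not stable:
        return None
    below = [bp for bp in stable if bp.K <= K]
    if not below:
        return None
    lo = max(below, key=lambda bp: bp.K)  # largest supported K not above target
    above = [bp for bp in stable if bp.K > K and bp.p > lo.p]
    if not above:
        return lo.state  # K beyond the computed branch: return the last point
    hi = min(above, key=lambda bp: bp.p)

    def k_err(p: float) -> float:
        bp = _branch_point(p, rates, params, cv_star)
        return (bp.K - K) if bp is not None else inf

    p_root = brentq(k_err, lo.p, hi.p, xtol=1e-300, rtol=ROOT_RTOL)
    bp = _branch_point(p_root, rates, params, cv_star)
    return bp.state if bp is not None else None


@dataclass(frozen=True)
class Thresholds:
    """The (K_C, K_P, K_A) triple at one environmental condition."""

    K_C: float
    K_P: float
    K_A: float


def thresholds(
    T: float,
    params: ModelParameters,
    scenario: ScenarioSpec,
    tsr_reference: str = "fixed",
) -> Thresholds:
    """All three productivity thresholds at temperature T."""
    return Thresholds(
        K_C=consumer_invasion_K(T, params, scenario, tsr_reference),
        K_P=predator_invasion_K(T, params, scenario, tsr_reference),
        K_A=predator_persistence_K(T, params, scenario, tsr_reference=tsr_reference),
    )
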