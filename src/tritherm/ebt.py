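"""Forward-in-time cohort simulation of the tri-trophic chain.

An escalator-boxcar-train style discretisation of the consumer
size-distribution PDE: the population is a set of cohorts (number density,
length), all individuals of a cohort sharing one length.  Newborns
accumulate in a boundary cohort whose number and first length moment are
integrated alongside; every renewal interval the boundary cohort is closed
into an ordinary internal cohort.  Resource and predator biomass follow
their ODEs with consumption summed over cohorts.

The simulator serves as the dynamic verification oracle for the
semi-analytic equilibria: stationarity of equilibrium states, invasion
thresholds, and initial-condition dependence in the bistable band.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import numpy as np

from .equilibrium import EquilibriumState
from .life_history import Environment, per_recruit_integrals, survival
from .params import ModelParameters
from .scenarios import ScenarioSpec
from .thermal import RateBundle, effective_rates

logger = logging.getLogger(__name__)

EXTINCTION_FLOOR = 1e-30  # individuals·L⁻¹
BIOMASS_SHARE_FLOOR = 1e-15
MERGE_LENGTH_TOL = 0.4  # mm; cohorts closer than this are dynamically identical


@dataclass
class CohortState:
    """Instantaneous simulator state."""

    n: np.ndarray  # cohort number densities (L⁻¹)
    l: np.ndarray  # cohort lengths (mm)
    R: float
    P: float
    t: float = 0.0
    nb: float = 0.0  # boundary-cohort numbers
    pib: float = 0.0  # boundary-cohort first length moment about lb

    def vulnerable_biomass(self, rates: RateBundle, omega: float) -> float:
        mask = self.l <= rates.lv_T
        cv = float(np.sum(self.n[mask] * omega * self.l[mask] ** 3))
        lb_eff = rates.lb + (self.pib / self.nb if self.nb > 0 else 0.0)
        if lb_eff <= rates.lv_T:
            cv += self.nb * omega * lb_eff ** 3
        return cv

    def consumer_biomass(self, rates: RateBundle, omega: float) -> float:
        lb_eff = rates.lb + (self.pib / self.nb if self.nb > 0 else 0.0)
        return float(np.sum(self.n * omega * self.l ** 3)) + self.nb * omega * lb_eff ** 3

    def stage_biomass(self, rates: RateBundle, omega: float) -> tuple[float, float, float]:
        w = omega * self.l ** 3
        bv = float(np.sum((self.n * w)[self.l <= rates.lv_T]))
        bj = float(np.sum((self.n * w)[(self.l > rates.lv_T) & (self.l <= rates.lmat_T)]))
        ba = float(np.sum((self.n * w)[self.l > rates.lmat_T]))
        lb_eff = rates.lb + (self.pib / self.nb if self.nb > 0 else 0.0)
        bv += self.nb * omega * lb_eff ** 3
        return bv, bj, ba


class EBTSimulator:
    """Cohort-based integrator of the tri-trophic dynamics.

    Parameters
    ----------
    params, scenario :
        Model parameterisation and temperature-dependence switchboard.
    T : float
        Environmental temperature (°C).
    renewal_interval : float
        Days between boundary-cohort closures (internal cohort spacing).
    dt : float
        Initial internal step of the classical Runge–Kutta substeps; the
        step is halved on negativity and relaxed back afterwards.
    """

    def __init__(
        self,
        params: ModelParameters,
        scenario: ScenarioSpec,
        T: float = 20.0,
        renewal_interval: float = 1.0,
        dt: float = 0.25,
        tsr_reference: str = "fixed",
    ) -> None:
        self.params = params
        self.scenario = scenario
        self.T = T
        self.rates = effective_rates(T, params, scenario, tsr_reference)
        self.renewal_interval = renewal_interval
        self.dt0 = dt

    # ------------------------------------------------------------------ RHS
    def _rhs(self, state: CohortState) -> tuple[np.ndarray, np.ndarray, float, float, float, float]:
        pr, rb = self.params, self.rates
        sigma = state.R / (state.R + pr.Rh)
        lb_eff = rb.lb + (state.pib / state.nb if state.nb > 0 else 0.0)
        cv = state.vulnerable_biomass(rb, pr.omega)
        sat = 1.0 + pr.attack * pr.handling * cv
        p = rb.f_T * pr.attack * state.P / sat
        intake = rb.f_T * pr.attack * cv / sat

        growth = rb.G_T * (rb.linf_T * sigma - state.l)
        vulnerable = state.l <= rb.lv_T
        dn = -(rb.mu_C + p * vulnerable) * state.n
        dl = growth

        ingestion = rb.I_T * sigma * (
            float(np.sum(state.n * state.l ** 2)) + state.nb * lb_eff ** 2
        )
        dR = pr.rho * (pr.K - state.R) - ingestion
        dP = (pr.eps * intake - rb.mu_P) * state.P

        adults = state.l > rb.lmat_T
        births = rb.B_T * sigma * float(np.sum((state.n * state.l ** 2)[adults]))
        g_lb = rb.G_T * (rb.linf_T * sigma - rb.lb)
        dnb = births - (rb.mu_C + p) * state.nb
        dpib = g_lb * state.nb - rb.G_T * state.pib - (rb.mu_C + p) * state.pib
        return dn, dl, dR, dP, dnb, dpib

    def _rk4_step(self, state: CohortState, dt: float) -> CohortState:
        def add(s: CohortState, deriv, h: float) -> CohortState:
            dn, dl, dR, dP, dnb, dpib = deriv
            return CohortState(
                n=s.n + h * dn,
                l=s.l + h * dl,
                R=s.R + h * dR,
                P=s.P + h * dP,
                t=s.t + h,
                nb=s.nb + h * dnb,
                pib=s.pib + h * dpib,
            )

        k1 = self._rhs(state)
        k2 = self._rhs(add(state, k1, dt / 2))
        k3 = self._rhs(add(state, k2, dt / 2))
        k4 = self._rhs(add(state, k3, dt))
        combined = tuple(
            (a + 2 * b + 2 * c + d) / 6.0 for a, b, c, d in zip(k1, k2, k3, k4)
        )
        return add(state, combined, dt)

    def step(self, state: CohortState, duration: float | None = None) -> CohortState:
        """Advance by one renewal interval (or ``duration`` days).

        Internally uses classical Runge–Kutta substeps with step halving
        whenever a substep would drive a state variable negative; at the
        end the boundary cohort is closed into a new internal cohort and
        negligible cohorts are pruned/merged.
        """
        duration = duration or self.renewal_interval
        t_end = state.t + duration
        dt = self.dt0
        while state.t < t_end - 1e-12:
            h = min(dt, t_end - state.t)
            trial = self._rk4_step(state, h)
            if self._admissible(trial):
                state = trial
                dt = min(self.dt0, dt * 1.5)
            else:
                dt = h / 2.0
                if dt < 1e-6:
                    # clamp tiny negatives and accept
                    trial.n = np.maximum(trial.n, 0.0)
                    trial.R = max(trial.R, 0.0)
                    trial.P = max(trial.P, 0.0)
                    trial.nb = max(trial.nb, 0.0)
                    trial.pib = max(trial.pib, 0.0)
                    state = trial
                    dt = self.dt0
        return self._renew(state)

    @staticmethod
    def _admissible(state: CohortState) -> bool:
        return (
            state.R >= 0.0
            and state.P >= 0.0
            and state.nb >= -1e-300
            and float(np.min(state.n, initial=0.0)) >= 0.0
        )

    def _renew(self, state: CohortState) -> CohortState:
        n, l = state.n, state.l
        if state.nb > EXTINCTION_FLOOR:
            l_new = self.rates.lb + state.pib / state.nb
            n = np.append(n, state.nb)
            l = np.append(l, l_new)
        # prune extinct / negligible cohorts
        if n.size:
            biomass = n * l ** 3
            total = float(np.sum(biomass))
            keep = (n > EXTINCTION_FLOOR) & (
                biomass > BIOMASS_SHARE_FLOOR * total if total > 0 else n > 0
            )
            n, l = n[keep], l[keep]
        # merge dynamically identical neighbours (old cohorts pile up at l_max)
        if n.size > 1:
            order = np.argsort(l)
            n, l = n[order], l[order]
            merged_n: list[float] = [float(n[0])]
            merged_l: list[float] = [float(l[0])]
            for ni, li in zip(n[1:], l[1:]):
                if li - merged_l[-1] < MERGE_LENGTH_TOL:
                    w = merged_n[-1] + ni
                    merged_l[-1] = (merged_l[-1] * merged_n[-1] + li * ni) / w
                    merged_n[-1] = w
                else:
                    merged_n.append(float(ni))
                    merged_l.append(float(li))
            n, l = np.array(merged_n), np.array(merged_l)
        return CohortState(n=n, l=l, R=state.R, P=state.P, t=state.t)

    # ------------------------------------------------------- initial states
    def initial_state(
        self, R: float | None = None, P: float = 0.0, seed_consumers: float | None = None
    ) -> CohortState:
        """Fresh state: resource at R (default K), optional consumer seed.

        ``seed_consumers`` is a number density placed in a single newborn
        cohort.
        """
        n = np.array([seed_consumers]) if seed_consumers else np.empty(0)
        l = np.array([self.rates.lb]) if seed_consumers else np.empty(0)
        return CohortState(n=n, l=l, R=self.params.K if R is None else R, P=P)

    def state_from_equilibrium(
        self, eq: EquilibriumState, age_step: float | None = None
    ) -> CohortState:
        """Discretise a semi-analytic equilibrium into cohorts.

        Samples the stationary age distribution c(a) = b·S(a) on an age
        grid with the simulator's renewal spacing, which reproduces the
        cohort structure the EBT itself converges to.
        """
        pr, rb = self.params, self.rates
        da = age_step or self.renewal_interval
        stats = per_recruit_integrals(
            Environment(R_tilde=eq.R_tilde, p=eq.p), rb, pr.Rh, pr.omega
        )
        sigma = eq.R_tilde / (eq.R_tilde + pr.Rh)
        l_max = rb.linf_T * sigma
        a_v = stats.a_v
        ages, numbers, lengths = [], [], []
        a = 0.5 * da
        while True:
            s = survival(a, rb.mu_C, eq.p, a_v)
            if s < 1e-14:
                break
            ages.append(a)
            numbers.append(eq.b * s * da)
            lengths.append(l_max + (rb.lb - l_max) * np.exp(-rb.G_T * a))
            a += da
        return self._renew(
            CohortState(
                n=np.array(numbers),
                l=np.array(lengths),
                R=eq.R_tilde,
                P=eq.P,
            )
        )

    # ------------------------------------------------------------ attractor
    def run_to_attractor(
        self,
        state: CohortState,
        t_max: float = 20000.0,
        window: float = 500.0,
        settle_rtol: float = 1e-6,
    ) -> tuple[EquilibriumState, bool]:
        """Integrate until the windowed averages settle, or ``t_max``.

        Convergence: relative change of the window means of (R, P, total
        consumer biomass) between consecutive windows below
        ``settle_rtol``.  Returns the time-averaged state over the last
        window and a convergence flag.
        """
        pr, rb = self.params, self.rates
        steps_per_window = max(1, int(round(window / self.renewal_interval)))
        prev_means: np.ndarray | None = None
        converged = False
        acc = np.zeros(3)
        acc_states: list[tuple[float, float, float, float, float, float]] = []
        while state.t < t_max:
            acc[:] = 0.0
            acc_states.clear()
            for _ in range(steps_per_window):
                state = self.step(state)
                cb = state.consumer_biomass(rb, pr.omega)
                acc += (state.R, state.P, cb)
                bv, bj, ba = state.stage_biomass(rb, pr.omega)
                acc_states.append(
                    (state.R, state.P, state.vulnerable_biomass(rb, pr.omega), bv, bj, ba)
                )
            means = acc / steps_per_window
            if prev_means is not None:
                scale = np.maximum(np.abs(prev_means), 1e-300)
                delta = np.abs(means - prev_means) / np.where(
                    prev_means == 0.0, 1.0, scale
                )
                # ignore components that are identically zero (e.g. extinct P)
                active = (np.abs(means) > 0) | (np.abs(prev_means) > 0)
                if not np.any(active) or float(np.max(delta[active], initial=0.0)) < settle_rtol:
                    converged = True
                    break
            prev_means = means
        if not converged:
            logger.warning("run_to_attractor: not settled after t=%.0f days", state.t)
        avg = np.mean(np.array(acc_states), axis=0)
        R_bar, P_bar, Cv_bar, bv, bj, ba = (float(x) for x in avg)
        total_c = bv + bj + ba
        if total_c <= 1e-12 * pr.K:
            tag = "R"
        elif P_bar <= 1e-12 * pr.K:
            tag = "CR"
        else:
            tag = "PCR"
        eq = EquilibriumState(
            community=tag,
            R_tilde=R_bar,
            P=P_bar,
            Cv=Cv_bar,
            stage_biomass=(bv, bj, ba),
        )
        return eq, converged

    # ------------------------------------------------------------- output
    def write_trajectory(self, states: list[CohortState], path) -> None:
        """CSV trajectory dump: (t, R, P, Cv, B_v, B_j, B_a, cohorts)."""
        pr, rb = self.params, self.rates
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["t", "R", "P", "Cv", "B_v", "B_j", "B_a", "n_cohorts"])
            for s in states:
                bv, bj, ba = s.stage_biomass(rb, pr.omega)
                writer.writerow(
                    [s.t, s.R, s.P, s.vulnerable_biomass(rb, pr.omega), bv, bj, ba, s.n.size]
                )
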