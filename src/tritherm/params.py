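"""Parameter data model: thermal niches and the full model parameter set.

Default values describe a planktivorous lake food chain (cladoceran resource,
roach-like size-structured consumer, perch-like top predator) calibrated to an
environmental temperature of 20 °C.  All temperatures are handled in degrees
Celsius; conversion to Kelvin happens only inside the Boltzmann–Arrhenius
exponent of the loss rates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


class ConfigurationError(ValueError):
    """Raised for physically inadmissible parameter combinations."""


@dataclass(frozen=True)
class ThermalNiche:
    """Thermal performance window of one species.

    A niche is the triple (tmin, topt, tmax) plus an optional uniform shift
    applied to all three boundaries, used to model thermal-niche mismatch
    between interacting species.  Vital-rate scaling is zero at and beyond
    tmin/tmax and maximal at topt.

    Parameters
    ----------
    tmin, topt, tmax : float
        Lower limit, optimum and upper limit of the performance window (°C).
    shift : float, default 0.0
        Uniform niche displacement (°C); positive values describe a
        warm-adapted variant of the species.
    """

    tmin: float = 5.0
    topt: float = 20.0
    tmax: float = 25.0
    shift: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tmin < self.topt < self.tmax):
            raise ConfigurationError(
                f"degenerate thermal niche: require tmin < topt < tmax, "
                f"got ({self.tmin}, {self.topt}, {self.tmax})"
            )

    # Shifted (effective) boundaries -------------------------------------
    @property
    def tmin_eff(self) -> float:
        return self.tmin + self.shift

    @property
    def topt_eff(self) -> float:
        return self.topt + self.shift

    @property
    def tmax_eff(self) -> float:
        return self.tmax + self.shift

    def shifted(self, delta: float) -> "ThermalNiche":
        """Return a copy with the niche shift set to ``delta`` (°C)."""
        return dataclasses.replace(self, shift=delta)


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter set of the tri-trophic chain model.

    Units follow the source parameterisation: biomasses in g·L⁻¹, lengths in
    mm, rates in day⁻¹.  ``K`` (resource carrying capacity) is the habitat
    productivity axis of all analyses.

    Attributes
    ----------
    K : float
        Resource carrying capacity (g·L⁻¹).
    rho : float
        Resource renewal rate of the semi-chemostat dynamics (day⁻¹).
    omega : float
        Length–weight allometric coefficient, w = ω·l³ (g·mm⁻³).
    lb, lv, lmat, linf : float
        Consumer length at birth, predation-vulnerability threshold,
        maturation length and asymptotic length at the 20 °C reference (mm).
    I_topt : float
        Mass-specific ingestion coefficient at the thermal optimum
        (g·day⁻¹·mm⁻²).
    Rh : float
        Half-saturation resource density of the consumer functional
        response (g·L⁻¹).
    G_topt : float
        von Bertalanffy growth-rate constant at the optimum (day⁻¹).
    B_topt : float
        Birth-rate coefficient at the optimum (day⁻¹·mm⁻²).
    attack : float
        Predator attack rate on vulnerable consumers (L·day⁻¹).
    handling : float
        Predator handling time (day·g⁻¹).
    f_topt : float
        Functional-response scaling constant at the optimum (–).
    eps : float
        Predator food-conversion efficiency (–).
    mu0 : float
        Scaling constant of background mortality / biomass loss (day⁻¹);
        the temperature-independent variant of both loss rates is 2·mu0.
    E_act : float
        Activation energy of the loss rates (eV); printed as −0.55, the
        magnitude is used in the Arrhenius exponent.
    beta : float
        Temperature–size-rule slope (°C⁻¹); −0.05 encodes a 5 % mass
        reduction per °C of warming, applied to lengths as exp(β·ΔT/3).
    T0 : float
        Celsius→Kelvin offset (K).
    k_boltz : float
        Boltzmann constant (eV·K⁻¹).
    consumer_niche, predator_niche : ThermalNiche
        Thermal performance windows of the two animal species.
    """

    K: float = 5e-4
    rho: float = 0.1
    omega: float = 9e-6
    lb: float = 7.0
    lv: float = 27.0
    lmat: float = 110.0
    linf: float = 300.0
    I_topt: float = 1e-4
    Rh: float = 1.5e-5
    G_topt: float = 6e-3
    B_topt: float = 3e-3
    attack: float = 5000.0
    handling: float = 0.1
    f_topt: float = 1.0
    eps: float = 0.5
    mu0: float = 5e-3
    E_act: float = -0.55
    beta: float = -0.05
    T0: float = 273.15
    k_boltz: float = 8.617e-5
    tsr_ref: float = 20.0
    consumer_niche: ThermalNiche = field(default_factory=ThermalNiche)
    predator_niche: ThermalNiche = field(default_factory=ThermalNiche)

    def __post_init__(self) -> None:
        positive = (
            "K rho omega lb lv lmat linf I_topt Rh G_topt B_topt "
            "attack handling f_topt mu0 T0 k_boltz"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"parameter {name} must be > 0")
        if not (0 < self.eps <= 1):
            raise ConfigurationError("eps must lie in (0, 1]")
        if self.beta > 0:
            raise ConfigurationError("beta must be <= 0 (sizes shrink with warming)")
        if not (self.lb < self.lv < self.lmat < self.linf):
            raise ConfigurationError(
                "reference sizes must be ordered lb < lv < lmat < linf"
            )

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def with_shifts(self, consumer: float = 0.0, predator: float = 0.0) -> "ModelParameters":
        """Return a copy with the species niche shifts set (°C)."""
        return self.replace(
            consumer_niche=self.consumer_niche.shifted(consumer),
            predator_niche=self.predator_niche.shifted(predator),
        )


DEFAULT_PARAMETERS = ModelParameters()
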