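"""Scenario definitions: which processes are temperature dependent.

Twelve standard scenarios combine three ingredients:

* direct kinetic (thermal-performance-curve) scaling of the consumer's
  ingestion/growth/birth rates and mortality, and of the predator's
  functional response and biomass loss;
* the temperature–size rule (TSR) applied to the consumer size thresholds
  lmat and l∞ and/or to the predation-vulnerability threshold lv (a proxy
  for predator size);
* a uniform thermal-niche shift of one species (scenarios 11 and 12 only).

Scenario 1 is the fully temperature-independent baseline; scenario 10 turns
everything on for both species; 11 and 12 add a consumer or predator niche
shift on top of scenario 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import ConfigurationError

#: processes that can be individually toggled for fine-grained decompositions
CONSUMER_PROCESSES = frozenset({"ingestion", "growth", "birth", "mortality"})
PREDATOR_PROCESSES = frozenset({"response", "loss"})


@dataclass(frozen=True)
class ScenarioSpec:
    """Switchboard for the temperature dependences of one model run.

    ``consumer_processes`` / ``predator_processes`` refine the two rate
    flags: when a rates flag is on, only the listed processes are scaled
    (all of them by default), supporting one-process-at-a-time
    decompositions.
    """

    consumer_rates_thermal: bool = False
    predator_rates_thermal: bool = False
    tsr_lmat: bool = False
    tsr_linf: bool = False
    tsr_lv: bool = False
    consumer_shift: float = 0.0
    predator_shift: float = 0.0
    consumer_processes: frozenset = field(default=CONSUMER_PROCESSES)
    predator_processes: frozenset = field(default=PREDATOR_PROCESSES)

    def __post_init__(self) -> None:
        if not self.consumer_processes <= CONSUMER_PROCESSES:
            raise ConfigurationError(
                f"unknown consumer processes: {self.consumer_processes - CONSUMER_PROCESSES}"
            )
        if not self.predator_processes <= PREDATOR_PROCESSES:
            raise ConfigurationError(
                f"unknown predator processes: {self.predator_processes - PREDATOR_PROCESSES}"
            )


# scenario id -> (consumer_rates, predator_rates, tsr_lmat, tsr_linf, tsr_lv)
_SCENARIO_FLAGS = {
    1: (False, False, False, False, False),
    2: (True, False, False, False, False),
    3: (False, True, False, False, False),
    4: (True, True, False, False, False),
    5: (False, False, True, True, False),
    6: (False, False, False, False, True),
    7: (False, False, True, True, True),
    8: (True, False, True, True, False),
    9: (False, True, False, False, True),
    10: (True, True, True, True, True),
    11: (True, True, True, True, True),
    12: (True, True, True, True, True),
}


def scenario_parameterization(
    scenario_id: int,
    consumer_shift: float = 0.0,
    predator_shift: float = 0.0,
) -> ScenarioSpec:
    """Build the :class:`ScenarioSpec` for one of the 12 standard scenarios.

    Scenarios 2–4 switch on thermal vital rates (consumer / predator /
    both), 5–7 the TSR in sizes (consumer lmat+l∞ / predator lv / all),
    8–10 combine rates and TSR per species, and 11/12 add a consumer or
    predator niche shift to the all-on scenario 10.

    Parameters
    ----------
    scenario_id : int
        Scenario number, 1–12.
    consumer_shift, predator_shift : float
        Niche shift ΔTPC (°C); only allowed for scenarios 11 and 12
        respectively.
    """
    if scenario_id not in _SCENARIO_FLAGS:
        raise ConfigurationError(f"unknown scenario id {scenario_id!r} (valid: 1-12)")
    if consumer_shift != 0.0 and scenario_id != 11:
        raise ConfigurationError("consumer_shift is only meaningful for scenario 11")
    if predator_shift != 0.0 and scenario_id != 12:
        raise ConfigurationError("predator_shift is only meaningful for scenario 12")
    crt, prt, tmat, tinf, tlv = _SCENARIO_FLAGS[scenario_id]
    return ScenarioSpec(
        consumer_rates_thermal=crt,
        predator_rates_thermal=prt,
        tsr_lmat=tmat,
        tsr_linf=tinf,
        tsr_lv=tlv,
        consumer_shift=consumer_shift if scenario_id == 11 else 0.0,
        predator_shift=predator_shift if scenario_id == 12 else 0.0,
    )


BASELINE = scenario_parameterization(1)
ALL_ON = scenario_parameterization(10)
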