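"""Light and temperature forcing.

The model is driven by a 24-h light:dark cycle (photoperiod) and by an
ambient-temperature scenario.  Light enters the equations through a smooth,
periodic waveform ``L(t)`` in [0, 1]; temperature acts purely parametrically,
through two couplings: a scaling of the Evening Complex's binding affinity for
the *PIF4* promoter (warmth weakens EC repression) and a uniform, additive
activation of *FT* transcription (standing in for warmth-released repressors
such as SVP/FLM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class Photoperiod:
    """A 24-h light:dark cycle: ``hours_light`` of light starting at dawn (ZT0)."""

    hours_light: float
    period: float = 24.0
    dawn_zt: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hours_light <= 24.0:
            raise ValueError(f"hours_light must lie in [0, 24], got {self.hours_light}")
        if self.period != 24.0 or self.dawn_zt != 0.0:
            raise ValueError("period is fixed at 24 h and dawn at ZT0")

    @property
    def dusk(self) -> float:
        return self.dawn_zt + self.hours_light

    @property
    def label(self) -> str:
        h = self.hours_light
        return f"{h:g}L:{24 - h:g}D"


@dataclass(frozen=True)
class LightFunction:
    """Smoothed square-wave light input.

    Dawn/dusk transitions are logistic ramps of half-width ``twilight`` so the
    ODE right-hand side stays continuous for the stiff solver.  ``twilight``
    can be reduced towards a near-step waveform.
    """

    photoperiod: Photoperiod
    twilight: float = 0.05
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.twilight <= 0:
            raise ValueError("twilight must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    def __call__(self, t: float) -> float:
        return light_at(t, self)


def light_at(t: float, lf: LightFunction) -> float:
    """Light level at time ``t`` (hours): ``amplitude`` in the photophase, 0 in
    darkness, with smooth logistic ramps of width ~2*twilight at dawn and dusk.
    Total function, 24-h periodic."""
    pp = lf.photoperiod
    h = pp.hours_light
    if h <= 0.0:
        return 0.0
    if h >= 24.0:
        return lf.amplitude
    zt = t % 24.0
    w = lf.twilight / 2.0  # logistic scale; ramp width ~2*twilight

    def pulse(u: float) -> float:
        return _sigmoid(u / w) * _sigmoid((pp.dusk - u) / w)

    # superpose the day pulse and its 24-h translates so the waveform is
    # smooth and exactly periodic across the midnight wrap
    s = pulse(zt) + pulse(zt - 24.0) + pulse(zt + 24.0)
    return lf.amplitude * min(1.0, s)


def _sigmoid(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    ez = math.exp(z)
    return ez / (1.0 + ez)


_SCENARIO_LABELS = ("reference_22C", "warm_27C", "warm_28C")


@dataclass(frozen=True)
class TemperatureScenario:
    """Parametric temperature scenario.

    ``ec_pif4_affinity_scale`` multiplies the EC half-repression constant on the
    *PIF4* promoter (values > 1 = weaker repression, i.e. warmth); it is applied
    to *PIF5* too when ``scale_pif5`` is set.  ``ft_uniform_activation`` is an
    additive transcription rate on *FT* (warmth-released repression), in the
    model's rate units (1/h).
    """

    label: str
    ec_pif4_affinity_scale: float = 1.0
    ft_uniform_activation: float = 0.0
    scale_pif5: bool = False

    def __post_init__(self) -> None:
        if self.label not in _SCENARIO_LABELS:
            raise ValueError(f"label must be one of {_SCENARIO_LABELS}")
        if self.ec_pif4_affinity_scale < 0 or self.ft_uniform_activation < 0:
            raise ValueError("negative scale/activation is not a valid scenario")
        if self.label == "reference_22C" and (
            self.ec_pif4_affinity_scale != 1.0 or self.ft_uniform_activation != 0.0
        ):
            raise ValueError("reference_22C must have scale 1 and activation 0")


#: Calibrated scenarios. 28 C is used for the PIF4/ATHB2 comparison; 27 C for the
#: FT comparison; both act through the same two knobs.
REFERENCE_22C = TemperatureScenario("reference_22C")
WARM_28C = TemperatureScenario("warm_28C", ec_pif4_affinity_scale=5.0)
WARM_27C = TemperatureScenario(
    "warm_27C", ec_pif4_affinity_scale=4.0, ft_uniform_activation=0.18
)

SCENARIOS = {s.label: s for s in (REFERENCE_22C, WARM_27C, WARM_28C)}


def apply_temperature(p, ts: TemperatureScenario):
    """Return a copy of parameter set ``p`` with the scenario's two couplings
    applied; every other entry is unchanged.

    The EC->PIF4 half-repression constant ``k_ec_pif4`` is multiplied by
    ``ec_pif4_affinity_scale`` (and ``k_ec_pif5`` too if the scenario says so);
    ``ft_temp_activation`` is set to ``ft_uniform_activation``.
    """
    q = p.copy()
    q["k_ec_pif4"] = p["k_ec_pif4"] * ts.ec_pif4_affinity_scale
    if ts.scale_pif5:
        q["k_ec_pif5"] = p["k_ec_pif5"] * ts.ec_pif4_affinity_scale
    q["ft_temp_activation"] = ts.ft_uniform_activation
    return q


@dataclass(frozen=True)
class Environment:
    """Everything external to the genotype: the light cycle and temperature."""

    light: LightFunction
    temperature: TemperatureScenario = REFERENCE_22C

    @classmethod
    def make(
        cls,
        hours_light: float,
        temperature: str | TemperatureScenario = "reference_22C",
        twilight: float = 0.05,
    ) -> "Environment":
        if isinstance(temperature, str):
            temperature = SCENARIOS[temperature]
        return cls(
            light=LightFunction(Photoperiod(hours_light), twilight=twilight),
            temperature=temperature,
        )

    def light_at(self, t: float) -> float:
        return light_at(t, self.light)
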