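"""Stair-step CED infusion protocols.

A convection-enhanced delivery pump ramps its flow rate up in unit
steps, holds a plateau, and ramps back down; a protocol is an ordered
list of (rate, duration) steps. The cumulative infused volume is the
piecewise-linear integral of the rate schedule and is the x-axis of
every volume trajectory in this package (the "Vi" of the Vd/Vi slope).

Three presets reproduce the bench schedules used for cortical (50 µL
over 14 min, peak 5 µL/min), thalamic (246 µL over 84 min, long
3 µL/min plateau) and medial-temporal-lobe (15 µL over 7 min)
infusions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from cedphantom.errors import RangeError, ValidationError

__all__ = [
    "InfusionStep",
    "InfusionProtocol",
    "build_protocol",
    "get_preset",
    "protocol_totals",
    "cumulative_volume",
    "PRESETS",
]


@dataclass(frozen=True)
class InfusionStep:
    """One constant-rate pump segment.

    Parameters
    ----------
    rate : float
        Flow rate in µL/min, strictly positive.
    duration : float
        Segment length in minutes, strictly positive.
    """

    rate: float
    duration: float

    def __post_init__(self) -> None:
        for field in ("rate", "duration"):
            value = getattr(self, field)
            if not np.isfinite(value) or value <= 0:
                raise ValidationError(
                    f"InfusionStep {field} must be finite and > 0, got {value!r}"
                )

    @property
    def volume(self) -> float:
        """Volume delivered by this step, µL."""
        return self.rate * self.duration


@dataclass(frozen=True)
class InfusionProtocol:
    """An ordered stair-step rate schedule.

    ``cumulative_volume`` is continuous, piecewise linear and
    non-decreasing in time; step boundaries belong to the later step
    (half-open intervals), so the right-derivative at a boundary is the
    next step's rate.
    """

    name: str
    steps: tuple[InfusionStep, ...]

    @property
    def total_volume(self) -> float:
        """Total infused volume, µL."""
        return float(sum(s.volume for s in self.steps))

    @property
    def total_time(self) -> float:
        """Total infusion time, min."""
        return float(sum(s.duration for s in self.steps))

    @property
    def step_end_times(self) -> np.ndarray:
        return np.cumsum([s.duration for s in self.steps])


def build_protocol(
    steps: Iterable[tuple[float, float] | Sequence[float]],
    name: str = "custom",
) -> InfusionProtocol:
    """Build a protocol from (rate µL/min, duration min) pairs.

    Raises
    ------
    ValidationError
        If the step list is empty or any rate/duration is non-positive,
        naming the offending step.
    """
    step_list = list(steps)
    if not step_list:
        raise ValidationError("protocol needs at least one step")
    built = []
    for i, pair in enumerate(step_list):
        rate, duration = pair
        try:
            built.append(InfusionStep(float(rate), float(duration)))
        except ValidationError as exc:
            raise ValidationError(f"step {i}: {exc}") from None
    return InfusionProtocol(name=name, steps=tuple(built))


#: Bench gel schedules: rate ramps mirror the surgical stair-step pumping.
PRESETS: dict[str, InfusionProtocol] = {
    "cortical": build_protocol(
        [(1, 1), (2, 1), (3, 1), (4, 1), (5, 6), (4, 1), (3, 1), (2, 1), (1, 1)],
        name="cortical",
    ),
    "thalamic": build_protocol(
        [(1, 1), (2, 1), (3, 80), (2, 1), (1, 1)], name="thalamic"
    ),
    "mtl": build_protocol(
        [(1, 1), (2, 1), (3, 3), (2, 1), (1, 1)], name="mtl"
    ),
}


def get_preset(name: str) -> InfusionProtocol:
    """Return a named preset schedule (cortical | thalamic | mtl)."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None


def protocol_totals(protocol: InfusionProtocol) -> tuple[float, float]:
    """Return (total volume µL, total time min) for a protocol."""
    return protocol.total_volume, protocol.total_time


def cumulative_volume(protocol: InfusionProtocol, t: float) -> float:
    """Infused volume at time ``t`` minutes after infusion start.

    Piecewise-linear in ``t``: within a step the volume grows at that
    step's rate. ``t`` must lie in ``[0, total_time]``.

    Raises
    ------
    RangeError
        If ``t`` lies outside the infusion window.
    """
    total_time = protocol.total_time
    if not (0 <= t <= total_time):
        raise RangeError(
            f"t={t} outside infusion window [0, {total_time}] min"
        )
    volume = 0.0
    elapsed = 0.0
    for step in protocol.steps:
        if t >= elapsed + step.duration:
            volume += step.volume
            elapsed += step.duration
        else:
            volume += step.rate * (t - elapsed)
            break
    return volume
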