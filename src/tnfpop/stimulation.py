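"""TNF stimulation protocols: dose conversion and pulse/continuous schedules.

A protocol is a TNF dose (ng/ml) plus a stimulation mode: continuous
exposure, or a short pulse followed by washout.  Washout emulates the
three-wash removal of free ligand: at the washout time, the free
(extracellular) TNF species is reset to exactly zero while receptor-bound
complexes are untouched — bound and internalized receptor signaling
continues.  The reset is a hard state discontinuity at which the solver is
restarted, not a fast degradation term, so runs are bit-reproducible and
the washout adds no stiffness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError
from .network import ReactionNetwork

__all__ = [
    "StimulusProtocol",
    "Schedule",
    "ScheduleEvent",
    "dose_to_model_units",
    "apply_protocol",
]

CONTINUOUS = "continuous"
PULSE = "pulse"


@dataclass(frozen=True)
class StimulusProtocol:
    """TNF dose and timing. Times are hours post stimulus.

    ``horizon_hours`` is the fate-classification horizon: cells with no
    death event before it are censored survivors (default 100 h).
    """

    dose_ng_ml: float
    mode: str = CONTINUOUS
    pulse_minutes: float = 30.0
    horizon_hours: float = 100.0

    def __post_init__(self):
        if self.dose_ng_ml < 0:
            raise ValueError("dose must be >= 0")
        if self.mode not in (CONTINUOUS, PULSE):
            raise ValueError(f"mode must be {CONTINUOUS!r} or {PULSE!r}, got {self.mode!r}")
        if self.mode == PULSE and self.pulse_minutes <= 0:
            raise ValueError("pulse_duration must be > 0 for pulse mode")
        if self.horizon_hours <= 0:
            raise ValueError("horizon must be > 0")

    @property
    def label(self) -> str:
        return f"{self.dose_ng_ml:g}ng/ml {self.mode}"


@dataclass(frozen=True)
class ScheduleEvent:
    """A hard state reset at ``time_h``.

    ``resets`` maps species id -> amount set at the event.  Species listed
    in ``clamp`` are additionally held constant from the event onward: a
    washed-out ligand stays absent even if complex dissociation would
    otherwise return it to the medium.
    """

    time_h: float
    resets: dict[str, float]
    clamp: tuple[str, ...] = ()


@dataclass
class Schedule:
    """Piecewise-smooth simulation plan produced by :func:`apply_protocol`.

    ``initial_overrides`` set species amounts at t = 0 (the TNF input on top
    of the equilibrated state); each event is a hard reset at which the
    solver is restarted.
    """

    horizon_hours: float
    initial_overrides: dict[str, float] = field(default_factory=dict)
    events: list[ScheduleEvent] = field(default_factory=list)

    def segments(self) -> list[tuple[float, float]]:
        times = [0.0] + [e.time_h for e in self.events if 0.0 < e.time_h < self.horizon_hours]
        times.append(self.horizon_hours)
        return list(zip(times[:-1], times[1:]))


def dose_to_model_units(dose_ng_ml: float, network: ReactionNetwork) -> float:
    """Convert a TNF dose in ng/ml to the model's TNF species units.

    The conversion is linear, with the factor taken from the model metadata
    key ``tnf_units_per_ng_ml`` (the deposited model fixes its own TNF
    amount convention; toy models declare theirs on construction).
    """
    if dose_ng_ml < 0:
        raise ValueError("dose must be >= 0")
    factor = network.metadata.get("tnf_units_per_ng_ml")
    if factor is None:
        raise ConfigurationError(
            "network metadata lacks 'tnf_units_per_ng_ml'; cannot convert an "
            "ng/ml dose to model units"
        )
    return float(dose_ng_ml) * float(factor)


def apply_protocol(network: ReactionNetwork, protocol: StimulusProtocol) -> Schedule:
    """Turn a protocol into a schedule of TNF inputs and washout events."""
    tnf_id = network.metadata.get("tnf_species_id")
    if tnf_id is None:
        raise ConfigurationError(
            "network metadata lacks 'tnf_species_id'; cannot apply a TNF protocol"
        )
    if tnf_id not in network.species_ids:
        raise ConfigurationError(f"TNF species {tnf_id!r} not present in the network")
    amount = dose_to_model_units(protocol.dose_ng_ml, network)
    schedule = Schedule(
        horizon_hours=protocol.horizon_hours,
        initial_overrides={tnf_id: amount},
    )
    if protocol.mode == PULSE:
        schedule.events.append(
            ScheduleEvent(
                time_h=protocol.pulse_minutes / 60.0,
                resets={tnf_id: 0.0},
                clamp=(tnf_id,),
            )
        )
    return schedule
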