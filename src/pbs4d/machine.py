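"""Synchrotron operating parameters and the spot-by-spot delivery-time model.

The beam delivery time (BDT) of a PBS field decomposes into active beam-on
time (MU / extraction current), scanning-magnet transitions between spots,
multi-energy-extraction (MEE) layer switches within a spill, and spill
changes when the stored charge is exhausted.  ``simulate_delivery`` walks a
plan's spot sequence against a spill ledger and emits a fully tiled
timeline of beam-on events and dead-time gaps; everything downstream (phase
sorting, 4D dose) keys off the event time stamps.

Spill ledger
------------
A spill opens with ``L = max_mu_per_spill`` MU and a layer counter ``k = 1``.
Delivering a spot requires ``L >= mu`` and decrements the ledger.  At a
layer boundary the spill continues (an MEE layer switch) when ``k`` is below
the per-spill layer limit and ``recapture_efficiency * L`` still covers the
next spot; the ledger is then multiplied by the recapture efficiency.
Otherwise — and whenever the ledger cannot cover the next spot mid-layer —
the spill closes and a spill change is inserted.  Spots are atomic and are
never split across spills.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .plan import TreatmentPlan

__all__ = [
    "PROTON_REST_MASS_MEV",
    "MachineParameters",
    "BeamEvent",
    "TimelineGap",
    "DeliveryTimeline",
    "UnservablePlanError",
    "proton_momentum",
    "scanning_speed_at_energy",
    "spot_transition_time",
    "simulate_delivery",
    "beam_delivery_time",
    "load_machine",
    "list_machine_presets",
]

PROTON_REST_MASS_MEV = 938.272

#: Relative slack used when testing the spill ledger against a spot MU, so
#: that n-fold rescanned weights (mu/n) summing back to the budget do not
#: trip on the last representable bit.
_LEDGER_RTOL = 1e-9


class UnservablePlanError(ValueError):
    """A single spot exceeds the spill MU budget and can never be delivered."""


@dataclass(frozen=True)
class MachineParameters:
    """One synchrotron operating-parameter set.

    ``max_mee_layers_per_spill`` is a positive integer, or ``None`` for
    "unlimited" (the layer counter never ends a spill).
    """

    name: str
    scan_speed_x_max_energy: float  # m/s at max_energy
    scan_speed_y_max_energy: float  # m/s at max_energy
    magnet_prep_time: float  # s per spot transition
    spill_change_time: float  # s
    max_mu_per_spill: float  # MU
    max_mee_layers_per_spill: int | None  # None = unlimited
    recapture_efficiency: float  # fraction in [0, 1]
    mee_layer_switch_time: float  # s
    beam_current: float  # MU/s
    max_energy: float = 230.0  # MeV the speeds refer to

    def __post_init__(self) -> None:
        if self.scan_speed_x_max_energy <= 0 or self.scan_speed_y_max_energy <= 0:
            raise ValueError("scanning speeds must be positive")
        for attr in ("magnet_prep_time", "spill_change_time", "mee_layer_switch_time"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")
        if self.beam_current <= 0:
            raise ValueError("beam_current must be positive")
        if self.max_mu_per_spill <= 0:
            raise ValueError("max_mu_per_spill must be positive")
        if not 0.0 <= self.recapture_efficiency <= 1.0:
            raise ValueError("recapture_efficiency must lie in [0, 1]")
        k = self.max_mee_layers_per_spill
        if k is not None and (int(k) != k or k < 1):
            raise ValueError("max_mee_layers_per_spill must be >= 1 or None (unlimited)")
        if self.max_energy <= 0:
            raise ValueError("max_energy must be positive")


def proton_momentum(energy_mev: float) -> float:
    """Relativistic momentum times c, in MeV, for kinetic energy E (MeV).

    pc = sqrt(E^2 + 2 E m0c^2) with m0c^2 = 938.272 MeV.
    """
    if energy_mev <= 0:
        raise ValueError(f"kinetic energy must be positive, got {energy_mev}")
    return math.sqrt(energy_mev * (energy_mev + 2.0 * PROTON_REST_MASS_MEV))


def scanning_speed_at_energy(params: MachineParameters, energy_mev: float) -> tuple[float, float]:
    """Lateral scanning speeds (vx, vy) in m/s at the given energy.

    The scanning magnets ramp at a fixed rate of field change, so the sweep
    speed of the beam scales inversely with magnetic rigidity, i.e. with
    beam momentum: lower-energy beams are deflected faster.
    """
    if not 0 < energy_mev <= params.max_energy:
        raise ValueError(
            f"energy {energy_mev} MeV outside (0, {params.max_energy}] MeV"
        )
    ratio = proton_momentum(params.max_energy) / proton_momentum(energy_mev)
    return (params.scan_speed_x_max_energy * ratio, params.scan_speed_y_max_energy * ratio)


def spot_transition_time(
    params: MachineParameters,
    from_xy: tuple[float, float],
    to_xy: tuple[float, float],
    energy_mev: float,
) -> float:
    """Dead time between two spots of the same layer, in seconds.

    The x and y magnets move concurrently, so travel takes the larger of the
    two axis times; magnet preparation/verification is a serial per-spot
    overhead on top.
    """
    vx, vy = scanning_speed_at_energy(params, energy_mev)
    dx_m = abs(to_xy[0] - from_xy[0]) * 1e-3
    dy_m = abs(to_xy[1] - from_xy[1]) * 1e-3
    return params.magnet_prep_time + max(dx_m / vx, dy_m / vy)


@dataclass(frozen=True)
class BeamEvent:
    """One beam-on interval delivering a single spot instance."""

    layer_index: int
    spot_index: int  # original spot index within the layer (pattern position)
    rescan_pass: int
    mu: float
    t_start: float
    t_end: float
    spill_index: int


@dataclass(frozen=True)
class TimelineGap:
    kind: str  # spot_switch | layer_switch | spill_change
    t_start: float
    t_end: float


@dataclass
class DeliveryTimeline:
    """Time-ordered beam-on events and the dead-time gaps between them.

    Events and gaps together tile [first event start, last event end] with
    no overlaps; t = 0 is the start of the first beam-on event.
    """

    events: list[BeamEvent]
    gaps: list[TimelineGap]
    machine: MachineParameters

    def beam_on_time(self) -> float:
        return sum(e.t_end - e.t_start for e in self.events)

    def n_spills(self) -> int:
        return self.events[-1].spill_index + 1 if self.events else 0

    def n_spill_changes(self) -> int:
        return sum(1 for g in self.gaps if g.kind == "spill_change")

    def midpoints(self):
        import numpy as np

        return np.array([(e.t_start + e.t_end) / 2.0 for e in self.events])

    def validate(self, atol: float = 1e-9) -> None:
        """Check the tiling/ordering invariants; raise AssertionError if broken."""
        assert self.events, "empty timeline"
        segs = sorted(
            [(e.t_start, e.t_end, "event") for e in self.events]
            + [(g.t_start, g.t_end, "gap") for g in self.gaps]
        )
        t0 = self.events[0].t_start
        cursor = t0
        for a, b, _ in segs:
            assert b >= a - atol
            assert abs(a - cursor) <= atol, f"hole or overlap at t={a}"
            cursor = b
        assert abs(cursor - self.events[-1].t_end) <= atol
        spills = [e.spill_index for e in self.events]
        assert all(b >= a for a, b in zip(spills, spills[1:])), "spill_index decreased"
        bc = self.machine.beam_current
        for e in self.events:
            assert abs((e.t_end - e.t_start) - e.mu / bc) <= atol

    def to_dataframe(self):
        """Tabular export: one row per event or gap, time-ordered."""
        import pandas as pd

        rows = [
            {
                "event_kind": "beam_on",
                "layer_index": e.layer_index,
                "spot_index": e.spot_index,
                "rescan_pass": e.rescan_pass,
                "mu": e.mu,
                "t_start": e.t_start,
                "t_end": e.t_end,
                "spill_index": e.spill_index,
            }
            for e in self.events
        ] + [
            {
                "event_kind": g.kind,
                "layer_index": -1,
                "spot_index": -1,
                "rescan_pass": -1,
                "mu": 0.0,
                "t_start": g.t_start,
                "t_end": g.t_end,
                "spill_index": -1,
            }
            for g in self.gaps
        ]
        return pd.DataFrame(rows).sort_values("t_start", ignore_index=True)


def simulate_delivery(plan: TreatmentPlan, params: MachineParameters) -> DeliveryTimeline:
    """Event-walk a plan through the machine's time structure and spill ledger.

    Raises :class:`UnservablePlanError` if any single spot exceeds the spill
    MU budget (spots are atomic and cannot be split across spills).
    """
    for layer in plan.layers:
        for s in layer.spots:
            if s.mu > params.max_mu_per_spill * (1.0 + _LEDGER_RTOL):
                raise UnservablePlanError(
                    f"spot of {s.mu} MU exceeds the {params.max_mu_per_spill} MU spill budget"
                )

    events: list[BeamEvent] = []
    gaps: list[TimelineGap] = []
    t = 0.0
    spill = 0
    ledger = params.max_mu_per_spill
    layer_count = 1
    kmax = params.max_mee_layers_per_spill
    slack = params.max_mu_per_spill * _LEDGER_RTOL
    n_rescans = plan.rescan_count

    for j, layer in enumerate(plan.layers):
        m = len(layer.spots) // n_rescans
        first_mu = layer.spots[0].mu
        if j > 0:
            # Layer boundary: MEE switch if the spill can continue, else refill.
            if (kmax is None or layer_count < kmax) and (
                params.recapture_efficiency * ledger >= first_mu - slack
            ):
                gaps.append(TimelineGap("layer_switch", t, t + params.mee_layer_switch_time))
                t += params.mee_layer_switch_time
                ledger *= params.recapture_efficiency
                layer_count += 1
            else:
                gaps.append(TimelineGap("spill_change", t, t + params.spill_change_time))
                t += params.spill_change_time
                spill += 1
                ledger = params.max_mu_per_spill
                layer_count = 1
        prev_xy: tuple[float, float] | None = None
        for i, spot in enumerate(layer.spots):
            if prev_xy is None:
                # First spot of a layer: magnet preparation only.  For the
                # very first spot of the field no gap is emitted at all so
                # that t = 0 coincides with the first beam-on event.
                if events:
                    gaps.append(TimelineGap("spot_switch", t, t + params.magnet_prep_time))
                    t += params.magnet_prep_time
            else:
                dt = spot_transition_time(params, prev_xy, (spot.x, spot.y), layer.energy)
                gaps.append(TimelineGap("spot_switch", t, t + dt))
                t += dt
            if ledger < spot.mu - slack:
                gaps.append(TimelineGap("spill_change", t, t + params.spill_change_time))
                t += params.spill_change_time
                spill += 1
                ledger = params.max_mu_per_spill
                layer_count = 1
            dur = spot.mu / params.beam_current
            events.append(
                BeamEvent(
                    layer_index=j,
                    spot_index=i % m,
                    rescan_pass=i // m,
                    mu=spot.mu,
                    t_start=t,
                    t_end=t + dur,
                    spill_index=spill,
                )
            )
            ledger -= spot.mu
            t += dur
            prev_xy = (spot.x, spot.y)

    return DeliveryTimeline(events=events, gaps=gaps, machine=params)


def beam_delivery_time(timeline: DeliveryTimeline) -> float:
    """BDT in seconds: last beam-off minus first beam-on."""
    if not timeline.events:
        raise ValueError("empty timeline has no beam delivery time")
    return timeline.events[-1].t_end - timeline.events[0].t_start


# --- presets ------------------------------------------------------------


def _params_from_mapping(doc: dict) -> MachineParameters:
    doc = dict(doc)
    k = doc.get("max_mee_layers_per_spill")
    if isinstance(k, str):
        if k.lower() != "unlimited":
            raise ValueError(f"max_mee_layers_per_spill: expected integer or 'unlimited', got {k!r}")
        doc["max_mee_layers_per_spill"] = None
    doc["name"] = str(doc.get("name", "custom"))
    return MachineParameters(**doc)


def load_machine(name_or_path: str | Path) -> MachineParameters:
    """Load a shipped preset by name ("2015", "2025A", "2025B") or a YAML file."""
    path = Path(name_or_path)
    if path.suffix in (".yaml", ".yml") and path.exists():
        doc = yaml.safe_load(path.read_text())
    else:
        ref = resources.files("pbs4d.data.machines").joinpath(f"{name_or_path}.yaml")
        try:
            doc = yaml.safe_load(ref.read_text())
        except FileNotFoundError:
            raise ValueError(
                f"unknown machine preset {name_or_path!r}; available: {list_machine_presets()}"
            ) from None
    return _params_from_mapping(doc)


def list_machine_presets() -> list[str]:
    base = resources.files("pbs4d.data.machines")
    return sorted(p.name[:-5] for p in base.iterdir() if p.name.endswith(".yaml"))
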