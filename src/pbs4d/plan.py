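"""Pencil-beam-scanning treatment plans and scaled layer rescanning.

A plan is an ordered list of energy layers (strictly descending energy, the
natural order for multi-energy extraction from a decelerating synchrotron
spill), each holding an ordered spot sequence.  Spot positions are lateral
coordinates at isocenter in mm; weights are monitor units (MU).

Scaled layer rescanning post-processes a plan so that every layer's spot
pattern is repeated ``n`` times with each repetition carrying ``mu / n``:
total MU is conserved while the delivery of each layer is spread over a
longer time window, statistically averaging spot delivery over breathing
phases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "Spot",
    "EnergyLayer",
    "TreatmentPlan",
    "PlanValidationError",
    "PlanParseError",
    "MinMuViolation",
    "build_layer_rescanning_plan",
    "validate_min_mu",
    "read_plan",
    "write_plan",
]

#: Minimum spot weight enforced at planning time, MU (3 mMU).
PLANNING_MIN_MU = 0.003
#: Lowest spot weight the delivery system itself can serve, MU (0.1 mMU).
MACHINE_MIN_MU = 0.0001


class PlanValidationError(ValueError):
    """A plan violates a structural invariant (ordering, positivity...)."""


class PlanParseError(ValueError):
    """The plan text file is malformed; the message names the line."""


@dataclass(frozen=True)
class Spot:
    """One pencil-beam spot: lateral position (mm at isocenter) and weight (MU)."""

    x: float
    y: float
    mu: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise PlanValidationError(f"non-finite spot position ({self.x}, {self.y})")
        if not (math.isfinite(self.mu) and self.mu > 0):
            raise PlanValidationError(f"spot MU must be positive and finite, got {self.mu}")


@dataclass(frozen=True)
class EnergyLayer:
    """One energy layer: nominal proton kinetic energy (MeV) and its spots."""

    energy: float
    spots: tuple[Spot, ...]

    def __post_init__(self) -> None:
        if not (math.isfinite(self.energy) and self.energy > 0):
            raise PlanValidationError(f"layer energy must be positive, got {self.energy}")
        if len(self.spots) < 1:
            raise PlanValidationError("an energy layer needs at least one spot")
        object.__setattr__(self, "spots", tuple(self.spots))

    @property
    def total_mu(self) -> float:
        return sum(s.mu for s in self.spots)


@dataclass(frozen=True)
class TreatmentPlan:
    """Ordered spot-list plan with prescription metadata.

    ``rescan_count`` is the layer-rescan number n: every layer's spot
    sequence consists of n consecutive repetitions of the base pattern.
    """

    layers: tuple[EnergyLayer, ...]
    rescan_count: int = 1
    dose_per_fraction_gy: float = 10.0
    n_fractions: int = 5
    beam: str = "PA"
    name: str = "plan"

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if len(self.layers) == 0:
            raise PlanValidationError("plan has no energy layers")
        energies = [l.energy for l in self.layers]
        if any(b >= a for a, b in zip(energies, energies[1:])):
            raise PlanValidationError(
                f"layers must be in strictly descending energy order, got {energies}"
            )
        if self.rescan_count < 1:
            raise PlanValidationError(f"rescan_count must be >= 1, got {self.rescan_count}")
        if self.total_mu <= 0:
            raise PlanValidationError("plan total MU must be positive")

    @property
    def total_mu(self) -> float:
        return sum(l.total_mu for l in self.layers)

    @property
    def n_spot_instances(self) -> int:
        return sum(len(l.spots) for l in self.layers)

    def base_spots_per_layer(self) -> list[int]:
        """Number of distinct spot positions per layer (instances / rescans)."""
        return [len(l.spots) // self.rescan_count for l in self.layers]


def build_layer_rescanning_plan(plan: TreatmentPlan, n: int) -> TreatmentPlan:
    """Post-process ``plan`` for n-fold scaled layer rescanning.

    Every layer's spot sequence is replaced by ``n`` consecutive repetitions
    of the original sequence, each instance carrying ``mu / n``.  Total MU is
    conserved exactly up to floating point; layer order is untouched.
    """
    if int(n) != n or n < 1:
        raise ValueError(f"rescan number must be a positive integer, got {n}")
    n = int(n)
    if n == 1:
        return plan
    layers = []
    for layer in plan.layers:
        scaled = tuple(Spot(s.x, s.y, s.mu / n) for s in layer.spots)
        layers.append(EnergyLayer(layer.energy, scaled * n))
    return replace(plan, layers=tuple(layers), rescan_count=n)


@dataclass(frozen=True)
class MinMuViolation:
    layer_index: int
    spot_index: int
    mu: float
    threshold: float


def validate_min_mu(plan: TreatmentPlan, threshold: float) -> list[MinMuViolation]:
    """List every spot instance whose MU falls below ``threshold``.

    An empty list means the plan is deliverable with respect to the minimum
    MU limit (3 mMU is the common planning constraint; 0.1 mMU is the
    hardware floor of the machines modeled here).
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    out = []
    for j, layer in enumerate(plan.layers):
        for i, spot in enumerate(layer.spots):
            if spot.mu < threshold:
                out.append(MinMuViolation(j, i, spot.mu, threshold))
    return out


# --- text serialization -------------------------------------------------
#
# UTF-8 text: "key: value" header lines, then one block per layer:
#   layer <energy_MeV>
#   <x_mm> <y_mm> <mu>
# Floats are written with repr() (shortest round-trip form) so that
# read(write(plan)) reproduces the plan bit-for-bit.

_HEADER_KEYS = ("name", "beam", "rescan_count", "fractions", "dose_per_fraction_gy")


def write_plan(plan: TreatmentPlan, path) -> None:
    lines = [
        f"name: {plan.name}",
        f"beam: {plan.beam}",
        f"rescan_count: {plan.rescan_count}",
        f"fractions: {plan.n_fractions}",
        f"dose_per_fraction_gy: {plan.dose_per_fraction_gy!r}",
    ]
    for layer in plan.layers:
        lines.append(f"layer {layer.energy!r}")
        for s in layer.spots:
            lines.append(f"{s.x!r} {s.y!r} {s.mu!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_plan(path) -> TreatmentPlan:
    header: dict[str, str] = {}
    layers: list[EnergyLayer] = []
    cur_energy: float | None = None
    cur_spots: list[Spot] = []

    def flush() -> None:
        nonlocal cur_energy, cur_spots
        if cur_energy is not None:
            layers.append(EnergyLayer(cur_energy, tuple(cur_spots)))
        cur_energy, cur_spots = None, []

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("layer "):
                flush()
                try:
                    cur_energy = float(line.split(None, 1)[1])
                except ValueError as exc:
                    raise PlanParseError(f"{path}:{lineno}: bad layer energy: {line}") from exc
                continue
            if ":" in line and cur_energy is None:
                key, _, value = line.partition(":")
                key = key.strip()
                if key not in _HEADER_KEYS:
                    raise PlanParseError(f"{path}:{lineno}: unknown header key {key!r}")
                header[key] = value.strip()
                continue
            if cur_energy is None:
                raise PlanParseError(f"{path}:{lineno}: spot line before any 'layer' block")
            parts = line.split()
            if len(parts) != 3:
                raise PlanParseError(f"{path}:{lineno}: expected 'x y mu', got {line!r}")
            try:
                x, y, mu = (float(p) for p in parts)
            except ValueError as exc:
                raise PlanParseError(f"{path}:{lineno}: non-numeric spot field in {line!r}") from exc
            try:
                cur_spots.append(Spot(x, y, mu))
            except PlanValidationError as exc:
                raise PlanParseError(f"{path}:{lineno}: {exc}") from exc
    flush()
    if not layers:
        raise PlanParseError(f"{path}: no energy layers found")
    try:
        return TreatmentPlan(
            layers=tuple(layers),
            rescan_count=int(header.get("rescan_count", "1")),
            dose_per_fraction_gy=float(header.get("dose_per_fraction_gy", "10.0")),
            n_fractions=int(header.get("fractions", "5")),
            beam=header.get("beam", "PA"),
            name=header.get("name", "plan"),
        )
    except PlanValidationError as exc:
        raise PlanParseError(f"{path}: {exc}") from exc
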