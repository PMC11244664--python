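"""Synthetic single-field PA plan generation on the moving phantom.

Stands in for the treatment planning system: energy layers are chosen so
the Bragg peaks tile the target's water-equivalent depth band, a lateral
spot lattice covers the IGTV cross-section with one spot-spacing margin,
and spot weights come from a nonnegative least-squares (NNLS) fit to a
uniform prescription dose.

Coordinate convention: the beam travels along phantom +y, so a spot's
isocenter coordinates (x, y) land on phantom axes (x, z) — spot ``y`` is
the superior-inferior direction the target moves along.

Robustness: the fitted objective stacks uniform-dose terms for the IGTV on
the reference-phase geometry together with the GTV of every motion phase on
its own geometry.  This is a lightweight geometric stand-in for the robust
optimization clinical plans of moving targets receive; without it a plan
tuned to a single geometry under- or over-shoots whenever the target sits
elsewhere in its cycle, and no amount of rescanning can average that away.

The absolute MU scale is set last: the plan is normalized so the static
reference-phase IGTV D95 equals the prescription, then the dose-calibration
constant is chosen so the plan's total MU equals ``total_mu`` (default
180 MU — a realistic monitor-unit scale for a 10 Gy(RBE) lung SBRT
fraction at ~10^9 protons per MU, and one that gives the synthetic field a
no-rescan delivery time structure representative of this machine family).
Spots fitted below the 3-mMU planning floor are pruned and the
normalization repeated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from . import dose as dose_mod
from .dose import DoseGrid, PencilBeamModel, plan_dose
from .phantom import VoxelPhantom
from .plan import PLANNING_MIN_MU, EnergyLayer, Spot, TreatmentPlan

__all__ = ["GeneratedPlan", "PlanGenerationError", "generate_plan"]


class PlanGenerationError(RuntimeError):
    """The spot-weight optimizer could not reach the coverage goal."""


@dataclass
class GeneratedPlan:
    plan: TreatmentPlan
    model: PencilBeamModel  # carries the fitted dose calibration
    info: dict = field(default_factory=dict)


def _layer_energies(model: PencilBeamModel, phantom: VoxelPhantom, layer_spacing_wet: float):
    """Energies whose peaks tile the target WET band, distal-first."""
    wets = []
    for p in range(phantom.motion.n_phases):
        mask = phantom.gtv_mask(p)
        pts = phantom.grid_points()[mask.ravel()]
        wets.append(phantom.wet_at(pts, p))
    w = np.concatenate(wets)
    wmin, wmax = float(w.min()), float(w.max())
    n_layers = max(2, int(np.ceil((wmax - wmin) / layer_spacing_wet)) + 1)
    targets = np.linspace(wmax, wmin, n_layers)  # descending WET = descending energy
    energies = [model.energy_for_range_mm(t) for t in targets]
    for e in energies:
        if not model.energy_min <= e <= model.energy_max:
            raise PlanGenerationError(
                f"required energy {e:.1f} MeV outside commissioned "
                f"[{model.energy_min}, {model.energy_max}] MeV; "
                "adjust the phantom depth or layer spacing"
            )
    return energies, (wmin, wmax)


def _spot_lattice(phantom: VoxelPhantom, spot_spacing: float) -> np.ndarray:
    """Lateral (x, z) lattice covering the IGTV silhouette plus one spot margin.

    The IGTV projects onto the x-z plane as a capsule: a circle of the
    target radius swept along the motion direction's lateral component.
    """
    r = phantom.target_radius
    margin = spot_spacing
    d = np.asarray(phantom.motion.direction)
    a = phantom.motion.half_excursion
    seg = np.array([d[0], d[2]]) * a  # lateral component of the half-excursion
    half_span = np.abs(seg) + r + margin
    nx = int(np.ceil(half_span[0] / spot_spacing))
    nz = int(np.ceil(half_span[1] / spot_spacing))
    gx = np.arange(-nx, nx + 1) * spot_spacing
    gz = np.arange(-nz, nz + 1) * spot_spacing
    X, Z = np.meshgrid(gx, gz, indexing="ij")
    pts = np.stack([X.ravel(), Z.ravel()], axis=1)
    # distance from each lattice point to the motion segment [-seg, +seg]
    if np.allclose(seg, 0):
        dist = np.linalg.norm(pts, axis=1)
    else:
        t = np.clip((pts @ seg) / (seg @ seg), -1.0, 1.0)
        dist = np.linalg.norm(pts - t[:, None] * seg[None, :], axis=1)
    return pts[dist <= r + margin]


def _objective_points(phantom: VoxelPhantom, subsample: int, robust_phases: bool):
    """(points, phase) scenario blocks for the uniform-dose objective."""
    ref = phantom.motion.reference_phase
    grid = phantom.grid_points()
    blocks = []
    igtv = np.flatnonzero(phantom.igtv_mask().ravel())[:: subsample]
    blocks.append((grid[igtv], ref))
    if robust_phases:
        for p in range(phantom.motion.n_phases):
            gtv = np.flatnonzero(phantom.gtv_mask(p).ravel())[:: subsample]
            blocks.append((grid[gtv], p))
    return blocks


def _igtv_d95(model, phantom, plan) -> float:
    ref = phantom.motion.reference_phase
    d = plan_dose(model, phantom, plan, phase=ref)
    vals = d.values[phantom.igtv_mask()]
    return float(np.percentile(vals, 5.0))


def generate_plan(
    phantom: VoxelPhantom,
    model: PencilBeamModel | None = None,
    spot_spacing: float = 5.0,
    layer_spacing_wet: float = 5.0,
    dose_per_fraction_gy: float = 10.0,
    n_fractions: int = 5,
    total_mu: float = 180.0,
    min_spot_mu: float = PLANNING_MIN_MU,
    robust_phases: bool = True,
    subsample: int = 5,
    coverage_tol: float = 0.02,
    seed: int = 0,
    name: str = "synthetic-pa",
) -> GeneratedPlan:
    """Generate the synthetic PA plan and its calibrated dose model.

    Deterministic for a given phantom and arguments (``seed`` is accepted
    for interface symmetry; no stochastic step currently uses it).
    Raises :class:`PlanGenerationError` when the static reference-phase
    IGTV D95 cannot be brought within ``coverage_tol`` of prescription.
    """
    model = model or PencilBeamModel()
    energies, wet_band = _layer_energies(model, phantom, layer_spacing_wet)
    lattice = _spot_lattice(phantom, spot_spacing)
    m = len(lattice)

    blocks = _objective_points(phantom, subsample, robust_phases)
    rows = sum(len(pts) for pts, _ in blocks)
    cols = len(energies) * m
    A = np.empty((rows, cols))
    r0 = 0
    for pts, phase in blocks:
        for j, e in enumerate(energies):
            A[r0 : r0 + len(pts), j * m : (j + 1) * m] = dose_mod.unit_spot_doses_at_points(
                model, phantom, phase, e, lattice, pts
            )
        r0 += len(pts)
    b = np.full(rows, dose_per_fraction_gy)
    w, _ = nnls(A, b)

    def build(weights: np.ndarray) -> TreatmentPlan:
        layers = []
        for j, e in enumerate(energies):
            spots = [
                Spot(lattice[i, 0], lattice[i, 1], weights[j * m + i])
                for i in range(m)
                if weights[j * m + i] > 0
            ]
            if spots:
                layers.append(EnergyLayer(e, tuple(spots)))
        return TreatmentPlan(
            layers=tuple(layers),
            dose_per_fraction_gy=dose_per_fraction_gy,
            n_fractions=n_fractions,
            name=name,
        )

    # Normalize to prescription at IGTV D95, fix the MU scale, prune sub-3-mMU
    # spots, and renormalize until stable (a couple of passes suffice).
    plan = build(w)
    for _ in range(4):
        d95 = _igtv_d95(model, phantom, plan)
        if d95 <= 0:
            raise PlanGenerationError("optimizer produced zero target coverage")
        scale = dose_per_fraction_gy / d95
        w *= scale
        calibration = float(w.sum()) / total_mu  # Gy mm^2 per MU so that sum(mu)=total_mu
        mu = w / calibration
        keep = mu >= min_spot_mu
        if np.count_nonzero(keep) == 0:
            raise PlanGenerationError("all spots fell below the minimum-MU floor")
        pruned = np.where(keep, w, 0.0)
        plan = build(pruned / calibration)
        model = model.with_calibration(calibration)
        w = pruned
        d95 = _igtv_d95(model, phantom, plan)
        if abs(d95 / dose_per_fraction_gy - 1.0) <= 1e-9 or np.all(keep):
            break

    d95 = _igtv_d95(model, phantom, plan)
    if abs(d95 / dose_per_fraction_gy - 1.0) > coverage_tol:
        raise PlanGenerationError(
            f"static IGTV D95 {d95:.3f} Gy misses prescription "
            f"{dose_per_fraction_gy} Gy by more than {coverage_tol:.0%}"
        )
    info = {
        "n_layers": len(plan.layers),
        "n_spots": plan.n_spot_instances,
        "total_mu": plan.total_mu,
        "wet_band_mm": wet_band,
        "energies_mev": [l.energy for l in plan.layers],
        "static_igtv_d95_gy": d95,
        "calibration_gy_mm2_per_mu": model.calibration,
    }
    return GeneratedPlan(plan=plan, model=model, info=info)
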