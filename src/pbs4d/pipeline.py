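"""Dynamic 4D dose (D4DD) reconstruction and the rescanning experiments.

A fraction's D4DD is reconstructed by (1) simulating the delivery timeline,
(2) assigning every spot instance to the respiratory phase containing its
beam-on midpoint, given a random uniform starting phase, (3) computing each
phase's dose on that phase's geometry, (4) mapping it to the reference (50%)
phase by the exact inverse rigid translation of the target motion, and
(5) summing.  A course is five fractions with independent uniform starting
phases; the accumulated D4DD is the voxelwise sum.

Because the phantom is rigid and the dose engine is linear in MU, the
mapped dose restricted to a fixed evaluation voxel set is a linear map of
the per-phase MU vector.  :class:`DoseInfluence` precomputes that map once
(one matrix per phase, evaluated analytically at the translated points) and
the rescan sweep then reduces to small matrix products per machine/rescan
cell, instead of thousands of full grid dose computations.  The delivery
timeline is deterministic for a given plan and machine, so a fraction's
dose depends on the starting phase only — there are just ``n_phases``
distinct fraction doses per cell, which the sweep exploits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import dose as dose_mod
from .dose import DoseGrid, PencilBeamModel, plan_dose
from .machine import DeliveryTimeline, MachineParameters, beam_delivery_time, simulate_delivery
from .phantom import MotionModel, VoxelPhantom, phase_of_time
from .plan import TreatmentPlan, build_layer_rescanning_plan

__all__ = [
    "DvhMetrics",
    "FractionResult",
    "CourseResult",
    "dvh_metrics",
    "split_plan_by_phase",
    "phase_mu_matrix",
    "reconstruct_fraction",
    "run_course",
    "worst_case_course",
    "best_case_course",
    "reference_metrics",
    "DoseInfluence",
    "rescan_sweep",
    "adequate_rescan_number",
]

V_THRESHOLD_GY = 20.0  # V20: percent of structure volume receiving >= 20 Gy(RBE)


@dataclass(frozen=True)
class DvhMetrics:
    """Dose-volume summary of one structure: D95, D5, D5/D95, Dmean, V20."""

    d95: float
    d5: float
    d5_over_d95: float
    dmean: float
    v20: float


def dvh_metrics(dose, mask=None) -> DvhMetrics:
    """DVH metrics of a dose field over a structure mask.

    ``Dq`` is the dose exceeded by q% of the structure's voxels, computed by
    linear interpolation on the sorted dose distribution (the (100-q)-th
    percentile).  ``dose`` may be a :class:`DoseGrid` or an array; ``mask``
    selects the structure (omit it to treat ``dose`` as the flat list of
    structure-voxel doses).
    """
    values = dose.values if isinstance(dose, DoseGrid) else np.asarray(dose, dtype=float)
    if mask is not None:
        values = values[mask]
    values = np.ravel(values)
    if values.size == 0:
        raise ValueError("empty structure mask")
    d95, d5 = np.percentile(values, [5.0, 95.0])
    return DvhMetrics(
        d95=float(d95),
        d5=float(d5),
        d5_over_d95=float(d5 / d95) if d95 > 0 else math.inf,
        dmean=float(values.mean()),
        v20=float(100.0 * np.mean(values >= V_THRESHOLD_GY)),
    )


# --- phase sorting ------------------------------------------------------


def split_plan_by_phase(
    timeline: DeliveryTimeline, motion: MotionModel, start_phase: int
) -> list[list]:
    """Sort spot instances into respiratory phases by beam-on midpoint.

    Returns ``n_phases`` lists of events; each spot instance appears in
    exactly one list, so the MU totals over phases sum to the plan total.
    """
    phases = phase_of_time(motion, timeline.midpoints(), start_phase)
    out: list[list] = [[] for _ in range(motion.n_phases)]
    for event, p in zip(timeline.events, np.atleast_1d(phases)):
        out[int(p)].append(event)
    return out


def _base_offsets(plan: TreatmentPlan) -> tuple[np.ndarray, int]:
    counts = plan.base_spots_per_layer()
    offsets = np.concatenate([[0], np.cumsum(counts)])
    return offsets, int(offsets[-1])


def phase_mu_matrix(
    timeline: DeliveryTimeline,
    plan: TreatmentPlan,
    motion: MotionModel,
    start_phase: int = 0,
) -> np.ndarray:
    """(n_phases, n_base_spots) MU totals, aggregating rescan passes.

    Rescanned instances of the same base spot share position and energy, so
    for dose purposes only the MU landing in each phase per base spot
    matters.  Because phase assignment shifts cyclically with the starting
    phase, the matrix for start phase ``s`` is ``np.roll(M0, s, axis=0)`` of
    the start-phase-0 matrix.
    """
    offsets, n_flat = _base_offsets(plan)
    M = np.zeros((motion.n_phases, n_flat))
    phases = phase_of_time(motion, timeline.midpoints(), start_phase)
    for event, p in zip(timeline.events, np.atleast_1d(phases)):
        M[int(p), offsets[event.layer_index] + event.spot_index] += event.mu
    return M


# --- full-grid reconstruction ------------------------------------------


def _map_to_reference(values: np.ndarray, shift_mm: np.ndarray, spacing: float) -> np.ndarray:
    """Translate a dose field by ``-shift_mm`` with trilinear resampling."""
    shift_vox = -np.asarray(shift_mm) / spacing
    if np.allclose(shift_vox, 0.0, atol=1e-12):
        return values
    return ndimage.shift(values, shift_vox, order=1, mode="constant", cval=0.0, prefilter=False)


@dataclass
class FractionResult:
    start_phase: int
    dose: DoseGrid  # fraction D4DD on the reference phase
    timeline: DeliveryTimeline
    gtv: DvhMetrics
    lung: DvhMetrics


@dataclass
class CourseResult:
    fractions: list[FractionResult]
    dose: DoseGrid  # accumulated D4DD (voxelwise sum over fractions)
    gtv: DvhMetrics
    lung: DvhMetrics
    start_phases: list[int]


def reconstruct_fraction(
    plan: TreatmentPlan,
    machine: MachineParameters,
    motion: MotionModel,
    phantom: VoxelPhantom,
    model: PencilBeamModel,
    start_phase: int,
    timeline: DeliveryTimeline | None = None,
) -> FractionResult:
    """Reconstruct one fraction's D4DD on the full grid.

    Per-phase doses are computed on that phase's geometry and mapped to the
    reference phase by translating the field by minus the phase's relative
    target displacement — exact for this rigidly translating phantom.
    """
    if timeline is None:
        timeline = simulate_delivery(plan, machine)
    M = phase_mu_matrix(timeline, plan, motion, start_phase)
    offsets, _ = _base_offsets(plan)
    base = _base_spot_arrays(plan)
    ref = motion.reference_phase
    disp_ref = motion.phase_displacement(ref)
    total = DoseGrid.zeros_like(phantom)
    for p in range(motion.n_phases):
        if not np.any(M[p] > 0):
            continue
        phase_dose = np.zeros(phantom.shape)
        for j, (energy, xz) in enumerate(base):
            mus = M[p, offsets[j] : offsets[j + 1]]
            live = mus > 0
            if not np.any(live):
                continue
            dose_mod._layer_dose_into(
                phase_dose, model, phantom, p, energy, xz[live, 0], xz[live, 1], mus[live]
            )
        shift = motion.phase_displacement(p) - disp_ref
        total.values += _map_to_reference(phase_dose, shift, phantom.spec.spacing)
    gtv = dvh_metrics(total, phantom.gtv_mask(ref))
    lung = dvh_metrics(total, phantom.healthy_lung_mask())
    return FractionResult(start_phase=start_phase, dose=total, timeline=timeline, gtv=gtv, lung=lung)


def _base_spot_arrays(plan: TreatmentPlan) -> list[tuple[float, np.ndarray]]:
    """Per layer: (energy, (m, 2) base-pattern lateral positions)."""
    out = []
    for layer, m in zip(plan.layers, plan.base_spots_per_layer()):
        xz = np.array([[s.x, s.y] for s in layer.spots[:m]])
        out.append((layer.energy, xz))
    return out


def run_course(
    plan: TreatmentPlan,
    machine: MachineParameters,
    motion: MotionModel,
    phantom: VoxelPhantom,
    model: PencilBeamModel,
    seed: int,
    n_fractions: int | None = None,
) -> CourseResult:
    """Five-fraction course with independent uniform random starting phases."""
    n_fractions = n_fractions or plan.n_fractions
    rng = np.random.default_rng(seed)
    start_phases = [int(s) for s in rng.integers(0, motion.n_phases, n_fractions)]
    timeline = simulate_delivery(plan, machine)
    fractions = [
        reconstruct_fraction(plan, machine, motion, phantom, model, s, timeline=timeline)
        for s in start_phases
    ]
    acc = DoseGrid.zeros_like(phantom)
    for f in fractions:
        acc.values += f.dose.values
    ref = motion.reference_phase
    return CourseResult(
        fractions=fractions,
        dose=acc,
        gtv=dvh_metrics(acc, phantom.gtv_mask(ref)),
        lung=dvh_metrics(acc, phantom.healthy_lung_mask()),
        start_phases=start_phases,
    )


def _scenario_course(course: CourseResult, pick, ranking: str, reference_d95=None) -> DvhMetrics:
    """Scale the picked fraction's dose-type metrics by the fraction count.

    The hot/cold homogeneity ratio D5/D95 is dimensionless and is reported
    from the selected fraction unscaled.
    """
    n = len(course.fractions)
    d95s = np.array([f.gtv.d95 for f in course.fractions])
    if ranking == "value":
        key = d95s
    elif ranking == "distance":
        if reference_d95 is None:
            raise ValueError("distance ranking needs the per-fraction reference D95")
        key = -np.abs(d95s - reference_d95)  # most-distant fraction ranks lowest
    else:
        raise ValueError(f"unknown ranking {ranking!r}")
    f = course.fractions[pick(range(n), key=lambda i: key[i])]
    return DvhMetrics(
        d95=n * f.gtv.d95,
        d5=n * f.gtv.d5,
        d5_over_d95=f.gtv.d5_over_d95,
        dmean=n * f.gtv.dmean,
        v20=f.gtv.v20,
    )


def worst_case_course(course: CourseResult, ranking: str = "value", reference_d95=None) -> DvhMetrics:
    """Course metrics assuming every fraction repeats the worst one.

    With the default ``"value"`` ranking the worst fraction for target
    coverage is the one with the lowest GTV D95; ``"distance"`` ranks by
    distance from the per-fraction reference value instead (both readings
    of "worst" are exposed because a fraction can be hot rather than cold).
    The selected fraction's dose-type metrics are multiplied by the number
    of fractions.
    """
    return _scenario_course(course, min, ranking, reference_d95)


def best_case_course(course: CourseResult, ranking: str = "value", reference_d95=None) -> DvhMetrics:
    """Course metrics assuming every fraction repeats the best one.

    ``"value"`` picks the highest-D95 fraction; ``"distance"`` the fraction
    closest to the per-fraction reference.
    """
    return _scenario_course(course, max, ranking, reference_d95)


def reference_metrics(
    plan: TreatmentPlan,
    phantom: VoxelPhantom,
    model: PencilBeamModel,
) -> dict:
    """Static reference-plan values the D4DD is compared against.

    The reference dose is the plan's static dose on the reference-phase
    geometry, independent of machine parameters and rescanning.  Target
    values are evaluated on the IGTV; healthy-lung values at course scale
    (number of fractions times the static fraction dose).
    """
    ref = phantom.motion.reference_phase
    static = plan_dose(model, phantom, plan, phase=ref)
    igtv_fx = dvh_metrics(static, phantom.igtv_mask())
    course_scale = plan.n_fractions
    lung = dvh_metrics(static.values * course_scale, phantom.healthy_lung_mask())
    return {
        "static_dose": static,
        "igtv_per_fraction": igtv_fx,
        "igtv_course_d95": course_scale * igtv_fx.d95,
        "igtv_course_d5": course_scale * igtv_fx.d5,
        "d5_over_d95": igtv_fx.d5_over_d95,
        "lung_course": lung,
        "n_fractions": course_scale,
    }


# --- influence-matrix fast path ----------------------------------------


class DoseInfluence:
    """Per-phase linear maps from base-spot MU vectors to mapped dose values.

    ``A[p][v, i]`` is the dose that one MU of base spot ``i``, delivered in
    phase ``p``, contributes to evaluation voxel ``v`` after mapping to the
    reference phase.  The mapping is applied analytically (the phase dose is
    evaluated directly at the translated voxel positions), so no grid
    resampling error enters.

    Evaluation voxels are the full reference-phase GTV plus the healthy
    lung subsampled by ``lung_stride`` along each axis (lung DVH statistics
    are smooth; the stride keeps the matrices small).
    """

    def __init__(
        self,
        model: PencilBeamModel,
        phantom: VoxelPhantom,
        plan: TreatmentPlan,
        lung_stride: int = 2,
        dtype=np.float32,
    ):
        motion = phantom.motion
        ref = motion.reference_phase
        gtv = phantom.gtv_mask(ref)
        lung = phantom.healthy_lung_mask()
        s = lung_stride
        strided = np.zeros_like(lung)
        strided[::s, ::s, ::s] = True
        lung_sel = lung & strided
        self.n_gtv = int(gtv.sum())
        self.n_lung = int(lung_sel.sum())
        grid = phantom.grid_points()
        pts = np.concatenate([grid[gtv.ravel()], grid[lung_sel.ravel()]])
        self.gtv_slice = slice(0, self.n_gtv)
        self.lung_slice = slice(self.n_gtv, self.n_gtv + self.n_lung)
        self.offsets, self.n_flat = _base_offsets(plan)
        self.n_phases = motion.n_phases
        base = _base_spot_arrays(plan)
        disp_ref = motion.phase_displacement(ref)
        self.A: list[np.ndarray] = []
        for p in range(self.n_phases):
            shifted = pts + (motion.phase_displacement(p) - disp_ref)[None, :]
            Ap = np.empty((len(pts), self.n_flat), dtype=dtype)
            for j, (energy, xz) in enumerate(base):
                Ap[:, self.offsets[j] : self.offsets[j + 1]] = dose_mod.unit_spot_doses_at_points(
                    model, phantom, p, energy, xz, shifted, dtype=dtype
                )
            self.A.append(Ap)

    def fraction_dose(self, mu_matrix: np.ndarray) -> np.ndarray:
        """Mapped fraction dose at the evaluation voxels for one MU split."""
        out = np.zeros(self.A[0].shape[0])
        for p in range(self.n_phases):
            if np.any(mu_matrix[p] > 0):
                out += self.A[p] @ mu_matrix[p].astype(self.A[p].dtype)
        return out

    def fraction_doses_all_starts(self, mu0: np.ndarray) -> np.ndarray:
        """(n_phases, n_eval) fraction doses for every possible starting phase."""
        return np.stack([self.fraction_dose(np.roll(mu0, s, axis=0)) for s in range(self.n_phases)])

    def static_dose(self, mu_flat: np.ndarray) -> np.ndarray:
        """Reference-phase static dose at the evaluation voxels.

        The reference phase's map has zero shift by construction, so its
        influence matrix doubles as the static-delivery operator.
        """
        out = self.A[self.n_phases // 2] @ mu_flat.astype(self.A[0].dtype)
        return np.asarray(out, dtype=float)


def flat_base_mu(plan: TreatmentPlan) -> np.ndarray:
    """Total MU per base spot (rescan passes summed), flattened over layers."""
    offsets, n_flat = _base_offsets(plan)
    out = np.zeros(n_flat)
    for j, (layer, m) in enumerate(zip(plan.layers, plan.base_spots_per_layer())):
        for i, s in enumerate(layer.spots):
            out[offsets[j] + i % m] += s.mu
    return out


# --- the rescan sweep ---------------------------------------------------


def rescan_sweep(
    plan: TreatmentPlan,
    machines: list[MachineParameters],
    phantom: VoxelPhantom,
    model: PencilBeamModel,
    ns: tuple[int, ...] = (1, 4, 6, 8, 10, 12, 16, 20, 24),
    n_seeds: int = 20,
    seed: int = 0,
    influence: DoseInfluence | None = None,
    reference: dict | None = None,
    pass_tolerance: float = 0.02,
) -> tuple[pd.DataFrame, dict]:
    """Sweep (machine, rescan number) cells and summarize D4DD metrics.

    For every cell the delivery timeline, BDT, accumulated-course GTV
    D95 and D5/D95 (median over seeds, with deviations from the static
    reference and a ±``pass_tolerance`` pass flag), healthy-lung course
    Dmean and V20, the per-fraction spread, and the worst-/best-case
    scenario values are reported.  Randomness is confined to start-phase
    sampling, seeded per cell from ``seed``.

    Returns ``(summary DataFrame, details dict)``; details hold per-seed
    arrays keyed by ``(machine_name, n)``.
    """
    motion = phantom.motion
    influence = influence or DoseInfluence(model, phantom, plan)
    reference = reference or reference_metrics(plan, phantom, model)
    nfx = reference["n_fractions"]
    ref_course_d95 = reference["igtv_course_d95"]
    ref_ratio = reference["d5_over_d95"]
    gsl, lsl = influence.gtv_slice, influence.lung_slice

    rows = []
    details: dict = {}
    for mi, machine in enumerate(machines):
        for n in ns:
            plan_n = build_layer_rescanning_plan(plan, n)
            timeline = simulate_delivery(plan_n, machine)
            bdt = beam_delivery_time(timeline)
            mu0 = phase_mu_matrix(timeline, plan_n, motion, start_phase=0)
            F = influence.fraction_doses_all_starts(mu0)  # (n_phases, n_eval)

            frac_d95 = np.percentile(F[:, gsl], 5.0, axis=1)
            frac_d5 = np.percentile(F[:, gsl], 95.0, axis=1)
            frac_ratio = frac_d5 / frac_d95

            rng = np.random.default_rng([seed, mi, n])
            starts = rng.integers(0, motion.n_phases, size=(n_seeds, nfx))
            acc_d95 = np.empty(n_seeds)
            acc_d5 = np.empty(n_seeds)
            lung_dmean = np.empty(n_seeds)
            lung_v20 = np.empty(n_seeds)
            worst_d95 = np.empty(n_seeds)
            best_d95 = np.empty(n_seeds)
            worst_ratio = np.empty(n_seeds)
            best_ratio = np.empty(n_seeds)
            for k in range(n_seeds):
                acc = F[starts[k]].sum(axis=0)
                g = acc[gsl]
                acc_d95[k], acc_d5[k] = np.percentile(g, [5.0, 95.0])
                lung = acc[lsl]
                lung_dmean[k] = lung.mean()
                lung_v20[k] = 100.0 * np.mean(lung >= V_THRESHOLD_GY)
                sel = starts[k]
                w = sel[np.argmin(frac_d95[sel])]
                b = sel[np.argmax(frac_d95[sel])]
                worst_d95[k] = nfx * frac_d95[w]
                best_d95[k] = nfx * frac_d95[b]
                worst_ratio[k] = frac_ratio[w]
                best_ratio[k] = frac_ratio[b]

            acc_ratio = acc_d5 / acc_d95
            dev_d95 = np.median(acc_d95) / ref_course_d95 - 1.0
            dev_ratio = np.median(acc_ratio) / ref_ratio - 1.0
            rows.append(
                {
                    "machine": machine.name,
                    "n_rescans": n,
                    "bdt_s": bdt,
                    "acc_gtv_d95_gy": float(np.median(acc_d95)),
                    "acc_gtv_d5_over_d95": float(np.median(acc_ratio)),
                    "dev_d95": float(dev_d95),
                    "dev_d5_over_d95": float(dev_ratio),
                    "pass_2pct": bool(
                        abs(dev_d95) <= pass_tolerance and abs(dev_ratio) <= pass_tolerance
                    ),
                    "lung_dmean_gy": float(np.median(lung_dmean)),
                    "lung_v20_pct": float(np.median(lung_v20)),
                    "frac_d95_spread_gy": float(frac_d95.max() - frac_d95.min()),
                    "worst_case_d95_gy": float(np.median(worst_d95)),
                    "best_case_d95_gy": float(np.median(best_d95)),
                }
            )
            details[(machine.name, n)] = {
                "acc_d95": acc_d95,
                "acc_ratio": acc_ratio,
                "worst_d95": worst_d95,
                "best_d95": best_d95,
                "worst_ratio": worst_ratio,
                "best_ratio": best_ratio,
                "lung_dmean": lung_dmean,
                "lung_v20": lung_v20,
                "frac_d95_by_start": frac_d95,
                "frac_ratio_by_start": frac_ratio,
                "starts": starts,
                "bdt_s": bdt,
            }
    df = pd.DataFrame(rows)
    return df, details


def adequate_rescan_number(df: pd.DataFrame, machine_name: str) -> int | None:
    """Smallest swept rescan number whose median deviations pass the ±2% test."""
    sub = df[(df["machine"] == machine_name) & df["pass_2pct"]]
    return int(sub["n_rescans"].min()) if len(sub) else None
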