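"""Synthetic moving thorax phantom and respiratory motion model.

The phantom emulates a CIRS-style dynamic thorax: a rectangular block of
soft-tissue-equivalent material with a lung-equivalent slab inside it, and a
25-mm soft-tissue-equivalent sphere (the target) riding on a movable rod
within the lung.  The beam enters the posterior surface at y = 0 and travels
along +y; target motion is one-dimensional and sinusoidal, by default along
z (superior-inferior), discretized into 10 respiratory phases the way a
phase-binned 4DCT is.

Conventions
-----------
* Phase 0 is maximum displacement (cosine convention); the phase-center time
  of phase p is t_p = (p + 0.5) T / n_phases, which defines that phase's
  target position.
* The reference phase (the accumulation target of the 4D dose pipeline) is
  the 50% phase, index n_phases / 2.
* "10-mm motion amplitude" is read as the programmed amplitude of the
  sinusoid A*cos(2*pi*t/T), i.e. a 20-mm peak-to-peak excursion — the
  waveform convention of the phantom's motion controller, and a
  representative superior-inferior excursion for lower-lobe lung SBRT.  Set
  ``amplitude_is_peak_to_peak=True`` to read the figure as the total
  excursion instead.

All geometry is analytic (slabs plus a sphere), so water-equivalent depths
and masks are evaluated exactly at arbitrary points, not only on the grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import yaml

__all__ = [
    "MotionModel",
    "PhantomSpec",
    "VoxelPhantom",
    "PhantomSpecError",
    "displacement",
    "phase_of_time",
    "build_phantom",
]


class PhantomSpecError(ValueError):
    """The phantom/motion specification is geometrically inconsistent."""


@dataclass(frozen=True)
class MotionModel:
    """Sinusoidal 1-D rigid target motion with 4DCT-style phase binning."""

    period: float = 5.0  # s
    amplitude: float = 10.0  # mm, peak-to-peak by default
    n_phases: int = 10
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    amplitude_is_peak_to_peak: bool = False

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.n_phases < 1:
            raise ValueError("n_phases must be >= 1")
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("direction must be a non-zero vector")
        object.__setattr__(self, "direction", tuple(d / n))

    @property
    def half_excursion(self) -> float:
        """Displacement amplitude A/2 in mm (cosine prefactor)."""
        return self.amplitude / 2.0 if self.amplitude_is_peak_to_peak else self.amplitude

    @property
    def reference_phase(self) -> int:
        return self.n_phases // 2

    def displacement(self, t) -> np.ndarray:
        """Target displacement vector (mm) at time t (s); vectorized over t."""
        t = np.asarray(t, dtype=float)
        mag = self.half_excursion * np.cos(2.0 * math.pi * t / self.period)
        return np.multiply.outer(mag, np.asarray(self.direction))

    def phase_center_time(self, phase: int) -> float:
        return (phase + 0.5) * self.period / self.n_phases

    def phase_displacement(self, phase: int) -> np.ndarray:
        return self.displacement(self.phase_center_time(phase % self.n_phases))


def displacement(motion: MotionModel, t) -> np.ndarray:
    """Module-level alias for :meth:`MotionModel.displacement`."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("time must be non-negative")
    return motion.displacement(t)


def phase_of_time(motion: MotionModel, t, start_phase: int):
    """Respiratory phase index of time t when delivery starts in ``start_phase``.

    phase = floor(n_phases * (t mod T) / T + start_phase) mod n_phases.
    Vectorized over t; returns an int (or int array).
    """
    if not 0 <= start_phase < motion.n_phases:
        raise ValueError(f"start_phase {start_phase} outside [0, {motion.n_phases})")
    t = np.asarray(t, dtype=float)
    frac = np.mod(t, motion.period) / motion.period
    idx = np.mod(np.floor(motion.n_phases * frac + start_phase).astype(int), motion.n_phases)
    return int(idx) if idx.ndim == 0 else idx


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the slab phantom, all lengths in mm, densities in g/cm^3.

    The posterior tissue wall spans y in [0, tissue_thickness), the lung
    slab the next ``lung_thickness`` mm, and an anterior tissue wall closes
    the block.  The target sphere's baseline center sits on the beam axis
    (x = z = 0) at depth ``target_center_y``.
    """

    spacing: float = 2.0
    x_extent: tuple[float, float] = (-48.0, 48.0)
    y_extent: tuple[float, float] = (0.0, 120.0)
    z_extent: tuple[float, float] = (-60.0, 60.0)
    tissue_thickness: float = 30.0
    lung_thickness: float = 80.0
    target_diameter: float = 25.0
    target_center_y: float = 90.0
    tissue_density: float = 1.00
    lung_density: float = 0.26

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise PhantomSpecError("grid spacing must be positive")
        if self.lung_density <= 0 or self.tissue_density <= 0:
            raise PhantomSpecError("densities must be positive")
        if self.target_diameter <= 0:
            raise PhantomSpecError("target diameter must be positive")

    @property
    def lung_y(self) -> tuple[float, float]:
        return (self.tissue_thickness, self.tissue_thickness + self.lung_thickness)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        doc = yaml.safe_load(open(path).read()) or {}
        for key in ("x_extent", "y_extent", "z_extent"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = {
            "spacing": self.spacing,
            "x_extent": list(self.x_extent),
            "y_extent": list(self.y_extent),
            "z_extent": list(self.z_extent),
            "tissue_thickness": self.tissue_thickness,
            "lung_thickness": self.lung_thickness,
            "target_diameter": self.target_diameter,
            "target_center_y": self.target_center_y,
            "tissue_density": self.tissue_density,
            "lung_density": self.lung_density,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)


class VoxelPhantom:
    """Voxelized view of the analytic phantom, one geometry per motion phase.

    Axes are (x, y, z); voxel centers at extent_min + (i + 0.5) * spacing.
    Use :func:`build_phantom` to construct (it validates the motion fits).
    """

    def __init__(self, spec: PhantomSpec, motion: MotionModel):
        self.spec = spec
        self.motion = motion
        s = spec.spacing
        self.x = np.arange(spec.x_extent[0] + s / 2, spec.x_extent[1], s)
        self.y = np.arange(spec.y_extent[0] + s / 2, spec.y_extent[1], s)
        self.z = np.arange(spec.z_extent[0] + s / 2, spec.z_extent[1], s)
        self.shape = (len(self.x), len(self.y), len(self.z))
        self.voxel_volume = s**3
        self._wet_cache: dict[int, np.ndarray] = {}

    # --- geometry helpers ----------------------------------------------

    @property
    def target_radius(self) -> float:
        return self.spec.target_diameter / 2.0

    def target_center(self, phase: int) -> np.ndarray:
        base = np.array([0.0, self.spec.target_center_y, 0.0])
        return base + self.motion.phase_displacement(phase)

    def grid_points(self) -> np.ndarray:
        """All voxel centers as an (N, 3) array in (x, y, z) order."""
        X, Y, Z = np.meshgrid(self.x, self.y, self.z, indexing="ij")
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    # --- masks ----------------------------------------------------------

    def body_mask(self) -> np.ndarray:
        return np.ones(self.shape, dtype=bool)

    def lung_mask(self) -> np.ndarray:
        lo, hi = self.spec.lung_y
        m = np.zeros(self.shape, dtype=bool)
        m[:, (self.y >= lo) & (self.y < hi), :] = True
        return m

    def gtv_mask(self, phase: int) -> np.ndarray:
        c = self.target_center(phase % self.motion.n_phases)
        X, Y, Z = np.meshgrid(self.x, self.y, self.z, indexing="ij")
        r2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
        return r2 <= self.target_radius**2

    def igtv_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        for p in range(self.motion.n_phases):
            m |= self.gtv_mask(p)
        return m

    def healthy_lung_mask(self) -> np.ndarray:
        """Ipsilateral lung minus IGTV."""
        return self.lung_mask() & ~self.igtv_mask()

    # --- density and water-equivalent depth ------------------------------

    def density_at(self, points: np.ndarray, phase: int) -> np.ndarray:
        """Mass density (g/cm^3) at arbitrary points for one phase geometry."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        spec = self.spec
        lo, hi = spec.lung_y
        rho = np.full(len(points), spec.tissue_density)
        in_lung = (points[:, 1] >= lo) & (points[:, 1] < hi)
        rho[in_lung] = spec.lung_density
        c = self.target_center(phase)
        r2 = ((points - c) ** 2).sum(axis=1)
        rho[r2 <= self.target_radius**2] = spec.tissue_density
        return rho

    def density_grid(self, phase: int) -> np.ndarray:
        rho = np.full(self.shape, self.spec.tissue_density)
        rho[self.lung_mask()] = self.spec.lung_density
        rho[self.gtv_mask(phase)] = self.spec.tissue_density
        return rho

    def wet_at(self, points: np.ndarray, phase: int) -> np.ndarray:
        """Water-equivalent depth (mm) from the posterior surface to each point.

        Exact line integral of density along the +y beam axis through the
        slab/sphere geometry (density stands in for relative stopping power).
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        spec = self.spec
        x, yq, z = points[:, 0], points[:, 1], points[:, 2]
        if np.any(yq < self.spec.y_extent[0] - 1e-9) or np.any(yq > self.spec.y_extent[1] + 1e-9):
            raise ValueError("point outside the phantom grid along the beam axis")
        t1 = spec.tissue_thickness
        lung_lo, lung_hi = spec.lung_y
        wet = np.clip(yq, 0.0, t1) * spec.tissue_density
        wet += np.clip(np.minimum(yq, lung_hi) - lung_lo, 0.0, None) * spec.lung_density
        wet += np.clip(yq - lung_hi, 0.0, None) * spec.tissue_density
        # Sphere chord up to depth yq replaces lung with tissue density.
        c = self.target_center(phase)
        rho2 = (x - c[0]) ** 2 + (z - c[2]) ** 2
        inside = rho2 < self.target_radius**2
        if np.any(inside):
            h = np.sqrt(self.target_radius**2 - rho2[inside])
            y_in = c[1] - h
            y_out = c[1] + h
            chord = np.clip(np.minimum(yq[inside], y_out) - y_in, 0.0, None)
            wet[inside] += chord * (spec.tissue_density - spec.lung_density)
        return wet

    def wet_grid(self, phase: int) -> np.ndarray:
        """Cached water-equivalent depth of every voxel center for one phase."""
        phase = phase % self.motion.n_phases
        if phase not in self._wet_cache:
            w = self.wet_at(self.grid_points(), phase)
            self._wet_cache[phase] = w.reshape(self.shape)
        return self._wet_cache[phase]


def build_phantom(spec: PhantomSpec | None = None, motion: MotionModel | None = None) -> VoxelPhantom:
    """Construct the voxel phantom, checking that the moving target fits.

    The target sphere must stay inside the lung slab (and the grid) at the
    extremes of its excursion, otherwise the specification is rejected.
    """
    spec = spec or PhantomSpec()
    motion = motion or MotionModel()
    r = spec.target_diameter / 2.0
    lo, hi = spec.lung_y
    a = motion.half_excursion
    d = np.asarray(motion.direction)
    for sign in (-1.0, 1.0):
        c = np.array([0.0, spec.target_center_y, 0.0]) + sign * a * d
        if not (lo <= c[1] - r and c[1] + r <= hi):
            raise PhantomSpecError("target excursion leaves the lung slab along the beam axis")
        if not (spec.x_extent[0] <= c[0] - r and c[0] + r <= spec.x_extent[1]):
            raise PhantomSpecError("target excursion leaves the grid laterally (x)")
        if not (spec.z_extent[0] <= c[2] - r and c[2] + r <= spec.z_extent[1]):
            raise PhantomSpecError("target excursion leaves the grid laterally (z)")
    return VoxelPhantom(spec, motion)
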