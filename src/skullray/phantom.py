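"""Synthetic skull phantoms, transducer geometries, and treatment tables.

Real treatment exports pair a patient CT with the hemispherical phased-array
geometry and a per-sonication record of energies and focal temperature rises.
This module emulates all three with known ground truth:

* a spherical-shell "skull" of configurable radii and layer HU (cortical tables
  bracketing a trabecular core), optionally with hemispheric porosity and/or
  shell-thinning gradients, embedded in water with brain-like tissue inside;
* a quasi-uniform spherical-cap array of transducer elements focused on a
  target (deterministic Fibonacci layout);
* a treatment table whose temperature rises follow delta_t = eff * energy with
  per-treatment heating efficiency, plus abort flags.

Every generator is driven by a single integer seed; there is no global RNG
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GeometryError
from .volume import CTVolume

__all__ = [
    "ShellPhantomSpec",
    "ShellGroundTruth",
    "TransducerArray",
    "make_shell_phantom",
    "make_transducer",
    "make_treatment_table",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class ShellPhantomSpec:
    """Geometry and composition of a spherical-shell skull phantom.

    The shell spans [inner_radius, outer_radius] around ``center_mm``; a
    cortical layer of thickness (1 - trabecular_fraction)/2 of the shell sits
    at each table, with trabecular bone between.  ``porosity_gradient``
    optionally lowers trabecular HU on the hemisphere facing a unit axis:
    HU_trab(r) = trabecular_hu * (1 - amplitude * max(0, r_hat . axis)).
    """

    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    outer_radius_mm: float = 70.0
    inner_radius_mm: float = 60.0
    cortical_hu: float = 1800.0
    trabecular_hu: float = 1300.0
    tissue_hu: float = 40.0
    water_hu: float = 0.0
    noise_sd: float = 0.0
    trabecular_fraction: float = 0.4
    porosity_gradient: tuple[tuple[float, float, float], float] | None = None
    thinning_gradient: tuple[tuple[float, float, float], float] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius_mm < self.outer_radius_mm:
            raise GeometryError(
                f"need 0 < inner radius < outer radius, got {self.inner_radius_mm}, {self.outer_radius_mm}"
            )
        if not (self.cortical_hu > self.trabecular_hu > self.tissue_hu >= self.water_hu):
            raise GeometryError("HU layers must be ordered cortical > trabecular > tissue >= water")
        if not 0.0 <= self.trabecular_fraction <= 1.0:
            raise GeometryError("trabecular_fraction must lie in [0, 1]")
        for name, grad in (("porosity", self.porosity_gradient), ("thinning", self.thinning_gradient)):
            if grad is None:
                continue
            axis, amplitude = grad
            if not 0.0 <= amplitude <= 1.0:
                raise GeometryError(f"{name} gradient amplitude must lie in [0, 1]")
            if np.linalg.norm(axis) == 0:
                raise GeometryError(f"{name} gradient axis must be nonzero")


@dataclass
class ShellGroundTruth:
    """Analytic truth for a shell phantom: radii, masks, and surface normals."""

    center_mm: np.ndarray
    outer_radius_mm: float
    inner_radius_mm: float
    spec: ShellPhantomSpec
    shell_mask: np.ndarray = field(repr=False)

    def normal(self, point_mm) -> np.ndarray:
        """Outward (radial) unit surface normal at a world point."""
        v = np.asarray(point_mm, dtype=float) - self.center_mm
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("normal undefined at the phantom center")
        return v / n

    def surface_point(self, direction, table: str = "outer") -> np.ndarray:
        """World point where the given radial direction pierces a table."""
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        r = self.outer_radius_mm if table == "outer" else self.inner_radius_mm
        return self.center_mm + r * d

    def to_dict(self) -> dict:
        return {
            "center_mm": self.center_mm.tolist(),
            "outer_radius_mm": self.outer_radius_mm,
            "inner_radius_mm": self.inner_radius_mm,
            "cortical_hu": self.spec.cortical_hu,
            "trabecular_hu": self.spec.trabecular_hu,
            "trabecular_fraction": self.spec.trabecular_fraction,
            "noise_sd": self.spec.noise_sd,
            "porosity_gradient": (
                None
                if self.spec.porosity_gradient is None
                else {
                    "axis": list(self.spec.porosity_gradient[0]),
                    "amplitude": self.spec.porosity_gradient[1],
                }
            ),
            "thinning_gradient": (
                None
                if self.spec.thinning_gradient is None
                else {
                    "axis": list(self.spec.thinning_gradient[0]),
                    "fraction": self.spec.thinning_gradient[1],
                }
            ),
        }


def make_shell_phantom(
    spec: ShellPhantomSpec,
    shape: tuple[int, int, int] = (96, 96, 96),
    spacing: float | tuple[float, float, float] = 2.0,
    seed: int = 0,
) -> tuple[CTVolume, ShellGroundTruth]:
    """Voxelize a shell phantom; HU assigned by voxel-center radius plus noise.

    The volume is centered on ``spec.center_mm``.  Raises GeometryError when the
    outer shell does not fit inside the volume extent.
    """
    shape = tuple(int(s) for s in shape)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    center = np.asarray(spec.center_mm, dtype=float)
    extent = (np.array(shape) - 1) * spacing
    if np.any(spec.outer_radius_mm * 2 > extent):
        raise GeometryError(
            f"shell diameter {2 * spec.outer_radius_mm} mm exceeds volume extent {extent} mm"
        )
    origin = center - extent / 2.0

    # broadcast per-axis offsets instead of full meshgrids: one 3D array, not four
    dx = (origin[0] + spacing[0] * np.arange(shape[0]) - center[0])[:, None, None]
    dy = (origin[1] + spacing[1] * np.arange(shape[1]) - center[1])[None, :, None]
    dz = (origin[2] + spacing[2] * np.arange(shape[2]) - center[2])[None, None, :]
    r = np.sqrt(dx * dx + dy * dy + dz * dz)

    cortical_t = 0.5 * (1.0 - spec.trabecular_fraction) * (spec.outer_radius_mm - spec.inner_radius_mm)
    band = (r > spec.inner_radius_mm) & (r <= spec.outer_radius_mm)
    inner_eff = np.float32(spec.inner_radius_mm)
    if spec.thinning_gradient is not None:
        # shell thins toward the axis: the inner table is locally pushed outward
        t_axis, t_frac = spec.thinning_gradient
        t_axis = np.asarray(t_axis, dtype=float)
        t_axis = t_axis / np.linalg.norm(t_axis)
        cos_t = (dx * t_axis[0] + dy * t_axis[1] + dz * t_axis[2])[band] / r[band]
        inner_eff = np.full(band.sum(), spec.inner_radius_mm, dtype=np.float32)
        inner_eff += (
            t_frac * (spec.outer_radius_mm - spec.inner_radius_mm) * np.clip(cos_t, 0.0, None)
        ).astype(np.float32)
        shell = np.zeros(shape, dtype=bool)
        shell[band] = r[band] > inner_eff
    else:
        shell = band
    trab = np.zeros(shape, dtype=bool)
    if spec.thinning_gradient is not None:
        trab[band] = (r[band] > inner_eff + cortical_t) & (r[band] <= spec.outer_radius_mm - cortical_t)
    else:
        trab = shell & (r > spec.inner_radius_mm + cortical_t) & (r <= spec.outer_radius_mm - cortical_t)

    data = np.full(shape, spec.water_hu, dtype=np.float32)
    data[r <= spec.inner_radius_mm] = spec.tissue_hu
    data[band & ~shell] = spec.tissue_hu
    data[shell] = spec.cortical_hu
    if spec.porosity_gradient is not None:
        axis, amplitude = spec.porosity_gradient
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        cosang = (dx * axis[0] + dy * axis[1] + dz * axis[2])[trab] / r[trab]
        data[trab] = spec.trabecular_hu * (1.0 - amplitude * np.clip(cosang, 0.0, None))
    else:
        data[trab] = spec.trabecular_hu

    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)

    vol = CTVolume(data, spacing, origin)
    gt = ShellGroundTruth(center, spec.outer_radius_mm, spec.inner_radius_mm, spec, shell)
    return vol, gt


# ---------------------------------------------------------------------------
# Transducer
# ---------------------------------------------------------------------------


@dataclass
class TransducerArray:
    """Phased-array element positions (mm) with a geometric focus and flags."""

    element_ids: np.ndarray
    positions: np.ndarray  # (n, 3) mm
    focus_mm: np.ndarray
    active: np.ndarray

    def __post_init__(self) -> None:
        self.element_ids = np.asarray(self.element_ids, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.focus_mm = np.asarray(self.focus_mm, dtype=float)
        self.active = np.asarray(self.active, dtype=bool)
        if len(self.element_ids) != len(self.positions) or len(self.active) != len(self.positions):
            raise ValueError("element_ids, positions and active must have equal length")

    def __len__(self) -> int:
        return len(self.positions)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.element_ids,
                "x_mm": self.positions[:, 0],
                "y_mm": self.positions[:, 1],
                "z_mm": self.positions[:, 2],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, focus_mm=(0.0, 0.0, 0.0)) -> "TransducerArray":
        df = pd.read_csv(path)
        pos = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        return cls(df["id"].to_numpy(), pos, focus_mm, np.ones(len(df), dtype=bool))


def make_transducer(
    n_elements: int = 1024,
    radius_mm: float = 150.0,
    aperture_deg: float = 90.0,
    focus_mm=(0.0, 0.0, 0.0),
    axis=(0.0, 0.0, 1.0),
    seed: int | None = None,
) -> TransducerArray:
    """Hemispherical-cap phased array with a deterministic Fibonacci layout.

    Elements sit quasi-uniformly on the spherical cap of polar half-angle
    ``aperture_deg`` about ``axis``, all at ``radius_mm`` from the focus.  The
    seed only applies a random azimuthal offset to the whole cap; the layout is
    otherwise deterministic.
    """
    if n_elements < 1:
        raise ValueError("n_elements must be >= 1")
    if radius_mm <= 0:
        raise ValueError("radius_mm must be > 0")
    if not 0 < aperture_deg <= 180:
        raise ValueError(f"aperture must lie in (0, 180] degrees, got {aperture_deg}")
    cos_ap = np.cos(np.radians(aperture_deg))
    if n_elements == 1:
        dirs = np.array([[0.0, 0.0, 1.0]])
    else:
        i = np.arange(n_elements)
        z = 1.0 - (1.0 - cos_ap) * (i + 0.5) / n_elements
        phi = i * _GOLDEN_ANGLE
        if seed is not None:
            phi = phi + np.random.default_rng(seed).uniform(0.0, 2 * np.pi)
        s = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
        dirs = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    if not np.allclose(axis, [0.0, 0.0, 1.0]):
        dirs = dirs @ _rotation_z_to(axis).T
    focus = np.asarray(focus_mm, dtype=float)
    positions = focus + radius_mm * dirs
    return TransducerArray(np.arange(n_elements), positions, focus, np.ones(n_elements, dtype=bool))


def _rotation_z_to(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z onto a unit axis (Rodrigues)."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, axis))
    if np.isclose(c, -1.0):
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(z, axis)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


# ---------------------------------------------------------------------------
# Treatment tables
# ---------------------------------------------------------------------------


def make_treatment_table(
    n_treatments: int = 30,
    sonications_per_treatment: int = 12,
    efficiency_range: tuple[float, float] = (0.5, 3.5),
    abort_prob: float = 0.1,
    seed: int = 0,
    noise_sd: float = 0.0,
    energy_range_kj: tuple[float, float] = (2.0, 12.0),
) -> pd.DataFrame:
    """Synthetic per-sonication treatment records.

    Each treatment draws a heating efficiency ``eff`` (degC/kJ) from
    ``efficiency_range``; completed sonications obey
    delta_t = eff * energy + noise.  Treatments with low efficiency need more
    stepwise sonications and abort more often, mirroring the clinical pattern
    that inefficient heating prolongs treatment; counts scale inversely with
    efficiency around ``sonications_per_treatment``.  Aborted rows keep their
    (partial) temperature rise but are flagged.

    Columns: treatment_id, sonication_id, energy_kj, delta_t_c, aborted.
    """
    if not 0.0 <= abort_prob <= 1.0:
        raise ValueError("abort_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lo, hi = efficiency_range
    mean_eff = 0.5 * (lo + hi)
    rows = []
    for tid in range(n_treatments):
        eff = rng.uniform(lo, hi)
        n_son = max(2, int(round(sonications_per_treatment * mean_eff / eff + rng.normal(0.0, 1.0))))
        p_abort = float(np.clip(abort_prob * mean_eff / eff, 0.0, 1.0)) if abort_prob > 0 else 0.0
        for sid in range(n_son):
            energy = rng.uniform(*energy_range_kj)
            aborted = bool(rng.random() < p_abort)
            dt = eff * energy
            if aborted:
                dt *= rng.uniform(0.2, 0.8)  # sonication stopped partway
            if noise_sd > 0:
                dt += rng.normal(0.0, noise_sd)
            rows.append((tid, sid, energy, max(dt, 0.0), aborted))
    return pd.DataFrame(rows, columns=["treatment_id", "sonication_id", "energy_kj", "delta_t_c", "aborted"])
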