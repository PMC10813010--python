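"""CT-like volume container, I/O, thresholding, and voxel traversal along rays.

The volume model is deliberately simple: an axis-aligned 3D grid of Hounsfield
units (HU) where world coordinates address voxel centers,

    world = origin + index * spacing        (per axis, mm)

Oblique direction matrices are rejected at load time.  Rays are traversed with a
3D digital differential analyzer (DDA) that lists every voxel a segment passes
through, and HU values along a ray can be smoothed with a 26-neighbor average,
which removes voxelization noise without any tunable filter parameter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import FormatError

__all__ = [
    "CTVolume",
    "HUProfile",
    "load_volume",
    "save_volume",
    "hu_histogram",
    "threshold_mask",
    "dda_traverse",
    "neighbor_average_sample",
    "hu_profile",
]


@dataclass
class CTVolume:
    """3D HU voxel grid with spacing (mm) and origin (mm, voxel (0,0,0) center)."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    _smoothed: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"volume must be 3D, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("volume contains non-finite HU values")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing.shape != (3,) or self.origin.shape != (3,):
            raise FormatError("spacing and origin must be 3-vectors")
        if np.any(self.spacing <= 0):
            raise FormatError("all spacing components must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_to_voxel(self, point_mm) -> np.ndarray:
        """Continuous voxel coordinate of a world point (inverse of voxel_to_world)."""
        return (np.asarray(point_mm, dtype=float) - self.origin) / self.spacing

    def voxel_to_world(self, coord) -> np.ndarray:
        """World coordinate (mm) of a (possibly fractional) voxel coordinate."""
        return self.origin + np.asarray(coord, dtype=float) * self.spacing

    def contains_voxel(self, coord) -> bool:
        c = np.asarray(coord)
        return bool(np.all(c >= 0) and np.all(c <= np.array(self.shape) - 1))

    @property
    def smoothed(self) -> np.ndarray:
        """26-neighbor mean of every voxel (center excluded).

        At the volume boundary only the existing neighbors enter the mean; no HU
        is invented outside the scan.  Computed once and cached.
        """
        if self._smoothed is None:
            work_dtype = self.data.dtype if self.data.dtype.kind == "f" else np.float32
            kernel = np.ones((3, 3, 3), dtype=work_dtype)
            kernel[1, 1, 1] = 0.0
            total = ndimage.convolve(self.data.astype(work_dtype), kernel, mode="constant", cval=0.0)
            counts = ndimage.convolve(np.ones(self.shape, dtype=work_dtype), kernel, mode="constant", cval=0.0)
            self._smoothed = total / counts
        return self._smoothed


@dataclass
class HUProfile:
    """HU samples along a ray: arc length (mm), value, and the voxel visited."""

    positions: np.ndarray  # arc length from the requested start point, mm
    values: np.ndarray
    voxel_coords: np.ndarray  # (n, 3) integer voxel coordinates

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=int).reshape(-1, 3)
        n = len(self.positions)
        if len(self.values) != n or len(self.voxel_coords) != n:
            raise ValueError("profile arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("profile positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_META_SUFFIXES = (".mha", ".mhd")


def _detect_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(_NIFTI_SUFFIXES):
        return "nifti"
    if name.endswith(_META_SUFFIXES):
        return "metaimage"
    if name.endswith((".raw", ".json")):
        return "raw+json"
    raise FormatError(f"cannot infer volume format from {path.name!r}")


def load_volume(path, format: str | None = None) -> CTVolume:
    """Read a volume from NIfTI, MetaImage, or raw int16 + JSON sidecar."""
    path = Path(path)
    fmt = format or _detect_format(path)
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        rot = affine[:3, :3]
        if not np.allclose(rot, np.diag(np.diag(rot))):
            raise FormatError("oblique direction matrices are not supported")
        spacing = np.diag(rot)
        if np.any(spacing <= 0):
            raise FormatError("negative/zero NIfTI spacing is not supported")
        data = np.asanyarray(img.dataobj)
        return CTVolume(data, spacing, affine[:3, 3])
    if fmt == "metaimage":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        if img.GetDimension() != 3:
            raise FormatError(f"volume must be 3D, got {img.GetDimension()}D")
        if not np.allclose(np.array(img.GetDirection()).reshape(3, 3), np.eye(3)):
            raise FormatError("oblique direction matrices are not supported")
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return CTVolume(data, np.array(img.GetSpacing()), np.array(img.GetOrigin()))
    if fmt == "raw+json":
        sidecar = path.with_suffix(".json") if path.suffix != ".json" else path
        rawfile = sidecar.with_suffix(".raw")
        if not sidecar.exists():
            raise FormatError(f"missing JSON sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        for key in ("shape", "spacing_mm", "origin_mm", "dtype"):
            if key not in meta:
                raise FormatError(f"sidecar missing required key {key!r}")
        shape = tuple(meta["shape"])
        if len(shape) != 3:
            raise FormatError(f"volume must be 3D, got shape {shape}")
        data = np.fromfile(rawfile, dtype=np.dtype(meta["dtype"])).reshape(shape)
        return CTVolume(data, meta["spacing_mm"], meta["origin_mm"])
    raise FormatError(f"unknown volume format {fmt!r}")


def save_volume(vol: CTVolume, path, format: str | None = None) -> Path:
    """Write a volume; the inverse of :func:`load_volume` on data and metadata."""
    path = Path(path)
    fmt = format or _detect_format(path)
    if fmt == "nifti":
        import nibabel as nib

        affine = np.eye(4)
        affine[:3, :3] = np.diag(vol.spacing)
        affine[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(vol.data, affine), str(path))
    elif fmt == "metaimage":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in vol.spacing))
        img.SetOrigin(tuple(float(o) for o in vol.origin))
        sitk.WriteImage(img, str(path))
    elif fmt == "raw+json":
        sidecar = path.with_suffix(".json") if path.suffix != ".json" else path
        rawfile = sidecar.with_suffix(".raw")
        data = np.ascontiguousarray(vol.data)
        data.tofile(rawfile)
        sidecar.write_text(
            json.dumps(
                {
                    "shape": list(vol.shape),
                    "spacing_mm": vol.spacing.tolist(),
                    "origin_mm": vol.origin.tolist(),
                    "dtype": data.dtype.name,
                }
            )
        )
    else:
        raise FormatError(f"unknown volume format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# Histogram / threshold
# ---------------------------------------------------------------------------

def hu_histogram(vol: CTVolume, bins: int = 256):
    """Histogram of voxel HU over [min, max]; sum of counts == voxel count."""
    if bins < 1:
        raise ValueError("bins must be >= 1")
    lo, hi = float(vol.data.min()), float(vol.data.max())
    if lo == hi:
        hi = lo + 1.0  # degenerate constant volume: one nonempty bin
    counts, edges = np.histogram(vol.data, bins=bins, range=(lo, hi))
    return edges, counts


def threshold_mask(vol: CTVolume, lo: float, hi: float) -> np.ndarray:
    """Binary foreground mask: true exactly where lo <= HU <= hi."""
    if lo > hi:
        raise ValueError(f"threshold window lower bound {lo} exceeds upper bound {hi}")
    return (vol.data >= lo) & (vol.data <= hi)


# ---------------------------------------------------------------------------
# Ray traversal
# ---------------------------------------------------------------------------

def _segment_voxels(p0: np.ndarray, p1: np.ndarray):
    """Voxels visited by the segment p0->p1 in continuous voxel-index space.

    Returns (coords (n,3) int, t_entry (n,)) where t_entry is the segment
    parameter in [0, 1] at which each voxel is entered.  Voxel i spans
    [i-0.5, i+0.5) per axis.  Corner hits (simultaneous boundary crossings)
    merge into a single diagonal step, matching a dense sample-and-round
    oracle.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    ts = [np.array([0.0])]
    for ax in range(3):
        if d[ax] == 0.0:
            continue
        lo, hi = sorted((p0[ax], p1[ax]))
        # half-integer planes strictly inside the segment extent on this axis
        first = np.ceil(lo - 0.5)
        planes = np.arange(first, np.floor(hi - 0.5) + 1) + 0.5
        t = (planes - p0[ax]) / d[ax]
        ts.append(t[(t > 0.0) & (t < 1.0)])
    bounds = np.concatenate(ts)
    bounds.sort()
    # merge simultaneous crossings (corner hits) into one boundary
    keep = np.concatenate(([True], np.diff(bounds) > 1e-12))
    bounds = bounds[keep]
    uppers = np.append(bounds[1:], 1.0)
    mids = 0.5 * (bounds + uppers)
    coords = np.rint(p0[None, :] + mids[:, None] * d[None, :]).astype(int)
    return coords, bounds


def dda_traverse(start_voxel, end_voxel) -> np.ndarray:
    """Integer voxel coordinates along the segment joining two voxel centers.

    First element is ``start_voxel``, last is ``end_voxel``; consecutive
    coordinates differ by -1/0/+1 per axis, with corner ties advancing all tied
    axes in one (diagonal) step.
    """
    start = np.asarray(start_voxel, dtype=int)
    end = np.asarray(end_voxel, dtype=int)
    if np.array_equal(start, end):
        return start.reshape(1, 3).copy()
    coords, _ = _segment_voxels(start, end)
    return coords


def neighbor_average_sample(vol: CTVolume, coord) -> float:
    """Mean HU of the 26 neighbors of a voxel (center excluded).

    At the volume boundary only the existing neighbors contribute.
    """
    coord = np.asarray(coord, dtype=int)
    if not vol.contains_voxel(coord):
        raise IndexError(f"voxel coordinate {coord.tolist()} out of bounds for shape {vol.shape}")
    return float(vol.smoothed[tuple(coord)])


def _clip_to_volume(vol: CTVolume, q0: np.ndarray, q1: np.ndarray):
    """Clip a segment (continuous voxel-index space) to the voxel extent box.

    The box spans [-0.5, N-0.5) per axis.  Returns (s0, s1) segment parameters
    or None when the segment misses the volume entirely.
    """
    d = q1 - q0
    s0, s1 = 0.0, 1.0
    eps = 1e-9
    for ax in range(3):
        lo, hi = -0.5, vol.shape[ax] - 0.5 - eps
        if d[ax] == 0.0:
            if not (lo <= q0[ax] <= hi):
                return None
            continue
        ta = (lo - q0[ax]) / d[ax]
        tb = (hi - q0[ax]) / d[ax]
        ta, tb = min(ta, tb), max(ta, tb)
        s0, s1 = max(s0, ta), min(s1, tb)
        if s0 > s1:
            return None
    return s0, s1


def hu_profile(vol: CTVolume, start_mm, end_mm, smooth: bool = True) -> HUProfile:
    """HU values along the ray start->end (mm), one sample per visited voxel.

    ``positions`` is arc length from ``start_mm`` measured at each voxel's
    segment-entry point; ``values`` come from the 26-neighbor average when
    ``smooth`` else the raw HU.  A segment entirely outside the volume yields an
    empty profile.
    """
    start_mm = np.asarray(start_mm, dtype=float)
    end_mm = np.asarray(end_mm, dtype=float)
    q0 = vol.world_to_voxel(start_mm)
    q1 = vol.world_to_voxel(end_mm)
    clip = _clip_to_volume(vol, q0, q1)
    if clip is None:
        return HUProfile(np.empty(0), np.empty(0), np.empty((0, 3), dtype=int))
    s0, s1 = clip
    c0 = q0 + s0 * (q1 - q0)
    c1 = q0 + s1 * (q1 - q0)
    if np.allclose(c0, c1):
        coords = np.rint(c0).astype(int).reshape(1, 3)
        t_entry = np.array([0.0])
    else:
        coords, t_entry = _segment_voxels(c0, c1)
    coords = np.clip(coords, 0, np.array(vol.shape) - 1)
    source = vol.smoothed if smooth else vol.data
    values = source[coords[:, 0], coords[:, 1], coords[:, 2]]
    w0 = start_mm + s0 * (end_mm - start_mm)
    w1 = start_mm + s1 * (end_mm - start_mm)
    offset = float(np.linalg.norm(w0 - start_mm))
    seg_len = float(np.linalg.norm(w1 - w0))
    positions = offset + t_entry * seg_len
    return HUProfile(positions, values, coords)
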