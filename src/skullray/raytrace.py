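"""Per-channel skull-crossing raytrace and sonication-efficiency aggregation.

Each transducer element casts a ray at the sonication target.  The trace

1. finds the outer-table collision by walking the (smoothed) HU profile until
   it enters the skull threshold window;
2. estimates the outer surface normal with a 5x5x5 Zucker-Hummel gradient
   operator and refracts the ray into the skull via Snell's law, deactivating
   the channel at or beyond the critical angle;
3. follows the refracted ray to the inner-table collision (profile leaves the
   window), with the inner normal flipped against the in-skull ray;
4. derives layer thickness, solidity, and region-specific density/speed from
   the HU profile between the two collisions, then composes the two interface
   transmissions with the bulk absorption into a total per-channel
   transmission.

Channel energies assume unit input power per element and a common phase;
sonication efficiency is the mean total transmission over active channels
(x100), and delivered energy is its sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import acoustics
from .acoustics import (
    AbsorptionParams,
    DensityCalibration,
    MediumProperties,
    VelocityCurve,
    absorption_fraction,
    hu_to_density,
    snell_refract,
    transmission_coefficient,
)
from .errors import DegenerateNormalError
from .phantom import TransducerArray
from .volume import CTVolume, HUProfile, hu_profile

__all__ = [
    "SimulationConfig",
    "ChannelResult",
    "SonicationResult",
    "find_collision",
    "surface_normal",
    "solidity",
    "trace_channel",
    "simulate",
    "channel_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the transcranial transmission model."""

    skull_window: tuple[float, float] = (1155.0, 3000.0)
    density_cal: DensityCalibration = field(default_factory=DensityCalibration)
    velocity_curve: VelocityCurve = field(default_factory=VelocityCurve)
    absorption: AbsorptionParams = field(default_factory=AbsorptionParams)
    mode: str = "intensity"
    smooth: bool = True
    water: MediumProperties = acoustics.WATER
    brain: MediumProperties = acoustics.BRAIN

    def __post_init__(self) -> None:
        lo, hi = self.skull_window
        if not lo < hi:
            raise ValueError("skull window lower bound must be below upper bound")
        if self.mode not in ("intensity", "pressure"):
            raise ValueError("mode must be 'intensity' or 'pressure'")


@dataclass
class ChannelResult:
    """Trace record of a single transducer element."""

    element_id: int
    active: bool
    inactive_reason: str = "none"
    p_outer: np.ndarray | None = None
    p_inner: np.ndarray | None = None
    theta_i_ws: float = np.nan
    theta_t_ws: float = np.nan
    theta_i_sb: float = np.nan
    theta_t_sb: float = np.nan
    thickness_mm: float = 0.0
    mu: float = np.nan
    skull_rho: float = np.nan
    skull_c: float = np.nan
    t_ws: float = np.nan
    t_sb: float = np.nan
    ap: float = np.nan
    t_total: float = 0.0


@dataclass
class SonicationResult:
    """Aggregate over all channels of one simulated sonication."""

    channels: list[ChannelResult]
    efficiency_pct: float
    active_count: int
    delivered_energy: float

    @classmethod
    def from_channels(cls, channels: list[ChannelResult]) -> "SonicationResult":
        active = [ch for ch in channels if ch.active]
        delivered = float(sum(ch.t_total for ch in active))
        n = len(active)
        efficiency = 100.0 * delivered / n if n else 0.0
        return cls(channels, efficiency, n, delivered)

    def summary(self) -> dict:
        return {
            "efficiency_pct": self.efficiency_pct,
            "active_count": self.active_count,
            "delivered_energy": self.delivered_energy,
        }


def channel_table(result: SonicationResult) -> pd.DataFrame:
    """One row per element with all ChannelResult fields (CSV-friendly)."""
    rows = []
    for ch in result.channels:
        rows.append(
            {
                "element_id": ch.element_id,
                "active": ch.active,
                "inactive_reason": ch.inactive_reason,
                "p_outer_x": np.nan if ch.p_outer is None else ch.p_outer[0],
                "p_outer_y": np.nan if ch.p_outer is None else ch.p_outer[1],
                "p_outer_z": np.nan if ch.p_outer is None else ch.p_outer[2],
                "p_inner_x": np.nan if ch.p_inner is None else ch.p_inner[0],
                "p_inner_y": np.nan if ch.p_inner is None else ch.p_inner[1],
                "p_inner_z": np.nan if ch.p_inner is None else ch.p_inner[2],
                "theta_i_ws": ch.theta_i_ws,
                "theta_t_ws": ch.theta_t_ws,
                "theta_i_sb": ch.theta_i_sb,
                "theta_t_sb": ch.theta_t_sb,
                "thickness_mm": ch.thickness_mm,
                "mu": ch.mu,
                "skull_rho": ch.skull_rho,
                "skull_c": ch.skull_c,
                "t_ws": ch.t_ws,
                "t_sb": ch.t_sb,
                "ap": ch.ap,
                "t_total": ch.t_total,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Collision detection
# ---------------------------------------------------------------------------


def _ray_far_point(vol: CTVolume, origin_mm: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """A point on the ray safely beyond the volume's bounding box."""
    corner0 = vol.voxel_to_world(np.full(3, -0.5))
    corner1 = vol.voxel_to_world(np.array(vol.shape) - 0.5)
    center = 0.5 * (corner0 + corner1)
    reach = float(np.linalg.norm(origin_mm - center) + np.linalg.norm(corner1 - corner0)) + 1.0
    return origin_mm + direction * reach


def _sample_midpoints(positions: np.ndarray) -> np.ndarray:
    """Chord-midpoint arc lengths for profile samples.

    Profile positions mark each voxel's segment-entry point, but the sampled
    (smoothed) HU belongs to the whole chord through the voxel; anchoring the
    value at the chord midpoint removes a direction-dependent half-chord bias
    (the chord is 1 voxel long along an axis but sqrt(3) along a diagonal).
    """
    if len(positions) == 1:
        return positions.astype(float)
    mids = np.empty_like(positions, dtype=float)
    mids[:-1] = 0.5 * (positions[:-1] + positions[1:])
    mids[-1] = positions[-1] + 0.5 * (positions[-1] - positions[-2])
    return mids


def _interp_crossing(positions: np.ndarray, values: np.ndarray, k: int, level: float) -> float:
    """Arc-length position where the profile crosses ``level`` between k-1 and k."""
    if k == 0:
        return float(positions[0])
    p0, p1 = positions[k - 1], positions[k]
    v0, v1 = values[k - 1], values[k]
    if v1 == v0:
        return float(p1)
    frac = (level - v0) / (v1 - v0)
    return float(p0 + np.clip(frac, 0.0, 1.0) * (p1 - p0))


def find_collision(
    vol: CTVolume,
    origin_mm,
    direction,
    window: tuple[float, float],
    sense: str = "entering",
    smooth: bool = True,
) -> np.ndarray | None:
    """First threshold crossing of the HU profile along a ray, in world mm.

    ``entering``: the first point where the profile enters [lo, hi];
    ``exiting``: the first point where it leaves the window after having been
    inside.  The crossing is located to sub-voxel precision by linear
    interpolation between adjacent profile samples.  Returns None when the ray
    never produces the requested event inside the volume.
    """
    if sense not in ("entering", "exiting"):
        raise ValueError("sense must be 'entering' or 'exiting'")
    origin_mm = np.asarray(origin_mm, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    lo, hi = window
    profile = hu_profile(vol, origin_mm, _ray_far_point(vol, origin_mm, direction), smooth=smooth)
    if len(profile) == 0:
        return None
    inside = (profile.values >= lo) & (profile.values <= hi)
    if not inside.any():
        return None
    mids = _sample_midpoints(profile.positions)
    if sense == "entering":
        k = int(np.argmax(inside))
        level = lo if k == 0 or profile.values[k - 1] < lo else hi
    else:
        k_in = int(np.argmax(inside))
        outside_after = ~inside[k_in:]
        if not outside_after.any():
            return None
        k = k_in + int(np.argmax(outside_after))
        level = lo if profile.values[k] < lo else hi
    pos = _interp_crossing(mids, profile.values, k, level)
    return origin_mm + direction * pos


# ---------------------------------------------------------------------------
# Surface normal (Zucker-Hummel 5x5x5 gradient operator)
# ---------------------------------------------------------------------------


def _zucker_hummel_kernels() -> np.ndarray:
    """Radius-2 Zucker-Hummel kernels: per-axis weight = offset / |offset|^2."""
    off = np.arange(-2, 3)
    ox, oy, oz = np.meshgrid(off, off, off, indexing="ij")
    r2 = (ox * ox + oy * oy + oz * oz).astype(float)
    r2[2, 2, 2] = 1.0  # center weight is zero anyway
    kernels = np.stack([ox / r2, oy / r2, oz / r2])
    kernels[:, 2, 2, 2] = 0.0
    return kernels


_ZH_KERNELS = _zucker_hummel_kernels()


def surface_normal(vol: CTVolume, point_mm, incoming_dir) -> np.ndarray:
    """Unit surface normal at a point from the 5x5x5 intensity gradient.

    The gradient is evaluated on the raw HU around the voxel nearest to
    ``point_mm`` and sign-flipped if needed so that it opposes
    ``incoming_dir`` (dot < 0), which handles the inner-table case where the
    intensity gradient points back along the ray.
    """
    point_mm = np.asarray(point_mm, dtype=float)
    incoming_dir = np.asarray(incoming_dir, dtype=float)
    c = np.rint(vol.world_to_voxel(point_mm)).astype(int)
    if not vol.contains_voxel(c):
        raise IndexError(f"point {point_mm.tolist()} maps outside the volume")
    lo = np.maximum(c - 2, 0)
    hi = np.minimum(c + 3, vol.shape)
    window = vol.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    klo = lo - (c - 2)
    khi = klo + (hi - lo)
    kern = _ZH_KERNELS[:, klo[0] : khi[0], klo[1] : khi[1], klo[2] : khi[2]]
    grad = kern.reshape(3, -1) @ window.reshape(-1)
    # gradient is in index space; convert to world (mm) gradient for anisotropic voxels
    grad = grad / vol.spacing
    norm = float(np.linalg.norm(grad))
    scale = float(np.abs(window).max()) + 1.0
    if norm < 1e-9 * scale:
        raise DegenerateNormalError(f"intensity gradient vanishes near {point_mm.tolist()}")
    n = grad / norm
    if float(np.dot(n, incoming_dir)) > 0:
        n = -n
    return n


# ---------------------------------------------------------------------------
# Solidity
# ---------------------------------------------------------------------------


def _local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices that are >= both existing neighbors (endpoints included)."""
    n = len(values)
    left_ok = np.ones(n, dtype=bool)
    right_ok = np.ones(n, dtype=bool)
    left_ok[1:] = values[1:] >= values[:-1]
    right_ok[:-1] = values[:-1] >= values[1:]
    return np.where(left_ok & right_ok)[0]


def solidity(profile: HUProfile, seg_start_mm: float, seg_end_mm: float) -> float:
    """Skull solidity mu: profile area over filled (peak-height) area.

    The integration bounds are the first and last local maxima of the profile
    inside [seg_start_mm, seg_end_mm] (the two cortical-table peaks); with
    fewer than two maxima the segment endpoints are used instead.  Result is
    clamped to (0, 1].
    """
    sel = (profile.positions >= seg_start_mm) & (profile.positions <= seg_end_mm)
    pos = profile.positions[sel]
    val = profile.values[sel]
    if len(pos) < 2:
        raise ValueError("solidity needs >= 2 profile samples inside the segment")
    maxima = _local_maxima(val)
    if len(maxima) >= 2:
        i0, i1 = int(maxima[0]), int(maxima[-1])
    else:
        logger.debug("solidity: fewer than 2 local maxima, falling back to segment endpoints")
        i0, i1 = 0, len(pos) - 1
    if i1 <= i0:
        return 1.0
    span = pos[i0 : i1 + 1]
    curve = val[i0 : i1 + 1]
    width = float(span[-1] - span[0])
    peak = float(curve.max())
    if width <= 0 or peak <= 0:
        return 1.0
    mu = float(np.trapezoid(curve, span) / (peak * width))
    return float(np.clip(mu, 1e-6, 1.0))


# ---------------------------------------------------------------------------
# Channel trace
# ---------------------------------------------------------------------------


def _skull_medium(mean_hu: float, cfg: SimulationConfig) -> MediumProperties:
    rho = hu_to_density(mean_hu, cfg.density_cal)
    return MediumProperties(rho=rho, c=cfg.velocity_curve(rho))


def _theta(direction: np.ndarray, normal: np.ndarray) -> float:
    return float(np.arccos(np.clip(-np.dot(direction, normal), -1.0, 1.0)))


def trace_channel(vol: CTVolume, element_mm, target_mm, cfg: SimulationConfig = SimulationConfig()) -> ChannelResult:
    """Trace one element's ray to the target through the skull layer."""
    element_mm = np.asarray(element_mm, dtype=float)
    target_mm = np.asarray(target_mm, dtype=float)
    tgt_vox = vol.world_to_voxel(target_mm)
    if not np.all((tgt_vox >= -0.5) & (tgt_vox <= np.array(vol.shape) - 0.5)):
        raise ValueError(f"target {target_mm.tolist()} lies outside the volume")
    d0 = target_mm - element_mm
    d0 = d0 / np.linalg.norm(d0)
    element_id = -1  # set by simulate()

    p_outer = find_collision(vol, element_mm, d0, cfg.skull_window, "entering", smooth=cfg.smooth)
    if p_outer is None:
        # pure water path: full transmission by policy
        return ChannelResult(element_id, active=True, t_total=1.0, t_ws=1.0, t_sb=1.0, ap=0.0)

    try:
        n_outer = surface_normal(vol, p_outer, d0)
    except DegenerateNormalError:
        logger.debug("degenerate outer normal at %s", p_outer)
        return ChannelResult(element_id, active=False, inactive_reason="degenerate_normal", p_outer=p_outer)
    theta_i_ws = _theta(d0, n_outer)

    # provisional skull speed from the straight path (for the refraction step)
    lo, hi = cfg.skull_window
    straight = hu_profile(vol, p_outer, target_mm, smooth=cfg.smooth)
    in_win = straight.values[(straight.values >= lo) & (straight.values <= hi)]
    prov_hu = float(in_win.mean()) if len(in_win) else float(straight.values.mean())
    skull_prov = _skull_medium(prov_hu, cfg)

    d_in = snell_refract(d0, n_outer, cfg.water.c, skull_prov.c)
    if d_in is None:
        return ChannelResult(
            element_id,
            active=False,
            inactive_reason="critical_angle",
            p_outer=p_outer,
            theta_i_ws=theta_i_ws,
        )

    p_inner = find_collision(vol, p_outer, d_in, cfg.skull_window, "exiting", smooth=cfg.smooth)
    if p_inner is None:
        return ChannelResult(
            element_id,
            active=False,
            inactive_reason="no_inner_collision",
            p_outer=p_outer,
            theta_i_ws=theta_i_ws,
        )
    try:
        n_inner = surface_normal(vol, p_inner, d_in)
    except DegenerateNormalError:
        logger.debug("degenerate inner normal at %s", p_inner)
        return ChannelResult(
            element_id, active=False, inactive_reason="degenerate_normal", p_outer=p_outer, p_inner=p_inner
        )
    theta_i_sb = _theta(d_in, n_inner)

    thickness = float(np.linalg.norm(p_inner - p_outer))
    layer = hu_profile(vol, p_outer, p_inner, smooth=cfg.smooth)
    if len(layer) >= 2:
        mu = solidity(layer, float(layer.positions[0]), float(layer.positions[-1]))
        mean_hu = float(layer.values.mean())
    else:
        mu = 1.0
        mean_hu = float(layer.values.mean()) if len(layer) else prov_hu
    skull = _skull_medium(mean_hu, cfg)

    t_ws = transmission_coefficient(theta_i_ws, cfg.water, skull, mode=cfg.mode)
    if t_ws == 0.0:
        return ChannelResult(
            element_id,
            active=False,
            inactive_reason="critical_angle",
            p_outer=p_outer,
            p_inner=p_inner,
            theta_i_ws=theta_i_ws,
        )
    t_sb = transmission_coefficient(theta_i_sb, skull, cfg.brain, mode=cfg.mode)
    _, ap = absorption_fraction(mu, thickness, cfg.absorption)
    if cfg.mode == "intensity":
        t_total = acoustics.total_transmission(t_ws, ap, t_sb)
    else:
        t_total = float(t_ws * (1.0 - ap) * t_sb)

    sin_t_ws = (skull.c / cfg.water.c) * np.sin(theta_i_ws)
    sin_t_sb = (cfg.brain.c / skull.c) * np.sin(theta_i_sb)
    return ChannelResult(
        element_id,
        active=True,
        p_outer=p_outer,
        p_inner=p_inner,
        theta_i_ws=theta_i_ws,
        theta_t_ws=float(np.arcsin(np.clip(sin_t_ws, -1.0, 1.0))),
        theta_i_sb=theta_i_sb,
        theta_t_sb=float(np.arcsin(np.clip(sin_t_sb, -1.0, 1.0))),
        thickness_mm=thickness,
        mu=mu,
        skull_rho=skull.rho,
        skull_c=skull.c,
        t_ws=t_ws,
        t_sb=t_sb,
        ap=ap,
        t_total=t_total,
    )


def simulate(vol: CTVolume, tx: TransducerArray, target_mm, cfg: SimulationConfig = SimulationConfig()) -> SonicationResult:
    """Trace every active element and aggregate into a sonication result.

    Unit input power per channel; per-channel failures deactivate that channel
    and never abort the aggregate.
    """
    if len(tx) == 0:
        raise ValueError("transducer array is empty")
    target_mm = np.asarray(target_mm, dtype=float)
    tgt_vox = vol.world_to_voxel(target_mm)
    if not np.all((tgt_vox >= -0.5) & (tgt_vox <= np.array(vol.shape) - 0.5)):
        raise ValueError(f"target {target_mm.tolist()} lies outside the volume")
    channels: list[ChannelResult] = []
    for eid, pos, on in zip(tx.element_ids, tx.positions, tx.active):
        if not on:
            continue
        try:
            ch = trace_channel(vol, pos, target_mm, cfg)
        except Exception as exc:  # noqa: BLE001 - per-channel isolation by contract
            logger.debug("channel %d failed: %s", eid, exc)
            ch = ChannelResult(int(eid), active=False, inactive_reason="trace_error")
        ch.element_id = int(eid)
        channels.append(ch)
    return SonicationResult.from_channels(channels)
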