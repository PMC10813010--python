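"""Transducer tilt-grid scan: rotate, re-simulate, and report the optimum.

The transducer is rigidly rotated about the sonication target over a 2D grid
of frontal-axis (x) and sagittal-axis (y) angles, by default +/-15 degrees,
the mechanical tilting limit of the clinical frame.  Each grid point is a full
re-simulation; the cell maximizing delivered energy is the recommended tilt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .phantom import TransducerArray
from .raytrace import SimulationConfig, SonicationResult, simulate
from .volume import CTVolume

__all__ = [
    "TiltGrid",
    "TiltScanResult",
    "rotate_transducer",
    "tilt_scan",
    "improvement_report",
    "plot_tilt_map",
]

logger = logging.getLogger(__name__)

TILT_LIMIT_DEG = 15.0


def _default_angles() -> tuple[float, ...]:
    return tuple(float(a) for a in range(-int(TILT_LIMIT_DEG), int(TILT_LIMIT_DEG) + 1))


@dataclass(frozen=True)
class TiltGrid:
    """Frontal (x) and sagittal (y) tilt angles, degrees; must contain 0."""

    ax_deg: tuple[float, ...] = field(default_factory=_default_angles)
    ay_deg: tuple[float, ...] = field(default_factory=_default_angles)

    def __post_init__(self) -> None:
        if len(self.ax_deg) == 0 or len(self.ay_deg) == 0:
            raise ValueError("tilt grid must be non-empty")
        if 0.0 not in self.ax_deg or 0.0 not in self.ay_deg:
            raise ValueError("tilt grid must contain the reference angle 0 on both axes")

    @classmethod
    def from_range(cls, limit_deg: float = TILT_LIMIT_DEG, step_deg: float = 1.0) -> "TiltGrid":
        angles = np.arange(-limit_deg, limit_deg + step_deg / 2, step_deg)
        if not np.any(np.isclose(angles, 0.0)):
            raise ValueError("range does not contain 0; pick a step dividing the limit")
        angles = tuple(float(a) for a in np.where(np.isclose(angles, 0.0), 0.0, angles))
        return cls(angles, angles)


@dataclass
class TiltScanResult:
    """Per-angle sonication summaries plus reference/best/worst cells."""

    cells: dict[tuple[float, float], dict]
    reference_key: tuple[float, float]
    best_key: tuple[float, float]
    worst_key: tuple[float, float]
    reference_result: SonicationResult | None = None

    @property
    def reference(self) -> dict:
        return self.cells[self.reference_key]

    @property
    def best(self) -> dict:
        return self.cells[self.best_key]

    @property
    def worst(self) -> dict:
        return self.cells[self.worst_key]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"ax_deg": ax, "ay_deg": ay, **summary}
            for (ax, ay), summary in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows)


def rotate_transducer(tx: TransducerArray, ax_deg: float, ay_deg: float, pivot_mm=None) -> TransducerArray:
    """Rigidly rotate all element positions: Rx(ax) then Ry(ay) about the pivot.

    The pivot defaults to the geometric focus (the sonication target), so the
    focus stays on-target while tilting.  Zero angles return the positions
    unchanged bit-for-bit.
    """
    if not np.isfinite(ax_deg) or not np.isfinite(ay_deg):
        raise ValueError("tilt angles must be finite")
    if ax_deg == 0.0 and ay_deg == 0.0:
        return TransducerArray(tx.element_ids.copy(), tx.positions.copy(), tx.focus_mm.copy(), tx.active.copy())
    pivot = np.asarray(tx.focus_mm if pivot_mm is None else pivot_mm, dtype=float)
    rot = Rotation.from_euler("xy", [ax_deg, ay_deg], degrees=True).as_matrix()
    positions = pivot + (tx.positions - pivot) @ rot.T
    focus = pivot + rot @ (tx.focus_mm - pivot)
    return TransducerArray(tx.element_ids.copy(), positions, focus, tx.active.copy())


def tilt_scan(
    vol: CTVolume,
    tx: TransducerArray,
    target_mm,
    grid: TiltGrid = TiltGrid(),
    cfg: SimulationConfig = SimulationConfig(),
    progress: bool = False,
) -> TiltScanResult:
    """Simulate one sonication per grid angle pair and locate best/worst tilts.

    Per-angle failures are logged and leave the cell missing; the reference
    cell (0, 0) is a plain simulation of the untilted transducer.
    """
    target_mm = np.asarray(target_mm, dtype=float)
    cells: dict[tuple[float, float], dict] = {}
    reference_result = None
    for ax in grid.ax_deg:
        for ay in grid.ay_deg:
            try:
                rotated = rotate_transducer(tx, ax, ay, pivot_mm=target_mm)
                result = simulate(vol, rotated, target_mm, cfg)
            except Exception as exc:  # noqa: BLE001 - per-cell isolation by contract
                logger.warning("tilt (%g, %g) failed: %s", ax, ay, exc)
                continue
            cells[(float(ax), float(ay))] = result.summary()
            if ax == 0.0 and ay == 0.0:
                reference_result = result
            if progress:
                logger.info(
                    "tilt (%+g, %+g): efficiency %.4g%%, active %d, delivered %.6g",
                    ax, ay, result.efficiency_pct, result.active_count, result.delivered_energy,
                )
    if (0.0, 0.0) not in cells:
        raise ValueError("reference cell (0, 0) failed; scan result undefined")
    ordered = sorted(cells.items())
    best_key = max(ordered, key=lambda kv: kv[1]["delivered_energy"])[0]
    worst_key = min(ordered, key=lambda kv: kv[1]["delivered_energy"])[0]
    return TiltScanResult(cells, (0.0, 0.0), best_key, worst_key, reference_result)


def improvement_report(result: TiltScanResult) -> dict:
    """Percent improvement of the best tilt and decrease of the worst tilt.

    Both are relative to the untilted reference and are >= 0 by construction of
    the argmax/argmin.
    """
    ref = result.reference["delivered_energy"]
    if ref == 0:
        raise ValueError("reference delivered energy is zero; improvement undefined")
    best = result.best["delivered_energy"]
    worst = result.worst["delivered_energy"]
    return {
        "reference": {"angles_deg": list(result.reference_key), **result.reference},
        "best": {"angles_deg": list(result.best_key), **result.best},
        "worst": {"angles_deg": list(result.worst_key), **result.worst},
        "improvement_pct": 100.0 * (best - ref) / ref,
        "decrease_pct": 100.0 * (ref - worst) / ref,
    }


def plot_tilt_map(result: TiltScanResult, path, quantity: str = "delivered_energy"):
    """Heat map of a scan quantity over the tilt grid, saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.to_dataframe()
    pivot = df.pivot(index="ay_deg", columns="ax_deg", values=quantity)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(
        pivot.to_numpy(),
        origin="lower",
        extent=(min(pivot.columns), max(pivot.columns), min(pivot.index), max(pivot.index)),
        aspect="auto",
    )
    ax.set_xlabel("frontal tilt (deg)")
    ax.set_ylabel("sagittal tilt (deg)")
    ax.set_title(quantity)
    for key, marker, color in ((result.reference_key, "x", "white"), (result.best_key, "P", "tab:blue"), (result.worst_key, "X", "tab:red")):
        ax.plot(key[0], key[1], marker, color=color, markersize=10)
    fig.colorbar(im, ax=ax)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
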