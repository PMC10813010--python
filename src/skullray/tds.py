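"""Treatment difficulty score (TDS) from per-sonication treatment records.

A treatment record lists, per sonication, the delivered energy (kJ), the focal
temperature rise (degC), and whether the sonication was aborted.  Heating
efficiency is temperature rise per unit energy (degC/kJ) over completed
sonications.  The TDS combines four cohort-normalized factors:

    TDS = w1 * norm_inv(he_mean) + w2 * norm(he_std)
        + w3 * norm(aborted_count) + w4 * norm(total_count)

where norm is min-max normalization across the analyzed cohort and the
heating-efficiency mean enters inverted (norm_inv(x) = (max - x)/(max - min)),
so that efficient, stable, short treatments score low.  Scores are therefore
cohort-relative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError

__all__ = [
    "TDSWeights",
    "heating_efficiency",
    "compute_features",
    "tds_scores",
    "correlation_matrix",
]

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ["he_mean", "he_std", "aborted_count", "total_count"]


@dataclass(frozen=True)
class TDSWeights:
    """Factor weights: heating-efficiency mean, its std, aborts, total count."""

    w1: float = 1.0
    w2: float = 0.25
    w3: float = 0.25
    w4: float = 0.5

    def __post_init__(self) -> None:
        if min(self.w1, self.w2, self.w3, self.w4) < 0:
            raise ValueError("TDS weights must be >= 0")


def heating_efficiency(table: pd.DataFrame, treatment_id) -> tuple[float, float]:
    """Mean and population-sd heating efficiency (degC/kJ) of one treatment.

    Only completed (non-aborted) sonications contribute.
    """
    rows = table[(table["treatment_id"] == treatment_id) & (~table["aborted"].astype(bool))]
    if len(rows) == 0:
        raise InsufficientDataError(f"treatment {treatment_id!r} has no completed sonications")
    he = rows["delta_t_c"].to_numpy(dtype=float) / rows["energy_kj"].to_numpy(dtype=float)
    return float(he.mean()), float(he.std(ddof=0))


def compute_features(table: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment factors: he_mean, he_std, aborted_count, total_count."""
    rows = []
    for tid, grp in table.groupby("treatment_id"):
        he_mean, he_std = heating_efficiency(table, tid)
        aborted = int(grp["aborted"].astype(bool).sum())
        rows.append({"treatment_id": tid, "he_mean": he_mean, "he_std": he_std,
                     "aborted_count": aborted, "total_count": int(len(grp))})
    return pd.DataFrame(rows).set_index("treatment_id")


def _minmax(x: np.ndarray, invert: bool = False) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        logger.warning("constant factor across cohort; normalized contribution set to 0")
        return np.zeros_like(x, dtype=float)
    return (hi - x) / (hi - lo) if invert else (x - lo) / (hi - lo)


def tds_scores(features: pd.DataFrame, weights: TDSWeights = TDSWeights()) -> pd.Series:
    """Weighted sum of cohort-normalized difficulty factors, one per treatment.

    Needs >= 2 treatments for min-max normalization to be defined.  The
    heating-efficiency mean is inverted (higher efficiency lowers difficulty).
    """
    if len(features) < 2:
        raise InsufficientDataError("TDS normalization needs at least 2 treatments")
    he_mean = features["he_mean"].to_numpy(dtype=float)
    he_std = features["he_std"].to_numpy(dtype=float)
    aborted = features["aborted_count"].to_numpy(dtype=float)
    total = features["total_count"].to_numpy(dtype=float)
    score = (
        weights.w1 * _minmax(he_mean, invert=True)
        + weights.w2 * _minmax(he_std)
        + weights.w3 * _minmax(aborted)
        + weights.w4 * _minmax(total)
    )
    return pd.Series(score, index=features.index, name="tds")


def correlation_matrix(features: pd.DataFrame, weights: TDSWeights = TDSWeights()) -> pd.DataFrame:
    """4x4 Pearson correlation over (he_mean, aborted_count, total_count, TDS).

    Symmetric with unit diagonal.  Raises on fewer than 3 treatments or on a
    constant column (undefined correlation), naming the offending column.
    """
    if len(features) < 3:
        raise InsufficientDataError("correlation needs at least 3 treatments")
    df = features[["he_mean", "aborted_count", "total_count"]].astype(float).copy()
    df["tds"] = tds_scores(features, weights)
    for col in df.columns:
        if df[col].nunique() <= 1:
            raise InsufficientDataError(f"column {col!r} is constant; correlation undefined")
    return df.corr(method="pearson")
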