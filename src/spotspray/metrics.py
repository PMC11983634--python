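"""Bench evaluation metrics and model-comparison arithmetic.

Rates follow the water-sensitive-paper protocol: recognition rate is
detected weeds over all weeds, spraying rate is wetted (paper turned
red) weeds over detected weeds, and hit rate is their product. Coverage
relates weed length to discoloration length; targeting error is the
offset between weed center and discoloration center, summarized as MAE
and RMSE. Report tables use one decimal place in percent (errors in
cm); internal values stay unrounded.

Aggregation over trials pools raw counts before taking ratios, so the
campaign hit rate equals the product of the pooled recognition and
spraying rates.

The model-comparison helpers (:func:`percent_reduction`,
:func:`metric_delta`) do the ablation-table arithmetic on externally
reported detector figures (GFLOPs, model size, mAP, F1); no detector is
trained or evaluated here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialMetrics",
    "AblationRow",
    "recognition_rate",
    "spraying_rate",
    "hit_rate",
    "coverage_rate",
    "targeting_errors",
    "percent_reduction",
    "metric_delta",
    "spray_table",
    "coverage_table",
    "ablation_table",
    "write_metrics_tsv",
    "read_metrics_tsv",
]

Interval = tuple[float, float]


@dataclass(frozen=True)
class TrialMetrics:
    """Pooled metrics for one speed interval (or one trial)."""

    recognition_rate: float
    spraying_rate: float
    hit_rate: float
    coverage_rate: float
    mae: float  # meters
    rmse: float  # meters

    def __post_init__(self) -> None:
        for name in ("recognition_rate", "spraying_rate", "hit_rate", "coverage_rate"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if not (self.rmse >= self.mae >= 0 or math.isnan(self.mae)):
            raise ValueError("need rmse >= mae >= 0")


@dataclass(frozen=True)
class AblationRow:
    """One detector variant's externally reported cost/accuracy figures."""

    model: str
    gflops: float
    size_kb: float
    map_pct: float
    f1_pct: float

    def __post_init__(self) -> None:
        if min(self.gflops, self.size_kb, self.map_pct, self.f1_pct) <= 0:
            raise ValueError("ablation figures must be positive")


def recognition_rate(n_detected: int, n_total: int) -> float:
    """Detected weeds over all weeds."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if n_detected > n_total:
        raise ValueError("n_detected cannot exceed n_total")
    return n_detected / n_total


def spraying_rate(n_wetted_detected: int, n_detected: int) -> float:
    """Wetted detected weeds over detected weeds (0, with a warning, if
    nothing was detected)."""
    if n_detected == 0:
        warnings.warn("spraying_rate with zero detected weeds; returning 0", stacklevel=2)
        return 0.0
    if n_wetted_detected > n_detected:
        raise ValueError("n_wetted_detected cannot exceed n_detected")
    return n_wetted_detected / n_detected


def hit_rate(recognition: float, spraying: float) -> float:
    """Product of recognition and spraying rates."""
    if not (0.0 <= recognition <= 1.0 and 0.0 <= spraying <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    return recognition * spraying


def coverage_rate(
    weed_span: Interval,
    discoloration_span: Interval | None,
    mode: str = "as_printed",
) -> float:
    """Coverage of one weed by its discoloration mark.

    ``as_printed`` divides the weed length by the discoloration length
    (capped at 1) — the bench protocol's stated ratio, kept verbatim even
    though it reads inverted: a mark *longer* than the weed scores below
    1. ``overlap`` scores the fraction of the weed span actually covered:
    |discoloration ∩ weed| / |weed|. Both are 0 without discoloration.
    """
    w0, w1 = weed_span
    if not w1 > w0:
        raise ValueError("weed span must have positive length")
    if discoloration_span is None:
        return 0.0
    d0, d1 = discoloration_span
    dlen = max(d1 - d0, 0.0)
    if mode == "as_printed":
        if dlen == 0:
            return 0.0
        return min((w1 - w0) / dlen, 1.0)
    if mode == "overlap":
        inter = min(w1, d1) - max(w0, d0)
        return max(inter, 0.0) / (w1 - w0)
    raise ValueError("mode must be 'as_printed' or 'overlap'")


def targeting_errors(offsets: Sequence[float]) -> tuple[float, float]:
    """(MAE, RMSE) of center offsets, meters."""
    if len(offsets) == 0:
        raise ValueError("offsets must be nonempty")
    arr = np.asarray(offsets, dtype=float)
    mae = float(np.mean(np.abs(arr)))
    rmse = float(np.sqrt(np.mean(arr**2)))
    return mae, rmse


def percent_reduction(before: float, after: float) -> float:
    """100 * (before - after) / before, to one decimal."""
    if before <= 0:
        raise ValueError("before must be > 0")
    return round(100.0 * (before - after) / before, 1)


def metric_delta(a: float, b: float) -> float:
    """a - b in percentage points, to one decimal."""
    return round(a - b, 1)


# ---------------------------------------------------------------------------
# report tables


def spray_table(rows: dict[str, tuple[int, int, int]]) -> pd.DataFrame:
    """Spray-performance table from pooled counts per speed range.

    ``rows`` maps a speed-range label to (n_total, n_detected,
    n_wetted_detected). Percentages to one decimal.
    """
    recs = []
    for label, (n_total, n_det, n_wet) in rows.items():
        r = recognition_rate(n_det, n_total)
        s = spraying_rate(n_wet, n_det)
        recs.append(
            {
                "speed_range_m_s": label,
                "recognition_rate_pct": round(100 * r, 1),
                "spraying_rate_pct": round(100 * s, 1),
                "hit_rate_pct": round(100 * hit_rate(r, s), 1),
            }
        )
    return pd.DataFrame(recs)


def coverage_table(rows: dict[str, tuple[float, Sequence[float]]]) -> pd.DataFrame:
    """Coverage/error table: label -> (mean coverage fraction, offsets[m]).

    Errors are reported in centimeters, everything to one decimal.
    """
    recs = []
    for label, (cov, offsets) in rows.items():
        mae, rmse = targeting_errors(offsets)
        recs.append(
            {
                "speed_range_m_s": label,
                "coverage_rate_pct": round(100 * cov, 1),
                "mae_cm": round(100 * mae, 1),
                "rmse_cm": round(100 * rmse, 1),
            }
        )
    return pd.DataFrame(recs)


def ablation_table(rows: Sequence[AblationRow], baseline: str) -> pd.DataFrame:
    """Cost/accuracy comparison against a named baseline row.

    Adds percent reductions of GFLOPs and size and percentage-point mAP/F1
    deltas relative to the baseline.
    """
    base = next((r for r in rows if r.model == baseline), None)
    if base is None:
        raise ValueError(f"baseline {baseline!r} not among rows")
    recs = []
    for r in rows:
        recs.append(
            {
                "model": r.model,
                "gflops": r.gflops,
                "size_kb": r.size_kb,
                "map_pct": r.map_pct,
                "f1_pct": r.f1_pct,
                "gflops_reduction_pct": percent_reduction(base.gflops, r.gflops),
                "size_reduction_pct": percent_reduction(base.size_kb, r.size_kb),
                "map_delta_pts": metric_delta(r.map_pct, base.map_pct),
                "f1_delta_pts": metric_delta(r.f1_pct, base.f1_pct),
            }
        )
    return pd.DataFrame(recs)


def write_metrics_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_metrics_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
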