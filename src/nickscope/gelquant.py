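"""Densitometric arithmetic for plasmid nicking and exonuclease assays.

A nicking assay separates plasmid topoisomers on an agarose gel:
supercoiled substrate, open-circular (nicked) product, and occasionally a
linear form.  Band intensities come from image densitometry (e.g. ImageJ)
as arbitrary units; this module implements the downstream arithmetic only:

* percent nicked = 100 * nicked / (supercoiled + nicked + linear) — all
  topoisomers in the lane form the denominator;
* background correction — the percent nicked of the matched no-protein
  control lane is subtracted, clamped at zero;
* fold stimulation = corrected(treated) / corrected(baseline);
* replicate mean and SEM (sample SD / sqrt(n); zero for n = 1) and the
  two-tailed t-test for comparing replicate percent vectors.

Exonuclease gels are quantified with the same fraction-of-signal
arithmetic via ``percent_degraded`` (product over substrate + product).

Background subtraction operates on percents, not raw intensities, and
negative corrected values clamp to zero — both are package conventions
where the underlying protocol leaves the choice open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LaneMeasurement",
    "QuantResult",
    "percent_nicked",
    "percent_degraded",
    "subtract_background",
    "fold_stimulation",
    "replicate_stats",
    "compare_replicates",
    "quantify_table",
]


@dataclass(frozen=True)
class LaneMeasurement:
    """Band intensities of one gel lane (arbitrary units, >= 0)."""

    lane: str
    supercoiled: float = 0.0
    nicked: float = 0.0
    linear: float = 0.0
    is_control: bool = False

    def __post_init__(self) -> None:
        for name in ("supercoiled", "nicked", "linear"):
            if getattr(self, name) < 0:
                raise ValueError(f"lane {self.lane!r}: negative {name} intensity")

    @property
    def total(self) -> float:
        return self.supercoiled + self.nicked + self.linear


@dataclass(frozen=True)
class QuantResult:
    lane: str
    raw_percent: float
    corrected_percent: float


def percent_nicked(lane: LaneMeasurement) -> float:
    """Percentage of nicked DNA versus the total DNA in the lane."""
    if lane.total <= 0:
        raise ValueError(f"lane {lane.lane!r} has zero total intensity")
    return 100.0 * lane.nicked / lane.total


def percent_degraded(substrate: float, product: float) -> float:
    """Fraction-of-signal metric for exonuclease gels, as a percentage."""
    if substrate < 0 or product < 0:
        raise ValueError("intensities must be non-negative")
    total = substrate + product
    if total <= 0:
        raise ValueError("lane has zero total intensity")
    return 100.0 * product / total


def subtract_background(values, control: float):
    """Subtract the no-protein control percent, clamping at zero."""
    arr = np.asarray(values, dtype=float)
    corrected = np.maximum(arr - control, 0.0)
    if arr.ndim == 0:
        return float(corrected)
    return corrected


def fold_stimulation(treated: float, baseline: float) -> float:
    """Ratio of corrected percents; NaN (not-computable) if baseline is 0."""
    if baseline == 0:
        return math.nan
    return treated / baseline


def replicate_stats(values) -> tuple[float, float]:
    """Mean and SEM over independent replicates.

    SEM is the sample standard deviation (ddof=1) over sqrt(n); a single
    replicate has SEM 0 by convention (no spread is estimable).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("at least one replicate is required")
    mean = float(arr.mean())
    sem = 0.0 if arr.size == 1 else float(arr.std(ddof=1) / math.sqrt(arr.size))
    return mean, sem


def compare_replicates(a, b) -> float:
    """Two-tailed t-test p-value between two replicate percent vectors."""
    return float(stats.ttest_ind(np.asarray(a, float), np.asarray(b, float)).pvalue)


def quantify_table(
    bands: pd.DataFrame, control_lane: str | None = None
) -> pd.DataFrame:
    """Per-lane quantification of a band-intensity table.

    ``bands`` needs columns ``lane, supercoiled, nicked`` (``linear`` and
    ``is_control`` optional).  The control lane is taken from
    ``control_lane`` or the ``is_control`` flag; exactly one is required.
    Returns a DataFrame with ``lane, raw_percent, corrected_percent``.
    """
    df = bands.copy()
    if "linear" not in df.columns:
        df["linear"] = 0.0
    if control_lane is None:
        if "is_control" not in df.columns:
            raise ValueError("no control lane specified and no is_control column")
        controls = df.loc[df["is_control"], "lane"].tolist()
        if len(controls) != 1:
            raise ValueError(f"expected exactly one control lane, found {controls}")
        control_lane = controls[0]
    if control_lane not in set(df["lane"]):
        raise ValueError(f"control lane {control_lane!r} not in table")

    lanes = [
        LaneMeasurement(str(r.lane), float(r.supercoiled), float(r.nicked), float(r.linear))
        for r in df.itertuples(index=False)
    ]
    raw = {m.lane: percent_nicked(m) for m in lanes}
    control = raw[control_lane]
    return pd.DataFrame(
        {
            "lane": [m.lane for m in lanes],
            "raw_percent": [raw[m.lane] for m in lanes],
            "corrected_percent": [
                float(subtract_background(raw[m.lane], control)) for m in lanes
            ],
        }
    )
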