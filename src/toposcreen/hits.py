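"""Hit selection: rank TopoUnits and call top/bottom hits by median +/- k*SD.

The screen labels a unit ``high`` when its metric strictly exceeds
``median + k_top * SD`` and ``low`` when it falls strictly below
``median + k_bottom * SD`` (``k_bottom`` negative), with median and sample
standard deviation computed over the units where the metric is defined.
Default multiples per metric follow the screen's conventions: +2/-2 for the
differentiated-cell percentage, +2/-0.5 for spread area, +2/-1 for roundness.
A quantile rule is available as an alternative bottom threshold for skewed
metrics whose SD-based bottom cutoff falls below the metric's range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: (k_top, k_bottom) per metric
DEFAULT_K = {
    "pct_pos": (2.0, -2.0),
    "avg_spread_area_pos": (2.0, -0.5),
    "mean_roundness_pos": (2.0, -1.0),
}

METRICS = tuple(DEFAULT_K)


@dataclass
class HitResult:
    """Per-unit hit labels for one metric, plus the cutoffs used."""

    table: pd.DataFrame  # unit keys + value, label in {high, low, mid, excluded}
    metric: str
    top_cutoff: float
    bottom_cutoff: float

    @property
    def counts(self) -> dict[str, int]:
        return self.table["label"].value_counts().to_dict()


def select_hits(
    units: pd.DataFrame,
    metric: str,
    k_top: float | None = None,
    k_bottom: float | None = None,
    bottom_quantile: float | None = None,
    min_units: int = 10,
) -> HitResult:
    """Label every unit high/low/mid for ``metric``.

    Cutoffs are recomputed from the data: top = median + k_top*SD, bottom =
    median + k_bottom*SD, or the ``bottom_quantile`` of the defined values
    when given.  Units with an undefined metric (e.g. shape statistics of
    units without positive cells) are labeled ``excluded`` and do not enter
    the median/SD.  Strict inequalities on both sides.
    """
    if metric not in units.columns:
        raise KeyError(f"metric {metric!r} not in unit table")
    if k_top is None:
        k_top = DEFAULT_K.get(metric, (2.0, -2.0))[0]
    if k_bottom is None:
        k_bottom = DEFAULT_K.get(metric, (2.0, -2.0))[1]
    if k_top <= k_bottom:
        raise ValueError("k_top must exceed k_bottom")
    if len(units) - units[metric].isna().sum() < min_units:
        raise ValueError(
            f"need at least {min_units} units with a defined metric")

    values = units[metric].to_numpy(dtype=float)
    defined = ~np.isnan(values)
    vals = values[defined]
    med = float(np.median(vals))
    sd = float(np.std(vals, ddof=1))
    if sd == 0.0:
        warnings.warn(f"all {metric} values identical: no hits called",
                      stacklevel=2)
        top = np.inf
        bottom = -np.inf
    else:
        top = med + k_top * sd
        bottom = (float(np.quantile(vals, bottom_quantile))
                  if bottom_quantile is not None else med + k_bottom * sd)

    label = np.full(len(values), "mid", dtype=object)
    with np.errstate(invalid="ignore"):
        label[values > top] = "high"
        label[values < bottom] = "low"
    label[~defined] = "excluded"
    table = units.copy()
    table["value"] = values
    table["label"] = label
    table["top_cutoff"] = top
    table["bottom_cutoff"] = bottom
    return HitResult(table=table, metric=metric,
                     top_cutoff=top, bottom_cutoff=bottom)


def make_labels(hits_high: HitResult, hits_low: HitResult) -> pd.DataFrame:
    """Collapse unit-level hits to a binary design-level label table.

    A design is ``high`` if either of its duplicate units is high in
    ``hits_high`` and ``low`` if either is low in ``hits_low``; designs
    qualifying for both classes are excluded with a warning.  Returns a
    DataFrame ``(design_id, label)`` restricted to the hit designs.
    """
    t_hi, t_lo = hits_high.table, hits_low.table
    if set(zip(t_hi["row"], t_hi["col"])) != set(zip(t_lo["row"], t_lo["col"])):
        raise ValueError("hit tables cover different unit universes")
    high_ids = set(t_hi.loc[t_hi["label"] == "high", "design_id"])
    low_ids = set(t_lo.loc[t_lo["label"] == "low", "design_id"])
    conflicts = high_ids & low_ids
    if conflicts:
        warnings.warn(
            f"{len(conflicts)} designs qualify as both high and low; excluded",
            stacklevel=2)
    rows = [{"design_id": d, "label": "high"} for d in sorted(high_ids - conflicts)]
    rows += [{"design_id": d, "label": "low"} for d in sorted(low_ids - conflicts)]
    return pd.DataFrame(rows, columns=["design_id", "label"])
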