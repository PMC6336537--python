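"""Synthetic TopoChip screen with a planted topography -> phenotype model.

The generator emulates a keratinocyte differentiation screen: each TopoUnit
carries 5-25 cells; a unit's topography descriptors determine, through an
ordered rule list (the *planted model*), the probability that a cell
terminally differentiates (becomes TGM1-positive) and whether differentiated
cells adopt a round or a spread morphology.  Per-cell TGM1 median fluorescence
intensity (MFI) is bimodal: differentiated cells are bright, undifferentiated
cells dim, with the standard MFI > 270 cutoff falling between the modes.

Cell geometry is parameterized by (area, roundness); the perimeter follows
from the circularity identity ``roundness = 4*pi*area / perimeter**2``, so
``P = sqrt(4*pi*A / roundness)`` holds by construction.

Units can additionally be rendered into 3-channel fluorescence image stacks
(DAPI nuclei, F-actin cell bodies, TGM1) with a ground-truth label raster, so
the segmentation stage can be exercised end to end.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .library import ChipLayout, TopoUnitDesign, UnitMask
from .descriptors import library_descriptors

Expr = dict | list | tuple

_OPS = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
}


def eval_predicate(expr: Expr, dv: Mapping[str, float | None]) -> bool:
    """Evaluate a JSON-serializable predicate over a descriptor mapping.

    Grammar: ``{"all": [...]}, {"any": [...]}`` or a comparison triple
    ``[feature, op, threshold]`` with op one of ``< <= > >=``.  A comparison
    on an absent (None/NaN) descriptor is False.
    """
    if isinstance(expr, dict):
        if "all" in expr:
            return all(eval_predicate(e, dv) for e in expr["all"])
        if "any" in expr:
            return any(eval_predicate(e, dv) for e in expr["any"])
        raise ValueError(f"bad predicate node: {expr!r}")
    feature, op, threshold = expr
    value = dv.get(feature)
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    return _OPS[op](value, float(threshold))


def predicate_features(expr: Expr) -> set[str]:
    """All descriptor names referenced by a predicate."""
    if isinstance(expr, dict):
        (branches,) = expr.values()
        out: set[str] = set()
        for e in branches:
            out |= predicate_features(e)
        return out
    return {expr[0]}


@dataclass(frozen=True)
class PlantedRule:
    predicate: Expr
    p_diff: float
    morph: str  # "round" | "spread"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_diff <= 1.0):
            raise ValueError("p_diff must lie in [0, 1]")
        if self.morph not in ("round", "spread"):
            raise ValueError(f"unknown morphology {self.morph!r}")


@dataclass(frozen=True)
class PlantedModel:
    """Ordered rule list mapping descriptors to (differentiation probability,
    morphology of differentiated cells); the first matching rule wins, and
    units matching no rule fall back to the baseline."""

    rules: tuple[PlantedRule, ...]
    baseline_p: float = 0.12
    baseline_morph: str = "round"

    def match(self, dv: Mapping[str, float | None]) -> tuple[float, str, int]:
        """Return (p_diff, morph, rule index); index -1 means baseline."""
        for i, rule in enumerate(self.rules):
            if eval_predicate(rule.predicate, dv):
                return rule.p_diff, rule.morph, i
        return self.baseline_p, self.baseline_morph, -1

    def feature_names(self) -> set[str]:
        out: set[str] = set()
        for rule in self.rules:
            out |= predicate_features(rule.predicate)
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {
                "baseline_p": self.baseline_p,
                "baseline_morph": self.baseline_morph,
                "rules": [
                    {"predicate": r.predicate, "p_diff": r.p_diff, "morph": r.morph}
                    for r in self.rules
                ],
            },
            indent=1,
        ))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            rules=tuple(
                PlantedRule(predicate=r["predicate"], p_diff=float(r["p_diff"]),
                            morph=r["morph"])
                for r in obj["rules"]
            ),
            baseline_p=float(obj["baseline_p"]),
            baseline_morph=obj.get("baseline_morph", "round"),
        )


def default_planted_model() -> PlantedModel:
    """The default ground truth: high coverage with large circle elements
    drives round differentiation; low coverage with short line elements
    drives differentiation that is spread when the surface is additionally
    low-coverage-noisy or irregular, round otherwise."""
    return PlantedModel(
        rules=(
            PlantedRule(
                predicate={"all": [["fcp", ">=", 0.256], ["circ_diam", ">=", 8.293]]},
                p_diff=0.5, morph="round",
            ),
            PlantedRule(
                predicate={"all": [
                    ["fcp", "<", 0.256],
                    ["line_len", "<", 15.849],
                    {"any": [["fcpn01", "<", 0.397], ["rot_sd", ">=", 40.876]]},
                ]},
                p_diff=0.45, morph="spread",
            ),
            PlantedRule(
                predicate={"all": [["fcp", "<", 0.256], ["line_len", "<", 15.849]]},
                p_diff=0.45, morph="round",
            ),
        ),
        baseline_p=0.12,
        baseline_morph="round",
    )


# ---------------------------------------------------------------------------
# per-cell morphology and intensity parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorphologyParams:
    """Log-normal area (um^2, parameterized by median and sigma of log) and
    Beta-distributed roundness (mean, concentration)."""

    area_median: float
    area_sigma_log: float
    roundness_mean: float
    roundness_conc: float = 20.0


#: differentiated-cell morphology classes and the undifferentiated default.
#: The class parameters place the screen's working cutoffs (spread area
#: 1272 / 670 um^2, roundness 0.62 / 0.38) between the class modes.
MORPHOLOGY = {
    "round": MorphologyParams(500.0, 0.3, 0.70),
    "spread": MorphologyParams(1800.0, 0.3, 0.30),
    "undiff": MorphologyParams(700.0, 0.3, 0.55),
}

#: TGM1 MFI: Normal(600, 120) for differentiated cells, Normal(80, 40)
#: truncated at zero for undifferentiated cells; both tails clear the
#: MFI > 270 cutoff with misclassification < 0.5%.
MFI_DIFF = (600.0, 120.0)
MFI_UNDIFF = (80.0, 40.0)

N_CELLS_RANGE = (5, 25)
NUCLEUS_SPACING = 20.0  # um, minimum center-to-center distance
NUCLEUS_DIAMETER = 10.0  # um
PLACEMENT_MARGIN = 10.0  # um, keeps nucleus disks inside the unit


class PlacementError(RuntimeError):
    """Raised when non-overlapping nucleus placement fails."""


def _place_nuclei(n: int, unit_side: float, rng: np.random.Generator,
                  spacing: float = NUCLEUS_SPACING,
                  margin: float = PLACEMENT_MARGIN,
                  max_attempts: int = 5000) -> np.ndarray:
    pts: list[tuple[float, float]] = []
    attempts = 0
    lo, hi = margin, unit_side - margin
    while len(pts) < n:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {n} nuclei with {spacing} um spacing "
                f"after {max_attempts} attempts"
            )
        attempts += 1
        x, y = rng.uniform(lo, hi, size=2)
        if all((x - px) ** 2 + (y - py) ** 2 >= spacing ** 2 for px, py in pts):
            pts.append((x, y))
    return np.asarray(pts)


def _draw_cells(n: int, diff: np.ndarray, morph: str,
                rng: np.random.Generator) -> pd.DataFrame:
    area = np.empty(n)
    roundness = np.empty(n)
    mfi = np.empty(n)
    for is_diff in (True, False):
        sel = diff == is_diff
        k = int(sel.sum())
        if k == 0:
            continue
        params = MORPHOLOGY[morph if is_diff else "undiff"]
        area[sel] = np.exp(rng.normal(math.log(params.area_median),
                                      params.area_sigma_log, size=k))
        a = params.roundness_mean * params.roundness_conc
        b = (1.0 - params.roundness_mean) * params.roundness_conc
        roundness[sel] = rng.beta(a, b, size=k)
        mean, sd = MFI_DIFF if is_diff else MFI_UNDIFF
        draws = rng.normal(mean, sd, size=k)
        while np.any(draws < 0):  # truncate at zero by redrawing
            neg = draws < 0
            draws[neg] = rng.normal(mean, sd, size=int(neg.sum()))
        mfi[sel] = draws
    perimeter = np.sqrt(4.0 * np.pi * area / roundness)
    return pd.DataFrame({
        "true_diff": diff,
        "area_um2": area,
        "roundness": roundness,
        "perimeter_um": perimeter,
        "tgm1_mfi": mfi,
    })


def simulate_unit(
    dv: Mapping[str, float | None],
    model: PlantedModel,
    seed: int | Sequence[int],
    unit_side: float = 300.0,
    n_range: tuple[int, int] = N_CELLS_RANGE,
) -> pd.DataFrame:
    """Simulate one TopoUnit's cells given its descriptor mapping.

    Returns a cell table with geometry (area, perimeter, roundness), TGM1
    MFI, nucleus center and the ground-truth differentiation/morphology
    flags.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    p_diff, morph, rule_idx = model.match(dv)
    n = int(rng.integers(n_range[0], n_range[1] + 1))
    diff = rng.random(n) < p_diff
    cells = _draw_cells(n, diff, morph, rng)
    centers = _place_nuclei(n, unit_side, rng)
    cells.insert(0, "cell_id", np.arange(1, n + 1))
    cells["true_morph"] = np.where(diff, morph, "undiff")
    cells["nx_um"] = centers[:, 0]
    cells["ny_um"] = centers[:, 1]
    cells.attrs["p_diff"] = p_diff
    cells.attrs["morph"] = morph
    cells.attrs["rule_index"] = rule_idx
    return cells


def simulate_screen(
    library: Sequence[TopoUnitDesign],
    layout: ChipLayout,
    model: PlantedModel,
    seed: int,
    descriptors: pd.DataFrame | None = None,
    resolution: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every occupied grid position of a chip.

    Duplicate units of a design share planted parameters (they are a pure
    function of the design's descriptors) but receive independent cell draws.
    Returns ``(cells, truth)``: the per-cell table and the per-unit planted
    ground truth.  Fully deterministic per seed; each unit's randomness is
    keyed by (seed, row, col), so realizations are independent of iteration
    order.
    """
    if descriptors is None:
        descriptors = library_descriptors(library, resolution=resolution, seed=seed)
    designs = {d.design_id: d for d in library}
    cell_frames = []
    truth_rows = []
    for (row, col), design_id in sorted(layout.cells.items()):
        dv = descriptors.loc[design_id].to_dict()
        unit = simulate_unit(dv, model,
                             seed=[seed, row, col],
                             unit_side=designs[design_id].unit_side)
        unit.insert(0, "design_id", design_id)
        unit.insert(0, "col", col)
        unit.insert(0, "row", row)
        truth_rows.append({
            "row": row, "col": col, "design_id": design_id,
            "p_diff": unit.attrs["p_diff"],
            "morph": unit.attrs["morph"],
            "rule_index": unit.attrs["rule_index"],
            "n_cells": len(unit),
        })
        cell_frames.append(unit)
    cells = pd.concat(cell_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return cells, truth


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class ImageStack:
    """Rendered 3-channel unit image plus ground-truth cell labels."""

    dapi: np.ndarray
    factin: np.ndarray
    tgm1: np.ndarray
    labels: np.ndarray
    resolution: float


DAPI_INTENSITY = 200.0
FACTIN_INTENSITY = 200.0


def _ellipse_axes(area: float, roundness: float) -> tuple[float, float]:
    """Semi-axes (a >= b) of the ellipse with the given area whose Ramanujan
    perimeter reproduces the given circularity statistic."""

    def circ_of_logk(logk: float) -> float:
        k = math.exp(logk)
        a = math.sqrt(area * k / math.pi)
        b = math.sqrt(area / (math.pi * k))
        h = ((a - b) / (a + b)) ** 2
        p = math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))
        return 4.0 * math.pi * area / p ** 2

    if roundness >= circ_of_logk(0.0):  # >= 1 up to rounding: a circle
        r = math.sqrt(area / math.pi)
        return r, r
    logk = brentq(lambda lk: circ_of_logk(lk) - roundness, 0.0, math.log(1e6))
    k = math.exp(logk)
    return math.sqrt(area * k / math.pi), math.sqrt(area / (math.pi * k))


def _fill_ellipse(canvas: np.ndarray, value: float, cx: float, cy: float,
                  a: float, b: float, theta: float, resolution: float,
                  out_mask: np.ndarray | None = None) -> None:
    n_rows, n_cols = canvas.shape
    r = max(a, b)
    j0 = max(0, int((cx - r) / resolution) - 1)
    j1 = min(n_cols, int((cx + r) / resolution) + 2)
    i0 = max(0, int((cy - r) / resolution) - 1)
    i1 = min(n_rows, int((cy + r) / resolution) + 2)
    if j0 >= j1 or i0 >= i1:
        return
    xs = (np.arange(j0, j1) + 0.5) * resolution - cx
    ys = (np.arange(i0, i1) + 0.5) * resolution - cy
    X, Y = np.meshgrid(xs, ys)
    ct, st = math.cos(theta), math.sin(theta)
    U = ct * X + st * Y
    V = -st * X + ct * Y
    inside = (U / a) ** 2 + (V / b) ** 2 <= 1.0
    region = canvas[i0:i1, j0:j1]
    region[inside] = np.maximum(region[inside], value)
    if out_mask is not None:
        out_mask[i0:i1, j0:j1] |= inside


def render_unit(
    cells: pd.DataFrame,
    mask: UnitMask,
    noise_sd: float = 0.0,
    seed: int | Sequence[int] = 0,
) -> ImageStack:
    """Render a simulated unit into DAPI / F-actin / TGM1 rasters.

    Each cell is a rotated ellipse centered on its nucleus, with semi-axes
    chosen so that the pixelated ellipse matches the cell's (area, roundness).
    Nuclei are 10 um disks.  Where ellipses overlap, pixel ownership (the
    ground-truth label raster, and hence the TGM1 fill) is resolved by
    nearest-nucleus flooding within the union foreground -- the same
    assignment rule the segmentation stage uses, so a noise-free rendering
    round-trips exactly through it.  Gaussian noise of ``noise_sd`` is added
    to every channel.
    """
    from .morphometry import assign_to_markers  # shared assignment rule

    rng = np.random.default_rng(seed)
    res = mask.resolution
    shape = mask.shape
    dapi = np.zeros(shape)
    factin = np.zeros(shape)
    tgm1 = np.zeros(shape)
    foreground = np.zeros(shape, dtype=bool)
    markers = np.zeros(shape, dtype=np.int32)

    cells = cells.reset_index(drop=True)
    for idx, cell in cells.iterrows():
        a, b = _ellipse_axes(cell["area_um2"], cell["roundness"])
        theta = float(rng.uniform(0.0, math.pi))
        _fill_ellipse(factin, FACTIN_INTENSITY, cell["nx_um"], cell["ny_um"],
                      a, b, theta, res, out_mask=foreground)
        marker_disk = np.zeros(shape, dtype=bool)
        _fill_ellipse(dapi, DAPI_INTENSITY, cell["nx_um"], cell["ny_um"],
                      NUCLEUS_DIAMETER / 2.0, NUCLEUS_DIAMETER / 2.0, 0.0, res,
                      out_mask=marker_disk)
        markers[marker_disk] = idx + 1

    foreground |= markers > 0  # nuclei always belong to their cell footprint
    # flood from scan-order-relabeled markers -- the same input segmentation
    # reconstructs from the DAPI channel -- then translate the resulting
    # partition back to cell order for the ground-truth raster
    from skimage.measure import label as cc_label

    scan = cc_label(markers > 0, connectivity=2).astype(np.int32)
    scan_assign = assign_to_markers(foreground, scan)
    mapping = np.zeros(int(scan.max()) + 1, dtype=np.int32)
    for cell_idx in range(1, len(cells) + 1):
        owned = scan[markers == cell_idx]
        mapping[owned[0]] = cell_idx
    labels = mapping[scan_assign]
    mfi = cells["tgm1_mfi"].to_numpy()
    covered = labels > 0
    tgm1[covered] = mfi[labels[covered] - 1]

    if noise_sd > 0:
        dapi = dapi + rng.normal(0.0, noise_sd, shape)
        factin = factin + rng.normal(0.0, noise_sd, shape)
        tgm1 = tgm1 + rng.normal(0.0, noise_sd, shape)
    return ImageStack(dapi=dapi, factin=factin, tgm1=tgm1, labels=labels,
                      resolution=res)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a unit's channels and label raster as one multi-page TIFF."""
    import tifffile

    pages = np.stack([
        stack.dapi, stack.factin, stack.tgm1, stack.labels.astype(float),
    ]).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack", metadata={
        "axes": "CYX",
        "channels": "dapi,factin,tgm1,labels",
        "resolution_um_per_px": stack.resolution,
    })


def read_stack(path: str | Path) -> ImageStack:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        pages = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    res = float(meta.get("resolution_um_per_px", 0.5))
    return ImageStack(dapi=pages[0], factin=pages[1], tgm1=pages[2],
                      labels=pages[3].astype(np.int32), resolution=res)
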