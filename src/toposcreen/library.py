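"""Virtual micro-topography library.

A TopoChip carries thousands of 300x300 um wells ("TopoUnits"), each decorated
with a distinct surface topography built from randomized combinations of three
primitive shapes: circles, equilateral triangles and rectangles.  This module
generates such a virtual library, lays designs out on a chip grid with
diagonally displaced internal duplicates, rasterizes designs into binary unit
masks, and reads/writes the design file formats.

Geometry conventions
--------------------
Positions and sizes are in micrometres in the unit frame, with the origin at
the top-left corner of the unit.  Rasters use a pixel-center convention: pixel
(i, j) samples the point ((j + 0.5) * res, (i + 0.5) * res).  A mask pixel is 1
iff its center lies inside at least one (rotated) primitive; overlapping
primitives are unioned and primitives are clipped at the unit boundary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PRIMITIVE_KINDS = ("circle", "triangle", "rectangle")

#: default sampled size interval (um) per primitive kind: circle diameter,
#: triangle side, rectangle length
DEFAULT_SIZE_RANGES: dict[str, tuple[float, float]] = {
    "circle": (3.0, 80.0),
    "triangle": (3.0, 80.0),
    "rectangle": (3.0, 80.0),
}

#: rectangle width is sampled as a fraction of its length, keeping width <= length
DEFAULT_WIDTH_FRAC_RANGE = (0.05, 1.0)

#: number of primitives per design
DEFAULT_COUNT_RANGE = (1, 30)

DEFAULT_UNIT_SIDE = 300.0
DEFAULT_FEATURE_HEIGHT = 5.0
DEFAULT_RESOLUTION = 0.5
FLAT_DESIGN_ID = "FLAT"


class DesignParseError(ValueError):
    """Raised when a design file is malformed; names the offending design."""


@dataclass(frozen=True)
class Primitive:
    """One elementary shape of a topography.

    ``size1`` is the circle diameter, the triangle side, or the rectangle
    length; ``size2`` is the rectangle width (unused for other kinds).
    ``rot`` is the placement angle in degrees, in [0, 360).
    """

    kind: str
    size1: float
    cx: float
    cy: float
    rot: float = 0.0
    size2: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in PRIMITIVE_KINDS:
            raise ValueError(f"unknown primitive kind {self.kind!r}")
        if not self.size1 > 0:
            raise ValueError(f"size1 must be positive, got {self.size1}")
        if self.kind == "rectangle":
            if self.size2 is None or not self.size2 > 0:
                raise ValueError("rectangle requires size2 > 0")
            if self.size2 > self.size1:
                raise ValueError("rectangle width (size2) must not exceed length (size1)")
        if not (0.0 <= self.rot < 360.0):
            raise ValueError(f"rot must lie in [0, 360), got {self.rot}")

    @property
    def aspect(self) -> float:
        """Length/width ratio; 1.0 for non-rectangles."""
        if self.kind == "rectangle":
            return self.size1 / self.size2  # type: ignore[operator]
        return 1.0


@dataclass(frozen=True)
class TopoUnitDesign:
    """A single TopoUnit's topography: an ordered set of primitives.

    The design with an empty primitive list is the flat control.
    """

    design_id: str
    primitives: tuple[Primitive, ...]
    unit_side: float = DEFAULT_UNIT_SIDE
    feature_height: float = DEFAULT_FEATURE_HEIGHT

    def __post_init__(self) -> None:
        if not self.unit_side > 0:
            raise ValueError("unit_side must be positive")
        for p in self.primitives:
            if not (0.0 <= p.cx <= self.unit_side and 0.0 <= p.cy <= self.unit_side):
                raise ValueError(
                    f"design {self.design_id}: primitive center ({p.cx}, {p.cy}) "
                    f"outside unit [0, {self.unit_side}]"
                )

    @property
    def is_flat(self) -> bool:
        return len(self.primitives) == 0


@dataclass(frozen=True)
class ChipLayout:
    """Grid placement of a library on one chip.

    ``cells`` maps (row, col) -> design_id for occupied positions; positions
    absent from the mapping are empty.  Every design appears exactly twice,
    with the duplicate displaced diagonally (never sharing a row or column).
    """

    grid_rows: int
    grid_cols: int
    cells: Mapping[tuple[int, int], str]
    n_designs: int

    def positions_of(self, design_id: str) -> list[tuple[int, int]]:
        return sorted(pos for pos, d in self.cells.items() if d == design_id)


@dataclass
class UnitMask:
    """Binary raster of one TopoUnit at ``resolution`` um per pixel."""

    pixels: np.ndarray
    resolution: float = DEFAULT_RESOLUTION

    def __post_init__(self) -> None:
        self.pixels = np.ascontiguousarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 2:
            raise ValueError("mask raster must be 2-D")
        bad = set(np.unique(self.pixels)) - {0, 1}
        if bad:
            raise ValueError(f"mask values must be binary, found {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# library generation
# ---------------------------------------------------------------------------

def generate_library(
    n_designs: int,
    seed: int,
    size_ranges: Mapping[str, tuple[float, float]] | None = None,
    count_range: tuple[int, int] = DEFAULT_COUNT_RANGE,
    width_frac_range: tuple[float, float] = DEFAULT_WIDTH_FRAC_RANGE,
    unit_side: float = DEFAULT_UNIT_SIDE,
    feature_height: float = DEFAULT_FEATURE_HEIGHT,
) -> list[TopoUnitDesign]:
    """Sample ``n_designs`` random topographies plus one flat control.

    Each design draws a primitive count uniformly from ``count_range``, then
    for every primitive a kind (uniform over circle/triangle/rectangle), a
    size from the kind's interval, a continuous position in the unit and a
    rotation in [0, 360).  The output is a pure function of the arguments.

    The flat control (empty primitive list, id ``FLAT``) is appended last.
    """
    if n_designs < 1:
        raise ValueError("n_designs must be >= 1")
    ranges = dict(DEFAULT_SIZE_RANGES)
    if size_ranges:
        ranges.update(size_ranges)
    for kind, (lo, hi) in ranges.items():
        if not (0 < lo <= hi):
            raise ValueError(f"invalid size range for {kind}: ({lo}, {hi})")
    c_lo, c_hi = count_range
    if not (1 <= c_lo <= c_hi):
        raise ValueError(f"invalid count range {count_range}")

    rng = np.random.default_rng(seed)
    designs: list[TopoUnitDesign] = []
    n_digits = max(4, len(str(n_designs)))
    for i in range(n_designs):
        n_prim = int(rng.integers(c_lo, c_hi + 1))
        prims = []
        for _ in range(n_prim):
            kind = PRIMITIVE_KINDS[int(rng.integers(0, len(PRIMITIVE_KINDS)))]
            lo, hi = ranges[kind]
            size1 = float(rng.uniform(lo, hi))
            size2 = None
            if kind == "rectangle":
                size2 = size1 * float(rng.uniform(*width_frac_range))
            prims.append(
                Primitive(
                    kind=kind,
                    size1=size1,
                    size2=size2,
                    cx=float(rng.uniform(0.0, unit_side)),
                    cy=float(rng.uniform(0.0, unit_side)),
                    rot=float(rng.uniform(0.0, 360.0)) % 360.0,
                )
            )
        designs.append(
            TopoUnitDesign(
                design_id=f"T{i:0{n_digits}d}",
                primitives=tuple(prims),
                unit_side=unit_side,
                feature_height=feature_height,
            )
        )
    designs.append(
        TopoUnitDesign(
            design_id=FLAT_DESIGN_ID,
            primitives=(),
            unit_side=unit_side,
            feature_height=feature_height,
        )
    )
    return designs


# ---------------------------------------------------------------------------
# chip layout
# ---------------------------------------------------------------------------

def layout_chip(
    library: Sequence[TopoUnitDesign],
    rows: int = 66,
    cols: int = 66,
    seed: int = 0,
    offset: tuple[int, int] = (33, 33),
) -> ChipLayout:
    """Place every design twice on a ``rows`` x ``cols`` grid.

    The second copy sits at a fixed diagonal displacement ``offset`` (modulo
    the grid), so duplicates never share a row or a column; this guards the
    screen against positional bias.  Placement of the first copies is a
    seeded random assignment.
    """
    if 2 * len(library) > rows * cols:
        raise ValueError(
            f"library of {len(library)} designs does not fit twice on a "
            f"{rows}x{cols} grid"
        )
    dr, dc = offset[0] % rows, offset[1] % cols
    if dr == 0 or dc == 0:
        raise ValueError("duplicate offset must displace both row and column")

    # the shift p -> p + (dr, dc) permutes grid positions in disjoint cycles;
    # consecutive cycle elements form valid (position, diagonal partner)
    # pairs, and taking every other edge yields floor(cycle/2) disjoint pairs
    pairs: list[tuple[tuple[int, int], tuple[int, int]]] = []
    visited: set[tuple[int, int]] = set()
    for r in range(rows):
        for c in range(cols):
            if (r, c) in visited:
                continue
            cycle = []
            pos = (r, c)
            while pos not in visited:
                visited.add(pos)
                cycle.append(pos)
                pos = ((pos[0] + dr) % rows, (pos[1] + dc) % cols)
            for i in range(0, len(cycle) - 1, 2):
                pairs.append((cycle[i], cycle[i + 1]))
    if len(library) > len(pairs):
        raise ValueError(
            f"library of {len(library)} designs does not fit: the "
            f"{rows}x{cols} grid admits only {len(pairs)} diagonal pairs "
            f"at offset ({dr}, {dc})"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    occupied: dict[tuple[int, int], str] = {}
    for design, k in zip(library, order):
        a, b = pairs[int(k)]
        occupied[a] = design.design_id
        occupied[b] = design.design_id
    return ChipLayout(grid_rows=rows, grid_cols=cols, cells=occupied, n_designs=len(library))


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _pixel_centers(n: int, resolution: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * resolution


def _fill_primitive(mask: np.ndarray, p: Primitive, resolution: float) -> None:
    """OR the pixels whose centers lie inside primitive ``p`` into ``mask``."""
    n_rows, n_cols = mask.shape
    if p.kind == "circle":
        radius = p.size1 / 2.0
    elif p.kind == "rectangle":
        radius = math.hypot(p.size1, p.size2) / 2.0  # type: ignore[arg-type]
    else:  # equilateral triangle: circumradius = side / sqrt(3)
        radius = p.size1 / math.sqrt(3.0)

    j0 = max(0, int((p.cx - radius) / resolution) - 1)
    j1 = min(n_cols, int((p.cx + radius) / resolution) + 2)
    i0 = max(0, int((p.cy - radius) / resolution) - 1)
    i1 = min(n_rows, int((p.cy + radius) / resolution) + 2)
    if j0 >= j1 or i0 >= i1:
        return

    xs = _pixel_centers(n_cols, resolution)[j0:j1] - p.cx
    ys = _pixel_centers(n_rows, resolution)[i0:i1] - p.cy
    X, Y = np.meshgrid(xs, ys)

    if p.kind == "circle":
        inside = X * X + Y * Y <= (p.size1 / 2.0) ** 2
    else:
        theta = math.radians(p.rot)
        ct, st = math.cos(theta), math.sin(theta)
        U = ct * X + st * Y
        V = -st * X + ct * Y
        if p.kind == "rectangle":
            inside = (np.abs(U) <= p.size1 / 2.0) & (np.abs(V) <= p.size2 / 2.0)  # type: ignore[operator]
        else:
            # equilateral triangle centered at its centroid, one vertex on the
            # +u axis at rot = 0; interior = intersection of three half-planes
            r_in = p.size1 / (2.0 * math.sqrt(3.0))  # inradius
            inside = U >= -r_in
            for ang in (2.0 * math.pi / 3.0, -2.0 * math.pi / 3.0):
                ca, sa = math.cos(ang), math.sin(ang)
                inside &= (ca * U + sa * V) >= -r_in
    mask[i0:i1, j0:j1] |= inside


def rasterize(design: TopoUnitDesign, resolution: float = DEFAULT_RESOLUTION) -> UnitMask:
    """Rasterize a design to a binary mask via pixel-center inclusion tests.

    Overlapping primitives are unioned; anything beyond the unit boundary is
    clipped.  Resolution must not be coarser than a tenth of the unit side.
    """
    if not (0 < resolution <= design.unit_side / 10.0):
        raise ValueError(
            f"resolution must be in (0, {design.unit_side / 10.0}] um/px, got {resolution}"
        )
    n = int(round(design.unit_side / resolution))
    mask = np.zeros((n, n), dtype=bool)
    for p in design.primitives:
        _fill_primitive(mask, p, resolution)
    return UnitMask(pixels=mask.astype(np.uint8), resolution=resolution)


# ---------------------------------------------------------------------------
# design file IO
# ---------------------------------------------------------------------------

def _design_to_record(d: TopoUnitDesign) -> dict:
    return {
        "design_id": d.design_id,
        "unit_side_um": d.unit_side,
        "feature_height_um": d.feature_height,
        "primitives": [
            {
                "kind": p.kind,
                "size1_um": p.size1,
                "size2_um": p.size2,
                "cx_um": p.cx,
                "cy_um": p.cy,
                "rot_deg": p.rot,
            }
            for p in d.primitives
        ],
    }


def _record_to_design(rec: dict) -> TopoUnitDesign:
    design_id = rec.get("design_id", "<missing id>")
    try:
        prims = tuple(
            Primitive(
                kind=pr["kind"],
                size1=float(pr["size1_um"]),
                size2=None if pr.get("size2_um") is None else float(pr["size2_um"]),
                cx=float(pr["cx_um"]),
                cy=float(pr["cy_um"]),
                rot=float(pr["rot_deg"]),
            )
            for pr in rec.get("primitives", [])
        )
        return TopoUnitDesign(
            design_id=design_id,
            primitives=prims,
            unit_side=float(rec.get("unit_side_um", DEFAULT_UNIT_SIDE)),
            feature_height=float(rec.get("feature_height_um", DEFAULT_FEATURE_HEIGHT)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise DesignParseError(f"design {design_id!r}: {exc}") from exc


def write_designs(library: Iterable[TopoUnitDesign], path: str | Path) -> None:
    """Write a library as JSON (one record per design)."""
    records = [_design_to_record(d) for d in library]
    Path(path).write_text(json.dumps(records, indent=1, sort_keys=True))


def read_designs(path: str | Path) -> list[TopoUnitDesign]:
    """Read a JSON design library, validating records and id uniqueness."""
    try:
        records = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise DesignParseError(f"not valid JSON: {exc}") from exc
    designs = [_record_to_design(rec) for rec in records]
    seen: set[str] = set()
    for d in designs:
        if d.design_id in seen:
            raise DesignParseError(f"design {d.design_id!r}: duplicate design_id")
        seen.add(d.design_id)
    return designs


def write_designs_csv(library: Iterable[TopoUnitDesign], path: str | Path) -> None:
    """Write the flat CSV dialect: one primitive per row; flat designs emit a
    single row with an empty kind."""
    rows = []
    for d in library:
        if d.is_flat:
            rows.append(
                {
                    "design_id": d.design_id,
                    "unit_side_um": d.unit_side,
                    "feature_height_um": d.feature_height,
                    "kind": "",
                    "size1_um": np.nan,
                    "size2_um": np.nan,
                    "cx_um": np.nan,
                    "cy_um": np.nan,
                    "rot_deg": np.nan,
                }
            )
        for p in d.primitives:
            rows.append(
                {
                    "design_id": d.design_id,
                    "unit_side_um": d.unit_side,
                    "feature_height_um": d.feature_height,
                    "kind": p.kind,
                    "size1_um": p.size1,
                    "size2_um": np.nan if p.size2 is None else p.size2,
                    "cx_um": p.cx,
                    "cy_um": p.cy,
                    "rot_deg": p.rot,
                }
            )
    # %.17g keeps every float bit-exact through the text round-trip
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_designs_csv(path: str | Path) -> list[TopoUnitDesign]:
    """Read the flat CSV dialect written by :func:`write_designs_csv`."""
    df = pd.read_csv(path, float_precision="round_trip")
    designs = []
    for design_id, grp in df.groupby("design_id", sort=False):
        recs = []
        for _, r in grp.iterrows():
            if not isinstance(r["kind"], str) or r["kind"] == "":
                continue
            recs.append(
                {
                    "kind": r["kind"],
                    "size1_um": r["size1_um"],
                    "size2_um": None if pd.isna(r["size2_um"]) else r["size2_um"],
                    "cx_um": r["cx_um"],
                    "cy_um": r["cy_um"],
                    "rot_deg": r["rot_deg"],
                }
            )
        designs.append(
            _record_to_design(
                {
                    "design_id": str(design_id),
                    "unit_side_um": grp["unit_side_um"].iloc[0],
                    "feature_height_um": grp["feature_height_um"].iloc[0],
                    "primitives": recs,
                }
            )
        )
    return designs


def write_mask(mask: UnitMask, path: str | Path) -> None:
    """Save a mask as an 8-bit 0/255 TIFF/PNG with a JSON resolution sidecar."""
    import tifffile
    import imageio.v3 as iio

    path = Path(path)
    img = (mask.pixels * 255).astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, img)
    else:
        iio.imwrite(path, img)
    Path(str(path) + ".json").write_text(
        json.dumps({"resolution_um_per_px": mask.resolution})
    )


def read_mask(path: str | Path) -> UnitMask:
    """Load a mask saved by :func:`write_mask`."""
    import tifffile
    import imageio.v3 as iio

    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    return UnitMask(pixels=(np.asarray(img) > 0).astype(np.uint8),
                    resolution=float(sidecar["resolution_um_per_px"]))
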