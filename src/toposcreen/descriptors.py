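"""Per-design topography descriptors.

These are the feature inputs to the phenotype models:

- **FCP** — fraction of the unit's pixels covered by topography.
- **FCPN01** — FCP recomputed under small random pixel perturbations
  (Bernoulli flips at p = 0.01, averaged over replicates), modelling minor
  experimental variation of the fabricated surface.
- **WnX** — fraction of the mask's non-DC spectral energy carried by radial
  spatial frequencies near X cycles per 10 um (bands centered at
  0.1, 0.2, 0.3, 0.5, 1, 2 and 4).
- **LineLen** — mean length of the design's line elements (rectangles with
  aspect ratio >= 3).
- **CircDiam** — mean diameter of the design's circle elements.
- **RotSD** — standard deviation of the angles under which primitives are
  placed, an irregularity measure.

LineLen, CircDiam and RotSD come from the in-silico design metadata; FCP,
FCPN01 and WnX from the rasterized mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .library import TopoUnitDesign, UnitMask, rasterize, DEFAULT_RESOLUTION

#: band centers in cycles per 10 um
DEFAULT_BAND_CENTERS = (0.1, 0.2, 0.3, 0.5, 1.0, 2.0, 4.0)

#: aspect ratio at or above which a rectangle counts as a "line" element
LINE_ASPECT_MIN = 3.0

#: symmetry fold period (degrees) per orientable primitive kind
_SYMMETRY_PERIOD = {"triangle": 120.0, "rectangle": 180.0}


@dataclass
class DescriptorVector:
    """All descriptors of one design.  Absent values are ``None`` (no
    qualifying primitives); ``wn_defined`` is False for constant masks,
    which carry no AC spectral energy."""

    fcp: float
    fcpn01: float
    wn: dict[float, float]
    wn_defined: bool
    line_len: float | None
    circ_diam: float | None
    rot_sd: float | None

    def as_dict(self) -> dict[str, float | None]:
        d: dict[str, float | None] = {
            "fcp": self.fcp,
            "fcpn01": self.fcpn01,
            "line_len": self.line_len,
            "circ_diam": self.circ_diam,
            "rot_sd": self.rot_sd,
        }
        for center, frac in self.wn.items():
            d[wn_column(center)] = frac
        return d


def wn_column(center: float) -> str:
    """Column name for a band center, e.g. ``wn_0.1`` or ``wn_4``."""
    return f"wn_{center:g}"


def _check_mask(mask: UnitMask) -> np.ndarray:
    px = np.asarray(mask.pixels)
    if px.size == 0:
        raise ValueError("empty raster")
    return px


def compute_fcp(mask: UnitMask) -> float:
    """Fraction of covered pixels: count of 1-pixels over total pixels."""
    px = _check_mask(mask)
    return float(px.sum()) / px.size


def compute_fcpn01(
    mask: UnitMask,
    flip_p: float = 0.01,
    reps: int = 25,
    seed: int = 0,
) -> float:
    """FCP under added variation: mean FCP over ``reps`` replicate masks in
    which every pixel flips independently with probability ``flip_p``.

    Each replicate's covered fraction depends on the flips only through the
    two binomial counts (flipped ones, flipped zeros), which are drawn
    directly.  Expectation: ``fcp * (1 - flip_p) + (1 - fcp) * flip_p``.
    """
    if not (0.0 <= flip_p < 0.5):
        raise ValueError(f"flip_p must lie in [0, 0.5), got {flip_p}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    px = _check_mask(mask)
    if flip_p == 0.0:
        return compute_fcp(mask)
    n = px.size
    n1 = int(px.sum())
    n0 = n - n1
    rng = np.random.default_rng(seed)
    lost = rng.binomial(n1, flip_p, size=reps)
    gained = rng.binomial(n0, flip_p, size=reps)
    return float(np.mean((n1 - lost + gained) / n))


_ANNULUS_CACHE: dict[tuple, tuple[np.ndarray, int]] = {}


def band_edges(centers: tuple[float, ...] = DEFAULT_BAND_CENTERS) -> np.ndarray:
    """Band edges in cycles per 10 um: geometric midpoints between consecutive
    centers; the lowest edge sits just above DC and the highest is open so the
    bands tile the whole non-DC spectrum."""
    c = np.asarray(centers, dtype=float)
    if np.any(c <= 0) or np.any(np.diff(c) <= 0):
        raise ValueError("band centers must be positive and strictly increasing")
    mids = np.sqrt(c[:-1] * c[1:])
    return np.concatenate([[1e-12], mids, [np.inf]])


def _annulus_bins(shape: tuple[int, int], resolution: float,
                  centers: tuple[float, ...]) -> tuple[np.ndarray, int]:
    key = (shape, resolution, centers)
    cached = _ANNULUS_CACHE.get(key)
    if cached is not None:
        return cached
    fy = np.fft.fftfreq(shape[0], d=resolution)  # cycles per um
    fx = np.fft.rfftfreq(shape[1], d=resolution)
    radial = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2) * 10.0  # per 10 um
    edges = band_edges(centers)
    idx = np.digitize(radial, edges) - 1  # -1 => DC, len(centers) never (inf edge)
    flat = idx.ravel()
    n_bands = len(centers)
    _ANNULUS_CACHE[key] = (flat, n_bands)
    return flat, n_bands


def compute_wn(
    mask: UnitMask,
    centers: tuple[float, ...] = DEFAULT_BAND_CENTERS,
) -> tuple[dict[float, float], bool]:
    """Radial spectral energy fractions of the mean-subtracted mask.

    The 2-D power spectrum of ``mask - mean(mask)`` is summed over annuli of
    radial spatial frequency (cycles per 10 um) and each band's share of the
    total non-DC power is reported.  Over the default full tiling the shares
    sum to 1.  A constant mask has no AC energy: all shares are 0 and the
    second return value is False.
    """
    px = _check_mask(mask).astype(float)
    if px.shape[0] != px.shape[1]:
        raise ValueError("mask must be square")
    centered = px - px.mean()
    if not np.any(centered):
        return {c: 0.0 for c in centers}, False
    spec = np.fft.rfft2(centered)
    power = np.abs(spec) ** 2
    # double the energy of columns whose conjugate half is omitted by rfft2
    weights = np.full(power.shape[1], 2.0)
    weights[0] = 1.0
    if px.shape[1] % 2 == 0:
        weights[-1] = 1.0
    power = power * weights[None, :]
    flat_idx, n_bands = _annulus_bins(px.shape, mask.resolution, centers)
    sums = np.bincount(flat_idx + 1, weights=power.ravel(), minlength=n_bands + 1)
    band_power = sums[1:]  # index 0 is DC
    total = band_power.sum()
    fractions = band_power / total
    return {c: float(f) for c, f in zip(centers, fractions)}, True


def compute_rotsd(design: TopoUnitDesign, fold_by_symmetry: bool = True) -> float | None:
    """Standard deviation of primitive placement angles, in degrees.

    Circles carry no orientation and are excluded; a design with only circles
    (or no primitives) returns ``None``.  With ``fold_by_symmetry`` (default)
    each angle is folded into its primitive's rotational symmetry period
    (triangle 120 deg, rectangle 180 deg) and rescaled to a common [0, 180)
    range before taking the sample standard deviation; without folding the raw
    [0, 360) angles are used.
    """
    angles = []
    for p in design.primitives:
        period = _SYMMETRY_PERIOD.get(p.kind)
        if period is None:
            continue
        if fold_by_symmetry:
            angles.append((p.rot % period) * (180.0 / period))
        else:
            angles.append(p.rot)
    if not angles:
        return None
    if len(angles) == 1:
        return 0.0
    return float(np.std(angles, ddof=1))


def design_descriptors(
    design: TopoUnitDesign,
    mask: UnitMask | None = None,
    resolution: float = DEFAULT_RESOLUTION,
    band_centers: tuple[float, ...] = DEFAULT_BAND_CENTERS,
    flip_p: float = 0.01,
    reps: int = 25,
    seed: int = 0,
    line_aspect_min: float = LINE_ASPECT_MIN,
    fold_by_symmetry: bool = True,
) -> DescriptorVector:
    """Assemble the full descriptor vector of one design.

    ``mask`` must have been rasterized from ``design`` at ``resolution``; if
    omitted it is rasterized here.
    """
    if mask is None:
        mask = rasterize(design, resolution)
    expected = int(round(design.unit_side / mask.resolution))
    if mask.shape != (expected, expected):
        raise ValueError(
            f"design {design.design_id}: mask shape {mask.shape} inconsistent "
            f"with unit side {design.unit_side} at {mask.resolution} um/px"
        )
    lines = [p.size1 for p in design.primitives
             if p.kind == "rectangle" and p.aspect >= line_aspect_min]
    circles = [p.size1 for p in design.primitives if p.kind == "circle"]
    wn, wn_defined = compute_wn(mask, band_centers)
    return DescriptorVector(
        fcp=compute_fcp(mask),
        fcpn01=compute_fcpn01(mask, flip_p=flip_p, reps=reps, seed=seed),
        wn=wn,
        wn_defined=wn_defined,
        line_len=float(np.mean(lines)) if lines else None,
        circ_diam=float(np.mean(circles)) if circles else None,
        rot_sd=compute_rotsd(design, fold_by_symmetry=fold_by_symmetry),
    )


def descriptor_columns(band_centers: tuple[float, ...] = DEFAULT_BAND_CENTERS) -> list[str]:
    return ["fcp", "fcpn01", *(wn_column(c) for c in band_centers),
            "line_len", "circ_diam", "rot_sd"]


def library_descriptors(
    designs,
    resolution: float = DEFAULT_RESOLUTION,
    band_centers: tuple[float, ...] = DEFAULT_BAND_CENTERS,
    flip_p: float = 0.01,
    reps: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Descriptor table for a whole library: one row per design_id, empty
    cells for absent values.  FCPN01 replicate noise is seeded per design."""
    rows = {}
    for i, design in enumerate(designs):
        dv = design_descriptors(
            design,
            resolution=resolution,
            band_centers=band_centers,
            flip_p=flip_p,
            reps=reps,
            seed=int(np.random.default_rng([seed, i]).integers(0, 2**31)),
        )
        rows[design.design_id] = dv.as_dict()
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "design_id"
    return df[descriptor_columns(band_centers)]
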