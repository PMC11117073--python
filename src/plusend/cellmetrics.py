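"""Image- and geometry-level readouts: bundling, shape, closure, budgets.

Filament bundling is read out as the skewness of the pixel-intensity
distribution — a minority of multi-filament bundles adds a bright right
tail to an otherwise symmetric single-filament field. Cell shape is
summarised by circularity ``4πA/P²``; migration by wound closure; and the
Discussion-style molecule budget converts compartment geometry and
regulator concentrations into counts of occupied and free filament ends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage import measure

from .errors import ConfigurationError, InsufficientDataError, MultipleComponentsError
from .types import CompartmentSpec

#: Avogadro constant as used in the budget arithmetic.
AVOGADRO = 6.02e23


def intensity_skewness(pixels) -> float:
    """Third standardised central moment m₃/m₂^1.5 of a pixel sample.

    Returns NaN for a zero-variance sample (the metric is undefined).
    """
    pixels = np.asarray(pixels, dtype=float).ravel()
    if pixels.size < 3:
        raise InsufficientDataError("need >= 3 pixels for skewness")
    if np.var(pixels) == 0:
        return math.nan
    return float(stats.skew(pixels, bias=True))


@dataclass
class BinaryMask:
    """Boolean foreground grid with a physical pixel size (µm/pixel)."""

    grid: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.size == 0 or self.grid.ndim != 2:
            raise ConfigurationError("mask must be a non-empty 2-D grid")
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be positive")


def contour_perimeter(grid: np.ndarray) -> float:
    """Corner-corrected perimeter from the traced object contour.

    The 0.5-level marching-squares contour is decomposed into axial and
    diagonal chain segments; raw chain length overestimates smooth
    boundaries (a digitised circle by ≈ 5%), so the segments are reweighted
    with the classic corner-corrected coefficients (0.980 per axial unit,
    1.406 per diagonal step, −0.091 per direction change). A rasterised
    disk of radius 200 px then scores circularity ≥ 0.99.
    """
    padded = np.pad(np.asarray(grid, dtype=float), 1)
    total = 0.0
    for c in measure.find_contours(padded, 0.5):
        d = np.diff(c, axis=0)
        seglen = np.hypot(d[:, 0], d[:, 1])
        diag = (np.abs(d[:, 0]) > 1e-9) & (np.abs(d[:, 1]) > 1e-9)
        axial = float(seglen[~diag].sum())
        diagonal = float(seglen[diag].sum())
        dirs = np.arctan2(d[:, 0], d[:, 1]).round(6)
        n_corner = int(np.sum(dirs != np.roll(dirs, 1)))
        total += 0.980 * axial + (1.406 / math.sqrt(2)) * diagonal - 0.091 * n_corner
    return total


def circularity(mask: BinaryMask) -> float:
    """Circularity 4πA/P² of a single connected foreground component.

    The perimeter comes from :func:`contour_perimeter`; the result is
    clipped to ≤ 1. Masks with several components raise an error listing
    their sizes.
    """
    labels, n_comp = measure.label(mask.grid, connectivity=2, return_num=True)
    if n_comp == 0:
        raise InsufficientDataError("mask has no foreground pixels")
    if n_comp > 1:
        sizes = [int(np.sum(labels == i)) for i in range(1, n_comp + 1)]
        raise MultipleComponentsError(
            f"mask has {n_comp} components (sizes {sizes}); expected one", sizes
        )
    area = float(mask.grid.sum())
    perim = contour_perimeter(mask.grid)
    if perim <= 0:
        return 1.0
    return min(4.0 * math.pi * area / perim**2, 1.0)


def signal_ratio(image, threshold_mode: str | float | None = None) -> float:
    """Thresholded integrated signal divided by the total pixel count.

    ``threshold_mode`` may be None (sum everything), a number (keep pixels
    strictly above it), or ``"otsu"``. The denominator is always the full
    pixel count of the image ("available pixels"), so a uniform image at
    value v with no threshold returns v.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ConfigurationError("empty image")
    if threshold_mode is None or threshold_mode == "none":
        kept = image
    elif threshold_mode == "otsu":
        from skimage.filters import threshold_otsu

        kept = image * (image > threshold_otsu(image))
    else:
        kept = image * (image > float(threshold_mode))
    return float(kept.sum() / image.size)


@dataclass(frozen=True)
class WoundClosure:
    """Normalized closure (difference form, primary) plus the ratio form."""

    normalized: float  # coverage_t12 − coverage_t0
    ratio: float  # coverage_t12 / coverage_t0 (NaN when t0 coverage is 0)


def wound_closure(coverage_t0: float, coverage_t12: float) -> WoundClosure:
    """Normalized wound closure from cell-coverage fractions at 0 h and 12 h."""
    for name, c in (("coverage_t0", coverage_t0), ("coverage_t12", coverage_t12)):
        if not 0.0 <= c <= 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1], got {c}")
    ratio = coverage_t12 / coverage_t0 if coverage_t0 > 0 else math.nan
    return WoundClosure(normalized=coverage_t12 - coverage_t0, ratio=ratio)


@dataclass(frozen=True)
class SpeciesBudget:
    name: str
    concentration: float  # mol/L
    oligomer_size: int
    molecules: float
    oligomers: int  # floor(molecules / oligomer_size)


@dataclass(frozen=True)
class MoleculeBudget:
    volume_liters: float
    footprint_um2: float
    free_ends: float
    species: tuple[SpeciesBudget, ...]
    occupied_ends: float  # Σ oligomers across species
    remaining_free_ends: float


def molecule_budget(spec: CompartmentSpec) -> MoleculeBudget:
    """Molecule and filament-end bookkeeping for a cell compartment.

    The compartment volume is x·y·z µm³ converted to litres; each species
    contributes ``conc × N_A × volume`` molecules, and one oligomer (of
    ``oligomer_size`` molecules, counted rounded down) occupies one
    filament end. Free ends available are ``filament_density`` × the x·y
    footprint; the remainder is what is left for other regulators.
    """
    x, y, z = spec.dimensions
    volume = x * y * z * 1e-15  # µm³ → L
    budgets = []
    occupied = 0.0
    for name, conc, size in spec.species:
        molecules = conc * AVOGADRO * volume
        oligomers = int(molecules // size)
        budgets.append(SpeciesBudget(name, conc, size, molecules, oligomers))
        occupied += oligomers
    free_ends = spec.filament_density * (x * y)
    return MoleculeBudget(
        volume_liters=volume,
        footprint_um2=x * y,
        free_ends=free_ends,
        species=tuple(budgets),
        occupied_ends=occupied,
        remaining_free_ends=free_ends - occupied,
    )
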