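"""From raw illumination-triplet cubes to corrected, normalized block spectra.

The acquisition records three cubes per biopsy: blue (fluorescence), dark
(sensor background) and white (reflectance reference).  Processing follows the
acquisition protocol: subtract the dark cube, segment the tissue on the 634 nm
fluorescence band, average non-overlapping 10x10 pixel tiles into block
spectra (each an independent data point), and normalize each block by the
geometric mean of its white-light reflectance in two reference bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from skimage import filters, measure, morphology

from .exceptions import DegenerateReferenceError, GridMismatchError
from .simulate import DEFAULT_EXPOSURE_MS, PX_PER_MM
from .spectral import Spectrum, WavelengthGrid

__all__ = [
    "HyperspectralCube",
    "TumorMask",
    "BlockSpectra",
    "dark_correct",
    "dual_band_normalize",
    "segment_tumor",
    "extract_block_spectra",
    "preprocess_triplet",
    "DEFAULT_BAND_A",
    "DEFAULT_BAND_B",
]

#: Default dual-band normalization windows (nm): an autofluorescence-dominated
#: window and the PpIX emission window.
DEFAULT_BAND_A = (460.0, 480.0)
DEFAULT_BAND_B = (620.0, 640.0)

SEGMENTATION_WAVELENGTH_NM = 634.0


@dataclass(eq=False)
class HyperspectralCube:
    """H x W x n_bands intensity cube for one illumination phase."""

    data: np.ndarray
    grid: WavelengthGrid
    phase: str
    exposure_ms: float = DEFAULT_EXPOSURE_MS
    px_per_mm: float = PX_PER_MM

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3 or arr.shape[2] != self.grid.n_bands:
            raise GridMismatchError("cube must be (H, W, n_bands) on its grid")
        if self.phase not in ("blue", "dark", "white"):
            raise ValueError(f"unknown illumination phase {self.phase!r}")
        self.data = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def band_image(self, wavelength_nm: float) -> np.ndarray:
        return self.data[:, :, self.grid.nearest_band(wavelength_nm)]


@dataclass
class TumorMask:
    """Tissue segmentation with provenance of how it was produced."""

    mask: np.ndarray
    method: str
    checked: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class BlockSpectra:
    """Per-tile mean spectra with their 0-based top-left pixel coordinates."""

    grid: WavelengthGrid
    values: np.ndarray  # (n_blocks, n_bands)
    block_origin: np.ndarray  # (n_blocks, 2) as (row, col)
    block_size: int = 10
    norm_factors: np.ndarray | None = None  # per-block dual-band divisor, if applied

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1, self.grid.n_bands)
        self.block_origin = np.asarray(self.block_origin, dtype=int).reshape(-1, 2)
        if len(self.values) != len(self.block_origin):
            raise ValueError("one origin per spectrum required")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def spectra(self) -> Iterator[Spectrum]:
        for row in self.values:
            yield Spectrum(self.grid, row)


def dark_correct(blue: HyperspectralCube, dark: HyperspectralCube) -> HyperspectralCube:
    """Subtract the no-light cube from the blue cube, clipping at zero."""
    if blue.shape != dark.shape or blue.grid != dark.grid:
        raise GridMismatchError("blue and dark cubes must share shape and grid")
    if blue.phase != "blue" or dark.phase != "dark":
        raise ValueError("expected a (blue, dark) phase pair")
    corrected = np.clip(blue.data.astype(np.float64) - dark.data, 0.0, None)
    return replace(blue, data=corrected)


def _band_means(values: np.ndarray, grid: WavelengthGrid, band: tuple[float, float]) -> np.ndarray:
    mask = grid.window_mask(*band)
    if not mask.any():
        raise ValueError(f"normalization band {band} outside the grid")
    return np.asarray(values)[..., mask].mean(axis=-1)


def dual_band_normalize(
    y: Spectrum,
    white: Spectrum,
    band_a: tuple[float, float] = DEFAULT_BAND_A,
    band_b: tuple[float, float] = DEFAULT_BAND_B,
) -> Spectrum:
    """Divide a spectrum by the geometric mean of two white-light band means.

    ``out = y / sqrt(mean_a(white) * mean_b(white))``.  Because both bands are
    measured under the same illumination, a uniform illumination rescaling
    applied to ``y`` and ``white`` together leaves the output unchanged.
    """
    if y.grid != white.grid:
        raise GridMismatchError("spectrum and white reference on different grids")
    ra = float(_band_means(white.values, white.grid, band_a))
    rb = float(_band_means(white.values, white.grid, band_b))
    if ra <= 0 or rb <= 0:
        raise DegenerateReferenceError(
            f"white reference non-positive in a normalization band (means {ra}, {rb})"
        )
    return Spectrum(y.grid, y.values / np.sqrt(ra * rb))


def segment_tumor(
    blue: HyperspectralCube,
    exclude_artifacts: bool = True,
    opening_radius: int = 2,
) -> TumorMask:
    """Threshold-based tissue segmentation on the 634 nm fluorescence band.

    Otsu threshold, morphological opening, then (with ``exclude_artifacts``)
    retention of the largest connected component only — bright disjoint
    artifacts such as fluid splashes are dropped even if above threshold.
    """
    if not (blue.grid.start_nm <= SEGMENTATION_WAVELENGTH_NM <= blue.grid.stop_nm):
        raise ValueError("grid does not cover the 634 nm segmentation band")
    band = blue.band_image(SEGMENTATION_WAVELENGTH_NM)
    method = "otsu+opening"
    if not np.any(band > 0) or band.max() == band.min():
        warnings.warn("segmentation band is constant; returning an empty mask")
        return TumorMask(np.zeros(band.shape, dtype=bool), method=method + "+empty")
    thresh = filters.threshold_otsu(band)
    raw = band > thresh
    opened = morphology.opening(raw, morphology.disk(opening_radius))
    if not opened.any():
        warnings.warn("no component survived morphological opening; empty mask")
        return TumorMask(opened, method=method + "+empty")
    if exclude_artifacts:
        lab = measure.label(opened)
        largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
        opened = lab == largest
        method += "+largest_cc"
    return TumorMask(opened, method=method)


def extract_block_spectra(
    cube: HyperspectralCube,
    mask: TumorMask | np.ndarray,
    block_size: int = 10,
) -> BlockSpectra:
    """Average non-overlapping, fully-masked block_size^2 tiles into spectra.

    Tiling is anchored at the mask bounding-box origin; a tile is kept only if
    all of its pixels are inside the mask (partial tiles are discarded), so
    every output spectrum is an independent, disjoint region.
    """
    m = mask.mask if isinstance(mask, TumorMask) else np.asarray(mask, dtype=bool)
    if m.shape != cube.data.shape[:2]:
        raise GridMismatchError("mask and cube spatial shapes differ")
    if not m.any():
        return BlockSpectra(cube.grid, np.empty((0, cube.grid.n_bands)), np.empty((0, 2)))
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    r0, c0 = rows[0], cols[0]
    origins, values = [], []
    for r in range(r0, m.shape[0] - block_size + 1, block_size):
        for c in range(c0, m.shape[1] - block_size + 1, block_size):
            if m[r : r + block_size, c : c + block_size].all():
                origins.append((r, c))
                values.append(
                    cube.data[r : r + block_size, c : c + block_size].mean(axis=(0, 1))
                )
    if not origins:
        return BlockSpectra(cube.grid, np.empty((0, cube.grid.n_bands)), np.empty((0, 2)),
                            block_size=block_size)
    return BlockSpectra(cube.grid, np.array(values), np.array(origins), block_size=block_size)


def preprocess_triplet(
    blue: HyperspectralCube,
    dark: HyperspectralCube,
    white: HyperspectralCube,
    band_a: tuple[float, float] = DEFAULT_BAND_A,
    band_b: tuple[float, float] = DEFAULT_BAND_B,
    block_size: int = 10,
    exclude_artifacts: bool = True,
    mask: TumorMask | None = None,
) -> BlockSpectra:
    """Full preprocessing chain: dark-correct, segment, extract, normalize.

    The white reference is dark-corrected and averaged over the same tiles, so
    each block spectrum is divided by its own tile-local dual-band factor; the
    factors are kept in ``norm_factors`` so abundance estimates can be mapped
    back to raw count units when needed.
    """
    corrected = dark_correct(blue, dark)
    if mask is None:
        mask = segment_tumor(corrected, exclude_artifacts=exclude_artifacts)
    blocks = extract_block_spectra(corrected, mask, block_size=block_size)
    if len(blocks) == 0:
        return blocks
    white_corr = np.clip(white.data.astype(np.float64) - dark.data, 0.0, None)
    factors = np.empty(len(blocks))
    for i, (r, c) in enumerate(blocks.block_origin):
        tile = white_corr[r : r + block_size, c : c + block_size].mean(axis=(0, 1))
        ra = _band_means(tile, white.grid, band_a)
        rb = _band_means(tile, white.grid, band_b)
        if ra <= 0 or rb <= 0:
            raise DegenerateReferenceError("white reference non-positive in a tile")
        factors[i] = np.sqrt(ra * rb)
    return BlockSpectra(
        grid=blocks.grid,
        values=blocks.values / factors[:, None],
        block_origin=blocks.block_origin,
        block_size=block_size,
        norm_factors=factors,
    )
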