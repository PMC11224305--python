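"""Wavelength grids, fluorophore emission bases, and non-negative least-squares unmixing.

A measured emission spectrum ``y`` (counts per band over the visible range) is
modeled as a non-negative linear combination of five fluorophore basis spectra:
the two photo-states of protoporphyrin IX (PpIX634, PpIX620) plus the
autofluorescent NADH, lipofuscin, and flavins.  With the basis spectra stacked
as columns of ``B``, the abundance vector ``c`` solves

    c = argmin_c  1/2 * ||y - B c||^2   subject to  c >= 0.

The canonical internal grid has 310 bands at 1 nm from 420 to 729 nm; coarser
instrument grids (liquid-crystal tunable filters sweep in 3-5 nm steps) are
supported by resampling spectra and bases onto a common grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import FormatError, GridMismatchError

__all__ = [
    "FLUOROPHORES",
    "WavelengthGrid",
    "FluorophoreBasis",
    "Spectrum",
    "AbundanceVector",
    "PeakShape",
    "DEFAULT_PEAKS",
    "build_synthetic_basis",
    "save_basis_csv",
    "load_basis_csv",
    "resample_to_grid",
    "resample_basis",
    "unmix_nnls",
    "unmix_many",
    "reconstruct_spectrum",
]

#: Canonical fluorophore order used everywhere in the package.
FLUOROPHORES: tuple[str, ...] = ("PpIX634", "PpIX620", "NADH", "lipofuscin", "flavins")

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True, eq=False)
class WavelengthGrid:
    """Ordered band-center wavelengths in nanometres."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("grid needs at least two band centers")
        if not np.all(np.diff(vals) > 0):
            raise ValueError("band centers must be strictly increasing")
        object.__setattr__(self, "values", vals)

    @classmethod
    def default(cls) -> "WavelengthGrid":
        """310 bands at 1 nm covering 420-729 nm."""
        return cls(np.arange(420.0, 730.0, 1.0))

    @classmethod
    def from_step(cls, start_nm: float, stop_nm: float, step_nm: float) -> "WavelengthGrid":
        return cls(np.arange(start_nm, stop_nm + 1e-9, step_nm))

    @property
    def start_nm(self) -> float:
        return float(self.values[0])

    @property
    def stop_nm(self) -> float:
        return float(self.values[-1])

    @property
    def n_bands(self) -> int:
        return int(self.values.size)

    def nearest_band(self, wavelength_nm: float) -> int:
        return int(np.argmin(np.abs(self.values - wavelength_nm)))

    def window_mask(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Boolean mask of bands whose centers fall in [lo_nm, hi_nm]."""
        return (self.values >= lo_nm) & (self.values <= hi_nm)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, WavelengthGrid)
            and self.values.shape == other.values.shape
            and bool(np.allclose(self.values, other.values))
        )

    def __len__(self) -> int:
        return self.n_bands


@dataclass(frozen=True, eq=False)
class Spectrum:
    """A single emission spectrum on a wavelength grid (arbitrary count units)."""

    grid: WavelengthGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (self.grid.n_bands,):
            raise GridMismatchError(
                f"spectrum length {vals.shape} does not match grid ({self.grid.n_bands} bands)"
            )
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class AbundanceVector:
    """Non-negative fluorophore abundances and the residual of the NNLS fit."""

    values: np.ndarray
    residual_norm: float

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if np.any(vals < 0):
            raise ValueError("abundances must be non-negative")
        if self.residual_norm < 0:
            raise ValueError("residual norm must be non-negative")


@dataclass(frozen=True, eq=False)
class FluorophoreBasis:
    """Endmember emission spectra as columns of a non-negative matrix B."""

    grid: WavelengthGrid
    matrix: np.ndarray
    names: tuple[str, ...] = FLUOROPHORES
    normalization: str = "peak"

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[0] != self.grid.n_bands:
            raise GridMismatchError("basis rows must match the grid length")
        if mat.shape[1] != len(self.names):
            raise ValueError("one name per basis column required")
        if np.any(mat < 0):
            raise ValueError("basis entries must be non-negative")
        if np.any(mat.max(axis=0) <= 0):
            raise ValueError("basis has an all-zero column")
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def n_fluorophores(self) -> int:
        return self.matrix.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def with_column(self, name: str, values: np.ndarray) -> "FluorophoreBasis":
        """Return a basis extended by one endmember (used e.g. for residual studies)."""
        col = np.asarray(values, dtype=float).reshape(-1, 1)
        return FluorophoreBasis(
            grid=self.grid,
            matrix=np.hstack([self.matrix, col]),
            names=self.names + (name,),
            normalization=self.normalization,
        )


@dataclass(frozen=True)
class PeakShape:
    """Skew-normal emission peak: location given as the mode, width as FWHM."""

    name: str
    center_nm: float
    fwhm_nm: float
    skew: float = 0.0


#: Default synthetic endmember shapes.  PpIX peak positions (634 / 620 nm) are
#: the physically established ones; the autofluorophore centers/widths are
#: literature-typical stand-ins so that the pipeline is self-contained.  Real
#: endmember tables can be dropped in via :func:`load_basis_csv`.
DEFAULT_PEAKS: tuple[PeakShape, ...] = (
    PeakShape("PpIX634", 634.0, 20.0, 3.0),
    PeakShape("PpIX620", 620.0, 25.0, 2.0),
    PeakShape("NADH", 460.0, 100.0, 1.5),
    PeakShape("lipofuscin", 570.0, 120.0, 0.0),
    PeakShape("flavins", 525.0, 80.0, 2.0),
)


def _skewnorm_mode_std(a: float) -> float:
    """Mode of the standardized skew-normal, located numerically."""
    if a == 0.0:
        return 0.0
    res = optimize.minimize_scalar(
        lambda x: -stats.skewnorm.pdf(x, a), bounds=(-3.0, 3.0), method="bounded"
    )
    return float(res.x)


def _normalize_columns(mat: np.ndarray, grid: WavelengthGrid, mode: str) -> np.ndarray:
    if mode == "peak":
        return mat / mat.max(axis=0, keepdims=True)
    if mode == "area":
        areas = np.trapezoid(mat, grid.values, axis=0)
        return mat / areas[np.newaxis, :]
    raise ValueError(f"unknown normalization mode: {mode!r}")


def build_synthetic_basis(
    grid: WavelengthGrid | None = None,
    peaks: Sequence[PeakShape] = DEFAULT_PEAKS,
    normalization: str = "peak",
) -> FluorophoreBasis:
    """Construct a parameterized endmember basis from skew-normal peaks.

    Each column is a skew-normal density re-located so that its mode sits at
    ``center_nm`` (so e.g. the PpIX634 column attains its maximum at the band
    nearest 634 nm), then normalized per ``normalization``.
    """
    if grid is None:
        grid = WavelengthGrid.default()
    cols = []
    for pk in peaks:
        if not (grid.start_nm <= pk.center_nm <= grid.stop_nm):
            raise ValueError(
                f"peak center {pk.center_nm} nm of {pk.name!r} outside grid "
                f"[{grid.start_nm}, {grid.stop_nm}]"
            )
        if pk.fwhm_nm <= 0:
            raise ValueError(f"width of {pk.name!r} must be positive")
        scale = pk.fwhm_nm * _FWHM_TO_SIGMA
        loc = pk.center_nm - _skewnorm_mode_std(pk.skew) * scale
        col = stats.skewnorm.pdf(grid.values, pk.skew, loc=loc, scale=scale)
        cols.append(col)
    mat = _normalize_columns(np.column_stack(cols), grid, normalization)
    return FluorophoreBasis(
        grid=grid,
        matrix=mat,
        names=tuple(pk.name for pk in peaks),
        normalization=normalization,
    )


def save_basis_csv(basis: FluorophoreBasis, path: str | Path) -> None:
    """Write a basis to CSV with header ``wavelength_nm,<name1>,...``."""
    frame = pd.DataFrame(basis.matrix, columns=list(basis.names))
    frame.insert(0, "wavelength_nm", basis.grid.values)
    frame.to_csv(path, index=False, float_format="%.17g")


def load_basis_csv(path: str | Path, normalization: str = "as-is") -> FluorophoreBasis:
    """Read an endmember table written by :func:`save_basis_csv` (or external)."""
    frame = pd.read_csv(path)
    if "wavelength_nm" not in frame.columns:
        raise FormatError("basis CSV must have a 'wavelength_nm' column")
    names = tuple(c for c in frame.columns if c != "wavelength_nm")
    if not names:
        raise FormatError("basis CSV has no fluorophore columns")
    wl = frame["wavelength_nm"].to_numpy(dtype=float)
    if not np.all(np.diff(wl) > 0):
        raise FormatError("basis CSV wavelengths must be strictly increasing")
    mat = frame[list(names)].to_numpy(dtype=float)
    grid = WavelengthGrid(wl)
    if normalization in ("peak", "area"):
        mat = _normalize_columns(mat, grid, normalization)
    return FluorophoreBasis(grid=grid, matrix=mat, names=names, normalization=normalization)


def resample_to_grid(spectrum: Spectrum, target: WavelengthGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``target``; clip at zero.

    ``target`` must lie within the source grid's range (no extrapolation).
    """
    src = spectrum.grid
    if target.start_nm < src.start_nm - 1e-9 or target.stop_nm > src.stop_nm + 1e-9:
        raise ValueError("target grid extends beyond the source grid")
    vals = np.interp(target.values, src.values, spectrum.values)
    return Spectrum(grid=target, values=np.clip(vals, 0.0, None))


def resample_basis(basis: FluorophoreBasis, target: WavelengthGrid) -> FluorophoreBasis:
    """Resample every endmember column onto ``target`` (linear, clipped at 0)."""
    cols = [
        resample_to_grid(Spectrum(basis.grid, basis.matrix[:, j]), target).values
        for j in range(basis.n_fluorophores)
    ]
    return replace(basis, grid=target, matrix=np.column_stack(cols))


def unmix_nnls(y: Spectrum | np.ndarray, basis: FluorophoreBasis) -> AbundanceVector:
    """Solve ``min ||y - B c||^2  s.t.  c >= 0`` for one spectrum.

    The active-set solution satisfies the KKT conditions: the gradient
    ``g = B'(Bc - y)`` vanishes on the support and is non-negative off it.
    """
    if isinstance(y, Spectrum):
        if y.grid != basis.grid:
            raise GridMismatchError("spectrum and basis are on different grids")
        yv = y.values
    else:
        yv = np.asarray(y, dtype=float)
        if yv.shape != (basis.grid.n_bands,):
            raise GridMismatchError("spectrum length does not match the basis grid")
    coef, rnorm = optimize.nnls(basis.matrix, yv)
    return AbundanceVector(values=coef, residual_norm=float(rnorm))


def unmix_many(spectra: np.ndarray, basis: FluorophoreBasis) -> tuple[np.ndarray, np.ndarray]:
    """Unmix an ``(n, n_bands)`` array row-wise; returns (abundances, residual norms)."""
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2 or spectra.shape[1] != basis.grid.n_bands:
        raise GridMismatchError("spectra must be (n, n_bands) on the basis grid")
    out = np.empty((spectra.shape[0], basis.n_fluorophores))
    res = np.empty(spectra.shape[0])
    for i, row in enumerate(spectra):
        coef, rnorm = optimize.nnls(basis.matrix, row)
        out[i] = coef
        res[i] = rnorm
    return out, res


def reconstruct_spectrum(c: AbundanceVector | np.ndarray, basis: FluorophoreBasis) -> Spectrum:
    """Forward model: the spectrum ``B c`` implied by an abundance vector."""
    vals = c.values if isinstance(c, AbundanceVector) else np.asarray(c, dtype=float)
    return Spectrum(grid=basis.grid, values=basis.matrix @ vals)
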