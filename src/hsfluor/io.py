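"""On-disk formats: multi-band TIFF cubes with JSON sidecars, spectra CSVs.

A cube is stored as a band-interleaved multi-page TIFF (one page per band)
next to a JSON sidecar carrying the wavelength grid, illumination phase,
exposure, pixel pitch, seed and labels.  Block spectra travel as a wide CSV
with one column per band.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .exceptions import FormatError
from .preprocess import BlockSpectra, HyperspectralCube
from .spectral import WavelengthGrid

__all__ = [
    "write_cube",
    "read_cube",
    "write_cube_triplet",
    "read_cube_triplet",
    "write_block_spectra_csv",
    "read_block_spectra_csv",
]


def write_cube(
    cube: HyperspectralCube,
    path: str | Path,
    seed: int | None = None,
    labels: dict | None = None,
) -> Path:
    """Write one cube as multi-page TIFF + ``<stem>.json`` sidecar."""
    path = Path(path)
    # pages = bands: (n_bands, H, W)
    tifffile.imwrite(path, np.moveaxis(cube.data.astype(np.float32), 2, 0))
    sidecar = {
        "grid_nm": [float(v) for v in cube.grid.values],
        "phase": cube.phase,
        "exposure_ms": cube.exposure_ms,
        "px_per_mm": cube.px_per_mm,
        "seed": seed,
        "labels": labels or {},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True, indent=1))
    return path


def read_cube(path: str | Path) -> HyperspectralCube:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"cube sidecar missing: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    data = np.moveaxis(tifffile.imread(path), 0, 2)
    return HyperspectralCube(
        data=data,
        grid=WavelengthGrid(np.asarray(meta["grid_nm"], dtype=float)),
        phase=meta["phase"],
        exposure_ms=float(meta.get("exposure_ms", 500.0)),
        px_per_mm=float(meta.get("px_per_mm", 47.62)),
    )


def write_cube_triplet(
    triplet, directory: str | Path, stem: str, seed: int | None = None,
    labels: dict | None = None,
) -> dict[str, Path]:
    """Write a (blue, dark, white) triplet under ``directory`` as ``<stem>_<phase>.tif``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for cube in triplet:
        out[cube.phase] = write_cube(
            cube, directory / f"{stem}_{cube.phase}.tif", seed=seed, labels=labels
        )
    return out


def read_cube_triplet(directory: str | Path, stem: str):
    directory = Path(directory)
    cubes = []
    for phase in ("blue", "dark", "white"):
        p = directory / f"{stem}_{phase}.tif"
        if not p.exists():
            raise FormatError(f"missing {phase} cube: {p}")
        cubes.append(read_cube(p))
    return tuple(cubes)


def write_block_spectra_csv(
    blocks: BlockSpectra, path: str | Path, biopsy_id: str = "B0000"
) -> None:
    """Wide spectra CSV: sample_id, biopsy_id, block coords, one column per band."""
    cols = [f"{v:.6g}" for v in blocks.grid.values]
    frame = pd.DataFrame(blocks.values, columns=cols)
    frame.insert(0, "sample_id", [f"{biopsy_id}_{i:05d}" for i in range(len(blocks))])
    frame.insert(1, "biopsy_id", biopsy_id)
    frame.insert(2, "block_row", blocks.block_origin[:, 0])
    frame.insert(3, "block_col", blocks.block_origin[:, 1])
    if blocks.norm_factors is not None:
        frame["norm_factor"] = blocks.norm_factors
    frame.to_csv(path, index=False, float_format="%.9g")


def read_block_spectra_csv(path: str | Path) -> tuple[pd.DataFrame, BlockSpectra]:
    """Read a wide spectra CSV; returns (metadata frame, BlockSpectra)."""
    frame = pd.read_csv(path)
    meta_cols = [c for c in ("sample_id", "biopsy_id", "block_row", "block_col", "norm_factor")
                 if c in frame.columns]
    band_cols = [c for c in frame.columns if c not in meta_cols]
    try:
        wl = np.array([float(c) for c in band_cols])
    except ValueError as exc:
        raise FormatError("spectra CSV band columns must be wavelengths") from exc
    if not np.all(np.diff(wl) > 0):
        raise FormatError("spectra CSV wavelengths must be strictly increasing")
    origin = (
        frame[["block_row", "block_col"]].to_numpy()
        if {"block_row", "block_col"} <= set(frame.columns)
        else np.zeros((len(frame), 2), dtype=int)
    )
    blocks = BlockSpectra(
        grid=WavelengthGrid(wl),
        values=frame[band_cols].to_numpy(dtype=float),
        block_origin=origin,
        norm_factors=frame["norm_factor"].to_numpy() if "norm_factor" in frame.columns else None,
    )
    return frame[meta_cols], blocks
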