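"""Synthetic labeled hyperspectral biopsies.

No public accession exists for the ex vivo patient measurements this pipeline
targets, so this module generates datasets with the statistical structure the
analysis assumes:

* class-conditional fluorophore abundances, log-normal with a shared
  per-biopsy random effect on the log scale;
* biopsy geometry: a roughly circular sample of 4-10 mm diameter (190-476 px
  at 47.62 px/mm) on a glass background inside the camera field, optionally
  with a bright fluid splash next to the tissue;
* the acquisition protocol's illumination triplet: blue (405 nm excitation,
  fluorescence = B.c per pixel), dark (sensor offset + read noise) and
  broadband white (reflectance reference), with a Gaussian read +
  Gaussian-approximated shot-noise sensor model.

Class rosters for the four tasks (tissue type, margin, WHO grade, IDH status)
default to the published cohort sizes; a separability knob ``delta`` scales
between-class mean differences (``delta = 0`` is an exact null).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import GeometryError
from .spectral import FLUOROPHORES, FluorophoreBasis, WavelengthGrid

__all__ = [
    "ClassProfile",
    "AcquisitionNoiseModel",
    "BiopsyPhantom",
    "SimulatedDataset",
    "COHORT_ROSTERS",
    "TASKS",
    "class_profiles",
    "sample_abundances",
    "make_phantom",
    "simulate_biopsy_cube",
    "simulate_dataset",
    "blocks_in_disk",
    "PX_PER_MM",
    "FIELD_SHAPE_FULL",
]

PX_PER_MM = 47.62
FIELD_SHAPE_FULL = (2048, 2048)
DEFAULT_EXPOSURE_MS = 500.0
TASKS = ("tissue_type", "margin", "who_grade", "idh")

#: Published per-class biopsy counts used as default rosters.
COHORT_ROSTERS: dict[str, dict[str, int]] = {
    "tissue_type": {
        "PA": 5, "DA": 57, "AA": 51, "GB": 410, "OD": 24, "GG": 4,
        "MB": 6, "AE": 8, "AO": 4, "MN": 37, "MT": 6, "RN": 20,
    },
    "margin": {"ST": 131, "IZ": 57, "RABT": 100},
    "who_grade": {"I": 9, "II": 84, "III": 57, "IV": 421},
    "idh": {"mutant": 126, "wildtype": 285},
}

#: Baseline log-abundance (arbitrary count units, peak-normalized basis).
BASE_LOG_ABUNDANCE = np.log(np.array([1.0, 0.55, 0.6, 0.4, 0.5]))

# Per-class mean-shift directions on the log scale, applied as
# mean = BASE + delta * offset.  Order: [PpIX634, PpIX620, NADH, lipofuscin,
# flavins].  Margin/grade/IDH shifts encode the expected biology (PpIX rises
# with tumor content and grade, autofluorescence relatively falls); the tissue
# type offsets are synthetic stand-ins chosen to be mutually spread out.
_OFFSETS: dict[str, dict[str, list[float]]] = {
    "margin": {
        "ST": [0.90, 0.60, -0.30, -0.25, -0.35],
        "IZ": [0.30, 0.15, 0.05, 0.10, 0.00],
        "RABT": [-0.60, -0.45, 0.35, 0.40, 0.30],
    },
    "who_grade": {
        "I": [-0.80, -0.60, 0.50, 0.30, 0.40],
        "II": [-0.35, -0.25, 0.20, 0.15, 0.20],
        "III": [0.30, 0.25, -0.15, -0.10, -0.15],
        "IV": [0.90, 0.70, -0.40, -0.30, -0.40],
    },
    "idh": {
        "mutant": [-0.45, -0.30, 0.25, 0.20, 0.15],
        "wildtype": [0.45, 0.30, -0.25, -0.20, -0.15],
    },
    "tissue_type": {
        "PA": [-0.55, -0.35, 0.45, -0.30, 0.35],
        "DA": [-0.25, -0.15, 0.20, 0.15, 0.10],
        "AA": [0.25, 0.20, -0.10, 0.05, -0.15],
        "GB": [0.85, 0.60, -0.35, -0.25, -0.40],
        "OD": [-0.10, 0.35, 0.30, -0.20, -0.30],
        "GG": [-0.70, -0.50, -0.20, 0.45, 0.40],
        "MB": [0.40, -0.45, 0.40, 0.35, -0.25],
        "AE": [0.55, 0.45, 0.35, -0.40, 0.25],
        "AO": [0.05, 0.55, -0.40, 0.30, 0.35],
        "MN": [-0.45, 0.25, -0.35, -0.45, -0.20],
        "MT": [0.30, -0.30, -0.45, 0.40, 0.45],
        "RN": [-0.85, -0.60, 0.55, 0.50, 0.50],
    },
}

# Fraction of biopsies that are IDH-wildtype, by tissue type (used so that the
# WHO-2021 relabeling rule has material to act on in tissue-type datasets).
_WILDTYPE_FRACTION: dict[str, float] = {
    "PA": 0.9, "DA": 0.2, "AA": 0.6, "GB": 0.9, "OD": 0.05, "GG": 0.5,
    "MB": 0.5, "AE": 0.5, "AO": 0.05, "MN": 0.5, "MT": 0.5, "RN": 0.5,
}


@dataclass(frozen=True)
class ClassProfile:
    """Class-conditional abundance distribution (log-normal with biopsy effect)."""

    label: str
    task: str
    mean_log_abundance: np.ndarray
    sd_log_abundance: np.ndarray
    biopsy_effect_sd: float = 0.15

    def __post_init__(self) -> None:
        mu = np.asarray(self.mean_log_abundance, dtype=float)
        sd = np.asarray(self.sd_log_abundance, dtype=float)
        if mu.shape != (5,) or sd.shape != (5,):
            raise ValueError("profiles are over the five fluorophores")
        if np.any(sd < 0) or self.biopsy_effect_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        object.__setattr__(self, "mean_log_abundance", mu)
        object.__setattr__(self, "sd_log_abundance", sd)


def class_profiles(
    task: str,
    delta: float = 1.0,
    sd_log: float = 0.3,
    biopsy_effect_sd: float = 0.15,
) -> list[ClassProfile]:
    """Preset profiles for one task; ``delta`` scales between-class separation."""
    if task not in _OFFSETS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    profiles = []
    for label, off in _OFFSETS[task].items():
        mu = BASE_LOG_ABUNDANCE + delta * np.asarray(off)
        profiles.append(
            ClassProfile(
                label=label,
                task=task,
                mean_log_abundance=mu,
                sd_log_abundance=np.full(5, sd_log),
                biopsy_effect_sd=biopsy_effect_sd,
            )
        )
    return profiles


def sample_abundances(
    profile: ClassProfile,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` abundance vectors for one biopsy of the given class.

    One biopsy-level random effect is drawn per call and shared by all rows:
    log c = mean + b + eps,  b ~ N(0, biopsy_effect_sd^2 I),
    eps ~ N(0, diag(sd_log^2)).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    b = rng.normal(0.0, profile.biopsy_effect_sd, size=5)
    eps = rng.normal(0.0, 1.0, size=(n, 5)) * profile.sd_log_abundance
    return np.exp(profile.mean_log_abundance + b + eps)


@dataclass(frozen=True)
class AcquisitionNoiseModel:
    """sCMOS sensor model: constant dark offset, Gaussian read noise, and a
    Gaussian approximation of shot noise with variance = gain * signal."""

    read_noise_sd: float = 2.0
    shot_noise_gain: float = 0.5
    dark_offset: float = 100.0

    def __post_init__(self) -> None:
        if min(self.read_noise_sd, self.shot_noise_gain, self.dark_offset) < 0:
            raise ValueError("noise parameters must be non-negative")

    @classmethod
    def noiseless(cls, dark_offset: float = 100.0) -> "AcquisitionNoiseModel":
        return cls(read_noise_sd=0.0, shot_noise_gain=0.0, dark_offset=dark_offset)


@dataclass
class BiopsyPhantom:
    """Ground-truth biopsy: tissue mask and per-pixel abundance field."""

    biopsy_id: str
    labels: dict[str, str]
    diameter_px: float
    abundance_field: np.ndarray  # (H, W, 5), zero outside tissue
    tissue_mask: np.ndarray  # (H, W) bool
    artifact_mask: np.ndarray | None = None
    has_fluid_artifact: bool = False

    @property
    def field_shape(self) -> tuple[int, int]:
        return self.tissue_mask.shape


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def make_phantom(
    biopsy_id: str,
    profile: ClassProfile,
    diameter_px: float = 288.0,
    seed: int | None = None,
    field_shape: tuple[int, int] = (512, 512),
    has_fluid_artifact: bool = False,
    correlation_length_px: float = 20.0,
    labels: Mapping[str, str] | None = None,
) -> BiopsyPhantom:
    """Render a circular biopsy with a spatially smooth abundance field.

    The per-pixel log-abundance is mean + biopsy effect + sd * smooth field,
    where the smooth field is unit-variance Gaussian-filtered white noise
    (stand-in for the unknown within-biopsy correlation structure).
    """
    rng = np.random.default_rng(seed)
    radius = diameter_px / 2.0
    margin = 36.0 if has_fluid_artifact else 2.0
    if diameter_px + 2 * margin > min(field_shape):
        raise GeometryError(
            f"phantom of diameter {diameter_px} px does not fit field {field_shape}"
        )
    center = (field_shape[0] / 2.0, field_shape[1] / 2.0)
    tissue = _disk_mask(field_shape, center, radius)

    b_eff = rng.normal(0.0, profile.biopsy_effect_sd, size=5)
    log_field = np.empty(field_shape + (5,), dtype=np.float32)
    for k in range(5):
        white = rng.normal(size=field_shape)
        smooth = ndimage.gaussian_filter(white, sigma=correlation_length_px)
        sd = smooth.std()
        smooth = smooth / sd if sd > 0 else smooth
        log_field[:, :, k] = (
            profile.mean_log_abundance[k] + b_eff[k] + profile.sd_log_abundance[k] * smooth
        )
    abundance = np.exp(log_field, dtype=np.float32)
    abundance[~tissue] = 0.0

    artifact = None
    if has_fluid_artifact:
        angle = rng.uniform(0, 2 * np.pi)
        art_r = rng.uniform(18.0, 30.0)
        dist = radius + art_r + 4.0
        art_center = (center[0] + dist * np.sin(angle), center[1] + dist * np.cos(angle))
        artifact = _disk_mask(field_shape, art_center, art_r) & ~tissue
        if not artifact.any():  # fell outside the field; retry opposite side
            art_center = (center[0] - dist * np.sin(angle), center[1] - dist * np.cos(angle))
            artifact = _disk_mask(field_shape, art_center, art_r) & ~tissue

    task_labels = dict(labels) if labels is not None else {profile.task: profile.label}
    return BiopsyPhantom(
        biopsy_id=biopsy_id,
        labels=task_labels,
        diameter_px=diameter_px,
        abundance_field=abundance,
        tissue_mask=tissue,
        artifact_mask=artifact,
        has_fluid_artifact=has_fluid_artifact,
    )


def simulate_biopsy_cube(
    phantom: BiopsyPhantom,
    basis: FluorophoreBasis,
    noise: AcquisitionNoiseModel | None = None,
    seed: int | None = None,
    illumination: float = 500.0,
    white_reflectance: float = 1.0,
    tissue_attenuation: float = 1.0,
    dtype=np.float32,
):
    """Simulate the blue/dark/white illumination triplet for one phantom.

    Blue-phase tissue pixels carry fluorescence ``illumination * B . c(pixel)``
    plus the dark offset and sensor noise; glass background pixels carry no
    fluorescence.  The white-phase cube is a flat reflectance reference
    (optionally attenuated over tissue); the dark cube is offset + read noise.
    ``illumination`` converts unit abundance to sensor counts (default 500,
    i.e. order-100s of counts at the 500 ms exposure, well above read noise).
    Dual-band normalization cancels this factor downstream.  Returns a
    ``(blue, dark, white)`` triplet of :class:`~hsfluor.preprocess.HyperspectralCube`.
    """
    from .preprocess import HyperspectralCube  # local import to avoid a cycle

    if noise is None:
        noise = AcquisitionNoiseModel()
    rng = np.random.default_rng(seed)
    h, w = phantom.field_shape
    n_bands = basis.grid.n_bands
    if phantom.abundance_field.shape[2] != basis.n_fluorophores:
        raise ValueError("phantom abundance channels do not match the basis")

    signal = np.einsum(
        "hwk,lk->hwl", phantom.abundance_field.astype(dtype), basis.matrix.astype(dtype)
    ).astype(dtype)
    signal *= illumination
    if phantom.artifact_mask is not None and phantom.has_fluid_artifact:
        # bright, spectrally broad splash of fluid next to the tissue
        art_spec = np.exp(-0.5 * ((basis.grid.values - 550.0) / 90.0) ** 2)
        art_amp = 3.0 * float(signal.max()) if signal.max() > 0 else 1.0
        signal[phantom.artifact_mask] = (art_amp * art_spec).astype(dtype)

    def _noisy(mean: np.ndarray, with_shot: bool) -> np.ndarray:
        out = mean.astype(dtype, copy=True)
        if with_shot and noise.shot_noise_gain > 0:
            out += rng.normal(size=mean.shape).astype(dtype) * np.sqrt(
                noise.shot_noise_gain * np.clip(mean, 0, None), dtype=dtype
            )
        if noise.read_noise_sd > 0:
            out += rng.normal(0.0, noise.read_noise_sd, size=mean.shape).astype(dtype)
        return out

    blue = _noisy(signal + dtype(noise.dark_offset), with_shot=True)

    dark = np.full((h, w, n_bands), noise.dark_offset, dtype=dtype)
    dark = _noisy(dark, with_shot=False)

    refl = np.full((h, w), illumination * white_reflectance, dtype=dtype)
    refl[phantom.tissue_mask] *= tissue_attenuation
    white = np.repeat(refl[:, :, None], n_bands, axis=2) + dtype(noise.dark_offset)
    white = _noisy(white, with_shot=False)

    meta = dict(px_per_mm=PX_PER_MM, exposure_ms=DEFAULT_EXPOSURE_MS)
    return (
        HyperspectralCube(data=blue, grid=basis.grid, phase="blue", **meta),
        HyperspectralCube(data=dark, grid=basis.grid, phase="dark", **meta),
        HyperspectralCube(data=white, grid=basis.grid, phase="white", **meta),
    )


def blocks_in_disk(diameter_px: float, block_size: int = 10) -> np.ndarray:
    """Origins (row, col) of non-overlapping tiles fully inside a centered disk."""
    radius = diameter_px / 2.0
    n = int(np.ceil(diameter_px / block_size))
    origins = []
    for i in range(n):
        for j in range(n):
            r0, c0 = i * block_size, j * block_size
            corners = np.array(
                [[r0, c0], [r0 + block_size, c0], [r0, c0 + block_size],
                 [r0 + block_size, c0 + block_size]],
                dtype=float,
            )
            d = np.hypot(corners[:, 0] - radius, corners[:, 1] - radius)
            if d.max() <= radius:
                origins.append((r0, c0))
    return np.array(origins, dtype=int).reshape(-1, 2)


@dataclass
class SimulatedDataset:
    """Block-level labeled abundances for one task, reproducible from its seed."""

    task: str
    blocks: pd.DataFrame
    profiles: list[ClassProfile]
    seed: int
    provenance: dict = field(default_factory=dict)

    @property
    def abundance_columns(self) -> list[str]:
        return [f"c_{name}" for name in FLUOROPHORES]

    def abundances(self) -> np.ndarray:
        return self.blocks[self.abundance_columns].to_numpy()

    def to_csv(self, path) -> None:
        self.blocks.to_csv(path, index=False, float_format="%.9g")

    def manifest(self) -> pd.DataFrame:
        per = (
            self.blocks.groupby("biopsy_id", sort=True)
            .agg(
                task=("task", "first"),
                label=("label", "first"),
                n_pixels=("biopsy_id", "size"),
                has_fluid_artifact=("has_fluid_artifact", "first"),
                seed=("seed", "first"),
            )
            .reset_index()
        )
        return per


def simulate_dataset(
    task: str,
    class_profiles_list: Sequence[ClassProfile] | None = None,
    n_biopsies_per_class: int | Mapping[str, int] | None = None,
    seed: int = 0,
    delta: float = 1.0,
    block_size: int = 10,
    diameter_range_px: tuple[float, float] = (190.0, 476.0),
    mode_diameter_px: float = 288.0,
    fluid_artifact_rate: float = 0.05,
) -> SimulatedDataset:
    """Generate a labeled block-abundance dataset for one classification task.

    Each biopsy gets a diameter (triangular over the 4-10 mm range, mode 6 mm),
    a set of non-overlapping 10x10 tile positions inside its disk, a shared
    biopsy random effect, and iid log-normal block abundances.  Rosters default
    to the published per-class biopsy counts.
    """
    if class_profiles_list is None:
        class_profiles_list = class_profiles(task, delta=delta)
    if len(class_profiles_list) < 2:
        raise ValueError("at least two classes are required")
    rng = np.random.default_rng(seed)
    rows = []
    biopsy_counter = 0
    for profile in class_profiles_list:
        if n_biopsies_per_class is None:
            n_biop = COHORT_ROSTERS.get(task, {}).get(profile.label)
            if n_biop is None:
                raise ValueError(f"no default roster for class {profile.label!r}")
        elif isinstance(n_biopsies_per_class, Mapping):
            n_biop = n_biopsies_per_class[profile.label]
        else:
            n_biop = int(n_biopsies_per_class)
        for _ in range(n_biop):
            bid = f"B{biopsy_counter:04d}"
            biopsy_counter += 1
            diam = rng.triangular(diameter_range_px[0], mode_diameter_px, diameter_range_px[1])
            origins = blocks_in_disk(diam, block_size=block_size)
            n_blocks = len(origins)
            ab = sample_abundances(profile, n_blocks, rng=rng)
            has_art = bool(rng.random() < fluid_artifact_rate)
            frame = pd.DataFrame(ab, columns=[f"c_{n}" for n in FLUOROPHORES])
            frame.insert(0, "biopsy_id", bid)
            frame.insert(1, "task", task)
            frame.insert(2, "label", profile.label)
            frame.insert(3, "tile_row", origins[:, 0])
            frame.insert(4, "tile_col", origins[:, 1])
            frame["diameter_px"] = round(float(diam), 3)
            frame["has_fluid_artifact"] = has_art
            frame["seed"] = seed
            if task == "tissue_type":
                p_wt = _WILDTYPE_FRACTION.get(profile.label, 0.5)
                frame["idh"] = "wildtype" if rng.random() < p_wt else "mutant"
            rows.append(frame)
    blocks = pd.concat(rows, ignore_index=True)
    provenance = {
        "task": task,
        "delta": delta,
        "seed": seed,
        "classes": [p.label for p in class_profiles_list],
        "n_biopsies": biopsy_counter,
        "block_size": block_size,
    }
    return SimulatedDataset(
        task=task, blocks=blocks, profiles=list(class_profiles_list), seed=seed,
        provenance=provenance,
    )
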