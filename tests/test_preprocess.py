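"""Dark correction, dual-band normalization, segmentation, block extraction."""

import numpy as np
import pytest
from skimage import measure

from hsfluor.exceptions import DegenerateReferenceError, GridMismatchError
from hsfluor.preprocess import (
    HyperspectralCube,
    dark_correct,
    dual_band_normalize,
    extract_block_spectra,
    preprocess_triplet,
    segment_tumor,
)
from hsfluor.simulate import (
    AcquisitionNoiseModel,
    class_profiles,
    make_phantom,
    simulate_biopsy_cube,
)
from hsfluor.spectral import Spectrum, unmix_many


def _cube(data, grid, phase="blue"):
    return HyperspectralCube(data=np.asarray(data, dtype=float), grid=grid, phase=phase)


class TestDarkCorrect:
    def test_zero_dark_is_identity(self, coarse_grid):
        rng = np.random.default_rng(0)
        blue = _cube(rng.uniform(0, 10, (8, 8, coarse_grid.n_bands)), coarse_grid)
        dark = _cube(np.zeros_like(blue.data), coarse_grid, "dark")
        np.testing.assert_array_equal(dark_correct(blue, dark).data, blue.data)

    def test_blue_equals_dark_gives_zero(self, coarse_grid):
        data = np.full((4, 4, coarse_grid.n_bands), 7.0)
        out = dark_correct(_cube(data, coarse_grid), _cube(data, coarse_grid, "dark"))
        assert not out.data.any()

    def test_known_signal_recovered_exactly(self, coarse_grid):
        rng = np.random.default_rng(1)
        dark = rng.uniform(90, 110, (6, 6, coarse_grid.n_bands))
        signal = rng.uniform(0, 5, dark.shape)
        out = dark_correct(
            _cube(dark + signal, coarse_grid), _cube(dark, coarse_grid, "dark")
        )
        np.testing.assert_allclose(out.data, signal, atol=1e-12)

    def test_phase_mismatch_rejected(self, coarse_grid):
        a = _cube(np.zeros((4, 4, coarse_grid.n_bands)), coarse_grid, "blue")
        with pytest.raises(ValueError, match="phase"):
            dark_correct(a, a)


class TestDualBandNormalize:
    def test_unit_reference_is_identity(self, coarse_grid):
        y = Spectrum(coarse_grid, np.arange(coarse_grid.n_bands, dtype=float))
        white = Spectrum(coarse_grid, np.ones(coarse_grid.n_bands))
        np.testing.assert_array_equal(dual_band_normalize(y, white).values, y.values)

    def test_formula_with_unequal_band_means(self, coarse_grid):
        # white = 4 in band A (460-480), 1 in band B (620-640) -> divide by 2
        w = np.ones(coarse_grid.n_bands)
        w[coarse_grid.window_mask(460, 480)] = 4.0
        y = Spectrum(coarse_grid, np.full(coarse_grid.n_bands, 10.0))
        out = dual_band_normalize(y, Spectrum(coarse_grid, w))
        np.testing.assert_allclose(out.values, 5.0)

    def test_invariant_under_uniform_illumination_scaling(self, coarse_grid):
        rng = np.random.default_rng(2)
        y = rng.uniform(0, 5, coarse_grid.n_bands)
        w = rng.uniform(0.5, 2, coarse_grid.n_bands)
        base = dual_band_normalize(Spectrum(coarse_grid, y), Spectrum(coarse_grid, w))
        for alpha in (0.25, 3.0, 117.0):
            scaled = dual_band_normalize(
                Spectrum(coarse_grid, alpha * y), Spectrum(coarse_grid, alpha * w)
            )
            np.testing.assert_allclose(scaled.values, base.values, rtol=1e-12)

    def test_zero_reference_band_rejected(self, coarse_grid):
        y = Spectrum(coarse_grid, np.ones(coarse_grid.n_bands))
        white = Spectrum(coarse_grid, np.zeros(coarse_grid.n_bands))
        with pytest.raises(DegenerateReferenceError):
            dual_band_normalize(y, white)


class TestSegmentation:
    def _disk_cube(self, grid, centers_radii_values, shape=(128, 128)):
        data = np.zeros(shape + (grid.n_bands,))
        rr, cc = np.mgrid[: shape[0], : shape[1]]
        for (r, c), rad, val in centers_radii_values:
            inside = (rr - r) ** 2 + (cc - c) ** 2 <= rad**2
            data[inside] = val
        return _cube(data, grid)

    def test_bright_disk_on_dark_background(self, coarse_grid):
        cube = self._disk_cube(coarse_grid, [((64, 64), 30, 50.0)])
        mask = segment_tumor(cube).mask
        truth = self._disk_cube(coarse_grid, [((64, 64), 30, 1.0)]).data[:, :, 0] > 0
        jaccard = (mask & truth).sum() / (mask | truth).sum()
        assert jaccard >= 0.99

    def test_constant_cube_gives_empty_mask(self, coarse_grid):
        cube = _cube(np.zeros((64, 64, coarse_grid.n_bands)), coarse_grid)
        with pytest.warns(UserWarning, match="empty mask"):
            mask = segment_tumor(cube)
        assert not mask.mask.any()

    def test_artifact_excluded_as_smaller_component(self, coarse_grid):
        cube = self._disk_cube(
            coarse_grid, [((60, 50), 25, 40.0), ((20, 105), 10, 80.0)]
        )
        kept = segment_tumor(cube, exclude_artifacts=True).mask
        both = segment_tumor(cube, exclude_artifacts=False).mask
        # oracle: the kept mask must be the largest connected component of the
        # above-threshold image
        lab = measure.label(both)
        sizes = np.bincount(lab.ravel())[1:]
        largest = lab == (np.argmax(sizes) + 1)
        np.testing.assert_array_equal(kept, largest)
        assert kept.sum() < both.sum()  # the bright splash was dropped
        assert kept[60, 50] and not kept[20, 105]


class TestBlockExtraction:
    def test_40x40_mask_yields_exactly_16_blocks(self, coarse_grid):
        data = np.ones((64, 64, coarse_grid.n_bands))
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:50, 12:52] = True
        blocks = extract_block_spectra(_cube(data, coarse_grid), mask)
        assert len(blocks) == 16

    def test_constant_cube_gives_constant_spectra(self, coarse_grid):
        data = np.full((40, 40, coarse_grid.n_bands), 3.25)
        mask = np.ones((40, 40), dtype=bool)
        blocks = extract_block_spectra(_cube(data, coarse_grid), mask)
        np.testing.assert_allclose(blocks.values, 3.25)

    def test_9x9_mask_yields_no_blocks(self, coarse_grid):
        data = np.ones((32, 32, coarse_grid.n_bands))
        mask = np.zeros((32, 32), dtype=bool)
        mask[3:12, 3:12] = True
        assert len(extract_block_spectra(_cube(data, coarse_grid), mask)) == 0

    def test_blocks_are_pairwise_disjoint(self, coarse_grid):
        rng = np.random.default_rng(3)
        mask = rng.random((96, 96)) > 0.25
        data = np.ones((96, 96, coarse_grid.n_bands))
        blocks = extract_block_spectra(_cube(data, coarse_grid), mask)
        painted = np.zeros((96, 96), dtype=int)
        for r, c in blocks.block_origin:
            painted[r : r + 10, c : c + 10] += 1
        assert painted.max() <= 1
        assert mask[painted > 0].all()  # blocks fully inside the mask


class TestEndToEnd:
    def test_noiseless_pipeline_recovers_block_abundances(self, coarse_basis):
        profile = class_profiles("margin")[0]
        phantom = make_phantom("B0", profile, diameter_px=288.0, seed=3,
                               field_shape=(352, 352))
        illumination = 500.0
        blue, dark, white = simulate_biopsy_cube(
            phantom, coarse_basis, noise=AcquisitionNoiseModel.noiseless(),
            seed=5, illumination=illumination, dtype=np.float64,
        )
        blocks = preprocess_triplet(blue, dark, white)
        assert len(blocks) > 100
        ab, _ = unmix_many(blocks.values, coarse_basis)
        # map back to raw counts, then to phantom units
        ab = ab * blocks.norm_factors[:, None] / illumination
        worst = 0.0
        for (r, c), a in zip(blocks.block_origin, ab):
            truth = (
                phantom.abundance_field[r : r + 10, c : c + 10]
                .astype(np.float64).reshape(-1, 5).mean(0)
            )
            worst = max(worst, np.abs(a - truth).max())
        assert worst < 1e-6

    def test_segmentation_recall_on_noisy_phantom(self, coarse_basis):
        profile = class_profiles("margin")[2]  # dimmest class (RABT)
        phantom = make_phantom("B1", profile, diameter_px=200.0, seed=11,
                               field_shape=(256, 256))
        blue, dark, white = simulate_biopsy_cube(
            phantom, coarse_basis, noise=AcquisitionNoiseModel(), seed=12
        )
        mask = segment_tumor(dark_correct(blue, dark)).mask
        recall = (mask & phantom.tissue_mask).sum() / phantom.tissue_mask.sum()
        assert recall >= 0.95
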