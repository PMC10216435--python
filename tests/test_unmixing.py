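"""Constrained unmixing: exactness, constraints, and the grid oracle."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from unmixlabel.errors import BandGridError, IllPosedUnmixingError
from unmixlabel.phantom import make_endmembers
from unmixlabel.unmixing import (
    AbundanceVector,
    EndmemberSet,
    extract_endmember,
    tumor_abundance,
    unmix_patch,
    unmix_spectrum,
)


def simplex_grid(C: int, step: float = 0.01) -> np.ndarray:
    """All abundance vectors on the simplex with entries in multiples of step.

    Independent brute-force oracle for the constrained solver.
    """
    n = int(round(1.0 / step))
    if C == 2:
        k = np.arange(n + 1)
        return np.column_stack([k, n - k]) * step
    grids = []
    if C == 3:
        for i in range(n + 1):
            for j in range(n + 1 - i):
                grids.append((i, j, n - i - j))
    elif C == 4:
        for i in range(n + 1):
            for j in range(n + 1 - i):
                k = np.arange(n + 1 - i - j)
                grids.extend((i, j, kk, n - i - j - kk) for kk in k)
    else:
        raise NotImplementedError
    return np.asarray(grids, dtype=float) * step


def grid_best(E: np.ndarray, x: np.ndarray, step: float = 0.01):
    """Best simplex grid point by exhaustive objective evaluation."""
    A = simplex_grid(E.shape[0], step)
    G = E @ E.T
    h = E @ x
    obj = np.einsum("ij,jk,ik->i", A, G, A) - 2.0 * A @ h
    i = int(np.argmin(obj))
    return A[i], float(obj[i] + x @ x)


def random_case(rng, C, n_bands=60, noise=0.01):
    E = rng.normal(size=(C, n_bands))
    a = rng.dirichlet(np.ones(C))
    x = a @ E + noise * rng.normal(size=n_bands)
    return E, a, x


class TestUnmixSpectrum:
    @pytest.mark.parametrize("mode", ["constrained", "rescaled"])
    def test_pure_endmember_recovered(self, small_endmembers, mode):
        av = unmix_spectrum(small_endmembers.spectra[0], small_endmembers, sum_to_one=mode)
        assert np.allclose(av.values, [1, 0, 0], atol=1e-8)
        assert av.residual_norm < 1e-8

    @pytest.mark.parametrize("mode", ["constrained", "rescaled"])
    def test_even_mixture_recovered(self, small_endmembers, mode):
        x = 0.5 * small_endmembers.spectra[1] + 0.5 * small_endmembers.spectra[2]
        av = unmix_spectrum(x, small_endmembers, sum_to_one=mode)
        assert np.allclose(av.values, [0, 0.5, 0.5], atol=1e-6)

    @pytest.mark.parametrize("mode", ["constrained", "rescaled"])
    def test_noiseless_identifiability(self, endmember_set, mode):
        rng = np.random.default_rng(99)
        for _ in range(10):
            a = rng.dirichlet(np.ones(4))
            x = a @ endmember_set.spectra
            av = unmix_spectrum(x, endmember_set, sum_to_one=mode)
            assert np.abs(av.values - a).max() < 1e-6

    def test_constraints_hold_under_noise(self, endmember_set):
        rng = np.random.default_rng(5)
        for mode in ("constrained", "rescaled"):
            for _ in range(20):
                x = rng.dirichlet(np.ones(4)) @ endmember_set.spectra
                x = x + 0.05 * rng.normal(size=x.size)
                av = unmix_spectrum(x, endmember_set, sum_to_one=mode)
                assert av.values.min() >= 0.0
                assert abs(av.values.sum() - 1.0) <= 1e-6

    def test_solver_not_worse_than_grid_oracle(self):
        """Exhaustive simplex-grid oracle (step 0.01), 3 and 4 endmembers."""
        rng = np.random.default_rng(2024)
        for C in (3, 4):
            for _ in range(15):
                E_arr, a_true, x = random_case(rng, C)
                E = EndmemberSet(E_arr, ("IC", "CIS", "fat", "connective")[:C])
                av = unmix_spectrum(x, E, sum_to_one="constrained")
                recon = av.values @ E_arr
                obj = float(np.sum((recon - x) ** 2))
                a_grid, obj_grid = grid_best(E_arr, x)
                assert obj <= obj_grid + 1e-10
                assert np.abs(av.values - a_grid).max() <= 0.02

    def test_rescaled_mode_undoes_snv_scaling(self, endmember_set):
        """A mixture rescaled by its own sd (SNV geometry) unmixes exactly."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            a = rng.dirichlet(np.ones(4))
            mix = a @ endmember_set.spectra
            snv_like = mix / mix.std(ddof=1)
            av = unmix_spectrum(snv_like, endmember_set, sum_to_one="rescaled")
            assert np.abs(av.values - a).max() < 1e-8

    def test_band_grid_mismatch_rejected(self, small_endmembers):
        with pytest.raises(BandGridError):
            unmix_spectrum(np.zeros(13), small_endmembers)

    def test_rank_deficient_endmembers_rejected(self):
        row = np.arange(12.0)
        with pytest.raises(IllPosedUnmixingError):
            EndmemberSet(np.array([row, 2 * row]), ("IC", "fat"))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_abundances_always_on_simplex(self, small_endmembers, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        for mode in ("constrained", "rescaled"):
            av = unmix_spectrum(x, small_endmembers, sum_to_one=mode)
            assert av.values.min() >= 0
            assert abs(av.values.sum() - 1) <= 1e-6


class TestTumorAbundance:
    def test_combination_rule(self):
        av = AbundanceVector(np.array([0.3, 0.2, 0.4, 0.1]),
                             ("IC", "CIS", "fat", "connective"), 0.0)
        assert tumor_abundance(av) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "values,expected",
        [([0, 0, 1, 0], 0.0), ([1, 0, 0, 0], 1.0), ([0, 1, 0, 0], 1.0)],
    )
    def test_pure_pixels(self, values, expected):
        av = AbundanceVector(np.array(values, dtype=float),
                             ("IC", "CIS", "fat", "connective"), 0.0)
        assert tumor_abundance(av) == pytest.approx(expected)

    def test_monotone_in_true_tumor_fraction(self, endmember_set):
        """More true tumor never yields less recovered tumor (noiseless)."""
        fractions = np.linspace(0, 1, 11)
        recovered = []
        for f in fractions:
            a = np.array([f * 0.7, f * 0.3, (1 - f) * 0.6, (1 - f) * 0.4])
            x = a @ endmember_set.spectra
            recovered.append(tumor_abundance(unmix_spectrum(x, endmember_set)))
        assert np.all(np.diff(recovered) >= -1e-9)


class TestExtractEndmember:
    def test_round_trip_on_pure_phantom_region(self, reference_scene):
        from unmixlabel.phantom import preprocess_scene

        cube = preprocess_scene(reference_scene)
        for sm in reference_scene.marks:
            spec, prov = extract_endmember(cube, sm.mark.center, sm.pure_class)
            idx = {"IC": 0, "CIS": 1, "fat": 2, "connective": 3}[sm.pure_class]
            assert np.allclose(spec.values, reference_scene.endmembers_snv[idx],
                               atol=1e-9)
            assert prov[0] == sm.pure_class

    def test_noisy_extraction_correlates_with_truth(self, noiseless_config):
        from dataclasses import replace

        from unmixlabel.phantom import make_scene, preprocess_scene, pure_reference_marks

        cfg = replace(noiseless_config, noise_sd=0.01)
        scene = make_scene(cfg, seed=11, marks=pure_reference_marks())
        cube = preprocess_scene(scene)
        for i, sm in enumerate(scene.marks):
            spec, _ = extract_endmember(cube, sm.mark.center, sm.pure_class)
            idx = {"IC": 0, "CIS": 1, "fat": 2, "connective": 3}[sm.pure_class]
            rho = np.corrcoef(spec.values, scene.endmembers_snv[idx])[0, 1]
            assert rho > 0.99

    def test_out_of_bounds_rejected(self, reference_scene):
        from unmixlabel.phantom import preprocess_scene

        cube = preprocess_scene(reference_scene)
        with pytest.raises(IndexError):
            extract_endmember(cube, (cube.rows, 0), "fat")


class TestUnmixPatch:
    def test_all_fat_patch_has_zero_tumor_layer(self, endmember_set):
        block = np.tile(endmember_set.spectra[2], (10, 10, 1))
        amap = unmix_patch(block, endmember_set)
        assert amap.tumor_map.max() < 1e-8

    def test_hotspot_argmax_recovered(self, endmember_set):
        """Tumor-layer maximum sits at the constructed hotspot, off-center."""
        rr, cc = np.mgrid[0:10, 0:10]
        tumor = 0.8 * np.exp(-((rr - 2.0) ** 2 + (cc - 7.0) ** 2) / 4.0)
        a = np.stack([0.6 * tumor, 0.4 * tumor, (1 - tumor) * 0.5, (1 - tumor) * 0.5], -1)
        block = np.tensordot(a, endmember_set.spectra, axes=([2], [0]))
        amap = unmix_patch(block, endmember_set)
        assert np.unravel_index(np.argmax(amap.tumor_map), (10, 10)) == (2, 7)
        assert np.abs(amap.tumor_map - tumor).max() < 1e-6
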