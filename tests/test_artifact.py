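"""Artifact-simulation chain: segmentation, attenuation conversion,
polychromatic counts, log conversion, and the composed simulator."""

import numpy as np
import pytest

from ctmar.artifact import (SimConfig, counts_to_line_integrals,
                            density_map, extract_metal, hu_to_density,
                            hu_to_mu, polychromatic_counts, segment_tissues,
                            simulate_artifact)
from ctmar.attenuation import (DEFAULT_TABLE, monochromatic_spectrum,
                               Spectrum)
from ctmar.core import CTSlice, LINE_INTEGRAL, Sinogram
from ctmar.phantom import PhantomSpec, make_thorax_phantom


def _slice(values, spacing=1.4):
    return CTSlice(values=np.asarray(values, dtype=float),
                   pixel_spacing=spacing)


def _body_slice(fill_hu=0.0, n=32):
    """A slice whose interior is one HU value surrounded by air."""
    v = np.full((n, n), -1000.0)
    v[4:-4, 4:-4] = fill_hu
    return _slice(v)


class TestExtractMetal:
    def test_below_threshold_gives_empty_mask(self):
        mask, count = extract_metal(_body_slice(1800.0))
        assert count == 0 and not mask.any()

    def test_threshold_comparator_is_inclusive(self):
        v = np.full((8, 8), 0.0)
        v[0, :3] = [1999.0, 2000.0, 2001.0]
        mask, count = extract_metal(_slice(v))
        assert count == 2
        assert not mask[0, 0] and mask[0, 1] and mask[0, 2]

    def test_core_recovered_exactly_from_synthetic_probe(self):
        v = np.full((16, 16), -50.0)
        v[6:10, 2:14] = 3000.0
        mask, _ = extract_metal(_slice(v))
        assert np.array_equal(mask, v == 3000.0)


class TestSegmentTissues:
    def test_matches_phantom_label_map(self):
        spec = PhantomSpec.default(128, texture_sigma_hu=0.0,
                                   edge_sigma_px=0.0)
        ct, label = make_thorax_phantom(spec, seed=0)
        masks = segment_tissues(ct)
        assert np.array_equal(masks.lung, label == 2)
        assert np.array_equal(masks.water_equiv, (label == 1) | (label == 3))
        assert np.array_equal(masks.bone, label == 4)
        assert np.array_equal(masks.background, label == 0)
        assert not masks.metal.any()

    def test_all_water_slice(self):
        masks = segment_tissues(_body_slice(0.0))
        assert masks.water_equiv.sum() == 24 * 24
        assert not masks.lung.any() and not masks.bone.any()

    def test_partition_for_arbitrary_input(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(-1100, 2500, size=(32, 32))
        masks = segment_tissues(_slice(v))
        total = sum(m.astype(int) for m in masks.all_masks().values())
        assert np.all(total == 1)

    def test_enclosed_air_is_not_background(self):
        v = np.full((32, 32), 40.0)
        v[0, :] = v[-1, :] = v[:, 0] = v[:, -1] = -1000.0
        v[15:18, 15:18] = -950.0  # enclosed air pocket
        masks = segment_tissues(_slice(v))
        assert masks.lung[16, 16]
        assert not masks.background[16, 16]

    def test_non_monotone_thresholds_rejected(self):
        with pytest.raises(ValueError, match="lung_max < bone_min"):
            segment_tissues(_body_slice(), lung_max=200.0, bone_min=150.0)


class TestHuToMu:
    def test_water_pixel_reproduces_table_value(self):
        ct = _body_slice(0.0)
        masks = segment_tissues(ct)
        mu = hu_to_mu(ct, masks, energy_keV=70.0)
        expected = DEFAULT_TABLE.mu("water", 70.0)
        assert mu[16, 16] == pytest.approx(expected, rel=1e-12)

    def test_air_maps_to_zero_everywhere(self):
        ct = _slice(np.full((16, 16), -1000.0))
        masks = segment_tissues(ct)
        for e in (30.0, 70.0, 120.0):
            assert np.all(hu_to_mu(ct, masks, energy_keV=e) == 0.0)

    def test_mu_decreases_with_energy_for_body_pixels(self):
        spec = PhantomSpec.default(64)
        ct, label = make_thorax_phantom(spec, seed=2)
        masks = segment_tissues(ct)
        lo = hu_to_mu(ct, masks, energy_keV=50.0)
        hi = hu_to_mu(ct, masks, energy_keV=100.0)
        inside = ~masks.background & (ct.values > -999)
        assert np.all(lo[inside] >= hi[inside])

    def test_generic_density_ramp_knots(self):
        assert hu_to_density(np.array([-1000.0]))[0] == 0.0
        assert hu_to_density(np.array([0.0]))[0] == 1.0
        assert hu_to_density(np.array([1000.0]))[0] == pytest.approx(1.6)
        assert hu_to_density(np.array([3000.0]))[0] == pytest.approx(1.6)
        assert hu_to_density(np.array([-2000.0]))[0] == 0.0

    def test_ramp_model_available(self):
        ct = _body_slice(500.0)
        masks = segment_tissues(ct)
        rho = density_map(ct, masks, model="ramp")
        assert rho[16, 16] == pytest.approx(1.3)


def _flat_sinos(values, n=4, nd=8):
    angles = np.linspace(0, 179, n)
    return [Sinogram(data=np.full((n, nd), v), angles_deg=angles,
                     detector_spacing=1.0, kind=LINE_INTEGRAL)
            for v in np.atleast_1d(values)]


class TestPolychromaticCounts:
    def test_no_attenuation_gives_i0(self):
        sp = monochromatic_spectrum(70.0, i0=1e5)
        realized, expected = polychromatic_counts(_flat_sinos(0.0), sp,
                                                  noise=False)
        assert np.all(expected.data == 1e5)
        assert np.all(realized.data == 1e5)

    def test_monochromatic_ln2_halves_counts(self):
        sp = monochromatic_spectrum(70.0, i0=2e5)
        _, expected = polychromatic_counts(_flat_sinos(np.log(2.0)), sp,
                                           noise=False)
        assert np.allclose(expected.data, 1e5)

    def test_poisson_variance_at_1e4(self):
        sp = Spectrum(energies_keV=np.array([70.0]), weights=np.array([1.0]),
                      i0=1e4)
        n_draws = 10 ** 5
        sino = [Sinogram(data=np.zeros((1, n_draws)),
                         angles_deg=np.array([0.0]), detector_spacing=1.0)]
        realized, _ = polychromatic_counts(sino, sp, seed=0, noise=True)
        assert realized.data.std() == pytest.approx(100.0, rel=0.02)

    def test_negative_optical_depth_rejected(self):
        sp = monochromatic_spectrum(70.0)
        with pytest.raises(ValueError, match="negative"):
            polychromatic_counts(_flat_sinos(-0.1), sp)

    def test_bin_count_mismatch_rejected(self):
        sp = monochromatic_spectrum(70.0)
        with pytest.raises(ValueError, match="per spectrum bin"):
            polychromatic_counts(_flat_sinos([0.0, 1.0]), sp)


class TestCountsToLineIntegrals:
    def test_full_transmission_gives_zero(self):
        sp = monochromatic_spectrum(70.0, i0=1e5)
        counts = Sinogram(data=np.full((2, 4), 1e5),
                          angles_deg=np.array([0.0, 90.0]),
                          detector_spacing=1.0, kind="photon_count")
        p = counts_to_line_integrals(counts, sp)
        assert np.all(p.data == 0.0)

    def test_zero_counts_floored_to_ln_i0(self):
        sp = monochromatic_spectrum(70.0, i0=1e5)
        counts = Sinogram(data=np.zeros((1, 4)), angles_deg=np.array([0.0]),
                          detector_spacing=1.0, kind="photon_count")
        p = counts_to_line_integrals(counts, sp)
        assert np.allclose(p.data, np.log(1e5))

    def test_noise_free_monochromatic_roundtrip(self):
        rng = np.random.default_rng(1)
        sp = monochromatic_spectrum(70.0, i0=1e6)
        data = rng.uniform(0.0, 5.0, size=(8, 16))
        sino = [Sinogram(data=data, angles_deg=np.linspace(0, 179, 8),
                         detector_spacing=1.0)]
        realized, _ = polychromatic_counts(sino, sp, noise=False)
        p = counts_to_line_integrals(realized, sp)
        assert np.allclose(p.data, data, atol=1e-10)


class TestSimulateArtifact:
    def test_same_config_same_seed_bit_identical(self):
        spec = PhantomSpec.default(64)
        ct, _ = make_thorax_phantom(spec, seed=4)
        cfg = SimConfig(n_views=90)
        a = simulate_artifact(ct, None, cfg, seed=9)
        b = simulate_artifact(ct, None, cfg, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_provenance_recorded(self):
        spec = PhantomSpec.default(64)
        ct, _ = make_thorax_phantom(spec, seed=4)
        art = simulate_artifact(ct, None, SimConfig(n_views=90), seed=9)
        assert art.meta["seed"] == 9
        assert art.meta["n_views"] == 90
        assert art.meta["i0"] == 2e5
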