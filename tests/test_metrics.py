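"""Image-quality metrics and HU-restoration evaluation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctmar.core import CTSlice, PairedSample
from ctmar.metrics import (build_report, hu_improvement_percent, psnr,
                           region_hu_stats, rmse, ssim, write_report)


def _ct(v):
    return CTSlice(np.asarray(v, dtype=float))


class TestRmse:
    def test_identical_slices_zero(self):
        a = _ct(np.random.default_rng(0).normal(0, 100, (16, 16)))
        assert rmse(a, a) == 0.0

    def test_constant_offset(self):
        a = _ct(np.zeros((8, 8)))
        b = _ct(np.full((8, 8), 10.0))
        assert rmse(a, b) == pytest.approx(10.0)

    def test_four_pixel_hand_arithmetic(self):
        a = _ct([[0.0, 0.0], [0.0, 0.0]])
        b = _ct([[0.0, 0.0], [0.0, 20.0]])
        assert rmse(a, b) == pytest.approx(10.0)

    def test_mask_restriction(self):
        a = _ct(np.zeros((4, 4)))
        b = _ct(np.zeros((4, 4)))
        b.values[0, 0] = 8.0
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True
        assert rmse(a, b, mask) == pytest.approx(8.0)
        with pytest.raises(ValueError, match="empty mask"):
            rmse(a, b, np.zeros((4, 4), bool))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="congruent"):
            rmse(_ct(np.zeros((4, 4))), _ct(np.zeros((5, 5))))


class TestPsnr:
    def test_closed_form_40_db(self):
        a = _ct(np.zeros((8, 8)))
        b = _ct(np.full((8, 8), 20.0))
        assert psnr(a, b, data_range=2000.0) == pytest.approx(40.0)

    def test_identical_slices_sentinel_infinity(self):
        a = _ct(np.zeros((8, 8)))
        assert math.isinf(psnr(a, a))

    def test_monotone_in_rmse(self):
        a = _ct(np.zeros((8, 8)))
        vals = [psnr(a, _ct(np.full((8, 8), d))) for d in (5.0, 20.0, 80.0)]
        assert vals[0] > vals[1] > vals[2]

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_consistency_with_rmse(self, seed):
        rng = np.random.default_rng(seed)
        a = _ct(rng.normal(0, 200, (12, 12)))
        b = _ct(rng.normal(0, 200, (12, 12)))
        assert psnr(a, b) == pytest.approx(
            20.0 * np.log10(2000.0 / rmse(a, b)), abs=1e-12)


class TestSsim:
    def test_identical_slices_unity(self):
        a = _ct(np.random.default_rng(0).normal(0, 100, (32, 32)))
        assert ssim(a, a) == pytest.approx(1.0)

    def test_anticorrelated_zero_mean_pattern_negative(self):
        # high-frequency pattern: local window means ~0, so the luminance
        # term is ~1 and the negative covariance drives the sign
        i = np.arange(64)
        v = 400.0 * np.outer(np.cos(2 * np.pi * i / 4),
                             np.cos(2 * np.pi * i / 4))
        assert ssim(_ct(v), _ct(-v)) < 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = _ct(rng.normal(0, 100, (32, 32))), _ct(
            rng.normal(0, 100, (32, 32)))
        assert ssim(a, b) == pytest.approx(ssim(b, a), abs=1e-12)

    def test_image_smaller_than_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            ssim(_ct(np.zeros((8, 8))), _ct(np.zeros((8, 8))))


class TestRegionStats:
    def test_uniform_region(self):
        ct = _ct(np.full((8, 8), 35.0))
        st_ = region_hu_stats(ct, np.ones((8, 8), bool), "heart")
        assert st_.mean_hu == 35.0 and st_.std_hu == 0.0
        assert st_.pixel_count == 64

    def test_two_pixel_hand_arithmetic(self):
        ct = _ct([[30.0, 40.0]])
        st_ = region_hu_stats(ct, np.ones((1, 2), bool))
        assert st_.mean_hu == pytest.approx(35.0)
        assert st_.std_hu == pytest.approx(5.0)  # population STD

    def test_delta_against_identical_reference_zero(self):
        ct = _ct(np.random.default_rng(0).normal(0, 50, (8, 8)))
        st_ = region_hu_stats(ct, np.ones((8, 8), bool), reference=ct)
        assert st_.abs_dmean_hu == 0.0 and st_.dstd_hu == 0.0

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            region_hu_stats(_ct(np.zeros((4, 4))), np.zeros((4, 4), bool))


class TestImprovement:
    def test_endpoints(self):
        assert hu_improvement_percent(46.55, 0.0) == 100.0
        assert hu_improvement_percent(46.55, 46.55) == 0.0

    def test_reported_heart_region_values(self):
        # aggregate deltas 46.55 HU (artifacted) and 9.18 HU (corrected)
        assert hu_improvement_percent(46.55, 9.18) == pytest.approx(80.28,
                                                                    abs=0.01)

    def test_negative_when_correction_worsens(self):
        assert hu_improvement_percent(10.0, 15.0) == pytest.approx(-50.0)

    def test_sign_convention_enforced(self):
        assert hu_improvement_percent(-46.55, -9.18) == pytest.approx(
            hu_improvement_percent(46.55, 9.18))

    def test_zero_baseline_not_applicable(self):
        assert math.isnan(hu_improvement_percent(0.0, 5.0))


def _report_samples(n, with_cor=True, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        ref = rng.normal(0, 150, (32, 32))
        art = ref + rng.normal(30, 60, (32, 32))
        cor = ref + rng.normal(5, 15, (32, 32)) if with_cor else None
        out.append(PairedSample(
            ref=_ct(ref), art=_ct(art), cor=_ct(cor) if with_cor else None,
            patient_id=f"p{i}", slice_id=f"p{i}s0"))
    return out


class TestBuildReport:
    def test_single_slice_aggregate_equals_value(self):
        s = _report_samples(1)
        rep = build_report(s)
        for alg in ("art", "cor"):
            for metric, (mean, std) in rep.aggregates[alg].items():
                row = [r for r in rep.rows if r["algorithm"] == alg][0]
                assert mean == pytest.approx(row[metric])
                assert std == 0.0

    def test_permutation_invariance(self):
        s = _report_samples(6)
        rep1 = build_report(s)
        rep2 = build_report(list(reversed(s)))
        assert rep1.aggregates == rep2.aggregates

    def test_noop_corrector_reproduces_art_statistics(self):
        samples = _report_samples(50, with_cor=False, seed=3)
        for s in samples:
            s.cor = s.art.copy()
        masks = {s.slice_id: {"heart": np.ones((32, 32), bool)}
                 for s in samples}
        rep = build_report(samples, masks)
        assert rep.aggregates["cor"] == rep.aggregates["art"]
        assert rep.region_tables["cor"] == rep.region_tables["art"]
        assert rep.improvements["heart"]["aggregate"] == pytest.approx(0.0)
        assert rep.improvements["heart"]["per_scan"] == pytest.approx(0.0)

    def test_dual_aggregation_modes_both_reported(self):
        samples = _report_samples(50, seed=4)
        masks = {s.slice_id: {"heart": np.ones((32, 32), bool)}
                 for s in samples}
        rep = build_report(samples, masks)
        imp = rep.improvements["heart"]
        assert 0 < imp["aggregate"] <= 100
        assert 0 < imp["per_scan"] <= 100

    def test_missing_pairing_named(self):
        s = _report_samples(2, with_cor=False)
        with pytest.raises(ValueError, match="p0s0"):
            build_report(s, algorithms=("art", "cor"))

    def test_written_tables_deterministic(self, tmp_path):
        rep = build_report(_report_samples(4))
        write_report(rep, tmp_path / "a")
        write_report(rep, tmp_path / "b")
        for name in ("per_slice.tsv", "summary.json"):
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes())
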