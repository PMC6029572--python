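"""Gain correction, current normalisation, averaging and data rejection."""

import itertools

import numpy as np
import pytest

from mfeit import (GainModel, average_frames, build_reference, clean,
                   extract_real, gain_correct, normalize_current)
from mfeit.errors import PlanError
from mfeit.postproc import process_frames
from mfeit.protocol import FrequencyPlan, PlanEntry


@pytest.fixture(scope="module")
def table1():
    return FrequencyPlan.table1()


class TestGainModel:
    def test_dc_gain_is_unity(self):
        assert GainModel().gain(0.0) == 1.0

    def test_correction_factor_at_3db_point(self, table1):
        # at the -3 dB corner the single-pole correction is sqrt(2)
        model = GainModel()
        assert 1.0 / model.gain(3000.0) == pytest.approx(np.sqrt(2), rel=1e-9)

    def test_correction_factor_at_2khz(self, table1):
        # first-order low-pass: sqrt(1 + (2/3)^2)
        bv = np.ones((4, 17))
        out = gain_correct(bv, table1, GainModel())
        assert out[0, -1] == pytest.approx(1.2018504, abs=1e-5)

    def test_gain_monotone_nonincreasing(self):
        model = GainModel()
        g = [model.gain(f) for f in (0, 10, 100, 1000, 3000, 10000)]
        assert all(a >= b for a, b in zip(g, g[1:]))

    def test_calibration_table_interpolates(self):
        model = GainModel("calibration-table",
                          table=((10.0, 1.0), (1000.0, 0.9), (10000.0, 0.5)))
        assert model.gain(1000.0) == pytest.approx(0.9)
        assert 0.5 < model.gain(3000.0) < 0.9

    def test_increasing_table_rejected(self):
        with pytest.raises(ValueError):
            GainModel("calibration-table", table=((10.0, 0.5), (100.0, 0.9)))


class TestNormalizeCurrent:
    def test_factors_from_plan_amplitudes(self, table1):
        values = np.ones((2, 17))
        out = normalize_current(values, table1)
        carriers = table1.carriers.tolist()
        assert out[0, carriers.index(2000.0)] == pytest.approx(1.0)
        assert out[0, carriers.index(700.0)] == pytest.approx(2.0)  # 280/140
        assert out[0, carriers.index(5.0)] == pytest.approx(6.2222, abs=1e-4)

    def test_zero_amplitude_is_unrepresentable(self):
        with pytest.raises(PlanError):
            FrequencyPlan((PlanEntry(100.0, 0.0, 32, 320),))


class TestExtractReal:
    @pytest.mark.parametrize("bv, pa, expected", [
        (3.0, 0.0, 3.0),
        (3.0, np.pi / 2, 0.0),
        (2.0, np.pi / 3, 1.0),
        (2.0, np.pi, -2.0),
    ])
    def test_elementwise_projection(self, bv, pa, expected):
        out = extract_real(np.array([[bv]]), np.array([[pa]]))
        assert out[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            extract_real(np.ones((2, 3)), np.ones((3, 2)))


class TestAverageFrames:
    def test_identical_frames_unchanged(self):
        v = np.tile(np.array([[1.5], [2.5]])[..., None], (1, 1, 3))
        assert np.array_equal(average_frames(v), [[1.5], [2.5]])

    def test_arithmetic_mean(self):
        v = np.array([[[1.0, 2.0, 3.0]]])
        assert average_frames(v)[0, 0] == 2.0

    def test_flagged_frames_skipped(self):
        v = np.array([[[1.0, 100.0, 3.0]]])
        flags = np.array([[[False, True, False]]])
        assert average_frames(v, flags)[0, 0] == 2.0

    def test_all_flagged_cell_stays_nan(self):
        v = np.ones((1, 1, 2))
        flags = np.ones((1, 1, 2), dtype=bool)
        assert np.isnan(average_frames(v, flags)[0, 0])


class TestClean:
    def test_threshold_is_strict(self):
        v = np.array([[0.0, 25.0, 20.0, -25.0]])
        ref = np.zeros((1, 4))
        cleaned, report = clean(v, ref)
        assert np.isnan(cleaned[0, 1]) and np.isnan(cleaned[0, 3])
        assert cleaned[0, 2] == 20.0  # exactly 20 mV is kept
        assert report.n_removed == 2

    def test_identical_to_reference_keeps_everything(self):
        v = np.arange(12.0).reshape(3, 4)
        cleaned, report = clean(v, v.copy())
        assert np.array_equal(cleaned, v)
        assert report.n_removed == 0

    def test_survivors_bit_identical_and_counts_balance(self):
        rng = np.random.default_rng(5)
        v = rng.normal(scale=30.0, size=(20, 7))
        ref = np.zeros_like(v)
        cleaned, report = clean(v, ref)
        keep = ~np.isnan(cleaned)
        assert np.array_equal(cleaned[keep], v[keep])
        assert report.n_removed + keep.sum() == v.size
        assert report.n_removed == np.isnan(cleaned).sum()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            clean(np.ones((2, 2)), np.ones((2, 3)))


class TestBuildReference:
    def test_single_dataset_is_itself(self):
        d = np.arange(6.0).reshape(2, 3)
        assert np.array_equal(build_reference([d]), d)

    def test_mean_of_two(self):
        a, b = np.zeros((2, 2)), np.full((2, 2), 4.0)
        assert np.array_equal(build_reference([a, b]), np.full((2, 2), 2.0))

    def test_nan_ignored(self):
        a = np.array([[1.0, np.nan]])
        b = np.array([[3.0, 5.0]])
        assert np.array_equal(build_reference([a, b]), [[2.0, 5.0]])

    def test_median_option(self):
        ds = [np.full((1, 1), v) for v in (1.0, 2.0, 100.0)]
        assert build_reference(ds, method="median")[0, 0] == 2.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            build_reference([])


class TestPipelineAlgebra:
    def test_per_frequency_scalings_commute(self, table1):
        rng = np.random.default_rng(0)
        bv = rng.uniform(0.5, 5.0, size=(10, 17, 3))
        pa = rng.uniform(-0.2, 0.2, size=bv.shape)
        model = GainModel()

        def run(order):
            v = bv
            for step in order:
                v = (gain_correct(v, table1, model) if step == "gain"
                     else normalize_current(v, table1))
            return average_frames(extract_real(v, pa))

        results = [run(order) for order in itertools.permutations(["gain", "norm"])]
        assert np.allclose(results[0], results[1], rtol=1e-12)

    def test_process_frames_shape(self, table1):
        rng = np.random.default_rng(1)
        bv = rng.uniform(0.5, 5.0, size=(930, 17, 3))
        pa = rng.uniform(-0.1, 0.1, size=bv.shape)
        full = process_frames(bv, pa, table1, gain_model=GainModel())
        assert full.shape == (930, 17)
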