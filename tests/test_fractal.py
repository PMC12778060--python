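import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fractalmorph import (
    CalibrationModel,
    DEFAULT_CALIBRATION,
    ProtocolConfig,
    Silhouette,
    box_count,
    correct_dimension,
    estimate_dimension,
    estimate_lacunarity,
    fit_calibration,
    measure_protocol,
    scaling_series,
    theoretical_dimension,
)
from fractalmorph.fractal import BoxCountSample, ScalingSeries, default_box_sizes

from conftest import brute_force_box_count


class TestTheoreticalDimension:
    @pytest.mark.parametrize(
        "n,s,expect",
        [(1, 3, 0.0), (3, 3, 1.0), (9, 3, 2.0), (27, 3, 3.0), (4, 3, 1.26186)],
    )
    def test_self_similarity_rule(self, n, s, expect):
        assert theoretical_dimension(n, s) == pytest.approx(expect, abs=1e-5)

    def test_invalid_scale(self):
        with pytest.raises(ValueError):
            theoretical_dimension(4, 1.0)


class TestBoxCount:
    def test_uniform_coverage(self):
        sample = box_count(np.ones((8, 8), dtype=bool), 4)
        assert (sample.n_boxes, sample.mu, sample.sigma) == (4, 16.0, 0.0)
        assert sample.lambda_eps == 0.0

    def test_heterogeneous_boxes_hand_computed(self):
        # occupied boxes hold {16, 4} pixels -> mu=10, sigma=6, lambda=0.36
        mask = np.zeros((8, 8), dtype=bool)
        mask[0:4, 0:4] = True
        mask[0:2, 4:6] = True
        s = box_count(mask, 4)
        assert s.n_boxes == 2
        assert s.mu == pytest.approx(10.0)
        assert s.sigma == pytest.approx(6.0)
        assert s.lambda_eps == pytest.approx(0.36)

    def test_single_pixel(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[17, 3] = True
        for size, off in [(4, (0, 0)), (7, (3, 2)), (16, (15, 1))]:
            s = box_count(mask, size, off)
            assert s.n_boxes == 1 and s.lambda_eps == 0.0

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            box_count(np.zeros((8, 8), dtype=bool), 4)

    def test_offset_bounds_validated(self):
        with pytest.raises(ValueError):
            box_count(np.ones((8, 8), dtype=bool), 4, (4, 0))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            mask = rng.random((64, 64)) < rng.uniform(0.05, 0.6)
            if not mask.any():
                continue
            for size in (4, 5, 8, 16):
                for off in ((0, 0), (1, 2), (size - 1, size - 1)):
                    s = box_count(mask, size, off)
                    n, mu, sd = brute_force_box_count(mask, size, *off)
                    assert s.n_boxes == n
                    assert s.mu == pytest.approx(mu)
                    assert s.sigma == pytest.approx(sd)

    @given(
        data=st.data(),
        size=st.integers(min_value=2, max_value=9),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_conservation_invariant(self, data, size):
        bits = data.draw(
            st.lists(st.booleans(), min_size=256, max_size=256), label="mask"
        )
        mask = np.array(bits, dtype=bool).reshape(16, 16)
        if not mask.any():
            return
        dx = data.draw(st.integers(0, size - 1))
        dy = data.draw(st.integers(0, size - 1))
        s = box_count(mask, size, (dx, dy))
        assert s.n_boxes * s.mu == pytest.approx(mask.sum())


class TestScalingSeries:
    def test_filled_block_exact_counts(self):
        series = scaling_series(np.ones((8, 8), dtype=bool), sizes=[2, 4, 8])
        assert series.counts().tolist() == [16, 4, 1]

    def test_counts_non_increasing(self, rng):
        mask = rng.random((128, 128)) < 0.3
        series = scaling_series(mask, sizes=[4, 8, 16, 32, 64])
        counts = series.counts()
        assert np.all(np.diff(counts) <= 0)

    def test_default_ladder(self):
        sizes = default_box_sizes(1000)
        assert sizes[0] == 4 and sizes[-1] == 200 and len(sizes) == 50

    def test_ladder_scaling_is_opt_in(self):
        cfg = ProtocolConfig(scale_sizes_with_canvas=True)
        assert default_box_sizes(1416, cfg)[-1] == pytest.approx(283, abs=1)
        assert default_box_sizes(1416)[-1] == 200


def _series(points):
    samples = tuple(
        BoxCountSample(box_size=s, offset=(0, 0), n_boxes=n, mu=1.0, sigma=0.0)
        for s, n in points
    )
    return ScalingSeries(samples=samples)


class TestEstimateDimension:
    def test_exact_collinear_slope(self):
        est = estimate_dimension(_series([(2, 16), (4, 4), (8, 1)]))
        assert est.D_raw == pytest.approx(2.0)
        assert est.r_squared == pytest.approx(1.0)

    def test_point_series_is_zero(self):
        est = estimate_dimension(_series([(4, 1), (8, 1), (16, 1), (32, 1)]))
        assert est.D_raw == 0.0

    def test_standardized_thin_line_near_one(self, std_line):
        est = estimate_dimension(scaling_series(std_line))
        assert est.D_raw == pytest.approx(1.0, abs=0.08)

    def test_too_few_sizes(self):
        with pytest.raises(ValueError):
            estimate_dimension(_series([(2, 16), (4, 4)]))


class TestLacunarity:
    def test_uniform_is_zero(self):
        series = scaling_series(np.ones((64, 64), dtype=bool), sizes=[4, 8, 16])
        assert estimate_lacunarity(series) == 0.0

    def test_mean_of_lambdas(self):
        samples = (
            BoxCountSample(4, (0, 0), 2, 10.0, 6.0),  # lambda 0.36
            BoxCountSample(8, (0, 0), 1, 10.0, 2.0),  # lambda 0.04
        )
        assert estimate_lacunarity(ScalingSeries(samples)) == pytest.approx(0.20)


class TestCalibration:
    def test_packaged_constants(self):
        assert (DEFAULT_CALIBRATION.c1, DEFAULT_CALIBRATION.gamma, DEFAULT_CALIBRATION.c0) == (
            0.4565, 1.8027, 0.55436,
        )

    @pytest.mark.parametrize(
        "raw,expect", [(1.0, 1.01086), (1.9, 2.0064), (0.0, 0.55436)]
    )
    def test_correction_values(self, raw, expect):
        assert correct_dimension(raw) == pytest.approx(expect, abs=1e-3)

    def test_monotone(self):
        grid = np.linspace(0.0, 2.2, 50)
        out = correct_dimension(grid, DEFAULT_CALIBRATION)
        assert np.all(np.diff(out) > 0)

    def test_recovers_generating_coefficients(self):
        x = np.linspace(0.9, 2.0, 12)
        y = 0.4565 * x**1.8027 + 0.55436
        model = fit_calibration(list(zip(x, y)))
        assert model.c1 == pytest.approx(0.4565, abs=1e-4)
        assert model.gamma == pytest.approx(1.8027, abs=1e-4)
        assert model.c0 == pytest.approx(0.55436, abs=1e-4)

    def test_identity_pairs(self):
        x = np.linspace(1.0, 2.0, 8)
        model = fit_calibration(list(zip(x, x)))
        assert model.c1 == pytest.approx(1.0, abs=1e-6)
        assert model.gamma == pytest.approx(1.0, abs=1e-6)
        assert model.c0 == pytest.approx(0.0, abs=1e-6)

    def test_requires_spread_and_count(self):
        with pytest.raises(ValueError):
            fit_calibration([(1.0, 1.0), (2.0, 2.0)])
        with pytest.raises(ValueError):
            fit_calibration([(1.0, v) for v in (1, 1.2, 1.4, 1.6, 1.8)])

    def test_non_monotone_model_rejected(self):
        with pytest.raises(ValueError):
            CalibrationModel(c1=-1.0, gamma=1.0, c0=0.0)


class TestProtocol:
    def test_deterministic_repeat(self, std_line):
        m1 = measure_protocol(std_line)
        m2 = measure_protocol(std_line)
        assert m1 == m2

    def test_line_measurement(self, std_line):
        m = measure_protocol(std_line)
        assert m.D_SI == pytest.approx(1.0, abs=0.05)
        assert m.D_SK == pytest.approx(m.D_SI, abs=0.02)  # a line is its skeleton
        assert not m.singular
        assert m.n_replicates == 120
        assert m.sd_D_SI < 0.05

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            measure_protocol(Silhouette(np.zeros((10, 10), dtype=bool)))
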