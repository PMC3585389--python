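"""eFAST sampling geometry, Fourier variance partition and dummy tests."""

import math

import numpy as np
import pandas as pd
import pytest

from simsens import ParameterSpec, efast_sample
from simsens.efast import (
    curve_indices,
    dummy_comparison,
    efast_indices,
    fourier_variances,
    sample_grid,
    search_curve,
)


def _unit_params(k, with_dummy=True):
    params = [ParameterSpec(f"p{i}", 0.0, 1.0, 0.5) for i in range(k)]
    if with_dummy:
        params.append(ParameterSpec("dummy", 0.0, 1.0, 0.5))
    return params


class TestSampling:
    def test_worked_example_set_totals(self):
        # 7 parameters + dummy, 65 samples, 3 curves -> 1,560 sets / 24 files.
        design = efast_sample(_unit_params(7), 65, 3, 4, seed=0, dummy_name="dummy")
        assert design.total_sets == 1560
        assert len(design.design_files()) == 24

    def test_case_study_set_totals(self, case_study):
        params = list(case_study) + [ParameterSpec("dummy", 0.0, 1.0, 0.5)]
        design = efast_sample(params, 65, 3, 4, seed=0, dummy_name="dummy")
        assert design.total_sets == 1365
        assert design.sets_per_parameter == 195

    def test_even_ns_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            efast_sample(_unit_params(2), 64, 3, 4)

    def test_too_small_ns_reports_minimum(self):
        with pytest.raises(ValueError, match="17"):
            efast_sample(_unit_params(2), 9, 1, 4)

    def test_frequencies_respect_interference_bands(self):
        design = efast_sample(_unit_params(6), 65, 2, 4, seed=1, dummy_name="dummy")
        assert design.omega_max == 8  # floor(64 / 8)
        for poi, omegas in design.frequencies.items():
            assert omegas[poi] == 8
            complement = [w for name, w in omegas.items() if name != poi]
            assert all(1 <= w <= 4 for w in complement)

    def test_samples_stay_in_bounds(self):
        params = [
            ParameterSpec("narrow", 0.015, 0.08, 0.04),
            ParameterSpec("wide", -5.0, 5.0, 0.0),
            ParameterSpec("dummy", 0.0, 1.0, 0.5),
        ]
        design = efast_sample(params, 33, 2, 4, seed=2, dummy_name="dummy")
        for frame in design.samples.values():
            for p in params:
                assert frame[p.name].min() >= p.lower
                assert frame[p.name].max() <= p.upper

    def test_triangle_wave_sweeps_range_symmetrically(self):
        # Unit range, one oscillation (omega = 1), phase pi/2: the curve is
        # symmetric about 0.5 and spans (0, 1).
        # Discrete-grid mean deviates from 1/2 only at O(1/NS^2).
        values = search_curve(0.0, 1.0, 1, math.pi / 2, 65)
        assert np.mean(values) == pytest.approx(0.5, abs=1e-3)
        assert values.min() < 0.05 and values.max() > 0.95


class TestFourierVariances:
    def test_single_frequency_signal_fully_attributed(self):
        s = sample_grid(65)
        d_total, d_omega = fourier_variances(np.cos(5 * s), 5, 4)
        assert d_omega / d_total == pytest.approx(1.0, abs=1e-9)

    def test_constant_signal_has_zero_variance(self):
        d_total, _ = fourier_variances(np.full(65, 3.7), 5, 4)
        assert d_total == pytest.approx(0.0, abs=1e-12)

    def test_two_well_separated_cosines_split_evenly(self):
        # Parseval: equal-amplitude components at 2 and 11 (11 > 4*2, and
        # not a harmonic of 2) each carry half the spectral variance.
        s = sample_grid(65)
        y = np.cos(2 * s) + np.cos(11 * s)
        d_total, d_omega = fourier_variances(y, 2, 4)
        assert d_omega / d_total == pytest.approx(0.5, abs=1e-6)

    def test_parseval_bound_against_sample_variance(self):
        s = sample_grid(257)
        y = np.cos(3 * s) + 0.5 * np.sin(7 * s)
        d_total, _ = fourier_variances(y, 3, 4)
        assert d_total <= 2.0 * y.var() + 1e-9
        assert d_total == pytest.approx(y.var(), rel=1e-6)  # band-limited signal


class TestIndices:
    def test_si_sti_bounds_on_random_functions(self, rng):
        """0 <= Si <= STi <= 1 on monotone, interacting and null responses."""
        design = efast_sample(_unit_params(3), 65, 2, 4, seed=4, dummy_name="dummy")
        for _ in range(100):
            coeffs = rng.normal(size=3)
            kind = rng.integers(3)
            for frame in design.samples.values():
                x = frame[["p0", "p1", "p2"]].to_numpy()
                if kind == 0:
                    y = x @ coeffs
                elif kind == 1:
                    y = x[:, 0] * x[:, 1] + coeffs[2] * np.sin(3 * x[:, 2])
                else:
                    y = np.full(len(x), coeffs[0])
                si, sti = curve_indices(y, design.omega_max, design.m)
                assert 0.0 <= si <= sti + 1e-9
                assert sti <= 1.0 + 1e-9

    def test_additive_model_variance_fractions(self):
        """y = x0 + 2 x1 + 0 x2: analytic Si = a_k^2 / sum a_m^2 (uniform ranges).

        Oracle: closed form a_k^2 * range^2 / 12 for independent uniform inputs.
        """
        design = efast_sample(_unit_params(3), 257, 5, 4, seed=5, dummy_name="dummy")
        responses = {
            key: pd.DataFrame(
                {"y": frame["p0"] + 2.0 * frame["p1"] + 0.0 * frame["p2"]}
            )
            for key, frame in design.samples.items()
        }
        result = efast_indices(responses, design)
        expected = {"p0": 0.2, "p1": 0.8, "p2": 0.0}
        for name, value in expected.items():
            assert result.mean_index(name, "y", "Si") == pytest.approx(value, abs=0.05)

    def test_dead_output_yields_zero_indices_with_warning(self, caplog):
        design = efast_sample(_unit_params(2), 65, 2, 4, seed=6, dummy_name="dummy")
        responses = {
            key: pd.DataFrame({"y": np.zeros(65)}) for key in design.samples
        }
        with caplog.at_level("WARNING", logger="simsens"):
            result = efast_indices(responses, design)
        assert (result.per_curve[["Si", "STi"]] == 0.0).all().all()
        assert "constant response" in caplog.text

    def test_misaligned_responses_rejected(self):
        design = efast_sample(_unit_params(2), 65, 2, 4, seed=6, dummy_name="dummy")
        responses = {key: pd.DataFrame({"y": np.zeros(63)}) for key in design.samples}
        with pytest.raises(ValueError, match="expected NS"):
            efast_indices(responses, design)


class TestDummyComparison:
    def test_clear_separation_is_significant(self):
        p = dummy_comparison([0.5, 0.52, 0.48], [0.01, 0.02, 0.015])
        assert p < 0.01

    def test_identical_indices_not_significant(self):
        p = dummy_comparison([0.5, 0.52, 0.48], [0.5, 0.52, 0.48])
        assert p == pytest.approx(0.5, abs=0.01)

    def test_single_curve_flagged_not_computable(self, caplog):
        with caplog.at_level("WARNING", logger="simsens"):
            p = dummy_comparison([0.5], [0.4])
        assert math.isnan(p)
        assert "at least 2" in caplog.text
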