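"""Unit and property tests for the cooperative and saturation binding models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from madskit.binding import (
    FitConfig,
    SaturationSeries,
    TitrationSeries,
    bound_from_total_probe,
    cooperativity,
    fit_cooperative,
    fit_saturation,
    fraction_matrix,
    predict_fractions,
    predict_saturation,
)
from madskit.exceptions import ValidationError
from madskit.simulate import default_protein_ladder, simulate_saturation, simulate_titration, NoiseModel

LADDER8 = np.geomspace(0.05, 3.0, 8)


class TestPredictFractions:
    @pytest.mark.parametrize(
        "p2,kd1,kd2,expected",
        [
            (0.0, 5.0, 3.0, (1.0, 0.0, 0.0)),  # no protein, all probe free
            (1.0, 1.0, 1.0, (0.25, 0.50, 0.25)),  # Z = 1 + 2 + 1
            (0.1, 1.0, 0.01, (5 / 11, 1 / 11, 5 / 11)),  # Z = 1 + 0.2 + 1 = 2.2
        ],
    )
    def test_hand_computed_values(self, p2, kd1, kd2, expected):
        assert predict_fractions(p2, kd1, kd2) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("kd1,kd2,p2", [(0, 1, 1), (1, -1, 1), (1, 1, -0.1)])
    def test_domain_errors(self, kd1, kd2, p2):
        with pytest.raises(ValidationError):
            predict_fractions(p2, kd1, kd2)

    @given(
        p2=st.floats(0, 1e6),
        kd1=st.floats(1e-6, 1e6),
        kd2=st.floats(1e-6, 1e6),
    )
    @settings(max_examples=200, derandomize=True)
    def test_fractions_normalized_and_bounded(self, p2, kd1, kd2):
        y = predict_fractions(p2, kd1, kd2)
        assert all(0 <= v <= 1 for v in y)
        assert sum(y) == pytest.approx(1.0, abs=1e-9)

    def test_monotonicity_in_protein(self):
        p = np.geomspace(1e-3, 1e3, 200)
        y = fraction_matrix(p, kd1=1.0, kd2=0.1)
        assert np.all(np.diff(y[:, 0]) < 0)  # free probe strictly decreasing
        assert np.all(np.diff(y[:, 2]) > 0)  # tetramer strictly increasing


class TestCooperativity:
    @pytest.mark.parametrize("kd1,kd2,expected", [(1, 1, 1), (1, 0.01, 100), (5, 5, 1)])
    def test_ratio(self, kd1, kd2, expected):
        assert cooperativity(kd1, kd2) == pytest.approx(expected)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            cooperativity(0, 1)


class TestTitrationIngest:
    def test_renormalizes_within_tolerance(self):
        series = TitrationSeries.from_arrays([0.1, 1.0, 10.0], np.array([
            [0.9, 0.06, 0.02],  # sums 0.98
            [0.30, 0.45, 0.28],  # sums 1.03
            [0.05, 0.20, 0.76],  # sums 1.01
        ]))
        assert np.allclose(series.fractions.sum(axis=1), 1.0)

    def test_rejects_outside_tolerance(self):
        with pytest.raises(ValidationError, match="fraction sums"):
            TitrationSeries.from_arrays([0.1, 1.0, 10.0], np.array([
                [0.5, 0.2, 0.2],  # sums 0.9
                [0.3, 0.4, 0.3],
                [0.1, 0.2, 0.7],
            ]))

    def test_fit_requires_three_distinct_amounts(self):
        series = simulate_titration(1.0, 10.0, [1.0, 1.0, 1.0])
        with pytest.raises(ValidationError, match="distinct"):
            fit_cooperative(series)


class TestCooperativeFit:
    @pytest.mark.parametrize("kd1", [0.1, 1.0, 10.0])
    @pytest.mark.parametrize("kcoop", [1.0, 10.0, 100.0])
    def test_noiseless_parameter_recovery(self, kd1, kcoop):
        """Fitting model-generated data returns the generating parameters."""
        ladder = kd1 * LADDER8  # same relative coverage at every scale
        series = simulate_titration(kd1, kcoop, ladder)
        fit = fit_cooperative(series)
        assert fit.converged
        assert fit.kd1 == pytest.approx(kd1, rel=1e-3)
        assert fit.kcoop == pytest.approx(kcoop, rel=1e-3)

    @pytest.mark.parametrize("c", [0.5, 3.7, 100.0])
    def test_scale_invariance_of_kcoop(self, c):
        """Rescaling protein units rescales kd1/kd2 but leaves kcoop fixed."""
        series = simulate_titration(1.0, 50.0, LADDER8)
        fit = fit_cooperative(series)
        fit_scaled = fit_cooperative(series.scaled(c))
        assert fit_scaled.kd1 == pytest.approx(c * fit.kd1, rel=1e-3)
        assert fit_scaled.kd2 == pytest.approx(c * fit.kd2, rel=1e-3)
        assert fit_scaled.kcoop == pytest.approx(fit.kcoop, rel=1e-3)

    def test_censoring_at_ceiling_when_intermediate_undetectable(self):
        """No visible one-dimer band -> kcoop reported as >= ceiling."""
        series = simulate_titration(1.0, 1e4, LADDER8)
        assert series.fractions[:, 1].max() < 0.02
        fit = fit_cooperative(series)
        assert fit.censored
        assert fit.kcoop == fit.ceiling == 200.0

    def test_uncensored_fit_reports_exact_ratio(self):
        fit = fit_cooperative(simulate_titration(1.0, 10.0, LADDER8))
        assert not fit.censored
        assert fit.kcoop == pytest.approx(fit.kd1 / fit.kd2, rel=1e-9)

    def test_noisy_fit_lands_in_the_right_ballpark(self):
        # a single noisy draw scatters widely at high cooperativity (the
        # intermediate band peaks at only ~0.1); the distributional 25%
        # bound lives in the acceptance suite as a median over replicates
        series = simulate_titration(
            1.0, 100.0, default_protein_ladder(12), NoiseModel(sd=0.05, seed=1)
        )
        fit = fit_cooperative(series)
        assert not fit.censored
        assert 50.0 <= fit.kcoop <= 200.0


class TestSaturation:
    @pytest.mark.parametrize(
        "d,pt,kd,expected",
        [(0.0, 1.0, 1.0, 0.0), (2.0, 1.0, 2.0, 0.5), (1e9, 3.0, 1.0, 3.0)],
    )
    def test_predict_values(self, d, pt, kd, expected):
        assert predict_saturation(d, pt, kd) == pytest.approx(expected, rel=1e-6)

    def test_predict_rejects_negatives(self):
        with pytest.raises(ValidationError):
            predict_saturation(-1.0, 1.0, 1.0)

    def test_total_probe_conversion_consistent(self):
        # bound from total probe must satisfy the free-probe relation
        pd = bound_from_total_probe(5.0, pt=1.0, kd=2.0)
        d_free = 5.0 - pd
        assert predict_saturation(d_free, 1.0, 2.0) == pytest.approx(pd, rel=1e-9)

    def test_noiseless_recovery(self):
        series = simulate_saturation(1.0, 2.0)
        fit = fit_saturation(series)
        assert fit.converged
        assert fit.pt == pytest.approx(1.0, rel=1e-3)
        assert fit.kd == pytest.approx(2.0, rel=1e-3)

    def test_flat_series_flagged_as_boundary(self):
        series = SaturationSeries.from_arrays([0.5, 1, 2, 4, 8], [1.0] * 5)
        with pytest.warns(UserWarning, match="half-saturation"):
            fit = fit_saturation(series)
        assert not fit.converged
        assert fit.kd < 1e-6

    def test_all_zero_bound_rejected(self):
        series = SaturationSeries.from_arrays([1, 2, 4], [0, 0, 0])
        with pytest.raises(ValidationError, match="zero"):
            fit_saturation(series)

    def test_noisy_recovery_seeded(self):
        # single-draw ballpark; the median-over-replicates 25% bound is an
        # acceptance-suite check
        series = simulate_saturation(1.0, 2.0, noise=NoiseModel(sd=0.05, seed=3))
        fit = fit_saturation(series)
        assert fit.kd == pytest.approx(2.0, rel=0.5)
        assert fit.pt > 0 and predict_saturation(1e12, fit.pt, fit.kd) <= fit.pt
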