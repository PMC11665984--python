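"""Knot curves, choice probabilities, likelihoods, and rescaling."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import triadscale as ts
from triadscale.models import triad_probabilities


def monotone_curve(increments, x0=0.0, dx=1.0):
    y = np.concatenate([[0.0], np.cumsum(increments)])
    x = x0 + dx * np.arange(len(y))
    return ts.KnotCurve(x, y)


class TestKnotCurve:
    def test_reproduces_knot_ordinates_exactly(self):
        curve = monotone_curve([2.0, 0.5, 3.0, 1.0])
        assert np.array_equal(curve(curve.knot_x), curve.knot_y)

    def test_collinear_knots_interpolate_linearly(self):
        curve = ts.KnotCurve([0, 1, 2, 3, 4], [0, 1, 2, 3, 4])
        assert curve(1.5) == pytest.approx(1.5, abs=1e-12)

    def test_origin_maps_to_zero(self):
        curve = monotone_curve([1.0, 2.0], x0=20.0, dx=40.0)
        assert curve(20.0) == 0.0

    @pytest.mark.parametrize(
        "x, y",
        [([0, 2, 1], [0, 1, 2]), ([0, 1, 2], [0, 2, 1]), ([0, 1, 2], [1, 2, 3])],
    )
    def test_malformed_knots_rejected(self, x, y):
        with pytest.raises(ValueError):
            ts.KnotCurve(x, y)

    @given(
        increments=st.lists(st.floats(0.01, 10.0), min_size=2, max_size=6),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bracketed_between_knots(self, increments):
        """PCHIP through monotone knots never decreases or overshoots."""
        curve = monotone_curve(increments)
        xs = np.linspace(curve.knot_x[0], curve.knot_x[-1], 300)
        ys = curve(xs)
        assert np.all(np.diff(ys) >= -1e-10)
        for i in range(len(curve.knot_x) - 1):
            seg = ys[(xs >= curve.knot_x[i]) & (xs <= curve.knot_x[i + 1])]
            assert np.all(seg >= curve.knot_y[i] - 1e-10)
            assert np.all(seg <= curve.knot_y[i + 1] + 1e-10)

    def test_flat_extrapolation_warns(self):
        curve = monotone_curve([1.0, 1.0])
        with pytest.warns(ts.ExtrapolationWarning):
            assert curve(99.0) == pytest.approx(curve.knot_y[-1])
        with pytest.warns(ts.ExtrapolationWarning):
            assert curve(-5.0) == 0.0


class TestChoiceProbability:
    def test_symmetric_triad_is_coin_flip(self):
        triad = ts.Triad(50, 5, 5)
        model = ts.ScalingModel(variant="baseline", slope=0.3)
        assert ts.choice_probability(model, triad) == 0.5

    def test_baseline_probit_value(self):
        """slope 0.2, d1 - d2 = 5: Phi(1)."""
        model = ts.ScalingModel(variant="baseline", slope=0.2)
        p = ts.choice_probability(model, ts.Triad(50, 10, 5))
        assert p == pytest.approx(norm.cdf(1.0), abs=1e-12)

    def test_identity_curves_reduce_to_baseline(self):
        g = ts.KnotCurve.linear(0.0, 100.0, 1.0, n_knots=5)
        f = ts.KnotCurve.linear(0.0, 40.0, 1.0, n_knots=5)
        gf = ts.ScalingModel(variant="gf", g=g, f=f)
        base = ts.ScalingModel(variant="baseline", slope=1.0)
        for triad in [ts.Triad(50, 10, 5), ts.Triad(60, 2.5, 12.5), ts.Triad(70, 20, 10)]:
            assert ts.choice_probability(gf, triad) == pytest.approx(
                ts.choice_probability(base, triad), abs=1e-9
            )

    def test_strictly_monotone_in_offsets(self):
        model = ts.make_truth_model("diminishing_returns")
        p_mid = ts.choice_probability(model, ts.Triad(60, 10, 5))
        assert ts.choice_probability(model, ts.Triad(60, 12.5, 5)) > p_mid
        assert ts.choice_probability(model, ts.Triad(60, 10, 7.5)) < p_mid

    def test_mirror_probabilities_sum_to_one(self):
        model = ts.ScalingModel(variant="baseline", slope=0.17)
        p = ts.choice_probability(model, ts.Triad(50, 10, 5))
        q = ts.choice_probability(model, ts.Triad(50, 5, 10))
        assert p + q == pytest.approx(1.0, abs=1e-12)

    def test_stimulus_outside_domain_named_in_error(self):
        model = ts.make_truth_model("concave_g")
        with pytest.raises(ValueError, match="light"):
            ts.choice_probability(model, ts.Triad(90, 0, 10), presentation_offset=5.0)


class TestLogLikelihood:
    def test_coin_flip_likelihood_is_n_log_half(self):
        model = ts.ScalingModel(variant="baseline", slope=0.3)
        triad = ts.Triad(50, 5, 5)
        records = [
            ts.ResponseRecord("p0", triad, chose_dark=(i % 2 == 0), correct=(i % 2 != 0))
            for i in range(8)
        ]
        assert ts.log_likelihood(model, records) == pytest.approx(-8 * math.log(2))

    def test_single_response_is_log_p(self):
        model = ts.ScalingModel(variant="baseline", slope=0.2)
        triad = ts.Triad(50, 10, 5)
        rec = ts.ResponseRecord("p0", triad, chose_dark=True, correct=True)
        assert ts.log_likelihood(model, [rec]) == pytest.approx(math.log(norm.cdf(1.0)))

    def test_matches_manual_bernoulli_sum_on_fixture(self):
        model = ts.ScalingModel(variant="baseline", slope=0.1)
        triads = [ts.Triad(50, 10, 5), ts.Triad(60, 5, 10), ts.Triad(70, 12.5, 2.5)]
        choices = [True, True, False, False, True]
        fixture = [
            ts.ResponseRecord(
                f"p{i}", t, chose_dark=c, correct=(c == (t.d1 > t.d2))
            )
            for i, (t, c) in enumerate(zip(triads * 2, choices))
        ]
        manual = 0.0
        for rec in fixture:
            p = ts.choice_probability(model, rec.triad)
            manual += math.log(p if rec.chose_dark else 1 - p)
        assert ts.log_likelihood(model, fixture) == pytest.approx(manual, abs=1e-10)

    def test_empty_responses_rejected(self):
        model = ts.ScalingModel(variant="baseline", slope=0.1)
        with pytest.raises(ValueError):
            ts.log_likelihood(model, [])

    def test_baseline_mle_matches_probit_grid(self, filtered_design):
        """The likelihood over slope peaks where a brute-force grid peaks."""
        truth = ts.ScalingModel(variant="baseline", slope=0.15)
        noise = ts.NoiseSpec(sigma_disc=1 / math.sqrt(2), sigma_err=0)
        data = ts.simulate_dataset(filtered_design, truth, noise, 50, seed=4).responses
        grid = np.linspace(0.05, 0.4, 141)
        lls = [
            ts.log_likelihood(ts.ScalingModel(variant="baseline", slope=s), data)
            for s in grid
        ]
        best_grid = grid[int(np.argmax(lls))]
        fitted = ts.fit_model(data, ts.FitConfig(variant="baseline", seed=0))
        assert fitted.model.slope == pytest.approx(best_grid, abs=grid[1] - grid[0])


class TestRescaleModel:
    def test_linear_g_normalizes_to_unit_interval(self):
        g = ts.KnotCurve.linear(20.0, 100.0, 1.0, n_knots=5)
        model = ts.ScalingModel(variant="g", g=g)
        rescaled, report = ts.rescale_model(model)
        assert rescaled.g(20.0, warn=False) == pytest.approx(0.0)
        assert rescaled.g(60.0, warn=False) == pytest.approx(0.5)
        assert rescaled.g(100.0, warn=False) == pytest.approx(1.0)
        assert report["scale"] == pytest.approx(1 / 80)

    def test_already_unit_span_unchanged(self):
        x = np.linspace(20, 100, 5)
        g = ts.KnotCurve(x, (x - 20) / 80)
        f = ts.KnotCurve.linear(0, 1, 1.0)
        model = ts.ScalingModel(variant="gf", g=g, f=f)
        rescaled, report = ts.rescale_model(model)
        assert report["scale"] == pytest.approx(1.0)
        assert np.allclose(rescaled.g.knot_y, g.knot_y)
        assert np.allclose(rescaled.f.knot_x, f.knot_x)

    def test_probabilities_invariant_on_design(self, filtered_design):
        rng = np.random.default_rng(12)
        x = np.linspace(20, 100, 5)
        g = ts.KnotCurve(x, np.concatenate([[0], np.cumsum(rng.uniform(5, 30, 4))]))
        f = ts.KnotCurve(
            np.linspace(0, 80, 5), np.concatenate([[0], np.cumsum(rng.uniform(2, 20, 4))])
        )
        model = ts.ScalingModel(variant="gf", g=g, f=f)
        rescaled, _ = ts.rescale_model(model)
        before = [ts.choice_probability(model, t) for t in filtered_design]
        after = [ts.choice_probability(rescaled, t) for t in filtered_design]
        assert max(abs(a - b) for a, b in zip(before, after)) < 1e-10

    def test_degenerate_flat_curve_rejected(self):
        g = ts.KnotCurve([0, 50, 100], [0, 0, 0])
        with pytest.raises(ValueError, match="flat"):
            ts.rescale_model(ts.ScalingModel(variant="g", g=g))

    def test_baseline_rejected(self):
        with pytest.raises(ValueError):
            ts.rescale_model(ts.ScalingModel(variant="baseline", slope=0.1))


class TestSerialization:
    def test_model_json_round_trip(self, tmp_path):
        model = ts.make_truth_model("diminishing_returns")
        path = tmp_path / "model.json"
        ts.save_model(model, path)
        loaded = ts.load_model(path)
        assert loaded.variant == model.variant
        assert np.max(np.abs(loaded.g.knot_y - model.g.knot_y)) < 1e-12
        assert np.max(np.abs(loaded.f.knot_y - model.f.knot_y)) < 1e-12

    def test_variant_field_validation(self):
        with pytest.raises(ValueError):
            ts.ScalingModel(variant="baseline", slope=-1.0)
        with pytest.raises(ValueError):
            ts.ScalingModel(variant="g")
        with pytest.raises(ValueError):
            ts.ScalingModel(variant="nonsense", slope=1.0)

    def test_response_record_consistency_enforced(self):
        triad = ts.Triad(50, 10, 5)
        with pytest.raises(ValueError):
            ts.ResponseRecord("p0", triad, chose_dark=True, correct=False)
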