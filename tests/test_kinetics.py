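import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nanorelease as nr
from nanorelease import kinetics


REFERENCE_PARAMS = {
    "zero_order": {"C0": 1.0, "K0": 0.5},
    "first_order": {"Cd": 2.0, "K1": 0.08},
    "second_order": {"Cd": 2.0, "K2": 0.03},
    "higuchi": {"KH": 0.5},
    "hixson_crowell": {"Cd": 8.0, "KHC": 0.05},
    "weibull": {"Cs": 1.0, "T": 0.0, "a": 5.0, "b": 0.6},
    "power_law": {"K": 0.12, "n": 0.3},
}


def make_curve(model, params, times, noise_sd=0.0, seed=0):
    curve, _ = nr.generate_release_curve(nr.SyntheticCurveSpec(
        model=model, params=params, times=times,
        noise_sd=noise_sd, seed=seed,
        value_kind="fraction" if model in ("weibull", "power_law")
        else "amount",
    ))
    return curve


class TestPredict:
    @pytest.mark.parametrize("model,params,t,expected", [
        ("zero_order", {"C0": 0, "K0": 2}, 5.0, 10.0),
        ("weibull", {"Cs": 1, "T": 0, "a": 1, "b": 1}, math.log(2), 0.5),
        # release at t = 1 min equals K for any exponent
        ("power_law", {"K": 0.7379, "n": 0.088}, 1.0, 0.7379),
        ("higuchi", {"KH": 2.0}, 9.0, 6.0),
    ])
    def test_point_values(self, model, params, t, expected):
        assert nr.predict(model, params, [t])[0] == pytest.approx(expected)

    def test_missing_parameter(self):
        with pytest.raises(nr.ParameterError):
            nr.predict("power_law", {"K": 0.5}, [1.0])

    def test_negative_exponent_rejected(self):
        with pytest.raises(nr.DomainError):
            nr.predict("power_law", {"K": 0.5, "n": -0.1}, [1.0])
        with pytest.raises(nr.DomainError):
            nr.predict("weibull", {"Cs": 1, "T": 0, "a": 1, "b": -1}, [1.0])
        with pytest.raises(nr.DomainError):
            nr.predict("zero_order", {"C0": 0, "K0": 1}, [-1.0])

    def test_hixson_crowell_clips_at_total(self):
        # once the cube root hits zero the release stays at Cd
        v = nr.predict("hixson_crowell", {"Cd": 1.0, "KHC": 0.5},
                       [0.0, 2.0, 10.0])
        assert v[1] == pytest.approx(1.0)
        assert v[2] == pytest.approx(1.0)

    def test_second_order_printed_sign_flag(self):
        # the printed sign makes 1/(Cd-Ct) fall with time instead of rise
        t = np.array([0.0, 1.0, 2.0])
        up = nr.predict("second_order", {"Cd": 2.0, "K2": 0.1}, t)
        down = nr.predict("second_order", {"Cd": 2.0, "K2": 0.1}, t,
                          printed_sign=True)
        assert np.all(np.diff(up) > 0)
        assert np.all(np.diff(down) < 0)

    @given(st.floats(0.01, 2.0), st.floats(0.0, 50.0))
    @settings(max_examples=50, deadline=None)
    def test_power_law_half_exponent_is_higuchi(self, k, t):
        pl = nr.predict("power_law", {"K": k, "n": 0.5}, [t])[0]
        hg = nr.predict("higuchi", {"KH": k}, [t])[0]
        assert pl == pytest.approx(hg, rel=1e-12, abs=1e-12)

    @given(st.floats(0.1, 5.0), st.floats(0.05, 3.0), st.floats(0.0, 50.0))
    @settings(max_examples=50, deadline=None)
    def test_weibull_b1_is_first_order(self, cs, a, t):
        wb = nr.predict("weibull", {"Cs": cs, "T": 0, "a": a, "b": 1}, [t])[0]
        fo = nr.predict("first_order", {"Cd": cs, "K1": 1 / a}, [t])[0]
        assert wb == pytest.approx(fo, rel=1e-12, abs=1e-12)

    @pytest.mark.parametrize("model", list(nr.MODELS))
    def test_monotone_nondecreasing(self, model):
        t = np.linspace(0.0, 40.0, 200)
        v = nr.predict(model, REFERENCE_PARAMS[model], t)
        assert np.all(np.diff(v) >= -1e-12)


class TestReleaseCurve:
    def test_validation(self, times):
        with pytest.raises(nr.InputError):
            nr.ReleaseCurve(times[:2], [0.1, 0.2])
        with pytest.raises(nr.InputError):
            nr.ReleaseCurve(times[::-1], np.zeros(6))
        with pytest.raises(nr.InputError):
            nr.ReleaseCurve(times, np.full(6, 2.0), "fraction")

    def test_amount_to_fraction(self, times):
        c = nr.ReleaseCurve(times, times * 2.0, "amount", c_inf=80.0)
        f = c.as_fraction()
        assert f.value_kind == "fraction"
        np.testing.assert_allclose(f.values, times * 2.0 / 80.0)

    def test_fraction_conversion_needs_c_inf(self, times):
        c = nr.ReleaseCurve(times, times, "amount")
        with pytest.raises(nr.InputError):
            c.as_fraction()


class TestRSquared:
    def test_perfect_and_mean_prediction(self):
        obs = np.array([1.0, 2.0, 4.0])
        assert nr.r_squared(obs, obs) == pytest.approx(1.0)
        assert nr.r_squared(obs, np.full(3, obs.mean())) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        # SSres = 1, SStot = 2 -> R^2 = 0.5
        assert nr.r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_degenerate_observations_undefined(self):
        assert math.isnan(nr.r_squared([1.0, 1.0, 1.0], [1.0, 1.0, 2.0]))


class TestFitModel:
    @pytest.mark.parametrize("model", list(nr.MODELS))
    def test_noiseless_roundtrip(self, model, times):
        params = REFERENCE_PARAMS[model]
        curve = make_curve(model, params, times)
        fr = nr.fit_model(curve, model)
        assert fr.converged
        for k, true in params.items():
            assert fr.estimates[k] == pytest.approx(
                true, rel=1e-6, abs=1e-6
            ), f"{model}.{k}"
        assert fr.r_squared >= 1 - 1e-10

    def test_noisy_power_law_matches_grid_oracle(self, times):
        curve = make_curve("power_law", {"K": 0.5, "n": 0.3}, times,
                           noise_sd=0.01, seed=7)
        fr = nr.fit_model(curve, "power_law")
        # exhaustive SSres minimisation over the (K, n) grid
        K = np.arange(0.0, 1.5 + 1e-12, 1e-3)
        n = np.arange(0.0, 1.5 + 1e-12, 1e-3)
        tv = curve.times[None, :] ** n[:, None]  # (n, t)
        ss = ((K[:, None, None] * tv[None, :, :]
               - curve.values[None, None, :]) ** 2).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(ss), ss.shape)
        assert fr.estimates["K"] == pytest.approx(K[i], abs=2e-3)
        assert fr.estimates["n"] == pytest.approx(n[j], abs=2e-3)

    def test_power_law_requires_fraction_scale(self, times):
        amount = nr.ReleaseCurve(times, times * 3.0, "amount")
        with pytest.raises(nr.InputError):
            nr.fit_model(amount, "power_law")
        with_cinf = nr.ReleaseCurve(times, times * 3.0, "amount", c_inf=90.0)
        fr = nr.fit_model(with_cinf, "power_law")
        assert fr.converged and fr.estimates["n"] == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_data_flagged(self, times):
        flat = nr.ReleaseCurve(times, np.full(6, 0.4), "fraction")
        fr = nr.fit_model(flat, "zero_order")
        assert math.isnan(fr.r_squared)
        assert "degenerate" in fr.message

    def test_too_few_points_rejected(self):
        curve = nr.ReleaseCurve([1.0, 2.0, 3.0], [0.1, 0.2, 0.3], "fraction")
        with pytest.raises(nr.InputError):
            nr.fit_model(curve, "weibull")  # 4 parameters need >= 5 points

    @pytest.mark.parametrize("model", ["zero_order", "first_order",
                                       "second_order", "higuchi",
                                       "hixson_crowell", "power_law"])
    def test_linearized_noiseless_recovery(self, model, times):
        params = REFERENCE_PARAMS[model]
        curve = make_curve(model, params, times)
        if "Cd" in params:
            # the anchored linearizations are exact only with the true total
            curve = nr.ReleaseCurve(curve.times, curve.values, "amount",
                                    c_inf=params["Cd"])
        fr = nr.fit_model(curve, model, scale="linearized")
        assert fr.fit_scale == "linearized"
        assert fr.r_squared == pytest.approx(1.0, abs=1e-6)
        # rate constants recover; Cd anchors are approximations by design
        rate = {"zero_order": "K0", "first_order": "K1", "higuchi": "KH",
                "power_law": "n"}.get(model)
        if rate:
            assert fr.estimates[rate] == pytest.approx(
                params[rate], rel=0.05)

    def test_linearized_weibull_unsupported(self, times):
        curve = make_curve("weibull", REFERENCE_PARAMS["weibull"], times)
        with pytest.raises(nr.InputError):
            nr.fit_model(curve, "weibull", scale="linearized")

    def test_power_law_loglog_matches_normal_equations(self, times):
        curve = make_curve("power_law", {"K": 0.4, "n": 0.25}, times,
                           noise_sd=0.005, seed=3)
        fr = nr.fit_model(curve, "power_law", scale="linearized")
        x, y = np.log(curve.times), np.log(curve.values)
        n_hat = (len(x) * (x * y).sum() - x.sum() * y.sum()) / \
            (len(x) * (x * x).sum() - x.sum() ** 2)
        k_hat = math.exp(y.mean() - n_hat * x.mean())
        assert fr.estimates["n"] == pytest.approx(n_hat, rel=1e-9)
        assert fr.estimates["K"] == pytest.approx(k_hat, rel=1e-9)


class TestFitAll:
    def test_linear_data_ranks_zero_order_first(self, times):
        curve = make_curve("zero_order", {"C0": 1.0, "K0": 0.5}, times)
        results = nr.fit_all(curve)
        assert results[0].name == "zero_order"
        assert results[0].r_squared == pytest.approx(1.0)

    def test_power_law_data_ranks_power_law_first(self, times):
        wins = 0
        for seed in range(20):
            curve = make_curve("power_law", {"K": 0.7379, "n": 0.1}, times,
                               noise_sd=0.01, seed=seed)
            wins += nr.fit_all(curve)[0].name == "power_law"
        assert wins >= 19

    def test_step_data_prefers_weibull(self, times):
        # constant-after-jump: only a steep sigmoid can track it
        values = np.where(times < 4.0, 0.0, 0.9)
        curve = nr.ReleaseCurve(times, values, "fraction")
        results = {r.name: r for r in nr.fit_all(curve)}
        wb = results["weibull"]
        assert wb.converged
        assert wb.estimates["b"] > 1.5
        ss = {name: float(np.sum(r.residuals ** 2))
              for name, r in results.items() if r.converged}
        assert ss["weibull"] == min(ss.values())

    def test_ranking_invariant_under_row_permutation(self, times, tmp_path):
        curve = make_curve("power_law", {"K": 0.5, "n": 0.2}, times,
                           noise_sd=0.01, seed=11)
        order1 = [r.name for r in nr.fit_all(curve)]
        path = tmp_path / "shuffled.csv"
        rows = list(zip(curve.times, curve.values))
        rng = np.random.default_rng(0)
        rng.shuffle(rows)
        lines = ["time_min,release"] + [f"{t},{v}" for t, v in rows] + \
            ["value_kind,fraction"]
        path.write_text("\n".join(lines))
        order2 = [r.name for r in nr.fit_all(nr.read_release_csv(path))]
        assert order1 == order2

    def test_failed_models_ranked_last(self, times):
        amount = nr.ReleaseCurve(times, times * 2.0, "amount")  # no c_inf
        results = nr.fit_all(amount)
        failed = [r.name for r in results if not r.converged]
        # fraction-scale models cannot run without c_inf ...
        assert {"power_law", "weibull"} <= set(failed)
        # ... and every unusable fit sits at the tail of the ranking
        assert [r.name for r in results[-len(failed):]] == failed

    def test_plain_r_squared_ranking_available(self, times):
        curve = make_curve("power_law", {"K": 0.5, "n": 0.2}, times,
                           noise_sd=0.01, seed=1)
        results = nr.fit_all(curve, rank_by="r_squared")
        usable = [r for r in results if r.converged]
        r2 = [r.r_squared for r in usable]
        assert r2 == sorted(r2, reverse=True)


class TestClassification:
    @pytest.mark.parametrize("n,label", [
        (0.088, "fickian"),      # the fitted exponent of the release data
        (0.3, "fickian"),
        (0.5, "anomalous"),      # boundary belongs to the upper class
        (0.7, "anomalous"),
        (1.0, "case_II"),
        (1.0 + 5e-10, "case_II"),
        (1.2, "super_case_II"),
    ])
    def test_power_law_thresholds(self, n, label):
        call = nr.classify_power_law(n)
        assert call.label == label
        assert call.source == "power_law_n"
        assert call.statistic_value == pytest.approx(n)

    @pytest.mark.parametrize("b,label", [
        (0.3612, "fickian"),     # the fitted Weibull shape factor
        (0.75, "fickian"),       # boundary is "less or equal"
        (0.9, "combined"),
        (1.0, "combined"),
        (1.2, "complex"),
    ])
    def test_weibull_thresholds(self, b, label):
        assert nr.classify_weibull(b).label == label

    def test_domain_errors(self):
        with pytest.raises(nr.DomainError):
            nr.classify_power_law(-0.1)
        with pytest.raises(nr.DomainError):
            nr.classify_weibull(0.0)

    @given(st.floats(0.0, 5.0))
    @settings(max_examples=200, deadline=None)
    def test_power_law_total_and_deterministic(self, n):
        call = nr.classify_power_law(n)
        assert call.label in {"fickian", "anomalous", "case_II",
                              "super_case_II"}
        assert nr.classify_power_law(n).label == call.label


class TestCsvIO:
    def test_roundtrip_with_metadata(self, times, tmp_path):
        curve = nr.ReleaseCurve(times, times / 40.0, "amount", c_inf=2.0)
        path = tmp_path / "curve.csv"
        nr.write_release_csv(curve, path)
        back = nr.read_release_csv(path)
        np.testing.assert_allclose(back.times, curve.times)
        np.testing.assert_allclose(back.values, curve.values)
        assert back.value_kind == "amount"
        assert back.c_inf == pytest.approx(2.0)
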