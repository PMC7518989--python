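"""Stock–flow integration: mass balance, oracle equivalence, scenarios."""

import numpy as np
import pytest

from heatsd import (
    InputError,
    ModelState,
    Scenario,
    compare,
    episode_table,
    detect_heatwaves,
    peak_reduction_days,
    simulate,
    step,
)

from .conftest import make_series, random_params


def brute_force_trajectories(series, profile, params, scenario, initial_ap):
    """Independent straight-line re-implementation of the model equations.

    Deliberately naive: per-day scalar arithmetic and literal formulas
    (stock update AP += APF - TPF - D, TPF = AP*AF, D = AP*mu*MA(t)*HDAF(h),
    AF = af0*EC*HF*GF with Cobb-Douglas factors, proportional scaling when
    outflows exceed stock + inflow), used as the oracle for the engine.
    """
    def interp(table, x):
        pts = table.breakpoints
        if x <= pts[0][0]:
            return pts[0][1]
        if x >= pts[-1][0]:
            return pts[-1][1]
        for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
            if x0 <= x <= x1:
                return y0 + (y1 - y0) * (x - x0) / (x1 - x0)
        raise AssertionError

    tmax = [r.tmax for r in series]
    if scenario.kind == "temp_offset":
        tmax = [t + scenario.delta_temp for t in tmax]

    def profile_on(day):
        if day < scenario.warning_day:
            return profile
        if scenario.kind == "bed_readiness":
            return profile.replace(beds=profile.beds * (1 + scenario.bed_fraction))
        if scenario.kind == "allowance_increase":
            return profile.replace(
                allowance=profile.allowance * scenario.allowance_multiplier)
        return profile

    def powerlaw(prof, fields):
        ad = params.adaptation
        v = 1.0
        for f in fields:
            w = ad.weights.get(f, 0.0)
            if w:
                ratio = max(getattr(prof, f) / getattr(ad.reference_profile, f),
                            ad.factor_floor)
                v *= ratio ** w
        return min(max(v, ad.factor_floor), ad.factor_cap)

    ex = params.exposure
    pop = profile.total_population * (
        1.0 + params.elderly_vulnerability * profile.share_over65)
    ap = initial_ap
    hot = 0
    out = {"apf": [], "tpf": [], "deaths": [], "ap": []}
    for t in range(len(tmax)):
        hot = hot + 1 if tmax[t] > params.hot_threshold else 0
        prof = profile_on(t)
        apf = pop / 1e7 * (ex.r_base + ex.beta_morb * max(0.0, tmax[t] - ex.t_morb))
        cf = interp(params.ma_table, tmax[t]) * interp(params.hdaf_table, hot)
        if params.cf_on_apf:
            apf *= cf
        if params.allowance_elasticity:
            apf *= (prof.allowance
                    / params.adaptation.reference_profile.allowance
                    ) ** (-params.allowance_elasticity)
        ec = powerlaw(prof, ("ac_rate", "income"))
        hf = powerlaw(prof, ("staff", "beds", "hospitals"))
        gf = powerlaw(prof, ("allowance", "insurance"))
        af = min(params.adaptation.af_cap, params.adaptation.af0 * ec * hf * gf)
        tpf = min(ap * af, prof.beds * params.bed_capacity)
        d = ap * ex.mu * cf
        if tpf + d > ap + apf and tpf + d > 0:
            s = (ap + apf) / (tpf + d)
            tpf, d = tpf * s, d * s
        ap = ap + apf - tpf - d
        for key, val in zip(("apf", "tpf", "deaths", "ap"), (apf, tpf, d, ap)):
            out[key].append(val)
    return {k: np.array(v) for k, v in out.items()}


class TestStep:
    def test_empty_system_is_inert(self, neutral_params, profile_2013):
        state = ModelState()
        params = neutral_params
        # no baseline inflow either
        from heatsd import ExposureParameters
        import dataclasses
        params = dataclasses.replace(
            params, exposure=ExposureParameters(beta_morb=0.0, r_base=0.0, mu=0.05))
        new, flows = step(state, 34.0, 0, profile_2013, params)
        assert flows["apf"] == flows["tpf"] == flows["deaths"] == 0.0
        assert new.ap == 0.0 and new.day == 1

    def test_hand_evaluated_flows(self, neutral_params, profile_2013):
        """ap=100, no inflow, af=0.3, mu*cf=0.05: tpf=30, d=5, ap'=65."""
        import dataclasses
        from heatsd import ExposureParameters
        params = dataclasses.replace(
            neutral_params,
            exposure=ExposureParameters(beta_morb=0.0, r_base=0.0, mu=0.05))
        state = ModelState(ap=100.0)
        new, flows = step(state, 34.0, 0, profile_2013, params)
        assert flows["tpf"] == pytest.approx(30.0)
        assert flows["deaths"] == pytest.approx(5.0)
        assert new.ap == pytest.approx(65.0)

    def test_outflow_demand_scaled_proportionally(self, neutral_params,
                                                  profile_2013):
        """Demand beyond stock+inflow is scaled; stock hits exactly zero."""
        import dataclasses
        from heatsd import AdaptationParameters, ExposureParameters
        params = dataclasses.replace(
            neutral_params,
            exposure=ExposureParameters(beta_morb=0.0, r_base=0.0, mu=0.9),
            adaptation=AdaptationParameters(
                reference_profile=profile_2013, af0=0.9),
        )
        state = ModelState(ap=100.0)
        new, flows = step(state, 34.0, 0, profile_2013, params)
        assert flows["tpf"] + flows["deaths"] == pytest.approx(100.0)
        # TPF:death ratio preserved (0.9 : 0.9)
        assert flows["tpf"] == pytest.approx(flows["deaths"])
        assert new.ap == pytest.approx(0.0)


class TestSimulate:
    def test_no_forcing_no_deaths(self, profile_2013, neutral_params):
        import dataclasses
        from heatsd import ExposureParameters
        params = dataclasses.replace(
            neutral_params,
            exposure=ExposureParameters(beta_morb=0.0, r_base=0.0, mu=0.05),
            background_rate=0.0,
        )
        series = make_series([36.0] * 10)
        result = simulate(series, profile_2013, params, Scenario(), initial_ap=0.0)
        assert np.all(result.deaths == 0.0)
        assert np.all(result.total_deaths == 0.0)

    def test_mass_balance_over_random_draws(self, profile_2013, hw2013_series):
        """initial + Σinflow = final stock + Σoutflows, to 1e-9 relative."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            params = random_params(rng, profile_2013)
            initial_ap = float(rng.uniform(0, 2000))
            r = simulate(hw2013_series, profile_2013, params,
                         Scenario(), initial_ap=initial_ap)
            lhs = initial_ap + r.apf.sum()
            rhs = r.final_ap + r.tpf.sum() + r.deaths.sum()
            assert lhs == pytest.approx(rhs, rel=1e-9)
            assert (r.ap >= 0).all()
            assert (r.deaths >= 0).all() and (r.tpf >= 0).all()

    def test_matches_brute_force_oracle(self, profile_2013, hw2013_series):
        """Engine trajectories equal a naive re-implementation, 10 draws."""
        rng = np.random.default_rng(7)
        scenarios = [
            Scenario(),
            Scenario(kind="temp_offset", delta_temp=1.0),
            Scenario(kind="bed_readiness"),
            Scenario(kind="allowance_increase", warning_day=3),
        ]
        for i in range(10):
            params = random_params(rng, profile_2013)
            scenario = scenarios[i % len(scenarios)]
            initial_ap = float(rng.uniform(0, 1000))
            r = simulate(hw2013_series, profile_2013, params, scenario,
                         initial_ap=initial_ap)
            oracle = brute_force_trajectories(
                hw2013_series, profile_2013, params, scenario, initial_ap)
            for key in ("apf", "tpf", "deaths", "ap"):
                np.testing.assert_allclose(
                    getattr(r, key), oracle[key], rtol=1e-9, atol=1e-12,
                    err_msg=f"draw {i} field {key}")

    def test_mitigation_never_increases_daily_deaths(self, profile_2013,
                                                     hw2013_series):
        rng = np.random.default_rng(3)
        for _ in range(5):
            params = random_params(rng, profile_2013)
            base = simulate(hw2013_series, profile_2013, params, Scenario(),
                            initial_ap=100.0)
            for kind in ("bed_readiness", "allowance_increase"):
                alt = simulate(hw2013_series, profile_2013, params,
                               Scenario(kind=kind), initial_ap=100.0)
                assert np.all(alt.total_deaths <= base.total_deaths + 1e-9)

    def test_warming_never_decreases_daily_deaths(self, profile_2013,
                                                  hw2013_series):
        rng = np.random.default_rng(4)
        for _ in range(5):
            params = random_params(rng, profile_2013)
            base = simulate(hw2013_series, profile_2013, params, Scenario(),
                            initial_ap=100.0)
            warm = simulate(hw2013_series, profile_2013, params,
                            Scenario(kind="temp_offset", delta_temp=1.0),
                            initial_ap=100.0)
            assert np.all(warm.total_deaths >= base.total_deaths - 1e-9)

    def test_two_degree_increase_exceeds_one_degree(self, profile_2013,
                                                    hw2013_series,
                                                    default_params):
        base = simulate(hw2013_series, profile_2013, default_params, Scenario())
        one = simulate(hw2013_series, profile_2013, default_params,
                       Scenario(kind="temp_offset", delta_temp=1.0))
        two = simulate(hw2013_series, profile_2013, default_params,
                       Scenario(kind="temp_offset", delta_temp=2.0))
        inc1 = np.mean((one.total_deaths - base.total_deaths) / base.total_deaths)
        inc2 = np.mean((two.total_deaths - base.total_deaths) / base.total_deaths)
        assert inc2 > inc1 > 0

    def test_treatment_delay_shifts_outflow_one_day(self, profile_2013,
                                                    neutral_params):
        """With the optional one-day lag, nothing is treated on day one and
        mass balance still holds."""
        import dataclasses
        params = dataclasses.replace(neutral_params, tpf_delay=True)
        series = make_series([37.0] * 6)
        r = simulate(series, profile_2013, params, Scenario(), initial_ap=500.0)
        assert r.tpf[0] == 0.0
        assert r.tpf[1] > 0.0
        lhs = 500.0 + r.apf.sum()
        assert lhs == pytest.approx(r.final_ap + r.tpf.sum() + r.deaths.sum(),
                                    rel=1e-9)

    def test_rejects_negative_initial_stock(self, profile_2013, neutral_params):
        with pytest.raises(InputError):
            simulate(make_series([36.0]), profile_2013, neutral_params,
                     Scenario(), initial_ap=-1.0)


class TestCompare:
    def test_identical_runs_zero_reduction(self, profile_2013, neutral_params,
                                           hw2013_series):
        r = simulate(hw2013_series, profile_2013, neutral_params, Scenario())
        table = compare(r, r)
        assert np.allclose(table["reduction"], 0.0)
        assert np.allclose(table["pct_reduction"], 0.0)

    def test_reduction_arithmetic(self, profile_2013, neutral_params):
        import dataclasses
        series = make_series([34.0] * 3)
        r = simulate(series, profile_2013, neutral_params, Scenario())
        # lower the background by a known amount and check the arithmetic
        r2 = dataclasses.replace(r, background=r.background * 0.8)
        table = compare(r, r2)
        expected = 100.0 * 0.2 * r.background / r.total_deaths
        assert np.allclose(table["reduction"], 0.2 * r.background)
        assert np.allclose(table["pct_reduction"], expected)

    def test_length_mismatch_rejected(self, profile_2013, neutral_params):
        a = simulate(make_series([34.0] * 3), profile_2013, neutral_params,
                     Scenario())
        b = simulate(make_series([34.0] * 4), profile_2013, neutral_params,
                     Scenario())
        with pytest.raises(InputError):
            compare(a, b)

    def test_zero_baseline_reported_as_nan(self, profile_2013, neutral_params):
        import dataclasses
        from heatsd import ExposureParameters
        params = dataclasses.replace(
            neutral_params,
            exposure=ExposureParameters(beta_morb=0.0, r_base=0.0, mu=0.0),
            background_rate=0.0,
        )
        r = simulate(make_series([34.0] * 3), profile_2013, params, Scenario())
        table = compare(r, r)
        assert table["pct_reduction"].isna().all()

    def test_episode_table_renumbers_days(self, profile_2013, default_params,
                                          hw2013_series):
        base = simulate(hw2013_series, profile_2013, default_params, Scenario())
        alt = simulate(hw2013_series, profile_2013, default_params,
                       Scenario(kind="bed_readiness"))
        ep = detect_heatwaves(hw2013_series)[0]
        tab = episode_table(compare(base, alt), ep)
        assert list(tab["day"]) == list(range(1, ep.duration + 1))

    def test_peak_days_ordering(self):
        import pandas as pd
        tab = pd.DataFrame({"day": [1, 2, 3, 4],
                            "pct_reduction": [1.0, 9.0, 9.0, 5.0]})
        assert peak_reduction_days(tab, n=2) == [2, 3]  # earliest wins tie
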