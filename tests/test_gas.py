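"""Gas calculus: sampling/leak correction, two-population decomposition,
survival fractions, the N2O emission index, electron flows, mass balance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualenrich.gas import (
    CorrectedSeries,
    GasSeries,
    NPools,
    RecoveryNotReachedError,
    VialSpec,
    composite_rate_fixture,
    correct_series,
    electron_flows,
    i_n2o,
    initial_and_end_rates,
    n_mass_balance,
    survival_fraction,
    two_population_fit,
)
from dualenrich.synth import GasPopulation, GasSimSpec, generate_gas_series


def series_from(times, amounts, sampled=None, injections=()):
    df = pd.DataFrame(amounts, index=pd.Index(times, name="time_h"))
    if sampled is None:
        sampled = np.zeros(len(times), dtype=bool)
    return GasSeries(amounts=df, sampled=np.asarray(sampled), injections=list(injections))


class TestCorrectSeries:
    def test_no_events_cumulative_is_amount_change(self):
        t = np.arange(0.0, 10.0, 1.0)
        raw = series_from(t, {"N2": 5.0 + 2.0 * t})
        corr = correct_series(raw, VialSpec())
        np.testing.assert_allclose(corr.cumulative["N2"].to_numpy(), 2.0 * t, atol=1e-12)

    def test_sampling_drop_attributed_to_dilution(self):
        # constant true amount; one sampling removes 1/10 of the headspace
        vial = VialSpec(total_volume=120.0, liquid_volume=50.0, sample_volume=7.0)
        t = [0.0, 1.0, 2.0]
        a = [10.0, 10.0, 9.0]  # drop reflects the sample taken at t=1
        raw = series_from(t, {"N2": a}, sampled=[False, True, False])
        corr = correct_series(raw, vial)
        np.testing.assert_allclose(corr.cumulative["N2"].to_numpy(), 0.0, atol=1e-12)

    def test_constant_production_with_sampling(self):
        # 1 umol/h true production, 1 mL of 70 mL sampled every 3 h
        vial = VialSpec(total_volume=120.0, liquid_volume=50.0, sample_volume=1.0)
        dil = vial.dilution_factor
        times = np.arange(0.0, 24.1, 3.0)
        amount = 0.0
        measured = []
        for k, t in enumerate(times):
            if k > 0:
                amount += 3.0  # production since the previous measurement
            measured.append(amount)
            amount *= dil  # sample withdrawn right after measuring
        raw = series_from(times, {"N2": measured}, sampled=np.ones(len(times), bool))
        corr = correct_series(raw, vial)
        assert corr.cumulative["N2"].iloc[-1] == pytest.approx(24.0, abs=1e-9)

    def test_oracle_equivalence_over_random_scenarios(self):
        # the generator tracks true production; correction must recover it
        rng = np.random.default_rng(42)
        for _ in range(50):
            spec = GasSimSpec(
                populations=(
                    GasPopulation(rng.uniform(1, 10), rng.uniform(-0.05, -0.005)),
                    GasPopulation(rng.uniform(1e-4, 1e-2), rng.uniform(0.02, 0.12)),
                ),
                o2_dose=float(rng.uniform(0, 60)),
                n2o_dose=124.7,
                vial=VialSpec(sample_volume=float(rng.uniform(0.5, 5.0))),
                duration=float(rng.uniform(40, 80)),
                sample_interval=float(rng.choice([1.0, 2.0, 3.0])),
                noise_cv=0.0,
                seed=int(rng.integers(0, 2**31)),
            )
            raw, true = generate_gas_series(spec)
            corr = correct_series(raw, spec.vial)
            for g in ("N2", "N2O", "O2"):
                scale = max(1.0, np.abs(true[g].to_numpy()).max())
                err = np.abs(corr.cumulative[g].to_numpy() - true[g].to_numpy()) / scale
                assert err.max() <= 1e-6

    def test_leak_correction_restores_first_order_loss(self):
        # constant true amount decaying only through leakage toward ambient 0
        lam, a0 = 0.01, 50.0
        t = np.arange(0.0, 30.0, 0.5)  # fine grid keeps midpoint rule accurate
        vial = VialSpec(leak_coefficient={"N2": lam})
        raw = series_from(t, {"N2": a0 * np.exp(-lam * t)})
        corr = correct_series(raw, vial)
        assert np.abs(corr.cumulative["N2"].to_numpy()).max() <= 1e-3 * a0

    def test_oversized_sample_volume_rejected(self):
        with pytest.raises(ValueError, match="sample_volume"):
            VialSpec(total_volume=120.0, liquid_volume=50.0, sample_volume=70.0)


class TestTwoPopulationFit:
    def test_pure_decline_recovery(self):
        t = np.arange(0.0, 100.0, 2.0)
        fit = two_population_fit(t, 8.0 * np.exp(-0.03 * t) + 1e-9)
        assert fit.rate_decline == pytest.approx(-0.03, rel=1e-3)

    def test_fixture_recovers_planted_exponents(self):
        t, r = composite_rate_fixture()
        fit = two_population_fit(t, r)
        assert fit.rate_decline == pytest.approx(-0.03, rel=1e-3)
        assert fit.rate_growth == pytest.approx(0.1, rel=1e-3)
        assert fit.amplitude_decline == pytest.approx(8.0, rel=1e-3)
        assert fit.amplitude_growth == pytest.approx(0.001, rel=1e-3)

    def test_time_shift_rescales_amplitudes_only(self):
        t, _ = composite_rate_fixture()
        c = 10.0
        r_shifted = 8.0 * np.exp(-0.03 * (t + c)) + 0.001 * np.exp(0.1 * (t + c))
        fit = two_population_fit(t, r_shifted)
        assert fit.rate_decline == pytest.approx(-0.03, rel=1e-3)
        assert fit.rate_growth == pytest.approx(0.1, rel=1e-3)
        assert fit.amplitude_decline == pytest.approx(8.0 * np.exp(-0.03 * c), rel=1e-3)
        assert fit.amplitude_growth == pytest.approx(0.001 * np.exp(0.1 * c), rel=1e-3)

    def test_exponent_grid_noise_free_and_noisy(self):
        rng = np.random.default_rng(42)
        for mu1 in (-0.01, -0.03, -0.06):
            for mu2 in (0.05, 0.1, 0.15):
                a, b = 8.0, 8.0 * np.exp((mu1 - mu2) * 60.0)  # crossover at 60 h
                t, r = composite_rate_fixture(
                    amplitude_decline=a, amplitude_growth=b,
                    rate_decline=mu1, rate_growth=mu2,
                )
                clean = two_population_fit(t, r)
                assert clean.rate_decline == pytest.approx(mu1, rel=1e-3)
                assert clean.rate_growth == pytest.approx(mu2, rel=1e-3)
                noisy = two_population_fit(t, r * rng.lognormal(0.0, 0.05, r.size))
                assert noisy.rate_decline == pytest.approx(mu1, rel=0.10)
                assert noisy.rate_growth == pytest.approx(mu2, rel=0.10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            two_population_fit([0, 1, 2], [1.0, 1.0, 1.0])


class TestSurvivalFraction:
    def test_full_survival_is_100(self):
        assert survival_fraction(10.0, 1.0, f=0.1) == pytest.approx(100.0)

    def test_zero_next_rate_is_0(self):
        assert survival_fraction(10.0, 0.0, f=0.1) == 0.0

    def test_linearity(self):
        assert survival_fraction(10.0, 0.5, f=0.1) == pytest.approx(50.0)

    def test_nonpositive_previous_rate_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            survival_fraction(0.0, 1.0)

    @settings(deadline=None, max_examples=50)
    @given(
        scale=st.floats(1e-6, 1e6),
        prev=st.floats(0.1, 100.0),
        ratio=st.floats(0.0, 2.0),
    )
    def test_scale_invariance(self, scale, prev, ratio):
        base = survival_fraction(prev, ratio * prev, f=0.1)
        scaled = survival_fraction(scale * prev, scale * ratio * prev, f=0.1)
        assert scaled == pytest.approx(base, rel=1e-9)


def corrected_from_curves(times, n2o, n2, no=None):
    no = np.zeros_like(np.asarray(n2)) if no is None else no
    cum = pd.DataFrame(
        {"N2O": n2o, "N2": n2, "NO": no}, index=pd.Index(times, name="time_h")
    )
    return CorrectedSeries(cumulative=cum, rates=pd.DataFrame())


class TestIN2O:
    times = np.array([0.0, 10.0, 20.0])

    def test_zero_n2o_gives_0(self):
        cs = corrected_from_curves(self.times, [0, 0, 0], [0, 20, 40])
        assert i_n2o(cs, NPools(NO3=40.0), 1.0) == 0.0

    def test_only_n2o_gives_100(self):
        cs = corrected_from_curves(self.times, [0, 20, 40], [0, 0, 0])
        assert i_n2o(cs, NPools(NO3=40.0), 1.0) == pytest.approx(100.0)

    def test_piecewise_linear_toy_matches_fine_grid_oracle(self):
        # N2O-N rises 0->10 umol over [0,10] h then falls to 0 at 20 h;
        # N2-N rises linearly 0->40 umol over [0,20] h; 40 umol oxyanions
        cs = corrected_from_curves(self.times, [0, 10, 0], [0, 20, 40])
        value = i_n2o(cs, NPools(NO3=40.0), 1.0)
        tf = np.linspace(0.0, 20.0, 200001)
        n2o = np.interp(tf, self.times, [0, 10, 0])
        total = n2o + np.interp(tf, self.times, [0, 20, 40])
        oracle = 100.0 * np.trapezoid(n2o, tf) / np.trapezoid(total, tf)
        assert value == pytest.approx(oracle, abs=1e-6)

    def test_computable_at_both_recovery_fractions(self):
        cs = corrected_from_curves(self.times, [0, 10, 0], [0, 20, 40])
        v40 = i_n2o(cs, NPools(NO3=40.0), 0.40)
        v100 = i_n2o(cs, NPools(NO3=40.0), 1.00)
        assert 0.0 <= v100 <= v40 <= 100.0

    def test_recovery_never_reached_raises_with_max_attained(self):
        cs = corrected_from_curves(self.times, [0, 2, 0], [0, 4, 8])
        with pytest.raises(RecoveryNotReachedError) as err:
            i_n2o(cs, NPools(NO3=40.0), 1.0)
        assert err.value.attained == pytest.approx(8.0 / 40.0)

    def test_invariant_under_uniform_rescaling(self):
        cs = corrected_from_curves(self.times, [0, 10, 0], [0, 20, 40])
        base = i_n2o(cs, NPools(NO3=40.0), 1.0)
        for c in (0.25, 4.0, 1000.0):
            scaled = corrected_from_curves(
                self.times, np.array([0, 10, 0]) * c, np.array([0, 20, 40]) * c
            )
            assert i_n2o(scaled, NPools(NO3=40.0 * c), 1.0) == pytest.approx(base, rel=1e-9)

    def test_monotone_in_n2o_scale_with_n2_fixed(self):
        values = []
        for c in (0.5, 1.0, 2.0, 4.0):
            cs = corrected_from_curves(
                self.times, np.array([0, 10, 0]) * c, [0, 20, 40]
            )
            values.append(i_n2o(cs, NPools(NO3=60.0), 0.5))
        assert all(a < b for a, b in zip(values[:-1], values[1:]))
        assert all(0.0 <= v <= 100.0 for v in values)


class TestElectronFlows:
    def test_stoichiometry(self):
        rates = pd.DataFrame({"O2": [1.0], "N2O": [2.0], "NO3": [1.0], "NO2": [3.0], "NO": [5.0]})
        flows = electron_flows(rates)
        assert flows["O2"].iloc[0] == 4.0
        assert flows["N2O"].iloc[0] == 2.0  # 1 e- per umol N
        assert flows["NO3"].iloc[0] == 2.0
        assert flows["NO2"].iloc[0] == 3.0
        assert flows["NO"].iloc[0] == 5.0

    def test_all_zero_rates_give_zero_flows(self):
        rates = pd.DataFrame({"O2": [0.0, 0.0], "N2O": [0.0, 0.0]})
        assert (electron_flows(rates).to_numpy() == 0).all()

    def test_unknown_acceptor_rejected(self):
        with pytest.raises(ValueError, match="unknown electron acceptor"):
            electron_flows(pd.DataFrame({"CH4": [1.0]}))


class TestNMassBalance:
    def test_closed_system_residual_is_zero(self, anoxic_gas_run):
        # N2O -> N2 conversion conserves N exactly; constant dissolved pools
        spec, raw, true, corrected = anoxic_gas_run
        pools = [NPools(NO3=100.0) for _ in corrected.times]
        residual = n_mass_balance(corrected, pools)
        assert np.abs(residual.to_numpy()).max() <= 1e-6

    def test_gas_only_production_residual_equals_gas_n(self):
        t = np.arange(0.0, 10.0, 1.0)
        raw = series_from(t, {"N2": 3.0 * t, "N2O": np.zeros_like(t), "NO": np.zeros_like(t)})
        corrected = correct_series(raw, VialSpec())
        pools = [NPools(NO3=50.0) for _ in t]
        residual = n_mass_balance(corrected, pools)
        np.testing.assert_allclose(residual.to_numpy(), 3.0 * t, atol=1e-9)

    def test_pool_change_without_gas(self):
        t = np.array([0.0, 5.0, 10.0])
        raw = series_from(t, {"N2": np.zeros(3), "N2O": np.zeros(3), "NO": np.zeros(3)})
        corrected = correct_series(raw, VialSpec())
        pools = [NPools(NO3=50.0), NPools(NO3=45.0), NPools(NO3=40.0)]
        residual = n_mass_balance(corrected, pools)
        np.testing.assert_allclose(residual.to_numpy(), [0.0, -5.0, -10.0], atol=1e-12)


class TestGeneratorContracts:
    def test_nitrogen_conserved_in_closed_system(self, anoxic_gas_run):
        spec, raw, true, corrected = anoxic_gas_run
        assert true["N2"].iloc[-1] == pytest.approx(-true["N2O"].iloc[-1], rel=1e-12)

    def test_same_seed_identical_series(self):
        spec = GasSimSpec(noise_cv=0.05, seed=9)
        raw1, true1 = generate_gas_series(spec)
        raw2, true2 = generate_gas_series(spec)
        pd.testing.assert_frame_equal(raw1.amounts, raw2.amounts)
        pd.testing.assert_frame_equal(true1, true2)
        assert raw1.injections == raw2.injections

    def test_reinjection_cap_enforced(self):
        spec = GasSimSpec(
            populations=(GasPopulation(50.0, 0.0),),
            o2_dose=0.0,
            max_reinjections=1,
            duration=100.0,
            seed=0,
        )
        with pytest.raises(RuntimeError, match="reinjection"):
            generate_gas_series(spec)

    def test_survival_estimator_on_stable_populations(self):
        # stable-rate vials: the first/last-three-interval estimator is exact
        prev = GasSimSpec(populations=(GasPopulation(5.0, 0.0),), o2_dose=0.0,
                          duration=24.0, seed=1)
        nxt = GasSimSpec(populations=(GasPopulation(0.8 * 0.1 * 5.0, 0.0),), o2_dose=0.0,
                         duration=24.0, seed=2)
        raw_p, _ = generate_gas_series(prev)
        raw_n, _ = generate_gas_series(nxt)
        _, prev_end = initial_and_end_rates(correct_series(raw_p, prev.vial))
        next_init, _ = initial_and_end_rates(correct_series(raw_n, nxt.vial))
        assert survival_fraction(prev_end, next_init, f=0.1) == pytest.approx(80.0, rel=1e-6)
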