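import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phycodyn.massbalance import volumetric_rate
from phycodyn.simulate import (
    ForcingSeries,
    NicheProfile,
    ReactorModelParams,
    biweekly_schedule,
    default_niches,
    generate_forcing,
    generate_qpcr_dataset,
    sample_campaign,
    scenario_params,
    simulate_community,
    simulate_reactor,
)


class TestForcing:
    def test_noiseless_is_exact_sinusoid_with_configured_peak(self):
        f = generate_forcing(horizon=120, noise_sd=0.0, peak_day=45.0)
        expected = 19.0 + 8.0 * np.cos(2 * np.pi * (f.days - 45.0) / 365.0)
        assert np.allclose(f.temperature, expected)
        assert f.days[np.argmax(f.temperature)] == 45.0
        assert f.days[np.argmax(f.irradiance)] == 45.0

    def test_same_seed_is_bit_identical(self):
        a = generate_forcing(seed=5)
        b = generate_forcing(seed=5)
        assert np.array_equal(a.temperature, b.temperature)
        assert np.array_equal(a.irradiance, b.irradiance)

    def test_irradiance_non_negative(self):
        f = generate_forcing(seed=3, noise_sd=5.0)
        assert (f.irradiance >= 0).all()

    def test_short_horizon_rejected(self):
        with pytest.raises(ValueError):
            generate_forcing(horizon=10)


class TestReactor:
    def test_washout_equilibrium(self, small_forcing):
        # no biology: C(t) relaxes to C_in exponentially with timescale HRT
        p = ReactorModelParams(biology_on=False,
                               x0={"NH4-N": 0.0, "NO2-N": 0, "NO3-N": 0,
                                   "PO4-P": 0, "sCOD": 0, "VSS": 0})
        camp = simulate_reactor(p, small_forcing)
        t = camp.t_grid
        expected = p.nh4_in * (1 - np.exp(-t / p.hrt))
        assert np.allclose(camp.states["NH4-N"].values, expected, rtol=1e-6, atol=1e-6)

    def test_injected_production_steady_state(self, small_forcing):
        # dC/dt=(C_in-C)/HRT + p has steady state C = C_in + p*HRT
        p = ReactorModelParams(biology_on=False, injected_production={"NO3-N": 2.0})
        camp = simulate_reactor(p, small_forcing)
        c_star = p.no3_in + 2.0 * p.hrt
        c0 = camp.states["NO3-N"].iloc[0]
        expected_final = c_star + (c0 - c_star) * np.exp(-camp.t_grid[-1] / p.hrt)
        assert camp.states["NO3-N"].iloc[-1] == pytest.approx(expected_final, rel=1e-6)

    def test_nitrogen_budget_conserved(self, pbr_campaign):
        scale = pbr_campaign.states[["NH4-N", "NO2-N", "NO3-N"]].values.max()
        assert np.abs(pbr_campaign.nitrogen_balance_residual).max() < 1e-6 * scale

    def test_states_stay_non_negative(self, pbr_campaign):
        assert (pbr_campaign.states.values >= 0).all()

    def test_true_rates_consistent_with_states(self, pbr_campaign):
        # d(state)/dt == dilution + stored instantaneous rate, checked by
        # central differences away from the influent step
        c = pbr_campaign
        dt = c.t_grid[1] - c.t_grid[0]
        t_mid = c.t_grid[1:-1]
        # daily forcing is linearly interpolated; skip differences spanning a kink
        smooth = np.abs(t_mid - np.round(t_mid)) > dt * 1.5
        for analyte in ("NO3-N", "VSS"):
            x = c.states[analyte].values
            deriv = (x[2:] - x[:-2]) / (2 * dt)
            dilution = (c.influent[analyte].values - x) / c.params.hrt
            model = dilution[1:-1] + c.true_rates[analyte].values[1:-1]
            assert np.allclose(deriv[smooth], model[smooth], rtol=5e-3, atol=5e-3)

    def test_invalid_parameters(self, small_forcing):
        with pytest.raises(ValueError):
            simulate_reactor(ReactorModelParams(mu_max=-1.0), small_forcing)

    def test_scenario_contrast_nitrite_vs_nitrate(self):
        # alkaline column accumulates nitrite; buffered raceway fully nitrifies
        forcing = generate_forcing(seed=2)
        pbr = simulate_reactor(scenario_params("pbr"), forcing)
        rwp = simulate_reactor(scenario_params("rwp"), forcing)
        m = pbr.t_grid > 30  # spin-up excluded
        pbr_no2 = pbr.true_rates["NO2-N"].values[m].mean()
        pbr_no3 = pbr.true_rates["NO3-N"].values[m].mean()
        rwp_no2 = rwp.true_rates["NO2-N"].values[m].mean()
        rwp_no3 = rwp.true_rates["NO3-N"].values[m].mean()
        assert pbr_no2 > 3 * pbr_no3
        assert rwp_no3 > 3 * rwp_no2
        assert pbr.free_ammonia[m].mean() > rwp.free_ammonia[m].mean()


class TestCommunity:
    def test_single_taxon_composition_is_one(self, small_forcing):
        truth = simulate_reactor(ReactorModelParams(), small_forcing)
        niches = [
            NicheProfile(name="a", domain="bacteria", lineage="k__B", baseline=0.1),
            NicheProfile(name="e", domain="eukaryote", lineage="k__E", baseline=0.1),
        ]
        comps = simulate_community(niches, small_forcing, truth)
        assert np.allclose(comps["bacteria"]["a"], 1.0)
        assert np.allclose(comps["eukaryote"]["e"], 1.0)

    def test_warm_taxon_dominates_warm_window(self):
        forcing = generate_forcing(noise_sd=0.0, peak_day=45.0)
        truth = simulate_reactor(ReactorModelParams(), forcing)
        niches = [
            NicheProfile(name="cold", domain="eukaryote", lineage="k__E",
                         optima={"temperature": (18.0, 5.0)}),
            NicheProfile(name="warm", domain="eukaryote", lineage="k__E",
                         optima={"temperature": (30.0, 5.0)}),
        ]
        comps = simulate_community(niches, forcing, truth)
        warm = comps["eukaryote"]["warm"]
        t_peak = warm.idxmax()
        # the warm specialist peaks while temperature is above its seasonal mean
        assert forcing.at(t_peak)[1] > forcing.temperature.mean()
        # and the cold specialist dominates the cool tail of the campaign
        assert comps["eukaryote"]["cold"].iloc[-1] > warm.iloc[-1]

    def test_grazer_prey_negative_association(self, small_forcing):
        truth = simulate_reactor(ReactorModelParams(), small_forcing)
        niches = [
            NicheProfile(name="alga", domain="eukaryote", lineage="k__E",
                         baseline=0.15, grazing_loss=1.5),
            NicheProfile(name="grazer", domain="eukaryote", lineage="k__E",
                         baseline=-0.3, is_grazer=True, grazing_gain=1.5),
        ]
        comps = simulate_community(niches, small_forcing, truth)
        tau = stats.kendalltau(
            comps["eukaryote"]["alga"], comps["eukaryote"]["grazer"]
        ).statistic
        assert tau < 0

    def test_needs_two_taxa(self, small_forcing):
        truth = simulate_reactor(ReactorModelParams(), small_forcing)
        with pytest.raises(ValueError):
            simulate_community([default_niches()[0]], small_forcing, truth)


class TestSampling:
    def test_zero_noise_reproduces_truth(self, pbr_campaign):
        niches = default_niches()
        comps = simulate_community(niches, pbr_campaign.forcing, pbr_campaign)
        sampled = sample_campaign(pbr_campaign, comps, niches, noise_cv=0.0, seed=1)
        ev = sampled["events"][3]
        idx = int(np.argmin(np.abs(pbr_campaign.t_grid - ev.t)))
        assert ev.analytes_out["NH4-N"] == pytest.approx(
            pbr_campaign.states["NH4-N"].iloc[idx]
        )

    def test_counts_sum_to_depth(self, pbr_campaign):
        niches = default_niches()
        comps = simulate_community(niches, pbr_campaign.forcing, pbr_campaign)
        sampled = sample_campaign(pbr_campaign, comps, niches, read_depth=5000, seed=2)
        for table in sampled["otu_tables"].values():
            assert (table.counts.sum(axis=1) == 5000).all()

    def test_deep_sequencing_recovers_composition(self, pbr_campaign):
        niches = default_niches()
        comps = simulate_community(niches, pbr_campaign.forcing, pbr_campaign)
        sampled = sample_campaign(pbr_campaign, comps, niches, read_depth=10**6, seed=3)
        table = sampled["otu_tables"]["16S"]
        t0 = sampled["schedule"][0]
        truth_comp = comps["bacteria"].loc[
            comps["bacteria"].index[np.argmin(np.abs(comps["bacteria"].index - t0))]
        ]
        observed = table.counts.iloc[0] / table.counts.iloc[0].sum()
        tv = 0.5 * np.abs(observed.values - truth_comp.values).sum()
        assert tv < 0.01

    def test_bit_reproducible_under_seed(self, pbr_campaign):
        niches = default_niches()
        comps = simulate_community(niches, pbr_campaign.forcing, pbr_campaign)
        s1 = sample_campaign(pbr_campaign, comps, niches, seed=9)
        s2 = sample_campaign(pbr_campaign, comps, niches, seed=9)
        pd.testing.assert_frame_equal(
            s1["otu_tables"]["ITS"].counts, s2["otu_tables"]["ITS"].counts
        )
        assert s1["events"][2].analytes_out == s2["events"][2].analytes_out

    def test_invalid_depth(self, pbr_campaign):
        niches = default_niches()
        comps = simulate_community(niches, pbr_campaign.forcing, pbr_campaign)
        with pytest.raises(ValueError):
            sample_campaign(pbr_campaign, comps, niches, read_depth=0)


class TestEndToEndRateRecovery:
    def test_noiseless_biweekly_recovery(self, small_forcing):
        # constant injected rate, no biology: the interval estimator applied
        # to noiseless biweekly samples recovers the true rate
        p_true = 3.0
        params = ReactorModelParams(biology_on=False,
                                    injected_production={"NO3-N": p_true})
        truth = simulate_reactor(params, small_forcing)
        schedule = biweekly_schedule(horizon=60.0, interval=14.0, start=14.0)
        sampled = sample_campaign(truth, {}, [], schedule=schedule, noise_cv=0.0, seed=0)
        rates = volumetric_rate(sampled["events"], "NO3-N")
        est = np.mean([r.pr for r in rates])
        # compare against the true interval-average rate (transient included)
        true_avg = np.mean(
            [truth.true_interval_rates("NO3-N", np.concatenate([[0.0], schedule]))]
        )
        assert est == pytest.approx(true_avg, rel=0.02)
        assert est == pytest.approx(p_true, rel=0.02)

    def test_noisy_recovery_unbiased_over_seeds(self, small_forcing):
        p_true = 3.0
        params = ReactorModelParams(biology_on=False,
                                    injected_production={"NO3-N": p_true})
        truth = simulate_reactor(params, small_forcing)
        schedule = biweekly_schedule(horizon=60.0, interval=14.0, start=14.0)
        means = []
        for seed in range(20):
            sampled = sample_campaign(truth, {}, [], schedule=schedule,
                                      noise_cv=0.05, seed=seed)
            rates = volumetric_rate(sampled["events"], "NO3-N")
            means.append(np.mean([r.pr for r in rates]))
        grand = np.mean(means)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(grand - p_true) < 2 * se + 0.02 * p_true


def test_qpcr_dataset_recovers_truth():
    data = generate_qpcr_dataset(seed=4, ct_noise_sd=0.0)
    from phycodyn.qpcr import StandardSeries, fit_standard_curve, quantify

    std = data["standards"].query("target == '16S'")
    curve = fit_standard_curve(
        StandardSeries("16S", std["log10_copies"].values, std["ct"].values)
    )
    assert curve.slope == pytest.approx(data["slope"], rel=1e-9)
    row = data["samples"].query("target == '16S'").iloc[0]
    copies, cv = quantify(curve, row[["ct_rep1", "ct_rep2", "ct_rep3"]].values)
    assert copies == pytest.approx(data["true_copies"]["16S"][0], rel=1e-6)
    assert cv == pytest.approx(0.0, abs=1e-9)
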