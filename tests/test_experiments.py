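import numpy as np
import pytest

from carrierflux import (
    ModelParams,
    build_network,
    exchange_params,
    fit_michaelis_menten,
    km_kcat_curves,
    michaelis_menten_curve,
    solve_steady_state,
    sweep_binding_energy,
    sweep_cyto_network,
    sweep_symmetric_no_binding,
    uniport_scenarios,
)
from carrierflux.experiments import SweepResult, michaelis_menten

# coarse but adequate concentration grid for in-suite fits (2 uM steps)
CONC_GRID = np.arange(0.0, 100e-6 + 1e-12, 2e-6)


class TestMichaelisMentenFit:
    def test_exact_data_recovered(self):
        s = np.linspace(1e-6, 1e-4, 25)
        v = michaelis_menten(s, 40.0, 1e-5)
        fit = fit_michaelis_menten(s, v)
        assert fit.converged
        assert fit.k_cat == pytest.approx(40.0, rel=1e-6)
        assert fit.K_M == pytest.approx(1e-5, rel=1e-6)
        assert fit.rms < 1e-8

    def test_noisy_data_recovered_within_5_percent(self, rng):
        s = np.linspace(1e-6, 1e-4, 50)
        v = michaelis_menten(s, 40.0, 1e-5)
        v_noisy = np.clip(v * (1 + 0.01 * rng.standard_normal(len(v))), 0, None)
        fit = fit_michaelis_menten(s, v_noisy)
        assert fit.converged
        assert fit.k_cat == pytest.approx(40.0, rel=0.05)
        assert fit.K_M == pytest.approx(1e-5, rel=0.05)

    def test_all_zero_rates_flagged(self):
        fit = fit_michaelis_menten([1e-6, 1e-5, 1e-4], [0.0, 0.0, 0.0])
        assert not fit.converged
        assert "zero" in fit.message

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            fit_michaelis_menten([1e-6, 1e-5], [1.0, 2.0])

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            fit_michaelis_menten([1e-6, 1e-5, 1e-4], [1.0, -2.0, 3.0])


@pytest.fixture(scope="module")
def symmetric_sweep():
    return sweep_symmetric_no_binding(np.arange(-700.0, -295.0, 50.0))


@pytest.fixture(scope="module")
def binding_sweep():
    return sweep_binding_energy(np.arange(-700.0, -395.0, 5.0))


@pytest.fixture(scope="module")
def cyto_sweep():
    return sweep_cyto_network(np.arange(-600.0, -495.0, 10.0))


@pytest.fixture(scope="module")
def km_table():
    return km_kcat_curves(
        dE_C_grid=np.array([-700.0, -600.0, -550.0, -450.0, -300.0]),
        concentrations=CONC_GRID,
    )


@pytest.fixture(scope="module")
def scenarios():
    return uniport_scenarios(np.arange(-700.0, -195.0, 10.0))


class TestSymmetricSweep:
    def test_transport_decays_exponentially(self, symmetric_sweep):
        # log-transport vs network strength is near-linear (R^2 > 0.99)
        x, y = symmetric_sweep.grid, np.log(symmetric_sweep.transport)
        A = np.vstack([x, np.ones_like(x)]).T
        coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
        r2 = 1 - res[0] / np.sum((y - y.mean()) ** 2)
        assert r2 > 0.99
        assert coef[0] > 0  # weaker (less negative) networks transport faster

    def test_influx_equals_counter_efflux(self, symmetric_sweep):
        assert np.allclose(symmetric_sweep.transport, symmetric_sweep.extras["unlabelled_efflux_per_s"], rtol=1e-6)

    def test_forward_flux_above_net_flux(self, symmetric_sweep):
        assert np.all(symmetric_sweep.extras["J_F_per_s"] > symmetric_sweep.transport)

    def test_zero_strength_limit_matches_direct_solve(self):
        sw = sweep_symmetric_no_binding(np.array([-10.0, 0.0]))
        p = exchange_params(dE_M=0.0, dE_C=0.0, dE_S=0.0)
        direct = solve_steady_state(build_network(p)).transport_rate
        assert sw.transport[-1] == pytest.approx(direct, rel=1e-12)
        assert direct > 1e3  # orders of magnitude above any barrier-limited rate

    def test_grid_must_be_monotone(self):
        with pytest.raises(ValueError, match="monotone"):
            SweepResult("x", np.array([0.0, 2.0, 1.0]), np.zeros(3))


class TestBindingEnergySweep:
    def test_optimum_near_network_strength(self, binding_sweep):
        # transport peaks when the substrate binding energy roughly matches
        # the network strength (within ~2 kBT of -550 mV)
        assert abs(binding_sweep.argmax - (-550.0)) < 2 * 26.73

    def test_intermediate_potential_matches_networks_at_optimum(self, binding_sweep):
        # the sharper statement: at the optimum the intermediate-state
        # chemical potential equals the network strength within kBT
        assert abs(binding_sweep.metadata["mu_I_at_optimum_mV"] - (-550.0)) < 26.73
        # and lies within 2 kBT of the end conformations
        assert abs(
            binding_sweep.metadata["mu_I_at_optimum_mV"] - binding_sweep.metadata["mu_end_at_optimum_mV"]
        ) < 2 * 26.73

    def test_no_induced_fit_point_matches_symmetric_sweep(self):
        sw = sweep_binding_energy(np.array([-10.0, 0.0]), dE_MC=-550.0)
        ref = sweep_symmetric_no_binding(np.array([-560.0, -550.0]))
        assert sw.transport[-1] == pytest.approx(ref.transport[-1], rel=1e-12)

    def test_kc_renormalization_equalises_maxima(self):
        # the tabulated per-strength base rates bring the peak transport of
        # different network strengths together
        maxima = []
        for dE in (-300.0, -500.0, -700.0):
            sw = sweep_binding_energy(
                np.arange(dE - 150.0, dE + 155.0, 25.0), dE_MC=dE, kc_renormalized=True
            )
            maxima.append(sw.transport.max())
        maxima = np.array(maxima)
        assert maxima.std() / maxima.mean() < 0.05

    def test_unknown_renormalization_strength_rejected(self):
        with pytest.raises(ValueError, match="renormalization"):
            sweep_binding_energy(np.array([-500.0, -400.0]), dE_MC=-450.0, kc_renormalized=True)


class TestCytoNetworkSweep:
    def test_optimum_slightly_above_matrix_strength(self, cyto_sweep):
        # the transport-maximising cytoplasmic network sits a few mV above
        # the matrix value on the signed scale (slightly weaker network)
        offset = cyto_sweep.metadata["signed_offset_mV"]
        assert 0.0 < offset <= 10.0

    def test_unimodal_over_scan(self, cyto_sweep):
        i = int(np.argmax(cyto_sweep.transport))
        assert np.all(np.diff(cyto_sweep.transport[: i + 1]) > 0)
        assert np.all(np.diff(cyto_sweep.transport[i:]) < 0)

    def test_symmetric_point_agrees_with_binding_sweep(self):
        sw = sweep_cyto_network(np.arange(-560.0, -535.0, 10.0))
        ref = sweep_binding_energy(np.array([-560.0, -550.0]), dE_MC=-550.0)
        i = int(np.argmin(np.abs(sw.grid - (-550.0))))
        assert sw.transport[i] == pytest.approx(ref.transport[-1], rel=1e-12)


class TestKmKcatCurves:
    def test_symmetric_point_sides_agree(self, km_table):
        row = km_table.set_index("dE_C_mV").loc[-550.0]
        assert row["K_M_cyt_M"] == pytest.approx(row["K_M_mat_M"], rel=0.01)
        assert row["k_cat_cyt_per_s"] == pytest.approx(row["k_cat_mat_per_s"], rel=0.01)

    def test_weak_cytoplasmic_network_km_structure(self, km_table):
        row = km_table.set_index("dE_C_mV").loc[-300.0]
        assert 10e-6 < row["K_M_cyt_M"] < 16e-6  # low tens of uM
        assert row["K_M_mat_M"] < 1e-6  # submicromolar

    def test_strong_cytoplasmic_network_km_structure(self, km_table):
        row = km_table.set_index("dE_C_mV").loc[-700.0]
        assert row["K_M_cyt_M"] < 1e-6
        assert 30e-6 < row["K_M_mat_M"] <= 40e-6  # approaches but stays below Kd

    def test_kcat_maximal_at_symmetric_point(self, km_table):
        t = km_table.set_index("dE_C_mV")
        assert t["k_cat_cyt_per_s"].idxmax() == -550.0

    def test_partition_approximation_within_10_percent(self, km_table):
        # a K_M far below the smallest nonzero concentration cannot be
        # resolved by the fit; such points are only checked to lie below
        # that resolution limit on both routes
        resolution = 0.5 * CONC_GRID[1]
        for _, row in km_table.iterrows():
            for tag in ("cyt", "mat"):
                fit, approx = row[f"K_M_{tag}_M"], row[f"K_M_{tag}_approx_M"]
                if fit >= resolution:
                    assert approx == pytest.approx(fit, rel=0.10)
                else:
                    assert approx < resolution

    def test_all_fits_converged(self, km_table):
        assert km_table["converged_cyt"].all()
        assert km_table["converged_mat"].all()


class TestUniportScenarios:
    def test_exchange_dominates_at_equal_networks(self, scenarios):
        a = scenarios["a"]
        i = int(np.argmin(np.abs(a.grid - (-550.0))))
        assert a.transport[i] == pytest.approx(40.0, abs=4.0)

    def test_efflux_negligible_everywhere(self, scenarios):
        peak_exchange = scenarios["a"].transport.max()
        assert np.abs(scenarios["b"].transport).max() < 0.01 * peak_exchange

    def test_influx_optimum_at_minus_330(self, scenarios):
        c = scenarios["c"]
        assert c.metadata["argmax_mV"] == pytest.approx(-330.0, abs=10.0)

    def test_influx_an_order_of_magnitude_below_exchange(self, scenarios):
        assert scenarios["c"].metadata["max_to_exchange_ratio"] <= 0.1

    def test_counter_substrate_abolishes_net_influx(self, scenarios):
        c, d = scenarios["c"], scenarios["d"]
        i = int(np.argmax(c.transport))
        assert d.transport[i] < 0.01 * c.transport[i]

    def test_sweep_points_recomputable_from_metadata(self, scenarios):
        # provenance: every record carries enough to recompute the point
        c = scenarios["c"]
        meta = c.metadata["params"]
        p = ModelParams(
            Kd=meta["Kd_M"], k_f=meta["kf_perM_perS"], k_r=meta["kr_perS"],
            k_c=meta["kc_perS"], temperature=meta["temperature_C"], n_half=meta["n_half"],
        )
        from carrierflux import Substrate

        i = 5
        p = p.with_networks(dE_M=c.metadata["dE_MS_mV"], dE_C=float(c.grid[i]),
                            dE_S=c.metadata["dE_MS_mV"]).with_substrates(
            [Substrate("labelled", 5e-3, 0.0)]
        )
        recomputed = solve_steady_state(build_network(p)).transport_rate
        assert recomputed == pytest.approx(c.transport[i], rel=1e-12)


class TestMichaelisMentenCurve:
    def test_curve_is_saturating_and_fit_consistent(self, default_params):
        concs, rates, fit = michaelis_menten_curve(
            default_params, side="cytoplasmic", concentrations=CONC_GRID
        )
        assert rates[0] == 0.0
        assert np.all(np.diff(rates) > 0)
        assert fit.converged
        # the fitted curve reproduces the computed rates closely
        assert fit.rms < 0.02 * rates.max()

    def test_sides_symmetric_at_equal_networks(self, default_params):
        _, _, fit_c = michaelis_menten_curve(default_params, "cytoplasmic", CONC_GRID)
        _, _, fit_m = michaelis_menten_curve(default_params, "matrix", CONC_GRID)
        assert fit_c.k_cat == pytest.approx(fit_m.k_cat, rel=1e-6)
        assert fit_c.K_M == pytest.approx(fit_m.K_M, rel=1e-6)
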