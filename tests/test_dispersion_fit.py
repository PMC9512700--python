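"""Global fitting: self-consistency, invariances, Monte-Carlo and surfaces."""

import dataclasses

import numpy as np
import pytest

import relaxdisp as rd
from relaxdisp import synthetic_data as sd
from relaxdisp import spin_physics as sp
from relaxdisp.dispersion_fit import _Objective  # internal, used as chi2 oracle
from relaxdisp.errors import ConfigurationError

from conftest import truth_start


def make_profile(acq, probe_id, value, sigma=1.0, freq=None):
    freq = np.asarray(freq if freq is not None else acq.nu_cpmg)
    return rd.DispersionProfile(
        probe_id=probe_id, acquisition=acq, freq=freq,
        value=np.asarray(value, dtype=float),
        sigma=np.full(freq.shape, sigma),
    )


class TestSigmaFloor:
    @pytest.mark.parametrize(
        "sigma,floor,expected",
        [(0.05, 0.2, 0.2), (5.0, 2.0, 5.0), (1.9, 2.0, 2.0)],
    )
    def test_floor_application(self, c13_acq_sq, sigma, floor, expected):
        prof = make_profile(c13_acq_sq, "p", np.full(13, 25.0), sigma=sigma)
        floored = rd.apply_sigma_floor(prof, floor)
        assert np.all(floored.sigma == expected)

    def test_default_floor_by_nucleus(self, c13_acq_sq, f19_acq_cpmg):
        c = make_profile(c13_acq_sq, "p", np.full(13, 25.0), sigma=0.01)
        f = make_profile(f19_acq_cpmg, "p", np.full(13, 125.0), sigma=0.01)
        assert np.all(rd.apply_sigma_floor(c).sigma == 0.2)
        assert np.all(rd.apply_sigma_floor(f).sigma == 2.0)


@pytest.fixture(scope="module")
def noiseless_small(f19_small_fixture):
    return sd.noiseless_profiles(f19_small_fixture)


@pytest.fixture(scope="module")
def small_fit(f19_small_profiles, f19_small_fixture):
    schema = rd.FitSchema(starts=[truth_start(f19_small_fixture)])
    return rd.fit_global(f19_small_profiles, schema, seed=11), schema


class TestFitGlobal:
    def test_noiseless_self_consistency(self, noiseless_small, f19_small_fixture):
        truth = truth_start(f19_small_fixture)
        schema = rd.FitSchema(starts=[truth])
        res = rd.fit_global(noiseless_small, schema)
        assert res.chi2 < 1e-6
        assert res.params["k_ex"] == pytest.approx(913.0, abs=0.1)
        assert res.params["dw[N12C-BTFA]"] == pytest.approx(0.15, abs=1e-4)

    def test_chi2_invariant_under_reordering(self, f19_small_profiles, small_fit):
        result, schema = small_fit
        obj = _Objective(f19_small_profiles, schema)
        x = np.array([result.params[n] for n in obj.free])
        chi2_fwd = obj.chi2(x)
        rev = list(reversed(f19_small_profiles))
        obj_rev = _Objective(rev, schema)
        x_rev = np.array([result.params[n] for n in obj_rev.free])
        assert obj_rev.chi2(x_rev) == pytest.approx(chi2_fwd, rel=1e-12)

    def test_duplicated_profile_doubles_its_chi2_block(
        self, f19_small_profiles, small_fit
    ):
        result, schema = small_fit
        block = [f19_small_profiles[0]]
        obj_all = _Objective(f19_small_profiles, schema)
        x = np.array([result.params[n] for n in obj_all.free])
        obj_block = _Objective(block, schema)
        xb = np.array([result.params.get(n, result.fixed.get(n))
                       for n in obj_block.free])
        obj_dup = _Objective(f19_small_profiles + block, schema)
        xd = np.array([result.params[n] for n in obj_dup.free])
        assert obj_dup.chi2(xd) == pytest.approx(
            obj_all.chi2(x) + obj_block.chi2(xb), rel=1e-12
        )

    def test_flat_profile_flags_unidentifiable_exchange(self, c13_acq_sq):
        rng = np.random.default_rng(0)
        values = 22.0 + rng.normal(0, 0.05, 13)
        prof = make_profile(c13_acq_sq, "flat", values, sigma=0.2)
        res = rd.fit_global([prof], rd.FitSchema(
            starts=[{"p_GS": 0.8, "k_ex": 1000.0}]))
        assert res.warnings  # dw ~ 0 and/or parameters pinned at bounds

    def test_too_few_points_rejected(self, c13_acq_sq):
        prof = make_profile(c13_acq_sq, "p", [20.0, 21.0, 22.0],
                            freq=[250.0, 500.0, 1000.0])
        with pytest.raises(ConfigurationError, match=">= 4"):
            rd.fit_global([prof])


class TestTemperatureSeries:
    def test_single_temperature_reduces_to_global(
        self, f19_small_profiles, f19_small_fixture
    ):
        schema = rd.FitSchema(starts=[truth_start(f19_small_fixture)])
        a = rd.fit_global(f19_small_profiles, schema, seed=1)
        b = rd.fit_temperature_series(f19_small_profiles, schema, seed=1)
        assert set(a.params) == set(b.params)
        for k in a.params:
            assert a.params[k] == pytest.approx(b.params[k], rel=1e-9)

    def test_recovered_k_ex_monotone_in_temperature(self):
        # two-temperature end members of the multi-temperature study
        full = sd.f19_multiT()
        fx = dataclasses.replace(
            full,
            name="f19_2T",
            exchange={t: full.exchange[t] for t in (303.0, 313.0)},
            acquisitions=tuple(
                a for a in full.acquisitions
                if a.temperature_K in (303.0, 313.0) and a.field_MHz == 500.0
            ),
        )
        profiles = sd.fixture_profiles(fx, seed=21)
        start = truth_start(fx)
        res = rd.fit_temperature_series(
            profiles, rd.FitSchema(starts=[start]), seed=2
        )
        assert res.params["k_ex@303K"] < res.params["k_ex@313K"]
        assert res.params["k_ex@313K"] == pytest.approx(913.0, abs=108.0)
        assert res.params["k_ex@303K"] == pytest.approx(445.0, abs=67.0)


def _mini_c13_fixture(k_ex, seed=77, p_GS=0.819):
    base = sd.c13_313K(seed)
    return dataclasses.replace(
        base,
        name=f"c13_mini_{k_ex:g}",
        exchange={313.0: sp.TwoStateExchange(p_GS, k_ex)},
        probes=base.probes[:2],
        acquisitions=tuple(
            a for a in base.acquisitions
            if a.experiment == "SQ" and a.field_MHz in (500.0, 800.0)
        ),
    )


def _mini_f19_fixture(k_ex, seed=78, p_GS=0.5):
    base = sd.f19_313K(seed)
    return dataclasses.replace(
        base,
        name=f"f19_mini_{k_ex:g}",
        exchange={313.0: sp.TwoStateExchange(p_GS, k_ex)},
        acquisitions=tuple(
            a for a in base.acquisitions if a.field_MHz == 500.0
        ),
    )


class TestJointNuclei:
    def test_empty_side_reduces_to_global(self, f19_small_profiles, small_fit):
        _, schema = small_fit
        joint = rd.fit_joint_nuclei([], f19_small_profiles, schema, seed=3)
        solo = rd.fit_global(f19_small_profiles, schema, seed=3)
        for k in solo.params:
            assert joint.params[k] == pytest.approx(solo.params[k], rel=1e-9)

    def test_joint_fit_recovers_shared_exchange_rate(self):
        c13 = _mini_c13_fixture(864.0)
        f19 = _mini_f19_fixture(864.0)
        c_prof = sd.fixture_profiles(c13, seed=5)
        f_prof = sd.fixture_profiles(f19, seed=6)
        schema = rd.FitSchema(starts=[{
            **{k: v for k, v in {**truth_start(c13), **truth_start(f19)}.items()
               if not k.startswith("p_GS")},
            "p_GS@13C": 0.819, "p_GS@19F": 0.5,
        }])
        res = rd.fit_joint_nuclei(c_prof, f_prof, schema, share_p_GS=False, seed=4)
        assert res.params["k_ex"] == pytest.approx(864.0, abs=112.0)

    def test_conflicting_generators_inflate_joint_chi2(self):
        # same population, exchange rates differing by 4x: a joint fit with a
        # shared k_ex cannot reconcile the two timescales
        c13 = _mini_c13_fixture(500.0, p_GS=0.7)
        f19 = _mini_f19_fixture(2000.0, p_GS=0.7)
        c_prof = sd.fixture_profiles(c13, seed=8)
        f_prof = sd.fixture_profiles(f19, seed=9)
        sep_c = rd.fit_global(c_prof, rd.FitSchema(starts=[truth_start(c13)]))
        sep_f = rd.fit_global(f_prof, rd.FitSchema(starts=[truth_start(f19)]))
        sj = rd.FitSchema(starts=[{
            **{k: v for k, v in {**truth_start(c13), **truth_start(f19)}.items()
               if not k.startswith(("p_GS", "k_ex"))},
            "p_GS": 0.7, "k_ex": 1000.0,
        }])
        joint = rd.fit_joint_nuclei(c_prof, f_prof, sj, share_p_GS=True)
        assert joint.chi2 > 1.5 * (sep_c.chi2 + sep_f.chi2)
        assert joint.chi2_nu > max(sep_c.chi2_nu, sep_f.chi2_nu) + 0.5

    def test_multiple_temperatures_rejected(self, f19_small_profiles):
        other = dataclasses.replace(
            f19_small_profiles[0],
            acquisition=dataclasses.replace(
                f19_small_profiles[0].acquisition, temperature_K=303.0
            ),
        )
        with pytest.raises(ConfigurationError, match="one temperature"):
            rd.fit_joint_nuclei([other], f19_small_profiles)


class TestMonteCarlo:
    def test_zero_sigma_gives_zero_spread(self, noiseless_small, f19_small_fixture):
        profiles = [dataclasses.replace(p, sigma=np.zeros_like(p.sigma) )
                    for p in noiseless_small]
        # sigma = 0 would zero the weights; fit with unit sigma, perturb with 0
        fit_profiles = noiseless_small
        schema = rd.FitSchema(starts=[truth_start(f19_small_fixture)])
        res = rd.fit_global(fit_profiles, schema)
        mc = rd.monte_carlo_errors(res, profiles_for_mc(profiles, fit_profiles),
                                   schema, n_cycles=5, seed=0)
        assert all(v == 0.0 for v in mc.errors.values())

    def test_deterministic_given_seed(self, f19_small_profiles, small_fit):
        result, schema = small_fit
        mc1 = rd.monte_carlo_errors(result, f19_small_profiles, schema,
                                    n_cycles=10, seed=123)
        mc2 = rd.monte_carlo_errors(result, f19_small_profiles, schema,
                                    n_cycles=10, seed=123)
        assert mc1.errors == mc2.errors

    def test_spread_stable_across_seeds(self, f19_small_profiles, small_fit):
        result, schema = small_fit
        mcs = [rd.monte_carlo_errors(result, f19_small_profiles, schema,
                                     n_cycles=150, seed=s) for s in (1, 2)]
        a, b = (m.errors["k_ex"] for m in mcs)
        assert abs(a - b) / a < 0.15

    def test_spread_consistent_with_chi2_surface_interval(
        self, f19_small_profiles, small_fit
    ):
        result, schema = small_fit
        mc = rd.monte_carlo_errors(result, f19_small_profiles, schema,
                                   n_cycles=150, seed=5)
        best = result.params["k_ex"]
        grid = np.linspace(best - 120, best + 120, 13)
        surf = rd.chi2_surface(result, f19_small_profiles, "k_ex", grid, schema)
        # half-width of the chi2 = chi2_min + 1 interval
        dof = result.ndata - result.nfree
        thresh = surf.chi2_nu.min() + 1.0 / dof
        inside = grid[surf.chi2_nu <= thresh]
        half_width = 0.5 * (inside.max() - inside.min())
        assert 0.3 * half_width < mc.errors["k_ex"] < 3.0 * half_width


def profiles_for_mc(zero_sigma, fitted):
    """Zero-sigma copies aligned with the fitted profiles."""
    return [dataclasses.replace(f, sigma=np.zeros_like(f.sigma))
            for f in fitted]


class TestChiSquareSurface:
    def test_surface_minimum_matches_unconstrained_fit(
        self, f19_small_profiles, small_fit
    ):
        result, schema = small_fit
        best = result.params["k_ex"]
        grid = np.array([0.8 * best, best, 1.2 * best])
        surf = rd.chi2_surface(result, f19_small_profiles, "k_ex", grid, schema)
        assert surf.chi2_nu[1] == pytest.approx(result.chi2_nu, abs=1e-6)
        assert surf.chi2_nu.min() <= result.chi2_nu + 1e-6

    def test_noiseless_surface_decreases_toward_excluded_minimum(
        self, noiseless_small, f19_small_fixture
    ):
        schema = rd.FitSchema(starts=[truth_start(f19_small_fixture)])
        res = rd.fit_global(noiseless_small, schema)
        grid = np.linspace(1200.0, 2000.0, 4)  # truth (913) below the grid
        surf = rd.chi2_surface(res, noiseless_small, "k_ex", grid, schema)
        assert np.all(np.diff(surf.chi2_nu) > 0)

    def test_population_surface_shallower_than_rate_surface(
        self, f19_small_profiles, small_fit
    ):
        result, schema = small_fit
        p_grid = np.linspace(0.52, 0.8, 5)
        k_grid = result.params["k_ex"] * np.linspace(0.6, 1.4, 5)
        p_surf = rd.chi2_surface(result, f19_small_profiles, "p_GS", p_grid, schema)
        k_surf = rd.chi2_surface(result, f19_small_profiles, "k_ex", k_grid, schema)
        assert np.ptp(p_surf.chi2_nu) < np.ptp(k_surf.chi2_nu)

    def test_unknown_parameter_rejected(self, f19_small_profiles, small_fit):
        result, schema = small_fit
        with pytest.raises(ConfigurationError, match="not a free parameter"):
            rd.chi2_surface(result, f19_small_profiles, "nope", [1.0], schema)


class TestParameterRecovery:
    def test_median_recovery_and_mc_coverage(self):
        """Stochastic replicates of a reduced single-field study.

        The median recovered k_ex must sit within 5% of truth.  The
        Monte-Carlo +/-1 sigma intervals are deliberately conservative (the
        per-nucleus sigma floors and the replicate standard deviation both
        overstate the uncertainty of the averaged rates), so coverage may
        exceed the 68% nominal level but must never fall below it by much.
        """
        fx = _mini_f19_fixture(913.0, seed=78)
        truth = 913.0
        schema = rd.FitSchema(starts=[truth_start(fx)])
        recovered, covered = [], []
        for rep in range(20):
            profiles = sd.fixture_profiles(fx, seed=1000 + rep)
            res = rd.fit_global(profiles, schema)
            recovered.append(res.params["k_ex"])
            mc = rd.monte_carlo_errors(res, profiles, schema,
                                       n_cycles=50, seed=rep)
            covered.append(abs(res.params["k_ex"] - truth) <= mc.errors["k_ex"])
        median = float(np.median(recovered))
        assert abs(median - truth) / truth < 0.05
        assert float(np.mean(covered)) >= 0.55
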