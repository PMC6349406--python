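"""Reversal estimation, regressions, group statistics and ANOVA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from electrotonus import (
    NeuronDataset,
    UncagingSite,
    estimate_reversal,
    fit_distance_regression,
    group_stats,
    identity_line_rmse,
    normalize_within_neuron,
    one_way_anova,
    table2_fixture,
)
from electrotonus.ephys import dataset_from_frame, dataset_to_frame

VM8 = np.linspace(-100.0, -40.0, 8)


def make_site(i, distance, e_rev, g=0.1, noise=0.0, rng=None,
              vm=VM8):
    eps = rng.normal(0, noise, len(vm)) if noise else 0.0
    dv = g * (e_rev - vm) + eps
    return UncagingSite(site_id=f"s{i}", distance_um=distance,
                        vm_mV=vm, dv_mV=dv,
                        max_amplitude_mV=abs(g * (e_rev + 50.0)))


class TestEstimateReversal:
    def test_exact_on_noiseless_line(self):
        vm = np.arange(-100.0, -39.0, 10.0)
        site = UncagingSite("s", 100.0, vm, 0.1 * (vm - (-75.0)))
        est = estimate_reversal(site)
        assert est.E_rev == pytest.approx(-75.0, abs=1e-9)
        assert est.r == pytest.approx(1.0)
        assert est.qc_pass

    @given(e_rev=st.floats(-120, -20), slope=st.floats(-0.5, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_exact_for_any_slope_sign(self, e_rev, slope):
        if abs(slope) < 1e-3:
            return
        vm = VM8
        site = UncagingSite("s", 0.0, vm, slope * (e_rev - vm))
        assert estimate_reversal(site).E_rev == pytest.approx(e_rev,
                                                              abs=1e-6)

    def test_noisy_estimate_within_bootstrap_interval(self, rng):
        true_e = -70.0
        site = make_site(0, 300.0, true_e, noise=0.2, rng=rng)
        est = estimate_reversal(site)
        # brute-force pairs bootstrap of the x-intercept
        boots = []
        n = len(site.vm_mV)
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            if np.unique(site.vm_mV[idx]).size < 2:
                continue
            b = np.polyfit(site.vm_mV[idx], site.dv_mV[idx], 1)
            boots.append(-b[1] / b[0])
        lo, hi = np.percentile(boots, [2.5, 97.5])
        assert lo <= true_e <= hi
        assert lo <= est.E_rev <= hi

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            estimate_reversal(UncagingSite("s", 0.0,
                                           np.array([-50.0, -50.0]),
                                           np.array([1.0, 2.0])))
        with pytest.raises(ValueError, match="reversal undefined"):
            estimate_reversal(UncagingSite("s", 0.0, VM8,
                                           np.zeros_like(VM8)))


class TestDistanceRegression:
    def test_flat_amplitudes_slope_within_se_of_zero(self, rng):
        sites = [make_site(i, d, -70.0, rng=rng)
                 for i, d in enumerate(np.linspace(50, 900, 12))]
        for s in sites:  # flat amplitude + noise
            s.max_amplitude_mV = 2.0 + rng.normal(0, 0.1)
        ds = NeuronDataset("n1", "PD", sites)
        fit = fit_distance_regression(ds, "amplitude")
        assert fit.p > 0.05
        assert abs(fit.r) < 0.5

    def test_perfect_linear_decline(self):
        sites = []
        for i, d in enumerate(np.linspace(0, 900, 10)):
            s = make_site(i, d, -70.0)
            s.max_amplitude_mV = 3.0 - 0.002 * d
            sites.append(s)
        fit = fit_distance_regression(NeuronDataset("n", "GM", sites),
                                      "amplitude")
        assert fit.r == pytest.approx(-1.0)
        assert fit.p < 1e-10
        assert fit.slope == pytest.approx(-0.002)

    def test_constant_reversal_zero_slope_zero_mse(self):
        sites = [make_site(i, d, -70.0)
                 for i, d in enumerate([100.0, 400.0, 800.0])]
        fit = fit_distance_regression(NeuronDataset("n", "LP", sites),
                                      "reversal")
        assert fit.slope == 0.0
        assert fit.mse == 0.0

    def test_input_validation(self):
        sites = [make_site(i, 100.0, -70.0) for i in range(3)]
        with pytest.raises(ValueError, match="identical"):
            fit_distance_regression(NeuronDataset("n", "PD", sites))
        with pytest.raises(ValueError, match="three"):
            fit_distance_regression(
                NeuronDataset("n", "PD", sites[:2]))


class TestNormalization:
    def test_largest_amplitude_maps_to_minus_one(self, rng):
        sites = [make_site(i, 100.0 * (i + 1), -70.0, g=0.05 * (i + 1),
                           rng=rng) for i in range(4)]
        table = normalize_within_neuron(NeuronDataset("n", "VD", sites))
        assert table["norm_amplitude"].min() == pytest.approx(-1.0)
        assert (table["norm_amplitude"] <= 0).all()

    def test_equal_reversals_normalize_to_one(self):
        sites = [make_site(i, 100.0 + i, -70.0) for i in range(3)]
        table = normalize_within_neuron(NeuronDataset("n", "GM", sites))
        np.testing.assert_allclose(table["norm_e_rev"], 1.0, atol=1e-12)

    def test_reversal_spread_lands_in_five_percent_band(self):
        # sites spanning −59 to −70 mV around their own mean
        e_revs = np.linspace(-59.0, -70.0, 6)
        sites = [make_site(i, 100.0 + i, e) for i, e in enumerate(e_revs)]
        table = normalize_within_neuron(NeuronDataset("n", "PD", sites))
        spread = table["norm_e_rev"] - 1.0
        assert spread.abs().max() < 0.10
        assert (spread.abs() > 0.05).any()  # extremes cross the ±5% band


class TestGroupStats:
    def test_negative_mean_gives_published_style_cv(self):
        # two values with mean −64.70 mV and sample SD 3.80 mV: CV must use
        # |mean| and reproduce the printed 0.0587 → 0.06
        d = 3.80 / np.sqrt(2.0)
        g = group_stats([-64.70 - d, -64.70 + d])
        assert g.mean == pytest.approx(-64.70)
        assert g.sd == pytest.approx(3.80)
        assert g.cv == pytest.approx(0.0587, abs=5e-4)
        assert round(g.cv, 2) == 0.06

    def test_identical_values_zero_sd(self):
        g = group_stats([-70.0, -70.0, -70.0])
        assert g.sd == 0.0
        assert g.cv == 0.0

    def test_cv_scale_invariant(self, rng):
        v = rng.normal(-70, 4, 30)
        a, b = group_stats(v), group_stats(3.0 * v)
        assert a.cv == pytest.approx(b.cv, rel=1e-12)
        shifted = group_stats(v + 10.0)
        assert shifted.mean == pytest.approx(a.mean + 10.0)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            group_stats([-70.0])


@pytest.fixture(scope="module")
def table2_groups():
    t = table2_fixture()
    t = t.assign(cv4=lambda d: (d.sd_mV / d.mean_erev_mV.abs()).round(4))
    return {ct: t[t.cell_type == ct] for ct in ("PD", "LP", "VD", "GM")}


class TestAnova:
    def test_published_cv_comparison(self, table2_groups):
        res = one_way_anova({k: v["cv4"] for k, v in
                             table2_groups.items()})
        assert (res.df_between, res.df_within) == (3, 17)
        assert round(res.F, 1) == 1.2
        assert res.p == pytest.approx(0.341, abs=0.01)

    def test_published_mean_reversal_comparison(self, table2_groups):
        res = one_way_anova({k: v["mean_erev_mV"] for k, v in
                             table2_groups.items()})
        assert res.F == pytest.approx(2.29, abs=0.02)
        assert res.p == pytest.approx(0.1154, abs=0.005)

    def test_identical_group_means_give_f_near_zero(self, rng):
        base = rng.normal(0, 1, 8)
        res = one_way_anova({"a": base, "b": base + 0.0,
                             "c": np.concatenate([base, -base])[:8]})
        assert res.F < 1.0

    def test_f_invariant_under_affine_rescaling(self, rng):
        groups = {k: rng.normal(-70 + i, 3, 6)
                  for i, k in enumerate("abc")}
        r0 = one_way_anova(groups)
        r1 = one_way_anova({k: 2.5 * v + 7.0 for k, v in groups.items()})
        assert r1.F == pytest.approx(r0.F, rel=1e-9)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError, match="F undefined"):
            one_way_anova({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        with pytest.raises(ValueError):
            one_way_anova({"a": [1.0, 2.0]})


class TestIdentityLine:
    def test_perfect_identity_zero_rmse(self):
        x = np.linspace(0, 5, 9)
        assert identity_line_rmse(x, x).rmse == 0.0

    def test_hand_computed_example(self):
        fit = identity_line_rmse([1.0, 3.0, 2.0], [2.0, 3.0, 1.0])
        assert fit.rmse == pytest.approx(np.sqrt(2.0 / 3.0))
        assert fit.n == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            identity_line_rmse([], [])


class TestIdentityLineOnSimulations:
    def test_tapered_summation_closer_to_identity_than_thin(self):
        # measured (inward) vs expected (arithmetic-sum) integrals across
        # a passive grid: the tapered cable sums near-linearly, so its
        # points hug the identity line much more tightly
        from electrotonus import (CableGeometry, CableModelSpec,
                                  PassiveProperties, run_summation)
        from conftest import COARSE

        rmse = {}
        for name, geom in [("thin", CableGeometry.uniform(0.5)),
                           ("tapered", CableGeometry(d0=20.0, d1=0.5))]:
            xs, ys = [], []
            for ra in (50.0, 100.0, 300.0):
                for rm in (5e3, 1e4):
                    spec = CableModelSpec(geom,
                                          PassiveProperties(Ra=ra, Rm=rm))
                    res = run_summation(spec, solver=COARSE)
                    xs.append(res.arithmetic_sum_integral)
                    ys.append(res.inward_integral)
            rmse[name] = identity_line_rmse(xs, ys).rmse
        assert rmse["tapered"] < rmse["thin"]


class TestDatasetIO:
    def test_round_trip_through_long_frame(self, rng):
        sites = [make_site(i, 100.0 * (i + 1), -70.0 - i, noise=0.1,
                           rng=rng) for i in range(4)]
        ds = NeuronDataset("n7", "LP", sites)
        frame = dataset_to_frame(ds)
        assert set(frame.columns) == {"neuron_id", "cell_type", "site_id",
                                      "branch_id", "distance_um", "vm_mV",
                                      "dv_mV"}
        back = dataset_from_frame(frame)
        assert len(back) == 1 and len(back[0].sites) == 4
        orig = estimate_reversal(ds.sites[2])
        rtrip = estimate_reversal(back[0].sites[2])
        assert rtrip.E_rev == pytest.approx(orig.E_rev, abs=1e-9)
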