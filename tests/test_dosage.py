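import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, logit

from dosagefold import (
    CellDensityModel,
    DryMassModel,
    DryMassPriors,
    FeatureTable,
    FlowObservation,
    MassObservation,
    SimulationConfig,
    classify_dosage,
    combine_rcd_dm,
    fc_per_cell,
    model1_loglik,
    pair_presence_filter,
    predict_p4n,
    simulate_flow_observations,
    simulate_mass_observations,
)

from conftest import make_table


class StubPosterior:
    """Minimal draws holder mimicking the Results interface for combining."""

    def __init__(self, rcd=None, rf=None):
        self._rcd, self._rf = rcd or {}, rf or {}
        self.strains = sorted(set(self._rcd) | set(self._rf))

    def rcd_draws(self, s):
        return np.asarray(self._rcd[s], dtype=float)

    def rf_dry_draws(self, s):
        return np.asarray(self._rf[s], dtype=float)


class TestPredictP4n:
    def test_intercept_only_limit_is_pg2(self):
        for rcd in (0.1, 1.0, 7.3):
            assert predict_p4n(rcd, 0.07, 0.0) == pytest.approx(0.07, abs=1e-15)

    def test_unit_odds_gives_half(self):
        assert predict_p4n(1.0, 0.0, 1.0) == 0.5
        assert predict_p4n(2.0, 0.0, 0.5) == 0.5

    def test_hand_evaluated_closed_form(self):
        # odds = 0.5*2 + (1/11)/(10/11) = 1.1 -> p = 1.1/2.1
        assert predict_p4n(0.5, 1 / 11, 2.0) == pytest.approx(1.1 / 2.1)

    def test_forward_inverse_consistency(self, rng):
        for _ in range(20):
            rcd, pg2, rmass = rng.uniform(0.2, 2), rng.uniform(0.01, 0.3), rng.uniform(0, 3)
            p = predict_p4n(rcd, pg2, rmass)
            back = logit(p) - np.log(rcd * rmass + pg2 / (1 - pg2))
            assert back == pytest.approx(0.0, abs=1e-10)

    def test_zero_odds_warns_and_returns_zero(self):
        with pytest.warns(RuntimeWarning):
            assert predict_p4n(1.0, 0.0, 0.0) == 0.0

    def test_domain_violations_rejected(self):
        with pytest.raises(ValueError):
            predict_p4n(-1.0, 0.1, 1.0)
        with pytest.raises(ValueError):
            predict_p4n(1.0, 1.2, 1.0)


def obs_with_phat(p_hat, strain="S", rmass=1.0, total=999):
    """FlowObservation whose continuity-corrected proportion is ~p_hat."""
    k4 = round(p_hat * (total + 1) - 0.5)
    return FlowObservation(strain=strain, rmass=rmass, count_2C=total - k4, count_4C=k4)


class TestModel1Loglik:
    def test_zero_residual_density_is_normal_normalizer(self):
        theta = 0.3
        mu = np.log(1.0 * 1.0 + 0.1 / 0.9)
        obs = obs_with_phat(expit(mu))
        ll = model1_loglik((1.0, 0.1, theta), [obs])
        resid = logit(obs.p4n_hat) - mu  # tiny discretization residual
        expected = -0.5 * np.log(2 * np.pi * theta**2) - 0.5 * (resid / theta) ** 2
        assert ll == pytest.approx(expected)

    def test_doubling_theta_at_zero_residual_lowers_by_ln2(self):
        mu = np.log(0.5 + 0.05 / 0.95)
        obs = obs_with_phat(expit(mu), rmass=0.5)
        base = stats.norm.logpdf(logit(obs.p4n_hat), mu, 0.2)
        ll1 = model1_loglik((1.0, 0.05, 0.2), [obs])
        ll2 = model1_loglik((1.0, 0.05, 0.4), [obs])
        # the residual term is negligible by construction
        assert ll1 - ll2 == pytest.approx(np.log(2), abs=1e-4)
        assert ll1 == pytest.approx(base)

    def test_five_observation_term_by_term_oracle(self, rng):
        obs = [
            obs_with_phat(rng.uniform(0.1, 0.9), rmass=rng.uniform(0.2, 2))
            for _ in range(5)
        ]
        rcd, pg2, theta = 0.7, 0.08, 0.15
        expected = sum(
            stats.norm.logpdf(
                logit(o.p4n_hat), np.log(rcd * o.rmass + pg2 / (1 - pg2)), theta
            )
            for o in obs
        )
        assert model1_loglik((rcd, pg2, theta), obs) == pytest.approx(expected)

    def test_out_of_domain_parameters_give_minus_inf(self):
        obs = [obs_with_phat(0.5)]
        assert model1_loglik((np.nan, 0.1, 0.1), obs) == -np.inf
        assert model1_loglik((1.0, 1.5, 0.1), obs) == -np.inf
        assert model1_loglik((1.0, 0.1, -0.1), obs) == -np.inf


def grid_map_rcd(obs, strain, pg2_grid, rcd_grid, theta=0.05):
    """Dense grid-search MAP-style oracle for a single strain's rcd."""
    best, best_ll = None, -np.inf
    for rcd in rcd_grid:
        for pg2 in pg2_grid:
            ll = model1_loglik((rcd, pg2, theta), obs)
            if ll > best_ll:
                best_ll, best = ll, (rcd, pg2)
    return best


@pytest.fixture(scope="module")
def flow_and_fit():
    cfg = SimulationConfig(seed=17)
    flow = simulate_flow_observations(cfg)
    res = CellDensityModel(flow).fit(iterations=1200, warmup=600, seed=17)
    return cfg, flow, res


class TestCellDensityFit:
    def test_recovers_generative_truth(self, flow_and_fit):
        cfg, _, res = flow_and_fit
        for s in res.strains:
            assert abs(res.rcd_mean(s) - cfg.true_rcd[s]) < 0.08
            assert abs(res.pg2_draws(s).mean() - cfg.true_pG2[s]) < 0.03

    def test_diagnostics_reported_and_converged(self, flow_and_fit):
        _, _, res = flow_and_fit
        for param, d in res.diagnostics.items():
            assert np.isfinite(d["rhat"]) and d["ess"] > 50
            assert d["rhat"] < 1.05

    def test_summary_table_schema(self, flow_and_fit):
        _, _, res = flow_and_fit
        summ = res.summary()
        assert {"mean", "sd", "q5", "q95", "rhat", "ess"} <= set(summ.columns)
        assert len(summ) == 2 * len(res.strains) + 1  # + shared theta

    def test_posterior_matches_grid_search_oracle(self, flow_and_fit):
        cfg, flow, res = flow_and_fit
        strain = "0013"
        obs = [o for o in flow if o.strain == strain]
        rcd_grid = np.linspace(0.3, 0.9, 121)
        pg2_grid = np.linspace(0.01, 0.12, 56)
        rcd_map, _ = grid_map_rcd(obs, strain, pg2_grid, rcd_grid)
        assert abs(res.rcd_mean(strain) - rcd_map) < 0.05

    def test_observation_order_is_irrelevant(self):
        cfg = SimulationConfig(seed=23)
        flow = simulate_flow_observations(cfg)
        res1 = CellDensityModel(flow).fit(iterations=400, warmup=200, seed=5)
        res2 = CellDensityModel(flow[::-1]).fit(iterations=400, warmup=200, seed=5)
        for s in res1.strains:
            np.testing.assert_allclose(res1.rcd_draws(s), res2.rcd_draws(s))

    def test_missing_diploid_samples_warns(self):
        obs = [obs_with_phat(0.4, rmass=r) for r in (0.5, 1.0, 1.5)]
        with pytest.warns(UserWarning, match="pure-diploid"):
            CellDensityModel(obs)


class TestDryMassFit:
    def test_noise_free_line_concentrates_at_slope(self):
        obs = [
            MassObservation("S", "2n", m=m, dm=0.05 * m) for m in (50.0, 100.0, 200.0)
        ]
        res = DryMassModel(obs).fit(iterations=800, warmup=400, seed=1)
        assert res.f_dry_mean("S", "2n") == pytest.approx(0.05, abs=0.002)

    def test_two_point_flat_prior_mean_is_weighted_slope(self):
        obs = [
            MassObservation("S", "2n", m=10.0, dm=1.0),
            MassObservation("S", "2n", m=20.0, dm=1.0),
            MassObservation("S", "2n", m=15.0, dm=0.9),
        ]
        # closed form includes the third point; check against the formula
        expected = sum(o.dm * o.m for o in obs) / sum(o.m**2 for o in obs)
        assert DryMassModel.closed_form_fdry(obs) == pytest.approx(expected)
        # and the two-point arithmetic from first principles
        two = obs[:2]
        assert DryMassModel.closed_form_fdry(two) == pytest.approx((10 + 20) / 500)

    def test_recovery_on_simulated_data(self):
        hits = 0
        for rep in range(10):
            cfg = SimulationConfig(
                seed=100 + rep,
                true_f_dry={("S", "2n"): 0.04},
                strains=("S",),
                true_rcd={"S": 0.6},
                true_pG2={"S": 0.05},
                mass_noise_sd=0.5,
            )
            masses = list(np.linspace(30, 900, 12))
            obs = simulate_mass_observations(cfg, masses, "S", "2n")
            res = DryMassModel(obs).fit(iterations=800, warmup=400, seed=rep)
            if abs(res.f_dry_mean("S", "2n") - 0.04) < 0.005:
                hits += 1
        assert hits >= 9

    def test_rf_dry_is_ratio_of_cytotype_fractions(self):
        obs = [MassObservation("S", p, m=m, dm=f * m)
               for p, f in (("2n", 0.05), ("4n", 0.04))
               for m in (50.0, 100.0, 150.0, 200.0)]
        res = DryMassModel(obs).fit(iterations=800, warmup=400, seed=2)
        assert np.mean(res.rf_dry_draws("S")) == pytest.approx(0.8, abs=0.02)

    def test_too_few_observations_rejected(self):
        obs = [MassObservation("S", "2n", m=10.0, dm=1.0)]
        with pytest.raises(ValueError, match=">= 3"):
            DryMassModel(obs)


class TestCombineRcdDm:
    def test_degenerate_posteriors_give_constant_ratio(self):
        cell = StubPosterior(rcd={"S": np.full(600, 0.6)})
        mass = StubPosterior(rf={"S": np.full(600, 1.2)})
        out = combine_rcd_dm(cell, mass, n_draws=500, seed=0)
        assert out["S"].shape == (250_000,)
        np.testing.assert_allclose(out["S"], 0.5)

    def test_unit_rf_dry_preserves_rcd_distribution(self, rng):
        rcd = rng.uniform(0.4, 0.8, 500)
        cell = StubPosterior(rcd={"S": rcd})
        mass = StubPosterior(rf={"S": np.ones(500)})
        out = combine_rcd_dm(cell, mass, n_draws=500, seed=1)
        assert sorted(np.unique(out["S"])) == pytest.approx(sorted(rcd))

    def test_three_by_three_exhaustive_oracle(self):
        rcd = np.array([0.5, 0.6, 0.7])
        rf = np.array([0.8, 1.0, 1.25])
        cell = StubPosterior(rcd={"S": rcd})
        mass = StubPosterior(rf={"S": rf})
        out = combine_rcd_dm(cell, mass, n_draws=3, seed=2)
        expected = sorted(r / f for r, f in itertools.product(rcd, rf))
        assert sorted(out["S"]) == pytest.approx(expected)

    def test_paired_mode_returns_n_draws(self):
        cell = StubPosterior(rcd={"S": np.full(600, 0.6)})
        mass = StubPosterior(rf={"S": np.full(600, 1.2)})
        out = combine_rcd_dm(cell, mass, n_draws=500, paired=True, seed=3)
        assert out["S"].shape == (500,)

    def test_insufficient_draws_rejected(self):
        cell = StubPosterior(rcd={"S": np.ones(100)})
        mass = StubPosterior(rf={"S": np.ones(100)})
        with pytest.raises(ValueError, match="draws"):
            combine_rcd_dm(cell, mass, n_draws=500)

    def test_all_draws_positive(self, rng):
        cell = StubPosterior(rcd={"S": rng.uniform(0.3, 1.0, 500)})
        mass = StubPosterior(rf={"S": rng.uniform(0.7, 1.2, 500)})
        out = combine_rcd_dm(cell, mass, n_draws=500, seed=4)
        assert (out["S"] > 0).all()


class TestPairPresenceFilter:
    def test_single_zero_anywhere_removes_feature(self):
        values = np.ones((4, 3)) * 5
        values[2, 1] = 0.0
        table = make_table(values, ["S1"] * 4, ["2n", "2n", "4n", "4n"])
        out = pair_presence_filter(table, "S1")
        assert out.feature_ids == ["F0", "F2"]

    def test_brute_force_on_known_zero_pattern(self, rng):
        values = rng.lognormal(3, 1, size=(6, 10))
        zero_mask = rng.random((6, 10)) < 0.2
        values[zero_mask] = 0.0
        table = make_table(
            values, ["S1"] * 6, ["2n"] * 3 + ["4n"] * 3, [1, 2, 3] * 2
        )
        out = pair_presence_filter(table, "S1")
        expected = [f"F{j}" for j in range(10) if (values[:, j] > 0).all()]
        assert out.feature_ids == expected

    def test_other_strains_do_not_matter(self):
        values = np.ones((4, 2)) * 3
        values[3, 0] = 0.0  # zero only in strain B
        table = make_table(values, ["A", "A", "B", "B"], ["2n", "4n", "2n", "4n"])
        out = pair_presence_filter(table, "A")
        assert out.feature_ids == ["F0", "F1"]


class TestFoldChangePerCell:
    def test_median_identity_holds_to_machine_precision(self, rng):
        lfc = pd.Series(rng.normal(0, 1, 101))
        draws = rng.uniform(0.5, 0.9, 400)
        fc = fc_per_cell({"S": lfc}, {"S": draws})
        med_dm = fc.summary.loc["S", "median_FCdm"]
        med_cell = fc.summary.loc["S", "median_FCcell"]
        assert med_cell == med_dm / draws.mean()

    def test_unit_mean_rcd_dm_is_identity_scaling(self, rng):
        lfc = pd.Series(rng.normal(0, 1, 50))
        fc = fc_per_cell({"S": lfc}, {"S": np.ones(100)})
        sub = fc.table[fc.table.strain == "S"]
        np.testing.assert_allclose(sub["FCcell"], sub["FCdm"])

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fc_per_cell({"S": pd.Series(dtype=float)}, {"S": np.ones(10)})


class TestClassifyDosage:
    def test_boundary_labels(self):
        labels, _ = classify_dosage(np.array([1.0, 2.0]))
        assert labels[0] == "full_compensation"
        assert labels[1] == "one_to_one_dosage"

    def test_one_value_per_region(self):
        labels, summary = classify_dosage(np.array([0.5, 1.5, 3.0]))
        assert list(labels) == [
            "overcompensation",
            "partial_compensation",
            "positive_dosage_effect",
        ]
        assert summary == {
            "overcompensation": pytest.approx(1 / 3),
            "partial_to_full_compensation": pytest.approx(1 / 3),
            "positive_dosage_effect": pytest.approx(1 / 3),
        }

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            classify_dosage(np.array([-0.1]))
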