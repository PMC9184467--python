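import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from emergehurdle.hurdle import PosteriorSamples, SamplerConfig, fit
from emergehurdle.summaries import (
    disaggregate_by_sex,
    exceedance_probability,
    group_difference,
    marginal_stay_probability,
    personality_scores,
    predict_curves,
    summary_table,
)
from emergehurdle.synthetic import GroupHyper, StudyDesign, simulate_dataset
from emergehurdle.trial_data import Dataset, Group, Sex, TrialRecord


def _two_group_ps(vf_draws, inf_draws, parameter="mu_a", n_ind=2, effects=None):
    """Posterior container with one comparable hyperparameter per group."""
    vf = np.atleast_2d(vf_draws)
    inf = np.atleast_2d(inf_draws)
    if vf.shape[0] == 1:  # single pseudo-chain -> split into two
        vf = vf.reshape(2, -1)
        inf = inf.reshape(2, -1)
    shape = vf.shape
    hyper = {f"{parameter}[virus_free]": vf, f"{parameter}[infected]": inf}
    # fill the remaining hyper names so prediction code can run when needed
    for name in ("mu_a", "mu_b", "mu_c", "mu_d"):
        for g in ("virus_free", "infected"):
            hyper.setdefault(f"{name}[{g}]", np.zeros(shape))
    eff = effects or {f: np.zeros(shape + (n_ind,)) for f in "abcd"}
    ids = [f"i{k}" for k in range(n_ind)]
    return PosteriorSamples(
        hyper,
        eff,
        ids,
        ["virus_free"] * (n_ind // 2) + ["infected"] * (n_ind - n_ind // 2),
        meta={"groups": ["virus_free", "infected"], "centring_constant": 4.5},
    )


class TestGroupDifference:
    def test_identical_groups_null(self):
        draws = np.random.default_rng(0).standard_normal(1000)
        ps = _two_group_ps(draws, draws.copy())
        comp = group_difference(ps, "mu_a")
        assert np.all(comp.difference_draws == 0)
        assert comp.difference_mean == 0.0
        assert comp.exceedance == 0.5  # all exact ties count one half

    def test_constant_shift(self):
        rng = np.random.default_rng(1)
        vf = rng.standard_normal(2000)
        ps = _two_group_ps(vf, vf + 10.0)
        comp = group_difference(ps, "mu_a")
        assert comp.difference_mean == pytest.approx(-10.0, abs=1e-12)
        assert comp.exceedance == 1.0

    def test_difference_mean_equals_mean_difference(self):
        rng = np.random.default_rng(2)
        vf, inf = rng.standard_normal(500), rng.standard_normal(500) + 0.3
        ps = _two_group_ps(vf, inf)
        comp = group_difference(ps, "mu_a")
        assert comp.difference_mean == pytest.approx(
            vf.mean() - inf.mean(), rel=1e-12
        )

    def test_unknown_parameter_rejected(self):
        ps = _two_group_ps(np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError, match="not available"):
            group_difference(ps, "sigma_q")


class TestExceedance:
    def test_identical_groups(self):
        draws = np.arange(100.0)
        ps = _two_group_ps(draws, draws.copy())
        assert exceedance_probability(ps, "mu_a") == 0.5

    def test_gaussian_shift_matches_phi(self):
        rng = np.random.default_rng(7)
        n = 10_000
        vf = rng.standard_normal(n)
        inf = vf + rng.normal(3.0, 1.0, size=n)
        ps = _two_group_ps(vf, inf)
        p = exceedance_probability(ps, "mu_a")
        expected = norm.cdf(3.0)  # P(N(3,1) > 0)
        mc_err = 3 * np.sqrt(expected * (1 - expected) / n)
        assert abs(p - expected) < mc_err + 1e-3

    def test_exceedance_plus_reverse_is_one(self):
        rng = np.random.default_rng(8)
        vf = rng.standard_normal(1000)
        inf = np.round(rng.standard_normal(1000), 1)  # force some ties
        vf[:50] = inf[:50]
        ps = _two_group_ps(vf, inf)
        ps_swapped = _two_group_ps(inf, vf)
        assert exceedance_probability(ps, "mu_a") + exceedance_probability(
            ps_swapped, "mu_a"
        ) == pytest.approx(1.0, abs=1e-12)


class TestPersonalityScores:
    def test_zero_variance_draws_give_exact_scores(self):
        shape = (2, 50)
        effects = {
            f: np.full(shape + (2,), v)
            for f, v in zip("abcd", [1.5, -0.2, 140.0, 3.0])
        }
        ps = _two_group_ps(np.zeros(100), np.zeros(100), n_ind=2, effects=effects)
        ds = Dataset(
            [
                TrialRecord("i0", Group.VIRUS_FREE, Sex.MALE, 1, False, None),
                TrialRecord("i1", Group.INFECTED, Sex.FEMALE, 1, True, 100.0),
            ]
        )
        table = personality_scores(ps, ds)
        assert len(table) == 2
        row = table.set_index("individual_id").loc["i0"]
        assert (row.a, row.b, row.c, row.d) == pytest.approx((1.5, -0.2, 140.0, 3.0), rel=1e-12)
        assert row.group == "virus_free" and row.sex == "male"

    def test_missing_individual_rejected(self):
        ps = _two_group_ps(np.zeros(100), np.zeros(100))
        ds = Dataset([TrialRecord("stranger", Group.INFECTED, None, 1, False, None)])
        with pytest.raises(ValueError, match="stranger"):
            personality_scores(ps, ds)

    def test_score_spread_tracks_sigma_a(self):
        # large vs tiny sigma_a in the truth -> large vs small spread of
        # posterior-mean a-scores
        spreads = {}
        for label, sigma_a in (("wide", 3.0), ("narrow", 0.05)):
            hypers = {
                Group.VIRUS_FREE: GroupHyper(
                    mu_a=0.0, sigma_a=sigma_a, mu_b=0.0, sigma_b=0.1,
                    mu_c=200.0, sigma_c=40.0, mu_d=0.0, sigma_d=3.0,
                )
            }
            design = StudyDesign(
                n_per_group_sex={(Group.VIRUS_FREE, Sex.MALE): 15},
                trials_per_individual=8,
                residual_sd=40.0,
            )
            ds, _ = simulate_dataset(hypers, design, seed=31)
            cfg = SamplerConfig(chains=2, warmup=300, iterations=400, seed=1, force=True)
            ps = fit(ds, cfg)
            scores = personality_scores(ps, ds)
            spreads[label] = scores["a"].std()
        assert spreads["wide"] > 4 * spreads["narrow"]
        assert spreads["narrow"] < 0.5

    def test_shrinkage_towards_group_mean(self):
        # every posterior-mean latency intercept lies between the individual
        # no-pooling OLS estimate and the group-level mean (small tolerance
        # for Monte-Carlo noise)
        hypers = {
            Group.VIRUS_FREE: GroupHyper(
                mu_a=0.0, sigma_a=0.5, mu_b=0.0, sigma_b=0.1,
                mu_c=200.0, sigma_c=60.0, mu_d=-5.0, sigma_d=4.0,
            )
        }
        design = StudyDesign(
            n_per_group_sex={(Group.VIRUS_FREE, Sex.MALE): 12},
            trials_per_individual=6,
            residual_sd=40.0,
            force_all_emerge=True,
        )
        ds, _ = simulate_dataset(hypers, design, seed=23)
        cfg = SamplerConfig(chains=2, warmup=400, iterations=600, seed=6, force=True)
        ps = fit(ds, cfg)
        scores = personality_scores(ps, ds).set_index("individual_id")
        mu_c_hat = ps.stacked("mu_c[virus_free]").mean()
        centring = ps.centring_constant
        ok = 0
        for iid, info in ds.individuals.items():
            recs = [r for r in ds.records if r.individual_id == iid]
            x = np.array([r.trial_index - centring for r in recs])
            y = np.array([r.latency_s for r in recs])
            no_pool = float(np.polyfit(x, y, 1)[1])  # OLS intercept
            score = scores.loc[iid, "c"]
            lo, hi = sorted([no_pool, mu_c_hat])
            if lo - 3.0 <= score <= hi + 3.0:
                ok += 1
        assert ok >= 0.9 * len(ds.individuals)


class TestDisaggregateBySex:
    def test_single_individual_stratum(self):
        table = pd.DataFrame(
            [
                {
                    "individual_id": "i0", "group": "virus_free", "sex": "male",
                    "a": 1.0, "b": 0.1, "c": 150.0, "d": -3.0,
                }
            ]
        )
        out = disaggregate_by_sex(table)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["n"] == 1
        assert row["c_mean"] == 150.0
        assert row["n_positive_d"] == 0

    def test_missing_sex_names_individuals(self):
        table = pd.DataFrame(
            [
                {
                    "individual_id": "x7", "group": "infected", "sex": None,
                    "a": 0.0, "b": 0.0, "c": 0.0, "d": 0.0,
                }
            ]
        )
        with pytest.raises(ValueError, match="x7"):
            disaggregate_by_sex(table)

    def test_sex_structured_slope_recovery(self):
        # infected males simulated with positive latency slope, everyone
        # else negative; the recovered stratum means must be ordered so
        hypers = {
            Group.VIRUS_FREE: GroupHyper(
                mu_a=-1.0, sigma_a=0.5, mu_b=0.0, sigma_b=0.1,
                mu_c=180.0, sigma_c=40.0, mu_d=-10.0, sigma_d=2.0,
            ),
            Group.INFECTED: GroupHyper(
                mu_a=-1.0, sigma_a=0.5, mu_b=0.0, sigma_b=0.1,
                mu_c=260.0, sigma_c=40.0, mu_d=0.0, sigma_d=2.0,
            ),
        }
        # build effects manually so the +5 / -10 split is by sex
        from emergehurdle.synthetic import sample_individual_effects, simulate_trials
        import dataclasses

        rng_seed = 41
        effects = {}
        for group in hypers:
            pairs = []
            for sex, n in ((Sex.MALE, 8), (Sex.FEMALE, 8)):
                for eff in sample_individual_effects(hypers[group], n, seed=rng_seed):
                    d_true = 5.0 if (group is Group.INFECTED and sex is Sex.MALE) else -10.0
                    pairs.append((sex, dataclasses.replace(eff, d=d_true + eff.d)))
                rng_seed += 1
            effects[group] = pairs
        design = StudyDesign(
            n_per_group_sex={},
            trials_per_individual=8,
            residual_sd=30.0,
        )
        ds = simulate_trials(effects, design, seed=3)
        cfg = SamplerConfig(chains=2, warmup=300, iterations=500, seed=5, force=True)
        ps = fit(ds, cfg)
        out = disaggregate_by_sex(personality_scores(ps, ds)).set_index(["group", "sex"])
        d_inf_male = out.loc[("infected", "male"), "d_mean"]
        others = [
            out.loc[("infected", "female"), "d_mean"],
            out.loc[("virus_free", "male"), "d_mean"],
            out.loc[("virus_free", "female"), "d_mean"],
        ]
        assert d_inf_male > 0
        assert all(d_inf_male > v for v in others)
        assert all(v < 0 for v in others)


class TestPredictCurves:
    def test_flat_when_slopes_zero(self):
        shape = (2, 100)
        rng = np.random.default_rng(0)
        hyper = {}
        for g in ("virus_free", "infected"):
            hyper[f"mu_a[{g}]"] = rng.normal(-1.0, 0.1, shape)
            hyper[f"mu_b[{g}]"] = np.zeros(shape)
            hyper[f"mu_c[{g}]"] = rng.normal(200.0, 5.0, shape)
            hyper[f"mu_d[{g}]"] = np.zeros(shape)
        eff = {f: np.zeros(shape + (1,)) for f in "abcd"}
        ps = PosteriorSamples(
            hyper, eff, ["i0"], ["virus_free"],
            meta={"groups": ["virus_free", "infected"], "centring_constant": 4.5},
        )
        cv = predict_curves(ps, "virus_free")
        assert np.allclose(cv.emergence_mean, cv.emergence_mean[0])
        assert np.allclose(cv.latency_mean, cv.latency_mean[0])

    def test_single_draw_degenerate_interval(self):
        shape = (2, 1)
        hyper = {}
        for g in ("virus_free", "infected"):
            hyper[f"mu_a[{g}]"] = np.full(shape, -1.0)
            hyper[f"mu_b[{g}]"] = np.full(shape, 0.2)
            hyper[f"mu_c[{g}]"] = np.full(shape, 200.0)
            hyper[f"mu_d[{g}]"] = np.full(shape, -5.0)
        eff = {f: np.zeros(shape + (1,)) for f in "abcd"}
        ps = PosteriorSamples(
            hyper, eff, ["i0"], ["virus_free"],
            meta={"groups": ["virus_free", "infected"], "centring_constant": 4.5},
        )
        cv = predict_curves(ps, "infected", trial_grid=[1, 5, 9])
        np.testing.assert_allclose(cv.emergence_lo, cv.emergence_mean)
        np.testing.assert_allclose(cv.emergence_hi, cv.emergence_mean)
        np.testing.assert_allclose(cv.latency_lo, cv.latency_mean)

    def test_interval_orders_and_probability_bounds(self, small_posterior):
        for group in small_posterior.groups:
            cv = predict_curves(small_posterior, group)
            assert np.all(cv.emergence_lo <= cv.emergence_mean + 1e-12)
            assert np.all(cv.emergence_mean <= cv.emergence_hi + 1e-12)
            assert np.all((cv.emergence_lo >= 0) & (cv.emergence_hi <= 1))
            assert np.all(cv.latency_lo <= cv.latency_hi)

    def test_unknown_group_rejected(self, small_posterior):
        with pytest.raises(ValueError, match="absent"):
            predict_curves(small_posterior, "martian")


class TestMarginalStayProbability:
    def test_symmetry_at_zero_mean(self):
        for sigma in (0.0, 0.5, 2.0, 10.0):
            assert marginal_stay_probability(0.0, sigma) == pytest.approx(0.5, abs=1e-9)

    def test_degenerate_sigma(self):
        expected = 1 / (1 + np.exp(-0.845))
        assert marginal_stay_probability(0.845, 0.0) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_mu(self):
        values = [marginal_stay_probability(mu, 1.5) for mu in np.linspace(-4, 4, 17)]
        assert np.all(np.diff(values) > 0)

    def test_wide_sigma_limit(self):
        assert marginal_stay_probability(0.0, 200.0) == pytest.approx(0.5, abs=1e-6)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            marginal_stay_probability(0.0, -1.0)

    def test_quadrature_matches_monte_carlo(self):
        rng = np.random.default_rng(11)
        z = rng.normal(0.845, 0.661, 500_000)
        mc = float((1 / (1 + np.exp(-z))).mean())
        quad = marginal_stay_probability(0.845, 0.661)
        assert abs(quad - mc) < 3 * 0.25 / np.sqrt(500_000) + 1e-4


class TestSummaryTable:
    def test_structure_and_consistency(self, small_posterior):
        table = summary_table(small_posterior)
        assert len(table) == 8  # 4 families x (mean, st.dev)
        assert set(table["summary"]) == {"mean", "st.dev"}
        assert ((table["prob_infected_gt_virus_free"] >= 0)
                & (table["prob_infected_gt_virus_free"] <= 1)).all()
        # difference column consistent with per-group means
        got = table["difference_mean"]
        want = table["virus_free_mean"] - table["infected_mean"]
        np.testing.assert_allclose(got, want, rtol=1e-10)
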