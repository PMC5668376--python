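"""Least-squares estimation: single-site priors, global fits, staged protocol."""

import numpy as np
import pytest

from palmstate.fitting import (
    IdentifiabilityError,
    Observation,
    PalmitoylationEstimator,
    fit_global,
    fit_single_site,
    predict_panel,
    r_squared,
    staged_protocol,
)
from palmstate.model import (
    ConstructSpec,
    ModelParams,
    SitePanel,
    cooperative_distribution,
    independent_distribution,
)
from palmstate.synthetic import generate_panel


def single_construct(site):
    return ConstructSpec(f"single_{site}", (site,))


class TestObservation:
    def test_fractions_within_slack_are_renormalized(self, caplog):
        obs = Observation("x", "r1", (0.5, 0.51))
        assert sum(obs.fractions) == pytest.approx(1.0)

    def test_fractions_outside_slack_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            Observation("x", "r1", (0.5, 0.6))

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            Observation("x", "r1", (-0.1, 1.1))


class TestSingleSite:
    def test_probability_is_palmitoylated_fraction(self):
        obs = [Observation("single_A", "r1", (0.14, 0.86))]
        params = fit_single_site(obs, [single_construct("A")])
        assert params.probability("A") == pytest.approx(0.86)
        assert params.c == 1.0

    def test_unpalmitoylated_site(self):
        obs = [Observation("single_A", "r1", (1.0, 0.0))]
        params = fit_single_site(obs, [single_construct("A")])
        assert params.probability("A") == 0.0

    def test_replicates_are_averaged(self):
        obs = [
            Observation("single_A", "r1", (0.3, 0.7)),
            Observation("single_A", "r2", (0.1, 0.9)),
        ]
        params = fit_single_site(obs, [single_construct("A")])
        assert params.probability("A") == pytest.approx(0.8)

    def test_multi_site_construct_rejected(self):
        obs = [Observation("wt", "r1", (0.1, 0.4, 0.5))]
        construct = ConstructSpec("wt", ("A", "B"))
        with pytest.raises(ValueError, match="exactly one"):
            fit_single_site(obs, [construct])


class TestRSquared:
    def test_perfect_prediction(self):
        assert r_squared([0.1, 0.9], [0.1, 0.9]) == pytest.approx(1.0)

    def test_mean_prediction_scores_zero(self):
        obs = [0.2, 0.8, 0.5]
        assert r_squared(obs, [0.5, 0.5, 0.5]) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # 1 - 0.02/0.18
        assert r_squared([0.2, 0.8], [0.3, 0.7]) == pytest.approx(0.8889, abs=1e-4)

    def test_zero_variance_is_undefined(self):
        with pytest.raises(ValueError, match="variance"):
            r_squared([0.5, 0.5], [0.4, 0.6])

    def test_pearson_variant(self):
        obs = [0.1, 0.4, 0.9]
        pred = [0.2, 0.5, 1.0]  # perfectly correlated but offset
        assert r_squared(obs, pred, method="pearson") == pytest.approx(1.0)
        assert r_squared(obs, pred, method="determination") < 1.0


class TestPredictPanel:
    def test_cd20_independent_prediction(self, cd20):
        params = ModelParams(
            panel=SitePanel(("C111", "C220")), p=(0.74, 0.82), c=1.0
        )
        preds = predict_panel(params, cd20.constructs, model="independent")
        assert preds["WT"].as_array() == pytest.approx([0.0468, 0.3464, 0.6068])

    def test_empty_panel_gives_empty_output(self):
        params = ModelParams(panel=SitePanel(("A",)), p=(0.5,))
        assert predict_panel(params, []) == {}

    def test_unset_site_rejected(self):
        params = ModelParams(panel=SitePanel(("A",)), p=(0.5,))
        with pytest.raises(KeyError, match="B"):
            predict_panel(params, [ConstructSpec("x", ("B",))])

    def test_cooperative_c1_equals_independent(self, cld3):
        params = ModelParams(panel=cld3.params.panel, p=cld3.params.p, c=1.0)
        indep = predict_panel(params, cld3.constructs, model="independent")
        coop = predict_panel(params, cld3.constructs, model="cooperative")
        for cid in indep:
            assert np.allclose(indep[cid].as_array(), coop[cid].as_array())


class TestGlobalFit:
    @pytest.mark.parametrize("c_true", [0.8, 1.0, 1.5, 2.0])
    def test_noiseless_round_trip_recovers_parameters(self, c_true):
        panel = SitePanel(("A", "B", "C"))
        truth = ModelParams(panel=panel, p=(0.2, 0.55, 0.9), c=c_true)
        constructs = [
            ConstructSpec("wt", ("A", "B", "C")),
            ConstructSpec("a", ("A",)),
            ConstructSpec("b", ("B",)),
            ConstructSpec("c", ("C",)),
            ConstructSpec("ab", ("A", "B")),
        ]
        obs = [
            Observation(
                s.construct_id,
                "r1",
                cooperative_distribution(truth, s).fractions,
            )
            for s in constructs
        ]
        result = fit_global(obs, constructs, model="cooperative", random_state=0)
        assert np.allclose(result.params.p, truth.p, atol=1e-6)
        assert result.params.c == pytest.approx(c_true, abs=1e-6)
        assert result.converged

    def test_c_one_data_fits_to_c_one(self):
        panel = SitePanel(("A", "B"))
        truth = ModelParams(panel=panel, p=(0.3, 0.7), c=1.0)
        constructs = [
            ConstructSpec("wt", ("A", "B")),
            ConstructSpec("a", ("A",)),
            ConstructSpec("b", ("B",)),
        ]
        obs = [
            Observation(s.construct_id, "r1",
                        independent_distribution(truth, s).fractions)
            for s in constructs
        ]
        result = fit_global(obs, constructs, model="cooperative", random_state=0)
        assert result.params.c == pytest.approx(1.0, abs=1e-6)

    def test_cld3_noiseless_recovers_printed_cooperativity(self, cld3):
        obs = generate_panel(cld3, noiseless=True)
        result = fit_global(obs, cld3.constructs, model="cooperative",
                            random_state=0)
        assert result.params.c == pytest.approx(1.24, abs=1e-4)
        assert np.allclose(result.params.p, cld3.params.p, atol=1e-4)

    def test_cooperativity_unidentifiable_from_single_site_panel(self):
        constructs = [single_construct("A"), single_construct("B")]
        obs = [
            Observation("single_A", "r1", (0.3, 0.7)),
            Observation("single_B", "r1", (0.2, 0.8)),
        ]
        with pytest.raises(IdentifiabilityError):
            fit_global(obs, constructs, model="cooperative")

    def test_nested_models_objective_ordering(self, cld3):
        """The independent model is the c = 1 slice of the cooperative one,
        so the cooperative optimum can never be worse."""
        obs = generate_panel(cld3, counts=500, replicates=2, seed=11)
        indep = fit_global(obs, cld3.constructs, model="independent",
                           random_state=0)
        coop = fit_global(obs, cld3.constructs, model="cooperative",
                          random_state=0)
        assert coop.objective <= indep.objective + 1e-12

    def test_site_relabeling_permutes_fitted_probabilities(self, cd20):
        obs = generate_panel(cd20, counts=800, replicates=2, seed=5)
        result = fit_global(obs, cd20.constructs, random_state=0)

        relabel = {"C111": "C220", "C220": "C111"}
        constructs2 = [
            ConstructSpec(s.construct_id, tuple(relabel[x] for x in s.sites))
            for s in cd20.constructs
        ]
        result2 = fit_global(obs, constructs2, random_state=0)
        assert result2.params.probability("C220") == pytest.approx(
            result.params.probability("C111"), abs=1e-8
        )
        assert result2.params.c == pytest.approx(result.params.c, abs=1e-8)

    def test_objective_minimal_at_generating_parameters(self, cd20):
        obs = generate_panel(cd20, noiseless=True)
        est = PalmitoylationEstimator(model="cooperative", random_state=0)
        est.fit(obs, cd20.constructs)
        assert est.result_.objective == pytest.approx(0.0, abs=1e-12)

        perturbed = ModelParams(
            panel=cd20.params.panel,
            p=(cd20.params.p[0] + 0.05, cd20.params.p[1]),
            c=cd20.params.c,
        )
        sse = 0.0
        preds = predict_panel(perturbed, cd20.constructs, model="cooperative")
        for o in obs:
            sse += float(
                np.sum((o.as_array() - preds[o.construct_id].as_array()) ** 2)
            )
        assert sse > est.result_.objective

    def test_fix_c_is_recorded(self, cd20):
        obs = generate_panel(cd20, noiseless=True)
        result = fit_global(obs, cd20.constructs, model="cooperative",
                            fix_c=1.24, random_state=0)
        assert result.fixed == {"c": 1.24}
        assert result.params.c == 1.24

    def test_estimator_follows_sklearn_conventions(self, cd20):
        est = PalmitoylationEstimator(model="cooperative", n_restarts=2)
        assert est.get_params()["n_restarts"] == 2
        est.set_params(n_restarts=0)
        obs = generate_panel(cd20, noiseless=True)
        est.fit(obs, cd20.constructs)
        assert hasattr(est, "params_") and hasattr(est, "r_squared_")
        preds = est.predict(cd20.constructs)
        assert set(preds) == {"WT", "single_C111", "single_C220"}
        assert est.score(obs, cd20.constructs) == pytest.approx(1.0, abs=1e-9)


class TestRecoveryUnderNoise:
    def test_multinomial_sampling_recovery(self, cld3):
        """With 1000 molecules per replicate and triplicates, the global
        cooperative fit should land within ±0.05 of each site probability
        and ±0.15 of the cooperativity in at least 90% of simulations."""
        truth_p = np.array(cld3.params.p)
        hits = 0
        n_sim = 100
        for seed in range(n_sim):
            obs = generate_panel(cld3, counts=1000, replicates=3, seed=seed)
            result = fit_global(
                obs, cld3.constructs, model="cooperative",
                n_restarts=0, random_state=seed,
            )
            ok_p = np.abs(np.array(result.params.p) - truth_p).max() <= 0.05
            ok_c = abs(result.params.c - cld3.params.c) <= 0.15
            hits += ok_p and ok_c
        assert hits >= 90


class TestStagedProtocol:
    def test_noiseless_panel_reaches_perfect_final_fit(self, cld3):
        obs = generate_panel(cld3, noiseless=True)
        report = staged_protocol(obs, cld3.constructs, random_state=0)
        assert [s["stage"] for s in report.stages] == [1, 2, 3, 4]
        assert report.stages[3]["r_squared"] == pytest.approx(1.0, abs=1e-9)
        assert report.final.params.c == pytest.approx(1.24, abs=1e-4)
        assert np.allclose(report.final.params.p, cld3.params.p, atol=1e-4)

    def test_single_site_priors_match_direct_fractions(self, cd20):
        obs = generate_panel(cd20, noiseless=True)
        report = staged_protocol(obs, cd20.constructs, random_state=0)
        direct = fit_single_site(
            [o for o in obs if o.construct_id.startswith("single")],
            [s for s in cd20.constructs if s.n_max == 1],
        )
        for site in ("C111", "C220"):
            assert report.priors.probability(site) == pytest.approx(
                direct.probability(site), abs=1e-9
            )

    def test_noisy_panel_cooperative_stage_improves_on_independent(self, cld3):
        obs = generate_panel(cld3, counts=1000, replicates=3, seed=7)
        report = staged_protocol(obs, cld3.constructs, random_state=0)
        assert report.stages[1]["r_squared"] < report.stages[3]["r_squared"]

    def test_borrowed_cooperativity_is_tagged(self, cd20):
        obs = generate_panel(cd20, noiseless=True)
        report = staged_protocol(obs, cd20.constructs, borrow_c=1.24,
                                 random_state=0)
        assert report.stages[2]["note"] == "borrowed c"
        assert report.stages[2]["params"]["c"] == 1.24
        # the final all-parameter fit still recovers the generating c
        assert report.final.params.c == pytest.approx(1.51, abs=1e-4)

    def test_report_serializes(self, cd20, tmp_path):
        obs = generate_panel(cd20, noiseless=True)
        report = staged_protocol(obs, cd20.constructs, random_state=0)
        path = tmp_path / "report.json"
        report.to_json(path)
        import json

        data = json.loads(path.read_text())
        assert {"priors", "stages", "final"} <= set(data)
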