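"""Multiple-group EM: recovery, constraints, pruning, omega, EAP scoring."""

import numpy as np
import pandas as pd
import pytest

from demprev import synthetic_data as sd
from demprev.config import IRTSettings, recovery_config
from demprev.irt_core import COGNITION, FUNCTION, ItemParameters, LatentSpec, loading_from_slope
from demprev.irt_fit import (
    FittedModel,
    eap_scores,
    fit_multigroup_em,
    make_grid,
    omega_reliability,
    prior_weights,
    prune_low_loadings,
)
from demprev.item_prep import build_matrices


def _true_slopes(bank):
    return {it.item_id: it.slope for it in bank if it.kind != "continuous"}


class TestRecovery:
    def test_slopes_and_loadings_recovered(self, recovery_fit):
        model = recovery_fit["model"]
        true = _true_slopes(recovery_fit["bank"])
        common = [i for i in model.items if i in true]
        est = np.array([model.items[i].slope for i in common])
        tru = np.array([true[i] for i in common])
        assert np.corrcoef(tru, est)[0, 1] >= 0.95
        lam_err = np.mean(
            [abs(loading_from_slope(true[i]) - loading_from_slope(model.items[i].slope))
             for i in common]
        )
        assert lam_err <= 0.05

    def test_factor_correlation_recovered(self, recovery_fit):
        rho_hat = recovery_fit["model"].latent["B"].correlation
        assert abs(rho_hat - recovery_fit["cfg"].scenario.rho) <= 0.10

    def test_anchor_items_have_single_parameter_set(self, recovery_fit):
        # one ItemParameters object serves both groups by construction;
        # anchor rows appear once in the parameter table
        model = recovery_fit["model"]
        table = model.parameter_table()
        anchors = table.loc[table["anchor"], "item_id"]
        assert anchors.is_unique and len(anchors) > 0

    def test_em_loglik_monotone(self, recovery_fit):
        trace = np.asarray(recovery_fit["model"].loglik_trace)
        tol = 1e-8 * max(1.0, np.abs(trace).max())
        assert np.all(np.diff(trace) >= -tol)

    def test_reference_scores_on_unit_scale(self, recovery_fit):
        # posterior decomposition reconstructs the reference group's
        # standard-normal prior: mean ~ 0, Var(EAP) + E[PSD^2] ~ 1
        scores = eap_scores(
            recovery_fit["pruned"], recovery_fit["matrices"], "B"
        )
        for dim in ("cog", "fun"):
            eap = scores[f"eap_{dim}"]
            psd = scores[f"psd_{dim}"]
            assert abs(eap.mean()) < 0.05
            assert abs(eap.var() + (psd**2).mean() - 1.0) < 0.05

    def test_scores_track_true_abilities(self, recovery_fit):
        scores = eap_scores(recovery_fit["pruned"], recovery_fit["matrices"], "B")
        truth = recovery_fit["sample_b"].set_index("person_id").loc[scores["person_id"]]
        assert np.corrcoef(scores["eap_cog"], truth["theta_cog"])[0, 1] >= 0.85
        assert np.corrcoef(scores["eap_fun"], truth["theta_fun"])[0, 1] >= 0.85

    def test_function_factor_more_reliable(self, recovery_fit):
        model = recovery_fit["pruned"]
        assert omega_reliability(model, FUNCTION) > omega_reliability(model, COGNITION)


class TestPruning:
    def test_low_loading_item_pruned_others_retained(self, recovery_fit):
        pruned = recovery_fit["pruned"]
        low_ids = {
            it.item_id
            for it in recovery_fit["bank"]
            if it.kind != "continuous"
            and it.slope == recovery_fit["cfg"].scenario.low_loading_slope
        }
        removed = {iid for iid, _ in pruned.pruned}
        assert low_ids <= removed
        strong = {
            it.item_id
            for it in recovery_fit["bank"]
            if it.kind != "continuous" and loading_from_slope(it.slope) > 0.4
        }
        assert strong <= set(pruned.items)

    def test_all_retained_loadings_clear_threshold(self, recovery_fit):
        assert all(l >= 0.3 for l in recovery_fit["pruned"].loadings().values())

    def test_zero_threshold_is_identity(self, recovery_fit):
        model = recovery_fit["model"]
        out = prune_low_loadings(
            model, recovery_fit["matrices"], recovery_fit["meta"], threshold=0.0
        )
        assert set(out.items) == set(model.items)
        assert out.pruned == []

    def test_pruning_cannot_empty_a_factor(self, recovery_fit):
        with pytest.raises(ValueError, match="fewer than 2"):
            prune_low_loadings(
                recovery_fit["model"],
                recovery_fit["matrices"],
                recovery_fit["meta"],
                threshold=0.999,
            )


class TestOmega:
    def _model_with_loadings(self, lams):
        from demprev.irt_core import slope_from_loading

        items = {
            f"i{k}": ItemParameters(f"i{k}", COGNITION, slope_from_loading(l), [0.0])
            for k, l in enumerate(lams)
        }
        return FittedModel(
            items=items,
            item_factor={i: COGNITION for i in items},
            latent={"B": LatentSpec.reference(0.0)},
            n_categories={i: 2 for i in items},
            loglik_trace=[0.0],
            converged=True,
        )

    def test_single_item(self):
        assert omega_reliability(self._model_with_loadings([0.8]), COGNITION) == pytest.approx(
            0.64, abs=1e-10
        )

    def test_three_equal_items(self):
        model = self._model_with_loadings([0.7, 0.7, 0.7])
        assert omega_reliability(model, COGNITION) == pytest.approx(4.41 / 5.94, abs=1e-10)

    def test_zero_loadings(self):
        model = self._model_with_loadings([0.0, 0.0])
        assert omega_reliability(model, COGNITION) == 0.0


class TestEAP:
    def _toy_model(self, rho=0.4):
        items = {
            "c1": ItemParameters("c1", COGNITION, 1.5, [0.0]),
            "c2": ItemParameters("c2", COGNITION, 1.0, [0.8]),
            "f1": ItemParameters("f1", FUNCTION, 1.8, [0.5]),
            "f2": ItemParameters("f2", FUNCTION, 1.2, [-0.5]),
        }
        return FittedModel(
            items=items,
            item_factor={i: p.factor for i, p in items.items()},
            latent={"B": LatentSpec.reference(rho)},
            n_categories={i: 2 for i in items},
            loglik_trace=[0.0],
            converged=True,
        )

    def test_no_responses_returns_prior_mean(self):
        model = self._toy_model()
        matrix = pd.DataFrame(
            {"c1": [np.nan], "c2": [np.nan], "f1": [np.nan], "f2": [np.nan]},
            index=pd.Index([1], name="person_id"),
        )
        scores = eap_scores(model, {"B": matrix}, "B")
        assert scores["eap_cog"].iloc[0] == pytest.approx(0.0, abs=1e-10)
        assert scores["eap_fun"].iloc[0] == pytest.approx(0.0, abs=1e-10)
        assert scores["psd_cog"].iloc[0] == pytest.approx(1.0, abs=0.01)

    def test_correlated_prior_borrows_across_domains(self):
        # with rho > 0, strong cognition responses pull the function score
        model = self._toy_model(rho=0.6)
        matrix = pd.DataFrame(
            {"c1": [1.0], "c2": [1.0], "f1": [np.nan], "f2": [np.nan]},
            index=pd.Index([1], name="person_id"),
        )
        scores = eap_scores(model, {"B": matrix}, "B")
        assert scores["eap_cog"].iloc[0] > 0.3
        assert scores["eap_fun"].iloc[0] > 0.1

    def test_unknown_group_rejected(self):
        model = self._toy_model()
        with pytest.raises(KeyError):
            eap_scores(model, {}, "B")

    def test_grid_refinement_oracle(self, recovery_fit):
        """EAPs from the 21-node default grid match a 201-node refinement."""
        model = recovery_fit["pruned"]
        matrix = recovery_fit["matrices"]["B"].iloc[:50]
        coarse = eap_scores(model, {"B": matrix}, "B")
        fine = eap_scores(model, {"B": matrix}, "B", n_nodes=201)
        for col in ("eap_cog", "eap_fun"):
            assert np.max(np.abs(coarse[col] - fine[col])) < 1e-3


class TestFitEdgeCases:
    def _tiny_data(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        theta = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], n)
        items = {
            "c1": (1.5, 0.0, COGNITION),
            "c2": (1.2, 0.5, COGNITION),
            "f1": (1.8, 0.0, FUNCTION),
            "f2": (1.4, -0.4, FUNCTION),
        }
        cols = {}
        for iid, (a, d, f) in items.items():
            p = 1 / (1 + np.exp(-(a * theta[:, f] + d)))
            cols[iid] = (rng.random(n) < p).astype(float)
        matrix = pd.DataFrame(cols, index=pd.Index(range(n), name="person_id"))
        meta = pd.DataFrame(
            {
                "item_id": list(items),
                "factor": ["cognition", "cognition", "function", "function"],
                "kind": "binary",
                "anchor": True,
            }
        )
        return matrix, meta

    def test_single_category_item_dropped_with_warning(self):
        matrix, meta = self._tiny_data()
        matrix = matrix.copy()
        matrix["c3"] = 1.0  # everyone endorses: boundary MLE
        meta = pd.concat(
            [
                meta,
                pd.DataFrame(
                    [{"item_id": "c3", "factor": "cognition", "kind": "binary", "anchor": True}]
                ),
            ],
            ignore_index=True,
        )
        half = len(matrix) // 2
        with pytest.warns(UserWarning, match="single category"):
            model = fit_multigroup_em(
                {"A": matrix.iloc[:half], "B": matrix.iloc[half:]}, meta,
                IRTSettings(max_cycles=30),
            )
        assert "c3" in model.dropped_items and "c3" not in model.items

    def test_factor_with_too_few_items_rejected(self):
        matrix, meta = self._tiny_data()
        half = len(matrix) // 2
        cols = ["c1", "c2", "f1"]
        with pytest.raises(ValueError, match="at least 2 items"):
            fit_multigroup_em(
                {"A": matrix.iloc[:half][cols], "B": matrix.iloc[half:][cols]},
                meta.loc[meta["item_id"] != "f2"],
            )

    def test_focal_mean_shift_recovered_through_anchors(self):
        """A +0.5 cognition offset in the focal group is recovered in the
        estimated focal latent mean, demonstrating anchor-based linking."""
        cfg = recovery_config(77, n_per_group=1500)
        sc = cfg.scenario
        pop = sd.generate_population(sc, cfg.seed_for("population"))
        bank = sd.default_item_bank(sc, cfg.seed_for("bank"))
        sample_a, sample_b = sd.draw_survey_samples(pop, sc, cfg.seed_for("sampling"))
        shifted = sample_a.copy()
        shifted["theta_cog"] = shifted["theta_cog"] + 0.5
        resp_a = sd.simulate_responses(shifted, bank, "A", 1)
        resp_b = sd.simulate_responses(sample_b, bank, "B", 2)
        meta = sd.item_metadata(bank)
        prep = build_matrices(resp_a, resp_b, meta, overlap_ids=sample_b["person_id"])
        model = fit_multigroup_em(
            {"A": prep.matrix_a, "B": prep.matrix_b}, meta,
            n_categories=prep.n_categories,
        )
        assert 0.35 <= model.latent["A"].mean[0] <= 0.65


def test_prior_weights_normalized_and_symmetric():
    nodes = make_grid(21, 5.0)
    w = prior_weights(nodes, LatentSpec.reference(0.3))
    assert w.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(w >= 0)
    np.testing.assert_allclose(w, w.T, atol=1e-12)  # exchangeable at rho, unit vars
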