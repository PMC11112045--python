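"""End-to-end model training, evaluation, prediction and persistence."""

import copy

import numpy as np
import pytest

from gslmpp import (GslMpp, InputError, MoleculeRecord, RunConfig,
                    SyntheticSpec, generate_dataset, scaffold_split)
from gslmpp.exceptions import ConfigurationError
from gslmpp.metrics import masked_auc


def _tiny_config(**kw):
    base = dict(task_type="regression", k_layers=1, hidden_dim=16, epochs=30,
                patience=10, t_rounds=2, seed=0)
    base.update(kw)
    return RunConfig(**base)


@pytest.fixture(scope="module")
def split_records():
    records = generate_dataset(
        SyntheticSpec(n_molecules=60, n_clusters=4, task_type="regression", seed=3))
    return scaffold_split(records, seed=0)


@pytest.fixture(scope="module")
def fitted(split_records):
    return GslMpp(copy.deepcopy(split_records), _tiny_config()).fit()


class TestRunConfig:
    @pytest.mark.parametrize("kw", [
        {"task_type": "segmentation"},
        {"ablation": "everything"},
        {"lam": 1.5},
        {"epsilon_y": 0.0},
        {"t_rounds": 0},
        {"learning_rate": -1.0},
    ])
    def test_invalid_fields_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            RunConfig(**kw).validate()

    def test_roundtrip_dict(self):
        cfg = RunConfig(task_type="regression", lam=0.6)
        assert RunConfig.from_dict(cfg.to_dict()) == cfg


class TestTraining:
    def test_seeded_determinism(self, split_records):
        a = GslMpp(copy.deepcopy(split_records), _tiny_config()).fit()
        b = GslMpp(copy.deepcopy(split_records), _tiny_config()).fit()
        assert a.report.loss_trace == b.report.loss_trace
        assert a.report.per_split == b.report.per_split
        np.testing.assert_array_equal(a.h_final, b.h_final)

    def test_not_any_never_builds_similarity_graph(self, split_records, monkeypatch):
        import gslmpp.model as model_mod
        calls = []
        orig = model_mod.build_initial_adjacency

        def spy(*args, **kw):
            calls.append(1)
            return orig(*args, **kw)

        monkeypatch.setattr(model_mod, "build_initial_adjacency", spy)
        res = GslMpp(copy.deepcopy(split_records),
                     _tiny_config(ablation="not_any")).fit()
        assert not calls
        assert res.a0 is None and res.gsl_trace is None

    def test_no_gsl_loss_still_refines_graph(self, split_records):
        res = GslMpp(copy.deepcopy(split_records),
                     _tiny_config(ablation="no_gsl_loss")).fit()
        assert all(t["L_gsl"] == 0.0 for t in res.report.loss_trace)
        assert res.gsl_trace and len(res.gsl_trace) == 2  # T rounds happened

    def test_only_gsl_ignores_fingerprint_graph(self, split_records):
        res = GslMpp(copy.deepcopy(split_records),
                     _tiny_config(ablation="only_gsl")).fit()
        assert not np.asarray(res.a0).any()

    def test_no_train_molecules_raises(self, split_records):
        records = copy.deepcopy(split_records)
        for rec in records:
            rec.split = "test"
        with pytest.raises(InputError):
            GslMpp(records, _tiny_config()).fit()

    def test_unsplit_records_treated_as_train(self):
        records = generate_dataset(SyntheticSpec(n_molecules=20, n_clusters=2,
                                                 task_type="regression", seed=1))
        res = GslMpp(records, _tiny_config(epochs=5)).fit()
        assert "train" in res.report.per_split


class TestEvaluation:
    def test_perfect_regression_metrics_zero(self):
        # bypass training: metric helpers judged on exact predictions
        from gslmpp.metrics import evaluate_predictions
        y = np.array([[1.0], [2.0], [3.0]])
        out = evaluate_predictions(y, y.copy(), np.ones_like(y, bool), "regression")
        assert out == {"rmse": 0.0, "mae": 0.0}

    def test_perfectly_separating_scores_auc_one(self):
        from gslmpp.metrics import evaluate_predictions
        y = np.array([[0.0], [0.0], [1.0], [1.0]])
        scores = np.array([[0.1], [0.2], [0.8], [0.9]])
        assert evaluate_predictions(y, scores, np.ones_like(y, bool),
                                    "classification") == {"auc": 1.0}

    def test_auc_matches_mann_whitney_pair_count(self):
        """Six-point AUC against the brute-force concordant-pair count."""
        y = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0])
        s = np.array([0.2, 0.9, 0.4, 0.3, 0.8, 0.1])
        pos, neg = s[y == 1], s[y == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        expected = wins / (len(pos) * len(neg))
        got = masked_auc(y[:, None], s[:, None], np.ones((6, 1), bool))
        assert got == pytest.approx(expected)

    def test_single_class_task_skipped(self):
        y = np.array([[1.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        s = np.random.default_rng(0).random((3, 2))
        auc = masked_auc(y, s, np.ones_like(y, bool))
        assert np.isfinite(auc)  # first task skipped, second scored

    def test_empty_split_raises(self, fitted):
        with pytest.raises(InputError):
            fitted.evaluate("unassigned")


class TestPredictNew:
    def test_duplicate_matches_reference_prediction(self, fitted):
        ref = fitted.model.records[0]
        out = fitted.predict_new([ref.smiles])[0]
        assert out["matched_reference"] == ref.id
        np.testing.assert_allclose(out["prediction"], fitted.predictions[0],
                                   atol=1e-5)

    def test_empty_list_empty_output(self, fitted):
        assert fitted.predict_new([]) == []

    def test_unparseable_smiles_reported_not_fatal(self, fitted):
        out = fitted.predict_new(["not_a_molecule", "CCO"])
        assert "error" in out[0] and "error" not in out[1]

    def test_insertion_leaves_reference_predictions_unchanged(self, split_records):
        res_a = GslMpp(copy.deepcopy(split_records), _tiny_config()).fit()
        before = res_a.predictions.copy()
        res_a.predict_new(["c1ccc(CBr)cc1", "CCCCOC(=O)c1ccccc1"])
        np.testing.assert_allclose(res_a.predictions, before, atol=1e-12)

    def test_new_molecule_gets_finite_prediction(self, fitted):
        out = fitted.predict_new(["c1ccc(CCl)cc1CO"])[0]
        assert out["matched_reference"] is None
        assert np.all(np.isfinite(out["prediction"]))


class TestExportAndCheckpoint:
    def test_export_embeddings_roundtrip(self, fitted, tmp_path):
        path = tmp_path / "embeddings.tsv"
        df = fitted.export_embeddings(path)
        assert len(df) == len(fitted.model.records)
        import pandas as pd
        back = pd.read_csv(path, sep="\t")
        dims = [c for c in back.columns if c.startswith("dim_")]
        np.testing.assert_allclose(back[dims].to_numpy(), fitted.h_final,
                                   atol=1e-12)
        # re-export without retraining is identical
        path2 = tmp_path / "again.tsv"
        fitted.export_embeddings(path2)
        assert path.read_text() == path2.read_text()

    def test_checkpoint_roundtrip(self, fitted, tmp_path, split_records):
        path = tmp_path / "model.npz"
        fitted.save(path)
        back = GslMpp.load_checkpoint(path, copy.deepcopy(split_records))
        np.testing.assert_allclose(back.predictions, fitted.predictions,
                                   atol=1e-10)
        assert back.config == fitted.config


class TestOverfitCapacity:
    def test_small_fixture_train_mse(self, small_regression_records):
        """The full model memorizes a 32-molecule draw (capacity check)."""
        cfg = RunConfig(task_type="regression", k_layers=2, hidden_dim=32,
                        epochs=200, t_rounds=2, seed=0)
        res = GslMpp(copy.deepcopy(small_regression_records), cfg).fit()
        mse = np.mean(((res.predictions - res.y) / res.target_std) ** 2)
        assert mse < 0.5  # strict bound is exercised in the acceptance suite


class TestProtocolHelpers:
    def test_grid_search_selects_on_validation(self, split_records):
        from gslmpp import grid_search
        out = grid_search(split_records, _tiny_config(epochs=8),
                          {"lam": [0.5, 0.9], "t_rounds": [1]})
        assert out["metric"] == "rmse"
        assert len(out["points"]) == 2
        assert out["best"]["params"]["lam"] in (0.5, 0.9)
        valids = [p["rmse"] for p in out["points"]]
        assert out["best"]["valid"] == min(valids)

    def test_run_benchmark_mean_std_over_seeds(self, split_records):
        from gslmpp import run_benchmark
        out = run_benchmark(split_records, _tiny_config(epochs=5),
                            seeds=(0, 1))
        assert out["metric"] == "rmse"
        assert len(out["per_seed"]) == 2
        assert np.isfinite(out["mean"]) and np.isfinite(out["std"])


def test_from_dataframe_constructor():
    import pandas as pd
    df = pd.DataFrame({"smiles": ["CCO", "CCN", "c1ccccc1", "bad$$smiles"],
                       "y": [0.1, 0.2, 0.3, 0.4]})
    model = GslMpp.from_dataframe(df, target_columns=["y"],
                                  config=_tiny_config(epochs=2))
    assert len(model.records) == 3  # invalid SMILES row dropped
    assert model.n_tasks == 1
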