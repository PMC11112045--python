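"""End-to-end model: GIN encoding, structure learning, training, prediction.

`GslMpp` follows the model/results convention of statistical modelling
packages: the model object is built from molecule records (or a
DataFrame) plus a `RunConfig`, and `fit()` returns a `GslMppResults`
carrying the trained weights, per-split metrics, the loss trace and the
cached forward state needed for inductive prediction on new molecules.

Training is transductive and full-batch: every molecule (train, valid and
test) is a node of the similarity graph during propagation, while the
losses only ever read training labels. Each epoch re-encodes the
molecular graphs, runs T structure-learning rounds, predicts, and
backpropagates L = Lpred + w * LGSL through the whole computation with
Adam updates; early stopping watches the validation metric.

Ablation variants mirror the model's component switches:

* ``not_any``     — prediction head directly on the GIN embeddings
                    (no similarity graph at all);
* ``only_a0``     — propagation over the fingerprint graph A(0), no
                    structure learning and no GSL loss;
* ``only_gsl``    — structure learning from scratch without A(0);
* ``no_gsl_loss`` — the full architecture trained with Lpred only.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import autodiff as ad
from . import objective
from .autodiff import Adam, Tensor
from .chem_io import (FeaturizationConfig, MoleculeRecord, canonical_smiles,
                      compute_fingerprint, featurize_molecule, scaffold_split)
from .exceptions import ConfigurationError, InputError, NumericalError, SmilesParseError
from .gin import GinEncoder
from .metrics import evaluate_predictions
from .similarity import build_initial_adjacency
from .structure import gsl_iterate
from .synthetic import SyntheticSpec, generate_dataset  # noqa: F401  (re-export)

logger = logging.getLogger(__name__)

ABLATIONS = ("full", "not_any", "only_a0", "only_gsl", "no_gsl_loss")


@dataclass
class RunConfig:
    """All hyperparameters of one training run.

    Graph-learning knobs: `t_rounds` (T) refinement iterations,
    `m_perspectives` weighted-cosine perspectives, `lam`/`eta` adjacency
    fusion weights, `epsilon_sparsify` neighborhood threshold,
    `inter_layers` (L) propagation layers, `epsilon_tc` fingerprint graph
    threshold. Encoder knobs: `k_layers` (K) GIN layers, `hidden_dim`,
    `readout_mode`. `epsilon_y` is the regression pair-filtering threshold
    on the standardized target scale.
    """

    task_type: str = "classification"
    k_layers: int = 3
    hidden_dim: int = 128
    readout_mode: str = "sum"
    radius: int = 2
    n_bits: int = 2048
    epsilon_tc: float = 0.3
    m_perspectives: int = 4
    epsilon_sparsify: float = 0.3
    lam: float = 0.8
    eta: float = 0.5
    inter_layers: int = 2
    t_rounds: int = 2
    epsilon_y: float = 0.5
    gsl_weight: float = 1.0
    learning_rate: float = 1e-3
    epochs: int = 300
    patience: int = 30
    seed: int = 0
    ablation: str = "full"
    normalize_propagation: bool = True
    center_metric: bool = True
    gsl_loss_on_predicted: bool = False
    max_nodes: int = 20_000

    def validate(self) -> None:
        if self.task_type not in ("classification", "regression"):
            raise ConfigurationError(f"unknown task type {self.task_type!r}")
        if self.ablation not in ABLATIONS:
            raise ConfigurationError(f"unknown ablation variant {self.ablation!r}")
        if self.k_layers < 1 or self.inter_layers < 1 or self.t_rounds < 1:
            raise ConfigurationError("k_layers, inter_layers and t_rounds must be >= 1")
        if self.hidden_dim < 1 or self.n_bits < 1 or self.radius < 0:
            raise ConfigurationError("invalid encoder/fingerprint sizes")
        if not (0 <= self.epsilon_tc <= 1 and 0 <= self.lam <= 1 and 0 <= self.eta <= 1):
            raise ConfigurationError("epsilon_tc, lam, eta must lie in [0, 1]")
        if self.epsilon_sparsify < 0 or self.gsl_weight < 0:
            raise ConfigurationError("epsilon_sparsify and gsl_weight must be >= 0")
        if self.epsilon_y <= 0:
            raise ConfigurationError("epsilon_y must be > 0")
        if self.learning_rate <= 0 or self.epochs < 1 or self.patience < 1:
            raise ConfigurationError("invalid training schedule")
        if self.readout_mode not in ("sum", "mean"):
            raise ConfigurationError(f"unknown readout mode {self.readout_mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        cfg.validate()
        return cfg


@dataclass
class MetricsReport:
    """Per-split metrics plus the per-epoch loss trace of one run."""

    task_type: str
    per_split: dict = field(default_factory=dict)
    loss_trace: list = field(default_factory=list)
    best_epoch: int = -1

    def to_dict(self) -> dict:
        return {"task_type": self.task_type, "per_split": self.per_split,
                "loss_trace": self.loss_trace, "best_epoch": self.best_epoch}


class GslMpp:
    """Transductive molecular property predictor over a learned similarity graph."""

    def __init__(self, records: list[MoleculeRecord], config: RunConfig | None = None):
        if not records:
            raise InputError("no molecule records")
        self.config = config or RunConfig()
        self.config.validate()
        self.records = records
        self.n_tasks = records[0].targets.size
        for rec in records:
            if rec.targets.size != self.n_tasks:
                raise ConfigurationError("inconsistent task count across records")
        self.feat_scheme = FeaturizationConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, smiles_column: str = "smiles",
                       target_columns: list[str] | None = None,
                       config: RunConfig | None = None) -> "GslMpp":
        from .chem_io import parse_dataset
        import io

        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        records = parse_dataset(buf, smiles_column, target_columns)
        return cls(records, config)

    # ------------------------------------------------------------------
    # parameter setup

    def _init_params(self, rng: np.random.Generator) -> dict:
        cfg = self.config
        encoder = GinEncoder(self.feat_scheme.dim, cfg.hidden_dim, cfg.k_layers,
                             cfg.readout_mode, rng)
        params: dict[str, Tensor] = dict(encoder.params)
        if cfg.ablation not in ("not_any", "only_a0"):
            # start the learned metric near plain cosine
            pw = np.ones((cfg.m_perspectives, cfg.hidden_dim))
            pw += 0.01 * rng.standard_normal(pw.shape)
            params["perspectives"] = Tensor(pw, requires_grad=True)
        if cfg.ablation != "not_any":
            for l in range(cfg.inter_layers):
                params[f"inter_W{l}"] = ad.parameter(
                    (cfg.hidden_dim, cfg.hidden_dim), rng)
        params["head_W"] = ad.parameter((cfg.hidden_dim, self.n_tasks), rng)
        params["head_b"] = Tensor(np.zeros((1, self.n_tasks)), requires_grad=True)
        return {"encoder": encoder, "tensors": params}

    # ------------------------------------------------------------------
    # forward pass

    def _forward(self, encoder: GinEncoder, tensors: dict, graphs, a0,
                 record_trace: bool = False):
        cfg = self.config
        x_r = encoder.encode(graphs)
        state = None
        if cfg.ablation == "not_any":
            h_final = x_r
        elif cfg.ablation == "only_a0":
            from .structure import propagate
            ws = [tensors[f"inter_W{l}"] for l in range(cfg.inter_layers)]
            if record_trace:
                h_final, layer_inputs = propagate(
                    x_r, a0, ws, normalize=cfg.normalize_propagation,
                    collect_layers=True)
                state = {"layer_inputs": layer_inputs,
                         "degrees": np.asarray(a0).sum(axis=1)}
            else:
                h_final = propagate(x_r, a0, ws,
                                    normalize=cfg.normalize_propagation)
        else:
            ws = [tensors[f"inter_W{l}"] for l in range(cfg.inter_layers)]
            state = gsl_iterate(x_r, a0, tensors["perspectives"],
                                cfg.epsilon_sparsify, cfg.lam, cfg.eta, ws,
                                cfg.t_rounds, normalize=cfg.normalize_propagation,
                                center_metric=cfg.center_metric,
                                record_trace=record_trace)
            h_final = state.H_r
        y_hat = objective.predict(h_final, tensors["head_W"], tensors["head_b"])
        return x_r, h_final, y_hat, state

    # ------------------------------------------------------------------
    # fitting

    def fit(self, verbose: bool = False) -> "GslMppResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        records = self.records
        n = len(records)

        graphs = [featurize_molecule(r.smiles, self.feat_scheme) for r in records]
        fingerprints = [compute_fingerprint(r.smiles, cfg.radius, cfg.n_bits)
                        for r in records]

        split_idx = {s: np.array([i for i, r in enumerate(records) if r.split == s],
                                 dtype=np.intp)
                     for s in ("train", "valid", "test")}
        unassigned = [i for i, r in enumerate(records) if r.split == "unassigned"]
        if unassigned and len(unassigned) == n:
            logger.warning("no split assignments; treating all molecules as train")
            split_idx["train"] = np.arange(n, dtype=np.intp)
        train_idx = split_idx["train"]
        if train_idx.size == 0:
            raise InputError("no training molecules")

        y = np.stack([r.targets for r in records])
        mask = np.stack([r.target_mask for r in records])
        if not mask[train_idx].any():
            raise InputError("no observed training labels")

        # regression targets are z-scored on train statistics
        if cfg.task_type == "regression":
            tr_y, tr_m = y[train_idx], mask[train_idx]
            mean = np.array([tr_y[tr_m[:, t], t].mean() if tr_m[:, t].any() else 0.0
                             for t in range(self.n_tasks)])
            std = np.array([tr_y[tr_m[:, t], t].std() if tr_m[:, t].any() else 1.0
                            for t in range(self.n_tasks)])
            std = np.where(std > 1e-8, std, 1.0)
            y_model = (y - mean) / std
        else:
            mean = np.zeros(self.n_tasks)
            std = np.ones(self.n_tasks)
            y_model = y

        if cfg.ablation == "not_any":
            a0 = None
        elif cfg.ablation == "only_gsl":
            a0 = np.zeros((n, n))
        else:
            sim_graph = build_initial_adjacency(
                fingerprints, cfg.epsilon_tc,
                [r.id for r in records], cfg.max_nodes)
            a0 = sim_graph.dense()

        bundle = self._init_params(rng)
        encoder, tensors = bundle["encoder"], bundle["tensors"]
        opt = Adam(list(tensors.values()), lr=cfg.learning_rate)

        use_gsl_loss = cfg.ablation in ("full", "only_gsl") and cfg.gsl_weight > 0
        has_valid = split_idx["valid"].size > 0 and mask[split_idx["valid"]].any()
        if not has_valid:
            logger.warning("empty validation split; early stopping disabled")
        # checkpoint selection minimizes the validation prediction loss (a
        # smooth surrogate; AUC/RMSE on small splits is too noisy to rank
        # epochs); the split metrics are still logged per epoch
        best_metric = np.inf
        best_state: dict | None = None
        best_epoch = -1
        bad_epochs = 0
        loss_trace: list[dict] = []

        for epoch in range(cfg.epochs):
            opt.zero_grad()
            _, _, y_hat, state = self._forward(encoder, tensors, graphs, a0)
            l_pred = objective.prediction_loss(
                ad.take(y_hat, train_idx, axis=0), y_model[train_idx],
                mask[train_idx], cfg.task_type)
            if use_gsl_loss:
                a_fused = state.A_fused
                if cfg.task_type == "classification":
                    l_gsl = objective.gsl_loss_classification(
                        a_fused, y, train_idx, label_mask=mask, rng=rng)
                else:
                    y_for_pairs = (y_hat.data if cfg.gsl_loss_on_predicted
                                   else y_model)
                    l_gsl = objective.gsl_loss_regression(
                        a_fused, y_for_pairs, train_idx, cfg.epsilon_y,
                        label_mask=mask, rng=rng)
                loss = objective.total_loss(l_pred, l_gsl, cfg.gsl_weight)
            else:
                l_gsl = 0.0
                loss = l_pred
            if not np.isfinite(loss.data):
                raise NumericalError(f"training diverged at epoch {epoch}")
            loss.backward()
            opt.step()

            # validation quantities straight from the transductive forward pass
            if has_valid:
                vi = split_idx["valid"]
                scores = self._to_output_units(y_hat.data, mean, std)
                vm = evaluate_predictions(y[vi], scores[vi], mask[vi], cfg.task_type)
                metric = float(objective.prediction_loss(
                    y_hat.data[vi], y_model[vi], mask[vi], cfg.task_type))
                vm_main = vm.get("auc", vm.get("rmse", float("nan")))
            else:
                metric = float(loss.data)
                vm_main = float("nan")
            loss_trace.append({
                "epoch": epoch,
                "L_pred": float(np.asarray(l_pred.data if isinstance(l_pred, Tensor)
                                           else l_pred)),
                "L_gsl": float(np.asarray(l_gsl.data if isinstance(l_gsl, Tensor)
                                          else l_gsl)),
                "L": float(loss.data),
                "valid_loss": float(metric),
                "valid_metric": float(vm_main),
            })
            if verbose and epoch % 10 == 0:
                logger.info("epoch %d L=%.4f valid=%.4f", epoch, float(loss.data), metric)

            if not has_valid:
                # nothing to select by: keep training and return the final state
                best_epoch = epoch
                best_state = {k: v.data.copy() for k, v in tensors.items()}
                continue
            improved = metric < best_metric
            if improved or best_state is None:
                best_metric = metric
                best_epoch = epoch
                best_state = {k: v.data.copy() for k, v in tensors.items()}
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= cfg.patience:
                    break

        for k, v in tensors.items():
            v.data = best_state[k]

        # final forward with cached trace for evaluation and node insertion
        x_r, h_final, y_hat, state = self._forward(
            encoder, tensors, graphs, a0, record_trace=True)
        scores = self._to_output_units(y_hat.data, mean, std)

        report = MetricsReport(cfg.task_type, loss_trace=loss_trace,
                               best_epoch=best_epoch)
        for split, idx in split_idx.items():
            if idx.size and mask[idx].any():
                report.per_split[split] = evaluate_predictions(
                    y[idx], scores[idx], mask[idx], cfg.task_type)

        return GslMppResults(
            model=self, encoder=encoder, tensors=tensors, report=report,
            graphs=graphs, fingerprints=fingerprints, a0=a0,
            x_r=x_r.data.copy(), h_final=np.asarray(
                h_final.data if isinstance(h_final, Tensor) else h_final).copy(),
            predictions=scores, y=y, mask=mask, target_mean=mean, target_std=std,
            gsl_trace=(state.trace if hasattr(state, "trace") else state),
        )

    @staticmethod
    def _to_output_units(y_hat: np.ndarray, mean: np.ndarray,
                         std: np.ndarray) -> np.ndarray:
        return y_hat * std + mean  # identity for classification logits

    # ------------------------------------------------------------------
    @classmethod
    def load_checkpoint(cls, path, records: list[MoleculeRecord]) -> "GslMppResults":
        """Rebuild a fitted model from `save()` output and re-run the forward."""
        blob = np.load(str(path), allow_pickle=False)
        meta = json.loads(bytes(blob["__meta"]).decode())
        config = RunConfig.from_dict(meta["config"])
        model = cls(records, config)
        rng = np.random.default_rng(config.seed)
        bundle = model._init_params(rng)
        for key, tensor in bundle["tensors"].items():
            tensor.data = np.asarray(blob[key], dtype=np.float64).copy()
        results = model._refit_forward(bundle)
        return results

    def _refit_forward(self, bundle) -> "GslMppResults":
        """Run the fitted forward pass without any training (used by load)."""
        cfg = self.config
        records = self.records
        graphs = [featurize_molecule(r.smiles, self.feat_scheme) for r in records]
        fingerprints = [compute_fingerprint(r.smiles, cfg.radius, cfg.n_bits)
                        for r in records]
        n = len(records)
        if cfg.ablation == "not_any":
            a0 = None
        elif cfg.ablation == "only_gsl":
            a0 = np.zeros((n, n))
        else:
            a0 = build_initial_adjacency(fingerprints, cfg.epsilon_tc,
                                         [r.id for r in records],
                                         cfg.max_nodes).dense()
        y = np.stack([r.targets for r in records])
        mask = np.stack([r.target_mask for r in records])
        train_idx = np.array([i for i, r in enumerate(records)
                              if r.split == "train"], dtype=np.intp)
        if cfg.task_type == "regression" and train_idx.size:
            tr_y, tr_m = y[train_idx], mask[train_idx]
            mean = np.array([tr_y[tr_m[:, t], t].mean() if tr_m[:, t].any() else 0.0
                             for t in range(self.n_tasks)])
            std = np.array([tr_y[tr_m[:, t], t].std() if tr_m[:, t].any() else 1.0
                            for t in range(self.n_tasks)])
            std = np.where(std > 1e-8, std, 1.0)
        else:
            mean = np.zeros(self.n_tasks)
            std = np.ones(self.n_tasks)
        encoder, tensors = bundle["encoder"], bundle["tensors"]
        x_r, h_final, y_hat, state = self._forward(
            encoder, tensors, graphs, a0, record_trace=True)
        scores = self._to_output_units(y_hat.data, mean, std)
        report = MetricsReport(cfg.task_type)
        for split in ("train", "valid", "test"):
            idx = np.array([i for i, r in enumerate(records) if r.split == split],
                           dtype=np.intp)
            if idx.size and mask[idx].any():
                report.per_split[split] = evaluate_predictions(
                    y[idx], scores[idx], mask[idx], cfg.task_type)
        return GslMppResults(
            model=self, encoder=encoder, tensors=tensors, report=report,
            graphs=graphs, fingerprints=fingerprints, a0=a0,
            x_r=x_r.data.copy(),
            h_final=np.asarray(h_final.data if isinstance(h_final, Tensor)
                               else h_final).copy(),
            predictions=scores, y=y, mask=mask, target_mean=mean,
            target_std=std,
            gsl_trace=(state.trace if hasattr(state, "trace") else state))


class GslMppResults:
    """Fitted-model container: weights, metrics, cached state, prediction API."""

    def __init__(self, model: GslMpp, encoder: GinEncoder, tensors: dict,
                 report: MetricsReport, graphs, fingerprints, a0,
                 x_r, h_final, predictions, y, mask, target_mean, target_std,
                 gsl_trace):
        self.model = model
        self.config = model.config
        self.encoder = encoder
        self.tensors = tensors
        self.report = report
        self.graphs = graphs
        self.fingerprints = fingerprints
        self.a0 = a0
        self.x_r = x_r
        self.h_final = h_final
        self.predictions = predictions  # original units / logits
        self.y = y
        self.mask = mask
        self.target_mean = target_mean
        self.target_std = target_std
        self.gsl_trace = gsl_trace
        self._canonical = {canonical_smiles(r.smiles): i
                           for i, r in enumerate(model.records)}

    # ------------------------------------------------------------------
    @property
    def probabilities(self) -> np.ndarray:
        """Per-task probabilities (classification); logistic of the logits."""
        if self.config.task_type != "classification":
            raise ConfigurationError("probabilities only defined for classification")
        return 1.0 / (1.0 + np.exp(-self.predictions))

    def evaluate(self, split: str = "test") -> dict[str, float]:
        idx = np.array([i for i, r in enumerate(self.model.records)
                        if r.split == split], dtype=np.intp)
        if idx.size == 0:
            raise InputError(f"split {split!r} is empty")
        scores = (self.probabilities if self.config.task_type == "classification"
                  else self.predictions)
        return evaluate_predictions(self.y[idx], scores[idx], self.mask[idx],
                                    self.config.task_type)

    # ------------------------------------------------------------------
    # inductive prediction for unseen molecules

    def predict_new(self, smiles_list: list[str]) -> list[dict]:
        """Predict properties of molecules not in the fitted similarity graph.

        Exact structural duplicates of fitted molecules map onto their
        existing graph node. Genuinely new molecules are inserted with
        one-directional message passing — they receive messages from the
        cached reference activations but send none — so every reference
        prediction is untouched.
        """
        out = []
        for smi in smiles_list:
            try:
                out.append(self._predict_one(smi))
            except SmilesParseError as exc:
                out.append({"smiles": smi, "error": str(exc)})
        return out

    def _predict_one(self, smi: str) -> dict:
        cfg = self.config
        canon = canonical_smiles(smi)
        if canon in self._canonical:
            i = self._canonical[canon]
            return {"smiles": smi, "prediction": self.predictions[i].copy(),
                    "matched_reference": self.model.records[i].id}

        graph = featurize_molecule(smi, self.model.feat_scheme)
        x_new = self.encoder.encode([graph]).data  # (1, hidden)
        if cfg.ablation == "not_any":
            h_new = x_new
        else:
            h_new = self._insert_and_propagate(smi, x_new)
        w = self.tensors["head_W"].data
        b = self.tensors["head_b"].data
        pred = (h_new @ w + b) * self.target_std + self.target_mean
        return {"smiles": smi, "prediction": pred[0].copy(),
                "matched_reference": None}

    def _fused_row_propagate(self, frow: np.ndarray, x_new: np.ndarray,
                             layer_inputs: list[np.ndarray],
                             ref_degrees: np.ndarray) -> np.ndarray:
        cfg = self.config
        ws = [self.tensors[f"inter_W{l}"].data for l in range(cfg.inter_layers)]
        if cfg.normalize_propagation:
            d_new = max(frow.sum(), 1e-12)
            coef_self = 0.5
            coef_ref = 0.5 * frow / np.sqrt(d_new * np.maximum(ref_degrees, 1e-12))
        else:
            coef_self = 0.0
            coef_ref = frow
        h = x_new
        for w_l, ref_in in zip(ws, layer_inputs):
            h = np.maximum((coef_self * h + coef_ref[None, :] @ ref_in) @ w_l, 0.0)
        return h

    def _insert_and_propagate(self, smi: str, x_new: np.ndarray) -> np.ndarray:
        cfg = self.config
        if cfg.ablation == "only_gsl":
            a0_row = np.zeros(len(self.fingerprints))
        else:
            fp = compute_fingerprint(smi, cfg.radius, cfg.n_bits)
            from .chem_io import tanimoto
            a0_row = np.array([tanimoto(fp, ref) for ref in self.fingerprints])
            a0_row[a0_row < cfg.epsilon_tc] = 0.0

        if cfg.ablation == "only_a0":
            trace = self.gsl_trace  # dict with layer_inputs and degrees
            return self._fused_row_propagate(a0_row, x_new,
                                             trace["layer_inputs"],
                                             trace["degrees"])

        pw = self.tensors["perspectives"].data
        h_prev = x_new
        a1_row = None
        for round_info in self.gsl_trace:
            ref_h_prev = round_info["H_prev"]
            mu = round_info.get("metric_mean")
            if mu is not None:
                s_row = _weighted_cosine_row(h_prev - mu, ref_h_prev - mu, pw)
            else:
                s_row = _weighted_cosine_row(h_prev, ref_h_prev, pw)
            a_row = np.where(s_row >= cfg.epsilon_sparsify, s_row, 0.0)
            if a1_row is None:
                a1_row = a_row
            frow = cfg.lam * a0_row + (1 - cfg.lam) * (
                cfg.eta * a_row + (1 - cfg.eta) * a1_row)
            h_prev = self._fused_row_propagate(frow, x_new,
                                               round_info["layer_inputs"],
                                               round_info["degrees"])
        return h_prev

    # ------------------------------------------------------------------
    def export_embeddings(self, path) -> pd.DataFrame:
        """Write the final molecular embeddings with ids, splits and labels."""
        recs = self.model.records
        cols = {"id": [r.id for r in recs], "split": [r.split for r in recs]}
        for t in range(self.model.n_tasks):
            cols[f"target_{t}"] = self.y[:, t]
            cols[f"observed_{t}"] = self.mask[:, t]
        for d in range(self.h_final.shape[1]):
            cols[f"dim_{d}"] = self.h_final[:, d]
        df = pd.DataFrame(cols)
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
        return df

    def save(self, path) -> None:
        """Checkpoint: all weights + config + fingerprint settings + id order."""
        meta = {"config": self.config.to_dict(),
                "molecule_ids": [r.id for r in self.model.records]}
        arrays = {k: v.data for k, v in self.tensors.items()}
        arrays["__meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(str(path), **arrays)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "GSL-MPP results",
            "=" * 46,
            f"task type        : {cfg.task_type}",
            f"ablation variant : {cfg.ablation}",
            f"molecules        : {len(self.model.records)}"
            f" ({sum(r.split == 'train' for r in self.model.records)} train)",
            f"GIN layers K     : {cfg.k_layers}   hidden dim: {cfg.hidden_dim}",
            f"GSL rounds T     : {cfg.t_rounds}   inter layers L: {cfg.inter_layers}",
            f"lambda / eta     : {cfg.lam} / {cfg.eta}",
            f"epsilon_tc/spars : {cfg.epsilon_tc} / {cfg.epsilon_sparsify}",
            f"best epoch       : {self.report.best_epoch}",
            "-" * 46,
        ]
        for split, metrics in self.report.per_split.items():
            parts = "  ".join(f"{k}={v:.4f}" for k, v in metrics.items())
            lines.append(f"{split:<8}: {parts}")
        return "\n".join(lines)


def _weighted_cosine_row(h_new: np.ndarray, ref_h: np.ndarray,
                         perspectives: np.ndarray) -> np.ndarray:
    """Similarity of one embedding to each reference row, averaged over perspectives."""
    acc = np.zeros(ref_h.shape[0])
    for wp in perspectives:
        v_new = (h_new * wp).ravel()
        v_ref = ref_h * wp
        n_new = np.sqrt((v_new ** 2).sum() + 1e-12)
        n_ref = np.sqrt((v_ref ** 2).sum(axis=1) + 1e-12)
        acc += (v_ref @ v_new) / (n_ref * n_new)
    return acc / perspectives.shape[0]


def grid_search(records: list[MoleculeRecord], base_config: RunConfig,
                grid: dict[str, list]) -> dict:
    """Small hyperparameter grid selected on the validation metric.

    `grid` maps RunConfig field names (e.g. "lam", "t_rounds") to candidate
    values; every combination is trained on the given (already split)
    records and the combination with the best validation metric (highest
    AUC / lowest RMSE) is returned along with all per-point results.
    """
    import itertools

    keys = list(grid)
    metric_name = "auc" if base_config.task_type == "classification" else "rmse"
    better = (lambda a, b: a > b) if metric_name == "auc" else (lambda a, b: a < b)
    best = None
    points = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        cfg = RunConfig.from_dict({**base_config.to_dict(),
                                   **dict(zip(keys, combo))})
        res = GslMpp(copy.deepcopy(records), cfg).fit()
        val = res.report.per_split.get("valid", {}).get(metric_name, float("nan"))
        points.append({"params": dict(zip(keys, combo)), metric_name: val,
                       "test": res.report.per_split.get("test", {})})
        if np.isfinite(val) and (best is None or better(val, best["valid"])):
            best = {"params": dict(zip(keys, combo)), "valid": val,
                    "results": res}
    return {"metric": metric_name, "points": points, "best": best}


def run_benchmark(records: list[MoleculeRecord], config: RunConfig,
                  seeds: tuple[int, ...] = (0, 1, 2)) -> dict:
    """Protocol helper: independent runs on random-seeded scaffold splits.

    Each seed draws its own scaffold split (80/10/10), trains a fresh
    model, and reports the test metric; the summary is mean ± std over
    seeds.
    """
    per_seed = []
    metric_name = "auc" if config.task_type == "classification" else "rmse"
    for seed in seeds:
        run_records = copy.deepcopy(records)
        scaffold_split(run_records, seed=seed)
        cfg = RunConfig.from_dict({**config.to_dict(), "seed": seed})
        res = GslMpp(run_records, cfg).fit()
        per_seed.append(res.report.per_split.get("test", {}).get(metric_name,
                                                                 float("nan")))
    arr = np.asarray(per_seed, dtype=np.float64)
    return {"metric": metric_name, "per_seed": per_seed,
            "mean": float(np.nanmean(arr)), "std": float(np.nanstd(arr))}
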