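"""statsmodels-style facade: a Model built from a curated dataset whose
``fit()`` returns a Results object carrying the trained flow, the GI50
head, training diagnostics and a ``summary()`` table; sampling and
latent optimization hang off the Results."""

from __future__ import annotations

import io
import json

import numpy as np
import pandas as pd

from . import __about__
from .chemgraph import AtomVocabulary, BondVocabulary, graph_to_smiles, smiles_to_graph
from .flow import FlowConfig, FlowModel, evaluate_nll, train_flow
from .generation import OptimizationConfig, report_candidates, run_generation, select_seed_molecules
from .head import RegressorConfig, encode_features, fit_regressor, predict_gi50, train_regressor
from .preprocess import ProcessedDataset, ScreeningRecord, build_dataset


class MoleculeFlow:
    """Two-stage graph normalizing flow + GI50 head over a curated dataset.

    Parameters
    ----------
    dataset : ProcessedDataset
        Curated unique molecules with one GI50 value each; its derived
        dimensions (dn, dv, de) size the model.
    flow_config, head_config : optional
        Architecture overrides; defaults are the desk-scale sizes
        (2 coupling layers, width 16; head hidden (64, 32)).
    """

    def __init__(self, dataset: ProcessedDataset, flow_config: FlowConfig | None = None,
                 head_config: RegressorConfig | None = None):
        if len(dataset) == 0:
            raise ValueError("dataset must be non-empty")
        self.dataset = dataset
        self.flow_config = flow_config or FlowConfig(
            dn=dataset.dn, dv=dataset.atom_vocab.dv, de=dataset.bond_vocab.de
        )
        self.head_config = head_config or RegressorConfig(hidden_widths=(64, 32))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, smiles_col="smiles", gi50_col="gi50",
                       **kwargs) -> "MoleculeFlow":
        """Curate a raw (smiles, gi50) frame through the standard filters."""
        records = [
            ScreeningRecord(i, str(row[smiles_col]), "", float(row[gi50_col]))
            for i, (_, row) in enumerate(df.iterrows())
        ]
        return cls(build_dataset(records), **kwargs)

    def fit(self, flow_epochs=30, batch_size=10, learning_rate=1e-3,
            seed=0, eval_seed=0) -> "MoleculeFlowResults":
        """Two-phase training: the flow by exact NLL, then the frozen-flow head.

        ``seed`` drives parameter initialization, dequantization noise and
        minibatch order; ``eval_seed`` fixes the noise draw used for the
        before/after NLL evaluations so they are comparable.
        """
        flow = FlowModel(self.flow_config, self.dataset.atom_vocab,
                         self.dataset.bond_vocab, seed=seed)
        graphs = [
            smiles_to_graph(s, flow.atom_vocab, flow.bond_vocab, self.flow_config.dn)
            for s in self.dataset.smiles
        ]
        nll_initial = evaluate_nll(flow, graphs, seed=eval_seed)
        history = train_flow(flow, graphs, epochs=flow_epochs, batch_size=batch_size,
                             learning_rate=learning_rate,
                             rng=np.random.default_rng(seed + 1))
        nll_final = evaluate_nll(flow, graphs, seed=eval_seed)
        regressor = train_regressor(self.dataset, flow, self.head_config,
                                    np.random.default_rng(seed + 2))
        X = encode_features(self.dataset, flow)
        resid = regressor.predict(X) - self.dataset.gi50
        return MoleculeFlowResults(
            model=self, flow=flow, regressor=regressor, nll_history=history,
            nll_initial=nll_initial, nll_final=nll_final,
            head_train_mse=float(np.mean(resid**2)),
        )


class MoleculeFlowResults:
    """Fitted flow + head with diagnostics, sampling and optimization."""

    def __init__(self, model, flow, regressor, nll_history,
                 nll_initial, nll_final, head_train_mse):
        self.model = model
        self.flow = flow
        self.regressor = regressor
        self.nll_history = list(nll_history)
        self.nll_initial = nll_initial
        self.nll_final = nll_final
        self.head_train_mse = head_train_mse

    # -- inference -------------------------------------------------------
    def predict(self, smiles: str) -> float:
        """Predicted GI50 of a molecule (lower = more potent)."""
        graph = smiles_to_graph(smiles, self.flow.atom_vocab, self.flow.bond_vocab,
                                self.flow.config.dn)
        return predict_gi50(graph, self.flow, self.regressor)

    def sample(self, n: int, temperature: float = 0.7, seed: int = 0):
        """Decode ``n`` prior draws; returns canonical SMILES (None = empty)."""
        rng = np.random.default_rng(seed)
        out = []
        for latent in self.flow.sample_prior(n, temperature, rng):
            graph = self.flow.decode(latent)
            out.append(graph_to_smiles(graph, self.flow.atom_vocab, self.flow.bond_vocab))
        return out

    def optimize(self, seeds=None, k: int = 5,
                 config: OptimizationConfig | None = None) -> pd.DataFrame:
        """Gradient-descent search from seeds (default: top-k most potent).

        Returns the ranked candidate table; raw trajectories are kept on
        ``self.last_trajectories``.
        """
        config = config or OptimizationConfig()
        if seeds is None:
            seeds = select_seed_molecules(self.model.dataset, k)
        self.last_trajectories = run_generation(seeds, self.flow, self.regressor, config)
        return report_candidates(self.last_trajectories, config)

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        cfg = self.flow.config
        n_params = sum(p.data.size for p in self.flow.parameters())
        n_head = sum(p.data.size for p in self.regressor.parameters())
        buf = io.StringIO()
        w = buf.write
        w("             Molecular Graph Flow Results\n")
        w("=======================================================\n")
        if self.model is not None:
            w(f"molecules:             {len(self.model.dataset):>10d}\n")
        w(f"node capacity dn:      {cfg.dn:>10d}\n")
        w(f"atom / bond channels:  {cfg.dv:>7d} / {cfg.de}\n")
        w(f"coupling layers (E/V): {cfg.bond_layers:>7d} / {cfg.atom_layers}\n")
        w(f"flow parameters:       {n_params:>10d}\n")
        w(f"NLL initial (nats):    {self.nll_initial:>10.2f}\n")
        w(f"NLL final (nats):      {self.nll_final:>10.2f}\n")
        w(f"head parameters:       {n_head:>10d}\n")
        w(f"head train MSE:        {self.head_train_mse:>10.4f}\n")
        w("=======================================================\n")
        return buf.getvalue()

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        save_checkpoint(path, self.flow, self.regressor, extra={
            "nll_history": self.nll_history,
            "nll_initial": self.nll_initial,
            "nll_final": self.nll_final,
            "head_train_mse": self.head_train_mse,
        })

    @classmethod
    def load(cls, path) -> "MoleculeFlowResults":
        flow, regressor, extra = load_checkpoint(path)
        return cls(model=None, flow=flow, regressor=regressor,
                   nll_history=extra.get("nll_history", []),
                   nll_initial=extra.get("nll_initial", float("nan")),
                   nll_final=extra.get("nll_final", float("nan")),
                   head_train_mse=extra.get("head_train_mse", float("nan")))


# ---------------------------------------------------------------------------
# single-file checkpoint: parameters + config + vocabularies
# ---------------------------------------------------------------------------

def save_checkpoint(path, flow: FlowModel, regressor=None, extra=None) -> None:
    cfg = flow.config
    meta = {
        "version": __about__,
        "flow_config": {
            k: getattr(cfg, k)
            for k in ("dn", "dv", "de", "bond_layers", "atom_layers", "bond_split",
                      "atom_split", "conv_width", "conv_kernel", "gnn_width",
                      "gnn_rounds", "mlp_width", "noise_scale")
        },
        "atom_symbols": list(flow.atom_vocab.symbols),
        "bond_orders": list(flow.bond_vocab.bond_orders),
        "flow_seed": flow.seed,
        "extra": extra or {},
    }
    arrays = {f"flow_{i}": p.data for i, p in enumerate(flow.parameters())}
    if regressor is not None:
        meta["head_config"] = {
            "hidden_widths": list(regressor.config.hidden_widths),
            "epochs": regressor.config.epochs,
            "batch_size": regressor.config.batch_size,
            "learning_rate": regressor.config.learning_rate,
            "hidden_decay": regressor.config.hidden_decay,
            "skip_decay": regressor.config.skip_decay,
            "raw_penalty_grid": list(regressor.config.raw_penalty_grid),
        }
        meta["head_pool_dims"] = (
            list(regressor.pool_dims) if regressor.pool_dims else None
        )
        meta["head_standardization"] = [regressor.target_mean, regressor.target_sd]
        meta["head_raw_penalty"] = regressor.raw_penalty
        meta["head_features"] = regressor.n_features
        arrays.update({f"head_{i}": p.data for i, p in enumerate(regressor.parameters())})
        arrays["head_feature_mean"] = regressor.feature_mean
        arrays["head_feature_sd"] = regressor.feature_sd
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path):
    from .head import GI50Regressor

    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        cfg = FlowConfig(**meta["flow_config"])
        flow = FlowModel(cfg, AtomVocabulary(tuple(meta["atom_symbols"])),
                         BondVocabulary(tuple(meta["bond_orders"])),
                         seed=meta["flow_seed"])
        for i, p in enumerate(flow.parameters()):
            p.data = data[f"flow_{i}"].copy()
        regressor = None
        if "head_config" in meta:
            hc = meta["head_config"]
            head_config = RegressorConfig(
                hidden_widths=tuple(hc["hidden_widths"]), epochs=hc["epochs"],
                batch_size=hc["batch_size"], learning_rate=hc["learning_rate"],
                hidden_decay=hc.get("hidden_decay", 1.0),
                skip_decay=hc.get("skip_decay", 1e-4),
                raw_penalty_grid=tuple(hc.get("raw_penalty_grid", (0.0,))),
            )
            pool_dims = meta.get("head_pool_dims")
            regressor = GI50Regressor(meta["head_features"], head_config,
                                      np.random.default_rng(0),
                                      pool_dims=tuple(pool_dims) if pool_dims else None)
            regressor.target_mean, regressor.target_sd = meta["head_standardization"]
            regressor.raw_penalty = meta.get("head_raw_penalty", 0.0)
            regressor.feature_mean = data["head_feature_mean"].copy()
            regressor.feature_sd = data["head_feature_sd"].copy()
            for i, p in enumerate(regressor.parameters()):
                p.data = data[f"head_{i}"].copy()
    return flow, regressor, meta.get("extra", {})
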