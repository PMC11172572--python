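"""GI50 property predictor on the flow's latent representation.

A molecule is encoded noise-free by the frozen flow and its latent pair
(H, Z) is flattened — H block first, then Z, row-major — into the
feature vector the head consumes.  The head is a small neural network
built for the structure of that vector:

* the input columns are standardized (statistics stored at fit time);
* channel-wise pooled means of the bond block (over node pairs) and the
  atom block (over nodes) are prepended — exchangeable summaries that
  let the head recover structure->activity signal with a sample
  complexity independent of the node capacity dn;
* a tanh hidden stack consumes the pooled summaries (the nonlinear
  path), while a linear skip connection spans the full augmented vector
  (the dense path);
* the dense path's raw-coordinate block carries a decoupled L2 penalty
  whose strength is chosen by an internal validation split, so the head
  leans on the low-dimensional summaries when they suffice and on the
  raw coordinates when the signal demands them.

Targets are standardized for training (mean-squared-error loss, Adam)
and de-standardized at prediction; the prediction is differentiable in
the input, which is what the latent optimizer consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Adam, Tensor, concat, matmul, tanh
from .flow import FlowModel, LatentPair


@dataclass(frozen=True)
class RegressorConfig:
    """Architecture and training controls of the GI50 head.

    ``raw_penalty_grid`` lists candidate decoupled L2 strengths for the
    raw-coordinate block of the linear skip; the winner on an internal
    validation split (``val_fraction``) is used for the final fit on all
    data.  ``hidden_decay`` and ``skip_decay`` are the fixed decoupled
    penalties of the hidden stack and the pooled skip columns.
    """

    hidden_widths: tuple = (64, 32)
    activation: str = "tanh"
    epochs: int = 300
    batch_size: int = 64
    learning_rate: float = 1e-3
    hidden_decay: float = 1.0
    skip_decay: float = 1e-4
    raw_penalty_grid: tuple = (0.0, 3.0, 30.0, 100.0)
    val_fraction: float = 1.0 / 6.0

    def __post_init__(self):
        if len(self.hidden_widths) < 1:
            raise ValueError("the head must be a nonlinear network: >= 1 hidden layer")
        if self.activation != "tanh":
            raise ValueError("only the smooth 'tanh' activation is supported")


def featurize_latent(latent: LatentPair) -> np.ndarray:
    """Deterministic flattening: H block first, then Z, row-major each."""
    return np.concatenate([latent.H.ravel(), latent.Z.ravel()])


def unflatten_latent(vector: np.ndarray, dn: int, dv: int, de: int) -> LatentPair:
    """Inverse of :func:`featurize_latent` for a model of dims (dn, dv, de)."""
    n_h = dn * dn * de
    if vector.size != n_h + dn * dv:
        raise ValueError("vector length does not match dn/dv/de")
    return LatentPair(vector[:n_h].reshape(dn, dn, de), vector[n_h:].reshape(dn, dv))


class GI50Regressor:
    """Pooled-summary tanh network with a penalized dense skip path.

    ``pool_dims = (dn, dv, de)`` enables the pooled summaries; without
    it the hidden stack consumes the full standardized input (generic
    regression mode used by some unit tests).
    """

    def __init__(self, n_features: int, config: RegressorConfig, rng,
                 pool_dims: tuple | None = None):
        self.n_features = n_features
        self.config = config
        self.pool_dims = tuple(pool_dims) if pool_dims is not None else None
        if self.pool_dims is not None:
            dn, dv, de = self.pool_dims
            if dn * dn * de + dn * dv != n_features:
                raise ValueError("pool_dims inconsistent with n_features")
            self.n_pool = dv + de
        else:
            self.n_pool = 0
        self.target_mean, self.target_sd = 0.0, 1.0
        n_aug = n_features + self.n_pool
        # feature standardization constants, set at fit time
        self.feature_mean = np.zeros(n_aug)
        self.feature_sd = np.ones(n_aug)
        self.raw_penalty = 0.0
        hidden_in = self.n_pool if self.pool_dims is not None else n_aug
        self.weights, self.biases = [], []
        widths = [hidden_in, *config.hidden_widths, 1]
        for i, (fan_in, fan_out) in enumerate(zip(widths[:-1], widths[1:])):
            last = i == len(widths) - 2
            # zero-init output layer: the untrained head predicts the target mean
            scale = 0.0 if last else fan_in**-0.5
            self.weights.append(
                Tensor(rng.normal(0.0, scale, size=(fan_in, fan_out)) if scale else
                       np.zeros((fan_in, fan_out)), requires_grad=True)
            )
            self.biases.append(Tensor(np.zeros(fan_out), requires_grad=True))
        self.skip = Tensor(np.zeros((n_aug, 1)), requires_grad=True)

    def parameters(self):
        return [*self.weights, *self.biases, self.skip]

    def _augment(self, x: Tensor) -> Tensor:
        """Prepend pooled channel means, then standardize all columns."""
        if self.pool_dims is not None:
            dn, dv, de = self.pool_dims
            n_h = dn * dn * de
            pooled_h = x[:, :n_h].reshape(-1, dn * dn, de).sum_axis(1) * (1.0 / (dn * dn))
            pooled_z = x[:, n_h:].reshape(-1, dn, dv).sum_axis(1) * (1.0 / dn)
            x = concat([pooled_h, pooled_z, x], axis=1)
        return (x - Tensor(self.feature_mean)) * Tensor(1.0 / self.feature_sd)

    def _forward(self, x: Tensor) -> Tensor:
        u = self._augment(x)
        h = u[:, : self.n_pool] if self.pool_dims is not None else u
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = tanh(matmul(h, w) + b)
        return matmul(h, self.weights[-1]) + self.biases[-1] + matmul(u, self.skip)

    def predict(self, x: np.ndarray) -> np.ndarray | float:
        """De-standardized GI50 prediction for (n, f) or a single (f,) vector."""
        single = np.ndim(x) == 1
        xa = np.atleast_2d(np.asarray(x, dtype=np.float64))
        out = self._forward(Tensor(xa)).data[:, 0]
        out = self.target_mean + self.target_sd * out
        return float(out[0]) if single else out

    def gradient(self, x: np.ndarray) -> np.ndarray:
        """Exact gradient of the de-standardized prediction w.r.t. the input."""
        xt = Tensor(np.asarray(x, dtype=np.float64)[None, :], requires_grad=True)
        self._forward(xt).sum().backward()
        return self.target_sd * xt.grad[0]

    def effective_linear_map(self) -> np.ndarray:
        """Gradient of the prediction at the training-feature mean.

        For a (near-)linear trained head this is the fitted linear map on
        the raw input coordinates.
        """
        return self.gradient(self.feature_mean[self.n_pool :])

    # -- training --------------------------------------------------------
    def _fit_run(self, X, y_std, raw_penalty, epochs, rng):
        cfg = self.config
        lr = cfg.learning_rate
        optimizer = Adam(self.parameters(), lr=lr, clip_norm=5.0)
        order = np.arange(len(X))
        for _ in range(epochs):
            rng.shuffle(order)
            for lo in range(0, len(X), cfg.batch_size):
                idx = order[lo : lo + cfg.batch_size]
                err = self._forward(Tensor(X[idx])) - Tensor(y_std[idx, None])
                loss = (err * err).mean()
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                # decoupled (AdamW-style) L2 shrinkage
                for w in self.weights:
                    w.data *= 1.0 - lr * cfg.hidden_decay
                self.skip.data[: self.n_pool] *= 1.0 - lr * cfg.skip_decay
                self.skip.data[self.n_pool :] *= 1.0 - lr * raw_penalty


def fit_regressor(X, y, config: RegressorConfig, rng,
                  pool_dims: tuple | None = None) -> GI50Regressor:
    """Train a head by MSE with Adam and decoupled L2 penalties.

    With ``pool_dims`` given, the raw-block penalty is selected from
    ``config.raw_penalty_grid`` on an internal validation split (each
    candidate trained at a third of the epoch budget), then the winner
    is refit on all data for the full budget.  Deterministic given
    ``rng``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or len(X) == 0 or len(X) != len(y):
        raise ValueError("X must be (n, f) with matching non-empty targets")
    target_mean = float(y.mean())
    sd = float(y.std())
    target_sd = sd if sd > 1e-12 else 1.0
    y_std = (y - target_mean) / target_sd

    probe = GI50Regressor(X.shape[1], config, np.random.default_rng(0), pool_dims)
    aug = probe._augment(Tensor(X)).data * probe.feature_sd + probe.feature_mean
    feature_mean = aug.mean(axis=0)
    feature_sd = aug.std(axis=0)
    feature_sd[feature_sd < 1e-8] = 1.0

    def make(seed):
        reg = GI50Regressor(X.shape[1], config, np.random.default_rng(seed), pool_dims)
        reg.target_mean, reg.target_sd = target_mean, target_sd
        reg.feature_mean, reg.feature_sd = feature_mean, feature_sd
        return reg

    init_seed = int(rng.integers(2**31 - 1))
    grid = tuple(config.raw_penalty_grid) if pool_dims is not None else (0.0,)
    best_penalty = grid[0]
    if len(grid) > 1 and len(X) >= 12:
        n_val = max(2, int(len(X) * config.val_fraction))
        perm = rng.permutation(len(X))
        val, trn = perm[:n_val], perm[n_val:]
        best = np.inf
        for penalty in grid:
            cand = make(init_seed)
            cand._fit_run(X[trn], y_std[trn], penalty,
                          max(20, config.epochs // 3), np.random.default_rng(init_seed + 1))
            v = float(np.mean((cand._forward(Tensor(X[val])).data[:, 0] - y_std[val]) ** 2))
            if v < best:
                best, best_penalty = v, penalty
    reg = make(init_seed)
    reg.raw_penalty = best_penalty
    reg._fit_run(X, y_std, best_penalty, config.epochs, np.random.default_rng(init_seed + 2))
    return reg


def encode_features(dataset, flow: FlowModel) -> np.ndarray:
    """Noise-free latent feature matrix of every dataset entry."""
    from .chemgraph import smiles_to_graph

    rows = []
    for smiles in dataset.smiles:
        graph = smiles_to_graph(smiles, flow.atom_vocab, flow.bond_vocab, flow.config.dn)
        latent, _, _ = flow.encode(graph, rng=None)
        rows.append(featurize_latent(latent))
    return np.asarray(rows)


def train_regressor(dataset, flow: FlowModel, config: RegressorConfig, rng) -> GI50Regressor:
    """Train the head on noise-free encodings of a curated dataset.

    The flow is frozen: its parameters are read, never updated.
    """
    if len(dataset) == 0:
        raise ValueError("dataset must be non-empty")
    X = encode_features(dataset, flow)
    cfg = flow.config
    return fit_regressor(X, dataset.gi50, config, rng,
                         pool_dims=(cfg.dn, cfg.dv, cfg.de))


def predict_gi50(obj, flow: FlowModel, regressor: GI50Regressor) -> float:
    """Predicted GI50 (original scale) of a MolGraph or LatentPair.

    Lower predicted value = higher predicted antitumoral efficacy.
    """
    from .chemgraph import MolGraph

    if isinstance(obj, MolGraph):
        latent, _, _ = flow.encode(obj, rng=None)
    elif isinstance(obj, LatentPair):
        latent = obj
    else:
        raise TypeError("expected MolGraph or LatentPair")
    return float(regressor.predict(featurize_latent(latent)))
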