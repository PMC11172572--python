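"""Two-stage normalizing flow over one-hot molecular graph tensors.

The generative model factorizes P(G) = P(E) * P(V | E): a *bond flow*
maps the (dequantized) edge tensor E to a latent H, and an *atom flow*,
conditioned on the discrete bonds, maps the node matrix V to a latent Z.
Both flows are stacks of affine coupling layers whose scale is a sigmoid
(not an exponential, for stability when stacking):

    y1 = x1,   y2 = x2 * sig(s(x1)) + t(x1),
    log|det J| = sum log sig(s(x1)) over the transformed entries.

Bond-coupling s,t nets are 2-D convolutions over the edge tensor;
atom-coupling s,t nets are MLPs on top of a relational message-passing
network that consumes the discrete bond channels.  Successive couplings
alternate which channel slab passes through unchanged so every dimension
gets transformed.  The latent priors are standard normals, so the exact
negative log-likelihood is the Gaussian energy minus the coupling
log-determinants.

Discrete one-hot tensors are lifted to the continuous domain by adding
uniform noise on [0, noise_scale) with noise_scale < 1, which leaves the
per-row / per-pair argmax — and hence the discrete graph — recoverable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Adam, Tensor, concat, conv2d, log_sigmoid, matmul, sigmoid, tanh
from .chemgraph import (
    AtomVocabulary,
    BondVocabulary,
    MolGraph,
    correct_validity,
    graph_from_index_form,
)
from .errors import ConfigError, UnderflowError

LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class CouplingSpec:
    """Shape of one coupling layer stack: channel split and net sizes."""

    split_index: int
    net_widths: tuple
    layer_count: int

    def validate(self, dim: int) -> None:
        if not 1 <= self.split_index < dim:
            raise ConfigError(f"split_index must be in [1, {dim})")
        if self.layer_count < 0:
            raise ConfigError("layer_count must be >= 0")


@dataclass(frozen=True)
class FlowConfig:
    """Architecture and dequantization settings of the two flows."""

    dn: int
    dv: int
    de: int
    bond_layers: int = 2
    atom_layers: int = 2
    bond_split: int = 0  # 0 -> de // 2
    atom_split: int = 0  # 0 -> dv // 2
    conv_width: int = 16
    conv_kernel: int = 3
    gnn_width: int = 16
    gnn_rounds: int = 2
    mlp_width: int = 16
    noise_scale: float = 0.6

    def __post_init__(self):
        object.__setattr__(self, "bond_split", self.bond_split or self.de // 2)
        object.__setattr__(self, "atom_split", self.atom_split or self.dv // 2)
        if not 0.0 < self.noise_scale < 1.0:
            raise ConfigError("noise_scale must lie in (0, 1)")
        self.bond_coupling_spec().validate(self.de)
        self.atom_coupling_spec().validate(self.dv)

    def bond_coupling_spec(self) -> CouplingSpec:
        return CouplingSpec(self.bond_split, (self.conv_width,), self.bond_layers)

    def atom_coupling_spec(self) -> CouplingSpec:
        return CouplingSpec(
            self.atom_split, (self.gnn_width, self.mlp_width), self.atom_layers
        )

    @classmethod
    def full_scale(cls, dn, dv, de, **overrides):
        """Depths/widths for training on a full curated screening set."""
        kw = dict(
            bond_layers=10, atom_layers=10, conv_width=128,
            gnn_width=128, mlp_width=64,
        )
        kw.update(overrides)
        return cls(dn=dn, dv=dv, de=de, **kw)

    @property
    def latent_dim(self) -> int:
        return self.dn * self.dn * self.de + self.dn * self.dv


@dataclass
class LatentPair:
    """Bond latent H (dn, dn, de) and atom latent Z (dn, dv)."""

    H: np.ndarray
    Z: np.ndarray

    def __post_init__(self):
        self.H = np.asarray(self.H, dtype=np.float64)
        self.Z = np.asarray(self.Z, dtype=np.float64)
        if not (np.isfinite(self.H).all() and np.isfinite(self.Z).all()):
            raise ValueError("latent entries must be finite")


def _param(rng, shape, scale):
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


def _zeros(shape):
    return Tensor(np.zeros(shape), requires_grad=True)


class _BondCoupling:
    """Affine coupling over edge-tensor channels with 2-D conv s,t nets.

    The final (1x1) conv is zero-initialized so a fresh layer starts as
    y2 = 0.5 * x2, t = 0 — the analytic reference used by the tests.
    """

    def __init__(self, de, split, flip, width, kernel, rng):
        self.split, self.flip = split, flip
        self.in_ch = (de - split) if flip else split
        self.out_ch = split if flip else (de - split)
        k = kernel
        self.w1 = _param(rng, (width, self.in_ch, k, k), (self.in_ch * k * k) ** -0.5)
        self.b1 = _zeros((width,))
        self.w2 = _zeros((2 * self.out_ch, width, 1, 1))
        self.b2 = _zeros((2 * self.out_ch,))

    def parameters(self):
        return [self.w1, self.b1, self.w2, self.b2]

    def _split(self, x):
        if self.flip:
            return x[self.split :], x[: self.split]
        return x[: self.split], x[self.split :]

    def _join(self, a, b):
        parts = [b, a] if self.flip else [a, b]
        return concat(parts, axis=0)

    def _nets(self, a):
        h = tanh(conv2d(a, self.w1, self.b1))
        o = conv2d(h, self.w2, self.b2)
        return o[: self.out_ch], o[self.out_ch :]

    def forward(self, x):
        a, b = self._split(x)
        s, t = self._nets(a)
        y_b = b * sigmoid(s) + t
        return self._join(a, y_b), log_sigmoid(s).sum()

    def inverse(self, y):
        a, y_b = self._split(y)
        s, t = self._nets(a)
        sig = sigmoid(s)
        if float(sig.data.min()) < 1e-30:
            raise UnderflowError("sigmoid scale underflowed in coupling inverse")
        return self._join(a, (y_b - t) / sig)


class _AtomCoupling:
    """Affine coupling over node-type channels.

    The s,t nets are MLPs fed by a relational message-passing network:
    node states are updated for a fixed number of rounds by a self map
    plus, per discrete bond channel, a relation-specific map aggregated
    over neighbours (sum aggregation).  Final layer zero-initialized.
    """

    def __init__(self, dv, n_rel, split, flip, gnn_width, rounds, mlp_width, rng):
        self.split, self.flip = split, flip
        self.in_f = (dv - split) if flip else split
        self.out_f = split if flip else (dv - split)
        g = gnn_width
        self.w_embed = _param(rng, (self.in_f, g), self.in_f**-0.5)
        self.b_embed = _zeros((g,))
        self.rounds = []
        for _ in range(rounds):
            self.rounds.append(
                {
                    "self": _param(rng, (g, g), g**-0.5),
                    "rel": [_param(rng, (g, g), (g * n_rel) ** -0.5) for _ in range(n_rel)],
                    "bias": _zeros((g,)),
                }
            )
        self.w_h = _param(rng, (g, mlp_width), g**-0.5)
        self.b_h = _zeros((mlp_width,))
        self.w_out = _zeros((mlp_width, 2 * self.out_f))
        self.b_out = _zeros((2 * self.out_f,))

    def parameters(self):
        ps = [self.w_embed, self.b_embed, self.w_h, self.b_h, self.w_out, self.b_out]
        for r in self.rounds:
            ps.extend([r["self"], r["bias"], *r["rel"]])
        return ps

    def _split(self, x):
        if self.flip:
            return x[:, self.split :], x[:, : self.split]
        return x[:, : self.split], x[:, self.split :]

    def _join(self, a, b):
        parts = [b, a] if self.flip else [a, b]
        return concat(parts, axis=1)

    def _nets(self, a, adjacency):
        h = tanh(matmul(a, self.w_embed) + self.b_embed)
        for r in self.rounds:
            m = matmul(h, r["self"]) + r["bias"]
            for rel_w, adj in zip(r["rel"], adjacency):
                m = m + matmul(adj, matmul(h, rel_w))
            h = tanh(m)
        o = matmul(tanh(matmul(h, self.w_h) + self.b_h), self.w_out) + self.b_out
        return o[:, : self.out_f], o[:, self.out_f :]

    def forward(self, x, adjacency):
        a, b = self._split(x)
        s, t = self._nets(a, adjacency)
        y_b = b * sigmoid(s) + t
        return self._join(a, y_b), log_sigmoid(s).sum()

    def inverse(self, y, adjacency):
        a, y_b = self._split(y)
        s, t = self._nets(a, adjacency)
        sig = sigmoid(s)
        if float(sig.data.min()) < 1e-30:
            raise UnderflowError("sigmoid scale underflowed in coupling inverse")
        return self._join(a, (y_b - t) / sig)


class FlowModel:
    """The invertible generative model over molecular graphs."""

    def __init__(self, config: FlowConfig, atom_vocab: AtomVocabulary,
                 bond_vocab: BondVocabulary, seed: int = 0):
        if config.dv != atom_vocab.dv or config.de != bond_vocab.de:
            raise ConfigError("config dims do not match vocabularies")
        self.config = config
        self.atom_vocab = atom_vocab
        self.bond_vocab = bond_vocab
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.bond_couplings = [
            _BondCoupling(config.de, config.bond_split, i % 2 == 1,
                          config.conv_width, config.conv_kernel, rng)
            for i in range(config.bond_layers)
        ]
        n_rel = bond_vocab.de - 1  # real bond channels condition the atom flow
        self.atom_couplings = [
            _AtomCoupling(config.dv, n_rel, config.atom_split, i % 2 == 1,
                          config.gnn_width, config.gnn_rounds, config.mlp_width, rng)
            for i in range(config.atom_layers)
        ]

    # -- parameters ------------------------------------------------------
    def parameters(self):
        ps = []
        for layer in self.bond_couplings + self.atom_couplings:
            ps.extend(layer.parameters())
        return ps

    def randomize_parameters(self, rng, scale=0.3):
        """Overwrite all parameters with small random values (test/demo use)."""
        for p in self.parameters():
            p.data = rng.normal(0.0, scale, size=p.data.shape)

    # -- flow passes (channel-first Tensors) ------------------------------
    def forward_bond(self, e_t):
        total = Tensor(0.0)
        for layer in self.bond_couplings:
            e_t, ld = layer.forward(e_t)
            total = total + ld
        return e_t, total

    def inverse_bond(self, h_t):
        for layer in reversed(self.bond_couplings):
            h_t = layer.inverse(h_t)
        return h_t

    def forward_atom(self, v_t, adjacency):
        total = Tensor(0.0)
        for layer in self.atom_couplings:
            v_t, ld = layer.forward(v_t, adjacency)
            total = total + ld
        return v_t, total

    def inverse_atom(self, z_t, adjacency):
        for layer in reversed(self.atom_couplings):
            z_t = layer.inverse(z_t, adjacency)
        return z_t

    def _adjacency(self, e_discrete: np.ndarray):
        return [
            Tensor(e_discrete[:, :, c].astype(np.float64))
            for c in range(self.bond_vocab.de - 1)
        ]

    # -- public operations -------------------------------------------------
    def encode(self, graph: MolGraph, rng=None):
        """Map a graph to its latents; returns (LatentPair, logdet_E, logdet_V).

        With ``rng`` given the tensors are dequantized first; ``rng=None``
        encodes noise-free (deterministic, used for seeds and the head).
        """
        if rng is None:
            v_c = graph.V.astype(np.float64)
            e_c = graph.E.astype(np.float64)
        else:
            v_c, e_c = dequantize(graph, self.config.noise_scale, rng)
        h_t, ld_e = self.forward_bond(Tensor(e_c.transpose(2, 0, 1)))
        adjacency = self._adjacency(graph.E)
        z_t, ld_v = self.forward_atom(Tensor(v_c), adjacency)
        latent = LatentPair(h_t.data.transpose(1, 2, 0).copy(), z_t.data.copy())
        return latent, float(ld_e.data), float(ld_v.data)

    def decode(self, latent: LatentPair) -> MolGraph:
        """Invert the flows and discretize by argmax; always returns a valid graph.

        The continuous edge tensor is symmetrized (channel-wise average of
        E[i,j,:] and E[j,i,:]) before the per-pair argmax; the atom flow is
        inverted conditioned on the resulting discrete bonds; finally
        :func:`correct_validity` repairs any chemical violations.
        """
        cfg = self.config
        nb = self.bond_vocab.no_bond_index
        e_c = self.inverse_bond(Tensor(latent.H.transpose(2, 0, 1))).data
        e_sym = 0.5 * (e_c + e_c.transpose(0, 2, 1))
        channels = e_sym.argmax(axis=0)
        np.fill_diagonal(channels, nb)
        e_disc = np.zeros((cfg.dn, cfg.dn, cfg.de), dtype=np.int8)
        e_disc[np.arange(cfg.dn)[:, None], np.arange(cfg.dn)[None, :], channels] = 1
        v_c = self.inverse_atom(Tensor(latent.Z), self._adjacency(e_disc)).data
        types = v_c.argmax(axis=1)
        orders = np.zeros((cfg.dn, cfg.dn), dtype=int)
        for k, order in enumerate(self.bond_vocab.bond_orders):
            orders[channels == k] = order
        pad = types == self.atom_vocab.pad_index
        orders[pad, :] = 0
        orders[:, pad] = 0
        graph = graph_from_index_form(types, orders, cfg.dn, self.atom_vocab, self.bond_vocab)
        return correct_validity(graph, self.atom_vocab, self.bond_vocab)

    def latent_nll(self, latent: LatentPair, logdet_e=0.0, logdet_v=0.0) -> float:
        """Exact NLL (nats) of one latent under the standard-normal priors."""
        d = latent.H.size + latent.Z.size
        energy = 0.5 * float((latent.H**2).sum() + (latent.Z**2).sum())
        return energy + 0.5 * d * LOG_2PI - logdet_e - logdet_v

    def _nll_tensor(self, graphs, rng):
        if not graphs:
            raise ValueError("batch must be non-empty")
        total = Tensor(0.0)
        for graph in graphs:
            if rng is None:
                v_c = graph.V.astype(np.float64)
                e_c = graph.E.astype(np.float64)
            else:
                v_c, e_c = dequantize(graph, self.config.noise_scale, rng)
            h_t, ld_e = self.forward_bond(Tensor(e_c.transpose(2, 0, 1)))
            z_t, ld_v = self.forward_atom(Tensor(v_c), self._adjacency(graph.E))
            energy = (h_t * h_t).sum() * 0.5 + (z_t * z_t).sum() * 0.5
            total = total + energy - ld_e - ld_v
        const = 0.5 * self.config.latent_dim * LOG_2PI
        return total * (1.0 / len(graphs)) + Tensor(const)

    def nll(self, graphs, rng=None) -> float:
        """Mean negative log-likelihood (nats) of a batch of graphs."""
        return self._nll_tensor(list(graphs), rng).item()

    def sample_prior(self, count: int, temperature: float = 1.0, rng=None):
        """i.i.d. standard-normal latent draws scaled by ``temperature``."""
        if count < 1:
            raise ValueError("count must be >= 1")
        if temperature <= 0:
            raise ValueError("temperature must be > 0")
        rng = rng if rng is not None else np.random.default_rng()
        cfg = self.config
        return [
            LatentPair(
                temperature * rng.standard_normal((cfg.dn, cfg.dn, cfg.de)),
                temperature * rng.standard_normal((cfg.dn, cfg.dv)),
            )
            for _ in range(count)
        ]


def dequantize(graph: MolGraph, noise_scale: float, rng):
    """Add uniform [0, noise_scale) noise to the one-hot tensors.

    noise_scale < 1 guarantees the per-row / per-pair argmax still
    recovers the original discrete object (1 + 0 > 0 + noise).
    """
    if not 0.0 < noise_scale < 1.0:
        raise ConfigError("noise_scale must lie in (0, 1)")
    v_c = graph.V + rng.uniform(0.0, noise_scale, size=graph.V.shape)
    e_c = graph.E + rng.uniform(0.0, noise_scale, size=graph.E.shape)
    return v_c, e_c


def train_flow(model: FlowModel, graphs, epochs=30, batch_size=10,
               learning_rate=1e-3, clip_norm=5.0, rng=None):
    """Adam training of the exact NLL; returns per-epoch mean training NLL."""
    rng = rng if rng is not None else np.random.default_rng(0)
    optimizer = Adam(model.parameters(), lr=learning_rate, clip_norm=clip_norm)
    graphs = list(graphs)
    order = np.arange(len(graphs))
    history = []
    for _ in range(epochs):
        rng.shuffle(order)
        losses = []
        for lo in range(0, len(graphs), batch_size):
            batch = [graphs[i] for i in order[lo : lo + batch_size]]
            loss = model._nll_tensor(batch, rng)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
    return history


def evaluate_nll(model: FlowModel, graphs, seed: int = 0) -> float:
    """NLL on a fixed dequantization-noise draw (comparable across calls)."""
    return model.nll(graphs, np.random.default_rng(seed))
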