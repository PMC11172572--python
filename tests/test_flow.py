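"""Invertible flow core: dequantization, couplings, likelihood, decode."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latentmol import AtomVocabulary, BondVocabulary, FlowConfig, FlowModel, LatentPair, dequantize
from latentmol._autodiff import Tensor
from latentmol.chemgraph import graph_from_index_form
from latentmol.errors import ConfigError, UnderflowError
from latentmol.flow import LOG_2PI
from latentmol.head import featurize_latent

DN = 9


def small_model(seed=0, bond_layers=2, atom_layers=2, dn=3):
    av = AtomVocabulary(("C", "N", "O"))
    bv = BondVocabulary()
    cfg = FlowConfig(dn=dn, dv=av.dv, de=bv.de, conv_width=6, gnn_width=6, mlp_width=6,
                     bond_layers=bond_layers, atom_layers=atom_layers)
    return FlowModel(cfg, av, bv, seed=seed)


class TestDequantize:
    def test_argmax_preserved(self, fixture_graphs, rng):
        g = fixture_graphs[0]
        v_c, e_c = dequantize(g, 0.6, rng)
        assert (v_c.argmax(axis=1) == g.V.argmax(axis=1)).all()
        assert (e_c.argmax(axis=2) == g.E.argmax(axis=2)).all()
        assert ((v_c - g.V) >= 0).all() and ((v_c - g.V) < 0.6).all()

    def test_noise_scale_validation(self, fixture_graphs, rng):
        for bad in (0.0, 1.0, -0.3, 1.7):
            with pytest.raises(ConfigError):
                dequantize(fixture_graphs[0], bad, rng)

    def test_same_seed_same_noise(self, fixture_graphs):
        g = fixture_graphs[0]
        a = dequantize(g, 0.6, np.random.default_rng(5))
        b = dequantize(g, 0.6, np.random.default_rng(5))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20)
    def test_argmax_preserved_for_random_noise(self, fixture_graphs, seed):
        g = fixture_graphs[1]
        v_c, e_c = dequantize(g, 0.999, np.random.default_rng(seed))
        assert (v_c.argmax(axis=1) == g.V.argmax(axis=1)).all()
        assert (e_c.argmax(axis=2) == g.E.argmax(axis=2)).all()


class TestCouplings:
    def test_zero_initialized_flow_halves_inputs_with_analytic_logdet(self, toy_flow, fixture_graphs):
        g = fixture_graphs[0]
        latent, ld_e, ld_v = toy_flow.encode(g, rng=None)
        np.testing.assert_allclose(latent.H, 0.5 * g.E, atol=1e-12)
        np.testing.assert_allclose(latent.Z, 0.5 * g.V, atol=1e-12)
        cfg = toy_flow.config
        m_e = DN * DN * cfg.de  # alternating slabs: each channel transformed once over 2 layers
        m_v = DN * cfg.dv
        assert ld_e == pytest.approx(m_e * math.log(0.5), rel=1e-12)
        assert ld_v == pytest.approx(m_v * math.log(0.5), rel=1e-12)

    def test_extra_zero_init_layer_shifts_logdet_by_analytic_offset(self):
        av, bv = AtomVocabulary(("C", "N", "O")), BondVocabulary()
        g = graph_from_index_form([0, 1, 2], np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]]),
                                  3, av, bv)
        two = small_model(bond_layers=2, atom_layers=2)
        three = small_model(bond_layers=3, atom_layers=2)
        _, ld2, _ = two.encode(g, rng=None)
        _, ld3, _ = three.encode(g, rng=None)
        m_third_layer = 3 * 3 * (three.config.de - three.config.bond_split)
        assert ld3 - ld2 == pytest.approx(m_third_layer * math.log(0.5), rel=1e-12)

    def test_inverse_forward_identity_random_tensors(self):
        model = small_model(dn=4)
        rng = np.random.default_rng(2)
        model.randomize_parameters(rng, scale=0.4)
        cfg = model.config
        adj = [Tensor(np.zeros((4, 4))) for _ in range(cfg.de - 1)]
        for _ in range(10):
            e = rng.normal(size=(cfg.de, 4, 4))
            v = rng.normal(size=(4, cfg.dv))
            h, _ = model.forward_bond(Tensor(e))
            back = model.inverse_bond(Tensor(h.data))
            assert np.abs(back.data - e).max() < 1e-5
            z, _ = model.forward_atom(Tensor(v), adj)
            back_v = model.inverse_atom(Tensor(z.data), adj)
            assert np.abs(back_v.data - v).max() < 1e-5

    def test_logdet_matches_finite_difference_jacobian(self):
        model = small_model(dn=2, bond_layers=1, atom_layers=1)
        rng = np.random.default_rng(3)
        model.randomize_parameters(rng, scale=0.4)
        cfg = model.config

        x0 = rng.normal(size=(cfg.de, 2, 2))
        _, ld = model.forward_bond(Tensor(x0))
        jac = np.zeros((x0.size, x0.size))
        h = 1e-5
        for k in range(x0.size):
            e = np.zeros_like(x0)
            e.ravel()[k] = h
            up, _ = model.forward_bond(Tensor(x0 + e))
            dn_, _ = model.forward_bond(Tensor(x0 - e))
            jac[:, k] = (up.data - dn_.data).ravel() / (2 * h)
        _, fd_ld = np.linalg.slogdet(jac)
        assert abs(ld.item() - fd_ld) / abs(fd_ld) < 1e-3

        adj_np = np.zeros((2, 2, cfg.de), dtype=np.int8)
        adj_np[0, 1, 0] = adj_np[1, 0, 0] = 1
        adj = model._adjacency(adj_np)
        v0 = rng.normal(size=(2, cfg.dv))
        _, ld_v = model.forward_atom(Tensor(v0), adj)
        jac = np.zeros((v0.size, v0.size))
        for k in range(v0.size):
            e = np.zeros_like(v0)
            e.ravel()[k] = h
            up, _ = model.forward_atom(Tensor(v0 + e), adj)
            dn_, _ = model.forward_atom(Tensor(v0 - e), adj)
            jac[:, k] = (up.data - dn_.data).ravel() / (2 * h)
        _, fd_ld = np.linalg.slogdet(jac)
        assert abs(ld_v.item() - fd_ld) / abs(fd_ld) < 1e-3

    def test_inverse_reports_sigmoid_underflow(self):
        model = small_model()
        # drive the scale net output hugely negative: sigmoid underflows to 0
        layer = model.bond_couplings[0]
        layer.b2.data[: layer.out_ch] = -800.0
        with pytest.raises(UnderflowError):
            model.inverse_bond(Tensor(np.zeros((model.config.de, 3, 3))))


class TestLikelihood:
    def test_zero_latent_identity_flow_nll_is_gaussian_entropy_term(self):
        model = small_model(bond_layers=0, atom_layers=0, dn=3)
        cfg = model.config
        latent = LatentPair(np.zeros((3, 3, cfg.de)), np.zeros((3, cfg.dv)))
        d = cfg.latent_dim
        assert model.latent_nll(latent) == pytest.approx(0.5 * d * LOG_2PI, abs=1e-9)

    def test_identity_flow_encodes_inputs_unchanged(self, fixture_graphs):
        av, bv = AtomVocabulary(), BondVocabulary()
        model = FlowModel(FlowConfig(dn=DN, dv=av.dv, de=bv.de,
                                     bond_layers=0, atom_layers=0), av, bv)
        g = fixture_graphs[0]
        latent, ld_e, ld_v = model.encode(g, rng=None)
        assert ld_e == 0.0 and ld_v == 0.0
        np.testing.assert_array_equal(latent.H, g.E)
        np.testing.assert_array_equal(latent.Z, g.V)

    def test_nll_invariant_to_batch_order(self, toy_flow, fixture_graphs):
        a = toy_flow.nll(fixture_graphs[:4], rng=None)
        b = toy_flow.nll(list(reversed(fixture_graphs[:4])), rng=None)
        assert a == pytest.approx(b, rel=1e-12)

    def test_empty_batch_rejected(self, toy_flow):
        with pytest.raises(ValueError):
            toy_flow.nll([], rng=None)


class TestSampling:
    def test_seeded_determinism(self, toy_flow):
        a = toy_flow.sample_prior(3, 0.7, np.random.default_rng(9))
        b = toy_flow.sample_prior(3, 0.7, np.random.default_rng(9))
        for s, t in zip(a, b):
            assert np.array_equal(s.H, t.H) and np.array_equal(s.Z, t.Z)

    def test_temperature_scales_to_zero_limit(self, toy_flow):
        (s,) = toy_flow.sample_prior(1, 1e-12, np.random.default_rng(0))
        assert np.abs(s.H).max() < 1e-10 and np.abs(s.Z).max() < 1e-10
        with pytest.raises(ValueError):
            toy_flow.sample_prior(1, 0.0, np.random.default_rng(0))
        with pytest.raises(ValueError):
            toy_flow.sample_prior(0, 1.0, np.random.default_rng(0))

    def test_sample_mean_within_clt_bound(self, toy_flow):
        samples = toy_flow.sample_prior(300, 1.0, np.random.default_rng(11))
        draws = np.concatenate([featurize_latent(s) for s in samples])
        n = draws.size
        assert n >= 1e5
        assert abs(draws.mean()) < 4.0 / math.sqrt(n)


class TestDecode:
    def test_noise_free_roundtrip_on_fixtures(self, toy_flow, fixture_graphs):
        for g in fixture_graphs:
            latent, _, _ = toy_flow.encode(g, rng=None)
            back = toy_flow.decode(latent)
            assert np.array_equal(back.V, g.V) and np.array_equal(back.E, g.E)

    def test_prior_samples_decode_to_valid_graphs(self, toy_flow):
        for latent in toy_flow.sample_prior(10, 0.7, np.random.default_rng(21)):
            g = toy_flow.decode(latent)
            g.validate(toy_flow.atom_vocab, toy_flow.bond_vocab)

    def test_asymmetric_latent_still_decodes_symmetric_bonds(self, toy_flow, fixture_graphs):
        latent, _, _ = toy_flow.encode(fixture_graphs[0], rng=None)
        latent.H[0, 1, :] += 0.37  # break H symmetry on purpose
        g = toy_flow.decode(latent)
        assert (g.E == g.E.transpose(1, 0, 2)).all()
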