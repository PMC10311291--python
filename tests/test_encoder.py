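"""Encoder: message/attention/GRU primitives vs scalar oracles; ablation contracts."""

import numpy as np
import pytest

from slkg import autodiff as ad
from slkg.autodiff import Tensor
from slkg.digraph import build_union_digraph
from slkg.encoder import (
    EncoderError,
    ModelParameters,
    TextEmbeddingTable,
    encode,
)
from slkg.reference import encode_reference


def make_params(K=3, d=4, n_rel=6, d_text=None, seed=0) -> ModelParameters:
    return ModelParameters(K, d, n_rel, d_text, seed=seed)


# -- message construction ------------------------------------------------


def test_message_zero_inputs_identity_w1():
    p = make_params(K=1, d=3, n_rel=2)
    p.tensors["W1_1"].data = np.eye(3)
    p.tensors["rel_emb_1"].data = np.zeros((2, 3))
    h = Tensor(np.zeros((1, 3)))
    msg = (h + ad.gather_rows(p["rel_emb_1"], [0])) @ p["W1_1"]
    assert np.allclose(msg.data, 0.0)


def test_message_structure_only_sum():
    # h_src = rel_emb = e1, W1 = I -> message 2*e1 (structure-only form)
    p = make_params(K=1, d=3, n_rel=1)
    p.tensors["W1_1"].data = np.eye(3)
    p.tensors["rel_emb_1"].data = np.array([[1.0, 0.0, 0.0]])
    h = Tensor(np.array([[1.0, 0.0, 0.0]]))
    msg = (h + ad.gather_rows(p["rel_emb_1"], [0])) @ p["W1_1"]
    assert np.allclose(msg.data, [[2.0, 0.0, 0.0]])


# -- attention gate ------------------------------------------------------


def test_attention_zero_message_is_half():
    p = make_params(K=1, d=4, n_rel=1)
    msg = Tensor(np.zeros((3, 4)))
    alpha = ad.sigmoid(ad.relu(msg @ p["Watt2_1"]) @ p["watt1_1"])
    assert np.allclose(alpha.data, 0.5)


def test_attention_zero_watt2_is_half_everywhere():
    p = make_params(K=1, d=4, n_rel=1)
    p.tensors["Watt2_1"].data = np.zeros((4, 4))
    msg = Tensor(np.random.default_rng(0).standard_normal((5, 4)))
    alpha = ad.sigmoid(ad.relu(msg @ p["Watt2_1"]) @ p["watt1_1"])
    assert np.allclose(alpha.data, 0.5)


def test_attention_in_open_interval(random_graph_factory):
    g = random_graph_factory(np.random.default_rng(0), n_nodes=15, n_edges=30)
    p = make_params(K=3, d=6, n_rel=g.n_relations)
    dg = build_union_digraph(g, 0, 3)
    res = encode(dg, p, None)
    for alpha in res.alphas:
        assert np.all((alpha > 0.0) & (alpha < 1.0))


# -- GRU update ----------------------------------------------------------


def test_gru_all_zero_weights_carries_half():
    """Zero weights: f = 0.5, n = sigmoid(0) = 0.5, h = 0.5*0.5 + 0.5*h_prev."""
    d = 3
    p = make_params(K=1, d=d, n_rel=1)
    for name in ("Wr", "Ur", "Wf", "Uf", "Wn", "Un"):
        p.tensors[f"{name}_1"].data = np.zeros((d, d))
    z = Tensor(np.zeros((1, d)))
    hp = Tensor(np.full((1, d), 0.8))
    r = ad.sigmoid(z @ p["Wr_1"] + hp @ p["Ur_1"] + p["br_1"])
    f = ad.sigmoid(z @ p["Wf_1"] + hp @ p["Uf_1"] + p["bf_1"])
    n = ad.sigmoid(z @ p["Wn_1"] + r * (hp @ p["Un_1"]) + p["bn_1"])
    h = (1.0 - f) * n + f * hp
    assert np.allclose(h.data, 0.5 * 0.5 + 0.5 * 0.8)


def test_gru_forget_limit_carries_previous_state():
    d = 3
    p = make_params(K=1, d=d, n_rel=1)
    for name in ("Wr", "Ur", "Wf", "Uf", "Wn", "Un"):
        p.tensors[f"{name}_1"].data = np.zeros((d, d))
    p.tensors["bf_1"].data = np.full(d, 50.0)  # f -> 1: pure carry
    z = Tensor(np.ones((1, d)))
    hp = Tensor(np.zeros((1, d)))
    f = ad.sigmoid(z @ p["Wf_1"] + hp @ p["Uf_1"] + p["bf_1"])
    n = ad.sigmoid(z @ p["Wn_1"] + f * (hp @ p["Un_1"]) + p["bn_1"])
    h = (1.0 - f) * n + f * hp
    assert np.allclose(h.data, 0.0, atol=1e-12)


# -- end-to-end oracle equivalence --------------------------------------


@pytest.mark.parametrize("use_text,use_attention,use_gru", [
    (False, True, True),
    (True, True, True),
    (False, False, True),
    (False, True, False),
    (True, False, False),
])
def test_encode_matches_scalar_reference(random_graph_factory, use_text,
                                         use_attention, use_gru):
    rng = np.random.default_rng(17)
    g = random_graph_factory(rng, n_nodes=14, n_edges=25, n_relations=3)
    texts = TextEmbeddingTable.synthetic(len(g.entities), d_text=5, seed=3)
    p = make_params(K=3, d=6, n_rel=g.n_relations, d_text=5, seed=1)
    dg = build_union_digraph(g, 2, 3)
    res = encode(dg, p, texts, use_text=use_text, use_attention=use_attention,
                 use_gru=use_gru)
    ref = encode_reference(dg, p, texts, use_text=use_text,
                           use_attention=use_attention, use_gru=use_gru)
    assert set(ref) == set(int(e) for e in res.frontier)
    for i, e in enumerate(res.frontier):
        assert np.allclose(res.h.data[i], ref[int(e)], atol=1e-10)


def test_encode_chain_fixture_matches_reference(chain_graph):
    g = chain_graph
    p = make_params(K=3, d=4, n_rel=g.n_relations, seed=5)
    q = g.entities.index_of("q")
    dg = build_union_digraph(g, q, 3)
    res = encode(dg, p, None)
    ref = encode_reference(dg, p, None)
    for i, e in enumerate(res.frontier):
        assert np.allclose(res.h.data[i], ref[int(e)], atol=1e-12)


def test_encode_isolated_source_defined_only_for_source():
    from slkg.graph import EntityTable, augment, build_graph

    entities = EntityTable.from_records([("q", "Gene", ""), ("z", "Gene", "")])
    g = augment(build_graph([("z", "r", "z")], entities))
    q = g.entities.index_of("q")
    p = make_params(K=3, d=4, n_rel=g.n_relations)
    res = encode(build_union_digraph(g, q, 3), p, None)
    assert res.frontier.tolist() == [q]
    assert res.h.data.shape == (1, 4)


def test_no_gru_variant_outputs_z(random_graph_factory):
    """With the recurrent update removed the layer output is exactly z."""
    rng = np.random.default_rng(8)
    g = random_graph_factory(rng, n_nodes=12, n_edges=20)
    p = make_params(K=2, d=5, n_rel=g.n_relations, seed=2)
    dg = build_union_digraph(g, 1, 2)
    res = encode(dg, p, None, use_gru=False)
    ref = encode_reference(dg, p, None, use_gru=False)
    for i, e in enumerate(res.frontier):
        assert np.allclose(res.h.data[i], ref[int(e)], atol=1e-12)
    # and differs from the GRU path
    res_gru = encode(dg, p, None, use_gru=True)
    assert not np.allclose(res.h.data, res_gru.h.data)


def test_no_att_variant_changes_output(random_graph_factory):
    g = random_graph_factory(np.random.default_rng(9), n_nodes=12, n_edges=20)
    p = make_params(K=2, d=5, n_rel=g.n_relations, seed=3)
    dg = build_union_digraph(g, 0, 2)
    with_att = encode(dg, p, None, use_attention=True)
    without = encode(dg, p, None, use_attention=False)
    assert np.allclose(without.alphas[0], 1.0)
    assert not np.allclose(with_att.h.data, without.h.data)


def test_text_absent_equals_structure_only(random_graph_factory):
    """No text table => bit-identical to the structure-only message form."""
    g = random_graph_factory(np.random.default_rng(10), n_nodes=12, n_edges=20)
    texts = TextEmbeddingTable.synthetic(len(g.entities), d_text=4, seed=1)
    p = make_params(K=2, d=5, n_rel=g.n_relations, d_text=4, seed=4)
    dg = build_union_digraph(g, 0, 2)
    no_table = encode(dg, p, None)
    flag_off = encode(dg, p, texts, use_text=False)
    assert np.array_equal(no_table.h.data, flag_off.h.data)


def test_missing_text_vector_hard_error(random_graph_factory):
    g = random_graph_factory(np.random.default_rng(11), n_nodes=12, n_edges=20)
    short = TextEmbeddingTable(np.zeros((3, 4)), provenance="pretrained")
    p = make_params(K=2, d=5, n_rel=g.n_relations, d_text=4)
    dg = build_union_digraph(g, 0, 2)
    with pytest.raises(EncoderError, match="missing vectors"):
        encode(dg, p, short)


def test_layer_count_mismatch_rejected(random_graph_factory):
    g = random_graph_factory(np.random.default_rng(12))
    p = make_params(K=2, d=4, n_rel=g.n_relations)
    dg = build_union_digraph(g, 0, 3)
    with pytest.raises(EncoderError, match="K="):
        encode(dg, p, None)


def test_target_locality_edge_knockout(random_graph_factory):
    """A target's representation depends only on its own in-edges."""
    rng = np.random.default_rng(20)
    g = random_graph_factory(rng, n_nodes=12, n_edges=18)
    p = make_params(K=2, d=5, n_rel=g.n_relations, seed=6)
    dg = build_union_digraph(g, 0, 2)
    res = encode(dg, p, None)
    # knock out one final-layer edge; only its destination may change
    layer = dg.layers[-1]
    kill = 0
    keep = np.arange(layer.n_edges) != kill
    from slkg.digraph import Layer, LayeredDigraph

    dg2 = LayeredDigraph(
        source=dg.source, K=dg.K,
        frontiers=list(dg.frontiers),
        layers=[dg.layers[0],
                Layer(layer.src[keep], layer.rel[keep], layer.dst[keep],
                      layer.src_pos[keep], layer.dst_pos[keep])],
    )
    res2 = encode(dg2, p, None)
    victim = int(layer.dst[kill])
    for i, e in enumerate(res.frontier):
        if int(e) == victim:
            continue
        assert np.allclose(res.h.data[i], res2.h.data[i], atol=1e-12)


def test_dropout_only_when_training(random_graph_factory):
    g = random_graph_factory(np.random.default_rng(13))
    p = make_params(K=2, d=5, n_rel=g.n_relations, seed=7)
    dg = build_union_digraph(g, 0, 2)
    a = encode(dg, p, None, training=False, dropout=0.5)
    b = encode(dg, p, None, training=False, dropout=0.5)
    assert np.array_equal(a.h.data, b.h.data)
    rng = np.random.default_rng(0)
    c = encode(dg, p, None, training=True, dropout=0.5, rng=rng)
    assert not np.array_equal(a.h.data, c.h.data)


def test_parameter_checkpoint_roundtrip(tmp_path):
    p = make_params(K=2, d=5, n_rel=3, d_text=4, seed=9)
    path = tmp_path / "w.npz"
    p.save(path)
    q = ModelParameters.load(path)
    assert q.K == 2 and q.d == 5 and q.d_text == 4
    for name, t in p.tensors.items():
        assert np.array_equal(t.data, q.tensors[name].data)
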