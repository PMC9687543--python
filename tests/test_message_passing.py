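import numpy as np
import pytest

from emphcn.message_passing import (
    AttentionHeadParams,
    EdgeNodeWeights,
    EmbeddingState,
    ProteinBranchParams,
    drop_edges,
    edge_to_node_features,
    gat_attention_coefficients,
    gat_project,
    neegcn_pass,
    protein_message_round,
)


def _oracle_neegcn(a, x_r, x_d, e_r, e_d, w_d2r, w_r2d):
    """Literal quadruple-loop transcription of the bipartite pass."""
    m, n = a.shape
    f_in = x_r.shape[1]
    f_out = w_d2r.shape[1]
    deg_r, deg_d = a.sum(1), a.sum(0)
    out_r = np.zeros((m, f_out))
    out_d = np.zeros((n, f_out))
    for i in range(m):
        msg = np.zeros(f_in)
        for j in range(n):
            if a[i, j]:
                msg += (x_d[j] * e_d[j]) / np.sqrt(deg_d[j] * deg_r[i])
        out_r[i] = np.maximum(msg @ w_d2r, 0)
    for j in range(n):
        msg = np.zeros(f_in)
        for i in range(m):
            if a[i, j]:
                msg += (x_r[i] * e_r[i]) / np.sqrt(deg_d[j] * deg_r[i])
        out_d[j] = np.maximum(msg @ w_r2d, 0)
    return out_r, out_d


def _oracle_gat(src_x, dst_x, adj, w_u, w_v, a, slope=0.2):
    """Scalar-loop attention: leaky-rectified scores, per-row softmax."""
    n_dst, n_src = adj.shape
    f_out = w_v.shape[1]
    a = a.reshape(-1)
    out = np.zeros((n_dst, f_out))
    alphas = np.zeros((n_dst, n_src))
    for u in range(n_dst):
        nbrs = [v for v in range(n_src) if adj[u, v]]
        if not nbrs:
            out[u] = dst_x[u] if dst_x.shape[1] == f_out else 0.0
            continue
        scores = []
        for v in nbrs:
            s = a[:f_out] @ (w_u.T @ dst_x[u]) + a[f_out:] @ (w_v.T @ src_x[v])
            scores.append(s if s > 0 else slope * s)
        scores = np.array(scores)
        e = np.exp(scores - scores.max())
        alpha = e / e.sum()
        agg = np.zeros(f_out)
        for alpha_v, v in zip(alpha, nbrs):
            alphas[u, v] = alpha_v
            agg += alpha_v * (w_v.T @ src_x[v])
        out[u] = np.maximum(agg, 0)
    return out, alphas


class TestEdgeToNodeFeatures:
    def test_isolated_drug_gets_zero(self):
        a = np.array([[0, 0], [1, 0]])
        out = edge_to_node_features(a, np.ones(3), "drug")
        np.testing.assert_array_equal(out[0], 0)

    def test_zero_weight_vector(self):
        out = edge_to_node_features(np.ones((2, 2)), np.zeros(4), "disease")
        np.testing.assert_array_equal(out, 0)

    def test_hand_summation(self):
        a = np.array([[1, 0, 1], [0, 1, 0]])
        out = edge_to_node_features(a, np.array([1.0, 2.0]), "drug")
        np.testing.assert_array_equal(out, [[2, 4], [1, 2]])
        out_d = edge_to_node_features(a, np.array([1.0, 2.0]), "disease")
        np.testing.assert_array_equal(out_d, [[1, 2], [1, 2], [1, 2]])


class TestNeegcnPass:
    def _weights(self, rng, f_in, f_out):
        return EdgeNodeWeights(
            w_edge_drug=np.ones(f_in), w_edge_disease=np.ones(f_in),
            w_d2r=rng.standard_normal((f_in, f_out)),
            w_r2d=rng.standard_normal((f_in, f_out)),
        )

    def test_empty_adjacency_gives_zero(self, rng):
        a = np.zeros((3, 4))
        w = self._weights(rng, 2, 2)
        r, d = neegcn_pass(a, rng.random((3, 2)), rng.random((4, 2)),
                           np.ones((3, 2)), np.ones((4, 2)), w)
        np.testing.assert_array_equal(r, 0)
        np.testing.assert_array_equal(d, 0)

    def test_single_edge_identity_normalization(self):
        a = np.zeros((2, 2))
        a[0, 0] = 1
        x_r = np.array([[0.3, 0.4], [9.0, 9.0]])
        x_d = np.array([[0.5, 0.6], [7.0, 7.0]])
        w = EdgeNodeWeights(np.ones(2), np.ones(2), np.eye(2), np.eye(2))
        r, d = neegcn_pass(a, x_r, x_d, np.ones((2, 2)), np.ones((2, 2)), w)
        np.testing.assert_allclose(r[0], x_d[0])
        np.testing.assert_allclose(d[0], x_r[0])

    def test_matches_quadruple_loop_oracle(self, rng):
        for _ in range(20):
            a = (rng.random((3, 4)) < 0.5).astype(float)
            x_r, x_d = rng.standard_normal((3, 3)), rng.standard_normal((4, 3))
            e_r, e_d = rng.standard_normal((3, 3)), rng.standard_normal((4, 3))
            w = EdgeNodeWeights(np.ones(3), np.ones(3),
                                rng.standard_normal((3, 2)),
                                rng.standard_normal((3, 2)))
            got_r, got_d = neegcn_pass(a, x_r, x_d, e_r, e_d, w)
            exp_r, exp_d = _oracle_neegcn(a, x_r, x_d, e_r, e_d, w.w_d2r, w.w_r2d)
            np.testing.assert_allclose(got_r, exp_r, atol=1e-10)
            np.testing.assert_allclose(got_d, exp_d, atol=1e-10)

    def test_joint_permutation_equivariance(self, rng):
        a = (rng.random((4, 5)) < 0.5).astype(float)
        x_r, x_d = rng.standard_normal((4, 3)), rng.standard_normal((5, 3))
        e_r, e_d = rng.standard_normal((4, 3)), rng.standard_normal((5, 3))
        w = EdgeNodeWeights(np.ones(3), np.ones(3),
                            rng.standard_normal((3, 2)), rng.standard_normal((3, 2)))
        pr, pd = rng.permutation(4), rng.permutation(5)
        base_r, base_d = neegcn_pass(a, x_r, x_d, e_r, e_d, w)
        perm_r, perm_d = neegcn_pass(a[np.ix_(pr, pd)], x_r[pr], x_d[pd],
                                     e_r[pr], e_d[pd], w)
        np.testing.assert_allclose(perm_r, base_r[pr], atol=1e-10)
        np.testing.assert_allclose(perm_d, base_d[pd], atol=1e-10)

    def test_unit_edges_identity_projection_reduce_to_plain_gcn(self, rng):
        """With edge features 1 and identity projections the pass is the
        symmetric-normalized bipartite convolution (checked against a
        direct normalized-adjacency product, rectified)."""
        a = (rng.random((4, 5)) < 0.6).astype(float)
        x_r, x_d = rng.standard_normal((4, 3)), rng.standard_normal((5, 3))
        w = EdgeNodeWeights(np.ones(3), np.ones(3), np.eye(3), np.eye(3))
        got_r, got_d = neegcn_pass(a, x_r, x_d, np.ones((4, 3)), np.ones((5, 3)), w)
        deg_r, deg_d = a.sum(1), a.sum(0)
        with np.errstate(divide="ignore"):
            ir = np.where(deg_r > 0, deg_r**-0.5, 0)
            idd = np.where(deg_d > 0, deg_d**-0.5, 0)
        norm = a * ir[:, None] * idd[None, :]
        np.testing.assert_allclose(got_r, np.maximum(norm @ x_d, 0), atol=1e-10)
        np.testing.assert_allclose(got_d, np.maximum(norm.T @ x_r, 0), atol=1e-10)


class TestGatProject:
    def _params(self, rng, f_dst, f_src, f_out):
        return AttentionHeadParams(
            w_u=rng.standard_normal((f_dst, f_out)),
            w_v=rng.standard_normal((f_src, f_out)),
            a=rng.standard_normal((2 * f_out, 1)),
        )

    def test_singleton_neighborhood_attention_is_one(self, rng):
        adj = np.array([[0.0, 1.0, 0.0]])
        src = rng.standard_normal((3, 2))
        dst = rng.standard_normal((1, 2))
        p = self._params(rng, 2, 2, 2)
        alpha = gat_attention_coefficients(src, dst, adj, p)
        np.testing.assert_allclose(alpha[0, 1], 1.0)
        out = gat_project(src, dst, adj, p)
        np.testing.assert_allclose(out[0], np.maximum(src[1] @ p.w_v, 0), atol=1e-12)

    def test_identical_neighbors_share_attention(self, rng):
        src = np.tile(rng.standard_normal(2), (2, 1))
        dst = rng.standard_normal((1, 2))
        adj = np.ones((1, 2))
        alpha = gat_attention_coefficients(src, dst, adj, self._params(rng, 2, 2, 3))
        np.testing.assert_allclose(alpha, [[0.5, 0.5]])

    def test_attention_rows_sum_to_one(self, rng):
        adj = (rng.random((5, 6)) < 0.5).astype(float)
        alpha = gat_attention_coefficients(
            rng.standard_normal((6, 3)), rng.standard_normal((5, 3)), adj,
            self._params(rng, 3, 3, 2))
        row_sums = alpha.sum(axis=1)
        has = adj.sum(axis=1) > 0
        np.testing.assert_allclose(row_sums[has], 1.0, atol=1e-12)
        np.testing.assert_allclose(row_sums[~has], 0.0)

    def test_matches_scalar_loop_oracle(self, rng):
        for _ in range(20):
            adj = (rng.random((3, 3)) < 0.6).astype(float)
            src = rng.standard_normal((3, 2))
            dst = rng.standard_normal((3, 2))
            p = self._params(rng, 2, 2, 2)
            exp_out, exp_alpha = _oracle_gat(src, dst, adj, p.w_u, p.w_v, p.a)
            np.testing.assert_allclose(gat_project(src, dst, adj, p), exp_out,
                                       atol=1e-10)
            np.testing.assert_allclose(
                gat_attention_coefficients(src, dst, adj, p), exp_alpha, atol=1e-10)

    def test_empty_neighborhood_passthrough_same_width(self, rng):
        adj = np.zeros((2, 3))
        src = rng.standard_normal((3, 2))
        dst = rng.standard_normal((2, 2))
        out = gat_project(src, dst, adj, self._params(rng, 2, 2, 2))
        np.testing.assert_array_equal(out, dst)

    def test_empty_neighborhood_zero_when_width_changes(self, rng):
        adj = np.zeros((2, 3))
        out = gat_project(rng.standard_normal((3, 2)), rng.standard_normal((2, 2)),
                          adj, self._params(rng, 2, 2, 4))
        np.testing.assert_array_equal(out, 0)


class TestProteinMessageRound:
    def _branch(self, rng, f, f_out):
        def head(f_dst, f_src):
            return AttentionHeadParams(
                w_u=rng.standard_normal((f_dst, f_out)),
                w_v=rng.standard_normal((f_src, f_out)),
                a=rng.standard_normal((2 * f_out, 1)),
            )
        return ProteinBranchParams(
            r2p=head(f, f), d2p=head(f, f), p2p=head(f_out, f_out),
            p2r=head(f, f_out), p2d=head(f, f_out),
            ep_proj=rng.standard_normal((2 * f_out, f_out)),
        )

    def test_zero_embeddings_give_zero_messages(self, rng):
        m, n, p, f = 2, 2, 3, 2
        state = EmbeddingState(np.zeros((m, f)), np.zeros((n, f)), np.zeros((p, f)))
        dp = np.ones((m, p))
        sp = np.ones((n, p))
        pp = 1 - np.eye(p)
        msgs = protein_message_round(state, dp, sp, pp, self._branch(rng, f, 3))
        np.testing.assert_array_equal(msgs.x_p_r, 0)
        np.testing.assert_array_equal(msgs.x_p_d, 0)

    def test_one_empty_side_determined_by_other(self, rng):
        m, n, p, f = 2, 2, 3, 2
        state = EmbeddingState(rng.standard_normal((m, f)),
                               rng.standard_normal((n, f)),
                               rng.standard_normal((p, f)))
        dp = np.zeros((m, p))  # drugs contribute nothing to proteins
        sp = np.ones((n, p))
        pp = 1 - np.eye(p)
        branch = self._branch(rng, f, 3)
        msgs = protein_message_round(state, dp, sp, pp, branch)
        # recompute with the drug->protein projection forced to zero: the
        # drug-side block was already zero, so nothing changes
        e_d2p = gat_project(state.diseases, state.proteins, sp.T, branch.d2p)
        e_p = np.concatenate([np.zeros((p, 3)), e_d2p], axis=1) @ branch.ep_proj
        e_p_s = gat_project(e_p, e_p, pp, branch.p2p)
        np.testing.assert_allclose(msgs.x_p_d,
                                   gat_project(e_p_s, state.diseases, sp, branch.p2d),
                                   atol=1e-10)

    def test_stagewise_composition_matches_sequential_oracle(self, rng):
        m, n, p, f, f_out = 2, 2, 3, 2, 2
        state = EmbeddingState(rng.standard_normal((m, f)),
                               rng.standard_normal((n, f)),
                               rng.standard_normal((p, f)))
        dp = (rng.random((m, p)) < 0.7).astype(float)
        sp = (rng.random((n, p)) < 0.7).astype(float)
        pp = ((rng.random((p, p)) < 0.7) | np.eye(p, dtype=bool)).astype(float)
        np.fill_diagonal(pp, 0)
        branch = self._branch(rng, f, f_out)
        msgs = protein_message_round(state, dp, sp, pp, branch)
        e_r2p = gat_project(state.drugs, state.proteins, dp.T, branch.r2p)
        e_d2p = gat_project(state.diseases, state.proteins, sp.T, branch.d2p)
        e_p = np.concatenate([e_r2p, e_d2p], axis=1) @ branch.ep_proj
        e_p_s = gat_project(e_p, e_p, pp, branch.p2p)
        np.testing.assert_allclose(msgs.x_p_r,
                                   gat_project(e_p_s, state.drugs, dp, branch.p2r),
                                   atol=1e-10)
        np.testing.assert_allclose(msgs.x_p_d,
                                   gat_project(e_p_s, state.diseases, sp, branch.p2d),
                                   atol=1e-10)
        np.testing.assert_allclose(msgs.protein_state, e_p_s, atol=1e-10)

    def test_missing_protein_state_rejected(self, rng):
        state = EmbeddingState(np.zeros((2, 2)), np.zeros((2, 2)), None)
        with pytest.raises(ValueError, match="protein"):
            protein_message_round(state, np.ones((2, 3)), np.ones((2, 3)),
                                  1 - np.eye(3), self._branch(rng, 2, 2))


class TestDropEdges:
    def test_zero_rate_is_identity(self, rng):
        a = (rng.random((4, 5)) < 0.5).astype(float)
        np.testing.assert_array_equal(drop_edges(a, 0.0, rng), a)

    def test_only_removes_edges(self, rng):
        a = (rng.random((10, 10)) < 0.5).astype(float)
        dropped = drop_edges(a, 0.5, rng)
        assert np.all(dropped <= a)
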