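"""Attribution methods against closed-form, Shapley and completeness oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plmscreen import (
    cluster_attributions,
    deeplift_windowed,
    exhaustive_shapley,
    integrated_gradients,
    make_vocab,
    shap_like,
    window_spans,
)
from plmscreen.attribution import completeness_gap
from plmscreen.model import CausalTransformer, ModelConfig


class _StubConfig:
    context_length = 512


class LinearStub:
    """Scorer whose target logit is w . sum_i e_i — additive by design.

    All other logits are identically zero, so gradients and Shapley
    values have closed forms against which the attribution code is
    checked.
    """

    def __init__(self, d=6, seed=0):
        self.vocab = make_vocab(["0", "1"])
        rng = np.random.default_rng(seed)
        self.table = rng.normal(size=(len(self.vocab), d))
        self.w = rng.normal(size=d)
        self.target = self.vocab.tag_ids["0"]
        self.config = _StubConfig()

    def token_embeddings(self, ids):
        ids = np.atleast_2d(ids)
        return self.table[ids]

    def forward_from_embeddings(self, x):
        single = x.ndim == 2
        if single:
            x = x[None]
        B, T, _ = x.shape
        logits = np.zeros((B, T, len(self.vocab)))
        logits[:, :, self.target] = np.cumsum(x @ self.w, axis=1)
        return logits[0] if single else logits

    def grad_wrt_embeddings(self, x, dlogits):
        single = x.ndim == 2
        if single:
            x, dlogits = x[None], dlogits[None]
        # d logits[t, target] / d x_i = w for i <= t
        coeff = dlogits[:, :, self.target]            # (B, T)
        csum = np.cumsum(coeff[:, ::-1], axis=1)[:, ::-1]  # sum over t >= i
        grads = csum[..., None] * self.w
        return grads[0] if single else grads


class ConstantStub(LinearStub):
    """Output independent of the input: all attributions must vanish."""

    def forward_from_embeddings(self, x):
        single = x.ndim == 2
        if single:
            x = x[None]
        logits = np.full((x.shape[0], x.shape[1], len(self.vocab)), 0.7)
        return logits[0] if single else logits

    def grad_wrt_embeddings(self, x, dlogits):
        return np.zeros_like(x)


class TestExhaustiveShapley:
    def test_additive_game_recovers_coefficients(self):
        c = np.array([1.5, -2.0, 0.25, 3.0])
        phi = exhaustive_shapley(lambda S: sum(c[i] for i in S), 4)
        assert np.allclose(phi, c, atol=1e-12)

    def test_symmetry_axiom(self):
        v = lambda S: float(len(S) >= 1)  # both players interchangeable
        phi = exhaustive_shapley(v, 2)
        assert phi[0] == pytest.approx(phi[1], abs=1e-12)

    def test_efficiency_axiom(self, rng):
        table = {frozenset(s): rng.normal()
                 for s in [(), (0,), (1,), (2,), (0, 1), (0, 2), (1, 2),
                           (0, 1, 2)]}
        v = lambda S: table[frozenset(S)]
        phi = exhaustive_shapley(v, 3)
        assert phi.sum() == pytest.approx(
            v({0, 1, 2}) - v(frozenset()), abs=1e-9)

    def test_combinatorial_guard(self):
        with pytest.raises(ValueError, match="<= 12"):
            exhaustive_shapley(lambda S: 0.0, 13)


class TestShapLike:
    def test_zero_embedding_token_gets_zero_score(self):
        model = CausalTransformer(
            ModelConfig(n_layers=1, d_model=16, n_heads=2, context_length=16,
                        dtype="float64"),
            make_vocab(["0", "1"]), seed=1)
        model.params["wte"][model.vocab.token_to_id["C"]] = 0.0
        att = shap_like(model, "ACDCA", "0")
        assert att.scores[1] == 0.0
        assert att.scores[3] == 0.0
        assert len(att.scores) == 5

    def test_linear_head_matches_analytic_loss_gradient(self):
        stub = LinearStub()
        seq = "ACDQ"
        att = shap_like(stub, seq, "0")
        emb = stub.token_embeddings(stub.vocab.encode(seq))[0]
        z = np.zeros(len(stub.vocab))
        z[stub.target] = (emb @ stub.w).sum()  # w . sum_i e_i
        p = np.exp(z - z.max())
        p /= p.sum()
        expected = (p[stub.target] - 1.0) * (emb @ stub.w)
        assert np.allclose(att.scores, expected, atol=1e-10)

    def test_logit_score_equals_exact_shapley_for_additive_model(self):
        stub = LinearStub()
        seq = "ACDQ"
        emb = stub.token_embeddings(stub.vocab.encode(seq))[0]
        contrib = emb @ stub.w

        def v(S):
            return float(sum(contrib[i] for i in S))

        phi_exact = exhaustive_shapley(v, 4)
        att = shap_like(stub, seq, "0", score="logit")
        assert np.allclose(att.scores, phi_exact, atol=1e-9)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            shap_like(LinearStub(), "", "0")


class TestIntegratedGradients:
    def test_baseline_equal_to_input_gives_zeros(self):
        stub = LinearStub()
        seq = "ACD"
        x = stub.token_embeddings(stub.vocab.encode(seq))[0]
        att = integrated_gradients(stub, seq, "0", steps=8, baseline=x)
        assert np.allclose(att.scores, 0.0)

    @pytest.mark.parametrize("steps", [1, 7, 50])
    def test_linear_model_exact_at_any_step_count(self, steps):
        stub = LinearStub()
        seq = "MKVW"
        x = stub.token_embeddings(stub.vocab.encode(seq))[0]
        att = integrated_gradients(stub, seq, "0", steps=steps,
                                   baseline=np.zeros_like(x))
        assert np.allclose(att.scores, x @ stub.w, atol=1e-12)

    def test_completeness_on_trained_model(self, tiny_model):
        seq = "QARQARQARQARQARQARQA"
        att = integrated_gradients(tiny_model, seq, "0", steps=50)
        assert completeness_gap(tiny_model, seq, "0", att) < 0.01

    def test_completeness_improves_with_steps(self, tiny_model):
        seq = "QARRAQQARAQRQARQARQA"
        gaps = []
        for steps in (5, 50, 500):
            att = integrated_gradients(tiny_model, seq, "0", steps=steps)
            gaps.append(completeness_gap(tiny_model, seq, "0", att))
        assert gaps[2] <= gaps[1] + 1e-9 <= gaps[0] + 2e-9

    def test_baseline_shape_mismatch_rejected(self):
        stub = LinearStub()
        with pytest.raises(ValueError, match="shape"):
            integrated_gradients(stub, "ACD", "0", baseline=np.zeros((2, 2)))


class TestWindowSpans:
    def test_printed_geometry_window32_stride16(self):
        spans = window_spans(100, 32, 16)
        assert (spans[0].start, spans[0].end) == (0, 31)
        assert (spans[1].start, spans[1].end) == (16, 47)
        overlaps = [spans[i].end - spans[i + 1].start + 1
                    for i in range(len(spans) - 2)]
        assert set(overlaps) == {16}

    def test_exact_fit_single_span(self):
        assert window_spans(32, 32, 16) == [type(window_spans(32)[0])(0, 31, 0)]

    def test_truncated_final_span_covers_tail(self):
        spans = window_spans(40, 32, 16)
        assert [(s.start, s.end) for s in spans] == [(0, 31), (16, 39)]

    def test_empty_sequence(self):
        assert window_spans(0, 32, 16) == []

    @given(seq_len=st.integers(1, 300), window=st.integers(1, 64),
           stride_frac=st.integers(1, 64))
    @settings(max_examples=120, deadline=None)
    def test_every_position_covered(self, seq_len, window, stride_frac):
        stride = min(stride_frac, window)
        spans = window_spans(seq_len, window, stride)
        covered = np.zeros(seq_len, dtype=int)
        for s in spans:
            assert 0 <= s.start <= s.end < seq_len
            covered[s.start : s.end + 1] += 1
        assert covered.min() >= 1


class TestDeepLiftWindowed:
    def test_constant_model_gives_zero_profile(self):
        prof = deeplift_windowed(ConstantStub(), "ACDEFGHIK" * 4, "0",
                                 window=8, stride=4, steps=4)
        assert np.allclose(prof.profile, 0.0)

    def test_per_window_sum_matches_output_delta(self, tiny_model):
        seq = "QARQARQARQARQARQARQA"
        prof = deeplift_windowed(tiny_model, seq, "0", window=8, stride=4,
                                 steps=128)
        target = tiny_model.vocab.token_to_id["0"]
        pad = tiny_model.vocab.pad_id
        for span, A in zip(prof.spans, prof.window_attributions):
            sub = seq[span.start : span.end + 1]
            ids = tiny_model.vocab.encode(sub)
            x = tiny_model.token_embeddings(ids)[0]
            x0 = np.broadcast_to(
                tiny_model.token_embeddings(np.array([pad]))[0, 0], x.shape)
            dy = (tiny_model.forward_from_embeddings(x)[-1, target]
                  - tiny_model.forward_from_embeddings(x0.copy())[-1, target])
            assert A.sum() == pytest.approx(dy, rel=0.01)

    def test_spans_delegate_to_window_spans(self, tiny_model):
        seq = "QAR" * 6
        prof = deeplift_windowed(tiny_model, seq, "0", window=8, stride=4,
                                 steps=2)
        assert prof.spans == window_spans(len(seq), 8, 4)

    def test_single_window_limit_equals_plain_ig(self, tiny_model):
        seq = "QARQARQAR"
        prof = deeplift_windowed(tiny_model, seq, "0", window=len(seq),
                                 stride=len(seq), steps=32)
        att = integrated_gradients(tiny_model, seq, "0", steps=32)
        assert np.allclose(prof.profile, att.scores, atol=1e-6)

    def test_window_beyond_context_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="context"):
            deeplift_windowed(tiny_model, "Q" * 20, "0", window=64, stride=16)


class TestClusterAttributions:
    def test_single_row_selects_one_cluster(self):
        res = cluster_attributions(np.ones((1, 5)))
        assert res.k_selected == 1
        assert list(res.assignments) == [0]

    def test_identical_rows_select_one_cluster(self):
        res = cluster_attributions(np.tile([1.0, 2.0, 3.0], (8, 1)))
        assert res.k_selected == 1
        assert res.inertia_curve[0][1] == pytest.approx(0.0, abs=1e-9)

    def test_elbow_rule_matches_independent_reimplementation(self, rng):
        centers = np.array([[0.0] * 4, [10.0] * 4, [-10.0, 10.0, -10.0, 10.0]])
        X = np.vstack([
            c + rng.normal(0, 0.01, size=(15, 4)) for c in centers
        ])
        res = cluster_attributions(X, seed=0)
        # Independent application of the stated 20%-decrease rule to the
        # returned inertia curve.
        inertias = dict(res.inertia_curve)
        expected = max(inertias)
        for k in range(2, max(inertias) + 1):
            if inertias[k - 1] <= 1e-12:
                expected = k - 1
                break
            if (inertias[k - 1] - inertias[k]) / inertias[k - 1] * 100 < 20:
                expected = k
                break
        assert res.k_selected == expected
        assert 1 <= res.k_selected <= min(10, len(X))

    def test_assignments_partition_well_separated_blobs(self, rng):
        # Near-duplicate points within each blob: inertia is ~0 at k=2,
        # so the elbow guard stops there and the blobs map to clusters.
        X = np.vstack([np.zeros((10, 3)), np.full((10, 3), 50.0)])
        X += rng.normal(0, 1e-8, X.shape)
        res = cluster_attributions(X, seed=1)
        assert res.k_selected == 2
        first, second = res.assignments[:10], res.assignments[10:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert set(first) != set(second)
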