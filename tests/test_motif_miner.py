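"""Motif mining: influence profiles, class separation, both motif finders."""

import numpy as np
import pytest

from plmscreen import (
    attention_self_diagonal,
    class_separation,
    flexible_motifs,
    influence_profile,
    strict_motifs,
)
from plmscreen.motifs import InfluenceProfile, raw_influence


def profile_from(avg: np.ndarray) -> InfluenceProfile:
    return InfluenceProfile(per_layer=avg[None], avg_influence=np.asarray(avg),
                            threshold=float(np.percentile(avg, 95)))


class TestInfluenceProfile:
    def test_identical_positions_give_zero_influence(self):
        H = np.tile([1.0, 2.0, 3.0], (6, 1))
        prof = influence_profile([H, H])
        assert np.allclose(prof.avg_influence, 0.0)

    def test_single_outlier_matches_mean_shift_oracle(self):
        # n-1 positions at the origin, one at distance r: the outlier's
        # raw influence is r(n-1)/n, the others' r/n.
        n, r = 8, 3.0
        H = np.zeros((n, 4))
        H[2, 0] = r
        raw = raw_influence(H)
        assert raw[2] == pytest.approx(r * (n - 1) / n)
        others = np.delete(raw, 2)
        assert np.allclose(others, r / n)

    def test_minmax_maps_extremes_to_unit_interval(self, rng):
        H = rng.normal(size=(10, 4))
        prof = influence_profile([H])
        assert prof.avg_influence.min() == pytest.approx(0.0)
        assert prof.avg_influence.max() == pytest.approx(1.0)

    def test_mismatched_layers_rejected(self):
        with pytest.raises(ValueError):
            influence_profile([np.zeros((4, 2)), np.zeros((5, 2))])
        with pytest.raises(ValueError):
            influence_profile([])


class TestClassSeparation:
    def test_identical_embeddings_give_zero_index_and_empty_seeds(self):
        seqs = ["AC", "CA", "AA"]
        embs = [np.ones((2, 3))] * 3
        res = class_separation(seqs, embs)
        assert all(v == 0.0 for v in res.index.values())
        assert res.seeds == set()

    def test_two_cluster_case_recovers_distance(self):
        u, v = np.array([1.0, 0.0]), np.array([0.0, 2.0])
        seqs = ["A", "A", "C", "C", "C"]
        embs = [u[None], u[None], v[None], v[None], v[None]]
        res = class_separation(seqs, embs)
        d = np.linalg.norm(u - v)
        assert res.index[("A", 0)] == pytest.approx(d)
        assert res.index[("C", 0)] == pytest.approx(d)

    def test_percentile_convention_linear_interpolation(self):
        # theta over I values {1..100} under the linear-interpolation
        # convention is 95.05.
        values = np.arange(1.0, 101.0)
        assert np.percentile(values, 95) == pytest.approx(95.05)

    def test_seed_equivariance_under_corpus_permutation(self, rng):
        seqs = ["ACAC", "CAAC", "CCCA", "AACC"]
        embs = [rng.normal(size=(4, 3)) for _ in seqs]
        res = class_separation(seqs, embs)
        order = [2, 0, 3, 1]
        res_p = class_separation([seqs[i] for i in order],
                                 [embs[i] for i in order])
        remap = {old: new for new, old in enumerate(order)}
        assert {(remap[s], p) for s, p in res.seeds} == res_p.seeds

    def test_single_identity_positions_are_excluded(self):
        seqs = ["AA", "AC"]
        embs = [np.zeros((2, 2)), np.ones((2, 2))]
        res = class_separation(seqs, embs)
        assert res.n_excluded == 1  # position 0 is all-'A'
        assert ("A", 0) not in res.index


class TestFlexibleMotifs:
    def test_constant_profile_yields_no_motifs(self):
        assert flexible_motifs(profile_from(np.full(60, 0.5)), "A" * 60) == []

    def test_single_sharp_peak_centres_one_motif(self):
        avg = np.zeros(200)
        avg[49:52] = [0.6, 1.0, 0.6]  # peak at 50 with 3 hot positions
        seq = "A" * 200
        hits = flexible_motifs(profile_from(avg), seq, window_size=5)
        assert len(hits) == 1
        assert hits[0].start <= 50 <= hits[0].end
        assert hits[0].pattern.count("X") == hits[0].length - 3

    def test_close_peaks_pruned_keeping_higher(self):
        avg = np.zeros(100)
        avg[40] = 1.0
        avg[41] = 0.9   # shoulders make both locations true local maxima
        avg[43] = 0.95  # 3 positions from 40: pruned at min distance 5
        avg[44] = 0.85
        hits = flexible_motifs(profile_from(avg), "M" * 100, window_size=5)
        # a single merged/retained region centred on the taller peak
        assert len(hits) == 1
        assert hits[0].start <= 40 <= hits[0].end

    def test_fewer_than_two_hot_residues_dropped(self):
        avg = np.zeros(100)
        avg[50] = 1.0  # a lone spike: only one above-threshold residue
        hits = flexible_motifs(profile_from(avg), "K" * 100, window_size=5)
        assert hits == []

    def test_degenerate_masking_preserves_hot_residues(self):
        avg = np.zeros(100)
        avg[50] = 1.0
        avg[52] = 0.9
        seq = "".join("RD"[i % 2] for i in range(100))
        hits = flexible_motifs(profile_from(avg), seq, window_size=5)
        assert len(hits) == 1
        pat = hits[0].pattern
        offset = 50 - hits[0].start
        assert pat[offset] == seq[50]
        assert pat[offset + 2] == seq[52]
        assert pat[offset + 1] == "X"

    def test_invariance_under_monotone_rescaling(self, rng):
        avg = rng.uniform(0.0, 1.0, size=120)
        seq = "".join(rng.choice(list("ACDEFG"), size=120))
        base = flexible_motifs(profile_from(avg), seq, window_size=5)
        resc = flexible_motifs(profile_from(np.exp(3 * avg)), seq,
                               window_size=5)
        assert [(h.pattern, h.start) for h in base] == \
               [(h.pattern, h.start) for h in resc]

    def test_merged_motifs_never_overlap(self, rng):
        avg = rng.uniform(0.0, 1.0, size=200)
        seq = "".join(rng.choice(list("ACDEFGHIK"), size=200))
        hits = flexible_motifs(profile_from(avg), seq, window_size=5)
        spans = sorted((h.start, h.end) for h in hits)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            flexible_motifs(profile_from(np.zeros(10)), "A" * 11)


class TestStrictMotifs:
    def seq(self, n):
        return "".join("ACDEFGHIKLMNPQRSTVWY"[i % 20] for i in range(n))

    def test_composite_weights_sum_to_one_at_saturated_position(self):
        n = 40
        div = np.zeros(n)
        att = np.zeros(n)
        ig = np.zeros(n)
        div[10] = att[10] = ig[10] = 1.0
        composite = 0.4 * div + 0.3 * att + 0.3 * ig
        assert composite[10] == pytest.approx(1.0)

    def test_divergence_only_contributes_point_four(self):
        n = 40
        div = np.zeros(n)
        div[10] = 1.0
        composite = 0.4 * div
        assert composite[10] == pytest.approx(0.4)

    def test_all_zero_channels_give_no_motifs(self):
        n = 50
        z = np.zeros(n)
        assert strict_motifs(z, z, z, self.seq(n)) == []

    def test_matches_brute_force_enumeration(self, rng):
        n = 120
        div, att, ig = (rng.uniform(size=n) for _ in range(3))
        seq = self.seq(n)
        hits = strict_motifs(div, att, ig, seq, min_len=3, max_len=6)

        def mm(x):
            return (x - x.min()) / (x.max() - x.min())

        composite = 0.4 * mm(div) + 0.3 * mm(att) + 0.3 * mm(ig)
        thr = np.percentile(composite, 95)
        expected = []
        for length in range(3, 7):
            for start in range(n - length + 1):
                w = composite[start : start + length]
                if w.mean() > thr and np.mean(w > thr) >= 0.75:
                    expected.append((start, length))
        kept = [
            (s, l) for s, l in expected
            if not any(
                (s2, l2) != (s, l) and s2 <= s and s + l <= s2 + l2 and l2 > l
                for s2, l2 in expected
            )
        ]
        assert sorted((h.start, h.length) for h in hits) == sorted(kept)
        assert all("X" not in h.pattern for h in hits)

    def test_length_one_windows_reduce_to_thresholding(self, rng):
        n = 60
        div, att, ig = (rng.uniform(size=n) for _ in range(3))
        seq = self.seq(n)
        hits = strict_motifs(div, att, ig, seq, min_len=1, max_len=1,
                             coverage=1.0)

        def mm(x):
            return (x - x.min()) / (x.max() - x.min())

        composite = 0.4 * mm(div) + 0.3 * mm(att) + 0.3 * mm(ig)
        thr = np.percentile(composite, 95)
        assert sorted(h.start for h in hits) == \
            sorted(np.flatnonzero(composite > thr).tolist())

    def test_channel_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            strict_motifs(np.zeros(5), np.zeros(6), np.zeros(5), "ACDEF")


class TestAttentionSelfDiagonal:
    def test_matches_hand_average_of_head_diagonals(self, tiny_model):
        seq = "QARQARQARQ"
        states = tiny_model.forward_states(tiny_model.vocab.encode(seq))
        diags = [att[h].diagonal()
                 for att in states.attentions
                 for h in range(att.shape[0])]
        expected = np.mean(diags, axis=0)
        expected = (expected - expected.min()) / (expected.max() - expected.min())
        got = attention_self_diagonal(tiny_model, seq)
        assert np.allclose(got, expected, atol=1e-6)

    def test_first_position_attends_only_to_itself(self, tiny_model):
        states = tiny_model.forward_states(tiny_model.vocab.encode("QARQA"))
        for att in states.attentions:
            assert np.allclose(att[:, 0, 0], 1.0, atol=1e-6)

    def test_values_lie_in_unit_interval(self, tiny_model):
        got = attention_self_diagonal(tiny_model, "QARQARQAR")
        assert got.min() >= 0.0 and got.max() <= 1.0
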