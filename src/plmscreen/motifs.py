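"""Attribution-driven motif discovery.

Influential motifs are short stretches of residues whose hidden-state
representations carry a disproportionate share of the model's decision
signal.  Two finders are provided.

Flexible (degenerate) finder
    Per layer, the influence of position ``i`` is the L2 norm of the
    deviation of its hidden state from the layer's mean representation;
    each layer's profile is min-max normalized to [0, 1] and the layer
    average gives one influence score per position.  Peaks above the
    95th percentile (minimum inter-peak distance = window size) seed
    windows; inside a window, positions below the threshold are masked
    to 'X'.  Windows with at least two above-threshold residues are
    kept, overlapping or adjacent hits are merged, and output is ranked
    by mean influence — yielding degenerate patterns such as "XRXDX".

Strict finder
    Three per-position channels — hidden-state divergence, the mean
    self-attention diagonal, and integrated gradients — are each
    min-max normalized and combined as

        composite = 0.4 * divergence + 0.3 * attention + 0.3 * IG.

    Fully specified motifs of 3-9 residues are extracted when the
    window's mean composite exceeds the 95th percentile of composite
    scores and at least 75% of its residues individually exceed that
    threshold.

A class-separation index complements both:
``I(a, i) = || mu_{a,i} - mu_{not a,i} ||_2`` measures how far the mean
embedding of residue ``a`` at aligned position ``i`` sits from the mean
of all other residues at that position; sites with ``I`` above the 95th
percentile form the motif seed set ``M``.

All percentiles use linear interpolation between closest ranks
(``numpy.percentile`` default), fixed for reproducibility.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks


@dataclasses.dataclass(frozen=True)
class InfluenceProfile:
    per_layer: np.ndarray       # layers x positions, min-max per layer
    avg_influence: np.ndarray   # positions
    threshold: float


@dataclasses.dataclass(frozen=True)
class ClassSeparationIndex:
    index: dict[tuple[str, int], float]
    theta: float
    seeds: set[tuple[int, int]]  # (sequence index, position)
    n_excluded: int              # (a, i) cells with an empty complement


@dataclasses.dataclass(frozen=True)
class MotifHit:
    pattern: str
    start: int
    mean_influence: float
    mode: str  # "flexible" | "strict"

    @property
    def length(self) -> int:
        return len(self.pattern)

    @property
    def end(self) -> int:  # inclusive
        return self.start + len(self.pattern) - 1


# ---------------------------------------------------------------------------
# Influence profiles
# ---------------------------------------------------------------------------

def _minmax(x: np.ndarray) -> np.ndarray:
    """Min-max to [0, 1]; a constant vector maps to all zeros."""
    span = x.max() - x.min()
    if span <= 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.min()) / span


def influence_profile(hidden: Sequence[np.ndarray],
                      percentile: float = 95.0) -> InfluenceProfile:
    """Position-wise influence from per-layer hidden states.

    Per layer: ``influence_i = || h_i - mean(h) ||_2``, min-max
    normalized; the average across layers gives ``avg_influence``.
    """
    if len(hidden) == 0:
        raise ValueError("need at least one layer of hidden states")
    n_pos = hidden[0].shape[0]
    if any(h.shape[0] != n_pos for h in hidden):
        raise ValueError("layers disagree on position count")
    per_layer = np.stack([
        _minmax(np.linalg.norm(h - h.mean(0, keepdims=True), axis=1))
        for h in hidden
    ])
    avg = per_layer.mean(0)
    return InfluenceProfile(per_layer, avg, float(np.percentile(avg, percentile)))


def raw_influence(hidden: np.ndarray) -> np.ndarray:
    """Un-normalized single-layer influence (mean-deviation L2 norms)."""
    return np.linalg.norm(hidden - hidden.mean(0, keepdims=True), axis=1)


# ---------------------------------------------------------------------------
# Class-separation index
# ---------------------------------------------------------------------------

def class_separation(
    sequences: Sequence[str],
    embeddings: Sequence[np.ndarray],
    percentile: float = 95.0,
) -> ClassSeparationIndex:
    """I(a, i) = ||mu_{a,i} - mu_{not a,i}|| over an aligned corpus.

    ``embeddings[s][p]`` is the vector for residue ``sequences[s][p]``.
    Positions where the complement set is empty (only one residue
    identity present) are excluded and counted.
    """
    if len(sequences) != len(embeddings):
        raise ValueError("sequences and embeddings must align")
    n_pos = min(len(s) for s in sequences)
    index: dict[tuple[str, int], float] = {}
    n_excluded = 0
    for i in range(n_pos):
        vecs = np.stack([emb[i] for emb in embeddings])
        residues = np.array([s[i] for s in sequences])
        for a in np.unique(residues):
            in_mask = residues == a
            if in_mask.all():
                n_excluded += 1
                continue
            mu_in = vecs[in_mask].mean(0)
            mu_out = vecs[~in_mask].mean(0)
            index[(str(a), i)] = float(np.linalg.norm(mu_in - mu_out))
    values = np.array(list(index.values()))
    theta = float(np.percentile(values, percentile)) if len(values) else 0.0
    seeds = {
        (s_idx, p)
        for s_idx, seq in enumerate(sequences)
        for p in range(min(len(seq), n_pos))
        if index.get((seq[p], p), -np.inf) > theta
    }
    return ClassSeparationIndex(index, theta, seeds, n_excluded)


# ---------------------------------------------------------------------------
# Flexible (degenerate) motifs
# ---------------------------------------------------------------------------

def flexible_motifs(
    profile: InfluenceProfile,
    sequence: str,
    window_size: int = 5,
    percentile: float = 95.0,
) -> list[MotifHit]:
    """Peak-centred degenerate motifs from an averaged influence profile.

    Peaks are local maxima above the percentile threshold with minimum
    inter-peak distance equal to the window size; a window centred on
    each peak is extracted, below-threshold positions are masked to
    'X', windows with fewer than two above-threshold residues are
    dropped, overlapping/adjacent hits are merged (length-weighted mean
    influence), and results are ranked by mean influence.
    """
    avg = profile.avg_influence
    if len(avg) != len(sequence):
        raise ValueError("profile length must equal sequence length")
    threshold = float(np.percentile(avg, percentile))
    peaks, _ = find_peaks(avg, height=threshold, distance=window_size)
    half = window_size // 2
    spans: list[tuple[int, int]] = []
    for peak in peaks:
        start = max(0, peak - half)
        end = min(len(sequence) - 1, start + window_size - 1)
        start = max(0, end - window_size + 1)
        spans.append((start, end))

    merged: list[tuple[int, int]] = []
    for start, end in sorted(spans):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))

    hits = []
    for start, end in merged:
        # Strictly above: "exceeding the percentile" — with a sparse
        # profile the threshold can sit at the background level.
        above = avg[start : end + 1] > threshold
        if above.sum() < 2:
            continue
        pattern = "".join(
            ch if above[i] else "X"
            for i, ch in enumerate(sequence[start : end + 1])
        )
        hits.append(MotifHit(pattern, start,
                             float(avg[start : end + 1].mean()), "flexible"))
    hits.sort(key=lambda h: (-h.mean_influence, h.start))
    return hits


# ---------------------------------------------------------------------------
# Strict motifs
# ---------------------------------------------------------------------------

def strict_motifs(
    divergence: np.ndarray,
    attention_diag: np.ndarray,
    ig: np.ndarray,
    sequence: str,
    min_len: int = 3,
    max_len: int = 9,
    percentile: float = 95.0,
    coverage: float = 0.75,
    weights: tuple[float, float, float] = (0.4, 0.3, 0.3),
) -> list[MotifHit]:
    """Composite-scored fully specified motifs.

    Channels are min-max normalized, combined with the 0.4/0.3/0.3
    weights, and thresholded at the given percentile of the composite.
    A candidate window is accepted when its mean composite exceeds the
    threshold and at least ``coverage`` of its residues individually
    exceed it.  Hits strictly contained in a longer accepted hit are
    dropped; output is ranked by mean composite score.
    """
    channels = [np.asarray(c, dtype=float) for c in (divergence, attention_diag, ig)]
    L = len(sequence)
    if any(len(c) != L for c in channels):
        raise ValueError("channel lengths must equal sequence length")
    w_div, w_att, w_ig = weights
    composite = (w_div * _minmax(channels[0]) + w_att * _minmax(channels[1])
                 + w_ig * _minmax(channels[2]))
    threshold = float(np.percentile(composite, percentile))
    above = composite > threshold

    accepted: list[MotifHit] = []
    for length in range(min_len, max_len + 1):
        for start in range(0, L - length + 1):
            window = composite[start : start + length]
            if window.mean() > threshold and above[start : start + length].mean() >= coverage:
                accepted.append(
                    MotifHit(sequence[start : start + length], start,
                             float(window.mean()), "strict")
                )

    kept = [
        h for h in accepted
        if not any(
            o is not h and o.start <= h.start and h.end <= o.end
            and o.length > h.length
            for o in accepted
        )
    ]
    kept.sort(key=lambda h: (-h.mean_influence, h.start))
    return kept


def attention_self_diagonal(model, sequence: str) -> np.ndarray:
    """Mean self-attention weight per position, min-max normalized.

    Averages ``att[i, i]`` over all layers and heads; raises for
    architectures that do not expose attention weights.
    """
    states = model.forward_states(model.vocab.encode(sequence))
    if not states.attentions:
        raise NotImplementedError("model exposes no attention weights")
    diag = np.mean(
        [np.diagonal(att, axis1=-2, axis2=-1) for att in states.attentions],
        axis=(0, 1),
    )
    return _minmax(diag)


def aggregate_motifs(
    hits_by_sequence: Mapping[str, Sequence[MotifHit]]
) -> list[tuple[str, int, float]]:
    """Corpus-level (pattern, occurrence count, mean influence) table."""
    counts: dict[str, list[float]] = {}
    for hits in hits_by_sequence.values():
        for h in hits:
            counts.setdefault(h.pattern, []).append(h.mean_influence)
    table = [(pat, len(vals), float(np.mean(vals))) for pat, vals in counts.items()]
    table.sort(key=lambda row: (-row[1] * row[2], row[0]))
    return table
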