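"""Layer-wise 2D projection of hidden states via SVD.

For one input sequence, the residual-stream matrix at layer ``l``,
``H(l) in R^{n x d}`` (rows = residues), is decomposed as

    H(l) = U(l) Sigma(l) V(l)^T

and every residue is projected onto the first two right-singular axes:

    Z(l) = H(l) V(l)[:, :2].

The decomposition is deliberately *uncentered* — it operates on the raw
hidden states rather than mean-subtracted ones — with conventional
(centered) PCA available as an option.  Tracking ``Z(l)`` across layers
shows how residue representations spread and cluster with depth; a
separation statistic (mean inter-class centroid distance over mean
intra-class spread, classes = residue identity) quantifies the
progressive separation of residue features in deeper layers.

Sign convention: each right-singular vector is scaled so that its
largest-magnitude entry is positive, making output deterministic.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations

import numpy as np


@dataclasses.dataclass(frozen=True)
class LayerProjection:
    layer: int
    coords: np.ndarray            # n x 2
    singular_values: np.ndarray   # descending
    residue_labels: tuple[str, ...]
    tied: bool                    # near-degenerate top-2 singular values
    separation: float | None = None


def layer_projection(
    H: np.ndarray,
    layer: int = 0,
    residue_labels: tuple[str, ...] | None = None,
    centered: bool = False,
) -> LayerProjection:
    """Project rows of ``H`` onto the first two right-singular axes."""
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[1] < 2:
        raise ValueError("H must be an n x d matrix with d >= 2")
    M = H - H.mean(0, keepdims=True) if centered else H
    _, s, vt = np.linalg.svd(M, full_matrices=False)
    V = vt.T[:, :2].copy()
    for j in range(2):
        pivot = np.argmax(np.abs(V[:, j]))
        if V[pivot, j] < 0:
            V[:, j] = -V[:, j]
    coords = M @ V
    tied = bool(len(s) > 2 and s[0] > 0 and (s[1] - s[2]) / s[0] < 1e-9)
    labels = residue_labels or tuple("?" * H.shape[0])
    return LayerProjection(layer, coords, s, labels, tied)


def residue_separation(coords: np.ndarray, labels: tuple[str, ...]) -> float:
    """Mean inter-class centroid distance over mean intra-class spread.

    Classes are residue identities; singleton classes contribute no
    spread.  Returns inf when the intra-class spread is zero but
    centroids differ, and 0.0 when fewer than two classes are present.
    """
    groups: dict[str, np.ndarray] = {}
    labels_arr = np.array(labels)
    for lbl in np.unique(labels_arr):
        groups[str(lbl)] = coords[labels_arr == lbl]
    if len(groups) < 2:
        return 0.0
    centroids = {k: v.mean(0) for k, v in groups.items()}
    inter = np.mean([
        np.linalg.norm(centroids[a] - centroids[b])
        for a, b in combinations(sorted(groups), 2)
    ])
    spreads = [
        np.linalg.norm(v - centroids[k], axis=1).mean()
        for k, v in groups.items() if len(v) > 1
    ]
    intra = float(np.mean(spreads)) if spreads else 0.0
    if intra == 0.0:
        return float("inf") if inter > 0 else 0.0
    return float(inter / intra)


def project_all_layers(
    model, sequence: str, centered: bool = False
) -> list[LayerProjection]:
    """One projection per layer, including the embedding layer (layer 0).

    Layer 0 is the residual stream after positional mixing; layers
    1..n are the block outputs, giving ``n_layers + 1`` projections.
    Each carries the residue-separation statistic for its coordinates.
    """
    states = model.forward_states(model.vocab.encode(sequence))
    labels = tuple(sequence)
    out = []
    for l, H in enumerate(states.hidden):
        proj = layer_projection(H, layer=l, residue_labels=labels,
                                centered=centered)
        # Separation is measured on the full hidden state, not the 2D
        # shadow: the projection is for display, the statistic for trend.
        out.append(dataclasses.replace(
            proj, separation=residue_separation(H, labels)))
    return out
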