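"""Gradient-based per-residue attribution methods.

Three complementary views of which residues drive a tag prediction:

``shap_like``
    Gradient x embedding scores.  With ``G = dL/dE(x)`` the gradient of
    the tag-prediction loss with respect to the input token embeddings,
    the per-residue score is ``phi_i = sum_j G_ij * e_ij``, i.e.
    ``phi = (G (Hadamard) E(x)) 1_d``.  An exact Shapley enumerator is
    provided as the independent test oracle for the additive case.

``integrated_gradients``
    Path-integral attribution from a reference embedding (the padding
    token by default) to the true input,

        IG_i = (x_i - x0_i) . integral_0^1 dF/dx_i (x0 + a(x - x0)) da,

    with ``F`` the pre-softmax logit of the target tag and the integral
    approximated by a midpoint Riemann sum.  IG satisfies completeness:
    the scores sum to ``F(x) - F(x0)``.

``deeplift_windowed``
    Reference-based attribution computed in sliding windows (default
    32 residues, stride 16, so adjacent windows share 16 positions:
    window 1 covers 0-31, window 2 covers 16-47, ...).  Each window is
    attributed independently against the reference via the same
    straight-line path integral, which makes the per-window scores sum
    to Delta-y = y(x) - y(x0) exactly in the many-step limit; the
    per-position profile averages all windows covering a position.

All methods operate through the model's embedding interface
(``token_embeddings`` / ``forward_from_embeddings`` /
``grad_wrt_embeddings``), so any differentiable sequence scorer with
that surface can be attributed, including hand-built linear heads used
as closed-form oracles in the tests.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Callable, Sequence

import numpy as np
from sklearn.cluster import KMeans


@dataclasses.dataclass(frozen=True)
class AttributionVector:
    scores: np.ndarray
    method: str
    target: str
    baseline_id: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite attribution scores")


@dataclasses.dataclass(frozen=True)
class WindowSpan:
    start: int
    end: int  # inclusive
    index: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclasses.dataclass
class WindowedAttributionProfile:
    profile: np.ndarray
    window_attributions: list[np.ndarray]
    spans: list[WindowSpan]
    window: int
    stride: int
    baseline_id: str


@dataclasses.dataclass(frozen=True)
class ClusteringResult:
    k_selected: int
    assignments: np.ndarray
    inertia_curve: list[tuple[int, float]]


# ---------------------------------------------------------------------------
# Shared plumbing
# ---------------------------------------------------------------------------

def _target_id(model, target_tag: str) -> int:
    t2i = model.vocab.token_to_id
    if target_tag not in t2i:
        raise ValueError(f"target tag {target_tag!r} not in vocabulary")
    return t2i[target_tag]


def _encode_no_pad(model, sequence: str) -> np.ndarray:
    if not sequence:
        raise ValueError("cannot attribute a zero-length sequence")
    return model.vocab.encode(sequence)


def _baseline_embeddings(model, shape: tuple[int, int], baseline) -> tuple[np.ndarray, str]:
    if isinstance(baseline, np.ndarray):
        if baseline.shape != shape:
            raise ValueError(
                f"baseline shape {baseline.shape} != input shape {shape}")
        return baseline, "custom"
    if baseline == "zero":
        return np.zeros(shape), "zero"
    if baseline == "pad":
        pad_row = model.token_embeddings(np.array([model.vocab.pad_id]))[0, 0]
        return np.broadcast_to(pad_row, shape).copy(), "pad"
    raise ValueError(f"unknown baseline {baseline!r}")


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max()
    e = np.exp(z)
    return e / e.sum()


# ---------------------------------------------------------------------------
# SHAP-like gradient x embedding
# ---------------------------------------------------------------------------

def shap_like(model, sequence: str, target_tag: str,
              score: str = "loss") -> AttributionVector:
    """phi_i = sum_j (dL/de_ij) e_ij for the target-tag prediction loss.

    ``L`` is the cross-entropy of predicting ``target_tag`` as the next
    token after the sequence; the gradient is taken with respect to the
    input token embeddings and contracted with them per residue.  With
    ``score="logit"`` the raw pre-softmax tag logit is attributed
    instead, which makes the scores coincide with exact Shapley values
    whenever the logit is additive in the embeddings.
    """
    if score not in ("loss", "logit"):
        raise ValueError(f"unknown score {score!r}")
    ids = _encode_no_pad(model, sequence)
    target = _target_id(model, target_tag)
    emb = model.token_embeddings(ids)[0]
    logits = model.forward_from_embeddings(emb)
    dlogits = np.zeros_like(logits)
    if score == "loss":
        p = _softmax(np.asarray(logits[-1], dtype=np.float64))
        p[target] -= 1.0  # d(-log softmax_target)/dlogits
        dlogits[-1] = p
    else:
        dlogits[-1, target] = 1.0
    grad = model.grad_wrt_embeddings(emb, dlogits)
    phi = np.asarray((grad * emb).sum(-1), dtype=np.float64)
    return AttributionVector(phi, "shap_like", target_tag)


def exhaustive_shapley(
    value_function: Callable[[frozenset[int]], float], n_features: int
) -> np.ndarray:
    """Exact Shapley values by full 2^n subset enumeration (test oracle).

    Phi_i = sum over S not containing i of
            |S|! (n-|S|-1)! / n! * [v(S + {i}) - v(S)].
    """
    if n_features > 12:
        raise ValueError("exhaustive enumeration limited to n_features <= 12")
    n = n_features
    phi = np.zeros(n)
    features = range(n)
    fact = math.factorial
    for i in features:
        rest = [j for j in features if j != i]
        for r in range(len(rest) + 1):
            weight = fact(r) * fact(n - r - 1) / fact(n)
            for subset in itertools.combinations(rest, r):
                s = frozenset(subset)
                phi[i] += weight * (value_function(s | {i}) - value_function(s))
    return phi


# ---------------------------------------------------------------------------
# Integrated gradients
# ---------------------------------------------------------------------------

def integrated_gradients(
    model,
    sequence: str,
    target_tag: str,
    steps: int = 50,
    baseline: str | np.ndarray = "pad",
) -> AttributionVector:
    """Midpoint-rule integrated gradients toward the target tag logit."""
    if steps < 1:
        raise ValueError("steps must be >= 1")
    ids = _encode_no_pad(model, sequence)
    target = _target_id(model, target_tag)
    x = model.token_embeddings(ids)[0]
    x0, baseline_id = _baseline_embeddings(model, x.shape, baseline)
    delta = x - x0

    alphas = (np.arange(steps) + 0.5) / steps
    path = x0[None] + alphas[:, None, None] * delta[None]  # (steps, T, d)
    dlogits = np.zeros((steps,) + model.forward_from_embeddings(x).shape)
    dlogits[:, -1, target] = 1.0
    grads = model.grad_wrt_embeddings(path, dlogits)  # (steps, T, d)
    ig = (delta * grads.mean(0)).sum(-1)
    return AttributionVector(
        np.asarray(ig, dtype=np.float64), "integrated_gradients",
        target_tag, baseline_id,
    )


def completeness_gap(
    model, sequence: str, target_tag: str, attribution: AttributionVector,
    baseline: str | np.ndarray = "pad",
) -> float:
    """Relative gap |sum(IG) - (F(x) - F(x0))| / |F(x) - F(x0)|."""
    ids = _encode_no_pad(model, sequence)
    target = _target_id(model, target_tag)
    x = model.token_embeddings(ids)[0]
    x0, _ = _baseline_embeddings(model, x.shape, baseline)
    fx = float(model.forward_from_embeddings(x)[-1, target])
    f0 = float(model.forward_from_embeddings(x0)[-1, target])
    delta_y = fx - f0
    return abs(attribution.scores.sum() - delta_y) / max(abs(delta_y), 1e-12)


# ---------------------------------------------------------------------------
# Windowed reference-based attribution
# ---------------------------------------------------------------------------

def window_spans(seq_len: int, window: int = 32, stride: int = 16) -> list[WindowSpan]:
    """Sliding spans from position 0, ``stride`` apart, covering every position.

    Full windows are emitted while they fit; if trailing residues would
    be uncovered, one final truncated span is appended (starting one
    stride after the last full window).
    """
    if window < 1 or not 1 <= stride <= window:
        raise ValueError("need window >= 1 and 1 <= stride <= window")
    if seq_len == 0:
        return []
    spans = []
    start = 0
    while start + window <= seq_len:
        spans.append(WindowSpan(start, start + window - 1, len(spans)))
        start += stride
    covered = spans[-1].end if spans else -1
    if covered < seq_len - 1:
        trunc_start = spans[-1].start + stride if spans else 0
        spans.append(WindowSpan(trunc_start, seq_len - 1, len(spans)))
    return spans


def deeplift_windowed(
    model,
    sequence: str,
    target_tag: str,
    window: int = 32,
    stride: int = 16,
    steps: int = 32,
    baseline: str | np.ndarray = "pad",
    reducer: str = "mean",
) -> WindowedAttributionProfile:
    """Per-window reference-based attribution, averaged per position.

    Each window is tokenized and attributed independently against the
    reference embedding; within a window the scores sum to the window's
    output difference Delta-y.  Overlapping windows are combined by the
    arithmetic mean per position (``reducer="sum"`` keeps the raw sum).
    """
    if window > model.config.context_length:
        raise ValueError("window exceeds model context length")
    if reducer not in ("mean", "sum"):
        raise ValueError(f"unknown reducer {reducer!r}")
    L = len(sequence)
    spans = window_spans(L, window, stride)
    profile = np.zeros(L)
    coverage = np.zeros(L)
    per_window: list[np.ndarray] = []
    baseline_id = ""
    for span in spans:
        sub = sequence[span.start : span.end + 1]
        att = integrated_gradients(model, sub, target_tag, steps=steps,
                                   baseline=baseline)
        baseline_id = att.baseline_id
        per_window.append(att.scores)
        profile[span.start : span.end + 1] += att.scores
        coverage[span.start : span.end + 1] += 1.0
    if reducer == "mean" and L:
        profile /= np.maximum(coverage, 1.0)
    return WindowedAttributionProfile(
        profile=profile, window_attributions=per_window, spans=spans,
        window=window, stride=stride, baseline_id=baseline_id,
    )


# ---------------------------------------------------------------------------
# Clustering of attribution matrices
# ---------------------------------------------------------------------------

def cluster_attributions(
    matrix: np.ndarray,
    kmax: int = 10,
    seed: int = 0,
    drop_threshold_pct: float = 20.0,
) -> ClusteringResult:
    """Elbow-selected k-means over z-scored attribution rows.

    Inertia is computed for k = 1..min(kmax, n); the selected k is the
    first whose percentage decrease in inertia relative to k-1 falls
    below ``drop_threshold_pct`` (if the inertia is already ~0 at k-1,
    that k-1 is selected; if no k qualifies, the largest k is used).
    """
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    n = X.shape[0]
    mu = X.mean(0)
    sd = X.std(0)
    sd[sd == 0] = 1.0
    Xz = (X - mu) / sd

    upper = min(kmax, n)
    curve: list[tuple[int, float]] = []
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(1, upper + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Xz)
        curve.append((k, float(km.inertia_)))
        labels_by_k[k] = km.labels_

    k_selected = upper
    for k in range(2, upper + 1):
        prev = curve[k - 2][1]
        if prev <= 1e-12:
            k_selected = k - 1
            break
        pct = (prev - curve[k - 1][1]) / prev * 100.0
        if pct < drop_threshold_pct:
            k_selected = k
            break
    if upper == 1:
        k_selected = 1
    return ClusteringResult(k_selected, labels_by_k[k_selected], curve)
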