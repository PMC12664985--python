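"""Next-token tag-aggregation classification and evaluation metrics.

A trained model classifies a sequence by the decision rule

    y_hat = argmax_y p(y | x; theta),

where the posterior over class labels is the next-token softmax
restricted to the class-tag tokens at the first generated position.
Full-length proteins in TI-free mode are cut into non-overlapping
100-residue windows, each window votes, and the sequence label is the
majority vote (ties -> "unknown").  The remainder shorter than 100
residues is classified as its own padded fragment so that inference
covers whole proteins.

Metrics follow the standard one-vs-rest confusion convention:

    Precision = TP/(TP+FP),  Recall = TP/(TP+FN),
    F1 = 2 P R/(P+R),
    macro F1  = unweighted mean of per-class F1,
    weighted F1 = support-weighted mean.

An "unknown" prediction counts as a false negative for its true class
and never as a false positive for any class.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import CausalTransformer, DELIMITER, softmax
from .synthetic_data import SequenceRecord

UNKNOWN = "unknown"
FRAGMENT_LEN = 100


@dataclasses.dataclass(frozen=True)
class ClassPrediction:
    id: str
    predicted: str
    posterior: dict[str, float]
    n_tag_tokens_generated: int
    tie: bool = False


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    per_class: dict[str, dict[str, float]]  # precision/recall/f1/support + counts
    macro_f1: float
    weighted_f1: float
    accuracy: float
    n_unknown: int


def _tag_label_map(model: CausalTransformer,
                   tag_map: Mapping[str, str]) -> dict[int, str]:
    return {model.vocab.tag_ids[tag]: label for label, tag in tag_map.items()}


def predict_tag(
    model: CausalTransformer,
    sequence: str,
    tag_map: Mapping[str, str],
    mode: str = "tifree",
    scan_k: int | None = None,
    seq_id: str = "",
) -> ClassPrediction:
    """Classify one sequence (or fragment) from the next-token tags.

    The posterior is the softmax at the first generated position
    restricted to tag tokens; ``predicted`` is the argmax with a
    deterministic tie-break to the first class in ``tag_map`` order
    (flagged).  With ``scan_k`` the model instead generates ``scan_k``
    tokens greedily and the first tag token found decides the class
    ("unknown" when none of the generated tokens is a tag).
    """
    if not sequence:
        raise ValueError("cannot classify an empty sequence")
    prompt = sequence + DELIMITER if mode == "tiinc" else sequence
    ids = model.vocab.encode(prompt)
    logits = model.forward(ids)
    probs = softmax(logits[-1])
    id_to_label = _tag_label_map(model, tag_map)
    posterior = {label: float(probs[tid]) for tid, label in id_to_label.items()}

    if scan_k is not None:
        generated = model.generate_greedy(ids, scan_k)
        hit = next((t for t in generated if t in id_to_label), None)
        predicted = id_to_label[hit] if hit is not None else UNKNOWN
        return ClassPrediction(seq_id, predicted, posterior, len(generated))

    labels = list(tag_map)  # configured class order
    best = max(posterior.values())
    winners = [lbl for lbl in labels if posterior[lbl] == best]
    return ClassPrediction(
        id=seq_id,
        predicted=winners[0],
        posterior=posterior,
        n_tag_tokens_generated=1,
        tie=len(winners) > 1,
    )


def _fragments_for_inference(sequence: str, l: int = FRAGMENT_LEN) -> list[str]:
    """Non-overlapping l-mers plus the trailing remainder as its own piece."""
    frags = [sequence[i : i + l] for i in range(0, len(sequence), l)]
    return frags if frags else [sequence]


def classify_fasta(
    model: CausalTransformer,
    records: Sequence[SequenceRecord],
    tag_map: Mapping[str, str],
    mode: str = "tifree",
    scan_k: int | None = None,
) -> pd.DataFrame:
    """Classify records; long TI-free inputs vote over 100-mer windows.

    Returns a table with one row per record: predicted label, mean tag
    posterior per class, number of fragment votes, and a tie flag.
    A ``coverage`` attribute on the frame reports the fraction of
    inputs that received a non-"unknown" prediction.
    """
    rows = []
    labels = list(tag_map)
    for rec in records:
        if mode == "tifree" and len(rec.sequence) > FRAGMENT_LEN:
            pieces = _fragments_for_inference(rec.sequence)
        else:
            pieces = [rec.sequence]
        preds = [
            predict_tag(model, piece, tag_map, mode=mode, scan_k=scan_k,
                        seq_id=rec.id)
            for piece in pieces
        ]
        votes = pd.Series([p.predicted for p in preds]).value_counts()
        votes = votes[votes.index != UNKNOWN]
        if votes.empty:
            final, tie = UNKNOWN, False
        else:
            top = votes[votes == votes.max()]
            tie = len(top) > 1
            final = UNKNOWN if tie else str(top.index[0])
        mean_post = {
            lbl: float(np.mean([p.posterior[lbl] for p in preds]))
            for lbl in labels
        }
        rows.append(
            {"id": rec.id, "predicted": final, "n_fragments": len(pieces),
             "tie": tie, **{f"p_{lbl}": mean_post[lbl] for lbl in labels}}
        )
    df = pd.DataFrame(rows)
    df.attrs["coverage"] = (
        float((df["predicted"] != UNKNOWN).mean()) if len(df) else 0.0
    )
    return df


def compute_metrics(
    predictions: Mapping[str, str] | pd.DataFrame,
    truths: Mapping[str, str],
    class_labels: Sequence[str] | None = None,
) -> MetricsReport:
    """Per-class precision/recall/F1 plus macro, weighted F1 and accuracy."""
    if isinstance(predictions, pd.DataFrame):
        predictions = dict(zip(predictions["id"], predictions["predicted"]))
    missing = set(predictions) - set(truths)
    if missing:
        raise ValueError(f"predictions without ground truth: {sorted(missing)}")
    ids = list(predictions)
    y_pred = [predictions[i] for i in ids]
    y_true = [truths[i] for i in ids]
    if class_labels is None:
        class_labels = sorted(set(y_true))

    per_class: dict[str, dict[str, float]] = {}
    f1s, supports = [], []
    for c in class_labels:
        tp = sum(p == c and t == c for p, t in zip(y_pred, y_true))
        fp = sum(p == c and t != c for p, t in zip(y_pred, y_true))
        fn = sum(t == c and p != c for p, t in zip(y_pred, y_true))
        tn = len(ids) - tp - fp - fn
        support = tp + fn
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[c] = {
            "precision": prec, "recall": rec, "f1": f1, "support": support,
            "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        }
        f1s.append(f1)
        supports.append(support)

    total_support = sum(supports)
    return MetricsReport(
        per_class=per_class,
        macro_f1=float(np.mean(f1s)) if f1s else 0.0,
        weighted_f1=(
            float(np.dot(f1s, supports) / total_support) if total_support else 0.0
        ),
        accuracy=float(np.mean([p == t for p, t in zip(y_pred, y_true)])),
        n_unknown=sum(p == UNKNOWN for p in y_pred),
    )
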