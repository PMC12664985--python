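"""Training-set construction: TI-free chimeras and TI-inclusive tagging.

Terminal information (TI) — the N-/C-terminal signal and gene-boundary
cues of natural proteins — is deliberately destroyed in the TI-free
regime: all sequences of a class are concatenated into one continuous
"unisequence" (headers and line breaks removed), segmented into fixed
100-residue fragments

    f_j = (a_{(j-1)l+1}, ..., a_{jl}),  l = 100,  j = 1..floor(L/l),

and fully shuffled.  Fragments may straddle gene boundaries; that
chimerism is the point.  The trailing remainder shorter than ``l`` is
discarded so every fragment has exactly the same length, removing
length as a predictive cue.

The TI-inclusive regime keeps full-length natural sequences and appends
``"<" + tag``; the ``<`` delimiter marks the switch from sequence
sampling to label sampling during generation.

Class balance is enforced by downsampling every pool to the smallest
(1:1 for two classes, equal counts for the four-way mode), and holdout
splits are screened against the training set by fixed-string,
whole-line matching of the bare fragment text.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Mapping, Sequence

import numpy as np

from .synthetic_data import SequenceRecord

DEFAULT_FRAGMENT_LEN = 100
DEFAULT_SPLITS = (0.8, 0.1, 0.1)
SPLIT_NAMES = ("train", "eval", "test")


@dataclasses.dataclass
class LabeledDataset:
    """An ordered list of (text, label) items for one split."""

    items: list[tuple[str, str]]
    split: str
    class_counts: dict[str, int]

    @classmethod
    def from_items(cls, items: Sequence[tuple[str, str]], split: str) -> "LabeledDataset":
        return cls(list(items), split, dict(Counter(lbl for _, lbl in items)))

    def __len__(self) -> int:
        return len(self.items)


@dataclasses.dataclass(frozen=True)
class DedupReport:
    n_overlap: int
    n_before: int
    n_after: int
    removed_ids: list[int]


def build_unisequence(records: Sequence[SequenceRecord]) -> str:
    """Concatenate sequences in input order, headers/newlines removed."""
    if not records:
        raise ValueError("cannot build a unisequence from zero records")
    return "".join(r.sequence for r in records)


def fragment(unisequence: str, l: int = DEFAULT_FRAGMENT_LEN) -> list[str]:
    """Cut ``floor(L/l)`` fragments of exactly ``l`` residues.

    The trailing remainder of fewer than ``l`` residues is discarded.
    An empty unisequence yields an empty list.
    """
    if l < 1:
        raise ValueError("fragment length must be >= 1")
    n = len(unisequence) // l
    return [unisequence[j * l : (j + 1) * l] for j in range(n)]


def assemble_tifree(
    frags_by_class: Mapping[str, Sequence[str]],
    seed: int,
    splits: Sequence[float] = DEFAULT_SPLITS,
) -> dict[str, LabeledDataset]:
    """Balance, shuffle and partition per-class fragment pools.

    Every pool is downsampled (seeded, without replacement) to the size
    of the smallest pool, enforcing equal class counts.  The combined,
    labelled pool is then shuffled once and partitioned by the split
    fractions (train/eval/test).
    """
    if len(frags_by_class) < 2:
        raise ValueError("need at least two class pools")
    if any(len(v) == 0 for v in frags_by_class.values()):
        empty = [k for k, v in frags_by_class.items() if len(v) == 0]
        raise ValueError(f"empty fragment pool(s): {empty}")
    if abs(sum(splits) - 1.0) > 1e-9 or len(splits) != len(SPLIT_NAMES):
        raise ValueError("split fractions must be three values summing to 1")

    rng = np.random.default_rng(seed)
    n_keep = min(len(v) for v in frags_by_class.values())
    pool: list[tuple[str, str]] = []
    for label in sorted(frags_by_class):
        frags = list(frags_by_class[label])
        if len(frags) > n_keep:
            idx = rng.choice(len(frags), size=n_keep, replace=False)
            frags = [frags[i] for i in sorted(idx)]
        pool.extend((text, label) for text in frags)

    order = rng.permutation(len(pool))
    pool = [pool[i] for i in order]

    bounds = np.floor(np.cumsum(splits) * len(pool)).astype(int)
    out: dict[str, LabeledDataset] = {}
    start = 0
    for name, stop in zip(SPLIT_NAMES, bounds):
        out[name] = LabeledDataset.from_items(pool[start:stop], name)
        start = stop
    return out


def prep_tiinclusive(
    records: Sequence[SequenceRecord], tag_map: Mapping[str, str]
) -> list[str]:
    """Append ``"<" + tag`` to each full-length sequence."""
    bad = [r.id for r in records
           if r.true_class is None or r.true_class not in tag_map]
    if bad:
        raise ValueError(f"records with missing/unknown class: {bad}")
    return [r.sequence + "<" + tag_map[r.true_class] for r in records]


def strip_tag(tagged: str) -> str:
    """Recover the original sequence from a tagged training string."""
    return tagged[: tagged.rindex("<")]


def dedup_screen(
    holdout: LabeledDataset, train: LabeledDataset
) -> tuple[LabeledDataset, DedupReport]:
    """Drop holdout items whose bare text exactly matches any training text."""
    train_texts = {text for text, _ in train.items}
    kept, removed = [], []
    for i, (text, label) in enumerate(holdout.items):
        if text in train_texts:
            removed.append(i)
        else:
            kept.append((text, label))
    report = DedupReport(
        n_overlap=len(removed),
        n_before=len(holdout.items),
        n_after=len(kept),
        removed_ids=removed,
    )
    return LabeledDataset.from_items(kept, holdout.split), report
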