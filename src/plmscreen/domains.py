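"""Motif-to-domain scanning and weighted relevance scoring.

Model-derived motifs (possibly degenerate, with 'X' matching any single
residue) are scanned against a PFAM-A-like domain FASTA.  For every
(motif, accession) pair the number of occurrences is counted —
overlapping matches included — and combined with the motif's mean model
influence into

    weighted_score = count x mean_score,

favouring motifs that are both salient to the model and recurrent in
known domain families.  Rows are ranked by weighted score descending
(ties: higher count first, then motif lexicographically), and the
ranked table can be collapsed to the unique accessions among the top-k
rows.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

_PFAM_ACC = re.compile(r"PF\d{5}(?:\.\d+)?$")

COLUMNS = ["motif", "accession", "count", "mean_score"]


def parse_accession(header: str) -> str | None:
    """Accession from a FASTA header: first ``PFxxxxx[.v]`` token
    (version stripped), else the first token; None for empty headers."""
    tokens = header.split()
    for tok in tokens:
        if _PFAM_ACC.match(tok):
            return tok.split(".")[0]
    return tokens[0] if tokens else None


def count_occurrences(pattern: str, sequence: str) -> int:
    """Occurrences of a motif in a sequence, overlaps included.

    'X' in the pattern matches any single residue; counting uses a
    lookahead so "AAA" occurs twice in "AAAA".
    """
    regex = re.compile("(?=" + pattern.replace("X", ".") + ")")
    return sum(1 for _ in regex.finditer(sequence))


def scan_motifs(
    motifs: Sequence[tuple[str, float]],
    domain_fasta: str | Path | Iterable,
) -> pd.DataFrame:
    """Count every motif in every domain sequence, aggregated by accession.

    ``motifs`` is a list of (pattern, mean influence score) pairs;
    ``domain_fasta`` is a path or an iterable of Biopython records with
    accession-bearing headers.  Records without a parseable accession
    are skipped with a warning.  Zero-count pairs are suppressed.
    """
    if isinstance(domain_fasta, (str, Path)):
        records = SeqIO.parse(str(domain_fasta), "fasta")
    else:
        records = domain_fasta
    counts: dict[tuple[str, str], int] = {}
    n_skipped = 0
    for rec in records:
        accession = parse_accession(rec.description or rec.id)
        if accession is None:
            n_skipped += 1
            continue
        seq = str(rec.seq).upper()
        for pattern, _ in motifs:
            n = count_occurrences(pattern, seq)
            if n:
                key = (pattern, accession)
                counts[key] = counts.get(key, 0) + n
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} record(s) without accession")
    scores = dict(motifs)
    df = pd.DataFrame(
        [
            {"motif": m, "accession": acc, "count": n, "mean_score": scores[m]}
            for (m, acc), n in counts.items()
        ],
        columns=COLUMNS,
    )
    df.attrs["n_skipped"] = n_skipped
    return df


def score_and_rank(table: pd.DataFrame) -> pd.DataFrame:
    """Append ``weighted_score = count x mean_score`` and sort descending.

    Ties break by count descending then motif ascending.  The operation
    is a pure permutation of the input rows plus one appended column.
    """
    out = table.copy()
    out["weighted_score"] = out["count"] * out["mean_score"]
    out = out.sort_values(
        ["weighted_score", "count", "motif"],
        ascending=[False, False, True],
        kind="mergesort",  # stable, streaming-friendly external-sort analogue
    ).reset_index(drop=True)
    return out


def top_k_unique_domains(sorted_table: pd.DataFrame, k: int) -> set[str]:
    """Unique accessions among the top-k rows of a ranked table."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return set(sorted_table.head(k)["accession"])
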