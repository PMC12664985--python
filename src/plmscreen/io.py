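"""FASTA and tabular input/output helpers.

FASTA handling is delegated to Biopython; records are exposed as
:class:`~plmscreen.synthetic_data.SequenceRecord`.  Headers written by
this package carry the ground-truth class as a ``class=<label>`` token,
and the reader recovers it when present.  Sequences are upper-cased and
'*' stop codons are stripped on read.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioRecord

from .synthetic_data import SequenceRecord

_CLASS_RE = re.compile(r"\bclass=(\S+)")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read protein FASTA; case-folds to upper and strips '*' stops."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _CLASS_RE.search(rec.description)
        seq = str(rec.seq).upper().replace("*", "")
        records.append(
            SequenceRecord(id=rec.id, sequence=seq,
                           true_class=m.group(1) if m else None)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records wrapped at 60 columns, header ``><id> class=<label>``."""
    bio = [
        BioRecord(
            Seq(r.sequence),
            id=r.id,
            description=f"class={r.true_class}" if r.true_class else "",
        )
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_lines(path: str | Path) -> list[str]:
    """One bare string per line (fragment / tagged-string dataset files)."""
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def write_lines(lines: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
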