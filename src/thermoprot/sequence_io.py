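"""Reading, validating and writing protein sequences and their class labels.

Sequences are plain FASTA (Biopython does the parsing); labels arrive either
as a pair of FASTA files (positive class = thermophilic by convention) or as a
header-less two-column TSV ``id<TAB>{0,1}``.  Validation enforces the
canonical 20-letter alphabet: any ambiguity code (B, J, O, U, X, Z), stop
('*') or gap character rejects the sequence.  Database-level screening rules
(manual annotation status, fragment flags, inferred-by-homology evidence) are
metadata filters that cannot be checked from the residue string and are
deliberately not enforced here.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tables import AMINO_ACIDS

logger = logging.getLogger(__name__)

_VALID_RE = re.compile(rf"[{AMINO_ACIDS}]+\Z")


@dataclass
class ProteinSequence:
    """A validated-alphabet protein sequence with an identifier and optional label."""

    id: str
    residues: str
    label: int | None = None

    def __len__(self) -> int:
        return len(self.residues)


class ValidationVerdict(NamedTuple):
    accepted: bool
    reason: str | None = None


def validate_sequence(seq: ProteinSequence) -> ValidationVerdict:
    """Accept iff every residue is one of the 20 canonical letters.

    The verdict for a rejected sequence names the first offending character
    and its 1-based position.  Callers decide whether rejection is fatal.
    """
    if not seq.residues:
        return ValidationVerdict(False, "empty sequence")
    if _VALID_RE.fullmatch(seq.residues):
        return ValidationVerdict(True)
    for pos, ch in enumerate(seq.residues, start=1):
        if ch not in AMINO_ACIDS:
            return ValidationVerdict(
                False, f"non-canonical residue {ch!r} at position {pos}"
            )
    raise AssertionError("unreachable")  # pragma: no cover


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a FASTA file into :class:`ProteinSequence` records, order preserved.

    Wrapped sequence lines are concatenated and uppercased.  A missing or
    empty file, or a record with no residues, is a hard error naming the
    record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        if not residues:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        records.append(ProteinSequence(id=rec.id, residues=residues))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path) -> None:
    """Write sequences as FASTA, wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(Path(path)), "fasta")


@dataclass
class LabeledDataset:
    """An ordered collection of labeled sequences with both classes present."""

    sequences: list[ProteinSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dup = next(i for i, c in Counter(ids).items() if c > 1)
            raise ValueError(f"duplicate sequence id {dup!r} in dataset")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[ProteinSequence]:
        return iter(self.sequences)

    @property
    def class_counts(self) -> dict[int, int]:
        return dict(Counter(s.label for s in self.sequences if s.label is not None))

    def require_both_classes(self) -> None:
        counts = self.class_counts
        if counts.get(0, 0) == 0 or counts.get(1, 0) == 0:
            raise ValueError(
                f"both classes must be present; got class counts {counts}"
            )


def _validate_group(
    sequences: list[ProteinSequence], label: int, strict: bool
) -> list[ProteinSequence]:
    kept = []
    dropped = 0
    for seq in sequences:
        verdict = validate_sequence(seq)
        if verdict.accepted:
            kept.append(ProteinSequence(seq.id, seq.residues, label))
        elif strict:
            raise ValueError(f"sequence {seq.id!r} rejected: {verdict.reason}")
        else:
            dropped += 1
            logger.warning("dropping %s: %s", seq.id, verdict.reason)
    if dropped:
        logger.warning("dropped %d invalid sequence(s) for label %d", dropped, label)
    return kept


def load_labeled(
    pos_path: str | Path, neg_path: str | Path, strict: bool = False
) -> LabeledDataset:
    """Load a positive (label 1) and negative (label 0) FASTA pair.

    Invalid sequences are dropped with a logged count; under ``strict`` they
    raise.  A duplicate id across the two files, or a class left empty after
    validation, is an error.
    """
    positives = _validate_group(read_fasta(pos_path), 1, strict)
    negatives = _validate_group(read_fasta(neg_path), 0, strict)
    data = LabeledDataset(positives + negatives)
    data.require_both_classes()
    return data


def read_label_tsv(path: str | Path) -> dict[str, int]:
    """Read a header-less ``id<TAB>{0,1}`` label table."""
    labels: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2 or parts[1] not in {"0", "1"}:
            raise ValueError(f"{path}:{lineno}: expected 'id<TAB>0|1', got {line!r}")
        seq_id, label = parts[0], int(parts[1])
        if seq_id in labels and labels[seq_id] != label:
            raise ValueError(f"{path}: conflicting labels for id {seq_id!r}")
        labels[seq_id] = label
    return labels


def write_label_tsv(data: LabeledDataset, path: str | Path) -> None:
    lines = [f"{s.id}\t{s.label}" for s in data if s.label is not None]
    Path(path).write_text("\n".join(lines) + "\n")


def load_labeled_tsv(
    fasta_path: str | Path, tsv_path: str | Path, strict: bool = False
) -> LabeledDataset:
    """Load one FASTA file with labels supplied by a TSV table.

    Every FASTA id must appear in the table; conflicting table entries raise.
    """
    labels = read_label_tsv(tsv_path)
    sequences = read_fasta(fasta_path)
    missing = [s.id for s in sequences if s.id not in labels]
    if missing:
        raise ValueError(f"ids missing from label table: {missing[:5]}")
    pos = [s for s in sequences if labels[s.id] == 1]
    neg = [s for s in sequences if labels[s.id] == 0]
    data = LabeledDataset(
        _validate_group(pos, 1, strict) + _validate_group(neg, 0, strict)
    )
    data.require_both_classes()
    return data
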