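"""Reading, validating and writing protein sequences and pair-label tables.

Sequences are plain 20-letter amino-acid strings.  Interaction data is a
flat table of (id_a, id_b, label) rows with binary labels; datasets are
expected (but not required) to be class-balanced, as is conventional for
benchmark PPI sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)


class SequenceError(ValueError):
    """A sequence or sequence file violates the package's contracts."""


class PairTableError(ValueError):
    """A pair-label table violates the package's contracts."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier plus its validated amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise SequenceError(f"protein {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_natural(self) -> bool:
        """True if the sequence uses only the 20 standard letters."""
        return set(self.sequence) <= _STANDARD_SET


@dataclass(frozen=True)
class LabeledPair:
    """Two protein identifiers with a binary interaction label."""

    id_a: str
    id_b: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise PairTableError(
                f"pair ({self.id_a}, {self.id_b}): label must be 0 or 1, "
                f"got {self.label!r}"
            )


def _clean_sequence(raw: str, rec_id: str) -> str:
    """Uppercase and strip terminal stop characters ('*') from a raw sequence."""
    seq = raw.upper().strip("*")
    if not seq:
        raise SequenceError(f"protein {rec_id!r}: empty sequence after cleanup")
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into a list of :class:`ProteinRecord`.

    Sequences are uppercased; terminal ``*`` stop characters are stripped.
    Duplicate identifiers are rejected.  An empty file yields an empty list.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, FileNotFoundError) as exc:
        raise SequenceError(f"cannot parse FASTA {path}: {exc}") from exc
    for rec in parsed:
        if rec.id in seen:
            raise SequenceError(f"duplicate protein id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, _clean_sequence(str(rec.seq), rec.id)))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA; round-trips exactly through :func:`read_fasta`."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def filter_natural(
    records: Sequence[ProteinRecord], strict: bool = False
) -> tuple[list[ProteinRecord], list[str]]:
    """Split records into those over the standard alphabet and the rest.

    Ambiguity and non-standard codes (B, J, O, U, X, Z, internal ``*``, or
    anything else outside the 20 letters) mark a protein as non-natural.
    In strict mode the first offending residue raises instead of filtering.

    Returns
    -------
    kept, excluded_ids
        Records whose sequences use only the 20 standard letters, and the
        identifiers of every excluded record.
    """
    kept: list[ProteinRecord] = []
    excluded: list[str] = []
    for rec in records:
        bad = next(
            ((i, c) for i, c in enumerate(rec.sequence) if c not in _STANDARD_SET),
            None,
        )
        if bad is None:
            kept.append(rec)
        elif strict:
            pos, letter = bad
            raise SequenceError(
                f"protein {rec.id!r}: non-natural residue {letter!r} "
                f"at position {pos + 1}"
            )
        else:
            excluded.append(rec.id)
    if excluded:
        logger.info("excluded %d proteins with non-natural residues", len(excluded))
    return kept, excluded


def read_pairs(
    path: str | Path, records: Sequence[ProteinRecord]
) -> list[LabeledPair]:
    """Read a tab-separated pair-label table validated against *records*.

    Expected columns: ``id_a<TAB>id_b<TAB>label`` with an optional header
    row; lines starting with ``#`` are ignored.  Pairs referencing unknown
    (e.g. excluded) proteins are dropped with a logged count; labels outside
    {0, 1} raise.
    """
    path = Path(path)
    known = {r.id for r in records}
    pairs: list[LabeledPair] = []
    dropped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise PairTableError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            id_a, id_b, raw_label = fields
            if lineno == 1 and raw_label.lower() == "label":
                continue  # header row
            try:
                label = int(raw_label)
            except ValueError as exc:
                raise PairTableError(
                    f"{path}:{lineno}: label {raw_label!r} is not an integer"
                ) from exc
            if label not in (0, 1):
                raise PairTableError(
                    f"{path}:{lineno}: label must be 0 or 1, got {label}"
                )
            if id_a not in known or id_b not in known:
                dropped += 1
                continue
            pairs.append(LabeledPair(id_a, id_b, label))
    if dropped:
        logger.info("dropped %d pairs referencing unknown proteins", dropped)
    return pairs


def write_pairs(pairs: Iterable[LabeledPair], path: str | Path) -> None:
    """Write pairs as a TSV with an ``id_a<TAB>id_b<TAB>label`` header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id_a\tid_b\tlabel\n")
        for p in pairs:
            fh.write(f"{p.id_a}\t{p.id_b}\t{p.label}\n")


def class_balance(pairs: Sequence[LabeledPair]) -> tuple[int, int]:
    """Return (count of label-1 pairs, count of label-0 pairs)."""
    pos = sum(1 for p in pairs if p.label == 1)
    return pos, len(pairs) - pos
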