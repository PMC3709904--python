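"""Protein sequence (FASTA) and labeled interaction-pair table I/O.

The pair table is the central input: each row anchors a known transcription
factor (first column) against one of its experimentally observed binding
partners (second column), optionally labeled with the partner's functional
class — ``TF``, ``TCOF`` (transcription co-factor) or ``OTHER`` (other
nuclear protein).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

from Bio import SeqIO

from .aaindex import RESIDUE_ORDER

__all__ = [
    "STANDARD_RESIDUES",
    "AMBIGUOUS_RESIDUES",
    "LABELS",
    "ProteinRecord",
    "InteractionPair",
    "read_fasta",
    "write_fasta",
    "read_pair_table",
    "write_pair_table",
    "resolve_pairs",
]

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = frozenset(RESIDUE_ORDER)
#: Tolerated ambiguity/nonstandard letters (B/Z ambiguous, X unknown,
#: U selenocysteine, O pyrrolysine, J Leu/Ile); how they contribute to
#: features is decided by the featurization ambiguity policy.
AMBIGUOUS_RESIDUES = frozenset("BZXUOJ")
LABELS = ("TF", "TCOF", "OTHER")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier and its uppercase amino-acid sequence."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.protein_id!r} has an empty sequence")
        allowed = STANDARD_RESIDUES | AMBIGUOUS_RESIDUES
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in allowed:
                raise ValueError(
                    f"record {self.protein_id!r}: invalid residue {ch!r} at position {pos}"
                )


@dataclass(frozen=True)
class InteractionPair:
    """One interaction instance: (known TF, binding partner, optional class label)."""

    tf_id: str
    partner_id: str
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.tf_id or not self.partner_id:
            raise ValueError("tf_id and partner_id must be non-empty")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(
                f"unknown label {self.label!r} for pair ({self.tf_id}, {self.partner_id}); "
                f"expected one of {LABELS}"
            )


def _normalize_id(raw_id: str) -> str:
    # UniProt-style "db|ACC|name" headers reduce to the accession.
    parts = raw_id.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1]
    return raw_id


def read_fasta(stream: IO[str] | str) -> list[ProteinRecord]:
    """Read FASTA records; identifiers are the first header token, with
    UniProt ``db|ACC|name`` headers reduced to ``ACC``.

    Sequences are uppercased and line breaks joined.  Duplicate identifiers,
    empty sequences and residues outside the tolerated alphabet are errors.
    """
    handle = io.StringIO(stream) if isinstance(stream, str) else stream
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(handle, "fasta"):
        pid = _normalize_id(rec.id)
        if pid in seen:
            raise ValueError(f"duplicate protein identifier {pid!r} in FASTA input")
        seen.add(pid)
        records.append(ProteinRecord(protein_id=pid, sequence=str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord], stream: IO[str], width: int = 60) -> None:
    """Write records as wrapped FASTA."""
    for rec in records:
        stream.write(f">{rec.protein_id}\n")
        for i in range(0, len(rec.sequence), width):
            stream.write(rec.sequence[i : i + width] + "\n")


def read_pair_table(stream: IO[str] | str, labeled: bool = True) -> list[InteractionPair]:
    """Read a TSV interaction-pair table.

    Two columns (tf_id, partner_id) when ``labeled`` is false, three columns
    (tf_id, partner_id, label) when true.  Lines starting with ``#`` are
    comments.  Exact duplicate rows collapse with a logged warning (the
    training data consists of unique interaction instances); the same id pair
    carrying two different labels is an error.
    """
    text = stream if isinstance(stream, str) else stream.read()
    expected_cols = 3 if labeled else 2
    pairs: list[InteractionPair] = []
    seen_rows: set[tuple] = set()
    label_by_pair: dict[tuple[str, str], str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) != expected_cols:
            raise ValueError(
                f"line {lineno}: expected {expected_cols} tab-separated columns, got {len(cols)}"
            )
        tf_id, partner_id = cols[0].strip(), cols[1].strip()
        label = cols[2].strip().upper() if labeled else None
        row_key = (tf_id, partner_id, label)
        if row_key in seen_rows:
            logger.warning("line %d: duplicate pair row %r collapsed", lineno, row_key)
            continue
        if labeled:
            prev = label_by_pair.get((tf_id, partner_id))
            if prev is not None and prev != label:
                raise ValueError(
                    f"line {lineno}: conflicting labels {prev!r} and {label!r} "
                    f"for pair ({tf_id}, {partner_id})"
                )
            try:
                pair = InteractionPair(tf_id, partner_id, label)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
            label_by_pair[(tf_id, partner_id)] = label
        else:
            pair = InteractionPair(tf_id, partner_id, None)
        seen_rows.add(row_key)
        pairs.append(pair)
    return pairs


def write_pair_table(pairs: Iterable[InteractionPair], stream: IO[str]) -> None:
    for p in pairs:
        if p.label is None:
            stream.write(f"{p.tf_id}\t{p.partner_id}\n")
        else:
            stream.write(f"{p.tf_id}\t{p.partner_id}\t{p.label}\n")


def resolve_pairs(
    pairs: Sequence[InteractionPair],
    records: Sequence[ProteinRecord] | dict[str, ProteinRecord],
    strict: bool = True,
) -> tuple[list[InteractionPair], list[str]]:
    """Cross-reference pair identifiers against available sequences.

    Returns (resolved pairs, sorted list of unresolved identifiers).  In
    strict mode any unresolved identifier aborts with ``KeyError``; in lenient
    mode pairs touching an unresolved identifier are dropped and reported.
    """
    if not isinstance(records, dict):
        records = {r.protein_id: r for r in records}
    unresolved: set[str] = set()
    kept: list[InteractionPair] = []
    for p in pairs:
        missing = [i for i in (p.tf_id, p.partner_id) if i not in records]
        if missing:
            unresolved.update(missing)
        else:
            kept.append(p)
    if unresolved and strict:
        raise KeyError(f"unresolved protein identifiers: {sorted(unresolved)}")
    if unresolved:
        logger.warning(
            "dropped %d pair(s) with %d unresolved identifier(s)",
            len(pairs) - len(kept),
            len(unresolved),
        )
    return kept, sorted(unresolved)
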