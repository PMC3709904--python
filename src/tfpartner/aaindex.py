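"""Reading, selecting and writing amino-acid index tables (AAindex1 flat-file dialect).

An AAindex1 entry assigns one numerical physico-chemical value to each of the
20 standard amino acids.  Entries are keyed by a 10-character accession and may
contain missing values (the literal token ``NA``).  Only the single-residue
dialect is supported here; the 20x20 substitution-matrix dialects (AAindex2/3)
are out of scope.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Sequence

__all__ = [
    "RESIDUE_ORDER",
    "MissingPolicy",
    "AminoAcidIndex",
    "IndexSet",
    "AAindexParseError",
    "parse_aaindex",
    "write_aaindex",
    "select_indices",
    "drop_or_impute_missing",
    "read_accession_list",
    "index_set_to_tsv",
]

#: Canonical residue order of the two AAindex1 value rows:
#: first row A R N D C Q E G H I, second row L K M F P S T W Y V.
RESIDUE_ORDER = "ARNDCQEGHILKMFPSTWYV"


class AAindexParseError(ValueError):
    """Raised when an AAindex1 stream violates the flat-file layout."""


class MissingPolicy(str, Enum):
    """How to treat indices with undefined (NA) residue values."""

    DROP = "drop"
    IMPUTE_MEAN = "impute_mean"


@dataclass(frozen=True)
class AminoAcidIndex:
    """One AAindex1 entry: an accession, a description, and 20 residue values.

    ``values`` maps every standard one-letter residue to a float, or ``None``
    for an explicitly missing (NA) value.  At least one value must be defined.
    """

    accession: str
    description: str
    values: dict[str, float | None]

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("index accession must be non-empty")
        if set(self.values) != set(RESIDUE_ORDER):
            raise ValueError(
                f"index {self.accession!r} must define exactly the 20 standard residues"
            )
        if all(v is None for v in self.values.values()):
            raise ValueError(f"index {self.accession!r} has no defined values")

    @property
    def has_missing(self) -> bool:
        return any(v is None for v in self.values.values())

    def value_array(self) -> list[float]:
        """Residue values in canonical order; raises if any value is missing."""
        out = []
        for r in RESIDUE_ORDER:
            v = self.values[r]
            if v is None:
                raise ValueError(
                    f"index {self.accession!r} has a missing value for residue {r!r}; "
                    "apply drop_or_impute_missing first"
                )
            out.append(v)
        return out


def _signature(accessions: Sequence[str]) -> str:
    h = hashlib.sha256("\n".join(accessions).encode("utf-8"))
    return h.hexdigest()[:16]


@dataclass(frozen=True)
class IndexSet:
    """An ordered, duplicate-free collection of amino-acid indices.

    The ``signature`` is a stable hash of the ordered accession list and is
    carried through featurization and model artifacts so that a trained model
    can refuse feature vectors built under a different index configuration.
    """

    indices: tuple[AminoAcidIndex, ...]
    signature: str = field(init=False)

    def __post_init__(self) -> None:
        accs = [ix.accession for ix in self.indices]
        if len(set(accs)) != len(accs):
            dupes = sorted({a for a in accs if accs.count(a) > 1})
            raise ValueError(f"duplicate accessions in index set: {dupes}")
        object.__setattr__(self, "signature", _signature(accs))

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    @property
    def accessions(self) -> tuple[str, ...]:
        return tuple(ix.accession for ix in self.indices)

    @property
    def has_missing(self) -> bool:
        return any(ix.has_missing for ix in self.indices)


def _parse_token(token: str, accession: str, lineno: int) -> float | None:
    if token == "NA":
        return None
    try:
        return float(token)
    except ValueError:
        raise AAindexParseError(
            f"entry {accession!r}, line {lineno}: cannot parse value token {token!r}"
        ) from None


def parse_aaindex(stream: IO[str] | str) -> list[AminoAcidIndex]:
    """Parse an AAindex1 flat file into a list of :class:`AminoAcidIndex`.

    Only the ``H`` (accession), ``D`` (description) and ``I`` (value) records
    are interpreted; ``R``, ``A``, ``T``, ``J``, ``C`` and correlation records
    are tolerated and ignored.  The two data rows following the ``I`` header
    hold ten values each, in the order A R N D C Q E G H I / L K M F P S T W Y V,
    with the literal ``NA`` marking a missing value.  Entries end with ``//``.

    An empty stream yields an empty list.  Duplicate accessions and malformed
    value rows raise :class:`AAindexParseError`.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()

    entries: list[AminoAcidIndex] = []
    seen: set[str] = set()
    accession: str | None = None
    description_parts: list[str] = []
    tokens: list[tuple[str, int]] = []
    in_values = False

    def finalize(lineno: int) -> None:
        nonlocal accession, description_parts, tokens, in_values
        if accession is None:
            raise AAindexParseError(f"line {lineno}: entry terminator '//' without an H record")
        if len(tokens) != 20:
            raise AAindexParseError(
                f"entry {accession!r}, line {lineno}: expected 20 value tokens, got {len(tokens)}"
            )
        values = {
            RESIDUE_ORDER[i]: _parse_token(tok, accession, ln)
            for i, (tok, ln) in enumerate(tokens)
        }
        entries.append(
            AminoAcidIndex(
                accession=accession,
                description=" ".join(description_parts).strip(),
                values=values,
            )
        )
        accession = None
        description_parts = []
        tokens = []
        in_values = False

    current_key = ""
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip()
        if not line.strip():
            continue
        if line.startswith("//"):
            finalize(lineno)
            current_key = ""
            continue
        is_continuation = line[0] in " \t"
        key = current_key if is_continuation else line[0]
        body = line[1:].strip() if not is_continuation else line.strip()
        if not is_continuation:
            current_key = key
        if key == "H":
            if accession is not None:
                raise AAindexParseError(
                    f"line {lineno}: new H record before '//' terminator of {accession!r}"
                )
            accession = body.split()[0] if body else ""
            if not accession:
                raise AAindexParseError(f"line {lineno}: empty accession in H record")
            if accession in seen:
                raise AAindexParseError(f"line {lineno}: duplicate accession {accession!r}")
            seen.add(accession)
            in_values = False
        elif key == "D":
            description_parts.append(body)
        elif key == "I":
            if is_continuation and in_values:
                # data row under the I header
                row = body.split()
                if len(row) != 10:
                    raise AAindexParseError(
                        f"entry {accession!r}, line {lineno}: value row has "
                        f"{len(row)} tokens, expected 10"
                    )
                tokens.extend((tok, lineno) for tok in row)
            else:
                in_values = True
        else:
            # R, A, T, J, C, *: ignored metadata records
            continue

    if accession is not None:
        raise AAindexParseError("stream ended inside an unterminated entry "
                                f"{accession!r} (missing '//')")
    return entries


def _format_value(v: float | None) -> str:
    if v is None:
        return "NA"
    return repr(float(v)).removesuffix(".0") if float(v).is_integer() else repr(float(v))


def write_aaindex(indices: Iterable[AminoAcidIndex], stream: IO[str]) -> None:
    """Write entries back out in AAindex1 layout (H, D, I records, '//')."""
    for ix in indices:
        stream.write(f"H {ix.accession}\n")
        if ix.description:
            stream.write(f"D {ix.description}\n")
        stream.write("I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V\n")
        vals = [_format_value(ix.values[r]) for r in RESIDUE_ORDER]
        stream.write("  " + " ".join(vals[:10]) + "\n")
        stream.write("  " + " ".join(vals[10:]) + "\n")
        stream.write("//\n")


def select_indices(all_indices: Sequence[AminoAcidIndex], accessions: Sequence[str]) -> IndexSet:
    """Select indices by accession, preserving the order of the request list.

    Raises ``KeyError`` naming every accession absent from ``all_indices`` and
    ``ValueError`` on a duplicated request.
    """
    if len(set(accessions)) != len(accessions):
        dupes = sorted({a for a in accessions if list(accessions).count(a) > 1})
        raise ValueError(f"duplicate accessions requested: {dupes}")
    by_acc = {ix.accession: ix for ix in all_indices}
    missing = [a for a in accessions if a not in by_acc]
    if missing:
        raise KeyError(f"accessions not found in parsed indices: {missing}")
    return IndexSet(indices=tuple(by_acc[a] for a in accessions))


def drop_or_impute_missing(index_set: IndexSet, policy: MissingPolicy | str = MissingPolicy.DROP) -> IndexSet:
    """Resolve NA values: DROP removes affected indices, IMPUTE_MEAN fills
    each NA with the mean of that index's defined values.

    Averaging a sequence over an index with undefined residue values is itself
    undefined, so featurization requires an NA-free index set.  DROP is the
    default because imputation invents values.  Raises ``ValueError`` if DROP
    empties the set.
    """
    policy = MissingPolicy(policy)
    if policy is MissingPolicy.DROP:
        kept = tuple(ix for ix in index_set if not ix.has_missing)
        if not kept:
            raise ValueError("DROP policy removed every index (all contain NA values)")
        return IndexSet(indices=kept)
    out = []
    for ix in index_set:
        if not ix.has_missing:
            out.append(ix)
            continue
        defined = [v for v in ix.values.values() if v is not None]
        mean = sum(defined) / len(defined)
        filled = {r: (mean if v is None else v) for r, v in ix.values.items()}
        out.append(AminoAcidIndex(ix.accession, ix.description, filled))
    return IndexSet(indices=tuple(out))


def read_accession_list(stream: IO[str] | str) -> list[str]:
    """Read a plain-text accession list (one per line, '#' comments allowed)."""
    text = stream if isinstance(stream, str) else stream.read()
    out = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def index_set_to_tsv(index_set: IndexSet, stream: IO[str]) -> None:
    """Tabular export: accession then the 20 residue columns in canonical order."""
    stream.write("accession\t" + "\t".join(RESIDUE_ORDER) + "\n")
    for ix in index_set:
        vals = [_format_value(ix.values[r]) for r in RESIDUE_ORDER]
        stream.write(ix.accession + "\t" + "\t".join(vals) + "\n")
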