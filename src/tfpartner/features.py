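"""Composition-averaged physico-chemical featurization of proteins and pairs.

Each protein is represented by one number per amino-acid index: the arithmetic
mean of that index's residue values over every residue of the sequence.  This
deliberately discards positional information — the classification task relies
on bulk sequence composition only.  An interacting pair becomes the
concatenation of the two per-protein vectors; the ordering of the two halves
is significant and is what the dual sub-model construction symmetrizes over.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import IO, Mapping, Sequence

import numpy as np

from .aaindex import RESIDUE_ORDER, IndexSet
from .sequences import InteractionPair, ProteinRecord

__all__ = [
    "AmbiguityPolicy",
    "Orientation",
    "Task",
    "FeatureVector",
    "PairFeatureRow",
    "DesignMatrix",
    "index_matrix",
    "protein_feature_vector",
    "featurize_proteins",
    "pair_feature_row",
    "build_design_matrix",
    "write_feature_table",
]


class AmbiguityPolicy(str, Enum):
    """Handling of nonstandard residues (B, Z, X, U, O, J) during averaging."""

    SKIP = "skip"    # excluded from numerator and denominator
    ERROR = "error"  # any nonstandard residue aborts


class Orientation(str, Enum):
    FORWARD = "forward"    # (known TF, partner)
    REVERSED = "reversed"  # halves swapped for TF-TF instances


class Task(str, Enum):
    """The two binary classification tasks.

    MODEL1 separates partners into TF-or-TcoF (positive) versus other nuclear
    protein (negative).  MODEL2, applied to the pairs MODEL1 accepts, separates
    TcoF (positive) from TF (negative).
    """

    MODEL1 = "MODEL1"
    MODEL2 = "MODEL2"


#: Binary target encoding per task: label -> 0/1, absent label -> row excluded.
TASK_TARGETS: dict[Task, dict[str, int]] = {
    Task.MODEL1: {"TF": 1, "TCOF": 1, "OTHER": 0},
    Task.MODEL2: {"TCOF": 1, "TF": 0},
}


@dataclass(frozen=True)
class FeatureVector:
    """Per-protein feature vector, ordered by the index set that produced it."""

    protein_id: str
    values: np.ndarray
    index_signature: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite feature value for protein {self.protein_id!r}")


@dataclass(frozen=True)
class PairFeatureRow:
    """Concatenated pair vector: [first protein features || second protein features]."""

    tf_id: str
    partner_id: str
    values: np.ndarray
    orientation: Orientation
    index_signature: str


def index_matrix(index_set: IndexSet) -> np.ndarray:
    """Dense (20, k) matrix of residue values in canonical residue order."""
    if index_set.has_missing:
        raise ValueError(
            "index set contains NA values; apply drop_or_impute_missing before featurizing"
        )
    return np.array([ix.value_array() for ix in index_set], dtype=float).T


_RESIDUE_POS = {r: i for i, r in enumerate(RESIDUE_ORDER)}


def _residue_counts(sequence: str, protein_id: str, policy: AmbiguityPolicy) -> np.ndarray:
    counts = np.zeros(20, dtype=float)
    for ch in sequence:
        pos = _RESIDUE_POS.get(ch)
        if pos is None:
            if policy is AmbiguityPolicy.ERROR:
                raise ValueError(
                    f"protein {protein_id!r}: nonstandard residue {ch!r} under ERROR policy"
                )
            continue
        counts[pos] += 1
    return counts


def protein_feature_vector(
    record: ProteinRecord,
    index_set: IndexSet,
    ambiguity_policy: AmbiguityPolicy | str = AmbiguityPolicy.SKIP,
    _matrix: np.ndarray | None = None,
) -> FeatureVector:
    """Average each index over the sequence's residues.

    Entry j is the arithmetic mean of index j's values across all scorable
    residues.  Under SKIP, nonstandard residues contribute to neither the
    numerator nor the denominator; a sequence with zero scorable residues is
    an error.
    """
    policy = AmbiguityPolicy(ambiguity_policy)
    M = index_matrix(index_set) if _matrix is None else _matrix
    counts = _residue_counts(record.sequence, record.protein_id, policy)
    total = counts.sum()
    if total == 0:
        raise ValueError(
            f"protein {record.protein_id!r} has no scorable (standard) residues"
        )
    values = counts @ M / total
    return FeatureVector(record.protein_id, values, index_set.signature)


def featurize_proteins(
    records: Sequence[ProteinRecord],
    index_set: IndexSet,
    ambiguity_policy: AmbiguityPolicy | str = AmbiguityPolicy.SKIP,
) -> dict[str, FeatureVector]:
    """Featurize many proteins, sharing the dense index matrix."""
    M = index_matrix(index_set)
    return {
        r.protein_id: protein_feature_vector(r, index_set, ambiguity_policy, _matrix=M)
        for r in records
    }


def pair_feature_row(
    pair: InteractionPair,
    features: Mapping[str, FeatureVector],
    orientation: Orientation | str = Orientation.FORWARD,
) -> PairFeatureRow:
    """Concatenate the two per-protein vectors under the stated orientation.

    FORWARD places the known TF first; REVERSED swaps the halves.  Both halves
    must have been built under the same index set.
    """
    orientation = Orientation(orientation)
    for pid in (pair.tf_id, pair.partner_id):
        if pid not in features:
            raise KeyError(f"no feature vector for protein {pid!r}")
    tf_fv, partner_fv = features[pair.tf_id], features[pair.partner_id]
    if tf_fv.index_signature != partner_fv.index_signature:
        raise ValueError(
            f"index signature mismatch between {pair.tf_id!r} and {pair.partner_id!r}"
        )
    if orientation is Orientation.FORWARD:
        values = np.concatenate([tf_fv.values, partner_fv.values])
    else:
        values = np.concatenate([partner_fv.values, tf_fv.values])
    return PairFeatureRow(pair.tf_id, pair.partner_id, values, orientation, tf_fv.index_signature)


@dataclass(frozen=True)
class DesignMatrix:
    """Task-specific design matrix with aligned binary targets.

    ``n_excluded`` counts pairs whose label plays no role in the task
    (OTHER-labeled pairs under MODEL2).
    """

    X: np.ndarray
    y: np.ndarray
    pairs: tuple[InteractionPair, ...]
    task: Task
    orientation: Orientation
    index_signature: str
    n_excluded: int


def build_design_matrix(
    pairs: Sequence[InteractionPair],
    features: Mapping[str, FeatureVector],
    task: Task | str,
    orientation: Orientation | str = Orientation.FORWARD,
) -> DesignMatrix:
    """Assemble the training matrix for one task and one orientation.

    Row order follows input order.  Under REVERSED only the rows whose partner
    class is TF (i.e. TF-TF instances, where either ordering is legitimate)
    have their halves swapped; TF-TcoF and TF-other rows keep the TF-first
    order, since their orientation is fixed by construction.
    """
    task = Task(task)
    orientation = Orientation(orientation)
    targets = TASK_TARGETS[task]
    rows, ys, kept = [], [], []
    n_excluded = 0
    signature: str | None = None
    for pair in pairs:
        if pair.label is None:
            raise ValueError(
                f"pair ({pair.tf_id}, {pair.partner_id}) is unlabeled; labels are "
                "required to build a training design matrix"
            )
        if pair.label not in targets:
            n_excluded += 1
            continue
        row_orientation = (
            orientation if (orientation is Orientation.REVERSED and pair.label == "TF")
            else Orientation.FORWARD
        )
        row = pair_feature_row(pair, features, row_orientation)
        signature = row.index_signature if signature is None else signature
        rows.append(row.values)
        ys.append(targets[pair.label])
        kept.append(pair)
    if not rows:
        raise ValueError(f"no usable labeled pairs for task {task.value}")
    return DesignMatrix(
        X=np.vstack(rows),
        y=np.asarray(ys, dtype=int),
        pairs=tuple(kept),
        task=task,
        orientation=orientation,
        index_signature=signature or "",
        n_excluded=n_excluded,
    )


def write_feature_table(
    pairs: Sequence[InteractionPair],
    features: Mapping[str, FeatureVector],
    index_set: IndexSet,
    stream: IO[str],
    manifest_stream: IO[str] | None = None,
    ambiguity_policy: AmbiguityPolicy | str = AmbiguityPolicy.SKIP,
    missing_policy: str = "drop",
) -> None:
    """Write the featurized pair table as TSV plus a JSON manifest sidecar.

    Columns: tf_id, partner_id, label, then f1..f2k in FORWARD orientation.
    """
    k = len(index_set)
    header = ["tf_id", "partner_id", "label"] + [f"f{i + 1}" for i in range(2 * k)]
    stream.write("\t".join(header) + "\n")
    for pair in pairs:
        row = pair_feature_row(pair, features, Orientation.FORWARD)
        cells = [pair.tf_id, pair.partner_id, pair.label or ""]
        cells.extend(repr(v) for v in row.values.tolist())
        stream.write("\t".join(cells) + "\n")
    if manifest_stream is not None:
        manifest = {
            "index_signature": index_set.signature,
            "accessions": list(index_set.accessions),
            "n_features_per_protein": k,
            "ambiguity_policy": AmbiguityPolicy(ambiguity_policy).value,
            "missing_value_policy": missing_policy,
        }
        json.dump(manifest, manifest_stream, indent=2)
        manifest_stream.write("\n")
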