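"""Synthetic interaction datasets with a planted compositional class signal.

The generator emulates the structure of a curated TF-interaction training set:
labeled pairs of three kinds (TF-TcoF, TF-TF, TF-other) whose partner classes
differ only in bulk amino-acid composition.  Each functional role gets a
residue-frequency profile; the ``separation`` parameter delta moves the three
role profiles apart linearly (delta = 0 makes them identical — the null
configuration), and ``concentration`` controls how tightly individual
proteins scatter around their role profile (Dirichlet concentration).

Because the featurization averages physico-chemical indices over residues,
compositional signal is exactly the signal the classifier can see, which
makes planted-signal recovery a fair end-to-end test of the pipeline.  The
generator also emits a fully defined AAindex1-format fixture file of random
indices, so no database content is required anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .aaindex import RESIDUE_ORDER, AminoAcidIndex, IndexSet, write_aaindex
from .sequences import InteractionPair, ProteinRecord, write_fasta, write_pair_table

__all__ = [
    "ROLES",
    "SyntheticConfig",
    "SyntheticDataset",
    "make_class_profiles",
    "sample_protein",
    "make_fixture_indices",
    "generate_dataset",
    "well_separated_config",
    "null_config",
]

ROLES = ("TF", "TCOF", "OTHER")
_ROLE_PREFIX = {"TF": "TF", "TCOF": "CO", "OTHER": "NP"}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one generated dataset.

    Defaults are the well-separated reference configuration: 200 pairs per
    interaction class, separation 0.5, high concentration (tight per-protein
    scatter), 40 fixture indices.
    """

    n_tf_tcof: int = 200
    n_tf_tf: int = 200
    n_tf_other: int = 200
    length_range: tuple[int, int] = (50, 200)
    separation: float = 0.5
    concentration: float = 100.0
    n_indices: int = 40
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.n_tf_tcof, self.n_tf_tf, self.n_tf_other) < 0:
            raise ValueError("pair counts must be non-negative")
        lo, hi = self.length_range
        if lo < 10 or hi < lo:
            raise ValueError("length_range must satisfy 10 <= min <= max")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


@dataclass(frozen=True)
class SyntheticDataset:
    """In-memory dataset plus writers for the standard on-disk formats."""

    records: tuple[ProteinRecord, ...]
    pairs: tuple[InteractionPair, ...]
    index_set: IndexSet
    config: SyntheticConfig
    profiles: Mapping[str, np.ndarray] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write proteins.fasta, pairs.tsv and aaindex.txt; byte-identical
        for identical configs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "proteins.fasta",
            "pairs": outdir / "pairs.tsv",
            "aaindex": outdir / "aaindex.txt",
        }
        with open(paths["fasta"], "w") as fh:
            write_fasta(self.records, fh)
        with open(paths["pairs"], "w") as fh:
            write_pair_table(self.pairs, fh)
        with open(paths["aaindex"], "w") as fh:
            write_aaindex(self.index_set, fh)
        return paths


def make_class_profiles(separation: float, seed: int) -> dict[str, np.ndarray]:
    """Residue-frequency profile per role.

    A near-uniform base profile is mixed with a role-specific random extreme
    profile with weight min(separation, 1): pairwise total-variation distance
    between roles grows linearly in the separation, and separation 0 returns
    three identical profiles.
    """
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    base = rng.dirichlet(np.full(20, 50.0))
    w = min(separation, 1.0)
    profiles = {}
    for role in ROLES:
        extreme = rng.dirichlet(np.ones(20))
        profiles[role] = (1.0 - w) * base + w * extreme
    return profiles


def sample_protein(
    role: str,
    profiles: Mapping[str, np.ndarray],
    length_range: tuple[int, int],
    concentration: float,
    rng: np.random.Generator,
    serial: int,
) -> ProteinRecord:
    """Draw one protein: length uniform in range, residues i.i.d. from a
    per-protein profile drawn Dirichlet(concentration * role profile).

    An infinite concentration uses the role profile directly (no per-protein
    scatter).  Identifiers encode the role and a serial number.
    """
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}")
    profile = np.asarray(profiles[role], dtype=float)
    lo, hi = length_range
    length = int(rng.integers(lo, hi + 1))
    if math.isinf(concentration):
        p = profile / profile.sum()
    else:
        support = profile > 0
        p = np.zeros(20)
        p[support] = rng.dirichlet(concentration * profile[support])
    residues = rng.choice(list(RESIDUE_ORDER), size=length, p=p)
    return ProteinRecord(
        protein_id=f"{_ROLE_PREFIX[role]}{serial:06d}",
        sequence="".join(residues),
    )


def make_fixture_indices(n_indices: int, rng: np.random.Generator) -> IndexSet:
    """Random, fully defined AAindex1-style fixture indices with values in
    [-5, 5] rounded to 3 decimals (so the flat-file round-trip is exact)."""
    indices = []
    for i in range(n_indices):
        values = {
            r: float(round(rng.uniform(-5.0, 5.0), 3)) for r in RESIDUE_ORDER
        }
        indices.append(
            AminoAcidIndex(
                accession=f"SYN{i:07d}",
                description=f"synthetic physico-chemical index {i}",
                values=values,
            )
        )
    return IndexSet(indices=tuple(indices))


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full dataset: proteins, labeled pairs and fixture indices.

    Every pair samples a fresh anchor TF (role TF) and a partner drawn from
    the role matching the pair label, in the order TF-TcoF, TF-TF, TF-other.
    Fully reproducible from the config seed.
    """
    total = config.n_tf_tcof + config.n_tf_tf + config.n_tf_other
    if total == 0:
        raise ValueError("at least one pair is required")
    rng = np.random.default_rng(config.seed)
    profiles = make_class_profiles(config.separation, config.seed)
    index_set = make_fixture_indices(config.n_indices, rng)

    records: list[ProteinRecord] = []
    pairs: list[InteractionPair] = []
    serial = 0

    def draw(role: str) -> ProteinRecord:
        nonlocal serial
        serial += 1
        rec = sample_protein(role, profiles, config.length_range,
                             config.concentration, rng, serial)
        records.append(rec)
        return rec

    for label, count in (("TCOF", config.n_tf_tcof),
                         ("TF", config.n_tf_tf),
                         ("OTHER", config.n_tf_other)):
        for _ in range(count):
            anchor = draw("TF")
            partner = draw(label)
            pairs.append(InteractionPair(anchor.protein_id, partner.protein_id, label))

    return SyntheticDataset(
        records=tuple(records),
        pairs=tuple(pairs),
        index_set=index_set,
        config=config,
        profiles=profiles,
    )


def well_separated_config(seed: int = 42) -> SyntheticConfig:
    """The reference well-separated configuration (defaults), reseedable."""
    return SyntheticConfig(seed=seed)


def null_config(seed: int = 42) -> SyntheticConfig:
    """Zero-signal configuration: identical class profiles (separation 0)."""
    return replace(SyntheticConfig(), separation=0.0, seed=seed)
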