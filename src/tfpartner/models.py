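"""Dual sub-model Random Forest ensembles and the cascaded three-class decision.

A pair of interacting proteins is directional only by convention: when both
partners are transcription factors, (TFa, TFb) and (TFb, TFa) describe the
same biological instance.  To keep predictions stable under that ordering
choice, each task trains two Random Forests — one on the TF-first design
matrix, one with the TF-TF rows half-swapped — and averages their confidence
scores at prediction time.  The confidence score of a single forest is the
mean positive-class probability across its decision trees.

Two models cascade into a three-class call: MODEL1 decides "TF or TcoF"
versus "other nuclear protein"; pairs passing MODEL1 go to MODEL2, which
decides TcoF (positive) versus TF.
"""

from __future__ import annotations

import datetime
import io
import json
import math
import zipfile
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from . import __version__
from .features import (
    DesignMatrix,
    FeatureVector,
    Orientation,
    Task,
    build_design_matrix,
    pair_feature_row,
)
from .sequences import InteractionPair

__all__ = [
    "ScoringMode",
    "Hyperparameters",
    "SubModel",
    "DualModel",
    "Prediction",
    "ModelArtifactError",
    "train_submodel",
    "train_dual_model",
    "predict_pair",
    "cascade_predict",
    "save_model",
    "load_model",
]

ARTIFACT_FORMAT_VERSION = 1
DEFAULT_THRESHOLD = 0.5


class ScoringMode(str, Enum):
    """How sub-model scores combine at prediction time.

    DUAL_AVERAGE feeds the pair as given (TF first) to both sub-models and
    averages the two scores.  STRICT_SYMMETRIC additionally evaluates the swapped
    ordering and averages all four scores, which makes score(a, b) and
    score(b, a) bit-identical for every pair.
    """

    DUAL_AVERAGE = "dual_average"
    STRICT_SYMMETRIC = "strict_symmetric"


@dataclass(frozen=True)
class Hyperparameters:
    """Random Forest settings shared by the two sub-models of a task.

    ``max_features="sqrt"`` examines sqrt(2k) candidate features per split
    for a 2k-wide pair vector; depth is unlimited by default.
    """

    n_trees: int = 100
    max_features: int | float | str = "sqrt"
    max_depth: int | None = None

    def to_dict(self) -> dict:
        return {
            "n_trees": self.n_trees,
            "max_features": self.max_features,
            "max_depth": self.max_depth,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Hyperparameters":
        return cls(**d)


@dataclass
class SubModel:
    """One trained forest plus the context needed to refuse foreign inputs."""

    task: Task
    orientation: Orientation
    forest: RandomForestClassifier
    hyperparameters: Hyperparameters
    seed: int
    index_signature: str
    n_features: int

    def _check(self, X: np.ndarray, index_signature: str | None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"input width {X.shape[1]} != trained width {self.n_features}"
            )
        if index_signature is not None and index_signature != self.index_signature:
            raise ValueError(
                f"index signature mismatch: input {index_signature!r}, "
                f"model {self.index_signature!r}"
            )
        return X

    def predict_proba_positive(self, X: np.ndarray, index_signature: str | None = None) -> np.ndarray:
        """Positive-class confidence per row: the mean class-1 probability
        over all decision trees."""
        X = self._check(X, index_signature)
        proba = self.forest.predict_proba(X)
        if not np.allclose(proba.sum(axis=1), 1.0, atol=1e-9):
            raise AssertionError("class probabilities do not sum to 1")
        pos_col = int(np.flatnonzero(self.forest.classes_ == 1)[0])
        return proba[:, pos_col]


@dataclass
class DualModel:
    """Forward- and reverse-trained sub-models for one task, plus metadata."""

    task: Task
    sub_forward: SubModel
    sub_reverse: SubModel
    scoring_mode: ScoringMode = ScoringMode.DUAL_AVERAGE
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a, b = self.sub_forward, self.sub_reverse
        if a.task != b.task or a.task != self.task:
            raise ValueError("sub-model tasks disagree")
        if a.hyperparameters != b.hyperparameters:
            raise ValueError("sub-model hyperparameters disagree")
        if a.index_signature != b.index_signature:
            raise ValueError("sub-model index signatures disagree")

    @property
    def index_signature(self) -> str:
        return self.sub_forward.index_signature


@dataclass(frozen=True)
class Prediction:
    """A scored call for one pair under one task (or the cascade)."""

    tf_id: str
    partner_id: str
    task: str
    score: float
    predicted_label: str
    sub_scores: dict[str, float]
    threshold: float = DEFAULT_THRESHOLD


class ModelArtifactError(RuntimeError):
    """A model archive is unreadable, inconsistent or from a foreign configuration."""


def train_submodel(
    X: np.ndarray,
    y: np.ndarray,
    hyperparameters: Hyperparameters,
    orientation: Orientation | str,
    task: Task | str,
    seed: int,
    index_signature: str = "",
) -> SubModel:
    """Fit one Random Forest sub-model; deterministic given data and seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.isnan(X).any():
        raise ValueError("design matrix contains NaN")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(
            f"training set contains a single class ({classes.tolist()}); "
            "both classes are required"
        )
    hp = hyperparameters
    forest = RandomForestClassifier(
        n_estimators=hp.n_trees,
        max_features=hp.max_features,
        max_depth=hp.max_depth,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return SubModel(
        task=Task(task),
        orientation=Orientation(orientation),
        forest=forest,
        hyperparameters=hp,
        seed=seed,
        index_signature=index_signature,
        n_features=X.shape[1],
    )


def train_dual_model(
    pairs: Sequence[InteractionPair],
    features: Mapping[str, FeatureVector],
    task: Task | str,
    hyperparameters: Hyperparameters | None = None,
    seeds: tuple[int, int] = (1, 2),
    scoring_mode: ScoringMode | str = ScoringMode.DUAL_AVERAGE,
) -> DualModel:
    """Train the forward and reverse sub-models of one task.

    The forward sub-model sees every pair TF-first; the reverse sub-model sees
    the same rows with the TF-TF instances half-swapped.  Independent seeds
    (default 1 and 2) decorrelate the two forests' tree-level randomness.
    """
    task = Task(task)
    hp = hyperparameters or Hyperparameters()
    fwd: DesignMatrix = build_design_matrix(pairs, features, task, Orientation.FORWARD)
    rev: DesignMatrix = build_design_matrix(pairs, features, task, Orientation.REVERSED)
    sub_f = train_submodel(fwd.X, fwd.y, hp, Orientation.FORWARD, task, seeds[0], fwd.index_signature)
    sub_r = train_submodel(rev.X, rev.y, hp, Orientation.REVERSED, task, seeds[1], rev.index_signature)
    labels = [p.label for p in fwd.pairs]
    metadata = {
        "task": task.value,
        "class_counts": {lbl: labels.count(lbl) for lbl in sorted(set(labels))},
        "n_excluded": fwd.n_excluded,
        "seeds": list(seeds),
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "tool_version": __version__,
    }
    return DualModel(task, sub_f, sub_r, ScoringMode(scoring_mode), metadata)


def _label_for(task: Task, positive: bool) -> str:
    if task is Task.MODEL1:
        return "TF/TCOF" if positive else "OTHER"
    return "TCOF" if positive else "TF"


def predict_pair(
    model: DualModel,
    pair: InteractionPair,
    features: Mapping[str, FeatureVector],
    mode: ScoringMode | str | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> Prediction:
    """Score one pair with a dual model.

    DUAL_AVERAGE mode: score = mean of the two sub-model scores on the pair
    as given.
    STRICT_SYMMETRIC mode: score = mean of the four scores over both
    sub-models and both orderings, summed in sorted order so the result is
    bit-identical under argument swap.  A score exactly at the threshold is
    called positive.
    """
    mode = ScoringMode(mode) if mode is not None else model.scoring_mode
    row_fwd = pair_feature_row(pair, features, Orientation.FORWARD)
    if row_fwd.index_signature != model.index_signature:
        raise ValueError(
            f"index signature mismatch: features {row_fwd.index_signature!r}, "
            f"model {model.index_signature!r}"
        )
    s_f = float(model.sub_forward.predict_proba_positive(row_fwd.values)[0])
    s_r = float(model.sub_reverse.predict_proba_positive(row_fwd.values)[0])
    sub_scores = {"forward": s_f, "reverse": s_r}
    if mode is ScoringMode.DUAL_AVERAGE:
        score = (s_f + s_r) / 2.0
    else:
        row_rev = pair_feature_row(pair, features, Orientation.REVERSED)
        s_f2 = float(model.sub_forward.predict_proba_positive(row_rev.values)[0])
        s_r2 = float(model.sub_reverse.predict_proba_positive(row_rev.values)[0])
        sub_scores.update({"forward_swapped": s_f2, "reverse_swapped": s_r2})
        # summing in sorted order makes the result independent of argument order
        score = math.fsum(sorted((s_f, s_r, s_f2, s_r2))) / 4.0
    positive = score >= threshold
    return Prediction(
        tf_id=pair.tf_id,
        partner_id=pair.partner_id,
        task=model.task.value,
        score=score,
        predicted_label=_label_for(model.task, positive),
        sub_scores=sub_scores,
        threshold=threshold,
    )


def cascade_predict(
    model1: DualModel,
    model2: DualModel,
    pair: InteractionPair,
    features: Mapping[str, FeatureVector],
    mode: ScoringMode | str | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> Prediction:
    """Three-class call: MODEL1 gates OTHER, MODEL2 splits TF from TcoF."""
    if model1.task is not Task.MODEL1 or model2.task is not Task.MODEL2:
        raise ValueError("cascade_predict requires (MODEL1, MODEL2) in that order")
    if model1.index_signature != model2.index_signature:
        raise ValueError("the two models were trained under different index sets")
    p1 = predict_pair(model1, pair, features, mode, threshold)
    sub_scores = {f"model1_{k}": v for k, v in p1.sub_scores.items()}
    if p1.predicted_label == "OTHER":
        return Prediction(pair.tf_id, pair.partner_id, "CASCADE", p1.score,
                          "OTHER", sub_scores, threshold)
    p2 = predict_pair(model2, pair, features, mode, threshold)
    sub_scores.update({f"model2_{k}": v for k, v in p2.sub_scores.items()})
    sub_scores["model1_score"] = p1.score
    label = "TCOF" if p2.predicted_label == "TCOF" else "TF"
    return Prediction(pair.tf_id, pair.partner_id, "CASCADE", p2.score,
                      label, sub_scores, threshold)


# ---------------------------------------------------------------------------
# serialization

_PROBE_ROWS = 20


def _make_probe(model: DualModel, rng_seed: int = 20130712) -> np.ndarray:
    rng = np.random.default_rng(rng_seed)
    return rng.standard_normal((_PROBE_ROWS, model.sub_forward.n_features))


def save_model(model: DualModel, path) -> None:
    """Serialize a dual model to a single zip archive.

    The archive holds the two forests (joblib), a JSON manifest (task,
    hyperparameters, seeds, index signature, scoring mode, class counts) and a
    probe matrix with the model's own scores on it, so a later load can verify
    that deserialization reproduces predictions bit-exactly.
    """
    probe = _make_probe(model)
    expected_f = model.sub_forward.predict_proba_positive(probe)
    expected_r = model.sub_reverse.predict_proba_positive(probe)
    manifest = {
        "format_version": ARTIFACT_FORMAT_VERSION,
        "tool_version": __version__,
        "task": model.task.value,
        "scoring_mode": model.scoring_mode.value,
        "hyperparameters": model.sub_forward.hyperparameters.to_dict(),
        "seeds": [model.sub_forward.seed, model.sub_reverse.seed],
        "index_signature": model.index_signature,
        "n_features": model.sub_forward.n_features,
        "metadata": model.metadata,
    }
    probe_blob = {
        "matrix": probe.tolist(),
        "expected_forward": expected_f.tolist(),
        "expected_reverse": expected_r.tolist(),
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=2))
        zf.writestr("probe.json", json.dumps(probe_blob))
        for name, sub in (("forest_forward", model.sub_forward),
                          ("forest_reverse", model.sub_reverse)):
            buf = io.BytesIO()
            joblib.dump(sub.forest, buf)
            zf.writestr(f"{name}.joblib", buf.getvalue())


def load_model(path, expected_accessions: Sequence[str] | None = None,
               expected_signature: str | None = None) -> DualModel:
    """Load a dual model archive, verifying format, signature and probe outputs.

    ``expected_signature`` (or the signature derived from
    ``expected_accessions``) guards against applying a model to features built
    under a different index configuration.  Any inconsistency raises
    :class:`ModelArtifactError`; a truncated or corrupt archive never loads
    silently.
    """
    try:
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            probe_blob = json.loads(zf.read("probe.json"))
            forests = {
                name: joblib.load(io.BytesIO(zf.read(f"{name}.joblib")))
                for name in ("forest_forward", "forest_reverse")
            }
    except (zipfile.BadZipFile, KeyError, EOFError, OSError, json.JSONDecodeError) as exc:
        raise ModelArtifactError(f"cannot read model archive {path}: {exc}") from exc

    if manifest.get("format_version") != ARTIFACT_FORMAT_VERSION:
        raise ModelArtifactError(
            f"unsupported artifact format version {manifest.get('format_version')!r}"
        )
    if expected_accessions is not None:
        from .aaindex import _signature
        expected_signature = _signature(list(expected_accessions))
    if expected_signature is not None and expected_signature != manifest["index_signature"]:
        raise ModelArtifactError(
            f"index configuration mismatch: artifact signature "
            f"{manifest['index_signature']!r}, expected {expected_signature!r}"
        )
    task = Task(manifest["task"])
    hp = Hyperparameters.from_dict(manifest["hyperparameters"])
    seeds = manifest["seeds"]
    subs = {}
    for name, orientation, seed in (
        ("forest_forward", Orientation.FORWARD, seeds[0]),
        ("forest_reverse", Orientation.REVERSED, seeds[1]),
    ):
        subs[name] = SubModel(
            task=task,
            orientation=orientation,
            forest=forests[name],
            hyperparameters=hp,
            seed=seed,
            index_signature=manifest["index_signature"],
            n_features=manifest["n_features"],
        )
    model = DualModel(task, subs["forest_forward"], subs["forest_reverse"],
                      ScoringMode(manifest["scoring_mode"]), manifest.get("metadata", {}))
    probe = np.asarray(probe_blob["matrix"], dtype=float)
    got_f = model.sub_forward.predict_proba_positive(probe)
    got_r = model.sub_reverse.predict_proba_positive(probe)
    if not (np.array_equal(got_f, np.asarray(probe_blob["expected_forward"]))
            and np.array_equal(got_r, np.asarray(probe_blob["expected_reverse"]))):
        raise ModelArtifactError(
            f"probe predictions of {path} do not reproduce the stored values; "
            "artifact is corrupt or from an incompatible library version"
        )
    return model
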