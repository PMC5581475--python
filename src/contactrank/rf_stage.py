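"""Stage-1 scorer: under-sampled random-forest ensembles per range class.

Contacts are rare (~2-3% of considered pairs), so training pools are
rebalanced by drawing non-contacts at a 4:1 ratio against contacts.  To
counteract the information discarded by under-sampling, three independent
under-samples are drawn and one random-forest classifier is trained on each;
the stage-1 score of a pair is the arithmetic mean of the three members'
contact probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .geometry import RangeClass

__all__ = [
    "SampledTrainingSet",
    "RFEnsembleModel",
    "undersample",
    "train_rf_ensemble",
    "rf_score",
    "save_rf_model",
    "load_rf_model",
    "DEFAULT_RATIO",
    "DEFAULT_N_MEMBERS",
    "DEFAULT_N_TREES",
]

DEFAULT_RATIO = 4
DEFAULT_N_MEMBERS = 3
DEFAULT_N_TREES = 500

MODEL_FORMAT_VERSION = 1


@dataclass
class SampledTrainingSet:
    """One under-sampled, rebalanced training subset."""

    X: np.ndarray
    y: np.ndarray           # 1 = contact, 0 = non-contact
    seed: int
    ratio: int
    range_class: RangeClass | None = None

    @property
    def n_contacts(self) -> int:
        return int(self.y.sum())

    @property
    def n_noncontacts(self) -> int:
        return int((self.y == 0).sum())


@dataclass
class RFEnsembleModel:
    """Ensemble of independently under-sampled random-forest members."""

    members: list[RandomForestClassifier]
    range_class: RangeClass | None
    n_features: int
    metadata: dict = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return len(self.members)


def undersample(X: np.ndarray, y: np.ndarray, ratio: int = DEFAULT_RATIO,
                seed: int = 0,
                range_class: RangeClass | None = None) -> SampledTrainingSet:
    """Keep all contacts; draw ``ratio`` non-contacts per contact.

    Non-contacts are drawn uniformly without replacement under ``seed``,
    capped at availability.  Deterministic given (inputs, ratio, seed).
    Raises when the pool contains no contacts.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if ratio < 1:
        raise ValueError(f"ratio must be >= 1, got {ratio}")
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if pos_idx.size == 0:
        raise ValueError("training pool contains no contact samples")
    n_neg = min(ratio * pos_idx.size, neg_idx.size)
    rng = np.random.default_rng(seed)
    drawn = rng.choice(neg_idx, size=n_neg, replace=False)
    keep = np.concatenate([pos_idx, np.sort(drawn)])
    return SampledTrainingSet(
        X=X[keep], y=y[keep], seed=seed, ratio=ratio, range_class=range_class
    )


def train_rf_ensemble(X: np.ndarray, y: np.ndarray,
                      n_members: int = DEFAULT_N_MEMBERS,
                      seeds: list[int] | None = None,
                      ratio: int = DEFAULT_RATIO,
                      n_trees: int = DEFAULT_N_TREES,
                      range_class: RangeClass | None = None,
                      n_jobs: int = 1) -> RFEnsembleModel:
    """Train ``n_members`` forests, each on an independent under-sample.

    All members share the positive set and draw disjoint seeds.  The pool
    must contain both classes.  Callers are expected to pass the pool in a
    canonical order (by target id, then i, then j) so seeded sampling does
    not depend on file order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(set(np.unique(y)) & {0, 1}) < 2:
        raise ValueError("training pool must contain both contact and non-contact samples")
    if seeds is None:
        seeds = list(range(n_members))
    if len(seeds) != n_members:
        raise ValueError(f"need {n_members} seeds, got {len(seeds)}")
    members = []
    for seed in seeds:
        subset = undersample(X, y, ratio=ratio, seed=seed, range_class=range_class)
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, n_jobs=n_jobs
        )
        clf.fit(subset.X, subset.y)
        members.append(clf)
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "range_class": range_class.value if range_class else None,
        "seeds": list(seeds),
        "ratio": ratio,
        "n_trees": n_trees,
        "n_features": int(X.shape[1]),
    }
    return RFEnsembleModel(
        members=members, range_class=range_class,
        n_features=int(X.shape[1]), metadata=meta,
    )


def rf_score(model: RFEnsembleModel, X: np.ndarray) -> np.ndarray:
    """Mean contact probability over ensemble members; values in [0, 1]."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature length {X.shape[1]} does not match model "
            f"fingerprint {model.n_features}"
        )
    probs = np.zeros(X.shape[0])
    for clf in model.members:
        pos = list(clf.classes_).index(1)
        probs += clf.predict_proba(X)[:, pos]
    return probs / len(model.members)


def rf_member_scores(model: RFEnsembleModel, X: np.ndarray) -> np.ndarray:
    """Per-member contact probabilities, shape (n_samples, n_members)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError("feature length does not match model fingerprint")
    cols = []
    for clf in model.members:
        pos = list(clf.classes_).index(1)
        cols.append(clf.predict_proba(X)[:, pos])
    return np.column_stack(cols)


def save_rf_model(model: RFEnsembleModel, path) -> None:
    """Persist members plus a JSON metadata sidecar in one joblib archive."""
    payload = {
        "metadata_json": json.dumps(model.metadata),
        "members": model.members,
        "range_class": model.range_class.value if model.range_class else None,
        "n_features": model.n_features,
    }
    joblib.dump(payload, path)


def load_rf_model(path) -> RFEnsembleModel:
    payload = joblib.load(path)
    meta = json.loads(payload["metadata_json"])
    if meta.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format in {path}")
    rc = payload["range_class"]
    return RFEnsembleModel(
        members=payload["members"],
        range_class=RangeClass(rc) if rc else None,
        n_features=payload["n_features"],
        metadata=meta,
    )
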