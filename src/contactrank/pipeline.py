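"""End-to-end orchestration: train both stages, predict, evaluate.

This is the glue used by the command-line interface and the tests.  A
``TargetData`` bundles everything known about one target; training builds,
per range class, a stage-1 RF ensemble on the pooled windowed pair vectors
and a stage-2 rank model on the per-protein fusion features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import evaluation, features, ranker, rf_stage
from .config import RunConfig
from .geometry import ASSESSED_RANGES, ContactMap, ProteinRecord, RangeClass, enumerate_pairs
from .io_formats import CMScoreMatrix, PredictionList, PSSMProfile
from .synthetic import SyntheticTarget

__all__ = [
    "TargetData",
    "TrainedModels",
    "train_models",
    "predict_target",
    "merge_predictions",
    "evaluate_predictions",
    "save_models",
    "load_models",
    "load_target_dir",
]


@dataclass
class TargetData:
    """All per-target inputs the two stages consume."""

    record: ProteinRecord
    cm_scores: dict[str, CMScoreMatrix]
    pssm: PSSMProfile
    ss_string: str
    sa_string: str
    cmap: ContactMap | None = None      # required for training / evaluation

    @classmethod
    def from_synthetic(cls, t: SyntheticTarget) -> "TargetData":
        return cls(record=t.record, cm_scores=t.cm_scores, pssm=t.pssm,
                   ss_string=t.ss_string, sa_string=t.sa_string, cmap=t.cmap)

    def feature_table(self) -> features.ResidueFeatureTable:
        return features.build_feature_table(
            self.record, self.pssm, self.ss_string, self.sa_string
        )


@dataclass
class TrainedModels:
    """Per-range stage-1 ensembles and stage-2 rank models."""

    rf_models: dict[RangeClass, rf_stage.RFEnsembleModel]
    rank_models: dict[RangeClass, ranker.RankModel]
    cm_tags: list[str]
    config: RunConfig = field(default_factory=RunConfig)


def _pair_matrix(target: TargetData, range_class: RangeClass,
                 window: int) -> tuple[list[tuple[int, int]], np.ndarray]:
    table = target.feature_table()
    pairs = enumerate_pairs(target.record.length, range_class)
    if not pairs:
        return [], np.zeros((0, features.pair_vector_length(window)))
    X = np.vstack([
        features.build_pair_vector(table, i, j, window=window).vector
        for i, j in pairs
    ])
    return pairs, X


def _phi_matrix(target: TargetData, pairs: list[tuple[int, int]],
                rf_scores: np.ndarray, cm_tags: list[str]) -> np.ndarray:
    cols = []
    for tag in cm_tags:
        if tag not in target.cm_scores:
            raise KeyError(
                f"{target.record.id}: missing correlated-mutations input {tag!r}"
            )
        m = target.cm_scores[tag].scores
        cols.append(np.array([m[i - 1, j - 1] for i, j in pairs]))
    cols.append(np.asarray(rf_scores))
    return np.column_stack(cols) if cols else np.zeros((len(pairs), 0))


def train_models(targets: list[TargetData], config: RunConfig | None = None,
                 ranges: tuple[RangeClass, ...] = ASSESSED_RANGES) -> TrainedModels:
    """Train stage-1 ensembles and stage-2 rank models on labelled targets.

    Targets are pooled in canonical order (by id, then pair) so results do
    not depend on input order.  Stage-2 fusion features for a training
    target use RF scores from an ensemble fitted without that target
    (``config.cross_fit_folds``-fold cross-fitting), so the rank model sees
    stage-1 scores with held-out noise levels rather than optimistic
    in-sample ones.
    """
    config = config or RunConfig()
    if not targets:
        raise ValueError("no training targets")
    for t in targets:
        if t.cmap is None:
            raise ValueError(f"{t.record.id}: training requires a contact map")
    targets = sorted(targets, key=lambda t: t.record.id)
    cm_tags = sorted(targets[0].cm_scores)
    rf_models: dict[RangeClass, rf_stage.RFEnsembleModel] = {}
    rank_models: dict[RangeClass, ranker.RankModel] = {}
    for rc in ranges:
        per_target = []
        X_all, y_all = [], []
        for t in targets:
            pairs, X = _pair_matrix(t, rc, config.window)
            labels = np.array([
                int(t.cmap.contacts[i - 1, j - 1]) if t.cmap.defined[i - 1, j - 1]
                else -1
                for i, j in pairs
            ])
            per_target.append((t, pairs, X, labels))
            keep = labels >= 0
            X_all.append(X[keep])
            y_all.append(labels[keep])
        X_pool = np.vstack(X_all)
        y_pool = np.concatenate(y_all)
        rf = rf_stage.train_rf_ensemble(
            X_pool, y_pool,
            n_members=config.n_members,
            seeds=[config.seed + k for k in range(config.n_members)],
            ratio=config.ratio, n_trees=config.n_trees,
            range_class=rc, n_jobs=config.n_jobs,
        )
        rf_models[rc] = rf

        # cross-fitted RF scores for stage-2 training
        n_folds = max(1, min(config.cross_fit_folds, len(targets)))
        fold_of = {t.record.id: k % n_folds for k, t in enumerate(targets)}
        fold_rf: dict[int, rf_stage.RFEnsembleModel] = {}
        if n_folds > 1:
            for fold in range(n_folds):
                Xf, yf = [], []
                for (t, pairs, X, labels) in per_target:
                    if fold_of[t.record.id] == fold:
                        continue
                    keep = labels >= 0
                    Xf.append(X[keep])
                    yf.append(labels[keep])
                Xf = np.vstack(Xf)
                yf = np.concatenate(yf)
                if len(np.unique(yf)) < 2:
                    continue  # degenerate fold: fall back to the full model
                fold_rf[fold] = rf_stage.train_rf_ensemble(
                    Xf, yf, n_members=config.n_members,
                    seeds=[config.seed + k for k in range(config.n_members)],
                    ratio=config.ratio, n_trees=config.n_trees,
                    range_class=rc, n_jobs=config.n_jobs,
                )

        groups: dict[str, np.ndarray] = {}
        for t, pairs, X, labels in per_target:
            if not pairs:
                continue
            scorer = fold_rf.get(fold_of[t.record.id], rf)
            scores = rf_stage.rf_score(scorer, X)
            phi = _phi_matrix(t, pairs, scores, cm_tags)
            dists = np.array([
                t.cmap.distances[i - 1, j - 1] for i, j in pairs
            ])
            examples = ranker.build_rank_examples(
                qid=f"{t.record.id}/{rc.value}", phi=phi, pairs=pairs,
                distances=dists, bins=config.relevance_bins,
                pair_cap=config.pair_cap, seed=config.seed,
            )
            if examples:
                groups[examples[0].qid] = ranker.pairwise_differences(examples)
        if not groups:
            raise ValueError(f"no ranking constraints for range {rc.value}")
        if config.C is not None:
            C = config.C
        else:
            C = ranker.cross_validate_C(
                groups, C_grid=config.C_grid, seed=config.seed,
                tol=config.svm_tol, max_iter=config.svm_max_iter,
            )
        diffs = np.vstack([g for g in groups.values() if g.shape[0]])
        rank_models[rc] = ranker.train_rank_svm(
            diffs, C=C, tol=config.svm_tol, max_iter=config.svm_max_iter
        )
    return TrainedModels(rf_models=rf_models, rank_models=rank_models,
                         cm_tags=cm_tags, config=config)


def predict_target(models: TrainedModels, target: TargetData,
                   allow_missing_cm: bool = False,
                   ) -> dict[RangeClass, PredictionList]:
    """Score every considered pair of a target, per range class.

    Returns one ranked PredictionList per range, scores min-max mapped to
    [0, 1].  Missing CM inputs raise unless ``allow_missing_cm``; then the
    missing feature column is zero and a warning is issued.
    """
    config = models.config
    out: dict[RangeClass, PredictionList] = {}
    for rc, rank_model in models.rank_models.items():
        pairs, X = _pair_matrix(target, rc, config.window)
        if not pairs:
            out[rc] = PredictionList(target_id=target.record.id, records=[],
                                     range_class=rc)
            continue
        rf_scores = rf_stage.rf_score(models.rf_models[rc], X)
        cols = []
        for tag in models.cm_tags:
            if tag in target.cm_scores:
                m = target.cm_scores[tag].scores
                cols.append(np.array([m[i - 1, j - 1] for i, j in pairs]))
            elif allow_missing_cm:
                warnings.warn(
                    f"{target.record.id}: CM input {tag!r} missing; feature zeroed"
                )
                cols.append(np.zeros(len(pairs)))
            else:
                raise KeyError(
                    f"{target.record.id}: missing correlated-mutations input {tag!r}"
                )
        cols.append(rf_scores)
        phi = np.column_stack(cols)
        scores = ranker.rank_score(rank_model, phi)
        out[rc] = ranker.predictions_from_scores(
            target.record.id, pairs, scores, range_class=rc
        )
    return out


def merge_predictions(per_range: dict[RangeClass, PredictionList]) -> PredictionList:
    """Merge per-range lists into one (scores are already on [0, 1])."""
    records: list[tuple[int, int, float]] = []
    tid = ""
    for rc, plist in per_range.items():
        tid = plist.target_id or tid
        records.extend(plist.records)
    return PredictionList(target_id=tid, records=records)


def evaluate_predictions(targets: list[TargetData],
                         predictions: dict[str, dict[RangeClass, PredictionList]],
                         ):
    """Evaluation report over targets with known structures (length > 50)."""
    evals = []
    for t in targets:
        if t.cmap is None:
            continue
        if t.record.length <= 50:
            continue  # evaluation convention: domains longer than 50 residues
        per_range = predictions.get(t.record.id)
        if not per_range:
            continue
        evals.append(
            evaluation.evaluate_target(per_range, t.cmap, t.record.length)
        )
    if not evals:
        raise ValueError("predictions and targets share no evaluable target")
    return evaluation.aggregate_report(evals)


def save_models(models: TrainedModels, path) -> None:
    """Persist both stages plus the resolved config in one joblib archive."""
    import joblib
    from dataclasses import asdict

    payload = {
        "format_version": 1,
        "cm_tags": models.cm_tags,
        "config": asdict(models.config),
        "rf": {rc.value: m for rc, m in models.rf_models.items()},
        "rank": {
            rc.value: {"weights": m.weights, "C": m.C, "diagnostics": m.diagnostics}
            for rc, m in models.rank_models.items()
        },
    }
    joblib.dump(payload, path)


def load_models(path) -> TrainedModels:
    import joblib

    payload = joblib.load(path)
    if payload.get("format_version") != 1:
        raise ValueError(f"unsupported model archive format in {path}")
    cfg = RunConfig(**{
        k: (tuple(v) if isinstance(v, list) else v)
        for k, v in payload["config"].items()
    })
    return TrainedModels(
        rf_models={RangeClass(k): v for k, v in payload["rf"].items()},
        rank_models={
            RangeClass(k): ranker.RankModel(
                weights=np.asarray(v["weights"]), C=v["C"],
                diagnostics=v["diagnostics"],
            )
            for k, v in payload["rank"].items()
        },
        cm_tags=payload["cm_tags"],
        config=cfg,
    )


def load_target_dir(directory, with_structures: bool = True) -> list[TargetData]:
    """Load every target from a fixture directory.

    Expects, per target id: ``{id}.pssm``, ``{id}.ss``, ``{id}.sa``,
    triplet CM files ``{id}.{tag}.cm`` and (optionally) ``{id}.pdb``.
    """
    from pathlib import Path

    from . import geometry, io_formats

    directory = Path(directory)
    targets = []
    for pssm_path in sorted(directory.glob("*.pssm")):
        tid = pssm_path.stem
        pssm = io_formats.read_pssm(pssm_path)
        L = pssm.length
        ss = io_formats.read_ss(directory / f"{tid}.ss", L)
        sa = io_formats.read_sa(directory / f"{tid}.sa", L)
        cms = {}
        for cm_path in sorted(directory.glob(f"{tid}.*.cm")):
            tag = cm_path.name[len(tid) + 1:-3]
            cms[tag] = io_formats.read_cm_scores(cm_path, "triplet", L, method_tag=tag)
        pdb_path = directory / f"{tid}.pdb"
        cmap = None
        if with_structures and pdb_path.exists():
            record = geometry.read_pdb(pdb_path, record_id=tid)
            if record.length != L:
                raise ValueError(
                    f"{tid}: structure length {record.length} conflicts with PSSM length {L}"
                )
            cmap = geometry.contact_map(record)
        else:
            record = geometry.ProteinRecord(
                id=tid, sequence=pssm.sequence or "X" * L,
                coords=np.full((L, 3), np.nan),
            )
        targets.append(TargetData(record=record, cm_scores=cms, pssm=pssm,
                                  ss_string=ss, sa_string=sa, cmap=cmap))
    if not targets:
        raise ValueError(f"no targets found in {directory}")
    return targets
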