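"""Stage-2 fusion: a per-protein pairwise ranking SVM over stage-1 scores.

Each residue pair d of a target t gets a fusion feature vector Phi(t, d)
holding the normalized correlated-mutations scores plus the RF ensemble
score.  Pairs of the same target are ordered by their true inter-residue
distance (smaller distance => higher relevance), and a linear ranking
function w . Phi is learned from the induced pairwise constraints

    w . Phi(t, d_i) >= w . Phi(t, d_j) + 1 - xi_ijk     (rel(d_i) > rel(d_j))

by minimizing the soft-margin objective

    V(w, xi) = 1/2 w.w + C * sum xi_ijk,   xi_ijk >= 0.

Rearranged over difference vectors D = Phi(t, d_i) - Phi(t, d_j) this is a
standard hinge-loss problem, solved here exactly (to a duality-gap
tolerance) by dual coordinate descent.  Constraints never cross targets:
ranking is always relative to the pairs of one protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import RangeClass
from .io_formats import PredictionList

__all__ = [
    "RankExample",
    "RankModel",
    "DEFAULT_RELEVANCE_BINS",
    "DEFAULT_PAIR_CAP",
    "DEFAULT_C_GRID",
    "build_rank_examples",
    "pairwise_differences",
    "train_rank_svm",
    "rank_score",
    "cross_validate_C",
    "predictions_from_scores",
]

#: distance bin edges (Angstrom); bin 0 (< 8) has the highest relevance
DEFAULT_RELEVANCE_BINS = (8.0, 12.0, 16.0, 20.0)
DEFAULT_PAIR_CAP = 2000
DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class RankExample:
    """One residue pair of one target in the ranking training set."""

    qid: str                      # target id (one qid per target x range)
    pair: tuple[int, int]
    phi: np.ndarray               # fusion features, each in [0, 1]
    relevance: int                # larger = closer in space


@dataclass
class RankModel:
    """Trained linear ranking function w . Phi."""

    weights: np.ndarray
    C: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]


def relevance_from_distance(distance: float,
                            bins: tuple[float, ...] = DEFAULT_RELEVANCE_BINS) -> int:
    """Ordinal relevance from distance: strictly decreasing across bins.

    With the default edges (8, 12, 16, 20): d < 8 -> 4, 8-12 -> 3, 12-16 -> 2,
    16-20 -> 1, >= 20 -> 0.
    """
    if not np.isfinite(distance):
        raise ValueError("relevance needs a defined distance")
    return int(len(bins) - np.searchsorted(bins, distance, side="right"))


def build_rank_examples(qid: str, phi: np.ndarray, pairs: list[tuple[int, int]],
                        distances: np.ndarray,
                        bins: tuple[float, ...] = DEFAULT_RELEVANCE_BINS,
                        pair_cap: int = DEFAULT_PAIR_CAP,
                        seed: int = 0) -> list[RankExample]:
    """Turn one target's stage-1 scores into grouped ranking examples.

    ``phi`` is (n_pairs, k+1), ``distances`` the matching true distances.
    Pairs with undefined distance are dropped.  If more than ``pair_cap``
    pairs remain, a stratified subsample is drawn under ``seed``: scarce
    high-relevance levels (close pairs, above all true contacts) are kept in
    full and the budget left over is spent on the abundant far levels, so
    capping never starves the constraints that order contacts above the rest.
    """
    phi = np.asarray(phi, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if phi.shape[0] != len(pairs) or distances.shape[0] != len(pairs):
        raise ValueError("phi, pairs and distances must cover the same pair set")
    keep = np.flatnonzero(np.isfinite(distances))
    if keep.size == 0:
        warnings.warn(f"{qid}: no pairs with defined distances; empty rank group")
        return []
    if keep.size > pair_cap:
        rng = np.random.default_rng(seed)
        rel = np.array([relevance_from_distance(distances[k], bins) for k in keep])
        by_level = {lv: keep[rel == lv] for lv in np.unique(rel)}
        chosen: list[np.ndarray] = []
        budget = pair_cap
        # scarcest levels first so each gets up to an equal share
        for pos, lv in enumerate(sorted(by_level, key=lambda l: len(by_level[l]))):
            quota = budget // (len(by_level) - pos)
            members = by_level[lv]
            if len(members) > quota:
                members = rng.choice(members, size=quota, replace=False)
            chosen.append(members)
            budget -= len(members)
        keep = np.sort(np.concatenate(chosen))
    return [
        RankExample(
            qid=qid,
            pair=tuple(pairs[k]),
            phi=phi[k],
            relevance=relevance_from_distance(distances[k], bins),
        )
        for k in keep
    ]


def pairwise_differences(examples: list[RankExample]) -> np.ndarray:
    """Difference vectors Phi(hi) - Phi(lo) for every cross-relevance pair.

    Only examples sharing a qid are compared; mixing qids raises.  Returns
    an (n_constraints, k+1) array; equal-relevance pairs contribute nothing.
    """
    if not examples:
        return np.zeros((0, 0))
    qids = {e.qid for e in examples}
    if len(qids) > 1:
        raise ValueError(f"pairwise differences must not cross qids, got {sorted(qids)}")
    by_rel: dict[int, list[np.ndarray]] = {}
    for e in examples:
        by_rel.setdefault(e.relevance, []).append(np.asarray(e.phi, dtype=float))
    levels = sorted(by_rel, reverse=True)
    diffs = []
    for a_pos, hi in enumerate(levels):
        for lo in levels[a_pos + 1:]:
            for u in by_rel[hi]:
                for v in by_rel[lo]:
                    diffs.append(u - v)
    if not diffs:
        return np.zeros((0, len(examples[0].phi)))
    return np.vstack(diffs)


def hinge_objective(w: np.ndarray, diffs: np.ndarray, C: float) -> float:
    """Primal objective 1/2 ||w||^2 + C * sum max(0, 1 - w . D)."""
    w = np.asarray(w, dtype=float)
    margins = 1.0 - diffs @ w
    return 0.5 * float(w @ w) + C * float(np.clip(margins, 0.0, None).sum())


def _cd_epoch(diffs: np.ndarray, sq: np.ndarray, alpha: np.ndarray,
              w: np.ndarray, C: float) -> None:
    """One pass of dual coordinate updates, in place."""
    n = diffs.shape[0]
    for i in range(n):
        if sq[i] == 0.0:
            continue
        g = 1.0 - diffs[i] @ w
        a_new = min(max(alpha[i] + g / sq[i], 0.0), C)
        if a_new != alpha[i]:
            w += (a_new - alpha[i]) * diffs[i]
            alpha[i] = a_new


try:  # JIT the hot loop when numba is around; the fallback is identical
    from numba import njit

    _cd_epoch = njit(cache=True)(_cd_epoch)
except ImportError:  # pragma: no cover
    pass


def train_rank_svm(diffs: np.ndarray, C: float = 1.0, tol: float = 1e-9,
                   max_iter: int = 100_000) -> RankModel:
    """Exact soft-margin solve over difference vectors by dual coordinate descent.

    Maximizes the dual sum(a) - 1/2 ||sum(a_i D_i)||^2 with 0 <= a_i <= C;
    the primal weights are w = sum(a_i D_i).  Iterates epochs of single-
    coordinate updates until the duality gap falls below ``tol`` (relative
    to 1 + |primal|).  Raises on non-convergence.
    """
    diffs = np.ascontiguousarray(np.asarray(diffs, dtype=np.float64))
    if diffs.ndim != 2 or diffs.shape[0] == 0:
        raise ValueError("need at least one difference vector")
    if C <= 0:
        raise ValueError(f"C must be positive, got {C}")
    n, d = diffs.shape
    sq = (diffs**2).sum(axis=1)
    alpha = np.zeros(n)
    w = np.zeros(d)
    # zero difference vectors: hinge is identically 1, alpha pinned at C
    alpha[sq == 0.0] = C
    gap = np.inf
    for epoch in range(max_iter):
        _cd_epoch(diffs, sq, alpha, w, float(C))
        primal = hinge_objective(w, diffs, C)
        dual = float(alpha.sum()) - 0.5 * float(w @ w)
        gap = primal - dual
        if gap <= tol * (1.0 + abs(primal)):
            return RankModel(
                weights=w, C=C,
                diagnostics={
                    "iterations": epoch + 1,
                    "objective": primal,
                    "dual": dual,
                    "duality_gap": gap,
                    "n_constraints": n,
                },
            )
    raise RuntimeError(
        f"ranking SVM did not converge in {max_iter} epochs "
        f"(duality gap {gap:.3e}, objective {hinge_objective(w, diffs, C):.6e})"
    )


def rank_score(model: RankModel, phi: np.ndarray) -> np.ndarray:
    """Linear ranking score w . Phi; higher means more likely contact."""
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 1:
        phi = phi[None, :]
    if phi.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {phi.shape[1]} does not match model "
            f"dimension {model.n_features}"
        )
    return phi @ model.weights


def _ordering_accuracy(w: np.ndarray, diffs: np.ndarray) -> float:
    """Fraction of held-out constraints ranked in the correct direction."""
    if diffs.shape[0] == 0:
        return np.nan
    return float((diffs @ w > 0).mean())


def cross_validate_C(groups: dict[str, np.ndarray],
                     C_grid: tuple[float, ...] = DEFAULT_C_GRID,
                     n_folds: int = 5, seed: int = 0,
                     tol: float = 1e-7, max_iter: int = 100_000) -> float:
    """Pick C by k-fold cross-validation with folds split by qid (protein).

    ``groups`` maps qid -> difference-vector array.  Score is the mean
    held-out pairwise ordering accuracy.  Ties prefer the smallest C.
    """
    qids = sorted(groups)
    if len(qids) < 2:
        return C_grid[len(C_grid) // 2]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(qids))
    n_folds = min(n_folds, len(qids))
    folds = [sorted(order[f::n_folds]) for f in range(n_folds)]
    best_C, best_score = C_grid[0], -np.inf
    for C in C_grid:
        scores = []
        for fold in folds:
            held = {qids[k] for k in fold}
            train = [groups[q] for q in qids if q not in held and groups[q].shape[0]]
            test = [groups[q] for q in held if groups[q].shape[0]]
            if not train or not test:
                continue
            model = train_rank_svm(np.vstack(train), C=C, tol=tol, max_iter=max_iter)
            accs = [_ordering_accuracy(model.weights, t) for t in test]
            scores.append(float(np.nanmean(accs)))
        mean = float(np.mean(scores)) if scores else -np.inf
        if mean > best_score + 1e-12:
            best_C, best_score = C, mean
    return best_C


def predictions_from_scores(target_id: str, pairs: list[tuple[int, int]],
                            scores: np.ndarray,
                            range_class: RangeClass | None = None) -> PredictionList:
    """Sort pairs by descending score and min-max map scores into [0, 1].

    Constant scores map to all 0.5; ties fall back to (i, j) lexicographic
    order inside PredictionList.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != len(pairs):
        raise ValueError("scores and pairs length mismatch")
    if len(pairs) == 0:
        return PredictionList(target_id=target_id, records=[], range_class=range_class)
    lo, hi = scores.min(), scores.max()
    norm = np.full_like(scores, 0.5) if hi == lo else (scores - lo) / (hi - lo)
    records = [(int(i), int(j), float(s)) for (i, j), s in zip(pairs, norm)]
    return PredictionList(target_id=target_id, records=records, range_class=range_class)
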