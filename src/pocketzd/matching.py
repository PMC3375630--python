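"""Patch weighting, weighted patch distances, thresholded bipartite
matching, pocket scoring, database search and ligand prediction.

Patch distance is a weight-combined sum of per-channel L2 distances between
unit-normalized descriptors; the per-patch channel weights are derived from
the spread of descriptors at equivalent positions (patches whose nearest
ligand atom is the same) across pockets binding the same ligand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .structure import Pocket, SurfacePatch
from .properties import CHANNELS

__all__ = [
    "PatchWeights",
    "PatchMatching",
    "RetrievalResult",
    "weights_from_stats",
    "compute_weights",
    "patch_distance",
    "match_cost_matrix",
    "match_patches",
    "pocket_score",
    "search_database",
    "predict_ligand",
    "MAX_PDIST",
]

# pdist upper bound with unit-normalized descriptors and weights summing to 1:
# each channel L2 <= 2, so the weighted sum is <= 2
MAX_PDIST = 2.0

_EPS = 1e-12


@dataclass
class PatchWeights:
    values: np.ndarray  # order follows CHANNELS: (shape, ele, hyd, conc)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (4,):
            raise ValueError("four channel weights required")
        if np.any(self.values < 0):
            raise ValueError("weights must be nonnegative")
        if abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


@dataclass
class PatchMatching:
    pairs: list  # (query patch index, target patch index, distance)
    unmatched_query: list
    unmatched_target: list

    @property
    def total_distance(self) -> float:
        return float(sum(d for _, _, d in self.pairs))

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class RetrievalResult:
    query_id: str
    entries: list  # (pocket id, ligand code, score), ascending score


def _normalized(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _channel_l2(a: SurfacePatch, b: SurfacePatch, channel: str) -> float:
    da, db = a.descriptors[channel], b.descriptors[channel]
    if len(da) != len(db):
        raise ValueError(
            f"descriptor length mismatch on channel {channel}: {len(da)} vs {len(db)}"
        )
    return float(np.linalg.norm(_normalized(da) - _normalized(db)))


def weights_from_stats(avg: np.ndarray, std: np.ndarray) -> PatchWeights:
    """w_t = (1 / (avg_t + 2 std_t)) normalized to sum 1 across channels."""
    avg = np.asarray(avg, dtype=float)
    std = np.asarray(std, dtype=float)
    denom = avg + 2.0 * std
    if np.any(denom < _EPS):
        warnings.warn(
            "degenerate descriptor spread; flooring avg + 2*std at 1e-12",
            stacklevel=2,
        )
        denom = np.maximum(denom, _EPS)
    inv = 1.0 / denom
    return PatchWeights(values=inv / inv.sum())


def compute_weights(equivalent_patches: list) -> PatchWeights:
    """Channel weights from the descriptor spread of equivalent patches.

    For each channel, all-pairs L2 distances (unit-normalized descriptors)
    among the group give avg and std. Groups with fewer than two patches
    fall back to uniform weights.
    """
    if len(equivalent_patches) < 2:
        return PatchWeights(values=np.full(4, 0.25))
    avg = np.empty(4)
    std = np.empty(4)
    for t, ch in enumerate(CHANNELS):
        mats = np.stack(
            [_normalized(p.descriptors[ch]) for p in equivalent_patches]
        )
        diffs = mats[:, None, :] - mats[None, :, :]
        d = np.linalg.norm(diffs, axis=2)
        iu = np.triu_indices(len(equivalent_patches), k=1)
        pair_d = d[iu]
        avg[t] = pair_d.mean()
        std[t] = pair_d.std()
    return weights_from_stats(avg, std)


def patch_distance(
    query_patch: SurfacePatch,
    db_patch: SurfacePatch,
    weights: np.ndarray = None,
) -> float:
    """Weighted sum of per-channel descriptor L2 distances.

    Weights default to the database patch's stored weights; descriptors are
    normalized to unit Euclidean length per channel before the L2.
    """
    w = np.asarray(db_patch.weights if weights is None else weights, dtype=float)
    return float(
        sum(w[t] * _channel_l2(query_patch, db_patch, ch)
            for t, ch in enumerate(CHANNELS) if w[t] != 0.0)
    )


def match_cost_matrix(cost: np.ndarray, threshold: float = None) -> PatchMatching:
    """Optimal one-to-one assignment on a rectangular cost matrix.

    Without a threshold every row or column of the smaller side is matched
    at minimum total cost. With a threshold, pairs costing more than it are
    forbidden; the assignment maximizes pair count, then minimizes total
    cost (forbidden pairs carry a cost large enough to dominate any sum of
    allowed ones, and are stripped from the result).
    """
    cost = np.asarray(cost, dtype=float)
    nq, nt = cost.shape
    if threshold is None:
        rows, cols = linear_sum_assignment(cost)
        pairs = [(int(r), int(c), float(cost[r, c])) for r, c in zip(rows, cols)]
    else:
        big = 1e9
        masked = np.where(cost <= threshold, cost, big)
        rows, cols = linear_sum_assignment(masked)
        pairs = [
            (int(r), int(c), float(cost[r, c]))
            for r, c in zip(rows, cols)
            if cost[r, c] <= threshold
        ]
    matched_q = {r for r, _, _ in pairs}
    matched_t = {c for _, c, _ in pairs}
    return PatchMatching(
        pairs=sorted(pairs),
        unmatched_query=[i for i in range(nq) if i not in matched_q],
        unmatched_target=[j for j in range(nt) if j not in matched_t],
    )


def _cost_matrix(query: Pocket, target: Pocket, shape_only: bool) -> np.ndarray:
    w_override = np.array([1.0, 0.0, 0.0, 0.0]) if shape_only else None
    cost = np.empty((query.n_patches, target.n_patches))
    for i, qp in enumerate(query.patches):
        for j, tp in enumerate(target.patches):
            cost[i, j] = patch_distance(qp, tp, weights=w_override)
    return cost


def match_patches(
    query: Pocket,
    target: Pocket,
    threshold: float = None,
    shape_only: bool = False,
) -> PatchMatching:
    """Thresholded bipartite matching between two pockets' patches."""
    if query.n_patches == 0 or target.n_patches == 0:
        raise ValueError("both pockets must have at least one patch")
    return match_cost_matrix(_cost_matrix(query, target, shape_only), threshold)


def pocket_score(
    matching: PatchMatching,
    query: Pocket,
    target: Pocket,
    term_weights=(1.0, 0.5, 0.5),
    threshold: float = None,
) -> float:
    """Linear combination of matched-distance, coverage and size terms.

    score = c1 * mean matched distance
          + c2 * fraction of query patches left unmatched
          + c3 * |n_query - n_target| / max(n_query, n_target)

    Lower is more similar. An empty matching takes the worst distance term
    (the threshold, or the distance upper bound) so such pockets rank last.
    """
    c1, c2, c3 = term_weights
    nq, nt = query.n_patches, target.n_patches
    size_term = abs(nq - nt) / max(nq, nt)
    if matching.n_pairs == 0:
        worst = threshold if threshold is not None else MAX_PDIST
        return c1 * worst + c2 + c3 * size_term
    mean_d = matching.total_distance / matching.n_pairs
    unmatched_frac = len(matching.unmatched_query) / nq
    return c1 * mean_d + c2 * unmatched_frac + c3 * size_term


def search_database(
    query: Pocket,
    db,
    threshold: float = None,
    properties: str = "all",
    term_weights=(1.0, 0.5, 0.5),
) -> RetrievalResult:
    """Score the query against every database pocket, ascending order.

    ``properties`` is "all" (stored per-patch weights) or "shape"
    (weights forced to the shape channel only). Ties break on pocket ID.
    """
    if len(db.entries) == 0:
        raise ValueError("database is empty")
    if properties not in ("all", "shape"):
        raise ValueError("properties must be 'all' or 'shape'")
    order = db.metadata.get("order")
    if order is not None and query.patches:
        expected = sum(n // 2 + 1 for n in range(order + 1))
        if len(query.patches[0].descriptors["shape"]) != expected:
            raise ValueError(
                f"query descriptors do not match database order {order}"
            )
    shape_only = properties == "shape"
    scored = []
    for entry in db.entries:
        m = match_patches(query, entry, threshold=threshold, shape_only=shape_only)
        s = pocket_score(m, query, entry, term_weights=term_weights,
                        threshold=threshold)
        scored.append((entry.source_id, entry.ligand_code, s))
    scored.sort(key=lambda t: (t[2], t[0]))
    return RetrievalResult(query_id=query.source_id, entries=scored)


def predict_ligand(result: RetrievalResult, k: int = 10) -> list:
    """Rank ligand types by sum of 1/rank over their top-k occurrences."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(result.entries):
        warnings.warn(
            f"k={k} exceeds result size {len(result.entries)}; clamping",
            stacklevel=2,
        )
        k = len(result.entries)
    scores: dict = {}
    for rank, (_, ligand, _) in enumerate(result.entries[:k], start=1):
        scores[ligand] = scores.get(ligand, 0.0) + 1.0 / rank
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
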