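"""Enrichment-factor evaluation of ranked pocket retrieval.

EF at x percent is the fraction of correct entries among the top
ceil(x/100 * T_DB) ranks, divided by the fraction expected at random
(T_P / T_DB). EF = 1 is random, T_DB / T_P is maximal, and EF at 100% is
exactly 1 for any ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["EFPoint", "enrichment_factor", "ef_curve", "mean_ef"]


@dataclass
class EFPoint:
    x: float        # percent of database scanned
    n_x: int        # entries in the top x percent
    n_correct: int  # correct entries among them
    total_correct: int
    db_size: int
    ef: float


def enrichment_factor(ranking: list, correct_set, x: float) -> EFPoint:
    """EF for one ranked list of database entry IDs.

    ``ranking`` must cover the database; ``correct_set`` holds the IDs of
    the entries counted as correct.
    """
    correct_set = set(correct_set)
    if not correct_set:
        raise ValueError("correct_set is empty; EF is undefined")
    if not 0 < x <= 100:
        raise ValueError(f"x must be in (0, 100], got {x}")
    missing = correct_set - set(ranking)
    if missing:
        raise ValueError(f"ranking does not cover correct entries: {sorted(missing)}")
    t_db = len(ranking)
    t_p = len(correct_set)
    n_x = math.ceil(x / 100.0 * t_db)
    n_correct = sum(1 for entry in ranking[:n_x] if entry in correct_set)
    ef = (n_correct / n_x) / (t_p / t_db)
    return EFPoint(x=x, n_x=n_x, n_correct=n_correct,
                   total_correct=t_p, db_size=t_db, ef=ef)


def ef_curve(ranking: list, correct_set, x_values) -> list:
    """EFPoint per cutoff; ``x_values`` must be sorted ascending."""
    x_values = list(x_values)
    if x_values != sorted(x_values):
        raise ValueError("x_values must be sorted ascending")
    return [enrichment_factor(ranking, correct_set, x) for x in x_values]


def mean_ef(rankings: list, correct_sets: list, x_values) -> list:
    """Unweighted mean EF across a query set, one value per cutoff."""
    if len(rankings) != len(correct_sets):
        raise ValueError("one correct set per ranking required")
    curves = [ef_curve(r, c, x_values) for r, c in zip(rankings, correct_sets)]
    return [
        sum(curve[i].ef for curve in curves) / len(curves)
        for i in range(len(list(x_values)))
    ]
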