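"""Particle-set cleaning: duplicate removal, score thresholding, neighbor counts.

Reduces oversampled or poorly aligned particle tables the way subtomogram-
averaging pipelines do after alignment.  All cleaners only delete rows —
surviving poses are never mutated — and each returns a
:class:`CleaningReport` whose counts reconcile exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class CleaningReport:
    """Bookkeeping for one cleaning pass."""

    stage: str
    n_input: int
    n_output: int
    n_removed_duplicate: int = 0
    n_removed_score: int = 0
    n_removed_isolated: int = 0
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self):
        removed = (
            self.n_removed_duplicate + self.n_removed_score + self.n_removed_isolated
        )
        if self.n_output != self.n_input - removed or min(
            self.n_input, self.n_output, removed
        ) < 0:
            raise ValueError("cleaning report counts do not reconcile")

    def to_dict(self) -> dict:
        return asdict(self)


def remove_duplicates(table: pd.DataFrame, min_dist_A: float):
    """Greedy score-ranked duplicate removal.

    Particles are visited by descending score (ties: ascending particle_id);
    a particle survives iff no already-accepted particle lies within
    ``min_dist_A``.  Idempotent; survivors keep their original row order.
    """
    if min_dist_A <= 0:
        raise ValueError("min_dist must be positive")
    n = len(table)
    if n == 0:
        return table.copy(), CleaningReport(
            "remove_duplicates", 0, 0, thresholds={"min_dist_A": min_dist_A}
        )
    pos = table[["x_A", "y_A", "z_A"]].to_numpy(dtype=float)
    order = np.lexsort(
        (table["particle_id"].to_numpy(), -table["score"].to_numpy(dtype=float))
    )
    tree = cKDTree(pos)
    keep = np.zeros(n, dtype=bool)
    killed = np.zeros(n, dtype=bool)
    for i in order:
        if killed[i]:
            continue
        keep[i] = True
        for j in tree.query_ball_point(pos[i], min_dist_A):
            if j != i and not keep[j]:
                killed[j] = True
    out = table.loc[keep].copy()
    return out, CleaningReport(
        "remove_duplicates",
        n_input=n,
        n_output=int(keep.sum()),
        n_removed_duplicate=int(n - keep.sum()),
        thresholds={"min_dist_A": min_dist_A},
    )


def score_threshold_clean(table: pd.DataFrame, min_score: float):
    """Keep particles with score >= min_score; order preserved."""
    mask = table["score"].to_numpy(dtype=float) >= min_score
    out = table.loc[mask].copy()
    return out, CleaningReport(
        "score_threshold_clean",
        n_input=len(table),
        n_output=int(mask.sum()),
        n_removed_score=int(len(table) - mask.sum()),
        thresholds={"min_score": min_score},
    )


def neighbor_count_clean(table: pd.DataFrame, radius_A: float, min_neighbors: int):
    """Drop particles with fewer than ``min_neighbors`` within ``radius_A``.

    Counts are computed on the input table in a single pass before any
    removal, so the result is order-independent and deterministic.
    """
    if radius_A <= 0:
        raise ValueError("radius must be positive")
    if min_neighbors < 0:
        raise ValueError("min_neighbors must be >= 0")
    n = len(table)
    if n == 0 or min_neighbors == 0:
        return table.copy(), CleaningReport(
            "neighbor_count_clean",
            n_input=n,
            n_output=n,
            thresholds={"radius_A": radius_A, "min_neighbors": min_neighbors},
        )
    pos = table[["x_A", "y_A", "z_A"]].to_numpy(dtype=float)
    tree = cKDTree(pos)
    counts = np.array([len(tree.query_ball_point(p, radius_A)) - 1 for p in pos])
    mask = counts >= min_neighbors
    out = table.loc[mask].copy()
    return out, CleaningReport(
        "neighbor_count_clean",
        n_input=n,
        n_output=int(mask.sum()),
        n_removed_isolated=int(n - mask.sum()),
        thresholds={"radius_A": radius_A, "min_neighbors": min_neighbors},
    )
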