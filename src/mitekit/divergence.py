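"""Pairwise p-distances and within/between-group divergence summaries.

The p-distance is the proportion of differing sites among sites where
both rows carry an unambiguous base (pairwise deletion of gap/N sites),
so short fragments still contribute over the region they cover. Group
summaries average the pairwise values within each species and across
each species pair and are reported as percentages, matching the usual
presentation of transposable-element family divergence tables.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .consensus import StackedAlignment

_BASES = frozenset("ACGT")


@dataclass
class DistanceMatrix:
    ids: list[str]
    labels: list[Optional[str]]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(np.diag(v), 0, equal_nan=True):
            raise ValueError("distance matrix diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites, pairwise-deleting gap/N sites.

    Returns NaN (flagged undefined) when the rows share no comparable
    site.
    """
    if len(a) != len(b):
        raise ValueError("rows must have equal (aligned) length")
    comparable = 0
    diffs = 0
    for x, y in zip(a, b):
        if x in _BASES and y in _BASES:
            comparable += 1
            if x != y:
                diffs += 1
    if comparable == 0:
        return math.nan
    return diffs / comparable


def pairwise_matrix(aln: StackedAlignment, metric: str = "p_distance",
                    gamma_a: Optional[float] = None) -> DistanceMatrix:
    """All pairwise distances between alignment rows.

    ``metric`` is ``p_distance`` or ``t92_gamma`` (Tamura 1992,
    optionally gamma-corrected via ``gamma_a``).
    """
    if metric == "p_distance":
        fn = p_distance
    elif metric == "t92_gamma":
        from .phylogeny import t92_distance

        def fn(a, b):
            return t92_distance(a, b, gamma_a)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    n = aln.n_rows
    vals = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = fn(aln.matrix[i], aln.matrix[j])
        vals[i, j] = vals[j, i] = d
    return DistanceMatrix(list(aln.row_ids), list(aln.species), vals, metric)


def _pair_values(dm: DistanceMatrix, idx_a: Sequence[int], idx_b: Sequence[int],
                 within: bool) -> list[float]:
    if within:
        pairs = itertools.combinations(idx_a, 2)
    else:
        pairs = itertools.product(idx_a, idx_b)
    return [dm.values[i, j] for i, j in pairs if not math.isnan(dm.values[i, j])]


def group_divergence(aln: StackedAlignment, labels: Optional[Sequence[str]] = None,
                     metric: str = "p_distance") -> pd.DataFrame:
    """Within/between-group mean divergence as percentages.

    Returns a square DataFrame with group names on both axes: the
    diagonal holds the within-group mean over all unordered pairs
    inside the group (NaN for singleton groups), off-diagonal cells the
    mean over all cross pairs.
    """
    labels = list(labels) if labels is not None else [s or "?" for s in aln.species]
    if len(labels) != aln.n_rows:
        raise ValueError("one label per alignment row required")
    dm = pairwise_matrix(aln, metric)
    groups = sorted(set(labels))
    index = {g: [i for i, l in enumerate(labels) if l == g] for g in groups}
    out = pd.DataFrame(np.nan, index=groups, columns=groups)
    for g in groups:
        vals = _pair_values(dm, index[g], index[g], within=True)
        if vals:
            out.loc[g, g] = 100.0 * float(np.mean(vals))
    for g, h in itertools.combinations(groups, 2):
        vals = _pair_values(dm, index[g], index[h], within=False)
        if vals:
            out.loc[g, h] = out.loc[h, g] = 100.0 * float(np.mean(vals))
    return out


def overall_mean_divergence(aln: StackedAlignment, metric: str = "p_distance") -> float:
    """Mean pairwise distance over all unordered row pairs, in percent."""
    dm = pairwise_matrix(aln, metric)
    n = aln.n_rows
    vals = [
        dm.values[i, j]
        for i, j in itertools.combinations(range(n), 2)
        if not math.isnan(dm.values[i, j])
    ]
    if not vals:
        raise ValueError("no comparable pairs in alignment")
    return 100.0 * float(np.mean(vals))
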