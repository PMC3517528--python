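"""Distance-based phylogenetics: T92(+gamma) distances, NJ, bootstrap.

The Tamura (1992) distance corrects the observed transition (P) and
transversion (Q) fractions for multiple hits while accounting for G+C
content bias; with h = 2*theta*(1-theta) for mean G+C content theta:

    d = -h ln(1 - P/h - Q) - ((1-h)/2) ln(1 - 2Q)

and, under gamma-distributed rate variation with shape a:

    d = a h [(1 - P/h - Q)^(-1/a) - 1] + a ((1-h)/2) [(1 - 2Q)^(-1/a) - 1]

Pairs whose log/power arguments are non-positive are saturated and
flagged NaN. Trees are built by Saitou-Nei neighbor joining with
deterministic tie-breaking, and clade support by nonparametric
bootstrap over alignment columns.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from skbio import TreeNode

from .consensus import StackedAlignment
from .divergence import DistanceMatrix, p_distance

_BASES = frozenset("ACGT")
_PURINES = frozenset("AG")


def t92_distance(a: str, b: str, gamma_a: Optional[float] = None) -> float:
    """Tamura three-parameter distance between two aligned rows.

    Gap/N sites are pairwise-deleted. ``gamma_a`` is the gamma shape
    parameter for among-site rate variation (None = uniform rates).
    Returns NaN for saturated pairs.
    """
    if len(a) != len(b):
        raise ValueError("rows must have equal (aligned) length")
    if gamma_a is not None and gamma_a <= 0:
        raise ValueError("gamma shape must be positive")
    n = transitions = transversions = gc = 0
    for x, y in zip(a, b):
        if x not in _BASES or y not in _BASES:
            continue
        n += 1
        gc += (x in "GC") + (y in "GC")
        if x != y:
            if (x in _PURINES) == (y in _PURINES):
                transitions += 1
            else:
                transversions += 1
    if n == 0:
        return math.nan
    P = transitions / n
    Q = transversions / n
    theta = gc / (2 * n)
    h = 2.0 * theta * (1.0 - theta)
    arg2 = 1.0 - 2.0 * Q
    if h == 0.0:
        # all-AT or all-GC pair: no transition term is estimable
        if P > 0 or arg2 <= 0:
            return math.nan
        if gamma_a is None:
            return -0.5 * math.log(arg2)
        return gamma_a * 0.5 * (arg2 ** (-1.0 / gamma_a) - 1.0)
    arg1 = 1.0 - P / h - Q
    if arg1 <= 0 or arg2 <= 0:
        return math.nan
    if gamma_a is None:
        return -h * math.log(arg1) - 0.5 * (1.0 - h) * math.log(arg2)
    inv = -1.0 / gamma_a
    return gamma_a * (h * (arg1 ** inv - 1.0) + 0.5 * (1.0 - h) * (arg2 ** inv - 1.0))


@dataclass
class PhyloTree:
    """Unrooted NJ tree (stored with a trifurcating root)."""

    tree: TreeNode

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()

    def leaf_names(self) -> list[str]:
        return sorted(t.name for t in self.tree.tips())

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Non-trivial bipartitions, keyed by the canonical leaf side.

        The canonical side is the one NOT containing the
        alphabetically first leaf, making the keys invariant to
        rooting and leaf order.
        """
        leaves = set(self.leaf_names())
        anchor = min(leaves)
        out: dict[frozenset, TreeNode] = {}
        for node in self.tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if anchor in side:
                side = frozenset(leaves - side)
            if 2 <= len(side) <= len(leaves) - 2:
                out[side] = node
        return out


def drop_saturated(dm: DistanceMatrix) -> DistanceMatrix:
    """Greedily drop taxa involved in NaN (saturated) distances."""
    vals = dm.values.copy()
    keep = list(range(len(dm.ids)))
    while True:
        sub = vals[np.ix_(keep, keep)]
        nan_counts = np.isnan(sub).sum(axis=1)
        if nan_counts.max(initial=0) == 0:
            break
        worst = keep[int(np.argmax(nan_counts))]
        warnings.warn(
            f"dropping taxon {dm.ids[worst]!r}: saturated distances", stacklevel=2
        )
        keep.remove(worst)
    return DistanceMatrix(
        [dm.ids[i] for i in keep],
        [dm.labels[i] for i in keep],
        vals[np.ix_(keep, keep)],
        dm.metric,
    )


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with the standard Q criterion.

    Deterministic: on Q ties the lowest-index pair is joined. Negative
    branch lengths are clamped to zero. The result is the unrooted NJ
    topology stored with a trifurcating root.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.isnan(dm.values).any():
        raise ValueError("distance matrix contains NaN; use drop_saturated first")
    D = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index pair on ties: argmin scans row-major
        flat = int(np.argmin(Q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node to the remaining taxa
        new_row = np.zeros(D.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (D[i, ak] + D[j, ak] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for k, l in zip((a, b, c), (la, lb, lc)):
        nodes[k].length = max(l, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root)


def _matrix_for(rows: list[str], ids: list[str], metric: str,
                gamma_a: Optional[float]) -> DistanceMatrix:
    n = len(rows)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "p_distance":
                d = p_distance(rows[i], rows[j])
            else:
                d = t92_distance(rows[i], rows[j], gamma_a)
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(ids, [None] * n, vals, metric)


def bootstrap_support(aln: StackedAlignment, metric: str = "p_distance",
                      gamma_a: Optional[float] = None, n_reps: int = 1000,
                      seed: int = 0) -> PhyloTree:
    """NJ tree with bootstrap supports on internal edges.

    Alignment columns are resampled with replacement ``n_reps`` times;
    each replicate's distance matrix is rebuilt with the same metric
    and NJ rerun. Every internal edge of the full-data tree is labelled
    with the percentage of replicates containing the same bipartition.
    Fully reproducible from ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    dm = _matrix_for(aln.matrix, aln.row_ids, metric, gamma_a)
    dm = drop_saturated(dm)
    keep_ids = set(dm.ids)
    rows = [r for rid, r in zip(aln.row_ids, aln.matrix) if rid in keep_ids]
    ids = [rid for rid in aln.row_ids if rid in keep_ids]
    base = nj_tree(dm)
    target = base.bipartitions()
    hit_counts = {bp: 0 for bp in target}

    rng = np.random.default_rng(seed)
    arr = np.array([list(r) for r in rows])
    ncol = arr.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_rows = ["".join(r) for r in arr[:, cols]]
        rep_dm = _matrix_for(rep_rows, ids, metric, gamma_a)
        if np.isnan(rep_dm.values).any():
            rep_dm = drop_saturated(rep_dm)
            if len(rep_dm.ids) < 3:
                continue
        rep_tree = nj_tree(rep_dm)
        rep_bps = set(rep_tree.bipartitions())
        for bp in hit_counts:
            if bp in rep_bps:
                hit_counts[bp] += 1

    for bp, node in target.items():
        node.name = str(int(round(100.0 * hit_counts[bp] / n_reps)))
    return base
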