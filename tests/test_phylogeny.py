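import itertools
import math

import numpy as np
import pytest

from conftest import random_seq
from mitekit.consensus import StackedAlignment
from mitekit.divergence import DistanceMatrix, p_distance
from mitekit.phylogeny import (
    PhyloTree, bootstrap_support, drop_saturated, nj_tree, t92_distance,
)
from mitekit.simulate import simulate_species_set


def t92_oracle(a, b, gamma=None):
    """Independent site-counting + closed-form evaluation (numpy path)."""
    pairs = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
    n = len(pairs)
    ts = sum((x in "AG") == (y in "AG") and x != y for x, y in pairs)
    tv = sum((x in "AG") != (y in "AG") for x, y in pairs)
    gc = sum((x in "GC") + (y in "GC") for x, y in pairs)
    P, Q = ts / n, tv / n
    theta = gc / (2 * n)
    h = 2 * theta * (1 - theta)
    if gamma is None:
        return float(-h * np.log(1 - P / h - Q) - (1 - h) / 2 * np.log(1 - 2 * Q))
    return float(
        gamma * h * ((1 - P / h - Q) ** (-1 / gamma) - 1)
        + gamma * (1 - h) / 2 * ((1 - 2 * Q) ** (-1 / gamma) - 1)
    )


def dm(ids, values):
    return DistanceMatrix(ids, [None] * len(ids), np.asarray(values, float),
                          "p_distance")


def tree_path_lengths(tree: PhyloTree):
    t = tree.tree
    out = {}
    tips = list(t.tips())
    for a, b in itertools.combinations(tips, 2):
        out[frozenset((a.name, b.name))] = a.distance(b)
    return out


class TestT92:
    def test_identical_rows_zero(self):
        for g in (None, 2.0):
            assert t92_distance("ACGTACGT", "ACGTACGT", g) == 0.0

    def test_matches_independent_evaluation(self, rng):
        for _ in range(30):
            a = random_seq(rng, 300)
            b = "".join(
                c if rng.random() > 0.2 else rng.choice(list("ACGT")) for c in a
            )
            for g in (None, 2.0, 0.7):
                got = t92_distance(a, b, g)
                if not math.isnan(got):
                    assert got == pytest.approx(t92_oracle(a, b, g), abs=1e-12)

    def test_gamma_limit_recovers_uncorrected(self, rng):
        for _ in range(10):
            a = random_seq(rng, 400)
            b = "".join(
                c if rng.random() > 0.15 else rng.choice(list("ACGT")) for c in a
            )
            d_inf = t92_distance(a, b, 1e6)
            d_none = t92_distance(a, b, None)
            if not (math.isnan(d_inf) or math.isnan(d_none)):
                assert d_inf == pytest.approx(d_none, abs=1e-6)

    def test_correction_inflates_over_p_distance(self, rng):
        for _ in range(30):
            a = random_seq(rng, 300)
            b = "".join(
                c if rng.random() > 0.25 else rng.choice(list("ACGT")) for c in a
            )
            d = t92_distance(a, b)
            if not math.isnan(d):
                assert d >= p_distance(a, b) - 1e-12

    def test_saturated_pair_flagged(self):
        a = "A" * 50 + "C" * 50
        b = "G" * 50 + "T" * 50  # every site a transition: P = 1
        assert math.isnan(t92_distance(a, b))

    def test_invalid_gamma_raises(self):
        with pytest.raises(ValueError):
            t92_distance("ACGT", "ACGT", -1.0)


class TestNJ:
    def test_three_taxa_closed_form(self):
        D = [[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]
        tree = nj_tree(dm(["a", "b", "c"], D))
        lengths = {t.name: t.length for t in tree.tree.children}
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_additive_four_taxon_recovery(self):
        # tree ((a:1,b:2):3,(c:4,d:5)) -> additive distances
        D = [
            [0, 3, 8, 9],
            [3, 0, 9, 10],
            [8, 9, 0, 9],
            [9, 10, 9, 0],
        ]
        tree = nj_tree(dm(list("abcd"), D))
        assert frozenset(["a", "b"]) in tree.bipartitions() or \
            frozenset(["c", "d"]) in tree.bipartitions()
        paths = tree_path_lengths(tree)
        for (i, x) in enumerate("abcd"):
            for (j, y) in enumerate("abcd"):
                if i < j:
                    assert paths[frozenset((x, y))] == pytest.approx(D[i][j], abs=1e-9)

    def test_identical_taxa_become_siblings(self, rng):
        rows = [random_seq(rng, 100) for _ in range(4)]
        rows.append(rows[0])
        ids = ["a", "b", "c", "d", "a2"]
        vals = np.zeros((5, 5))
        for i, j in itertools.combinations(range(5), 2):
            vals[i, j] = vals[j, i] = p_distance(rows[i], rows[j])
        tree = nj_tree(dm(ids, vals))
        # {a, a2} vs the rest; canonical form excludes the anchor leaf "a"
        sib = frozenset(["b", "c", "d"])
        bps = {bp for bp in tree.bipartitions()}
        # a and a2 at distance 0 must be joined with 0-length pendants
        ta = [t for t in tree.tree.tips() if t.name == "a"][0]
        t2 = [t for t in tree.tree.tips() if t.name == "a2"][0]
        assert ta.distance(t2) == pytest.approx(0.0, abs=1e-12)
        assert sib in bps

    def test_fewer_than_three_taxa_raises(self):
        with pytest.raises(ValueError):
            nj_tree(dm(["a", "b"], [[0, 1], [1, 0]]))

    def test_nan_matrix_rejected(self):
        D = [[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]]
        with pytest.raises(ValueError):
            nj_tree(dm(["a", "b", "c"], D))

    def test_topology_agrees_with_skbio(self, rng):
        """Independent oracle: scikit-bio's NJ on the same matrix."""
        import skbio

        for _ in range(5):
            n = 7
            rows = [random_seq(rng, 200) for _ in range(n)]
            ids = [f"t{i}" for i in range(n)]
            vals = np.zeros((n, n))
            for i, j in itertools.combinations(range(n), 2):
                vals[i, j] = vals[j, i] = p_distance(rows[i], rows[j])
            ours = nj_tree(dm(ids, vals))
            theirs = skbio.tree.nj(skbio.DistanceMatrix(vals, ids))
            anchor = min(ids)
            their_bps = set()
            for node in theirs.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if anchor in side:
                    side = frozenset(set(ids) - side)
                if 2 <= len(side) <= n - 2:
                    their_bps.add(side)
            assert set(ours.bipartitions()) == their_bps


class TestDropSaturated:
    def test_drops_minimal_taxa(self):
        vals = np.array([
            [0, 1, np.nan, 1],
            [1, 0, 1, 1],
            [np.nan, 1, 0, 1],
            [1, 1, 1, 0],
        ])
        d = DistanceMatrix(list("abcd"), [None] * 4, vals, "p_distance")
        with pytest.warns(UserWarning):
            kept = drop_saturated(d)
        assert len(kept.ids) == 3
        assert not np.isnan(kept.values).any()


class TestBootstrap:
    def _species_aln(self, reference, seed=0):
        recs, _ = simulate_species_set(
            reference, n_species=2, copies_per_species=5,
            within_div=0.01, between_div=0.20, seed=seed,
        )
        return StackedAlignment(
            [r.id for r in recs], [r.species for r in recs],
            [r.residues for r in recs],
        )

    def test_two_clade_split_strongly_supported(self, reference):
        aln = self._species_aln(reference)
        tree = bootstrap_support(aln, n_reps=100, seed=1)
        clade = frozenset(rid for rid in aln.row_ids if rid.startswith("sp2"))
        bps = tree.bipartitions()
        assert clade in bps
        assert int(bps[clade].name) >= 95

    def test_single_replicate_supports_binary(self, reference):
        aln = self._species_aln(reference, seed=3)
        tree = bootstrap_support(aln, n_reps=1, seed=5)
        supports = {int(n.name) for n in tree.bipartitions().values()}
        assert supports <= {0, 100}

    def test_same_seed_reproducible(self, reference):
        aln = self._species_aln(reference, seed=2)
        t1 = bootstrap_support(aln, n_reps=20, seed=9)
        t2 = bootstrap_support(aln, n_reps=20, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_newick_output_parses(self, reference):
        import skbio

        aln = self._species_aln(reference, seed=4)
        tree = bootstrap_support(aln, n_reps=5, seed=0)
        import io

        parsed = skbio.TreeNode.read(io.StringIO(tree.to_newick()))
        assert {t.name for t in parsed.tips()} == set(aln.row_ids)
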