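"""Protein distances, neighbor joining, and bootstrap supports."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from sweeplab._wag import AMINO_ACIDS, WAG_FREQUENCIES
from sweeplab.protphylo import (ProteinAlignment, bootstrap_support,
                                ml_distance_matrix, neighbor_joining,
                                percent_identity_matrix, wag_ml_distance,
                                _bipartitions)


class TestPercentIdentity:
    def test_identical_sequences(self):
        aln = ProteinAlignment(["a", "b"], ["ACDE", "ACDE"])
        m = percent_identity_matrix(aln)
        assert m.loc["a", "b"] == 100.0

    def test_three_of_four(self):
        aln = ProteinAlignment(["a", "b"], ["ACDE", "ACDK"])
        assert percent_identity_matrix(aln).loc["a", "b"] == 75.0

    def test_gap_columns_excluded(self):
        aln = ProteinAlignment(["a", "b"], ["AC-EF", "ACDE-"])
        # comparable columns: 1,2,4 -> identical at 1,2 only... column 4 is
        # E vs '-' (excluded); comparable = {0,1,3}: A=A, C=C, E vs E
        m = percent_identity_matrix(aln)
        assert m.loc["a", "b"] == pytest.approx(100.0 * 3 / 3)

    def test_no_comparable_columns_rejected(self):
        aln = ProteinAlignment(["a", "b"], ["A-", "-A"])
        with pytest.raises(ValueError):
            percent_identity_matrix(aln)


class TestWagDistance:
    def test_identical_sequences_at_lower_clamp(self):
        d = wag_ml_distance("ACDEFGHIKLMNPQRSTVWY", "ACDEFGHIKLMNPQRSTVWY")
        assert d <= 1e-5

    def test_symmetry(self, rng):
        a = "".join(rng.choice(list(AMINO_ACIDS), size=120))
        b = "".join(rng.choice(list(AMINO_ACIDS), size=120))
        assert wag_ml_distance(a, b) == pytest.approx(
            wag_ml_distance(b, a), abs=1e-9)

    def test_monotone_in_divergence(self, rng):
        base = "".join(rng.choice(list(AMINO_ACIDS), size=150))
        prev = 0.0
        seq = list(base)
        for k in (5, 15, 30):
            while sum(x != y for x, y in zip(base, seq)) < k:
                i = rng.integers(0, len(seq))
                seq[i] = rng.choice([a for a in AMINO_ACIDS if a != base[i]])
            d = wag_ml_distance(base, "".join(seq))
            assert d > prev
            prev = d

    def test_equal_rate_model_matches_closed_form(self, rng):
        # with all exchangeabilities equal and uniform frequencies the ML
        # distance has the 20-state Jukes-Cantor closed form
        ones = np.ones(190)
        unif = np.full(20, 0.05)
        n = 400
        base = rng.choice(list(AMINO_ACIDS), size=n)
        seq = base.copy()
        flip = rng.random(n) < 0.15
        for i in np.nonzero(flip)[0]:
            seq[i] = rng.choice([a for a in AMINO_ACIDS if a != base[i]])
        p_hat = np.mean(base != seq)
        closed = -(19 / 20) * np.log(1 - 20 / 19 * p_hat)
        est = wag_ml_distance("".join(base), "".join(seq),
                              exchangeabilities=ones, frequencies=unif)
        assert est == pytest.approx(closed, rel=0.01)


def tree_distances(tree):
    """Leaf-to-leaf path lengths from a dendropy tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return lambda a, b: pdm.distance(taxa[a], taxa[b])


class TestNeighborJoining:
    ADDITIVE = pd.DataFrame(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
        index=list("ABCD"), columns=list("ABCD"), dtype=float)

    def test_recovers_additive_tree_exactly(self):
        tree = neighbor_joining(self.ADDITIVE)
        d = tree_distances(tree)
        for a in "ABCD":
            for b in "ABCD":
                if a < b:
                    assert d(a, b) == pytest.approx(
                        self.ADDITIVE.loc[a, b], abs=1e-9)
        # topology: AB vs CD split
        assert _bipartitions(tree) == {frozenset({"C", "D"})}

    def test_three_taxa_star(self):
        dm = pd.DataFrame([[0, 2, 3], [2, 0, 5], [3, 5, 0]],
                          index=list("XYZ"), columns=list("XYZ"), dtype=float)
        tree = neighbor_joining(dm)
        d = tree_distances(tree)
        assert d("X", "Y") == pytest.approx(2.0)
        assert d("X", "Z") == pytest.approx(3.0)
        assert d("Y", "Z") == pytest.approx(5.0)

    def test_too_few_taxa(self):
        dm = pd.DataFrame([[0, 1], [1, 0]], index=list("AB"),
                          columns=list("AB"), dtype=float)
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    @staticmethod
    def random_additive_matrix(rng, n):
        """Pairwise leaf distances of a random binary tree with positive
        branch lengths (hence an additive matrix)."""
        names = [f"t{i}" for i in range(n)]
        clusters = [{nm: 0.0} for nm in names]   # leaf -> dist to cluster root
        D = pd.DataFrame(0.0, index=names, columns=names)
        while len(clusters) > 1:
            i, j = rng.choice(len(clusters), size=2, replace=False)
            a, b = clusters[int(i)], clusters[int(j)]
            la, lb = rng.uniform(0.1, 2.0, size=2)
            for x, dx in a.items():
                for y, dy in b.items():
                    D.loc[x, y] = D.loc[y, x] = dx + la + dy + lb
            merged = {x: d + la for x, d in a.items()}
            merged.update({y: d + lb for y, d in b.items()})
            clusters = [c for k, c in enumerate(clusters)
                        if k not in (int(i), int(j))] + [merged]
        return D

    @given(st.integers(0, 1_000_000))
    @settings(max_examples=20, deadline=None,
              suppress_health_check=list(HealthCheck))
    def test_recovers_random_additive_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 11))
        dm = self.random_additive_matrix(rng, n)
        tree = neighbor_joining(dm)
        d = tree_distances(tree)
        for a in dm.index:
            for b in dm.index:
                if a < b:
                    assert d(a, b) == pytest.approx(dm.loc[a, b], abs=1e-8)

    def test_topology_agrees_with_scikit_bio(self, rng):
        import io
        import dendropy
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj
        dm = self.random_additive_matrix(rng, 8)
        mine = neighbor_joining(dm)
        sk_tree = sk_nj(SkDM(dm.to_numpy(), ids=list(dm.index)))
        theirs = dendropy.Tree.get(data=str(sk_tree.write(io.StringIO(),
                                                          format="newick")
                                            .getvalue()),
                                   schema="newick",
                                   preserve_underscores=True)
        assert _bipartitions(mine) == _bipartitions(theirs)

    def test_ultrametric_matrix_matches_upgma_topology(self):
        # perfectly clock-like distances: ((A,B),(C,D)) with heights 1, 3
        dm = pd.DataFrame([[0, 2, 6, 6], [2, 0, 6, 6],
                           [6, 6, 0, 2], [6, 6, 2, 0]],
                          index=list("ABCD"), columns=list("ABCD"),
                          dtype=float)
        tree = neighbor_joining(dm)
        assert _bipartitions(tree) == {frozenset({"C", "D"})}


class TestBootstrap:
    def make_two_cluster_alignment(self, rng, n_diff=60):
        base = rng.choice(list(AMINO_ACIDS), size=150)
        other = base.copy()
        idx = rng.choice(150, size=n_diff, replace=False)
        for i in idx:
            other[i] = rng.choice([a for a in AMINO_ACIDS if a != other[i]])
        def jitter(seq, k):
            s = seq.copy()
            for i in rng.choice(150, size=k, replace=False):
                s[i] = rng.choice(list(AMINO_ACIDS))
            return "".join(s)
        seqs = [jitter(base, 3), jitter(base, 3), jitter(base, 3),
                jitter(other, 3), jitter(other, 3), jitter(other, 3)]
        return ProteinAlignment([f"s{i}" for i in range(6)], seqs)

    def test_long_internal_edge_gets_high_support(self, rng):
        aln = self.make_two_cluster_alignment(rng)
        tree, support = bootstrap_support(aln, n_reps=60, seed=1)
        main = frozenset({"s3", "s4", "s5"})
        assert main in support
        assert support[main] >= 95.0

    def test_single_replicate_supports_are_binary(self, rng):
        aln = self.make_two_cluster_alignment(rng)
        _, support = bootstrap_support(aln, n_reps=1, seed=2)
        assert set(support.values()) <= {0.0, 100.0}

    def test_same_seed_same_supports(self, rng):
        aln = self.make_two_cluster_alignment(rng)
        _, s1 = bootstrap_support(aln, n_reps=20, seed=3)
        _, s2 = bootstrap_support(aln, n_reps=20, seed=3)
        assert s1 == s2


def test_gene_families_cluster_by_homolog_not_species(rng):
    # three divergent families sampled across three "species"
    families = [rng.choice(list(AMINO_ACIDS), size=120) for _ in range(3)]
    names, seqs = [], []
    for f, fam in enumerate(families):
        for s in range(3):
            seq = fam.copy()
            for i in rng.choice(120, size=4, replace=False):
                seq[i] = rng.choice(list(AMINO_ACIDS))
            names.append(f"fam{f}_sp{s}")
            seqs.append("".join(seq))
    tree = neighbor_joining(ml_distance_matrix(
        ProteinAlignment(names, seqs)))
    bps = _bipartitions(tree)
    for f in (1, 2):   # family 0 contains the anchor taxon
        assert frozenset({f"fam{f}_sp0", f"fam{f}_sp1", f"fam{f}_sp2"}) in bps
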