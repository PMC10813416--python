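import math

import numpy as np
import pytest

from pbminer import phylo
from pbminer.seqcore import ProtSequence
from pbminer.simulate import build_template, evolve_copy


def _additive_matrix_4taxon():
    # tree ((A:2,B:3):4,(C:3,D:4):0) -> unique additive distances
    d = np.array(
        [[0, 5, 9, 10], [5, 0, 10, 11], [9, 10, 0, 7], [10, 11, 7, 0]], float
    )
    return phylo.DistanceMatrix(labels=list("ABCD"), d=d)


def _clade_proteins(rng, n_clades=3, members=3, within_k=0.15, query_k=0.05):
    from Bio.Seq import Seq

    refs, queries = [], []
    for ci in range(n_clades):
        clade = chr(ord("A") + ci)
        t = build_template(rng, f"T{clade}", transposase_len=520)
        for i in range(members):
            cds = evolve_copy(t.cds, within_k, 2.0, rng)
            refs.append(
                (ProtSequence(f"{clade}{i}", str(Seq(cds[:-3]).translate()).replace("*", "X")), clade)
            )
        qcds = evolve_copy(t.cds, query_k, 2.0, rng)
        queries.append(
            ProtSequence(f"q{clade}", str(Seq(qcds[:-3]).translate()).replace("*", "X"))
        )
    out = [ProtSequence("outgroup1", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=520)))]
    return refs, queries, out


class TestProteinDistance:
    def test_identical_rows_zero(self):
        dm = phylo.protein_distance(["MKVL", "MKVL"], ["a", "b"])
        assert dm.d[0, 1] == 0.0

    def test_poisson_correction_closed_form(self):
        rows = ["A" * 90 + "C" * 10, "A" * 100]
        dm = phylo.protein_distance(rows, ["a", "b"])
        assert dm.d[0, 1] == pytest.approx(-math.log(0.9), abs=1e-12)

    def test_gap_columns_excluded(self):
        rows = ["AAAA----", "----CCCC"]
        with pytest.raises(ValueError, match="share no ungapped columns"):
            phylo.protein_distance(rows, ["a", "b"])

    def test_saturation_capped_and_flagged(self):
        rows = ["A" * 100, "C" * 100]
        dm = phylo.protein_distance(rows, ["a", "b"])
        assert dm.d[0, 1] == phylo.SATURATION_CAP
        assert dm.saturated[0, 1]


class TestNeighborJoining:
    def test_additive_four_taxon_recovered_exactly(self):
        tree = phylo.nj_tree(_additive_matrix_4taxon())
        dm = _additive_matrix_4taxon()
        for i, a in enumerate(dm.labels):
            for j, b in enumerate(dm.labels):
                if i < j:
                    assert tree.distance(a, b) == pytest.approx(dm.d[i, j], abs=1e-9)
        assert tree.bipartitions() == {frozenset({"C", "D"})}

    def test_additive_five_taxon_recovered_exactly(self):
        # caterpillar tree with known branch lengths
        paths = {}
        bl = {"A": 1.0, "B": 2.0, "C": 1.5, "D": 2.5, "E": 3.0}
        # topology: ((A,B),C,(D,E)) with internal edges 1.2 and 0.8
        def pd(x, y):
            side = {"A": 0, "B": 0, "C": 1, "D": 2, "E": 2}
            extra = {(0, 1): 1.2, (0, 2): 2.0, (1, 2): 0.8}
            sx, sy = sorted((side[x], side[y]))
            e = 0.0 if sx == sy else extra[(sx, sy)]
            return bl[x] + bl[y] + e

        labels = list("ABCDE")
        d = np.zeros((5, 5))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    d[i, j] = pd(a, b)
        tree = phylo.nj_tree(phylo.DistanceMatrix(labels=labels, d=d))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert tree.distance(a, b) == pytest.approx(d[i, j], abs=1e-9)

    def test_identical_taxa_zero_cherry(self):
        d = np.array([[0, 0, 4], [0, 0, 4], [4, 4, 0]], float)
        tree = phylo.nj_tree(phylo.DistanceMatrix(labels=list("ABC"), d=d))
        assert tree.distance("A", "B") == pytest.approx(0.0, abs=1e-12)

    def test_leaf_set_preserved(self, rng):
        n = 7
        x = rng.random((n, n))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        tree = phylo.nj_tree(phylo.DistanceMatrix(labels=[f"t{i}" for i in range(n)], d=d))
        assert tree.labels == sorted(f"t{i}" for i in range(n))

    def test_matches_scikit_bio_topology(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        n = 6
        x = rng.random((n, n)) + 0.5
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        labels = [f"t{i}" for i in range(n)]
        ours = phylo.nj_tree(phylo.DistanceMatrix(labels=labels, d=d))
        theirs = sk_nj(SkDM(d, ids=labels))
        their_splits = set()
        for node in theirs.non_tips():
            tips = frozenset(t.name for t in node.tips())
            if 2 <= len(tips) <= n - 2:
                ref = min(labels)
                their_splits.add(
                    tips if ref not in tips else frozenset(labels) - tips
                )
        assert ours.bipartitions() == their_splits

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            phylo.nj_tree(phylo.DistanceMatrix(labels=["a", "b"], d=np.zeros((2, 2))))


class TestBootstrap:
    def test_congruent_alignment_full_support(self):
        # duplicated diagnostic columns: every split perfectly supported
        rows = ["AAAAAAAAAACCCCCCCCCC", "AAAAAAAAAACCCCCCCCCC",
                "CCCCCCCCCCAAAAAAAAAA", "CCCCCCCCCCAAAAAAAAAA",
                "GGGGGGGGGGGGGGGGGGGG"]
        labels = ["a1", "a2", "b1", "b2", "out"]
        tree = phylo.bootstrap_support(rows, labels, n_replicates=50, seed=0)
        assert tree.supports
        assert all(v == 100.0 for v in tree.supports.values())

    def test_same_seed_reproducible(self, rng):
        rows = ["".join(rng.choice(list("ACDEFG"), size=60)) for _ in range(5)]
        labels = [f"t{i}" for i in range(5)]
        t1 = phylo.bootstrap_support(rows, labels, n_replicates=40, seed=7)
        t2 = phylo.bootstrap_support(rows, labels, n_replicates=40, seed=7)
        assert t1.supports == t2.supports
        assert t1.newick() == t2.newick()

    def test_short_alignment_rejected(self):
        with pytest.raises(ValueError):
            phylo.bootstrap_support(["AAA", "AAC", "ACC"], ["a", "b", "c"])


class TestAssignClades:
    def test_simulated_queries_assigned_to_their_clade(self, rng):
        refs, queries, out = _clade_proteins(rng)
        res = phylo.assign_clades(queries, refs, out, n_replicates=100, seed=1)
        for a in res:
            assert a.clade == a.query[1]  # query ids are q<clade>
            assert a.support > 80

    def test_query_identical_to_reference(self, rng):
        refs, _, out = _clade_proteins(rng, n_clades=2)
        q = ProtSequence("qcopy", refs[0][0].residues)
        res = phylo.assign_clades([q], refs, out, n_replicates=100, seed=2)
        assert res[0].clade == refs[0][1]

    def test_never_assigns_below_support_threshold(self, rng):
        refs, queries, out = _clade_proteins(rng)
        res = phylo.assign_clades(
            queries, refs, out, n_replicates=100, seed=1, support_threshold=100.0
        )
        for a in res:
            assert a.clade == "unassigned"

    def test_outgroup_required(self, rng):
        refs, queries, _ = _clade_proteins(rng, n_clades=2)
        with pytest.raises(ValueError):
            phylo.assign_clades(queries, refs, [])

    def test_supports_invariant_under_taxon_reordering(self, rng):
        rows = ["".join(rng.choice(list("ACDEFG"), size=80)) for _ in range(6)]
        labels = [f"t{i}" for i in range(6)]
        t1 = phylo.nj_tree(phylo.protein_distance(rows, labels))
        order = [3, 1, 5, 0, 4, 2]
        t2 = phylo.nj_tree(
            phylo.protein_distance([rows[i] for i in order], [labels[i] for i in order])
        )
        assert t1.bipartitions() == t2.bipartitions()
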