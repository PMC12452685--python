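"""UPGMA construction, Newick round-trips, tree cutting and composition."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from goxprofile.distances import DistanceMatrix
from goxprofile.phylogeny import (
    cluster_composition,
    cophenetic_matrix,
    cut_clusters,
    is_ultrametric,
    node_heights,
    parse_newick,
    select_representatives,
    supergroup_clusters,
    to_newick,
    upgma,
)
from goxprofile.synthetic import planted_cluster_matrix


def random_ultrametric(rng, n):
    """Random ultrametric matrix built from random sequential merges."""
    clusters = [[i] for i in range(n)]
    height = 0.0
    d = np.zeros((n, n))
    while len(clusters) > 1:
        height += float(rng.uniform(0.1, 1.0))
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                d[a, b] = d[b, a] = 2 * height
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return d


class TestUpgma:
    def test_two_leaves(self):
        dm = DistanceMatrix(labels=["A", "B"], d=np.array([[0.0, 2.0], [2.0, 0.0]]))
        tree = upgma(dm)
        assert to_newick(tree) == "(A:1.0,B:1.0);"

    def test_three_leaf_hand_oracle(self):
        """d(A,B)=2, d(A,C)=4, d(B,C)=4: (A,B) merge at height 1, C joins at 2."""
        dm = DistanceMatrix(
            labels=["A", "B", "C"],
            d=np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float),
        )
        tree = upgma(dm)
        heights = node_heights(tree)
        assert heights[id(tree)] == pytest.approx(2.0)
        np.testing.assert_allclose(
            cophenetic_matrix(tree, ["A", "B", "C"]), dm.d, atol=1e-12
        )

    def test_ultrametric_inputs_reconstructed_exactly(self):
        rng = np.random.default_rng(51)
        for n in (3, 4, 5, 6, 7, 8):
            for _ in range(5):
                d = random_ultrametric(rng, n)
                labels = [f"L{i}" for i in range(n)]
                tree = upgma(DistanceMatrix(labels=labels, d=d))
                assert is_ultrametric(tree, tol=1e-9)
                np.testing.assert_allclose(
                    cophenetic_matrix(tree, labels), d, atol=1e-9
                )

    def test_agrees_with_scipy_average_linkage(self):
        """Cophenetic distances match scipy's UPGMA on tie-free matrices."""
        rng = np.random.default_rng(52)
        for n in (4, 6, 8):
            cond = rng.permutation(np.linspace(1.0, 5.0, n * (n - 1) // 2))
            d = squareform(cond)
            labels = [f"L{i}" for i in range(n)]
            tree = upgma(DistanceMatrix(labels=labels, d=d))
            ours = cophenetic_matrix(tree, labels)
            theirs = squareform(cophenet(average(cond)))
            np.testing.assert_allclose(ours, theirs, atol=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(labels=["A", "B"], d=np.array([[0.0, -1.0], [-1.0, 0.0]]))
        with pytest.raises(ValueError):
            upgma(DistanceMatrix(labels=["A"], d=np.zeros((1, 1))))


class TestNewick:
    def test_round_trip_random_trees(self):
        rng = np.random.default_rng(53)
        for _ in range(100):
            n = int(rng.integers(2, 9))
            d = random_ultrametric(rng, n)
            labels = [f"L{i}" for i in range(n)]
            tree = upgma(DistanceMatrix(labels=labels, d=d))
            back = parse_newick(to_newick(tree))
            assert {t.name for t in back.tips()} == set(labels)
            np.testing.assert_allclose(
                cophenetic_matrix(back, labels),
                cophenetic_matrix(tree, labels),
                atol=1e-9,
            )

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(ValueError, match="Newick"):
            parse_newick("((A:1.0,B:1.0;")


@pytest.fixture(scope="module")
def planted():
    dm, truth = planted_cluster_matrix()
    return upgma(dm), dm, truth


class TestCutClusters:
    def test_k1_and_kn(self, planted):
        tree, dm, _ = planted
        assert set(cut_clusters(tree, 1).assignment.values()) == {1}
        assert len(set(cut_clusters(tree, len(dm)).assignment.values())) == len(dm)

    def test_out_of_range_k(self, planted):
        tree, dm, _ = planted
        with pytest.raises(ValueError):
            cut_clusters(tree, 0)
        with pytest.raises(ValueError):
            cut_clusters(tree, len(dm) + 1)

    def test_planted_clades_recovered(self, planted):
        tree, _, truth = planted
        assignment = cut_clusters(tree, 10)
        got = {}
        for leaf, cid in assignment.assignment.items():
            got.setdefault(cid, set()).add(leaf)
        want = {}
        for row in truth.itertuples():
            want.setdefault(row.clade, set()).add(row.leaf)
        assert sorted(got.values(), key=min) == sorted(want.values(), key=min)

    def test_clusters_are_monophyletic(self, planted):
        tree, _, _ = planted
        assignment = cut_clusters(tree, 7)
        heights = node_heights(tree)
        for cid in range(1, 8):
            members = set(assignment.members(cid))
            lca = tree.lca([t for t in tree.tips() if t.name in members])
            lca_leaves = {t.name for t in lca.tips()} or {lca.name}
            assert lca_leaves == members


class TestSupergroups:
    def test_planted_groups_recovered(self):
        dm, truth = planted_cluster_matrix()
        tree = upgma(dm)
        assignment = cut_clusters(tree, 10)
        groups = supergroup_clusters(tree, assignment, 4)
        got = {}
        for leaf, cid in assignment.assignment.items():
            got.setdefault(groups[cid], set()).add(leaf)
        want = {}
        for row in truth.itertuples():
            want.setdefault(row.group, set()).add(row.leaf)
        assert sorted(got.values(), key=min) == sorted(want.values(), key=min)

    def test_groups_equal_clusters_when_counts_match(self):
        dm, _ = planted_cluster_matrix(n_clades=4, groups={1: "A", 2: "B", 3: "C", 4: "D"})
        tree = upgma(dm)
        assignment = cut_clusters(tree, 4)
        groups = supergroup_clusters(tree, assignment, 4)
        assert len(set(groups.values())) == 4

    def test_two_groups_partition_adjacent_clusters(self):
        dm, _ = planted_cluster_matrix()
        tree = upgma(dm)
        assignment = cut_clusters(tree, 10)
        groups = supergroup_clusters(tree, assignment, 2)
        assert len(set(groups.values())) == 2

    def test_too_many_groups_rejected(self):
        dm, _ = planted_cluster_matrix()
        tree = upgma(dm)
        assignment = cut_clusters(tree, 4)
        with pytest.raises(ValueError):
            supergroup_clusters(tree, assignment, 5)


class TestComposition:
    def _records_with(self, make_record, assignment, subtype_by_cluster):
        recs = []
        for leaf, cid in assignment.assignment.items():
            recs.append(
                make_record(
                    leaf,
                    "MKV",
                    ontology_grouped=subtype_by_cluster.get(cid, "other"),
                    taxonomy={"class": "a-proteobacteria"},
                )
            )
        return recs

    def test_single_class_composition(self, make_record):
        dm, _ = planted_cluster_matrix(n_clades=2, groups={1: "A", 2: "B"})
        tree = upgma(dm)
        assignment = cut_clusters(tree, 1)
        recs = self._records_with(make_record, assignment, {})
        comp = cluster_composition(assignment, recs)
        assert comp["class_counts"].loc[1, "a-proteobacteria"] == len(recs)

    def test_median_of_planted_fraction_vector(self, make_record):
        """Per-cluster focus-subtype fractions median exactly as planted."""
        from goxprofile.phylogeny import ClusterAssignment

        planted_frac = [0.0, 0.0, 0.22, 0.03, 0.04, 0.04, 0.05, 0.05, 0.01, 0.04]
        leaves_per_cluster = 100
        mapping = {
            f"C{cid:02d}_{i}": cid
            for cid in range(1, 11)
            for i in range(leaves_per_cluster)
        }
        assignment = ClusterAssignment(assignment=mapping, k=10, cut_height=1.0)
        recs = []
        for cid in range(1, 11):
            members = assignment.members(cid)
            n_focus = round(planted_frac[cid - 1] * len(members))
            for i, leaf in enumerate(sorted(members)):
                subtype = "(D-) amino acid dehydrogenase" if i < n_focus else "other"
                recs.append(
                    SequenceRecordFactory(leaf, subtype)
                )
        comp = cluster_composition(
            assignment, recs, subtype="(D-) amino acid dehydrogenase"
        )
        assert comp["subtype_median"] == pytest.approx(float(np.median(planted_frac)))
        # rows conserve cluster sizes
        assert (
            comp["class_counts"].sum(axis=1).tolist()
            == [len(assignment.members(c)) for c in range(1, 11)]
        )

    def test_missing_record_rejected(self, make_record):
        dm, _ = planted_cluster_matrix(n_clades=2, groups={1: "A", 2: "B"})
        tree = upgma(dm)
        assignment = cut_clusters(tree, 2)
        with pytest.raises(ValueError, match="no record"):
            cluster_composition(assignment, [])


def SequenceRecordFactory(acc, subtype):
    from goxprofile.seqio import SequenceRecord

    return SequenceRecord(
        accession=acc, description=acc, residues="MKV", ontology_grouped=subtype
    )


@pytest.fixture(scope="module")
def dataset():
    from goxprofile.seqio import SequenceRecord

    dm, truth = planted_cluster_matrix(leaves_per_clade=6)
    tree = upgma(dm)
    assignment = cut_clusters(tree, 10)
    subtypes = [f"subtype{i}" for i in range(11)]
    recs = [
        SequenceRecord(
            accession=leaf, description=leaf, residues="MKV",
            ontology_grouped=subtypes[i % 11],
        )
        for i, leaf in enumerate(sorted(assignment.assignment))
    ]
    return recs, assignment


class TestSelectRepresentatives:
    def test_every_cluster_and_subtype_covered(self, dataset):
        recs, assignment = dataset
        subset = select_representatives(recs, assignment, n=40, seed=1,
                                        reference=recs[0].accession)
        accs = {r.accession for r in subset}
        assert recs[0].accession in accs
        assert {assignment.assignment[a] for a in accs} == set(range(1, 11))
        assert {r.ontology_grouped for r in subset} == {f"subtype{i}" for i in range(11)}

    def test_same_seed_same_subset(self, dataset):
        recs, assignment = dataset
        s1 = select_representatives(recs, assignment, n=30, seed=7)
        s2 = select_representatives(recs, assignment, n=30, seed=7)
        assert [r.accession for r in s1] == [r.accession for r in s2]

    def test_infeasible_n_rejected(self, dataset):
        recs, assignment = dataset
        with pytest.raises(ValueError):
            select_representatives(recs, assignment, n=5)
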