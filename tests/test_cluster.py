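import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import (
    adjusted_rand_score,
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

import naive_oracles as nv
from prsubtype.cluster import (
    ClusterError,
    assign_classes,
    cross_cohort_consistency,
    cut_tree,
    distance_matrix,
    hierarchical_cluster,
    majority_choice,
    refine_split,
    to_newick,
    validity_vote,
)
from prsubtype.indices import ValidityPanel
from prsubtype.prs import PRSMatrix
from prsubtype.simulate import simulate_prs_blobs


def _prs(X, standardized=True):
    X = np.asarray(X, float)
    return PRSMatrix(
        "c",
        pd.DataFrame(X, index=[f"s{i}" for i in range(len(X))],
                     columns=[f"t{j}" for j in range(X.shape[1])]),
        standardized=standardized,
    )


class TestDistanceMatrix:
    def test_three_four_five(self):
        d = distance_matrix(_prs([[0, 0], [3, 4], [0, 1]]))
        assert np.isclose(d[0, 1], 5.0)
        assert np.allclose(np.diag(d), 0.0)

    def test_identical_rows_zero_distance(self):
        d = distance_matrix(_prs([[1, 2], [1, 2], [0, 0]]))
        assert d[0, 1] == 0.0

    def test_matches_naive_double_loop(self, rng):
        X = rng.normal(size=(10, 4))
        d = distance_matrix(_prs(X))
        for i in range(10):
            for j in range(10):
                assert np.isclose(d[i, j], np.linalg.norm(X[i] - X[j]), atol=1e-12)

    def test_requires_standardized_and_no_missing(self):
        with pytest.raises(ClusterError, match="standardized"):
            distance_matrix(_prs([[0, 0], [1, 1], [2, 2]], standardized=False))


class TestHierarchy:
    def test_two_separated_pairs_merge_first(self):
        X = np.array([[0.0, 0], [0.1, 0], [10, 0], [10.1, 0]])
        tree = hierarchical_cluster(_prs(X))
        first_two = {frozenset(map(int, m[:2])) for m in tree.Z[:2]}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_n_two_single_merge_at_distance(self):
        X = np.array([[0.0, 0], [3.0, 4.0]])
        tree = hierarchical_cluster(_prs(X))
        assert tree.Z.shape[0] == 1
        assert np.isclose(tree.Z[0, 2], 5.0)

    def test_label_permutation_invariance(self, rng):
        X = rng.normal(size=(25, 3))
        perm = rng.permutation(25)
        t1 = hierarchical_cluster(_prs(X))
        t2 = hierarchical_cluster(_prs(X[perm]))
        for k in (2, 3, 5):
            l1 = cut_tree(t1, k)
            l2 = cut_tree(t2, k)
            assert adjusted_rand_score(l1[perm], l2) == 1.0

    def test_cut_tree_extremes_and_errors(self, rng):
        tree = hierarchical_cluster(_prs(rng.normal(size=(6, 2))))
        assert len(set(cut_tree(tree, 6))) == 6
        assert len(set(cut_tree(tree, 1))) == 1
        with pytest.raises(ClusterError):
            cut_tree(tree, 0)
        with pytest.raises(ClusterError):
            cut_tree(tree, 7)

    def test_two_blob_recovery(self):
        prs, truth = simulate_prs_blobs(80, 4, 2, separation=10.0, seed=3)
        tree = hierarchical_cluster(prs)
        assert adjusted_rand_score(truth, cut_tree(tree, 2)) == 1.0

    def test_partitions_are_nested(self, rng):
        tree = hierarchical_cluster(_prs(rng.normal(size=(30, 3))))
        for k in range(2, 10):
            coarse = cut_tree(tree, k - 1)
            fine = cut_tree(tree, k)
            # each fine cluster maps into exactly one coarse cluster
            for c in set(fine):
                assert len(set(coarse[fine == c])) == 1


@pytest.fixture(scope="module")
def instance():
    rng = np.random.default_rng(55)
    X = rng.normal(size=(30, 3)) + rng.integers(0, 3, size=30)[:, None] * 2.0
    tree = hierarchical_cluster(_prs(X))
    labels_by_k = {k: cut_tree(tree, k) for k in range(1, 7)}
    return X, labels_by_k


class TestIndexOracles:
    """Every panel index must match its from-definition reimplementation."""

    @pytest.mark.parametrize("k", [2, 3, 4])
    @pytest.mark.parametrize(
        "name",
        ["calinski_harabasz", "silhouette", "c_index", "dunn", "davies_bouldin",
         "mcclain_rao", "point_biserial", "ratkowsky_lance", "ball",
         "trace_w", "trcov_w", "rubin"],
    )
    def test_single_partition_indices(self, instance, name, k):
        X, labels_by_k = instance
        panel = ValidityPanel(X, labels_by_k)
        got = getattr(panel, name)(k)
        want = getattr(nv, name)(X, labels_by_k[k])
        assert np.isclose(got, want, atol=1e-8, rtol=1e-8)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_hierarchy_level_indices(self, instance, k):
        X, labels_by_k = instance
        panel = ValidityPanel(X, labels_by_k)
        assert np.isclose(panel.hartigan(k),
                          nv.hartigan(X, labels_by_k[k], labels_by_k[k + 1]),
                          atol=1e-8, rtol=1e-8)
        assert np.isclose(panel.duda_hart(k),
                          nv.duda_hart(X, labels_by_k[k], labels_by_k[k + 1]),
                          atol=1e-8, rtol=1e-8)
        assert np.isclose(panel.pseudo_t2(k),
                          nv.pseudo_t2(X, labels_by_k[k], labels_by_k[k + 1]),
                          atol=1e-8, rtol=1e-8)
        assert np.isclose(
            panel.krzanowski_lai(k),
            nv.krzanowski_lai(X, labels_by_k[k - 1], labels_by_k[k], labels_by_k[k + 1]),
            atol=1e-8, rtol=1e-8,
        )

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_sklearn_cross_checks(self, instance, k):
        X, labels_by_k = instance
        panel = ValidityPanel(X, labels_by_k)
        lab = labels_by_k[k]
        assert np.isclose(panel.calinski_harabasz(k),
                          calinski_harabasz_score(X, lab), rtol=1e-10)
        assert np.isclose(panel.silhouette(k), silhouette_score(X, lab), rtol=1e-10)
        assert np.isclose(panel.davies_bouldin(k),
                          davies_bouldin_score(X, lab), rtol=1e-10)


class TestVoting:
    def test_majority_choice_tie_breaks_to_smallest_k(self):
        assert majority_choice({3: 6, 4: 6, 2: 1}) == (3, 6)
        assert majority_choice({4: 11, 3: 5, 2: 4}) == (4, 11)

    def test_clear_blobs_win_the_vote(self):
        prs, truth = simulate_prs_blobs(200, 8, 3, separation=8.0, seed=11)
        tree = hierarchical_cluster(prs)
        vote = validity_vote(prs, tree, k_range=(2, 8))
        assert vote.chosen_k == 3
        assert vote.endorsements >= 9  # most of the 16-index panel
        assert vote.endorsements == vote.tally[vote.chosen_k]

    def test_deterministic_and_k_range_validated(self):
        prs, _ = simulate_prs_blobs(60, 4, 2, separation=6.0, seed=5)
        tree = hierarchical_cluster(prs)
        v1 = validity_vote(prs, tree, (2, 6))
        v2 = validity_vote(prs, tree, (2, 6))
        assert v1.best_k == v2.best_k and v1.tally == v2.tally
        with pytest.raises(ClusterError, match="k_range"):
            validity_vote(prs, tree, (1, 6))


class TestAssignmentAndRefinement:
    def test_classes_ordered_by_decreasing_size(self):
        prs, truth = simulate_prs_blobs(120, 6, 3, separation=9.0, seed=21)
        tree = hierarchical_cluster(prs)
        assign = assign_classes(tree, 3)
        names = assign.class_names
        sizes = [assign.size_of(c) for c in names]
        assert names[0] == "I" == assign.reference_class
        assert sizes == sorted(sizes, reverse=True)

    def test_refine_preserves_other_classes_and_splits_target(self):
        prs, truth = simulate_prs_blobs(150, 8, 4, separation=9.0, seed=31)
        tree = hierarchical_cluster(prs)
        assign = assign_classes(tree, 4)
        target = assign.class_names[0]
        refined = refine_split(tree, assign, target, 2)
        assert refined.labels.nunique() == 5
        old_members = set(assign.labels.index[assign.labels == target])
        # the union of members of the two new classes equals the old class
        untouched = {
            c: set(assign.labels.index[assign.labels == c])
            for c in assign.class_names if c != target
        }
        new_sets = {
            c: set(refined.labels.index[refined.labels == c])
            for c in refined.class_names
        }
        matched = [c for c, s in new_sets.items() if s in untouched.values()]
        split_parts = [s for c, s in new_sets.items() if c not in matched]
        assert len(matched) == 3 and len(split_parts) == 2
        assert split_parts[0] | split_parts[1] == old_members

    def test_refine_to_singletons(self):
        prs, _ = simulate_prs_blobs(12, 4, 2, separation=9.0, seed=41)
        tree = hierarchical_cluster(prs)
        assign = assign_classes(tree, 2)
        smallest = assign.class_names[-1]
        size = assign.size_of(smallest)
        refined = refine_split(tree, assign, smallest, size)
        assert refined.labels.nunique() == 2 - 1 + size

    def test_merged_blobs_recovered_by_subsplit(self):
        # 5 planted blobs cut at k=4 (two merged), then split the merged class
        prs, truth = simulate_prs_blobs(300, 10, 5, separation=10.0, seed=51)
        tree = hierarchical_cluster(prs)
        assign4 = assign_classes(tree, 4)
        # find the class containing two true blobs
        lab = assign4.labels.to_numpy()
        merged = None
        for c in assign4.class_names:
            if len(set(truth[lab == c])) == 2:
                merged = c
                break
        assert merged is not None
        refined = refine_split(tree, assign4, merged, 2)
        codes = pd.factorize(refined.labels)[0]
        assert adjusted_rand_score(truth, codes) == 1.0

    def test_refine_errors(self):
        prs, _ = simulate_prs_blobs(20, 4, 2, separation=9.0, seed=61)
        tree = hierarchical_cluster(prs)
        assign = assign_classes(tree, 2)
        with pytest.raises(ClusterError):
            refine_split(tree, assign, "XIV", 2)
        with pytest.raises(ClusterError):
            refine_split(tree, assign, "I", 1)


class TestConsistencyAndExport:
    def test_identical_votes_agree_fully(self):
        prs, _ = simulate_prs_blobs(80, 6, 3, separation=8.0, seed=71)
        tree = hierarchical_cluster(prs)
        v = validity_vote(prs, tree, (2, 6))
        rep = cross_cohort_consistency(v, v)
        assert rep.same_chosen_k and rep.per_index_agreement == 1.0

    def test_mismatched_k_ranges_fatal(self):
        prs, _ = simulate_prs_blobs(80, 6, 3, separation=8.0, seed=71)
        tree = hierarchical_cluster(prs)
        va = validity_vote(prs, tree, (2, 6))
        vb = validity_vote(prs, tree, (2, 7))
        with pytest.raises(ClusterError, match="mismatched"):
            cross_cohort_consistency(va, vb)

    def test_structure_disagreement_reported(self):
        pa, _ = simulate_prs_blobs(90, 6, 3, separation=9.0, seed=81)
        pb, _ = simulate_prs_blobs(90, 6, 4, separation=9.0, seed=82)
        va = validity_vote(pa, hierarchical_cluster(pa), (2, 6))
        vb = validity_vote(pb, hierarchical_cluster(pb), (2, 6))
        rep = cross_cohort_consistency(va, vb)
        assert rep.chosen_k == (va.chosen_k, vb.chosen_k)
        assert rep.same_chosen_k == (va.chosen_k == vb.chosen_k)

    def test_newick_parses_and_preserves_leaves(self, rng):
        import io as _io

        from Bio import Phylo

        prs = _prs(rng.normal(size=(12, 3)))
        tree = hierarchical_cluster(prs)
        nwk = to_newick(tree)
        phylo = Phylo.read(_io.StringIO(nwk), "newick")
        leaves = {t.name for t in phylo.get_terminals()}
        assert leaves == set(tree.sample_ids)
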