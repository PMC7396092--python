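"""Hierarchical subtype clustering with majority-rule selection of k.

Patients (cases only) are clustered on the standardized PRS matrix using
Euclidean distances and Ward linkage by default.  The number of clusters
is chosen by majority vote across the validity-index panel (see
:mod:`prsubtype.indices`).  Classes are labeled by decreasing size with
Roman numerals; the largest class (Class I) is the regression reference.
A dendrogram-guided sub-split of one class is supported as an explicit
analyst action.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from .indices import INDEX_NAMES, PANEL_VERSION, PanelResult, ValidityPanel
from .prs import PRSMatrix


class ClusterError(ValueError):
    pass


LINKAGE_METHODS = ("ward", "average", "complete")


def _roman(i: int) -> str:
    numerals = [
        (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
        (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
        (5, "V"), (4, "IV"), (1, "I"),
    ]
    out = []
    for val, sym in numerals:
        while i >= val:
            out.append(sym)
            i -= val
    return "".join(out)


@dataclass
class LinkageTree:
    """Agglomeration result: scipy linkage matrix plus leaf sample IDs."""

    Z: np.ndarray  # (n-1, 4) scipy linkage matrix
    method: str
    sample_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.sample_ids)

    def heights(self) -> np.ndarray:
        return self.Z[:, 2]


@dataclass
class ClusterVote:
    """Per-index best-k votes and the majority-rule choice."""

    k_range: tuple[int, int]
    best_k: dict  # index name -> k or None (abstained)
    tally: dict  # k -> vote count
    chosen_k: int
    endorsements: int
    panel_version: str = PANEL_VERSION
    values: dict = field(default_factory=dict, repr=False)
    abstentions: dict = field(default_factory=dict, repr=False)


@dataclass
class ClassAssignment:
    """Sample -> class label (Roman numerals, decreasing size)."""

    labels: pd.Series  # index sample_id, values "I", "II", ...
    reference_class: str = "I"
    labeling_rule: str = "decreasing_size"

    @property
    def class_names(self) -> list[str]:
        sizes = self.labels.value_counts()
        return sorted(sizes.index, key=lambda s: (-sizes[s], s))

    def size_of(self, name: str) -> int:
        return int((self.labels == name).sum())


def distance_matrix(prs: PRSMatrix) -> np.ndarray:
    """Pairwise Euclidean distances between cases (symmetric, zero diagonal)."""
    if not prs.standardized:
        raise ClusterError("clustering expects a standardized PRS matrix")
    X = prs.values()
    if len(X) < 3:
        raise ClusterError("need at least 3 cases to cluster")
    if np.isnan(X).any():
        raise ClusterError("PRS matrix contains missing scores")
    return squareform(pdist(X))


def hierarchical_cluster(
    d: np.ndarray | PRSMatrix,
    linkage: str = "ward",
    sample_ids: list[str] | None = None,
) -> LinkageTree:
    """Agglomerate with the chosen linkage (Ward on Euclidean by default).

    Accepts either a square distance matrix (with ``sample_ids``) or a
    standardized :class:`PRSMatrix`.  scipy's nearest-neighbor-chain
    agglomeration is deterministic; merge ties resolve by cluster index.
    """
    if linkage not in LINKAGE_METHODS:
        raise ClusterError(f"linkage must be one of {LINKAGE_METHODS}")
    if isinstance(d, PRSMatrix):
        sample_ids = d.sample_ids
        dm = pdist(d.values())
    else:
        d = np.asarray(d, float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ClusterError("expected a square distance matrix")
        if d.shape[0] < 2:
            raise ClusterError("need at least 2 observations")
        if sample_ids is None:
            sample_ids = [f"s{i}" for i in range(d.shape[0])]
        dm = squareform(d, checks=False)
    Z = sch.linkage(dm, method=linkage)
    return LinkageTree(Z=Z, method=linkage, sample_ids=list(sample_ids))


def cut_tree(tree: LinkageTree, k: int) -> np.ndarray:
    """Partition labels (0..k-1) from cutting the merge sequence at k groups."""
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ClusterError(f"k={k} out of range 1..{n}")
    return sch.cut_tree(tree.Z, n_clusters=k).ravel().astype(int)


def assign_classes(tree: LinkageTree, k: int) -> ClassAssignment:
    """Cut at k and label classes by decreasing size (largest = Class I)."""
    raw = cut_tree(tree, k)
    return _relabel(raw, tree.sample_ids)


def _relabel(raw: np.ndarray, sample_ids: list[str]) -> ClassAssignment:
    sizes = np.bincount(raw)
    # decreasing size; ties by first appearance for determinism
    first_seen = np.full(sizes.shape, len(raw))
    for pos, lab in enumerate(raw):
        if pos < first_seen[lab]:
            first_seen[lab] = pos
    order = sorted(range(len(sizes)), key=lambda c: (-sizes[c], first_seen[c]))
    name_of = {c: _roman(rank + 1) for rank, c in enumerate(order)}
    labels = pd.Series(
        [name_of[c] for c in raw], index=pd.Index(sample_ids, name="sample_id")
    )
    return ClassAssignment(labels=labels)


def majority_choice(tally: dict[int, int]) -> tuple[int, int]:
    """Majority rule over best-k votes: most endorsements, ties to smallest k."""
    chosen = min(tally, key=lambda k: (-tally[k], k))
    return chosen, tally[chosen]


def validity_vote(
    prs: PRSMatrix,
    tree: LinkageTree,
    k_range: tuple[int, int] = (2, 10),
) -> ClusterVote:
    """Compute the index panel over the cuts at each k and take the majority.

    Each index contributes one best-k vote by its published optimality
    direction; undefined values make the index abstain at that k (recorded).
    The majority-rule winner is the k with the most votes; ties break to the
    smallest k.
    """
    k_min, k_max = k_range
    n = tree.n_leaves
    if not (2 <= k_min <= k_max <= n - 1):
        raise ClusterError(f"k_range {k_range} must lie within (2, {n - 1})")
    X = prs.values()
    if X.shape[0] != n:
        raise ClusterError("PRS matrix and tree disagree on the number of cases")

    labels_by_k = {
        k: cut_tree(tree, k)
        for k in range(max(1, k_min - 1), min(n, k_max + 2))
    }
    panel = ValidityPanel(X, labels_by_k)
    result: PanelResult = panel.evaluate((k_min, k_max))

    tally: dict[int, int] = {k: 0 for k in range(k_min, k_max + 1)}
    for name in INDEX_NAMES:
        k = result.best_k.get(name)
        if k is not None:
            tally[k] += 1
    chosen_k, _ = majority_choice(tally)
    return ClusterVote(
        k_range=k_range,
        best_k=result.best_k,
        tally=tally,
        chosen_k=chosen_k,
        endorsements=tally[chosen_k],
        values=result.values,
        abstentions=result.abstentions,
    )


def refine_split(
    tree: LinkageTree,
    assignment: ClassAssignment,
    class_to_split: str,
    sub_k: int,
) -> ClassAssignment:
    """Re-cut the subtree spanning one class into ``sub_k`` groups.

    Other classes are untouched; labels are re-assigned by the standard
    decreasing-size rule afterwards.  This is an explicit, logged analyst
    action (e.g. the trial-cohort dendrogram suggesting one cluster is a
    union of finer groups), never an automatic heuristic.
    """
    labels = assignment.labels
    members = labels.index[labels == class_to_split]
    if len(members) == 0:
        raise ClusterError(f"class {class_to_split!r} does not exist")
    if sub_k < 2 or sub_k > len(members):
        raise ClusterError(f"sub_k={sub_k} invalid for class of size {len(members)}")

    pos = {s: i for i, s in enumerate(tree.sample_ids)}
    member_pos = np.array([pos[s] for s in members])
    k0 = labels.nunique()

    # hierarchical nesting: raising the global cut count splits one cluster at
    # a time, so walk k upward until the chosen class has sub_k pieces
    for k in range(k0, tree.n_leaves + 1):
        raw = cut_tree(tree, k)
        n_pieces = len(np.unique(raw[member_pos]))
        if n_pieces == sub_k:
            break
    else:  # pragma: no cover - unreachable for a valid tree cut
        raise AssertionError("subtree not contiguous under the tree")

    # new raw labels: untouched classes keep their identity, split class
    # members take their fine-cut identity
    base = pd.factorize(labels)[0].copy()
    fine = raw[member_pos]
    fine_ids = {f: base.max() + 1 + i for i, f in enumerate(np.unique(fine))}
    base_pos = {s: i for i, s in enumerate(labels.index)}
    for s, f in zip(members, fine):
        base[base_pos[s]] = fine_ids[f]
    # compress ids
    base = pd.factorize(base)[0]
    return _relabel(np.asarray(base), list(labels.index))


@dataclass
class ConsistencyReport:
    same_chosen_k: bool
    chosen_k: tuple[int, int]
    endorsements: tuple[int, int]
    per_index_agreement: float
    tally_a: dict
    tally_b: dict


def cross_cohort_consistency(vote_a: ClusterVote, vote_b: ClusterVote) -> ConsistencyReport:
    """Compare two cohorts' votes: chosen-k agreement and per-index agreement."""
    if vote_a.k_range != vote_b.k_range or vote_a.panel_version != vote_b.panel_version:
        raise ClusterError("votes come from mismatched k ranges or index panels")
    agree = 0
    voted = 0
    for name in INDEX_NAMES:
        ka, kb = vote_a.best_k.get(name), vote_b.best_k.get(name)
        if ka is not None and kb is not None:
            voted += 1
            agree += ka == kb
    return ConsistencyReport(
        same_chosen_k=vote_a.chosen_k == vote_b.chosen_k,
        chosen_k=(vote_a.chosen_k, vote_b.chosen_k),
        endorsements=(vote_a.endorsements, vote_b.endorsements),
        per_index_agreement=agree / voted if voted else np.nan,
        tally_a=dict(vote_a.tally),
        tally_b=dict(vote_b.tally),
    )


def to_newick(tree: LinkageTree) -> str:
    """Export the dendrogram as Newick (branch length = merge-height delta)."""
    n = tree.n_leaves
    Z = tree.Z
    height = {i: 0.0 for i in range(n)}
    for m, (a, b, h, _) in enumerate(Z):
        height[n + m] = float(h)

    def render(node: int) -> str:
        if node < n:
            return tree.sample_ids[node]
        a, b, h, _ = Z[node - n]
        a, b = int(a), int(b)
        la = max(height[node] - height[a], 0.0)
        lb = max(height[node] - height[b], 0.0)
        return f"({render(a)}:{la:.10g},{render(b)}:{lb:.10g})"

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * n + 100))
    try:
        return render(2 * n - 2) + ";"
    finally:
        sys.setrecursionlimit(old)


def vote_table(vote: ClusterVote) -> pd.DataFrame:
    """Long-form per-index table of best-k votes for reporting."""
    rows = [
        {"index": name, "best_k": vote.best_k.get(name)}
        for name in INDEX_NAMES
    ]
    return pd.DataFrame(rows)
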