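"""Neighbor-joining phylogeny over aligned MYB domains and landmark-based
clade assignment.

Distances are p-distances under pairwise deletion of gap columns,
optionally Poisson-corrected (d = -ln(1 - p), capped as p -> 1). The NJ
agglomeration is the classical Q-criterion algorithm with deterministic
tie-breaking (lexicographically smallest taxon-label pair). Bootstrap
support resamples alignment columns with replacement and scores each
internal edge by the fraction of replicates containing the same
bipartition. Clade labels transfer from functionally characterised
landmark proteins: a query inherits clade X when the smallest supported
bipartition separating it together with at least one landmark contains
landmarks of clade X only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix, TreeNode

GAP_CHARS = frozenset("-.")

DEFAULT_P_CAP = 0.95


def _as_pairs(alignment) -> list[tuple[str, str]]:
    if isinstance(alignment, dict):
        return list(alignment.items())
    return [(str(a), str(b)) for a, b in alignment]


def pairwise_distance(
    alignment,
    model: str = "poisson",
    p_cap: float = DEFAULT_P_CAP,
) -> DistanceMatrix:
    """Pairwise distances over an equal-length alignment.

    p-distance = mismatches / compared sites, where columns with a gap in
    either sequence are deleted pairwise; the Poisson correction maps p to
    -ln(1 - p), with p >= p_cap capped at -ln(1 - p_cap) so the correction
    cannot diverge. A pair with zero comparable sites is an error naming
    the pair.
    """
    pairs = _as_pairs(alignment)
    if len(pairs) < 3:
        raise ValueError("need at least 3 taxa")
    ids = [pid for pid, _ in pairs]
    length = len(pairs[0][1])
    if any(len(seq) != length for _, seq in pairs):
        raise ValueError("alignment sequences differ in length")

    seqs = np.array([list(seq.upper()) for _, seq in pairs])
    valid = ~np.isin(seqs, list(GAP_CHARS))
    n = len(ids)
    d = np.zeros((n, n))
    d_max = -math.log(1.0 - p_cap)
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            compared = int(both.sum())
            if compared == 0:
                raise ValueError(f"no comparable sites between {ids[i]} and {ids[j]}")
            p = float((seqs[i][both] != seqs[j][both]).sum()) / compared
            if model == "p-distance":
                dist = p
            elif model == "poisson":
                dist = -math.log(1.0 - p) if p < p_cap else d_max
            else:
                raise ValueError(f"unknown model {model!r}")
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(d, ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classical neighbor joining with deterministic tie-breaking.

    The Q-matrix minimum decides each join; ties are broken by the
    lexicographically smallest (cluster label, cluster label) pair, where
    a cluster is labelled by its smallest member leaf. Negative branch
    lengths are clamped to zero. The result is the unrooted NJ tree,
    represented with a trifurcating root (the final three-cluster join).
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    D = dm.data.astype(float).copy()
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix is not symmetric")

    nodes: list[TreeNode] = [TreeNode(name=name) for name in ids]
    labels: list[str] = list(ids)  # lexicographic cluster labels

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                pair_label = tuple(sorted((labels[active[ai]], labels[active[aj]])))
                key = (q, pair_label)
                if best is None or key < best[0]:
                    best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i, j]
        bi = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        bj = dij - bi
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(0.0, bi)
        child_j.length = max(0.0, bj)
        new = TreeNode(children=[child_i, child_j])
        # distances from the new cluster to the rest
        new_row = np.zeros(D.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (D[i, ak] + D[j, ak] - dij)
        D = np.vstack([D, new_row[:-1][None, :]])
        D = np.hstack([D, new_row[:, None]])
        nodes.append(new)
        labels.append(min(labels[i], labels[j]))
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    # final three clusters join at the (trifurcating) root
    a, b, c = active
    va = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    vb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    vc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, v in zip((a, b, c), (va, vb, vc)):
        nodes[idx].length = max(0.0, v)
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


def tree_bipartitions(tree: TreeNode) -> dict[frozenset, TreeNode]:
    """Non-trivial bipartitions of the (unrooted) tree, canonicalised as
    the smaller leaf-name side (lexicographic tie-break), keyed to the
    internal node under the defining edge."""
    all_leaves = frozenset(l.name for l in tree.tips())
    out = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(l.name for l in node.tips())
        out[canonical_bipartition(side, all_leaves)] = node
    return out


def canonical_bipartition(side: frozenset, all_leaves: frozenset) -> frozenset:
    other = all_leaves - side
    if len(side) != len(other):
        return side if len(side) < len(other) else other
    return min(side, other, key=lambda s: tuple(sorted(s)))


def path_length_matrix(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path lengths of a tree (for additivity checks)."""
    return tree.tip_tip_distances()


def bootstrap_support(
    alignment,
    n_reps: int = 1000,
    seed: int = 0,
    model: str = "poisson",
    p_cap: float = DEFAULT_P_CAP,
) -> TreeNode:
    """NJ tree of the full alignment with per-edge bootstrap supports.

    Alignment columns are resampled with replacement `n_reps` times, NJ is
    rebuilt per replicate, and every internal edge of the original tree is
    scored by the percentage of replicates whose tree contains the same
    bipartition (stored as `node.support`, in [0, 100]). Taxa are
    canonicalised by sorting on label before resampling, so supports do
    not depend on input order; replicate r uses the r-th pre-drawn column
    block of a single seeded generator.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    pairs = sorted(_as_pairs(alignment))
    ids = [pid for pid, _ in pairs]
    cols = np.array([list(seq) for _, seq in pairs]).T  # columns x taxa
    n_cols = cols.shape[0]

    tree = neighbor_joining(pairwise_distance(pairs, model=model, p_cap=p_cap))
    biparts = tree_bipartitions(tree)
    counts = {bp: 0 for bp in biparts}

    rng = np.random.default_rng(seed)
    draws = rng.integers(0, n_cols, size=(n_reps, n_cols))
    all_leaves = frozenset(ids)
    for r in range(n_reps):
        resampled = cols[draws[r]]
        rep_pairs = [(pid, "".join(resampled[:, t])) for t, pid in enumerate(ids)]
        try:
            rep_tree = neighbor_joining(
                pairwise_distance(rep_pairs, model=model, p_cap=p_cap)
            )
        except ValueError:  # a pair with zero comparable resampled sites
            continue
        rep_biparts = set(tree_bipartitions(rep_tree))
        for bp in counts:
            if bp in rep_biparts:
                counts[bp] += 1
    for bp, node in biparts.items():
        node.support = 100.0 * counts[bp] / n_reps
    return tree


@dataclass
class CladeAssignment:
    query_id: str
    clade: str  # C-label or "unassigned"
    subgroup: str | None = None
    landmarks: list[str] = field(default_factory=list)
    support: float | None = None
    #: co-members of a supported all-query group (novel-clade candidate)
    novel_group: list[str] = field(default_factory=list)


def assign_clades(
    tree: TreeNode,
    landmark_map: dict[str, tuple[str, str | None]],
    support_threshold: float = 50.0,
) -> list[CladeAssignment]:
    """Assign every non-landmark leaf to a landmark-defined clade.

    For each query, the candidate groups are the query-containing sides of
    all supported internal edges, smallest first. The first decisive group
    settles the query: a group containing landmarks of one clade only
    assigns that clade (with that edge's support); a landmark-containing
    group mixing clades leaves the query unassigned; a landmark-free group
    of two or more queries marks them as a novel-clade candidate (the
    species-specific-clade pattern) and stays unassigned rather than
    inheriting the nearest landmark clade further up.
    """
    leaves = {l.name for l in tree.tips()}
    missing = set(landmark_map) - leaves
    if missing:
        raise ValueError(f"landmarks missing from tree: {sorted(missing)}")
    all_leaves = frozenset(leaves)
    landmark_ids = set(landmark_map)

    edges = []  # (q-side determined later) store raw sides with support
    for node in tree.non_tips(include_self=False):
        side = frozenset(l.name for l in node.tips())
        support = getattr(node, "support", None)
        edges.append((side, support))

    assignments = []
    for query in sorted(leaves - landmark_ids):
        sides = []
        for side, support in edges:
            q_side = side if query in side else all_leaves - side
            sides.append((len(q_side), q_side, support))
        sides.sort(key=lambda t: (t[0], tuple(sorted(t[1]))))

        assignment = CladeAssignment(query_id=query, clade="unassigned")
        for _, q_side, support in sides:
            if support is not None and support < support_threshold:
                continue
            group_landmarks = sorted(q_side & landmark_ids)
            if group_landmarks:
                clades = {landmark_map[l][0] for l in group_landmarks}
                if len(clades) == 1:
                    subgroups = {landmark_map[l][1] for l in group_landmarks}
                    assignment.clade = clades.pop()
                    assignment.subgroup = (
                        subgroups.pop() if len(subgroups) == 1 else None
                    )
                    assignment.landmarks = group_landmarks
                    assignment.support = support
                break  # smallest landmark-containing group decides
            if len(q_side) >= 2:
                assignment.novel_group = sorted(q_side)
                break  # a supported landmark-free group is its own clade
        assignments.append(assignment)
    return assignments


def write_newick(tree: TreeNode, path) -> None:
    """Newick with branch lengths; bootstrap supports become integer
    internal node labels."""
    for node in tree.non_tips(include_self=False):
        support = getattr(node, "support", None)
        if support is not None:
            node.support = int(round(support))
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    """Read Newick written by :func:`write_newick`; numeric internal
    labels are restored as supports."""
    tree = TreeNode.read(str(path), format="newick")
    tree.assign_supports()
    return tree
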