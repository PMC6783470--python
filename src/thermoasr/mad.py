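"""Minimal ancestor deviation (MAD) rooting.

MAD roots an unrooted tree with branch lengths by asking, for every possible
root position, how badly the molecular-clock expectation is violated: under a
clock, the ancestor of any leaf pair (b, c) should be equidistant from both,
so the relative deviation ``|2·d(ancestor, b)/d(b, c) − 1|`` should vanish.
For a candidate root on a branch, pairs spanning that branch have the root
itself as their ancestor; pairs on one side keep their fixed divergence node.
Each branch admits a closed-form position minimizing the squared deviations
of its spanning pairs; the branch (and position) with the smallest
root-mean-square deviation over all leaf pairs wins.

Deviations are ratios of path lengths, so scores are invariant under uniform
scaling of all branch lengths, and on an ultrametric tree the MAD root is the
midpoint root.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, TreeError
from .io import Node, PhyloTree, _subtree_leaves


def pairwise_leaf_distances(tree: PhyloTree) -> tuple[list[str], np.ndarray]:
    """Leaf labels (in tree preorder) and the matrix of path-length distances."""
    labels, D = _leaf_and_node_distances(tree)[:2]
    return labels, D


def _leaf_and_node_distances(tree: PhyloTree):
    """Returns (leaf labels, leaf×leaf distances, node→leaf distance map).

    The node→leaf map gives, for every node object, a vector of path lengths
    to each leaf (indexed like the label list).
    """
    leaves = tree.leaves()
    labels = [l.label for l in leaves]
    n = len(labels)
    col = {id(l): i for i, l in enumerate(leaves)}

    # distances from the top node by accumulating depths, then propagate to
    # every node using the under/not-under leaf partition of its subtree
    under: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        mask = np.zeros(n, dtype=bool)
        if node.is_leaf:
            mask[col[id(node)]] = True
        else:
            for child in node.children:
                mask |= under[id(child)]
        under[id(node)] = mask

    dist: dict[int, np.ndarray] = {}
    root_d = np.zeros(n)

    def seed_depths(node: Node, acc: float):
        if node.is_leaf:
            root_d[col[id(node)]] = acc
        for child in node.children:
            seed_depths(child, acc + child.length)

    seed_depths(tree.root, 0.0)
    dist[id(tree.root)] = root_d
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_d = dist[id(node.parent)]
        sign = np.where(under[id(node)], -1.0, 1.0)
        dist[id(node)] = parent_d + sign * node.length

    D = np.zeros((n, n))
    for i, leaf in enumerate(leaves):
        D[i] = dist[id(leaf)]
        D[i, i] = 0.0
    D = 0.5 * (D + D.T)  # exact symmetry against float round-off
    return labels, D, dist, under


@dataclass
class RootCandidate:
    """One branch's best root position and its deviation score."""

    branch_id: int
    parent_label: str | None
    child_label: str | None
    length: float
    x: float  # distance of the root from the parent-side endpoint
    score: float
    rank: int = 0


def unrooted_view(tree: PhyloTree) -> PhyloTree:
    """A copy with any degree-2 root collapsed into a multifurcation."""
    work = tree.copy()
    if not work.rooted:
        return work
    a, b = work.root.children
    keep, fold = (a, b) if not a.is_leaf else (b, a)
    if keep.is_leaf:
        raise TreeError("cannot unroot a 2-leaf tree")
    fold.length = fold.length + keep.length
    keep.length = None
    keep.parent = None
    keep.add_child(fold)
    return PhyloTree(keep)


def _branches(tree: PhyloTree) -> list[Node]:
    return [n for n in tree.preorder() if n is not tree.root]


def _score_edge(child: Node, D: np.ndarray, node_dist, under, fixed_x: float | None = None):
    """Optimal root position and RMS deviation score for one branch.

    ``child`` is the branch's child-side endpoint in the traversal
    orientation; x is measured from the parent-side endpoint.
    """
    n = D.shape[0]
    length = child.length
    side_j = under[id(child)]  # leaves below the child endpoint
    side_i = ~side_j
    d_u = node_dist[id(child.parent)]  # parent endpoint to every leaf

    iu = np.where(side_i)[0]
    jv = np.where(side_j)[0]
    Dspan = D[np.ix_(iu, jv)]
    dib = d_u[iu][:, None]

    if fixed_x is not None:
        x = fixed_x
    elif length == 0:
        x = 0.0
    else:
        # minimize sum over spanning pairs of (2(d_ib + x)/D − 1)^2
        x = float(((Dspan - 2 * dib) / Dspan**2).sum() / (2 * (1.0 / Dspan**2).sum()))
        x = min(max(x, 0.0), length)

    dev_span = 2 * (dib + x) / Dspan - 1.0
    sq = float((dev_span**2).sum())

    # same-side pairs: ancestor is the fixed divergence node; deviation
    # reduces to |d(u,b) − d(u,c)| / d(b,c) for b, c on one side
    for side in (iu, jv):
        if len(side) < 2:
            continue
        sub = D[np.ix_(side, side)]
        du = d_u[side]
        dev = (du[:, None] - du[None, :]) / np.where(sub == 0, 1.0, sub)
        iupper = np.triu_indices(len(side), k=1)
        sq += float((dev[iupper] ** 2).sum())

    n_pairs = n * (n - 1) // 2
    return x, float(np.sqrt(sq / n_pairs))


def score_branch(tree: PhyloTree, branch_id: int, fixed_x: float | None = None) -> RootCandidate:
    """Score a single branch of the (unrooted view of the) tree."""
    work = unrooted_view(tree)
    _, D, node_dist, under = _leaf_and_node_distances(work)
    _check_pairs(work, D)
    child = _branches(work)[branch_id]
    x, score = _score_edge(child, D, node_dist, under, fixed_x)
    return RootCandidate(branch_id, child.parent.label, child.label, child.length, x, score)


def _check_pairs(tree: PhyloTree, D: np.ndarray) -> None:
    labels = tree.leaf_labels()
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] == 0:
                raise DegenerateInputError(
                    f"leaves {labels[i]!r} and {labels[j]!r} are at distance 0; "
                    "MAD deviations are undefined for coincident leaves"
                )


def _reroot_at(tree: PhyloTree, child: Node, x: float) -> PhyloTree:
    """Root the tree on the branch above ``child``, ``x`` below the parent."""
    length = child.length
    u = child.parent
    u.children.remove(child)
    new_root = Node()
    new_root.add_child(child)
    child.length = length - x

    node, parent_of, hang_len = u, new_root, x
    while node is not None:
        grand = node.parent
        edge_up = node.length
        if grand is not None:
            grand.children.remove(node)
        parent_of.add_child(node)
        node.length = hang_len
        parent_of, hang_len, node = node, edge_up, grand

    # a former top node left with a single child is a spurious degree-2 node
    for node in list(new_root.children):
        _suppress_unary(node)
    return PhyloTree(new_root)


def _suppress_unary(node: Node) -> None:
    while True:
        target = None
        for desc in [node] + list(node.children):
            if not desc.is_leaf and len(desc.children) == 1 and desc.parent is not None:
                target = desc
                break
        if target is None:
            return
        (only,) = target.children
        only.length += target.length
        parent = target.parent
        idx = parent.children.index(target)
        parent.children[idx] = only
        only.parent = parent


def mad_root(tree: PhyloTree) -> tuple[PhyloTree, list[RootCandidate], float]:
    """Root by minimal ancestor deviation.

    Returns the rooted tree, all branch candidates ranked by score, and the
    ambiguity index (best score / second-best score, in (0, 1]; values near
    1 mean the root placement is ambiguous).
    """
    work = unrooted_view(tree)
    if len(work.leaves()) < 3:
        raise TreeError("MAD rooting needs at least 3 leaves")
    if work.total_length() <= 0:
        raise DegenerateInputError("tree has zero total length")
    _, D, node_dist, under = _leaf_and_node_distances(work)
    _check_pairs(work, D)

    candidates: list[RootCandidate] = []
    for bid, child in enumerate(_branches(work)):
        x, score = _score_edge(child, D, node_dist, under)
        candidates.append(
            RootCandidate(bid, child.parent.label, child.label, child.length, x, score)
        )
    candidates.sort(key=lambda c: (c.score, c.branch_id))
    for rank, cand in enumerate(candidates, start=1):
        cand.rank = rank

    best = candidates[0]
    if len(candidates) > 1 and candidates[1].score > 0:
        ambiguity = best.score / candidates[1].score
    else:
        ambiguity = 1.0

    rooted = _reroot_at(work, _branches(work)[best.branch_id], best.x)
    return rooted, candidates, ambiguity


def export_candidates_tsv(candidates: list[RootCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tbranch_id\tparent\tchild\tlength\tx\tscore\n")
        for c in candidates:
            fh.write(
                f"{c.rank}\t{c.branch_id}\t{c.parent_label or ''}\t{c.child_label or ''}\t"
                f"{c.length:.10g}\t{c.x:.10g}\t{c.score:.10g}\n"
            )
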