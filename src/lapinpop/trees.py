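"""Distance-based phylogenetics: neighbour joining, weighted least squares,
locus bootstrap and majority-rule consensus.

Trees are unrooted with non-negative branch lengths, serialised as
Newick with bootstrap supports stored as internal-node labels.  The
least-squares search minimises the Fitch–Margoliash criterion
``sum_ij w_ij (d_ij - t_ij)^2`` with ``w_ij = 1/d_ij^2``, starting from
the neighbour-joining topology and hill-climbing over nearest-neighbour
interchanges; branch lengths are fitted by non-negative least squares at
every step.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .distances import DistanceMatrix
from .genotypes import GenotypeDataset, allele_frequencies
from .distances import allele_sharing_distance_matrix, chord_distance_matrix

__all__ = [
    "Tree",
    "neighbor_joining",
    "least_squares_tree",
    "ls_branch_lengths",
    "bootstrap_consensus",
]


@dataclass
class Tree:
    """Unrooted tree: adjacency with branch lengths, leaves labelled.

    Node ids are integers; leaves are the keys of ``leaf_labels``.
    ``edge_support`` optionally maps a frozenset {u, v} to a replicate
    count (consensus trees).
    """

    adjacency: dict[int, dict[int, float]]
    leaf_labels: dict[int, str]
    edge_support: dict[frozenset, int] = field(default_factory=dict)

    # -- basics -------------------------------------------------------

    @property
    def leaves(self) -> list[int]:
        return sorted(self.leaf_labels)

    def edges(self) -> list[tuple[int, int]]:
        out = []
        for u, nbrs in self.adjacency.items():
            for v in nbrs:
                if u < v:
                    out.append((u, v))
        return sorted(out)

    def copy(self) -> "Tree":
        return Tree(
            {u: dict(nbrs) for u, nbrs in self.adjacency.items()},
            dict(self.leaf_labels),
            dict(self.edge_support),
        )

    def total_length(self) -> float:
        return sum(l for _, nbrs in self.adjacency.items() for l in nbrs.values()) / 2

    # -- metrics ------------------------------------------------------

    def path_lengths(self) -> DistanceMatrix:
        """Leaf-to-leaf patristic distance matrix (label order = sorted leaves)."""
        leaves = self.leaves
        labels = [self.leaf_labels[v] for v in leaves]
        n = len(leaves)
        values = np.zeros((n, n))
        for a, start in enumerate(leaves):
            dist = {start: 0.0}
            stack = [start]
            while stack:
                u = stack.pop()
                for v, l in self.adjacency[u].items():
                    if v not in dist:
                        dist[v] = dist[u] + l
                        stack.append(v)
            for b, leaf in enumerate(leaves):
                values[a, b] = dist[leaf]
        np.fill_diagonal(values, 0.0)
        values = (values + values.T) / 2  # exact symmetry
        return DistanceMatrix(labels, values, "custom")

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions, each as the leaf-label side excluding
        the first (sorted) label."""
        ref = min(self.leaf_labels.values())
        out = set()
        for u, v in self.edges():
            side = self._leafset_beyond(u, v)
            labels = frozenset(self.leaf_labels[x] for x in side)
            if ref in labels:
                labels = frozenset(self.leaf_labels.values()) - labels
            if 1 < len(labels) < len(self.leaf_labels) - 1:
                out.add(labels)
        return out

    def _leafset_beyond(self, u: int, v: int) -> set[int]:
        """Leaves on v's side of edge (u, v)."""
        seen = {u, v}
        stack = [v]
        out = set()
        while stack:
            x = stack.pop()
            if x in self.leaf_labels:
                out.add(x)
            for y in self.adjacency[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return out

    # -- newick -------------------------------------------------------

    def to_newick(self, root_label: str | None = None) -> str:
        """Serialise; rooted for display at the edge leading to
        ``root_label`` (default: an arbitrary internal node)."""
        label_to_node = {lb: v for v, lb in self.leaf_labels.items()}
        if root_label is not None:
            leaf = label_to_node[root_label]
            start = next(iter(self.adjacency[leaf]))
        else:
            internals = [v for v in self.adjacency if v not in self.leaf_labels]
            start = internals[0] if internals else self.leaves[0]

        def rec(u: int, parent: int | None) -> str:
            if u in self.leaf_labels:
                return self.leaf_labels[u]
            parts = []
            for v, l in sorted(self.adjacency[u].items()):
                if v == parent:
                    continue
                sup = self.edge_support.get(frozenset((u, v)))
                tag = "" if sup is None or v in self.leaf_labels else str(sup)
                parts.append(f"{rec(v, u)}{tag}:{l:.6f}")
            return "(" + ",".join(parts) + ")"

        return rec(start, None) + ";"


# ---------------------------------------------------------------------
# neighbour joining


def neighbor_joining(dist: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbour joining with deterministic tie-breaking.

    Ties on the Q criterion resolve to the lowest-index pair.  Negative
    intermediate branch lengths are clamped to zero with the deficit
    transferred to the sister branch.
    """
    if dist.has_absent():
        raise ValueError(
            "distance matrix has absent entries; impute or drop entities first"
        )
    n = len(dist.labels)
    if n < 3:
        raise ValueError("neighbour joining requires at least 3 labels")
    d = dist.values.copy()
    active = list(range(n))
    adjacency: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    leaf_labels = dict(enumerate(dist.labels))
    nxt = n
    # index into the growing d matrix == node id
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = divmod(int(np.argmin(q)), m)  # row-major => lowest index pair
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        bi = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2 * (m - 2))
        bj = dij - bi
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        u = nxt
        nxt += 1
        newrow = np.zeros(d.shape[0] + 1)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d[i, k] + d[j, k] - dij)
            d[u, k] = d[k, u] = max(duk, 0.0)
        adjacency[u] = {i: bi, j: bj}
        adjacency[i][u] = bi
        adjacency[j][u] = bj
        active = [k for k in active if k not in (i, j)] + [u]
        del newrow
    i, j, k = active
    bi = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    bj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    bk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    center = nxt
    adjacency[center] = {}
    for node, b in ((i, bi), (j, bj), (k, bk)):
        b = max(b, 0.0)
        adjacency[center][node] = b
        adjacency[node][center] = b
    return Tree(adjacency, leaf_labels)


# ---------------------------------------------------------------------
# weighted least squares + NNI search


def _design_matrix(tree: Tree, leaves: list[int]) -> tuple[np.ndarray, list]:
    """Binary pair-by-edge incidence matrix for the current topology."""
    edges = tree.edges()
    e_index = {frozenset(e): k for k, e in enumerate(edges)}
    n = len(leaves)
    pairs = list(itertools.combinations(range(n), 2))
    a = np.zeros((len(pairs), len(edges)))
    # parent pointers from each leaf
    for row, (ia, ib) in enumerate(pairs):
        start, goal = leaves[ia], leaves[ib]
        parent = {start: None}
        stack = [start]
        while stack:
            u = stack.pop()
            if u == goal:
                break
            for v in tree.adjacency[u]:
                if v not in parent:
                    parent[v] = u
                    stack.append(v)
        v = goal
        while parent[v] is not None:
            a[row, e_index[frozenset((v, parent[v]))]] = 1.0
            v = parent[v]
    return a, edges


def ls_branch_lengths(
    tree: Tree, dist: DistanceMatrix, max_weight: float = 1e6
) -> tuple[Tree, float]:
    """Fit non-negative branch lengths minimising the weighted criterion.

    Returns the refitted tree and its objective value.  Weights are
    1/d^2, capped at ``max_weight`` for (near-)zero observed distances.
    """
    label_to_leaf = {lb: v for v, lb in tree.leaf_labels.items()}
    leaves = [label_to_leaf[lb] for lb in dist.labels]
    a, edges = _design_matrix(tree, leaves)
    pairs = list(itertools.combinations(range(len(leaves)), 2))
    dvec = np.array([dist.values[i, j] for i, j in pairs])
    w = np.minimum(1.0 / np.maximum(dvec, 1e-12) ** 2, max_weight)
    sw = np.sqrt(w)
    x, _ = nnls(a * sw[:, None], dvec * sw)
    fitted = tree.copy()
    for (u, v), length in zip(edges, x):
        fitted.adjacency[u][v] = fitted.adjacency[v][u] = float(length)
    resid = a @ x - dvec
    return fitted, float((w * resid**2).sum())


def _nni_neighbours(tree: Tree):
    """Yield topologies one nearest-neighbour interchange away."""
    for u, v in tree.edges():
        if u in tree.leaf_labels or v in tree.leaf_labels:
            continue
        u_nbrs = [x for x in tree.adjacency[u] if x != v]
        v_nbrs = [x for x in tree.adjacency[v] if x != u]
        if len(u_nbrs) != 2 or len(v_nbrs) != 2:
            continue
        b = u_nbrs[1]
        for c in v_nbrs:
            t = tree.copy()
            # swap subtree b (on u) with subtree c (on v)
            del t.adjacency[u][b], t.adjacency[b][u]
            del t.adjacency[v][c], t.adjacency[c][v]
            t.adjacency[u][c] = t.adjacency[c][u] = 0.0
            t.adjacency[v][b] = t.adjacency[b][v] = 0.0
            yield t


def least_squares_tree(
    dist: DistanceMatrix,
    start: Tree | None = None,
    max_weight: float = 1e6,
    max_rounds: int = 50,
) -> Tree:
    """Fitch–Margoliash-style weighted least-squares tree.

    Hill-climbs over nearest-neighbour interchanges from the
    neighbour-joining topology (or ``start``), accepting a move only if
    it strictly lowers the objective, so the objective never increases.
    """
    if start is None:
        start = neighbor_joining(dist)
    best, best_obj = ls_branch_lengths(start, dist, max_weight)
    for _ in range(max_rounds):
        improved = False
        for cand in _nni_neighbours(best):
            fitted, obj = ls_branch_lengths(cand, dist, max_weight)
            if obj < best_obj - 1e-12:
                best, best_obj = fitted, obj
                improved = True
                break
        if not improved:
            break
    best.ls_objective = best_obj  # type: ignore[attr-defined]
    return best


# ---------------------------------------------------------------------
# bootstrap over loci + majority-rule consensus


def _distance_for(
    dataset: GenotypeDataset, metric: str, level: str
) -> DistanceMatrix:
    if metric == "chord":
        if level == "individual":
            return chord_distance_matrix(dataset)
        return chord_distance_matrix(allele_frequencies(dataset, level))
    if metric == "allele_sharing":
        if level != "individual":
            raise ValueError("allele-sharing distance is defined between individuals")
        return allele_sharing_distance_matrix(dataset)
    raise ValueError(f"unknown metric {metric!r}")


def _build(dist: DistanceMatrix, method: str) -> Tree:
    if method == "nj":
        return neighbor_joining(dist)
    if method == "least_squares":
        return least_squares_tree(dist)
    raise ValueError(f"unknown method {method!r}")


def consensus_from_trees(
    trees: list[Tree], outgroup: set[str] | None = None
) -> Tree:
    """Greedy majority-rule (>50%) consensus with supports as counts."""
    n_reps = len(trees)
    all_labels = sorted(trees[0].leaf_labels.values())
    ref = sorted(outgroup)[0] if outgroup else all_labels[0]
    full = frozenset(all_labels)

    counts: dict[frozenset, int] = {}
    for t in trees:
        for s in t.splits():
            s = s if ref not in s else full - s
            counts[s] = counts.get(s, 0) + 1
    majority = sorted(
        ((s, c) for s, c in counts.items() if c > n_reps / 2),
        key=lambda sc: (-sc[1], -len(sc[0]), sorted(sc[0])),
    )

    # build rooted-at-ref clade structure greedily (majority splits are
    # mutually compatible, so insertion cannot fail)
    leaf_node = {lb: i for i, lb in enumerate(all_labels)}
    nxt = len(all_labels)
    children: dict[int, set[int]] = {nxt: set(leaf_node.values())}
    cluster: dict[int, frozenset] = {
        **{v: frozenset([lb]) for lb, v in leaf_node.items()},
        nxt: full,
    }
    root = nxt
    nxt += 1
    support: dict[int, int] = {}
    for s, c in majority:
        # deepest node whose cluster contains s
        node = root
        while True:
            nested = [
                ch for ch in children.get(node, ()) if s <= cluster[ch] and s != cluster[ch]
            ]
            if nested:
                node = nested[0]
            else:
                break
        if cluster[node] == s:
            support[node] = c
            continue
        grouped = {ch for ch in children[node] if cluster[ch] <= s}
        if frozenset().union(*(cluster[ch] for ch in grouped)) != s:
            continue  # incompatible with already-placed splits (sub-majority)
        new = nxt
        nxt += 1
        children[node] -= grouped
        children[node].add(new)
        children[new] = grouped
        cluster[new] = s
        support[new] = c

    adjacency: dict[int, dict[int, float]] = {v: {} for v in cluster}
    edge_support: dict[frozenset, int] = {}
    for parent, chs in children.items():
        for ch in chs:
            adjacency[parent][ch] = adjacency.setdefault(ch, {})[parent] = 0.0
            adjacency[ch][parent] = 0.0
            if ch in support:
                edge_support[frozenset((parent, ch))] = support[ch]
    leaf_labels = {v: lb for lb, v in leaf_node.items()}
    return Tree(adjacency, leaf_labels, edge_support)


def bootstrap_consensus(
    dataset: GenotypeDataset,
    metric: str = "chord",
    method: str = "nj",
    n_replicates: int = 1000,
    outgroup: set[str] | None = None,
    seed: int = 0,
    level: str = "unit",
    resample: bool = True,
) -> Tree:
    """Majority-rule consensus of trees built on locus-bootstrap replicates.

    Loci are resampled with replacement per replicate (``resample=False``
    rebuilds the same tree each time, a degenerate check).  Supports are
    replicate counts on internal edges.  With an ``outgroup`` the Newick
    serialisation roots the tree at the first outgroup label.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    n_loci = dataset.n_loci
    trees = []
    for _ in range(n_replicates):
        if resample:
            pick = rng.integers(0, n_loci, size=n_loci)
            sub = GenotypeDataset(
                [
                    type(dataset.loci[j])(
                        f"{dataset.loci[j].name}_b{k}",
                        dataset.loci[j].chromosome_class,
                        dataset.loci[j].motif_length,
                    )
                    for k, j in enumerate(pick)
                ],
                dataset.individuals,
                dataset.calls[:, pick, :].copy(),
            )
        else:
            sub = dataset
        dist = _distance_for(sub, metric, level)
        if dist.has_absent():
            keep = [
                i for i in range(len(dist.labels))
                if not np.isnan(np.delete(dist.values[i], i)).any()
            ]
            dist = DistanceMatrix(
                [dist.labels[i] for i in keep],
                dist.values[np.ix_(keep, keep)],
                dist.metric_name,
            )
        trees.append(_build(dist, method))
    return consensus_from_trees(trees, outgroup)
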