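"""Distance-based paralog phylogenetics: p/JC69 distances, deterministic
neighbor-joining with midpoint rooting, bootstrap branch support, anchor-based
clade labelling, and strict-clock node dating.

Neighbor joining is implemented in-package so that tie-breaking is fully
deterministic (lexicographic on clade leaf labels); trees are dendropy objects.
"""
from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


@dataclass
class DistanceMatrix:
    labels: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix must be symmetric")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class CladeAssignment:
    labels: dict                      # leaf/copy -> paralog label
    provenance: dict                  # leaf/copy -> anchor|nearest-neighbor|merged
    merge_distance: float = 0.0


def _encode(seqs: dict) -> tuple[list, np.ndarray]:
    labels = sorted(seqs)
    lens = {len(seqs[l]) for l in labels}
    if len(lens) != 1:
        raise ValueError("sequences must be aligned to equal length")
    mat = np.vstack([np.frombuffer(seqs[l].encode(), dtype=np.uint8)
                     for l in labels])
    return labels, mat


def pairwise_distance(seqs: dict, model: str = "p") -> DistanceMatrix:
    """p-distance or JC69 over shared comparable columns; gap ('-') and 'N'
    columns are excluded pairwise. JC69 = -(3/4) ln(1 - 4p/3)."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    labels, mat = _encode(seqs)
    bad = (mat == ord("N")) | (mat == ord("-"))
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~bad[i] & ~bad[j]
            tot = int(ok.sum())
            p = (float(np.count_nonzero(mat[i, ok] != mat[j, ok])) / tot
                 if tot else 0.0)
            if model == "p":
                d = p
            elif model == "JC69":
                if p >= 0.75:
                    raise ValueError(f"JC69 undefined at p={p:.3f} >= 0.75")
                d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            else:
                raise ValueError(f"unknown model {model!r}")
            D[i, j] = D[j, i] = d
    return DistanceMatrix(labels, D)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def build_nj(dm: DistanceMatrix, midpoint_root: bool = True) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; negative branch lengths clamped to zero,
    agglomeration ties broken lexicographically on clade leaf-label tuples."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 labels")
    taxa = dendropy.TaxonNamespace()
    nodes, keys = [], []
    for lab in dm.labels:
        nd = dendropy.Node()
        nd.taxon = taxa.new_taxon(label=str(lab))
        nodes.append(nd)
        keys.append((str(lab),))
    D = dm.values.astype(float).copy()
    while len(nodes) > 2:
        r = len(nodes)
        rs = D.sum(axis=1)
        Q = (r - 2) * D - rs[:, None] - rs[None, :]
        # floating summation order can differ across the diagonal by one ulp;
        # use the upper triangle only so tie detection stays exact
        Q[np.tril_indices(r)] = np.inf
        qmin = Q.min()
        ties = np.argwhere(Q <= qmin)
        i, j = min((tuple(sorted((keys[a], keys[b]))), a, b)
                   for a, b in ties)[1:]
        dab = D[i, j]
        la = 0.5 * dab + (rs[i] - rs[j]) / (2.0 * (r - 2))
        lb = dab - la
        parent = dendropy.Node()
        nodes[i].edge.length = max(la, 0.0)
        nodes[j].edge.length = max(lb, 0.0)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        newrow = 0.5 * (D[i] + D[j] - dab)
        keep = [k for k in range(r) if k not in (i, j)]
        D2 = np.empty((r - 1, r - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = np.maximum(newrow[keep], 0.0)
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [tuple(sorted(keys[i] + keys[j]))]
    root = dendropy.Node()
    na, nb = nodes
    half = max(D[0, 1], 0.0) / 2.0
    na.edge.length = half
    nb.edge.length = half
    root.add_child(na)
    root.add_child(nb)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = True
    if midpoint_root:
        _midpoint_root(tree)
        if tree.seed_node.taxon is not None:
            # the midpoint can land exactly on a leaf; keep that taxon a leaf
            leaf = dendropy.Node()
            leaf.taxon = tree.seed_node.taxon
            leaf.edge.length = 0.0
            tree.seed_node.taxon = None
            tree.seed_node.add_child(leaf)
    return tree


def _midpoint_root(tree: dendropy.Tree) -> None:
    """Deterministic midpoint rooting (diameter ties broken by leaf label)."""
    nbrs = {}
    for nd in tree.preorder_node_iter():
        for ch in nd.child_nodes():
            w = ch.edge.length or 0.0
            nbrs.setdefault(nd, []).append((ch, w))
            nbrs.setdefault(ch, []).append((nd, w))
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    if len(leaves) < 2:
        return

    def farthest(start):
        dist, prev = {start: 0.0}, {start: None}
        stack = [start]
        while stack:
            nd = stack.pop()
            for nb, w in nbrs[nd]:
                if nb not in dist:
                    dist[nb] = dist[nd] + w
                    prev[nb] = nd
                    stack.append(nb)
        m = max(dist[l] for l in leaves)
        best = min((l for l in leaves if dist[l] >= m - 1e-12),
                   key=lambda l: l.taxon.label)
        return best, dist, prev

    u, _, _ = farthest(leaves[0])
    v, dist, prev = farthest(u)
    path = [v]
    while prev[path[-1]] is not None:
        path.append(prev[path[-1]])
    path.reverse()  # u .. v
    half = dist[v] / 2.0
    acc = 0.0
    for a, b in zip(path, path[1:]):
        w = next(wt for nb, wt in nbrs[a] if nb is b)
        if acc + w >= half - 1e-12:
            off = half - acc  # distance from a along the a-b edge
            if b.parent_node is a:
                edge, d_parent = b.edge, off
            else:
                edge, d_parent = a.edge, w - off
            node_hit = (a if off <= 1e-12 else b if off >= w - 1e-12 else None)
            if node_hit is not None:
                if node_hit is not tree.seed_node:
                    tree.reroot_at_node(node_hit, update_bipartitions=False,
                                        suppress_unifurcations=True)
            else:
                tree.reroot_at_edge(edge, length1=d_parent,
                                    length2=w - d_parent,
                                    update_bipartitions=False,
                                    suppress_unifurcations=True)
            return
        acc += w


def bipartitions(tree: dendropy.Tree) -> set:
    """Non-trivial unrooted bipartitions as frozensets of leaf labels on the
    side not containing the lexicographically first leaf."""
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    ref = leaves[0]
    full = set(leaves)
    out = set()
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in nd.leaf_iter())
        if ref in side:
            side = frozenset(full - side)
        if 1 < len(side) < len(full) - 1:
            out.add(side)
    return out


def bootstrap_support(seqs: dict, n_reps: int = 100, seed: int = 0,
                      model: str = "p") -> dendropy.Tree:
    """NJ tree with internal-branch support = percent of column-resampled
    replicate NJ trees containing the same bipartition. Columns containing
    'N' or '-' in any sequence are not resampled."""
    labels, mat = _encode(seqs)
    bad = ((mat == ord("N")) | (mat == ord("-"))).any(axis=0)
    mat = mat[:, ~bad]
    L = mat.shape[1]
    if L < 50:
        raise ValueError("need >= 50 comparable columns to bootstrap")
    tree = build_nj(pairwise_distance(
        {l: mat[i].tobytes().decode() for i, l in enumerate(labels)},
        model=model))
    var = np.flatnonzero((mat != mat[0]).any(axis=0))
    onehot = [np.ascontiguousarray((mat[:, var] == b).astype(np.float32))
              for b in (65, 67, 71, 84)]
    rng = np.random.default_rng(seed)
    counts = {}
    n = len(labels)
    for _ in range(n_reps):
        w = rng.multinomial(L, np.full(L, 1.0 / L)).astype(np.float32)
        wv = w[var]
        match = sum((oh * wv) @ oh.T for oh in onehot)
        diff = wv.sum() - match
        D = diff / float(L)
        np.fill_diagonal(D, 0.0)
        D = np.maximum(0.0, (D + D.T) / 2.0)
        if model == "JC69":
            D = -0.75 * np.log(np.maximum(1.0 - 4.0 * D / 3.0, 1e-12))
            np.fill_diagonal(D, 0.0)
        rep = build_nj(DistanceMatrix(labels, D), midpoint_root=False)
        for bp in bipartitions(rep):
            counts[bp] = counts.get(bp, 0) + 1
    full = set(labels)
    ref = sorted(labels)[0]
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in nd.leaf_iter())
        if ref in side:
            side = frozenset(full - side)
        if 1 < len(side) < len(full) - 1:
            nd.label = str(round(100.0 * counts.get(side, 0) / n_reps, 1))
        else:
            nd.label = None
    return tree


# ---------------------------------------------------------------------------
# clade labelling
# ---------------------------------------------------------------------------

def _patristic(tree: dendropy.Tree) -> tuple[list, np.ndarray]:
    pdm = tree.phylogenetic_distance_matrix()
    leaves = sorted([l.taxon for l in tree.leaf_node_iter()],
                    key=lambda t: t.label)
    n = len(leaves)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(leaves[i], leaves[j])
    return [t.label for t in leaves], D


def assign_paralogs(tree: dendropy.Tree, anchors: dict,
                    support_threshold: float = 75.0,
                    merge_distance: float | None = None) -> CladeAssignment:
    """Label every leaf from reference-anchored supported clades.

    Maximal clades with support > threshold containing exactly one anchor group
    inherit that anchor's label; anchors separated by less than
    ``merge_distance`` (default: 3x the median intra-anchor-clade distance) or
    by no supported clade are merged into a joint 'X/Y' label; supported
    anchorless clades are named after the nearest labelled anchor with an 'L'
    suffix numbered by descending clade size; anything left falls back to its
    nearest anchor.
    """
    if not anchors:
        raise ValueError("need at least one anchor")
    leaf_labels, D = _patristic(tree)
    idx = {l: i for i, l in enumerate(leaf_labels)}
    anchor_leaves = sorted(anchors)
    clades = []  # (leafset frozenset, support)
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        try:
            sup = float(nd.label) if nd.label is not None else None
        except ValueError:
            sup = None
        if sup is not None and sup > support_threshold:
            clades.append(frozenset(l.taxon.label for l in nd.leaf_iter()))

    # default merge distance: 3x the median intra-clade distance, taken over
    # each anchor's tightest supported clade
    smallest = {}
    for a in anchor_leaves:
        own = [c for c in clades if a in c and len(c) > 1]
        smallest[a] = min(own, key=len) if own else None
    if merge_distance is None:
        intra = []
        for a, c in smallest.items():
            if c is not None:
                ii = [idx[l] for l in c]
                sub = D[np.ix_(ii, ii)]
                intra.append(float(np.median(sub[np.triu_indices(len(ii), 1)])))
        merge_distance = 3.0 * float(np.median(intra)) if intra else 0.0

    # merge anchors whose tight clades interleave or that sit closer than the
    # merge distance
    groups = {a: {a} for a in anchor_leaves}
    for i, a in enumerate(anchor_leaves):
        for b in anchor_leaves[i + 1:]:
            interleave = ((smallest[a] is not None and b in smallest[a])
                          or (smallest[b] is not None and a in smallest[b]))
            if D[idx[a], idx[b]] < merge_distance or interleave:
                ga, gb = groups[a], groups[b]
                if ga is not gb:
                    ga |= gb
                    for m in gb:
                        groups[m] = ga
    group_label = {}
    for a, g in groups.items():
        group_label[a] = "/".join(sorted({anchors[m] for m in g}))

    labels_out, prov = {}, {}
    for leaf in leaf_labels:
        best = None
        for c in clades:
            if leaf not in c:
                continue
            present = {frozenset(groups[a]) for a in anchor_leaves if a in c}
            if len(present) == 1:
                if best is None or len(c) > len(best):
                    best = c
        if best is not None:
            a = next(a for a in anchor_leaves if a in best)
            labels_out[leaf] = group_label[a]
            prov[leaf] = "merged" if len(groups[a]) > 1 else "anchor"
    # anchors always keep their own (possibly merged) label
    for a in anchor_leaves:
        labels_out[a] = group_label[a]
        prov[a] = "merged" if len(groups[a]) > 1 else "anchor"

    # supported anchorless clades -> nearest label + L suffix
    anchorless = [c for c in clades
                  if not any(a in c for a in anchor_leaves)
                  and not all(l in labels_out for l in c)]
    maximal = [c for c in anchorless
               if not any(c < o for o in anchorless)]
    counter = {}
    for c in sorted(maximal, key=lambda c: (-len(c), sorted(c)[0])):
        ii = [idx[l] for l in c]
        aj = min(anchor_leaves,
                 key=lambda a: float(D[np.ix_(ii, [idx[a]])].mean()))
        base = group_label[aj]
        counter[base] = counter.get(base, 0) + 1
        lab = f"{base}L{counter[base]}"
        for l in c:
            if l not in labels_out:
                labels_out[l] = lab
                prov[l] = "nearest-neighbor"

    for leaf in leaf_labels:
        if leaf not in labels_out:
            a = min(anchor_leaves, key=lambda a: D[idx[leaf], idx[a]])
            labels_out[leaf] = group_label[a]
            prov[leaf] = "nearest-neighbor"
    return CladeAssignment(labels_out, prov, merge_distance)


# ---------------------------------------------------------------------------
# strict-clock dating
# ---------------------------------------------------------------------------

def date_nodes(tree: dendropy.Tree, outgroup: str, root_age: float) -> dict:
    """Proportional strict-clock ages: each node's height is its mean distance
    to descendant leaves; age = root_age x height / root height, clamped so
    ages decrease root-to-leaf. Returns {frozenset(descendant leaves): age}."""
    if root_age <= 0:
        raise ValueError("root_age must be positive")
    t = tree.clone(depth=1)
    og = None
    for l in t.leaf_node_iter():
        if l.taxon.label == outgroup:
            og = l
    if og is None:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    # root at the outgroup attachment point, keeping its full branch length
    if og.parent_node is not t.seed_node:
        t.reroot_at_node(og.parent_node, update_bipartitions=False)

    # node height = mean path length to its descendant leaves
    dists = {}
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            dists[nd] = [0.0]
        else:
            dists[nd] = [d + (ch.edge.length or 0.0)
                         for ch in nd.child_nodes() for d in dists[ch]]
    heights = {nd: float(np.mean(v)) for nd, v in dists.items()}
    root_h = heights[t.seed_node]
    if root_h <= 0:
        raise ValueError("zero root height")
    ages = {}
    for nd in t.preorder_node_iter():
        age = root_age * heights[nd] / root_h
        if nd.parent_node is not None:
            age = min(age, ages[frozenset(
                l.taxon.label for l in nd.parent_node.leaf_iter())])
        ages[frozenset(l.taxon.label for l in nd.leaf_iter())] = age
    return ages
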