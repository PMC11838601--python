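"""Distances, neighbor joining, bootstrap support, clade labelling and
strict-clock dating."""
import dendropy
import numpy as np
import pytest

from paraloscope import phylo
from paraloscope import synthdata as sd


def leaf_distances(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted([l.taxon for l in tree.leaf_node_iter()],
                  key=lambda t: t.label)
    out = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            out[(a.label, b.label)] = pdm.patristic_distance(a, b)
    return out


def random_additive_matrix(rng, n):
    """Distances induced by a random binary tree with positive branch lengths."""
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
        taxon_namespace=taxa,
        rng=__import__("random").Random(int(rng.integers(0, 2**31))))
    for e in tree.preorder_edge_iter():
        if e.head_node.parent_node is not None:
            e.length = float(rng.uniform(0.05, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in taxa)
    tmap = {t.label: t for t in taxa}
    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(tmap[a],
                                                       tmap[labels[j]])
    return phylo.DistanceMatrix(labels, D), tree


def test_pairwise_distance_models():
    assert phylo.pairwise_distance(
        {"a": "ACGT" * 25, "b": "ACGT" * 25}).values[0, 1] == 0.0
    s1 = "A" * 100
    s2 = "C" * 10 + "A" * 90
    assert phylo.pairwise_distance({"a": s1, "b": s2}).values[0, 1] == \
        pytest.approx(0.10)
    jc = phylo.pairwise_distance({"a": s1, "b": s2}, model="JC69")
    assert jc.values[0, 1] == pytest.approx(-0.75 * np.log(1 - 0.4 / 3),
                                            abs=1e-9)
    with pytest.raises(ValueError):
        phylo.pairwise_distance({"a": "A" * 100, "b": "C" * 100},
                                model="JC69")
    # gaps and Ns excluded pairwise
    d = phylo.pairwise_distance({"a": "ANAA", "b": "ACCA"}).values[0, 1]
    assert d == pytest.approx(1 / 3)


def test_nj_recovers_additive_matrices(rng):
    for _ in range(30):
        n = int(rng.integers(4, 11))
        dm, true_tree = random_additive_matrix(rng, n)
        est = phylo.build_nj(dm)
        # additive recovery: all leaf-to-leaf path lengths match the input
        got = leaf_distances(est)
        idx = {l: i for i, l in enumerate(dm.labels)}
        for (a, b), d in got.items():
            assert d == pytest.approx(dm.values[idx[a], idx[b]], abs=1e-6)


def test_nj_matches_external_implementation(rng):
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sk_nj
    for _ in range(10):
        n = int(rng.integers(4, 9))
        dm, _ = random_additive_matrix(rng, n)
        ours = phylo.build_nj(dm, midpoint_root=False)
        theirs = sk_nj(SkDM(dm.values, ids=dm.labels))
        t2 = dendropy.Tree.get(data=str(theirs), schema="newick",
                               taxon_namespace=ours.taxon_namespace)
        assert phylo.bipartitions(ours) == phylo.bipartitions(t2)


def test_nj_tie_break_deterministic():
    dm = phylo.DistanceMatrix(["a", "b", "c"],
                              np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.0]]))
    n1 = phylo.build_nj(dm).as_string(schema="newick")
    n2 = phylo.build_nj(dm).as_string(schema="newick")
    assert n1 == n2
    with pytest.raises(ValueError):
        phylo.build_nj(phylo.DistanceMatrix(["a", "b"], np.zeros((2, 2))))


def test_bootstrap_diagnostic_columns_give_full_support(rng):
    base = sd._random_dna(rng, 150)
    other = list(base)
    for i in range(0, 100, 2):
        other[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[i]]
    other = "".join(other)
    seqs = {"a1": base, "a2": base, "b1": other, "b2": other}
    tree = phylo.bootstrap_support(seqs, n_reps=100, seed=0)
    sups = [float(nd.label) for nd in tree.preorder_node_iter()
            if nd.label is not None]
    assert sups and all(s == 100.0 for s in sups)


def test_paralog_clades_fully_supported(small_sim, rng):
    tr = small_sim.truth
    seqs, labels = {}, {}
    picked = tr.copy_coordinates.groupby("paralog").head(4)
    for r in picked.itertuples():
        seqs[r.copy_id] = tr.to_ancestral(r.copy_id)
        labels[r.copy_id] = r.paralog
    tree = phylo.bootstrap_support(seqs, n_reps=100, seed=3)
    full = set(seqs)
    bps = {}
    ref = sorted(full)[0]
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None or nd.label is None:
            continue
        side = frozenset(l.taxon.label for l in nd.leaf_iter())
        if ref in side:
            side = frozenset(full - side)
        bps[side] = float(nd.label)
    for paralog in sorted(set(labels.values())):
        clade = frozenset(n for n, l in labels.items() if l == paralog)
        if len(clade) < 2 or len(clade) > len(full) - 2:
            continue
        key = clade if ref not in clade else frozenset(full - clade)
        assert bps.get(key, 0.0) >= 95.0, paralog


def test_assign_paralogs_anchor_merge_and_suffix_rules(rng):
    # three well-separated clades; one anchorless, two with anchors that are
    # nearly identical in a fourth joint clade
    base = sd._random_dna(rng, 400)
    mut = lambda seq, rate: sd._mutated(seq, rate, rng, None)
    inner = mut(base, 0.08)           # (A,B) share an ancestor; C is sister
    cladeA = mut(inner, 0.05)
    cladeB = mut(inner, 0.05)
    cladeC = mut(base, 0.13)
    seqs = {}
    for nm, cons in (("A", cladeA), ("B", cladeB), ("C", cladeC)):
        for i in range(3):
            seqs[f"{nm}{i}"] = mut(cons, 0.005)
    tree = phylo.bootstrap_support(seqs, n_reps=100, seed=1)
    # distinct anchors in A and B; C anchorless
    asg = phylo.assign_paralogs(tree, {"A0": "P1", "B0": "P2"})
    assert all(asg.labels[f"A{i}"] == "P1" for i in range(3))
    assert all(asg.labels[f"B{i}"] == "P2" for i in range(3))
    c_labels = {asg.labels[f"C{i}"] for i in range(3)}
    assert len(c_labels) == 1
    lab = c_labels.pop()
    assert lab.endswith("L1") and asg.provenance["C0"] == "nearest-neighbor"
    # two anchors inside one tight clade merge into a joint label
    asg2 = phylo.assign_paralogs(tree, {"A0": "X", "A1": "Y"})
    assert asg2.labels["A2"] == "X/Y"
    assert asg2.provenance["A2"] == "merged"


def test_date_nodes_proportional_and_scale_invariant():
    nwk = "((a:1.0,b:1.0):1.0,(c:1.0,d:1.0):1.0,og:2.0);"
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    ages = phylo.date_nodes(tree, "og", root_age=28.8)
    assert ages[frozenset({"a"})] == 0.0
    assert ages[frozenset({"a", "b"})] == pytest.approx(14.4)
    # scaling all branch lengths leaves ages unchanged
    tree2 = dendropy.Tree.get(data=nwk, schema="newick")
    for e in tree2.preorder_edge_iter():
        if e.length:
            e.length *= 7.0
    ages2 = phylo.date_nodes(tree2, "og", root_age=28.8)
    for k, v in ages.items():
        assert ages2[k] == pytest.approx(v, abs=1e-9)


def test_date_nodes_recovers_clock_simulation(rng):
    # strict clock: split at 3.0 units, root (outgroup join) at 28.8; branch
    # lengths are Poisson substitution counts over 50 kb
    L, rate = 50_000, 1e-5
    est = []
    for _ in range(20):
        def blen(t):
            return rng.poisson(t * rate * L) / (rate * L) * rate
        t_split, t_root = 3.0, 28.8
        nwk = (f"((a:{blen(t_split)},b:{blen(t_split)}):"
               f"{blen(t_root - t_split)},og:{blen(t_root)});")
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        ages = phylo.date_nodes(tree, "og", root_age=28.8)
        est.append(ages[frozenset({"a", "b"})])
    assert np.mean(est) == pytest.approx(3.0, abs=0.5)
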