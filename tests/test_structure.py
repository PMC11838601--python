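"""Configuration encoding, catalogs, DCJ-indel distance (formula vs exhaustive
search) and inversion calls."""
import numpy as np
import pandas as pd
import pytest

from paraloscope import structure as st
from paraloscope.discovery import LocusCopy


def cfgstr(tokens, locus="L"):
    return st.ConfigurationString(locus, tuple(tokens))


def rand_ops(tokens, n_ops, rng):
    """Apply random inversions / transpositions / indels to the interior of an
    anchored token string."""
    t = list(tokens)
    for _ in range(n_ops):
        op = rng.integers(0, 3)
        lo, hi = 1, len(t) - 1
        if hi - lo < 1:
            continue
        if op == 0:
            i = rng.integers(lo, hi)
            j = rng.integers(i + 1, hi + 1)
            t[i:j] = [(n, -s) for n, s in reversed(t[i:j])]
        elif op == 1:
            i = rng.integers(lo, hi)
            j = rng.integers(i + 1, hi + 1)
            seg = t[i:j]
            rest = t[:i] + t[j:]
            k = rng.integers(1, len(rest))
            t = rest[:k] + seg + rest[k:]
        else:
            if rng.random() < 0.5 and hi - lo > 1:
                i = rng.integers(lo, hi)
                j = min(hi, i + 1 + int(rng.integers(0, 3)))
                del t[i:j]
            else:
                i = rng.integers(lo, hi + 1)
                t[i:i] = [(f"n{rng.integers(0, 100)}", 1)]
    return t


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def _mk_copy(start, end, strand, label):
    return LocusCopy("h", "h", start, end, strand, "A" * (end - start),
                     paralog_label=label)


def _markers(items):
    return pd.DataFrame([{"name": n, "start": s, "end": e, "strand": d}
                         for n, s, e, d in items])


def test_encode_reference_orientation_template():
    copies = [_mk_copy(10_000, 30_000, "+", "A1")]
    mk = _markers([("M0", 0, 2_000, "+"), ("M1", 40_000, 42_000, "+")])
    enc = st.encode_configuration(copies, mk, "L", "M0", "M1")
    assert enc.tokens == (("M0", 1), ("A1", 1), ("M1", 1))


def test_encode_flips_reversed_haplotype_and_drops_short_tokens():
    copies = [_mk_copy(10_000, 30_000, "-", "A1")]
    mk = _markers([("M1", 0, 2_000, "-"), ("M0", 40_000, 42_000, "-"),
                   ("tiny", 5_000, 5_500, "+")])
    enc = st.encode_configuration(copies, mk, "L", "M0", "M1")
    assert enc.tokens == (("M0", 1), ("A1", 1), ("M1", 1))
    none = st.encode_configuration(copies, _markers([]), "L", "M0", "M1")
    assert none is None


def test_encode_middle_block_inversion():
    copies = [_mk_copy(10_000, 30_000, "-", "A1")]
    mk = _markers([("M0", 0, 2_000, "+"), ("M1", 5_000, 7_000, "-"),
                   ("M2", 40_000, 42_000, "+")])
    enc = st.encode_configuration(copies, mk, "L", "M0", "M2")
    assert enc.tokens == (("M0", 1), ("M1", -1), ("A1", -1), ("M2", 1))


def test_catalog_thresholds_and_frequencies():
    a = cfgstr([("M0", 1), ("A1", 1), ("M1", 1)])
    b = cfgstr([("M0", 1), ("A1", -1), ("M1", 1)])
    singleton = cfgstr([("M0", 1), ("M1", 1)])
    encs = [(f"h{i}", a) for i in range(7)] + \
        [(f"g{i}", b) for i in range(3)] + [("x0", singleton)]
    val = {h: True for h, _ in encs}
    cat = st.catalog_configurations(encs, val)
    assert len(cat) == 2
    assert cat.iloc[0]["count"] == 7
    assert cat.iloc[0]["frequency"] == pytest.approx(7 / 11)
    # never-validated configurations are dropped
    val_none = dict(val)
    for i in range(3):
        val_none[f"g{i}"] = False
    cat2 = st.catalog_configurations(encs, val_none)
    assert len(cat2) == 1


# ---------------------------------------------------------------------------
# DCJ-indel distance
# ---------------------------------------------------------------------------

BASE = [("L", 1), ("a", 1), ("b", 1), ("c", 1), ("d", 1), ("R", 1)]


def test_dcj_identity_inversion_and_indel():
    assert st.dcj_indel_distance(BASE, BASE) == 0
    inv = [("L", 1), ("a", 1), ("c", -1), ("b", -1), ("d", 1), ("R", 1)]
    assert st.dcj_indel_distance(BASE, inv) == 1
    assert st.dcj_indel_distance_exhaustive(BASE, inv) == 1
    extra = [("L", 1), ("a", 1), ("x", 1), ("y", 1), ("b", 1), ("c", 1),
             ("d", 1), ("R", 1)]
    assert st.dcj_indel_distance(BASE, extra) == 1
    assert st.dcj_indel_distance_exhaustive(BASE, extra) == 1


def test_dcj_empty_configuration_rule():
    assert st.dcj_indel_distance([], []) == 0
    assert st.dcj_indel_distance([], BASE) == 1
    assert st.dcj_indel_distance(BASE, []) == 1


def test_dcj_duplicate_tokens_positional_matching():
    two = [("L", 1), ("a", 1), ("a", 1), ("R", 1)]
    three = [("L", 1), ("a", 1), ("a", 1), ("a", 1), ("R", 1)]
    assert st.dcj_indel_distance(two, three) == 1  # one private-run insertion
    assert st.dcj_indel_distance(two, two) == 0


def test_dcj_formula_equals_exhaustive_search(rng):
    names = list("abcd")
    for _ in range(100):
        base = [("L", 1)] + [(n, 1 if rng.random() < 0.5 else -1)
                             for n in names] + [("R", 1)]
        other = rand_ops(base, int(rng.integers(1, 5)), rng)
        f = st.dcj_indel_distance(base, other)
        e = st.dcj_indel_distance_exhaustive(base, other)
        assert f == e, (base, other)


def test_dcj_metric_properties(rng):
    names = list("abcdef")
    for _ in range(200):
        cfgs = []
        for _ in range(3):
            mid = [(str(n), 1 if rng.random() < 0.5 else -1)
                   for n in rng.permutation(names)[:rng.integers(2, 5)]]
            cfgs.append([("L", 1)] + mid + [("R", 1)])
        d01 = st.dcj_indel_distance(cfgs[0], cfgs[1])
        d10 = st.dcj_indel_distance(cfgs[1], cfgs[0])
        d12 = st.dcj_indel_distance(cfgs[1], cfgs[2])
        d02 = st.dcj_indel_distance(cfgs[0], cfgs[2])
        assert d01 == d10
        assert d02 <= d01 + d12
        assert (d01 == 0) == (tuple(cfgs[0]) == tuple(cfgs[1]))


# ---------------------------------------------------------------------------
# configuration tree and inversions
# ---------------------------------------------------------------------------

def test_config_tree_distance_additivity():
    a = cfgstr(BASE)
    b = cfgstr(rand_ops(BASE, 1, np.random.default_rng(3)))
    c = cfgstr([("L", 1), ("d", -1), ("c", -1), ("b", -1), ("a", -1),
                ("R", 1)])
    cat = pd.DataFrame({"configuration": [a, b, c]})
    tree, labels = st.config_tree(cat)
    assert len(labels) == 3
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    d_tree = pdm.patristic_distance(taxa["config1"], taxa["config2"])
    assert d_tree >= 0
    trivial, labs = st.config_tree(pd.DataFrame({"configuration": [a]}))
    assert labs == ["config1"]


def test_detect_inversions_counts_and_orientation():
    ref = cfgstr([("M0", 1), ("A", 1), ("M1", 1), ("B", 1), ("M2", 1)])
    inv = cfgstr([("M0", 1), ("B", -1), ("M1", -1), ("A", -1), ("M2", 1)])
    encs = [(f"h{i}", inv if i < 69 else ref) for i in range(100)]
    calls = st.detect_inversions(encs, ref)
    assert len(calls) == 1
    assert calls[0].allele_frequency == pytest.approx(0.69)
    assert calls[0].orientation["h0"] == "I"
    assert calls[0].orientation["h99"] == "D"
    assert st.detect_inversions([("h", ref)], ref) == []
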