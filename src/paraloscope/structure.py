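"""Locus structural configurations: signed-token encoding, capping-free
DCJ-indel rearrangement distance, configuration clustering and inversion calls.

Configurations are single linear chromosomes of signed tokens (paralogs and
marker genes). Duplicate token names are disambiguated by positional matching
(k-th occurrence in one string pairs with the k-th in the other; leftovers
become indel runs), after which the distance is the double-cut-and-join indel
distance: DCJ operations (including through circular intermediates) and
insertions/deletions of contiguous runs of one-side-private tokens, one unit
of cost each. An exhaustive bidirectional search over the same move set is
provided as the reference for small instances.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo import DistanceMatrix, build_nj


@dataclass(frozen=True)
class ConfigurationString:
    locus_id: str
    tokens: tuple                      # ((name, sign +1/-1), ...)
    haplotypes: tuple = ()
    count: int = 0

    def __post_init__(self):
        for name, sign in self.tokens:
            if sign not in (1, -1):
                raise ValueError("token signs must be +1/-1")

    def __str__(self):
        return " ".join(("" if s > 0 else "-") + n for n, s in self.tokens)


@dataclass
class InversionCall:
    locus_id: str
    left_token: str
    right_token: str
    allele_frequency: float
    inverted_haplotypes: tuple
    orientation: dict                  # haplotype -> 'I' | 'D'
    span_bp: int | None = None
    divergence: float | None = None


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def encode_configuration(copies, markers: pd.DataFrame, locus_id: str,
                         distal: str, proximal: str,
                         min_token_len: int = 1_000
                         ) -> ConfigurationString | None:
    """Signed token string for one haplotype, distal marker leading.

    ``copies`` are labelled LocusCopy objects on the contig; ``markers`` needs
    columns name/start/end/strand. Features below ``min_token_len`` are
    dropped; returns None (locus skipped) when both boundary markers are
    missing.
    """
    feats = []
    for c in copies:
        if c.end - c.start >= min_token_len:
            feats.append((c.start, c.paralog_label or "copy",
                          1 if c.strand == "+" else -1))
    for r in markers.itertuples():
        if r.end - r.start >= min_token_len:
            feats.append((r.start, r.name, 1 if r.strand == "+" else -1))
    feats.sort()
    names = [f[1] for f in feats]
    if distal not in names and proximal not in names:
        return None
    tokens = [(n, s) for _, n, s in feats]
    flip = False
    if distal in names and proximal in names:
        flip = names.index(distal) > names.index(proximal)
    elif distal in names:
        flip = tokens[names.index(distal)][1] < 0
    else:
        flip = tokens[names.index(proximal)][1] < 0
    if flip:
        tokens = [(n, -s) for n, s in reversed(tokens)]
    return ConfigurationString(locus_id, tuple(tokens))


def catalog_configurations(encodings, validated: dict | None = None,
                           min_haplotypes: int = 2,
                           require_validated: bool = True) -> pd.DataFrame:
    """Distinct configurations with counts and frequencies.

    ``encodings`` is a list of (haplotype_id, ConfigurationString-or-None);
    configurations seen in fewer than ``min_haplotypes`` haplotypes, or (when
    required) validated in none, are excluded. Frequencies are over all
    encodable haplotypes.
    """
    groups = {}
    encodable = 0
    for hap, cfg in encodings:
        if cfg is None:
            continue
        encodable += 1
        groups.setdefault((cfg.locus_id, cfg.tokens), []).append(hap)
    rows = []
    for (locus, tokens), haps in groups.items():
        if len(haps) < min_haplotypes:
            continue
        if require_validated and validated is not None:
            if not any(validated.get(h, False) for h in haps):
                continue
        cfg = ConfigurationString(locus, tokens, tuple(sorted(haps)),
                                  len(haps))
        rows.append({"locus_id": locus, "configuration": cfg,
                     "tokens": str(cfg), "count": len(haps),
                     "frequency": len(haps) / encodable if encodable else 0.0,
                     "haplotypes": ",".join(sorted(haps))})
    return (pd.DataFrame(rows)
            .sort_values(["locus_id", "count"], ascending=[True, False])
            .reset_index(drop=True)
            if rows else pd.DataFrame(columns=[
                "locus_id", "configuration", "tokens", "count",
                "frequency", "haplotypes"]))


# ---------------------------------------------------------------------------
# DCJ-indel distance
# ---------------------------------------------------------------------------

def _positional_match(a_tokens, b_tokens):
    """k-th occurrence of a name in one string pairs with the k-th in the
    other; returns token lists over matched ids plus private marker ids."""
    def tag(tokens):
        seen = {}
        out = []
        for name, sign in tokens:
            k = seen.get(name, 0)
            seen[name] = k + 1
            out.append(((name, k), sign))
        return out

    ta, tb = tag(a_tokens), tag(b_tokens)
    ids_a = {i for i, _ in ta}
    ids_b = {i for i, _ in tb}
    shared = ids_a & ids_b
    return ta, tb, shared, ids_a - shared, ids_b - shared


def _adjacencies(tagged, shared, side):
    """Adjacency list for one genome restricted to shared markers.

    Returns a list of (extremity_or_None, extremity_or_None, has_run) where
    None marks a telomere; extremities are (marker_id, 'h'|'t').
    """
    run_pending = False
    adjs = []
    prev_right = None          # right extremity of previous shared marker
    for mid, sign in tagged:
        if mid not in shared:
            run_pending = True
            continue
        left = (mid, "t") if sign > 0 else (mid, "h")
        right = (mid, "h") if sign > 0 else (mid, "t")
        adjs.append((prev_right, left, run_pending))
        run_pending = False
        prev_right = right
    adjs.append((prev_right, None, run_pending))
    return adjs


def dcj_indel_distance(a: ConfigurationString | tuple,
                       b: ConfigurationString | tuple) -> int:
    """Adjacency-graph DCJ-indel distance between two linear configurations:
    d = N - C - I/2 + sum over components of the indel potential
    ceil((lambda+1)/2), where N counts shared markers, C cycles, I odd paths,
    and lambda is the number of runs (maximal same-genome stretches of private
    tokens, empty adjacencies skipped, merged cyclically on cycles) met along
    each component. Exact for marker-anchored configurations (shared boundary
    tokens keep runs off the telomere paths, where inter-path recombination
    corrections would otherwise apply)."""
    at = a.tokens if isinstance(a, ConfigurationString) else tuple(a)
    bt = b.tokens if isinstance(b, ConfigurationString) else tuple(b)
    ta, tb, shared, priv_a, priv_b = _positional_match(at, bt)
    if not shared:
        return (1 if at else 0) + (1 if bt else 0)

    adj_a = _adjacencies(ta, shared, "A")
    adj_b = _adjacencies(tb, shared, "B")

    # vertex = (genome, index into its adjacency list); connect via extremities
    loc = {}
    for g, adjs in (("A", adj_a), ("B", adj_b)):
        for i, (l, r, _) in enumerate(adjs):
            for e in (l, r):
                if e is not None:
                    loc.setdefault(e, {})[g] = i

    N = len(shared)
    C = 0
    I = 0
    run_cost = 0
    seen = set()
    verts = [("A", i) for i in range(len(adj_a))] + \
            [("B", i) for i in range(len(adj_b))]
    adj_of = {"A": adj_a, "B": adj_b}

    def vertex_exts(v):
        g, i = v
        l, r, _ = adj_of[g][i]
        return [e for e in (l, r) if e is not None]

    for v0 in verts:
        if v0 in seen:
            continue
        # walk the component
        comp = []
        # find an endpoint if this is a path
        def neighbors(v):
            g, i = v
            other = "B" if g == "A" else "A"
            return [(other, loc[e][other]) for e in vertex_exts(v)
                    if other in loc.get(e, {})]
        # BFS to collect component
        stack, comp_set = [v0], {v0}
        while stack:
            v = stack.pop()
            for w in neighbors(v):
                if w not in comp_set:
                    comp_set.add(w)
                    stack.append(w)
        seen |= comp_set
        # classify: cycle iff every vertex has 2 neighbours
        degs = {v: len(neighbors(v)) for v in comp_set}
        ends = [v for v, d in degs.items() if d <= 1]
        if not ends:  # cycle
            C += 1
            order = [v0]
            prev = None
            while True:
                nbrs = [w for w in neighbors(order[-1]) if w != prev]
                if not nbrs:
                    break
                prev = order[-1]
                nxt = nbrs[0]
                if nxt == order[0]:
                    break
                order.append(nxt)
            labels = [adj_of[v[0]][v[1]][2] and v[0] for v in order]
            labels = [l for l in labels if l]
            # cyclic merge of equal neighbours
            lam = 0
            if labels:
                merged = [labels[0]]
                for l in labels[1:]:
                    if l != merged[-1]:
                        merged.append(l)
                if len(merged) > 1 and merged[0] == merged[-1]:
                    merged.pop()
                lam = len(merged)
            run_cost += (lam + 2) // 2 if lam else 0
        else:
            # path: count edges; walk from one end
            start = sorted(ends)[0] if ends else v0
            order = [start]
            prev = None
            while True:
                nbrs = [w for w in neighbors(order[-1]) if w != prev]
                if not nbrs:
                    break
                prev = order[-1]
                order.append(nbrs[0])
            edges = len(order) - 1
            if edges % 2 == 1:
                I += 1
            labels = [adj_of[v[0]][v[1]][2] and v[0] for v in order]
            labels = [l for l in labels if l]
            lam = 0
            if labels:
                merged = [labels[0]]
                for l in labels[1:]:
                    if l != merged[-1]:
                        merged.append(l)
                lam = len(merged)
            run_cost += (lam + 2) // 2 if lam else 0
    # the number of odd paths is always even (telomere parity)
    return int(N - C - I // 2 + run_cost)


# ---------------------------------------------------------------------------
# exhaustive reference (small instances)
# ---------------------------------------------------------------------------

def _ext(mid, sign, end):
    # left extremity of +m is its tail; right its head
    if end == "l":
        return (mid, "t") if sign > 0 else (mid, "h")
    return (mid, "h") if sign > 0 else (mid, "t")


def _state_of(tagged):
    adjs = set()
    for (m1, s1), (m2, s2) in zip(tagged, tagged[1:]):
        adjs.add(frozenset({_ext(m1, s1, "r"), _ext(m2, s2, "l")}))
    markers = frozenset(m for m, _ in tagged)
    return frozenset(adjs), markers


def _chromosome_walk(state):
    """Reconstruct chromosomes (list of (marker,sign) sequences, plus a
    circular flag) from an adjacency-set state."""
    adjs, markers = state
    nbr = {}
    for adj in adjs:
        pair = tuple(adj)
        if len(pair) == 2:
            nbr[pair[0]] = pair[1]
            nbr[pair[1]] = pair[0]
        else:
            nbr[pair[0]] = pair[0]
    chroms = []
    visited = set()
    for m in sorted(markers):
        if m in visited:
            continue
        # try to find a telomeric start in this chromosome
        cur, sign = m, 1
        chain = []
        # walk left to a telomere (or back to m if circular)
        steps = 0
        start = (cur, sign)
        while True:
            left = _ext(cur, sign, "l")
            if left not in nbr or nbr[left] == left:
                break
            prev_ext = nbr[left]
            pm, pe = prev_ext
            psign = 1 if pe == "h" else -1
            cur, sign = pm, psign
            steps += 1
            if (cur, sign) == start or steps > len(markers):
                break
        circular = (cur, sign) == start and steps > 0
        # walk right collecting the chromosome
        chain = [(cur, sign)]
        visited.add(cur)
        while True:
            right = _ext(chain[-1][0], chain[-1][1], "r")
            if right not in nbr or nbr[right] == right:
                break
            nxt_ext = nbr[right]
            nm, ne = nxt_ext
            nsign = 1 if ne == "t" else -1
            if nm == chain[0][0]:
                break
            chain.append((nm, nsign))
            visited.add(nm)
            if len(chain) > len(markers):
                break
        chroms.append((chain, circular))
    return chroms


def _indel_successors(state, priv_a, priv_b, all_arrangements):
    out = []
    adjs, markers = state
    # deletions: contiguous same-side-private segments
    for chain, circular in _chromosome_walk(state):
        L = len(chain)
        for i in range(L):
            for j in range(i, L):
                seg = chain[i:j + 1]
                ids = {m for m, _ in seg}
                if not (ids <= priv_a or ids <= priv_b):
                    continue
                seg_exts = {_ext(m, s, e) for m, s in seg for e in ("l", "r")}
                new_adjs = {a for a in adjs if not (a & seg_exts)}
                boundary = [a for a in adjs if a & seg_exts and a - seg_exts]
                outer = [next(iter(a - seg_exts)) for a in boundary]
                if len(outer) == 2:
                    new_adjs.add(frozenset(outer))
                out.append((frozenset(new_adjs), markers - frozenset(ids)))
    # insertions
    absent_a = sorted(priv_a - set(markers))
    absent_b = sorted(priv_b - set(markers))
    for absent in (absent_a, absent_b):
        for size in range(1, min(3, len(absent)) + 1):
            for combo in itertools.combinations(absent, size):
                for arr in all_arrangements(combo):
                    internal = set()
                    for (m1, s1), (m2, s2) in zip(arr, arr[1:]):
                        internal.add(frozenset({_ext(m1, s1, "r"),
                                                _ext(m2, s2, "l")}))
                    first_l = _ext(arr[0][0], arr[0][1], "l")
                    last_r = _ext(arr[-1][0], arr[-1][1], "r")
                    new_markers = markers | frozenset(m for m, _ in arr)
                    # as its own linear chromosome
                    out.append((frozenset(adjs | internal), new_markers))
                    # spliced into an existing adjacency
                    for adj in adjs:
                        pair = tuple(adj)
                        if len(pair) != 2:
                            continue
                        u, v = pair
                        na = (adjs - {adj}) | internal | {
                            frozenset({u, first_l}), frozenset({last_r, v})}
                        out.append((frozenset(na), new_markers))
                    # attached at a telomere
                    used = {e for a in adjs for e in a}
                    telos = [_ext(m, 1, e) for m in markers for e in ("l", "r")
                             if _ext(m, 1, e) not in used]
                    for t in telos:
                        na = set(adjs) | internal | {frozenset({t, first_l})}
                        out.append((frozenset(na), new_markers))
                        na2 = set(adjs) | internal | {frozenset({t, last_r})}
                        out.append((frozenset(na2), new_markers))
    return out


def _dcj_successors(state):
    adjs, markers = state
    out = []
    used = {e for a in adjs for e in a}
    free = [(m, x) for m in sorted(markers) for x in ("t", "h")
            if (m, x) not in used]
    alist = sorted(adjs, key=lambda a: sorted(a))
    for i in range(len(alist)):
        p = tuple(sorted(alist[i]))
        a_, b_ = p
        # cut
        out.append((frozenset(adjs - {alist[i]}), markers))
        for j in range(i + 1, len(alist)):
            q = tuple(sorted(alist[j]))
            c_, d_ = q
            base = adjs - {alist[i], alist[j]}
            out.append((frozenset(base | {frozenset({a_, c_}),
                                          frozenset({b_, d_})}), markers))
            out.append((frozenset(base | {frozenset({a_, d_}),
                                          frozenset({b_, c_})}), markers))
        for t in free:
            base = adjs - {alist[i]}
            out.append((frozenset(base | {frozenset({a_, t})}), markers))
            out.append((frozenset(base | {frozenset({b_, t})}), markers))
    for i in range(len(free)):
        for j in range(i + 1, len(free)):
            out.append((frozenset(adjs | {frozenset({free[i], free[j]})}),
                        markers))
    return out


def dcj_indel_distance_exhaustive(a, b, max_cost: int = 10) -> int:
    """Bidirectional breadth-first search over the DCJ+indel move graph;
    exact on small instances and independent of the closed-form path."""
    at = a.tokens if isinstance(a, ConfigurationString) else tuple(a)
    bt = b.tokens if isinstance(b, ConfigurationString) else tuple(b)
    ta, tb, shared, priv_a, priv_b = _positional_match(at, bt)
    sa, sb = _state_of(ta), _state_of(tb)
    if sa == sb:
        return 0

    def arrangements(combo):
        for perm in itertools.permutations(combo):
            for signs in itertools.product((1, -1), repeat=len(perm)):
                yield list(zip(perm, signs))

    def successors(state):
        yield from _dcj_successors(state)
        yield from _indel_successors(state, priv_a, priv_b, arrangements)

    fa, fb = {sa: 0}, {sb: 0}
    fronts = [{sa}, {sb}]
    dists = [fa, fb]
    level = [0, 0]
    while level[0] + level[1] < max_cost:
        side = 0 if len(fronts[0]) <= len(fronts[1]) else 1
        new = set()
        for st in fronts[side]:
            for nxt in successors(st):
                if nxt not in dists[side]:
                    dists[side][nxt] = level[side] + 1
                    new.add(nxt)
        level[side] += 1
        fronts[side] = new
        hits = [dists[0][s] + dists[1][s] for s in new if s in dists[1 - side]]
        if hits:
            return min(hits)
        if not new:
            break
    raise RuntimeError("no path within max_cost")


# ---------------------------------------------------------------------------
# configuration tree and inversion calls
# ---------------------------------------------------------------------------

def config_tree(catalog: pd.DataFrame):
    """Midpoint-rooted NJ over pairwise DCJ-indel distances; trivial for
    fewer than 3 configurations."""
    configs = list(catalog["configuration"])
    labels = [f"config{i + 1}" for i in range(len(configs))]
    if len(configs) < 3:
        import dendropy
        taxa = dendropy.TaxonNamespace()
        root = dendropy.Node()
        for lab in labels:
            nd = dendropy.Node()
            nd.taxon = taxa.new_taxon(label=lab)
            nd.edge.length = 0.0
            root.add_child(nd)
        t = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
        return t, labels
    n = len(configs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dcj_indel_distance(configs[i], configs[j])
    return build_nj(DistanceMatrix(labels, D)), labels


def detect_inversions(encodings, reference: ConfigurationString
                      ) -> list[InversionCall]:
    """Maximal token intervals reversed and sign-flipped relative to the
    reference configuration, with allele frequencies over encodable haplotypes.

    Only tokens that occur exactly once in the reference and in every
    encodable configuration are compared (copy-number-variable paralogs would
    otherwise make interval keys unstable); these are typically the unique
    marker genes bracketed by family copies.
    """
    encodable = [(h, c) for h, c in encodings if c is not None]

    def name_counts(tokens):
        out = {}
        for n, _ in tokens:
            out[n] = out.get(n, 0) + 1
        return out

    unique = {n for n, c in name_counts(reference.tokens).items() if c == 1}
    for _, cfg in encodable:
        cc = name_counts(cfg.tokens)
        unique = {n for n in unique if cc.get(n, 0) == 1}

    ref_unique = [(n, s) for n, s in reference.tokens if n in unique]
    pos = {n: i for i, (n, _) in enumerate(ref_unique)}
    ref_sign = {n: s for n, s in ref_unique}

    found = {}
    for hap, cfg in encodable:
        seq = [(n, s) for n, s in cfg.tokens if n in unique]
        i = 0
        while i < len(seq):
            n, s = seq[i]
            if s * ref_sign[n] < 0:
                j = i
                while (j + 1 < len(seq)
                       and seq[j + 1][1] * ref_sign[seq[j + 1][0]] < 0
                       and pos[seq[j + 1][0]] == pos[seq[j][0]] - 1):
                    j += 1
                lo, hi = pos[seq[j][0]], pos[seq[i][0]]
                if hi >= lo:
                    found.setdefault((ref_unique[lo][0], ref_unique[hi][0]),
                                     []).append(hap)
                i = j + 1
            else:
                i += 1
    calls = []
    total = len(encodable)
    for (lt, rt), haps in sorted(found.items()):
        orientation = {h: ("I" if h in haps else "D") for h, _ in encodable}
        calls.append(InversionCall(
            locus_id=reference.locus_id, left_token=lt, right_token=rt,
            allele_frequency=len(haps) / total if total else 0.0,
            inverted_haplotypes=tuple(sorted(haps)),
            orientation=orientation))
    return calls
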