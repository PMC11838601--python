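"""Copy discovery in haplotype assemblies, locus validation, collapse flagging
and short-read segment-depth copy-number estimation.

Homology search is shared-k-mer anchor chaining against the ancestral locus
query (adequate below ~10% divergence); coordinates are 0-based half-open
throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kmers import INVALID, kmer_codes, revcomp


@dataclass
class LocusCopy:
    """One gene-family copy on one haplotype."""

    haplotype_id: str
    contig: str
    start: int
    end: int
    strand: str
    sequence: str               # in query (ancestral) orientation
    paralog_label: str | None = None
    validation: str = "untested"
    n_anchors: int = 0
    identity: float = 1.0

    def __post_init__(self):
        if self.end - self.start != len(self.sequence):
            raise ValueError("sequence length must equal end - start")


def _anchor_hits(hap: str, query_codes_sorted, query_pos_of, k: int,
                 stride: int):
    codes = kmer_codes(hap, k)
    if not len(codes):
        return np.empty(0, int), np.empty(0, int)
    sub = np.arange(0, len(codes), stride)
    c = codes[sub]
    ok = c != INVALID
    idx = np.searchsorted(query_codes_sorted, c[ok])
    idx = np.clip(idx, 0, len(query_codes_sorted) - 1)
    hit = query_codes_sorted[idx] == c[ok]
    hpos = sub[ok][hit]
    qpos = np.array([query_pos_of[int(x)] for x in c[ok][hit]], dtype=int)
    return hpos, qpos


def find_copies(haplotype: str, query: str, haplotype_id: str = "hap",
                contig: str | None = None, min_len: int = 15_000,
                max_divergence: float = 0.20, k: int = 21,
                stride: int = 3, merge_gap: int = 5_000) -> list[LocusCopy]:
    """Maximal non-overlapping homologs of ``query`` on both strands.

    Shared-k-mer anchors are clustered along the haplotype (gaps < merge_gap
    join a cluster); each cluster's extent is extrapolated to full query
    boundaries. Identity is estimated from the anchored k-mer fraction f as
    f**(1/k), which is unbiased for uniform substitution divergence. Hits
    shorter than ``min_len`` or below 1 - max_divergence identity are dropped.
    """
    if len(query) < min_len:
        raise ValueError("query shorter than min_len")
    if contig is None:
        contig = haplotype_id
    qlen = len(query)
    n_kmers = qlen - k + 1

    clusters = []
    for strand, qseq in (("+", query), ("-", revcomp(query))):
        codes = kmer_codes(qseq, k)
        pos_of = {}
        for p, c in enumerate(codes):
            if c != INVALID and int(c) not in pos_of:
                pos_of[int(c)] = p
        order = np.sort(codes[codes != INVALID])
        hpos, qpos = _anchor_hits(haplotype, order, pos_of, k, stride)
        if not len(hpos):
            continue
        srt = np.argsort(hpos)
        hpos, qpos = hpos[srt], qpos[srt]
        brk = np.flatnonzero(np.diff(hpos) > merge_gap)
        bounds = np.concatenate([[0], brk + 1, [len(hpos)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            h, q = hpos[a:b], qpos[a:b]
            start = int(max(0, (h - q).min()))
            end = int(min(len(haplotype), (h + (qlen - q)).max()))
            qspan = int(q.max() - q.min()) + k
            frac = min(1.0, len(h) * stride / n_kmers)
            ident = frac ** (1.0 / k)
            clusters.append({"start": start, "end": end, "strand": strand,
                             "n": int(len(h)), "ident": ident,
                             "qspan": qspan})

    # resolve overlaps: keep the cluster with more anchors
    clusters.sort(key=lambda c: (-c["n"], c["start"]))
    kept = []
    for c in clusters:
        if all(c["end"] <= o["start"] or c["start"] >= o["end"] for o in kept):
            kept.append(c)
    out = []
    for c in sorted(kept, key=lambda c: c["start"]):
        # the aligned (anchored) query span decides the length filter; the
        # reported interval extrapolates to full query boundaries
        if (c["qspan"] < min_len or c["end"] - c["start"] < min_len
                or c["ident"] < 1 - max_divergence):
            continue
        seq = haplotype[c["start"]:c["end"]]
        if c["strand"] == "-":
            seq = revcomp(seq)
        out.append(LocusCopy(haplotype_id, contig, c["start"], c["end"],
                             c["strand"], seq, n_anchors=c["n"],
                             identity=c["ident"]))
    return out


def validate_locus(copy: LocusCopy, copies_on_contig: list[LocusCopy],
                   contig_length: int, flank: int = 30_000) -> str:
    """'pass' iff the contig extends >= ``flank`` beyond both copy ends and no
    other detected copy overlaps those flanks."""
    if copy.start < flank or contig_length - copy.end < flank:
        copy.validation = "fail"
        return "fail"
    lo, hi = copy.start - flank, copy.end + flank
    for other in copies_on_contig:
        if other is copy or (other.start, other.end) == (copy.start, copy.end):
            continue
        if other.start < copy.start and other.end > lo:
            copy.validation = "fail"
            return "fail"
        if other.start < hi and other.end > copy.end:
            copy.validation = "fail"
            return "fail"
    copy.validation = "pass"
    return "pass"


# ---------------------------------------------------------------------------
# ancestral-coordinate projection
# ---------------------------------------------------------------------------

def project_to_ancestral(copy_seq: str, query: str, k: int = 21) -> str:
    """Lay a copy out in ancestral (query) coordinates.

    Anchors at shared k-mers are grouped into co-diagonal runs; within a run
    the whole spanned segment is transferred (so substitution positions between
    anchors are preserved); bases with no co-diagonal support (e.g. inside
    insertions or near indel breakpoints) are left as 'N'.
    """
    qlen = len(query)
    out = bytearray(b"N" * qlen)
    qcodes = kmer_codes(query, k)
    pos_of = {}
    for p, c in enumerate(qcodes):
        if c != INVALID:
            pos_of.setdefault(int(c), []).append(p)
    ccodes = kmer_codes(copy_seq, k)
    anchors = []  # (qpos, cpos)
    for cp, code in enumerate(ccodes):
        if code == INVALID:
            continue
        qps = pos_of.get(int(code))
        if qps is not None and len(qps) == 1:
            anchors.append((qps[0], cp))
    anchors.sort()
    cseq = copy_seq.encode()
    run_q0 = run_c0 = None
    prev_q = prev_c = None
    for qp, cp in anchors:
        diag = cp - qp
        if run_q0 is not None and diag == prev_c - prev_q and qp >= prev_q:
            prev_q, prev_c = qp, cp
            continue
        if run_q0 is not None:
            s, e = run_q0, prev_q + k
            out[s:e] = cseq[run_c0:run_c0 + (e - s)]
        run_q0, run_c0 = qp, cp
        prev_q, prev_c = qp, cp
    if run_q0 is not None:
        s, e = run_q0, prev_q + k
        out[s:e] = cseq[run_c0:run_c0 + (e - s)]
    return out.decode()


# ---------------------------------------------------------------------------
# collapse flagging
# ---------------------------------------------------------------------------

def pileup_reads(reads, reference: str, k: int = 21) -> np.ndarray:
    """Ungapped placement of reads by k-mer diagonal voting; returns a
    positions x 4 base-count array (A, C, G, T)."""
    refcodes = kmer_codes(reference, k)
    pos_of = {}
    for p, c in enumerate(refcodes):
        if c != INVALID:
            pos_of.setdefault(int(c), []).append(p)
    L = len(reference)
    counts = np.zeros((L, 4), dtype=np.int32)
    code_of = {65: 0, 67: 1, 71: 2, 84: 3}
    for read in reads:
        seq = read if isinstance(read, str) else read.sequence
        rc = kmer_codes(seq, k)
        votes = {}
        for rp in range(0, len(rc), 4):
            c = rc[rp]
            if c == INVALID:
                continue
            for refp in pos_of.get(int(c), ()):
                d = refp - rp
                votes[d] = votes.get(d, 0) + 1
        if not votes:
            continue
        diag = max(sorted(votes), key=lambda d: votes[d])
        for i, ch in enumerate(seq.encode()):
            p = diag + i
            if 0 <= p < L and ch in code_of:
                counts[p, code_of[ch]] += 1
    return counts


def flag_collapse(pileup: np.ndarray, min_frac: float = 0.10,
                  min_reads: int = 5, cluster_window: int = 500,
                  min_sites: int = 2) -> list[tuple[int, int]]:
    """Intervals where >= ``min_sites`` discordant pileup positions fall within
    ``cluster_window`` bp. A position is discordant when its second-most
    frequent base has count >= min_reads and fraction >= min_frac."""
    if pileup is None or len(pileup) == 0:
        return []
    counts = np.asarray(pileup)
    totals = counts.sum(axis=1)
    part = np.sort(counts, axis=1)
    second = part[:, -2]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(totals > 0, second / totals, 0.0)
    disc = np.flatnonzero((second >= min_reads) & (frac >= min_frac))
    intervals = []
    i = 0
    while i < len(disc):
        j = i
        while j + 1 < len(disc) and disc[j + 1] - disc[i] <= cluster_window:
            j += 1
        if j - i + 1 >= min_sites:
            intervals.append((int(disc[i]), int(disc[j]) + 1))
        i = j + 1
    return intervals


# ---------------------------------------------------------------------------
# read-depth copy number
# ---------------------------------------------------------------------------

def estimate_copy_number(reads, reference: str, control_windows,
                         segment_len: int = 36, max_mismatch: int = 2,
                         window: int = 1_000, excluded_windows=()
                         ) -> pd.DataFrame:
    """fastCN-style copy number: reads are cut into non-overlapping
    ``segment_len`` pieces, each placed at every reference position within
    Hamming distance <= ``max_mismatch`` (fractional weight 1/sites), and
    per-window depth is scaled so the copy-number-2 control windows average 2.
    """
    L = len(reference)
    seed_len = segment_len // (max_mismatch + 1)  # pigeonhole seeding
    seeds = kmer_codes(reference, seed_len)
    order = np.argsort(seeds, kind="stable")
    sorted_codes = seeds[order]
    refbytes = np.frombuffer(reference.encode(), dtype=np.uint8)

    def candidates(segcodes, offsets):
        cand = set()
        for off in offsets:
            c = segcodes[off]
            if c == INVALID:
                continue
            lo = np.searchsorted(sorted_codes, c, "left")
            hi = np.searchsorted(sorted_codes, c, "right")
            for p in order[lo:hi]:
                start = int(p) - off
                if 0 <= start <= L - segment_len:
                    cand.add(start)
        return cand

    depth = np.zeros(L, dtype=float)
    offsets = [i * seed_len for i in range(max_mismatch + 1)]
    for read in reads:
        seq = read if isinstance(read, str) else read.sequence
        for s0 in range(0, len(seq) - segment_len + 1, segment_len):
            seg = seq[s0:s0 + segment_len]
            segb = np.frombuffer(seg.encode(), dtype=np.uint8)
            segcodes = kmer_codes(seg, seed_len)
            sites = []
            for start in candidates(segcodes, offsets):
                mm = int(np.count_nonzero(
                    refbytes[start:start + segment_len] != segb))
                if mm <= max_mismatch:
                    sites.append(start)
            if sites:
                w = 1.0 / len(sites)
                for st in sites:
                    depth[st] += w

    rows = []
    for start in range(0, L, window):
        end = min(start + window, L)
        rows.append({"start": start, "end": end,
                     "depth": float(depth[start:end].sum())})
    tab = pd.DataFrame(rows)
    ctrl = np.zeros(len(tab), dtype=bool)
    for cs, ce in control_windows:
        ctrl |= (tab["start"] < ce) & (tab["end"] > cs)
    ctrl_depth = tab.loc[ctrl, "depth"].mean()
    if not ctrl_depth or np.isnan(ctrl_depth):
        raise ValueError("zero control depth")
    tab["copy_number"] = 2.0 * tab["depth"] / ctrl_depth
    excl = np.zeros(len(tab), dtype=bool)
    for es, ee in excluded_windows:
        excl |= (tab["start"] < ee) & (tab["end"] > es)
    tab["excluded"] = excl
    tab["control"] = ctrl
    return tab


def gene_copy_number(cn_table: pd.DataFrame, gene_interval: tuple[int, int]
                     ) -> float:
    """Gene-level CN: median over non-excluded windows overlapping the gene."""
    gs, ge = gene_interval
    sel = cn_table[(cn_table["start"] < ge) & (cn_table["end"] > gs)
                   & ~cn_table["excluded"]]
    return float(sel["copy_number"].median())
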