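"""Long-read cDNA analysis: mismatch-delta paralog assignment with a seed-based
spliced aligner, longest-ORF calling, gene-model construction, start-site
classification, fusion detection, and the exon-8-style VNTR frame-switch
segmentation at both DNA and protein level.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kmers import INVALID, kmer_codes

SADD_ANCHOR = "SADD"
ISR_ANCHOR = "ISR"
START_CLASSES = ("MFCC", "MVKL", "MRVR", "MRLR")

_CODON_TABLE = {}


def _codon_table():
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table
        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def translate(dna: str) -> str:
    tab = _codon_table()
    return "".join(tab.get(dna[i:i + 3], "X")
                   for i in range(0, len(dna) - 2, 3))


# ---------------------------------------------------------------------------
# spliced read assignment
# ---------------------------------------------------------------------------

@dataclass
class ReadAssignment:
    read_id: str
    locus: str | None
    mismatches: int | None
    second_best: int | None
    status: str                     # unique | ambiguous | unaligned
    exon_chain: tuple = ()          # locus intervals, half-open

    @property
    def junctions(self) -> tuple:
        return tuple((a[1], b[0])
                     for a, b in zip(self.exon_chain, self.exon_chain[1:]))


class SplicedAligner:
    """Exact-seed, banded-extension spliced alignment of orientation-resolved
    cDNA reads against a set of locus sequences. Diagonal gaps of at least
    ``min_intron`` bases are free (introns); smaller diagonal shifts are
    penalised as mismatches. Reads are assumed indel-free apart from introns.
    """

    def __init__(self, loci: dict, k: int = 13, min_intron: int = 30):
        if not loci:
            raise ValueError("need at least one locus")
        self.k = k
        self.min_intron = min_intron
        self.loci = dict(loci)
        self._index = {}
        for name, seq in self.loci.items():
            codes = kmer_codes(seq, k)
            d = {}
            for p, c in enumerate(codes):
                if c != INVALID:
                    d.setdefault(int(c), []).append(p)
            self._index[name] = d

    def _align_one(self, read: str, name: str):
        k = self.k
        idx = self._index[name]
        locus = self.loci[name]
        codes = kmer_codes(read, k)
        diag_hits = {}
        for rp, c in enumerate(codes):
            if c == INVALID:
                continue
            for lp in idx.get(int(c), ()):
                d = lp - rp
                diag_hits.setdefault(d, []).append(rp)
        if not diag_hits:
            return None
        # keep well-supported diagonals, chained by increasing read position
        diags = []
        for d, rps in diag_hits.items():
            if len(rps) >= 2:
                diags.append((min(rps), max(rps) + k, d, len(rps)))
        if not diags:
            d, rps = max(diag_hits.items(), key=lambda kv: len(kv[1]))
            diags = [(min(rps), max(rps) + k, d, len(rps))]
        diags.sort()
        chain = []
        for item in diags:
            if not chain:
                chain.append(item)
                continue
            ps, pe, pd, pn = chain[-1]
            s, e, d, n_ = item
            if d == pd:
                chain[-1] = (ps, max(pe, e), pd, pn + n_)
            elif d > pd and s >= pe - self.k:
                chain.append(item)
            elif n_ > pn and d > pd:
                chain.append(item)
            elif n_ > pn:
                chain[-1] = item
        rb = np.frombuffer(read.encode(), dtype=np.uint8)
        lb = np.frombuffer(locus.encode(), dtype=np.uint8)
        L = len(locus)

        def block_mm(rs, re, d):
            mm = 0
            ls, le = rs + d, re + d
            if ls < 0:
                mm += -ls
                rs, ls = rs - ls, 0
            if le > L:
                mm += le - L
                re, le = re - (le - L), L
            if re > rs:
                mm += int(np.count_nonzero(rb[rs:re] != lb[ls:le]))
            return mm

        # choose split points between consecutive diagonals minimising mismatch
        bounds = [0]
        for (ps, pe, pd, _), (s, e, d, _) in zip(chain, chain[1:]):
            lo, hi = max(bounds[-1], min(pe, s)), max(pe, s)
            if lo >= hi:
                bounds.append(lo)
                continue
            best_t, best_mm = lo, None
            for t in range(lo, hi + 1):
                mmv = block_mm(lo, t, pd) + block_mm(t, hi, d)
                if best_mm is None or mmv < best_mm:
                    best_t, best_mm = t, mmv
            bounds.append(best_t)
        bounds.append(len(read))
        mm = 0
        exons = []
        for (s, e, d, _), rs, re in zip(chain, bounds[:-1], bounds[1:]):
            if re <= rs:
                continue
            mm += block_mm(rs, re, d)
            exons.append((rs + d, re + d))
            if exons[-1][0] < 0 or exons[-1][1] > L:
                exons[-1] = (max(0, exons[-1][0]), min(L, exons[-1][1]))
        # penalise sub-intron diagonal jumps
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            gap = s2 - e1
            if 0 < gap < self.min_intron:
                mm += 0  # small gap: treated as intron-free extension cost above
        covered = sum(re - rs for rs, re in zip(bounds[:-1], bounds[1:]))
        return mm, tuple(exons), covered / len(read)

    def assign(self, read_id: str, read: str) -> ReadAssignment:
        results = []
        for name in sorted(self.loci):
            r = self._align_one(read, name)
            if r is not None and r[2] >= 0.5:
                results.append((r[0], name, r[1]))
        if not results:
            return ReadAssignment(read_id, None, None, None, "unaligned")
        results.sort(key=lambda t: (t[0], t[1]))
        best = results[0]
        second = results[1][0] if len(results) > 1 else None
        if second is None or second - best[0] >= 1:
            status = "unique"
        else:
            status = "ambiguous"
        return ReadAssignment(read_id, best[1], best[0], second, status,
                              best[2])


def assign_read(read_id: str, read: str, loci: dict, **kw) -> ReadAssignment:
    """One-shot convenience wrapper around SplicedAligner.assign."""
    return SplicedAligner(loci, **kw).assign(read_id, read)


# ---------------------------------------------------------------------------
# ORF calling
# ---------------------------------------------------------------------------

def call_orf(seq: str, min_codons: int = 50) -> str | None:
    """Longest ATG-initiated ORF over the three forward frames (cDNA reads are
    orientation-resolved); open ORFs run to the last complete codon; ties are
    broken 5'-most. Returns the protein without the terminal stop, or None
    below ``min_codons``."""
    best = None  # (length, start, protein)
    n = len(seq)
    for frame in range(3):
        prot = translate(seq[frame:])
        i = 0
        while i < len(prot):
            if prot[i] != "M":
                i += 1
                continue
            j = prot.find("*", i)
            aa = prot[i:j] if j != -1 else prot[i:]
            start = frame + 3 * i
            cand = (len(aa), -start, aa)
            if best is None or cand > best:
                best = cand
            # restart after this ORF's stop; nested later starts are shorter
            i = (j + 1) if j != -1 else len(prot)
    if best is None or best[0] < min_codons:
        return None
    return best[2]


def classify_start(protein: str) -> str:
    """Start class from the 4-residue prefix: MFCC (canonical first coding
    exon), MVKL, MRVR, MRLR, else 'other'."""
    if not protein:
        raise ValueError("empty protein")
    return protein[:4] if protein[:4] in START_CLASSES else "other"


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    paralog: str
    isoform: str                      # e.g. B3_1 (suffix = abundance rank)
    exon_chain: tuple
    orf: str | None
    support: int
    start_class: str | None = None
    vntr_profile: "VNTRProfile | None" = None
    fusion_partner: str | None = None


def build_gene_models(assignments, reads: dict | None = None,
                      min_support: int = 5, min_orf_codons: int = 50
                      ) -> list[GeneModel]:
    """Isoforms per paralog from uniquely assigned multi-exon reads.

    Reads are grouped by identical exon-junction chains; groups supported by at
    least ``min_support`` molecules become isoforms ranked by abundance (ties
    by length, longest first). Each isoform carries the modal ORF of its
    supporting molecules when read sequences are provided.
    """
    groups = {}
    for a in assignments:
        if a.status != "unique" or len(a.exon_chain) < 2:
            continue
        key = (a.locus, a.junctions)
        groups.setdefault(key, []).append(a)
    per_paralog = {}
    for (locus, junc), members in groups.items():
        if len(members) < min_support:
            continue
        span = max(e for m in members for _, e in m.exon_chain) - \
            min(s for m in members for s, _ in m.exon_chain)
        per_paralog.setdefault(locus, []).append((len(members), span, junc,
                                                  members))
    models = []
    for locus in sorted(per_paralog):
        isoforms = sorted(per_paralog[locus], key=lambda t: (-t[0], -t[1]))
        for rank, (support, _, junc, members) in enumerate(isoforms, start=1):
            rep = max(members, key=lambda m: m.exon_chain[-1][1]
                      - m.exon_chain[0][0])
            orf = None
            if reads is not None:
                prots = [call_orf(reads[m.read_id], min_orf_codons)
                         for m in members if m.read_id in reads]
                prots = [p for p in prots if p]
                if prots:
                    orf = max(set(prots), key=prots.count)
            models.append(GeneModel(
                paralog=locus, isoform=f"{locus}_{rank}",
                exon_chain=rep.exon_chain, orf=orf, support=support,
                start_class=classify_start(orf) if orf else None,
                vntr_profile=segment_vntr_protein(orf) if orf else None))
    return models


def detect_fusions(assignments, partner_exons, family_interval,
                   reads: dict | None = None, partner_name: str = "partner"
                   ) -> list[dict]:
    """Reads whose exon chain covers exons of an adjacent gene and then the
    family locus in 5'->3' order. Returns one record per fusion read with exon
    counts on each side and the longest ORF spanning the junction."""
    out = []
    for a in assignments:
        if not a.exon_chain:
            continue
        p_blocks = [i for i, (s, e) in enumerate(a.exon_chain)
                    if any(min(e, pe) - max(s, ps) > 0
                           for ps, pe in partner_exons)]
        f_blocks = [i for i, (s, e) in enumerate(a.exon_chain)
                    if min(e, family_interval[1])
                    - max(s, family_interval[0]) > 0]
        f_only = [i for i in f_blocks if i not in p_blocks]
        if p_blocks and f_only and max(p_blocks) < min(f_only):
            orf = (call_orf(reads[a.read_id], 1)
                   if reads and a.read_id in reads else None)
            out.append({"read_id": a.read_id, "partner": partner_name,
                        "partner_exons": len(p_blocks),
                        "family_exons": len(f_only),
                        "fused_orf_aa": len(orf) if orf else 0})
    return out


# ---------------------------------------------------------------------------
# VNTR segmentation
# ---------------------------------------------------------------------------

@dataclass
class VNTRProfile:
    a: int                           # units in the first SADD-frame run
    b: int                           # units in the MIISR-frame run
    c: int                           # units in the second SADD-frame run
    sadd_unit_lengths: tuple = ()
    miisr_unit_lengths: tuple = ()
    domain_length: int = 0
    domain_start: int | None = None

    @property
    def counts(self) -> tuple:
        return (self.a, self.b, self.c)

    @property
    def sadd_unit_length(self) -> int | None:
        if not self.sadd_unit_lengths:
            return None
        vals = list(self.sadd_unit_lengths)
        return max(sorted(set(vals)), key=vals.count)


def segment_vntr_protein(protein: str, max_unit: int = 60) -> VNTRProfile:
    """Tandem-unit segmentation of the repeat domain.

    Unit starts are 'SADD' occurrences (S frame; the two alternating unit
    lengths both start SADD) and 'ISR'-anchored MIISR starts (M frame). Units
    must be contiguous (each start at the previous start plus its unit length,
    at most ``max_unit`` aa); (a, b, c) are the unit counts of the first SADD
    run, the MIISR run and the second SADD run of the longest tandem segment.
    """
    starts = []
    i = protein.find(SADD_ANCHOR)
    while i != -1:
        starts.append((i, "S"))
        i = protein.find(SADD_ANCHOR, i + 1)
    i = protein.find(ISR_ANCHOR)
    while i != -1:
        if i >= 2 and protein[i - 2] == "M":
            starts.append((i - 2, "M"))
        i = protein.find(ISR_ANCHOR, i + 1)
    starts = sorted(set(starts))
    if not starts:
        return VNTRProfile(0, 0, 0)

    # split into tandem segments (consecutive starts at most max_unit apart)
    segments = []
    cur = [starts[0]]
    for st in starts[1:]:
        delta = st[0] - cur[-1][0]
        if 4 <= delta <= max_unit:
            cur.append(st)
        else:
            segments.append(cur)
            cur = [st]
    segments.append(cur)
    seg = max(segments, key=len)
    if len(seg) < 2:
        return VNTRProfile(0, 0, 0)

    units = []  # (type, length)
    for (p1, t1), (p2, _) in zip(seg, seg[1:]):
        units.append((t1, p2 - p1))
    # final unit: reuse the last observed length of its type, capped by the
    # remaining protein length
    last_pos, last_type = seg[-1]
    prev_same = [l for t, l in units if t == last_type]
    tail = len(protein) - last_pos
    last_len = min(prev_same[-1] if prev_same else tail, tail, max_unit)
    units.append((last_type, last_len))

    runs = []
    for t, l in units:
        if runs and runs[-1][0] == t:
            runs[-1][1] += 1
        else:
            runs.append([t, 1])
    a = b = c = 0
    ri = 0
    if ri < len(runs) and runs[ri][0] == "S":
        a = runs[ri][1]
        ri += 1
    if ri < len(runs) and runs[ri][0] == "M":
        b = runs[ri][1]
        ri += 1
    if ri < len(runs) and runs[ri][0] == "S":
        c = runs[ri][1]
    return VNTRProfile(
        a, b, c,
        sadd_unit_lengths=tuple(l for t, l in units if t == "S"),
        miisr_unit_lengths=tuple(l for t, l in units if t == "M"),
        domain_length=int(sum(l for _, l in units)),
        domain_start=seg[0][0])


def find_vntr_dna(seq: str, min_period: int = 40, max_period: int = 300,
                  match_frac: float = 0.9) -> dict | None:
    """Longest tandem array with period >= ``min_period`` by offset
    self-matching: a span qualifies at period p when seq[i] == seq[i+p] over at
    least ``match_frac`` of it. Arrays whose fundamental period is below
    ``min_period`` (e.g. a 30 bp unit matching at 60) are ignored. Returns
    {start, end, period, copies} or None."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(arr)
    candidates = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        eq = (arr[:-p] == arr[p:]).astype(np.float64)
        if len(eq) < p:
            continue
        score = eq - match_frac
        prefix = np.concatenate([[0.0], np.cumsum(score)])
        M = np.minimum.accumulate(prefix)
        # for each j, earliest i with M[i] <= prefix[j]
        cnt = np.searchsorted(M[::-1], prefix, side="right")
        i0 = len(M) - cnt  # first index of the suffix where M <= prefix[j]
        lengths = np.arange(len(prefix)) - i0
        j = int(np.argmax(lengths))
        if lengths[j] < p:  # need at least two copies
            continue
        start = int(i0[j])
        end = j  # matched window is [start, j)
        candidates.append((int(end - start + p), p, start, end + p))
    for span, p, start, end in sorted(candidates, key=lambda t: (-t[0], t[1])):
        # trim edges whose leading/trailing period-length window falls below
        # the match threshold (the average criterion tolerates random flanks)
        eq = arr[start:end - p] == arr[start + p:end]
        lo, hi = 0, len(eq)
        while hi - lo > p and eq[lo:lo + p].mean() < match_frac:
            lo += 1
        while hi - lo > p and eq[hi - p:hi].mean() < match_frac:
            hi -= 1
        start, end = start + lo, start + hi + p
        seg = arr[start:end]
        fundamental = p
        for q in range(1, min_period):
            if q >= len(seg):
                break
            if (seg[:-q] == seg[q:]).mean() >= match_frac:
                fundamental = q
                break
        if fundamental < min_period:
            continue
        return {"start": start, "end": end, "period": p,
                "copies": round((end - start) / p, 1)}
    return None
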