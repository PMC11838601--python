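"""Synthetic haplotype assemblies, variant pools and read sets for a high-identity
multicopy gene family, with a machine-readable truth set.

The generator emulates the structure of an interspersed segmental-duplication
family: a ~20 kbp ancestral duplicon present in a variable number of copies per
haplotype, 0.3-5% inter-paralog divergence organised as subfamily + paralog
private substitutions, interlocus gene conversion (IGC) tracts copied between
paralogs, inversion polymorphisms that reorder marker genes, an in-frame
amino-acid VNTR with a SADD->MIISR->SADD frame-switch structure in one
subfamily, and paralog-specific transcript pools.

Within copies the mutation model is substitutions only; the only length changes
are the configured VNTR insertions, so every copy is colinear with the
ancestral locus outside its recorded inserts and PSV bookkeeping stays exact.
Random streams are namespaced per component so adding one feature never
perturbs another's draws.
"""
from __future__ import annotations

import json
import zlib
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._kmers import revcomp
from .selection import VariantMatrix

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
STOP_CODONS = {"TAA", "TAG", "TGA"}

# one fixed codon per amino acid (frequent human codons), for reverse-translating
# the repeat motifs into in-frame DNA units
CODON = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC", "G": "GGC",
    "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG", "M": "ATG", "N": "AAC",
    "P": "CCC", "Q": "CAG", "R": "AGA", "S": "AGC", "T": "ACC", "V": "GTG",
    "W": "TGG", "Y": "TAC",
}

# exon-8 style repeat motifs: two SADD-frame unit lengths (alternating) and the
# MIISR-frame unit
SADD_UNIT_19 = "SADDNLKTPSERQLTPLPP"
SADD_UNIT_23 = "SADDNIKTPAERLRGPLPPSAPP"
MIISR_UNIT_25 = "MIISRHLPSVSSLPFHPQLHPQQMI"

START_PREFIX = {
    "MFCC": "MFCC", "MVKL": "MVKL", "MRVR": "MRVR", "MRLR": "MRLR",
}


class ConfigError(ValueError):
    pass


def reverse_translate(protein: str) -> str:
    return "".join(CODON[aa] for aa in protein)


def _rng(seed: int, stream: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng(
        [int(seed) & 0x7FFFFFFF, zlib.crc32(stream.encode()), *map(int, extra)]
    )


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return BASES[rng.integers(0, 4, size=n)].tobytes().decode()


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class VNTRSpec:
    """In-frame amino-acid VNTR inserted into one paralog's final coding exon.

    The array is built as a SADD-frame run of ``a`` units (the 19- and 23-residue
    unit types alternating), a MIISR-frame run of ``b`` units, and a second
    SADD-frame run of ``c`` units. Unit DNA lengths are divisible by 3.
    """

    paralog: str = "B3"
    insert_at: int = 15_000  # ancestral coordinate, codon-aligned with the CDS
    a_range: tuple[int, int] = (7, 15)
    b_range: tuple[int, int] = (6, 14)
    c_range: tuple[int, int] = (5, 11)
    sadd_units: tuple[str, str] = (SADD_UNIT_19, SADD_UNIT_23)
    miisr_unit: str = MIISR_UNIT_25

    def array_dna(self, a: int, b: int, c: int) -> str:
        s0 = reverse_translate(self.sadd_units[0])
        s1 = reverse_translate(self.sadd_units[1])
        m = reverse_translate(self.miisr_unit)
        sadd = lambda k: "".join(s0 if i % 2 == 0 else s1 for i in range(k))
        return sadd(a) + m * b + sadd(c)


@dataclass
class InversionSpec:
    locus_id: str
    left_marker: str
    right_marker: str
    af: float

    def __post_init__(self):
        if not 0.0 <= self.af <= 1.0:
            raise ConfigError(f"inversion AF {self.af} outside [0, 1]")


@dataclass
class SimConfig:
    """Study conditions for the default synthetic family.

    Defaults model 20 diploid samples from two populations, a single locus with
    six paralogs in two subfamilies (A/B) at ~2% inter-paralog divergence and
    0.1% within-paralog diversity, one segregating inversion polymorphism, one
    expected IGC event per haplotype restricted to within-subfamily exchange,
    and a frame-switching VNTR in paralog B3.
    """

    seed: int = 0
    n_samples: int = 20
    populations: dict = field(default_factory=lambda: {"AFR": 10, "EUR": 10})
    ancestral_locus_length: int = 20_000
    subfamily: dict = field(default_factory=lambda: {
        "A1": "A", "A2": "A", "A3": "A", "B1": "B", "B2": "B", "B3": "B"})
    subfamily_divergence: float = 0.008
    paralog_divergence: dict = field(default_factory=lambda: {
        "A1": 0.010, "A2": 0.010, "A3": 0.010,
        "B1": 0.010, "B2": 0.010, "B3": 0.010})
    copy_divergence: float = 0.001
    locus_templates: dict = field(default_factory=lambda: {
        "L1": ["M0", "A1", "M1", "A2", "M2", "A3", "M3",
               "B1", "M4", "B2", "M5", "B3", "M6"]})
    cn_distribution: dict = field(default_factory=lambda: {
        "A1": {1: 1.0},
        "A2": {1: 0.6, 2: 0.4},
        "A3": {0: 0.3, 1: 0.5, 2: 0.2},
        "B1": {1: 1.0},
        "B2": {1: 0.5, 2: 0.3, 3: 0.2},
        "B3": {0: 0.2, 1: 0.8}})
    marker_length: int = 2_000
    spacer_length: int = 35_000
    igc_rate: float = 1.0
    igc_tract_mean: float = 3_000.0
    igc_tract_min: int = 500
    igc_within_subfamily: bool = True
    inversions: list = field(default_factory=lambda: [
        InversionSpec("L1", "M2", "M4", 0.4)])
    vntr: VNTRSpec | None = field(default_factory=VNTRSpec)
    # gene model shared by all paralogs (ancestral coordinates); exon lengths are
    # multiples of 3 so every exon starts on a codon boundary
    exons: list = field(default_factory=lambda: [
        (1_000, 1_300), (3_000, 3_600), (6_000, 6_900), (13_800, 16_500)])
    start_class: dict = field(default_factory=lambda: {
        "A1": "MFCC", "A2": "MVKL", "A3": "MRVR",
        "B1": "MRLR", "B2": "MRLR", "B3": "MVKL"})
    theta: float = 10.0
    sweep_freq: float = 0.75
    expression_rates: dict = field(default_factory=lambda: _default_expression())
    read_length: int = 100
    read_error_rate: float = 0.005
    depth: float = 20.0

    @property
    def paralogs(self) -> list[str]:
        return sorted(self.paralog_divergence)

    @property
    def markers(self) -> list[str]:
        out = []
        for toks in self.locus_templates.values():
            out.extend(t for t in toks if t not in self.paralog_divergence)
        return sorted(set(out))

    def validate(self) -> None:
        for locus, toks in self.locus_templates.items():
            for t in toks:
                if t in self.paralog_divergence:
                    continue
                if not t.startswith("M"):
                    raise ConfigError(f"token {t!r} in {locus} is neither a "
                                      "configured paralog nor a marker")
        for p in self.cn_distribution:
            if p not in self.paralog_divergence:
                raise ConfigError(f"CN distribution for unknown paralog {p!r}")
            for cn, pr in self.cn_distribution[p].items():
                if cn < 0 or not 0 <= pr <= 1:
                    raise ConfigError("CN >= 0 and probabilities in [0,1] required")
        if self.vntr is not None:
            if self.vntr.paralog not in self.paralog_divergence:
                raise ConfigError("VNTR paralog not in the paralog set")
            for u in (*self.vntr.sadd_units, self.vntr.miisr_unit):
                if (3 * len(u)) % 3 != 0:
                    raise ConfigError("VNTR unit length must be divisible by 3")
        if sum(self.populations.values()) != self.n_samples:
            raise ConfigError("population sizes must sum to n_samples")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "inversions" in raw:
            raw["inversions"] = [InversionSpec(**d) for d in raw["inversions"]]
        if "vntr" in raw and raw["vntr"] is not None:
            raw["vntr"] = VNTRSpec(**raw["vntr"])
        if "cn_distribution" in raw:
            raw["cn_distribution"] = {
                p: {int(k): float(v) for k, v in d.items()}
                for p, d in raw["cn_distribution"].items()}
        if "exons" in raw:
            raw["exons"] = [tuple(e) for e in raw["exons"]]
        return cls(**raw)


def _default_expression() -> dict:
    tissues = ["brain", "cerebellum", "heart", "kidney", "liver", "lung",
               "muscle", "ovary", "pancreas", "spleen", "testis", "thymus"]
    rates = {p: {t: 1.0 for t in tissues}
             for p in ["A1", "A2", "A3", "B1", "B2", "B3"]}
    for t in tissues:
        rates["B3"][t] = 5.0 if t == "brain" else 1.0
    return rates


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Ground truth emitted by the simulator; the oracle for acceptance tests."""

    copy_table: pd.DataFrame          # haplotype x paralog CN
    copy_coordinates: pd.DataFrame    # one row per emitted copy
    copy_sequences: dict              # copy_id -> sequence in ancestral orientation
    igc_events: pd.DataFrame
    inversion_states: pd.DataFrame
    samples: pd.DataFrame
    paralog_consensus: dict
    ancestral: str
    exons: list
    expression_proportions: pd.DataFrame | None = None

    def verify(self, assemblies: dict) -> None:
        """Re-extract every copy from the emitted FASTA; must match exactly."""
        for row in self.copy_coordinates.itertuples():
            seg = assemblies[row.contig][row.start:row.end]
            if row.strand == "-":
                seg = revcomp(seg)
            if seg != self.copy_sequences[row.copy_id]:
                raise AssertionError(f"regeneration mismatch for {row.copy_id}")

    def copy_inserts(self, copy_id: str) -> list:
        raw = self.copy_coordinates.set_index("copy_id").loc[copy_id, "inserts"]
        return json.loads(raw)

    def to_ancestral(self, copy_id: str) -> str:
        """Copy sequence with recorded inserts removed (ancestral coordinates)."""
        seq = self.copy_sequences[copy_id]
        for pos, ln in reversed(self.copy_inserts(copy_id)):
            seq = seq[:pos] + seq[pos + ln:]
        return seq

    def copy_transcript(self, copy_id: str, exon_subset=None) -> tuple[str, list]:
        """Spliced transcript of one copy; exons covering a recorded insert
        stretch to include it. Returns (sequence, exon intervals on the copy)."""
        inserts = self.copy_inserts(copy_id)
        exons = exon_subset if exon_subset is not None else self.exons
        seq = self.copy_sequences[copy_id]
        chain = []
        for (s, e) in exons:
            cs, ce = s, e
            for ipos, iln in inserts:
                if ipos <= s:
                    cs += iln
                    ce += iln
                elif s < ipos < e:
                    ce += iln
            chain.append((cs, ce))
        return "".join(seq[s:e] for s, e in chain), chain


# ---------------------------------------------------------------------------
# sequence construction helpers
# ---------------------------------------------------------------------------

class _CDSMap:
    """Codon-boundary bookkeeping for stop-avoiding substitutions."""

    def __init__(self, exons):
        self.exons = sorted(exons)
        self.starts = [s for s, _ in self.exons]

    def exon_of(self, pos: int):
        i = bisect_right(self.starts, pos) - 1
        if i >= 0 and self.exons[i][0] <= pos < self.exons[i][1]:
            return self.exons[i]
        return None

    def codon_start(self, pos: int):
        ex = self.exon_of(pos)
        if ex is None:
            return None
        return ex[0] + 3 * ((pos - ex[0]) // 3)

    def snap(self, start: int, end: int) -> tuple[int, int]:
        """Snap an interval outward to codon boundaries where it cuts a codon."""
        cs = self.codon_start(start)
        if cs is not None:
            start = cs
        ce = self.codon_start(end - 1)
        if ce is not None:
            end = ce + 3
        return start, end


def _substitute(seq: bytearray, positions, rng: np.random.Generator,
                cds: _CDSMap | None) -> None:
    bases = b"ACGT"
    for pos in positions:
        cur = seq[pos]
        cands = [b for b in bases if b != cur]
        if cds is not None:
            cstart = cds.codon_start(int(pos))
            if cstart is not None:
                ok = []
                for b in cands:
                    codon = bytearray(seq[cstart:cstart + 3])
                    codon[pos - cstart] = b
                    if codon.decode() not in STOP_CODONS:
                        ok.append(b)
                cands = ok or cands
        seq[pos] = cands[rng.integers(0, len(cands))]


def _mutated(base: str, rate: float, rng, cds) -> str:
    n = rng.binomial(len(base), rate)
    arr = bytearray(base.encode())
    if n:
        pos = np.sort(rng.choice(len(base), size=n, replace=False))
        _substitute(arr, pos, rng, cds)
    return arr.decode()


def _build_ancestor(cfg: SimConfig, rng) -> str:
    seq = bytearray(_random_dna(rng, cfg.ancestral_locus_length).encode())
    # overwrite exons with one contiguous stop-free CDS: ATG ... internal
    # non-stop codons ... TAA
    total = sum(e - s for s, e in cfg.exons)
    if total % 3 != 0:
        raise ConfigError("total exon length must be a multiple of 3")
    ncod = total // 3
    non_stop = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                if a + b + c not in STOP_CODONS]
    idx = rng.integers(0, len(non_stop), size=ncod)
    codons = [non_stop[i] for i in idx]
    codons[0] = "ATG"
    codons[-1] = "TAA"
    cds = "".join(codons).encode()
    off = 0
    for s, e in sorted(cfg.exons):
        seq[s:e] = cds[off:off + (e - s)]
        off += e - s
    return seq.decode()


def _paralog_consensuses(cfg: SimConfig, anc: str) -> dict:
    cdsmap = _CDSMap(cfg.exons)
    subfams = sorted(set(cfg.subfamily.get(p, p) for p in cfg.paralogs))
    sub_seq = {}
    for sf in subfams:
        rng = _rng(cfg.seed, "subfamily", zlib.crc32(sf.encode()))
        sub_seq[sf] = _mutated(anc, cfg.subfamily_divergence, rng, cdsmap)
    out = {}
    cds_start = sorted(cfg.exons)[0][0]
    for p in cfg.paralogs:
        rng = _rng(cfg.seed, "paralog", zlib.crc32(p.encode()))
        base = sub_seq[cfg.subfamily.get(p, p)]
        seq = bytearray(_mutated(base, cfg.paralog_divergence[p],
                                 rng, cdsmap).encode())
        cls = cfg.start_class.get(p)
        if cls:
            prefix = reverse_translate(START_PREFIX[cls]).encode()
            seq[cds_start:cds_start + len(prefix)] = prefix
        out[p] = seq.decode()
    return out


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

@dataclass
class FamilySim:
    config: SimConfig
    assemblies: dict            # haplotype id -> sequence
    annotations: pd.DataFrame   # contig, type, name, start, end, strand
    truth: SimTruth

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "assemblies.fasta", "w") as fa:
            for hap, seq in self.assemblies.items():
                fa.write(f">{hap}\n")
                for i in range(0, len(seq), 80):
                    fa.write(seq[i:i + 80] + "\n")
        write_gff3(self.annotations, outdir / "annotations.gff3")
        self.truth.copy_table.to_csv(outdir / "truth_copy_table.tsv", sep="\t")
        self.truth.copy_coordinates.to_csv(
            outdir / "truth_copies.tsv", sep="\t", index=False)
        self.truth.igc_events.to_csv(
            outdir / "truth_igc.tsv", sep="\t", index=False)
        self.truth.inversion_states.to_csv(
            outdir / "truth_inversions.tsv", sep="\t", index=False)
        self.truth.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        with open(outdir / "truth_meta.json", "w") as fh:
            json.dump({"exons": self.truth.exons,
                       "seed": self.config.seed}, fh, indent=1)


def write_gff3(ann: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in ann.iterrows():
            fh.write(f"{r['contig']}\tparaloscope\t{r['type']}\t{r['start'] + 1}"
                     f"\t{r['end']}\t.\t{r['strand']}\t.\t"
                     f"Name={r['name']};ID={r['name']}\n")


def read_gff3(path) -> pd.DataFrame:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
        rows.append({"contig": f[0], "type": f[2], "start": int(f[3]) - 1,
                     "end": int(f[4]), "strand": f[6],
                     "name": attrs.get("Name", attrs.get("ID", ""))})
    return pd.DataFrame(rows)


def simulate_family(cfg: SimConfig) -> FamilySim:
    """Generate per-haplotype assemblies, marker annotations and the truth set."""
    cfg.validate()
    anc = _build_ancestor(cfg, _rng(cfg.seed, "ancestor"))
    consensus = _paralog_consensuses(cfg, anc)
    cdsmap = _CDSMap(cfg.exons)

    mrng = _rng(cfg.seed, "marker")
    marker_seq = {m: _random_dna(mrng, cfg.marker_length) for m in cfg.markers}

    samples, haps = [], []
    pop_of = {}
    i = 0
    for pop, npop in sorted(cfg.populations.items()):
        for _ in range(npop):
            sid = f"S{i:03d}"
            samples.append({"sample": sid, "population": pop,
                            "hap1": f"{sid}_h1", "hap2": f"{sid}_h2"})
            pop_of[sid] = pop
            haps.extend([f"{sid}_h1", f"{sid}_h2"])
            i += 1

    assemblies = {}
    ann_rows, copy_rows, igc_rows, inv_rows = [], [], [], []
    copy_seqs = {}
    cn_rows = {}

    paralog_set = set(cfg.paralogs)
    by_subfam = {}
    for p in cfg.paralogs:
        by_subfam.setdefault(cfg.subfamily.get(p, p), []).append(p)

    for hidx, hap in enumerate(haps):
        rng_cn = _rng(cfg.seed, "cn", hidx)
        rng_copy = _rng(cfg.seed, "copy", hidx)
        rng_igc = _rng(cfg.seed, "igc", hidx)
        rng_inv = _rng(cfg.seed, "inversion", hidx)
        rng_sp = _rng(cfg.seed, "spacer", hidx)
        rng_vntr = _rng(cfg.seed, "vntr", hidx)

        cn = {p: 0 for p in cfg.paralogs}
        pieces = []  # dicts: kind, name, seq, strand, meta
        for locus, tokens in sorted(cfg.locus_templates.items()):
            for tok in tokens:
                if tok in paralog_set:
                    dist = cfg.cn_distribution.get(tok, {1: 1.0})
                    ks = sorted(dist)
                    probs = np.array([dist[k] for k in ks], dtype=float)
                    probs /= probs.sum()
                    n_copies = int(ks[rng_cn.choice(len(ks), p=probs)])
                    for ci in range(n_copies):
                        seq = _mutated(consensus[tok], cfg.copy_divergence,
                                       rng_copy, cdsmap)
                        pieces.append({"kind": "copy", "name": tok, "seq": seq,
                                       "strand": "+", "locus": locus,
                                       "inserts": [], "igc": []})
                        cn[tok] += 1
                else:
                    pieces.append({"kind": "marker", "name": tok,
                                   "seq": marker_seq[tok], "strand": "+",
                                   "locus": locus, "inserts": [], "igc": []})

        # IGC: whole-tract replacement from the donor paralog consensus
        copies = [p for p in pieces if p["kind"] == "copy"]
        n_events = rng_igc.poisson(cfg.igc_rate)
        for _ in range(n_events):
            if not copies:
                break
            acc = copies[rng_igc.integers(0, len(copies))]
            if cfg.igc_within_subfamily:
                pool = [q for q in by_subfam[cfg.subfamily.get(acc["name"],
                                                               acc["name"])]
                        if q != acc["name"]]
            else:
                pool = [q for q in cfg.paralogs if q != acc["name"]]
            if not pool:
                continue
            donor = pool[rng_igc.integers(0, len(pool))]
            L = cfg.ancestral_locus_length
            tlen = max(cfg.igc_tract_min,
                       int(round(rng_igc.exponential(cfg.igc_tract_mean))))
            tlen = min(tlen, L - 1)
            start = int(rng_igc.integers(0, L - tlen))
            start, end = cdsmap.snap(start, start + tlen)
            end = min(end, L)
            seq = acc["seq"]
            acc["seq"] = seq[:start] + consensus[donor][start:end] + seq[end:]
            acc["igc"].append({"donor": donor, "start": start, "end": end})

        # VNTR insertion into designated paralog copies
        if cfg.vntr is not None:
            v = cfg.vntr
            for piece in copies:
                if piece["name"] != v.paralog:
                    continue
                a = int(rng_vntr.integers(v.a_range[0], v.a_range[1] + 1))
                b = int(rng_vntr.integers(v.b_range[0], v.b_range[1] + 1))
                c = int(rng_vntr.integers(v.c_range[0], v.c_range[1] + 1))
                arr = v.array_dna(a, b, c)
                piece["seq"] = (piece["seq"][:v.insert_at] + arr
                                + piece["seq"][v.insert_at:])
                piece["inserts"].append((v.insert_at, len(arr)))
                piece["vntr"] = (a, b, c)

        # inversion polymorphisms: reverse-complement the spanned piece interval
        for inv_idx, inv in enumerate(cfg.inversions):
            inverted = bool(rng_inv.random() < inv.af)
            inv_rows.append({"haplotype": hap, "locus_id": inv.locus_id,
                             "inversion": inv_idx, "inverted": inverted})
            if not inverted:
                continue
            idx = {p["name"]: i for i, p in enumerate(pieces)
                   if p["locus"] == inv.locus_id and p["kind"] == "marker"}
            li, ri = idx[inv.left_marker], idx[inv.right_marker]
            mid = pieces[li + 1:ri]
            for p in mid:
                p["seq"] = revcomp(p["seq"])
                p["strand"] = "-" if p["strand"] == "+" else "+"
            pieces[li + 1:ri] = mid[::-1]

        # assemble with unique spacers
        parts = [_random_dna(rng_sp, cfg.spacer_length)]
        pos = cfg.spacer_length
        ci = 0
        for piece in pieces:
            start, end = pos, pos + len(piece["seq"])
            if piece["kind"] == "copy":
                cid = f"{hap}:{piece['locus']}:{ci}"
                ci += 1
                seq_anc = (revcomp(piece["seq"]) if piece["strand"] == "-"
                           else piece["seq"])
                copy_seqs[cid] = seq_anc
                copy_rows.append({
                    "copy_id": cid, "haplotype": hap, "contig": hap,
                    "locus_id": piece["locus"], "paralog": piece["name"],
                    "start": start, "end": end, "strand": piece["strand"],
                    "inserts": json.dumps(piece["inserts"]),
                    "vntr": json.dumps(piece.get("vntr"))})
                for ev in piece["igc"]:
                    igc_rows.append({"copy_id": cid, "haplotype": hap,
                                     "acceptor": piece["name"], **ev})
                ann_rows.append({"contig": hap, "type": "family_copy",
                                 "name": cid, "start": start, "end": end,
                                 "strand": piece["strand"]})
            else:
                ann_rows.append({"contig": hap, "type": "marker_gene",
                                 "name": piece["name"], "start": start,
                                 "end": end, "strand": piece["strand"]})
            parts.append(piece["seq"])
            parts.append(_random_dna(rng_sp, cfg.spacer_length))
            pos = end + cfg.spacer_length
        assemblies[hap] = "".join(parts)
        cn_rows[hap] = cn

    copy_table = pd.DataFrame.from_dict(cn_rows, orient="index")
    copy_table = copy_table[cfg.paralogs]
    copy_table.index.name = "haplotype"

    truth = SimTruth(
        copy_table=copy_table,
        copy_coordinates=pd.DataFrame(copy_rows),
        copy_sequences=copy_seqs,
        igc_events=pd.DataFrame(
            igc_rows, columns=["copy_id", "haplotype", "acceptor",
                               "donor", "start", "end"]),
        inversion_states=pd.DataFrame(inv_rows),
        samples=pd.DataFrame(samples),
        paralog_consensus=consensus,
        ancestral=anc,
        exons=[list(e) for e in sorted(cfg.exons)],
    )
    truth.verify(assemblies)
    ann = pd.DataFrame(ann_rows)
    return FamilySim(config=cfg, assemblies=assemblies,
                     annotations=ann, truth=truth)


# ---------------------------------------------------------------------------
# transcript pools
# ---------------------------------------------------------------------------

def transcript_pool(cfg: SimConfig, consensus: dict | None = None,
                    include_vntr: bool = False) -> dict:
    """Per-paralog isoform sequences spliced from the paralog consensuses.

    Isoform 1 uses all exons; isoform 2 skips the second exon. By default the
    repeat array is left out of the VNTR paralog's isoforms: tandem-repeat
    sequence is internally multi-copy, so its k-mers occupy many transcript
    positions and would make that paralog disproportionately classifiable in
    k-mer quantification. With ``include_vntr`` the paralog carries a
    mid-range array in both isoforms.
    """
    if consensus is None:
        anc = _build_ancestor(cfg, _rng(cfg.seed, "ancestor"))
        consensus = _paralog_consensuses(cfg, anc)
    exons = sorted(cfg.exons)
    out = {}
    for p, seq in consensus.items():
        if include_vntr and cfg.vntr is not None and p == cfg.vntr.paralog:
            v = cfg.vntr
            a = (v.a_range[0] + v.a_range[1]) // 2
            b = (v.b_range[0] + v.b_range[1]) // 2
            c = (v.c_range[0] + v.c_range[1]) // 2
            arr = v.array_dna(a, b, c)
            seq = seq[:v.insert_at] + arr + seq[v.insert_at:]
            shift = len(arr)
            ex = [(s, e) if e <= v.insert_at else (s, e + shift)
                  for (s, e) in exons]
        else:
            ex = exons
        iso1 = "".join(seq[s:e] for s, e in ex)
        iso2 = "".join(seq[s:e] for i, (s, e) in enumerate(ex) if i != 1)
        out[p] = {f"{p}_1": iso1, f"{p}_2": iso2}
    return out


# ---------------------------------------------------------------------------
# coalescent windows
# ---------------------------------------------------------------------------

def simulate_coalescent_window(n: int, theta: float, mode: str = "neutral",
                               seed: int = 0, length: int = 30_000,
                               sweep_freq: float = 0.75,
                               rng: np.random.Generator | None = None
                               ) -> VariantMatrix:
    """One non-recombining window under the infinite-sites model.

    ``neutral`` draws a standard Kingman coalescent; ``star`` models an
    ongoing hard sweep in which a carrier fraction ``sweep_freq`` (default
    3/4) of haplotypes coalesces simultaneously in a star with short terminal
    branches (0.01 coalescent units), the carrier-clade root then joining the
    remaining lineages in a neutral coalescent. The default fraction leaves
    enough non-carrier lineages for polarized haplotype statistics to have
    scorable sites while keeping the site-frequency spectrum strongly skewed
    to rare alleles. ``sweep_freq=1.0`` is the literal pure star genealogy
    with unit terminal branches (every variant a singleton). Mutations are Poisson(theta/2 x total branch length) so
    E[pairwise differences] = theta under neutrality.
    """
    if n < 2:
        raise ValueError("need n >= 2 haplotypes")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    if rng is None:
        rng = _rng(seed, "coalescent")

    branches = []  # (tip frozenset, length)

    def neutral_coalescent(lineages):
        t = 0.0
        active = {i: (set(tips), t0) for i, (tips, t0) in enumerate(lineages)}
        nxt = len(active)
        t = max(t0 for _, t0 in active.values()) if active else 0.0
        # all lineages enter at their own start time; with our uses they share it
        while len(active) > 1:
            k = len(active)
            t += rng.exponential(2.0 / (k * (k - 1)))
            keys = sorted(active)
            i, j = rng.choice(len(keys), size=2, replace=False)
            a, b = keys[min(i, j)], keys[max(i, j)]
            for key in (a, b):
                tips, t0 = active[key]
                branches.append((frozenset(tips), t - t0))
            merged = active[a][0] | active[b][0]
            del active[a], active[b]
            active[nxt] = (merged, t)
            nxt += 1

    if mode == "neutral":
        neutral_coalescent([({i}, 0.0) for i in range(n)])
    elif mode == "star":
        if not 0 < sweep_freq <= 1:
            raise ValueError("sweep_freq in (0, 1]")
        m = max(2, int(round(sweep_freq * n)))
        if m >= n:
            for i in range(n):
                branches.append((frozenset({i}), 1.0))
        else:
            eps = 0.01
            for i in range(m):
                branches.append((frozenset({i}), eps))
            lineages = [(set(range(m)), eps)]
            lineages += [({i}, eps) for i in range(m, n)]
            neutral_coalescent(lineages)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    total = sum(l for _, l in branches)
    nmut = rng.poisson(theta / 2.0 * total) if total > 0 else 0
    positions = np.sort(rng.choice(length, size=min(nmut, length),
                                   replace=False)) if nmut else np.array([], int)
    S = len(positions)
    geno = np.zeros((n, S), dtype=np.uint8)
    if S:
        lens = np.array([l for _, l in branches])
        probs = lens / lens.sum()
        which = rng.choice(len(branches), size=S, p=probs)
        for col, bi in enumerate(which):
            for tip in branches[bi][0]:
                geno[tip, col] = 1
        keep = (geno.sum(axis=0) > 0) & (geno.sum(axis=0) < n)
        geno, positions = geno[:, keep], positions[keep]
    return VariantMatrix(contig="sim", positions=np.asarray(positions, int),
                         genotypes=geno,
                         ancestral=np.zeros(geno.shape[1], dtype=np.int8),
                         haplotypes=[f"h{i}" for i in range(n)])


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

@dataclass
class SimRead:
    read_id: str
    sequence: str
    source: str


def _add_errors(seq: str, error_rate: float, rng) -> str:
    if error_rate <= 0:
        return seq
    n = rng.binomial(len(seq), error_rate)
    if not n:
        return seq
    arr = bytearray(seq.encode())
    pos = rng.choice(len(seq), size=n, replace=False)
    for p in pos:
        cands = [b for b in b"ACGT" if b != arr[p]]
        arr[p] = cands[rng.integers(0, 3)]
    return arr.decode()


def simulate_reads(sources, mode: str = "short", read_length: int = 100,
                   depth: float | None = None, n_reads: int | None = None,
                   weights=None, error_rate: float = 0.0, seed: int = 0,
                   rng: np.random.Generator | None = None) -> list:
    """Short fixed-length substrings or long full-length copies with
    substitution errors; every read carries its source identity."""
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate in [0, 1)")
    items = list(sources.items()) if isinstance(sources, dict) else list(sources)
    if not items:
        raise ValueError("empty source pool")
    if rng is None:
        rng = _rng(seed, "reads")
    reads = []
    if mode == "short":
        if n_reads is not None:
            w = (np.array([len(s) for _, s in items], float)
                 if weights is None else np.asarray(weights, float))
            w = w / w.sum()
            counts = rng.multinomial(n_reads, w)
        elif depth is not None:
            counts = [int(round(depth * len(s) / read_length)) for _, s in items]
        else:
            raise ValueError("short mode needs depth or n_reads")
        rid = 0
        for (name, seq), cnt in zip(items, counts):
            if len(seq) < read_length:
                continue
            starts = rng.integers(0, len(seq) - read_length + 1, size=cnt)
            for st in starts:
                r = _add_errors(seq[st:st + read_length], error_rate, rng)
                reads.append(SimRead(f"r{rid}", r, name))
                rid += 1
    elif mode == "long":
        if n_reads is None:
            n_reads = len(items) if depth is None else int(depth) * len(items)
        w = (np.ones(len(items)) if weights is None
             else np.asarray(weights, float))
        w = w / w.sum()
        counts = rng.multinomial(n_reads, w)
        rid = 0
        for (name, seq), cnt in zip(items, counts):
            for _ in range(cnt):
                reads.append(SimRead(f"r{rid}",
                                     _add_errors(seq, error_rate, rng), name))
                rid += 1
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return reads


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id} source={r.source}\n{r.sequence}\n+\n"
                     f"{'I' * len(r.sequence)}\n")
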