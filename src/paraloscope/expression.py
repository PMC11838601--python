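"""Unique-k-mer expression quantification for paralog groups: a background-
filtered 31-mer index over gene models, iterative merging of paralogs to a
detectability floor, vectorized read classification, tissue-enrichment
z-scores with UPGMA clustering, and developmental trend statistics.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from ._kmers import INVALID, canonical_codes, kmer_codes


@dataclass
class KmerIndex:
    """Canonical k-mer -> owning paralogs, after background exclusion.

    ``owners`` maps each indexed k-mer code to the frozenset of paralogs whose
    gene models contain it; ``position_count`` is the number of transcript
    positions carrying the k-mer (summed over isoforms).
    """

    k: int
    owners: dict
    position_count: dict
    background_excluded: int = 0
    groups: list = field(default_factory=list)   # list of frozensets
    group_labels: list = field(default_factory=list)

    def unique_positions(self, group: frozenset) -> int:
        return sum(self.position_count[c] for c, ow in self.owners.items()
                   if ow <= group)

    def shared_kmer_types(self, g1: frozenset, g2: frozenset) -> int:
        return sum(1 for ow in self.owners.values()
                   if ow & g1 and ow & g2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"kmer_code": c, "owners": "/".join(sorted(ow)),
              "positions": self.position_count[c]}
             for c, ow in self.owners.items()])


def _transcript_seqs(gene_models) -> dict:
    """Normalise {paralog: seq | [seqs] | {isoform: seq}} to {paralog: [seqs]}."""
    out = {}
    for p, v in gene_models.items():
        if isinstance(v, str):
            out[p] = [v]
        elif isinstance(v, dict):
            out[p] = list(v.values())
        else:
            out[p] = list(v)
    return out


def build_kmer_index(gene_models: dict, background, k: int = 31) -> KmerIndex:
    """Index every canonical k-mer of the transcripts that is absent from the
    background genome; annotate each with the set of paralogs containing it."""
    if not (15 <= k <= 31 and k % 2 == 1):
        raise ValueError("k must be odd and within [15, 31]")
    seqs = _transcript_seqs(gene_models)
    if any(all(len(s) < k for s in v) for v in seqs.values() if v):
        raise ValueError("k exceeds transcript length for some paralog")
    bg = set()
    bgseqs = [background] if isinstance(background, str) else list(background)
    for b in bgseqs:
        codes = canonical_codes(kmer_codes(b, k), k)
        bg.update(int(c) for c in codes[codes != INVALID])
    owners, pos_count = {}, {}
    excluded = 0
    for p, trans in seqs.items():
        for t in trans:
            codes = canonical_codes(kmer_codes(t, k), k)
            for c in codes[codes != INVALID]:
                c = int(c)
                if c in bg:
                    excluded += 1
                    continue
                owners.setdefault(c, set()).add(p)
                pos_count[c] = pos_count.get(c, 0) + 1
    owners = {c: frozenset(ow) for c, ow in owners.items()}
    paralogs = sorted(seqs)
    return KmerIndex(k=k, owners=owners, position_count=pos_count,
                     background_excluded=excluded,
                     groups=[frozenset({p}) for p in paralogs],
                     group_labels=paralogs)


def merge_groups(index: KmerIndex, min_unique: int = 5) -> KmerIndex:
    """Iteratively merge paralogs into detectable groups: while some group has
    fewer than ``min_unique`` uniquely identifying k-mer positions, the most
    deficient group (fewest unique positions, ties lexicographic) is merged
    with the group sharing the most of its k-mers (ties lexicographic), until
    all groups pass or a single group remains."""
    groups = list(index.groups)

    def label(g):
        return "/".join(sorted(g))

    while len(groups) > 1:
        uniq = [(index.unique_positions(g), label(g), i)
                for i, g in enumerate(groups)]
        deficient = sorted(u for u in uniq if u[0] < min_unique)
        if not deficient:
            break
        _, _, i = deficient[0]
        best = None
        for j, g in enumerate(groups):
            if j == i:
                continue
            sh = index.shared_kmer_types(groups[i], g)
            cand = (-sh, label(g), j)
            if best is None or cand < best:
                best = cand
        j = best[2]
        merged = groups[i] | groups[j]
        groups = [g for idx2, g in enumerate(groups) if idx2 not in (i, j)]
        groups.append(merged)
        groups.sort(key=label)
    out = KmerIndex(k=index.k, owners=index.owners,
                    position_count=index.position_count,
                    background_excluded=index.background_excluded,
                    groups=groups, group_labels=[label(g) for g in groups])
    return out


# ---------------------------------------------------------------------------
# read classification
# ---------------------------------------------------------------------------

def _batch_codes(reads: list, k: int) -> np.ndarray:
    """Canonical k-mer codes for equal-length reads, INVALID padded."""
    L = max(len(r) for r in reads)
    mat = np.full((len(reads), L), ord("N"), dtype=np.uint8)
    for i, r in enumerate(reads):
        mat[i, :len(r)] = np.frombuffer(r.encode(), dtype=np.uint8)
    from ._kmers import _BASE_CODE
    base = _BASE_CODE[mat]
    npos = L - k + 1
    if npos <= 0:
        return np.full((len(reads), 0), INVALID, dtype=np.uint64)
    code = np.zeros((len(reads), npos), dtype=np.uint64)
    rc = np.zeros((len(reads), npos), dtype=np.uint64)
    bad = np.zeros((len(reads), npos), dtype=bool)
    vals = base.astype(np.uint64)
    for j in range(k):
        code = (code << np.uint64(2)) | vals[:, j:j + npos]
        rc |= (np.uint64(3) - vals[:, j:j + npos]) << np.uint64(2 * j)
        bad |= base[:, j:j + npos] > 3
    canon = np.minimum(code, rc)
    canon[bad] = INVALID
    return canon


def classify_reads(reads, index: KmerIndex, batch: int = 100_000) -> dict:
    """Assign each read to the single paralog group whose unique k-mers it
    contains; reads with unique k-mers of two or more groups, or only shared
    family k-mers, count as family-ambiguous; others are ignored."""
    if not index.groups:
        raise ValueError("index has no groups; call merge_groups first")
    seqs = [r if isinstance(r, str) else r.sequence for r in reads]
    if seqs and min(len(s) for s in seqs) < index.k:
        raise ValueError("read shorter than k")
    glabel = index.group_labels
    # precompute sorted code table with group-id (-1 = shared within family)
    codes = np.fromiter(index.owners.keys(), dtype=np.uint64,
                        count=len(index.owners))
    gids = np.full(len(codes), -1, dtype=np.int64)
    member_of = {}
    for gi, g in enumerate(index.groups):
        for p in g:
            member_of[p] = gi
    for i, (c, ow) in enumerate(index.owners.items()):
        gs = {member_of[p] for p in ow}
        if len(gs) == 1:
            gids[i] = gs.pop()
    order = np.argsort(codes)
    codes_s, gids_s = codes[order], gids[order]

    counts = {lab: 0 for lab in glabel}
    ambiguous = 0
    total_family = 0
    for lo in range(0, len(seqs), batch):
        chunk = seqs[lo:lo + batch]
        canon = _batch_codes(chunk, index.k)
        n, npos = canon.shape
        if npos == 0:
            continue
        flat = canon.ravel()
        idx = np.searchsorted(codes_s, flat)
        idx = np.clip(idx, 0, len(codes_s) - 1)
        hit = codes_s[idx] == flat
        gid = np.where(hit, gids_s[idx], -2)  # -2: not a family k-mer
        masks = np.zeros(len(flat), dtype=np.uint64)
        uniq = gid >= 0
        masks[uniq] = np.uint64(1) << gid[uniq].astype(np.uint64)
        masks = masks.reshape(n, npos)
        read_mask = np.bitwise_or.reduce(masks, axis=1)
        has_family = (gid > -2).reshape(n, npos).any(axis=1)
        popcnt = np.array([bin(int(m)).count("1") for m in read_mask])
        for gi, lab in enumerate(glabel):
            counts[lab] += int(((popcnt == 1)
                                & (read_mask == np.uint64(1) << np.uint64(gi))
                                ).sum())
        ambiguous += int(((popcnt >= 2)
                          | ((popcnt == 0) & has_family)).sum())
        total_family += int(has_family.sum())
    counts["__ambiguous__"] = ambiguous
    counts["__family_total__"] = total_family
    return counts


def expression_matrix(sample_reads: dict, index: KmerIndex) -> pd.DataFrame:
    """Group x sample classified-read counts (plus ambiguous/family totals)."""
    cols = {}
    for sample, reads in sample_reads.items():
        cols[sample] = classify_reads(reads, index)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# enrichment and trends
# ---------------------------------------------------------------------------

def shares(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-sample share of classified reads per group."""
    counts = matrix.drop(index=[r for r in ("__ambiguous__", "__family_total__")
                                if r in matrix.index])
    return counts / counts.sum(axis=0)


def enrichment(matrix: pd.DataFrame):
    """Z-scores of per-sample shares against each group's cross-sample mean,
    one-sided normal p-values, and UPGMA (correlation-distance) linkages for
    groups and samples. Requires >= 2 groups and samples."""
    sh = shares(matrix)
    if sh.shape[0] < 2 or sh.shape[1] < 2:
        raise ValueError("need at least 2 groups and 2 samples")
    mu = sh.mean(axis=1)
    sd = sh.std(axis=1, ddof=1)
    z = sh.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    pvals = pd.DataFrame(stats.norm.sf(z.to_numpy()),
                         index=z.index, columns=z.columns)

    def upgma(df):
        x = df.fillna(0.0).to_numpy()
        if len(x) < 2:
            return None
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(x)   # zero-variance profiles yield nan rows
        corr = np.nan_to_num(corr, nan=0.0)
        d = 1.0 - corr
        np.fill_diagonal(d, 0.0)
        from scipy.spatial.distance import squareform
        return hierarchy.average(squareform(np.maximum(d, 0.0), checks=False))

    return {"shares": sh, "z": z, "p": pvals,
            "group_linkage": upgma(z), "sample_linkage": upgma(z.T)}


def developmental_profile(long_table: pd.DataFrame, n_boot: int = 200,
                          seed: int = 0) -> pd.DataFrame:
    """Monotonic-trend statistics per (group, tissue): Spearman correlation of
    share with timepoint order plus bootstrap 95% bands of per-timepoint mean
    shares. ``long_table`` columns: group, tissue, timepoint (orderable),
    share. Returns one row per group/tissue with rho, p and band table."""
    rng = np.random.default_rng(seed)
    rows = []
    for (g, t), grp in long_table.groupby(["group", "tissue"]):
        order = {tp: i for i, tp in enumerate(sorted(grp["timepoint"].unique()))}
        if len(order) < 2:
            rows.append({"group": g, "tissue": t, "rho": np.nan,
                         "p_value": np.nan, "bands": None})
            continue
        x = grp["timepoint"].map(order).to_numpy()
        y = grp["share"].to_numpy()
        rho, p = stats.spearmanr(x, y)
        bands = {}
        for tp, sub in grp.groupby("timepoint"):
            v = sub["share"].to_numpy()
            boots = np.array([v[rng.integers(0, len(v), len(v))].mean()
                              for _ in range(n_boot)])
            bands[tp] = (float(np.percentile(boots, 2.5)),
                         float(v.mean()),
                         float(np.percentile(boots, 97.5)))
        rows.append({"group": g, "tissue": t, "rho": float(rho),
                     "p_value": float(p), "bands": bands})
    return pd.DataFrame(rows)
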