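"""Haplotype-based selection scans: assembly SNP calling, Tajima's D in fixed
30 kbp windows, and the nS_L haplotype-homozygosity statistic with frequency-bin
standardization, percentile ranking and IGC-exclusion sensitivity.

Sign conventions follow the field: Tajima's D is negative under an excess of
rare alleles; unstandardized nS_L = ln(SL_A / SL_D), so sweeps on the derived
background give negative scores. Window-level nS_L is the fraction of scored
sites with |standardized score| > 2, which is direction-agnostic.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class VariantMatrix:
    """Haplotype x biallelic-SNP matrix (0 = reference-matching allele).

    ``ancestral`` holds, per SNP, which allele (0/1) is ancestral, or -1 when
    the outgroup was uninformative.
    """

    contig: str
    positions: np.ndarray
    genotypes: np.ndarray           # n_hap x S, uint8 in {0,1}
    ancestral: np.ndarray           # S, int8 in {-1, 0, 1}
    haplotypes: list = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.uint8)
        self.ancestral = np.asarray(self.ancestral, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D")
        if self.genotypes.shape[1] != len(self.positions):
            raise ValueError("positions/genotypes shape mismatch")
        if len(self.positions) > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def s(self) -> int:
        return self.genotypes.shape[1]

    def subset(self, mask) -> "VariantMatrix":
        return VariantMatrix(self.contig, self.positions[mask],
                             self.genotypes[:, mask], self.ancestral[mask],
                             self.haplotypes)


def call_variants(reference: str, haplotypes: dict, outgroup: str | None = None,
                  contig: str = "ref") -> VariantMatrix:
    """Substitution SNPs from haplotype sequences laid out in reference
    coordinates ('N' marks unanchored bases; such haplotypes are treated as
    reference-matching at that site). Sites with more than two observed alleles
    are dropped; polarity comes from the outgroup allele when it matches one of
    the two observed alleles."""
    if not haplotypes:
        raise ValueError("no haplotypes to call from")
    names = sorted(haplotypes)
    L = len(reference)
    ref = np.frombuffer(reference.encode(), dtype=np.uint8)
    mat = np.vstack([
        np.frombuffer(haplotypes[h].encode(), dtype=np.uint8) for h in names])
    if mat.shape[1] != L:
        raise ValueError("haplotypes must be in reference coordinates")
    missing = mat == ord("N")
    diff = (mat != ref[None, :]) & ~missing
    cols = np.flatnonzero(diff.any(axis=0))
    positions, genos, anc = [], [], []
    og = (np.frombuffer(outgroup.encode(), dtype=np.uint8)
          if outgroup is not None else None)
    for c in cols:
        alts = set(mat[diff[:, c], c].tolist())
        if len(alts) != 1:
            continue  # >2 observed alleles
        alt = alts.pop()
        positions.append(c)
        genos.append(diff[:, c].astype(np.uint8))
        if og is None:
            anc.append(-1)
        elif og[c] == ref[c]:
            anc.append(0)
        elif og[c] == alt:
            anc.append(1)
        else:
            anc.append(-1)
    geno = (np.array(genos, dtype=np.uint8).T if positions
            else np.zeros((len(names), 0), dtype=np.uint8))
    return VariantMatrix(contig, np.array(positions, dtype=np.int64), geno,
                         np.array(anc, dtype=np.int8), names)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict:
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    return {"a1": a1, "a2": a2, "e1": c1 / a1, "e2": c2 / (a1 ** 2 + a2)}


def tajimas_d(matrix: VariantMatrix, window: tuple[int, int] | None = None
              ) -> float | None:
    """Tajima (1989) D for the sites inside ``window`` (half-open bp interval);
    None when no site segregates (the denominator vanishes)."""
    n = matrix.n
    if n < 4:
        raise ValueError("need at least 4 haplotypes")
    g = matrix.genotypes
    if window is not None:
        mask = (matrix.positions >= window[0]) & (matrix.positions < window[1])
        g = g[:, mask]
    counts = g.sum(axis=0).astype(float)
    seg = (counts > 0) & (counts < n)
    counts = counts[seg]
    S = len(counts)
    if S == 0:
        return None
    k = tajima_constants(n)
    pi = float(np.sum(2.0 * counts * (n - counts)) / (n * (n - 1)))
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    return (pi - S / k["a1"]) / np.sqrt(var)


def tajima_windows(matrix: VariantMatrix, width: int = 30_000,
                   region_length: int | None = None) -> pd.DataFrame:
    """Non-overlapping tiles of ``width`` bp; windows without segregating sites
    get a missing value rather than zero."""
    if region_length is None:
        region_length = (int(matrix.positions.max()) + 1 if matrix.s else width)
    rows = []
    for start in range(0, region_length, width):
        end = start + width
        mask = (matrix.positions >= start) & (matrix.positions < end)
        rows.append({"contig": matrix.contig, "start": start, "end": end,
                     "n_snps": int(mask.sum()), "statistic": "tajima_d",
                     "value": tajimas_d(matrix, (start, end))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nS_L
# ---------------------------------------------------------------------------

def _site_sl(matrix: VariantMatrix) -> pd.DataFrame:
    """Per-site mean SL over ancestral-carrying and derived-carrying pairs.

    SL for a pair at a site is the number of consecutive segregating sites in
    the maximal interval of pairwise identity containing the site."""
    g = matrix.genotypes
    n, S = g.shape
    if S == 0:
        return pd.DataFrame(columns=["pos", "daf", "score"])
    anc = matrix.ancestral
    scored = anc >= 0
    sl_sum = {0: np.zeros(S), 1: np.zeros(S)}
    sl_cnt = {0: np.zeros(S), 1: np.zeros(S)}
    for i in range(n):
        gi = g[i]
        for j in range(i + 1, n):
            agree = gi == g[j]
            run_id = np.cumsum(~agree)
            run_len = np.bincount(run_id[agree], minlength=run_id[-1] + 1
                                  if S else 1)
            lens = np.zeros(S)
            lens[agree] = run_len[run_id[agree]]
            for allele in (0, 1):
                m = agree & (gi == allele)
                sl_sum[allele][m] += lens[m]
                sl_cnt[allele][m] += 1
    rows = []
    for s in range(S):
        if not scored[s]:
            continue
        a = int(anc[s])
        d = 1 - a
        if sl_cnt[a][s] == 0 or sl_cnt[d][s] == 0:
            continue
        sl_a = sl_sum[a][s] / sl_cnt[a][s]
        sl_d = sl_sum[d][s] / sl_cnt[d][s]
        if sl_a <= 0 or sl_d <= 0:
            continue
        derived_count = int((g[:, s] == d).sum())
        rows.append({"pos": int(matrix.positions[s]),
                     "daf": derived_count / n,
                     "score": float(np.log(sl_a / sl_d))})
    return pd.DataFrame(rows)


def nsl_scan(matrices, n_bins: int = 100, min_snps: int = 10,
             window: int = 30_000, norm_matrices=None
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardized nS_L over one window-matrix or a list of them.

    Scores are standardized to zero mean and unit variance within
    derived-allele-frequency bins (at most ``n_bins``; identical frequencies
    always share a bin). The standardization is fit on ``norm_matrices`` when
    given — the chromosome-wide, predominantly neutral background a selection
    scan normalizes against — and on the scored inputs themselves otherwise.
    Returns (site table, window table); the window statistic is the fraction of
    scored sites with |standardized score| > 2, reported only for windows with
    >= ``min_snps`` scored sites.
    """
    if not isinstance(matrices, (list, tuple)):
        matrices = [matrices]

    def site_table(ms):
        tables = []
        for w, m in enumerate(ms):
            t = _site_sl(m)
            t["window"] = w
            t["contig"] = m.contig
            tables.append(t)
        tables = [t for t in tables if not t.empty]
        if not tables:
            return pd.DataFrame(columns=["pos", "daf", "score",
                                         "window", "contig"])
        return pd.concat(tables, ignore_index=True)

    sites = site_table(matrices)
    if sites.empty:
        sites["z"] = []
        return sites, pd.DataFrame(
            columns=["window", "contig", "n_scored", "statistic", "value"])
    ref = sites if norm_matrices is None else site_table(
        norm_matrices if isinstance(norm_matrices, (list, tuple))
        else [norm_matrices])
    # frequency bins: quantile cuts collapsed over ties, fit on the reference
    uniq = np.unique(ref["daf"])
    nb = min(n_bins, len(uniq))
    edges = np.unique(np.quantile(uniq, np.linspace(0, 1, nb + 1)))

    def binner(daf):
        return np.clip(np.searchsorted(edges, daf, "right") - 1,
                       0, len(edges) - 2)

    ref = ref.assign(bin=binner(ref["daf"]))
    stats_by_bin = ref.groupby("bin")["score"].agg(["mean", "std"])
    sites["bin"] = binner(sites["daf"])
    mu = sites["bin"].map(stats_by_bin["mean"])
    sd = sites["bin"].map(stats_by_bin["std"]).replace(0.0, np.nan)
    sites["z"] = (sites["score"] - mu) / sd
    rows = []
    for w, grp in sites.groupby("window"):
        zz = grp["z"].dropna()
        if len(zz) < min_snps:
            continue
        rows.append({"window": w, "contig": grp["contig"].iloc[0],
                     "n_scored": len(zz), "statistic": "nsl_window",
                     "value": float((zz.abs() > 2).mean())})
    return sites, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ranking and sensitivity
# ---------------------------------------------------------------------------

def rank_windows(stats: pd.DataFrame, gene_intervals=None,
                 min_overlap: int = 5_000) -> pd.DataFrame:
    """Chromosome-wide percentile per statistic plus gene-overlap flags
    (a window is gene-overlapping when the intersection is >= ``min_overlap``)."""
    out = stats.copy()
    out["percentile"] = np.nan
    for _, idx in out.groupby("statistic").groups.items():
        vals = out.loc[idx, "value"]
        ok = vals.notna()
        ranks = vals[ok].rank(pct=True) * 100.0
        out.loc[ranks.index, "percentile"] = ranks
    genes = []
    if gene_intervals is not None and {"start", "end"}.issubset(out.columns):
        for _, r in out.iterrows():
            hit = []
            for g in gene_intervals:
                name, gs, ge = (g.get("name", "gene"), g["start"], g["end"]) \
                    if isinstance(g, dict) else (g[0], g[1], g[2])
                ov = min(r["end"], ge) - max(r["start"], gs)
                if ov >= min_overlap:
                    hit.append(name)
            genes.append(",".join(hit))
        out["genes"] = genes
    out["extreme_low1"] = out["percentile"] <= 1
    out["extreme_low5"] = out["percentile"] <= 5
    out["extreme_high95"] = out["percentile"] >= 95
    out["extreme_high99"] = out["percentile"] >= 99
    return out


def igc_sensitivity(stats: pd.DataFrame) -> pd.DataFrame:
    """1st/5th percentile cutoffs of each statistic with all windows versus
    IGC-overlapping windows excluded."""
    if "igc_overlap" not in stats.columns:
        raise ValueError("stats must carry an igc_overlap flag")
    rows = []
    for stat, grp in stats.groupby("statistic"):
        vals = grp["value"].dropna()
        sub = grp.loc[~grp["igc_overlap"], "value"].dropna()
        for pct in (1, 5):
            rows.append({
                "statistic": stat, "percentile": pct,
                "with_igc": float(np.percentile(vals, pct)) if len(vals) else np.nan,
                "without_igc": (float(np.percentile(sub, pct))
                                if len(sub) else np.nan)})
    return pd.DataFrame(rows)
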