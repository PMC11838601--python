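"""Interlocus gene conversion detection via runs of paralogous sequence
variants (PSVs), with donor/acceptor directionality and hotspot summaries.

A PSV is an ancestral-locus column where at least two paralog consensuses
disagree. A conversion tract on a copy of paralog P is a maximal run of at
least ``min_run`` consecutive P-vs-Q discriminating PSVs at which the copy
carries donor Q's allele while the immediately flanking discriminating PSVs
match P.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class IGCTract:
    haplotype: str
    copy_id: str
    acceptor: str            # paralog label of the converted copy
    donor: str
    start: int               # ancestral coordinates, half-open
    end: int
    n_psv: int


def build_psv_catalog(consensuses: dict) -> pd.DataFrame:
    """Catalog of ancestral-coordinate columns where >= 2 paralog consensuses
    disagree; one column per paralog holding its allele."""
    if len(consensuses) < 2:
        raise ValueError("need at least two paralog consensuses")
    labels = sorted(consensuses)
    mat = np.vstack([np.frombuffer(consensuses[l].encode(), dtype=np.uint8)
                     for l in labels])
    informative = (mat != mat[0]).any(axis=0)
    pos = np.flatnonzero(informative)
    out = pd.DataFrame({"pos": pos})
    for i, l in enumerate(labels):
        out[l] = [chr(b) for b in mat[i, pos]]
    return out


def detect_igc(copy_aligned: str, label: str, catalog: pd.DataFrame,
               min_run: int = 5, haplotype: str = "", copy_id: str = ""
               ) -> list[IGCTract]:
    """Conversion tracts on one copy laid out in ancestral coordinates
    ('N' for unanchored bases). Overlapping candidate donors are resolved by
    longest run, then lexicographic donor label."""
    if catalog.empty:
        return []
    labels = [c for c in catalog.columns if c != "pos"]
    if label not in labels:
        raise ValueError(f"unknown paralog label {label!r}")
    pos = catalog["pos"].to_numpy()
    cbytes = np.frombuffer(copy_aligned.encode(), dtype=np.uint8)
    copy_allele = cbytes[pos]
    own = catalog[label].map(ord).to_numpy()
    candidates = []
    for donor in labels:
        if donor == label:
            continue
        da = catalog[donor].map(ord).to_numpy()
        disc = own != da             # P-vs-Q discriminating PSVs
        dpos = pos[disc]
        if not len(dpos):
            continue
        calleles = copy_allele[disc]
        match_q = calleles == da[disc]
        match_p = calleles == own[disc]
        i = 0
        m = len(dpos)
        while i < m:
            if not match_q[i]:
                i += 1
                continue
            j = i
            while j + 1 < m and match_q[j + 1]:
                j += 1
            n_run = j - i + 1
            flank_ok = ((i == 0 or match_p[i - 1])
                        and (j == m - 1 or match_p[j + 1]))
            if n_run >= min_run and flank_ok:
                candidates.append(IGCTract(
                    haplotype, copy_id, label, donor,
                    int(dpos[i]), int(dpos[j]) + 1, n_run))
            i = j + 1
    candidates.sort(key=lambda t: (-t.n_psv, t.donor, t.start))
    chosen = []
    for t in candidates:
        if all(t.end <= c.start or t.start >= c.end for c in chosen):
            chosen.append(t)
    return sorted(chosen, key=lambda t: t.start)


def tracts_table(tracts) -> pd.DataFrame:
    return pd.DataFrame(
        [{"haplotype": t.haplotype, "copy_id": t.copy_id,
          "acceptor": t.acceptor, "donor": t.donor, "start": t.start,
          "end": t.end, "n_psv": t.n_psv} for t in tracts],
        columns=["haplotype", "copy_id", "acceptor", "donor",
                 "start", "end", "n_psv"])


def directionality(tracts) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(donor, acceptor) ordered-pair counts plus per-paralog asymmetry
    (donor - acceptor)/(donor + acceptor) with a two-sided binomial p-value
    against symmetric exchange."""
    tab = tracts if isinstance(tracts, pd.DataFrame) else tracts_table(tracts)
    if tab.empty:
        return (pd.DataFrame(columns=["donor", "acceptor", "count"]),
                pd.DataFrame(columns=["paralog", "donor_events",
                                      "acceptor_events", "asymmetry",
                                      "p_value"]))
    pairs = (tab.groupby(["donor", "acceptor"]).size()
             .rename("count").reset_index())
    paralogs = sorted(set(tab["donor"]) | set(tab["acceptor"]))
    rows = []
    for p in paralogs:
        d = int((tab["donor"] == p).sum())
        a = int((tab["acceptor"] == p).sum())
        asym = (d - a) / (d + a) if d + a else np.nan
        pval = (stats.binomtest(d, d + a, 0.5).pvalue if d + a else np.nan)
        rows.append({"paralog": p, "donor_events": d, "acceptor_events": a,
                     "asymmetry": asym, "p_value": pval})
    return pairs, pd.DataFrame(rows)


def hotspots(tracts, genome_length: int, bin_size: int = 100_000,
             coord_cols: tuple[str, str] = ("genomic_start", "genomic_end")
             ) -> pd.DataFrame:
    """Tract counts in fixed genomic bins; hotspots are bins exceeding the
    95th percentile of non-zero bins."""
    tab = tracts if isinstance(tracts, pd.DataFrame) else tracts_table(tracts)
    edges = np.arange(0, genome_length + bin_size, bin_size)
    counts = np.zeros(len(edges) - 1, dtype=int)
    if not tab.empty:
        scol = coord_cols[0] if coord_cols[0] in tab.columns else "start"
        mids = tab[scol].to_numpy()
        idx = np.clip(mids // bin_size, 0, len(counts) - 1).astype(int)
        np.add.at(counts, idx, 1)
    out = pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:],
                        "count": counts})
    nz = counts[counts > 0]
    if len(nz):
        thr = np.percentile(nz, 95)
        out["hotspot"] = counts > thr
        # degenerate flat distributions: a strictly unique maximum still counts
        if not out["hotspot"].any():
            mx = counts.max()
            if mx > 0 and (counts == mx).sum() == 1:
                out.loc[out["count"] == mx, "hotspot"] = True
    else:
        out["hotspot"] = False
    return out


def annotate_windows_igc(windows: pd.DataFrame, tracts) -> pd.DataFrame:
    """Flag each window that any tract interval intersects (shared coordinate
    system; half-open intervals)."""
    tab = tracts if isinstance(tracts, pd.DataFrame) else tracts_table(tracts)
    out = windows.copy()
    flags = np.zeros(len(out), dtype=bool)
    if not tab.empty:
        scol = "genomic_start" if "genomic_start" in tab.columns else "start"
        ecol = "genomic_end" if "genomic_end" in tab.columns else "end"
        for ts, te in zip(tab[scol], tab[ecol]):
            flags |= ((out["start"] < te) & (out["end"] > ts)).to_numpy()
    out["igc_overlap"] = flags
    return out
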