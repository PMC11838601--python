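"""Per-paralog copy-number summaries across haplotypes: heterozygosity,
invariance classes, subfamily roll-ups and population comparisons."""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def copy_number_table(assignments: pd.DataFrame, qc: dict,
                      samples: pd.DataFrame,
                      paralogs=None) -> pd.DataFrame:
    """Sample x (paralog, haplotype index) copy counts.

    ``assignments`` needs columns haplotype/paralog (one row per copy);
    ``samples`` needs sample/hap1/hap2 (and optionally population). Cells of
    QC-fail haplotypes are missing; samples failing QC on both haplotypes are
    retained with all values missing.
    """
    if paralogs is None:
        paralogs = (sorted(assignments["paralog"].unique())
                    if len(assignments) else [])
    if len(assignments):
        counts = (assignments.groupby(["haplotype", "paralog"])
                  .size().unstack(fill_value=0))
    else:
        counts = pd.DataFrame()
    rows = {}
    for r in samples.itertuples():
        row = {}
        for hi, hap in enumerate((r.hap1, r.hap2), start=1):
            for p in paralogs:
                if not qc.get(hap, False):
                    row[(p, hi)] = np.nan
                else:
                    row[(p, hi)] = float(counts.loc[hap, p]
                                         if hap in counts.index
                                         and p in counts.columns else 0)
        rows[r.sample] = row
    tab = pd.DataFrame.from_dict(rows, orient="index")
    tab.columns = pd.MultiIndex.from_tuples(tab.columns,
                                            names=["paralog", "haplotype"])
    tab = tab.sort_index(axis=1)
    tab.index.name = "sample"
    if "population" in samples.columns:
        tab.attrs["population"] = dict(
            zip(samples["sample"], samples["population"]))
    return tab


def heterozygosity(table: pd.DataFrame, paralog: str) -> float | None:
    """Fraction of samples with discordant copy number between their two
    QC-pass haplotypes; None when no sample has both haplotypes passing."""
    h1, h2 = table[(paralog, 1)], table[(paralog, 2)]
    both = h1.notna() & h2.notna()
    if not both.any():
        return None
    return float((h1[both] != h2[both]).mean())


def classify_invariance(table: pd.DataFrame,
                        subfamilies: dict | None = None) -> pd.Series:
    """Per-paralog class: fixed_single_copy (every QC-pass haplotype has CN 1),
    always_present (CN >= 1 but not fixed), else variable. With
    ``subfamilies`` (name -> member labels), roll-ups are classified on the
    summed member columns."""
    cols = {}
    for p in table.columns.get_level_values("paralog").unique():
        cols[p] = pd.concat([table[(p, 1)], table[(p, 2)]])
    if subfamilies:
        for name, members in subfamilies.items():
            s1 = sum(table[(m, 1)] for m in members)
            s2 = sum(table[(m, 2)] for m in members)
            cols[name] = pd.concat([s1, s2])
    out = {}
    for name, vals in cols.items():
        v = vals.dropna()
        if len(v) == 0:
            out[name] = "variable"
        elif (v == 1).all():
            out[name] = "fixed_single_copy"
        elif (v >= 1).all():
            out[name] = "always_present"
        else:
            out[name] = "variable"
    return pd.Series(out, name="class")


def total_copy_number(table: pd.DataFrame) -> pd.DataFrame:
    """Per-haplotype total copies (rows: sample, haplotype index)."""
    rows = []
    for hi in (1, 2):
        sub = table.xs(hi, axis=1, level="haplotype")
        tot = sub.sum(axis=1, min_count=len(sub.columns))
        for sample, v in tot.items():
            rows.append({"sample": sample, "haplotype": hi, "total": v})
    return pd.DataFrame(rows)


def compare_populations(table: pd.DataFrame, group_a: str, group_b: str
                        ) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum on per-haplotype total copy number."""
    pops = table.attrs.get("population", {})
    tot = total_copy_number(table).dropna()
    tot["population"] = tot["sample"].map(pops)
    a = tot.loc[tot["population"] == group_a, "total"]
    b = tot.loc[tot["population"] == group_b, "total"]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.ranksums(a, b)
    return float(res.statistic), float(res.pvalue)
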