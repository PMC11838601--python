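"""SNP calling, Tajima's D against an independent closed form, nS_L behaviour,
window ranking and IGC-exclusion sensitivity."""
import numpy as np
import pandas as pd
import pytest

from paraloscope import selection as sel
from paraloscope import synthdata as sd


def tajima_oracle(n, S, pi):
    """Independent direct evaluation of Tajima (1989)."""
    if S == 0:
        return None
    i = np.arange(1, n)
    a1 = (1 / i).sum()
    a2 = (1 / i**2).sum()
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def mean_pairwise(m):
    g = m.genotypes.astype(int)
    n = g.shape[0]
    c = g.sum(axis=0)
    return float((c * (n - c)).sum() / (n * (n - 1) / 2))


# ---------------------------------------------------------------------------
# variant calling
# ---------------------------------------------------------------------------

def test_call_variants_substitutions_and_polarity(rng):
    ref = sd._random_dna(rng, 300)
    hap = list(ref)
    subs = sorted(rng.choice(300, size=3, replace=False))
    for p in subs:
        hap[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[hap[p]]
    m = sel.call_variants(ref, {"h1": "".join(hap), "h2": ref}, outgroup=ref)
    assert list(m.positions) == subs
    assert (m.genotypes[m.haplotypes.index("h1")] == 1).all()
    assert (m.ancestral == 0).all()
    empty = sel.call_variants(ref, {"h1": ref})
    assert empty.s == 0


def test_call_variants_round_trip_from_coalescent(rng):
    ref = sd._random_dna(rng, 2000)
    m = sd.simulate_coalescent_window(8, 6.0, "neutral", length=2000, rng=rng)
    flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
    haps = {}
    for i in range(8):
        h = list(ref)
        for j, pos in enumerate(m.positions):
            if m.genotypes[i, j]:
                h[pos] = flip[ref[pos]]
        haps[f"h{i}"] = "".join(h)
    called = sel.call_variants(ref, haps, outgroup=ref)
    assert called.s == m.s
    assert list(called.positions) == list(m.positions)
    order = [called.haplotypes.index(f"h{i}") for i in range(8)]
    assert np.array_equal(called.genotypes[order], m.genotypes)


def test_triallelic_sites_dropped(rng):
    ref = "A" * 50
    m = sel.call_variants(ref, {"h1": "C" + ref[1:], "h2": "G" + ref[1:],
                                "h3": ref})
    assert m.s == 0


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def test_tajima_missing_when_no_segregating_sites():
    m = sel.VariantMatrix("c", np.array([], int),
                          np.zeros((5, 0), np.uint8), np.array([], np.int8))
    assert sel.tajimas_d(m) is None
    with pytest.raises(ValueError):
        sel.tajimas_d(sel.VariantMatrix("c", np.array([], int),
                                        np.zeros((3, 0), np.uint8),
                                        np.array([], np.int8)))


def test_tajima_equals_independent_oracle(rng):
    for _ in range(1000):
        n = int(rng.integers(4, 30))
        m = sd.simulate_coalescent_window(n, float(rng.uniform(0.5, 15)),
                                          "neutral", rng=rng)
        d = sel.tajimas_d(m)
        o = tajima_oracle(n, m.s, mean_pairwise(m))
        if o is None:
            assert d is None
        else:
            assert d == pytest.approx(o, abs=1e-9)


def test_tajima_windows_tile_and_mark_missing(rng):
    m = sd.simulate_coalescent_window(10, 8.0, "neutral", length=30_000,
                                      rng=rng)
    tab = sel.tajima_windows(m, width=30_000, region_length=60_000)
    assert len(tab) == 2
    assert tab.iloc[1]["n_snps"] == 0 and pd.isna(tab.iloc[1]["value"])


# ---------------------------------------------------------------------------
# nS_L
# ---------------------------------------------------------------------------

def test_nsl_sweep_sign_convention():
    # derived-background sweep: derived carriers identical across the window,
    # ancestral carriers diverse -> SL_D >> SL_A -> negative ln(SL_A/SL_D)
    rng = np.random.default_rng(5)
    n, S = 12, 40
    g = rng.integers(0, 2, size=(n, S)).astype(np.uint8)
    g[:6] = 0                      # derived group all-identical background
    focal = S // 2
    g[:, focal] = 0
    g[:6, focal] = 1               # derived allele on the swept haplotypes
    m = sel.VariantMatrix("c", np.arange(S) * 100, g,
                          np.zeros(S, np.int8))
    sites = sel._site_sl(m)
    row = sites[sites["pos"] == focal * 100].iloc[0]
    assert row["score"] < -1.0


def test_nsl_standardization_is_calibrated_within_bins(rng):
    mats = [sd.simulate_coalescent_window(20, 10.0, "neutral", rng=rng)
            for _ in range(150)]
    sites, _ = sel.nsl_scan(mats, min_snps=10)
    g = sites.dropna(subset=["z"]).groupby("bin")["z"]
    big = g.count() >= 20
    assert g.mean().abs()[big].max() <= 0.05
    assert g.var(ddof=1)[big].between(0.9, 1.1).all()


def test_nsl_min_snps_and_monomorphic_window():
    empty = sel.VariantMatrix("c", np.array([], int),
                              np.zeros((6, 0), np.uint8),
                              np.array([], np.int8))
    sites, wins = sel.nsl_scan([empty])
    assert sites.empty and wins.empty


# ---------------------------------------------------------------------------
# ranking and sensitivity
# ---------------------------------------------------------------------------

def test_rank_windows_percentiles_and_gene_flags():
    stats = pd.DataFrame({
        "statistic": "tajima_d", "value": np.linspace(-2.5, 2.5, 200),
        "start": np.arange(200) * 30_000,
        "end": (np.arange(200) + 1) * 30_000})
    genes = [{"name": "G1", "start": 0, "end": 4_999},
             {"name": "G2", "start": 30_000, "end": 36_000}]
    out = sel.rank_windows(stats, genes)
    assert out.iloc[0]["percentile"] <= 1 and out.iloc[0]["extreme_low1"]
    assert out.iloc[0]["genes"] == ""           # 4,999 bp < 5 kbp threshold
    assert out.iloc[1]["genes"] == "G2"
    assert out.iloc[-1]["extreme_high99"]


def test_igc_sensitivity_shortens_left_tail():
    rng = np.random.default_rng(2)
    base = rng.normal(0, 1, size=900)
    igc_vals = rng.normal(-2.0, 0.5, size=100)   # IGC windows add rare alleles
    stats = pd.DataFrame({
        "statistic": "tajima_d",
        "value": np.concatenate([base, igc_vals]),
        "igc_overlap": [False] * 900 + [True] * 100})
    tab = sel.igc_sensitivity(stats).set_index("percentile")
    assert tab.loc[1, "without_igc"] > tab.loc[1, "with_igc"]
    same = sel.igc_sensitivity(stats.assign(igc_overlap=False))
    assert (same["with_igc"] == same["without_igc"]).all()
    allflag = sel.igc_sensitivity(stats.assign(igc_overlap=True))
    assert allflag["without_igc"].isna().all()
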