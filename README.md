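# paraloscope

Paralog-resolved analysis of high-identity multicopy gene families in phased
haplotype assemblies.

Recently duplicated gene families — segmental duplications with 0.3–5%
inter-paralog divergence, variable copy number between haplotypes, gene
conversion between loci, and inversion polymorphisms that shuffle gene order —
defeat most standard genomics pipelines, which assume a single-copy reference.
`paraloscope` provides the full analysis chain for such a family, built for
researchers working with phased long-read assemblies, and exercises every
step end-to-end against a synthetic-data generator with a machine-readable
truth set.

The pipeline:

* **synthdata** — generates haplotype assemblies carrying a ~20 kbp duplicon
  in 1–n copies with subfamily/paralog/copy-level divergence, interlocus
  gene-conversion (IGC) tracts, inversion polymorphisms, an in-frame
  amino-acid VNTR with a SADD→MIISR→SADD frame switch, neutral and
  sweep coalescent windows, and short/long read sets — plus the truth tables
  used as oracles.
* **discovery** — k-mer anchor-chained homology search (copies ≥ 15 kbp),
  30 kbp flanking-sequence locus validation, pileup-based collapse flagging,
  and fastCN-style 36-mer read-depth copy-number estimation.
* **phylo** — p/JC69 distances, deterministic neighbor joining with bootstrap
  support, paralog labelling from reference-anchored clades (support > 75,
  nearest-neighbour "L" labels, "B12/B13"-style merges), and strict-clock
  dating calibrated at the root (e.g. 28.8 Myr).
* **copynum** — per-paralog copy-number tables, heterozygosity (fraction of
  samples with discordant haplotypes), fixed/always-present/variable classes,
  Wilcoxon rank-sum population comparisons.
* **structure** — signed-token locus configurations, capping-free DCJ-indel
  rearrangement distance (with an exhaustive search as the small-instance
  reference), configuration NJ trees, inversion calls with allele
  frequencies.
* **igc** — PSV catalogs, conversion-tract detection from runs of
  donor-matching PSVs, donor/acceptor directionality, hotspot binning.
* **selection** — biallelic SNP calling from assemblies, Tajima's D in 30 kbp
  windows, the nS_L haplotype statistic with 100-bin frequency
  standardization, chromosome-wide percentiles and IGC-exclusion
  sensitivity.
* **transcripts** — mismatch-delta unique read assignment with a spliced
  seed aligner, longest-ORF calling, ≥5-molecule gene models,
  MFCC/MVKL/MRVR/MRLR start classes, fusion-transcript detection, and VNTR
  segmentation at DNA and protein level.
* **expression** — background-filtered unique 31-mer index, iterative paralog
  merging to a ≥5-unique-k-mer detectability floor, read classification,
  tissue-enrichment z-scores with UPGMA clustering, developmental trends.

The central statistic for the VNTR is its frame-switch profile
`(a, b, c)` — the unit counts of the first SADD-frame run (19/23-residue
units alternating), the MIISR-frame run (25-residue units) and the second
SADD-frame run. For rearrangements the statistic is the DCJ-indel distance
`d = N − C − I/2 + Σ⌈(λ+1)/2⌉` over adjacency-graph components; for
selection, Tajima's `D = (π − S/a₁)/√(e₁S + e₂S(S−1))` and
`nS_L = ln(SL_A/SL_D)` standardized within derived-allele-frequency bins.

See `docs/methods.md` for the models, parameter choices and limitations.

## Worked example

```python
import pandas as pd
from paraloscope import synthdata as sd, discovery as dc, phylo, copynum as cn

cfg = sd.SimConfig(seed=7, n_samples=6, populations={"AFR": 3, "EUR": 3})
sim = sd.simulate_family(cfg)

copies, qc = {}, {}
for hap, seq in sim.assemblies.items():
    copies[hap] = dc.find_copies(seq, sim.truth.ancestral, haplotype_id=hap)
    qc[hap] = all(dc.validate_locus(c, copies[hap], len(seq)) == "pass"
                  for c in copies[hap])

seqs = {f"{hap}.{i}": dc.project_to_ancestral(c.sequence, sim.truth.ancestral)
        for hap, cs in copies.items() for i, c in enumerate(cs)}
tree = phylo.bootstrap_support(seqs, n_reps=100, seed=1)

# anchor one reference copy per paralog using the truth table
anchors = {}
for r in sim.truth.copy_coordinates.groupby("paralog").head(1).itertuples():
    for hap, cs in copies.items():
        for i, c in enumerate(cs):
            if (hap, c.start, c.end) == (r.haplotype, r.start, r.end):
                anchors[f"{hap}.{i}"] = r.paralog
labels = phylo.assign_paralogs(tree, anchors).labels

rows = [{"haplotype": hap, "paralog": labels[f"{hap}.{i}"]}
        for hap, cs in copies.items() for i in range(len(cs))]
table = cn.copy_number_table(pd.DataFrame(rows), qc, sim.truth.samples)

print(f"copies discovered: {sum(map(len, copies.values()))} "
      f"on {len(copies)} haplotypes")
for p in cfg.paralogs:
    print(f"  {p}: heterozygosity={cn.heterozygosity(table, p):.2f} "
          f"class={cn.classify_invariance(table)[p]}")
```

which prints:

```
copies discovered: 79 on 12 haplotypes
  A1: heterozygosity=0.00 class=fixed_single_copy
  A2: heterozygosity=0.67 class=always_present
  A3: heterozygosity=0.17 class=variable
  B1: heterozygosity=0.00 class=fixed_single_copy
  B2: heterozygosity=0.67 class=always_present
  B3: heterozygosity=0.50 class=variable
```

Every one of the 79 copies here was found at its exact simulated coordinates
and labelled with its true paralog; the heterozygosities are the fractions of
the six samples whose two haplotypes disagree in that paralog's copy number,
and the classes mark paralogs that are fixed at one copy, always present, or
copy-number variable.

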