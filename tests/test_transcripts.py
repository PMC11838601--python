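"""Read assignment, ORF calling vs an exhaustive oracle, gene models, start
classes, fusion detection and VNTR segmentation."""
import numpy as np
import pytest

from paraloscope import synthdata as sd
from paraloscope import transcripts as tx
from paraloscope.synthdata import MIISR_UNIT_25, SADD_UNIT_19, SADD_UNIT_23


def orf_oracle(seq, min_codons=50):
    """Brute force over all start positions in all forward frames."""
    best = None
    for start in range(len(seq) - 2):
        if seq[start:start + 3] != "ATG":
            continue
        prot = tx.translate(seq[start:])
        stop = prot.find("*")
        aa = prot[:stop] if stop != -1 else prot
        cand = (len(aa), -start, aa)
        if best is None or cand > best:
            best = cand
    if best is None or best[0] < min_codons:
        return None
    return best[2]


# ---------------------------------------------------------------------------
# ORFs and start classes
# ---------------------------------------------------------------------------

def test_call_orf_thresholds_and_ties(rng):
    assert tx.call_orf("CCATGGCCTAACC") is None        # 2 codons < floor
    assert tx.call_orf("CCATGGCCTAACC", min_codons=1) == "MA"
    orf60 = "ATG" + "GCC" * 59 + "TAA"
    orf80 = "ATG" + "TGC" * 79 + "TAA"
    seq = "CC" + orf60 + "TT" + orf80
    assert tx.call_orf(seq) == "M" + "C" * 79


def test_call_orf_matches_exhaustive_oracle(rng):
    for _ in range(100):
        seq = sd._random_dna(rng, int(rng.integers(30, 800)))
        assert tx.call_orf(seq, min_codons=5) == orf_oracle(seq, 5)


def test_start_site_classes():
    for cls in ("MFCC", "MVKL", "MRVR", "MRLR"):
        assert tx.classify_start(cls + "AEKL") == cls
    assert tx.classify_start("MAAA") == "other"
    with pytest.raises(ValueError):
        tx.classify_start("")


# ---------------------------------------------------------------------------
# VNTR segmentation
# ---------------------------------------------------------------------------

def test_vntr_unit_lengths_from_pure_arrays():
    p19 = tx.segment_vntr_protein(SADD_UNIT_19 * 10)
    assert p19.counts == (10, 0, 0)
    assert p19.sadd_unit_length == 19
    p23 = tx.segment_vntr_protein(SADD_UNIT_23 * 10)
    assert p23.counts == (10, 0, 0)
    assert p23.sadd_unit_length == 23


def test_vntr_frame_switch_counts():
    arr = (SADD_UNIT_19 * 7) + (MIISR_UNIT_25 * 6) + (SADD_UNIT_19 * 5)
    prof = tx.segment_vntr_protein("MSTART" + arr + "TAILSEQ")
    assert prof.counts == (7, 6, 5)
    assert prof.miisr_unit_lengths and set(prof.miisr_unit_lengths) == {25}
    assert tx.segment_vntr_protein("MKLLNNNPQRS").counts == (0, 0, 0)


def test_vntr_roundtrip_through_simulated_transcript(small_sim):
    tr = small_sim.truth
    import json
    b3 = tr.copy_coordinates[tr.copy_coordinates.paralog == "B3"]
    checked = 0
    for r in b3.itertuples():
        truth = json.loads(r.vntr)
        seq, _ = tr.copy_transcript(r.copy_id)
        orf = tx.call_orf(seq)
        if orf is None:
            continue
        assert tx.segment_vntr_protein(orf).counts == tuple(truth)
        checked += 1
    assert checked >= 3


def test_find_vntr_dna_period_rules(rng):
    unit = sd._random_dna(rng, 57)
    seq = sd._random_dna(rng, 3000) + unit * 12 + sd._random_dna(rng, 3000)
    hit = tx.find_vntr_dna(seq)
    assert hit is not None
    assert hit["period"] == 57 and hit["copies"] == pytest.approx(12.0,
                                                                  abs=0.5)
    # arrays of sub-threshold fundamental period are ignored
    small_unit = sd._random_dna(rng, 30)
    seq30 = sd._random_dna(rng, 2000) + small_unit * 20 + sd._random_dna(
        rng, 2000)
    assert tx.find_vntr_dna(seq30) is None


def test_find_vntr_dna_tolerates_unit_divergence(rng):
    unit = sd._random_dna(rng, 60)
    units = [sd._mutated(unit, 0.02, rng, None) for _ in range(15)]
    start = 5_000
    seq = sd._random_dna(rng, start) + "".join(units) + sd._random_dna(
        rng, 5_000)
    truth = (start, start + 15 * 60)
    hit = tx.find_vntr_dna(seq)
    assert hit is not None
    ov = min(hit["end"], truth[1]) - max(hit["start"], truth[0])
    assert ov / (truth[1] - truth[0]) >= 0.95


# ---------------------------------------------------------------------------
# read assignment and gene models
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def loci_and_transcripts():
    sim = sd.simulate_family(sd.SimConfig(
        seed=9, n_samples=2, populations={"P": 2}, igc_rate=0.0,
        inversions=[]))
    tr = sim.truth
    loci = {r.copy_id: tr.copy_sequences[r.copy_id]
            for r in tr.copy_coordinates.itertuples()}
    chosen = tr.copy_coordinates.groupby("paralog").head(1)
    transcripts = {}
    for r in chosen.itertuples():
        seq, chain = tr.copy_transcript(r.copy_id)
        transcripts[r.copy_id] = (r.paralog, seq, chain)
    return sim, loci, transcripts


def test_assign_read_unique_on_error_free_transcripts(loci_and_transcripts):
    sim, loci, transcripts = loci_and_transcripts
    aligner = tx.SplicedAligner(loci)
    for cid, (paralog, seq, chain) in transcripts.items():
        a = aligner.assign("r", seq)
        assert a.status == "unique"
        assert a.locus == cid
        assert len(a.exon_chain) == len(chain)


def test_assign_read_ambiguous_and_unaligned(rng):
    locus = sd._random_dna(rng, 3000)
    aligner = tx.SplicedAligner({"c1": locus, "c2": locus})
    a = aligner.assign("r", locus[500:1500])
    assert a.status == "ambiguous"
    b = aligner.assign("r", sd._random_dna(rng, 500))
    assert b.status == "unaligned"


def test_gene_models_support_and_rank(rng):
    def asg(i, locus, chain):
        return tx.ReadAssignment(f"r{i}", locus, 0, 5, "unique", chain)

    iso1 = ((0, 100), (200, 300), (400, 500))
    iso2 = ((0, 100), (400, 500))
    mono = ((0, 500),)
    assignments = (
        [asg(i, "P1", iso1) for i in range(7)]
        + [asg(100 + i, "P1", iso2) for i in range(3)]   # below support
        + [asg(200 + i, "P1", mono) for i in range(9)])  # mono-exonic
    models = tx.build_gene_models(assignments)
    assert len(models) == 1
    assert models[0].isoform == "P1_1" and models[0].support == 7
    # 70/30 two-isoform ranking
    assignments2 = ([asg(i, "P2", iso1) for i in range(70)]
                    + [asg(100 + i, "P2", iso2) for i in range(30)])
    models2 = tx.build_gene_models(assignments2)
    assert [m.isoform for m in models2] == ["P2_1", "P2_2"]
    assert models2[0].exon_chain[1] == (200, 300)


def test_detect_fusions_order_and_counts(rng):
    partner_exons = [(0, 200), (400, 600), (800, 1000)]
    family = (5_000, 25_000)
    fused_chain = ((0, 200), (400, 600), (800, 1000),
                   (6_000, 6_300), (8_000, 8_400), (9_000, 9_500),
                   (12_000, 12_800))
    family_only = ((6_000, 6_300), (8_000, 8_400))
    wrong_order = ((6_000, 6_300), (0, 200))
    mk = lambda i, ch: tx.ReadAssignment(f"r{i}", "L", 0, 3, "unique", ch)
    out = tx.detect_fusions([mk(0, fused_chain), mk(1, family_only),
                             mk(2, wrong_order)],
                            partner_exons, family, partner_name="PKD1-like")
    assert len(out) == 1
    assert out[0]["partner_exons"] == 3 and out[0]["family_exons"] == 4
    # frame-breaking junction: reported ORF shorter than the transcript
    read = "ATG" + "GCC" * 30 + "TAA" + "CCC" * 100
    out2 = tx.detect_fusions([mk(0, fused_chain)], partner_exons, family,
                             reads={"r0": read})
    assert out2[0]["fused_orf_aa"] == 31
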