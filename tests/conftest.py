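"""Shared fixtures: the default synthetic family and the discovery-to-labels
pipeline run once per session."""
import numpy as np
import pandas as pd
import pytest

from paraloscope import copynum as cn
from paraloscope import discovery as dc
from paraloscope import phylo
from paraloscope import synthdata as sd


@pytest.fixture(scope="session")
def small_sim():
    cfg = sd.SimConfig(seed=2, n_samples=6, populations={"AFR": 3, "EUR": 3})
    return sd.simulate_family(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """The default study conditions: 20 samples, 6 paralogs, fixed seed."""
    return sd.simulate_family(sd.SimConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline(default_sim):
    """Discovery, validation, projection, bootstrap NJ and paralog labels for
    every haplotype of the default simulation."""
    sim = default_sim
    tr = sim.truth
    copies = {hap: dc.find_copies(sim.assemblies[hap], tr.ancestral,
                                  haplotype_id=hap)
              for hap in sim.assemblies}
    qc = {}
    for hap, cs in copies.items():
        L = len(sim.assemblies[hap])
        qc[hap] = all(dc.validate_locus(c, cs, L) == "pass" for c in cs)
    seqs, meta = {}, {}
    for hap, cs in copies.items():
        for i, c in enumerate(cs):
            name = f"{hap}.{i}"
            seqs[name] = dc.project_to_ancestral(c.sequence, tr.ancestral)
            meta[name] = (hap, c)
    # truth labels for accuracy checks; anchors = first copy seen per paralog
    truth_label = {}
    for name, (hap, c) in meta.items():
        trh = tr.copy_coordinates[tr.copy_coordinates.haplotype == hap]
        m = trh[(trh.start == c.start) & (trh.end == c.end)]
        truth_label[name] = m.iloc[0].paralog if len(m) else None
    anchors = {}
    for name in sorted(truth_label):
        lab = truth_label[name]
        if lab is not None and lab not in anchors.values():
            anchors[name] = lab
    tree = phylo.bootstrap_support(seqs, n_reps=100, seed=1)
    assignment = phylo.assign_paralogs(tree, anchors)
    for name, (hap, c) in meta.items():
        c.paralog_label = assignment.labels[name]
    table = cn.copy_number_table(
        pd.DataFrame([{"haplotype": h, "paralog": assignment.labels[n]}
                      for n, (h, c) in meta.items()]),
        qc, tr.samples)
    return {"sim": sim, "copies": copies, "qc": qc, "seqs": seqs,
            "meta": meta, "truth_label": truth_label, "anchors": anchors,
            "tree": tree, "assignment": assignment, "cn_table": table}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
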