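"""Compile a heterogeneous interaction table into per-domain datasets.

Affinity rows are labeled by the K_d < 2000 nM binding threshold, positives
duplicated across sources are collapsed (the peptide-array source is
authoritative), contradictory (domain, peptide) pairs are discarded from
both sides, and domains with too few positives are dropped.
"""

import itertools

from sh2pep import InteractionRecord, Peptide, compile_datasets
from sh2pep.peptides import AMINO_ACIDS

windows = (Peptide(a + b + "Y" + c + "AAA")
           for a, b, c in itertools.product(AMINO_ACIDS, repeat=3))
w = [next(windows) for _ in range(120)]

records = []
records += [InteractionRecord("SRC", p, label=1, source="arrays") for p in w[:50]]
records += [InteractionRecord("GRB2", p, label=1, source="arrays") for p in w[50:80]]
# microarray rows: labeled through their affinity
records += [InteractionRecord("SRC", p, kd_nM=3500.0, source="chip") for p in w[80:110]]
# 5 contradictions: array-positive but chip-negative
records += [InteractionRecord("SRC", p, kd_nM=3500.0, source="chip") for p in w[:5]]
# 10 chip positives that duplicate array positives
records += [InteractionRecord("SRC", p, kd_nM=160.0, source="chip") for p in w[5:15]]

datasets, report = compile_datasets(records, primary_source="arrays", min_positives=40)
print(f"input rows: {report.n_input}")
print(f"chip positives shared with arrays (collapsed): {report.n_shared_positives}")
print(f"contradictory pairs discarded from both sides: {report.n_conflict_pairs}")
print(f"domains retained: {list(datasets)} (dropped: {report.dropped_domains})")
ds = datasets["SRC"]
print(f"SRC dataset: {ds.n_pos} positives, {ds.n_neg} negatives — "
      "50 - 5 conflicts = 45 positives, 30 clean negatives")
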