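"""Replay compilation bookkeeping from summary marginals.

The compiler's arithmetic (source-wise positive dedup, conflict discard,
domain filtering) can be validated against the summary statistics of a
study corpus without access to the underlying measurements: given only the
marginal counts — how many positives each source contributed, how many were
shared with the primary source, how many cross-source disagreements existed
— this module materializes a synthetic record table with exactly those
marginals and runs it through the real compilation pipeline, so every
derived count (unique positives per source, retained negatives, surviving
domains) is recomputed rather than assumed.
"""

from __future__ import annotations

import itertools
from typing import Dict, Iterator, List, Mapping, Tuple

from .compilation import (
    InteractionRecord,
    compile_datasets,
    filter_domains,
    group_by_domain,
)
from .peptides import AMINO_ACIDS, Peptide


def _distinct_windows() -> Iterator[Peptide]:
    """Deterministic stream of distinct 7-mer windows (20^4 available)."""
    for a, b, c, d in itertools.product(AMINO_ACIDS, repeat=4):
        yield Peptide(a + b + "Y" + c + d + "AA")


def compilation_replay(
    n_primary_positives: int,
    chip_sources: Mapping[str, Tuple[int, int, int]],
    n_conflicts: int,
    primary_source: str = "peptide_array",
) -> Dict[str, object]:
    """Build a record table with the given marginals and compile it.

    Parameters
    ----------
    n_primary_positives
        Positive interactions reported by the primary (peptide-array) source.
    chip_sources
        Per-source marginals ``{name: (n_positives, n_shared_with_primary,
        n_negatives)}`` for the affinity (microarray) sources.
    n_conflicts
        Number of pairs positive in the primary source but negative on a
        chip; these rows are planted and must be discarded by the compiler.

    Returns the derived counts recomputed by the compilation pipeline:
    per-source unique/shared positives, total chip positives, conflict
    discards, and the retained primary positives and chip negatives.
    """
    windows = _distinct_windows()
    primary_peps = [next(windows) for _ in range(n_primary_positives)]
    records: List[InteractionRecord] = [
        InteractionRecord("D", p, label=1, source=primary_source) for p in primary_peps
    ]

    # shared positives and conflicts draw on disjoint slices of the primary set
    cursor = 0
    conflict_peps = primary_peps[:n_conflicts]
    cursor = n_conflicts
    total_chip_pos = 0
    for source, (n_pos, n_shared, n_neg) in chip_sources.items():
        shared = primary_peps[cursor : cursor + n_shared]
        cursor += n_shared
        fresh_pos = [next(windows) for _ in range(n_pos - n_shared)]
        for p in shared + fresh_pos:
            records.append(InteractionRecord(source=source, domain_id="D", peptide=p, label=1))
        total_chip_pos += n_pos
        # negatives: plant this source's share of the conflicting pairs first
        share = round(n_conflicts * n_neg / sum(s[2] for s in chip_sources.values()))
        take = conflict_peps[:share] if source != list(chip_sources)[-1] else conflict_peps
        conflict_peps = conflict_peps[len(take) :]
        fresh_neg = [next(windows) for _ in range(n_neg - len(take))]
        for p in take + fresh_neg:
            records.append(InteractionRecord(source=source, domain_id="D", peptide=p, label=-1))

    datasets, report = compile_datasets(records, primary_source=primary_source, min_positives=0)
    ds = datasets["D"]
    n_unique_total = sum(report.n_unique_positives.values())
    # retained primary positives = positives minus the chip-unique ones kept alongside
    n_primary_retained = ds.n_pos - n_unique_total
    return {
        "n_input_records": report.n_input,
        "total_chip_positives": total_chip_pos,
        "n_shared_per_source": dict(report.n_shared_positives),
        "n_unique_per_source": dict(report.n_unique_positives),
        "n_shared_total": sum(report.n_shared_positives.values()),
        "n_unique_total": n_unique_total,
        "n_conflicts_discarded": report.n_conflict_pairs,
        "n_primary_positives_retained": n_primary_retained,
        "n_chip_negatives_retained": ds.n_neg,
    }


def domain_filter_replay(
    n_domains: int, n_below_threshold: int, min_positives: int = 40
) -> Dict[str, int]:
    """Materialize a domain panel where ``n_below_threshold`` domains sit one
    positive short of the cutoff, and count the survivors."""
    windows = _distinct_windows()
    records: List[InteractionRecord] = []
    for d in range(n_domains):
        n_pos = min_positives - 1 if d < n_below_threshold else min_positives
        for _ in range(n_pos):
            records.append(
                InteractionRecord(f"D{d:03d}", next(windows), label=1, source="arrays")
            )
    datasets = group_by_domain(records)
    kept, dropped = filter_domains(datasets, min_positives)
    return {
        "n_domains_input": len(datasets),
        "n_domains_retained": len(kept),
        "n_domains_dropped": len(dropped),
    }
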