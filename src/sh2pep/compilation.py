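"""Compile heterogeneous interaction measurements into per-domain datasets.

The training material for an SH2 binding model comes from two kinds of
experiments with different evidential value: high-density peptide arrays,
which report only confirmed (positive) interactions, and protein
microarrays, which report apparent dissociation constants and therefore
also support calling a pair non-binding.  Compilation proceeds as:

1. label microarray measurements by affinity: K_d below 2000 nM is binding,
   everything else non-binding;
2. deduplicate positives across sources, keeping the primary (peptide-array)
   source authoritative and counting the residual unique positives;
3. discard every (domain, peptide) pair on which sources disagree — a
   positive in one experiment and a negative in another is unreliable on
   both sides;
4. group by domain and drop domains with too few positives (default
   minimum 40) to fit a complex model reliably.

All bookkeeping is conserved and reported: input records are partitioned
into retained, conflict-discarded and duplicate-collapsed, with counts at
every stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .peptides import Peptide, encode_many

#: Apparent dissociation constant (nM) below which a pair counts as binding.
KD_BINDING_THRESHOLD_NM: float = 2000.0
#: Minimum positives a domain needs for model fitting to be attempted.
MIN_POSITIVES_DEFAULT: int = 40


@dataclass(frozen=True)
class InteractionRecord:
    """One measured domain-peptide pair.

    At least one of ``kd_nM`` (affinity) or ``label`` must be present.
    Labels are +1 (binding), -1 (non-binding) or 0 for a peptide that
    belongs to the unlabeled pool (observed in an assay but with no
    definitive interaction evidence).  ``source`` tags the experiment the
    row came from.
    """

    domain_id: str
    peptide: Peptide
    kd_nM: Optional[float] = None
    label: Optional[int] = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.kd_nM is None and self.label is None:
            raise ValueError(
                f"record for ({self.domain_id}, {self.peptide.residues}) carries "
                "neither an affinity nor a label"
            )
        if self.label is not None and self.label not in (1, -1, 0):
            raise ValueError(f"label must be +1, -1 or 0 (unlabeled), got {self.label}")

    @property
    def key(self) -> Tuple[str, str]:
        """Identity for dedup/conflict resolution: exact (domain, 7-mer)."""
        return (self.domain_id, self.peptide.residues)


def label_from_kd(kd_nM: float) -> int:
    """Class label from affinity: +1 iff K_d is strictly below 2000 nM."""
    if kd_nM is None or not kd_nM > 0:
        raise ValueError(f"K_d must be a positive affinity in nM, got {kd_nM!r}")
    return 1 if kd_nM < KD_BINDING_THRESHOLD_NM else -1


def assign_labels(records: Iterable[InteractionRecord]) -> List[InteractionRecord]:
    """Fill in missing labels from K_d; an explicit label wins on disagreement."""
    out = []
    for rec in records:
        if rec.label is None:
            out.append(
                InteractionRecord(
                    rec.domain_id, rec.peptide, rec.kd_nM, label_from_kd(rec.kd_nM), rec.source
                )
            )
        else:
            if rec.kd_nM is not None and rec.label in (1, -1) and label_from_kd(rec.kd_nM) != rec.label:
                warnings.warn(
                    f"explicit label {rec.label:+d} overrides K_d={rec.kd_nM} nM for "
                    f"({rec.domain_id}, {rec.peptide.residues})",
                    stacklevel=2,
                )
            out.append(rec)
    return out


def resolve_conflicts(
    records: Sequence[InteractionRecord],
) -> Tuple[List[InteractionRecord], int, int]:
    """Remove contradictory pairs and collapse exact duplicates.

    A (domain, peptide) pair that appears with both a positive and a
    negative label across sources is removed entirely from both sides.
    Duplicate (domain, peptide, label) rows collapse to the first occurrence.

    Returns ``(retained, n_conflict_pairs, n_duplicates_collapsed)``; the
    partition is conserved:
    ``len(records) == len(retained) + rows_in_conflicts + n_duplicates``.
    """
    labels_by_key: Dict[Tuple[str, str], set] = {}
    for rec in records:
        if rec.label is None:
            raise ValueError("resolve_conflicts requires labeled records; run assign_labels first")
        labels_by_key.setdefault(rec.key, set()).add(rec.label)
    # a conflict needs a positive AND a negative; pool rows (0) never conflict
    conflicted = {k for k, labs in labels_by_key.items() if {1, -1} <= labs}

    retained: List[InteractionRecord] = []
    seen: set = set()
    n_dup = 0
    for rec in records:
        if rec.key in conflicted:
            continue
        ident = (rec.key, rec.label)
        if ident in seen:
            n_dup += 1
            continue
        seen.add(ident)
        retained.append(rec)
    return retained, len(conflicted), n_dup


def deduplicate_positives(
    primary_keys: Iterable[Tuple[str, str]],
    other_positives: Mapping[str, Sequence[InteractionRecord]],
) -> Tuple[Dict[str, List[InteractionRecord]], Dict[str, int], Dict[str, int]]:
    """Remove positives already present in the primary source from the others.

    ``primary_keys`` are the (domain, peptide) identities of the primary
    (authoritative) positive set; ``other_positives`` maps a source name to
    its positive records.  Returns the surviving unique records per source
    plus per-source counts of unique and shared positives.
    """
    primary = set(primary_keys)
    unique: Dict[str, List[InteractionRecord]] = {}
    n_unique: Dict[str, int] = {}
    n_shared: Dict[str, int] = {}
    for source, recs in other_positives.items():
        kept = [r for r in recs if r.key not in primary]
        unique[source] = kept
        n_unique[source] = len(kept)
        n_shared[source] = len(recs) - len(kept)
    return unique, n_unique, n_shared


@dataclass
class DomainDataset:
    """Per-domain training material: labeled peptides plus an unlabeled pool."""

    domain_id: str
    positives: List[Peptide] = field(default_factory=list)
    negatives: List[Peptide] = field(default_factory=list)
    unlabeled: List[Peptide] = field(default_factory=list)

    def __post_init__(self) -> None:
        pos = {p.residues for p in self.positives}
        neg = {p.residues for p in self.negatives}
        overlap = pos & neg
        if overlap:
            raise ValueError(
                f"domain {self.domain_id}: peptides with both labels: {sorted(overlap)[:3]}"
            )
        if len(pos) != len(self.positives) or len(neg) != len(self.negatives):
            raise ValueError(f"domain {self.domain_id}: duplicate (peptide, label) pairs")

    @property
    def n_pos(self) -> int:
        return len(self.positives)

    @property
    def n_neg(self) -> int:
        return len(self.negatives)

    def encoded(self, scheme: str = "full20") -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (X, y, X_pool): stacked encodings and +1/-1 labels."""
        Xp = encode_many(self.positives, scheme)
        Xn = encode_many(self.negatives, scheme)
        X = np.vstack([Xp, Xn]) if len(Xp) or len(Xn) else Xp
        y = np.concatenate([np.ones(len(Xp)), -np.ones(len(Xn))])
        return X, y, encode_many(self.unlabeled, scheme)


def group_by_domain(records: Sequence[InteractionRecord]) -> Dict[str, DomainDataset]:
    """Partition clean labeled records (and unlabeled rows) into datasets."""
    pos: Dict[str, List[Peptide]] = {}
    neg: Dict[str, List[Peptide]] = {}
    unl: Dict[str, List[Peptide]] = {}
    for rec in records:
        bucket = pos if rec.label == 1 else neg if rec.label == -1 else unl
        bucket.setdefault(rec.domain_id, []).append(rec.peptide)
    out = {}
    for dom in sorted(set(pos) | set(neg) | set(unl)):
        out[dom] = DomainDataset(
            dom, pos.get(dom, []), neg.get(dom, []), unl.get(dom, [])
        )
    return out


def filter_domains(
    datasets: Mapping[str, DomainDataset], min_positives: int = MIN_POSITIVES_DEFAULT
) -> Tuple[Dict[str, DomainDataset], Dict[str, int]]:
    """Drop domains with fewer than ``min_positives`` positive interactions.

    Returns the retained datasets and a report mapping every dropped domain
    to its positive count.
    """
    retained = {d: ds for d, ds in datasets.items() if ds.n_pos >= min_positives}
    dropped = {d: ds.n_pos for d, ds in datasets.items() if ds.n_pos < min_positives}
    return retained, dropped


@dataclass
class CompilationReport:
    """Counts at every compilation stage, for auditing and replay."""

    n_input: int = 0
    n_primary_positives: int = 0
    n_other_positives: Dict[str, int] = field(default_factory=dict)
    n_unique_positives: Dict[str, int] = field(default_factory=dict)
    n_shared_positives: Dict[str, int] = field(default_factory=dict)
    n_conflict_pairs: int = 0
    n_duplicates_collapsed: int = 0
    n_retained: int = 0
    n_domains_input: int = 0
    n_domains_retained: int = 0
    dropped_domains: Dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def compile_datasets(
    records: Sequence[InteractionRecord],
    primary_source: Optional[str] = None,
    min_positives: int = MIN_POSITIVES_DEFAULT,
) -> Tuple[Dict[str, DomainDataset], CompilationReport]:
    """Full compilation pipeline: label, dedupe, de-conflict, group, filter.

    If ``primary_source`` is given, its positives are authoritative: positive
    records from other sources that duplicate a primary positive are dropped
    (and counted as shared) before conflict resolution.
    """
    report = CompilationReport(n_input=len(records))
    labeled = assign_labels(records)

    if primary_source is not None:
        primary = [r for r in labeled if r.source == primary_source]
        others = [r for r in labeled if r.source != primary_source]
        primary_pos_keys = {r.key for r in primary if r.label == 1}
        report.n_primary_positives = len(primary_pos_keys)
        by_source: Dict[str, List[InteractionRecord]] = {}
        for r in others:
            if r.label == 1:
                by_source.setdefault(r.source, []).append(r)
        unique, n_unique, n_shared = deduplicate_positives(primary_pos_keys, by_source)
        report.n_other_positives = {s: len(v) for s, v in by_source.items()}
        report.n_unique_positives = n_unique
        report.n_shared_positives = n_shared
        kept_other_pos = {id(r) for recs in unique.values() for r in recs}
        labeled = primary + [
            r for r in others if r.label != 1 or id(r) in kept_other_pos
        ]

    retained, n_conflicts, n_dup = resolve_conflicts(labeled)
    report.n_conflict_pairs = n_conflicts
    report.n_duplicates_collapsed = n_dup
    report.n_retained = len(retained)

    datasets = group_by_domain(retained)
    report.n_domains_input = len(datasets)
    kept, dropped = filter_domains(datasets, min_positives)
    report.n_domains_retained = len(kept)
    report.dropped_domains = dropped
    return kept, report
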