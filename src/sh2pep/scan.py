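"""Proteome-wide application of trained per-domain models.

Scoring every tyrosine in a proteome against every domain model would
drown real signal in biologically impossible pairs, so a candidate
(domain, site) pair must pass three eligibility filters before scoring:

1. the site's residue is tyrosine;
2. the site's phosphorylation is experimentally verified (it appears in
   the supplied phosphosite list);
3. the target protein and the domain-bearing protein share at least one
   subcellular-localization term (proteins with no localization
   annotation are skipped entirely).

Eligible windows are scored by the domain's SVM and ranked by decision
value; the top-k per domain are reported.  Peptides predicted to bind
more than a threshold number of distinct domains are flagged as
promiscuous (likely a-specific) and reported separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Set, Tuple

from .peptides import Peptide, PeptideError, encode, extract_window
from .svm import SVMModel


@dataclass
class ScanConfig:
    """Inputs and knobs for a proteome scan.

    ``models`` maps a domain id to its trained model; ``domain_proteins``
    maps a domain id to the protein that carries it (for the localization
    filter).  ``phosphosites`` holds experimentally verified
    (protein_id, 1-based Tyr position) pairs; ``localization`` maps protein
    ids to their term sets.
    """

    models: Dict[str, SVMModel]
    phosphosites: Set[Tuple[str, int]]
    localization: Dict[str, Set[str]]
    domain_proteins: Dict[str, str] = field(default_factory=dict)
    top_k: int = 50
    promiscuity_threshold: int = 40
    scheme: str = "full20"

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass(frozen=True)
class Prediction:
    domain_id: str
    protein_id: str
    site: int
    window: str
    decision_value: float
    rank: int = 0


def eligible(
    protein_id: str,
    site: int,
    domain_id: str,
    proteome: Mapping[str, str],
    config: ScanConfig,
) -> bool:
    """All three eligibility criteria for one (domain, site) candidate."""
    seq = proteome.get(protein_id)
    if seq is None:
        warnings.warn(f"unknown protein {protein_id!r}; skipped", stacklevel=2)
        return False
    if not 1 <= site <= len(seq) or seq[site - 1].upper() != "Y":
        return False
    if (protein_id, site) not in config.phosphosites:
        return False
    target_terms = config.localization.get(protein_id)
    if not target_terms:
        return False  # unannotated proteins are skipped entirely
    domain_protein = config.domain_proteins.get(domain_id, domain_id)
    domain_terms = config.localization.get(domain_protein)
    if not domain_terms:
        return False
    return bool(target_terms & domain_terms)


@dataclass
class ScanResult:
    predictions: Dict[str, List[Prediction]]  # per-domain, ranked, top-k
    promiscuous: List[Tuple[str, str, int, int]]  # (window, protein, site, n_domains)
    n_scored: int = 0

    def as_rows(self) -> List[tuple]:
        rows = []
        for dom in sorted(self.predictions):
            for p in self.predictions[dom]:
                rows.append((p.domain_id, p.protein_id, p.site, p.window, p.decision_value, p.rank))
        return rows


def scan(proteome: Mapping[str, str], config: ScanConfig) -> ScanResult:
    """Score every eligible (domain, phosphosite) pair and rank per domain.

    Ranking is by non-increasing decision value with deterministic
    (protein_id, site) lexicographic tie-breaking.  The promiscuity report
    lists windows predicted positive by more than
    ``config.promiscuity_threshold`` distinct domains.
    """
    if not config.models:
        raise ValueError("scan requires at least one trained model")

    # candidate sites: verified phosphosites present in this proteome
    candidates: List[Tuple[str, int, Peptide]] = []
    for protein_id, site in sorted(config.phosphosites):
        if protein_id not in proteome:
            continue
        seq = proteome[protein_id]
        if not 1 <= site <= len(seq) or seq[site - 1].upper() != "Y":
            continue
        try:
            pep = extract_window(seq, site)
        except PeptideError:
            continue
        candidates.append((protein_id, site, pep))

    predictions: Dict[str, List[Prediction]] = {}
    positive_domains: Dict[Tuple[str, str, int], int] = {}
    n_scored = 0
    for domain_id, model in sorted(config.models.items()):
        scored: List[Prediction] = []
        for protein_id, site, pep in candidates:
            if not eligible(protein_id, site, domain_id, proteome, config):
                continue
            dv = model.decision_value(encode(pep, config.scheme))
            n_scored += 1
            scored.append(Prediction(domain_id, protein_id, site, pep.residues, dv))
            if dv >= 0:
                key = (pep.residues, protein_id, site)
                positive_domains[key] = positive_domains.get(key, 0) + 1
        scored.sort(key=lambda p: (-p.decision_value, p.protein_id, p.site))
        predictions[domain_id] = [
            Prediction(p.domain_id, p.protein_id, p.site, p.window, p.decision_value, rank=i + 1)
            for i, p in enumerate(scored[: config.top_k])
        ]

    promiscuous = sorted(
        (
            (window, protein_id, site, n)
            for (window, protein_id, site), n in positive_domains.items()
            if n > config.promiscuity_threshold
        ),
        key=lambda t: (-t[3], t[1], t[2]),
    )
    return ScanResult(predictions=predictions, promiscuous=promiscuous, n_scored=n_scored)
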