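"""Synthetic per-domain binding problems with controlled statistical structure.

Real SH2 training data has three awkward properties: strong class imbalance
(positives up to 15x more abundant than verified negatives for some domains),
label noise from low signal-to-noise assays, and binding rules that are not
purely additive over positions (e.g. Asn at +2 and Lys at -1 being jointly,
but not individually, sufficient).  This module generates peptide datasets
with exactly those properties from an explicit, inspectable ground-truth
rule, so every downstream stage — rebalancing, model selection, the PSSM
baseline, the genome scan — can be tested end-to-end without any external
download and scored against the generating rule as an oracle.

A :class:`BindingRule` scores a window as an additive position-specific part
plus pairwise terms over *residue sets*:

* ``AND`` term: the effect fires only when both positions carry a residue
  from their respective sets (joint requirement);
* ``XOR`` term: the effect fires when exactly one of the two does (mutual
  exclusion).

A single amino acid is the singleton-set special case.  Half-alphabet XOR
rules (see :func:`make_xor_rule`) make every single one-hot feature carry
zero marginal information about the label, so a linear model is provably at
chance while a quadratic one separates perfectly — the cleanest testbed for
the linear-vs-polynomial comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .peptides import AMINO_ACIDS, FLANK_OFFSETS, Peptide, PTYR_INDEX, WINDOW_LENGTH

def _window_index(offset: int) -> int:
    """Map a flanking offset (-2..+4, never 0) to an index in the 7-mer."""
    if offset not in FLANK_OFFSETS:
        raise ValueError(f"offset {offset} not in flanking offsets {FLANK_OFFSETS}")
    return offset + PTYR_INDEX


class SamplingBudgetError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the requested counts."""


@dataclass(frozen=True)
class PairwiseTerm:
    """A non-additive dependency between two window positions.

    ``kind='AND'`` adds ``effect`` when both positions carry a residue from
    their sets; ``kind='XOR'`` adds it when exactly one does.
    """

    offset_i: int
    residues_i: FrozenSet[str]
    offset_j: int
    residues_j: FrozenSet[str]
    effect: float
    kind: str = "AND"

    def __post_init__(self) -> None:
        if self.kind not in ("AND", "XOR"):
            raise ValueError(f"unknown pairwise kind {self.kind!r}")
        if self.offset_i == self.offset_j:
            raise ValueError("pairwise term must span two distinct positions")

    def fires(self, residues: str) -> bool:
        a = residues[_window_index(self.offset_i)] in self.residues_i
        b = residues[_window_index(self.offset_j)] in self.residues_j
        return (a and b) if self.kind == "AND" else (a != b)


@dataclass
class BindingRule:
    """Ground-truth scoring rule for a synthetic SH2 domain.

    ``score >= threshold`` defines binding; observed labels are flipped with
    probability ``noise_rate`` (symmetric noise).
    """

    additive_weights: Dict[Tuple[int, str], float]
    pairwise_terms: List[PairwiseTerm]
    threshold: float = 0.0
    noise_rate: float = 0.0

    def score(self, peptide: Peptide | str) -> float:
        residues = peptide.residues if isinstance(peptide, Peptide) else Peptide(peptide).residues
        total = 0.0
        for off in FLANK_OFFSETS:
            total += self.additive_weights.get((off, residues[_window_index(off)]), 0.0)
        for term in self.pairwise_terms:
            if term.fires(residues):
                total += term.effect
        return total

    def label(self, peptide: Peptide | str) -> int:
        """Noise-free ground-truth label (+1 binding / -1 non-binding)."""
        return 1 if self.score(peptide) >= self.threshold else -1


@dataclass
class SyntheticDomainProblem:
    """One simulated domain: labeled sets, an unlabeled pool, and the rule."""

    rule: BindingRule
    positives: List[Peptide]
    negatives: List[Peptide]
    unlabeled_pool: List[Peptide]
    seed: int
    degenerate: bool = False  # flagged when one class was requested empty

    @property
    def imbalance(self) -> Optional[float]:
        if not self.negatives:
            return None
        return len(self.positives) / len(self.negatives)


def _random_window(rng: np.random.Generator, background: Optional[np.ndarray] = None) -> Peptide:
    probs = background
    flanks = rng.choice(list(AMINO_ACIDS), size=WINDOW_LENGTH - 1, p=probs)
    residues = "".join(flanks[:PTYR_INDEX]) + "Y" + "".join(flanks[PTYR_INDEX:])
    return Peptide(residues)


def sample_background(
    n: int, seed: int, frequencies: Optional[Dict[str, float]] = None
) -> List[Peptide]:
    """Draw ``n`` i.i.d. background windows (uniform residues by default)."""
    rng = np.random.default_rng(seed)
    probs = None
    if frequencies is not None:
        probs = np.array([frequencies.get(aa, 0.0) for aa in AMINO_ACIDS], dtype=float)
        probs = probs / probs.sum()
    return [_random_window(rng, probs) for _ in range(n)]


def _calibrate_threshold(
    weights: Dict[Tuple[int, str], float],
    terms: List[PairwiseTerm],
    prevalence: float,
    rng: np.random.Generator,
    n_calibration: int = 20000,
) -> float:
    rule = BindingRule(weights, terms, threshold=-np.inf)
    scores = np.array([rule.score(_random_window(rng)) for _ in range(n_calibration)])
    return float(np.quantile(scores, 1.0 - prevalence))


def make_rule(
    seed: int,
    n_pairwise: int = 1,
    noise_rate: float = 0.0,
    prevalence: float = 0.1,
    additive_scale: float = 1.0,
    pairwise_effect: float = 3.0,
    set_size: int = 6,
) -> BindingRule:
    """Build a deterministic binding rule.

    With ``n_pairwise=0`` the rule is purely additive, so a linear
    discriminator is Bayes-optimal.  With ``n_pairwise>0``, AND terms over
    residue sets of ``set_size`` amino acids are added with a large positive
    ``pairwise_effect``, giving genuine non-additive structure.  The
    threshold is calibrated so that a background (uniform-residue) peptide
    is positive with probability ``prevalence``.
    """
    if not 0.0 <= noise_rate < 0.5:
        raise ValueError("noise_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    weights = {
        (off, aa): additive_scale * float(rng.normal())
        for off in FLANK_OFFSETS
        for aa in AMINO_ACIDS
    }
    terms: List[PairwiseTerm] = []
    for _ in range(n_pairwise):
        off_i, off_j = rng.choice(FLANK_OFFSETS, size=2, replace=False)
        res_i = frozenset(rng.choice(list(AMINO_ACIDS), size=set_size, replace=False))
        res_j = frozenset(rng.choice(list(AMINO_ACIDS), size=set_size, replace=False))
        terms.append(PairwiseTerm(int(off_i), res_i, int(off_j), res_j, pairwise_effect, "AND"))
    threshold = _calibrate_threshold(weights, terms, prevalence, rng)
    return BindingRule(weights, terms, threshold=threshold, noise_rate=noise_rate)


def make_and_rule(
    seed: int,
    offset_i: int = -1,
    residue_i: str = "K",
    offset_j: int = 2,
    residue_j: str = "N",
    noise_rate: float = 0.0,
) -> BindingRule:
    """Joint-requirement rule: binding iff both residues co-occur.

    Defaults encode the canonical motivating case — Lys at -1 AND Asn at +2
    jointly required, neither sufficient alone.
    """
    term = PairwiseTerm(offset_i, frozenset(residue_i), offset_j, frozenset(residue_j), 1.0, "AND")
    return BindingRule({}, [term], threshold=0.5, noise_rate=noise_rate)


def make_xor_rule(
    seed: int, noise_rate: float = 0.0, n_letters: int = 4
) -> Tuple[BindingRule, Dict[str, float]]:
    """Balanced mutual-exclusion rule: linear models are exactly at chance.

    ``n_letters`` residues are drawn as the working alphabet; two positions
    are each assigned a random half of it, and a peptide binds iff exactly
    one position carries a residue from its half.  Returns the rule together
    with the matching background frequency table (uniform over the working
    alphabet) to pass to :func:`sample_problem`.

    Under that background every single (position, residue) indicator has
    P(binding | indicator) = 1/2, so no linear functional of the one-hot
    encoding beats AUC 0.5, while a degree-2 model — which sees
    position-pair products — separates perfectly.  The default 4-letter
    alphabet keeps the 16 residue-pair cells at the interacting positions
    well populated at realistic sample sizes.
    """
    if n_letters < 2 or n_letters % 2:
        raise ValueError("n_letters must be an even number >= 2")
    rng = np.random.default_rng(seed)
    letters = list(rng.choice(list(AMINO_ACIDS), size=n_letters, replace=False))
    off_i, off_j = rng.choice(FLANK_OFFSETS, size=2, replace=False)
    half_i = frozenset(rng.choice(letters, size=n_letters // 2, replace=False))
    half_j = frozenset(rng.choice(letters, size=n_letters // 2, replace=False))
    term = PairwiseTerm(int(off_i), half_i, int(off_j), half_j, 1.0, "XOR")
    rule = BindingRule({}, [term], threshold=0.5, noise_rate=noise_rate)
    background = {aa: 1.0 / n_letters for aa in letters}
    return rule, background


def sample_problem(
    rule: BindingRule,
    n_pos: int,
    n_neg: int,
    n_unlabeled: int,
    seed: int,
    background: Optional[Dict[str, float]] = None,
    budget: int = 1_000_000,
) -> SyntheticDomainProblem:
    """Draw a labeled problem with the exact requested class counts.

    Peptides are drawn i.i.d. from the background distribution and assigned
    their ground-truth class by the rule; observed labels are then flipped
    with probability ``rule.noise_rate``.  Rejection sampling keeps drawing
    until both classes reach their quota or ``budget`` draws are exhausted.
    The unlabeled pool is a plain background sample whose hidden labels stay
    recomputable through ``rule.label``.
    """
    if n_pos < 0 or n_neg < 0 or n_unlabeled < 0:
        raise ValueError("requested counts must be non-negative")
    rng = np.random.default_rng(seed)
    probs = None
    if background is not None:
        probs = np.array([background.get(aa, 0.0) for aa in AMINO_ACIDS], dtype=float)
        probs = probs / probs.sum()

    positives: List[Peptide] = []
    negatives: List[Peptide] = []
    draws = 0
    while (len(positives) < n_pos or len(negatives) < n_neg) and draws < budget:
        pep = _random_window(rng, probs)
        draws += 1
        true_label = rule.label(pep)
        observed = true_label
        if rule.noise_rate > 0 and rng.random() < rule.noise_rate:
            observed = -observed
        if observed > 0 and len(positives) < n_pos:
            positives.append(pep)
        elif observed < 0 and len(negatives) < n_neg:
            negatives.append(pep)
    if len(positives) < n_pos or len(negatives) < n_neg:
        raise SamplingBudgetError(
            f"could not draw {n_pos} positives / {n_neg} negatives within "
            f"{budget} draws (got {len(positives)}/{len(negatives)}); the rule's "
            "background acceptance rate is too extreme"
        )
    pool = [_random_window(rng, probs) for _ in range(n_unlabeled)]
    return SyntheticDomainProblem(
        rule=rule,
        positives=positives,
        negatives=negatives,
        unlabeled_pool=pool,
        seed=seed,
        degenerate=(n_pos == 0 or n_neg == 0),
    )


def problem_to_records(problem: SyntheticDomainProblem, domain_id: str) -> "pd.DataFrame":
    """Emit the problem in the interaction-table TSV schema the compiler reads.

    Labeled peptides carry explicit +1/-1 labels; the unlabeled pool is
    emitted with label 0 (source ``pool``), matching the
    high-density-array situation where only positives are observed.
    """
    import pandas as pd

    rows = []
    for pep in problem.positives:
        rows.append((domain_id, pep.residues, "", 1, "synthetic"))
    for pep in problem.negatives:
        rows.append((domain_id, pep.residues, "", -1, "synthetic"))
    for pep in problem.unlabeled_pool:
        rows.append((domain_id, pep.residues, "", 0, "pool"))
    return pd.DataFrame(rows, columns=["domain_id", "peptide", "kd_nM", "label", "source"])


def embed_in_proteome(
    windows: Sequence[Peptide],
    seed: int,
    flank_length: int = 20,
    protein_prefix: str = "SYN",
) -> Tuple[Dict[str, str], List[Tuple[str, int]]]:
    """Plant peptide windows inside random synthetic proteins.

    Returns ``(proteome, sites)`` where ``proteome`` maps protein id to
    sequence and ``sites`` lists the (protein_id, 1-based Tyr position) of
    every planted window — the ground truth for scan-recovery tests.  Pad
    symbols in a window are replaced by random residues, so the re-extracted
    window may differ at padded positions only.
    """
    rng = np.random.default_rng(seed)
    proteome: Dict[str, str] = {}
    sites: List[Tuple[str, int]] = []
    for k, pep in enumerate(windows):
        left = "".join(rng.choice(list(AMINO_ACIDS), size=flank_length))
        right = "".join(rng.choice(list(AMINO_ACIDS), size=flank_length))
        core = "".join(
            ch if ch != "-" else str(rng.choice(list(AMINO_ACIDS))) for ch in pep.residues
        )
        pid = f"{protein_prefix}{k:04d}"
        proteome[pid] = left + core + right
        sites.append((pid, flank_length + PTYR_INDEX + 1))
    return proteome, sites
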