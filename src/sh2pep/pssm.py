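"""Position-specific scoring-matrix baseline with relative-score thresholding.

The classical linear comparator: a 19 x 6 weight matrix (cysteine is not
represented, reflecting its exclusion from the oriented peptide array
libraries such matrices are usually trained on) scores a peptide as the dot
product between vec(W) and the 114-dimensional Cys-free one-hot encoding.

The default weights are frequency differences,

    W[a, j] = freq(a at position j | positives) - freq(a at position j | background),

geometrically the difference vector between the center of mass of the
positive set and of the overall peptide population.  An optional log-odds
transform (pseudocount 1) is available behind a flag.

Classification uses a *relative* score: the raw score divided by a
reference score S_ref calibrated so that a fixed small percentile (default
4.5%) of a large background window population scores at or above it.  A
relative score >= 1 predicts binding.  Being strictly linear and
positives-only, this baseline is structurally blind to non-additive
inter-position dependencies — the mechanism the kernel SVM is built to
capture.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, log
from typing import Iterable, Optional, Sequence

import numpy as np

from .peptides import AMINO_ACIDS_NO_CYS, FLANK_OFFSETS, Peptide, encode, encode_many

#: Default reference percentile: the top share of background windows whose
#: raw score defines S_ref (average of the 3.5% / 5.5% values estimated on
#: two representative domains in the original SMALI calibration).
REFERENCE_PERCENTILE_DEFAULT: float = 4.5


class CalibrationError(ValueError):
    """Raised when the reference score cannot be calibrated."""


@dataclass
class WeightMatrix:
    """19 x 6 PSSM with an optional calibrated reference score.

    Rows follow :data:`~sh2pep.peptides.AMINO_ACIDS_NO_CYS`, columns the
    flanking offsets (-2, -1, +1, +2, +3, +4).
    """

    weights: np.ndarray
    s_ref: Optional[float] = None
    percentile: float = REFERENCE_PERCENTILE_DEFAULT

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(AMINO_ACIDS_NO_CYS), len(FLANK_OFFSETS)):
            raise ValueError(
                f"weight matrix must be {len(AMINO_ACIDS_NO_CYS)} x {len(FLANK_OFFSETS)}, "
                f"got {self.weights.shape}"
            )

    @property
    def vec(self) -> np.ndarray:
        """Position-major flattening matching the noCys19 encoding layout."""
        return self.weights.T.reshape(-1)

    @property
    def calibrated(self) -> bool:
        return self.s_ref is not None


def _position_frequencies(peptides: Sequence[Peptide | str]) -> np.ndarray:
    """freq(a at position j | set): counts over peptides, Cys/pads excluded
    from the numerator, peptide count as the denominator."""
    X = encode_many(peptides, "noCys19")
    if len(X) == 0:
        raise ValueError("cannot compute frequencies of an empty peptide set")
    counts = X.sum(axis=0) / len(X)
    return counts.reshape(len(FLANK_OFFSETS), len(AMINO_ACIDS_NO_CYS)).T


def build_pssm(
    positives: Sequence[Peptide | str],
    background: Sequence[Peptide | str],
    transform: str = "diff",
    pseudocount: float = 1.0,
) -> WeightMatrix:
    """Train a weight matrix from positive peptides against a background.

    ``transform='diff'`` (default) gives the plain frequency-difference
    matrix; ``'logodds'`` gives log((c_pos + p) / (c_bg + p)) on
    pseudocounted per-position counts.
    """
    if not positives or not background:
        raise ValueError("build_pssm requires non-empty positive and background sets")
    f_pos = _position_frequencies(positives)
    f_bg = _position_frequencies(background)
    if transform == "diff":
        W = f_pos - f_bg
    elif transform == "logodds":
        c_pos = f_pos * len(positives) + pseudocount
        c_bg = f_bg * len(background) + pseudocount
        W = np.log((c_pos / c_pos.sum(axis=0)) / (c_bg / c_bg.sum(axis=0)))
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return WeightMatrix(W)


def raw_score(matrix: WeightMatrix, peptide: Peptide | str) -> float:
    """vec(W) . x on the Cys-free encoding; Cys and pad positions score 0."""
    return float(matrix.vec @ encode(peptide, "noCys19"))


def raw_scores(matrix: WeightMatrix, peptides: Iterable[Peptide | str]) -> np.ndarray:
    return encode_many(peptides, "noCys19") @ matrix.vec


def calibrate_reference(
    matrix: WeightMatrix,
    proteome_windows: Sequence[Peptide | str],
    percentile: float = REFERENCE_PERCENTILE_DEFAULT,
) -> WeightMatrix:
    """Set S_ref so the top ``percentile`` % of background windows reach it.

    S_ref is the k-th highest raw score over the window population with
    k = ceil(percentile/100 * N); for distinct scores exactly k windows then
    score >= S_ref.  Requires at least 100 windows for the percentile to be
    meaningful.
    """
    n = len(proteome_windows)
    if n < 100:
        raise CalibrationError(f"need >= 100 windows to calibrate, got {n}")
    if not 0.0 < percentile < 100.0:
        raise CalibrationError(f"percentile must lie in (0, 100), got {percentile}")
    scores = np.sort(raw_scores(matrix, proteome_windows))[::-1]
    k = ceil(percentile / 100.0 * n)
    s_ref = float(scores[k - 1])
    if s_ref <= 0:
        raise CalibrationError(
            f"reference score {s_ref:.4g} is not positive; the matrix does not "
            "separate its positives from this background at the requested percentile"
        )
    return WeightMatrix(matrix.weights.copy(), s_ref=s_ref, percentile=percentile)


def relative_score(matrix: WeightMatrix, peptide: Peptide | str) -> float:
    """Raw score over S_ref; the unit threshold then defines binding."""
    if not matrix.calibrated:
        raise CalibrationError("weight matrix has no reference score; calibrate first")
    return raw_score(matrix, peptide) / matrix.s_ref


def relative_scores(matrix: WeightMatrix, peptides: Iterable[Peptide | str]) -> np.ndarray:
    if not matrix.calibrated:
        raise CalibrationError("weight matrix has no reference score; calibrate first")
    return raw_scores(matrix, peptides) / matrix.s_ref


def predict_binding(matrix: WeightMatrix, peptide: Peptide | str) -> bool:
    """Binding iff relative score >= 1 (boundary inclusive)."""
    return relative_score(matrix, peptide) >= 1.0
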