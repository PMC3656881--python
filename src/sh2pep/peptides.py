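"""Phosphotyrosine-centered peptide windows and their one-hot encodings.

An SH2 domain reads a short linear stretch of a target protein around a
phosphorylated tyrosine.  Following the convention in the SH2 specificity
literature, the window covers offsets -2..+4 around the pTyr (offset 0), i.e.
seven residues with the tyrosine fixed at index 2.  The six flanking
positions are one-hot encoded position-major:

* ``full20`` -- 20 amino-acid slots per position, 20 x 6 = 120 dimensions
  (the central Tyr is constant and never encoded);
* ``noCys19`` -- the cysteine slot is dropped, 19 x 6 = 114 dimensions, the
  layout used by SMALI-style weight matrices.

Padded positions (windows truncated by a protein terminus) encode as
all-zero blocks, as do ambiguity codes (B/J/O/U/X/Z), which trigger a
warning rather than an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import numpy as np

#: The 20 standard amino acids in fixed alphabetical one-letter order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
#: Alphabet with cysteine removed, used by the PSSM (SMALI-style) encoding.
AMINO_ACIDS_NO_CYS: str = "ADEFGHIKLMNPQRSTVWY"
#: Pad symbol for window positions falling outside the protein sequence.
PAD: str = "-"
#: Ambiguity / non-standard codes encoded as all-zero blocks with a warning.
AMBIGUOUS: str = "BJOUXZ"

#: Flanking offsets relative to the pTyr, in window order.
FLANK_OFFSETS: Tuple[int, ...] = (-2, -1, 1, 2, 3, 4)
WINDOW_LENGTH: int = 7
PTYR_INDEX: int = 2  # index of the central Tyr inside the 7-mer

FULL20_DIM: int = len(AMINO_ACIDS) * len(FLANK_OFFSETS)  # 120
NOCYS19_DIM: int = len(AMINO_ACIDS_NO_CYS) * len(FLANK_OFFSETS)  # 114

SCHEMES = ("full20", "noCys19")

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_AA_INDEX_NO_CYS = {aa: i for i, aa in enumerate(AMINO_ACIDS_NO_CYS)}


class PeptideError(ValueError):
    """Raised for malformed peptide windows or extraction sites."""


@dataclass(frozen=True)
class Peptide:
    """A 7-residue pTyr-centered window, optionally with provenance.

    Parameters
    ----------
    residues
        Exactly seven characters over the amino-acid alphabet plus the pad
        symbol ``-``, with ``Y`` at index 2 (the phosphotyrosine).
    protein_id, site
        Optional provenance: source protein accession and the 1-based
        position of the central tyrosine in that protein.
    """

    residues: str
    protein_id: Optional[str] = None
    site: Optional[int] = None

    def __post_init__(self) -> None:
        residues = self.residues.upper()
        object.__setattr__(self, "residues", residues)
        if len(residues) != WINDOW_LENGTH:
            raise PeptideError(
                f"peptide window must have length {WINDOW_LENGTH}, "
                f"got {len(residues)!r} for {residues!r}"
            )
        if residues[PTYR_INDEX] != "Y":
            raise PeptideError(
                f"central residue (index {PTYR_INDEX}) must be Y, got "
                f"{residues[PTYR_INDEX]!r} in {residues!r}"
            )
        for ch in residues:
            if ch not in AMINO_ACIDS and ch != PAD and ch not in AMBIGUOUS:
                raise PeptideError(f"invalid residue character {ch!r} in {residues!r}")

    @property
    def flanks(self) -> str:
        """The six flanking residues in window order (central Tyr dropped)."""
        return self.residues[:PTYR_INDEX] + self.residues[PTYR_INDEX + 1 :]

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.residues


def extract_window(protein_sequence: str, site: int) -> Peptide:
    """Extract the pTyr-centered 7-mer around a 1-based tyrosine position.

    Positions falling outside the protein are filled with ``-`` so that
    N- and C-terminal sites still yield fixed-length windows.

    Raises
    ------
    PeptideError
        If ``site`` is out of range or the residue there is not tyrosine.
    """
    seq = protein_sequence.upper()
    if not 1 <= site <= len(seq):
        raise PeptideError(
            f"site {site} out of range for sequence of length {len(seq)}"
        )
    if seq[site - 1] != "Y":
        raise PeptideError(
            f"residue at site {site} is {seq[site - 1]!r}, expected 'Y'"
        )
    chars = []
    for off in range(-PTYR_INDEX, WINDOW_LENGTH - PTYR_INDEX):
        pos = site - 1 + off
        chars.append(seq[pos] if 0 <= pos < len(seq) else PAD)
    return Peptide("".join(chars), site=site)


def encode(peptide: Peptide | str, scheme: str = "full20") -> np.ndarray:
    """One-hot encode a peptide window.

    Returns a float vector of length 120 (``full20``) or 114 (``noCys19``),
    position-major with amino acids in fixed alphabetical order inside each
    block.  Pad symbols, and cysteine under ``noCys19``, contribute all-zero
    blocks.
    """
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    if scheme == "full20":
        alphabet, index = AMINO_ACIDS, _AA_INDEX
    elif scheme == "noCys19":
        alphabet, index = AMINO_ACIDS_NO_CYS, _AA_INDEX_NO_CYS
    else:
        raise ValueError(f"unknown encoding scheme {scheme!r}; expected one of {SCHEMES}")
    block = len(alphabet)
    vec = np.zeros(block * len(FLANK_OFFSETS), dtype=float)
    for j, aa in enumerate(peptide.flanks):
        if aa == PAD:
            continue
        if aa in AMBIGUOUS or (scheme == "noCys19" and aa == "C"):
            if aa in AMBIGUOUS:
                warnings.warn(
                    f"ambiguous residue {aa!r} in {peptide.residues!r} encoded as zeros",
                    stacklevel=2,
                )
            continue
        vec[j * block + index[aa]] = 1.0
    return vec


def decode(vector: np.ndarray, scheme: str = "full20") -> Peptide:
    """Invert :func:`encode`: recover the window (zero blocks decode to pads).

    Exact round-trip holds for full20 encodings of pad-free peptides over the
    20-letter alphabet; pad and ambiguous positions both come back as ``-``.
    """
    alphabet = AMINO_ACIDS if scheme == "full20" else AMINO_ACIDS_NO_CYS
    block = len(alphabet)
    vec = np.asarray(vector)
    if vec.shape != (block * len(FLANK_OFFSETS),):
        raise ValueError(
            f"expected vector of length {block * len(FLANK_OFFSETS)} for {scheme}"
        )
    flanks = []
    for j in range(len(FLANK_OFFSETS)):
        chunk = vec[j * block : (j + 1) * block]
        hot = np.nonzero(chunk)[0]
        if len(hot) > 1:
            raise ValueError(f"position block {j} has {len(hot)} bits set")
        flanks.append(alphabet[hot[0]] if len(hot) == 1 else PAD)
    residues = "".join(flanks[:PTYR_INDEX]) + "Y" + "".join(flanks[PTYR_INDEX:])
    return Peptide(residues)


def encode_many(peptides: Iterable[Peptide | str], scheme: str = "full20") -> np.ndarray:
    """Stack encodings of an iterable of peptides into an (n, dim) matrix."""
    rows = [encode(p, scheme) for p in peptides]
    if not rows:
        dim = FULL20_DIM if scheme == "full20" else NOCYS19_DIM
        return np.zeros((0, dim))
    return np.vstack(rows)
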