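"""Extract a pTyr-centered window from a protein and one-hot encode it.

The model input is the 7-residue stretch at offsets -2..+4 around a
phosphotyrosine; the six flanking residues are one-hot encoded into a
20 x 6 = 120-dimensional binary vector (the constant central Tyr is not
encoded).  The PSSM baseline uses a Cys-free 19 x 6 = 114 variant.
"""

from sh2pep import FULL20_DIM, NOCYS19_DIM, decode, encode, extract_window

protein = "MKNGYENPTAK"
pep = extract_window(protein, site=5)  # 1-based position of the tyrosine
print(f"window around Y5 of {protein}: {pep.residues}")

v120 = encode(pep, "full20")
v114 = encode(pep, "noCys19")
print(f"full20 encoding: {int(v120.sum())} bits set in {v120.shape[0]} dims "
      f"(= {FULL20_DIM}); one bit per flanking residue")
print(f"noCys19 encoding: {int(v114.sum())} bits set in {v114.shape[0]} dims (= {NOCYS19_DIM})")

edge = extract_window("YAAAA", site=1)
print(f"N-terminal site pads missing offsets: {edge.residues!r}")
print(f"decode inverts encode: {decode(v120).residues} == {pep.residues}")
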