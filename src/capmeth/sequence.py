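"""Low-level sequence helpers shared by the simulator, aligner and caller.

Coordinates are 0-based, half-open throughout. "Watson" is the forward
reference strand; "Crick" is its reverse complement. A cytosine on the Crick
strand sits at a forward-strand G.
"""

from __future__ import annotations

import numpy as np

# Integer encoding used for vectorised comparisons. N (and any other letter)
# maps to 4 and never matches anything.
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

A, C, G, T = 0, 1, 2, 3

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_CT_TABLE = str.maketrans("Cc", "Tt")
_GA_TABLE = str.maketrans("Gg", "Aa")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def ct_convert(seq: str) -> str:
    """Apply in-silico bisulfite conversion C->T (Watson-informative space)."""
    return seq.translate(_CT_TABLE)


def ga_convert(seq: str) -> str:
    """Apply G->A (the Crick-informative space seen on forward coordinates)."""
    return seq.translate(_GA_TABLE)


def classify_context(seq: str, pos: int, strand: str) -> str:
    """Classify the trinucleotide context of a cytosine.

    ``seq`` is the forward-strand chromosome sequence. For ``strand == '+'``
    the cytosine is a forward-strand C at ``pos``; for ``'-'`` it is a Crick
    cytosine, i.e. a forward-strand G at ``pos`` whose context runs leftwards.
    Cytosines within 2 bp of a chromosome end that cannot be classified are
    CHH by convention.
    """
    n = len(seq)
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(f"no forward-strand cytosine at position {pos}")
        if pos + 1 < n and seq[pos + 1] == "G":
            return "CpG"
        if pos + 2 < n and seq[pos + 2] == "G":
            return "CHG"
        return "CHH"
    if strand == "-":
        if seq[pos] != "G":
            raise ValueError(f"no reverse-strand cytosine at position {pos}")
        if pos - 1 >= 0 and seq[pos - 1] == "C":
            return "CpG"
        if pos - 2 >= 0 and seq[pos - 2] == "C":
            return "CHG"
        return "CHH"
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")
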