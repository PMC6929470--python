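"""Standard genetic code tables for the 61 sense codons.

Codons are indexed 0..60 in lexicographic (A<C<G<T) order with the three
stop codons (TAA, TAG, TGA) removed.  All selection machinery in this
package works on these integer codes; translation to/from nucleotide
strings happens only at the IO boundary.
"""

from __future__ import annotations

import itertools

import numpy as np

NUCLEOTIDES = "ACGT"

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = ("TAA", "TAG", "TGA")

#: the 61 sense codons in lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)
    if _CODON_TABLE["".join(c)] != "*"
)
N_CODONS = len(SENSE_CODONS)  # 61

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: amino acid encoded by each sense codon, aligned with SENSE_CODONS
AMINO_ACIDS: tuple[str, ...] = tuple(_CODON_TABLE[c] for c in SENSE_CODONS)

_TRANSITION_PAIRS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a→b is a transition."""
    return (a, b) in _TRANSITION_PAIRS


def translate(codon: str) -> str:
    """Amino acid (one letter, '*' for stop) for an unambiguous codon."""
    return _CODON_TABLE[codon.upper().replace("U", "T")]


def _single_change_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean 61x61 tables: single-nt change, transition, nonsynonymous."""
    n = N_CODONS
    single = np.zeros((n, n), dtype=bool)
    transition = np.zeros((n, n), dtype=bool)
    nonsyn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [p for p in range(3) if ci[p] != cj[p]]
            if len(diff) != 1:
                continue
            p = diff[0]
            single[i, j] = True
            transition[i, j] = is_transition(ci[p], cj[p])
            nonsyn[i, j] = AMINO_ACIDS[i] != AMINO_ACIDS[j]
    return single, transition, nonsyn


SINGLE_CHANGE, IS_TRANSITION, IS_NONSYN = _single_change_tables()

#: position of the differing nucleotide for single-change pairs (else -1)
_DIFF_POS = np.full((N_CODONS, N_CODONS), -1, dtype=np.int8)
#: target nucleotide index (into NUCLEOTIDES) for single-change pairs
_TARGET_NT = np.full((N_CODONS, N_CODONS), -1, dtype=np.int8)
for _i, _ci in enumerate(SENSE_CODONS):
    for _j, _cj in enumerate(SENSE_CODONS):
        if SINGLE_CHANGE[_i, _j]:
            _p = next(p for p in range(3) if _ci[p] != _cj[p])
            _DIFF_POS[_i, _j] = _p
            _TARGET_NT[_i, _j] = NUCLEOTIDES.index(_cj[_p])


def codon_compatibility(codon: str) -> np.ndarray:
    """Indicator vector over the 61 sense codons compatible with a
    possibly ambiguous/gapped codon string.

    A gap character or fully unresolvable codon yields the all-ones vector
    (missing data).  Stop codons are never compatible.
    """
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    if any(ch in "-.?" for ch in codon):
        return np.ones(N_CODONS, dtype=bool)
    sets = []
    for ch in codon:
        if ch not in IUPAC:
            raise ValueError(f"invalid nucleotide character {ch!r} in codon {codon!r}")
        sets.append(IUPAC[ch])
    mask = np.zeros(N_CODONS, dtype=bool)
    for a in sets[0]:
        for b in sets[1]:
            for c in sets[2]:
                idx = CODON_INDEX.get(a + b + c)
                if idx is not None:
                    mask[idx] = True
    if not mask.any():
        raise ValueError(f"codon {codon!r} is compatible only with stop codons")
    return mask
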