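"""Genetic-code tables shared by the codon and amino-acid machinery.

The standard code and the bacterial/plastid code (NCBI table 11) have the
same 61 sense codons and the same stop triplets (TAA, TAG, TGA), so a single
sense-codon table serves chloroplast genes; the table id is kept as a config
field for future codes.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"
NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

#: amino acids in the order used by PAML-style empirical matrix files
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

THREE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

GAP_CODON = -1  # sentinel for gap/ambiguous codons, only legal pre-cleaning

_PURINES = frozenset("AG")


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


@lru_cache(maxsize=4)
def code_tables(table_id: int = 1):
    """Sense codons, stops and translation for an NCBI code table.

    Returns (codons, codon_index, stop_codons, aa_of_codon) where ``codons``
    is the tuple of sense codons in TCAG lexicographic order and
    ``aa_of_codon`` maps codon index -> amino-acid index in PAML order.
    """
    table = CodonTable.unambiguous_dna_by_id[table_id]
    all_codons = [a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES]
    stops = frozenset(table.stop_codons)
    codons = tuple(c for c in all_codons if c not in stops)
    codon_index = {c: i for i, c in enumerate(codons)}
    aa_of_codon = np.array([AA_INDEX[table.forward_table[c]] for c in codons], dtype=np.int8)
    return codons, codon_index, stops, aa_of_codon


@lru_cache(maxsize=4)
def codon_pair_structure(table_id: int = 1):
    """Single-nucleotide codon neighbour structure for GY94-type matrices.

    Returns arrays (i, j, transition, nonsynonymous) over ordered pairs of
    sense codons that differ at exactly one position.
    """
    codons, _, _, aa = code_tables(table_id)
    n = len(codons)
    ii, jj, ts, nonsyn = [], [], [], []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            diffs = [k for k in range(3) if codons[i][k] != codons[j][k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            ii.append(i)
            jj.append(j)
            ts.append(_is_transition(codons[i][k], codons[j][k]))
            nonsyn.append(aa[i] != aa[j])
    return (np.array(ii), np.array(jj),
            np.array(ts, dtype=bool), np.array(nonsyn, dtype=bool))


def translate_codon_indices(codons: np.ndarray, table_id: int = 1) -> np.ndarray:
    """Map an array of sense-codon indices to amino-acid indices."""
    _, _, _, aa = code_tables(table_id)
    return aa[codons]
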