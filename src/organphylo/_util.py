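"""Small shared helpers: strand arithmetic, coordinate conversion, codon tables."""

from __future__ import annotations

from Bio.Data import CodonTable

_COMPLEMENT = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
BASES = "ACGT"

GAP = "-"
MISSING = "N"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """GFF3 1-based inclusive -> 0-based half-open.

    The single audited conversion point: every coordinate entering the package
    passes through here, and ``to_gff`` is its exact inverse.
    """
    return start_1based - 1, end_1based


def to_gff(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> GFF3 1-based inclusive. Inverse of :func:`to_internal`."""
    return start0 + 1, end0


def codon_table(table_id: int = 1) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[table_id]


def translate_codon(codon: str, table_id: int = 1) -> str:
    """One-letter amino acid, or '*' for a stop codon."""
    tbl = codon_table(table_id)
    if codon in tbl.stop_codons:
        return "*"
    return tbl.forward_table[codon]


def is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


def canonical_rotation(motif: str) -> str:
    """Lexicographically smallest rotation of a repeat motif."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def is_primitive(motif: str) -> bool:
    """True if the motif is not itself a repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True
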