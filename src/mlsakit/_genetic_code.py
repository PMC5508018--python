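"""Standard genetic code lookups shared by diversity and synthetic_data.

Built from Biopython's codon table (NCBI table 1). Codons are plain
uppercase DNA strings.
"""
from __future__ import annotations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

BASES = "ACGT"
UNAMBIGUOUS = frozenset(BASES)

#: codon -> one-letter amino acid, sense codons only
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: the 61 sense codons, in lexicographic order (stable indexing for simulation)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def is_transition(b1: str, b2: str) -> bool:
    """True if b1->b2 is a purine<->purine or pyrimidine<->pyrimidine change."""
    return (b1 in _PURINES and b2 in _PURINES) or (
        b1 in _PYRIMIDINES and b2 in _PYRIMIDINES
    )


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def is_synonymous(c1: str, c2: str) -> bool:
    """True if both are sense codons encoding the same amino acid."""
    return CODON_TO_AA[c1] == CODON_TO_AA[c2]
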