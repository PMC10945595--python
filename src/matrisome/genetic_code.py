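"""Standard nuclear genetic code and small codon utilities.

Built once from Biopython's table 1; alternative codes are out of scope.
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

NUCLEOTIDES = "ACGT"

_tbl = unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_tbl.forward_table)
for _stop in _tbl.stop_codons:
    CODON_TO_AA[_stop] = "*"
STOP_CODONS = frozenset(_tbl.stop_codons)
SENSE_CODONS = tuple(sorted(c for c, aa in CODON_TO_AA.items() if aa != "*"))

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def translate_codon(codon: str) -> str:
    """Amino acid for a codon; '*' for stop. Raises on ambiguous codons."""
    aa = CODON_TO_AA.get(codon)
    if aa is None:
        raise ValueError(f"cannot translate codon {codon!r}")
    return aa


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def is_transition(a: str, b: str) -> bool:
    """True for purine<->purine or pyrimidine<->pyrimidine changes."""
    if a == b:
        raise ValueError("not a substitution")
    return (a in _PURINES) == (b in _PURINES)


def codon_neighbors(codon: str):
    """Yield (position, new_nucleotide, neighbor_codon) for all 9 single-nt
    neighbors of a codon."""
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[pos]:
                yield pos, nt, codon[:pos] + nt + codon[pos + 1:]
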