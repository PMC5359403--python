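"""Genetic-code bookkeeping for codon-usage analysis.

Uses the bacterial/archaeal genetic code (NCBI translation table 11), whose
degeneracy classes coincide with the standard code. Ser, Leu and Arg are
treated as single six-fold degenerate families rather than split 2+4 boxes,
matching the plain definition of relative synonymous codon usage.

The informative comparison axis excludes the three stop codons and the two
non-degenerate amino acids Met (ATG) and Trp (TGG), leaving 59 codons.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[11]

BASES = "ACGT"

#: all 64 codons in lexicographic order
ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
)

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: codon -> one-letter amino acid, stops excluded
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

#: amino acid -> tuple of its synonymous codons (lexicographic)
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon in ALL_CODONS:
    if _codon in STOP_CODONS:
        continue
    AA_TO_CODONS.setdefault(CODON_TO_AA[_codon], ())
AA_TO_CODONS = {
    aa: tuple(c for c in ALL_CODONS if c not in STOP_CODONS and CODON_TO_AA[c] == aa)
    for aa in AA_TO_CODONS
}

#: amino acid -> degeneracy n_i (number of synonymous codons)
DEGENERACY: dict[str, int] = {aa: len(cs) for aa, cs in AA_TO_CODONS.items()}

#: amino acids with n_i >= 2, alphabetical
DEGENERATE_AAS: tuple[str, ...] = tuple(
    sorted(aa for aa, n in DEGENERACY.items() if n >= 2)
)

#: the 59-codon comparison axis: synonymous codons of degenerate amino acids,
#: grouped by amino acid (alphabetical), codons lexicographic within a group
CANONICAL_CODONS: tuple[str, ...] = tuple(
    c for aa in DEGENERATE_AAS for c in AA_TO_CODONS[aa]
)

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CANONICAL_CODONS)}

#: amino acid of each canonical-axis position
CANONICAL_AA: tuple[str, ...] = tuple(CODON_TO_AA[c] for c in CANONICAL_CODONS)

N_INFORMATIVE_CODONS = len(CANONICAL_CODONS)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_valid_dna(seq: str, allow_n: bool = True) -> bool:
    allowed = set("ACGTN" if allow_n else "ACGT")
    return set(seq.upper()) <= allowed
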