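"""Codon-usage metrics: codon counts, RSCU, SCUO, GC and GC3 content.

RSCU (relative synonymous codon usage) is the ratio of a codon's observed
count to the count expected if all synonymous codons for its amino acid
were used equally:

    RSCU_ij = x_ij / ((1/n_i) * sum_j x_ij)

where x_ij is the count of codon j of amino acid i and n_i the amino
acid's degeneracy. RSCU = 1 means no bias; the sum over an amino acid's
codons equals n_i.

SCUO (synonymous codon usage order) is a Shannon-entropy bias score.
For each degenerate amino acid i with total count x_i > 0:

    H_i = -sum_j p_ij log2 p_ij,   p_ij = x_ij / x_i   (0 log 0 = 0)
    O_i = (log2 n_i - H_i) / log2 n_i            in [0, 1]

and the genome-level SCUO is the count-weighted mean of O_i over the
degenerate amino acids present. SCUO = 0 means uniform synonymous usage;
SCUO = 1 means one codon per amino acid (maximal bias).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genetics import (
    ALL_CODONS,
    AA_TO_CODONS,
    CANONICAL_AA,
    CANONICAL_CODONS,
    CODON_INDEX,
    DEGENERACY,
    DEGENERATE_AAS,
)


@dataclass
class CodonCountTable:
    """Counts of each of the 64 codons over a set of in-frame CDS."""

    counts: dict[str, int]
    n_codons: int
    n_skipped: int = 0
    source_id: str = ""

    def __post_init__(self) -> None:
        for c in ALL_CODONS:
            self.counts.setdefault(c, 0)
        total = sum(self.counts.values())
        if total != self.n_codons:
            raise ValueError(
                f"count total {total} != n_codons {self.n_codons} ({self.source_id})"
            )

    def aa_count(self, aa: str) -> int:
        return sum(self.counts[c] for c in AA_TO_CODONS[aa])


@dataclass
class RscuVector:
    """RSCU over the 59-codon comparison axis (stops, Met, Trp excluded).

    Positions whose amino acid is absent from the source are undefined:
    stored as 0 with ``undefined_mask`` True.
    """

    values: np.ndarray
    undefined_mask: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.undefined_mask = np.asarray(self.undefined_mask, dtype=bool)
        if self.values.shape != (len(CANONICAL_CODONS),):
            raise ValueError(
                f"RSCU vector must have {len(CANONICAL_CODONS)} entries, "
                f"got {self.values.shape}"
            )
        if self.undefined_mask.shape != self.values.shape:
            raise ValueError("mask/value shape mismatch")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(CANONICAL_CODONS, self.values))


@dataclass
class ScuoResult:
    """Per-amino-acid entropies and the composite SCUO in [0, 1]."""

    per_aa: dict[str, tuple[int, int, float, float]]  # aa -> (x_i, n_i, H_i, O_i)
    scuo: float
    source_id: str = ""


def count_codons(cds_list: list[str], source_id: str = "") -> CodonCountTable:
    """Tally codons over in-frame coding sequences (5'->3', per sequence).

    Codons containing any non-ACGT character are skipped and tallied in
    ``n_skipped``. Sequences whose length is not a multiple of 3 raise —
    upstream filtering should have removed them.
    """
    counts: dict[str, int] = {c: 0 for c in ALL_CODONS}
    skipped = 0
    for seq in cds_list:
        seq = seq.upper()
        if len(seq) % 3 != 0:
            raise ValueError(
                f"CDS length {len(seq)} not a multiple of 3 ({source_id})"
            )
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if codon in counts:
                counts[codon] += 1
            else:
                skipped += 1
    return CodonCountTable(
        counts=counts,
        n_codons=sum(counts.values()),
        n_skipped=skipped,
        source_id=source_id,
    )


def rscu(table: CodonCountTable) -> RscuVector:
    """RSCU vector of a count table over the canonical 59-codon axis."""
    if table.n_codons == 0:
        raise ValueError(f"empty codon count table ({table.source_id})")
    values = np.zeros(len(CANONICAL_CODONS))
    mask = np.zeros(len(CANONICAL_CODONS), dtype=bool)
    for aa in DEGENERATE_AAS:
        codons = AA_TO_CODONS[aa]
        x_i = sum(table.counts[c] for c in codons)
        if x_i == 0:
            for c in codons:
                mask[CODON_INDEX[c]] = True
            continue
        expected = x_i / DEGENERACY[aa]
        for c in codons:
            values[CODON_INDEX[c]] = table.counts[c] / expected
    return RscuVector(values=values, undefined_mask=mask, source_id=table.source_id)


def scuo(table: CodonCountTable) -> ScuoResult:
    """Entropy-based synonymous codon usage order of a count table."""
    per_aa: dict[str, tuple[int, int, float, float]] = {}
    weights = []
    orders = []
    for aa in DEGENERATE_AAS:
        codons = AA_TO_CODONS[aa]
        n_i = DEGENERACY[aa]
        x = np.array([table.counts[c] for c in codons], dtype=float)
        x_i = int(x.sum())
        if x_i == 0:
            continue
        p = x[x > 0] / x_i
        h_i = float(-(p * np.log2(p)).sum())
        h_max = np.log2(n_i)
        o_i = (h_max - h_i) / h_max
        per_aa[aa] = (x_i, n_i, h_i, o_i)
        weights.append(x_i)
        orders.append(o_i)
    if not per_aa:
        raise ValueError(
            f"SCUO undefined: no degenerate amino acid observed ({table.source_id})"
        )
    w = np.array(weights, dtype=float)
    composite = float(np.dot(w / w.sum(), np.array(orders)))
    # clamp tiny negative float error at the uniform limit
    composite = min(max(composite, 0.0), 1.0)
    return ScuoResult(per_aa=per_aa, scuo=composite, source_id=table.source_id)


def gc_content(sequence: str) -> float:
    """Mol% G+C of a DNA string; N's excluded from both sides of the ratio."""
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return 100.0 * gc / (gc + at)


def gc3(cds_list: list[str]) -> float:
    """GC percentage over third codon positions of in-frame CDS only."""
    thirds = []
    for seq in cds_list:
        seq = seq.upper()
        if len(seq) % 3 != 0:
            raise ValueError(f"CDS length {len(seq)} not a multiple of 3")
        thirds.append(seq[2::3])
    return gc_content("".join(thirds))
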