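"""Genome record input/output.

Reads annotated genomes from GenBank flat files (CDS and tRNA features),
plain coding sequences from FASTA, and the pipeline's tabular interchange
files (per-genome metrics TSV, cluster-label TSV).

Coordinates are converted on read from GenBank's 1-based inclusive
convention to 0-based half-open, which is what every downstream operation
assumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.SeqFeature import CompoundLocation

from .genetics import is_valid_dna, reverse_complement

log = logging.getLogger(__name__)

METRICS_COLUMNS = [
    "id",
    "cluster",
    "genome_length_nt",
    "n_cds",
    "n_codons",
    "gc_percent",
    "gc3_percent",
    "trna_count",
    "scuo",
]


@dataclass
class CodingRegion:
    """A protein-coding feature in 0-based half-open genome coordinates.

    ``segments`` holds the exon-like parts of a ``join(...)`` location in
    5'->3' order on the coding strand; simple CDS have a single segment.
    ``frame_offset`` is the number of leading bases to drop, from the
    GenBank ``codon_start`` qualifier (codon_start=2 -> offset 1).
    """

    start: int
    end: int
    strand: str  # '+' or '-'
    segments: list[tuple[int, int]] = field(default_factory=list)
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            self.segments = [(self.start, self.end)]
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e in self.segments) - self.frame_offset


@dataclass
class GenomeRecord:
    """One genome: sequence, accepted CDS regions and the tRNA tally."""

    id: str
    description: str
    sequence: str
    cds_regions: list[CodingRegion] = field(default_factory=list)
    trna_count: int = 0
    cluster_label: str | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


def _location_to_region(feature) -> CodingRegion:
    loc = feature.location
    strand = "-" if loc.strand == -1 else "+"
    if isinstance(loc, CompoundLocation):
        parts = sorted(((int(p.start), int(p.end)) for p in loc.parts))
    else:
        parts = [(int(loc.start), int(loc.end))]
    offset = 0
    if "codon_start" in feature.qualifiers:
        offset = int(feature.qualifiers["codon_start"][0]) - 1
    return CodingRegion(
        start=parts[0][0],
        end=parts[-1][1],
        strand=strand,
        segments=parts,
        frame_offset=offset,
    )


def read_genbank(path: str | Path) -> list[GenomeRecord]:
    """Parse a (possibly multi-record) GenBank flat file.

    One :class:`GenomeRecord` per LOCUS. CDS features are captured with
    strand and join structure; features annotated ``/pseudo`` are excluded
    (not translated). ``trna_count`` is the number of tRNA-typed features.
    A record with zero CDS features is retained with a warning.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    try:
        parsed = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ValueError(f"unparseable GenBank file {path}: {exc}") from exc
    if not parsed:
        raise ValueError(f"no GenBank records found in {path}")
    for rec in parsed:
        cds = []
        trna = 0
        for feat in rec.features:
            if feat.type == "CDS":
                if "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers:
                    log.info("%s: skipping pseudo CDS at %s", rec.id, feat.location)
                    continue
                cds.append(_location_to_region(feat))
            elif feat.type == "tRNA":
                trna += 1
        if not cds:
            warnings.warn(f"record {rec.id} has no CDS features", stacklevel=2)
        records.append(
            GenomeRecord(
                id=rec.id,
                description=rec.description,
                sequence=str(rec.seq).upper(),
                cds_regions=cds,
                trna_count=trna,
            )
        )
    return records


def read_fasta_cds(path: str | Path) -> list[tuple[str, str]]:
    """Read coding sequences from FASTA: one CDS per record, coding strand.

    Sequences are uppercased; file order is preserved. Non-IUPAC
    characters raise, naming the offending record.
    """
    path = Path(path)
    out: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not is_valid_dna(seq):
            raise ValueError(f"record {rec.id}: non-IUPAC characters in sequence")
        out.append((rec.id, seq))
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def extract_coding_sequence(record: GenomeRecord, region: CodingRegion) -> str:
    """Coding-strand sequence of a region (segments concatenated 5'->3').

    Minus-strand regions are reverse-complemented. Raises ``ValueError``
    if the length after the frame offset is not a multiple of 3; callers
    treat that as "region rejected" and log the reason.
    """
    for s, e in region.segments:
        if not (0 <= s < e <= record.length):
            raise ValueError(
                f"{record.id}: segment [{s},{e}) outside genome [0,{record.length})"
            )
    raw = "".join(record.sequence[s:e] for s, e in region.segments)
    if region.strand == "-":
        raw = reverse_complement(raw)
    raw = raw[region.frame_offset :]
    if len(raw) % 3 != 0:
        raise ValueError(
            f"{record.id}: coding region [{region.start},{region.end}){region.strand} "
            f"length {len(raw)} not a multiple of 3"
        )
    return raw


def coding_sequences(record: GenomeRecord) -> list[str]:
    """All accepted CDS of a genome; frameshifted regions are dropped and logged."""
    out = []
    for region in record.cds_regions:
        try:
            out.append(extract_coding_sequence(record, region))
        except ValueError as exc:
            log.warning("rejected CDS: %s", exc)
    return out


def write_metrics_table(rows: list[dict], path: str | Path) -> None:
    """Write the per-genome metrics TSV (lossless round-trip with pandas)."""
    if not rows:
        raise ValueError("no metric rows to write")
    ids = [r["id"] for r in rows]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids in metrics rows")
    df = pd.DataFrame(rows)
    cols = [c for c in METRICS_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in METRICS_COLUMNS
    ]
    df[cols].to_csv(path, sep="\t", index=False)


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df["id"].duplicated().any():
        raise ValueError(f"duplicate ids in metrics table {path}")
    return df


def read_labels(path: str | Path, known_ids: list[str] | None = None) -> dict[str, str]:
    """Read a TSV of ``id<TAB>cluster`` labels.

    Duplicate ids raise; ids absent from ``known_ids`` (when given) are
    dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "id" not in df.columns or "cluster" not in df.columns:
        raise ValueError(f"label file {path} must have columns 'id' and 'cluster'")
    if df["id"].duplicated().any():
        dups = sorted(df.loc[df["id"].duplicated(), "id"])
        raise ValueError(f"duplicate ids in label file: {dups}")
    labels = dict(zip(df["id"], df["cluster"]))
    if known_ids is not None:
        unknown = sorted(set(labels) - set(known_ids))
        if unknown:
            warnings.warn(
                f"{len(unknown)} label ids not in cohort, ignored: {unknown[:5]}...",
                stacklevel=2,
            )
            labels = {k: v for k, v in labels.items() if k in set(known_ids)}
    return labels
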