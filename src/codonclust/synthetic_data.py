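"""Synthetic annotated genomes with controlled codon-usage regimes.

Ground truth for every pipeline stage: cohorts of multi-gene genomes are
generated from per-amino-acid codon-preference profiles (points on the
synonymous-codon simplex), with tunable within-regime scatter (Dirichlet
concentration), intergenic GC, genome size and annotated tRNA features.
Records are emitted as minimal valid GenBank flat files so the real reader
is exercised, not bypassed.

A cohort draws k regimes; each genome's own profile is a Dirichlet draw
centred on its regime's base profile, so between-regime separation and
within-regime scatter are controlled independently. The generator returns
the true regime of every genome alongside the records, which makes
clustering-recovery experiments measurable against known truth.

Defaults emulate the mycobacteriophage cohorts this pipeline targets:
GC-rich genomes of 40-160 kb with on the order of a hundred genes, a
GC-skewed amino-acid composition, and 0-41 annotated tRNA genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .genetics import (
    AA_TO_CODONS,
    DEGENERATE_AAS,
    reverse_complement,
)
from .seqio import GenomeRecord, read_genbank

# Average amino-acid composition of GC-rich actinobacterial proteomes
# (Ala/Gly/Pro/Arg/Val enriched, Lys/Asn/Ile depleted); normalized on use.
# Gene bodies draw amino acids i.i.d. from this unless overridden.
AA_COMPOSITION: dict[str, float] = {
    "A": 0.120, "R": 0.060, "N": 0.025, "D": 0.058, "C": 0.008,
    "Q": 0.030, "E": 0.055, "G": 0.090, "H": 0.021, "I": 0.040,
    "L": 0.100, "K": 0.020, "F": 0.030, "P": 0.058, "S": 0.052,
    "T": 0.060, "Y": 0.023, "V": 0.085,
}

START_CODON = "ATG"
STOP_CODON = "TAA"
TRNA_LENGTH = 75  # typical tRNA gene length, nt


@dataclass
class CodonProfile:
    """Per-amino-acid probability vectors over synonymous codons."""

    probs: dict[str, np.ndarray]  # aa -> simplex over AA_TO_CODONS[aa]
    label: str = ""

    def __post_init__(self) -> None:
        for aa in DEGENERATE_AAS:
            if aa not in self.probs:
                raise ValueError(f"profile missing amino acid {aa}")
            p = np.asarray(self.probs[aa], dtype=float)
            if p.shape != (len(AA_TO_CODONS[aa]),):
                raise ValueError(f"wrong number of codon probabilities for {aa}")
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"probabilities for {aa} not a simplex point")
            self.probs[aa] = p


def uniform_profile(label: str = "uniform") -> CodonProfile:
    """Equal use of every synonymous codon (RSCU = 1 everywhere)."""
    return CodonProfile(
        {aa: np.full(n := len(AA_TO_CODONS[aa]), 1.0 / n) for aa in DEGENERATE_AAS},
        label=label,
    )


def concentrated_profile(rng: np.random.Generator, label: str = "max-bias") -> CodonProfile:
    """One codon per amino acid (SCUO = 1 in the limit)."""
    probs = {}
    for aa in DEGENERATE_AAS:
        n = len(AA_TO_CODONS[aa])
        p = np.zeros(n)
        p[rng.integers(n)] = 1.0
        probs[aa] = p
    return CodonProfile(probs, label=label)


def random_profile(
    rng: np.random.Generator, alpha: float = 0.3, label: str = ""
) -> CodonProfile:
    """A distinct random profile: flat-Dirichlet(alpha) draw per amino acid.

    Small ``alpha`` gives strongly biased (near-vertex) profiles, which is
    what distinct codon-usage regimes look like.
    """
    return CodonProfile(
        {
            aa: rng.dirichlet(np.full(len(AA_TO_CODONS[aa]), alpha))
            for aa in DEGENERATE_AAS
        },
        label=label,
    )


def gc3_biased_profile(weight_gc: float, label: str = "") -> CodonProfile:
    """Profile whose codon preference follows the third base's GC status.

    ``weight_gc`` in (0,1): relative weight of G/C-ending codons within
    each amino acid (0.5 = neutral). Raising it raises the GC3 of
    generated genomes monotonically.
    """
    if not (0.0 < weight_gc < 1.0):
        raise ValueError("weight_gc must be in (0, 1)")
    probs = {}
    for aa in DEGENERATE_AAS:
        w = np.array(
            [weight_gc if c[2] in "GC" else 1.0 - weight_gc for c in AA_TO_CODONS[aa]]
        )
        probs[aa] = w / w.sum()
    return CodonProfile(probs, label=label)


def mix_profiles(a: CodonProfile, b: CodonProfile, weight_b: float, label: str = "") -> CodonProfile:
    """Convex combination (1-w)*a + w*b, amino acid by amino acid."""
    if not (0.0 <= weight_b <= 1.0):
        raise ValueError("weight_b must be in [0, 1]")
    probs = {
        aa: (1.0 - weight_b) * a.probs[aa] + weight_b * b.probs[aa]
        for aa in DEGENERATE_AAS
    }
    # renormalize away float error
    probs = {aa: p / p.sum() for aa, p in probs.items()}
    return CodonProfile(probs, label=label)


def sample_profile(
    base: CodonProfile, concentration: float, rng: np.random.Generator
) -> CodonProfile:
    """Dirichlet draw centred on ``base``; higher concentration = closer.

    Per amino acid the draw is Dirichlet(concentration * base + eps), whose
    mean is (essentially) the base profile and whose scatter shrinks as
    concentration grows.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    probs = {}
    for aa in DEGENERATE_AAS:
        alpha = concentration * base.probs[aa] + 1e-9
        probs[aa] = rng.dirichlet(alpha)
    return CodonProfile(probs, label=base.label)


def empirical_profile(counts: dict[str, int], label: str = "") -> CodonProfile:
    """Profile implied by observed codon counts (for convergence checks)."""
    probs = {}
    for aa in DEGENERATE_AAS:
        x = np.array([counts.get(c, 0) for c in AA_TO_CODONS[aa]], dtype=float)
        n = len(AA_TO_CODONS[aa])
        probs[aa] = x / x.sum() if x.sum() > 0 else np.full(n, 1.0 / n)
    return CodonProfile(probs, label=label)


def profile_tv_distance(
    a: CodonProfile, b: CodonProfile, weights: dict[str, float] | None = None
) -> float:
    """Total variation distance between two profiles.

    Without ``weights``: the max per-amino-acid TV (strict profile
    equality). With ``weights`` (e.g. an amino-acid composition): the
    weighted mean per-amino-acid TV, the distance that empirical codon
    frequencies of a finite genome actually converge under — rare amino
    acids contribute few codons and proportionally little weight.
    """
    tvs = {
        aa: 0.5 * float(np.abs(a.probs[aa] - b.probs[aa]).sum())
        for aa in DEGENERATE_AAS
    }
    if weights is None:
        return max(tvs.values())
    w = np.array([weights.get(aa, 0.0) for aa in DEGENERATE_AAS], dtype=float)
    return float(np.dot(w / w.sum(), np.array([tvs[aa] for aa in DEGENERATE_AAS])))


def _random_dna(rng: np.random.Generator, length: int, gc_percent: float) -> str:
    g = gc_percent / 100.0
    p = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])  # A C G T
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _sample_cds(
    profile: CodonProfile,
    n_codons_body: int,
    rng: np.random.Generator,
    aa_composition: dict[str, float],
) -> str:
    aas = list(aa_composition)
    w = np.array([aa_composition[a] for a in aas], dtype=float)
    w = w / w.sum()
    draws = rng.choice(len(aas), size=n_codons_body, p=w)
    codons = np.empty(n_codons_body, dtype=object)
    for idx in np.unique(draws):
        aa = aas[idx]
        positions = np.where(draws == idx)[0]
        synonyms = np.array(AA_TO_CODONS[aa], dtype=object)
        codons[positions] = synonyms[
            rng.choice(len(synonyms), size=positions.size, p=profile.probs[aa])
        ]
    return START_CODON + "".join(codons.tolist()) + STOP_CODON


def generate_genome(
    profile: CodonProfile,
    n_genes: int,
    gene_lengths: list[int],
    trna_count: int,
    rng: np.random.Generator,
    genome_id: str = "SYN1",
    gc_intergenic: float = 65.0,
    aa_composition: dict[str, float] | None = None,
) -> GenomeRecord:
    """One annotated genome sampled from a codon profile.

    Each gene is a start codon, ``gene_lengths[i] - 2`` body codons drawn
    i.i.d. (amino acid from ``aa_composition``, codon from the profile) and
    a stop codon. Genes alternate strand and are separated by intergenic
    spacers at ``gc_intergenic`` mol% GC; ``trna_count`` tRNA features are
    annotated in dedicated non-coding blocks.
    """
    if len(gene_lengths) != n_genes:
        raise ValueError("gene_lengths must have n_genes entries")
    if any(l < 2 for l in gene_lengths):
        raise ValueError("every gene needs at least 2 codons (start + stop)")
    if trna_count < 0:
        raise ValueError("trna_count must be >= 0")
    comp = aa_composition or AA_COMPOSITION
    parts: list[str] = []
    features: list[tuple[str, int, int, str]] = []  # (type, start, end, strand)
    pos = 0
    for i, length in enumerate(gene_lengths):
        spacer = _random_dna(rng, int(rng.integers(20, 80)), gc_intergenic)
        parts.append(spacer)
        pos += len(spacer)
        cds = _sample_cds(profile, length - 2, rng, comp)
        strand = "+" if i % 2 == 0 else "-"
        parts.append(cds if strand == "+" else reverse_complement(cds))
        features.append(("CDS", pos, pos + len(cds), strand))
        pos += len(cds)
    for _ in range(trna_count):
        spacer = _random_dna(rng, int(rng.integers(20, 50)), gc_intergenic)
        parts.append(spacer)
        pos += len(spacer)
        parts.append(_random_dna(rng, TRNA_LENGTH, gc_intergenic))
        features.append(("tRNA", pos, pos + TRNA_LENGTH, "+"))
        pos += TRNA_LENGTH
    parts.append(_random_dna(rng, int(rng.integers(20, 80)), gc_intergenic))
    sequence = "".join(parts)
    from .seqio import CodingRegion  # local import avoids cycle at module load

    record = GenomeRecord(
        id=genome_id,
        description=f"synthetic genome ({profile.label or 'unlabeled'})",
        sequence=sequence,
        cds_regions=[
            CodingRegion(start=s, end=e, strand=st)
            for t, s, e, st in features
            if t == "CDS"
        ],
        trna_count=sum(1 for t, *_ in features if t == "tRNA"),
    )
    record._features = features  # full feature list kept for GenBank export
    return record


@dataclass
class RegimeSpec:
    """One codon-usage regime within a synthetic cohort."""

    label: str
    profile: CodonProfile
    n_genomes: int
    n_genes: int = 100
    gene_length_mean: int = 200  # codons, incl. start/stop
    gene_length_sd: int = 60
    trna_range: tuple[int, int] = (0, 12)
    gc_intergenic: float = 65.0
    concentration: float = 5000.0  # within-regime Dirichlet concentration


@dataclass
class CohortSpec:
    """A k-regime synthetic cohort with a single master seed.

    Per-genome randomness derives from ``(seed, genome_index)`` counter
    substreams, so output is reproducible independent of generation order.
    """

    regimes: list[RegimeSpec]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.regimes:
            raise ValueError("cohort needs at least one regime")
        labels = [r.label for r in self.regimes]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate regime labels")

    @property
    def k_regimes(self) -> int:
        return len(self.regimes)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[GenomeRecord], dict[str, str]]:
    """Generate all genomes of a cohort plus the id -> regime truth table."""
    records: list[GenomeRecord] = []
    truth: dict[str, str] = {}
    genome_index = 0
    for regime in spec.regimes:
        for _ in range(regime.n_genomes):
            rng = np.random.default_rng([spec.seed, genome_index])
            profile = sample_profile(regime.profile, regime.concentration, rng)
            lengths = np.clip(
                rng.normal(regime.gene_length_mean, regime.gene_length_sd,
                           regime.n_genes),
                20, None,
            ).astype(int).tolist()
            trna = int(rng.integers(regime.trna_range[0], regime.trna_range[1] + 1))
            genome_id = f"G{genome_index:03d}"
            rec = generate_genome(
                profile,
                regime.n_genes,
                lengths,
                trna,
                rng,
                genome_id=genome_id,
                gc_intergenic=regime.gc_intergenic,
            )
            rec.cluster_label = regime.label
            records.append(rec)
            truth[genome_id] = regime.label
            genome_index += 1
    return records, truth


def separated_regime_profiles(
    k: int, separation: float, rng: np.random.Generator
) -> list[CodonProfile]:
    """k regime base profiles at a controlled separation in [0, 1].

    Each regime's profile interpolates between one shared random profile
    (separation 0: regimes indistinguishable) and its own distinct random
    profile (separation 1: fully separated).
    """
    if not (0.0 <= separation <= 1.0):
        raise ValueError("separation must be in [0, 1]")
    shared = random_profile(rng, alpha=0.5, label="shared")
    return [
        mix_profiles(
            shared, random_profile(rng, alpha=0.3), separation, label=f"R{i + 1}"
        )
        for i in range(k)
    ]


def write_genbank(records: list[GenomeRecord], path: str | Path) -> None:
    """Emit records as a minimal valid multi-record GenBank flat file."""
    seq_records = []
    for rec in records:
        features = getattr(
            rec,
            "_features",
            [("CDS", r.start, r.end, r.strand) for r in rec.cds_regions],
        )
        sr = SeqRecord(
            Seq(rec.sequence),
            id=rec.id,
            name=rec.id[:16],
            description=rec.description,
            annotations={
                "molecule_type": "DNA",
                "topology": "linear",
                "data_file_division": "PHG",
                "date": "01-JAN-2016",
            },
        )
        sr.features.append(
            SeqFeature(FeatureLocation(0, rec.length), type="source")
        )
        n_cds = 0
        n_trna = 0
        for ftype, start, end, strand in features:
            if ftype == "CDS":
                n_cds += 1
                tag = f"{rec.id}_CDS{n_cds:04d}"
            else:
                n_trna += 1
                tag = f"{rec.id}_tRNA{n_trna:03d}"
            sr.features.append(
                SeqFeature(
                    FeatureLocation(start, end, strand=1 if strand == "+" else -1),
                    type=ftype,
                    qualifiers={"locus_tag": [tag]},
                )
            )
        seq_records.append(sr)
    SeqIO.write(seq_records, str(path), "genbank")


def write_truth_table(truth: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tcluster\n")
        for genome_id, regime in truth.items():
            fh.write(f"{genome_id}\t{regime}\n")


def roundtrip_cohort(
    spec: CohortSpec, out_dir: str | Path
) -> tuple[list[GenomeRecord], dict[str, str], Path]:
    """Generate, write to GenBank + truth TSV, and re-read via the real parser."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, truth = generate_cohort(spec)
    gb_path = out_dir / "cohort.gb"
    write_genbank(records, gb_path)
    write_truth_table(truth, out_dir / "truth.tsv")
    return read_genbank(gb_path), truth, gb_path
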