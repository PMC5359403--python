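"""Shared fixtures: hand-written GenBank text and small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest


def format_genbank(name: str, seq: str, feature_lines: list[str]) -> str:
    """Render a minimal GenBank flat file around a literal sequence."""
    header = (
        f"LOCUS       {name:<16}{len(seq):>12} bp    DNA     linear   PHG 01-JAN-2016\n"
        f"DEFINITION  synthetic test record.\n"
        f"ACCESSION   {name}\n"
        f"VERSION     {name}.1\n"
        f"KEYWORDS    .\n"
        f"SOURCE      synthetic\n"
        f"  ORGANISM  synthetic\n"
        f"FEATURES             Location/Qualifiers\n"
        f"     source          1..{len(seq)}\n"
    )
    body = "".join(f"     {line}\n" for line in feature_lines)
    origin_lines = []
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60].lower()
        groups = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        origin_lines.append(f"{i + 1:>9} {groups}")
    return header + body + "ORIGIN\n" + "\n".join(origin_lines) + "\n//\n"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_genbank(tmp_path):
    """Single record, 2 CDS (one minus strand), 3 tRNA features.

    Plus-strand CDS at 10..57 (48 nt), minus-strand CDS at complement(70..117).
    """
    rng = np.random.default_rng(7)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
    text = format_genbank(
        "TESTPHAGE",
        seq,
        [
            "CDS             10..57",
            "CDS             complement(70..117)",
            "tRNA            130..205",
            "tRNA            210..250",
            "tRNA            complement(255..295)",
        ],
    )
    path = tmp_path / "simple.gb"
    path.write_text(text)
    return path, seq


@pytest.fixture
def simple_genbank_no_trna(tmp_path):
    rng = np.random.default_rng(7)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
    text = format_genbank(
        "TESTPHAG2",
        seq,
        ["CDS             10..57", "CDS             complement(70..117)"],
    )
    path = tmp_path / "no_trna.gb"
    path.write_text(text)
    return path, seq


@pytest.fixture
def join_genbank(tmp_path):
    """One CDS spanning two joined segments of lengths 30 and 33."""
    rng = np.random.default_rng(9)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
    text = format_genbank(
        "TESTJOIN", seq, ["CDS             join(10..39,50..82)"]
    )
    path = tmp_path / "join.gb"
    path.write_text(text)
    return path, seq


@pytest.fixture
def small_cohort(rng):
    """12-genome, 3-regime synthetic cohort with well-separated profiles."""
    from codonclust import synthetic_data as sd

    profiles = sd.separated_regime_profiles(3, 1.0, rng)
    regimes = [
        sd.RegimeSpec(
            label=p.label,
            profile=p,
            n_genomes=4,
            n_genes=30,
            gene_length_mean=100,
            gene_length_sd=25,
        )
        for p in profiles
    ]
    return sd.generate_cohort(sd.CohortSpec(regimes=regimes, seed=11))
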