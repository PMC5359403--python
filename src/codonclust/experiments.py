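"""Reusable synthetic-cohort experiments over the full pipeline.

These wrap generate -> write GenBank -> re-read -> metrics -> distance ->
UPGMA -> concordance into single calls with fixed problem sizes, so the
same experiment backs the analysis scripts, the test suite and the
acceptance script.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from . import clustering, synthetic_data as sd
from .pipeline import genome_metrics


def three_regime_recovery(
    seed: int,
    n_genomes_per_regime: int = 8,
    n_genes: int = 200,
    gene_length_mean: int = 120,
    separation: float = 1.0,
    concentration: float = 5000.0,
    through_genbank: bool = True,
    work_dir: str | Path | None = None,
) -> float:
    """Concordance at the true k = 3 on a well-separated synthetic cohort.

    With ``through_genbank`` the cohort is serialized to a GenBank flat
    file and re-read, so the whole pipeline (including the parser) is
    exercised. Returns the Fowlkes-Mallows index between the UPGMA 3-cut
    and the generator's regime truth.
    """
    rng = np.random.default_rng([seed, 0])
    profiles = sd.separated_regime_profiles(3, separation, rng)
    regimes = [
        sd.RegimeSpec(
            label=p.label,
            profile=p,
            n_genomes=n_genomes_per_regime,
            n_genes=n_genes,
            gene_length_mean=gene_length_mean,
            gene_length_sd=max(gene_length_mean // 4, 5),
            concentration=concentration,
        )
        for p in profiles
    ]
    spec = sd.CohortSpec(regimes=regimes, seed=seed)
    if through_genbank:
        if work_dir is None:
            with tempfile.TemporaryDirectory() as tmp:
                records, truth, _ = sd.roundtrip_cohort(spec, tmp)
        else:
            records, truth, _ = sd.roundtrip_cohort(spec, work_dir)
    else:
        records, truth = sd.generate_cohort(spec)
    vectors = [genome_metrics(rec)[1] for rec in records]
    tree = clustering.upgma(clustering.distance_matrix(vectors))
    return clustering.concordance(tree, truth, 3)


RECOVERY_CURVE_LEVELS = (0.0, 0.06, 0.12, 0.25, 0.5)


def recovery_curve(
    seed: int,
    levels: tuple[float, ...] = RECOVERY_CURVE_LEVELS,
    n_replicates: int = 20,
    n_genomes_per_regime: int = 6,
    n_genes: int = 40,
    gene_length_mean: int = 100,
    concentration: float = 100.0,
) -> list[float]:
    """Mean regime-recovery concordance at increasing regime separation.

    At separation 0 the three regimes share one codon profile and recovery
    sits at the Fowlkes-Mallows chance level; as separation grows past the
    within-regime Dirichlet scatter, recovery climbs to 1. Each level is
    averaged over ``n_replicates`` independent cohorts (profile draws and
    genome sampling both re-seeded per replicate).
    """

    def one(sep: float, rep: int) -> float:
        rng = np.random.default_rng([seed, rep, 1])
        profiles = sd.separated_regime_profiles(3, sep, rng)
        regimes = [
            sd.RegimeSpec(
                label=p.label,
                profile=p,
                n_genomes=n_genomes_per_regime,
                n_genes=n_genes,
                gene_length_mean=gene_length_mean,
                gene_length_sd=max(gene_length_mean // 4, 5),
                concentration=concentration,
            )
            for p in profiles
        ]
        records, truth = sd.generate_cohort(
            sd.CohortSpec(regimes=regimes, seed=(seed * 1009 + rep) % (2**31))
        )
        vectors = [genome_metrics(rec)[1] for rec in records]
        tree = clustering.upgma(clustering.distance_matrix(vectors))
        return clustering.concordance(tree, truth, 3)

    return [
        float(np.mean([one(sep, rep) for rep in range(n_replicates)]))
        for sep in levels
    ]


def upgma_vs_average_linkage(
    seed: int, n_cases: int = 1000, max_n: int = 8
) -> float:
    """Max cophenetic-distance discrepancy between this package's UPGMA and
    scipy's average linkage over random distance matrices with n <= max_n.

    Returns the largest absolute difference observed (0 means exact
    agreement everywhere).
    """
    from scipy.cluster.hierarchy import cophenet, linkage
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        n = int(rng.integers(2, max_n + 1))
        condensed = rng.uniform(1.0, 100.0, size=n * (n - 1) // 2)
        d = squareform(condensed)
        ids = [f"L{i:02d}" for i in range(n)]
        tree = clustering.upgma(clustering.DistanceMatrix(ids=ids, d=d))
        ours = clustering.cophenetic(tree).d
        ref = squareform(cophenet(linkage(condensed, method="average")))
        worst = max(worst, float(np.abs(ours - ref).max()))
    return worst
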