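"""End-to-end orchestration: ingest -> metrics -> clustering -> hosts -> stats.

A single :func:`run_pipeline` call reads annotated genomes, computes the
per-genome codon-usage metrics, builds the Pearson-distance UPGMA tree,
optionally scores concordance against external cluster labels, ranks
candidate hosts, runs the cohort-level statistical tests and writes a
plain-text summary. Every decision that silently shapes RSCU (rejected
frameshifted CDS, ignored labels) is logged at INFO/WARNING.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, codon_metrics, host_inference, stats
from .seqio import (
    GenomeRecord,
    coding_sequences,
    read_genbank,
    read_labels,
    write_metrics_table,
)
from .genetics import CANONICAL_CODONS

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genbank: list[str] = field(default_factory=list)  # files or directories
    labels: str | None = None
    host_panel: str | None = None
    k: int | None = None  # tree-cut size for concordance
    gc_window: float = 2.0
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def validate(self) -> None:
        if not self.genbank:
            raise ValueError("no GenBank inputs configured")
        for p in self.genbank:
            if not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")
        for p in (self.labels, self.host_panel):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")
        if self.k is not None and self.k < 2:
            raise ValueError("k must be >= 2 when concordance is requested")


def _collect_genbank_paths(inputs: list[str]) -> list[Path]:
    paths: list[Path] = []
    for p in inputs:
        p = Path(p)
        if p.is_dir():
            paths.extend(sorted(p.glob("*.gb")) + sorted(p.glob("*.gbk")))
        else:
            paths.append(p)
    if not paths:
        raise ValueError("no GenBank files found in configured inputs")
    return paths


def genome_metrics(record: GenomeRecord) -> tuple[dict, codon_metrics.RscuVector]:
    """All per-genome metrics plus the RSCU vector for one record."""
    cds = coding_sequences(record)
    if not cds:
        raise ValueError(f"{record.id}: no accepted CDS, cannot compute codon metrics")
    table = codon_metrics.count_codons(cds, source_id=record.id)
    vec = codon_metrics.rscu(table)
    result = codon_metrics.scuo(table)
    row = {
        "id": record.id,
        "cluster": record.cluster_label or "",
        "genome_length_nt": record.length,
        "n_cds": len(cds),
        "n_codons": table.n_codons,
        "gc_percent": codon_metrics.gc_content(record.sequence),
        "gc3_percent": codon_metrics.gc3(cds),
        "trna_count": record.trna_count,
        "scuo": result.scuo,
    }
    return row, vec


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full analysis; returns a name -> path map of outputs."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    records: list[GenomeRecord] = []
    for path in _collect_genbank_paths(config.genbank):
        records.extend(read_genbank(path))
    log.info("ingested %d genomes", len(records))

    labels: dict[str, str] | None = None
    if config.labels:
        labels = read_labels(config.labels, known_ids=[r.id for r in records])
        for rec in records:
            rec.cluster_label = labels.get(rec.id)

    rows = []
    vectors = []
    for rec in records:
        row, vec = genome_metrics(rec)
        rows.append(row)
        vectors.append(vec)

    metrics_path = out / "metrics.tsv"
    write_metrics_table(rows, metrics_path)
    outputs["metrics"] = metrics_path

    rscu_df = pd.DataFrame(
        [v.values for v in vectors],
        index=[v.source_id for v in vectors],
        columns=list(CANONICAL_CODONS),
    )
    rscu_path = out / "rscu.tsv"
    rscu_df.to_csv(rscu_path, sep="\t", index_label="id")
    outputs["rscu"] = rscu_path

    dm = clustering.distance_matrix(vectors)
    dist_path = out / "distance.tsv"
    pd.DataFrame(dm.d, index=dm.ids, columns=dm.ids).to_csv(
        dist_path, sep="\t", index_label="id"
    )
    outputs["distance"] = dist_path

    tree = clustering.upgma(dm)
    newick_path = out / "tree.nwk"
    newick_path.write_text(clustering.to_newick(tree) + "\n")
    outputs["newick"] = newick_path

    if labels is not None and config.k is not None:
        score = clustering.concordance(tree, labels, config.k)
        conc_path = out / "concordance.tsv"
        pd.DataFrame([{"k": config.k, "fowlkes_mallows": score}]).to_csv(
            conc_path, sep="\t", index=False
        )
        outputs["concordance"] = conc_path
    else:
        log.info("no labels or k configured: concordance stage skipped")

    if config.host_panel:
        panel = host_inference.read_host_panel(config.host_panel)
        rankings = [
            host_inference.rank_hosts(vec, row["gc_percent"], panel)
            for row, vec in zip(rows, vectors)
        ]
        hosts_path = out / "host_rankings.tsv"
        host_inference.ranking_table(rankings).to_csv(
            hosts_path, sep="\t", index=False
        )
        outputs["host_rankings"] = hosts_path
        phage_gcs = [(r["id"], r["gc_percent"], r["cluster"] or None) for r in rows]
        gc_path = out / "gc_compatibility.tsv"
        host_inference.gc_compatibility_table(
            phage_gcs, panel, config.gc_window
        ).to_csv(gc_path, sep="\t", index=False)
        outputs["gc_compatibility"] = gc_path

    stat_rows = []
    df = pd.DataFrame(rows)
    if labels is not None and df["cluster"].nunique() >= 2:
        groups = [g["gc_percent"].tolist() for _, g in df.groupby("cluster")]
        if all(len(g) >= 1 for g in groups) and len(df) > df["cluster"].nunique():
            a = stats.one_way_anova(groups)
            stat_rows.append(
                {"test": "anova_gc_by_cluster", "stat": a.f, "p": a.p,
                 "df1": a.df_between, "df2": a.df_within}
            )
    if df["trna_count"].nunique() > 1:
        r, p = stats.pearson_test(df["scuo"].tolist(), df["trna_count"].tolist())
        stat_rows.append({"test": "scuo_vs_trna_pearson", "stat": r, "p": p,
                          "df1": None, "df2": None})
        reg = stats.regression_f(
            df["genome_length_nt"].tolist(), df["trna_count"].tolist()
        )
        stat_rows.append({"test": "trna_vs_size_regression_f", "stat": reg.f,
                          "p": reg.p, "df1": reg.df_between, "df2": reg.df_within})
    stats_path = out / "stats.tsv"
    pd.DataFrame(
        stat_rows, columns=["test", "stat", "p", "df1", "df2"]
    ).to_csv(stats_path, sep="\t", index=False)
    outputs["stats"] = stats_path

    summary_path = out / "summary.txt"
    with open(summary_path, "w") as fh:
        fh.write(f"genomes analyzed: {len(records)}\n")
        fh.write(
            f"genomes with tRNA genes: {sum(1 for r in records if r.trna_count > 0)}\n"
        )
        fh.write(f"total codons counted: {int(df['n_codons'].sum())}\n")
        fh.write(
            f"genome GC mol%: min {df['gc_percent'].min():.1f}, "
            f"median {df['gc_percent'].median():.1f}, "
            f"max {df['gc_percent'].max():.1f}\n"
        )
        if df["cluster"].str.len().gt(0).any():
            fh.write("\nper-cluster mean GC mol%:\n")
            for cluster, grp in df[df["cluster"] != ""].groupby("cluster"):
                fh.write(
                    f"  {cluster}: {grp['gc_percent'].mean():.1f} "
                    f"(n={len(grp)})\n"
                )
    outputs["summary"] = summary_path
    log.info("pipeline outputs written to %s", out)
    return outputs
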