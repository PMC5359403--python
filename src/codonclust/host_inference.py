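"""Codon-bias host ranking for phages.

A phage that depends on its host's translational machinery is expected to
mirror the host's codon usage, so candidate hosts are ranked by the
Pearson correlation between phage and host RSCU vectors. DNA GC content
enters only as a tie-break and through a separate GC-compatibility table;
no composite score is formed — the two signals argue separately.

The ranking operationalizes a qualitative argument: a top-ranked host is
the one whose translational environment the phage's codon usage matches
best, not a claim of actual infectivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import pearson_r
from .codon_metrics import RscuVector
from .genetics import CANONICAL_CODONS, CODON_INDEX


@dataclass
class HostPanel:
    """Candidate hosts: (id, RSCU vector, genome GC mol%)."""

    hosts: list[tuple[str, RscuVector, float]]

    def __post_init__(self) -> None:
        ids = [h[0] for h in self.hosts]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate host ids in panel")

    @property
    def ids(self) -> list[str]:
        return [h[0] for h in self.hosts]


@dataclass
class HostRanking:
    """Hosts ordered by descending correlation with one phage."""

    phage_id: str
    entries: list[tuple[str, float, float, float]]  # (host, r, d, gc_delta)
    failed: list[tuple[str, str]] | None = None  # (host, reason)


def rank_hosts(
    phage: RscuVector, phage_gc: float, panel: HostPanel
) -> HostRanking:
    """Rank panel hosts for one phage by RSCU correlation.

    Ties in r are broken by smaller \\|gc_delta\\| then host id; a host whose
    correlation cannot be computed is flagged and the ranking continues.
    gc_delta is signed: phage GC minus host GC.
    """
    if not panel.hosts:
        raise ValueError("empty host panel")
    rows = []
    failed = []
    for host_id, host_rscu, host_gc in panel.hosts:
        try:
            r = pearson_r(phage, host_rscu)
        except ValueError as exc:
            failed.append((host_id, str(exc)))
            continue
        rows.append((host_id, r, (1.0 - r) * 100.0, phage_gc - host_gc))
    rows.sort(key=lambda e: (-round(e[1], 12), abs(e[3]), e[0]))
    return HostRanking(
        phage_id=phage.source_id, entries=rows, failed=failed or None
    )


def gc_compatibility_table(
    phages: list[tuple[str, float, str | None]],
    panel: HostPanel,
    window: float,
) -> pd.DataFrame:
    """Hosts within +/- ``window`` GC mol% of each phage.

    ``phages`` rows are (id, gc_percent, cluster_label or None). Returns a
    table with one row per phage (compatible hosts comma-joined) plus the
    per-cluster mean GC in the attribute-free companion produced by
    :func:`cluster_gc_means`.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    for phage_id, gc, cluster in phages:
        compatible = sorted(
            host_id
            for host_id, _, host_gc in panel.hosts
            if abs(gc - host_gc) <= window
        )
        rows.append(
            {
                "phage": phage_id,
                "cluster": cluster if cluster is not None else "",
                "gc_percent": gc,
                "n_compatible": len(compatible),
                "compatible_hosts": ",".join(compatible),
            }
        )
    return pd.DataFrame(rows)


def cluster_gc_means(
    phages: list[tuple[str, float, str | None]]
) -> pd.DataFrame:
    """Mean genome GC per cluster label (unlabeled phages grouped as '')."""
    df = pd.DataFrame(phages, columns=["phage", "gc_percent", "cluster"])
    df["cluster"] = df["cluster"].fillna("")
    out = (
        df.groupby("cluster")["gc_percent"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_gc_percent", "count": "n_phages"})
    )
    return out


def read_host_panel(path: str | Path) -> HostPanel:
    """Load a host panel from a codon-bias-database style TSV.

    Long format with columns ``host``, ``codon``, ``rscu`` and (repeated
    per host) ``gc_percent``; codons outside the 59-codon comparison axis
    (stops, ATG, TGG) are ignored; axis positions a host never mentions are
    marked undefined.
    """
    df = pd.read_csv(path, sep="\t", dtype={"host": str, "codon": str})
    required = {"host", "codon", "rscu", "gc_percent"}
    if not required <= set(df.columns):
        raise ValueError(f"host panel must have columns {sorted(required)}")
    hosts = []
    for host_id, grp in df.groupby("host", sort=True):
        values = np.zeros(len(CANONICAL_CODONS))
        mask = np.ones(len(CANONICAL_CODONS), dtype=bool)
        for codon, val in zip(grp["codon"].str.upper(), grp["rscu"]):
            idx = CODON_INDEX.get(codon)
            if idx is not None:
                values[idx] = float(val)
                mask[idx] = False
        gc = float(grp["gc_percent"].iloc[0])
        hosts.append(
            (str(host_id), RscuVector(values, mask, source_id=str(host_id)), gc)
        )
    if not hosts:
        raise ValueError(f"no hosts found in {path}")
    return HostPanel(hosts=hosts)


def ranking_table(rankings: list[HostRanking]) -> pd.DataFrame:
    """Flatten rankings to a TSV-ready table (phage, rank, host, r, d, gc_delta)."""
    rows = []
    for ranking in rankings:
        for rank, (host, r, d, gc_delta) in enumerate(ranking.entries, start=1):
            rows.append(
                {
                    "phage": ranking.phage_id,
                    "rank": rank,
                    "host": host,
                    "r": r,
                    "d": d,
                    "gc_delta": gc_delta,
                }
            )
    return pd.DataFrame(rows)
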