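"""Generate the study cohort: 3 codon-usage regimes, 24 annotated genomes.

Writes a multi-record GenBank flat file, the regime truth table and a
host panel TSV (one "host" genome generated from each regime's base
profile) under results/synthetic/. Everything downstream (02-05) consumes
these files through the ordinary readers, exactly as real GenBank input
would be.
"""

from pathlib import Path

import numpy as np

from codonclust import synthetic_data as sd
from codonclust.codon_metrics import gc_content
from codonclust.genetics import CANONICAL_CODONS
from codonclust.pipeline import genome_metrics

SEED = 11
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([SEED, 0])
    profiles = sd.separated_regime_profiles(3, separation=1.0, rng=rng)
    regimes = [
        sd.RegimeSpec(
            label=p.label,
            profile=p,
            n_genomes=8,
            n_genes=200,
            gene_length_mean=120,
            gene_length_sd=30,
            trna_range=(0, 12),
            gc_intergenic=65.0,
        )
        for p in profiles
    ]
    spec = sd.CohortSpec(regimes=regimes, seed=SEED)
    records, truth = sd.generate_cohort(spec)
    sd.write_genbank(records, OUT / "cohort.gb")
    sd.write_truth_table(truth, OUT / "truth.tsv")

    # host panel: one genome per regime base profile, RSCU in long format
    lines = ["host\tcodon\trscu\tgc_percent"]
    for i, profile in enumerate(profiles):
        host_rng = np.random.default_rng([SEED, 1000 + i])
        rec = sd.generate_genome(
            profile, 150, [150] * 150, 0, host_rng, genome_id=f"HOST_{profile.label}"
        )
        _, vec = genome_metrics(rec)
        gc = gc_content(rec.sequence)
        for codon, value, masked in zip(
            CANONICAL_CODONS, vec.values, vec.undefined_mask
        ):
            if not masked:
                lines.append(f"HOST_{profile.label}\t{codon}\t{value}\t{gc}")
    (OUT / "host_panel.tsv").write_text("\n".join(lines) + "\n")

    sizes = [r.length for r in records]
    print(f"wrote {len(records)} genomes to {OUT / 'cohort.gb'}")
    print(f"genome sizes: {min(sizes)/1e3:.1f}-{max(sizes)/1e3:.1f} kb")
    print(f"regimes: {sorted(set(truth.values()))} (8 genomes each)")
    print(f"host panel: 3 hosts at {OUT / 'host_panel.tsv'}")


if __name__ == "__main__":
    main()
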