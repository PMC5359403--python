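# codonclust

Codon-usage-bias analysis for bacteriophage and bacterial genomes, built
around the question of phage host range: a phage borrows its host's
translational machinery, so its synonymous codon usage should mirror the
codon usage of its preferred host. Given annotated genomes (GenBank flat
files), `codonclust` computes per-genome codon-usage fingerprints,
clusters them, compares the clustering with externally supplied genomic
cluster labels, and ranks candidate bacterial hosts for each phage.

The package is organised as an analysis project: the library under
`src/codonclust/` holds every computation; the numbered scripts under
`analysis/` run the study end to end on a simulated cohort and write
their tables under `results/`.

## What it computes

**RSCU** (relative synonymous codon usage). For codon *j* of amino acid
*i* with degeneracy *n<sub>i</sub>* and observed count *x<sub>ij</sub>*:

    RSCU_ij = x_ij / ((1/n_i) Σ_j x_ij)

RSCU = 1 means no bias; the values for an amino acid always sum to
*n<sub>i</sub>*. Genomes are compared on the 59-dimensional RSCU axis
(64 codons minus 3 stops, Met and Trp).

**SCUO** (synonymous codon usage order), a Shannon-entropy bias score.
Per degenerate amino acid, H<sub>i</sub> = −Σ<sub>j</sub> p<sub>ij</sub>
log₂ p<sub>ij</sub> with p<sub>ij</sub> = x<sub>ij</sub>/x<sub>i</sub>,
normalised order O<sub>i</sub> = (log₂ n<sub>i</sub> − H<sub>i</sub>)/log₂
n<sub>i</sub>, and the genome-level SCUO is the count-weighted mean of
O<sub>i</sub>. SCUO ∈ [0, 1]: 0 = uniform synonymous usage, 1 = one codon
per amino acid.

**Clustering.** Pairwise Pearson correlation *r* between RSCU vectors is
turned into the distance d = (1 − r) × 100 ∈ [0, 200], and the matrix is
clustered by UPGMA (size-weighted average linkage; merge height = half
the merging distance, so the cophenetic distance between two leaves is
twice the height of their lowest common merge). Trees serialise to
Newick. Agreement between a k-cut of the tree and external cluster
labels is scored with the Fowlkes–Mallows index.

**Host ranking.** Each phage is correlated against a panel of host RSCU
vectors (computed from GenBank CDS or imported from a codon-bias-database
style TSV); hosts are ranked by *r*, with genome GC content used only for
tie-breaks and a separate ±window GC-compatibility table.

**Statistics.** One-way ANOVA (GC content across clusters), Pearson
tests (e.g. SCUO vs tRNA-gene count) and a slope F test (tRNA count vs
genome size), plus GC, GC3 and annotated-tRNA tallies per genome.

**Synthetic cohorts.** `codonclust.synthetic_data` generates annotated
genomes from per-amino-acid codon profiles with k regimes, tunable
regime separation and within-regime Dirichlet scatter, emitted as valid
GenBank so the real parser is exercised. Every recovery claim in the
test suite is measured against this generator's ground truth.

## Worked example

```
python analysis/01_simulate_cohort.py
python analysis/02_codon_metrics.py
python analysis/03_cluster_concordance.py
python analysis/04_host_ranking.py
python analysis/05_statistical_checks.py
```

On the default simulated cohort (3 codon-usage regimes × 8 genomes,
~200 genes each, 79–85 kb) this prints, among other lines:

```
24 genomes, 571843 codons counted
genome GC mol%: 55.3-59.0
 k  fowlkes_mallows
 2           0.7534
 3           1.0000
 4           0.9063
concordance peaks at k=3 (FM=1.0000); true number of regimes is 3
phages whose generating host ranks first: 24/24
GC by regime: F(2,21) = 985.35, p = 1.74e-21
ANOVA empirical type-I error at alpha=0.05: 0.0467 (10,000 sims)
```

i.e. the UPGMA tree cut at the true k reproduces the generating regimes
exactly (Fowlkes–Mallows 1.0), every phage's generating host wins the
codon-bias ranking, and the regimes differ sharply in GC while the ANOVA
itself is correctly calibrated under the null.

The same pipeline runs on real data via the CLI:

```
codonclust ingest --genbank genomes/ --labels labels.tsv --out cohort.tsv
codonclust cluster --genbank genomes/ --newick tree.nwk --labels labels.tsv --k 26
codonclust hosts --genbank genomes/ --panel hosts.tsv --out rankings.tsv
codonclust run --config config.yaml
```

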