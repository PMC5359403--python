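# Methods

## Model and procedure

The pipeline treats a genome's synonymous codon usage as its
translational fingerprint. All codon metrics are computed over the
concatenated accepted coding sequences of a genome; genome GC content
alone is computed over the full DNA sequence, because "DNA GC mol%" is a
whole-genome quantity while codon metrics only make sense in frame.

Codon counting uses NCBI translation table 11 (bacterial). Ser, Leu and
Arg are treated as single six-fold families (n_i = 6) rather than split
2+4 boxes; this matches the plain RSCU definition, and the canonical
59-codon axis orders codons by amino acid (alphabetical one-letter code)
then codon. RSCU, SCUO, GC and GC3 are defined in the README; the
entropy convention is 0·log 0 = 0, and SCUO weights each amino acid's
normalised order O_i by its codon count, over degenerate amino acids
with nonzero count only.

CDS filtering rules (all logged):

- GenBank coordinates are converted to 0-based half-open on read.
- A CDS whose length after the `codon_start` offset is not a multiple of
  3 is excluded — a frameshifted tally would corrupt RSCU.
- Overlapping CDS are counted independently (gene-wise counting): each
  annotated gene contributes its codons.
- `/pseudo` CDS are excluded (not translated).
- Codons containing non-ACGT characters are skipped and tallied in a
  separate skipped-codon counter.
- tRNA abundance is the count of annotated tRNA features; no de-novo
  prediction is attempted.

Distances are d = (1 − r) × 100 with r the Pearson correlation over RSCU
positions defined in *both* genomes (pairwise-complete masking; an
absent amino acid carries no usage signal). At least 3 shared positions
are required and zero-variance vectors are an error naming both genomes.

UPGMA is implemented directly: merge the closest pair, inter-cluster
distance is the size-weighted mean of cross-pair leaf distances, merge
height is half the merging distance (hence cophenetic distance =
2 × height and ultrametricity by construction). Equal minimal distances
are broken by the lexicographically smallest pair of cluster
representative ids (the smallest leaf id in each cluster), making trees
bit-reproducible. The implementation is cross-checked in the tests
against scipy's average linkage on random matrices; scipy is the oracle
there, never the implementation.

Concordance between a k-cut of the tree and external cluster labels uses
the Fowlkes–Mallows index (scikit-learn), chosen over adjusted Rand for
its stability with many small clusters.

Host ranking sorts panel hosts by descending r, breaking ties by smaller
|phage GC − host GC| then host id. GC enters only tie-breaks and the
separate ±window compatibility table; no composite score is formed,
because codon correlation and GC proximity are two separate arguments
and collapsing them would manufacture a "preferred host" criterion that
the underlying reasoning does not define. A top-ranked host is a
statement about translational match, not infectivity.

The "tRNA count vs genome size" test is a simple linear regression with
an F test for the slope (F on 1, n−2 df): the predictor is continuous,
so a grouped ANOVA would require inventing bins. F and t tail
probabilities come from scipy's beta-function-backed distributions.

## Synthetic data: what it emulates, what it does not

A cohort is defined by k regimes; each regime has a base codon profile
(per-amino-acid probability vectors over synonymous codons), and each
genome draws its own profile from a Dirichlet centred on the regime base
with concentration c (per amino acid: Dirichlet(c · p + 1e-9)). Genes
are a start codon, i.i.d. body codons (amino acid from a fixed
composition, codon from the genome's profile) and a stop codon, placed
on alternating strands with GC-controlled intergenic spacers; tRNA
features are annotated in dedicated non-coding blocks. Records are
emitted as valid GenBank flat files and re-read through the real parser.

Key parameters and defaults:

- `n_genes` 100–200 and `gene_length_mean` 120–200 codons, giving 40–160
  kb genomes — the size range of the phage genomes this pipeline
  targets.
- `gc_intergenic` 65 mol%, `trna_range` (0, 12) per genome (real phage
  annotations run 0–41).
- Amino-acid composition: a fixed GC-rich actinobacterial-like table
  (`AA_COMPOSITION`), configurable; composition matters because it sets
  the SCUO weights.
- Within-regime concentration 5000 (genomes of a regime nearly share a
  profile) for recovery experiments; 100 when the experiment needs
  visible within-regime scatter.
- Regime separation s ∈ [0, 1]: each regime's base profile is the convex
  mixture (1−s)·shared + s·own of one shared random profile and a
  regime-specific random profile (flat Dirichlet draws, α = 0.5 and 0.3
  respectively — small α gives the near-vertex, strongly biased profiles
  that distinct codon-usage regimes look like).
- Reproducibility: genome i of a cohort is generated from the substream
  `default_rng([seed, i])`, so output is byte-identical for a seed and
  independent of generation order.

The generator does not emulate genomic mosaicism, recombination,
homology or any nucleotide-level similarity structure between genomes —
regime membership is carried *only* by codon usage. Passing recovery
tests therefore show that the pipeline separates genuine codon-usage
regimes; they say nothing about cohorts whose labels derive from
nucleotide similarity, where codon-usage clustering can legitimately
disagree with the labels (that disagreement is, in fact, the interesting
signal on real data). tRNA counts are assigned independently of codon
bias, so the SCUO-vs-tRNA correlation is expected to be null on
synthetic cohorts.

`codonclust simulate --spec cohort.yaml --out DIR` drives the generator
from a YAML file with top-level keys `seed` (int), `separation` (float
in [0, 1]) and `regimes`, a list of mappings with `label` and
`n_genomes` (required) and optional `n_genes`, `gene_length_mean`,
`trna_range`, `gc_intergenic`, `concentration` — the RegimeSpec fields
above. It writes `cohort.gb` and `truth.tsv`.

## Experiment sizes and numerical choices

- Headline recovery: 3 regimes × 8 genomes × 200 genes (~120 codons
  each, ~570k codons cohort-wide), full GenBank round trip, concordance
  at the true k = 3. Sizes chosen to exercise realistic genome lengths
  while keeping the whole study a desk-scale computation.
- Recovery-vs-separation curve: separation levels (0, 0.06, 0.12, 0.25,
  0.5), 3 regimes × 6 genomes × 40 genes, within-regime concentration
  100, 20 replicate cohorts per level. The mean curve rises from the
  Fowlkes–Mallows chance level (~0.43 for 18 leaves in 3 balanced
  groups) to 1.0; 20 replicates make the per-level mean precise enough
  that its monotonicity is not at the mercy of chance-region noise.
- UPGMA oracle agreement: 1000 random matrices, 2–8 leaves, entries
  U(1, 100); ties have probability zero, so the tie rule is tested
  separately on constructed matrices.
- ANOVA calibration: 10,000 null datasets (3 groups × 10 standard
  normals), rejection rate at α = 0.05 compared with 0.05 ± 0.01.
- Tolerances: RSCU sum law and SCUO bounds at 1e-9 absolute; profile
  convergence uses composition-weighted total variation (< 0.02 at
  ~10^5 codons) because rare amino acids contribute few codons and a
  max-over-amino-acids criterion would be dominated by their sampling
  noise.
- Degenerate inputs: empty count tables, SCUO with only Met/Trp/stops,
  zero-variance correlation inputs, all-N sequences and frameshifted CDS
  raise informative errors; the all-groups-constant ANOVA reports F = ∞
  with p = 0 rather than dividing by zero.

## Known limitations

- SCUO follows the published entropy formula; tool-specific variants
  (e.g. different handling of six-fold families in legacy software) may
  differ slightly, and per-genome SCUO values from such tools are not
  expected to match to more than ~2 decimals.
- The reference-value check for the real Myrna (41 tRNA genes) and
  Patience (50.4 mol% GC) records requires downloading those GenBank
  files into `data/external/`; they are too large to ship with the
  package.
- Host ranking assumes the host panel's RSCU vectors are comparable to
  phage vectors computed here; imported database values computed under
  other CDS filters carry that filter's bias.
- With pairwise-complete masking, correlations in a cohort are not all
  computed over the identical codon subset when amino acids are absent
  from some genomes; for genomes with ≥ 50 genes every amino acid is
  essentially always present and the masks are empty.
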