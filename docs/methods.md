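# Methods

This note records the models, parameter choices and numerical decisions
behind `metapan`, and what the bundled synthetic data does and does not
establish.

## Homology scoring and the minbit graph

Gene clustering operates on translated sequences. The built-in backend is
Smith–Waterman local alignment with BLOSUM62 and affine gaps costing
`11 + k` for a gap of length k, the convention of protein BLAST, so that
imported BLAST tables and built-in scores live on one scale. Raw scores S
are converted to bits with the gapped Karlin–Altschul constants
λ = 0.267, K = 0.041:

    bitscore = (λ·S − ln K) / ln 2

Self-scores — the minbit normaliser — are computed as ungapped full-length
self-alignments (the sum of diagonal substitution scores, in bits). This
is deterministic and aligner-independent, and makes a gene's self-hit
normalise to exactly 1.

minbit of a hit is its bitscore divided by the smaller of the two
self-scores; pairs at or above the threshold (default **0.5**) become
undirected edges. When the two directions of a reciprocal hit disagree,
the edge takes the larger minbit — the permissive reading of a heuristic
pre-filter. The edge weight handed to MCL is the minbit value itself: it
is length-normalised and bounded in [0, 1]; raw bitscores or percent
identity can be substituted by constructing edges directly.

The all-vs-all step optionally (and by default) skips pairs of sequences
sharing no 5-mer. Two sequences with no common 5-mer cannot produce an
alignment anywhere near the minbit threshold at the divergence levels gene
families exhibit, and a dedicated test confirms the filtered and
unfiltered graphs are identical on simulated families; `kmer_prefilter_k=0`
disables it.

## Markov clustering

The transition matrix is the symmetric minbit adjacency with a self-loop
per node equal to its maximum incident edge weight (1 for isolated nodes)
— the standard damping against period-2 oscillation — normalised to
column-stochastic form. Iterations alternate expansion (M ← M·M) and
inflation (entrywise power, default **10**, then renormalisation).

Pruning keeps the matrix sparse: after each inflation, entries below
`mcl_prune_epsilon` (default 1e-8) are dropped and columns renormalised.
Two refinements matter in practice: pruning is applied to the *normalised*
column (so the epsilon is scale-meaningful), and a column's largest entry
is never pruned — at inflation 10 a column spread over many moderate
entries can otherwise fall entirely below epsilon and lose its support.

Convergence is declared when the maximum absolute entrywise change between
successive iterations falls below `mcl_convergence_tol` (1e-6), with a cap
of 100 iterations (non-convergence returns the current partition with a
warning). Clusters are the connected components of the converged support,
which is robust to overlapping attractor systems and guarantees a
partition of all nodes. Cluster ids are assigned by (size descending,
lexicographically smallest member), so output files are byte-stable under
any input permutation. The module contains no randomness.

## Pangenome layer

The occurrence matrix counts genes per (cluster, genome); presence is
`count > 0`. Bin assignment uses strict set logic with precedence
CORE_ALL > SINGLETON > CORE_HL/CORE_LL > OTHER:

* CORE_ALL — present in every genome (requires ≥ 2 genomes; in a
  single-genome project everything is a SINGLETON);
* CORE_HL — present in every HL genome and in no other genome, and only
  awarded when both light classes exist (symmetrically CORE_LL); a genome
  of light class "other" carrying the cluster blocks both clade-core bins;
* OTHER — everything else.

Dendrograms use Ward linkage on Euclidean distances between presence
(0/1) vectors — presence rather than counts because the relationships of
interest are in the distribution of clusters, not paralog multiplicity
(`use_counts=True` switches). Rows are sorted lexicographically before
linkage so ties resolve identically on every run. One caveat the test
suite makes explicit: binary presence vectors give integer squared
distances, so merge-order ties are essentially certain, and under ties
Ward's result is tie-break-defined; the cross-implementation agreement
check therefore adds a seeded jitter of U(0, 1e-4) to make the linkage
unique before demanding 1e-9 agreement. Newick export sanitises labels
(reserved characters → `_`) and writes branch lengths as parent height
minus child height.

## Recruitment layer

Depth is the count of aligned read bases per reference position; mapping
quality is ignored and secondary/supplementary alignments excluded. Gene
coverage is the arithmetic mean over the half-open span [start, stop);
breadth is the covered-position fraction pooled over contigs, so it is
invariant to contig order and splitting. Detection is **strictly**
`breadth > 0.5` at `min_depth ≥ 1`: a genome covered on exactly half its
positions is not detected. The canonical interchange is a pair of TSV
matrices (gene × metagenome mean coverage, genome × metagenome breadth)
plus per-metagenome read totals; the BAM backend (pysam) produces the
identical profile from alignments and is checked against a brute-force
pileup. Relative distribution is 100 × mapped reads / total
quality-filtered reads, with totals supplied as metadata because BAMs
produced without unaligned reads cannot provide them. For paired reads,
counting read bases (rather than fragments) can differ slightly from
fragment-based profilers in overlapping pairs.

## Environmental classification

Per genome, each gene's mean coverages are summed over the metagenomes
where the genome is detected. The median of these sums is taken over *all*
the genome's genes, zeros included; a gene is EAG when its sum is
**strictly below** `fraction_of_median_coverage` (default **0.25**) times
the median, else ECG. The rule is ratio-based, so rescaling a genome's
coverages changes nothing, and adding metagenomes where the genome is not
detected changes nothing. An even gene count takes the midpoint of the two
central sums, which decides boundary labels. Genomes detected nowhere are
entirely UNCLASSIFIED, and unclassified genes are excluded from every
downstream denominator (per-genome EAG fractions, function ratios, bin
percentages). Function connectivity ranks (source, accession, function)
keys by EAG ratio, then EAG count, then key — deterministic under input
permutation. Island summaries are simply maximal runs of consecutive EAGs
in genomic order per contig; no changepoint or HMM machinery is implied.

Per-bin EAG percentages are pooled per-gene (100 × ΣEAG / Σclassified over
the bin's clusters), not averaged per cluster; averaging per cluster is a
one-line variant on the summaries if needed.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

* **Families.** Defaults: 2 clades (4 HL + 4 LL genomes), 50 universal
  core families, 10 clade-core families per class, 5 singletons per
  genome, 16 patchy families present in a random 2..n−1 subset (redrawn if
  the subset coincides with a whole light class), and one island of 8
  dedicated families per genome, present in all genomes. ~650 genes total.
* **Sequences.** One i.i.d. ancestor per family (uniform over the 20
  residues, length 60–120); each genome's copy mutates every site with
  probability 1 − identity (default identity 0.9) to a uniformly chosen
  different residue; no indels by default, keeping alignment scores
  predictable. Independent ancestors put between-family identity near 5%,
  far below the 0.2 ceiling the parameters require. Nucleotide genes are
  back-translated with one fixed codon per residue plus a stop codon and
  laid on one contig per genome with 30 bp spacers, island genes as one
  contiguous block at a random position; all genes on the + strand.
* **Coverage.** A clade × metagenome abundance plan (staggered windows of
  ~20X so every genome has both detected and undetected metagenomes);
  per-gene coverages are Normal(abundance, 10% dispersion) truncated at 0,
  island genes multiplied by the island multiplier (default 0); breadth is
  a constant 0.95 where present and 0.02 where absent. Mapped read counts
  follow coverage × genome length / 100 bp against 10⁷ total reads per
  metagenome, giving relative distributions of a few hundredths of a
  percent.
* **Read fixture.** A separate three-contig, 50-read fixture is generated
  as SAM text with brute-force depth vectors, exercising the per-position
  BAM path that the gene-level simulation bypasses.

Everything derives from one integer seed and iterates over sorted
containers, so equal seeds give byte-identical files.

What passing tests on this generator shows: the pipeline's stages are
correct against their definitions and recover planted structure when
within-family divergence is far from the between-family level, coverage
contrasts are strong, and detection is unambiguous. What it does not show:
performance on real data with phylogenetically structured divergence,
indels and domain shuffling, non-specific read recruitment between
conserved regions, paralog expansion, or fragmented assemblies. Boundary
regimes (families near the minbit threshold, breadth near 0.5, coverage
sums near 25% of the median) are exercised by constructed cases, not by
the generator's defaults.

## Problem sizes and numerical conventions

The default test/acceptance project is 8 genomes × ~80 genes; oracle
comparisons use 200 random graphs of ≤ 8 nodes for MCL and 10–12-row
matrices for Ward — sizes at which the independent dense references are
exact and the whole suite completes in seconds while every contract is
still exercised end-to-end. Floats in TSVs are written with 10 significant
digits (breadth/coverage) so round-trips preserve comparisons; newick
branch lengths use repr-stable formatting; all rates and ratios are exact
fractions of integer counts. Degenerate inputs fail loudly: empty
sequences, missing coverage cells, unknown contigs or gene ids, zero
column sums and non-stochastic matrices all raise with the offending
identifier.

## Known limitations

* MCL here reproduces the algorithm, not any particular external
  implementation's scheme flags; on real data, cluster counts can differ
  slightly from other MCL-based pipelines even at the same inflation.
* The clade-core bins demand strict absence from the complement class;
  pipelines that bin interactively may count a few clusters differently.
* E-values, compositional score adjustment and alignment-coverage filters
  are deliberately absent; the minbit threshold is the only hit filter.
* The environmental rule uses mean gene coverage; trimmed-mean variants
  would need a different profiling layer.
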