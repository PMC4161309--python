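# Methods note

This note records the models, parameter choices, and numerical decisions
behind `sagkit`, in the package's own terms. Module references are to
`src/sagkit/`.

## 1. Read cleanup (readclean)

Model: index hopping on a patterned flow cell relabels a small fraction of
read pairs between multiplexed libraries. Because MDA coverage is extremely
skewed, hopped reads come almost entirely from ultra-high-coverage
("hotspot") regions of their source genome, but land thinly spread in the
recipient dataset.

Procedure: (1) collect foreign contigs with declared mean coverage
> `coverage_region_threshold` (5000×); (2) map the recipient's reads
against those regions with an exact-k-mer-seeded ungapped mapper capped at
`mapper_max_mismatches` (2); (3) compute each mapped read's pile-up depth
as the number of reads of the same set whose mapped footprint overlaps it;
(4) remove reads piling ≤ `read_removal_depth` (20×); (5) for deeper piles
(conserved sequence also present in the recipient genome), keep the read
only if it aligns to the recipient's own assembly at
≥ `min_rescue_identity` (0.90) identity over ≥ 90% of its length; (6) a
removed mate drags its partner.

Numerical choices:

- **Seed length k = 25.** For 76 nt reads and a 2-mismatch cap, the
  pigeonhole bound ⌊76/(2+1)⌋ = 25 guarantees that any qualifying placement
  contains at least one exact 25-mer, so the seeded mapper is exactly
  equivalent to exhaustive enumeration — no sensitivity parameter to tune.
- **Rescue fast path.** An ungapped own-assembly hit with at most
  ⌊(1 − 0.90)·len⌋ mismatches implies the rescue criterion, so the k-mer
  mapper short-circuits the affine local aligner; the aligner remains the
  fallback for gapped or partial matches. This is a pure optimization.
- **Identifiability limit.** A hopped read from a locus that is
  near-identical between source and recipient (e.g. a homogenized rRNA
  operon inside a hotspot contig) is indistinguishable from a genuine read;
  the rescue step keeps it by design. Cleanup scoring scenarios therefore
  disable rRNA homogenization (see §8).

## 2. Contig QC (contigqc)

Exclusion rules in order: (i) length < 250 bp; (ii) length < 500 bp and
(coverage < 5× or no translated six-frame hit against the species reference
proteome at E ≤ 1e−5); (iii) no translated hit against a bacterial protein
panel (skipped with a warning when the panel is empty). Redundancy: a
contig equal to, or an exact substring of (either strand), a strictly
longer retained contig is dropped; equal-length duplicates keep the
lexicographically smaller id. Completeness is the fraction of a minimal
essential-protein set recovered at ≥ 50% identity over ≥ 50% of both
sequences.

Translated screens use a peptide 5-mer index over the panel: only panel
members sharing an exact 5-mer with a six-frame fragment are aligned. At
the divergences involved a true homolog essentially always shares a 5-mer,
and the index removes an O(fragments × panel) alignment cost.

## 3. Protein alignment statistics (palign)

Local alignment uses BLOSUM62 with gap open −11 / extend −1
(Bio.Align.PairwiseAligner). Significance uses fixed Karlin–Altschul
parameters λ = 0.267, K = 0.041 (the standard gapped-BLOSUM62 values):
E = K·m·n·e^(−λS). Identity is computed over aligned columns; coverage as
aligned span over sequence length.

## 4. Ortholog inference (orthomap)

Hits at ≥ 50% identity covering > 50% of both proteins form a
score-weighted undirected graph, clustered by Markov clustering (MCL):
self-loops at the column maximum, column normalization, alternating
expansion (power 2) and inflation (Hadamard power 1.5, configurable),
pruning at 1e−6, convergence at max-change < 1e−8 (RuntimeError reporting
the residual otherwise). MCL is implemented on dense numpy matrices; at
pipeline scale (hundreds of genes) density is not a constraint. Clusters
are named `OGnnnnn` in order of their smallest member; singletons are not
clusters. Paralogs resolve to the copy with the highest mean identity to
other-genome members (ties: smaller id). Unclustered genes with any
cross-genome hit are "remnants", otherwise "genome-specific"; proteins
< 50 aa never count toward per-genome unique totals (short-gene false
positives).

## 5. Divergence estimation (codon, divstats, mlcodon)

**NG86 counting.** Synonymous site counts per codon are the fraction of
single-base changes that are synonymous; changes creating a stop count as
nonsynonymous. Multi-position codon differences average the
synonymous/nonsynonymous step counts over all orderings of the single-base
path, excluding orderings that pass through a stop (unless all do).
Columns with gaps, ambiguity, or stops are removed pairwise (complete
deletion). pS and pN are corrected by Jukes–Cantor
d = −¾ ln(1 − 4p/3); p ≥ ¾ is saturated. dS ≥ 3 (or saturation) is
reported with dS capped at `ds_cap` (3.0). The hand-checkable example —
ten Phe codons, one synonymous third-position difference — gives
pS = 1/(10/3) = 0.3 and dS = 0.383119…, frozen in tests as 0.3831.

**Pairwise ML.** Goldman–Yang-style codon model: rate between sense codons
differing at one position is π_j · κ^[transition] · ω^[nonsynonymous],
zero otherwise; π from F3×4 frequencies of the two sequences. Q is scaled
to one expected substitution per codon per unit t, so
dS = t·ρS/S\* where ρS is the synonymous flux fraction under the fitted
(κ, ω) and S\* = 3·ρS(ω = 1) is the synonymous mutational-opportunity
sites per codon. The likelihood Σ c_ij·log(π_i P_ij(t)) is maximized over
log-parameters with L-BFGS-B from three starts (t₀ ∈ {0.1, 1, 3}),
bounds t ∈ [1e−4, 50], κ ∈ [0.05, 50], ω ∈ [1e−4, 20]. P(t) = e^{Qt} is
computed by symmetric eigendecomposition of the π^{1/2}-similarity
transform (valid because the model is time-reversible); eigh is
numerically stable and reused across the optimizer's evaluations only via
the per-call decomposition (matrix size 61 makes this cheap). Identical
sequences return exact zeros without optimization.

**Other statistics.** Pairwise identity: global alignment (match 2 /
mismatch −1 / open −5 / extend −0.5) with free terminal gaps; identity =
matches over aligned columns including internal gaps, rounded to 2
decimals. π is the mean pairwise proportion of differing comparable sites.
Sliding windows (200/50 by default) run over the gap-stripped alignment,
always including the final full window; saturated windows are NaN.

**Ternary analysis.** Per-gene triplets (dS_AB, dS_AC, dS_BC) are capped
at 3, normalized to sum 1, and plotted in ternary coordinates
(x = y′ + z′/2, y = √3·z′/2). Colors follow the maximum raw dS: < 0.1
yellow, ≥ 0.1 orange, ≥ 1 red. The spread statistic is the mean (or
median — both are reported, as the mean is outlier-sensitive and the
median robust) Euclidean distance of gene points to their mean point.
All-zero triplets are dropped and listed.

## 6. Recombination (recomb)

**R_m.** Biallelic segregating sites failing the four-gamete test define
intervals that must each contain a breakpoint; the minimum number of
stabbing points, computed by the right-endpoint greedy (provably optimal
for interval stabbing), is the Hudson–Kaplan lower bound. Tests verify
exact equality with a subset-enumeration oracle.

**Gene-conversion fragments.** Over polymorphic columns, each sequence
pair's agreement vector scores +1 per match and a penalty per mismatch;
the maximal-scoring segment (Kadane) is the candidate fragment.
Penalties: gscale 0 ends a run at any mismatch (penalty −1e9); gscales 1
and 2 use −(2g+1) = −3, −5. The −(2g+1) calibration is this package's own
choice — small integer penalties that make one mismatch cost 1.5× / 2.5×
the score of a matching site, giving a graded tolerance ladder.
Significance: the observed maximum is compared to the same statistic under
joint random permutations of polymorphic columns (all pairs share one
permutation set per gscale), p = (1 + #null ≥ obs)/(1 + N), Bonferroni ×
number of pairs, reported when corrected p ≤ 0.05. The library default is
N = 10000 permutations; the pipeline and tests use 2000, whose p-value
resolution (5e−4) is far below the 0.05 decision point, to stay inside
time budgets.

**r/m.** From per-site recombination-origin probabilities p_i over
substituted sites: `all_positions` = Σp_i / Σ(1 − p_i);
`confident_only` = #{p ≥ 0.95} / #{p ≤ 0.05} (infinite when the
denominator is 0 and the numerator positive).

## 7. Phylogenetics (phylo)

Neighbor joining on JC-corrected distances; a negative branch-length
estimate is clamped to 0 and the deficit moved to the sibling edge,
preserving the joined pair's path length; the root is the standard
trifurcation. Bootstrap: column resampling with replacement, NJ per
replicate, support = percentage of replicates displaying each split of the
point-estimate tree (saturated replicates are skipped but still count in
the denominator — a conservative choice). Splits are canonically oriented
as the side not containing the lexicographically smallest taxon.
Concordance: each reference split is restricted to the taxa shared with a
gene tree; gene trees that cannot display the restricted split (< 2 taxa a
side) leave that split's denominator. Congruent = gene tree contains the
split; supported = contains it with bootstrap ≥ 80. scikit-bio's NJ is
used in tests as an independent topology oracle only.

## 8. Simulator (simulate): what it emulates, and its limits

The generator mirrors the assumed data-generating process, not any
specific dataset:

- **Sequence evolution.** Star phylogeny; per-site substitution proposals
  arrive as Poisson(d); synonymous changes are always accepted,
  nonsynonymous ones with probability ω. Under this scheme d *is* the
  expected synonymous substitutions per synonymous site (the NG86 sense of
  dS), so divergence-recovery checks have an analytically known truth.
  Residual bias from multiple hits at two-fold degenerate sites is ~2–3%
  at d = 0.2, well inside the 5% recovery tolerance.
- **rRNA homogenization.** Every strain's rRNA-like locus is overwritten
  with strain 0's copy (a recorded donor tract) plus residual point
  mutations at 0.002/site, keeping locus identity > 99% regardless of
  genome-wide divergence — the marker-gene blindness the analysis is meant
  to expose.
- **Partial recovery.** Removal intervals (mean 20 kb) delete exactly
  round(dropout_fraction · L) nt; retained segments become contigs.
- **Coverage decoupling.** Declared per-contig coverage (lognormal, median
  60, σ = 1; hotspots boosted to ~8000×) drives the *cleanup geometry*,
  while emitted read depth is a separate, desk-scale knob
  (`sequencing_depth`, default 30×). Emulating hotspot coverage with
  literal reads would need millions of reads per genome; decoupling keeps
  fixtures tiny while preserving every decision the cleanup makes
  (region flagging by declared coverage; pile-up from actual reads).
- **Index hopping.** A Binomial(pairs, rate) number of pairs per genome is
  relabeled to another library; hopped pairs are drawn from hotspot
  contigs (declared coverage > 5000×) with probability 0.99,
  coverage-weighted, matching the observed concentration of hopping in
  ultra-amplified regions. The 1% non-hotspot remainder bounds achievable
  cleanup recall from above, which the scoring scenarios account for.
- **Limits.** No sequencing error by default (configurable), error-free
  assemblies (no misassembly/chimera model), star phylogeny only, single
  replicon, and recombination tracts drawn uniformly rather than from a
  donor-similarity kernel.

## 9. Scoring scenarios and sizes

- R_m oracle: 200 random alignments, ≤ 12 biallelic sites, 4–7 sequences.
- dS recovery: 100 pairs × 1000 codons at d = 0.2, ω = 0.1; NG86 and ML
  means within 5% of 0.2; |dS_NG86 − dS_ML| ≤ 0.05 per gene (genes with
  both estimates ≤ 0.3).
- Cleanup: 2 genomes, 50 kb, branch d = 0.2, 10% dropout, 0.3% hopping,
  rRNA homogenization off (identifiability, §1); recall ≥ 0.95, false
  removal ≤ 0.01. Observed across seeds: recall 0.95–1.0, false removal
  0.002–0.006.
- Gene conversion: 3 sequences × 1200 nt at 8% per-branch divergence,
  implanted 300 nt tract, gscale 1, 2000 permutations; detection (p ≤ 0.05,
  ≥ 80% tract overlap) in ≥ 90% of 50 runs; type-I error over 100
  tract-free runs ≤ 0.08 (observed 0–0.02).
- rRNA signature: 2 strains at branch d = 0.75 with homogenization on;
  pipeline reports concatenated ML dS > 1 with 16S-style identity ≥ 99%.

All seeds in tests are fixed constants; `scripts/acceptance.py` derives
its seeds as (seed·1009 + k) mod 2³¹ from the command-line `--seed`.
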