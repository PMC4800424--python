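# Methods

## Scope and data model

The package operates on four inputs: transcript sequences (FASTA), genomic
intervals (GFF3 or BED), a known coding-sequence set (FASTA), and a stage ×
transcript FPKM matrix (TSV with a `transcript_id` column followed by stage
columns in developmental order). All intervals are stored 0-based half-open;
GFF3 coordinates are converted once at the reader boundary. Sequences are
uppercase over {A, C, G, T, N}; `U` maps to `T` and all other ambiguity codes
are rejected, because the Fickett and hexamer statistics are defined over the
four bases (positions and windows containing N are skipped from counts).

## ORF model

An ORF runs from ATG to the first in-frame stop (complete) or to the
sequence end (3′-partial; included). 5′-partial stretches without an ATG are
not counted. Codons containing N are neither starts nor stops and terminate
a growing ORF without granting it a stop. `aa_length` counts residues
excluding the stop codon, so the ">100 amino acids" discovery filter removes
a transcript exactly when its longest ORF encodes 101+ residues; a 100-residue
ORF is retained. Both strands are searched by default (configurable to
forward-only), using the standard nuclear genetic code.

## Coding potential

Four features feed a logistic regression:

* `orf_size` — nucleotides of the maximal ORF, stop codon included;
* `orf_coverage` — `orf_size` / transcript length;
* `fickett` — the TESTCODE statistic over the whole transcript, using the
  published position/content probability tables, breakpoints and weights
  (embedded as module constants). The position parameter of base *b* is
  max/(min+1) over its three codon-position counts; the content parameter is
  its composition fraction; each resolves to the probability of the first
  breakpoint it meets scanning downward, and the eight weighted probabilities
  sum to the score.
* `hexamer` — mean natural-log likelihood ratio of in-frame hexamers
  (step 3) between class frequency tables. Coding training sequences are
  counted in the reading frame of their maximal ORF, noncoding in frame 0 of
  the whole transcript; a pseudocount (default 1 per hexamer) keeps all 4,096
  frequencies positive. Scoring covers the ORF residue codons only — the stop
  codon is excluded, since otherwise every short ORF carries exactly one
  stop-containing window whose extreme log-ratio dominates its mean and
  manufactures class separation that has nothing to do with codon usage.
  Whether to score the Fickett statistic on the whole transcript or only the
  ORF was an open choice; the whole transcript is used and recorded here.

The logistic fit is maximum likelihood with a small L2 ridge (default 1e-6)
so that separable synthetic data stay finite; features are standardized
internally and the coefficients mapped back to the raw scale, making the fit
deterministic and the stored model directly applicable to raw feature
values. A ridge of zero is allowed only when the design matrix has full
rank. The classification cutoff defaults to 0.39 with the strict convention
that probability < cutoff means noncoding (0.39 itself classifies coding).
No pre-trained model is bundled: the model file format stores the intercept,
the four coefficients, the cutoff and a checksum of the hexamer table, and
the CLI trains a model from the synthetic corpus on demand when none is
supplied.

## Discovery funnel

Stages run in the fixed order length → maximal ORF → coding potential →
CDS similarity → genomic context, even though the predicates commute,
because the per-stage counts of the funnel report depend on the order. The
report enforces `retained + removed = input` per stage and
`input_{i+1} = retained_i`.

The CDS screen is a seeded, ungapped local matcher: shared k-mers (default
k = 11) between candidate and CDS define diagonals; on each diagonal the
longest window with identity ≥ `min_identity` (default 0.8) is found by a
prefix-sum scan (matches weigh 1−t, mismatches −t; a window qualifies iff
its transformed sum is nonnegative), and a candidate is removed when some
window covers ≥ `min_coverage` (default 0.5) of it, on either strand. These
thresholds are package defaults, surfaced in the configuration; an external
tabular-hit hook (`cds_screen_from_hits`) accepts alignments from an outside
tool instead. Genomic context is a pure half-open overlap test against
coding-gene intervals on either strand, via an interval tree.

## Expression specificity

FPKM rows with positive totals are row-sum normalized into probability
vectors; all-zero rows are excluded rather than assigned a score (the
Jensen–Shannon divergence against a zero vector is undefined). The
specificity of profile *p* is `max_t [1 − sqrt(JSD(p, e_t))]` with base-2
logarithms, so JSD ∈ [0, 1] and the score's range [0, 1] holds without
rescaling; ties in the maximizing stage resolve to the earliest stage in
developmental order, compared with a 1e-12 tolerance so equal scores do not
split on floating-point summation order. Expression tiers are tertiles by
rank of mean FPKM (sorted descending, ties by transcript ID; remainders go
to the higher tiers) because the analysis calls for exactly three named
tiers without stated boundaries. The extreme-specificity band is the closed
interval [0.9, 1.0]. Housekeeping transcripts are excluded by an explicit
user-supplied ID list, never derived.

## Stage clustering

Profiles are per-row max-normalized before clustering (the heatmap
convention), distinct from the probability normalization used for JS. The
k-means uses city-block (L1) distance with element-wise *median* centroid
updates — the L1 cost minimizer — rather than means; this is the single most
consequential numerical choice and is asserted by a local-optimality test.
Initialization samples k distinct rows with a seeded generator; an empty
cluster is re-seeded with the row farthest from its centroid; the best of
`n_restarts` (default 20) runs by total cost is kept, with `max_iter` 300
and a cost-change tolerance of 1e-6, so results are a pure function of
(matrix, k, seed, n_restarts). Cluster counts default to k = 10 (embryonic),
8 (larval) and 9 (pupal), overridable.

A cluster is called stage-specific when its row-sum-normalized centroid's
peak stage holds a fraction strictly above the dominance threshold
(default 0.5 — a configuration default, not an inference about how
"specifically highly expressed" was originally operationalized); members
inherit the centroid's peak stage. A per-row argmax mode
(`per_row_stage_specific`) is available as an alternative.

## Statistical tests

Fisher's exact test conditions on the observed margins and computes the
hypergeometric p-value by integer enumeration: all support probabilities
share one denominator, so tables are compared by exact integer numerators
and the two-sided value (sum over tables no more probable than the observed
one, the probability-mass convention) is free of floating-point tie
ambiguity. The Mann–Whitney U uses midranks; for combined samples of at most
40 the permutation distribution is enumerated exactly by a dynamic program
over doubled midranks (two-sided: probability of a U at least as far from
n_x·n_y/2 as observed), and larger samples use the tie-corrected normal
approximation with continuity correction. Sidedness defaults to two-sided
and is configurable everywhere. No multiple-testing correction is applied by
default; a Benjamini–Hochberg helper exists but is off.

## Synthetic data

The generator encodes the statistical structure the analysis assumes, with
every draw a pure function of the config seed:

* **Sequences.** Coding records (default 1,000; 450–3,000 bp) embed an
  ATG…stop ORF covering 65–92% of the transcript and always exceeding
  100 residues, with codons drawn from a usage distribution
  `w ∝ exp(strength · z)` over the 61 sense codons; noncoding records
  (default 1,000; 250–1,500 bp, bracketing the short lengths typical of
  lncRNAs) are i.i.d. uniform bases with any chance ORF capped at 100 aa by
  rejection. The bias direction `z` is a fixed package constant — a property
  of the simulated organism — so a model trained on one corpus transfers to
  corpora with other seeds; only the strength (default 0.5) is configurable.
  At strength 0 coding codon usage is uniform over the sense codons, which
  equals the in-frame codon law of random sequence conditioned on containing
  no stop, so the hexamer contrast vanishes exactly (verified by an AUC ≈ 0.5
  test).
* **Expression.** Stage-specific rows (default 300) draw
  Dirichlet(α = 0.05) profiles over 12 stages, relabeled so the argmax sits
  at a round-robin designed stage; broad rows (default 600) draw
  Dirichlet(α = 5). Both scale by log-normal totals (μ = 2, σ = 1 on the log
  scale, median total ≈ 7.4 FPKM). All-zero rows make up 10% of the matrix.
  The sparse/broad concentration contrast stands in for the lncRNA/coding
  contrast; the effect sizes are configuration, not claims about biology.
  In the sparse limit the mean maximal JS score rises toward 1 (≈ 0.94 at
  α = 0.005 over 12 stages; at the default α = 0.05 it is ≈ 0.65, amply
  separated from the broad group's ≈ 0.18).
* **Annotation.** Coding genes sit on a regular grid (2 kb genes, 3 kb
  gaps); intergenic candidates are placed wholly inside gaps and genic
  candidates start inside genes, so the construction fixes the ground truth
  and context classification can be checked for exact recovery.
* Stage-panel presets mirror the embryonic/larval/pupal layouts
  (12/6/6 stages).

What the generator does **not** emulate: real codon usage or GC structure,
splice isoforms sharing loci, expression correlation between stages,
measurement noise models of tiling arrays or RNA-seq, and the genome-scale
class imbalance of a real transcriptome. Passing recovery tests therefore
demonstrates the correctness and discriminative machinery of the pipeline
under its own model assumptions, not field performance on real libraries.

## Problem sizes and determinism

The test suite exercises the classifier at 1,000 held-out transcripts per
class (trained on an independent 500-per-class corpus), stage-recovery at
600 designed rows, and the group contrast at 500 rows per group; exhaustive
oracles cover every 2×2 table with total ≤ 30, permutation enumeration up to
8 observations per group, and all 2-partitions of 8 points for the L1
k-means. These sizes were chosen as the smallest at which the recovery
thresholds are statistically comfortable. The end-to-end driver writes no
timestamps into its outputs, so identical configurations produce
byte-identical summaries.

## Known limitations

* The CDS screen is a k-mer/diagonal matcher, not an aligner: diverged or
  gapped homology below the seed identity escapes it; the external-hit hook
  exists for exactly that case.
* The logistic model is as good as its training corpus; no Drosophila-trained
  coefficients are bundled.
* The per-locus vs per-transcript distinction is left to the caller: every
  FASTA record and matrix row is treated as an independent transcript.
* Specificity scores are undefined for all-zero rows; they are reported as
  excluded IDs rather than zeros, and downstream proportions are computed
  over scored rows only.
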