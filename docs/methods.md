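# Methods

This note documents the statistical procedures, parameter choices and
numerical conventions of the package, and what the synthetic-data tests
do and do not demonstrate about real repertoire data.

## Curation and clonotype definition

A rearrangement is kept only if its CDR3 amino-acid junction starts with
the framework cysteine (IMGT position 104). Beyond that rule, records
with empty junctions, stop codons (`*`), out-of-frame markers (`_`), or a
non-productive flag are removed: none of these can be CDR3 amino-acid
clonotypes, and immunoSEQ-style exports routinely contain them. Each
removal is tallied under the first matching reason so the report
partitions the input exactly.

Clonotype identity is the CDR3 amino-acid sequence alone. V/J gene calls
are carried as annotation (from the highest-template contributing
rearrangement, V-call lexicographic tie-break) and never enter the
grouping key, because public/private sharing and cross-sample tracking
operate on amino-acid CDR3s. Frequencies are template-weighted
(templates approximate input cell counts in immunosequencing); an
unweighted mode (`weight_by_templates=False`) counts each rearrangement
once. A missing template count defaults to 1 with a warning rather than
an error, since a sequenced rearrangement implies at least one template.

## Clonality

Shannon entropy is computed in bits (base-2 logarithms), with
0·log 0 := 0. The clonality index is 1 − H/log₂N. A single-clonotype
sample makes H/H_max 0/0; clonality is defined as 1 there, honoring the
oligoclonal endpoint of the index. Frequencies must be non-negative and
sum to 1 within 1e−6 on input; clonotype-table invariants are enforced
at 1e−9.

The paired compartment comparison is a two-sided Wilcoxon signed-rank
test. Zero differences are dropped; |differences| receive average ranks
under ties; the statistic is min(W+, W−). For n ≤ 25 effective pairs the
two-sided p sums both tails of the exact W+ distribution, built by
dynamic programming over doubled (integer) ranks — mathematically
identical to enumerating all 2ⁿ sign assignments, and verified against
literal enumeration in the tests up to n = 10. Above n = 25 a normal
approximation with tie-corrected variance and a 0.5 continuity
correction is used; the result records which method applied. On the nine
published paired clonality indices the exact two-sided p is 6/512 =
0.0117 (reported elsewhere rounded to 0.01); both sidedness conventions
round to the same value on those data, so the choice of two-sided is not
load-bearing.

## Frequency tracking

The two-proportion test is the Pearson χ² on the 2×2 table (clonotype
vs. all other templates × sample), 1 df, computed in closed form (it
equals the squared pooled-proportion z statistic; the identity is checked
numerically to 1e−9, and the statistic is cross-checked against an
independent contingency-table implementation). No continuity correction
is applied by default — a Yates option exists — and no multiple-testing
correction by default, with Benjamini–Hochberg available, because the
direction calls (up/down at raw α = 0.05 two-sided) are intended to
mirror per-clonotype tables in the underlying study design. Degenerate
margins (pooled proportion 0 or 1) carry no signal and return χ² = 0,
p = 1.

When a clonotype is absent from one sample the test is still computed but
flagged with the absent side; `strict_absence` instead withholds the
p-value (direction `not_tested`), reproducing the "n.d." convention some
reports use. A clonotype absent from both samples is never tested.

Top-N extraction sorts by template count descending with a lexicographic
CDR3 tie-break — the rank-boundary tie rule is otherwise arbitrary, and
this choice makes repeated runs and permuted inputs byte-identical.

## CDR3 edit alignment

Unit-cost Levenshtein distance, with a canonical traceback preferring
match/substitution over deletion over insertion at equal cost, so exactly
one edit script is reported among co-optimal alignments (a rendering of
the alignment presumes one). Edit operations describe how the reference
differs from the query: substitutions replace a query residue, deletions
mark query residues the reference lacks (hyphen), insertions are residues
present only in the reference. Positions are 1-based on the query. The
annotation renders the aligned reference with substituted residues
lowercase, inserted residues bracketed and deletions as `-`, e.g. query
`CASATALNYGYTF` vs. reference `CASASANYGYTF` → `CASAsA-NYGYTF`.

Distances are verified against a brute-force recursive oracle
(exhaustively on a 3-letter alphabet to length 4, randomly to length 8)
and against an independent alignment library; edit-script soundness
(replaying the ops on the query yields the reference) is checked on
1,000 random pairs. Default `max_distance` for viral matching is 2,
which covers typical published near-matches; matches are sorted by
(distance, epitope, reference) for determinism. The HLA filter compares
allele strings by prefix after stripping the `HLA-` prefix, so `A*03`
matches `HLA-A*03:01`.

Public/private classification is exact sequence membership in a local
reference snapshot with a `min_subjects` threshold (default 1). Snapshot
checksums are recorded in the pipeline run log so calls are reproducible
against a versioned file.

## Expression signature

The module consumes an already-normalized genes × samples matrix
(platform normalization and batch correction are upstream). Values are
log2(x + 1) transformed; the pseudocount keeps zeros finite and is the
conventional choice for normalized counts.

Samples are projected onto principal components of the gene-wise centered
matrix; by default the number of components is the smallest explaining
80% of variance (the PC count feeding the clustering is otherwise a free
choice). Ward agglomeration on Euclidean distances between PC
coordinates is cut at k clusters (default 3). Cluster labels are
renumbered by ascending mean within-cluster total expression, so cluster
k is always the high-signature group — raw agglomeration labels are
arbitrary, and this makes the labeling deterministic and interpretable.

Marker selection uses a one-vs-rest Welch (unequal-variance) t-test per
gene at α = 1e−4, keeping genes with higher target-cluster mean; Welch is
robust to unequal cluster sizes and variances, and a Kruskal–Wallis
option is provided. Genes with zero variance across all samples carry no
signal and are assigned p = 1. The selection's false-positive behavior
is calibrated on pure-noise matrices in the tests (the one-sided
restriction halves the two-sided α).

Modified z-scores use the 0.6745·(x − median)/MAD convention. Zero-MAD
rows fall back to mean-absolute-deviation scaling
((x − median)/(1.253314·MeanAD)); rows still degenerate are all zeros.

Signature scores are unweighted per-sample means of log2 expression over
a cell-class gene set, compared by Pearson correlation. The unweighted
mean is the simplest defensible aggregate; no claim is made that it is
optimal.

## Synthetic data: what it emulates, and what it does not

Clone masses follow a Zipf law with exponent 1.05 by default, plus
explicit expanded clones sharing a configurable total mass. The
closed-form clonality of the zipf(1.05) mass vector over 10⁴ clones is
≈0.33, and its top-50 clones carry ≈60% of the repertoire at the default
settings — inside the 5–70% range such tissue repertoires show. A
genuinely near-diverse repertoire (clonality < 0.05) requires a much
flatter law; the lognormal option (e.g. μ = 0, σ = 0.5, closed-form
clonality ≈0.013) serves that regime. Public clones are planted by
sequence identity with a shared pool; brain enrichment multiplies chosen
clone masses before renormalization; longitudinal fold changes apply at
the second timepoint; each sample is a single multinomial draw of
`depth` templates (default 10⁵, typical of bulk genomic-DNA
immunosequencing). A single seed drives clone construction, with
per-sample substreams at fixed offsets, so identical parameters give
byte-identical AIRR files.

The generator does **not** emulate: V(D)J generation probabilities or
convergent recombination (public clones arise only by planted identity),
sequencing error or PCR bias, nucleotide-level clonotype structure, or
inter-subject repertoire correlation. Passing recovery tests therefore
shows the estimators and tests behave correctly under the assumed
sampling model (multinomial sampling of a fixed clone-mass vector), not
that real repertoires satisfy that model.

Power and calibration checks run at stated sizes: planted fold-5
expansions on 14 clones spanning ranks 10–1500 at depth 10⁵ (detection
power ≥ 85%; clones planted far into the Zipf tail would have expected
counts below 1 and no power at any method); a uniform 100-clone
multinomial null at depth 10⁴, 1,000 replicates, for type-I calibration
(expected counts ≈100 keep the χ² approximation accurate; heavy-tailed
nulls would make the asymptotic test conservative-to-invalid for rare
clones, which is a property of the test, not the implementation);
three-cluster expression designs at 3-SD separation for ARI ≥ 0.9. The
expression defaults (53 samples, 151 marker genes among 551, three
infiltration tiers) mirror an immune-panel screening cohort.

## Pipeline

`run_study` executes curate → clonality → top-N → annotate → track →
signature from a YAML config, aborts naming the failing stage and
sample, and writes TSV reports plus a `summary.json` built from the same
frames (single source of truth). Direction arrows are written as ASCII
tokens (`up`/`down`/`nc`/`nd`). Input-file and reference-database SHA-256
checksums, package version and parameters go to `run.log`; re-running an
identical config is byte-identical.

## Known limitations

- The exact signed-rank p sums both tails of the (possibly tied) exact
  distribution; some software instead doubles one tail, which can differ
  slightly under heavy ties.
- χ² proportion tests on clonotypes with very small expected counts are
  asymptotically justified only; a Fisher-exact alternative is not
  provided because the large sequencing depths of the intended use make
  the pooled-count regime adequate for all but singleton clones.
- Public/private calls depend entirely on the provided reference
  snapshot; no attempt is made to model database incompleteness.
- `pca_cluster` assumes more samples than clusters and at least two
  samples per cluster downstream (marker selection enforces the latter).
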