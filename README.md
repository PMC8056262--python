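# clonofocus

Clonal focusing analysis of T-cell-receptor β-chain repertoires, built for
studies that compare TCR repertoires between a tissue compartment (for
example resected brain tissue) and blood, within patients and over time,
and relate the dominant clonotypes to known antigen-specific sequences.

## What it computes

**Curation and aggregation.** TCRβ rearrangements are read from AIRR
Community Rearrangement TSVs or Adaptive immunoSEQ exports, curated (CDR3
junctions must start with the IMGT position-104 framework cysteine; stop
codons, out-of-frame markers, empty junctions and non-productive
rearrangements are removed and tallied), and aggregated into per-sample
clonotype tables keyed by CDR3 amino-acid sequence, with template-weighted
frequencies P_i.

**Clonality index.** For a sample with N unique clonotypes,

    H = −Σ P_i log₂ P_i,   H_max = log₂ N,   clonality = 1 − H / H_max

ranging from 0 (maximal diversity) to 1 (monoclonal); the normalization
makes samples of different sequencing depth comparable. Paired
compartment comparisons use the Wilcoxon signed-rank test with an exact
small-sample null (full sign-assignment distribution for n ≤ 25).

**Clonotype tracking.** Frequency changes of a clonotype between two
samples are tested with a Pearson χ² comparison of proportions on the
2×2 table (clonotype vs. rest × sample), 1 df, no continuity correction,
and classified up / down / no-change at α = 0.05 (no multiple-testing
correction by default, Benjamini–Hochberg optional). Top-N extraction
and 2–4-way Venn region counts support the overlap analyses.

**Public/private and viral matching.** Clonotypes are classified public
or private against a local snapshot of a cross-subject sequence database,
and aligned to virus-specific CDR3s (a VDJdb-style local table) by
unit-cost Levenshtein distance with a canonical traceback that yields a
unique annotated edit script (substitutions, insertions, deletions —
rendered lowercase / bracketed / hyphen).

**Immune-gene signature.** A normalized genes × samples expression matrix
is log2-transformed, samples are clustered by Ward agglomeration on their
PCA coordinates, cluster-defining marker genes are selected by one-vs-rest
Welch tests, median-based modified z-scores (0.6745·(x − median)/MAD) are
produced for heat maps, and per-sample cell-type signature scores are
correlated (for example T-cell vs. microglia genes).

**Synthetic data.** Every stage is testable offline: a generator produces
AIRR repertoires with skewed clone sizes, planted expansions, public
spikes, brain enrichment and longitudinal fold changes, matching
reference databases, and cell-type-mixture expression matrices — all with
ground-truth labels.

## Worked example

```python
from clonofocus import (SimParams, simulate_subject, clonality_index,
                        paired_signed_rank, top_n, edit_align)

sim = simulate_subject(SimParams(seed=1, depth=100_000))
brain, blood = sim.table("brain"), sim.table("blood")
print(clonality_index(brain).clonality)   # 0.35654...
print(clonality_index(blood).clonality)   # 0.35598...
print(top_n(brain, 50).repertoire_fraction)  # 0.60612

# paired clonality indices of nine subjects (brain, blood)
pairs = [(0.0100, 0.0043), (0.1057, 0.0465), (0.0638, 0.0414),
         (0.3702, 0.0094), (0.4281, 0.2385), (0.0340, 0.04154),
         (0.2173, 0.0575), (0.0811, 0.0442), (0.1084, 0.0183)]
res = paired_signed_rank([b for b, _ in pairs], [p for _, p in pairs])
print(res.p_two_sided, res.method)  # 0.01171875 exact

m = edit_align("CASSLVGGNTEAFF", "CASSLFGGNTEAFF")
print(m.distance, m.annotation)     # 1 CASSLfGGNTEAFF
```

The brain sample is more clonally focused than the blood (its top 50
clonotypes carry ~60% of the sampled repertoire), the exact signed-rank
test on the nine paired clonality indices gives p ≈ 0.012, and the two
CDR3s differ by a single substitution (shown lowercase in the rendered
alignment).

The `clonofocus` command exposes the same stages from a shell
(`curate`, `clonality`, `paired-test`, `topn`, `track`, `annotate`,
`signature`, `simulate`, `run`); `clonofocus run --config study.yaml`
executes the full pipeline and writes report TSVs plus a `summary.json`.

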