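# Methods

## Scoring model

A domain family is represented by its cross-species multiple alignment
*A* (length *L*, alphabet ψ = the 20 one-letter amino-acid codes). The
alignment is first restricted to eukaryote rows: prokaryotic, viral and
unclassified sequences are removed so the scores reflect the
evolutionary regime relevant to human proteins. Taxonomy comes from a
sidecar `sequence_id → group` TSV (canonical) or from `#=GS ... TX`
Stockholm tags; ids known to neither resolve to "other" and are removed
by the filter.

Per column *p* and letter *l*:

```
C(p, l)  = count of l in column p
F′(p, l) = (C(p, l) + c · f_l) / (Σ_l C(p, l) + c)
F″(p, l) = F′(p, l) / f_l
M(p, l)  = ln F″(p, l)
```

`c` is a pseudo-count and `f_l` the background frequency of letter *l*.
The pseudo-count keeps every frequency strictly positive so the log is
finite; dividing by `f_l` measures enrichment over what a random
protein position would show; the natural log turns products of odds
into sums. A substitution is summarized by `wt = M(p, wt)`,
`mut = M(p, mut)` and `Δ = mut − wt`. Δ is antisymmetric under wt↔mut
exchange and identically zero when wt = mut.

Gap characters ('.' and '-', unified to '-') and ambiguity codes
(B, Z, X, U, O) contribute to no count cell; they shrink the column's
effective depth instead. An all-gap column therefore collapses exactly
to the background (`F′ = f_l`, `F″ = 1`, `M = 0`) and is retained so
column indices stay aligned with the alignment. Lowercase (insert-state)
letters are counted as ordinary residues by default; the
`match_columns_only` switch turns them into gaps for users who want
match-state-only counting.

### Parameters

| parameter | default | meaning |
|---|---|---|
| pseudo-count `c` | 1 | dimensionless; negligible against real column depths, dominant only for near-empty columns |
| background `f_l` | packaged Swiss-Prot composition | expected letter frequencies; any 20-letter TSV accepted |
| taxon filter | `eukaryota` | group retained before counting |
| `match_columns_only` | off | count lowercase insert-state residues or not |

The packaged background table is the published UniProtKB/Swiss-Prot
amino-acid composition (percentages summing to 99.92; renormalized to 1
on load — tables off by more than 0.1% are rejected as malformed). Every
numeric expectation in the test suite is computed against whichever
table is loaded, never hard-coded, so swapping the background does not
silently invalidate the tests.

## Variant mapping

Variants are protein-level substitutions, either explicit
(protein, position, wt, mut) columns or HGVS p. three-letter notation
(`NP_000129.3:p.Thr2032Ser`). Nonsense, frameshift, indel and extension
notation is rejected — the model only speaks about amino-acid exchanges
and, as a protein-level method, can mislabel substitutions whose real
impact is on the mRNA (e.g. splicing); that is a known limitation, not
a bug. Domain instances are 1-based inclusive envelopes on the protein;
a variant at protein position *i* inside an envelope starting at *s* is
the instance's (*i* − *s* + 1)-th residue, and its alignment column is
found through the protein's own (possibly gapped) alignment row. The
alignment residue must equal the variant's stated wild type; a mismatch
is a hard error naming both letters. A residue covered by several
domain instances is scored in all of them; the instance with the
largest |Δ| becomes the primary annotation (the information-richest
call) and the others are reported alongside.

## Zone model

Labeled training variants (pathogenic-like = clinical classes 4/5,
benign-like = classes 1/2, review level ≥ 2 stars, in-domain missense
only) are clustered in the (wt, Δ) plane with k-means (scikit-learn, 25
restarts, fixed seed, best WSS kept). No standardization is applied by
default — both axes are commensurate natural-log scores — but a switch
exists. Zones are named A–D by descending pathogenic fraction; D ends
up the benign-majority cluster.

The fitted clusters are frozen into an axis-aligned geometry so
assignment is reproducible from the persisted JSON model alone:
boundaries at midpoints between adjacent centroid coordinates per axis
(three vertical, three horizontal lines for k = 4) cut the plane into a
4×4 cell grid; each cell takes the zone of the centroid nearest in
cell-index (Manhattan) distance. Ties between cells, and points landing
exactly on a threshold line, resolve by the preference C > D > B > A:
borderline points withhold evidence (or fall to benign support) rather
than over-call PM1. Evidence: A/B → PM1, D → BP8, C → none.

**Cluster-count selection.** The within-cluster sum of squares (WSS) is
computed over k = 1…8, each k keeping the best of 25 random starts plus
one warm start extending the previous k's centers with the point
farthest from them — this makes the WSS curve non-increasing by
construction. The elbow is the interior argmax of the second difference
of **log** WSS. The log scale is deliberate: raw second differences
peak at whatever split removes the most absolute variance (usually
k = 2), while relative-drop curvature recovers the true cluster count
on well-separated data and is scale-free. A curve that is already flat
at the smallest k (WSS ≈ 0) suggests that smallest k.

## Frequency index

For every observed variant with an allele frequency, the substitution
is projected onto its (domain, column, wt, mut) key and the index keeps
the **maximum** frequency over all contributing records — across all
proteins carrying the domain and all nucleotide events yielding the
same amino-acid exchange, a single max over rows. Frequency ties keep
the lexicographically smallest protein id (then smallest position) as
provenance, so rebuilds are deterministic. The query protein's own
record participates in the max like any other. Records with a missing
frequency contribute nothing; an absent key means "never observed in
any corresponding domain".

Evidence thresholds (fractions; percent only at display time, one
decimal, half away from zero): extrapolated frequency ≥ 0.01 → BS1;
null → PM2-supporting; otherwise none. Frequencies above 0.05 are
flagged as high but still map to BS1, never stand-alone BA1, because an
extrapolated frequency can derive from a different nucleotide context
than the query variant.

## Evaluation conventions

Predictions may be withheld (zone C → "none"); withheld calls are
counted as NA and excluded from all four metric denominators:
SPE = TN/(TN+FP), SEN = TP/(TP+FN), ACC over committed calls, and the
Matthews correlation coefficient. This is the only convention under
which a published confusion table's summary statistics follow from its
printed cells, which the acceptance tests verify arithmetically. Zero
denominators yield null, never 0. Display rounding is 2 decimals for
metrics and 1 decimal for percentages, half away from zero; full
precision is kept in machine-readable output.

## Synthetic data

The fixtures module generates every input class:

- **Alignments**: per-column conservation model (dominant letter with
  target fraction among residues, uniform elsewhere), independent
  per-cell gaps, rows assigned to taxon groups by a mixture (default
  70% eukaryote). Real alignments differ in having phylogenetic
  correlation between rows and structured gaps; these fixtures validate
  the arithmetic, not biological realism.
- **Variant tables**: positions drawn inside annotated envelopes, wt
  guaranteed equal to the underlying residue, allele frequencies
  log-uniform on [1e-6, 0.05] with a 70% null fraction emulating how
  sparsely population databases cover possible substitutions.
- **Score clouds**: four isotropic Gaussian clouds along the diagonal
  of the (wt, Δ) plane — centers (5.0, −9.4), (3.5, −6.2), (2.0, −3.0),
  (0.0, 0.0), spread 0.5 — with planted per-cloud pathogenic fractions
  0.92 / 0.80 / 0.45 / 0.19 mirroring the published per-zone
  composition. Cloud sizes are equal (800 each), a balanced
  recovery-experiment design; adjacent centers sit ~7 within-cloud
  standard deviations apart so membership recovery is essentially
  noiseless and deviations indicate bugs rather than sampling luck.

All generators are pure functions of (spec, seed); a master seed fans
out to per-generator children via a CRC-based derivation.

## Numerical choices and degenerate inputs

- Natural logarithm throughout (not log2/log10).
- F′ rows sum to 1 within 1e-9 (algebraic identity given Σ f_l = 1);
  equality with the brute-force oracle is asserted at 1e-12.
- Empty alignment, ragged rows, unknown characters, empty-after-filter,
  non-positive pseudo-count, frequencies outside [0, 1] and zero metric
  denominators are all named error conditions, not silent fallthroughs.
- k-means on fewer distinct points than k is a fit error; an empty
  cluster triggers one reseeded refit before failing.
- Matrix TSVs embed a content checksum verified on load.

## Problem sizes

The test suite and acceptance script run on desk-scale problems by
design: 50 random 5×8 alignments for formula fidelity, 3,200-point
score clouds for zone fitting, 1,000 ten-row variant tables for the
frequency-max equivalence. The published full-scale analysis (18,101
domain families, tens of millions of substitutions) is out of scope for
the automated suite; `scripts/full_scale_reproduction.py` applies the
identical code path to user-supplied full-size inputs.

## Known limitations

- Protein-level only: no transcript/genomic mapping, no codon
  awareness, no splicing assessment.
- No per-sequence weighting or Dirichlet mixtures; raw counts plus a
  single pseudo-count, by design.
- The published zone thresholds themselves are not asserted anywhere —
  they derive from a training set and alignment release we do not
  redistribute; the model is refit-able and the geometry is persisted,
  but exact published boundaries are not claimed.
- Mutational hotspots are intentionally out of scope; hotspot evidence
  is a separate, weaker signal best handled independently.
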