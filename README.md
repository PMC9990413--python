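# dolphin

Protein-domain conservation scores and ACMG-AMP evidence for human
missense variants.

Clinical variant classification under the ACMG-AMP guidelines struggles
with two criteria in particular: **PM1** ("located in a mutational hot
spot and/or critical functional domain") is hard to assign objectively,
and the frequency criteria **PM2/BS1** are limited by how few possible
substitutions have ever been observed in population databases. Protein
domains — conserved sequence modules shared across proteins and species
— carry information that helps with both. This package, aimed at
bioinformaticians building variant-annotation pipelines, turns
cross-species domain alignments into per-residue substitution scores and
cross-protein extrapolated frequencies, and maps both onto ACMG-style
evidence labels (PM1, a proposed BP8, PM2-supporting, BS1).

## The model

For a domain alignment *A* of length *L* over the 20-letter amino-acid
alphabet ψ, restricted to eukaryote sequences, four matrices are built:

- count matrix: `C(p, l)` = occurrences of letter *l* in column *p*;
- corrected frequency, with pseudo-count *c* (default 1) and background
  frequency `f_l`:
  `F′(p, l) = (C(p, l) + c · f_l) / (Σ_{l∈ψ} C(p, l) + c)`;
- corrected relative frequency: `F″(p, l) = F′(p, l) / f_l`;
- position-score matrix: `M(p, l) = ln F″(p, l)`.

A substitution wt→mut at column *p* gets a wild-type score `M(p, wt)`
(high values mark key conserved residues) and
`Δ = M(p, mut) − M(p, wt)` (strongly negative values mark substitutions
the domain's evolutionary record disfavors).

Labeled clinical variants form four clusters in the (wt, Δ) plane,
recovered by seeded k-means (the WSS elbow confirms k = 4) and frozen
into axis-aligned **zones A–D**, named by descending pathogenic
fraction: A and B ⇒ PM1; D ⇒ BP8 ("in a functional domain without
affecting a key residue"); C is the pathogenic/benign overlap and yields
no label.

Separately, a **frequency index** maps (domain, column, wt, mut) to the
maximal allele frequency of that substitution across *all* proteins
carrying the domain: ≥ 1% ⇒ BS1 (deliberately never stand-alone BA1,
since the extrapolated value can come from a different nucleotide
context), never observed anywhere ⇒ PM2-supporting.

## Worked example

```sh
python examples/02_extrapolated_frequency.py
```

```
NP_000129.3:p.Thr2032Ser maps to PF07645 column 135
extrapolated allele frequency: 2.41e-05 (from NP_001989.2:784)
frequency evidence: none  (below 1%, so neither BS1 nor PM2: the substitution HAS been seen)
own-record evidence would be: PM2_supporting (null frequency -> supporting absence)
```

Fibrillin-1 Thr2032 and fibulin-2 Thr784 occupy the same column (135)
of the calcium-binding EGF-like domain they share. The fibrillin-1
Thr2032Ser substitution has never been observed directly, but the same
change at the same domain position was seen in fibulin-2 at allele
frequency 2.41 × 10⁻⁵ — which becomes the extrapolated frequency of the
fibrillin-1 variant, with the fibulin-2 record as provenance.

The other examples (`examples/01...05`) cover matrix building and
scoring, zone fitting with the WSS elbow, confusion-matrix evaluation
with withheld predictions, and the end-to-end annotation pipeline. A
thin CLI wraps the same library calls:

```sh
dolphin make-fixtures --out fx --seed 3
dolphin annotate --alignments fx --taxonomy fx/taxonomy.tsv \
    --variants fx/variants.tsv --annotations fx/annotations.tsv --out out
```

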