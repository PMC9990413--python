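"""End-to-end annotation on generated inputs.

Generates a domain alignment, annotations and a variant table, builds
matrices and the frequency index, and annotates every variant with its
scores and frequency evidence. Each input row yields exactly one output
row; unmappable rows are flagged in the status column, never dropped.
"""

from dolphin.background import swissprot_background
from dolphin.fixtures import (
    AfModel,
    AlignmentSpec,
    annotations_for_alignment,
    generate_alignment,
    generate_variant_table,
)
from dolphin.frequency import build_frequency_index
from dolphin.pipeline import annotate_variants
from dolphin.scoring import build_matrix

aln, tax = generate_alignment(AlignmentSpec(seed=21, n_sequences=60, length=20))
annotations = annotations_for_alignment(aln)
variants = generate_variant_table(aln, annotations, AfModel(), seed=22, n_variants=40)

bg = swissprot_background()
matrices = {aln.domain_id: build_matrix(aln, bg)}
index = build_frequency_index(variants, annotations, {aln.domain_id: aln})

out = annotate_variants(
    variants, annotations, {aln.domain_id: aln}, matrices, freq_index=index
)
print(out[["protein_id", "position", "wt", "mut", "status", "column",
           "wt_score", "delta", "dolphin_af", "freq_evidence"]].head(8).to_string())
print(f"\n{len(out)} rows out for {len(variants)} rows in; status counts:")
print(out["status"].value_counts().to_string())
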