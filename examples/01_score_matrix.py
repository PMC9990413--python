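"""Build a position-score matrix and score a substitution.

A small synthetic domain alignment (80% column conservation) is turned
into the count / corrected-frequency / relative-frequency / score
matrices, then one substitution is scored.
"""

from dolphin.background import swissprot_background
from dolphin.fixtures import AlignmentSpec, generate_alignment
from dolphin.scoring import build_matrix, substitution_scores

bg = swissprot_background()
aln, tax = generate_alignment(
    AlignmentSpec(seed=11, n_sequences=100, length=25, conservation=0.9,
                  dominant="C" * 25, gap_rate=0.05)
)
M = build_matrix(aln, bg)

s = substitution_scores(M, column=10, wt="C", mut="Y")
print(f"domain {s.domain_id}, column {s.column}: {s.wt} -> {s.mut}")
print(f"  wt score  = {s.wt_score:+.2f}   (high: the column conserves {s.wt})")
print(f"  mut score = {s.mut_score:+.2f}   (negative: {s.mut} rarely seen there)")
print(f"  delta     = {s.delta:+.2f}   (strongly negative: disfavored change)")

# A substitution between two unremarkable letters at the same column
t = substitution_scores(M, column=10, wt="A", mut="S")
print(f"for comparison, {t.wt} -> {t.mut} at the same column: delta = {t.delta:+.2f}")
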