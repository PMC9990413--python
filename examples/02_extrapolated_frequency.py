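"""Cross-protein frequency extrapolation.

Fibrillin-1 Thr2032 and fibulin-2 Thr784 both sit on column 135 of the
calcium-binding EGF-like domain they share. The fibrillin-1 Thr2032Ser
substitution was never observed in the population, but the same
substitution at the same domain column was seen in fibulin-2 at allele
frequency 2.41e-5 — so that becomes its extrapolated frequency.
"""

from dolphin.fixtures import egf_frequency_fixture
from dolphin.frequency import (
    build_frequency_index,
    extrapolated_frequency,
    frequency_evidence,
)
from dolphin.variant_mapping import locate_in_domain, parse_hgvs_p

alignments, annotations, variants = egf_frequency_fixture()
index = build_frequency_index(variants, annotations, alignments)

query = parse_hgvs_p("NP_000129.3:p.Thr2032Ser")
(hit,) = locate_in_domain(query, annotations, alignments)
print(f"{query.hgvs_p} maps to {hit.domain_id} column {hit.column}")

af = extrapolated_frequency(index, hit.domain_id, hit.column, hit.wt, hit.mut)
prov = index.provenance(hit.domain_id, hit.column, hit.wt, hit.mut)
print(f"extrapolated allele frequency: {af:.3g} (from {prov.label})")
print(f"frequency evidence: {frequency_evidence(af)}  "
      "(below 1%, so neither BS1 nor PM2: the substitution HAS been seen)")
print(f"own-record evidence would be: {frequency_evidence(None)} "
      "(null frequency -> supporting absence)")
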