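#!/usr/bin/env python
"""Full-scale reproduction of published per-variant wt/Δ scores.

This is NOT a desk-scale check: it needs locally downloaded copies of
the real inputs (no fetching is performed):

* a Pfam-A Stockholm alignment for the domain of interest, e.g. the EGF
  domain PF00008 from Pfam release 33.1 — the release matters, column
  counts shift between releases;
* a taxonomy sidecar TSV (``sequence_id<TAB>group``) or Stockholm
  ``#=GS ... TX`` tags, so the alignment can be restricted to
  eukaryotes;
* the protein/domain coordinates of the variant.

Example: the NOTCH3 p.Cys1061Tyr variant lies in an EGF domain instance
spanning residues 1051-1080; against the Pfam 33.1 eukaryote-filtered
alignment its published scores are wt = 4.3 and Δ = -10.8 (tolerance
±0.2: background-table and alignment-release drift both move the third
significant digit).

Usage:
    python scripts/full_scale_reproduction.py \
        --alignment PF00008.sto --taxonomy tax.tsv \
        --row-id NOTC3_HUMAN/1051-1080 --residue-index 11 --wt C --mut Y
"""

import argparse
import json
import sys

from dolphin.alignment_io import TaxonomyMap, residue_to_column
from dolphin.background import read_background, swissprot_background
from dolphin.scoring import build_domain_matrix, substitution_scores


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--alignment", required=True, help="Pfam Stockholm file")
    ap.add_argument("--taxonomy", help="sequence_id<TAB>group sidecar TSV")
    ap.add_argument("--background", help="background frequency TSV (default: packaged)")
    ap.add_argument("--keep", default="eukaryota")
    ap.add_argument("--pseudo-count", type=float, default=1.0)
    ap.add_argument("--row-id", required=True,
                    help="alignment row carrying the protein's domain instance")
    ap.add_argument("--residue-index", type=int, required=True,
                    help="1-based residue index within the domain instance")
    ap.add_argument("--wt", required=True)
    ap.add_argument("--mut", required=True)
    args = ap.parse_args(argv)

    bg = read_background(args.background) if args.background else swissprot_background()
    tax = TaxonomyMap.from_tsv(args.taxonomy) if args.taxonomy else TaxonomyMap()
    M = build_domain_matrix(
        args.alignment, tax, bg,
        keep=args.keep or None, pseudo_count=args.pseudo_count,
    )

    from dolphin.alignment_io import filter_taxa, read_alignment

    aln = read_alignment(args.alignment, "stockholm")
    if args.keep:
        aln = filter_taxa(aln, tax, keep=args.keep)
    column = residue_to_column(aln, args.row_id, args.residue_index)
    s = substitution_scores(M, column, args.wt.upper(), args.mut.upper())
    json.dump(
        {
            "domain_id": s.domain_id,
            "column": column,
            "wt": s.wt,
            "mut": s.mut,
            "wt_score": round(s.wt_score, 4),
            "mut_score": round(s.mut_score, 4),
            "delta": round(s.delta, 4),
        },
        sys.stdout,
        indent=2,
    )
    print()
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
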