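"""Parsing missense variant records and resolving them to domain columns.

A variant is a protein-level substitution (HGVS p. notation or explicit
protein/position/wt/mut columns). Domain annotations place Pfam-style
domain instances on proteins as 1-based inclusive envelopes; a variant
inside an envelope maps to an alignment column through the protein's own
row of the domain alignment, so gapped rows are handled correctly.

Only simple substitutions are in scope: nonsense, frameshift and indel
notation is rejected, and anything involving a stop ('*') is not a
missense variant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio.SeqUtils import seq1

from .alignment_io import DomainAlignment, residue_to_column
from .alphabet import AMINO_ACIDS
from .errors import (
    HgvsParseError,
    ReferenceMismatchError,
    SchemaError,
    UnsupportedVariantError,
    ValidationError,
)


@dataclass(frozen=True)
class SubstitutionQuery:
    """One protein-level amino-acid substitution."""

    protein_id: str
    position: int  # 1-based residue position in the protein
    wt: str
    mut: str
    hgvs_p: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"protein position must be >= 1: {self.position}")
        for letter, role in ((self.wt, "wt"), (self.mut, "mut")):
            if letter == "*":
                raise UnsupportedVariantError(
                    f"{role} is a stop codon; only missense substitutions are supported"
                )
            if letter not in AMINO_ACIDS:
                raise ValidationError(f"{role} letter {letter!r} not an amino acid")

    @property
    def synonymous(self) -> bool:
        return self.wt == self.mut


@dataclass(frozen=True)
class DomainAnnotation:
    """One domain instance on one protein (envelope in protein coordinates)."""

    protein_id: str
    domain_id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    row_id: str  # alignment row carrying this protein's domain instance

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValidationError(
                f"bad envelope {self.start}..{self.end} for "
                f"{self.protein_id}/{self.domain_id}"
            )

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


_HGVS_RE = re.compile(
    r"^(?P<acc>[^:\s]+):p\.\(?(?P<wt>[A-Z][a-z]{2})(?P<pos>\d+)(?P<rest>.+?)\)?$"
)
_UNSUPPORTED = ("fs", "del", "ins", "dup", "ext", "=")


def parse_hgvs_p(s: str) -> SubstitutionQuery:
    """Parse ``<accession>:p.<Aaa><pos><Bbb>`` three-letter notation.

    Ter/stop, frameshift and del/ins/dup notation raise
    :class:`UnsupportedVariantError`; anything that does not match the
    substitution shape raises :class:`HgvsParseError`. A synonymous
    p.Xaa123Xaa parses fine (callers may warn on ``.synonymous``).
    """
    m = _HGVS_RE.match(s.strip())
    if not m:
        raise HgvsParseError(f"cannot parse HGVS p. string: {s!r}")
    rest = m.group("rest")
    if rest == "Ter" or rest == "*" or any(tok in rest for tok in _UNSUPPORTED):
        raise UnsupportedVariantError(
            f"not a simple missense substitution: {s!r}"
        )
    if not re.fullmatch(r"[A-Z][a-z]{2}", rest):
        raise HgvsParseError(f"unrecognized alternate residue in {s!r}")
    wt3, mut3 = m.group("wt"), rest
    wt, mut = seq1(wt3), seq1(mut3)
    if wt == "X" or mut == "X" or wt == "*" or mut == "*":
        raise UnsupportedVariantError(
            f"unsupported residue code in {s!r} ({wt3}/{mut3})"
        )
    return SubstitutionQuery(
        protein_id=m.group("acc"),
        position=int(m.group("pos")),
        wt=wt,
        mut=mut,
        hgvs_p=s.strip(),
    )


@dataclass(frozen=True)
class DomainHit:
    """A variant resolved into one domain instance."""

    domain_id: str
    column: int  # 1-based alignment column
    wt: str
    mut: str
    annotation: DomainAnnotation


def locate_in_domain(
    q: SubstitutionQuery,
    annotations: Iterable[DomainAnnotation],
    alignments: Mapping[str, DomainAlignment],
    *,
    check_reference: bool = True,
) -> list[DomainHit]:
    """Resolve a substitution to (domain, column) for every covering instance.

    The within-instance residue index is ``position − start + 1``; the
    alignment column comes from the protein's own (possibly gapped) row.
    An empty list means the position lies in no annotated domain. When
    the alignment row carries a residue different from the query's wt,
    a :class:`ReferenceMismatchError` names both letters.
    """
    hits: list[DomainHit] = []
    for ann in annotations:
        if ann.protein_id != q.protein_id or q.position not in ann:
            continue
        aln = alignments[ann.domain_id]
        residue_index = q.position - ann.start + 1
        column = residue_to_column(aln, ann.row_id, residue_index)
        if check_reference:
            observed = aln.row(ann.row_id).residues[column - 1]
            if observed != q.wt:
                raise ReferenceMismatchError(
                    f"{q.protein_id} position {q.position}: variant says wt "
                    f"{q.wt!r} but alignment row {ann.row_id!r} carries "
                    f"{observed!r} at column {column} of {ann.domain_id}"
                )
        hits.append(
            DomainHit(
                domain_id=ann.domain_id,
                column=column,
                wt=q.wt,
                mut=q.mut,
                annotation=ann,
            )
        )
    return hits


# --- tabular I/O -------------------------------------------------------------

VARIANT_COLUMNS = ("protein_id", "position", "wt", "mut")
OPTIONAL_COLUMNS = ("af", "clinical_class", "stars")


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a variant TSV.

    Either explicit ``protein_id, position, wt, mut`` columns or a single
    ``hgvs_p`` column (expanded on load). Optional columns ``af``,
    ``clinical_class`` and ``stars`` pass through.
    """
    df = pd.read_csv(path, sep="\t", dtype={"wt": str, "mut": str})
    if "hgvs_p" in df.columns and not all(c in df.columns for c in VARIANT_COLUMNS):
        parsed = [parse_hgvs_p(s) for s in df["hgvs_p"]]
        df = df.assign(
            protein_id=[q.protein_id for q in parsed],
            position=[q.position for q in parsed],
            wt=[q.wt for q in parsed],
            mut=[q.mut for q in parsed],
        )
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"variant table {path} lacks columns {missing}")
    if "af" in df.columns:
        af = df["af"].dropna()
        if ((af < 0) | (af > 1)).any():
            raise ValidationError(f"allele frequencies outside [0, 1] in {path}")
    return df


def read_annotation_table(path: str | Path) -> list[DomainAnnotation]:
    """Read ``protein_id, domain_id, start, end, row_id`` TSV."""
    df = pd.read_csv(path, sep="\t")
    required = ("protein_id", "domain_id", "start", "end", "row_id")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"annotation table {path} lacks columns {missing}")
    return [
        DomainAnnotation(
            protein_id=str(r.protein_id),
            domain_id=str(r.domain_id),
            start=int(r.start),
            end=int(r.end),
            row_id=str(r.row_id),
        )
        for r in df.itertuples(index=False)
    ]


def queries_from_table(df: pd.DataFrame) -> list[SubstitutionQuery]:
    """Turn validated variant-table rows into queries."""
    return [
        SubstitutionQuery(
            protein_id=str(r.protein_id),
            position=int(r.position),
            wt=str(r.wt),
            mut=str(r.mut),
        )
        for r in df.itertuples(index=False)
    ]
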