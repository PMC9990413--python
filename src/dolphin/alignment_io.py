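"""Reading, validating and taxonomically filtering domain alignments.

A protein domain family (a Pfam-style entry) is represented by a multiple
alignment of the domain instances found across species. Alignments arrive
in Stockholm or aligned-FASTA format; residues are uppercased, '.' and
'-' are both accepted as gaps and normalized to '-'. A sidecar two-column
TSV (``sequence_id<TAB>group``) is the canonical taxonomy source;
``#=GS <id> TX <group>`` lines in a Stockholm file populate the same map
when present.

Coordinates are 1-based and inclusive everywhere in the public interface.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import AlignIO, SeqIO

from .alphabet import GAP, TAXON_GROUPS, VALID_CHARS, is_gap, normalize_char
from .errors import (
    AlignmentShapeError,
    AlignmentValidationError,
    EmptyAfterFilterError,
    EmptyInputError,
    LookupFailedError,
    OutOfRangeError,
    ParameterError,
)

AlignmentFormat = Literal["stockholm", "aligned-fasta"]


@dataclass(frozen=True)
class AlignedSequence:
    """One row of a domain alignment."""

    sequence_id: str
    residues: str  # normalized: uppercase residues, '-' gaps
    taxon_group: str | None = None


@dataclass(frozen=True)
class DomainAlignment:
    """A validated multiple alignment of one protein domain family."""

    domain_id: str
    sequences: tuple[AlignedSequence, ...]
    domain_name: str = ""

    def __post_init__(self) -> None:
        if not self.sequences:
            raise EmptyInputError(f"alignment {self.domain_id!r} has no sequences")
        length = len(self.sequences[0].residues)
        if length < 1:
            raise AlignmentShapeError(f"alignment {self.domain_id!r} has zero columns")
        for seq in self.sequences:
            if len(seq.residues) != length:
                raise AlignmentShapeError(
                    f"sequence {seq.sequence_id!r} has {len(seq.residues)} columns, "
                    f"expected {length}"
                )
            bad = sorted({ch for ch in seq.residues if ch not in VALID_CHARS})
            if bad:
                raise AlignmentValidationError(
                    f"sequence {seq.sequence_id!r} contains unknown characters: {bad}"
                )

    @property
    def length(self) -> int:
        """Number of columns L."""
        return len(self.sequences[0].residues)

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def row(self, sequence_id: str) -> AlignedSequence:
        for seq in self.sequences:
            if seq.sequence_id == sequence_id:
                return seq
        raise LookupFailedError(
            f"sequence {sequence_id!r} not in alignment {self.domain_id!r}"
        )


class TaxonomyMap:
    """Total map from sequence id to taxonomic group.

    Ids absent from the underlying table resolve to ``"other"`` so the
    lookup is total over any alignment.
    """

    def __init__(self, mapping: dict[str, str] | None = None):
        mapping = mapping or {}
        for seq_id, group in mapping.items():
            if group not in TAXON_GROUPS:
                raise ParameterError(
                    f"unknown taxon group {group!r} for {seq_id!r}; "
                    f"expected one of {TAXON_GROUPS}"
                )
        self._mapping = dict(mapping)

    def __getitem__(self, sequence_id: str) -> str:
        return self._mapping.get(sequence_id, "other")

    def __contains__(self, sequence_id: str) -> bool:
        return sequence_id in self._mapping

    def __len__(self) -> int:
        return len(self._mapping)

    def items(self) -> Iterable[tuple[str, str]]:
        return self._mapping.items()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyMap":
        """Read the sidecar ``sequence_id<TAB>group`` table."""
        mapping: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParameterError(f"malformed taxonomy line: {line!r}")
            mapping[parts[0]] = parts[1].strip().lower()
        return cls(mapping)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for seq_id, group in sorted(self._mapping.items()):
                fh.write(f"{seq_id}\t{group}\n")


_GS_TX_RE = re.compile(r"^#=GS\s+(\S+)\s+TX\s+(\S+)\s*$")
_GF_ID_RE = re.compile(r"^#=GF\s+(AC|ID|DE)\s+(.+?)\s*$")


def read_alignment(
    path: str | Path,
    format: AlignmentFormat = "stockholm",
    *,
    domain_id: str | None = None,
    match_columns_only: bool = False,
) -> DomainAlignment:
    """Read and validate a domain alignment.

    Stockholm ``#=GF AC`` (falling back to ``#=GF ID``) supplies the
    domain accession when ``domain_id`` is not given; ``#=GS ... TX``
    lines, when present, attach per-sequence taxon groups. With
    ``match_columns_only`` lowercase (insert-state) residues become gaps
    instead of being uppercased.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise EmptyInputError(f"empty alignment file: {path}")

    name = ""
    tx: dict[str, str] = {}
    if format == "stockholm":
        rows = _parse_stockholm(text, path)
        for line in text.splitlines():
            m = _GS_TX_RE.match(line)
            if m and m.group(2).lower() in TAXON_GROUPS:
                tx[m.group(1)] = m.group(2).lower()
            m = _GF_ID_RE.match(line)
            if m:
                if m.group(1) in ("AC", "ID") and domain_id is None and not name:
                    name = m.group(2)
                if m.group(1) == "DE":
                    pass  # description; kept out of the id
    elif format == "aligned-fasta":
        rows = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
        if not rows:
            raise EmptyInputError(f"no FASTA records in {path}")
    else:
        raise ParameterError(f"unknown alignment format {format!r}")

    sequences = []
    for seq_id, raw in rows:
        normalized = "".join(
            normalize_char(ch, match_columns_only=match_columns_only) for ch in raw
        )
        sequences.append(
            AlignedSequence(seq_id, normalized, taxon_group=tx.get(seq_id))
        )

    did = domain_id or name or path.stem
    return DomainAlignment(domain_id=did, sequences=tuple(sequences))


def _parse_stockholm(text: str, path: Path) -> list[tuple[str, str]]:
    """Stockholm body via Bio.AlignIO, with shape errors re-raised by name."""
    from io import StringIO

    try:
        msa = AlignIO.read(StringIO(text), "stockholm")
    except ValueError as exc:
        # Biopython rejects ragged rows with a generic ValueError; find the
        # offender ourselves so the error names it.
        lengths: dict[str, int] = {}
        for line in text.splitlines():
            if not line.strip() or line.startswith("#") or line.strip() == "//":
                continue
            parts = line.split()
            if len(parts) == 2:
                lengths[parts[0]] = lengths.get(parts[0], 0) + len(parts[1])
        if lengths and len(set(lengths.values())) > 1:
            longest = max(lengths.values())
            bad = sorted(k for k, v in lengths.items() if v != longest)
            raise AlignmentShapeError(
                f"ragged alignment in {path}: sequence(s) {bad} differ in length"
            ) from exc
        raise AlignmentShapeError(f"cannot parse {path} as Stockholm: {exc}") from exc
    return [(rec.id, str(rec.seq)) for rec in msa]


def write_fasta(aln: DomainAlignment, path: str | Path) -> None:
    """Write the alignment as aligned FASTA (canonical gap '-')."""
    with open(path, "w") as fh:
        for seq in aln.sequences:
            fh.write(f">{seq.sequence_id}\n{seq.residues}\n")


def write_stockholm(aln: DomainAlignment, path: str | Path) -> None:
    """Write a single-block Stockholm file with TX taxon annotations."""
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        fh.write(f"#=GF AC {aln.domain_id}\n")
        for seq in aln.sequences:
            if seq.taxon_group:
                fh.write(f"#=GS {seq.sequence_id} TX {seq.taxon_group}\n")
        for seq in aln.sequences:
            fh.write(f"{seq.sequence_id} {seq.residues}\n")
        fh.write("//\n")


def filter_taxa(
    aln: DomainAlignment, tax: TaxonomyMap, keep: str = "eukaryota"
) -> DomainAlignment:
    """Keep only rows of one taxonomic group.

    The sidecar map wins over any taxon tag carried on the row itself;
    rows known to neither resolve to "other". Column count, row order
    and residue content of the survivors are untouched.
    """
    if keep not in TAXON_GROUPS:
        raise ParameterError(f"unknown taxon group {keep!r}")
    survivors = []
    for seq in aln.sequences:
        if seq.sequence_id in tax:
            group = tax[seq.sequence_id]
        else:
            group = seq.taxon_group or "other"
        if group == keep:
            survivors.append(seq)
    if not survivors:
        raise EmptyAfterFilterError(
            f"no {keep!r} sequences remain in alignment {aln.domain_id!r}"
        )
    return DomainAlignment(
        domain_id=aln.domain_id,
        sequences=tuple(survivors),
        domain_name=aln.domain_name,
    )


def residue_to_column(aln: DomainAlignment, sequence_id: str, residue_index: int) -> int:
    """Column (1-based) holding a row's residue_index-th non-gap character."""
    row = aln.row(sequence_id)
    if residue_index < 1:
        raise OutOfRangeError(f"residue_index must be >= 1, got {residue_index}")
    seen = 0
    for col, ch in enumerate(row.residues, start=1):
        if not is_gap(ch):
            seen += 1
            if seen == residue_index:
                return col
    raise OutOfRangeError(
        f"residue_index {residue_index} exceeds the {seen} residues of "
        f"{sequence_id!r}"
    )


def column_to_residue(aln: DomainAlignment, sequence_id: str, column: int) -> int:
    """Inverse of residue_to_column on non-gap columns (1-based)."""
    row = aln.row(sequence_id)
    if not 1 <= column <= aln.length:
        raise OutOfRangeError(f"column {column} outside 1..{aln.length}")
    ch = row.residues[column - 1]
    if is_gap(ch):
        raise OutOfRangeError(
            f"column {column} of {sequence_id!r} is a gap; no residue index"
        )
    return sum(1 for c in row.residues[:column] if not is_gap(c))
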