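"""Extrapolated substitution frequencies over homologous domains.

Population databases report the frequency of a variant in one protein;
because a domain recurs across many proteins, the same amino-acid
substitution at the same domain column may have been observed elsewhere
at a much higher frequency. The frequency index maps
``(domain_id, column, wt, mut)`` to the maximal allele frequency among
all contributing proteins, remembering which record supplied it. An
absent key means the substitution was never observed in any protein
carrying the domain.

Evidence rules (fractions, not percent):

* extrapolated frequency ≥ 0.01 → BS1 (deliberately BS1 even above 0.05,
  because the extrapolated value can come from a different nucleotide
  context than the query variant, so it never reaches stand-alone BA1
  strength);
* no observation at all (null) → PM2_supporting;
* anything in between → no frequency evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .alignment_io import DomainAlignment
from .errors import LookupFailedError, ValidationError
from .variant_mapping import (
    DomainAnnotation,
    SubstitutionQuery,
    locate_in_domain,
)

BS1_THRESHOLD = 0.01
HIGH_FREQ_THRESHOLD = 0.05  # reported, but still BS1 (never BA1)

Key = tuple[str, int, str, str]  # (domain_id, column, wt, mut)


@dataclass(frozen=True)
class FrequencyRecord:
    """Provenance of the maximizing observation for one key."""

    af: float
    protein_id: str
    position: int

    @property
    def label(self) -> str:
        return f"{self.protein_id}:{self.position}"


class FrequencyIndex:
    """(domain, column, wt, mut) → maximal observed allele frequency."""

    def __init__(self) -> None:
        self._entries: dict[Key, FrequencyRecord] = {}

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, key: Key) -> bool:
        return key in self._entries

    def add(self, key: Key, af: float, protein_id: str, position: int) -> None:
        """Fold one observation into the running maximum.

        Ties on af keep the lexicographically smallest protein_id (then
        smallest position) so provenance is deterministic.
        """
        if not 0.0 <= af <= 1.0:
            raise ValidationError(f"allele frequency {af} outside [0, 1]")
        new = FrequencyRecord(af=af, protein_id=protein_id, position=position)
        cur = self._entries.get(key)
        if (
            cur is None
            or new.af > cur.af
            or (new.af == cur.af and (new.protein_id, new.position)
                < (cur.protein_id, cur.position))
        ):
            self._entries[key] = new

    def lookup(self, domain_id: str, column: int, wt: str, mut: str) -> float | None:
        """Stored maximum, or None for "never observed in any homolog"."""
        rec = self._entries.get((domain_id, column, wt, mut))
        return None if rec is None else rec.af

    def provenance(
        self, domain_id: str, column: int, wt: str, mut: str
    ) -> FrequencyRecord | None:
        return self._entries.get((domain_id, column, wt, mut))

    # --- persistence ---------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "domain_id": k[0],
                "column": k[1],
                "wt": k[2],
                "mut": k[3],
                "af": rec.af,
                "provenance": rec.label,
            }
            for k, rec in sorted(self._entries.items())
        ]
        pd.DataFrame(
            rows, columns=["domain_id", "column", "wt", "mut", "af", "provenance"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencyIndex":
        idx = cls()
        df = pd.read_csv(path, sep="\t", dtype={"wt": str, "mut": str})
        for r in df.itertuples(index=False):
            protein_id, _, pos = str(r.provenance).rpartition(":")
            idx.add(
                (str(r.domain_id), int(r.column), r.wt, r.mut),
                float(r.af),
                protein_id,
                int(pos),
            )
        return idx


def build_frequency_index(
    variants: pd.DataFrame,
    annotations: Iterable[DomainAnnotation],
    alignments: Mapping[str, DomainAlignment],
) -> FrequencyIndex:
    """Aggregate a variant table (with ``af``) into a frequency index.

    Rows with a missing af contribute nothing; every domain instance a
    variant falls into receives the observation.
    """
    ann_list = list(annotations)
    idx = FrequencyIndex()
    if "af" not in variants.columns:
        return idx
    for r in variants.itertuples(index=False):
        af = getattr(r, "af", None)
        if af is None or (isinstance(af, float) and math.isnan(af)):
            continue
        q = SubstitutionQuery(
            protein_id=str(r.protein_id),
            position=int(r.position),
            wt=str(r.wt),
            mut=str(r.mut),
        )
        try:
            hits = locate_in_domain(q, ann_list, alignments)
        except LookupFailedError:
            # annotation points at a row not retained (e.g. taxon-filtered out)
            continue
        for hit in hits:
            idx.add(
                (hit.domain_id, hit.column, hit.wt, hit.mut),
                float(af),
                q.protein_id,
                q.position,
            )
    return idx


def extrapolated_frequency(
    idx: FrequencyIndex, domain_id: str, column: int, wt: str, mut: str
) -> float | None:
    """Maximal allele frequency of the substitution across homologous domains."""
    return idx.lookup(domain_id, column, wt, mut)


def frequency_evidence(af: float | None) -> str:
    """Map an extrapolated frequency to {BS1, PM2_supporting, none}."""
    if af is None:
        return "PM2_supporting"
    if not 0.0 <= af <= 1.0:
        raise ValidationError(f"allele frequency {af} outside [0, 1]")
    if af >= BS1_THRESHOLD:
        return "BS1"
    return "none"
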