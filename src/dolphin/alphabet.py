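"""The amino-acid alphabet and character classes used throughout.

The scoring alphabet psi is the 20 standard one-letter codes. Ambiguity
codes (B, Z, X and the rare translated letters U, O) are accepted in
alignments but excluded from counting: a column position occupied by one
of them simply contributes to no count cell, reducing that column's
effective depth. '.' and '-' are both gap characters; '-' is the
canonical symbol after normalization.
"""

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

AMBIGUITY_CODES: frozenset[str] = frozenset("BZXUO")
GAP_CHARS: frozenset[str] = frozenset(".-")
GAP: str = "-"

VALID_CHARS: frozenset[str] = frozenset(AMINO_ACIDS) | AMBIGUITY_CODES | GAP_CHARS

TAXON_GROUPS: tuple[str, ...] = ("eukaryota", "archaea", "bacteria", "viruses", "other")


def is_gap(ch: str) -> bool:
    return ch in GAP_CHARS


def normalize_char(ch: str, *, match_columns_only: bool = False) -> str:
    """Normalize one alignment character.

    Lowercase letters mark insert states in Pfam alignments; by default
    they are residues like any other and are uppercased. With
    ``match_columns_only`` they are converted to gaps instead, so only
    match-state residues enter downstream counts.
    """
    if ch in GAP_CHARS:
        return GAP
    if ch.islower():
        return GAP if match_columns_only else ch.upper()
    return ch
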