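"""Position-score matrices and wt/mut/Δ substitution scores.

For a domain alignment A of length L over the 20-letter alphabet psi,
four matrices are built in sequence:

* count matrix            C(p, l)  = occurrences of letter l in column p
* corrected frequency     F'(p, l) = (C(p, l) + c · f_l) / (Σ_l C(p, l) + c)
* corrected relative freq F''(p, l) = F'(p, l) / f_l
* position score          M(p, l)  = ln F''(p, l)

with c a pseudo-count (default 1) and f_l the background expectation of
letter l. The pseudo-count keeps every frequency strictly positive, so M
is finite everywhere; dividing by f_l re-contextualizes an observed
frequency against what a random protein position would show, and the
natural log turns the multiplicative model into an additive one.

A substitution wt→mut at column p is summarized by the wild-type score
M(p, wt) (high values flag key conserved residues), the mutant score
M(p, mut), and Δ = M(p, mut) − M(p, wt) (strongly negative Δ flags
changes the domain's evolutionary record disfavors).

Gaps and ambiguity codes contribute to no count cell; an all-gap column
collapses to the background (F' = f_l, F'' = 1, M = 0) and is retained so
column indices stay aligned with the source alignment.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment_io import DomainAlignment, TaxonomyMap, filter_taxa, read_alignment
from .alphabet import AA_INDEX, AMINO_ACIDS
from .background import BackgroundFrequencies
from .errors import (
    BackgroundError,
    OutOfRangeError,
    ParameterError,
    UnsupportedResidueError,
)

DEFAULT_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class CountMatrix:
    """Letter occurrence counts per alignment column (L x 20)."""

    counts: np.ndarray  # int array, shape (L, 20), AMINO_ACIDS column order
    n_rows: int
    domain_id: str = ""

    def __post_init__(self) -> None:
        if self.counts.ndim != 2 or self.counts.shape[1] != len(AMINO_ACIDS):
            raise ParameterError(
                f"count matrix must be L x 20, got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ParameterError("negative counts")
        if np.any(self.counts.sum(axis=1) > self.n_rows):
            raise ParameterError("column counts exceed the number of rows")

    @property
    def length(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class PositionScoreMatrix:
    """Per-column per-letter log scores M(p, l) with their intermediates."""

    scores: np.ndarray  # float, shape (L, 20), natural-log units
    pseudo_count: float
    background_source: str
    domain_id: str = ""
    corrected_freq: np.ndarray | None = field(default=None, compare=False)   # F'
    relative_freq: np.ndarray | None = field(default=None, compare=False)    # F''
    metadata: dict = field(default_factory=dict, compare=False)

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def score(self, column: int, letter: str) -> float:
        """M at a 1-based column for one letter."""
        if not 1 <= column <= self.length:
            raise OutOfRangeError(f"column {column} outside 1..{self.length}")
        try:
            return float(self.scores[column - 1, AA_INDEX[letter]])
        except KeyError:
            raise UnsupportedResidueError(
                f"letter {letter!r} is not one of the 20 amino acids"
            ) from None


@dataclass(frozen=True)
class DolphinScores:
    """The (wt, mut, Δ) score triple for one substitution at one column."""

    domain_id: str
    column: int
    wt: str
    mut: str
    wt_score: float
    mut_score: float

    @property
    def delta(self) -> float:
        return self.mut_score - self.wt_score


def count_matrix(aln: DomainAlignment) -> CountMatrix:
    """Tally letter occurrences per column; gaps/ambiguity codes count nowhere."""
    counts = np.zeros((aln.length, len(AMINO_ACIDS)), dtype=np.int64)
    for seq in aln.sequences:
        for p, ch in enumerate(seq.residues):
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[p, idx] += 1
    return CountMatrix(counts=counts, n_rows=aln.n_sequences, domain_id=aln.domain_id)


def corrected_frequency(
    C: CountMatrix,
    bg: BackgroundFrequencies,
    pseudo_count: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """F'(p, l) = (C(p, l) + c·f_l) / (Σ_l C(p, l) + c); rows sum to 1."""
    if pseudo_count <= 0:
        raise ParameterError(f"pseudo-count must be > 0, got {pseudo_count}")
    f = bg.as_vector()
    totals = C.counts.sum(axis=1, keepdims=True).astype(float)
    return (C.counts + pseudo_count * f) / (totals + pseudo_count)


def relative_frequency(
    F_prime: np.ndarray,
    bg: BackgroundFrequencies,
    *,
    built_with: str | None = None,
) -> np.ndarray:
    """F''(p, l) = F'(p, l) / f_l; 1 exactly at the background expectation.

    ``built_with`` (the source label of the background F' was computed
    against) guards against mixing two different background tables.
    """
    if built_with is not None and built_with != bg.source:
        raise BackgroundError(
            f"F' was built against background {built_with!r} but "
            f"{bg.source!r} was supplied"
        )
    if np.any(F_prime <= 0):
        raise ParameterError("corrected frequencies must be strictly positive")
    return F_prime / bg.as_vector()


def score_matrix(
    F_second: np.ndarray,
    *,
    pseudo_count: float = DEFAULT_PSEUDOCOUNT,
    background_source: str = "unspecified",
    domain_id: str = "",
    corrected_freq: np.ndarray | None = None,
    metadata: dict | None = None,
) -> PositionScoreMatrix:
    """M(p, l) = ln F''(p, l)."""
    if np.any(F_second <= 0):
        raise ParameterError("relative frequencies must be strictly positive")
    return PositionScoreMatrix(
        scores=np.log(F_second),
        pseudo_count=pseudo_count,
        background_source=background_source,
        domain_id=domain_id,
        corrected_freq=corrected_freq,
        relative_freq=F_second,
        metadata=metadata or {},
    )


def substitution_scores(
    M: PositionScoreMatrix, column: int, wt: str, mut: str
) -> DolphinScores:
    """wt/mut scores at a column and Δ = M(p, mut) − M(p, wt).

    Δ is antisymmetric under wt↔mut exchange and zero for wt == mut.
    """
    return DolphinScores(
        domain_id=M.domain_id,
        column=column,
        wt=wt,
        mut=mut,
        wt_score=M.score(column, wt),
        mut_score=M.score(column, mut),
    )


def build_matrix(
    aln: DomainAlignment,
    bg: BackgroundFrequencies,
    pseudo_count: float = DEFAULT_PSEUDOCOUNT,
    *,
    metadata: dict | None = None,
) -> PositionScoreMatrix:
    """Compose the four matrix-building steps on an alignment in memory."""
    C = count_matrix(aln)
    Fp = corrected_frequency(C, bg, pseudo_count)
    Fs = relative_frequency(Fp, bg)
    meta = {"n_rows": aln.n_sequences, "L": aln.length}
    meta.update(metadata or {})
    return score_matrix(
        Fs,
        pseudo_count=pseudo_count,
        background_source=bg.source,
        domain_id=aln.domain_id,
        corrected_freq=Fp,
        metadata=meta,
    )


def build_domain_matrix(
    path: str | Path,
    tax: TaxonomyMap | None,
    bg: BackgroundFrequencies,
    *,
    format: str = "stockholm",
    keep: str | None = "eukaryota",
    pseudo_count: float = DEFAULT_PSEUDOCOUNT,
    match_columns_only: bool = False,
) -> PositionScoreMatrix:
    """File-to-matrix pipeline: read, taxon-filter, build, with metadata."""
    aln = read_alignment(path, format=format, match_columns_only=match_columns_only)  # type: ignore[arg-type]
    n_before = aln.n_sequences
    if keep is not None:
        aln = filter_taxa(aln, tax or TaxonomyMap(), keep=keep)
    return build_matrix(
        aln,
        bg,
        pseudo_count,
        metadata={
            "source": str(path),
            "n_rows_before_filter": n_before,
            "keep": keep or "all",
        },
    )


# --- persistence: self-describing TSV ---------------------------------------

def save_matrix(M: PositionScoreMatrix, path: str | Path) -> None:
    """Write the score matrix as TSV with a '#' metadata header block."""
    lines = [
        f"# domain_id\t{M.domain_id}",
        f"# L\t{M.length}",
        f"# pseudo_count\t{M.pseudo_count!r}",
        f"# background\t{M.background_source}",
    ]
    for key, val in sorted(M.metadata.items()):
        lines.append(f"# meta:{key}\t{val}")
    body = "\n".join(
        "\t".join(format(v, ".17g") for v in row) for row in M.scores
    )
    checksum = hashlib.sha256(body.encode()).hexdigest()[:16]
    lines.append(f"# checksum\t{checksum}")
    lines.append("column\t" + "\t".join(AMINO_ACIDS))
    for p, row in enumerate(M.scores, start=1):
        lines.append(f"{p}\t" + "\t".join(format(v, ".17g") for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def load_matrix(path: str | Path) -> PositionScoreMatrix:
    """Read a matrix written by :func:`save_matrix`; verifies the checksum."""
    meta: dict[str, str] = {}
    extra: dict[str, str] = {}
    rows: list[list[float]] = []
    header_letters: list[str] | None = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("\t")
            if key.startswith("meta:"):
                extra[key[5:]] = val
            else:
                meta[key] = val
            continue
        parts = line.split("\t")
        if header_letters is None:
            header_letters = parts[1:]
            if "".join(header_letters) != AMINO_ACIDS:
                raise BackgroundError(
                    f"unexpected letter order in matrix file {path}"
                )
            continue
        rows.append([float(v) for v in parts[1:]])
    scores = np.array(rows, dtype=float)
    body = "\n".join(
        "\t".join(format(v, ".17g") for v in row) for row in scores
    )
    if "checksum" in meta:
        if hashlib.sha256(body.encode()).hexdigest()[:16] != meta["checksum"]:
            raise ParameterError(f"checksum mismatch reading {path}")
    return PositionScoreMatrix(
        scores=scores,
        pseudo_count=float(meta.get("pseudo_count", DEFAULT_PSEUDOCOUNT)),
        background_source=meta.get("background", "unspecified"),
        domain_id=meta.get("domain_id", Path(path).stem),
        metadata=extra,
    )
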