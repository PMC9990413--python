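"""Synthetic inputs with controlled, recoverable structure.

Every other module is testable offline through these generators: domain
alignments with a per-column conservation profile and a taxonomic
mixture, variant tables whose rows are guaranteed consistent with the
underlying sequences (with a log-uniform allele-frequency model and a
stated null fraction emulating sparse population data), and labeled
(wt, Δ) score clouds emulating the four-cluster structure that labeled
clinical variants display in that plane.

All generators are pure functions of (spec, seed): same seed, same
bytes. A single master seed fans out to per-generator child seeds via
``derive_seed`` so fixtures are independent yet jointly reproducible.

What these fixtures do NOT emulate: real alignments have phylogenetic
correlation between rows and position-dependent gap structure; real
population frequencies follow a site-frequency spectrum, not a
log-uniform law; real score clouds are not Gaussian. Passing tests
demonstrate correctness of the computations, not field performance.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment_io import AlignedSequence, DomainAlignment, TaxonomyMap
from .alphabet import AMINO_ACIDS, GAP
from .errors import ParameterError
from .scoring import DolphinScores
from .variant_mapping import DomainAnnotation
from .zones import BENIGN, PATHOGENIC, LabeledScore


def derive_seed(master: int, tag: str) -> int:
    """Deterministic child seed for one generator (below 2**31)."""
    return (int(master) ^ zlib.crc32(tag.encode())) & 0x7FFFFFFF


DEFAULT_TAXON_MIXTURE: dict[str, float] = {
    "eukaryota": 0.70,
    "bacteria": 0.15,
    "archaea": 0.05,
    "viruses": 0.05,
    "other": 0.05,
}


@dataclass(frozen=True)
class AlignmentSpec:
    """Recipe for one synthetic domain alignment.

    ``conservation`` is the target fraction of the column's dominant
    letter among its residues (scalar, or one value per column);
    ``dominant`` letters default to a seed-derived random choice per
    column. ``gap_rate`` applies independently per cell.
    """

    seed: int
    n_sequences: int = 50
    length: int = 30
    conservation: float | Sequence[float] = 0.8
    dominant: Sequence[str] | None = None
    gap_rate: float = 0.05
    taxon_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TAXON_MIXTURE)
    )
    domain_id: str = "PFTEST"

    def conservation_profile(self) -> np.ndarray:
        c = np.broadcast_to(np.asarray(self.conservation, dtype=float), self.length)
        if np.any((c < 0) | (c > 1)):
            raise ParameterError("conservation fractions must lie in [0, 1]")
        return np.asarray(c)


def generate_alignment(spec: AlignmentSpec) -> tuple[DomainAlignment, TaxonomyMap]:
    """Draw an alignment plus its taxonomy sidecar from a spec."""
    if not 0.0 <= spec.gap_rate <= 1.0:
        raise ParameterError(f"gap_rate {spec.gap_rate} outside [0, 1]")
    cons = spec.conservation_profile()
    if spec.gap_rate >= 1.0 and np.any(cons > 0):
        raise ParameterError("gap_rate 1.0 leaves no residues to conserve")
    if spec.n_sequences < 1 or spec.length < 1:
        raise ParameterError("need at least one sequence and one column")

    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(AMINO_ACIDS))
    if spec.dominant is None:
        dominant = rng.choice(letters, size=spec.length)
    else:
        dominant = np.asarray(list(spec.dominant))
        if len(dominant) != spec.length:
            raise ParameterError("dominant letters must match the column count")

    groups = sorted(spec.taxon_mixture)
    probs = np.array([spec.taxon_mixture[g] for g in groups], dtype=float)
    if np.any(probs < 0) or probs.sum() <= 0:
        raise ParameterError("taxon mixture must be non-negative and non-empty")
    probs = probs / probs.sum()
    row_groups = rng.choice(groups, size=spec.n_sequences, p=probs)

    rows: list[AlignedSequence] = []
    mapping: dict[str, str] = {}
    for i in range(spec.n_sequences):
        chars = []
        for p in range(spec.length):
            if rng.random() < spec.gap_rate:
                chars.append(GAP)
            elif rng.random() < cons[p]:
                chars.append(str(dominant[p]))
            else:
                others = letters[letters != dominant[p]]
                chars.append(str(rng.choice(others)))
        seq_id = f"seq{i:04d}"
        rows.append(
            AlignedSequence(seq_id, "".join(chars), taxon_group=str(row_groups[i]))
        )
        mapping[seq_id] = str(row_groups[i])
    aln = DomainAlignment(domain_id=spec.domain_id, sequences=tuple(rows))
    return aln, TaxonomyMap(mapping)


def annotations_for_alignment(
    aln: DomainAlignment, start: int = 1
) -> list[DomainAnnotation]:
    """One annotation per row, treating each row's ungapped residues as a
    protein whose domain instance starts at ``start``."""
    anns = []
    for seq in aln.sequences:
        n_res = sum(1 for ch in seq.residues if ch != GAP)
        if n_res == 0:
            continue
        anns.append(
            DomainAnnotation(
                protein_id=seq.sequence_id,
                domain_id=aln.domain_id,
                start=start,
                end=start + n_res - 1,
                row_id=seq.sequence_id,
            )
        )
    return anns


@dataclass(frozen=True)
class AfModel:
    """Log-uniform allele-frequency law with a null (unobserved) fraction."""

    null_fraction: float = 0.7
    af_min: float = 1e-6
    af_max: float = 5e-2

    def __post_init__(self) -> None:
        if not 0.0 <= self.null_fraction <= 1.0:
            raise ParameterError("null_fraction outside [0, 1]")
        if not 0 < self.af_min <= self.af_max <= 1:
            raise ParameterError("need 0 < af_min <= af_max <= 1")


def generate_variant_table(
    aln: DomainAlignment,
    annotations: Sequence[DomainAnnotation],
    af_model: AfModel,
    seed: int,
    n_variants: int = 100,
    *,
    with_labels: bool = False,
) -> pd.DataFrame:
    """Random substitutions consistent with the alignment's sequences.

    Each variant picks an annotated protein and an in-envelope position;
    wt is the residue actually present, mut a uniform different letter.
    af is missing with probability ``null_fraction``, else drawn
    log-uniformly on [af_min, af_max]. ``with_labels`` adds
    clinical_class (1/2/3/4/5) and stars (0-4) columns for
    evaluation-filter tests.
    """
    rng = np.random.default_rng(seed)
    anns = [a for a in annotations if a.end >= a.start]
    if not anns:
        raise ParameterError("no usable annotations")
    rows = []
    letters = np.array(list(AMINO_ACIDS))
    for _ in range(n_variants):
        ann = anns[int(rng.integers(len(anns)))]
        pos = int(rng.integers(ann.start, ann.end + 1))
        row = aln.row(ann.row_id)
        residue_index = pos - ann.start + 1
        seen = 0
        wt = None
        for ch in row.residues:
            if ch != GAP:
                seen += 1
                if seen == residue_index:
                    wt = ch
                    break
        if wt is None or wt not in AMINO_ACIDS:
            continue  # ambiguity-code residue: skip, like an unscorable site
        mut = str(rng.choice(letters[letters != wt]))
        if rng.random() < af_model.null_fraction:
            af = np.nan
        else:
            lo, hi = np.log10(af_model.af_min), np.log10(af_model.af_max)
            af = float(10 ** rng.uniform(lo, hi))
        rec = {
            "protein_id": ann.protein_id,
            "position": pos,
            "wt": wt,
            "mut": mut,
            "af": af,
        }
        if with_labels:
            rec["clinical_class"] = int(rng.integers(1, 6))
            rec["stars"] = int(rng.integers(0, 5))
        rows.append(rec)
    return pd.DataFrame(rows)


def egf_frequency_fixture() -> tuple[
    dict[str, DomainAlignment], list[DomainAnnotation], pd.DataFrame
]:
    """The cross-protein frequency worked example, desk scale.

    Two proteins carry the same calcium-binding EGF-like domain
    (PF07645): fibrillin-1 (NP_000129.3), whose Thr2032 is the domain's
    135th residue, and fibulin-2 (NP_001989.2), whose Thr784 lands on
    the same column. The fibulin-2 Thr784Ser variant was observed at
    allele frequency 2.41e-5 while the fibrillin-1 Thr2032Ser variant
    itself is unobserved, so the extrapolated frequency of the latter
    is 2.41e-5 with fibulin-2 provenance.

    The alignment rows are synthetic stand-ins (deterministic letters,
    ungapped, threonine at column 135); only the coordinate bookkeeping
    and the two variant records reflect the real proteins.
    """
    length = 140
    rng = np.random.default_rng(20320784)
    letters = np.array(list(AMINO_ACIDS))
    rows = []
    for seq_id in ("NP_000129.3", "NP_001989.2"):
        chars = [str(c) for c in rng.choice(letters, size=length)]
        chars[134] = "T"  # column 135 carries the shared threonine
        rows.append(AlignedSequence(seq_id, "".join(chars), taxon_group="eukaryota"))
    aln = DomainAlignment(domain_id="PF07645", sequences=tuple(rows))
    annotations = [
        # FBN1: residue 2032 is the 135th residue -> envelope starts at 1898
        DomainAnnotation("NP_000129.3", "PF07645", 1898, 1898 + length - 1,
                         "NP_000129.3"),
        # FBLN2: residue 784 is the 135th residue -> envelope starts at 650
        DomainAnnotation("NP_001989.2", "PF07645", 650, 650 + length - 1,
                         "NP_001989.2"),
    ]
    variants = pd.DataFrame(
        [
            {"protein_id": "NP_000129.3", "position": 2032, "wt": "T", "mut": "S",
             "af": np.nan, "hgvs_p": "NP_000129.3:p.Thr2032Ser"},
            {"protein_id": "NP_001989.2", "position": 784, "wt": "T", "mut": "S",
             "af": 2.41e-5, "hgvs_p": "NP_001989.2:p.Thr784Ser"},
        ]
    )
    return {"PF07645": aln}, annotations, variants


@dataclass(frozen=True)
class ScoreCloudSpec:
    """Four Gaussian clouds in the (wt, Δ) plane with planted labels.

    Defaults emulate the labeled-variant structure: cloud A sits at high
    wt / strongly negative Δ (key residues, disfavored changes) and is
    92% pathogenic; D sits near the origin (unremarkable positions) and
    is 81% benign; B and C interpolate at 80% and 45% pathogenic.
    Cloud sizes are equal by design — a balanced recovery experiment —
    and adjacent centers sit ~7 within-cloud standard deviations apart.
    """

    seed: int
    centers: tuple[tuple[float, float], ...] = (
        (5.0, -9.4),
        (3.5, -6.2),
        (2.0, -3.0),
        (0.0, 0.0),
    )
    spreads: tuple[float, ...] = (0.5, 0.5, 0.5, 0.5)
    pathogenic_fractions: tuple[float, ...] = (0.92, 0.80, 0.45, 0.19)
    sizes: tuple[int, ...] = (800, 800, 800, 800)

    def __post_init__(self) -> None:
        n = len(self.centers)
        if not (len(self.spreads) == len(self.pathogenic_fractions) == len(self.sizes) == n):
            raise ParameterError("cloud spec fields must have equal lengths")
        if any(s < 1 for s in self.sizes):
            raise ParameterError("cloud sizes must be >= 1")
        if any(not 0.0 <= f <= 1.0 for f in self.pathogenic_fractions):
            raise ParameterError("pathogenic fractions must lie in [0, 1]")


def generate_score_cloud(
    spec: ScoreCloudSpec,
) -> tuple[list[LabeledScore], np.ndarray]:
    """Draw labeled scores; also returns the planted cluster index per point."""
    rng = np.random.default_rng(spec.seed)
    points: list[LabeledScore] = []
    membership: list[int] = []
    for ci, ((cx, cy), sd, frac, size) in enumerate(
        zip(spec.centers, spec.spreads, spec.pathogenic_fractions, spec.sizes)
    ):
        xs = rng.normal(cx, sd, size)
        ys = rng.normal(cy, sd, size)
        labels = rng.random(size) < frac
        for x, y, is_path in zip(xs, ys, labels):
            scores = DolphinScores(
                domain_id="SYNTH",
                column=1,
                wt="A",
                mut="C",
                wt_score=float(x),
                mut_score=float(x + y),
            )
            points.append(
                LabeledScore(scores, PATHOGENIC if is_path else BENIGN, stars=2)
            )
            membership.append(ci)
    return points, np.array(membership)
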