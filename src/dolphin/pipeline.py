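"""End-to-end annotation: variants in, scores/zones/evidence out.

``run_annotate`` wires the whole workflow: read alignments (taxon
filtered), build position-score matrices, resolve each variant to its
domain column(s), score it, assign a zone and PM1/BP8 evidence when a
zone model is supplied, look up the extrapolated frequency and its
PM2/BS1 evidence, and emit one output row per input row with a status
column — unmappable variants are kept and flagged, never dropped. Every
run writes a manifest (config hash, seed, package version) sufficient
to reproduce the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .alignment_io import DomainAlignment, TaxonomyMap
from .background import BackgroundFrequencies, read_background, swissprot_background
from .errors import LookupFailedError, ParameterError, ReferenceMismatchError
from .frequency import FrequencyIndex, build_frequency_index, frequency_evidence
from .scoring import PositionScoreMatrix, substitution_scores
from .variant_mapping import (
    DomainAnnotation,
    SubstitutionQuery,
    locate_in_domain,
    read_annotation_table,
    read_variant_table,
)
from .zones import ZoneModel, assign_zone, evidence_label

logger = logging.getLogger("dolphin")


@dataclass
class RunConfig:
    """Paths and parameters of one annotation run."""

    alignments_dir: str | None = None
    alignment_format: str = "stockholm"
    taxonomy: str | None = None
    background: str | None = None  # None -> packaged Swiss-Prot table
    variants: str | None = None
    annotations: str | None = None
    model: str | None = None  # zone model JSON; None -> no zone labels
    out_dir: str = "dolphin-out"
    pseudo_count: float = 1.0
    keep_group: str | None = "eukaryota"
    k: int = 4
    seed: int = 0
    restarts: int = 25
    bs1_threshold: float = 0.01
    high_freq_threshold: float = 0.05
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pseudo_count <= 0:
            raise ParameterError("pseudo_count must be > 0")
        for name in ("bs1_threshold", "high_freq_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ParameterError(f"{name} must lie in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        extra = {k: v for k, v in data.items() if k not in cls.__dataclass_fields__}
        known.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**known)
        cfg.extra.update(extra)
        return cfg

    def digest(self) -> str:
        payload = {k: v for k, v in self.__dict__.items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_inputs(cfg: RunConfig) -> tuple[
    dict[str, DomainAlignment],
    dict[str, PositionScoreMatrix],
    list[DomainAnnotation],
    pd.DataFrame,
    BackgroundFrequencies,
]:
    """Materialize alignments, matrices, annotations and variants."""
    bg = read_background(cfg.background) if cfg.background else swissprot_background()
    tax = TaxonomyMap.from_tsv(cfg.taxonomy) if cfg.taxonomy else TaxonomyMap()
    if not cfg.alignments_dir:
        raise ParameterError("alignments_dir is required")
    suffix = {"stockholm": ".sto", "aligned-fasta": ".fasta"}[cfg.alignment_format]
    alignments: dict[str, DomainAlignment] = {}
    matrices: dict[str, PositionScoreMatrix] = {}
    paths = sorted(Path(cfg.alignments_dir).glob(f"*{suffix}"))
    if not paths:
        raise FileNotFoundError(
            f"no {suffix} alignments under {cfg.alignments_dir}"
        )
    from .alignment_io import filter_taxa, read_alignment
    from .scoring import build_matrix

    for path in paths:
        aln = read_alignment(path, format=cfg.alignment_format)  # type: ignore[arg-type]
        n_before = aln.n_sequences
        if cfg.keep_group:
            aln = filter_taxa(aln, tax, keep=cfg.keep_group)
        alignments[aln.domain_id] = aln
        matrices[aln.domain_id] = build_matrix(
            aln,
            bg,
            cfg.pseudo_count,
            metadata={
                "source": str(path),
                "n_rows_before_filter": n_before,
                "keep": cfg.keep_group or "all",
            },
        )
    if not cfg.annotations or not cfg.variants:
        raise ParameterError("annotations and variants paths are required")
    annotations = read_annotation_table(cfg.annotations)
    variants = read_variant_table(cfg.variants)
    return alignments, matrices, annotations, variants, bg


def annotate_variants(
    variants: pd.DataFrame,
    annotations: list[DomainAnnotation],
    alignments: dict[str, DomainAlignment],
    matrices: dict[str, PositionScoreMatrix],
    *,
    model: ZoneModel | None = None,
    freq_index: FrequencyIndex | None = None,
) -> pd.DataFrame:
    """One output row per input variant (status column, never dropped).

    A variant covered by several domain instances is scored in all of
    them; the instance with the largest |Δ| becomes the primary
    annotation and the rest are reported in ``other_hits``.
    """
    out_rows = []
    for r in variants.itertuples(index=False):
        rec: dict = {
            "protein_id": r.protein_id,
            "position": int(r.position),
            "wt": r.wt,
            "mut": r.mut,
        }
        try:
            q = SubstitutionQuery(
                protein_id=str(r.protein_id),
                position=int(r.position),
                wt=str(r.wt),
                mut=str(r.mut),
            )
            hits = locate_in_domain(q, annotations, alignments)
        except ReferenceMismatchError as exc:
            logger.warning("reference mismatch: %s", exc)
            rec.update(status="reference_mismatch")
            out_rows.append(rec)
            continue
        except LookupFailedError as exc:
            logger.warning("row not in (filtered) alignment: %s", exc)
            rec.update(status="row_not_in_alignment")
            out_rows.append(rec)
            continue
        except Exception as exc:  # unmappable row: keep it, flag it
            logger.warning("unmappable variant %s: %s", rec, exc)
            rec.update(status="error")
            out_rows.append(rec)
            continue
        if not hits:
            rec.update(
                status="not_in_domain",
                pm1_label="not_in_domain",
            )
            out_rows.append(rec)
            continue
        scored = [
            (hit, substitution_scores(matrices[hit.domain_id], hit.column, hit.wt, hit.mut))
            for hit in hits
        ]
        scored.sort(key=lambda hs: (-abs(hs[1].delta), hs[0].domain_id))
        hit, s = scored[0]
        rec.update(
            status="ok",
            domain_id=hit.domain_id,
            column=hit.column,
            wt_score=s.wt_score,
            mut_score=s.mut_score,
            delta=s.delta,
            other_hits=";".join(
                f"{h.domain_id}:{h.column}" for h, _ in scored[1:]
            ),
        )
        if model is not None:
            zone = assign_zone(model, s)
            rec["zone"] = zone
            rec["pm1_label"] = evidence_label(model, zone)
        if freq_index is not None:
            af = freq_index.lookup(hit.domain_id, hit.column, hit.wt, hit.mut)
            prov = freq_index.provenance(hit.domain_id, hit.column, hit.wt, hit.mut)
            rec["dolphin_af"] = af
            rec["af_provenance"] = prov.label if prov else None
            rec["freq_evidence"] = frequency_evidence(af)
        out_rows.append(rec)
    df = pd.DataFrame(out_rows)
    if "column" in df.columns:
        df["column"] = df["column"].astype("Int64")
    return df


def run_annotate(cfg: RunConfig) -> Path:
    """Execute the full workflow; returns the output TSV path."""
    logging.basicConfig(level=cfg.log_level)
    alignments, matrices, annotations, variants, _bg = load_inputs(cfg)
    logger.info(
        "loaded %d alignments, %d annotations, %d variants",
        len(alignments), len(annotations), len(variants),
    )
    model = ZoneModel.load(cfg.model) if cfg.model else None
    freq_index = build_frequency_index(variants, annotations, alignments)
    logger.info("frequency index holds %d keys", len(freq_index))
    annotated = annotate_variants(
        variants, annotations, alignments, matrices,
        model=model, freq_index=freq_index,
    )
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    out_path = out_dir / "annotated_variants.tsv"
    annotated.to_csv(out_path, sep="\t", index=False)
    manifest = {
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "version": __version__,
        "n_variants_in": int(len(variants)),
        "n_variants_out": int(len(annotated)),
        "n_domains": len(alignments),
        "status_counts": annotated["status"].value_counts().to_dict(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("wrote %s", out_path)
    return out_path
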