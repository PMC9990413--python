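"""Benchmarking PM1-style predictions against clinical labels.

The evaluation set mirrors how curated variant collections are used:
keep missense variants of clinical classes 1/2 (benign-like, negatives)
and 4/5 (pathogenic-like, positives) with a review level of at least
two stars, located in protein domains. Predictions may be committed
(PM1 = positive call, anything else = negative call) or withheld
("none"/NA, the indeterminate overlap zone); withheld predictions are
counted as NA and excluded from every metric denominator — the only
reading under which a confusion table's printed summary statistics
follow from its printed cells.

Metrics: SPE = TN/(TN+FP), SEN = TP/(TP+FN), ACC = (TP+TN)/committed,
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)). A zero
denominator yields None, never 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import PairingError, ReportError, SchemaError

POSITIVE_CLASSES = frozenset({4, 5})
NEGATIVE_CLASSES = frozenset({1, 2})
MIN_STARS = 2

NA_PREDICTIONS = frozenset({"none", "na", "uk", ""})
POSITIVE_PREDICTIONS = frozenset({"pm1", "yes", "1", "true"})


@dataclass(frozen=True)
class ConfusionStats:
    """2x2 confusion counts plus withheld (NA) predictions."""

    tp: int
    tn: int
    fp: int
    fn: int
    na: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn, self.na) < 0:
            raise PairingError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn + self.na

    @property
    def committed(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def round_half_away(x: float, ndigits: int) -> float:
    """Decimal rounding, halves away from zero (display convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def filter_eval_set(records: pd.DataFrame) -> pd.DataFrame:
    """Apply the evaluation-set selection rule.

    Keeps rows with clinical_class in {1, 2, 4, 5}, stars >= 2 and — when
    an ``in_domain`` column is present — located in a domain. Adds a
    boolean ``positive`` column (class 4/5 = True, 1/2 = False).
    """
    for col in ("clinical_class", "stars"):
        if col not in records.columns:
            raise SchemaError(f"evaluation input lacks column {col!r}")
    cls = pd.to_numeric(records["clinical_class"], errors="coerce")
    keep = cls.isin(POSITIVE_CLASSES | NEGATIVE_CLASSES)
    keep &= pd.to_numeric(records["stars"], errors="coerce") >= MIN_STARS
    if "in_domain" in records.columns:
        keep &= records["in_domain"].astype(bool)
    out = records.loc[keep].copy()
    out["positive"] = pd.to_numeric(out["clinical_class"]).isin(POSITIVE_CLASSES)
    return out


def _is_na(pred: object) -> bool:
    if pred is None:
        return True
    if isinstance(pred, float) and math.isnan(pred):
        return True
    return str(pred).strip().lower() in NA_PREDICTIONS


def confusion(
    labels: Sequence[bool], predictions: Sequence[object]
) -> ConfusionStats:
    """Pair true labels with possibly-withheld predictions.

    ``labels``: True = pathogenic-like. ``predictions``: "PM1" (or
    truthy boolean) commits a positive call; "none"/None/NaN withholds
    (NA); anything else (e.g. "BP8", "no") commits a negative call.
    """
    if len(labels) != len(predictions):
        raise PairingError(
            f"{len(labels)} labels vs {len(predictions)} predictions"
        )
    tp = tn = fp = fn = na = 0
    for truth, pred in zip(labels, predictions):
        if _is_na(pred):
            na += 1
            continue
        if isinstance(pred, bool):
            called_positive = pred
        else:
            called_positive = str(pred).strip().lower() in POSITIVE_PREDICTIONS
        if called_positive:
            if truth:
                tp += 1
            else:
                fp += 1
        else:
            if truth:
                fn += 1
            else:
                tn += 1
    return ConfusionStats(tp=tp, tn=tn, fp=fp, fn=fn, na=na)


def metrics(stats: ConfusionStats) -> dict[str, float | None]:
    """SPE/SEN/ACC/MCC at full precision; None where undefined."""
    tp, tn, fp, fn = stats.tp, stats.tn, stats.fp, stats.fn

    def ratio(num: float, den: float) -> float | None:
        return None if den == 0 else num / den

    mcc_den = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    return {
        "SPE": ratio(tn, tn + fp),
        "SEN": ratio(tp, tp + fn),
        "ACC": ratio(tp + tn, stats.committed),
        "MCC": None if mcc_den == 0 else (tp * tn - fp * fn) / mcc_den,
    }


def rounded_metrics(stats: ConfusionStats, ndigits: int = 2) -> dict[str, float | None]:
    """Display form of :func:`metrics` (2 decimals, half away from zero)."""
    return {
        k: None if v is None else round_half_away(v, ndigits)
        for k, v in metrics(stats).items()
    }


def coverage_report(
    counts: Mapping[str, tuple[int, int]]
) -> dict[str, float]:
    """Named (numerator, denominator) pairs → percentages.

    Each fraction is reported as a percent rounded to one decimal, half
    away from zero.
    """
    out: dict[str, float] = {}
    for name, (num, den) in counts.items():
        if den <= 0:
            raise ReportError(f"zero/negative denominator for {name!r}")
        if num < 0:
            raise ReportError(f"negative numerator for {name!r}")
        out[name] = round_half_away(100.0 * num / den, 1)
    return out


def format_coverage(report: Mapping[str, float]) -> str:
    return "\n".join(f"{name}\t{pct:.1f}%" for name, pct in report.items())
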