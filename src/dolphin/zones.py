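"""Zone model: k-means clusters of (wt, Δ) scores and ACMG evidence.

Labeled variants (pathogenic-like = ClinVar class 4/5, benign-like =
class 1/2) form clouds in the (wt, Δ) plane. k-means with multiple
restarts separates them into k = 4 clusters, named A, B, C, D by
descending fraction of pathogenic variants; D ends up the
benign-majority cluster. The clusters are then frozen into an
axis-aligned zone geometry so the decision boundary is reproducible
from the persisted model alone, without re-running k-means:

* boundaries sit at midpoints between adjacent centroid coordinates
  along each axis (three vertical and three horizontal threshold lines
  for k = 4), cutting the plane into a k x k cell grid;
* each cell takes the zone of the centroid closest in cell-index
  (Manhattan) distance; ties — and points landing exactly on a
  threshold line — resolve PM1-conservatively, preferring C, then D,
  then B, then A, so borderline points withhold evidence rather than
  over-call PM1.

Evidence: zones A and B support PM1 (key residue significantly
altered), zone D supports BP8 (in a functional domain without affecting
a key residue), zone C is the pathogenic/benign overlap area and yields
no label.
"""

from __future__ import annotations

import json
import string
import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .errors import FitError, NotFittedError, ParameterError
from .scoring import DolphinScores

PATHOGENIC = "pathogenic"
BENIGN = "benign"

DEFAULT_K = 4
DEFAULT_RESTARTS = 25

ZONE_EVIDENCE_4 = {"A": "PM1", "B": "PM1", "C": "none", "D": "BP8"}
# PM1-conservative tie preference: withhold first, then benign support.
TIE_PREFERENCE_4 = ("C", "D", "B", "A")


@dataclass(frozen=True)
class LabeledScore:
    """A scored substitution with its clinical training label."""

    scores: DolphinScores
    label: str  # PATHOGENIC or BENIGN
    stars: int = 2

    def __post_init__(self) -> None:
        if self.label not in (PATHOGENIC, BENIGN):
            raise ParameterError(f"label must be pathogenic/benign, got {self.label!r}")

    @property
    def point(self) -> tuple[float, float]:
        return (self.scores.wt_score, self.scores.delta)


def labeled_scores_from_frame(df) -> list[LabeledScore]:
    """Build training points from a table with wt_score/delta/positive columns.

    Residue letters and domain ids are carried when present; otherwise
    neutral placeholders are used (zoning only consumes wt and Δ).
    """
    out: list[LabeledScore] = []
    for r in df.itertuples(index=False):
        wt_score = float(r.wt_score)
        delta = float(r.delta)
        scores = DolphinScores(
            domain_id=str(getattr(r, "domain_id", "")),
            column=int(getattr(r, "column", 1)),
            wt=str(getattr(r, "wt", "A")),
            mut=str(getattr(r, "mut", "C")),
            wt_score=wt_score,
            mut_score=wt_score + delta,
        )
        label = PATHOGENIC if bool(r.positive) else BENIGN
        out.append(LabeledScore(scores, label, stars=int(getattr(r, "stars", 2))))
    return out


def _as_points(points: Sequence[LabeledScore] | np.ndarray) -> np.ndarray:
    if isinstance(points, np.ndarray):
        X = np.asarray(points, dtype=float)
    else:
        X = np.array([p.point for p in points], dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ParameterError(f"expected n x 2 (wt, delta) points, got {X.shape}")
    return X


def wss_curve(
    points: Sequence[LabeledScore] | np.ndarray,
    k_range: Sequence[int] = range(1, 9),
    seed: int = 0,
    restarts: int = DEFAULT_RESTARTS,
) -> tuple[list[tuple[int, float]], int]:
    """Within-cluster sum of squares over candidate k, plus the elbow k.

    Each k keeps the best of ``restarts`` random initializations and of
    one warm start that extends the previous k's centers with the point
    farthest from them — this guarantees WSS is non-increasing in k.
    The suggested k is the interior argmax of the second difference of
    the WSS curve taken on a log scale (the kink). Log scale makes the
    rule respond to relative drops, so a cluster structure whose first
    split removes most of the absolute variance does not mask the true
    kink. A flat curve (WSS already ≈ 0 at the smallest k) suggests the
    smallest k.
    """
    ks = sorted(set(int(k) for k in k_range))
    X = _as_points(points)
    if len(X) < max(ks):
        raise ParameterError(
            f"need at least {max(ks)} points for k up to {max(ks)}, have {len(X)}"
        )
    curve: list[tuple[int, float]] = []
    prev_centers: np.ndarray | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate-point inits on tiny fixtures
        for k in ks:
            km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(X)
            best = km
            if prev_centers is not None and prev_centers.shape[0] == k - 1:
                d = np.min(
                    ((X[:, None, :] - prev_centers[None, :, :]) ** 2).sum(-1), axis=1
                )
                init = np.vstack([prev_centers, X[int(np.argmax(d))]])
                warm = KMeans(n_clusters=k, init=init, n_init=1).fit(X)
                if warm.inertia_ < best.inertia_:
                    best = warm
            curve.append((k, float(best.inertia_)))
            prev_centers = best.cluster_centers_
    wss = [w for _, w in curve]
    if wss[0] <= 1e-9 * len(X):
        suggested = ks[0]
    elif len(ks) < 3:
        suggested = ks[int(np.argmin(wss))]
    else:
        logw = np.log(np.maximum(wss, 1e-12))
        d2 = [logw[i - 1] - 2 * logw[i] + logw[i + 1] for i in range(1, len(ks) - 1)]
        suggested = ks[1 + int(np.argmax(d2))]
    return curve, suggested


@dataclass(frozen=True)
class ZoneModel:
    """Frozen zone geometry plus the fit it came from."""

    centroids: dict[str, tuple[float, float]]  # zone -> (wt, delta)
    x_thresholds: tuple[float, ...]
    y_thresholds: tuple[float, ...]
    cell_zones: tuple[tuple[str, ...], ...]  # [x cell][y cell] -> zone
    zone_evidence: dict[str, str]
    tie_preference: tuple[str, ...]
    seed: int
    restarts: int
    training_composition: dict[str, dict[str, int]] = field(default_factory=dict)
    wss: float = float("nan")

    @property
    def zones(self) -> tuple[str, ...]:
        return tuple(sorted(self.centroids))

    # --- persistence ---------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "centroids": {z: list(c) for z, c in self.centroids.items()},
                "x_thresholds": list(self.x_thresholds),
                "y_thresholds": list(self.y_thresholds),
                "cell_zones": [list(row) for row in self.cell_zones],
                "zone_evidence": self.zone_evidence,
                "tie_preference": list(self.tie_preference),
                "seed": self.seed,
                "restarts": self.restarts,
                "training_composition": self.training_composition,
                "wss": self.wss,
            },
            indent=2,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def from_json(cls, text: str) -> "ZoneModel":
        d = json.loads(text)
        return cls(
            centroids={z: tuple(c) for z, c in d["centroids"].items()},
            x_thresholds=tuple(d["x_thresholds"]),
            y_thresholds=tuple(d["y_thresholds"]),
            cell_zones=tuple(tuple(row) for row in d["cell_zones"]),
            zone_evidence=dict(d["zone_evidence"]),
            tie_preference=tuple(d["tie_preference"]),
            seed=int(d["seed"]),
            restarts=int(d["restarts"]),
            training_composition={
                z: {k: int(v) for k, v in comp.items()}
                for z, comp in d.get("training_composition", {}).items()
            },
            wss=float(d.get("wss", float("nan"))),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ZoneModel":
        return cls.from_json(Path(path).read_text())


def _ranks(values: Sequence[float], names: Sequence[str]) -> dict[str, int]:
    """Rank of each named value after a stable (value, name) sort."""
    order = sorted(range(len(values)), key=lambda i: (values[i], names[i]))
    return {names[i]: rank for rank, i in enumerate(order)}


def fit_zones(
    points: Sequence[LabeledScore],
    k: int = DEFAULT_K,
    seed: int = 0,
    restarts: int = DEFAULT_RESTARTS,
    *,
    standardize: bool = False,
) -> ZoneModel:
    """Fit k-means on (wt, Δ) and freeze the axis-aligned zone geometry.

    Zones are named by descending pathogenic fraction (A most
    pathogenic-enriched ... last letter the benign-majority cluster).
    ``standardize`` optionally z-scores the two axes before clustering;
    off by default since wt and Δ are commensurate log scores.
    """
    if k < 2:
        raise ParameterError(f"k must be >= 2, got {k}")
    labels_in = [p.label for p in points]
    if PATHOGENIC not in labels_in or BENIGN not in labels_in:
        raise ParameterError("training points must contain both labels")
    X = _as_points(points)
    if len(np.unique(X, axis=0)) < k:
        raise FitError(f"fewer than {k} distinct points; cannot fit {k} clusters")

    Xf = X
    if standardize:
        Xf = (X - X.mean(axis=0)) / X.std(axis=0)

    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(Xf)
    assignments = km.labels_
    if len(set(assignments.tolist())) < k:  # pragma: no cover - k-means++ rarity
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed + 1).fit(Xf)
        assignments = km.labels_
        if len(set(assignments.tolist())) < k:
            raise FitError("empty cluster after refit")

    # Centroids in the original (wt, delta) coordinates.
    centers = np.array(
        [X[assignments == c].mean(axis=0) for c in range(k)], dtype=float
    )

    path_frac = np.array(
        [
            np.mean([labels_in[i] == PATHOGENIC for i in np.flatnonzero(assignments == c)])
            for c in range(k)
        ]
    )
    # Descending pathogenic fraction; centroid x breaks exact ties.
    order = sorted(range(k), key=lambda c: (-path_frac[c], centers[c, 0]))
    zone_names = list(string.ascii_uppercase[:k])
    cluster_to_zone = {c: zone_names[i] for i, c in enumerate(order)}

    centroids = {cluster_to_zone[c]: (float(centers[c, 0]), float(centers[c, 1])) for c in range(k)}
    composition = {
        cluster_to_zone[c]: {
            PATHOGENIC: int(sum(labels_in[i] == PATHOGENIC for i in np.flatnonzero(assignments == c))),
            BENIGN: int(sum(labels_in[i] == BENIGN for i in np.flatnonzero(assignments == c))),
        }
        for c in range(k)
    }

    names = zone_names
    xs = [centroids[z][0] for z in names]
    ys = [centroids[z][1] for z in names]
    rank_x = _ranks(xs, names)
    rank_y = _ranks(ys, names)
    sx = sorted(xs)
    sy = sorted(ys)
    x_thr = tuple((sx[i] + sx[i + 1]) / 2 for i in range(k - 1))
    y_thr = tuple((sy[i] + sy[i + 1]) / 2 for i in range(k - 1))

    if k == 4:
        evidence = dict(ZONE_EVIDENCE_4)
        preference = TIE_PREFERENCE_4
    else:
        evidence = {z: "none" for z in names}
        preference = tuple(reversed(names))

    pref_rank = {z: i for i, z in enumerate(preference)}
    cells = []
    for ix in range(k):
        row = []
        for iy in range(k):
            dists = {z: abs(ix - rank_x[z]) + abs(iy - rank_y[z]) for z in names}
            dmin = min(dists.values())
            winner = min(
                (z for z, d in dists.items() if d == dmin), key=lambda z: pref_rank[z]
            )
            row.append(winner)
        cells.append(tuple(row))

    return ZoneModel(
        centroids=centroids,
        x_thresholds=x_thr,
        y_thresholds=y_thr,
        cell_zones=tuple(cells),
        zone_evidence=evidence,
        tie_preference=preference,
        seed=seed,
        restarts=restarts,
        training_composition=composition,
        wss=float(km.inertia_),
    )


def _cell_candidates(thresholds: Sequence[float], v: float) -> range:
    lo = bisect_left(thresholds, v)
    hi = bisect_right(thresholds, v)
    return range(lo, hi + 1)


def assign_zone(model: ZoneModel, scores: DolphinScores | tuple[float, float]) -> str:
    """Zone of one (wt, Δ) point by the stored threshold geometry.

    Points exactly on a threshold line belong to every adjacent cell;
    if those cells disagree, the model's PM1-conservative tie
    preference decides.
    """
    if not model.centroids:
        raise NotFittedError("zone model has no centroids")
    if isinstance(scores, DolphinScores):
        x, y = scores.wt_score, scores.delta
    else:
        x, y = float(scores[0]), float(scores[1])
    candidates = {
        model.cell_zones[ix][iy]
        for ix in _cell_candidates(model.x_thresholds, x)
        for iy in _cell_candidates(model.y_thresholds, y)
    }
    if len(candidates) == 1:
        return next(iter(candidates))
    pref_rank = {z: i for i, z in enumerate(model.tie_preference)}
    return min(candidates, key=lambda z: pref_rank[z])


def evidence_label(model_or_zone: ZoneModel | str, zone: str | None = None, *, in_domain: bool = True) -> str:
    """Map a zone to its ACMG evidence: A/B → PM1, D → BP8, C → none.

    Accepts either ``evidence_label(model, zone)`` or, with the
    canonical 4-zone map, ``evidence_label(zone)``. Positions outside
    any annotated domain get ``"not_in_domain"``.
    """
    if not in_domain:
        return "not_in_domain"
    if isinstance(model_or_zone, ZoneModel):
        mapping = model_or_zone.zone_evidence
        z = zone
    else:
        mapping = ZONE_EVIDENCE_4
        z = model_or_zone
    if z not in mapping:
        raise ParameterError(f"unknown zone {z!r}")
    return mapping[z]


def classify(
    model: ZoneModel, scores: Iterable[DolphinScores | tuple[float, float]]
) -> list[tuple[str, str]]:
    """(zone, evidence) for each scored substitution."""
    out = []
    for s in scores:
        z = assign_zone(model, s)
        out.append((z, evidence_label(model, z)))
    return out
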