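"""One-class SVM ranking of genes by compositional atypicality.

A nu-SVM with a Gaussian kernel is fitted on *all* genes of a family (no
labels exist).  Each gene's signed distance to the decision boundary —
negative outside the boundary, positive inside — induces a ranking from
most atypical (most negative) to most typical.  The exact location of the
boundary matters little for ranking; parameters are therefore chosen for
*stability* of the ranking, measured as the windowed Spearman correlation
between rankings at neighbouring values of nu.

Defaults are nu = 0.2 and gamma = 1/(2D), D being the feature-space
dimensionality; the gamma rule of thumb was found to give stable rankings
across a wide range of nu.

A one-dimensional baseline ranks genes by the absolute deviation of their
GC content from the family median; it is not fed to the SVM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import OneClassSVM

from .errors import DegenerateFitError, ParameterError, ValidationError
from .feature_extraction import (
    FeatureMatrix,
    FeatureSpec,
    apply_standardization,
    build_feature_matrix,
    encode,
    gc_content,
    get_spec,
    standardize,
)
from .sequence_io import FamilyDataset, Segment

__all__ = [
    "SvmParams",
    "RankingResult",
    "StabilityProfile",
    "DEFAULT_NU",
    "RULE_OF_THUMB",
    "resolve_gamma",
    "default_nu_grid",
    "default_gamma_grid",
    "rank_genes",
    "gc_baseline_rank",
    "spearman_rho",
    "neighbor_stability",
    "stability_sweep",
    "rank_segments",
]

DEFAULT_NU = 0.2
RULE_OF_THUMB = "rule_of_thumb"
#: libsvm stopping tolerance, fixed and tight so that signed distances are
#: reproducible to ~1e-9 regardless of row order or evaluation order.
SOLVER_TOL = 1e-12


@dataclass(frozen=True)
class SvmParams:
    """nu in (0, 1]; gamma a positive real or "rule_of_thumb" = 1/(2D)."""

    nu: float = DEFAULT_NU
    gamma: float | str = RULE_OF_THUMB

    def __post_init__(self) -> None:
        if not (0.0 < self.nu <= 1.0):
            raise ParameterError(f"nu must be in (0, 1], got {self.nu}")
        if self.gamma != RULE_OF_THUMB and not (
            isinstance(self.gamma, (int, float)) and self.gamma > 0
        ):
            raise ParameterError(f"gamma must be positive or {RULE_OF_THUMB!r}, got {self.gamma}")

    def resolve(self, spec: FeatureSpec) -> "SvmParams":
        return SvmParams(nu=self.nu, gamma=resolve_gamma(spec, self.gamma))


def resolve_gamma(spec: FeatureSpec, gamma: float | str) -> float:
    """Numeric gamma passthrough; the rule of thumb resolves to 1/(2D)."""
    if gamma == RULE_OF_THUMB:
        if spec.dimension < 1:
            raise ParameterError("feature dimension must be >= 1")
        return 1.0 / (2.0 * spec.dimension)
    if not isinstance(gamma, (int, float)) or isinstance(gamma, bool) or gamma <= 0:
        raise ParameterError(f"gamma must be positive, got {gamma!r}")
    return float(gamma)


def default_nu_grid() -> np.ndarray:
    """1,000 equidistant nu values in (0, 1]: 0.001, 0.002, ..., 1.000."""
    return np.arange(1, 1001) / 1000.0


def default_gamma_grid(spec: FeatureSpec) -> list[float]:
    """The gamma exploration grid, including the 1/(2D) rule of thumb."""
    return [1e-6, 1e-5, 1e-4, 1e-3, 0.01, 0.1, 1.0, 10.0, 100.0,
            resolve_gamma(spec, RULE_OF_THUMB)]


@dataclass
class RankingResult:
    """Genes ordered most-atypical-first by signed boundary distance.

    ``signed_distance`` is aligned with ``ranked_gene_ids`` and ascending;
    ties break on dataset ingest order.
    """

    spec: FeatureSpec
    params: SvmParams | None
    ranked_gene_ids: list[str]
    signed_distance: np.ndarray
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signed_distance = np.asarray(self.signed_distance, dtype=float)
        if len(self.ranked_gene_ids) != len(self.signed_distance):
            raise ValidationError("ranking ids and distances differ in length")

    def __len__(self) -> int:
        return len(self.ranked_gene_ids)

    def rank_of(self, gene_id: str) -> int:
        """1-based rank (1 = most atypical)."""
        return self.ranked_gene_ids.index(gene_id) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self) + 1),
                "gene_id": self.ranked_gene_ids,
                "signed_distance": self.signed_distance,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def _order_ascending(scores: np.ndarray) -> np.ndarray:
    """Ascending stable argsort: equal scores keep ingest order."""
    return np.argsort(scores, kind="stable")


def _fit_scores(X: np.ndarray, nu: float, gamma: float, context: str = "") -> np.ndarray:
    if not (0.0 < nu <= 1.0):
        raise ParameterError(f"nu must be in (0, 1], got {nu}")
    if gamma <= 0:
        raise ParameterError(f"gamma must be positive, got {gamma}")
    clf = OneClassSVM(kernel="rbf", nu=nu, gamma=gamma, tol=SOLVER_TOL)
    try:
        clf.fit(X)
        scores = clf.decision_function(X)
    except Exception as exc:
        raise DegenerateFitError(f"one-class SVM fit failed{context}: {exc}") from exc
    if not np.all(np.isfinite(scores)):
        raise DegenerateFitError(f"non-finite decision values{context}")
    return scores


def rank_genes(fm: FeatureMatrix, params: SvmParams | None = None) -> RankingResult:
    """Fit a one-class SVM on all rows and rank by signed distance."""
    if not fm.standardized:
        raise ValidationError("rank_genes requires a standardized feature matrix")
    params = (params or SvmParams()).resolve(fm.spec)
    scores = _fit_scores(fm.values, params.nu, params.gamma, context=f" (spec={fm.spec.name})")
    order = _order_ascending(scores)
    return RankingResult(
        spec=fm.spec,
        params=params,
        ranked_gene_ids=[fm.gene_ids[i] for i in order],
        signed_distance=scores[order],
        exclusions=list(fm.excluded),
    )


def gc_baseline_rank(ds: FamilyDataset) -> RankingResult:
    """Baseline: rank by |GC - median family GC|, largest deviation first.

    The signed-distance field stores the negated absolute deviation so the
    ascending-order contract of :class:`RankingResult` holds.
    """
    ds.require_analyzable()
    ids, gcs, excluded = [], [], []
    for g in ds.genes:
        try:
            gcs.append(gc_content(g.seq))
            ids.append(g.gene_id)
        except Exception as e:
            excluded.append((g.gene_id, str(e)))
    if len(ids) < 4:
        raise ValidationError(f"family {ds.family!r}: fewer than 4 genes with defined GC")
    gcs = np.asarray(gcs)
    scores = -np.abs(gcs - np.median(gcs))
    order = _order_ascending(scores)
    return RankingResult(
        spec=get_spec("gc_content"),
        params=None,
        ranked_gene_ids=[ids[i] for i in order],
        signed_distance=scores[order],
        exclusions=excluded,
    )


# ---------------------------------------------------------------------------
# Ranking-stability parameter selection
# ---------------------------------------------------------------------------

def spearman_rho(rank_a, rank_b) -> float:
    """Spearman rank correlation of two equal-length score/rank vectors.

    Ties are handled by the mid-rank convention.  Returns NaN when either
    vector is constant (no ranking information).
    """
    a = np.asarray(rank_a, dtype=float)
    b = np.asarray(rank_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 1 or len(a) < 2:
        raise ValidationError("spearman_rho needs two 1-d vectors of length >= 2")
    rho = float(stats.spearmanr(a, b).statistic)
    # identical/reversed rankings are exactly +/-1; snap away rounding noise
    if np.isfinite(rho):
        rho = max(-1.0, min(1.0, rho))
        if abs(abs(rho) - 1.0) < 1e-12:
            rho = math.copysign(1.0, rho)
    return rho


def neighbor_stability(score_vectors: list[np.ndarray | None]) -> np.ndarray:
    """Windowed stability: rho_i = mean Spearman with the available neighbours.

    Grid boundary points use their single neighbour.  A missing (None)
    vector yields NaN at that point and is skipped as a neighbour.
    """
    n = len(score_vectors)
    rho = np.full(n, np.nan)
    for i, cur in enumerate(score_vectors):
        if cur is None:
            continue
        vals = []
        for j in (i - 1, i + 1):
            if 0 <= j < n and score_vectors[j] is not None:
                vals.append(spearman_rho(cur, score_vectors[j]))
        if vals:
            rho[i] = float(np.mean(vals))
    return rho


@dataclass
class StabilityProfile:
    """Per-nu windowed Spearman stability of the ranking at one gamma."""

    gamma: float
    nu_grid: np.ndarray
    rho: np.ndarray

    @property
    def coverage(self) -> float:
        """Fraction of grid points with a defined stability value."""
        return float(np.mean(np.isfinite(self.rho)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gamma": self.gamma, "nu": self.nu_grid, "rho": self.rho})


def stability_sweep(
    fm: FeatureMatrix,
    gamma_grid: list[float] | None = None,
    nu_grid: np.ndarray | None = None,
) -> list[StabilityProfile]:
    """Rank at every (gamma, nu) grid point and score neighbour stability.

    Degenerate fits are recorded as missing grid points, never abort the
    sweep.  Results do not depend on evaluation order.
    """
    if not fm.standardized:
        raise ValidationError("stability_sweep requires a standardized feature matrix")
    if gamma_grid is None:
        gamma_grid = default_gamma_grid(fm.spec)
    nu_grid = default_nu_grid() if nu_grid is None else np.asarray(nu_grid, dtype=float)
    profiles = []
    for gamma in gamma_grid:
        scores: list[np.ndarray | None] = []
        for nu in nu_grid:
            try:
                scores.append(_fit_scores(fm.values, float(nu), float(gamma)))
            except DegenerateFitError:
                scores.append(None)
        profiles.append(StabilityProfile(gamma=float(gamma), nu_grid=nu_grid.copy(),
                                         rho=neighbor_stability(scores)))
    return profiles


def profiles_to_tsv(profiles: list[StabilityProfile], path) -> None:
    pd.concat([p.to_frame() for p in profiles], ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


# ---------------------------------------------------------------------------
# Sliding-window (single genome) mode
# ---------------------------------------------------------------------------

def _encode_segments(segments: list[Segment], spec: FeatureSpec):
    rows, ids, excluded = [], [], []
    for s in segments:
        try:
            rows.append(encode(s.seq, spec))
            ids.append(s.segment_id)
        except Exception as e:
            excluded.append((s.segment_id, str(e)))
    if not rows:
        raise ValidationError("no encodable segment")
    return np.vstack(rows), ids, excluded


def rank_segments(
    segments: list[Segment],
    background: FamilyDataset | str,
    spec: FeatureSpec,
    params: SvmParams | None = None,
) -> RankingResult:
    """Rank genome windows by atypicality against self- or family statistics.

    ``background="self"``: the SVM is trained on the segments themselves
    (equivalent to :func:`rank_genes` on the segment matrix).  With a family
    background, the SVM and the standardization statistics come from the
    family's genes and the segments are only scored.
    """
    if not segments:
        raise ValidationError("no segments to rank")
    params = (params or SvmParams()).resolve(spec)
    if isinstance(background, str):
        if background != "self":
            raise ParameterError("background must be a FamilyDataset or 'self'")
        X, ids, excluded = _encode_segments(segments, spec)
        if len(ids) < 4:
            raise ValidationError("background too small: fewer than 4 encodable segments")
        fm = FeatureMatrix(spec=spec, gene_ids=ids, values=X, excluded=excluded)
        return rank_genes(standardize(fm), params)
    bg_fm = standardize(build_feature_matrix(background, spec))
    if bg_fm.n_genes < 4:
        raise ValidationError("background too small: fewer than 4 encodable genes")
    clf = OneClassSVM(kernel="rbf", nu=params.nu, gamma=params.gamma, tol=SOLVER_TOL)
    try:
        clf.fit(bg_fm.values)
    except Exception as exc:
        raise DegenerateFitError(f"background fit failed ({background.family}): {exc}") from exc
    X, ids, excluded = _encode_segments(segments, spec)
    scores = clf.decision_function(apply_standardization(X, bg_fm.center, bg_fm.scale))
    if not np.all(np.isfinite(scores)):
        raise DegenerateFitError("non-finite segment scores")
    order = _order_ascending(scores)
    return RankingResult(
        spec=spec,
        params=params,
        ranked_gene_ids=[ids[i] for i in order],
        signed_distance=scores[order],
        exclusions=excluded,
    )
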