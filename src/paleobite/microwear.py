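"""Low-magnification dental microwear quantification and ordination.

Nine feature classes — four pit types (small pits, large pits, small
puncture pits, large puncture pits) and five scratch types (cross, fine,
coarse, hypercoarse scratches, gouges) — are counted over a fixed 0.3 mm^2
field at x70 magnification.  Counts are normalized to percentages per
specimen, a dissimilarity matrix (Bray-Curtis by default) is built over
the percentage profiles, and principal coordinates analysis (PCoA; Gower
double-centering followed by eigendecomposition) ordinates specimens in a
diet space.  Unknown specimens are projected into the reference
ordination and classified by k-nearest-neighbour vote over diet guilds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "DIET_CATEGORIES",
    "MicrowearCounts",
    "MicrowearProfile",
    "OrdinationResult",
    "PCoA",
    "MicrowearDietClassifier",
    "normalize_counts",
    "microwear_distance",
    "pcoa",
    "intra_observer_error",
    "classify_diet",
]

FEATURE_NAMES = (
    "small_pits",
    "large_pits",
    "small_puncture_pits",
    "large_puncture_pits",
    "cross_scratches",
    "fine_scratches",
    "coarse_scratches",
    "hypercoarse_scratches",
    "gouges",
)

DIET_CATEGORIES = (
    "carnivory",
    "animal-dominated omnivory",
    "omnivory",
    "plant-dominated omnivory",
    "herbivory",
    "unknown",
)


@dataclass
class MicrowearCounts:
    specimen_id: str
    counts: np.ndarray
    taxon: str = ""
    diet_category: str = "unknown"
    area_mm2: float = 0.3
    magnification: float = 70.0
    damaged: bool = False

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"expected {len(FEATURE_NAMES)} feature counts")
        if np.any(self.counts < 0):
            raise ValueError("feature counts cannot be negative")
        if self.diet_category not in DIET_CATEGORIES:
            raise ValueError(f"unknown diet category {self.diet_category!r}")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class MicrowearProfile:
    """Percentage-normalized feature profile for one specimen."""

    specimen_id: str
    percentages: np.ndarray
    taxon: str = ""
    diet_category: str = "unknown"

    def __post_init__(self):
        self.percentages = np.asarray(self.percentages, dtype=float)
        if not np.isclose(self.percentages.sum(), 100.0):
            raise ValueError("profile percentages must sum to 100")


@dataclass
class OrdinationResult:
    coordinates: np.ndarray  # specimens x axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalue_mass: float
    specimen_ids: list[str] = field(default_factory=list)


def normalize_counts(c: MicrowearCounts) -> MicrowearProfile:
    """Convert raw feature counts to percentages of the specimen total.

    Specimens with zero total (or flagged taphonomic damage) are
    unanalysable; a ValueError is raised with the reason logged.
    """
    if c.damaged:
        logger.warning("specimen %s excluded: taphonomic damage", c.specimen_id)
        raise ValueError(f"specimen {c.specimen_id} flagged as damaged")
    if c.total <= 0:
        logger.warning("specimen %s excluded: zero total count", c.specimen_id)
        raise ValueError(f"specimen {c.specimen_id} has zero total count")
    return MicrowearProfile(
        specimen_id=c.specimen_id,
        percentages=c.counts * 100.0 / c.total,
        taxon=c.taxon,
        diet_category=c.diet_category,
    )


def _profile_matrix(profiles) -> np.ndarray:
    return np.vstack([np.asarray(getattr(p, "percentages", p), dtype=float)
                      for p in profiles])


def microwear_distance(profiles, metric: str = "bray-curtis") -> np.ndarray:
    """Symmetric pairwise dissimilarity over percentage profiles.

    Bray-Curtis on percentage data lies in [0, 1]; Euclidean is the
    alternative.
    """
    X = _profile_matrix(profiles)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 profiles")
    if metric in ("bray-curtis", "braycurtis"):
        d = pdist(X, metric="braycurtis")
    elif metric == "euclidean":
        d = pdist(X, metric="euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return squareform(d)


class PCoA(BaseEstimator, TransformerMixin):
    """Principal coordinates analysis (metric multidimensional scaling).

    ``fit`` takes an n x n symmetric distance matrix: Gower
    double-centering of -0.5 d^2 followed by eigendecomposition;
    coordinates are eigenvectors scaled by sqrt(eigenvalue) over the
    positive eigenvalues.  Negative eigenvalues (possible for
    non-Euclidean dissimilarities such as Bray-Curtis) are reported as
    ``negative_eigenvalue_mass_`` and dropped from the axes.

    Parameters
    ----------
    n_axes : int or None
        Number of retained axes (all positive-eigenvalue axes if None).
    """

    def __init__(self, n_axes: int | None = None):
        self.n_axes = n_axes

    def fit(self, D, y=None):
        D = np.asarray(D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(D, D.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(D), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        n = D.shape[0]
        A = -0.5 * D**2
        J = np.eye(n) - np.ones((n, n)) / n
        B = J @ A @ J
        evals, evecs = np.linalg.eigh(B)  # ascending
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        tol = np.max(np.abs(evals)) * 1e-10 if n else 0.0
        pos = evals > tol
        self.eigenvalues_ = evals
        self.negative_eigenvalue_mass_ = float(-np.sum(evals[evals < -tol]))
        pos_evals = evals[pos]
        denom = pos_evals.sum() if pos_evals.size else 1.0
        self.proportion_explained_ = pos_evals / denom
        coords = evecs[:, pos] * np.sqrt(pos_evals)
        if self.n_axes is not None:
            coords = coords[:, : self.n_axes]
            self.proportion_explained_ = self.proportion_explained_[: self.n_axes]
        self.coordinates_ = coords
        self._D_fit = D
        self._row_mean_sq = np.mean(D**2, axis=1)
        self._grand_mean_sq = float(np.mean(D**2))
        self._pos_evals = pos_evals[: coords.shape[1]]
        return self

    def transform(self, D_new):
        """Project new points given their distances to the training points.

        ``D_new`` is m x n: each row holds a new specimen's distances to
        the n reference specimens.  Uses the standard Gower projection of
        the double-centered squared distances onto the fitted axes.
        """
        check_is_fitted(self, "coordinates_")
        D_new = np.atleast_2d(np.asarray(D_new, dtype=float))
        n = self._D_fit.shape[0]
        if D_new.shape[1] != n:
            raise ValueError("columns must match the reference specimen count")
        # b_j = -0.5 (d_new_j^2 - mean_j(d^2) - mean(d_new^2) + grand mean)
        b = -0.5 * (
            D_new**2
            - self._row_mean_sq[None, :]
            - np.mean(D_new**2, axis=1, keepdims=True)
            + self._grand_mean_sq
        )
        # B u_i = lambda_i u_i, so b @ coords = lambda * (new coord); the
        # orthogonality of eigenvectors makes this exact for training rows
        # even when negative eigenvalues are present
        return b @ self.coordinates_ / self._pos_evals

    def fit_transform(self, D, y=None):
        return self.fit(D).coordinates_

    def to_result(self, specimen_ids=None) -> OrdinationResult:
        check_is_fitted(self, "coordinates_")
        return OrdinationResult(
            coordinates=self.coordinates_,
            eigenvalues=self.eigenvalues_,
            proportion_explained=self.proportion_explained_,
            negative_eigenvalue_mass=self.negative_eigenvalue_mass_,
            specimen_ids=list(specimen_ids) if specimen_ids is not None else [],
        )


def pcoa(d: np.ndarray, n_axes: int | None = None,
         specimen_ids=None) -> OrdinationResult:
    """Functional wrapper over the :class:`PCoA` transformer."""
    return PCoA(n_axes=n_axes).fit(d).to_result(specimen_ids)


def intra_observer_error(first, second) -> dict:
    """Spearman rank correlation between two independent recounts.

    Reports rho and two-sided p for the total feature count and
    separately for small pits and cross scratches (the dominant pit and
    scratch classes).
    """
    A = np.vstack([c.counts if isinstance(c, MicrowearCounts) else np.asarray(c, float)
                   for c in first])
    B = np.vstack([c.counts if isinstance(c, MicrowearCounts) else np.asarray(c, float)
                   for c in second])
    if A.shape != B.shape:
        raise ValueError("recount tables must be paired (same shape)")
    out = {}
    for name, a, b in [
        ("total_features", A.sum(axis=1), B.sum(axis=1)),
        ("small_pits", A[:, FEATURE_NAMES.index("small_pits")],
         B[:, FEATURE_NAMES.index("small_pits")]),
        ("cross_scratches", A[:, FEATURE_NAMES.index("cross_scratches")],
         B[:, FEATURE_NAMES.index("cross_scratches")]),
    ]:
        rho, p = stats.spearmanr(a, b)
        out[name] = {"rho": float(rho), "p": float(p)}
    return out


class MicrowearDietClassifier(BaseEstimator):
    """k-nearest-neighbour diet-guild classifier in PCoA microwear space.

    ``fit`` consumes reference percentage profiles with diet labels,
    builds the dissimilarity matrix and ordination; ``predict`` projects
    queries into that space and votes over the k nearest references.
    Ties are reported in full, never silently broken.
    """

    def __init__(self, k: int = 5, metric: str = "bray-curtis",
                 n_axes: int | None = None):
        self.k = k
        self.metric = metric
        self.n_axes = n_axes

    def fit(self, profiles, y=None):
        profiles = list(profiles)
        self.labels_ = np.array(
            [p.diet_category for p in profiles] if y is None else list(y)
        )
        self.ids_ = [p.specimen_id for p in profiles]
        self._X = _profile_matrix(profiles)
        if self.k > len(profiles):
            raise ValueError("k exceeds the reference set size")
        D = microwear_distance(profiles, metric=self.metric)
        self.ordination_ = PCoA(n_axes=self.n_axes).fit(D)
        return self

    def _query_coords(self, profiles):
        Xq = _profile_matrix(profiles)
        metric = "braycurtis" if self.metric in ("bray-curtis", "braycurtis") else self.metric
        from scipy.spatial.distance import cdist

        Dq = cdist(Xq, self._X, metric=metric)
        return self.ordination_.transform(Dq)

    def rank(self, query) -> dict:
        """Full classification report for one query profile."""
        check_is_fitted(self, "labels_")
        coords = self._query_coords([query])
        ref = self.ordination_.coordinates_
        d = np.linalg.norm(ref - coords[0], axis=1)
        order = np.argsort(d, kind="stable")[: self.k]
        votes: dict[str, int] = {}
        for i in order:
            votes[self.labels_[i]] = votes.get(self.labels_[i], 0) + 1
        top = max(votes.values())
        winners = sorted(c for c, v in votes.items() if v == top)
        return {
            "neighbours": [
                {"specimen_id": self.ids_[i], "diet_category": str(self.labels_[i]),
                 "distance": float(d[i])}
                for i in order
            ],
            "votes": votes,
            "predicted": winners,
            "tie": len(winners) > 1,
            "coordinates": coords[0],
        }

    def predict(self, profiles):
        return np.array([";".join(self.rank(p)["predicted"]) for p in profiles])


def classify_diet(query, references, k: int = 5,
                  metric: str = "bray-curtis") -> dict:
    """Place a query profile in the reference diet space and vote over
    its k nearest reference specimens."""
    clf = MicrowearDietClassifier(k=k, metric=metric).fit(references)
    return clf.rank(query)
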