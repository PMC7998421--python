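"""Sweet-liker phenotyping from sensory-liking correlation patterns.

The segmentation feature for each consumer is the 4-vector of Pearson
correlations, computed across the four-sample sucrose series, between
liking and each rated sensory property (sweetness, bitterness,
astringency, overall flavour). Subjects for whom any of these
correlations is undefined — zero variance in liking or in at least one
attribute across the series — are excluded and listed on a roster with
the offending attribute(s). K-means (k=3 by default) on the retained
vectors yields the phenotypes, which are named by the sign pattern of
their centroid:

* ``HighSweetLiker``      r_sweet > 0 and r_flavour > 0
* ``ModerateSweetLiker``  r_sweet > 0 and r_flavour < 0
* ``InvertedUShaped``     r_sweet < 0
* ``Unlabeled``           any other pattern (a nearest reference
  centroid is suggested)

The correlation vectors enter k-means unstandardized: all four
dimensions already live on the r scale, so Euclidean distance on raw r
is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from .datamodel import SENSORY_ATTRIBUTES, RatingTable

logger = logging.getLogger(__name__)

R_COLUMNS = ["r_sweet", "r_bitter", "r_astringent", "r_flavour"]

#: Reference phenotype centroids (sweet, bitter, astringent, flavour)
#: used only to suggest a nearest phenotype for degenerate sign patterns.
REFERENCE_CENTROIDS = pd.DataFrame(
    [
        [0.765, -0.662, -0.373, 0.567],
        [0.582, -0.713, -0.488, -0.580],
        [-0.194, 0.327, 0.309, 0.118],
    ],
    index=["HighSweetLiker", "ModerateSweetLiker", "InvertedUShaped"],
    columns=R_COLUMNS,
)


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r between matching rows of two (n, m) arrays.

    Rows where either side has zero variance yield NaN (the statistic's
    denominator vanishes).
    """
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return r


def compute_correlation_vectors(
    ratings: RatingTable,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject liking-vs-attribute Pearson correlation vectors.

    Returns
    -------
    vectors : DataFrame
        Indexed by subject_id, columns ``r_sweet, r_bitter,
        r_astringent, r_flavour``; only subjects with all four
        correlations defined.
    exclusions : DataFrame
        Columns ``subject_id, reason`` listing complete subjects whose
        liking or some attribute had zero variance across the series
        (reason names the constant series, comma-joined). Incomplete
        subjects are skipped with a log entry, not excluded.
    """
    complete = ratings.complete_subjects()
    skipped = sorted(set(ratings.subjects) - set(complete))
    if skipped:
        logger.warning("skipping %d incomplete subjects: %s", len(skipped), skipped[:10])
    if not complete:
        return (
            pd.DataFrame(columns=R_COLUMNS),
            pd.DataFrame(columns=["subject_id", "reason"]),
        )

    liking = ratings.wide("liking").loc[complete].to_numpy(dtype=float)
    mats = {a: ratings.wide(a).loc[complete].to_numpy(dtype=float) for a in SENSORY_ATTRIBUTES}

    cols = {}
    for col, attr in zip(R_COLUMNS, SENSORY_ATTRIBUTES):
        cols[col] = _pearson_rows(liking, mats[attr])
    vectors = pd.DataFrame(cols, index=pd.Index(complete, name="subject_id"))

    zero_lik = liking.var(axis=1) == 0
    reasons = []
    for i, subject in enumerate(complete):
        why = []
        if zero_lik[i]:
            why.append("liking")
        for attr in SENSORY_ATTRIBUTES:
            if mats[attr][i].var() == 0:
                why.append(attr)
        if why:
            reasons.append((subject, ",".join(why)))
    exclusions = pd.DataFrame(reasons, columns=["subject_id", "reason"])
    vectors = vectors.drop(index=exclusions["subject_id"])
    assert not vectors.isna().any().any()
    return vectors, exclusions


class SweetLikerKMeans(ClusterMixin, BaseEstimator):
    """K-means phenotyping of sensory-liking correlation vectors.

    Lloyd's algorithm run to convergence from ``restarts`` seeded
    initializations, keeping the solution with the lowest within-cluster
    sum of squares; nearest-centroid ties break toward the lower cluster
    index. After fitting, clusters are ordered by decreasing size and
    named by their centroid sign pattern.

    Parameters
    ----------
    k : int, default 3
        Number of phenotypes.
    restarts : int, default 50
        Number of k-means initializations.
    seed : int, default 0
        Seed making the fit deterministic.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (k, 4)
    labels_ : ndarray of shape (n,)
    inertia_ : float
    phenotypes_ : list of str, phenotype name per cluster index
    """

    def __init__(self, k: int = 3, restarts: int = 50, seed: int = 0):
        self.k = k
        self.restarts = restarts
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n_distinct = np.unique(X, axis=0).shape[0]
        if n_distinct < self.k:
            raise ValueError(
                f"k={self.k} exceeds the {n_distinct} distinct vectors available"
            )
        km = KMeans(
            n_clusters=self.k,
            n_init=self.restarts,
            random_state=self.seed,
            init="random",
        ).fit(X)
        order = np.argsort(-np.bincount(km.labels_, minlength=self.k), kind="stable")
        relabel = np.empty(self.k, dtype=int)
        relabel[order] = np.arange(self.k)
        self.cluster_centers_ = km.cluster_centers_[order]
        self.labels_ = relabel[km.labels_]
        self.inertia_ = float(km.inertia_)
        self.phenotypes_ = [label_centroid(c)[0] for c in self.cluster_centers_]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        X = np.asarray(X, dtype=float)
        d = ((X[:, None, :] - self.cluster_centers_[None]) ** 2).sum(axis=2)
        # argmin takes the first minimum: ties break toward lower index
        return d.argmin(axis=1)


def label_centroid(centroid) -> tuple[str, str | None]:
    """Phenotype name for one centroid via the sign-pattern rule.

    Returns ``(name, suggestion)``; for an ``Unlabeled`` pattern the
    suggestion is the nearest reference phenotype centroid.
    """
    r_sweet, _, _, r_flavour = np.asarray(centroid, dtype=float)
    if r_sweet > 0 and r_flavour > 0:
        return "HighSweetLiker", None
    if r_sweet > 0 and r_flavour < 0:
        return "ModerateSweetLiker", None
    if r_sweet < 0:
        return "InvertedUShaped", None
    d = ((REFERENCE_CENTROIDS.to_numpy() - np.asarray(centroid)) ** 2).sum(axis=1)
    return "Unlabeled", str(REFERENCE_CENTROIDS.index[int(d.argmin())])


@dataclass
class ClusterModel:
    """Fitted phenotype model plus bookkeeping for reporting."""

    k: int
    centroids: pd.DataFrame  # cluster index x R_COLUMNS
    assignments: pd.Series  # subject_id -> cluster index
    labels: dict  # cluster index -> phenotype name
    seed: int
    inertia: float
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["subject_id", "reason"])
    )

    @property
    def sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()


def kmeans_segment(
    vectors: pd.DataFrame,
    k: int = 3,
    restarts: int = 50,
    seed: int = 0,
    exclusions: pd.DataFrame | None = None,
) -> ClusterModel:
    """Segment correlation vectors into sweet-liker phenotypes."""
    est = SweetLikerKMeans(k=k, restarts=restarts, seed=seed).fit(
        vectors[R_COLUMNS].to_numpy()
    )
    centroids = pd.DataFrame(est.cluster_centers_, columns=R_COLUMNS)
    centroids.index.name = "cluster"
    return ClusterModel(
        k=k,
        centroids=centroids,
        assignments=pd.Series(est.labels_, index=vectors.index, name="cluster"),
        labels=dict(enumerate(est.phenotypes_)),
        seed=seed,
        inertia=est.inertia_,
        exclusions=exclusions
        if exclusions is not None
        else pd.DataFrame(columns=["subject_id", "reason"]),
    )


def label_phenotypes(model: ClusterModel) -> ClusterModel:
    """(Re)assign phenotype names to each cluster by the sign-pattern rule."""
    labels = {}
    for idx, row in model.centroids.iterrows():
        name, suggestion = label_centroid(row.to_numpy())
        labels[idx] = name if suggestion is None else f"Unlabeled(nearest={suggestion})"
    model.labels = labels
    return model


def segment_summary(model: ClusterModel, n_total: int | None = None) -> pd.DataFrame:
    """Per-cluster size, share of clustered subjects, and centroid.

    If ``n_total`` (the full cohort size) is given, a final row reports
    the excluded count and its fraction of the total.
    """
    sizes = model.sizes
    n_clustered = int(sizes.sum())
    rows = []
    for idx in sizes.index:
        rows.append(
            {
                "cluster": idx,
                "phenotype": model.labels.get(idx, ""),
                "n": int(sizes[idx]),
                "pct": 100.0 * sizes[idx] / n_clustered,
                **model.centroids.loc[idx].to_dict(),
            }
        )
    summary = pd.DataFrame(rows)
    if n_total is not None:
        excluded = n_total - n_clustered
        summary.loc[len(summary)] = {
            "cluster": -1,
            "phenotype": "excluded",
            "n": int(excluded),
            "pct": 100.0 * excluded / n_total,
            **{c: np.nan for c in R_COLUMNS},
        }
    return summary


def segment_ratings(
    ratings: RatingTable, k: int = 3, restarts: int = 50, seed: int = 0
) -> tuple[ClusterModel, pd.DataFrame]:
    """End-to-end: ratings -> correlation vectors -> labelled phenotypes."""
    vectors, exclusions = compute_correlation_vectors(ratings)
    model = kmeans_segment(vectors, k=k, restarts=restarts, seed=seed, exclusions=exclusions)
    return label_phenotypes(model), vectors
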