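"""Check-all-that-apply (CATA) product mapping.

The preliminary-study analysis pipeline: Cochran's Q screens each CATA
attribute for significant citation differences across products; the
product x attribute citation-count table of the retained attributes is
decomposed by correspondence analysis (CA); products are grouped by
k-means on their leading CA coordinates and the groups are named by the
nearest attribute pole (bitter/astringent, sweet, or intermediate);
finally an attribute's citation proportions are correlated with a
product-level polyphenol table.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

CATA_COLUMNS = ["respondent", "product", "attribute", "cited"]


@dataclass
class CATACube:
    """Binary citation data: respondent x product x attribute.

    Backed by a long DataFrame with columns ``respondent, product,
    attribute, cited`` (cited in {0, 1}), complete over the declared
    product and attribute lists.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CATA_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"CATA table missing columns: {missing}")
        self.records = self.records[CATA_COLUMNS].copy()
        vals = set(self.records["cited"].unique())
        if not vals <= {0, 1}:
            raise ValueError(f"citations must be 0/1, found {sorted(vals - {0, 1})}")
        counts = self.records.groupby(["respondent"]).size()
        expected = len(self.products) * len(self.attributes)
        bad = counts[counts != expected]
        if not bad.empty:
            raise ValueError(
                f"incomplete respondents (need {expected} cells): {list(bad.index[:5])}"
            )

    @property
    def products(self) -> list:
        return sorted(self.records["product"].unique())

    @property
    def attributes(self) -> list:
        return sorted(self.records["attribute"].unique())

    @property
    def n_respondents(self) -> int:
        return self.records["respondent"].nunique()

    def attribute_matrix(self, attribute: str) -> pd.DataFrame:
        """Respondent x product 0/1 matrix for one attribute."""
        sub = self.records[self.records["attribute"] == attribute]
        return sub.pivot(index="respondent", columns="product", values="cited")

    def citation_counts(self) -> pd.DataFrame:
        """Product x attribute citation totals (summed over respondents)."""
        return (
            self.records.pivot_table(
                index="product", columns="attribute", values="cited", aggfunc="sum"
            )
            .reindex(index=self.products, columns=self.attributes)
        )

    def citation_proportions(self) -> pd.DataFrame:
        return self.citation_counts() / self.n_respondents


def cochran_q(matrix) -> tuple[float, int, float]:
    """Cochran's Q for k matched binary treatments.

    ``matrix`` is respondents x k products of 0/1 citations. With column
    totals C_j and row totals R_i,

        Q = (k-1) * [k * sum(C_j^2) - (sum C_j)^2] / [k * sum(R_i) - sum(R_i^2)]

    referred to chi-square with k-1 df. Respondents citing none or all
    products contribute nothing to the denominator; if every respondent
    is constant the denominator vanishes and Q is undefined (NaN, with a
    warning).
    """
    X = np.asarray(pd.DataFrame(matrix), dtype=float)
    if not set(np.unique(X)) <= {0.0, 1.0}:
        raise ValueError("Cochran's Q requires a binary matrix")
    k = X.shape[1]
    C = X.sum(axis=0)
    R = X.sum(axis=1)
    denom = k * R.sum() - (R**2).sum()
    dof = k - 1
    if denom == 0:
        logger.warning("Cochran's Q undefined: every respondent row is constant")
        return float("nan"), dof, float("nan")
    Q = dof * (k * (C**2).sum() - C.sum() ** 2) / denom
    return float(Q), dof, float(stats.chi2.sf(Q, dof))


def screen_attributes(cube: CATACube, alpha: float = 0.05) -> pd.DataFrame:
    """Cochran's Q per attribute; ``retained`` marks p < alpha."""
    rows = []
    for attr in cube.attributes:
        Q, dof, p = cochran_q(cube.attribute_matrix(attr))
        rows.append(
            {"attribute": attr, "Q": Q, "df": dof, "p": p,
             "retained": bool(p < alpha) if np.isfinite(p) else False}
        )
    return pd.DataFrame(rows)


class CorrespondenceAnalysis(TransformerMixin, BaseEstimator):
    """Correspondence analysis of a two-way count table.

    The table of relative frequencies P = X/N is centred by its margin
    product and standardized, S = D_r^{-1/2} (P - r c') D_c^{-1/2}, then
    decomposed by SVD. Row and column principal coordinates are scaled
    by the singular values; per-axis inertia is the squared singular
    value, and total inertia times the grand total equals the table's
    Pearson chi-square.

    Attributes
    ----------
    row_coordinates_, column_coordinates_ : DataFrame
        Principal coordinates, axes ordered by inertia.
    singular_values_ : ndarray
    inertia_ : ndarray, per-axis principal inertias.
    total_inertia_ : float
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = pd.DataFrame(X).astype(float)
        if (X.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        N = X.to_numpy().sum()
        if N <= 0 or (X.sum(axis=1) <= 0).any() or (X.sum(axis=0) <= 0).any():
            raise ValueError("all margins must be positive")
        P = X.to_numpy() / N
        r = P.sum(axis=1)
        c = P.sum(axis=0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        U, sv, Vt = np.linalg.svd(S, full_matrices=False)
        keep = sv > 1e-12 * max(1.0, sv[0] if len(sv) else 1.0)
        U, sv, Vt = U[:, keep], sv[keep], Vt[keep]
        if self.n_components is not None:
            U, sv, Vt = U[:, : self.n_components], sv[: self.n_components], Vt[: self.n_components]

        axes = [f"F{i + 1}" for i in range(len(sv))]
        with np.errstate(divide="ignore", invalid="ignore"):
            rowc = (U * sv) / np.sqrt(r)[:, None]
            colc = (Vt.T * sv) / np.sqrt(c)[:, None]
        self.row_coordinates_ = pd.DataFrame(rowc, index=X.index, columns=axes)
        self.column_coordinates_ = pd.DataFrame(colc, index=X.columns, columns=axes)
        self.singular_values_ = sv
        self.inertia_ = sv**2
        self.total_inertia_ = float((S**2).sum())
        self.inertia_share_ = (
            self.inertia_ / self.total_inertia_
            if self.total_inertia_ > 0
            else np.zeros_like(sv)
        )
        self.row_masses_ = pd.Series(r, index=X.index)
        self.col_masses_ = pd.Series(c, index=X.columns)
        self.grand_total_ = float(N)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Project new rows (count profiles over the fitted columns)."""
        check_is_fitted(self, "column_coordinates_")
        X = pd.DataFrame(X).astype(float)
        profiles = X.to_numpy() / X.to_numpy().sum(axis=1, keepdims=True)
        # transition formula: f = profile @ standard column coordinates
        std_cols = self.column_coordinates_.to_numpy() / self.singular_values_
        return pd.DataFrame(
            profiles @ (std_cols * 1.0),
            index=X.index,
            columns=self.row_coordinates_.columns,
        )


GROUP_LABELS = ("more_bitter_astringent", "medium", "sweeter")


def assign_product_groups(
    ca: CorrespondenceAnalysis,
    k_groups: int = 3,
    seed: int = 0,
    restarts: int = 50,
    bitter_attributes=("bitter", "astringent"),
    sweet_attributes=("sweet",),
) -> pd.Series:
    """Group products on the first two CA axes and name the groups.

    K-means (seeded, multi-restart) partitions the product principal
    coordinates of the two leading axes into ``k_groups`` clusters; each
    cluster is then labelled by the pole nearest its centroid — the
    bitter/astringent attribute pole, the sweet attribute pole, or the
    origin (intermediate) — with a one-to-one matching so every label is
    used once. Because poles are located from the fitted attribute
    coordinates, the labelling is invariant under axis sign flips.
    """
    check_is_fitted(ca, "row_coordinates_")
    coords = ca.row_coordinates_.iloc[:, :2]
    if coords.shape[0] < k_groups:
        raise ValueError(f"need at least {k_groups} products, have {coords.shape[0]}")
    km = KMeans(
        n_clusters=k_groups, n_init=restarts, random_state=seed, init="random"
    ).fit(coords.to_numpy())

    colc = ca.column_coordinates_.iloc[:, :2]
    present_bitter = [a for a in bitter_attributes if a in colc.index]
    present_sweet = [a for a in sweet_attributes if a in colc.index]
    if not present_bitter or not present_sweet:
        raise ValueError("bitter/astringent and sweet attribute poles must be present")
    poles = np.vstack(
        [
            colc.loc[present_bitter].mean(axis=0).to_numpy(),
            np.zeros(2),
            colc.loc[present_sweet].mean(axis=0).to_numpy(),
        ]
    )
    dist = ((km.cluster_centers_[:, None, :] - poles[None, :, :]) ** 2).sum(axis=2)
    from scipy.optimize import linear_sum_assignment

    ci, pj = linear_sum_assignment(dist)
    label_of_cluster = {int(i): GROUP_LABELS[int(j)] for i, j in zip(ci, pj)}
    return pd.Series(
        [label_of_cluster[int(l)] for l in km.labels_],
        index=coords.index,
        name="group",
    )


def correlate_phenol(
    attribute_proportions: pd.Series, phenol: pd.Series
) -> tuple[float, float, int]:
    """Pearson correlation between citation proportions and phenol content.

    Products are matched by identifier; two-sided p-value from the t
    transform with n-2 degrees of freedom. Returns ``(r, p, n)``; r is
    NaN (with a warning) when either side has zero variance.
    """
    joined = pd.concat(
        [attribute_proportions.rename("prop"), phenol.rename("phenol")], axis=1
    ).dropna()
    n = len(joined)
    if n < 3:
        raise ValueError(f"need >= 3 matched products, have {n}")
    if (phenol.dropna() < 0).any():
        raise ValueError("phenol content must be non-negative")
    if joined["prop"].var() == 0 or joined["phenol"].var() == 0:
        logger.warning("zero variance: phenol correlation undefined")
        return float("nan"), float("nan"), n
    r, p = stats.pearsonr(joined["prop"], joined["phenol"])
    return float(r), float(p), n


def cata_report(
    cube: CATACube,
    phenol: pd.Series | None = None,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Full preliminary-study analysis: screen -> CA -> groups -> phenol."""
    screen = screen_attributes(cube, alpha=alpha)
    retained = list(screen.loc[screen["retained"], "attribute"])
    if len(retained) < 2:
        raise ValueError("fewer than two attributes survive Cochran's Q screening")
    counts = cube.citation_counts()[retained]
    ca = CorrespondenceAnalysis().fit(counts)
    groups = assign_product_groups(ca, seed=seed)
    out = {"screen": screen, "ca": ca, "groups": groups}
    if phenol is not None:
        props = cube.citation_proportions()
        rows = []
        for attr in retained:
            try:
                r, p, n = correlate_phenol(props[attr], phenol)
            except ValueError:
                continue
            rows.append({"attribute": attr, "r": r, "p": p, "n": n})
        out["phenol"] = pd.DataFrame(rows)
    return out
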