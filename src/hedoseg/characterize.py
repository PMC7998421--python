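"""Statistical battery for characterizing consumer phenotypes.

Covers the tests used to profile the clusters: factorial ANOVA with
Type III sums of squares, least-squares means and Bonferroni
compact-letter displays; one-way ANOVA; chi-square association with
per-cell Fisher-exact direction flags; Kruskal-Wallis with mean ranks;
and the Steel-Dwass-Critchlow-Fligner (SDCF) all-pairs nonparametric
procedure referred to the studentized-range distribution.

Sample ratings are treated as independent observations in the factorial
model (no repeated-measures correction), mirroring standard practice in
consumer-segmentation studies of this design.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05


# ---------------------------------------------------------------------------
# compact letter display
# ---------------------------------------------------------------------------

def letter_display(groups, pvalues: dict, alpha: float = ALPHA_DEFAULT) -> dict:
    """Compact letter display from a pairwise p-value map.

    Two groups share a letter iff their pairwise comparison is
    non-significant at ``alpha``. Letters are the maximal cliques of the
    non-significance graph, lettered a, b, c, ... in order of the best
    (first) group they contain.

    Parameters
    ----------
    groups : sequence
        Group identifiers in display order (typically by descending mean).
    pvalues : dict
        Mapping frozenset({g1, g2}) or tuple -> p-value; missing pairs
        are treated as non-significant.
    """
    groups = list(groups)
    k = len(groups)

    def pval(a, b):
        for key in (frozenset((a, b)), (a, b), (b, a)):
            if key in pvalues:
                return pvalues[key]
        return 1.0

    ns = {
        (i, j): pval(groups[i], groups[j]) >= alpha
        for i in range(k)
        for j in range(i + 1, k)
    }

    # maximal cliques by descending-size subset scan (k is small here)
    cliques: list[tuple] = []
    for size in range(k, 0, -1):
        for comb in itertools.combinations(range(k), size):
            if any(set(comb) <= set(c) for c in cliques):
                continue
            if all(ns[(a, b)] for a, b in itertools.combinations(comb, 2)):
                cliques.append(comb)
    cliques.sort(key=lambda c: c[0])

    letters: dict = {g: "" for g in groups}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for i in clique:
            letters[groups[i]] += letter
    return letters


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Fitted ANOVA: term table, residual bookkeeping, LS means, letters."""

    terms: pd.DataFrame  # name, df, ss, F, p
    residual_df: int
    residual_ss: float
    n_obs: int
    ls_means: pd.DataFrame
    letters: dict = field(default_factory=dict)

    @property
    def mse(self) -> float:
        return self.residual_ss / self.residual_df

    def check_df(self) -> bool:
        """Degree-of-freedom bookkeeping: sum of term df + residual = N-1."""
        return int(self.terms["df"].sum()) + self.residual_df == self.n_obs - 1


def one_way_anova(
    values, factor, alpha: float = ALPHA_DEFAULT
) -> AnovaResult:
    """Classical one-way ANOVA with Bonferroni pairwise letters.

    Groups with zero observations are dropped with a warning. LS means
    for a one-way layout are the group means; their standard errors use
    the pooled residual mean square.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "g": list(factor)}).dropna()
    counts = df.groupby("g").size()
    empty = [g for g in pd.unique(df["g"]) if counts.get(g, 0) == 0]
    if empty:
        logger.warning("dropping empty groups: %s", empty)
    levels = [g for g in counts.index if counts[g] > 0]
    if len(levels) < 2:
        raise ValueError("one-way ANOVA needs at least two non-empty groups")

    n = len(df)
    grand = df["y"].mean()
    means = df.groupby("g")["y"].mean()
    ss_between = float((counts * (means - grand) ** 2).sum())
    ss_within = float(((df["y"] - means.loc[df["g"]].to_numpy()) ** 2).sum())
    df_b = len(levels) - 1
    df_w = n - len(levels)
    if df_w < 1:
        raise ValueError("no residual degrees of freedom")
    if ss_within == 0:
        F = 0.0 if ss_between == 0 else np.inf
    else:
        F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0

    mse = ss_within / df_w
    ls = pd.DataFrame(
        {
            "level": levels,
            "n": [int(counts[g]) for g in levels],
            "mean": [means[g] for g in levels],
            "se": [np.sqrt(mse / counts[g]) for g in levels],
        }
    )

    pairs = {}
    m = len(levels)
    n_pairs = m * (m - 1) // 2
    for a, b in itertools.combinations(levels, 2):
        if mse == 0:
            praw = 1.0 if means[a] == means[b] else 0.0
        else:
            t = (means[a] - means[b]) / np.sqrt(mse * (1 / counts[a] + 1 / counts[b]))
            praw = 2 * stats.t.sf(abs(t), df_w)
        pairs[frozenset((a, b))] = min(1.0, praw * n_pairs)

    order = sorted(levels, key=lambda g: -means[g])
    letters = letter_display(order, pairs, alpha)

    terms = pd.DataFrame(
        [{"name": "group", "df": df_b, "ss": ss_between, "F": F, "p": p}]
    )
    return AnovaResult(terms, df_w, ss_within, n, ls, letters)


def two_way_anova(
    values, factor_a, factor_b, alpha: float = ALPHA_DEFAULT,
    names: tuple = ("A", "B"),
) -> AnovaResult:
    """Two-way factorial ANOVA with Type III sums of squares.

    The full model ``y ~ A + B + A:B`` is fitted with effects (sum)
    coding; each Type III term SS is the increase in residual SS when
    that term's columns are deleted from the full model. LS means are
    averages of cell means over the other factor's levels, and the
    Bonferroni letter display compares levels of ``A`` within each level
    of ``B`` (the comparison family shown in liking-curve figures).

    Raises on any empty cell (Type III inestimable there).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {"y": np.asarray(values, dtype=float), "a": list(factor_a), "b": list(factor_b)}
    ).dropna()
    cell_n = df.groupby(["a", "b"]).size().unstack(fill_value=0)
    if (cell_n == 0).any().any():
        empty = [
            (a, b)
            for a in cell_n.index
            for b in cell_n.columns
            if cell_n.loc[a, b] == 0
        ]
        raise ValueError(f"empty cells make Type III SS inestimable: {empty}")

    model = smf.ols("y ~ C(a, Sum) * C(b, Sum)", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = sm.stats.anova_lm(model, typ=3)

    rename = {
        "C(a, Sum)": names[0],
        "C(b, Sum)": names[1],
        "C(a, Sum):C(b, Sum)": f"{names[0]}:{names[1]}",
    }
    terms = []
    for row_name, row in table.iterrows():
        if row_name in ("Intercept", "Residual"):
            continue
        terms.append(
            {
                "name": rename.get(row_name, row_name),
                "df": int(row["df"]),
                "ss": float(row["sum_sq"]),
                "F": float(row["F"]),
                "p": float(row["PR(>F)"]),
            }
        )
    terms = pd.DataFrame(terms)
    residual_df = int(table.loc["Residual", "df"])
    residual_ss = float(table.loc["Residual", "sum_sq"])
    mse = residual_ss / residual_df

    cell_means = df.groupby(["a", "b"])["y"].mean().unstack()
    a_levels, b_levels = list(cell_means.index), list(cell_means.columns)

    ls_rows = []
    for a in a_levels:
        var = mse * (1 / cell_n.loc[a]).sum() / len(b_levels) ** 2
        ls_rows.append(
            {"factor": names[0], "level": a,
             "ls_mean": cell_means.loc[a].mean(), "se": np.sqrt(var)}
        )
    for b in b_levels:
        var = mse * (1 / cell_n[b]).sum() / len(a_levels) ** 2
        ls_rows.append(
            {"factor": names[1], "level": b,
             "ls_mean": cell_means[b].mean(), "se": np.sqrt(var)}
        )
    ls_means = pd.DataFrame(ls_rows)

    # letters: compare A levels within each B level, Bonferroni over the
    # displayed family (the A pairs at that B level)
    letters = {}
    n_pairs = len(a_levels) * (len(a_levels) - 1) // 2
    for b in b_levels:
        pairs = {}
        for a1, a2 in itertools.combinations(a_levels, 2):
            diff = cell_means.loc[a1, b] - cell_means.loc[a2, b]
            if mse == 0:
                praw = 1.0 if diff == 0 else 0.0
            else:
                se = np.sqrt(mse * (1 / cell_n.loc[a1, b] + 1 / cell_n.loc[a2, b]))
                praw = 2 * stats.t.sf(abs(diff) / se, residual_df)
            pairs[frozenset((a1, a2))] = min(1.0, praw * n_pairs)
        order = sorted(a_levels, key=lambda a: -cell_means.loc[a, b])
        letters[b] = letter_display(order, pairs, alpha)

    return AnovaResult(terms, residual_df, residual_ss, len(df), ls_means, letters)


# ---------------------------------------------------------------------------
# chi-square association with per-cell Fisher flags
# ---------------------------------------------------------------------------

@dataclass
class ContingencyResult:
    observed: pd.DataFrame
    expected: pd.DataFrame
    chi2: float
    df: int
    p: float
    contributions: pd.DataFrame
    std_residuals: pd.DataFrame
    flags: pd.DataFrame  # '<', '>' or ''
    cell_p: pd.DataFrame


def chi_square_association(
    table, alpha: float = ALPHA_DEFAULT
) -> ContingencyResult:
    """Pearson chi-square on an r x c count table with per-cell tests.

    Each cell gets a direction flag: ``>`` when observed exceeds
    expected and the per-cell test is significant at ``alpha``, ``<``
    symmetrically, empty otherwise. The per-cell test is a Fisher exact
    test on the 2x2 collapse of the table (cell vs rest of row / rest of
    column). Adjusted standardized residuals are reported alongside.
    """
    obs = pd.DataFrame(table).astype(float)
    if (obs.to_numpy() < 0).any() or not np.allclose(
        obs.to_numpy(), np.round(obs.to_numpy())
    ):
        raise ValueError("counts must be non-negative integers")
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValueError("all row and column margins must be positive")

    N = obs.to_numpy().sum()
    row = obs.sum(axis=1).to_numpy()
    col = obs.sum(axis=0).to_numpy()
    expected = pd.DataFrame(
        np.outer(row, col) / N, index=obs.index, columns=obs.columns
    )
    contrib = (obs - expected) ** 2 / expected
    chi2 = float(contrib.to_numpy().sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, dof)) if dof > 0 else 1.0

    with np.errstate(invalid="ignore"):
        std_res = (obs - expected) / np.sqrt(
            expected
            * (1 - row[:, None] / N)
            * (1 - col[None, :] / N)
        )

    flags = pd.DataFrame("", index=obs.index, columns=obs.columns)
    cell_p = pd.DataFrame(np.nan, index=obs.index, columns=obs.columns)
    O = obs.to_numpy()
    for i in range(obs.shape[0]):
        for j in range(obs.shape[1]):
            o = O[i, j]
            two_by_two = np.array(
                [[o, row[i] - o], [col[j] - o, N - row[i] - col[j] + o]]
            )
            _, pf = stats.fisher_exact(two_by_two.astype(int))
            cell_p.iat[i, j] = pf
            if pf < alpha:
                e = expected.iat[i, j]
                if o > e:
                    flags.iat[i, j] = ">"
                elif o < e:
                    flags.iat[i, j] = "<"
    return ContingencyResult(obs, expected, chi2, dof, p, contrib, std_res, flags, cell_p)


# ---------------------------------------------------------------------------
# Kruskal-Wallis and Steel-Dwass-Critchlow-Fligner
# ---------------------------------------------------------------------------

@dataclass
class RankTestResult:
    H: float
    df: int
    p: float
    mean_ranks: pd.Series
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)
    letters: dict = field(default_factory=dict)


def kruskal_wallis(values, groups) -> RankTestResult:
    """Tie-corrected Kruskal-Wallis H with per-group mean ranks.

    Mid-ranks over the pooled sample; the chi-square approximation with
    k-1 degrees of freedom gives the p-value. Per-group mean ranks are
    reported, the convention used for familiarity comparisons. If every
    value is identical, H = 0 is reported with a warning (the tie
    correction factor would vanish).
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "g": list(groups)}).dropna()
    levels = list(pd.unique(df["g"]))
    if len(levels) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    N = len(df)
    ranks = stats.rankdata(df["y"].to_numpy())
    df = df.assign(rank=ranks)
    mean_ranks = df.groupby("g")["rank"].mean().reindex(levels)
    ns = df.groupby("g").size().reindex(levels)

    H = 12.0 / (N * (N + 1)) * float((ns * (mean_ranks - (N + 1) / 2) ** 2).sum())
    _, tie_counts = np.unique(df["y"].to_numpy(), return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    denom = 1.0 - tie_term / (N**3 - N)
    if denom == 0:
        logger.warning("all values identical; H reported as 0")
        H = 0.0
    else:
        H /= denom
    dof = len(levels) - 1
    p = float(stats.chi2.sf(H, dof))
    return RankTestResult(H, dof, p, mean_ranks)


def _pairwise_z(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized Wilcoxon rank-sum on the jointly ranked pair.

    Mid-ranks with tie-corrected variance; returns z for group ``x``.
    """
    n1, n2 = len(x), len(y)
    N = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    W = ranks[:n1].sum()
    EW = n1 * (N + 1) / 2.0
    _, t = np.unique(pooled, return_counts=True)
    tie = float((t**3 - t).sum())
    varW = n1 * n2 / 12.0 * ((N + 1) - tie / (N * (N - 1)))
    if varW == 0:
        return 0.0
    return float((W - EW) / np.sqrt(varW))


def sdcf_pairwise(
    values,
    groups,
    alpha: float = ALPHA_DEFAULT,
    method: str = "asymptotic",
    n_perm: int = 20000,
    seed: int = 0,
) -> RankTestResult:
    """Steel-Dwass-Critchlow-Fligner all-pairs comparisons.

    For each pair of groups the two samples are re-ranked jointly
    (mid-ranks, tie-corrected variance), the Wilcoxon statistic is
    standardized to z, and ``q = sqrt(2)|z|`` is referred to the
    studentized-range distribution with k groups and infinite degrees of
    freedom. This asymptotic reference is standard for per-group sizes
    above ~8; ``method='permutation'`` instead refers each q to the
    seeded Monte-Carlo permutation distribution of the maximum pairwise
    q under joint relabelling (single-step max-q adjustment), for small
    samples.

    Groups of size < 2 have their pairs skipped with a warning.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "g": list(groups)}).dropna()
    levels = list(pd.unique(df["g"]))
    k = len(levels)
    if k < 2:
        raise ValueError("SDCF needs at least two groups")
    data = {g: df.loc[df["g"] == g, "y"].to_numpy() for g in levels}

    rows = []
    for a, b in itertools.combinations(levels, 2):
        if len(data[a]) < 2 or len(data[b]) < 2:
            logger.warning("skipping pair (%s, %s): group of size < 2", a, b)
            continue
        z = _pairwise_z(data[a], data[b])
        q = np.sqrt(2.0) * abs(z)
        rows.append({"group1": a, "group2": b, "z": z, "q": q})
    pairwise = pd.DataFrame(rows)

    if method == "asymptotic":
        pairwise["p"] = [
            float(stats.studentized_range.sf(q, k, np.inf)) for q in pairwise["q"]
        ]
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = df["y"].to_numpy()
        sizes = [len(data[g]) for g in levels]
        cuts = np.cumsum(sizes)[:-1]
        max_q = np.empty(n_perm)
        for it in range(n_perm):
            perm = rng.permutation(pooled)
            parts = np.split(perm, cuts)
            qs = [
                np.sqrt(2.0) * abs(_pairwise_z(parts[i], parts[j]))
                for i, j in itertools.combinations(range(k), 2)
            ]
            max_q[it] = max(qs)
        pairwise["p"] = [
            float((np.sum(max_q >= q) + 1) / (n_perm + 1)) for q in pairwise["q"]
        ]
    else:
        raise ValueError(f"unknown method {method!r}")

    kw = kruskal_wallis(df["y"], df["g"])
    pmap = {
        frozenset((r["group1"], r["group2"])): r["p"] for _, r in pairwise.iterrows()
    }
    order = sorted(levels, key=lambda g: -kw.mean_ranks[g])
    letters = letter_display(order, pmap, alpha)
    return RankTestResult(kw.H, kw.df, kw.p, kw.mean_ranks, pairwise, letters)


# ---------------------------------------------------------------------------
# stated liking with a "never tasted" option
# ---------------------------------------------------------------------------

def liking_with_never_tasted(
    responses: pd.DataFrame,
    never_tasted="never_tasted",
    item_col: str = "item",
    response_col: str = "response",
) -> pd.DataFrame:
    """Summarize 9-point stated-liking items that allow "never tasted it".

    Never-tasted responses are removed from the liking statistics and
    reported as a per-item percentage. With every response never-tasted
    the mean is undefined (NaN) and 100% is reported.
    """
    rows = []
    for item, grp in responses.groupby(item_col, sort=False):
        resp = grp[response_col]
        nt = resp.eq(never_tasted) | resp.isna()
        liked = pd.to_numeric(resp[~nt], errors="raise")
        rows.append(
            {
                "item": item,
                "n": int(len(liked)),
                "mean": float(liked.mean()) if len(liked) else float("nan"),
                "pct_never_tasted": 100.0 * float(nt.mean()),
            }
        )
    return pd.DataFrame(rows)
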