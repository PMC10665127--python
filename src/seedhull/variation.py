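"""Germplasm-variation statistics over seed trait tables.

Works on a tidy trait table (one row per seed) with ``variety`` and
``group`` labels and the nine trait columns.  Provides

* PCV — phenotypic coefficient of variation, 100 * SD / mean per trait,
* pooled or per-variety summary tables (mean / min / max / SD / PCV),
* a balanced-or-not two-level nested ANOVA (varieties nested in germplasm
  groups, seeds as residual replication), built from definitional sums of
  squares,
* GVF — the genetic variation factor comparing summed parental trait
  variance with each offspring variety's variance, normalised by the summed
  parental mean:  GVF = 100 * sqrt(|Var(P1) + Var(P2) - Var(F)|) /
  (mean(P1) + mean(P2)), population-variance convention,
* clustering of seeds into hybridisation batches with permutation-optimal
  precision scoring (evaluation plumbing around scikit-learn).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import linear_sum_assignment

from .errors import (
    DegenerateClustering,
    InsufficientReplication,
    MissingParent,
    TooFewValues,
    ZeroMean,
    ZeroParentMean,
)

__all__ = [
    "TRAIT_COLUMNS",
    "pcv",
    "summarize_traits",
    "AnovaResult",
    "nested_anova",
    "gvf",
    "GvfResult",
    "gvf_table",
    "cluster_and_score",
]

TRAIT_COLUMNS = [
    "length",
    "width",
    "thickness",
    "surface_area",
    "volume",
    "projection_area",
    "roundness",
    "cardioid_area",
    "j_index",
]


def _trait_columns(table: pd.DataFrame) -> list[str]:
    cols = [c for c in TRAIT_COLUMNS if c in table.columns]
    if not cols:
        raise ValueError("table has none of the expected trait columns")
    return cols


def pcv(values, ddof: int = 1) -> float:
    """Phenotypic coefficient of variation: 100 * SD / mean (percent).

    Sample SD (n-1 denominator) by default, matching summary-table
    convention.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise TooFewValues("PCV needs at least 2 values")
    m = x.mean()
    if m == 0:
        raise ZeroMean("PCV undefined for zero mean")
    return float(100.0 * x.std(ddof=ddof) / m)


def summarize_traits(table: pd.DataFrame, scope: str = "pooled") -> pd.DataFrame:
    """Per-trait mean / min / max / SD / PCV summary.

    ``scope='pooled'`` summarises all seeds together; ``'per-variety'``
    returns one block per variety.  PCVs are reported in percent; sort the
    result by PCV to rank trait variability.
    """
    cols = _trait_columns(table)

    def one(df: pd.DataFrame, label: str | None) -> pd.DataFrame:
        rec = []
        for c in cols:
            x = df[c].to_numpy(dtype=float)
            rec.append(
                {
                    **({"variety": label} if label is not None else {}),
                    "trait": c,
                    "mean": x.mean(),
                    "min": x.min(),
                    "max": x.max(),
                    "sd": x.std(ddof=1),
                    "pcv": pcv(x),
                }
            )
        return pd.DataFrame(rec)

    if scope == "pooled":
        return one(table, None)
    if scope == "per-variety":
        return pd.concat(
            [one(g, v) for v, g in table.groupby("variety", sort=True)],
            ignore_index=True,
        )
    raise ValueError("scope must be 'pooled' or 'per-variety'")


@dataclass(frozen=True)
class AnovaResult:
    """Two-level nested ANOVA for all traits.

    ``table`` has one row per trait with sums of squares, degrees of
    freedom, mean squares, F statistics (each effect over the residual mean
    square) and P values; ``all_equal`` flags traits whose observations were
    constant (F undefined, reported as NaN).
    """

    table: pd.DataFrame

    def __getitem__(self, trait: str) -> pd.Series:
        return self.table.set_index("trait").loc[trait]


def nested_anova(
    table: pd.DataFrame, group_col: str = "group", variety_col: str = "variety"
) -> AnovaResult:
    """Nested variance decomposition: among groups / varieties in groups / error.

    Sums of squares are definitional:

    * SS_among = sum_g n_g (mean_g - grand)^2
    * SS_within = sum_g sum_v n_gv (mean_gv - mean_g)^2
    * SS_error = sum (y - mean_gv)^2

    and always satisfy SS_total = SS_among + SS_within + SS_error.
    """
    groups = table[group_col].unique()
    if len(groups) < 2:
        raise InsufficientReplication("need >= 2 germplasm groups")
    for g, sub in table.groupby(group_col):
        if sub[variety_col].nunique() < 2:
            raise InsufficientReplication(f"group {g!r} needs >= 2 varieties")
    for v, sub in table.groupby(variety_col):
        if len(sub) < 2:
            raise InsufficientReplication(f"variety {v!r} needs >= 2 seeds")

    n_total = len(table)
    n_groups = len(groups)
    n_varieties = table.groupby(group_col)[variety_col].nunique().sum()
    df_among = n_groups - 1
    df_within = int(n_varieties - n_groups)
    df_error = int(n_total - n_varieties)

    rec = []
    for trait in _trait_columns(table):
        y = table[trait].to_numpy(dtype=float)
        grand = y.mean()
        ss_among = ss_within = ss_error = 0.0
        for _, sub in table.groupby(group_col):
            yg = sub[trait].to_numpy(dtype=float)
            gm = yg.mean()
            ss_among += len(yg) * (gm - grand) ** 2
            for _, vv in sub.groupby(variety_col):
                yv = vv[trait].to_numpy(dtype=float)
                vm = yv.mean()
                ss_within += len(yv) * (vm - gm) ** 2
                ss_error += float(((yv - vm) ** 2).sum())
        ms_among = ss_among / df_among
        ms_within = ss_within / df_within
        ms_error = ss_error / df_error
        all_equal = np.ptp(y) == 0
        if ms_error > 0:
            f_among = ms_among / ms_error
            f_within = ms_within / ms_error
            p_among = float(sps.f.sf(f_among, df_among, df_error))
            p_within = float(sps.f.sf(f_within, df_within, df_error))
        else:
            f_among = f_within = p_among = p_within = float("nan")
        rec.append(
            {
                "trait": trait,
                "ss_among": ss_among,
                "ss_within": ss_within,
                "ss_error": ss_error,
                "df_among": df_among,
                "df_within": df_within,
                "df_error": df_error,
                "ms_among": ms_among,
                "ms_within": ms_within,
                "ms_error": ms_error,
                "f_among": f_among,
                "f_within": f_within,
                "p_among": p_among,
                "p_within": p_within,
                "all_equal": bool(all_equal),
            }
        )
    return AnovaResult(table=pd.DataFrame(rec))


def gvf(p1, p2, f_i) -> float:
    """Genetic variation factor (percent) for one trait and one offspring.

    GVF = 100 * sqrt(|Var(P1) + Var(P2) - Var(F)|) / (mean(P1) + mean(P2)),
    with population variances (1/N).  The summed parental variance stands
    for the variance of the sum of independent parental samples; the
    absolute value guards the square root when the offspring variance
    exceeds the parental one.
    """
    arrs = [np.asarray(v, dtype=float) for v in (p1, p2, f_i)]
    if any(a.size < 2 for a in arrs):
        raise TooFewValues("GVF needs >= 2 values per sample")
    a1, a2, af = arrs
    denom = a1.mean() + a2.mean()
    if denom == 0:
        raise ZeroParentMean("summed parental mean is zero")
    diff = a1.var() + a2.var() - af.var()
    return float(100.0 * np.sqrt(abs(diff)) / denom)


@dataclass(frozen=True)
class GvfResult:
    """GVF matrix: rows = traits, columns = offspring varieties.

    ``averages`` holds the per-variety mean over the nine traits and
    ``ranking`` the offspring varieties sorted by decreasing average GVF.
    """

    matrix: pd.DataFrame
    averages: pd.Series
    ranking: list[str]


def gvf_table(
    table: pd.DataFrame,
    parent_labels: tuple[str, str] | list[str],
    offspring_labels: list[str] | None = None,
) -> GvfResult:
    """GVF percentages for every trait and offspring variety."""
    p1_label, p2_label = parent_labels
    varieties = set(table["variety"])
    for p in (p1_label, p2_label):
        if p not in varieties:
            raise MissingParent(f"parent variety {p!r} not in table")
    if offspring_labels is None:
        offspring_labels = sorted(varieties - {p1_label, p2_label})
    if not offspring_labels:
        raise MissingParent("no offspring varieties")
    cols = _trait_columns(table)
    p1 = table[table["variety"] == p1_label]
    p2 = table[table["variety"] == p2_label]
    data = {}
    for off in offspring_labels:
        sub = table[table["variety"] == off]
        if sub.empty:
            raise MissingParent(f"offspring variety {off!r} not in table")
        data[off] = [gvf(p1[c], p2[c], sub[c]) for c in cols]
    matrix = pd.DataFrame(data, index=cols)
    averages = matrix.mean(axis=0)
    ranking = list(averages.sort_values(ascending=False).index)
    return GvfResult(matrix=matrix, averages=averages, ranking=ranking)


def cluster_and_score(
    table: pd.DataFrame,
    method: str = "kmeans",
    k: int = 2,
    label_col: str = "group",
    random_state: int = 0,
    dbscan_eps: float = 1.0,
    dbscan_min_samples: int = 5,
) -> tuple[np.ndarray, float]:
    """Cluster seeds on standardized traits and score against true groups.

    Returns (labels, precision) where precision is the fraction of seeds
    correctly assigned after the optimal cluster-to-group permutation
    (Hungarian matching on the confusion matrix), so it is invariant to
    cluster relabelling.
    """
    from sklearn.cluster import DBSCAN, AgglomerativeClustering, KMeans
    from sklearn.preprocessing import StandardScaler

    cols = _trait_columns(table)
    X = table[cols].to_numpy(dtype=float)
    if len(np.unique(X, axis=0)) < k:
        raise DegenerateClustering(f"fewer than k={k} distinct points")
    Xs = StandardScaler().fit_transform(X)
    if method == "kmeans":
        labels = KMeans(n_clusters=k, n_init=10, random_state=random_state).fit_predict(Xs)
    elif method == "hierarchical":
        labels = AgglomerativeClustering(n_clusters=k).fit_predict(Xs)
    elif method == "dbscan":
        labels = DBSCAN(eps=dbscan_eps, min_samples=dbscan_min_samples).fit_predict(Xs)
    else:
        raise ValueError("method must be kmeans, hierarchical or dbscan")
    nonempty = np.unique(labels[labels >= 0])
    if len(nonempty) < k:
        raise DegenerateClustering(
            f"{method} produced {len(nonempty)} nonempty clusters, needed {k}"
        )
    truth = pd.factorize(table[label_col])[0]
    pred = labels.copy()
    pred[pred < 0] = len(nonempty)  # DBSCAN noise becomes its own bin
    conf = np.zeros((pred.max() + 1, truth.max() + 1))
    for p, t in zip(pred, truth):
        conf[p, t] += 1
    rows, colsi = linear_sum_assignment(-conf)
    precision = float(conf[rows, colsi].sum() / len(truth))
    return labels, precision
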