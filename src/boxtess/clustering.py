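"""Covariation and cluster analysis of scute morphology.

Pipeline: drop scutes without a computable plane-based area; size-correct
each dimensioned variable by SA^slope; natural-log transform everything
except the number of neighbors (curvature columns are first shifted to
be positive: x − min(x) + 0.001); remove extreme outliers; standardize;
PCA on the correlation structure; Ward hierarchical clustering on the
PC scores; per-cluster summaries and per-specimen cluster frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .morphometrics import MISSING_FLAG

#: the eight scute variables entering the multivariate analysis
CLUSTER_VARIABLES = ["n_neighbors", "volume", "area", "thickness",
                     "width", "aspect_ratio", "cgs", "cms"]

#: exponent key per dimensioned variable (n_neighbors enters raw)
_NORMALIZED = ["volume", "area", "thickness", "width", "aspect_ratio",
               "cgs", "cms"]

#: columns shifted positive before the log (normalized curvature can be
#: negative)
_SHIFT_LOG = ["cgs", "cms"]
SHIFT_CONSTANT = 0.001


@dataclass
class ScuteMatrix:
    """Standardized scute-variable matrix plus row provenance.

    ``data`` has one row per retained scute (mean 0, sd 1 per column);
    ``dropped`` records every removed row with its reason
    (area_missing | area_zero | outlier | missing_sa).
    """

    data: pd.DataFrame
    meta: pd.DataFrame          # specimen, scute_id per retained row
    dropped: pd.DataFrame       # specimen, scute_id, reason
    column_means: pd.Series = None
    column_sds: pd.Series = None


@dataclass
class ClusterModel:
    pc_scores: np.ndarray
    pc_loadings: pd.DataFrame       # variables × PCs, as correlations
    variance_explained: np.ndarray  # percent per PC, sums to 100
    linkage: np.ndarray
    k: int
    assignment: np.ndarray
    meta: pd.DataFrame = None
    summaries: pd.DataFrame = None
    frequencies: pd.DataFrame = None


def prepare_matrix(records: pd.DataFrame, sa_by_specimen: dict,
                   exponents: dict, mad_factor: float = 8.0) -> ScuteMatrix:
    """Filter, normalize, transform and standardize the scute table.

    ``exponents`` maps each dimensioned variable to its fitted scaling
    slope against SA.  Outliers are rows whose transformed value lies
    beyond median ± ``mad_factor`` × MAD in any column; dropped rows are
    reported, never silently discarded.
    """
    df = records.copy()
    dropped = []

    no_sa = ~df["specimen"].isin(sa_by_specimen)
    if no_sa.any():
        warnings.warn(f"{int(no_sa.sum())} scutes excluded: no SA for "
                      f"their specimen", stacklevel=2)
        for _, r in df[no_sa].iterrows():
            dropped.append((r["specimen"], r["scute_id"], "missing_sa"))
        df = df[~no_sa]

    miss = df["area"] == MISSING_FLAG
    zero = df["area"] == 0
    for _, r in df[miss].iterrows():
        dropped.append((r["specimen"], r["scute_id"], "area_missing"))
    for _, r in df[zero].iterrows():
        dropped.append((r["specimen"], r["scute_id"], "area_zero"))
    df = df[~(miss | zero)].copy()

    sa = df["specimen"].map(sa_by_specimen).to_numpy(dtype=float)
    for var in _NORMALIZED:
        if var not in exponents:
            raise KeyError(f"no scaling exponent for variable {var!r}")
        df[var] = df[var].to_numpy(dtype=float) / sa ** exponents[var]

    for var in CLUSTER_VARIABLES:
        if var == "n_neighbors":
            continue
        col = df[var].to_numpy(dtype=float)
        if var in _SHIFT_LOG:
            col = col - col.min() + SHIFT_CONSTANT
        elif np.any(col <= 0):
            # guard: shift any unexpectedly non-positive column too
            col = col - col.min() + SHIFT_CONSTANT
        df[var] = np.log(col)

    X = df[CLUSTER_VARIABLES].to_numpy(dtype=float)
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    mad = np.where(mad == 0, np.inf, mad)  # constant column: no outliers
    out_rows = np.any(np.abs(X - med) > mad_factor * mad, axis=1)
    for _, r in df[out_rows].iterrows():
        dropped.append((r["specimen"], r["scute_id"], "outlier"))
    df = df[~out_rows]
    X = X[~out_rows]

    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    sds = np.where(sds == 0, 1.0, sds)
    Z = (X - means) / sds
    data = pd.DataFrame(Z, columns=CLUSTER_VARIABLES, index=df.index)
    meta = df[["specimen", "scute_id"]].reset_index(drop=True)
    data = data.reset_index(drop=True)
    return ScuteMatrix(
        data=data, meta=meta,
        dropped=pd.DataFrame(dropped,
                             columns=["specimen", "scute_id", "reason"]),
        column_means=pd.Series(means, index=CLUSTER_VARIABLES),
        column_sds=pd.Series(sds, index=CLUSTER_VARIABLES))


def run_pca(matrix: ScuteMatrix):
    """PCA of the standardized matrix.

    Returns (scores, loadings, variance_explained).  Loadings are
    variable–PC Pearson correlations; each PC's sign is fixed so its
    largest-magnitude loading is positive.
    """
    Z = matrix.data.to_numpy(dtype=float)
    n, p = Z.shape
    if np.linalg.matrix_rank(Z) < p:
        warnings.warn("standardized matrix is rank-deficient; PCA "
                      "proceeds on the singular directions", stacklevel=2)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U * S
    eigvals = S ** 2 / n
    var_exp = 100.0 * eigvals / eigvals.sum()
    # loadings as correlations between variables and scores
    load = Vt.T * np.sqrt(eigvals)  # columns standardized => this is PCC
    for j in range(load.shape[1]):
        i = np.argmax(np.abs(load[:, j]))
        if load[i, j] < 0:
            load[:, j] = -load[:, j]
            scores[:, j] = -scores[:, j]
    loadings = pd.DataFrame(
        load, index=matrix.data.columns,
        columns=[f"PC{j + 1}" for j in range(load.shape[1])])
    return scores, loadings, var_exp


def correlation_panel(matrix: ScuteMatrix) -> pd.DataFrame:
    """Pairwise Pearson correlation table of the prepared variables."""
    return matrix.data.corr(method="pearson")


def hierarchical_clusters(scores: np.ndarray, k: int = 5,
                          meta: pd.DataFrame | None = None,
                          loadings: pd.DataFrame | None = None,
                          variance_explained: np.ndarray | None = None,
                          consolidate: bool = False,
                          random_state: int = 0) -> ClusterModel:
    """Ward-linkage agglomeration on PC scores, cut at ``k`` clusters.

    Merge heights are kept in ``linkage`` so the relative-branch-length
    criterion for choosing k can be inspected.  ``consolidate`` runs an
    optional k-means refinement seeded at the cluster centroids (off by
    default).  Cluster labels are renumbered 1..k by descending size.
    """
    scores = np.asarray(scores, dtype=float)
    if k > len(scores):
        raise ValueError("k exceeds the number of scutes")
    Zl = hierarchy.linkage(scores, method="ward")
    raw = hierarchy.fcluster(Zl, t=k, criterion="maxclust")
    if consolidate:
        from sklearn.cluster import KMeans
        centroids = np.array([scores[raw == c].mean(axis=0)
                              for c in np.unique(raw)])
        km = KMeans(n_clusters=len(centroids), init=centroids, n_init=1,
                    random_state=random_state).fit(scores)
        raw = km.labels_ + 1
    # stable renumbering by size
    sizes = pd.Series(raw).value_counts()
    order = {old: new + 1 for new, old in enumerate(sizes.index)}
    assignment = np.array([order[c] for c in raw])
    return ClusterModel(pc_scores=scores, pc_loadings=loadings,
                        variance_explained=variance_explained,
                        linkage=Zl, k=k, assignment=assignment, meta=meta)


def cluster_summaries(model: ClusterModel,
                      matrix: ScuteMatrix) -> ClusterModel:
    """Per-cluster boxplot statistics and per-specimen frequencies.

    Boxplot statistics are on the standardized variables (units =
    global standard deviations), so a cluster whose mean |z| exceeds 2
    in some variable is an outlier cluster in that variable.
    """
    df = matrix.data.copy()
    df["cluster"] = model.assignment
    stats_rows = []
    for c, grp in df.groupby("cluster"):
        for var in matrix.data.columns:
            v = grp[var]
            stats_rows.append({
                "cluster": c, "variable": var, "n": len(v),
                "mean": v.mean(), "median": v.median(),
                "q1": v.quantile(0.25), "q3": v.quantile(0.75),
                "min": v.min(), "max": v.max(),
                "outlier_cluster": bool(abs(v.mean()) > 2),
            })
    summaries = pd.DataFrame(stats_rows)

    freq = pd.DataFrame({
        "specimen": model.meta["specimen"].to_numpy(),
        "cluster": model.assignment,
    })
    counts = (freq.groupby(["specimen", "cluster"]).size()
              .unstack(fill_value=0))
    props = counts.div(counts.sum(axis=1), axis=0)
    counts.columns = [f"count_{c}" for c in counts.columns]
    props.columns = [f"prop_{c}" for c in props.columns]
    frequencies = counts.join(props).reset_index()
    model.summaries = summaries
    model.frequencies = frequencies
    return model


def full_rank_distance_check(matrix: ScuteMatrix, scores: np.ndarray,
                             n_sample: int = 200,
                             seed: int = 0) -> float:
    """Max |PC distance − standardized distance| over sampled pairs.

    With all PCs kept the PCA is an isometry of the standardized data;
    used as an internal consistency diagnostic.
    """
    rng = np.random.default_rng(seed)
    n = len(scores)
    idx = rng.choice(n, size=min(n, n_sample), replace=False)
    d1 = pdist(matrix.data.to_numpy()[idx])
    d2 = pdist(np.asarray(scores)[idx])
    return float(np.max(np.abs(d1 - d2)))
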