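"""K-means partitioning of bottom phases and backwards stepwise confirmation.

Per-dive bottom-use metrics are z-scored, partitioned by seeded multi-restart
k-means (the Lloyd algorithm with ``n_restarts`` initialisations, equivalent
in objective to Hartigan-Wong up to local optima; the best within-cluster
sum of squares is kept), and the number of clusters is chosen by the average
silhouette width over a k range (ties broken toward smaller k).

For two clusters, a backwards stepwise least-squares regression of the 0/1
cluster indicator on the z-scored predictors iteratively removes the single
least significant term with p > alpha; the clustering is then re-run on the
retained predictors until the predictor set is stable ("most parsimonious
model").  A logistic variant is available behind ``family='logistic'``.

The sklearn-style estimator :class:`BottomUseClusterer` wraps the whole loop;
the module-level functions are thin wrappers suitable for scripting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples, silhouette_score

log = logging.getLogger(__name__)


@dataclass
class StandardizedMatrix:
    """Z-scored predictor matrix with the column stats needed to invert it."""

    Z: pd.DataFrame
    means: pd.Series
    sds: pd.Series

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return (X[self.Z.columns] - self.means) / self.sds

    def inverse(self, Z: pd.DataFrame) -> pd.DataFrame:
        return Z * self.sds + self.means


@dataclass
class ClusterSolution:
    k: int
    assignments: np.ndarray
    centroids: pd.DataFrame          # k x p, z-space
    wcss: float
    bcss: float
    total_ss: float
    avg_silhouette: float
    silhouette_samples: np.ndarray
    sizes: np.ndarray


@dataclass
class StepwiseResult:
    retained: list[str]
    pvalues: dict[str, float]
    adj_r2: float
    history: list[tuple[str, float]] = field(default_factory=list)  # (term, p) removal order


def zscore(table: pd.DataFrame) -> StandardizedMatrix:
    """Column-wise z-scores ((x - mean) / sd, sample sd)."""
    if table.shape[0] < 2:
        raise ValueError("need at least 2 rows to z-score")
    sds = table.std(ddof=1)
    constant = sds[np.isclose(sds, 0.0)].index.tolist()
    if constant:
        raise ValueError(f"constant column(s) cannot be z-scored: {constant}")
    means = table.mean()
    return StandardizedMatrix((table - means) / sds, means, sds)


def _solution_from_labels(X: np.ndarray, labels: np.ndarray, columns) -> ClusterSolution:
    k = int(labels.max()) + 1
    grand = X.mean(axis=0)
    cents = np.vstack([X[labels == c].mean(axis=0) for c in range(k)])
    sizes = np.bincount(labels, minlength=k)
    wcss = float(sum(((X[labels == c] - cents[c]) ** 2).sum() for c in range(k)))
    bcss = float((sizes[:, None] * (cents - grand) ** 2).sum())
    total = float(((X - grand) ** 2).sum())
    if k >= 2 and np.unique(labels).size >= 2:
        sil = silhouette_samples(X, labels)
        avg = float(sil.mean())
    else:
        sil = np.zeros(len(X))
        avg = 0.0
    return ClusterSolution(
        k=k, assignments=labels,
        centroids=pd.DataFrame(cents, columns=list(columns),
                               index=pd.RangeIndex(1, k + 1, name="cluster")),
        wcss=wcss, bcss=bcss, total_ss=total,
        avg_silhouette=avg, silhouette_samples=sil, sizes=sizes,
    )


def _canonical_labels(X: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Relabel clusters by ascending centroid value on the first column.

    Gives reproducible, interpretable numbering: with bottom_time first,
    cluster 1 is the lower-effort group as conventional in the field.
    """
    cents = np.array([X[labels == c, 0].mean() for c in range(k)])
    order = np.argsort(cents, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[labels]


def kmeans_cluster(X: pd.DataFrame | np.ndarray, k: int,
                   n_restarts: int = 25, seed: int = 0) -> ClusterSolution:
    """Best-of-``n_restarts`` k-means solution by within-cluster SS (seeded)."""
    Xv = np.asarray(X, dtype=float)
    columns = X.columns if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(Xv.shape[1])]
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = np.unique(Xv, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct rows")
    if k == 1:
        labels = np.zeros(len(Xv), dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd")
        labels = km.fit_predict(Xv)
        labels = _canonical_labels(Xv, labels, k)
    return _solution_from_labels(Xv, labels, columns)


def silhouette_select(X: pd.DataFrame | np.ndarray, k_min: int = 2, k_max: int = 8,
                      n_restarts: int = 25, seed: int = 0):
    """Choose k maximising the average silhouette width (Euclidean distance).

    Returns (k_star, {k: avg width}); ties break toward smaller k.
    """
    Xv = np.asarray(X, dtype=float)
    n_distinct = np.unique(Xv, axis=0).shape[0]
    hi = min(k_max, n_distinct, len(Xv) - 1)
    if k_min < 2 or hi < k_min:
        raise ValueError(f"need 2 <= k_min <= k_max < n distinct rows (k_min={k_min}, max usable={hi})")
    widths: dict[int, float] = {}
    for k in range(k_min, hi + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd")
        labels = km.fit_predict(Xv)
        widths[k] = float(silhouette_score(Xv, labels)) if np.unique(labels).size > 1 else -1.0
    k_star = max(sorted(widths), key=lambda k: (widths[k], -k))
    return k_star, widths


def stepwise_select(X: pd.DataFrame, assignments: np.ndarray, alpha: float = 0.05,
                    family: str = "ols") -> StepwiseResult:
    """Backwards stepwise regression of the cluster indicator on predictors.

    Requires a two-cluster assignment (the indicator is 0/1).  At each step
    the single term with the largest p-value above ``alpha`` is removed and
    the model refitted, until every remaining term has p <= alpha.  Reports
    the final per-term p-values and adjusted R^2 (pseudo-R^2 for logistic).
    """
    labels = np.asarray(assignments)
    if np.unique(labels).size != 2:
        raise ValueError("stepwise selection requires exactly 2 clusters")
    y = (labels == labels.max()).astype(float)
    if len(X) <= X.shape[1] + 2:
        raise ValueError("need n > p + 2 observations for the stepwise fit")
    cols = list(X.columns)
    history: list[tuple[str, float]] = []
    fit = None
    while cols:
        design = sm.add_constant(X[cols].to_numpy(), has_constant="add")
        if family == "logistic":
            fit = sm.Logit(y, design).fit(disp=0, method="lbfgs", maxiter=500)
        else:
            fit = sm.OLS(y, design).fit()
        pvals = pd.Series(fit.pvalues[1:], index=cols)
        worst = pvals.idxmax()
        if pvals[worst] <= alpha:
            break
        history.append((worst, float(pvals[worst])))
        log.info("stepwise: removing %s (p=%.3g)", worst, pvals[worst])
        cols.remove(worst)
    if not cols:
        log.warning("stepwise: all terms removed at alpha=%.2f", alpha)
        return StepwiseResult([], {}, float("nan"), history)
    adj = float(fit.rsquared_adj) if family == "ols" else float(fit.prsquared)
    return StepwiseResult(cols, {c: float(p) for c, p in pvals.items()}, adj, history)


class BottomUseClusterer(BaseEstimator, ClusterMixin):
    """Standardise, cluster and stepwise-confirm bottom-use predictors.

    An sklearn-compatible estimator running the full selection loop:
    z-score -> silhouette choice of k -> k-means -> (for k=2) backwards
    stepwise confirmation of predictors; predictors dropped by the stepwise
    step are removed and the loop repeats until the set is stable.

    Parameters
    ----------
    k : int or None
        Fixed number of clusters; None selects k by average silhouette width.
    k_min, k_max : int
        Silhouette search range (used when ``k`` is None).
    n_restarts : int
        k-means initialisations per fit.
    alpha : float
        Stepwise removal threshold on per-term p-values.
    family : str
        'ols' (least squares on the 0/1 indicator) or 'logistic'.
    stepwise : bool
        Disable to cluster on the supplied predictors without confirmation.
    seed : int
        Random state for k-means restarts.

    Attributes (after fit)
    ----------------------
    columns_ : retained predictor names
    scaler_ : StandardizedMatrix on the retained predictors
    k_, labels_, solution_ : final clustering (labels are 1-based clusters)
    silhouette_curve_ : {k: average width} from the final selection pass
    stepwise_ : StepwiseResult or None (k != 2 or disabled)
    n_iterations_ : selection-loop passes executed
    """

    def __init__(self, k=None, k_min=2, k_max=8, n_restarts=25, alpha=0.05,
                 family="ols", stepwise=True, seed=0):
        self.k = k
        self.k_min = k_min
        self.k_max = k_max
        self.n_restarts = n_restarts
        self.alpha = alpha
        self.family = family
        self.stepwise = stepwise
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        if X.isna().any().any():
            raise ValueError("predictor table contains NaN")
        cols = list(X.columns)
        history: list[list[str]] = []
        last = None
        for _ in range(max(len(cols), 1)):
            scaler = zscore(X[cols])
            if self.k is not None:
                k_star, curve = int(self.k), {}
            else:
                k_star, curve = silhouette_select(
                    scaler.Z, self.k_min, self.k_max, self.n_restarts, self.seed
                )
            sol = kmeans_cluster(scaler.Z, k_star, self.n_restarts, self.seed)
            sw = None
            if self.stepwise and k_star == 2:
                sw = stepwise_select(scaler.Z, sol.assignments, self.alpha, self.family)
                removed = [c for c in cols if c not in sw.retained]
                if removed and len(sw.retained) >= 2:
                    history.append(removed)
                    cols = [c for c in cols if c in sw.retained]
                    last = (scaler, sol, sw, curve)
                    continue
                if removed:
                    log.warning("selection loop: fewer than 2 predictors would remain; "
                                "keeping previous solution")
            elif self.stepwise and k_star != 2:
                log.info("selection loop: stepwise confirmation only defined for k=2 "
                         "(k*=%d); skipping", k_star)
            last = (scaler, sol, sw, curve)
            break
        scaler, sol, sw, curve = last
        self.columns_ = cols
        self.scaler_ = scaler
        self.solution_ = sol
        self.k_ = sol.k
        self.labels_ = sol.assignments + 1
        self.silhouette_curve_ = curve
        self.stepwise_ = sw
        self.removal_history_ = history
        self.n_iterations_ = len(history) + 1
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Assign new dives to the fitted clusters (nearest z-space centroid)."""
        Z = self.scaler_.transform(pd.DataFrame(X)[self.columns_]).to_numpy()
        cents = self.solution_.centroids.to_numpy()
        d2 = ((Z[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1) + 1

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def iterate_cluster_selection(table: pd.DataFrame, k_min=2, k_max=8, n_restarts=25,
                              alpha=0.05, family="ols", seed=0):
    """Functional wrapper over :class:`BottomUseClusterer`.

    Returns (fitted clusterer, ClusterSolution, StepwiseResult-or-None).
    """
    est = BottomUseClusterer(k_min=k_min, k_max=k_max, n_restarts=n_restarts,
                             alpha=alpha, family=family, seed=seed).fit(table)
    return est, est.solution_, est.stepwise_


def cluster_percentages(sizes) -> list[float]:
    """Cluster shares as percentages of all bottom phases, rounded to 2 dp."""
    sizes = np.asarray(sizes, dtype=float)
    return [round(float(p), 2) for p in 100.0 * sizes / sizes.sum()]


def location_frequency_per_h(n_locations: int, duration_h: float) -> float:
    """GPS locations per hour of trip, rounded to 2 dp."""
    return round(n_locations / duration_h, 2)


def mean_fix_interval_min(n_locations: int, duration_h: float) -> float:
    """Average minutes between successive locations, rounded to whole minutes."""
    return round(duration_h * 60.0 / n_locations)


def summarize(est: BottomUseClusterer, metrics: pd.DataFrame,
              dive_df: pd.DataFrame | None = None,
              n_locations: int | None = None,
              trip_duration_h: float | None = None) -> dict:
    """Per-animal summary: trip/location/dive statistics plus cluster table.

    Percentages are reported to 2 dp and standardized centroid means to 3 dp,
    the conventional reporting precision for these tables.
    """
    out: dict = {}
    if n_locations is not None and trip_duration_h is not None:
        out["n_locations"] = int(n_locations)
        out["trip_duration_h"] = round(float(trip_duration_h), 2)
        out["locations_per_h"] = location_frequency_per_h(n_locations, trip_duration_h)
        out["mean_fix_interval_min"] = mean_fix_interval_min(n_locations, trip_duration_h)
    out["n_bottom_phases"] = int(len(metrics))
    out["mean_bottom_time_s"] = round(float(metrics["bottom_time"].mean()), 2)
    out["sd_bottom_time_s"] = round(float(metrics["bottom_time"].std(ddof=1)), 2)
    if dive_df is not None and len(dive_df):
        dive_dur = dive_df["t_end"] - dive_df["t_start"]
        out["mean_dive_time_s"] = round(float(dive_dur.mean()), 2)
        out["sd_dive_time_s"] = round(float(dive_dur.std(ddof=1)), 2)
        out["max_depth_m"] = round(float(dive_df["max_depth"].max()), 2)
        out["mean_max_depth_m"] = round(float(dive_df["max_depth"].mean()), 2)
    sol = est.solution_
    out["k"] = sol.k
    out["avg_silhouette"] = round(sol.avg_silhouette, 3)
    out["cluster_n"] = [int(n) for n in sol.sizes]
    out["cluster_pct"] = cluster_percentages(sol.sizes)
    out["centroids"] = {
        str(c): {col: round(float(v), 3) for col, v in row.items()}
        for c, row in sol.centroids.iterrows()
    }
    if est.stepwise_ is not None:
        out["adjusted_r2"] = round(est.stepwise_.adj_r2, 3)
        out["pvalues"] = {c: float(f"{p:.3g}") for c, p in est.stepwise_.pvalues.items()}
        out["retained_predictors"] = est.stepwise_.retained
    return out
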