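"""Co-expression module discovery: K-means with BIC model selection.

The number of modules K is chosen by sweeping a grid of K values (default 10
to 100 in steps of 5), fitting K-means at each and scoring the fit with a
spherical-Gaussian Bayesian Information Criterion; the best K minimizes BIC,
ties going to the smaller K.

BIC formula (X-means style, classified likelihood, shared spherical variance):

    sigma2_hat = inertia / (n * d)
    LL = sum_k n_k ln(n_k / n) - (n d / 2) ln(2 pi sigma2_hat) - n d / 2
    BIC(K) = -2 LL + q ln(n),   q = K d + K   (centroids + mixing weights)

Only relative BIC across K matters for model selection; the formula above is
the one every test in this package asserts against.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans

__all__ = [
    "ModuleAssignment",
    "ModuleKMeans",
    "ModuleKMeansResults",
    "kmeans_bic",
    "kmeans_bic_sweep",
    "assign_modules",
    "module_profiles",
    "central_gene",
    "heatmap_matrix",
]


@dataclasses.dataclass
class ModuleAssignment:
    """Gene→module labels with centroids and the BIC curve that chose K.

    Module ids are 1-based.  ``central_gene[m]`` is the member of module ``m``
    whose profile is nearest (Euclidean) to the module centroid.
    """

    labels: pd.Series  # gene -> module id (1..K)
    centroids: pd.DataFrame  # K x n_conditions
    K: int
    bic_curve: pd.Series  # K -> BIC
    central_genes: pd.Series  # module -> gene id
    inertia: float

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def kmeans_bic(X: np.ndarray, labels: np.ndarray, inertia: float) -> float:
    """Spherical-Gaussian BIC of a fitted K-means partition (see module docs)."""
    n, d = X.shape
    k = len(np.unique(labels))
    sigma2 = max(inertia / (n * d), 1e-12)
    counts = np.bincount(labels)
    counts = counts[counts > 0]
    ll = (
        float(np.sum(counts * np.log(counts / n)))
        - 0.5 * n * d * np.log(2.0 * np.pi * sigma2)
        - 0.5 * n * d
    )
    q = k * d + k
    return -2.0 * ll + q * np.log(n)


def _fit_kmeans(X: np.ndarray, k: int, n_init: int, seed: int) -> KMeans:
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    km.fit(X)
    return km


def kmeans_bic_sweep(
    X: pd.DataFrame | np.ndarray,
    k_min: int = 10,
    k_max: int = 100,
    step: int = 5,
    n_init: int = 10,
    seed: int = 0,
) -> tuple[pd.Series, int]:
    """Fit K-means over the K grid and return (bic_curve, best_K).

    Best K is the argmin of the BIC curve; on ties the smaller K wins.  If the
    grid extends past the number of rows it is truncated with a warning.
    """
    if k_min > k_max:
        raise ValueError(f"k_min ({k_min}) > k_max ({k_max})")
    if k_min < 1 or step < 1:
        raise ValueError("k_min and step must be >= 1")
    Xv = np.asarray(X, dtype=float)
    if not np.isfinite(Xv).all():
        raise ValueError("clustering input must be finite")
    n = Xv.shape[0]
    grid = [k for k in range(k_min, k_max + 1, step)]
    if grid and grid[-1] > n:
        warnings.warn(
            f"K grid truncated at the number of rows ({n}); requested up to {k_max}"
        )
        grid = [k for k in grid if k <= n]
    if not grid:
        raise ValueError(f"no feasible K in [{k_min}, {k_max}] for {n} rows")
    bics = {}
    for k in grid:
        km = _fit_kmeans(Xv, k, n_init=n_init, seed=seed)
        bics[k] = kmeans_bic(Xv, km.labels_, km.inertia_)
    curve = pd.Series(bics, name="BIC")
    best = int(curve.index[np.argmin(curve.to_numpy())])  # first min -> smaller K
    return curve, best


def assign_modules(
    X: pd.DataFrame,
    K: int,
    n_init: int = 10,
    seed: int = 0,
    bic_curve: pd.Series | None = None,
) -> ModuleAssignment:
    """Final K-means fit at K; labels come from the best-inertia restart."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > X.shape[0]:
        raise ValueError(f"K ({K}) exceeds the number of genes ({X.shape[0]})")
    Xv = X.to_numpy(dtype=float)
    km = _fit_kmeans(Xv, K, n_init=n_init, seed=seed)
    raw = km.labels_
    used = np.unique(raw)
    if len(used) < K:
        # K-means can return empty clusters when K exceeds the number of
        # distinct rows; compact to the populated clusters
        warnings.warn(
            f"only {len(used)} of {K} clusters populated; empty clusters dropped"
        )
        K = len(used)
    remap = {old: new for new, old in enumerate(used)}
    labels = pd.Series(
        [remap[v] + 1 for v in raw], index=X.index, name="module"
    )
    centroids = pd.DataFrame(
        km.cluster_centers_[used], index=range(1, K + 1), columns=X.columns
    )
    if bic_curve is None:
        bic_curve = pd.Series({K: kmeans_bic(Xv, km.labels_, km.inertia_)}, name="BIC")
    assignment = ModuleAssignment(
        labels=labels,
        centroids=centroids,
        K=K,
        bic_curve=bic_curve,
        central_genes=pd.Series(dtype=object),
        inertia=float(km.inertia_),
    )
    assignment.central_genes = central_gene(assignment, X)
    return assignment


def module_profiles(assignment: ModuleAssignment, expr: pd.DataFrame) -> pd.DataFrame:
    """Module x column matrix of member-gene arithmetic means."""
    missing = assignment.labels.index.difference(expr.index)
    if len(missing):
        raise ValueError(f"labelled genes absent from expression: {missing.tolist()[:5]}")
    member = expr.loc[assignment.labels.index]
    prof = member.groupby(assignment.labels).mean()
    prof.index.name = "module"
    return prof


def central_gene(assignment: ModuleAssignment, X: pd.DataFrame) -> pd.Series:
    """Per module, the member gene nearest its centroid (Euclidean).

    Distance ties (within 1e-12) break to the lexicographically smallest id.
    """
    out = {}
    for m in assignment.centroids.index:
        members = assignment.labels.index[assignment.labels == m]
        diffs = X.loc[members].to_numpy() - assignment.centroids.loc[m].to_numpy()
        dist = np.sqrt((diffs**2).sum(axis=1))
        tied = members[dist <= dist.min() + 1e-12]
        out[m] = sorted(tied)[0]
    return pd.Series(out, name="central_gene")


def heatmap_matrix(profiles: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Row-standardize module profiles and order rows by hierarchical clustering.

    Each row is z-scored (zero-variance rows become all-zero with a warning);
    the row order is the leaf order of average-linkage Euclidean agglomerative
    clustering of the z-scored rows.
    """
    if profiles.shape[1] < 2:
        raise ValueError("heatmap needs >= 2 conditions")
    v = profiles.to_numpy(dtype=float)
    mu = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, ddof=0, keepdims=True)
    flat = (sd[:, 0] == 0)
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant module profile(s) set to 0 in the heatmap"
        )
    z = np.where(sd > 0, (v - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    zdf = pd.DataFrame(z, index=profiles.index, columns=profiles.columns)
    if len(zdf) > 1:
        link = hierarchy.linkage(z, method="average", metric="euclidean")
        order = hierarchy.leaves_list(link)
    else:
        order = np.array([0])
    row_order = profiles.index[order].tolist()
    return zdf.loc[row_order], row_order


class ModuleKMeans:
    """K-means module model over a gene x condition expression matrix.

    Parameters
    ----------
    X : DataFrame
        Rows are genes (typically condition-averaged log2(FPKM+1) of DEGs),
        columns are conditions.
    k_min, k_max, step : int
        The K grid for BIC model selection.
    standardize : bool
        Row-standardize before clustering (default True): modules then group
        genes by profile *shape* rather than absolute level.  Zero-variance
        rows are dropped with a warning.
    n_init : int
        K-means restarts per K; the best-inertia restart wins.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        k_min: int = 10,
        k_max: int = 100,
        step: int = 5,
        standardize: bool = True,
        n_init: int = 10,
    ):
        v = X.to_numpy(dtype=float)
        if standardize:
            sd = v.std(axis=1, ddof=0)
            flat = sd == 0
            if flat.any():
                warnings.warn(
                    f"dropping {int(flat.sum())} zero-variance gene(s) before clustering"
                )
                X = X.loc[~flat]
                v = X.to_numpy(dtype=float)
                sd = sd[~flat]
            v = (v - v.mean(axis=1, keepdims=True)) / sd[:, None]
            X = pd.DataFrame(v, index=X.index, columns=X.columns)
        self.X = X
        self.k_min, self.k_max, self.step = k_min, k_max, step
        self.n_init = n_init

    def fit(self, seed: int = 0, K: int | None = None) -> "ModuleKMeansResults":
        """Run the BIC sweep (unless K is forced) and the final fit."""
        if K is None:
            curve, K = kmeans_bic_sweep(
                self.X, self.k_min, self.k_max, self.step, self.n_init, seed
            )
        else:
            curve = None
        assignment = assign_modules(
            self.X, K, n_init=self.n_init, seed=seed, bic_curve=curve
        )
        return ModuleKMeansResults(self, assignment)


class ModuleKMeansResults:
    """Fitted module assignment with profile/heatmap accessors."""

    def __init__(self, model: ModuleKMeans, assignment: ModuleAssignment):
        self.model = model
        self.assignment = assignment

    @property
    def K(self) -> int:
        return self.assignment.K

    @property
    def labels(self) -> pd.Series:
        return self.assignment.labels

    @property
    def bic_curve(self) -> pd.Series:
        return self.assignment.bic_curve

    def profiles(self, expr: pd.DataFrame | None = None) -> pd.DataFrame:
        """Module-mean profiles on ``expr`` (default: the clustering input)."""
        return module_profiles(self.assignment, expr if expr is not None else self.model.X)

    def heatmap(self, expr: pd.DataFrame | None = None):
        return heatmap_matrix(self.profiles(expr))

    def summary(self) -> str:
        a = self.assignment
        sizes = a.sizes
        big, small = sizes.idxmax(), sizes.idxmin()
        lines = [
            "Co-expression module model (K-means, BIC-selected K)",
            f"  genes clustered : {len(a.labels)}",
            f"  conditions      : {a.centroids.shape[1]}",
            f"  K (min BIC)     : {a.K}",
            f"  BIC (sweep min) : {a.bic_curve.min():.1f}",
            f"  largest module  : {big} ({sizes[big]} genes, "
            f"central gene {a.central_genes[big]})",
            f"  smallest module : {small} ({sizes[small]} genes, "
            f"central gene {a.central_genes[small]})",
        ]
        return "\n".join(lines)
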