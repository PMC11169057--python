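"""TF→module network inference: four independent scoring algorithms.

The inference input stacks module-mean expression profiles on top of the
differentially expressed TF profiles, columns being the experimental lines.
Every TF→module pair is scored by:

* **aracne** — pairwise mutual information pruned by the data-processing
  inequality: in every triangle the weakest edge is removed.
* **clr** — context likelihood of relatedness: each MI value is z-scored
  against the background MI distributions of both endpoints.
* **lars** — TIGRESS-style stability selection: least-angle regression of the
  module profile on all TF profiles over many column subsamples; the score is
  the fraction of subsamples in which a TF enters the path early.
* **pcor** — absolute shrinkage partial correlation, with the analytic
  Schäfer–Strimmer shrinkage intensity toward the identity correlation matrix.

An optional fifth scorer, absolute Spearman correlation, is available so that
five-method consensus configurations are expressible.

MI uses a Gaussian-copula estimator by default (Pearson correlation of
rank-normal scores, MI = -ln(1 - rho^2)/2), which is rank-based and therefore
invariant under monotone transforms and usable at very small sample sizes; an
equal-frequency binned plug-in estimator is provided for cross-checks.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lars

__all__ = [
    "InferenceMatrix",
    "ScoreMatrix",
    "build_inference_matrix",
    "mutual_information",
    "mi_matrix",
    "aracne",
    "clr",
    "lars_stability",
    "shrinkage_pcor",
    "spearman_score",
    "run_all_methods",
    "METHODS",
]


@dataclasses.dataclass
class InferenceMatrix:
    """Stacked (module profiles; TF profiles) x experimental-line matrix."""

    values: pd.DataFrame  # rows: modules then TFs
    module_ids: list  # row ids tagged as modules
    tf_ids: list  # row ids tagged as TFs

    def __post_init__(self) -> None:
        expected = list(self.module_ids) + list(self.tf_ids)
        if list(self.values.index) != expected:
            raise ValueError("rows must be modules first, then TFs, in tag order")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate row ids in inference matrix")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("inference matrix must be finite")

    @property
    def n_modules(self) -> int:
        return len(self.module_ids)

    @property
    def n_tfs(self) -> int:
        return len(self.tf_ids)

    @property
    def row_kind(self) -> pd.Series:
        return pd.Series(
            ["module"] * self.n_modules + ["tf"] * self.n_tfs,
            index=self.values.index,
            name="row_kind",
        )


@dataclasses.dataclass
class ScoreMatrix:
    """Per-method TF x module scores; orientation is always higher = stronger."""

    method: str
    values: pd.DataFrame  # index = TF ids, columns = module ids
    orientation: str = "higher=stronger"

    def long(self) -> pd.DataFrame:
        df = self.values.rename_axis(index="tf", columns="module").stack().rename(
            "score"
        ).reset_index()
        df["method"] = self.method
        df["rank"] = stats.rankdata(-df["score"], method="average")
        return df[["tf", "module", "method", "score", "rank"]]


def build_inference_matrix(
    profiles: pd.DataFrame, tf_expr: pd.DataFrame, de_tf_ids=None
) -> InferenceMatrix:
    """Stack module profiles over (differentially expressed) TF profiles.

    Columns of the two inputs must agree exactly and in order; only TFs in
    ``de_tf_ids`` are retained (all TFs if None).
    """
    if list(profiles.columns) != list(tf_expr.columns):
        diff = set(profiles.columns) ^ set(tf_expr.columns)
        raise ValueError(
            f"module and TF columns differ: {sorted(map(str, diff))[:10] or 'ordering mismatch'}"
        )
    if de_tf_ids is not None:
        keep = [t for t in tf_expr.index if t in set(de_tf_ids)]
        tf_expr = tf_expr.loc[keep]
    if tf_expr.shape[0] == 0:
        warnings.warn("no differentially expressed TFs: inference cannot run")
    values = pd.concat([profiles, tf_expr], axis=0)
    return InferenceMatrix(
        values=values,
        module_ids=list(profiles.index),
        tf_ids=list(tf_expr.index),
    )


# ---------------------------------------------------------------------------
# mutual information


def _rank_normal(x: np.ndarray) -> np.ndarray:
    r = stats.rankdata(x, method="average")
    return stats.norm.ppf(r / (len(x) + 1.0))


def mutual_information(
    x: np.ndarray,
    y: np.ndarray,
    estimator: str = "gauss_copula",
    bins: int = 3,
) -> float:
    """Mutual information in nats between two vectors.

    ``gauss_copula``: MI = -ln(1 - rho^2)/2 where rho is the Pearson
    correlation of rank-normal scores (rho clipped at 1 - 1e-12).
    ``binned``: plug-in MI on an equal-frequency discretization.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("vectors must have equal length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: MI set to 0")
        return 0.0
    if estimator == "gauss_copula":
        rho = np.corrcoef(_rank_normal(x), _rank_normal(y))[0, 1]
        rho = float(np.clip(rho, -(1 - 1e-12), 1 - 1e-12))
        return -0.5 * np.log1p(-rho**2)
    if estimator == "binned":
        qx = pd.qcut(x, q=min(bins, len(np.unique(x))), labels=False, duplicates="drop")
        qy = pd.qcut(y, q=min(bins, len(np.unique(y))), labels=False, duplicates="drop")
        joint = pd.crosstab(qx, qy).to_numpy(dtype=float)
        p = joint / joint.sum()
        px = p.sum(axis=1, keepdims=True)
        py = p.sum(axis=0, keepdims=True)
        mask = p > 0
        return float(np.sum(p[mask] * np.log(p[mask] / (px @ py)[mask])))
    raise ValueError(f"unknown MI estimator: {estimator!r}")


def mi_matrix(values: pd.DataFrame, estimator: str = "gauss_copula") -> pd.DataFrame:
    """Symmetric MI matrix over all rows (zero diagonal)."""
    v = values.to_numpy(dtype=float)
    n = v.shape[0]
    if estimator == "gauss_copula":
        # vectorized: rank-normal every row, then correlate
        sd = v.std(axis=1, ddof=0)
        z = np.vstack([_rank_normal(row) if s > 0 else np.zeros(v.shape[1])
                       for row, s in zip(v, sd)])
        with np.errstate(invalid="ignore"):
            rho = np.corrcoef(z)
        rho = np.nan_to_num(rho, nan=0.0)
        np.fill_diagonal(rho, 0.0)
        rho = np.clip(rho, -(1 - 1e-12), 1 - 1e-12)
        mi = -0.5 * np.log1p(-rho**2)
    else:
        mi = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    mi[i, j] = mi[j, i] = mutual_information(
                        v[i], v[j], estimator=estimator
                    )
    np.fill_diagonal(mi, 0.0)
    return pd.DataFrame(mi, index=values.index, columns=values.index)


# ---------------------------------------------------------------------------
# the four scorers


def _slice_tf_module(full: pd.DataFrame, matrix: InferenceMatrix) -> pd.DataFrame:
    return full.loc[matrix.tf_ids, matrix.module_ids]


def aracne(
    mi: pd.DataFrame, matrix: InferenceMatrix, dpi_tolerance: float = 0.0
) -> ScoreMatrix:
    """ARACNE: MI network pruned by the data-processing inequality.

    Edge (i, j) is removed iff some third node k satisfies
    ``MI_ij < min(MI_ik, MI_jk) - dpi_tolerance`` (all triangles evaluated on
    the original MI matrix).  Surviving TF→module edges keep their MI as score;
    removed edges score 0.
    """
    if dpi_tolerance < 0:
        raise ValueError("dpi_tolerance must be non-negative")
    M = mi.to_numpy(dtype=float)
    if not np.allclose(M, M.T):
        raise ValueError("MI matrix must be symmetric")
    if (M < 0).any():
        raise ValueError("MI matrix must be non-negative")
    n = M.shape[0]
    keep = np.ones((n, n), dtype=bool)
    # for each pair (i,j): removed iff max_k min(M_ik, M_jk) > M_ij + tol
    for i in range(n):
        for j in range(i + 1, n):
            floor = np.minimum(M[i], M[j])
            floor[i] = floor[j] = -np.inf
            if floor.max() - dpi_tolerance > M[i, j]:
                keep[i, j] = keep[j, i] = False
    pruned = pd.DataFrame(np.where(keep, M, 0.0), index=mi.index, columns=mi.columns)
    return ScoreMatrix("aracne", _slice_tf_module(pruned, matrix))


def clr(mi: pd.DataFrame, matrix: InferenceMatrix) -> ScoreMatrix:
    """Context likelihood of relatedness scores.

    ``z_i(j) = max(0, (MI_ij - mu_i) / sigma_i)`` over node i's off-diagonal MI
    background; the edge score is ``sqrt(z_i(j)^2 + z_j(i)^2)``.  Nodes whose
    background MI is constant contribute z = 0 with a warning.
    """
    M = mi.to_numpy(dtype=float)
    n = M.shape[0]
    off = ~np.eye(n, dtype=bool)
    mu = np.array([M[i, off[i]].mean() for i in range(n)])
    sd = np.array([M[i, off[i]].std(ddof=0) for i in range(n)])
    if (sd == 0).any():
        warnings.warn(
            f"{int((sd == 0).sum())} node(s) with constant MI background: z set to 0"
        )
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (M - mu[:, None]) / safe_sd[:, None]
    z[sd == 0, :] = 0.0
    z = np.clip(z, 0.0, None)
    score = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(score, 0.0)
    full = pd.DataFrame(score, index=mi.index, columns=mi.columns)
    return ScoreMatrix("clr", _slice_tf_module(full, matrix))


def lars_stability(
    matrix: InferenceMatrix,
    target,
    n_resamples: int = 200,
    n_steps: int = 3,
    subsample_fraction: float = 0.8,
    seed: int = 0,
) -> pd.Series:
    """Per-TF selection frequency for one module target (stability selection).

    The module profile is regressed on all TF profiles with least-angle
    regression limited to ``n_steps`` active variables, on ``n_resamples``
    random column subsamples (fraction ``subsample_fraction``, without
    replacement); the frequency is the fraction of subsamples in which a TF
    enters the path.
    """
    if target not in matrix.module_ids:
        raise ValueError(f"target {target!r} is not a module row")
    if not (0 < subsample_fraction <= 1):
        raise ValueError("subsample_fraction must be in (0, 1]")
    n_cols = matrix.values.shape[1]
    if n_cols < 4:
        raise ValueError("stability selection needs >= 4 columns")
    n_tfs = matrix.n_tfs
    if n_steps >= n_tfs:
        warnings.warn(f"n_steps capped at n_tfs - 1 = {n_tfs - 1}")
        n_steps = max(n_tfs - 1, 1)
    y_full = matrix.values.loc[target].to_numpy(dtype=float)
    X_full = matrix.values.loc[matrix.tf_ids].to_numpy(dtype=float).T  # cols x TFs
    rng = np.random.default_rng(seed)
    m = max(int(round(subsample_fraction * n_cols)), 3)
    hits = np.zeros(n_tfs)
    for _ in range(n_resamples):
        idx = rng.choice(n_cols, size=m, replace=False)
        X = X_full[idx]
        y = y_full[idx]
        Xc = X - X.mean(axis=0)
        sd = Xc.std(axis=0, ddof=0)
        ok = sd > 0
        Xs = np.zeros_like(Xc)
        Xs[:, ok] = Xc[:, ok] / sd[ok]
        yc = y - y.mean()
        if np.ptp(yc) == 0:
            continue
        model = Lars(n_nonzero_coefs=n_steps, fit_intercept=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xs, yc)
        active = np.asarray(model.active_, dtype=int)
        hits[active[: n_steps]] += 1
    freq = pd.Series(hits / n_resamples, index=matrix.tf_ids, name=target)
    return freq


def _lars_scores(
    matrix: InferenceMatrix,
    n_resamples: int = 200,
    n_steps: int = 3,
    subsample_fraction: float = 0.8,
    seed: int = 0,
) -> ScoreMatrix:
    cols = {}
    for i, mod in enumerate(matrix.module_ids):
        cols[mod] = lars_stability(
            matrix,
            mod,
            n_resamples=n_resamples,
            n_steps=n_steps,
            subsample_fraction=subsample_fraction,
            seed=seed + i,
        )
    values = pd.DataFrame(cols)[matrix.module_ids]
    return ScoreMatrix("lars", values)


def schafer_strimmer_lambda(values: np.ndarray) -> float:
    """Analytic shrinkage intensity toward the identity correlation target.

    ``lambda* = clip( sum_{i<j} Var_hat(r_ij) / sum_{i<j} r_ij^2, 0, 1 )``
    with the unbiased-variance estimate of the empirical correlations.
    """
    p, n = values.shape
    if n < 3:
        return 1.0
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    xs = (values - mu) / sd[:, None]  # standardized, so cov = correlation
    w = np.einsum("ik,jk->ijk", xs, xs)  # w_ijk = xs_ik * xs_jk
    wbar = w.mean(axis=2)
    var_r = n / (n - 1.0) ** 3 * ((w - wbar[:, :, None]) ** 2).sum(axis=2)
    r = n / (n - 1.0) * wbar
    iu = np.triu_indices(p, k=1)
    denom = (r[iu] ** 2).sum()
    if denom == 0:
        return 1.0
    return float(np.clip(var_r[iu].sum() / denom, 0.0, 1.0))


def shrinkage_pcor(
    matrix: InferenceMatrix, shrinkage: float | None = None
) -> ScoreMatrix:
    """Absolute partial correlations from a shrunk correlation matrix.

    The sample correlation matrix is shrunk toward the identity with the
    analytic Schäfer–Strimmer intensity (or a forced ``shrinkage``); partial
    correlations come from the standardized inverse of the shrunk matrix.
    """
    v = matrix.values.to_numpy(dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("non-finite values in inference matrix")
    if v.shape[1] < 3:
        raise ValueError("partial correlation needs >= 3 columns")
    lam = schafer_strimmer_lambda(v) if shrinkage is None else float(shrinkage)
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(v)
    R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 1.0)
    Rs = (1.0 - lam) * R + lam * np.eye(R.shape[0])
    omega = np.linalg.pinv(Rs) if lam == 0 else np.linalg.inv(Rs)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    full = pd.DataFrame(
        np.abs(pcor), index=matrix.values.index, columns=matrix.values.index
    )
    sm = ScoreMatrix("pcor", _slice_tf_module(full, matrix))
    sm.shrinkage = lam
    return sm


def spearman_score(matrix: InferenceMatrix) -> ScoreMatrix:
    """Optional fifth scorer: absolute Spearman correlation per TF–module pair."""
    rho, _ = stats.spearmanr(matrix.values.T)
    rho = np.atleast_2d(np.nan_to_num(rho, nan=0.0))
    full = pd.DataFrame(
        np.abs(rho), index=matrix.values.index, columns=matrix.values.index
    )
    return ScoreMatrix("spearman", _slice_tf_module(full, matrix))


METHODS = ("aracne", "clr", "lars", "pcor")


def run_all_methods(
    matrix: InferenceMatrix,
    methods=METHODS,
    mi_estimator: str = "gauss_copula",
    dpi_tolerance: float = 0.0,
    lars_resamples: int = 200,
    lars_steps: int = 3,
    lars_fraction: float = 0.8,
    seed: int = 0,
) -> list[ScoreMatrix]:
    """Score every TF→module pair with each enabled method.

    TF–TF and module–module pairs feed the MI background and DPI pruning
    internally but are never emitted; all outputs are bipartite TF x module
    matrices oriented higher = stronger.
    """
    if not methods:
        raise ValueError("at least one method must be enabled")
    unknown = set(methods) - {"aracne", "clr", "lars", "pcor", "spearman"}
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if matrix.n_tfs == 0:
        raise ValueError("inference matrix has no TF rows")
    mi = None
    if "aracne" in methods or "clr" in methods:
        mi = mi_matrix(matrix.values, estimator=mi_estimator)
    out = []
    for name in methods:
        if name == "aracne":
            out.append(aracne(mi, matrix, dpi_tolerance=dpi_tolerance))
        elif name == "clr":
            out.append(clr(mi, matrix))
        elif name == "lars":
            out.append(
                _lars_scores(
                    matrix,
                    n_resamples=lars_resamples,
                    n_steps=lars_steps,
                    subsample_fraction=lars_fraction,
                    seed=seed,
                )
            )
        elif name == "pcor":
            out.append(shrinkage_pcor(matrix))
        elif name == "spearman":
            out.append(spearman_score(matrix))
    return out
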