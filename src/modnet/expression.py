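"""Count normalization, FPKM, differential expression and sample QC.

Normalization follows the median-of-ratios estimator: each sample's size
factor is the median, over genes expressed in every sample, of that sample's
count divided by the gene's geometric mean across samples; factors are then
rescaled to geometric mean 1 so they are identifiable.  FPKM divides the
normalized count by transcript length in kb and the normalized library size in
millions.  Differential expression uses a Welch t-test on log2(normalized
count + 1) together with a pseudocounted log2 fold change; the up/down call
applies the filter |log2FC| >= 1 (inclusive) and p < 0.05 (strict).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "size_factors",
    "fpkm",
    "deg_test",
    "filter_degs",
    "sample_qc",
    "ma_data",
    "average_replicates",
]


@dataclasses.dataclass
class CountMatrix:
    """Integer gene x sample read counts with gene lengths attached."""

    values: pd.DataFrame
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup[:5]}")
        if (v.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.lengths is not None and (self.lengths <= 0).any():
            bad = self.lengths.index[self.lengths <= 0].tolist()
            raise ValueError(f"non-positive gene lengths: {bad[:5]}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclasses.dataclass
class ExpressionMatrix:
    """Real-valued gene x sample expression (FPKM or log2(FPKM+1))."""

    values: pd.DataFrame
    scale: str = "linear"  # "linear" | "log2"
    size_factors: pd.Series | None = None

    def log2p1(self) -> "ExpressionMatrix":
        if self.scale == "log2":
            return self
        return ExpressionMatrix(
            np.log2(self.values + 1.0), scale="log2", size_factors=self.size_factors
        )


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Genes with a zero count in any sample are excluded from the reference set.
    """
    v = counts.values.to_numpy(dtype=float)
    if not v.any():
        raise ValueError("all-zero count matrix: size factors undefined")
    positive = (v > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has a nonzero count in every sample; "
            "median-of-ratios reference set is empty"
        )
    ref = v[positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def fpkm(counts: CountMatrix, factors: pd.Series | None = None) -> ExpressionMatrix:
    """Fragments per kilobase per million, on median-of-ratios-normalized counts.

    ``FPKM_gs = (count_gs / factor_s) / ((length_g / 1e3) * (N_s / 1e6))`` where
    ``N_s`` is the normalized library size ``sum_g count_gs / factor_s``.
    """
    if counts.lengths is None:
        raise ValueError("gene lengths are required for FPKM")
    missing = counts.gene_ids.difference(counts.lengths.index)
    if len(missing):
        raise ValueError(f"genes without length annotation: {missing.tolist()[:10]}")
    if factors is None:
        factors = size_factors(counts)
    norm = counts.values / factors
    lib_millions = norm.sum(axis=0) / 1e6
    kb = counts.lengths.loc[counts.gene_ids] / 1000.0
    values = norm.div(lib_millions, axis=1).div(kb, axis=0)
    return ExpressionMatrix(values, scale="linear", size_factors=factors)


def deg_test(
    counts: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    factors: pd.Series | None = None,
    pseudocount: float = 1.0,
    lfc_min: float = 1.0,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Two-group differential expression table.

    Positive log2 fold change means higher in ``group_b`` (treatment).  The
    p-value comes from a two-sided Welch t-test on log2(normalized count + 1);
    genes constant in both groups get p = 1.  Returns a DataFrame with columns
    ``baseMean``, ``log2fc``, ``p_value`` and ``call`` in {up, down, ns}.
    """
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    missing = (set(group_a) | set(group_b)) - set(counts.sample_ids)
    if missing:
        raise ValueError(f"samples not in count matrix: {sorted(missing)[:5]}")
    if factors is None:
        factors = size_factors(counts)
    norm = counts.values / factors
    mean_a = norm[group_a].mean(axis=1)
    mean_b = norm[group_b].mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    logn = np.log2(norm + 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(
            logn[group_b], logn[group_a], axis=1, equal_var=False
        )
    p = pd.Series(p, index=counts.gene_ids).fillna(1.0)
    table = pd.DataFrame(
        {
            "baseMean": norm[group_a + group_b].mean(axis=1),
            "log2fc": log2fc,
            "p_value": p,
        }
    )
    table["call"] = "ns"
    table.loc[(table.log2fc >= lfc_min) & (table.p_value < p_max), "call"] = "up"
    table.loc[(table.log2fc <= -lfc_min) & (table.p_value < p_max), "call"] = "down"
    return table


def filter_degs(
    table: pd.DataFrame, lfc_min: float = 1.0, p_max: float = 0.05
) -> dict[str, pd.Index]:
    """Gene sets under the DEG filter: inclusive on |log2FC|, strict on p."""
    if lfc_min <= 0 or p_max <= 0:
        raise ValueError("thresholds must be positive")
    sig = table.p_value < p_max
    up = table.index[(table.log2fc >= lfc_min) & sig]
    down = table.index[(table.log2fc <= -lfc_min) & sig]
    return {"up": up, "down": down, "all_de": up.union(down)}


def sample_qc(expr: ExpressionMatrix) -> dict:
    """Pairwise Pearson correlation between samples plus 2-D PCoA coordinates.

    PCoA is classical metric multidimensional scaling on the distance
    ``d = 1 - r``.  Zero-variance samples are flagged and excluded from the
    ordination with a warning.
    """
    v = expr.values
    if v.shape[1] < 3:
        raise ValueError("sample QC needs >= 3 samples")
    sd = v.std(axis=0, ddof=0)
    flagged = sd.index[sd == 0].tolist()
    if flagged:
        warnings.warn(f"zero-variance samples excluded from PCoA: {flagged}")
    keep = [s for s in v.columns if s not in flagged]
    corr = v.corr(method="pearson")
    d = 1.0 - corr.loc[keep, keep].to_numpy()
    coords = _classical_mds(d, n_axes=2)
    pcoa = pd.DataFrame(coords, index=keep, columns=["PCo1", "PCo2"])
    return {"correlation": corr, "pcoa": pcoa, "flagged": flagged}


def _classical_mds(d: np.ndarray, n_axes: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS: double-center -d^2/2, take top eigenvectors."""
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:n_axes]
    w_top = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(w_top)[None, :]


def ma_data(table: pd.DataFrame, p_max: float = 0.05) -> pd.DataFrame:
    """Plot-ready MA data: x = normalized mean expression, y = log2FC,
    significant flag for p < p_max (the red-dot rule)."""
    if table.empty:
        raise ValueError("empty DEG table")
    return pd.DataFrame(
        {
            "mean_expression": table.baseMean,
            "log2fc": table.log2fc,
            "significant": table.p_value < p_max,
        }
    )


def average_replicates(
    expr: ExpressionMatrix, sheet: pd.DataFrame
) -> ExpressionMatrix:
    """Collapse sample columns to condition means (arithmetic, per gene)."""
    mapping = sheet.set_index("sample")["condition"]
    unmapped = expr.values.columns.difference(mapping.index)
    if len(unmapped):
        raise ValueError(f"samples missing from sample sheet: {unmapped.tolist()}")
    cond = mapping.loc[expr.values.columns]
    out = expr.values.T.groupby(cond.values, sort=False).mean().T
    # keep first-appearance condition order
    seen = list(dict.fromkeys(cond.values))
    out = out[seen]
    return ExpressionMatrix(out, scale=expr.scale, size_factors=None)
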