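"""Cross-method consensus: edge voting, signed scoring and classification.

Each inference method calls its top-ranked fraction of TF→module pairs; an
edge's *support* is the number of methods calling it, and the consensus keeps
edges with support at or above a configurable minimum (e.g. "four or more
methods").  A signed *consensus significance score* S aggregates the methods
on a common scale: each method's scores are converted to standard-normal
quantiles of their within-method ranks, summed across methods, and signed by
the Spearman correlation between the TF and module profiles.  Edges are then
classified at the ±5 / ±10 thresholds: S > 5 significant activator, S ≥ 10
highly significant activator, mirrored for suppressors.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .inference import InferenceMatrix, ScoreMatrix

__all__ = [
    "ConsensusNetwork",
    "ConsensusGRN",
    "ConsensusGRNResults",
    "call_edges",
    "consensus",
    "consensus_score",
    "classify_edges",
    "network_stats",
    "export_network",
    "read_network_tsv",
]

CLASS_LABELS = (
    "highly_significant_activator",
    "activator",
    "suppressor",
    "highly_significant_suppressor",
    "unclassified",
)


def call_edges(scores: ScoreMatrix, top_fraction: float = 0.02) -> pd.DataFrame:
    """Boolean call matrix: a pair is called iff its within-method rank is in
    the top ``ceil(top_fraction * n_pairs)``.  Ties get average ranks."""
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    v = scores.values.to_numpy(dtype=float)
    ranks = stats.rankdata(-v.ravel(), method="average").reshape(v.shape)
    n_called = math.ceil(top_fraction * v.size)
    called = ranks <= n_called
    return pd.DataFrame(called, index=scores.values.index, columns=scores.values.columns)


def consensus(calls: list[pd.DataFrame], min_support: int = 4) -> pd.DataFrame:
    """Edge list with per-pair support counts, retaining support >= min_support.

    Returns a DataFrame with columns (tf, module, support), sorted by support
    descending then (tf, module) lexicographically.
    """
    if not calls:
        raise ValueError("need at least one call matrix")
    if min_support > len(calls):
        warnings.warn(
            f"min_support {min_support} exceeds the number of methods {len(calls)}: "
            "empty consensus"
        )
    support = sum(c.astype(int) for c in calls)
    long = support.rename_axis(index="tf", columns="module").stack().rename(
        "support"
    ).reset_index()
    long = long[long.support >= min_support]
    long = long.sort_values(
        ["support", "tf", "module"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return long


def consensus_score(
    scores: list[ScoreMatrix], matrix: InferenceMatrix
) -> pd.DataFrame:
    """Signed consensus score S per TF→module pair.

    Per method, scores are mapped to z = Phi^{-1}(rank / (n_pairs + 1)) of
    their within-method average ranks (higher score → higher rank → larger z);
    S = sign(Spearman(tf profile, module profile)) * sum_methods z.  |S| grows
    with cross-method agreement; flipping the sign of a module profile flips
    the sign of S but not its magnitude.
    """
    if not scores:
        raise ValueError("need at least one score matrix")
    shape = scores[0].values.shape
    z_sum = np.zeros(shape)
    for sm in scores:
        if sm.values.shape != shape:
            raise ValueError("score matrices must share the pair universe")
        v = sm.values.to_numpy(dtype=float)
        ranks = stats.rankdata(v.ravel(), method="average").reshape(shape)
        z_sum += stats.norm.ppf(ranks / (v.size + 1.0))
    tf_ids = list(scores[0].values.index)
    mod_ids = list(scores[0].values.columns)
    sign = np.zeros(shape)
    tf_v = matrix.values.loc[tf_ids].to_numpy(dtype=float)
    mod_v = matrix.values.loc[mod_ids].to_numpy(dtype=float)
    for i in range(len(tf_ids)):
        for j in range(len(mod_ids)):
            if np.ptp(tf_v[i]) == 0 or np.ptp(mod_v[j]) == 0:
                warnings.warn(
                    f"zero-variance profile for pair ({tf_ids[i]}, {mod_ids[j]}): "
                    "sign defaults to +"
                )
                sign[i, j] = 1.0
                continue
            rho = stats.spearmanr(tf_v[i], mod_v[j]).statistic
            sign[i, j] = 1.0 if rho >= 0 else -1.0
    return pd.DataFrame(sign * z_sum, index=tf_ids, columns=mod_ids)


def classify_edges(S: float, sig: float = 5.0, high: float = 10.0) -> str:
    """Class label from the signed consensus score at the ±sig/±high cutoffs."""
    if not sig < high:
        raise ValueError("sig threshold must be below high threshold")
    if S >= high:
        return "highly_significant_activator"
    if S > sig:
        return "activator"
    if S <= -high:
        return "highly_significant_suppressor"
    if S < -sig:
        return "suppressor"
    return "unclassified"


@dataclasses.dataclass
class ConsensusNetwork:
    """Bipartite TF→module network with per-edge support, score and class."""

    edges: pd.DataFrame  # columns: tf, module, support, S, class
    n_methods: int

    def __post_init__(self) -> None:
        need = ["tf", "module", "support", "S", "class"]
        if list(self.edges.columns[: len(need)]) != need:
            raise ValueError(f"edge table must have columns {need}")

    @property
    def tfs(self) -> list:
        return sorted(self.edges.tf.unique())

    @property
    def modules(self) -> list:
        return sorted(self.edges.module.unique())

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for tf in self.tfs:
            g.add_node(str(tf), kind="tf")
        for m in self.modules:
            g.add_node(str(m), kind="module")
        for row in self.edges.to_dict("records"):
            g.add_edge(
                str(row["tf"]),
                str(row["module"]),
                support=int(row["support"]),
                S=float(row["S"]),
                edge_class=str(row["class"]),
            )
        return g


def network_stats(net: ConsensusNetwork) -> dict[str, pd.DataFrame]:
    """Degree tables per node kind plus the top hubs (degree desc, then id)."""
    if net.edges.empty:
        empty = pd.DataFrame(columns=["node", "kind", "degree"])
        return {"degree": empty, "hub_tfs": empty, "hub_modules": empty}
    tf_deg = net.edges.groupby("tf").size().rename("degree")
    mod_deg = net.edges.groupby("module").size().rename("degree")
    rows = [
        {"node": n, "kind": "tf", "degree": int(d)} for n, d in tf_deg.items()
    ] + [{"node": n, "kind": "module", "degree": int(d)} for n, d in mod_deg.items()]
    degree = pd.DataFrame(rows).sort_values(
        ["degree", "node"], ascending=[False, True], key=lambda c: c.astype(str)
        if c.name == "node" else c
    ).reset_index(drop=True)
    def hubs(kind):
        sub = degree[degree.kind == kind]
        return sub[sub.degree == sub.degree.max()].reset_index(drop=True)
    return {"degree": degree, "hub_tfs": hubs("tf"), "hub_modules": hubs("module")}


def export_network(net: ConsensusNetwork, path: str | Path, fmt: str = "tsv") -> Path:
    """Write the network as TSV (round-trippable), SIF or GraphML."""
    path = Path(path)
    if fmt == "tsv":
        net.edges.to_csv(path, sep="\t", index=False)
    elif fmt == "sif":
        lines = [
            f"{row.tf}\tregulates\t{row.module}" for row in net.edges.itertuples()
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        nx.write_graphml(net.to_graph(), path)
    else:
        raise ValueError(f"unknown export format: {fmt!r}")
    return path


def read_network_tsv(path: str | Path, n_methods: int = 4) -> ConsensusNetwork:
    edges = pd.read_csv(
        path, sep="\t", dtype={"tf": str, "class": str}
    )
    if edges.empty:
        edges = pd.DataFrame(columns=["tf", "module", "support", "S", "class"])
    return ConsensusNetwork(edges=edges, n_methods=n_methods)


class ConsensusGRN:
    """Consensus regulatory-network model over an inference matrix.

    Parameters
    ----------
    matrix : InferenceMatrix
        Stacked module profiles and TF profiles over experimental lines.
    methods : sequence of str
        Enabled scorers among {aracne, clr, lars, pcor, spearman}.
    top_fraction : float
        Per-method call rate (fraction of the TF x module pair universe).
    min_support : int
        Minimum number of calling methods for a consensus edge.
    sig, high : float
        Signed-score thresholds for (highly) significant edges.
    """

    def __init__(
        self,
        matrix: InferenceMatrix,
        methods=("aracne", "clr", "lars", "pcor"),
        top_fraction: float = 0.02,
        min_support: int = 4,
        sig: float = 5.0,
        high: float = 10.0,
        mi_estimator: str = "gauss_copula",
        dpi_tolerance: float = 0.0,
        lars_resamples: int = 200,
        lars_steps: int = 3,
        lars_fraction: float = 0.8,
    ):
        self.matrix = matrix
        self.methods = tuple(methods)
        self.top_fraction = top_fraction
        self.min_support = min_support
        self.sig, self.high = sig, high
        self.mi_estimator = mi_estimator
        self.dpi_tolerance = dpi_tolerance
        self.lars_resamples = lars_resamples
        self.lars_steps = lars_steps
        self.lars_fraction = lars_fraction

    def fit(self, seed: int = 0) -> "ConsensusGRNResults":
        from .inference import run_all_methods

        scores = run_all_methods(
            self.matrix,
            methods=self.methods,
            mi_estimator=self.mi_estimator,
            dpi_tolerance=self.dpi_tolerance,
            lars_resamples=self.lars_resamples,
            lars_steps=self.lars_steps,
            lars_fraction=self.lars_fraction,
            seed=seed,
        )
        calls = {sm.method: call_edges(sm, self.top_fraction) for sm in scores}
        edges = consensus(list(calls.values()), min_support=self.min_support)
        S = consensus_score(scores, self.matrix)
        edges = edges.assign(
            S=[S.loc[t, m] for t, m in zip(edges.tf, edges.module)]
        )
        edges["class"] = [
            classify_edges(s, self.sig, self.high) for s in edges.S
        ]
        for sm in scores:
            edges[f"score_{sm.method}"] = [
                sm.values.loc[t, m] for t, m in zip(edges.tf, edges.module)
            ]
        net = ConsensusNetwork(
            edges=edges[["tf", "module", "support", "S", "class"]
                        + [f"score_{sm.method}" for sm in scores]],
            n_methods=len(scores),
        )
        return ConsensusGRNResults(self, scores, calls, S, net)


class ConsensusGRNResults:
    """Fitted consensus network with per-method scores and summaries."""

    def __init__(self, model, scores, calls, score_table, network):
        self.model = model
        self.scores = scores  # list[ScoreMatrix]
        self.calls = calls  # dict method -> bool DataFrame
        self.score_table = score_table  # signed S for every pair
        self.network = network

    @property
    def edges(self) -> pd.DataFrame:
        return self.network.edges

    @property
    def n_pairs(self) -> int:
        return self.model.matrix.n_tfs * self.model.matrix.n_modules

    def support_matrix(self) -> pd.DataFrame:
        return sum(c.astype(int) for c in self.calls.values())

    def all_method_fraction(self) -> float:
        """Fraction (%) of the pair universe called by every enabled method."""
        full = int((self.support_matrix() == len(self.scores)).to_numpy().sum())
        return 100.0 * full / self.n_pairs

    def stats(self) -> dict[str, pd.DataFrame]:
        return network_stats(self.network)

    def summary(self) -> str:
        e = self.edges
        cls = e["class"].value_counts()
        lines = [
            "Consensus TF→module regulatory network",
            f"  methods          : {', '.join(m.method for m in self.scores)}",
            f"  pair universe    : {self.model.matrix.n_tfs} TFs x "
            f"{self.model.matrix.n_modules} modules = {self.n_pairs} pairs",
            f"  per-method calls : top {self.model.top_fraction:.1%} by rank",
            f"  consensus edges  : {len(e)} with support >= {self.model.min_support} "
            f"({len(e.tf.unique())} TFs, {len(e['module'].unique())} modules)",
            f"  all-method edges : {int((e.support == len(self.scores)).sum())} "
            f"({self.all_method_fraction():.3f}% of pairs)",
        ]
        for label in CLASS_LABELS:
            if cls.get(label, 0):
                lines.append(f"  {label:<32s}: {cls[label]}")
        return "\n".join(lines)
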