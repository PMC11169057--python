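"""Synthetic benchmark datasets with planted TF→module regulatory structure.

The generator emulates a small bulk RNA-seq study: a handful of experimental
conditions with a few biological replicates each, negative-binomially
distributed read counts, per-gene transcript lengths (so FPKM normalization is
exercised non-trivially) and per-sample library-size variation.  Regulation is
planted as a bipartite network: each transcription factor (TF) carries a latent
per-condition activity, each module's log-scale signal is a weighted sum of the
activities of its regulators, and member genes scatter around the module
signal.  Replicates share the condition signal and differ only through count
noise, mirroring the replicate structure of a designed experiment.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TruthNetwork",
    "SimulatedDataset",
    "simulate_network",
    "simulate_expression",
    "write_dataset",
    "read_dataset",
]


@dataclasses.dataclass(frozen=True)
class TruthNetwork:
    """A planted bipartite TF→module network with signed effect sizes.

    ``edges`` maps ``(tf_index, module_index)`` (0-based) to a signed real
    weight: positive weights are activators, negative are suppressors.
    """

    n_tfs: int
    n_modules: int
    edges: dict[tuple[int, int], float]

    def __post_init__(self) -> None:
        if self.n_tfs < 1 or self.n_modules < 1:
            raise ValueError("n_tfs and n_modules must be >= 1")
        for (t, m), w in self.edges.items():
            if not (0 <= t < self.n_tfs and 0 <= m < self.n_modules):
                raise ValueError(f"edge ({t}, {m}) outside the TF/module grid")
            if w == 0:
                raise ValueError(f"edge ({t}, {m}) has zero weight")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def weight_matrix(self) -> np.ndarray:
        """Dense (n_tfs, n_modules) weight matrix; zeros mean no edge."""
        W = np.zeros((self.n_tfs, self.n_modules))
        for (t, m), w in self.edges.items():
            W[t, m] = w
        return W

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"tf": tf_name(t), "module": m + 1, "weight": w}
            for (t, m), w in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["tf", "module", "weight"])


@dataclasses.dataclass
class SimulatedDataset:
    """Counts plus every side table the pipeline consumes, with ground truth."""

    counts: pd.DataFrame  # genes x samples, integer
    sample_sheet: pd.DataFrame  # columns: sample, condition, replicate
    gene_lengths: pd.Series  # gene -> length in bp
    tf_ids: list[str]
    truth: TruthNetwork
    module_membership: pd.Series  # gene -> module id (1-based); TFs absent

    def __post_init__(self) -> None:
        genes = set(self.counts.index)
        missing = [t for t in self.tf_ids if t not in genes]
        if missing:
            raise ValueError(f"TF ids missing from counts: {missing[:5]}")
        if not set(self.module_membership.index) <= genes:
            raise ValueError("module members missing from counts")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")


def tf_name(t: int) -> str:
    return f"TF{t + 1:03d}"


def module_gene_name(m: int, j: int) -> str:
    return f"M{m + 1:02d}G{j + 1:03d}"


def simulate_network(
    n_tfs: int = 40,
    n_modules: int = 10,
    edge_density: float = 0.05,
    activator_fraction: float = 0.6,
    weight_scale: float = 1.0,
    seed: int = 0,
) -> TruthNetwork:
    """Draw a random bipartite TF→module network.

    ``round(edge_density * n_tfs * n_modules)`` distinct (tf, module) pairs are
    drawn uniformly without replacement.  Each edge is an activator with
    probability ``activator_fraction``; magnitudes are uniform in
    ``[0.5, 1.5] * weight_scale``.
    """
    if not (0.0 <= edge_density <= 1.0):
        raise ValueError(f"edge_density must be in [0, 1], got {edge_density}")
    if not (0.0 <= activator_fraction <= 1.0):
        raise ValueError(
            f"activator_fraction must be in [0, 1], got {activator_fraction}"
        )
    if weight_scale <= 0:
        raise ValueError("weight_scale must be positive")
    if n_tfs < 1 or n_modules < 1:
        raise ValueError("n_tfs and n_modules must be >= 1")
    rng = np.random.default_rng(seed)
    n_pairs = n_tfs * n_modules
    n_edges = int(round(edge_density * n_pairs))
    chosen = rng.choice(n_pairs, size=n_edges, replace=False)
    signs = np.where(rng.random(n_edges) < activator_fraction, 1.0, -1.0)
    mags = weight_scale * rng.uniform(0.5, 1.5, size=n_edges)
    edges = {
        (int(idx) // n_modules, int(idx) % n_modules): float(s * g)
        for idx, s, g in zip(chosen, signs, mags)
    }
    return TruthNetwork(n_tfs=n_tfs, n_modules=n_modules, edges=edges)


def simulate_expression(
    truth: TruthNetwork,
    n_conditions: int = 2,
    n_replicates: int = 3,
    genes_per_module: int = 20,
    activity_sd: float = 1.0,
    module_noise_sd: float = 0.1,
    gene_noise_sd: float = 0.2,
    nb_dispersion: float = 0.05,
    libsize_cv: float = 0.1,
    base_log_mean: float = np.log(100.0),
    seed: int = 0,
) -> SimulatedDataset:
    """Simulate an NB count matrix driven by the planted network.

    Generative model (log scale, natural logs):

    * TF activity ``a_t(c) ~ Normal(0, activity_sd^2)`` per condition ``c``;
      the TF gene's own log-signal equals its activity.
    * Module signal ``m_k(c) = sum_t w_tk a_t(c) + Normal(0, module_noise_sd^2)``.
    * Member-gene log-signal ``= m_k(c) + Normal(0, gene_noise_sd^2)`` drawn
      per gene and condition; member genes are conditionally independent given
      the module signal.
    * Counts ``~ NB(mu, dispersion)`` with
      ``mu = exp(base_log_mean + signal) * length_kb * libfactor_s`` and
      ``Var = mu + dispersion * mu^2``.  Library factors are log-normal with
      coefficient of variation ``libsize_cv`` (all 1 when ``libsize_cv = 0``).

    Replicates of a condition share its signal and differ only by count noise.
    Gene lengths are log-uniform in [500, 5000] bp.
    """
    if nb_dispersion <= 0:
        raise ValueError(f"nb_dispersion must be > 0, got {nb_dispersion}")
    if min(n_conditions, n_replicates, genes_per_module) < 1:
        raise ValueError("n_conditions, n_replicates, genes_per_module must be >= 1")
    if module_noise_sd < 0 or gene_noise_sd < 0 or libsize_cv < 0:
        raise ValueError("noise parameters must be non-negative")
    rng = np.random.default_rng(seed)
    K, T = truth.n_modules, truth.n_tfs
    W = truth.weight_matrix()  # (T, K)

    activity = rng.normal(0.0, activity_sd, size=(T, n_conditions))
    module_signal = W.T @ activity + rng.normal(
        0.0, module_noise_sd, size=(K, n_conditions)
    )
    gene_signal = np.repeat(module_signal, genes_per_module, axis=0) + rng.normal(
        0.0, gene_noise_sd, size=(K * genes_per_module, n_conditions)
    )

    tf_ids = [tf_name(t) for t in range(T)]
    module_genes = [
        module_gene_name(m, j) for m in range(K) for j in range(genes_per_module)
    ]
    gene_ids = tf_ids + module_genes
    signal = np.vstack([activity, gene_signal])  # (T + K*G, n_conditions)

    lengths = np.exp(rng.uniform(np.log(500.0), np.log(5000.0), size=len(gene_ids)))
    lengths = np.round(lengths).astype(int)

    n_samples = n_conditions * n_replicates
    if libsize_cv > 0:
        sigma2 = np.log1p(libsize_cv**2)
        libfactors = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=n_samples)
    else:
        libfactors = np.ones(n_samples)

    # expand condition-level signal to sample columns
    cond_of_sample = np.repeat(np.arange(n_conditions), n_replicates)
    mu = (
        np.exp(base_log_mean + signal[:, cond_of_sample])
        * (lengths[:, None] / 1000.0)
        * libfactors[None, :]
    )
    r = 1.0 / nb_dispersion
    p = 1.0 / (1.0 + nb_dispersion * mu)
    counts = rng.negative_binomial(r, p)

    sample_ids = [
        f"C{c + 1}_R{rep + 1}" for c in range(n_conditions) for rep in range(n_replicates)
    ]
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    sheet = pd.DataFrame(
        {
            "sample": sample_ids,
            "condition": [f"C{c + 1}" for c in cond_of_sample],
            "replicate": [rep + 1 for c in range(n_conditions) for rep in range(n_replicates)],
        }
    )
    membership = pd.Series(
        {g: m + 1 for m in range(K) for g in
         [module_gene_name(m, j) for j in range(genes_per_module)]},
        name="module",
    )
    return SimulatedDataset(
        counts=counts_df,
        sample_sheet=sheet,
        gene_lengths=pd.Series(lengths, index=gene_ids, name="length_bp"),
        tf_ids=tf_ids,
        truth=truth,
        module_membership=membership,
    )


# ---------------------------------------------------------------------------
# on-disk fixture format: plain TSV/text files the pipeline consumes directly


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the standard pipeline input files plus ground-truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "sample_sheet": outdir / "sample_sheet.tsv",
        "gene_lengths": outdir / "gene_lengths.tsv",
        "tf_list": outdir / "tf_list.txt",
        "truth_edges": outdir / "truth_edges.tsv",
        "module_membership": outdir / "module_membership.tsv",
    }
    ds.counts.rename_axis("gene_id").to_csv(paths["counts"], sep="\t")
    ds.sample_sheet.to_csv(paths["sample_sheet"], sep="\t", index=False)
    ds.gene_lengths.rename_axis("gene_id").to_csv(paths["gene_lengths"], sep="\t")
    paths["tf_list"].write_text("\n".join(ds.tf_ids) + "\n")
    ds.truth.edge_frame().to_csv(paths["truth_edges"], sep="\t", index=False)
    ds.module_membership.rename_axis("gene_id").to_csv(
        paths["module_membership"], sep="\t"
    )
    return paths


def read_dataset(indir: str | Path) -> SimulatedDataset:
    """Read back a directory written by :func:`write_dataset`."""
    indir = Path(indir)
    counts = pd.read_csv(indir / "counts.tsv", sep="\t", index_col=0)
    counts.index.name = None
    sheet = pd.read_csv(indir / "sample_sheet.tsv", sep="\t")
    lengths = pd.read_csv(indir / "gene_lengths.tsv", sep="\t", index_col=0)[
        "length_bp"
    ]
    lengths.index.name = None
    tf_ids = [
        line.strip()
        for line in (indir / "tf_list.txt").read_text().splitlines()
        if line.strip()
    ]
    edge_df = pd.read_csv(indir / "truth_edges.tsv", sep="\t")
    membership = pd.read_csv(indir / "module_membership.tsv", sep="\t", index_col=0)[
        "module"
    ]
    membership.index.name = None
    n_tfs = len(tf_ids)
    n_modules = int(membership.max()) if len(membership) else 1
    tf_index = {name: i for i, name in enumerate(tf_ids)}
    edges = {
        (tf_index[row.tf], int(row.module) - 1): float(row.weight)
        for row in edge_df.itertuples()
    }
    truth = TruthNetwork(n_tfs=n_tfs, n_modules=n_modules, edges=edges)
    return SimulatedDataset(
        counts=counts,
        sample_sheet=sheet,
        gene_lengths=lengths,
        tf_ids=tf_ids,
        truth=truth,
        module_membership=membership,
    )


def default_fixture(seed: int = 0, **kwargs) -> SimulatedDataset:
    """The study-scale-down fixture: 40 TFs, 10 modules, 20 genes/module,
    2 conditions x 3 replicates (6 samples)."""
    net = simulate_network(seed=seed)
    return simulate_expression(net, seed=seed + 1, **kwargs)


def clustering_fixture(seed: int = 0) -> SimulatedDataset:
    """A low-noise, well-separated fixture for module-recovery benchmarks.

    Ten modules of 20 genes over 30 conditions with dense, strong regulation
    (edge density 0.2) and deep-sequencing count noise (NB dispersion 0.005,
    base mean ~1000 counts): module signals dominate every noise source, so a
    correct clustering procedure should recover the planted partition and K.
    """
    net = simulate_network(n_tfs=40, n_modules=10, edge_density=0.2, seed=seed)
    return simulate_expression(
        net,
        n_conditions=30,
        n_replicates=1,
        genes_per_module=20,
        module_noise_sd=0.05,
        gene_noise_sd=0.2,
        nb_dispersion=0.005,
        libsize_cv=0.1,
        base_log_mean=np.log(1000.0),
        seed=seed + 1000,
    )


def wide_fixture(seed: int = 0, n_conditions: int = 30, **kwargs) -> SimulatedDataset:
    """A 30-condition, single-replicate fixture for network-inference tests;
    inference on 6 columns is statistically degenerate, 30 is informative."""
    net = simulate_network(seed=seed)
    return simulate_expression(
        net, n_conditions=n_conditions, n_replicates=1, seed=seed + 1000, **kwargs
    )
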