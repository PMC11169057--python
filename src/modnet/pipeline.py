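"""End-to-end pipeline: configuration, validation, stage chaining, manifest.

Stage order: normalize → differential expression → module clustering →
network inference → consensus.  A single global seed fans out to per-stage
seeds by fixed offsets so stages are independently reproducible; re-running
with the same config and inputs reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import ModuleKMeans, heatmap_matrix
from .consensus import ConsensusGRN, export_network, network_stats
from .expression import (
    CountMatrix,
    average_replicates,
    deg_test,
    filter_degs,
    fpkm,
    ma_data,
    sample_qc,
    size_factors,
)
from .inference import build_inference_matrix

log = logging.getLogger("modnet")

__all__ = ["PipelineConfig", "run_all", "validate_inputs", "load_inputs"]

# per-stage seed offsets from the global seed
SEED_OFFSETS = {"simulate": 0, "cluster": 101, "infer": 211}


@dataclasses.dataclass
class PipelineConfig:
    """Every knob of the pipeline, round-trippable through YAML."""

    counts: str = "counts.tsv"
    sample_sheet: str = "sample_sheet.tsv"
    gene_lengths: str = "gene_lengths.tsv"
    tf_list: str = "tf_list.txt"
    outdir: str = "modnet_out"
    # DEG filter
    lfc_min: float = 1.0
    p_max: float = 0.05
    pseudocount: float = 1.0
    # clustering
    k_min: int = 10
    k_max: int = 100
    k_step: int = 5
    n_init: int = 10
    standardize: bool = True
    # inference / consensus
    methods: tuple = ("aracne", "clr", "lars", "pcor")
    mi_estimator: str = "gauss_copula"
    dpi_tolerance: float = 0.0
    lars_resamples: int = 200
    lars_steps: int = 3
    lars_fraction: float = 0.8
    top_fraction: float = 0.02
    min_support: int = 4
    sig: float = 5.0
    high: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_max < 1) or self.lfc_min <= 0:
            raise ValueError("invalid DEG thresholds")
        if self.k_min > self.k_max or self.k_step < 1:
            raise ValueError("invalid K grid")
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must be in (0, 1]")
        if not self.sig < self.high:
            raise ValueError("sig must be below high")
        if self.min_support < 1 or self.min_support > len(self.methods):
            raise ValueError("min_support must be in [1, n_methods]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "methods" in data:
            data["methods"] = tuple(data["methods"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["methods"] = list(d["methods"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_inputs(config: PipelineConfig):
    counts = pd.read_csv(config.counts, sep="\t", index_col=0)
    sheet = pd.read_csv(config.sample_sheet, sep="\t")
    lengths = pd.read_csv(config.gene_lengths, sep="\t", index_col=0).iloc[:, 0]
    tf_ids = [
        ln.strip()
        for ln in Path(config.tf_list).read_text().splitlines()
        if ln.strip()
    ]
    return CountMatrix(counts, lengths), sheet, tf_ids


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Return a list of human-readable problems; empty means inputs run cleanly."""
    problems: list[str] = []
    for key in ("counts", "sample_sheet", "gene_lengths", "tf_list"):
        p = Path(getattr(config, key))
        if not p.exists():
            raise OSError(f"cannot read {key} file: {p}")
    counts = pd.read_csv(config.counts, sep="\t", index_col=0)
    sheet = pd.read_csv(config.sample_sheet, sep="\t")
    lengths = pd.read_csv(config.gene_lengths, sep="\t", index_col=0).iloc[:, 0]
    tf_ids = [
        ln.strip()
        for ln in Path(config.tf_list).read_text().splitlines()
        if ln.strip()
    ]
    if counts.index.duplicated().any():
        problems.append(
            f"duplicate gene ids: {counts.index[counts.index.duplicated()].unique().tolist()[:5]}"
        )
    if counts.columns.duplicated().any():
        problems.append("duplicate sample ids in counts")
    non_numeric = counts.columns[
        [not np.issubdtype(dt, np.number) for dt in counts.dtypes]
    ].tolist()
    if non_numeric:
        problems.append(f"non-numeric count columns: {non_numeric}")
    else:
        neg = np.argwhere(counts.to_numpy() < 0)
        for i, j in neg[:5]:
            problems.append(
                f"negative count for gene {counts.index[i]} sample {counts.columns[j]}"
            )
    missing_len = counts.index.difference(lengths.index).tolist()
    if missing_len:
        problems.append(f"genes missing length annotation: {missing_len[:5]}")
    unmapped = set(counts.columns) - set(sheet["sample"])
    if unmapped:
        problems.append(f"samples absent from sample sheet: {sorted(unmapped)}")
    unknown_tfs = [t for t in tf_ids if t not in set(counts.index)]
    if unknown_tfs:
        problems.append(f"TF ids not present in counts: {unknown_tfs[:5]}")
    return problems


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_all(config: PipelineConfig) -> dict:
    """Run every stage, write all artifacts + a run manifest, return the manifest."""
    problems = validate_inputs(config)
    if problems:
        raise ValueError("input validation failed:\n" + "\n".join(problems))
    counts, sheet, tf_ids = load_inputs(config)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "modnet_version": __version__,
        "config": dataclasses.asdict(config) | {"methods": list(config.methods)},
        "counts": {},
    }

    # --- normalize ---------------------------------------------------------
    factors = size_factors(counts)
    expr = fpkm(counts, factors)
    _write_tsv(factors.to_frame(), out / "size_factors.tsv")
    _write_tsv(expr.values.rename_axis("gene_id"), out / "fpkm.tsv")
    log.info("normalize: %d genes x %d samples", *counts.values.shape)

    qc = sample_qc(expr.log2p1())
    _write_tsv(qc["correlation"], out / "qc_correlation.tsv")
    _write_tsv(qc["pcoa"].rename_axis("sample"), out / "pcoa.tsv")

    # --- differential expression ------------------------------------------
    conditions = list(dict.fromkeys(sheet["condition"]))
    if len(conditions) != 2:
        raise ValueError(
            f"DEG stage expects exactly 2 conditions, found {len(conditions)}"
        )
    group_a = sheet.loc[sheet.condition == conditions[0], "sample"].tolist()
    group_b = sheet.loc[sheet.condition == conditions[1], "sample"].tolist()
    table = deg_test(
        counts, group_a, group_b, factors,
        pseudocount=config.pseudocount,
        lfc_min=config.lfc_min, p_max=config.p_max,
    )
    _write_tsv(table.rename_axis("gene_id"), out / "deg_table.tsv")
    _write_tsv(ma_data(table, config.p_max).rename_axis("gene_id"), out / "ma_data.tsv")
    sets = filter_degs(table, config.lfc_min, config.p_max)
    de_genes = sets["all_de"]
    manifest["counts"]["deg_up"] = int(len(sets["up"]))
    manifest["counts"]["deg_down"] = int(len(sets["down"]))
    manifest["counts"]["deg_total"] = int(len(de_genes))
    log.info(
        "DEG: %d up + %d down = %d", len(sets["up"]), len(sets["down"]), len(de_genes)
    )
    if len(de_genes) < 3:
        raise ValueError("fewer than 3 DEGs: clustering cannot proceed")

    # --- module clustering -------------------------------------------------
    log_expr = expr.log2p1()
    cond_expr = average_replicates(log_expr, sheet)
    model = ModuleKMeans(
        cond_expr.values.loc[de_genes],
        k_min=config.k_min, k_max=config.k_max, step=config.k_step,
        standardize=config.standardize, n_init=config.n_init,
    )
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", UserWarning)
        res = model.fit(seed=config.seed + SEED_OFFSETS["cluster"])
    _write_tsv(res.labels.rename_axis("gene_id").to_frame(), out / "modules.tsv")
    _write_tsv(res.bic_curve.rename_axis("K").to_frame(), out / "bic_curve.tsv")
    _write_tsv(
        res.assignment.central_genes.rename_axis("module").to_frame(),
        out / "central_genes.tsv",
    )
    manifest["counts"]["n_modules"] = int(res.K)
    log.info("clustering: K = %d over %d DEGs", res.K, len(de_genes))

    # module profiles on per-sample expression: inference columns are the
    # experimental lines, not condition means
    profiles = res.profiles(log_expr.values)
    _write_tsv(profiles, out / "module_profiles.tsv")
    hm, row_order = heatmap_matrix(res.profiles(cond_expr.values))
    _write_tsv(hm, out / "heatmap_matrix.tsv")

    # --- inference ----------------------------------------------------------
    de_tfs = [t for t in tf_ids if t in set(de_genes)]
    manifest["counts"]["n_de_tfs"] = len(de_tfs)
    imat = build_inference_matrix(
        profiles, log_expr.values.loc[tf_ids], de_tf_ids=de_tfs
    )
    manifest["counts"]["inference_matrix_rows"] = int(imat.values.shape[0])
    manifest["counts"]["inference_matrix_cols"] = int(imat.values.shape[1])
    log.info(
        "inference matrix: %d modules + %d DE TFs = %d rows x %d lines",
        imat.n_modules, imat.n_tfs, imat.values.shape[0], imat.values.shape[1],
    )
    grn = ConsensusGRN(
        imat,
        methods=config.methods,
        top_fraction=config.top_fraction,
        min_support=config.min_support,
        sig=config.sig,
        high=config.high,
        mi_estimator=config.mi_estimator,
        dpi_tolerance=config.dpi_tolerance,
        lars_resamples=config.lars_resamples,
        lars_steps=config.lars_steps,
        lars_fraction=config.lars_fraction,
    )
    fitted = grn.fit(seed=config.seed + SEED_OFFSETS["infer"])
    all_scores = pd.concat([sm.long() for sm in fitted.scores], ignore_index=True)
    _write_tsv(all_scores, out / "scores.tsv", index=False)
    for sm in fitted.scores:
        _write_tsv(sm.values.rename_axis("tf"), out / f"scores_{sm.method}.tsv")

    # --- consensus ----------------------------------------------------------
    export_network(fitted.network, out / "consensus_edges.tsv", "tsv")
    export_network(fitted.network, out / "network.sif", "sif")
    export_network(fitted.network, out / "network.graphml", "graphml")
    st = network_stats(fitted.network)
    _write_tsv(st["degree"], out / "degree.tsv", index=False)
    _write_tsv(
        pd.concat([st["hub_tfs"], st["hub_modules"]], ignore_index=True),
        out / "hubs.tsv", index=False,
    )
    manifest["counts"]["consensus_edges"] = int(len(fitted.edges))
    manifest["counts"]["all_method_edges"] = int(
        (fitted.edges.support == len(fitted.scores)).sum()
    )
    (out / "summary.txt").write_text(res.summary() + "\n\n" + fitted.summary() + "\n")

    manifest["files"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.suffix in
        {".tsv", ".sif", ".graphml", ".txt"}
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
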