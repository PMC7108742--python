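"""End-to-end pipeline orchestration: preprocess -> diagnostics -> clustering
-> differential expression -> penalized selection -> co-expression ->
survival -> interaction networks, with every stage's tables collected into
the analysis-organized output tree."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import coexpr as _coexpr
from . import dea as _dea
from . import distcheck as _distcheck
from . import network as _network
from . import preprocess as _pre
from . import select as _select
from . import survival as _survival
from .io_meta import (ExpressionMatrix, RunConfig, SampleMetadata,
                      write_output_tree)


@dataclass
class PipelineResult:
    matrix: ExpressionMatrix
    meta: SampleMetadata
    dea_tables: dict[str, pd.DataFrame]
    up: set[str]
    down: set[str]
    en_runs: list
    en_frequency: pd.DataFrame
    en_set: set[str]
    consensus: _select.ConsensusSet
    report: _pre.NormalizationReport
    clustering: _cluster.ClusteringResult | None = None
    modules: _coexpr.ModuleSet | None = None
    module_fit: pd.DataFrame | None = None
    module_tops: dict[int, pd.DataFrame] = field(default_factory=dict)
    survival_table: pd.DataFrame | None = None
    survival_checks: pd.DataFrame | None = None
    network_top: pd.DataFrame | None = None
    network_full: pd.DataFrame | None = None
    bundles: dict[str, dict[str, pd.DataFrame]] = field(default_factory=dict)
    manifest: list[str] | None = None


def run_pipeline(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    config: RunConfig,
    transform: str = "none",
    center: str = "none",
    impute_method: str = "lls",
    impute_k: int = 10,
    write: bool = True,
) -> PipelineResult:
    """Run every requested analysis and (optionally) write the output tree.

    ``transform``/``center`` apply to continuous datatypes; count data follow
    the filter -> TMM -> precision-weight route. All randomness derives from
    ``config.seed``.
    """
    meta.check_against(matrix)
    meta = meta.aligned_to(matrix.sample_ids)
    report = _pre.NormalizationReport()
    bundles: dict[str, dict[str, pd.DataFrame]] = {}

    # -- preprocessing ------------------------------------------------------
    weights = None
    if matrix.missing_mask.any():
        matrix, n_imp = _pre.impute_missing(matrix, impute_method, impute_k)
        report.n_imputed = n_imp
    if config.datatype == "seq":
        matrix, removed = _pre.filter_low_counts(matrix, meta)
        report.n_filtered = len(removed)
        report.removed_ids = removed
        report.library_sizes = matrix.values.sum(axis=0)
        factors = _pre.tmm_factors(matrix)
        report.tmm_factors = factors
        design = _dea.build_design(meta)
        voom = _pre.voom_transform(matrix, factors, design.matrix)
        Y = voom.logcpm
        weights = voom.weights
        report.transformation = "voom"
        bundles["preprocess"] = {
            "tmm_factors.tsv": pd.DataFrame(
                {"sample_id": matrix.sample_ids, "lib_size": report.library_sizes,
                 "tmm_factor": factors}),
            "voom_trend.tsv": pd.DataFrame(
                {"mean_logcpm": voom.trend_x, "sqrt_sd": voom.trend_y}),
        }
    else:
        if transform != "none" or center != "none":
            matrix = _pre.normalize_continuous(matrix, transform, center)
            report.transformation = transform
            report.centering = center
        Y = matrix.values
        bundles["preprocess"] = {}
    bundles["preprocess"]["report.tsv"] = pd.DataFrame(
        [{
            "transformation": report.transformation,
            "centering": report.centering,
            "n_filtered": report.n_filtered,
            "n_imputed": report.n_imputed,
        }]
    )

    # -- distributional checks ---------------------------------------------
    reports = _distcheck.distcheck_random_variables(
        Y, matrix.variable_ids, n_variables=10, replicates=100, seed=config.seed)
    bundles["distcheck"] = {
        "moments.tsv": pd.DataFrame(
            [{"id": r.variable_id, "skewness": r.skewness, "kurtosis": r.kurtosis,
              "best_fit": r.best_fit.name if r.best_fit else ""} for r in reports]),
    }

    # -- clustering ---------------------------------------------------------
    clustering = None
    if config.kmeans:
        coords, share = _cluster.classical_mds(matrix, top_n=500)
        S = _top_variable_features(Y, 500)
        clustering = _cluster.select_k_bic(S, seed=config.seed)
        clustering.mds = coords
        clustering.mds_eigenvalue_share = share
        best = clustering.per_k[clustering.selected_k]
        meta_aug = meta.table.copy()
        meta_aug["kmeans_cluster"] = best.assignments
        bundles["cluster"] = {
            "bic.tsv": clustering.bic_table(),
            "mds.tsv": pd.DataFrame(
                {"sample_id": matrix.sample_ids, "dim1": coords[:, 0],
                 "dim2": coords[:, 1]}),
            "metadata_with_clusters.tsv": meta_aug.reset_index(
                names="sample_id"),
        }

    # -- differential expression -------------------------------------------
    dea_tables = _dea.run_dea(Y, matrix.variable_ids, meta, weights)
    up: set[str] = set()
    down: set[str] = set()
    bundles["dea"] = {}
    for name, table in dea_tables.items():
        u, d = _dea.significant_set(table, config.fdr, config.logfc)
        up |= u
        down |= d
        safe = name.replace("/", "_")
        bundles["dea"][f"{safe}.tsv"] = table
        bundles["dea"][f"{safe}_up.tsv"] = pd.DataFrame({"id": sorted(u)})
        bundles["dea"][f"{safe}_down.tsv"] = pd.DataFrame({"id": sorted(d)})
    de_ids = up | down

    # -- penalized selection -----------------------------------------------
    labels = meta.groups.to_numpy()
    en_runs, en_freq, en_set = _select.repeated_selection(
        Y, matrix.variable_ids, labels, alpha=config.alpha, runs=config.runs,
        base_seed=config.seed)
    consensus = _select.consensus_overlap(de_ids, en_set)
    per_run = pd.DataFrame(
        [{"run": r.run_index, "seed": r.seed, "chosen_lambda": r.chosen_lambda,
          "cv_min_deviance": float(np.min(r.cv_mean)),
          "n_selected": len(r.selected),
          "auc": np.nan if r.auc is None else r.auc,
          "split": r.split} for r in en_runs])
    joined = en_freq.copy()
    first = next(iter(dea_tables.values())).set_index("id")
    joined["logFC"] = [float(first.loc[i, "logFC"]) if i in first.index else np.nan
                       for i in joined["id"]]
    joined["FDR"] = [float(first.loc[i, "adj.P.Val"]) if i in first.index else np.nan
                     for i in joined["id"]]
    bundles["select"] = {
        "runs.tsv": per_run,
        "frequency.tsv": en_freq,
        "consensus.tsv": joined[joined["id"].isin(consensus.intersection)],
        "venn.tsv": pd.DataFrame([consensus.venn_counts()]),
    }

    # -- co-expression ------------------------------------------------------
    modules = module_fit = None
    module_tops: dict[int, pd.DataFrame] = {}
    if config.wgcna != "none":
        if config.wgcna == "de":
            wanted = [v for v in matrix.variable_ids if v in de_ids]
        else:
            wanted = list(matrix.variable_ids)
        if len(wanted) >= 3:
            sub_idx = [matrix.variable_ids.index(v) for v in wanted]
            Xw = Y[sub_idx]
            modules, module_fit, module_tops = _coexpr.wgcna_modules(
                Xw, wanted, seed=config.seed)
            bundles["coexpr"] = {
                "modules.tsv": pd.DataFrame(
                    {"id": wanted, "module": modules.labels,
                     "kWithin": modules.k_within}),
                "soft_threshold.tsv": module_fit,
            }
            for m, top in module_tops.items():
                bundles["coexpr"][f"module{m}_top.tsv"] = top
            if modules.eigengenes:
                bundles["coexpr"]["eigengenes.tsv"] = pd.DataFrame(
                    {f"ME{m}": e for m, e in modules.eigengenes.items()}
                ).assign(sample_id=matrix.sample_ids)

    # -- survival -----------------------------------------------------------
    survival_table = survival_checks = None
    if config.survival and meta.has_survival:
        records = _survival.survival_records(meta)
        screen_ids = sorted(de_ids) if de_ids else list(matrix.variable_ids)
        idx = [matrix.variable_ids.index(v) for v in screen_ids]
        adjust_cols = ["age"] + [c for c in meta.covariate_cols]
        adjust = meta.table[adjust_cols].to_numpy(float)
        survival_table, survival_checks = _survival.survival_screen(
            Y[idx], screen_ids, records["time"].to_numpy(),
            records["event"].to_numpy(), adjust, adjust_cols,
            fdr_cut=config.fdr)
        bundles["survival"] = {
            "cox_screen.tsv": survival_table,
            "assumption_checks.tsv": survival_checks,
        }

    # -- interaction networks ----------------------------------------------
    network_top = network_full = None
    if config.ppi_path:
        edges, _ = _network.load_interaction_table(config.ppi_path, "string_pp")
        first_table = next(iter(dea_tables.values()))
        inter = _network.extract_de_pairs(edges, first_table, de_ids)
        network_top, network_full = _network.rank_edges(inter, top_n=100)
        bundles["network"] = {
            "interactions.tsv": network_full,
            "top100.tsv": network_top,
        }

    result = PipelineResult(
        matrix=matrix, meta=meta, dea_tables=dea_tables, up=up, down=down,
        en_runs=en_runs, en_frequency=en_freq, en_set=en_set,
        consensus=consensus, report=report, clustering=clustering,
        modules=modules, module_fit=module_fit, module_tops=module_tops,
        survival_table=survival_table, survival_checks=survival_checks,
        network_top=network_top, network_full=network_full, bundles=bundles,
    )
    if write:
        result.manifest = write_output_tree(bundles, config.outdir,
                                            overwrite=config.overwrite)
    return result


def _top_variable_features(Y: np.ndarray, top_n: int) -> np.ndarray:
    variances = Y.var(axis=1)
    top = np.argsort(-variances, kind="stable")[: min(top_n, Y.shape[0])]
    return Y[top].T
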