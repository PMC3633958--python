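"""End-to-end pipeline: QC -> scores -> staged search -> core-SNP report.

Everything is driven by one flat YAML config and one seed; all randomness
(folds, per-combination permutation streams) is derived from that seed, so
identical config + inputs give byte-identical outputs. Subjects are sorted
by subject id before analysis, making results invariant to input row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .data_model import Dataset
from .engine import make_folds
from .io import (
    read_matrix_tsv,
    read_plink_text,
    write_core_snps_tsv,
    write_results_tsv,
    write_selection_tsv,
)
from .data_model import validate_dataset
from .permutation import PermutationConfig
from .qc import QCThresholds, apply_qc
from .scores import compute_scores, load_scores, write_scores
from .search import (
    SearchConfig,
    conditioned_search,
    detect_core_snps,
    exhaustive_search,
    harvest_top_snps,
    significance_filter,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Flat configuration of a full run; see the worked example in README."""

    # inputs (either ped+map, or genotypes_tsv [+ phenotype_tsv/covariates_tsv])
    ped: str | None = None
    map: str | None = None
    genotypes_tsv: str | None = None
    phenotype_tsv: str | None = None
    covariates_tsv: str | None = None
    scores_file: str | None = None  # user-supplied scores bypass the GLM
    trait: str = "binary"
    family: str = "auto"
    # analysis
    seed: int = 0
    folds: int = 10
    stratify: bool | None = None  # default: True for binary traits
    orders: list[int] = field(default_factory=lambda: [2])
    top_n_per_fold: int = 1  # also controls SNP harvesting for orders >= 3
    min_pair_distance_bp: int = 1_000_000
    # QC
    qc: bool = True
    max_missing: float = 0.10
    min_maf: float = 0.05
    min_hwe_p: float = 0.001
    hwe_method: str = "exact"
    # significance
    n_perm: int = 10_000
    perm_comparison: str = "ge"
    final_cvc_min: int = 7
    final_p_max: float | None = None  # default: 1/n_perm (permutation resolution)
    core_min_models: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    dataset: Dataset
    qc_report: object
    all_results: list
    significant: list
    core_snps: list
    output_dir: Path


def _load_dataset(config: PipelineConfig) -> Dataset:
    if config.genotypes_tsv:
        return read_matrix_tsv(
            config.genotypes_tsv,
            config.phenotype_tsv,
            config.covariates_tsv,
            trait_kind=config.trait,
        )
    if config.ped and config.map:
        genotypes, phenotype = read_plink_text(config.ped, config.map)
        return validate_dataset(genotypes, phenotype, None)
    raise ValueError("config must name either genotypes_tsv or ped+map inputs")


def run_pipeline(config: PipelineConfig, output_dir: str | Path) -> PipelineResult:
    """Execute every stage and write the result tables into ``output_dir``."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"gmdr {__version__}", "config:"]
    for key, val in asdict(config).items():
        log_lines.append(f"  {key}: {val}")

    dataset = _load_dataset(config).sort_subjects()
    log_lines.append(
        f"loaded {dataset.n_subjects} subjects x {dataset.genotypes.n_snps} SNPs "
        f"({dataset.n_removed} subjects removed by listwise deletion)"
    )

    # --- QC
    qc_report = None
    if config.qc:
        control_mask = None
        if dataset.phenotype.trait_kind == "binary":
            control_mask = dataset.phenotype.values == 0.0
        thresholds = QCThresholds(
            max_missing=config.max_missing,
            min_maf=config.min_maf,
            min_hwe_p=config.min_hwe_p,
        )
        filtered, qc_report = apply_qc(
            dataset.genotypes, control_mask, thresholds, hwe_method=config.hwe_method
        )
        qc_report.write_tsv(out / "qc_report.tsv")
        log_lines.append(
            f"QC: {qc_report.n_kept} SNPs remained, {qc_report.n_removed} removed"
        )
        dataset = Dataset(
            genotypes=filtered,
            phenotype=dataset.phenotype,
            covariates=dataset.covariates,
            n_removed=dataset.n_removed,
        )

    # --- scores
    if config.scores_file:
        scores = load_scores(config.scores_file, expected_n=dataset.n_subjects)
        log_lines.append(f"scores: user-supplied from {config.scores_file}")
    else:
        scores = compute_scores(dataset.phenotype, dataset.covariates, config.family)
        log_lines.append(
            f"scores: computed ({config.family} family, "
            f"{dataset.covariates.n_covariates} covariates)"
        )
    write_scores(scores, out / "scores.tsv", dataset.genotypes.subject_ids)

    # --- folds
    stratify = config.stratify
    if stratify is None:
        stratify = dataset.phenotype.trait_kind == "binary"
    labels = dataset.phenotype.values if stratify else None
    folds = make_folds(dataset.n_subjects, config.folds, config.seed, labels)

    # --- staged search
    search_cfg = SearchConfig(
        min_pair_distance_bp=config.min_pair_distance_bp,
        top_n_per_fold=config.top_n_per_fold,
        final_cvc_min=config.final_cvc_min,
        final_p_max=config.final_p_max or 1.0 / config.n_perm,
        core_min_models=config.core_min_models,
    )
    perm_cfg = PermutationConfig(
        n_perm=config.n_perm, seed=config.seed, comparison=config.perm_comparison
    )
    orders = sorted(set(config.orders))
    if not orders or orders[0] != 2:
        raise ValueError("orders must start with the exhaustive two-way search")

    all_results = []
    snps = dataset.genotypes.snps
    two_way = exhaustive_search(dataset, scores, folds, search_cfg, 2, perm_cfg)
    log_lines.append(
        f"order 2: {two_way.n_combinations_evaluated} combinations evaluated, "
        f"{len(two_way.results)} candidates (CVC > {folds.K // 2}/{folds.K})"
    )
    write_selection_tsv(
        two_way.selection, two_way.evaluations, snps, out / "selection_order2.tsv"
    )
    all_results.extend(two_way.results)

    higher = [k for k in orders if k >= 3]
    if higher:
        subset = harvest_top_snps(two_way.selection)
        log_lines.append(
            f"harvest: {len(subset)} unique SNPs from the top "
            f"{config.top_n_per_fold} two-way models per fold"
        )
        for k in higher:
            outcome = conditioned_search(
                dataset, scores, folds, subset, k, search_cfg, perm_cfg
            )
            log_lines.append(
                f"order {k}: {outcome.n_combinations_evaluated} combinations "
                f"evaluated, {len(outcome.results)} candidates"
            )
            all_results.extend(outcome.results)

    significant = significance_filter(
        all_results, search_cfg.final_cvc_min, search_cfg.final_p_max, config.n_perm
    )
    log_lines.append(
        f"significance filter (CVC >= {search_cfg.final_cvc_min}, "
        f"p <= {search_cfg.final_p_max:g}): {len(significant)} models kept"
    )
    cores = detect_core_snps(significant, snps, search_cfg.core_min_models)
    log_lines.append(
        f"core SNPs (>= {search_cfg.core_min_models} significant models): {len(cores)}"
    )

    core_ids = {c.snp_id for c in cores}
    write_results_tsv(all_results, snps, out / "results_all.tsv", core_ids)
    write_results_tsv(significant, snps, out / "results_significant.tsv", core_ids)
    write_core_snps_tsv(cores, snps, out / "core_snps.tsv")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    for line in log_lines:
        logger.info("%s", line)

    return PipelineResult(
        dataset=dataset,
        qc_report=qc_report,
        all_results=all_results,
        significant=significant,
        core_snps=cores,
        output_dir=out,
    )
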