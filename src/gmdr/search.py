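"""Staged interaction search: enumeration, filters, harvesting, core SNPs.

The staged analysis runs an exhaustive two-way search (skipping SNP pairs
closer than 1 Mb on the same chromosome, a linkage-disequilibrium guard),
harvests the unique SNPs appearing in each fold's top-ranked pairs, and then
runs three- to five-way searches restricted to those SNPs. Models surviving
the CVC output rule receive permutation p-values; a final filter keeps
models with CVC >= final_cvc_min and p <= final_p_max, and SNPs recurring
across several significant models (possibly at different orders) are
reported as core SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations as iter_combinations
from typing import Iterator, Sequence

import numpy as np

from .data_model import Dataset, SNPInfo, ScoreVector
from .engine import (
    CombinationEvaluation,
    FoldAssignment,
    InteractionResult,
    SelectionResult,
    evaluate_combination,
    rank_and_select,
)
from .permutation import PermutationConfig, permutation_pvalue

logger = logging.getLogger(__name__)

__all__ = [
    "SearchConfig",
    "SearchOutcome",
    "CoreSNP",
    "enumerate_combinations",
    "exhaustive_search",
    "harvest_top_snps",
    "conditioned_search",
    "significance_filter",
    "detect_core_snps",
]


@dataclass(frozen=True)
class SearchConfig:
    """Thresholds of the staged analysis.

    ``min_pair_distance_bp``: same-chromosome pairs strictly closer than
    this are skipped (1 Mb default). ``top_n_per_fold``: models selected per
    training set (1 by default; large values feed SNP harvesting).
    ``candidate_cvc_fraction``: candidates must have CVC strictly greater
    than this fraction of K (default CVC > K/2). ``final_cvc_min`` and
    ``final_p_max`` define the significance filter (CVC >= 7 of 10 and
    p <= 1e-7 in the method's genome-wide configuration).
    """

    min_pair_distance_bp: int = 1_000_000
    top_n_per_fold: int = 1
    candidate_cvc_fraction: float = 0.5
    final_cvc_min: int = 7
    final_p_max: float = 1e-7
    core_min_models: int = 2

    def __post_init__(self) -> None:
        if self.min_pair_distance_bp < 0:
            raise ValueError("min_pair_distance_bp must be >= 0")
        if not 0.0 <= self.candidate_cvc_fraction < 1.0:
            raise ValueError("candidate_cvc_fraction must be in [0, 1)")
        if not 0.0 < self.final_p_max <= 1.0:
            raise ValueError("final_p_max must be in (0, 1]")


def _conflict_matrix(snps: Sequence[SNPInfo], min_dist: int) -> np.ndarray:
    """Boolean matrix: True where two SNPs are same-chromosome and < min_dist apart."""
    m = len(snps)
    chrom = np.array([s.chromosome for s in snps], dtype=object)
    pos = np.array([s.position_bp for s in snps], dtype=np.int64)
    same = chrom[:, None] == chrom[None, :]
    close = np.abs(pos[:, None] - pos[None, :]) < min_dist
    conflict = same & close
    np.fill_diagonal(conflict, False)
    return conflict


def enumerate_combinations(
    snps: Sequence[SNPInfo],
    k: int,
    min_pair_distance_bp: int = 1_000_000,
    indices: Sequence[int] | None = None,
) -> Iterator[tuple[int, ...]]:
    """Lexicographic stream of size-k index tuples passing the distance filter.

    A tuple is skipped if any two of its SNPs lie on the same chromosome
    strictly closer than ``min_pair_distance_bp`` (exactly that distance
    passes); SNPs on different chromosomes are never filtered. ``indices``
    restricts the search to a subset of SNP columns (used by the
    conditioned search); emitted tuples are global column indices.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pool = sorted(int(i) for i in indices) if indices is not None else list(range(len(snps)))
    if k > len(pool):
        return
    conflict = _conflict_matrix(snps, min_pair_distance_bp)
    for combo in iter_combinations(pool, k):
        ok = True
        for a, b in iter_combinations(combo, 2):
            if conflict[a, b]:
                ok = False
                break
        if ok:
            yield combo


@dataclass
class CoreSNP:
    """A SNP recurring across multiple significant interaction models."""

    snp_index: int
    snp_id: str
    models: list[InteractionResult]
    orders: set[int]

    @property
    def n_models(self) -> int:
        return len(self.models)


@dataclass
class SearchOutcome:
    """Everything one order's search produced, for reporting and harvesting."""

    order: int
    results: list[InteractionResult]  # candidates passing the CVC rule, p attached
    selection: SelectionResult
    n_combinations_evaluated: int
    evaluations: dict[tuple[int, ...], CombinationEvaluation] = field(default_factory=dict)


def _sort_results(results: list[InteractionResult]) -> list[InteractionResult]:
    return sorted(
        results, key=lambda r: (-r.testing_accuracy, -r.cvc, r.combination)
    )


def _run_search(
    dataset: Dataset,
    scores: ScoreVector,
    folds: FoldAssignment,
    combos: Iterator[tuple[int, ...]],
    k: int,
    config: SearchConfig,
    perm_config: PermutationConfig | None,
) -> SearchOutcome:
    evaluations: dict[tuple[int, ...], CombinationEvaluation] = {}
    n_eval = 0
    values = dataset.genotypes.values
    for combo in combos:
        ev = evaluate_combination(values, scores, combo, folds)
        n_eval += 1
        if ev is not None:
            evaluations[combo] = ev
    selection = rank_and_select(
        list(evaluations.values()),
        K=folds.K,
        top_n=config.top_n_per_fold,
        cvc_retain_fraction=config.candidate_cvc_fraction,
    )
    results = []
    for combo in selection.retained:
        ev = evaluations[combo]
        res = InteractionResult(
            combination=combo,
            cvc=selection.cvc[combo],
            K=folds.K,
            training_accuracy=ev.training_accuracy,
            testing_accuracy=ev.testing_accuracy,
            testing_accuracy_per_fold=ev.testing_accuracy_per_fold,
        )
        if perm_config is not None:
            perm = permutation_pvalue(
                values, scores, combo, folds, ev.testing_accuracy, perm_config
            )
            res.p_value = perm.p_value
            res.p_is_bound = perm.is_bound
            res.n_perm = perm.N
        results.append(res)
    if not results:
        logger.info("order-%d search: no combination passed the CVC rule", k)
    return SearchOutcome(
        order=k,
        results=_sort_results(results),
        selection=selection,
        n_combinations_evaluated=n_eval,
        evaluations=evaluations,
    )


def exhaustive_search(
    dataset: Dataset,
    scores: ScoreVector,
    folds: FoldAssignment,
    config: SearchConfig = SearchConfig(),
    k: int = 2,
    perm_config: PermutationConfig | None = None,
) -> SearchOutcome:
    """Evaluate every distance-filtered k-way combination of all SNPs."""
    combos = enumerate_combinations(
        dataset.genotypes.snps, k, config.min_pair_distance_bp
    )
    return _run_search(dataset, scores, folds, combos, k, config, perm_config)


def conditioned_search(
    dataset: Dataset,
    scores: ScoreVector,
    folds: FoldAssignment,
    snp_subset: Sequence[int],
    k: int,
    config: SearchConfig = SearchConfig(),
    perm_config: PermutationConfig | None = None,
) -> SearchOutcome:
    """k-way search restricted to a harvested SNP subset (same machinery)."""
    subset = sorted(set(int(i) for i in snp_subset))
    if len(subset) < k:
        logger.warning(
            "conditioned order-%d search skipped: only %d SNPs in subset",
            k,
            len(subset),
        )
        return SearchOutcome(
            order=k,
            results=[],
            selection=rank_and_select([], K=folds.K, top_n=config.top_n_per_fold),
            n_combinations_evaluated=0,
        )
    combos = enumerate_combinations(
        dataset.genotypes.snps, k, config.min_pair_distance_bp, indices=subset
    )
    return _run_search(dataset, scores, folds, combos, k, config, perm_config)


def harvest_top_snps(
    selection: SelectionResult, top_n_per_fold: int | None = None
) -> list[int]:
    """Unique, sorted SNP indices in each fold's top-ranked combinations."""
    top_n = selection.top_n if top_n_per_fold is None else top_n_per_fold
    snps: set[int] = set()
    for chosen in selection.per_fold_selected:
        for combo in chosen[:top_n]:
            snps.update(combo)
    return sorted(snps)


def significance_filter(
    results: Sequence[InteractionResult],
    final_cvc_min: int = 7,
    final_p_max: float = 1e-7,
    n_perm: int | None = None,
) -> list[InteractionResult]:
    """Keep models with CVC >= final_cvc_min and p <= final_p_max.

    A bound "< 1/N" (M = 0) qualifies iff 1/N <= final_p_max; the stored
    p_value is 1/N in that case, so one comparison covers both. Warns when
    the permutation resolution cannot certify the threshold.
    """
    if n_perm is not None and final_p_max < 1.0 / n_perm:
        if not any(r.p_is_bound for r in results):
            logger.warning(
                "final_p_max=%g is below the permutation resolution 1/%d; "
                "no non-bound p-value can satisfy it",
                final_p_max,
                n_perm,
            )
    kept = [
        r
        for r in results
        if r.cvc >= final_cvc_min
        and r.p_value is not None
        and r.p_value <= final_p_max
    ]
    return _sort_results(kept)


def detect_core_snps(
    significant_results: Sequence[InteractionResult],
    snps: Sequence[SNPInfo],
    core_min_models: int = 2,
) -> list[CoreSNP]:
    """SNPs appearing in at least ``core_min_models`` distinct significant models.

    Models may be of any interaction order; the report lists, per core SNP,
    its supporting models and the set of orders they span.
    """
    if core_min_models < 1:
        raise ValueError("core_min_models must be >= 1")
    support: dict[int, list[InteractionResult]] = {}
    for res in significant_results:
        for idx in res.combination:
            support.setdefault(idx, []).append(res)
    cores = []
    for idx in sorted(support):
        models = support[idx]
        if len(models) >= core_min_models:
            cores.append(
                CoreSNP(
                    snp_index=idx,
                    snp_id=snps[idx].snp_id,
                    models=models,
                    orders={m.order for m in models},
                )
            )
    return cores
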