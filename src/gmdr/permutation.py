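"""Permutation test of the observed testing accuracy.

For each of N permutations the subject scores are shuffled uniformly at
random (genotypes and the fold assignment stay fixed), the cell models are
re-fit in every training set, and the mean testing accuracy is re-computed.
The p-value is M/N where M counts permutations whose accuracy is at least
the observed one. When M = 0 the result is reported as the bound "< 1/N"
rather than zero (an add-one estimator (M+1)/(N+1) is available).

The permutation stream for a combination is seeded from the global seed and
the combination's index tuple, so p-values do not depend on the order in
which combinations are evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .data_model import GenotypeMatrix, ScoreVector
from .engine import FoldAssignment, assign_cells

__all__ = ["PermutationConfig", "PermutationResult", "permutation_pvalue"]

_STREAM_SALT = 0x6D64_7221  # keeps per-combination streams disjoint from other rngs

#: Tie tolerance when comparing a permuted accuracy with the observed one;
#: both are means of ratios of floating-point sums, so exact ties must not
#: be broken by rounding noise.
_TIE_EPS = 1e-12


@dataclass(frozen=True)
class PermutationConfig:
    """Settings for the permutation test (method default 10^7; here 10^4)."""

    n_perm: int = 10_000
    seed: int = 0
    comparison: Literal["ge", "gt"] = "ge"
    estimator: Literal["bound", "add_one"] = "bound"
    batch_size: int = 512

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass(frozen=True)
class PermutationResult:
    p_value: float
    is_bound: bool  # True when reported as "< 1/N" (M = 0)
    M: int
    N: int

    def __str__(self) -> str:
        return f"<{self.p_value:.0e}" if self.is_bound else f"{self.p_value:.6g}"


def _combination_rng(seed: int, combination: Sequence[int]) -> np.random.Generator:
    entropy = [int(seed) & 0x7FFF_FFFF, _STREAM_SALT, *(int(c) for c in combination)]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def permutation_pvalue(
    genotypes: GenotypeMatrix | np.ndarray,
    scores: ScoreVector | np.ndarray,
    combination: Sequence[int],
    folds: FoldAssignment,
    observed_testing_accuracy: float,
    config: PermutationConfig = PermutationConfig(),
) -> PermutationResult:
    """Monte-Carlo permutation p-value for one SNP combination.

    Permutations are processed in batches; within a batch, per-fold cell
    sums for all permutations are obtained with one matrix product against
    the training set's cell-indicator matrix, and the score-weighted
    balanced accuracy is evaluated vectorised over permutations.
    """
    s = scores.values if isinstance(scores, ScoreVector) else np.asarray(scores, float)
    combo = tuple(int(c) for c in combination)
    cells = assign_cells(genotypes, combo)
    valid = cells >= 0
    K = folds.K
    n_cells = 3 ** len(combo)
    fold_of = folds.fold_of_subject

    # per-fold fixed structures
    fold_train_idx: list[np.ndarray] = []
    fold_train_onehot: list[np.ndarray] = []
    fold_test_idx: list[np.ndarray] = []
    fold_test_cells: list[np.ndarray] = []
    for f in range(K):
        tr = np.flatnonzero(valid & (fold_of != f))
        te = np.flatnonzero(valid & (fold_of == f))
        onehot = np.zeros((len(tr), n_cells))
        onehot[np.arange(len(tr)), cells[tr]] = 1.0
        fold_train_idx.append(tr)
        fold_train_onehot.append(onehot)
        fold_test_idx.append(te)
        fold_test_cells.append(cells[te])

    rng = _combination_rng(config.seed, combo)
    N = config.n_perm
    M = 0
    done = 0
    while done < N:
        B = min(config.batch_size, N - done)
        S = np.tile(s, (B, 1))
        S = rng.permuted(S, axis=1)
        acc = np.zeros(B)
        for f in range(K):
            sums = S[:, fold_train_idx[f]] @ fold_train_onehot[f]  # (B, n_cells)
            high = sums > 0
            st = S[:, fold_test_idx[f]]  # (B, n_test)
            is_high = high[:, fold_test_cells[f]] if st.shape[1] else np.zeros_like(st, bool)
            pos = st > 0
            neg = st < 0
            sum_pos = np.where(pos, st, 0.0).sum(axis=1)
            sum_neg = -np.where(neg, st, 0.0).sum(axis=1)
            hit_pos = np.where(pos & is_high, st, 0.0).sum(axis=1)
            hit_neg = -np.where(neg & ~is_high, st, 0.0).sum(axis=1)
            term_pos = np.where(sum_pos > 0, hit_pos / np.where(sum_pos > 0, sum_pos, 1.0), 0.5)
            term_neg = np.where(sum_neg > 0, hit_neg / np.where(sum_neg > 0, sum_neg, 1.0), 0.5)
            acc += 0.5 * (term_pos + term_neg)
        acc /= K
        if config.comparison == "ge":
            M += int(np.sum(acc >= observed_testing_accuracy - _TIE_EPS))
        else:
            M += int(np.sum(acc > observed_testing_accuracy + _TIE_EPS))
        done += B

    if M == 0 and config.estimator == "bound":
        return PermutationResult(p_value=1.0 / N, is_bound=True, M=0, N=N)
    if config.estimator == "add_one":
        return PermutationResult(p_value=(M + 1) / (N + 1), is_bound=False, M=M, N=N)
    return PermutationResult(p_value=M / N, is_bound=False, M=M, N=N)
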