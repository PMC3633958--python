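"""Cross-validated cell classification, accuracy, ranking and CVC.

A k-SNP combination partitions subjects into at most 3^k genotype cells.
Within a training fold each occupied cell is labelled high-risk when the sum
of its subjects' scores is positive and low-risk otherwise (ties and cells
never seen in training count as low-risk; scores are mean-zero, so 0 is the
natural threshold). The quality of a labelling on any subject set is the
score-weighted balanced accuracy

    acc = 1/2 * [ sum(s_i : i high-labelled, s_i > 0) / sum(s_i : s_i > 0)
                + sum(|s_i| : i low-labelled, s_i < 0) / sum(|s_i| : s_i < 0) ]

which reduces to classical MDR balanced accuracy when scores are +/-constant
(binary trait, no covariates). If an evaluation set has no positive-score
(or no negative-score) subjects the corresponding ratio term is set to 1/2.

K-fold cross-validation yields per-fold training accuracies (used to rank
combinations and compute the cross-validation consistency, CVC) and a mean
testing accuracy (the headline statistic, later assessed by permutation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Literal, Sequence

import numpy as np

from .data_model import GenotypeMatrix, ScoreVector

logger = logging.getLogger(__name__)

__all__ = [
    "FoldAssignment",
    "CellModel",
    "CombinationEvaluation",
    "InteractionResult",
    "SelectionResult",
    "make_folds",
    "assign_cells",
    "classify_cells",
    "balanced_accuracy",
    "evaluate_combination",
    "rank_and_select",
]


@dataclass
class FoldAssignment:
    """K-fold partition of subjects; fold sizes differ by at most one."""

    K: int
    fold_of_subject: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.fold_of_subject = np.asarray(self.fold_of_subject, dtype=np.int64)

    @property
    def n_subjects(self) -> int:
        return len(self.fold_of_subject)


def make_folds(
    n: int,
    K: int = 10,
    seed: int = 0,
    stratify_labels: Sequence | None = None,
) -> FoldAssignment:
    """Seeded equal-size random partition into K folds.

    With ``stratify_labels`` each label group is spread across folds as
    evenly as possible (the cyclic assignment continues across groups, so
    overall fold sizes still differ by at most one).
    """
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    if n < K:
        raise ValueError(f"cannot build {K} folds from {n} subjects")
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=np.int64)
    if stratify_labels is None:
        perm = rng.permutation(n)
        fold[perm] = np.arange(n) % K
    else:
        labels = np.asarray(stratify_labels)
        if len(labels) != n:
            raise ValueError("stratify_labels length must equal n")
        offset = 0
        for lab in np.unique(labels):
            idx = rng.permutation(np.flatnonzero(labels == lab))
            fold[idx] = (offset + np.arange(len(idx))) % K
            offset += len(idx)
    return FoldAssignment(K=K, fold_of_subject=fold, seed=seed)


def assign_cells(
    genotypes: GenotypeMatrix | np.ndarray, combination: Sequence[int]
) -> np.ndarray:
    """Map each subject to a genotype-cell index for one SNP combination.

    Returns an int array where entry i encodes the k-tuple of genotype codes
    in base 3 (first SNP most significant), or -1 when the subject has a
    missing call at any of the k SNPs (excluded for this combination only).
    """
    values = genotypes.values if isinstance(genotypes, GenotypeMatrix) else genotypes
    combo = tuple(int(c) for c in combination)
    if not 1 <= len(combo) <= values.shape[1]:
        raise ValueError(f"invalid combination {combo}")
    sub = values[:, combo].astype(np.int64)
    excluded = (sub < 0).any(axis=1)
    cells = np.zeros(values.shape[0], dtype=np.int64)
    for col in sub.T:
        cells = cells * 3 + np.where(col < 0, 0, col)
    cells[excluded] = -1
    return cells


def cell_index_to_tuple(index: int, k: int) -> tuple[int, ...]:
    """Inverse of the base-3 cell encoding used by :func:`assign_cells`."""
    out = []
    for _ in range(k):
        out.append(index % 3)
        index //= 3
    return tuple(reversed(out))


@dataclass
class CellModel:
    """High/low-risk labelling of the 3^k genotype cells from one training set."""

    combination: tuple[int, ...]
    fold: int
    score_sums: np.ndarray  # length 3^k, training-score sum per cell
    occupied: np.ndarray  # length 3^k bool, cell seen in training
    high: np.ndarray = field(init=False)  # sum > 0

    def __post_init__(self) -> None:
        self.high = self.score_sums > 0

    @property
    def k(self) -> int:
        return len(self.combination)

    @property
    def cell_risk(self) -> dict[tuple[int, ...], str]:
        """Mapping cell tuple -> 'high' | 'low' | 'unclassified'."""
        out = {}
        for idx, cell in enumerate(product(range(3), repeat=self.k)):
            if not self.occupied[idx]:
                out[cell] = "unclassified"
            else:
                out[cell] = "high" if self.high[idx] else "low"
        return out

    @property
    def cell_score_sum(self) -> dict[tuple[int, ...], float]:
        return {
            cell: float(self.score_sums[idx])
            for idx, cell in enumerate(product(range(3), repeat=self.k))
        }


def classify_cells(
    scores: ScoreVector | np.ndarray,
    cells: np.ndarray,
    training_mask: np.ndarray,
    combination: Sequence[int],
    fold: int = -1,
) -> CellModel:
    """Label every genotype cell by the sign of its training-score sum.

    Positive sum -> high risk; zero or negative -> low risk; cells with no
    training subject are unclassified (treated as low risk at evaluation).
    """
    s = scores.values if isinstance(scores, ScoreVector) else np.asarray(scores, float)
    mask = np.asarray(training_mask, dtype=bool) & (cells >= 0)
    if not mask.any():
        raise ValueError("training mask selects no subjects with complete genotypes")
    n_cells = 3 ** len(tuple(combination))
    sums = np.bincount(cells[mask], weights=s[mask], minlength=n_cells)
    occupied = np.bincount(cells[mask], minlength=n_cells) > 0
    return CellModel(
        combination=tuple(int(c) for c in combination),
        fold=fold,
        score_sums=sums,
        occupied=occupied,
    )


def _weighted_balanced_accuracy(s: np.ndarray, is_high: np.ndarray) -> float:
    """Core accuracy formula on an evaluation subset.

    A class with no subjects of the corresponding score sign contributes a
    term of 1/2 (vacuous half credit), so the empty set scores exactly 0.5.
    """
    pos = s > 0
    neg = s < 0
    sum_pos = s[pos].sum()
    sum_neg = -s[neg].sum()
    term_pos = s[pos & is_high].sum() / sum_pos if sum_pos > 0 else 0.5
    term_neg = -s[neg & ~is_high].sum() / sum_neg if sum_neg > 0 else 0.5
    return float(0.5 * (term_pos + term_neg))


def balanced_accuracy(
    scores: ScoreVector | np.ndarray,
    cells: np.ndarray,
    cell_model: CellModel,
    eval_mask: np.ndarray,
    unseen_cells: Literal["low", "exclude"] = "low",
) -> float:
    """Score-weighted balanced accuracy of a cell model on an evaluation set.

    Subjects whose cell the model never saw in training are treated as
    low-risk by default, or dropped with ``unseen_cells='exclude'``.
    """
    s = scores.values if isinstance(scores, ScoreVector) else np.asarray(scores, float)
    mask = np.asarray(eval_mask, dtype=bool) & (cells >= 0)
    if unseen_cells == "exclude":
        mask = mask & cell_model.occupied[np.where(cells >= 0, cells, 0)]
    sub = np.flatnonzero(mask)
    return _weighted_balanced_accuracy(s[sub], cell_model.high[cells[sub]])


@dataclass
class CombinationEvaluation:
    """Per-fold accuracies of one SNP combination under a fold assignment."""

    combination: tuple[int, ...]
    training_accuracy: np.ndarray  # length K
    testing_accuracy_per_fold: np.ndarray  # length K

    @property
    def testing_accuracy(self) -> float:
        """Observed testing accuracy: mean of per-fold testing accuracies."""
        return float(self.testing_accuracy_per_fold.mean())


@dataclass
class InteractionResult:
    """A selected SNP combination with its cross-validation statistics."""

    combination: tuple[int, ...]
    cvc: int
    K: int
    training_accuracy: np.ndarray
    testing_accuracy: float
    testing_accuracy_per_fold: np.ndarray
    p_value: float | None = None
    p_is_bound: bool = False
    n_perm: int | None = None

    @property
    def order(self) -> int:
        return len(self.combination)

    def format_p(self) -> str:
        if self.p_value is None:
            return "NA"
        if self.p_is_bound:
            return f"<{self.p_value:.0e}"
        return f"{self.p_value:.3g}"


def evaluate_combination(
    genotypes: GenotypeMatrix | np.ndarray,
    scores: ScoreVector | np.ndarray,
    combination: Sequence[int],
    folds: FoldAssignment,
    unseen_cells: Literal["low", "exclude"] = "low",
) -> CombinationEvaluation | None:
    """Train and test one combination across all K folds.

    For each fold f the cell model is fit on subjects outside f, the
    training accuracy is evaluated on those same subjects and the testing
    accuracy on fold-f subjects. Returns None (with a warning) when some
    training set contains no subject with complete genotypes.
    """
    values = genotypes.values if isinstance(genotypes, GenotypeMatrix) else genotypes
    s = scores.values if isinstance(scores, ScoreVector) else np.asarray(scores, float)
    combo = tuple(int(c) for c in combination)
    cells = assign_cells(values, combo)
    valid = cells >= 0
    K = folds.K
    n_cells = 3 ** len(combo)
    fold_of = folds.fold_of_subject
    train_acc = np.empty(K)
    test_acc = np.empty(K)
    for f in range(K):
        train = valid & (fold_of != f)
        if not train.any():
            logger.warning(
                "combination %s skipped: empty training set in fold %d", combo, f
            )
            return None
        test = valid & (fold_of == f)
        sums = np.bincount(cells[train], weights=s[train], minlength=n_cells)
        high = sums > 0
        if unseen_cells == "exclude":
            occupied = np.bincount(cells[train], minlength=n_cells) > 0
            test = test & occupied[np.where(valid, cells, 0)]
        train_acc[f] = _weighted_balanced_accuracy(s[train], high[cells[train]])
        test_acc[f] = _weighted_balanced_accuracy(s[test], high[cells[test]])
    return CombinationEvaluation(
        combination=combo,
        training_accuracy=train_acc,
        testing_accuracy_per_fold=test_acc,
    )


@dataclass
class SelectionResult:
    """Outcome of per-fold ranking: fold-wise selections and CVC counts."""

    K: int
    top_n: int
    per_fold_selected: list[list[tuple[int, ...]]]
    cvc: dict[tuple[int, ...], int]
    retained: list[tuple[int, ...]]  # combinations passing the CVC output rule


def rank_and_select(
    evaluations: Sequence[CombinationEvaluation],
    K: int,
    top_n: int = 1,
    cvc_retain_fraction: float = 0.5,
) -> SelectionResult:
    """Per-fold top-n selection by training accuracy; CVC = selection count.

    Ties in training accuracy break lexicographically by SNP index tuple.
    Combinations with CVC strictly greater than ``cvc_retain_fraction * K``
    (default: CVC > K/2) are retained as candidate interaction models.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    evals = list(evaluations)
    per_fold: list[list[tuple[int, ...]]] = []
    cvc: dict[tuple[int, ...], int] = {}
    if evals:
        combos = [e.combination for e in evals]
        acc = np.stack([e.training_accuracy for e in evals])  # (n_comb, K)
        order_lex = np.arange(len(evals))  # evals assumed in enumeration order
        for f in range(K):
            col = acc[:, f]
            # stable sort on -accuracy keeps lexicographic order among ties,
            # provided evaluations arrive lexicographically sorted
            ranked = sorted(order_lex, key=lambda i: (-col[i], combos[i]))
            chosen = [combos[i] for i in ranked[:top_n]]
            per_fold.append(chosen)
            for c in chosen:
                cvc[c] = cvc.get(c, 0) + 1
    else:
        per_fold = [[] for _ in range(K)]
    threshold = cvc_retain_fraction * K
    retained = sorted(c for c, v in cvc.items() if v > threshold)
    return SelectionResult(
        K=K, top_n=top_n, per_fold_selected=per_fold, cvc=cvc, retained=retained
    )
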