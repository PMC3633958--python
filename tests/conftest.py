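"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use plain Python loops and exact rational
arithmetic so they share no code path with the vectorised implementation.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from gmdr.data_model import GenotypeMatrix, SNPInfo


def brute_force_classify(scores, cells, training_idx):
    """Per-cell training-score sums and high/low labels by explicit loops."""
    sums: dict[int, float] = {}
    for i in training_idx:
        c = int(cells[i])
        if c < 0:
            continue
        sums[c] = sums.get(c, 0.0) + float(scores[i])
    high = {c for c, v in sums.items() if v > 0}
    return sums, high


def brute_force_accuracy(scores, cells, high_cells, eval_idx):
    """Score-weighted balanced accuracy by explicit per-subject loops."""
    sum_pos = sum_neg = hit_pos = hit_neg = 0.0
    for i in eval_idx:
        c = int(cells[i])
        if c < 0:
            continue
        s = float(scores[i])
        if s > 0:
            sum_pos += s
            if c in high_cells:
                hit_pos += s
        elif s < 0:
            sum_neg += -s
            if c not in high_cells:
                hit_neg += -s
    term_pos = hit_pos / sum_pos if sum_pos > 0 else 0.5
    term_neg = hit_neg / sum_neg if sum_neg > 0 else 0.5
    return 0.5 * (term_pos + term_neg)


def hwe_exact_oracle(n0: int, n1: int, n2: int) -> float:
    """Exact-rational enumeration of the conditional HWE test.

    Weights 2^h * C(n, h) * C(n-h, (rare-h)/2) over heterozygote counts h
    with the parity of the rare-allele total; the p-value is the exact
    fraction of weight on outcomes no more probable than the observed one.
    """
    n = n0 + n1 + n2
    n_a = 2 * n0 + n1
    n_b = 2 * n2 + n1
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    weights: dict[int, Fraction] = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - h) // 2
        weights[h] = Fraction(2) ** h * comb(n, h) * comb(n - h, hom_rare)
    total = sum(weights.values())
    observed = weights[n1]
    p = sum(w for w in weights.values() if w <= observed) / total
    return float(p)


def make_genotypes(values, chrom=None, pos=None, spacing=2_000_000):
    """GenotypeMatrix from a raw array, with well-spaced default positions."""
    values = np.asarray(values, dtype=np.int8)
    n, m = values.shape
    snps = [
        SNPInfo(
            snp_id=f"snp{j}",
            chromosome=str(chrom[j]) if chrom is not None else str(j + 1),
            position_bp=int(pos[j]) if pos is not None else 1 + j * spacing,
        )
        for j in range(m)
    ]
    return GenotypeMatrix(
        values=values, snps=snps, subject_ids=[f"S{i:04d}" for i in range(n)]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
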