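"""SNP-level quality control: missingness, minor allele frequency, HWE.

The default thresholds and their strictness follow standard GWAS practice
for this pipeline: a SNP is removed when missingness exceeds 10% (strictly),
MAF falls below 0.05 (strictly), or the exact Hardy-Weinberg test in
controls gives p strictly below 0.001. For binary traits the missingness
and MAF checks are applied separately to cases and controls and a SNP must
pass in both strata; for quantitative traits all checks use the full sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import lgamma
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import MISSING, GenotypeMatrix

__all__ = [
    "QCThresholds",
    "QCReport",
    "missing_rate",
    "minor_allele_frequency",
    "hwe_exact_p",
    "hwe_chisq_p",
    "apply_qc",
]


@dataclass(frozen=True)
class QCThresholds:
    max_missing: float = 0.10
    min_maf: float = 0.05
    min_hwe_p: float = 0.001


@dataclass
class QCReport:
    """Per-SNP QC metrics and the keep/remove decision.

    ``table`` columns: snp_id, chromosome, position_bp, missing_rate, maf,
    hwe_p, kept, reason. ``reason`` is ``pass`` for kept SNPs, otherwise the
    first failing filter in the order missingness -> maf -> hwe.
    """

    table: pd.DataFrame
    thresholds: QCThresholds

    @property
    def n_kept(self) -> int:
        return int(self.table["kept"].sum())

    @property
    def n_removed(self) -> int:
        return int((~self.table["kept"]).sum())

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def missing_rate(snp_column: np.ndarray) -> float:
    """Fraction of calls equal to the missing sentinel."""
    col = np.asarray(snp_column)
    if col.size == 0:
        raise ValueError("empty genotype column")
    return float(np.mean(col == MISSING))


def minor_allele_frequency(snp_column: np.ndarray) -> float:
    """MAF from non-missing calls: min(f, 1-f), f = (2*n2 + n1) / (2*n_called)."""
    col = np.asarray(snp_column)
    called = col[col != MISSING]
    if called.size == 0:
        raise ValueError("MAF undefined: all calls missing")
    f = (2.0 * np.sum(called == 2) + np.sum(called == 1)) / (2.0 * called.size)
    return float(min(f, 1.0 - f))


@lru_cache(maxsize=65536)
def _hwe_exact_cached(n0: int, n1: int, n2: int) -> float:
    n = n0 + n1 + n2
    n_a = 2 * n0 + n1  # copies of the first allele
    n_b = 2 * n2 + n1
    if n_a == 0 or n_b == 0:
        return 1.0  # monomorphic: HWE trivially holds
    rare = min(n_a, n_b)
    # Conditional distribution of the heterozygote count given allele totals:
    # P(n1) proportional to 2^n1 * n! / (n0! n1! n2!); n1 has the parity of
    # the rare-allele total.
    hets = np.arange(rare % 2, rare + 1, 2)
    homs_rare = (rare - hets) // 2
    homs_common = n - hets - homs_rare
    logp = (
        hets * np.log(2.0)
        + lgamma(n + 1)
        - np.array([lgamma(h + 1) for h in hets])
        - np.array([lgamma(h + 1) for h in homs_rare])
        - np.array([lgamma(h + 1) for h in homs_common])
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs_prob = probs[np.flatnonzero(hets == n1)[0]]
    # two-sided: sum all outcomes no more probable than the observed one
    p = float(probs[probs <= obs_prob * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def hwe_exact_p(n0: int, n1: int, n2: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sums, over all heterozygote counts compatible with the observed allele
    totals, the conditional probabilities that do not exceed the observed
    count's probability. Monomorphic input returns 1.0 by convention.
    """
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    if n0 + n1 + n2 < 1:
        raise ValueError("need at least one genotype call")
    return _hwe_exact_cached(int(n0), int(n1), int(n2))


def hwe_chisq_p(n0: int, n1: int, n2: int) -> float:
    """One-df chi-square HWE test (asymptotic alternative to the exact test)."""
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("need at least one genotype call")
    p = (2 * n0 + n1) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    chi2 = float(np.sum((np.array([n0, n1, n2]) - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    return (
        int(np.sum(col == 0)),
        int(np.sum(col == 1)),
        int(np.sum(col == 2)),
    )


def apply_qc(
    genotypes: GenotypeMatrix,
    control_mask: np.ndarray | None = None,
    thresholds: QCThresholds = QCThresholds(),
    hwe_method: Literal["exact", "chisq"] = "exact",
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter SNPs by missingness, MAF and HWE.

    With ``control_mask`` (binary trait), missingness and MAF are checked
    separately in cases and controls (fail in either stratum removes the
    SNP) and HWE is tested in controls only. Without it, all checks use the
    full sample. Comparisons are strict; filters are applied in the order
    missingness -> MAF -> HWE and the first failing reason is recorded.
    """
    hwe_fn = hwe_exact_p if hwe_method == "exact" else hwe_chisq_p
    values = genotypes.values
    n, m = values.shape
    if control_mask is not None:
        control_mask = np.asarray(control_mask, dtype=bool)
        if control_mask.shape != (n,):
            raise ValueError("control_mask length must match subject count")
        strata = [values[~control_mask], values[control_mask]]
        hwe_rows = values[control_mask]
    else:
        strata = [values]
        hwe_rows = values

    rows = []
    for j in range(m):
        full_col = values[:, j]
        rate = missing_rate(full_col)
        called = full_col[full_col != MISSING]
        maf = minor_allele_frequency(full_col) if called.size else float("nan")
        hwe_col = hwe_rows[:, j]
        hwe_called = hwe_col[hwe_col != MISSING]
        hwe_p = hwe_fn(*_genotype_counts(hwe_called)) if hwe_called.size else 1.0

        reason = "pass"
        for stratum in strata:
            if missing_rate(stratum[:, j]) > thresholds.max_missing:
                reason = "missingness"
                break
        if reason == "pass":
            for stratum in strata:
                scol = stratum[:, j]
                s_called = scol[scol != MISSING]
                s_maf = (
                    minor_allele_frequency(scol) if s_called.size else 0.0
                )
                if s_maf < thresholds.min_maf:
                    reason = "maf"
                    break
        if reason == "pass" and hwe_p < thresholds.min_hwe_p:
            reason = "hwe"

        info = genotypes.snps[j]
        rows.append(
            {
                "snp_id": info.snp_id,
                "chromosome": info.chromosome,
                "position_bp": info.position_bp,
                "missing_rate": rate,
                "maf": maf,
                "hwe_p": hwe_p,
                "kept": reason == "pass",
                "reason": reason,
            }
        )

    table = pd.DataFrame(rows)
    kept_idx = np.flatnonzero(table["kept"].to_numpy())
    filtered = genotypes.take_snps(kept_idx)
    return filtered, QCReport(table=table, thresholds=thresholds)
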