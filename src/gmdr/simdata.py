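"""Synthetic genotype/phenotype generator with known interaction structure.

Genotypes are independent Hardy-Weinberg draws at specified minor-allele
frequencies (no linkage disequilibrium is simulated; the pipeline's 1 Mb
distance filter is exercised through SNP positions instead). Phenotypes are
generated from a k-locus penetrance table (binary) or cell mean-shift table
(quantitative), optionally with additive covariate effects; a null model
draws the phenotype independently of all genotypes.

The canonical planted-interaction fixture is the XOR (checkerboard) model:
at MAF 0.5 a cell is "affected" exactly when one of the two loci is
heterozygous and the other is not, which has zero marginal effect at either
locus and is therefore invisible to single-SNP tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import CovariateMatrix, GenotypeMatrix, Phenotype, SNPInfo, TraitKind
from .engine import assign_cells

__all__ = [
    "SNPSpec",
    "PenetranceModel",
    "xor_model",
    "simulate_genotypes",
    "simulate_phenotype",
    "default_snp_specs",
]


@dataclass(frozen=True)
class SNPSpec:
    chromosome: str
    position_bp: int
    maf: float

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")


def default_snp_specs(
    n_snps: int, maf: float = 0.3, spacing_bp: int = 2_000_000
) -> list[SNPSpec]:
    """Convenience layout: one SNP per 'chromosome slot', well spaced.

    SNPs are placed on chromosomes 1..22 round-robin with generous spacing
    so the default 1 Mb distance filter never removes a pair.
    """
    return [
        SNPSpec(
            chromosome=str(j % 22 + 1),
            position_bp=1 + (j // 22 + 1) * spacing_bp,
            maf=maf,
        )
        for j in range(n_snps)
    ]


@dataclass
class PenetranceModel:
    """Penetrance (binary) or mean-shift (quantitative) table over 3^k cells.

    ``table`` has shape (3,)*k indexed by the genotype codes of ``loci``.
    Binary entries must lie in [0, 1].
    """

    loci: tuple[int, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        self.loci = tuple(int(i) for i in self.loci)
        self.table = np.asarray(self.table, dtype=float)
        if self.table.shape != (3,) * len(self.loci):
            raise ValueError(
                f"table shape {self.table.shape} does not cover 3^{len(self.loci)} cells"
            )

    def cell_values(self, genotypes: GenotypeMatrix) -> np.ndarray:
        """Per-subject table value; missing genotypes at the loci are not allowed."""
        cells = assign_cells(genotypes, self.loci)
        if (cells < 0).any():
            raise ValueError("penetrance model loci contain missing genotypes")
        return self.table.reshape(-1)[cells]


def xor_model(
    loci: Sequence[int] = (0, 1), high: float = 1.0, low: float = 0.0
) -> PenetranceModel:
    """Two-locus checkerboard: 'high' where exactly one locus is heterozygous.

    At MAF 0.5 both loci have zero marginal effect, isolating the pure
    interaction signal. ``high``/``low`` attenuate the penetrance contrast
    (e.g. 0.9/0.1) to create noisy versions of the fixture.
    """
    if len(loci) != 2:
        raise ValueError("xor_model is a two-locus fixture")
    g = np.arange(3)
    het = (g == 1).astype(int)
    mask = het[:, None] ^ het[None, :]
    return PenetranceModel(loci=tuple(loci), table=np.where(mask, high, low))


def simulate_genotypes(
    n: int, snp_specs: Sequence[SNPSpec], seed: int = 0
) -> GenotypeMatrix:
    """Independent Hardy-Weinberg genotype draws.

    P(0,1,2) = ((1-q)^2, 2q(1-q), q^2) with q the SNP's minor-allele
    frequency; no missing calls are generated (tests inject them).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    q = np.array([s.maf for s in snp_specs])
    p0 = (1.0 - q) ** 2
    p01 = p0 + 2.0 * q * (1.0 - q)
    u = rng.random((n, len(snp_specs)))
    values = ((u > p0).astype(np.int8) + (u > p01).astype(np.int8))
    snps = [
        SNPInfo(snp_id=f"snp{j:04d}", chromosome=s.chromosome, position_bp=s.position_bp)
        for j, s in enumerate(snp_specs)
    ]
    subject_ids = [f"S{i:05d}" for i in range(n)]
    return GenotypeMatrix(values=values, snps=snps, subject_ids=subject_ids)


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return np.log(p / (1.0 - p))


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    model: PenetranceModel | None,
    trait_kind: TraitKind = "binary",
    noise_sd: float = 1.0,
    covariate_effects: Sequence[float] | None = None,
    seed: int = 0,
    null_prevalence: float = 0.5,
    null_mean: float = 0.0,
) -> tuple[Phenotype, CovariateMatrix]:
    """Draw a phenotype from a penetrance/mean-shift model plus covariates.

    Binary: case probability is the subject's cell penetrance, shifted on
    the logit scale by the covariate term (penetrances of exactly 0/1 stay
    deterministic when there are no covariates). Quantitative: cell mean
    shift + covariate term + Normal(0, noise_sd). With ``model=None`` the
    phenotype is independent of all genotypes (prevalence
    ``null_prevalence`` / mean ``null_mean``). Covariates are iid standard
    normal, one per effect size.
    """
    rng = np.random.default_rng(seed)
    n = genotypes.n_subjects
    effects = np.asarray(covariate_effects if covariate_effects is not None else [], float)
    covars = rng.standard_normal((n, len(effects)))
    cov_term = covars @ effects if len(effects) else np.zeros(n)
    covariates = CovariateMatrix(
        values=covars, names=[f"cov{j}" for j in range(len(effects))]
    )

    if trait_kind == "binary":
        base = (
            np.full(n, null_prevalence) if model is None else model.cell_values(genotypes)
        )
        if len(effects):
            prob = 1.0 / (1.0 + np.exp(-(_logit(base) + cov_term)))
        else:
            prob = base
        y = (rng.random(n) < prob).astype(float)
    elif trait_kind == "quantitative":
        shift = np.full(n, null_mean) if model is None else model.cell_values(genotypes)
        y = shift + cov_term + rng.normal(0.0, noise_sd, size=n)
    elif trait_kind == "count":
        log_mu = (np.full(n, null_mean) if model is None else model.cell_values(genotypes)) + cov_term
        y = rng.poisson(np.exp(log_mu)).astype(float)
    else:
        raise ValueError(f"unknown trait_kind {trait_kind!r}")
    return Phenotype(values=y, trait_kind=trait_kind), covariates
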