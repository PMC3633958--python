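"""Core typed containers shared by all GMDR modules.

Genotypes are stored as minor-allele counts in {0, 1, 2} with a dedicated
missing sentinel (:data:`MISSING`). Missing genotypes are never imputed:
subjects carrying a missing call are excluded per SNP combination inside the
engine, while subjects with a missing phenotype or covariate are removed
globally (listwise) by :func:`validate_dataset`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call. Any negative value in the input is
#: normalised to this code.
MISSING: int = -1

TraitKind = Literal["binary", "quantitative", "count"]


class DimensionMismatchError(ValueError):
    """Container shapes disagree on the number of subjects or SNPs."""


@dataclass(frozen=True)
class SNPInfo:
    """Identity and physical location of one SNP.

    ``position_bp`` is the 1-based base-pair coordinate used by the
    physical-distance filter; ``chromosome`` is an opaque label (distances
    are only defined within a chromosome).
    """

    snp_id: str
    chromosome: str
    position_bp: int

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(
                f"SNP {self.snp_id}: position_bp must be >= 1, got {self.position_bp}"
            )


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs matrix of minor-allele counts.

    ``values[i, j]`` is the number of minor alleles subject ``i`` carries at
    SNP ``j`` (0, 1 or 2), or :data:`MISSING`.
    """

    values: np.ndarray
    snps: list[SNPInfo]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise DimensionMismatchError("genotype values must be 2-dimensional")
        n, m = self.values.shape
        if m != len(self.snps):
            raise DimensionMismatchError(
                f"{m} genotype columns but {len(self.snps)} SNP records"
            )
        if n != len(self.subject_ids):
            raise DimensionMismatchError(
                f"{n} genotype rows but {len(self.subject_ids)} subject ids"
            )
        vals = self.values
        bad = (vals > 2) | ((vals < 0) & (vals != MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {vals[i, j]} at subject "
                f"{self.subject_ids[i]!r}, SNP {self.snps[j].snp_id!r}"
            )
        ids = self.subject_ids
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids")
        snp_ids = [s.snp_id for s in self.snps]
        if len(set(snp_ids)) != len(snp_ids):
            raise ValueError("duplicate SNP ids")
        self.values = self.values.astype(np.int8, copy=False)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def take_subjects(self, index: np.ndarray) -> "GenotypeMatrix":
        """Row subset/reorder by positional index."""
        index = np.asarray(index)
        return GenotypeMatrix(
            values=self.values[index],
            snps=list(self.snps),
            subject_ids=[self.subject_ids[i] for i in index],
        )

    def take_snps(self, index: Sequence[int]) -> "GenotypeMatrix":
        """Column subset/reorder by positional index."""
        idx = np.asarray(index)
        return GenotypeMatrix(
            values=self.values[:, idx],
            snps=[self.snps[i] for i in idx],
            subject_ids=list(self.subject_ids),
        )


@dataclass
class Phenotype:
    """Per-subject trait values.

    Binary traits are canonicalised to 0/1 (the numerically smaller of the
    two observed levels maps to 0). Missing values are NaN and removed by
    :func:`validate_dataset`.
    """

    values: np.ndarray
    trait_kind: TraitKind

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.trait_kind not in ("binary", "quantitative", "count"):
            raise ValueError(f"unknown trait_kind {self.trait_kind!r}")
        if self.trait_kind == "binary":
            levels = np.unique(self.values[~np.isnan(self.values)])
            if len(levels) > 2:
                raise ValueError(
                    f"binary phenotype has {len(levels)} levels: {levels[:5]}"
                )
            if len(levels) == 2 and not np.array_equal(levels, [0.0, 1.0]):
                mapped = np.full_like(self.values, np.nan)
                mapped[self.values == levels[0]] = 0.0
                mapped[self.values == levels[1]] = 1.0
                self.values = mapped

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    def take(self, index: np.ndarray) -> "Phenotype":
        return Phenotype(self.values[np.asarray(index)], self.trait_kind)


@dataclass
class CovariateMatrix:
    """Subjects x p covariates; p may be zero."""

    values: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values.reshape(-1, 1)
        if self.values.ndim != 2:
            raise DimensionMismatchError("covariate values must be 2-dimensional")
        if self.values.shape[1] != len(self.names):
            raise DimensionMismatchError(
                f"{self.values.shape[1]} covariate columns but {len(self.names)} names"
            )

    @classmethod
    def empty(cls, n_subjects: int) -> "CovariateMatrix":
        return cls(np.empty((n_subjects, 0)), [])

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]

    def take(self, index: np.ndarray) -> "CovariateMatrix":
        return CovariateMatrix(self.values[np.asarray(index)], list(self.names))


@dataclass
class ScoreVector:
    """One real-valued score per subject; the quantity GMDR classifies.

    ``origin`` records whether the scores came from the package's own GLM fit
    (mean-zero by construction) or were supplied by the user.
    """

    values: np.ndarray
    origin: Literal["computed", "user_supplied"]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.isfinite(self.values).all():
            raise ValueError("scores must be finite")
        if self.origin not in ("computed", "user_supplied"):
            raise ValueError(f"unknown score origin {self.origin!r}")

    @property
    def n_subjects(self) -> int:
        return len(self.values)


@dataclass
class Dataset:
    """Validated bundle of genotypes, phenotype and covariates.

    All three containers cover the same subjects in the same order.
    """

    genotypes: GenotypeMatrix
    phenotype: Phenotype
    covariates: CovariateMatrix
    n_removed: int = 0

    @property
    def n_subjects(self) -> int:
        return self.genotypes.n_subjects

    def take_subjects(self, index: np.ndarray) -> "Dataset":
        index = np.asarray(index)
        return Dataset(
            genotypes=self.genotypes.take_subjects(index),
            phenotype=self.phenotype.take(index),
            covariates=self.covariates.take(index),
            n_removed=self.n_removed,
        )

    def sort_subjects(self) -> "Dataset":
        """Reorder subjects lexicographically by subject id."""
        order = np.argsort(np.asarray(self.genotypes.subject_ids, dtype=object))
        return self.take_subjects(order)


def validate_dataset(
    genotypes: GenotypeMatrix,
    phenotype: Phenotype,
    covariates: CovariateMatrix | None = None,
) -> Dataset:
    """Cross-check container shapes and listwise-delete incomplete subjects.

    Subjects with a missing (NaN) phenotype or any missing covariate are
    removed from all containers; missing genotypes are left in place (they
    are handled per combination downstream). Idempotent.
    """
    if covariates is None:
        covariates = CovariateMatrix.empty(genotypes.n_subjects)
    n = genotypes.n_subjects
    if phenotype.n_subjects != n:
        raise DimensionMismatchError(
            f"phenotype has {phenotype.n_subjects} subjects, genotypes have {n}"
        )
    if covariates.n_subjects != n:
        raise DimensionMismatchError(
            f"covariates have {covariates.n_subjects} subjects, genotypes have {n}"
        )
    keep = ~np.isnan(phenotype.values)
    if covariates.n_covariates:
        keep &= ~np.isnan(covariates.values).any(axis=1)
    n_removed = int(n - keep.sum())
    if n_removed:
        logger.info(
            "listwise deletion removed %d of %d subjects "
            "(missing phenotype or covariates)",
            n_removed,
            n,
        )
    if keep.sum() == 0:
        raise ValueError("no subjects remain after listwise deletion")
    idx = np.flatnonzero(keep)
    return Dataset(
        genotypes=genotypes.take_subjects(idx),
        phenotype=phenotype.take(idx),
        covariates=covariates.take(idx),
        n_removed=n_removed,
    )
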