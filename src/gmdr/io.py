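"""Readers and writers: PLINK text (.ped/.map), the matrix-TSV dialect, results.

Allele-pair PLINK input is converted to minor-allele counts by counting the
dataset-wide minor allele at each SNP (ties break to the alphabetically
first allele); "0 0" allele pairs become the missing sentinel. The matrix
TSV dialect is a subjects x SNPs table of {0,1,2,NA} with a SNP-id header
and two metadata rows (#chrom, #pos) carrying positions for the distance
filter.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    MISSING,
    CovariateMatrix,
    Dataset,
    GenotypeMatrix,
    Phenotype,
    SNPInfo,
    TraitKind,
    validate_dataset,
)
from .engine import InteractionResult
from .search import CoreSNP

logger = logging.getLogger(__name__)

__all__ = [
    "read_plink_text",
    "write_plink_text",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_phenotype_tsv",
    "write_phenotype_tsv",
    "read_covariates_tsv",
    "write_results_tsv",
    "write_core_snps_tsv",
    "write_selection_tsv",
]


class ParseError(ValueError):
    """Malformed input file; the message carries file and line context."""


# ---------------------------------------------------------------- PLINK text


def _read_map(map_path: Path) -> list[SNPInfo]:
    snps = []
    with map_path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) not in (3, 4):
                raise ParseError(
                    f"{map_path}:{lineno}: expected 3 or 4 columns, got {len(fields)}"
                )
            chrom, snp_id = fields[0], fields[1]
            pos = int(fields[-1])
            snps.append(SNPInfo(snp_id=snp_id, chromosome=chrom, position_bp=pos))
    if not snps:
        raise ParseError(f"{map_path}: no SNPs")
    return snps


def read_plink_text(
    ped_path: str | Path, map_path: str | Path
) -> tuple[GenotypeMatrix, Phenotype]:
    """Read PLINK text pedigree + map into minor-allele counts and a 0/1 trait.

    The .ped phenotype column uses the 1 (control) / 2 (case) convention;
    0 and -9 mean missing. Monomorphic or tied SNPs take the alphabetically
    first allele as minor.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    snps = _read_map(map_path)
    m = len(snps)
    subject_ids: list[str] = []
    fids: list[str] = []
    pheno_raw: list[float] = []
    allele_rows: list[list[str]] = []
    with ped_path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} columns "
                    f"(6 + 2 x {m} SNPs), got {len(fields)}"
                )
            fid, iid = fields[0], fields[1]
            code = fields[5]
            if code in ("0", "-9", "NA"):
                pheno_raw.append(float("nan"))
            elif code == "1":
                pheno_raw.append(0.0)
            elif code == "2":
                pheno_raw.append(1.0)
            else:
                raise ParseError(
                    f"{ped_path}:{lineno}: unknown phenotype code {code!r} "
                    "(expected 1/2, or 0/-9 for missing)"
                )
            fids.append(fid)
            subject_ids.append(iid)
            allele_rows.append(fields[6:])
    if not subject_ids:
        raise ParseError(f"{ped_path}: no subjects")
    if len(set(subject_ids)) != len(subject_ids):
        subject_ids = [f"{f}_{i}" for f, i in zip(fids, subject_ids)]
        if len(set(subject_ids)) != len(subject_ids):
            raise ParseError(f"{ped_path}: duplicate FID/IID pairs")

    n = len(subject_ids)
    values = np.full((n, m), MISSING, dtype=np.int8)
    alleles = np.array(allele_rows, dtype=object).reshape(n, m, 2)
    for j in range(m):
        a1 = alleles[:, j, 0]
        a2 = alleles[:, j, 1]
        called = (a1 != "0") & (a2 != "0")
        if ((a1 == "0") != (a2 == "0")).any():
            bad = int(np.flatnonzero((a1 == "0") != (a2 == "0"))[0])
            raise ParseError(
                f"{ped_path}: subject {subject_ids[bad]}, SNP {snps[j].snp_id}: "
                "half-missing allele pair"
            )
        observed = np.concatenate([a1[called], a2[called]])
        uniq, counts = np.unique(observed, return_counts=True)
        if len(uniq) > 2:
            raise ParseError(
                f"{ped_path}: SNP {snps[j].snp_id} has {len(uniq)} alleles: "
                f"{sorted(uniq)}"
            )
        if len(uniq) == 0:
            continue  # entirely missing column
        if len(uniq) == 1:
            # monomorphic: the unseen alternative is the minor allele
            minor = None
        else:
            order = np.lexsort((uniq, counts))  # by count, alphabetical on ties
            minor = uniq[order[0]]
        if minor is None:
            values[called, j] = 0
        else:
            values[called, j] = (a1[called] == minor).astype(np.int8) + (
                a2[called] == minor
            ).astype(np.int8)

    genotypes = GenotypeMatrix(values=values, snps=snps, subject_ids=subject_ids)
    phenotype = Phenotype(values=np.array(pheno_raw), trait_kind="binary")
    return genotypes, phenotype


def write_plink_text(
    genotypes: GenotypeMatrix,
    phenotype: Phenotype,
    ped_path: str | Path,
    map_path: str | Path,
) -> None:
    """Write PLINK text files; minor allele 'A', major 'B', missing '0 0'."""
    ped_path, map_path = Path(ped_path), Path(map_path)
    with map_path.open("w") as fh:
        for s in genotypes.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position_bp}\n")
    pairs = {0: "B B", 1: "A B", 2: "A A", MISSING: "0 0"}
    y = phenotype.values
    with ped_path.open("w") as fh:
        for i, sid in enumerate(genotypes.subject_ids):
            if np.isnan(y[i]):
                code = "0"
            else:
                code = "2" if y[i] == 1.0 else "1"
            row = [sid, sid, "0", "0", "0", code]
            row.extend(pairs[int(g)] for g in genotypes.values[i])
            fh.write(" ".join(row) + "\n")


# ---------------------------------------------------------------- matrix TSV


def write_matrix_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("subject_id\t" + "\t".join(genotypes.snp_ids) + "\n")
        fh.write("#chrom\t" + "\t".join(s.chromosome for s in genotypes.snps) + "\n")
        fh.write("#pos\t" + "\t".join(str(s.position_bp) for s in genotypes.snps) + "\n")
        for i, sid in enumerate(genotypes.subject_ids):
            cells = [
                "NA" if g == MISSING else str(int(g)) for g in genotypes.values[i]
            ]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    """Read the matrix-TSV genotype dialect written by :func:`write_matrix_tsv`."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "subject_id":
            raise ParseError(f"{path}:1: first header column must be 'subject_id'")
        snp_ids = header[1:]
        chrom_row = fh.readline().rstrip("\n").split("\t")
        pos_row = fh.readline().rstrip("\n").split("\t")
        if chrom_row[:1] != ["#chrom"] or pos_row[:1] != ["#pos"]:
            raise ParseError(f"{path}: expected '#chrom' and '#pos' metadata rows")
        if len(chrom_row) != len(header) or len(pos_row) != len(header):
            raise ParseError(f"{path}: metadata row width does not match header")
        snps = [
            SNPInfo(snp_id=sid, chromosome=c, position_bp=int(p))
            for sid, c, p in zip(snp_ids, chrom_row[1:], pos_row[1:])
        ]
        subject_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, raw in enumerate(fh, start=4):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}"
                )
            subject_ids.append(fields[0])
            row = []
            for j, tok in enumerate(fields[1:]):
                if tok in ("NA", ""):
                    row.append(MISSING)
                elif tok in ("0", "1", "2"):
                    row.append(int(tok))
                else:
                    raise ParseError(
                        f"{path}:{lineno}: invalid genotype {tok!r} for subject "
                        f"{fields[0]!r}, SNP {snp_ids[j]!r}"
                    )
            rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no subject rows")
    return GenotypeMatrix(
        values=np.array(rows, dtype=np.int8), snps=snps, subject_ids=subject_ids
    )


def read_phenotype_tsv(path: str | Path, trait_kind: TraitKind) -> pd.Series:
    """Subject-keyed phenotype table: columns subject_id, phenotype."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected subject_id and phenotype columns")
    ser = pd.Series(
        pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy(),
        index=df.iloc[:, 0].to_numpy(),
    )
    if ser.index.duplicated().any():
        raise ParseError(f"{path}: duplicate subject ids")
    return ser


def write_phenotype_tsv(
    phenotype: Phenotype, subject_ids: list[str], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        fh.write("subject_id\tphenotype\n")
        for sid, v in zip(subject_ids, phenotype.values):
            fh.write(f"{sid}\t{'NA' if np.isnan(v) else repr(float(v))}\n")


def read_covariates_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected subject_id plus covariate columns")
    df = df.set_index(df.columns[0])
    if df.index.duplicated().any():
        raise ParseError(f"{path}: duplicate subject ids")
    return df.apply(pd.to_numeric, errors="coerce")


def read_matrix_tsv(
    geno_path: str | Path,
    pheno_path: str | Path | None = None,
    covar_path: str | Path | None = None,
    trait_kind: TraitKind = "binary",
) -> Dataset:
    """Assemble and validate a dataset from the TSV dialect.

    Phenotype/covariate tables are joined on exact subject ids. Ids present
    in those tables but absent from the genotypes are an error (first 10
    listed); genotype subjects missing from a table get NaN and fall to
    listwise deletion.
    """
    genotypes = read_genotypes_tsv(geno_path)
    ids = pd.Index(genotypes.subject_ids)
    if pheno_path is not None:
        pheno_ser = read_phenotype_tsv(pheno_path, trait_kind)
        extra = pheno_ser.index.difference(ids)
        if len(extra):
            raise ParseError(
                f"{pheno_path}: {len(extra)} subject ids not in genotypes, "
                f"first 10: {sorted(extra)[:10]}"
            )
        y = pheno_ser.reindex(ids).to_numpy()
    else:
        raise ParseError("phenotype file required")
    phenotype = Phenotype(values=y, trait_kind=trait_kind)
    covariates = None
    if covar_path is not None:
        cdf = read_covariates_tsv(covar_path)
        extra = cdf.index.difference(ids)
        if len(extra):
            raise ParseError(
                f"{covar_path}: {len(extra)} subject ids not in genotypes, "
                f"first 10: {sorted(extra)[:10]}"
            )
        cdf = cdf.reindex(ids)
        covariates = CovariateMatrix(values=cdf.to_numpy(), names=list(cdf.columns))
    return validate_dataset(genotypes, phenotype, covariates)


# ------------------------------------------------------------------- results


def write_results_tsv(
    results: list[InteractionResult],
    snps,
    path: str | Path,
    core_snp_ids: set[str] | None = None,
) -> None:
    """Interaction-model table: one row per model, testing accuracy to 4 dp."""
    core_snp_ids = core_snp_ids or set()
    with Path(path).open("w") as fh:
        fh.write(
            "order\tsnp_ids\tchromosomes\tcvc\ttesting_accuracy\tp_value\tcore_snps\n"
        )
        for r in results:
            ids = [snps[i].snp_id for i in r.combination]
            chroms = [snps[i].chromosome for i in r.combination]
            cores = [s for s in ids if s in core_snp_ids]
            fh.write(
                f"{r.order}\t{','.join(ids)}\t{'-'.join(chroms)}\t"
                f"{r.cvc}/{r.K}\t{r.testing_accuracy:.4f}\t{r.format_p()}\t"
                f"{','.join(cores)}\n"
            )


def write_core_snps_tsv(cores: list[CoreSNP], snps, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("snp_id\tchromosome\tposition_bp\tn_models\torders\tmodels\n")
        for c in cores:
            info = snps[c.snp_index]
            model_strs = [
                "|".join(snps[i].snp_id for i in m.combination) for m in c.models
            ]
            fh.write(
                f"{c.snp_id}\t{info.chromosome}\t{info.position_bp}\t"
                f"{c.n_models}\t{','.join(str(o) for o in sorted(c.orders))}\t"
                f"{';'.join(model_strs)}\n"
            )


def write_selection_tsv(selection, evaluations, snps, path: str | Path) -> None:
    """Audit table of per-fold top selections (fold, model, training accuracy)."""
    with Path(path).open("w") as fh:
        fh.write("fold\trank\tsnp_ids\ttraining_accuracy\n")
        for f, chosen in enumerate(selection.per_fold_selected):
            for rank, combo in enumerate(chosen, start=1):
                acc = evaluations[combo].training_accuracy[f]
                ids = ",".join(snps[i].snp_id for i in combo)
                fh.write(f"{f}\t{rank}\t{ids}\t{acc:.6f}\n")
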