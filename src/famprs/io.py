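"""Readers and writers for the standard text formats the pipeline speaks.

Genotypes travel as VCF (GT field, one sample per individual; read back with
cyvcf2) or as a plain dosage TSV (individuals x SNPs, counts 0/1/2, empty
cell = missing). Pedigrees use the 6-column PED/FAM layout
(family, individual, father, mother, sex, phenotype); phenotypes and all
reports are TSVs with headers.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .cohort import FamilyCohort, Pedigree
from .kinship import KinshipMatrix

__all__ = [
    "write_vcf",
    "read_vcf_genotypes",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_fam",
    "read_fam",
    "write_phenotypes",
    "read_phenotypes",
    "write_kinship_tsv",
    "read_kinship_tsv",
    "write_cohort",
    "read_cohort",
]


def write_vcf(cohort: FamilyCohort, path: str) -> None:
    """Write genotypes as VCF v4.2 with one GT column per individual.

    The counted allele is written as ALT, so the ALT dosage in the file is
    the genotype value; missing calls become ``./.``."""
    meta = cohort.snp_meta
    ids = cohort.pedigree.ids
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=famprs\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids) + "\n")
        for j in range(cohort.n_snps):
            row = cohort.genotypes[:, j]
            calls = "\t".join(
                "./." if np.isnan(g) else gt_map[g] for g in row
            )
            fh.write(
                f"1\t{j + 1}\t{meta['snp_id'].iloc[j]}\t{meta['other_allele'].iloc[j]}\t"
                f"{meta['counted_allele'].iloc[j]}\t.\t.\t.\tGT\t{calls}\n"
            )


def read_vcf_genotypes(path: str) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Read a VCF into (genotype matrix of ALT counts, snp_meta, sample ids)."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    cols = []
    meta_rows = []
    for var in vcf:
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = var.gt_types.astype(float)
        col = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        cols.append(col)
        meta_rows.append((var.ID, var.ALT[0] if var.ALT else ".", var.REF))
    vcf.close()
    geno = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    meta = pd.DataFrame(meta_rows, columns=["snp_id", "counted_allele", "other_allele"])
    return geno, meta, samples


def write_dosage_tsv(cohort: FamilyCohort, path: str) -> None:
    frame = pd.DataFrame(
        cohort.genotypes, index=cohort.pedigree.ids, columns=cohort.snp_meta["snp_id"]
    )
    frame.to_csv(path, sep="\t", index_label="iid", na_rep="")


def read_dosage_tsv(path: str) -> tuple[np.ndarray, list[str], list[str]]:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame.to_numpy(dtype=float), list(frame.columns), list(frame.index.astype(str))


def write_fam(cohort: FamilyCohort, path: str) -> None:
    """6-column PED/FAM text; phenotype column is obesity coded 1/2 (control/case)."""
    tab = cohort.pedigree.table
    pheno = cohort.obesity + 1
    out = pd.DataFrame(
        {
            "fid": tab["fid"],
            "iid": tab["iid"],
            "father": tab["father"].replace("", "0"),
            "mother": tab["mother"].replace("", "0"),
            "sex": tab["sex"],
            "phenotype": pheno,
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_fam(path: str) -> tuple[Pedigree, np.ndarray]:
    """Read PED/FAM; returns the pedigree and the raw phenotype column."""
    tab = pd.read_csv(
        path, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype=str,
    )
    ped = Pedigree(tab[["fid", "iid", "father", "mother", "sex"]].assign(
        sex=tab["sex"].astype(int)
    ))
    return ped, tab["phenotype"].to_numpy()


def write_phenotypes(cohort: FamilyCohort, path: str) -> None:
    cohort.phenotypes.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_kinship_tsv(kin: KinshipMatrix, path: str) -> None:
    kin.to_frame().to_csv(path, sep="\t", index_label="iid")


def read_kinship_tsv(path: str) -> KinshipMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return KinshipMatrix(ids=np.asarray(frame.index.astype(str)), matrix=frame.to_numpy(dtype=float))


def write_cohort(cohort: FamilyCohort, prefix: str) -> dict[str, str]:
    """Write VCF + dosage TSV + FAM + phenotype TSV under a common prefix;
    returns the path of each artefact."""
    os.makedirs(os.path.dirname(prefix) or ".", exist_ok=True)
    paths = {
        "vcf": prefix + ".vcf",
        "dosage": prefix + ".dosage.tsv",
        "fam": prefix + ".fam",
        "phenotypes": prefix + ".pheno.tsv",
        "snp_meta": prefix + ".snps.tsv",
    }
    write_vcf(cohort, paths["vcf"])
    write_dosage_tsv(cohort, paths["dosage"])
    write_fam(cohort, paths["fam"])
    write_phenotypes(cohort, paths["phenotypes"])
    cohort.snp_meta.to_csv(paths["snp_meta"], sep="\t", index=False)
    return paths


def read_cohort(prefix: str, obesity_threshold: float = 30.0) -> FamilyCohort:
    """Rebuild a cohort from the artefacts of :func:`write_cohort` (dosage
    TSV + FAM + phenotype TSV + SNP table)."""
    geno, snp_ids, iids = read_dosage_tsv(prefix + ".dosage.tsv")
    ped, _ = read_fam(prefix + ".fam")
    phen = read_phenotypes(prefix + ".pheno.tsv")
    meta = pd.read_csv(prefix + ".snps.tsv", sep="\t")
    order = ped.index_of(iids)
    if (order < 0).any() or len(iids) != ped.n:
        raise ValueError("dosage individuals do not match the pedigree")
    # reorder matrices/phenotypes to pedigree order
    inv = np.empty(ped.n, dtype=int)
    inv[order] = np.arange(ped.n)
    phen = phen.set_index("iid").loc[ped.ids].reset_index()
    return FamilyCohort(
        pedigree=ped,
        genotypes=geno[inv],
        snp_meta=meta,
        phenotypes=phen,
        obesity_threshold=obesity_threshold,
    )
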