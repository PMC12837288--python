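"""Reading and writing genotype, phenotype and group files.

VCF input goes through cyvcf2; only diploid GT calls at biallelic SNP
records are accepted (multiallelic records can be skipped or rejected).
VCF output is a minimal GT-only v4.2 writer sufficient for round-tripping
dosage matrices.  A plain CSV dosage dialect (accessions as rows, loci as
``chrom:pos`` columns) is provided for small test matrices.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genotypes import MISSING, GenotypeMatrix

#: The 15 culm, branch and leaf traits carried by phenotype tables.
TRAIT_NAMES = [
    "DBH", "BD", "TCH", "TNN", "HFB", "NNFB", "IL", "CW",
    "ACWTB", "AWTH", "CCD", "LT", "LA", "LL", "LW",
]

_GT_TO_DOSAGE = {0: 0, 1: 1, 2: 2}


class VcfFormatError(ValueError):
    """Raised when a VCF record cannot be interpreted as a diploid biallelic GT."""


def read_vcf(path: str | os.PathLike, on_multiallelic: str = "error") -> GenotypeMatrix:
    """Parse a VCF with GT in FORMAT into a dosage matrix.

    0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2; any missing allele -> missing.
    Phase separators are ignored.  ``on_multiallelic`` is "error" or
    "skip" for records with more than one ALT allele.
    """
    if on_multiallelic not in ("error", "skip"):
        raise ValueError("on_multiallelic must be 'error' or 'skip'")
    vcf = VCF(str(path))
    if "GT" not in (vcf.raw_header or "") and not any(
        h.startswith("##FORMAT=<ID=GT") for h in vcf.raw_header.splitlines()
    ):
        raise VcfFormatError(f"{path}: no GT FORMAT declared in header")
    samples = list(vcf.samples)
    rows: list[dict] = []
    dosages: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1 or var.ALT[0] is None:
            if on_multiallelic == "skip":
                continue
            raise VcfFormatError(
                f"multiallelic record at {var.CHROM}:{var.POS} "
                f"(ALT={var.ALT}); pass on_multiallelic='skip' to drop"
            )
        gts = var.genotypes  # list of [a0, a1, ..., phased]
        d = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(gts):
            alleles = gt[:-1]
            if len(alleles) != 2:
                raise VcfFormatError(
                    f"non-diploid GT for sample {samples[i]} at "
                    f"{var.CHROM}:{var.POS} (ploidy {len(alleles)})"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                d[i] = MISSING
            else:
                d[i] = alleles[0] + alleles[1]
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
                "maf": np.nan,
                "missing_rate": np.nan,
            }
        )
        dosages.append(d)
    vcf.close()
    loci = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "maf", "missing_rate"])
    dosage = (
        np.stack(dosages, axis=1) if dosages else np.empty((len(samples), 0), np.int8)
    )
    return GenotypeMatrix(accession_ids=samples, loci=loci, dosage=dosage)


def write_vcf(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a minimal GT-only VCF v4.2 that round-trips the dosage matrix."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(g.loci["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.accession_ids)
            + "\n"
        )
        for j, locus in g.loci.iterrows():
            calls = "\t".join(gt_strings[int(v)] for v in g.dosage[:, j])
            fh.write(
                f"{locus['chrom']}\t{int(locus['pos'])}\t.\t{locus['ref']}\t"
                f"{locus['alt']}\t.\tPASS\t.\tGT\t{calls}\n"
            )


# ----------------------------------------------------------------------
# CSV dosage dialect (tests, small matrices)

def write_dosage_csv(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Accessions as rows, loci as ``chrom:pos`` columns; missing empty."""
    cols = [f"{c}:{p}" for c, p in zip(g.loci["chrom"], g.loci["pos"])]
    df = pd.DataFrame(g.dosage_float(), index=g.accession_ids, columns=cols)
    df.to_csv(path, index_label="accession", float_format="%.0f")


def read_dosage_csv(path: str | os.PathLike) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col="accession")
    chrom_pos = [c.split(":") for c in df.columns]
    loci = pd.DataFrame(
        {
            "chrom": [cp[0] for cp in chrom_pos],
            "pos": [int(cp[1]) for cp in chrom_pos],
            "ref": ".",
            "alt": ".",
            "maf": np.nan,
            "missing_rate": np.nan,
        }
    )
    dosage = df.to_numpy(dtype=float)
    out = np.where(np.isnan(dosage), MISSING, dosage).astype(np.int8)
    return GenotypeMatrix(
        accession_ids=[str(a) for a in df.index], loci=loci, dosage=out
    )


# ----------------------------------------------------------------------
# Phenotype / group tables

def read_phenotypes(path: str | os.PathLike) -> pd.DataFrame:
    """Phenotype CSV with 'accession' key column; traits as remaining columns."""
    df = pd.read_csv(path)
    if "accession" not in df.columns:
        raise ValueError("phenotype CSV must have an 'accession' column")
    df = df.set_index("accession")
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        raise ValueError("duplicate accession ids in phenotype table")
    return df


def write_phenotypes(phen: pd.DataFrame, path: str | os.PathLike) -> None:
    phen.to_csv(path, index_label="accession")


def read_groups(path: str | os.PathLike) -> pd.Series:
    """Group TSV ``accession<TAB>group`` -> Series indexed by accession."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["accession", "group"]:
        df.columns = ["accession", "group"] + list(df.columns[2:])
    return df.set_index("accession")["group"]


def write_groups(groups: pd.Series, path: str | os.PathLike) -> None:
    groups.rename("group").to_csv(path, sep="\t", index_label="accession")


def read_core_ids(path: str | os.PathLike) -> list[str]:
    """One accession id per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_core_ids(ids: Sequence[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for a in ids:
            fh.write(f"{a}\n")
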