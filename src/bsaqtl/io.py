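"""File-format plumbing: VCF, phenotype CSV, BLUP/bulk/region tables.

VCF reading goes through cyvcf2; writing uses a minimal VCF 4.2 text
emitter (GT-only FORMAT), which is all the downstream scan requires and
keeps outputs plain-text.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .genofilter import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix

_GT_STRING = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path: str | os.PathLike, contig_lengths: dict | None = None) -> None:
    """Write a minimal uncompressed VCF 4.2 with GT-only sample fields."""
    loci = G.loci
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bsaqtl\n")
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={int(length)}>\n")
        else:
            for chrom in G.chromosomes():
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.samples)
            + "\n"
        )
        chroms = loci["chrom"].to_numpy()
        poss = loci["pos"].to_numpy()
        refs = loci["ref"].to_numpy()
        alts = loci["alt"].to_numpy()
        for i in range(G.n_loci):
            gts = "\t".join(_GT_STRING[int(c)] for c in G.calls[i])
            fh.write(
                f"{chroms[i]}\t{int(poss[i])}\t{chroms[i]}_{int(poss[i])}\t"
                f"{refs[i]}\t{alts[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF via cyvcf2; multiallelic or indel
    records are skipped."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows = []
    calls = []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        g = var.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        calls.append(g)
    vcf.close()
    loci = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(loci=loci, samples=samples, calls=np.array(calls, dtype=np.int8))


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

PHENO_KEYS = ["ril", "environment", "block"]


def write_pheno(pheno: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write plot-level phenotypes as wide CSV: ril, environment, block,
    one column per trait."""
    wide = pheno.pivot_table(
        index=PHENO_KEYS, columns="trait", values="value", aggfunc="first"
    ).reset_index()
    wide.columns.name = None
    wide.to_csv(path, index=False)


def read_pheno(path: str | os.PathLike) -> pd.DataFrame:
    """Read a wide phenotype CSV into long form with columns
    ril, environment, block, trait, value."""
    wide = pd.read_csv(path)
    missing = [k for k in PHENO_KEYS if k not in wide.columns]
    if missing:
        raise ValueError(f"phenotype CSV lacks columns: {missing}")
    long = wide.melt(id_vars=PHENO_KEYS, var_name="trait", value_name="value")
    long = long.dropna(subset=["value"]).reset_index(drop=True)
    long["ril"] = long["ril"].astype(str)
    long["environment"] = long["environment"].astype(str)
    if long.duplicated(subset=PHENO_KEYS + ["trait"]).any():
        raise ValueError("duplicate (ril, environment, block, trait) records")
    return long


# ---------------------------------------------------------------------------
# Region tables
# ---------------------------------------------------------------------------

REGION_COLUMNS = [
    "population",
    "trait",
    "chrom",
    "mean_abs_delta",
    "ci",
    "start_bp",
    "end_bp",
    "length_bp",
    "pve",
    "sign",
    "n_snps",
    "n_beyond",
    "beyond_fraction",
    "validated",
    "validated_start_bp",
    "validated_end_bp",
]


def write_regions_tsv(regions: Iterable, path: str | os.PathLike) -> None:
    df = regions_to_frame(regions)
    df.to_csv(path, sep="\t", index=False)


def regions_to_frame(regions: Iterable) -> pd.DataFrame:
    rows = []
    for r in regions:
        rows.append(
            {
                "population": r.population,
                "trait": r.trait,
                "chrom": r.chrom,
                "mean_abs_delta": r.mean_abs_delta,
                "ci": r.ci,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "length_bp": r.length_bp,
                "pve": r.pve if r.pve is not None else np.nan,
                "sign": r.sign,
                "n_snps": r.n_snps,
                "n_beyond": r.n_beyond,
                "beyond_fraction": r.beyond_fraction,
                "validated": r.validated,
                "validated_start_bp": r.validated_start_bp if r.validated_start_bp is not None else np.nan,
                "validated_end_bp": r.validated_end_bp if r.validated_end_bp is not None else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def read_regions_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_regions_bed(regions: Iterable, path: str | os.PathLike) -> None:
    """BED output: 0-based half-open, converted from 1-based inclusive."""
    with open(path, "w") as fh:
        for r in regions:
            name = f"{r.population}:{r.trait}"
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{name}\n")
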