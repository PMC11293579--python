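"""Plain-text interchange: phased VCF, annotation/phenotype TSV, pedigree.

The phased VCF dialect is VCF 4.2 with FORMAT fields ``GT`` (phased, pipe
separator) and ``PP`` (per-genotype phasing confidence, absent on
homozygous genotypes where phase is undefined), and INFO fields ``GENE``,
``MASK``, ``MAC`` and ``MAF``.  Positions are 1-based.  A heterozygous
genotype written with the unphased ``/`` separator is accepted but flagged
phase unknown, so it can never support a CH or cis call downstream.

Writing goes through :mod:`pysam`, reading through :mod:`cyvcf2`.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import pysam
from cyvcf2 import VCF

from .cohort import PhasedCohort


def _vcf_header(sample_ids, contigs) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for c in contigs:
        header.add_line(f"##contig=<ID={c}>")
    header.add_line(
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">'
    )
    header.add_line(
        '##INFO=<ID=MASK,Number=1,Type=String,Description="Consequence mask">'
    )
    header.add_line('##INFO=<ID=MAC,Number=1,Type=Integer,Description="Minor allele count">')
    header.add_line('##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=PP,Number=1,Type=Float,Description="Phasing confidence">'
    )
    for s in sample_ids:
        header.add_sample(str(s))
    return header


def write_vcf(cohort: PhasedCohort, path: str) -> None:
    """Write the cohort's phased genotypes (and PP scores) to a VCF."""
    v = cohort.variants
    pos = v["pos"].to_numpy()
    for chrom, sub in v.groupby("chrom", sort=False):
        if not np.all(np.diff(sub["pos"].to_numpy()) > 0):
            raise ValueError(f"positions not strictly sorted on contig {chrom}")
    sample_ids = cohort.samples["sample_id"].to_numpy()
    header = _vcf_header(sample_ids, pd.unique(v["chrom"]))
    h0 = cohort.haplotypes[0::2]
    h1 = cohort.haplotypes[1::2]
    pp = cohort.pp
    with pysam.VariantFile(path, "w", header=header) as out:
        for j in range(len(v)):
            rec = out.new_record(
                contig=str(v["chrom"].iat[j]),
                start=int(pos[j]) - 1,
                alleles=(str(v["ref"].iat[j]), str(v["alt"].iat[j])),
            )
            rec.id = f"var{j}"
            rec.info["GENE"] = str(v["gene"].iat[j])
            rec.info["MASK"] = str(v["mask"].iat[j])
            rec.info["MAC"] = int(v["mac"].iat[j])
            rec.info["MAF"] = float(v["maf"].iat[j])
            for i in range(len(sample_ids)):
                s = rec.samples[i]
                s["GT"] = (int(h0[i, j]), int(h1[i, j]))
                s.phased = True
                if pp is not None and h0[i, j] != h1[i, j] and np.isfinite(pp[i, j]):
                    s["PP"] = float(pp[i, j])
            out.write(rec)


def read_vcf(path: str) -> PhasedCohort:
    """Read a phased VCF into a cohort.

    Unphased heterozygous genotypes are flagged in ``cohort.phased_mask``
    and treated as phase unknown downstream; missing PP is NaN.
    """
    vcf = VCF(path)
    sample_ids = np.array(vcf.samples)
    n = len(sample_ids)
    rows = []
    h0_cols, h1_cols, pp_cols, phased_cols = [], [], [], []
    for var in vcf:
        gts = np.array(var.genotypes)  # (n, 3): a0, a1, phased
        a0, a1, phased = gts[:, 0], gts[:, 1], gts[:, 2].astype(bool)
        try:
            pp = var.format("PP")
            pp = np.array(pp, dtype=float).reshape(-1) if pp is not None else np.full(n, np.nan)
        except KeyError:
            pp = np.full(n, np.nan)
        h0_cols.append(np.clip(a0, 0, 1).astype(np.uint8))
        h1_cols.append(np.clip(a1, 0, 1).astype(np.uint8))
        pp_cols.append(pp)
        phased_cols.append(phased | (a0 == a1))  # hom phase is trivially defined
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
                "gene": var.INFO.get("GENE"),
                "mask": var.INFO.get("MASK"),
                "mac": var.INFO.get("MAC"),
                "maf": var.INFO.get("MAF"),
            }
        )
    variants = pd.DataFrame(rows)
    m = len(variants)
    hap = np.zeros((2 * n, m), dtype=np.uint8)
    pp = np.full((n, m), np.nan)
    phased_mask = np.ones((n, m), dtype=bool)
    for j in range(m):
        hap[0::2, j] = h0_cols[j]
        hap[1::2, j] = h1_cols[j]
        pp[:, j] = pp_cols[j]
        phased_mask[:, j] = phased_cols[j]
    samples = pd.DataFrame({"sample_id": sample_ids})
    cohort = PhasedCohort(haplotypes=hap, variants=variants, samples=samples, pp=pp)
    cohort.phased_mask = phased_mask
    return cohort


def write_pedigree(cohort: PhasedCohort, path: str) -> None:
    """PLINK-style .fam: FID IID PAT MAT SEX PHENO (trio parents recorded)."""
    s = cohort.samples
    by_trio = {}
    for _, row in s.iterrows():
        if row["role"] in ("mother", "father"):
            by_trio.setdefault(row["trio_id"], {})[row["role"]] = row["sample_id"]
    lines = []
    for _, row in s.iterrows():
        trio = by_trio.get(row["trio_id"], {}) if row["role"] == "child" else {}
        pat = trio.get("father", "0")
        mat = trio.get("mother", "0")
        fid = f"F{row['trio_id']}" if row["trio_id"] >= 0 else row["sample_id"]
        sex = 1 if row.get("sex", 0) == 1 else 2
        lines.append(f"{fid}\t{row['sample_id']}\t{pat}\t{mat}\t{sex}\t-9")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_pedigree(path: str) -> pd.DataFrame:
    fam = pd.read_csv(
        path, sep="\t", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str,
    )
    return fam


def write_phenotypes(phenotypes: pd.DataFrame, path: str) -> None:
    phenotypes.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")


def write_cohort(
    cohort: PhasedCohort,
    out_dir: str,
    phenotypes: pd.DataFrame | None = None,
    prefix: str = "cohort",
) -> dict:
    """Write VCF + annotation TSV + pedigree (+ phenotype TSV); return paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, f"{prefix}.vcf"),
        "annotation": os.path.join(out_dir, f"{prefix}.annotation.tsv"),
        "pedigree": os.path.join(out_dir, f"{prefix}.fam"),
    }
    write_vcf(cohort, paths["vcf"])
    cohort.variants.to_csv(paths["annotation"], sep="\t", index=False)
    write_pedigree(cohort, paths["pedigree"])
    if phenotypes is not None:
        paths["phenotypes"] = os.path.join(out_dir, f"{prefix}.pheno.tsv")
        write_phenotypes(phenotypes, paths["phenotypes"])
    return paths


def write_pseudo_vcf(encodings, path: str, model: str = "recessive") -> None:
    """Serialize per-gene encodings as one pseudo-variant per gene.

    Recessive carriers (code 2) are written ``1|1``, additive code 1 as
    ``0|1`` and wild type as ``0|0``, so the VCF dosage equals the encoding
    under the additive model and twice the carrier indicator under the
    recessive one.
    """
    mat = encodings.recessive if model == "recessive" else encodings.additive
    header = _vcf_header(encodings.sample_ids, ["pseudo"])
    with pysam.VariantFile(path, "w", header=header) as out:
        for j, gene in enumerate(encodings.genes):
            rec = out.new_record(
                contig="pseudo", start=j, alleles=("A", "T")
            )
            rec.id = str(gene)
            rec.info["GENE"] = str(gene)
            rec.info["MASK"] = model
            rec.info["MAC"] = int(mat[:, j].sum())
            rec.info["MAF"] = float(mat[:, j].sum() / (2 * mat.shape[0]))
            col = mat[:, j]
            for i in range(mat.shape[0]):
                s = rec.samples[i]
                d = int(col[i])
                s["GT"] = (1, 1) if d == 2 else ((0, 1) if d == 1 else (0, 0))
                s.phased = True
            out.write(rec)


def read_pseudo_vcf(path: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a pseudo-variant VCF back into (dosages, genes, sample_ids)."""
    vcf = VCF(path)
    sample_ids = np.array(vcf.samples)
    genes, cols = [], []
    for var in vcf:
        gts = np.array(var.genotypes)
        cols.append(gts[:, 0] + gts[:, 1])
        genes.append(var.INFO.get("GENE"))
    dosages = np.stack(cols, axis=1) if cols else np.zeros((len(sample_ids), 0), int)
    return dosages.astype(np.int8), np.array(genes), sample_ids
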