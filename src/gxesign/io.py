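"""File input/output: genotype TSV / minimal VCF, phenotype TSV, panel export.

All joins between genotype and phenotype tables are by sample ID, so row
order never matters.  Genotype TSVs carry sample IDs in the header
(variants × samples) or in the first column (samples × variants); VCFs are
read through cyvcf2 with GT converted to alternate-allele dosage (haploid
GT allowed, missing calls rejected).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .regress import GxEDataset

__all__ = [
    "read_genotype_tsv",
    "read_genotype_vcf",
    "read_phenotype_tsv",
    "build_dataset",
    "write_panel",
    "write_vcf",
]


def read_genotype_tsv(path, orientation: str = "variants_by_samples"):
    """Read a dosage matrix TSV.

    Returns ``(variant_ids, sample_ids, genotypes)`` with genotypes as a
    samples × variants integer matrix.
    """
    if orientation not in ("variants_by_samples", "samples_by_variants"):
        raise ValueError("orientation must be 'variants_by_samples' or 'samples_by_variants'")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "variants_by_samples":
        variant_ids = [str(v) for v in df.index]
        sample_ids = [str(s) for s in df.columns]
        mat = df.to_numpy().T
    else:
        sample_ids = [str(s) for s in df.index]
        variant_ids = [str(v) for v in df.columns]
        mat = df.to_numpy()
    if not np.issubdtype(np.asarray(mat).dtype, np.number):
        raise ValueError(f"non-numeric genotype entries in {path}")
    return variant_ids, sample_ids, mat.astype(np.int8)


def read_genotype_vcf(path):
    """Read a (possibly haploid) VCF into dosages via cyvcf2.

    Returns ``(variant_ids, sample_ids, genotypes, ploidy)``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    variant_ids, rows, ploidy = [], [], 1
    for var in vcf:
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        variant_ids.append(str(vid))
        dosages = []
        for gt in var.genotypes:  # [allele0, (allele1,) phased]
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                raise ValueError(f"missing genotype call at {vid}")
            ploidy = max(ploidy, len(alleles))
            dosages.append(sum(1 for a in alleles if a > 0))
        rows.append(dosages)
    return variant_ids, sample_ids, np.asarray(rows, dtype=np.int8).T, ploidy


def read_phenotype_tsv(path, phenotype_col: str, exposure_col: str,
                       covariate_cols=(), id_col: str = "sample_id"):
    """Read phenotype/exposure/covariates keyed by sample ID."""
    df = pd.read_csv(path, sep="\t")
    needed = [id_col, phenotype_col, exposure_col, *covariate_cols]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file {path} missing column(s): {missing}")
    if df[id_col].duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    return df[needed].rename(columns={id_col: "sample_id"})


def build_dataset(variant_ids, sample_ids, genotypes, pheno_df,
                  phenotype_col, exposure_col, covariate_cols=(), ploidy=2) -> GxEDataset:
    """Join genotypes with the phenotype table by sample ID (order-independent)."""
    pheno = pheno_df.set_index(pheno_df["sample_id"].astype(str))
    missing = [s for s in sample_ids if s not in pheno.index]
    if missing:
        raise ValueError(f"samples missing from phenotype table: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    aligned = pheno.loc[[str(s) for s in sample_ids]]
    cov = aligned[list(covariate_cols)].to_numpy(dtype=float) if covariate_cols else None
    return GxEDataset(
        genotypes=genotypes,
        exposure=aligned[exposure_col].to_numpy(dtype=float),
        phenotype=aligned[phenotype_col].to_numpy(dtype=float),
        ploidy=ploidy, covariates=cov,
        variant_ids=list(variant_ids), sample_ids=[str(s) for s in sample_ids],
    )


def _jsonable(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    if hasattr(v, "__dataclass_fields__"):
        return {k: _jsonable(getattr(v, k)) for k in v.__dataclass_fields__}
    if isinstance(v, dict):
        return {str(k): _jsonable(x) for k, x in v.items()}
    return v


def write_panel(dataset: GxEDataset, out_dir) -> dict:
    """Export a panel as genotype TSV + phenotype TSV + truth JSON.

    Returns the mapping of written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples = dataset.sample_ids or [f"s{i}" for i in range(dataset.n_samples)]
    geno = pd.DataFrame(dataset.genotypes.T, index=dataset.variant_ids, columns=samples)
    geno.index.name = "variant_id"
    paths = {"genotypes": out / "genotypes.tsv", "phenotypes": out / "phenotypes.tsv",
             "truth": out / "truth.json"}
    geno.to_csv(paths["genotypes"], sep="\t")
    pd.DataFrame({"sample_id": samples, "phenotype": dataset.phenotype,
                  "exposure": dataset.exposure}).to_csv(
        paths["phenotypes"], sep="\t", index=False)
    truth = _jsonable(dataset.truth or {})
    paths["truth"].write_text(json.dumps(truth, indent=2) + "\n")
    return {k: str(v) for k, v in paths.items()}


def write_vcf(dataset: GxEDataset, path) -> None:
    """Write genotypes as a minimal unphased VCF (synthetic coordinates)."""
    samples = dataset.sample_ids or [f"s{i}" for i in range(dataset.n_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j, vid in enumerate(dataset.variant_ids):
            if dataset.ploidy == 1:
                gts = ["1" if g else "0" for g in dataset.genotypes[:, j]]
            else:
                enc = {0: "0/0", 1: "0/1", 2: "1/1"}
                gts = [enc[int(g)] for g in dataset.genotypes[:, j]]
            fh.write(f"1\t{j + 1}\t{vid}\tA\tB\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")
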