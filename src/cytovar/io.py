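"""Delimited-text and VCF readers/writers shared by the pipeline stages."""

from __future__ import annotations

import numpy as np
import pandas as pd

WELL_COLUMNS = [
    "chemical_id", "line_id", "batch", "plate", "role",
    "concentration_molar", "signal",
]

ROLES = {"treatment", "neg_ctrl", "pos_ctrl"}


def read_well_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"chemical_id": str, "line_id": str,
                            "batch": str, "plate": str})
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"well table {path}: missing columns {missing}")
    return df


def write_table(df: pd.DataFrame, path, stage: str, config_hash: str):
    """TSV with a provenance header comment naming the producing stage."""
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_genotype_matrix(prefix_or_path, map_path=None):
    """Sample x SNP integer/dosage matrix plus sidecar map.

    Accepts either a ``prefix`` (reads ``prefix.genotypes.tsv`` and
    ``prefix.map.tsv``) or explicit paths.
    """
    gpath = str(prefix_or_path)
    if map_path is None:
        gpath, map_path = f"{gpath}.genotypes.tsv", f"{gpath}.map.tsv"
    gdf = pd.read_csv(gpath, sep="\t", comment="#")
    samples = gdf["sample_id"].astype(str).tolist()
    geno = gdf.drop(columns="sample_id").to_numpy(float)
    snp_map = pd.read_csv(map_path, sep="\t", comment="#",
                          dtype={"snp_id": str, "chromosome": str})
    if list(gdf.columns[1:]) != list(snp_map["snp_id"]):
        raise ValueError("genotype matrix columns disagree with the map file")
    return geno, samples, snp_map


def read_vcf(path):
    """Genotypes from a VCF via cyvcf2; DS dosages honoured when present."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, ids, chroms, poss = [], [], [], []
    for var in vcf:
        try:
            dose = np.asarray(var.format("DS"), dtype=float).ravel()
        except (KeyError, TypeError, ValueError):
            gt = np.asarray(var.gt_types, dtype=float)  # 0,1,3=hom-alt, 2=missing
            dose = np.where(gt == 2, np.nan, np.where(gt == 3, 2.0, gt))
        rows.append(dose)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
    geno = np.array(rows, dtype=float).T  # samples x snps
    snp_map = pd.DataFrame({"snp_id": ids, "chromosome": chroms, "position_bp": poss})
    return geno, samples, snp_map
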