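#!/usr/bin/env python
"""Simulate the study: a genotyped cell-line panel screened against a
chemical library.

A scaled screen — 150 lines from 3 populations, 8 chemicals, 2,000 SNPs,
8-point concentration series, 1-2 plates per line — with two injected
genetic effects: an additive potency shift (chem000, 0.25 decades per
allele) and a high-concentration-only viability effect (chem001, 0.12 per
allele) that by construction leaves the true EC10 untouched.  Writes the
well table, genotypes and the full truth ledger under results/study/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cytovar import synthdata as sd

OUT = Path(__file__).resolve().parent.parent / "results" / "study"
SEED = 41

CONFIG = sd.SimConfig(
    n_lines=150, n_chemicals=8, n_snps=2000, n_populations=3,
    fst=0.1, maf_range=(0.2, 0.5), n_batches=4,
    seed=SEED,
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    geno, annot, snp_map = sd.simulate_genotypes(
        CONFIG.n_lines, CONFIG.n_snps, CONFIG.n_populations,
        CONFIG.fst, CONFIG.maf_range, SEED,
    )
    # causal SNPs must be testable by both routes: require the >=20-per-
    # genotype-class floor of the multivariate test before assigning roles
    from cytovar.association import filter_markers

    eligible = snp_map["snp_id"].to_numpy()[
        filter_markers(geno, min_per_genotype=20)["pass_manova"]
    ]
    CONFIG.causal_spec = [
        (f"chem000", str(eligible[100]), 0.25, "additive_shift"),
        (f"chem001", str(eligible[200]), 0.12, "high_conc_only"),
    ]
    baselines = pd.Series(
        np.linspace(-7.2, -4.8, CONFIG.n_chemicals),
        index=[f"chem{c:03d}" for c in range(CONFIG.n_chemicals)],
    )
    truth, deferred = sd.simulate_true_log_ec10(
        geno, annot, CONFIG.causal_spec, baselines,
        CONFIG.pop_shift_sd, CONFIG.line_sd, SEED + 1,
        snp_ids=list(snp_map["snp_id"]),
    )
    wells, ledger = sd.simulate_plates(truth, CONFIG, SEED + 2,
                                       deferred_effects=deferred)

    wells.to_csv(OUT / "wells.tsv", sep="\t", index=False)
    sd.write_genotype_matrix(geno, annot, snp_map, str(OUT / "panel"))
    sd.write_vcf(geno, annot, snp_map, OUT / "panel.vcf")
    truth.rename_axis("line_id").to_csv(OUT / "truth_log_ec10.tsv", sep="\t")
    pd.DataFrame({"well_id": ledger.injected_outliers}).to_csv(
        OUT / "truth_outliers.tsv", sep="\t", index=False)
    (OUT / "truth_meta.json").write_text(json.dumps({
        "batch_effects": {k: float(v) for k, v in ledger.batch_effects.items()},
        "causal_spec": CONFIG.causal_spec,
        "seed": SEED,
    }, indent=2))

    n_plates = wells["plate"].nunique()
    n_out = len(ledger.injected_outliers)
    print(f"simulated {CONFIG.n_lines} lines x {CONFIG.n_chemicals} chemicals "
          f"on {n_plates} plates ({len(wells):,} wells)")
    print(f"injected {n_out} outlier wells "
          f"({100 * n_out / (n_plates * CONFIG.n_chemicals * 8):.2f}% of "
          "treatment wells)")
    print(f"wrote {OUT}/wells.tsv, panel.* genotypes, truth ledger")


if __name__ == "__main__":
    main()
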