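import numpy as np
import pandas as pd
import pytest

from cytovar import synthdata as sd


@pytest.fixture(scope="session")
def small_genotypes():
    """400 lines x 300 SNPs from two moderately diverged populations."""
    return sd.simulate_genotypes(
        n_lines=400, n_snps=300, n_populations=2, fst=0.15,
        maf_range=(0.1, 0.5), seed=11,
    )


@pytest.fixture(scope="session")
def tiny_study():
    """A fully simulated miniature screen: wells, truth ledger, genotypes."""
    cfg = sd.SimConfig(
        n_lines=24, n_chemicals=3, n_snps=40, n_populations=2, n_batches=2,
        noise_sd=0.03, outlier_rate=0.0, p_second_plate=0.5, seed=5,
    )
    geno, annot, snp_map = sd.simulate_genotypes(
        cfg.n_lines, cfg.n_snps, cfg.n_populations, cfg.fst, cfg.maf_range, 21
    )
    baselines = pd.Series([-7.0, -6.0, -5.5], index=["cA", "cB", "cC"])
    truth, deferred = sd.simulate_true_log_ec10(
        geno, annot, [], baselines, pop_shift_sd=0.1, line_sd=0.3, seed=22
    )
    wells, ledger = sd.simulate_plates(truth, cfg, seed=23, deferred_effects=deferred)
    return {
        "config": cfg, "genotypes": geno, "annotation": annot,
        "snp_map": snp_map, "truth": truth, "wells": wells, "ledger": ledger,
    }
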