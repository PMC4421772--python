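"""Self-contained simulation studies over the pipeline's estimators.

Each function runs one ground-truth-controlled experiment — EC10 recovery,
outlier-rule operating characteristics, variability-factor shrinkage, null
calibration and power of the association tests, and the pi0 mixture
recovery — and returns its measured quantities.  The analysis drivers and
the acceptance harness both run these; all randomness flows from the single
``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import association as assoc
from . import doseresponse as dr
from . import synthdata as sd
from . import variability as vb


def _rngs(seed: int, n: int):
    return np.random.SeedSequence(seed).spawn(n)


def _seed_int(ss) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def ec10_recovery_study(n_profiles: int = 200, noise_sd: float = 0.05,
                        seed: int = 0) -> dict:
    """Fit accuracy on synthetic profiles with known log EC10."""
    s1, s2 = _rngs(seed, 2)
    rng = np.random.default_rng(s1)
    truth = rng.uniform(-7.5, -4.5, n_profiles)
    profiles, _ = sd.simulate_profiles(truth, seed=_seed_int(s2), noise_sd=noise_sd)
    errors = np.array([
        abs(dr.fit_logistic(p).log_ec10 - t) for p, t in zip(profiles, truth)
    ])
    return {"median_abs_error": float(np.median(errors)), "errors": errors}


def outlier_rule_study(n_clean: int = 1000, n_outlier: int = 1000,
                       magnitude: float = 0.5, noise_sd: float = 0.05,
                       seed: int = 0) -> dict:
    """Operating characteristics of the drop-one likelihood-factor-10 rule.

    Returns per-well and per-profile false-flag rates on clean profiles,
    sensitivity to a single injected displacement, and the profiles with
    their flag sets for external oracle comparison.
    """
    s1, s2, s3, s4 = _rngs(seed, 4)
    rng = np.random.default_rng(s1)

    clean_profiles, _ = sd.simulate_profiles(
        rng.uniform(-7.5, -4.5, n_clean), seed=_seed_int(s2), noise_sd=noise_sd
    )
    n_flags = n_flagged_profiles = 0
    clean_flags = []
    for p in clean_profiles:
        f = dr.detect_outliers(p)
        clean_flags.append(set(f.outliers))
        n_flags += len(f.outliers)
        n_flagged_profiles += bool(f.outliers)

    rng2 = np.random.default_rng(s3)
    out_profiles, truth = sd.simulate_profiles(
        rng2.uniform(-7.5, -4.5, n_outlier), seed=_seed_int(s4),
        noise_sd=noise_sd, outlier_magnitude=magnitude,
    )
    hits = 0
    out_flags = []
    for p, j in zip(out_profiles, truth["outlier_index"]):
        f = dr.detect_outliers(p)
        out_flags.append(set(f.outliers))
        hits += int(j) in f.outliers

    n_wells = n_clean * clean_profiles[0].d.size
    return {
        "false_flag_rate_per_well": n_flags / n_wells,
        "false_flag_rate_per_profile": n_flagged_profiles / n_clean,
        "sensitivity": hits / n_outlier,
        "clean_profiles": clean_profiles, "clean_flags": clean_flags,
        "outlier_profiles": out_profiles, "outlier_flags": out_flags,
        "outlier_truth": truth,
    }


def shrinkage_recovery_study(n_chemicals: int = 100, n_lines: int = 500,
                             line_sd: float = 0.3, sampling_sd: float = 0.2,
                             n_replicates: int = 2, seed: int = 0) -> dict:
    """Shrunken vs raw TDVF against the normal-theory truth 10^(z99 line_sd).

    Each chemical: per-line true log EC10 ~ N(base, line_sd^2), observed in
    ``n_replicates`` batches with N(0, sampling_sd^2) replicate noise; the
    pipeline's batch correction, sampling-variance estimate, VIF and
    shrinkage are then applied as on real data.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    raw, shrunk = [], []
    target = 10.0 ** (vb.z99() * line_sd)
    for c in range(n_chemicals):
        truth = rng.normal(-6.0, line_sd, n_lines)
        rows = []
        for b in range(n_replicates):
            obs = truth + rng.normal(0.0, sampling_sd, n_lines)
            for i in range(n_lines):
                rows.append({"chemical_id": f"c{c}", "line_id": f"l{i}",
                             "batch": f"b{b}", "plate": f"p{i}_{b}",
                             "log_ec10": obs[i], "censored": False,
                             "n_outliers": 0})
        per_line, registry = dr.batch_correct_and_aggregate(pd.DataFrame(rows))
        summary = vb.summarize_all(per_line, registry)
        raw.append(float(summary["tdvf"].iloc[0]))
        shrunk.append(float(summary["tdvf_shrunk"].iloc[0]))
    raw, shrunk = np.array(raw), np.array(shrunk)
    return {
        "target_factor": target,
        "mean_raw_tdvf": float(np.nanmean(raw)),
        "mean_shrunk_tdvf": float(np.nanmean(shrunk)),
        "n_shrunk_defined": int(np.isfinite(shrunk).sum()),
    }


def _null_response_set(n: int, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Realistic correlated null responses: per-line potency scatter plus
    well noise, with sex as a covariate and the EC10 phenotype alongside."""
    d = np.log10(sd.default_concentrations())
    le = rng.normal(-6.0, 0.3, n)
    b1 = rng.uniform(*sd.DEFAULT_SLOPE_RANGE, n)
    b0 = dr.LN9 - b1 * le
    Y = dr.curve(d[None, :], b0[:, None], b1[:, None], 1.0) \
        + rng.normal(0, 0.05, (n, d.size))
    X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
    pheno = le + rng.normal(0, 0.1, n)
    return Y, X, pheno


def null_calibration_study(n_snps: int = 5000, n_lines: int = 500,
                           alpha: float = 0.05, seed: int = 0) -> dict:
    """Type-I error of both association routes on null SNPs.

    Genotypes are drawn independently of the (correlated, realistic)
    response set, at MAFs keeping every genotype class above the
    20-individual floor of the multivariate test.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    Y, X, pheno = _null_response_set(n_lines, rng)
    rej_m = rej_e = n_tested = 0
    while n_tested < n_snps:
        g = rng.binomial(2, rng.uniform(0.25, 0.5), n_lines)
        if np.bincount(g, minlength=3).min() < 20:
            continue
        n_tested += 1
        rej_m += assoc.magwas_test(Y, g, X)["p"] < alpha
        rej_e += assoc.ec10_regression(pheno, g, X)["p"] < alpha
    return {"n_tests": n_tested,
            "magwas_rejection_rate": rej_m / n_tested,
            "ec10_rejection_rate": rej_e / n_tested}


def topconc_power_study(n_sims: int = 500, n_lines: int = 100,
                        effect: float = 0.06, alpha: float = 0.05,
                        seed: int = 0) -> dict:
    """Power when the genotype effect is confined to the top concentration.

    Per simulation: every line gets its own potency (line scatter 0.3
    decades), and the causal allele shifts viability only at the highest
    tested concentration by ``effect`` per allele — a pattern invisible to
    the EC10 summary.  The multivariate route tests the full profile; the
    EC10 route refits each profile and regresses the fitted log EC10 on
    dosage.  Genotype composition is fixed at 25/50/25 so the per-class
    floor of the multivariate test is always met.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    d = np.log10(sd.default_concentrations())
    g_fixed = np.repeat([0, 1, 2], [n_lines // 4, n_lines // 2,
                                    n_lines - n_lines // 4 - n_lines // 2])
    X = np.ones((n_lines, 1))
    rej_m = rej_e = 0
    for _ in range(n_sims):
        g = rng.permutation(g_fixed)
        le = rng.normal(-6.0, 0.3, n_lines)
        b1 = rng.uniform(*sd.DEFAULT_SLOPE_RANGE, n_lines)
        b0 = dr.LN9 - b1 * le
        Y = dr.curve(d[None, :], b0[:, None], b1[:, None], 1.0) \
            + rng.normal(0, 0.05, (n_lines, d.size))
        Y[:, -1] += effect * g
        rej_m += assoc.magwas_test(Y, g, X)["p"] < alpha
        ec10 = np.empty(n_lines)
        for i in range(n_lines):
            prof = dr.ResponseProfile("c", f"l{i}", "b", "p", d, Y[i])
            ec10[i] = dr.fit_logistic(prof).log_ec10
        rej_e += assoc.ec10_regression(ec10, g.astype(float), X)["p"] < alpha
    return {"magwas_power": rej_m / n_sims, "ec10_power": rej_e / n_sims}


def mixture_enrichment_study(n_chemicals: int = 179, alt_fraction: float = 0.25,
                             n_lines: int = 500, effect: float = 0.15,
                             n_reps: int = 20, seed: int = 0) -> dict:
    """Recovery of the true-discovery proportion for one SNP.

    One SNP is tested against every chemical's EC10 phenotype;
    ``alt_fraction`` of the chemicals carry a real additive effect.  The
    fixed-lambda pi0 estimate should recover the alternative fraction.  A
    single 179-chemical panel leaves the estimate with Monte-Carlo noise of
    about 0.07, so the study averages over ``n_reps`` replicate panels and
    reports the mean alongside the per-panel values.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_alt = int(round(alt_fraction * n_chemicals))
    X = np.ones((n_lines, 1))
    tdps = []
    for _ in range(n_reps):
        g = rng.binomial(2, 0.3, n_lines).astype(float)
        ps = []
        for c in range(n_chemicals):
            beta = effect if c < n_alt else 0.0
            y = beta * g + rng.normal(0, 0.3, n_lines)
            ps.append(assoc.ec10_regression(y, g, X)["p"])
        tdps.append(
            assoc.cross_chemical_enrichment(np.array(ps))["true_discovery_proportion"]
        )
    return {"true_discovery_proportion": float(np.mean(tdps)),
            "per_panel": np.array(tdps),
            "alt_fraction_true": n_alt / n_chemicals}
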