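"""Population variability in chemical potency: toxicodynamic variability
factors, technical-noise shrinkage, and comparison with in vivo estimates.

For each chemical, the spread of log10 EC10 across cell lines is summarised
by quantiles, and the ratio of the median individual's EC10 to the 1% most
sensitive individual's, ``TDVF = 10^(q50 - q01)``, serves as a
chemical-specific toxicodynamic variability factor (the quantity the
default 10^(1/2) uncertainty factor stands in for).

Observed variance is inflated by technical (sampling) noise.  With
per-observation sampling variance sigma_s^2 estimated from cross-batch
replicate pairs and n' replicates per line,

    VIF = var(logEC10) / (var(logEC10) - sigma_s^2 / mean(n')),

and the shrunken factor is ``10^((q50 - q01)/sqrt(VIF))``.  When estimated
technical variability is too large (denominator <= 0) no shrunken factor is
reported for the chemical.

In vivo toxicodynamic variability reported as a log-normal geometric SD is
converted to the same median-to-1%-tail scale via ``GSD^z99`` with
``z99 = Phi^-1(0.99) ~ 2.326``, enabling a two-sample Kolmogorov-Smirnov
comparison of the two factor distributions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ChemicalVariabilitySummary",
    "z99",
    "gsd_to_factor",
    "summarize_chemical",
    "estimate_sampling_variance",
    "compute_vif",
    "shrink_tdvf",
    "summarize_all",
    "compare_distributions",
    "population_anova",
]

logger = logging.getLogger(__name__)


def z99() -> float:
    """The 99% standard-normal quantile (~2.326), the GSD-to-factor exponent."""
    return float(stats.norm.ppf(0.99))


def gsd_to_factor(gsd) -> float:
    """Median-to-1%-quantile ratio of a log-normal with geometric SD ``gsd``."""
    gsd = np.asarray(gsd, dtype=float)
    if np.any(gsd < 1.0):
        raise ValueError("GSD must be >= 1")
    out = gsd ** z99()
    return float(out) if out.ndim == 0 else out


@dataclass
class ChemicalVariabilitySummary:
    chemical_id: str
    n_lines: int
    n_censored: int
    mean: float
    sd: float
    q01: float
    q05: float
    q50: float
    q95: float
    q99: float
    tdvf: float
    sigma_s2_hat: float = np.nan
    mean_nprime: float = np.nan
    vif: float = np.nan
    tdvf_shrunk: float = np.nan
    estimable: bool = True


def summarize_chemical(
    log_ec10: np.ndarray,
    censored: np.ndarray | None = None,
    chemical_id: str = "",
    min_n: int = 100,
) -> ChemicalVariabilitySummary:
    """Quantile summary and raw TDVF for one chemical.

    Censored (no-effect) lines are excluded and counted.  Quantiles use
    linear interpolation of order statistics.  Below ``min_n`` usable values
    a warning is logged (tail quantiles become unreliable); with no usable
    values the summary is marked inestimable.
    """
    log_ec10 = np.asarray(log_ec10, dtype=float)
    if censored is None:
        censored = np.zeros(log_ec10.shape, dtype=bool)
    censored = np.asarray(censored, dtype=bool)
    vals = log_ec10[~censored]
    n_cens = int(censored.sum())
    if vals.size == 0:
        logger.warning("chemical %s: all values censored; summary inestimable", chemical_id)
        nan = float("nan")
        return ChemicalVariabilitySummary(
            chemical_id, 0, n_cens, nan, nan, nan, nan, nan, nan, nan, nan,
            estimable=False,
        )
    if vals.size < min_n:
        logger.warning(
            "chemical %s: only %d non-censored values (< %d); tail quantiles unreliable",
            chemical_id, vals.size, min_n,
        )
    q01, q05, q50, q95, q99 = np.quantile(vals, [0.01, 0.05, 0.5, 0.95, 0.99])
    return ChemicalVariabilitySummary(
        chemical_id=chemical_id,
        n_lines=int(vals.size),
        n_censored=n_cens,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        q01=float(q01), q05=float(q05), q50=float(q50),
        q95=float(q95), q99=float(q99),
        tdvf=float(10.0 ** (q50 - q01)),
    )


def estimate_sampling_variance(registry: pd.DataFrame) -> float:
    """Per-observation sampling variance sigma_s^2 from cross-batch pairs.

    For each line with replicate observations in two different batches, the
    two-observation sample variance of (batch-corrected) log EC10 is
    ``(x1 - x2)^2 / 2``; sigma_s^2 is the mean over such pairs.  Returns NaN
    when the chemical has no cross-batch pair (no shrunken estimate).

    ``registry`` needs columns line_id, batch, log_ec10_corrected, censored
    (one row per plate-level observation for a single chemical).
    """
    usable = registry[~registry["censored"].astype(bool)]
    pair_vars = []
    for _, grp in usable.groupby("line_id"):
        if len(grp) < 2 or grp["batch"].nunique() < 2:
            continue
        # take the first observation in each of two distinct batches
        by_batch = grp.drop_duplicates("batch")
        x = by_batch["log_ec10_corrected"].to_numpy(float)[:2]
        pair_vars.append(float(np.var(x, ddof=1)))
    if not pair_vars:
        return float("nan")
    return float(np.mean(pair_vars))


def compute_vif(var_log_ec10: float, sigma_s2_hat: float, mean_nprime: float) -> float:
    """Variance inflation factor; NaN when technical noise is too large.

    ``VIF = var / (var - sigma_s^2 / mean(n'))``; undefined (NaN) when the
    denominator is <= 0, i.e. the estimated technical variability exceeds
    the observed between-line variance.  A defined VIF below 1 is
    impossible under the model and rejected as a data error.
    """
    if not (np.isfinite(var_log_ec10) and np.isfinite(sigma_s2_hat)):
        return float("nan")
    if mean_nprime < 1:
        raise ValueError("mean replicate count must be >= 1")
    denom = var_log_ec10 - sigma_s2_hat / mean_nprime
    if denom <= 0:
        return float("nan")
    vif = var_log_ec10 / denom
    if vif < 1.0 - 1e-12:
        raise ValueError("VIF < 1: negative sampling variance implied; data error")
    return float(vif)


def shrink_tdvf(summary: ChemicalVariabilitySummary) -> float:
    """Shrunken factor ``10^((q50 - q01)/sqrt(VIF))``; NaN when VIF undefined."""
    if not np.isfinite(summary.vif):
        return float("nan")
    return float(10.0 ** ((summary.q50 - summary.q01) / math.sqrt(summary.vif)))


def summarize_all(
    per_line: pd.DataFrame,
    registry: pd.DataFrame | None = None,
    min_n: int = 100,
) -> pd.DataFrame:
    """Per-chemical variability table (quantiles, TDVF, VIF, shrunken TDVF).

    ``per_line`` is the aggregated output of
    :func:`cytovar.doseresponse.batch_correct_and_aggregate`; ``registry``
    its replicate-level companion (needed for the shrinkage columns).
    """
    rows = []
    for chem, grp in per_line.groupby("chemical_id", sort=True):
        s = summarize_chemical(
            grp["log_ec10"].to_numpy(float),
            grp["censored"].to_numpy(bool),
            chemical_id=str(chem),
            min_n=min_n,
        )
        if s.estimable and registry is not None:
            ok = ~grp["censored"].astype(bool)
            if ok.sum() > 1:
                var = float(grp.loc[ok, "log_ec10"].var(ddof=1))
                s.mean_nprime = float(grp.loc[ok, "n_prime"].mean())
                s.sigma_s2_hat = estimate_sampling_variance(
                    registry[registry["chemical_id"] == chem]
                )
                s.vif = compute_vif(var, s.sigma_s2_hat, s.mean_nprime)
                s.tdvf_shrunk = shrink_tdvf(s)
        rows.append(vars(s).copy())
    return pd.DataFrame(rows)


def compare_distributions(in_vitro_factors, in_vivo_factors) -> dict:
    """Two-sample KS comparison of variability-factor distributions.

    The KS test runs on log10(factor); medians and central 90% intervals
    (empirical 5th-95th percentiles) of each sample are reported on the
    natural (fold) scale.
    """
    a = np.asarray(in_vitro_factors, dtype=float)
    b = np.asarray(in_vivo_factors, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both factor samples must be non-empty")
    ks = stats.ks_2samp(np.log10(a), np.log10(b), method="asymp")
    return {
        "median_in_vitro": float(np.median(a)),
        "interval_in_vitro": tuple(np.quantile(a, [0.05, 0.95])),
        "median_in_vivo": float(np.median(b)),
        "interval_in_vivo": tuple(np.quantile(b, [0.05, 0.95])),
        "ks_D": float(ks.statistic),
        "ks_p": float(ks.pvalue),
    }


def population_anova(
    per_line: pd.DataFrame,
    annotation: pd.DataFrame,
    min_lines_per_pop: int = 2,
) -> pd.DataFrame:
    """One-way ANOVA of log EC10 across populations, per chemical, with BH q.

    Chemicals with fewer than two populations having at least
    ``min_lines_per_pop`` usable lines are skipped (logged).
    """
    pop = annotation.set_index("sample_id")["population"]
    rows = []
    for chem, grp in per_line.groupby("chemical_id", sort=True):
        ok = ~grp["censored"].astype(bool)
        grp = grp[ok]
        labels = pop.reindex(grp["line_id"]).to_numpy()
        groups = [
            grp["log_ec10"].to_numpy(float)[labels == p]
            for p in pd.unique(labels[pd.notna(labels)])
        ]
        groups = [g for g in groups if g.size >= min_lines_per_pop]
        if len(groups) < 2:
            logger.info("chemical %s: degenerate population grouping; skipped", chem)
            continue
        f, p = stats.f_oneway(*groups)
        rows.append({"chemical_id": chem, "F": float(f), "p": float(p)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
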