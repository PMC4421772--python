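"""Genome-wide association of cytotoxicity with genotype.

Two mapping routes are provided:

* a multivariate analysis of covariance across the full 8-concentration
  viability profile — for the j-th individual with genotype class i,

      Y_ij = X_ij beta + mu_i + e_ij,   e_ij ~ N(0, Sigma),

  with covariates X (sex, batch indicators, 10 genotype principal
  components), unstructured error covariance Sigma, and the 2-df genotype
  effect tested by Pillai's trace with the standard F approximation.  This
  route is sensitive to response patterns (e.g. effects confined to the
  highest concentrations) that leave the EC10 unchanged;

* an ordinary least-squares regression of log EC10 on additive allele
  dosage with the same covariates, optionally after a rank-based inverse
  normal transform, with a two-stage genome scan (raw-scale prefilter at
  p < 5e-8, transformed-scale recomputation) to defuse phenotype outliers.

Marker QC (call rate, MAF, Hardy-Weinberg), per-chemical false discovery
control (Benjamini-Hochberg or Storey), +/-1 Mb regional pruning and a
cross-chemical pi0-based enrichment estimate for a single SNP complete the
mapping toolkit.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_markers",
    "hwe_pvalues",
    "genotype_pcs",
    "build_covariates",
    "magwas_test",
    "magwas_scan",
    "ec10_regression",
    "inverse_normal_transform",
    "two_stage_seq_scan",
    "per_chemical_fdr",
    "prune_regional",
    "cross_chemical_enrichment",
    "heritability_concordance_sim",
]

logger = logging.getLogger(__name__)

STAGE1_P = 5e-8


# ---------------------------------------------------------------------------
# marker QC


def hwe_pvalues(genotypes: np.ndarray) -> np.ndarray:
    """1-df chi-square Hardy-Weinberg test per SNP on hard calls.

    Missing entries (NaN) are ignored.  Monomorphic SNPs get p = 1.
    """
    g = np.asarray(genotypes, dtype=float)
    hard = np.where(np.isnan(g), np.nan, np.rint(g))
    n0 = np.nansum(hard == 0, axis=0).astype(float)
    n1 = np.nansum(hard == 1, axis=0).astype(float)
    n2 = np.nansum(hard == 2, axis=0).astype(float)
    n = n0 + n1 + n2
    p = (2 * n2 + n1) / (2 * n)
    q = 1.0 - p
    with np.errstate(divide="ignore", invalid="ignore"):
        e0, e1, e2 = n * q**2, 2 * n * p * q, n * p**2
        chi2 = ((n0 - e0) ** 2 / e0 + (n1 - e1) ** 2 / e1 + (n2 - e2) ** 2 / e2)
    pvals = stats.chi2.sf(chi2, df=1)
    pvals[(p == 0) | (p == 1)] = 1.0
    return pvals


def filter_markers(
    genotypes: np.ndarray,
    call_rate: float = 0.95,
    maf: float = 0.01,
    hwe_p: float = 1e-6,
    min_per_genotype: int | None = None,
) -> dict:
    """Marker QC masks.

    Drops SNPs with call rate < ``call_rate``, MAF < ``maf`` or
    Hardy-Weinberg p < ``hwe_p`` (all on hard calls; dosages are rounded to
    the nearest integer for counting).  When ``min_per_genotype`` is given,
    a second mask additionally requires that many samples in each of the
    three genotype classes (the asymptotic-theory requirement of the
    multivariate test).

    Returns a dict with ``pass_qc`` and ``pass_manova`` boolean masks plus
    the per-SNP ``maf``, ``call_rate``, ``hwe_p`` and genotype-class counts.
    """
    g = np.asarray(genotypes, dtype=float)
    n = g.shape[0]
    miss = np.isnan(g)
    cr = 1.0 - miss.mean(axis=0)
    hard = np.where(miss, np.nan, np.rint(g))
    counts = np.stack(
        [np.nansum(hard == k, axis=0) for k in (0, 1, 2)], axis=1
    ).astype(int)
    called = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = (2 * counts[:, 2] + counts[:, 1]) / (2.0 * np.maximum(called, 1))
    snp_maf = np.minimum(freq, 1.0 - freq)
    hwe = hwe_pvalues(g)
    pass_qc = (cr >= call_rate) & (snp_maf >= maf) & (hwe >= hwe_p)
    out = {
        "pass_qc": pass_qc,
        "maf": snp_maf,
        "call_rate": cr,
        "hwe_p": hwe,
        "genotype_counts": counts,
    }
    if min_per_genotype is not None:
        out["pass_manova"] = pass_qc & (counts.min(axis=1) >= min_per_genotype)
    return out


# ---------------------------------------------------------------------------
# covariates


def genotype_pcs(genotypes: np.ndarray, k: int = 10) -> np.ndarray:
    """Principal-component scores of the column-standardised dosage matrix.

    Missing dosages are mean-imputed and constant SNPs dropped before
    standardisation (mean 0, unit variance per SNP).  Scores are orthogonal;
    each component's sign is fixed so its largest-magnitude SNP loading is
    positive.
    """
    g = np.asarray(genotypes, dtype=float).copy()
    n, m = g.shape
    if n < k + 1 or m < k:
        raise ValueError(f"need more than {k} samples and SNPs for {k} PCs")
    col_mean = np.nanmean(g, axis=0)
    nan_idx = np.where(np.isnan(g))
    g[nan_idx] = np.take(col_mean, nan_idx[1])
    sd = g.std(axis=0)
    keep = sd > 0
    z = (g[:, keep] - g[:, keep].mean(axis=0)) / sd[keep]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            scores[:, j] *= -1.0
    return scores


def build_covariates(
    annotation: pd.DataFrame,
    genotypes: np.ndarray | None = None,
    n_pcs: int = 10,
    batch: pd.Series | None = None,
) -> np.ndarray:
    """Design matrix [intercept | sex | batch indicators | genotype PCs].

    Batch indicators drop the first level; raises if the assembled matrix is
    column-rank deficient.
    """
    n = len(annotation)
    cols = [np.ones(n)]
    sex = (annotation["sex"].to_numpy() == "M").astype(float)
    cols.append(sex)
    if batch is not None:
        dummies = pd.get_dummies(pd.Series(batch).astype(str), drop_first=True)
        cols.extend(dummies.to_numpy(float).T)
    if genotypes is not None:
        cols.extend(genotype_pcs(genotypes, k=n_pcs).T)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    return X


# ---------------------------------------------------------------------------
# multivariate (Pillai) test


def _pillai_from_sscp(H: np.ndarray, E: np.ndarray, q: int, ve: int) -> dict:
    """Pillai's trace and its F approximation from hypothesis/error SSCP."""
    p = H.shape[0]
    eig = np.linalg.eigvals(np.linalg.solve(E, H))
    eig = np.maximum(eig.real, 0.0)
    V = float(np.sum(eig / (1.0 + eig)))
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    nn = (ve - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    if V >= s:  # numerically saturated
        F = np.inf
    else:
        F = (df2 / df1) * (V / (s - V))
    pval = float(stats.f.sf(F, df1, df2))
    return {"V": V, "F": float(F), "df1": float(df1), "df2": float(df2),
            "p": pval, "s": s}


def magwas_test(
    Y: np.ndarray,
    genotype: np.ndarray,
    covariates: np.ndarray,
) -> dict:
    """Multivariate ANCOVA test of genotype on a multi-concentration response.

    ``Y`` is n x p (p responses per individual, replicate plates already
    averaged), ``genotype`` hard calls in {0, 1, 2} (classes present define
    the hypothesis df), ``covariates`` the n x c design including an
    intercept.  Fits Y = X beta + genotype-class means + error with
    unstructured Sigma, and tests the genotype effect by Pillai's trace V
    with the standard F approximation.

    Returns V, F, dfs, p and ``partial_r2 = V / s`` — bounded in [0, 1] and
    equal to the univariate partial R^2 when p = 1.

    Raises ``ValueError`` for a rank-deficient full design.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    g = np.rint(np.asarray(genotype, dtype=float)).astype(int)
    X = np.asarray(covariates, dtype=float)
    n, p = Y.shape

    classes = np.unique(g)
    q = len(classes) - 1
    if q < 1:
        raise ValueError("genotype has a single class; test refused")
    dummies = np.column_stack([(g == c).astype(float) for c in classes[1:]])
    Xfull = np.column_stack([X, dummies])
    rank_full = np.linalg.matrix_rank(Xfull)
    if rank_full < Xfull.shape[1]:
        raise ValueError("rank-deficient design; test refused")

    # residual SSCP under full and reduced models
    bf, _, _, _ = np.linalg.lstsq(Xfull, Y, rcond=None)
    Rf = Y - Xfull @ bf
    E = Rf.T @ Rf
    br, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    Rr = Y - X @ br
    H = Rr.T @ Rr - E

    ve = n - rank_full
    res = _pillai_from_sscp(E=E, H=H, q=q, ve=ve)
    res["partial_r2"] = res["V"] / res["s"]
    res["genotype_counts"] = tuple(int((g == c).sum()) for c in (0, 1, 2))
    return res


def magwas_scan(
    Y: np.ndarray,
    genotypes: np.ndarray,
    covariates: np.ndarray,
    snp_ids=None,
) -> pd.DataFrame:
    """Pillai test for each SNP column; rank-deficient SNPs skipped (logged)."""
    m = genotypes.shape[1]
    ids = snp_ids if snp_ids is not None else [f"snp{j}" for j in range(m)]
    rows = []
    for j in range(m):
        try:
            r = magwas_test(Y, genotypes[:, j], covariates)
        except ValueError as exc:
            logger.info("SNP %s skipped: %s", ids[j], exc)
            continue
        rows.append({"snp_id": ids[j], "method": "magwas", "p": r["p"],
                     "partial_r2": r["partial_r2"], "V": r["V"], "F": r["F"],
                     "genotype_counts": r["genotype_counts"]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# EC10 regression route


def inverse_normal_transform(y: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform, Phi^-1((rank - 0.5)/n).

    With no ties the output is exactly a permutation of the n standard
    normal quantiles; ties receive average ranks.
    """
    y = np.asarray(y, dtype=float)
    ranks = stats.rankdata(y, method="average")
    return stats.norm.ppf((ranks - 0.5) / y.size)


def ec10_regression(
    log_ec10: np.ndarray,
    dosage: np.ndarray,
    covariates: np.ndarray,
    transform: str = "none",
) -> dict:
    """OLS of (possibly transformed) log EC10 on additive allele dosage.

    Wald p-value for the dosage coefficient given the covariates.  Returns
    NaNs (and logs) for a zero-variance dosage.
    """
    y = np.asarray(log_ec10, dtype=float)
    if transform == "int":
        y = inverse_normal_transform(y)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    dose = np.asarray(dosage, dtype=float)
    if np.var(dose) == 0:
        logger.info("zero dosage variance; regression skipped")
        return {"beta": float("nan"), "se": float("nan"), "p": float("nan")}
    X = np.column_stack([np.asarray(covariates, float), dose])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = y.size - rank
    s2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(s2 * XtX_inv[-1, -1]))
    t = coef[-1] / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return {"beta": float(coef[-1]), "se": se, "p": float(p)}


def two_stage_seq_scan(
    log_ec10: np.ndarray,
    genotypes: np.ndarray,
    covariates: np.ndarray,
    snp_ids=None,
    stage1_p: float = STAGE1_P,
) -> pd.DataFrame:
    """Two-stage dense scan: raw-scale prefilter, then INT recomputation.

    Stage 1 regresses the untransformed phenotype on every SNP and keeps
    those with p < ``stage1_p``; stage 2 recomputes the survivors with the
    inverse-normal-transformed phenotype.  Stage-2 results are reported
    (phenotype outliers that manufacture stage-1 hits are neutralised).
    """
    m = genotypes.shape[1]
    ids = snp_ids if snp_ids is not None else [f"snp{j}" for j in range(m)]
    rows = []
    for j in range(m):
        r1 = ec10_regression(log_ec10, genotypes[:, j], covariates, transform="none")
        if np.isnan(r1["p"]) or r1["p"] >= stage1_p:
            continue
        r2 = ec10_regression(log_ec10, genotypes[:, j], covariates, transform="int")
        rows.append({"snp_id": ids[j], "method": "ec10_lm",
                     "p_stage1": r1["p"], "p": r2["p"], "beta": r2["beta"]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FDR, pruning, enrichment


def per_chemical_fdr(p: np.ndarray, method: str = "bh", storey_lambda: float = 0.5):
    """q-values for one chemical's p-value family.

    ``bh``: Benjamini-Hochberg step-up.  ``storey``: BH q-values scaled by
    the fixed-lambda pi0 estimate ``#{p > 0.5} / (0.5 m)`` (capped at 1).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    q_bh = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return q_bh
    if method == "storey":
        pi0 = min(1.0, np.mean(p > storey_lambda) / (1.0 - storey_lambda))
        return np.minimum(q_bh * pi0, 1.0)
    raise ValueError(f"unknown FDR method {method!r}")


def prune_regional(results: pd.DataFrame, window_bp: int = 1_000_000) -> pd.DataFrame:
    """Greedy +/-``window_bp`` pruning of redundant regional findings.

    Results are visited by ascending p; a SNP is kept iff no already-kept
    SNP on the same chromosome lies within the window.  Requires columns
    ``chrom``, ``pos``, ``p``.
    """
    if results.empty:
        return results.copy()
    ordered = results.sort_values("p", kind="mergesort")
    kept_pos: dict[str, list[int]] = {}
    keep_idx = []
    for idx, row in ordered.iterrows():
        c, x = str(row["chrom"]), int(row["pos"])
        if all(abs(x - x0) > window_bp for x0 in kept_pos.get(c, ())):
            kept_pos.setdefault(c, []).append(x)
            keep_idx.append(idx)
    return results.loc[keep_idx]


def cross_chemical_enrichment(p: np.ndarray, lam: float = 0.5, min_m: int = 20) -> dict:
    """pi0-based enrichment of one SNP's p-values across the chemical panel.

    ``pi0_hat = #{p > lambda} / ((1 - lambda) m)`` clipped to [0, 1]; the
    true-discovery proportion is ``1 - pi0_hat`` and the expected number of
    chemicals with a real association is ``round(m (1 - pi0_hat))``.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if m < min_m:
        raise ValueError(f"need at least {min_m} chemicals (got {m})")
    pi0 = float(np.clip(np.sum(p > lam) / ((1.0 - lam) * m), 0.0, 1.0))
    tdp = 1.0 - pi0
    return {"pi0_hat": pi0, "true_discovery_proportion": tdp,
            "expected_true_count": int(round(m * tdp))}


# ---------------------------------------------------------------------------
# heritability-estimator concordance


def heritability_concordance_sim(
    h2_truth: np.ndarray,
    se_a: np.ndarray,
    se_b: np.ndarray,
    n_reps: int = 10_000,
    seed: int = 0,
) -> dict:
    """Expected rank concordance of two noisy heritability estimators.

    Treating ``h2_truth`` as the true per-chemical heritabilities, each
    replicate adds independent N(0, se^2) errors elementwise to form paired
    estimate vectors and records their Spearman correlation.  Returns the
    full correlation sample and its mean — the concordance two unbiased
    estimators with these error levels should show.
    """
    t = np.asarray(h2_truth, dtype=float)
    sa = np.broadcast_to(np.asarray(se_a, dtype=float), t.shape)
    sb = np.broadcast_to(np.asarray(se_b, dtype=float), t.shape)
    if np.any(sa < 0) or np.any(sb < 0):
        raise ValueError("standard errors must be >= 0")
    rng = np.random.default_rng(seed)
    cors = np.empty(n_reps)
    for r in range(n_reps):
        ea = t + rng.normal(0.0, 1.0, t.size) * sa
        eb = t + rng.normal(0.0, 1.0, t.size) * sb
        cors[r] = stats.spearmanr(ea, eb).statistic
    return {"correlations": cors, "mean": float(np.mean(cors))}
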