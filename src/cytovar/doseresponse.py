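"""Concentration-response modelling for population cytotoxicity screens.

Raw plate signals are normalised against per-plate control wells, each
8-point profile is fitted with a logistic viability model by maximum
likelihood, suspect wells are flagged by a drop-one likelihood-ratio rule,
and per-plate log10 EC10 values are batch-corrected and averaged into one
value per (chemical, cell line).

Model
-----
The normalised viability ``y`` at log10 molar concentration ``d`` is

    y = eta + eps,   eps ~ N(0, sigma^2),
    logit(eta / theta_max) = beta0 + beta1 * d,

with the lower plateau fixed at zero (theta_min = 0) so that chemicals with
little or no cytotoxicity remain estimable.  ``theta_max`` is the viability
plateau at zero concentration; it is estimated because plates drift from the
nominal value of 1.  The EC10 is the concentration at which viability drops
10% below the fitted plateau, i.e. eta = 0.9 * theta_max, giving

    log10 EC10 = (ln 9 - beta0) / beta1        (beta1 < 0).

Profiles with beta1 >= 0 or an EC10 above the tested range are censored at
the highest tested concentration ("no-effect" values).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ResponseProfile",
    "LogisticFit",
    "curve",
    "normalize_plate",
    "normalize_well_table",
    "fit_logistic",
    "detect_outliers",
    "compute_log_ec10",
    "fit_well_table",
    "batch_correct_and_aggregate",
]

logger = logging.getLogger(__name__)

LN9 = math.log(9.0)

#: residual-variance floor (viability units squared) so that the profiled
#: Gaussian log-likelihood stays finite on noiseless (synthetic) profiles
SIGMA2_FLOOR = 1e-12


@dataclass
class ResponseProfile:
    """One normalised 8-concentration viability series for a single plate."""

    chemical_id: str
    line_id: str
    batch: str
    plate: str
    d: np.ndarray  # log10 molar concentration, strictly increasing
    y: np.ndarray  # normalised viability
    mask: np.ndarray = field(default=None)  # per-point inclusion flags

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.d.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.d.ndim != 1 or self.d.shape != self.y.shape:
            raise ValueError("d and y must be 1-D vectors of equal length")
        if np.any(np.diff(self.d) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("viability values must be finite")


@dataclass
class LogisticFit:
    """Maximum-likelihood fit of the logistic viability model."""

    beta0: float
    beta1: float
    sigma2: float
    theta_max: float
    theta_min: float = 0.0
    theta_max_fixed: bool = False
    log_likelihood: float = np.nan
    outliers: frozenset = frozenset()
    log_ec10: float = np.nan
    censored: bool = False
    converged: bool = False
    n_points: int = 0


def curve(d, beta0, beta1, theta_max):
    """Predicted viability eta = theta_max / (1 + exp(-(beta0 + beta1 d)))."""
    d = np.asarray(d, dtype=float)
    with np.errstate(over="ignore"):
        return theta_max / (1.0 + np.exp(-(beta0 + beta1 * d)))


# ---------------------------------------------------------------------------
# normalisation


def normalize_plate(wells: pd.DataFrame) -> tuple[list[ResponseProfile], list[str]]:
    """Normalise one plate's raw signals against its own control wells.

    ``y = (signal - median(pos)) / (median(neg) - median(pos))`` so that the
    negative (vehicle) controls define viability 1 and the positive (kill)
    controls define 0.

    Parameters
    ----------
    wells
        Rows for a single plate with columns ``chemical_id, line_id, batch,
        plate, role, concentration_molar, signal``; role is one of
        ``treatment``, ``neg_ctrl``, ``pos_ctrl``.

    Returns
    -------
    (profiles, issues) — profiles is empty and issues non-empty when the
    plate lacks a control class (the plate is rejected, not guessed at).
    """
    issues: list[str] = []
    plate_id = str(wells["plate"].iloc[0])
    neg = wells.loc[wells["role"] == "neg_ctrl", "signal"].to_numpy(float)
    pos = wells.loc[wells["role"] == "pos_ctrl", "signal"].to_numpy(float)
    if neg.size == 0 or pos.size == 0:
        issues.append(
            f"plate {plate_id}: missing "
            f"{'negative' if neg.size == 0 else 'positive'} controls; rejected"
        )
        logger.warning(issues[-1])
        return [], issues
    neg_med = float(np.median(neg))
    pos_med = float(np.median(pos))
    if neg_med <= pos_med:
        issues.append(f"plate {plate_id}: control medians inverted; rejected")
        logger.warning(issues[-1])
        return [], issues

    trt = wells[wells["role"] == "treatment"]
    profiles = []
    for (chem, line), grp in trt.groupby(["chemical_id", "line_id"], sort=True):
        grp = grp.sort_values("concentration_molar")
        conc = grp["concentration_molar"].to_numpy(float)
        y = (grp["signal"].to_numpy(float) - pos_med) / (neg_med - pos_med)
        profiles.append(
            ResponseProfile(
                chemical_id=str(chem),
                line_id=str(line),
                batch=str(grp["batch"].iloc[0]),
                plate=plate_id,
                d=np.log10(conc),
                y=y,
            )
        )
    return profiles, issues


def normalize_well_table(wells: pd.DataFrame):
    """Normalise every plate in a well table; returns (profiles, issues)."""
    profiles, issues = [], []
    for _, plate_wells in wells.groupby("plate", sort=True):
        p, iss = normalize_plate(plate_wells)
        profiles.extend(p)
        issues.extend(iss)
    return profiles, issues


# ---------------------------------------------------------------------------
# maximum-likelihood fitting

def _residuals(theta, d, y):
    b0, b1, tmax = theta
    with np.errstate(over="ignore"):
        u = 1.0 / (1.0 + np.exp(-(b0 + b1 * d)))
    return tmax * u - y


def _jacobian(theta, d, y):
    b0, b1, tmax = theta
    with np.errstate(over="ignore"):
        u = 1.0 / (1.0 + np.exp(-(b0 + b1 * d)))
    w = tmax * u * (1.0 - u)
    return np.column_stack([w, w * d, u])


def _residuals_fixed(theta, d, y, tmax):
    b0, b1 = theta
    with np.errstate(over="ignore"):
        u = 1.0 / (1.0 + np.exp(-(b0 + b1 * d)))
    return tmax * u - y


def _jacobian_fixed(theta, d, y, tmax):
    b0, b1 = theta
    with np.errstate(over="ignore"):
        u = 1.0 / (1.0 + np.exp(-(b0 + b1 * d)))
    w = tmax * u * (1.0 - u)
    return np.column_stack([w, w * d])


def _profile_loglik(rss: float, n: int) -> float:
    """Gaussian log-likelihood with sigma^2 profiled out (floored)."""
    s2 = max(rss / n, SIGMA2_FLOOR)
    return -0.5 * n * (math.log(2.0 * math.pi * s2) + 1.0)


def fit_logistic(
    profile: ResponseProfile,
    theta_max_rule: str | None = "plateau",
    n_starts: int = 5,
) -> LogisticFit:
    """Fit [beta0, beta1, sigma2, theta_max] by maximum likelihood.

    With Gaussian errors and sigma^2 profiled in closed form, the MLE of the
    mean parameters is the nonlinear least-squares solution; a multi-start
    Levenberg-Marquardt search over ``n_starts`` candidate midpoint
    locations x two slope scales guards against local optima.

    ``theta_max_rule`` handles low-toxicity chemicals whose response at the
    highest tested concentration stays above 0.4:

    - ``"plateau"`` (default): theta_max fixed at the zero-concentration
      plateau estimate, the mean of the two lowest-concentration responses;
    - ``"top"``: theta_max fixed at the observed highest-concentration
      response (the alternative literal reading);
    - ``None``: theta_max always free.

    Raises ``ValueError`` with fewer than 4 usable points.
    """
    m = profile.mask
    d = profile.d[m]
    y = profile.y[m]
    n = d.size
    if n < 4:
        raise ValueError(f"fit refused: only {n} usable points (need >= 4)")

    tmax_fixed = None
    if theta_max_rule is not None and y[-1] > 0.4:
        if theta_max_rule == "plateau":
            tmax_fixed = float(np.mean(y[:2]))
        elif theta_max_rule == "top":
            tmax_fixed = float(y[-1])
        else:
            raise ValueError(f"unknown theta_max_rule {theta_max_rule!r}")
        if tmax_fixed <= 0:  # degenerate profile; fall back to a free plateau
            tmax_fixed = None

    tmax0 = float(np.clip(np.mean(np.sort(y)[-2:]), 0.1, 2.0))
    d50s = np.linspace(d[0] - 0.5, d[-1] + 0.5, n_starts)
    slopes = (-1.0, -4.0)

    best = None
    for d50 in d50s:
        for b1 in slopes:
            if tmax_fixed is None:
                x0 = np.array([-b1 * d50, b1, tmax0])
                res = least_squares(
                    _residuals, x0, jac=_jacobian, args=(d, y),
                    method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                    max_nfev=400,
                )
            else:
                x0 = np.array([-b1 * d50, b1])
                res = least_squares(
                    _residuals_fixed, x0, jac=_jacobian_fixed,
                    args=(d, y, tmax_fixed),
                    method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                    max_nfev=400,
                )
            if best is None or res.cost < best.cost:
                best = res

    converged = bool(best is not None and best.status > 0)
    if tmax_fixed is None:
        b0, b1, tmax = best.x
    else:
        b0, b1 = best.x
        tmax = tmax_fixed
    rss = 2.0 * best.cost
    fit = LogisticFit(
        beta0=float(b0),
        beta1=float(b1),
        sigma2=max(rss / n, SIGMA2_FLOOR),
        theta_max=float(tmax),
        theta_max_fixed=tmax_fixed is not None,
        log_likelihood=_profile_loglik(rss, n),
        converged=converged,
        n_points=n,
    )
    if converged:
        le, cens = compute_log_ec10(fit, d_max=float(profile.d[-1]))
        fit.log_ec10, fit.censored = le, cens
    return fit


def compute_log_ec10(fit: LogisticFit, d_max: float) -> tuple[float, bool]:
    """log10 EC10 from a converged fit; censored at the top tested dose.

    Solves eta = 0.9 * theta_max, i.e. ``(ln 9 - beta0)/beta1``.  Returns
    ``(d_max, True)`` when the curve never drops 10% within the tested range
    (beta1 >= 0 or the solution exceeds d_max) — the "no-effect" case.
    """
    if fit.beta1 < 0:
        le = (LN9 - fit.beta0) / fit.beta1
        if le <= d_max:
            return float(le), False
    return float(d_max), True


def detect_outliers(
    profile: ResponseProfile,
    theta_max_rule: str | None = "plateau",
    n_starts: int = 5,
    lr_factor: float = 10.0,
) -> LogisticFit:
    """Drop-one outlier detection followed by a single refit.

    Each point is dropped in succession and the model refitted; a point is
    flagged iff the maximised likelihood of the reduced fit exceeds
    ``lr_factor`` times the full-fit likelihood (improvement of at least
    ln 10 in log-likelihood by default).  One pass only: all flags are
    collected against the full fit, then the model is refitted once on the
    non-flagged points, and that refit supplies the final parameters.

    If flagging would leave fewer than 4 points, the least-offending flagged
    points are retained (smallest likelihood improvement first) and a
    warning is logged.
    """
    full = fit_logistic(profile, theta_max_rule=theta_max_rule, n_starts=n_starts)
    base_mask = profile.mask.copy()
    idx = np.flatnonzero(base_mask)
    threshold = math.log(lr_factor)

    gains = {}
    for j in idx:
        m = base_mask.copy()
        m[j] = False
        sub = ResponseProfile(
            profile.chemical_id, profile.line_id, profile.batch, profile.plate,
            profile.d, profile.y, mask=m,
        )
        red = fit_logistic(sub, theta_max_rule=theta_max_rule, n_starts=n_starts)
        gains[int(j)] = red.log_likelihood - full.log_likelihood

    flagged = sorted(j for j, g in gains.items() if g >= threshold)
    if len(idx) - len(flagged) < 4:
        keep_back = len(flagged) - (len(idx) - 4)
        # retain the least-offending flagged points
        by_gain = sorted(flagged, key=lambda j: gains[j])
        restored = by_gain[:keep_back]
        flagged = sorted(set(flagged) - set(restored))
        logger.warning(
            "profile (%s, %s, plate %s): outlier flags would leave <4 points; "
            "kept %d least-offending point(s)",
            profile.chemical_id, profile.line_id, profile.plate, keep_back,
        )

    if not flagged:
        full.outliers = frozenset()
        return full

    m = base_mask.copy()
    m[flagged] = False
    refit_profile = ResponseProfile(
        profile.chemical_id, profile.line_id, profile.batch, profile.plate,
        profile.d, profile.y, mask=m,
    )
    final = fit_logistic(refit_profile, theta_max_rule=theta_max_rule, n_starts=n_starts)
    final.outliers = frozenset(flagged)
    return final


# ---------------------------------------------------------------------------
# plate-level driver and aggregation


def _profiles_from_normalized(wells: pd.DataFrame) -> list[ResponseProfile]:
    """Treat the signal column as already-normalised viability."""
    out = []
    trt = wells[wells["role"] == "treatment"] if "role" in wells else wells
    for (chem, line, plate), grp in trt.groupby(
        ["chemical_id", "line_id", "plate"], sort=True
    ):
        grp = grp.sort_values("concentration_molar")
        out.append(
            ResponseProfile(
                chemical_id=str(chem), line_id=str(line),
                batch=str(grp["batch"].iloc[0]), plate=str(plate),
                d=np.log10(grp["concentration_molar"].to_numpy(float)),
                y=grp["signal"].to_numpy(float),
            )
        )
    return out


def fit_well_table(
    wells: pd.DataFrame,
    theta_max_rule: str | None = "plateau",
    n_starts: int = 5,
    outlier_detection: bool = True,
    pre_normalized: bool = False,
) -> pd.DataFrame:
    """Normalise and fit every (chemical, line, plate) profile in a well table.

    With ``pre_normalized=True`` the signal column is taken as viability on
    the 0-1 scale and control wells are not required.  Returns one row per
    plate-level fit with full parameters for audit.
    """
    if pre_normalized:
        profiles = _profiles_from_normalized(wells)
    else:
        profiles, _ = normalize_well_table(wells)
    rows = []
    for prof in profiles:
        if outlier_detection:
            fit = detect_outliers(prof, theta_max_rule=theta_max_rule, n_starts=n_starts)
        else:
            fit = fit_logistic(prof, theta_max_rule=theta_max_rule, n_starts=n_starts)
        logger.debug(
            "fit %s/%s plate %s: beta0=%.4g beta1=%.4g theta_max=%.4g "
            "sigma2=%.3g logL=%.4g outliers=%s log_ec10=%.4g censored=%s",
            prof.chemical_id, prof.line_id, prof.plate, fit.beta0, fit.beta1,
            fit.theta_max, fit.sigma2, fit.log_likelihood,
            sorted(fit.outliers), fit.log_ec10, fit.censored,
        )
        rows.append(
            {
                "chemical_id": prof.chemical_id,
                "line_id": prof.line_id,
                "batch": prof.batch,
                "plate": prof.plate,
                "beta0": fit.beta0,
                "beta1": fit.beta1,
                "sigma2": fit.sigma2,
                "theta_max": fit.theta_max,
                "theta_max_fixed": fit.theta_max_fixed,
                "log_likelihood": fit.log_likelihood,
                "n_outliers": len(fit.outliers),
                "outlier_indices": ",".join(map(str, sorted(fit.outliers))),
                "log_ec10": fit.log_ec10,
                "censored": fit.censored,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def batch_correct_and_aggregate(
    plate_fits: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Additive batch correction and replicate averaging of log EC10.

    Per chemical, each batch's mean log EC10 (over non-censored fits) minus
    the grand mean is subtracted from that batch's observations; corrected
    values are then averaged across replicate plates per line.  A chemical
    seen in a single batch passes through uncorrected (logged).

    Returns
    -------
    per_line : one row per (chemical_id, line_id) with ``log_ec10``,
        ``censored`` (all replicates censored), ``n_prime`` (replicate
        count), ``batches``, ``n_outliers``.
    registry : the pre-average corrected replicate values, one row per
        plate-level observation — input to the sampling-variance stage.
    """
    needed = {"chemical_id", "line_id", "batch", "plate", "log_ec10", "censored"}
    missing = needed - set(plate_fits.columns)
    if missing:
        raise ValueError(f"plate_fits missing columns: {sorted(missing)}")

    out_lines, out_reg = [], []
    for chem, grp in plate_fits.groupby("chemical_id", sort=True):
        grp = grp.copy()
        usable = grp[~grp["censored"].astype(bool)]
        batches = grp["batch"].unique()
        if len(batches) < 2 or usable.empty:
            if len(batches) < 2:
                logger.info("chemical %s observed in a single batch; correction is identity", chem)
            shift = pd.Series(0.0, index=batches)
        else:
            batch_means = usable.groupby("batch")["log_ec10"].mean()
            grand = usable["log_ec10"].mean()
            shift = (batch_means - grand).reindex(batches).fillna(0.0)
        grp["log_ec10_corrected"] = grp["log_ec10"] - grp["batch"].map(shift).astype(float)

        for line, lg in grp.groupby("line_id", sort=True):
            ok = ~lg["censored"].astype(bool)
            all_censored = not ok.any()
            value = float(lg.loc[ok, "log_ec10_corrected"].mean()) if not all_censored else float(
                lg["log_ec10_corrected"].mean()
            )
            out_lines.append(
                {
                    "chemical_id": chem,
                    "line_id": line,
                    "log_ec10": value,
                    "censored": all_censored,
                    "n_prime": int(len(lg)),
                    "batches": ",".join(sorted(map(str, lg["batch"].unique()))),
                    "n_outliers": int(lg["n_outliers"].sum()) if "n_outliers" in lg else 0,
                }
            )
        out_reg.append(
            grp[["chemical_id", "line_id", "batch", "plate", "log_ec10",
                 "log_ec10_corrected", "censored"]]
        )

    per_line = pd.DataFrame(out_lines)
    registry = pd.concat(out_reg, ignore_index=True) if out_reg else pd.DataFrame()
    return per_line, registry
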