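"""Synthetic population cytotoxicity screens with known ground truth.

Emulates the structure of a large lymphoblastoid-cell-line screen: a panel
of genotyped cell lines drawn from several ancestral populations, each
screened against a chemical library over an 8-point concentration series
(0.33 nM - 92 uM by default), with 1-2 replicate plates per line, plate-level
viability-plateau drift, batch shifts in log EC10, Gaussian well noise and
sporadic outlier wells.  Every injected effect is recorded in a
:class:`TruthLedger` so downstream estimates can be scored against truth.

Genotypes follow the Balding-Nichols model: a per-SNP ancestral frequency
drawn uniformly from ``maf_range`` and per-population frequencies from
``Beta(p(1-F)/F, (1-p)(1-F)/F)`` at divergence ``F`` (FST), with genotypes
binomial(2, p_pop).  SNPs are independent (no linkage disequilibrium).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .doseresponse import LN9, ResponseProfile, curve

__all__ = [
    "SimConfig",
    "TruthLedger",
    "default_concentrations",
    "simulate_genotypes",
    "simulate_trios",
    "simulate_true_log_ec10",
    "simulate_plates",
    "simulate_profiles",
    "write_genotype_matrix",
    "write_vcf",
]

#: slope range: Hill coefficients 1-3, i.e. beta1 in [-3 ln10, -ln10] per
#: log10-molar unit — typical steepness for single-target cytotoxicity
DEFAULT_SLOPE_RANGE = (-3.0 * math.log(10.0), -math.log(10.0))


def default_concentrations(n: int = 8) -> np.ndarray:
    """Log-spaced molar concentration series, 0.33 nM to 92 uM."""
    return np.geomspace(0.33e-9, 92e-6, n)


@dataclass
class SimConfig:
    """Study design and noise structure of the synthetic screen.

    Defaults reproduce the screen dimensions the analysis assumes: 1,086
    lines from 9 populations, 179 chemicals, 8-point series, 1-2 plates per
    line.  Smaller studies are obtained by overriding the counts only.
    """

    n_lines: int = 1086
    n_chemicals: int = 179
    n_snps: int = 10_000
    n_populations: int = 9
    fst: float = 0.10
    maf_range: tuple[float, float] = (0.05, 0.5)
    concentrations: np.ndarray = field(default_factory=default_concentrations)
    causal_spec: list = field(default_factory=list)  # (chem, snp, effect, mode)
    batch_sd: float = 0.10  # log10 units
    noise_sd: float = 0.05  # viability units
    outlier_rate: float = 0.01
    outlier_magnitude: float = 0.5  # viability units
    p_second_plate: float = 0.65  # fraction of lines with a replicate plate
    n_batches: int = 8
    line_sd: float = 0.30  # per-line log10 EC10 scatter
    pop_shift_sd: float = 0.10  # per-(population, chemical) shift
    slope_range: tuple[float, float] = DEFAULT_SLOPE_RANGE
    theta_max_range: tuple[float, float] = (0.85, 1.05)  # plate plateau drift
    raw_neg_median: float = 40_000.0  # raw-luminescence anchors (arbitrary
    raw_pos_median: float = 2_000.0   # but fixed; the scale is not modelled)
    raw_noise_cv: float = 0.05  # multiplicative well noise on raw signal
    n_control_wells: int = 16  # per control class per plate
    emit_trios: bool = False
    seed: int = 0

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.outlier_rate < 1.0):
            raise ValueError("outlier_rate must lie in [0, 1)")
        for name in ("n_lines", "n_chemicals", "n_snps", "n_populations", "n_batches"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class TruthLedger:
    """Everything injected into a simulated screen, for scoring estimates."""

    true_log_ec10: pd.DataFrame  # line x chemical, log10 molar
    injected_outliers: list  # well_id strings
    causal_assignments: list  # copy of causal_spec
    batch_effects: dict  # batch -> log10 shift
    plate_theta_max: dict = field(default_factory=dict)  # plate -> plateau


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(
    n_lines: int,
    n_snps: int,
    n_populations: int,
    fst: float,
    maf_range: tuple[float, float],
    seed: int,
):
    """Balding-Nichols genotypes for ``n_lines`` samples.

    Returns ``(genotypes, annotation, snp_map)``: an int8 (lines x SNPs)
    matrix of allele counts, a sample annotation table (sample_id,
    population, sex), and a marker map (snp_id, chromosome, position_bp,
    1-based positions).  Populations are equal-sized (within 1) and sex is
    balanced.  ``fst = 0`` collapses every population to the ancestral
    frequency.
    """
    if n_lines <= 0 or n_snps <= 0 or n_populations <= 0:
        raise ValueError("counts must be positive")
    if not (0.0 <= fst < 1.0):
        raise ValueError("fst must lie in [0, 1)")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")

    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(lo, hi, size=n_snps)
    if fst == 0.0:
        p_pop = np.tile(p_anc, (n_populations, 1))
    else:
        a = p_anc * (1.0 - fst) / fst
        b = (1.0 - p_anc) * (1.0 - fst) / fst
        p_pop = rng.beta(a, b, size=(n_populations, n_snps))

    # equal-sized populations, sizes differing by at most 1
    base, extra = divmod(n_lines, n_populations)
    sizes = [base + (1 if k < extra else 0) for k in range(n_populations)]
    pop_labels = np.repeat(np.arange(n_populations), sizes)

    geno = np.empty((n_lines, n_snps), dtype=np.int8)
    start = 0
    for k, size in enumerate(sizes):
        geno[start:start + size] = rng.binomial(2, p_pop[k], size=(size, n_snps))
        start += size

    sex = np.array(["F", "M"] * (n_lines // 2 + 1))[:n_lines]
    rng.shuffle(sex)
    annotation = pd.DataFrame(
        {
            "sample_id": [f"L{i:05d}" for i in range(n_lines)],
            "population": [f"POP{p}" for p in pop_labels],
            "sex": sex,
        }
    )

    chrom = (np.arange(n_snps) % 22) + 1
    pos = np.empty(n_snps, dtype=np.int64)
    for c in range(1, 23):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = np.sort(rng.integers(1, 250_000_000, size=idx.size))
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"snp{i:06d}" for i in range(n_snps)],
            "chromosome": chrom.astype(str),
            "position_bp": pos,
        }
    )
    return geno, annotation, snp_map


def simulate_trios(
    n_trios: int,
    n_snps: int,
    n_populations: int,
    fst: float,
    maf_range: tuple[float, float],
    seed: int,
):
    """Parent-parent-child triples by Mendelian transmission.

    Parents are independent Balding-Nichols draws; each child allele is a
    fair pick from the corresponding parent's two alleles.  Annotation
    carries ``trio_id`` and ``trio_role`` (father/mother/child).
    """
    parents, annot, snp_map = simulate_genotypes(
        2 * n_trios, n_snps, n_populations, fst, maf_range, seed
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    fathers = parents[0::2]
    mothers = parents[1::2]
    # transmitted allele: Bernoulli(g/2) per parent per SNP
    child = rng.binomial(1, fathers / 2.0) + rng.binomial(1, mothers / 2.0)
    geno = np.vstack([fathers, mothers, child]).astype(np.int8)
    n = n_trios
    annot = pd.DataFrame(
        {
            "sample_id": [f"T{t:04d}_{r}" for r in ("F", "M", "C") for t in range(n)],
            "population": list(annot["population"][0::2]) * 3,
            "sex": ["M"] * n + ["F"] * n + list(rng.choice(["F", "M"], n)),
            "trio_id": [f"trio{t:04d}" for t in range(n)] * 3,
            "trio_role": ["father"] * n + ["mother"] * n + ["child"] * n,
        }
    )
    return geno, annot, snp_map


# ---------------------------------------------------------------------------
# true phenotypes


def simulate_true_log_ec10(
    genotypes: np.ndarray,
    annotation: pd.DataFrame,
    causal_spec: list,
    chem_baselines: dict | pd.Series,
    pop_shift_sd: float,
    line_sd: float,
    seed: int,
    snp_ids: list | None = None,
):
    """True per-line log10 EC10 matrix with additive structure.

    ``log EC10(line, chem) = baseline(chem) + pop_shift(pop, chem)
    + sum(additive causal effects x allele count) + N(0, line_sd^2)``.

    ``causal_spec`` entries are ``(chemical_id, snp_id, effect, mode)``;
    mode ``"additive_shift"`` enters the sum above, mode ``"high_conc_only"``
    is recorded and returned as a deferred effect (it perturbs only the
    top-concentration response at plate generation, never the EC10).

    Returns ``(truth, deferred)`` where ``truth`` is a (line x chemical)
    DataFrame and ``deferred`` a list of dicts with per-line allele counts.
    """
    rng = np.random.default_rng(seed)
    chem_baselines = pd.Series(chem_baselines, dtype=float)
    chems = list(chem_baselines.index)
    lines = list(annotation["sample_id"])
    pops = annotation["population"].to_numpy()
    n_lines = len(lines)

    snp_index = {s: i for i, s in enumerate(snp_ids)} if snp_ids is not None else None

    truth = np.tile(chem_baselines.to_numpy(), (n_lines, 1))
    uniq_pops = pd.unique(pops)
    shift = rng.normal(0.0, pop_shift_sd, size=(len(uniq_pops), len(chems)))
    pop_row = {p: i for i, p in enumerate(uniq_pops)}
    truth += shift[[pop_row[p] for p in pops], :]

    deferred = []
    for chem, snp, effect, mode in causal_spec:
        if chem not in chems:
            raise ValueError(f"causal chemical {chem!r} not in chem_baselines")
        if snp_index is not None:
            if snp not in snp_index:
                raise ValueError(f"causal SNP {snp!r} absent from genotype matrix")
            col = snp_index[snp]
        else:
            col = int(snp)
            if not (0 <= col < genotypes.shape[1]):
                raise ValueError(f"causal SNP index {snp} absent from genotype matrix")
        dosage = genotypes[:, col].astype(float)
        if mode == "additive_shift":
            truth[:, chems.index(chem)] += effect * dosage
        elif mode == "high_conc_only":
            deferred.append({"chemical_id": chem, "snp_id": snp,
                             "effect": float(effect), "dosage": dosage})
        else:
            raise ValueError(f"unknown causal mode {mode!r}")

    truth += rng.normal(0.0, line_sd, size=truth.shape)
    return pd.DataFrame(truth, index=lines, columns=chems), deferred


# ---------------------------------------------------------------------------
# plates


def simulate_plates(
    true_log_ec10: pd.DataFrame,
    config: SimConfig,
    seed: int,
    deferred_effects: list | None = None,
):
    """Raw plate-format well table realising the logistic forward model.

    Every line is seeded on one plate in its home batch and, with
    probability ``p_second_plate``, on a second plate in a batch drawn at
    random (so replicates may fall within or between batches).  A plate
    carries all chemicals (8 treatment wells each) plus negative (vehicle)
    and positive (kill) control wells.  Per plate the viability plateau
    theta_max drifts uniformly in ``theta_max_range``; per profile the slope
    is drawn from ``slope_range``; wells get additive N(0, noise_sd^2)
    viability noise; outlier wells (rate ``outlier_rate``) are displaced by
    ``outlier_magnitude`` with random sign.  Signals are mapped to a raw
    luminescence scale by a per-plate affine transform anchored at the
    control medians, with multiplicative well noise ``raw_noise_cv``.

    Returns ``(wells, ledger)``.
    """
    rng = np.random.default_rng(seed)
    lines = list(true_log_ec10.index)
    chems = list(true_log_ec10.columns)
    conc = config.concentrations
    d = np.log10(conc)
    n_conc = conc.size

    batch_ids = [f"B{k:02d}" for k in range(config.n_batches)]
    batch_shift = dict(zip(batch_ids, rng.normal(0.0, config.batch_sd, config.n_batches)))
    home_batch = rng.permutation(np.arange(len(lines)) % config.n_batches)

    top_effect = np.zeros((len(lines), len(chems)))
    for eff in deferred_effects or []:
        top_effect[:, chems.index(eff["chemical_id"])] += eff["effect"] * eff["dosage"]

    records = []
    outlier_wells = []
    plate_tmax = {}
    truth_mat = true_log_ec10.to_numpy()

    for i, line in enumerate(lines):
        plate_batches = [batch_ids[home_batch[i]]]
        if rng.random() < config.p_second_plate:
            plate_batches.append(batch_ids[rng.integers(config.n_batches)])
        for rep, batch in enumerate(plate_batches):
            plate = f"{line}_r{rep}"
            tmax = rng.uniform(*config.theta_max_range)
            plate_tmax[plate] = tmax
            span = config.raw_neg_median - config.raw_pos_median

            b1 = rng.uniform(config.slope_range[0], config.slope_range[1], len(chems))
            b0 = LN9 - b1 * (truth_mat[i] + batch_shift[batch])
            eta = tmax / (1.0 + np.exp(-(b0[:, None] + b1[:, None] * d[None, :])))
            y = eta + rng.normal(0.0, config.noise_sd, eta.shape)
            if top_effect.any():
                y[:, -1] += top_effect[i]
            out_mask = rng.random(y.shape) < config.outlier_rate
            y = y + out_mask * config.outlier_magnitude * rng.choice([-1.0, 1.0], y.shape)

            raw = config.raw_pos_median + y * span
            if config.raw_noise_cv > 0:
                raw = raw * (1.0 + config.raw_noise_cv * rng.standard_normal(raw.shape))

            for c, chem in enumerate(chems):
                for k in range(n_conc):
                    well_id = f"{plate}:{chem}:{k}"
                    records.append(
                        (well_id, chem, line, batch, plate, "treatment",
                         conc[k], raw[c, k])
                    )
                    if out_mask[c, k]:
                        outlier_wells.append(well_id)

            for role, level in (("neg_ctrl", 1.0), ("pos_ctrl", 0.0)):
                yc = level + rng.normal(0.0, config.noise_sd, config.n_control_wells)
                rawc = config.raw_pos_median + yc * span
                if config.raw_noise_cv > 0:
                    rawc = rawc * (1.0 + config.raw_noise_cv
                                   * rng.standard_normal(rawc.shape))
                for k in range(config.n_control_wells):
                    records.append(
                        (f"{plate}:{role}:{k}", "", line, batch, plate, role,
                         np.nan, rawc[k])
                    )

    wells = pd.DataFrame.from_records(
        records,
        columns=["well_id", "chemical_id", "line_id", "batch", "plate",
                 "role", "concentration_molar", "signal"],
    )
    ledger = TruthLedger(
        true_log_ec10=true_log_ec10.copy(),
        injected_outliers=outlier_wells,
        causal_assignments=list(config.causal_spec),
        batch_effects=batch_shift,
        plate_theta_max=plate_tmax,
    )
    return wells, ledger


def simulate_profiles(
    true_log_ec10: np.ndarray,
    seed: int,
    noise_sd: float = 0.05,
    slope_range: tuple[float, float] = DEFAULT_SLOPE_RANGE,
    theta_max: float = 1.0,
    concentrations: np.ndarray | None = None,
    outlier_magnitude: float = 0.0,
) -> tuple[list[ResponseProfile], pd.DataFrame]:
    """Normalised-scale profiles straight from the logistic model.

    A lighter companion to :func:`simulate_plates` for fit-level studies:
    one profile per entry of ``true_log_ec10``, slope drawn per profile,
    additive Gaussian noise, and (when ``outlier_magnitude > 0``) exactly
    one well per profile displaced by ``+/- outlier_magnitude`` at a random
    concentration index.  Returns the profiles and a truth table with the
    drawn parameters and the outlier index (-1 when none).
    """
    if concentrations is None:
        concentrations = default_concentrations()
    d = np.log10(np.asarray(concentrations, float))
    rng = np.random.default_rng(seed)
    true_log_ec10 = np.asarray(true_log_ec10, float)

    profiles, rows = [], []
    for i, le in enumerate(true_log_ec10):
        b1 = rng.uniform(slope_range[0], slope_range[1])
        b0 = LN9 - b1 * le
        y = curve(d, b0, b1, theta_max) + rng.normal(0.0, noise_sd, d.size)
        out_idx = -1
        if outlier_magnitude > 0:
            out_idx = int(rng.integers(d.size))
            y[out_idx] += outlier_magnitude * rng.choice([-1.0, 1.0])
        profiles.append(
            ResponseProfile(
                chemical_id=f"chem{i}", line_id=f"L{i}", batch="B0",
                plate=f"P{i}", d=d, y=y,
            )
        )
        rows.append({"true_log_ec10": le, "beta0": b0, "beta1": b1,
                     "theta_max": theta_max, "outlier_index": out_idx})
    return profiles, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# on-disk formats


def write_genotype_matrix(genotypes, annotation, snp_map, prefix):
    """Write the plain matrix + sidecar map + annotation trio of files."""
    gdf = pd.DataFrame(genotypes, columns=snp_map["snp_id"])
    gdf.insert(0, "sample_id", annotation["sample_id"].to_numpy())
    gdf.to_csv(f"{prefix}.genotypes.tsv", sep="\t", index=False)
    snp_map.to_csv(f"{prefix}.map.tsv", sep="\t", index=False)
    annotation.to_csv(f"{prefix}.annotation.tsv", sep="\t", index=False)


def write_vcf(genotypes, annotation, snp_map, path):
    """Write hard-call genotypes as a minimal VCFv4.2 text file (GT only)."""
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    samples = list(annotation["sample_id"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(snp_map["chromosome"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        order = snp_map.sort_values(["chromosome", "position_bp"]).index
        for j in order:
            row = snp_map.loc[j]
            gts = "\t".join(gt_codes[int(g)] for g in genotypes[:, j])
            fh.write(f"{row['chromosome']}\t{row['position_bp']}\t{row['snp_id']}"
                     f"\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")
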