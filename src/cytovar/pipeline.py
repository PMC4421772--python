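"""Run orchestration: simulate -> normalise/fit -> variability -> GWAS.

A :class:`RunConfig` (plain YAML on disk) names the inputs (or a synthetic
study design), the stages to run, and every statistical threshold — each
defaulting to the analysis's standard value (MAF 0.01, call rate 0.95,
Hardy-Weinberg p 1e-6, >=20 per genotype class for the multivariate test,
per-chemical q < 0.10, +/-1 Mb pruning, stage-1 prefilter p < 5e-8, TDVF
quantile pair (q01, q50)).  All randomness flows from one master seed, split
deterministically per stage, so identical config + seed reproduces every
output byte for byte; a manifest records the config hash and per-stage row
counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, doseresponse, io, synthdata, variability

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    maf: float = 0.01
    call_rate: float = 0.95
    hwe_p: float = 1e-6
    min_per_genotype: int = 20
    q_significant: float = 0.10
    prune_window_bp: int = 1_000_000
    stage1_p: float = 5e-8
    tdvf_quantiles: tuple[float, float] = (0.01, 0.50)
    n_pcs: int = 10
    min_lines_for_quantiles: int = 100


@dataclass
class RunConfig:
    outdir: str = "run"
    seed: int = 0
    stages: list = field(default_factory=lambda: ["simulate", "fit", "variability", "gwas"])
    synthetic: dict | None = field(default_factory=dict)  # SimConfig overrides
    well_table: str | None = None
    genotypes: str | None = None  # matrix prefix or .vcf path
    annotation: str | None = None
    invivo_gsd: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        cfg = cls(**raw)
        cfg.thresholds = thr
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(d.get("synthetic"), dict):
            d["synthetic"] = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in d["synthetic"].items()
            }
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # scientific config only, not output location
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def validate_inputs(config: RunConfig) -> list[str]:
    """Report-only schema and cross-file consistency checks."""
    issues: list[str] = []
    if config.well_table:
        try:
            wells = io.read_well_table(config.well_table)
        except Exception as exc:  # noqa: BLE001 - report, don't raise
            return [f"well table unreadable: {exc}"]
        bad_roles = set(wells["role"].unique()) - io.ROLES
        if bad_roles:
            issues.append(f"well table: unknown roles {sorted(bad_roles)}")
        for plate, grp in wells.groupby("plate"):
            for role in ("neg_ctrl", "pos_ctrl"):
                if not (grp["role"] == role).any():
                    issues.append(f"plate {plate}: no {role} wells")
            n_conc = grp.loc[grp["role"] == "treatment"]\
                .groupby(["chemical_id", "line_id"])["concentration_molar"].nunique()
            short = n_conc[n_conc != 8]
            if not short.empty:
                issues.append(
                    f"plate {plate}: {len(short)} profile(s) without 8 distinct concentrations"
                )
        if config.genotypes:
            try:
                if str(config.genotypes).endswith((".vcf", ".vcf.gz")):
                    _, samples, _ = io.read_vcf(config.genotypes)
                else:
                    _, samples, _ = io.read_genotype_matrix(config.genotypes)
                missing = set(wells["line_id"].unique()) - set(samples)
                if missing:
                    issues.append(
                        f"{len(missing)} sample(s) in wells but not in genotypes"
                    )
            except Exception as exc:  # noqa: BLE001
                issues.append(f"genotypes unreadable: {exc}")
    elif "simulate" not in config.stages:
        issues.append("no well table given and simulate stage disabled")
    if "gwas" in config.stages and not (config.genotypes or "simulate" in config.stages):
        issues.append("gwas stage enabled without genotypes")
    return issues


def run(config: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory."""
    issues = validate_inputs(config)
    hard = [i for i in issues if "unreadable" in i or "disabled" in i or "without genotypes" in i]
    if hard:
        raise ValueError("config rejected: " + "; ".join(hard))
    for msg in issues:
        logger.warning("input check: %s", msg)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(outdir / "run.log")
    logging.getLogger().addHandler(fh)

    chash = config.config_hash()
    manifest = {"config_hash": chash, "seed": config.seed,
                "config": config.to_dict(), "stages": {}}
    thr = config.thresholds

    wells = annot = geno = snp_map = None
    per_line = registry = None

    try:
        if "simulate" in config.stages:
            sim = synthdata.SimConfig(**(config.synthetic or {}), seed=config.seed)
            if sim.emit_trios:
                geno, annot, snp_map = synthdata.simulate_trios(
                    sim.n_lines // 3, sim.n_snps, sim.n_populations, sim.fst,
                    sim.maf_range, _stage_seed(config.seed, "genotypes"),
                )
            else:
                geno, annot, snp_map = synthdata.simulate_genotypes(
                    sim.n_lines, sim.n_snps, sim.n_populations, sim.fst,
                    sim.maf_range, _stage_seed(config.seed, "genotypes"),
                )
            baselines = pd.Series(
                np.linspace(-7.5, -4.5, sim.n_chemicals),
                index=[f"chem{c:03d}" for c in range(sim.n_chemicals)],
            )
            truth, deferred = synthdata.simulate_true_log_ec10(
                geno, annot, sim.causal_spec, baselines,
                sim.pop_shift_sd, sim.line_sd,
                _stage_seed(config.seed, "truth"),
                snp_ids=list(snp_map["snp_id"]),
            )
            wells, ledger = synthdata.simulate_plates(
                truth, sim, _stage_seed(config.seed, "plates"),
                deferred_effects=deferred,
            )
            io.write_table(wells, outdir / "wells.tsv", "simulate", chash)
            io.write_table(
                truth.reset_index().rename(columns={"index": "line_id"}),
                outdir / "truth_log_ec10.tsv", "simulate", chash,
            )
            synthdata.write_genotype_matrix(geno, annot, snp_map, str(outdir / "sim"))
            pd.DataFrame({"well_id": ledger.injected_outliers}).to_csv(
                outdir / "truth_outliers.tsv", sep="\t", index=False
            )
            manifest["stages"]["simulate"] = {"wells": len(wells),
                                              "lines": sim.n_lines,
                                              "snps": sim.n_snps}
        else:
            wells = io.read_well_table(config.well_table) if config.well_table else None
            if config.genotypes:
                if str(config.genotypes).endswith((".vcf", ".vcf.gz")):
                    geno, samples, snp_map = io.read_vcf(config.genotypes)
                else:
                    geno, samples, snp_map = io.read_genotype_matrix(config.genotypes)
                annot = pd.read_csv(config.annotation, sep="\t") if config.annotation else None

        if "fit" in config.stages:
            if wells is None:
                raise ValueError("fit stage requires a well table")
            plate_fits = doseresponse.fit_well_table(wells)
            per_line, registry = doseresponse.batch_correct_and_aggregate(plate_fits)
            io.write_table(plate_fits, outdir / "plate_fits.tsv", "fit", chash)
            io.write_table(per_line, outdir / "ec10_per_line.tsv", "fit", chash)
            io.write_table(registry, outdir / "ec10_registry.tsv", "fit", chash)
            manifest["stages"]["fit"] = {"plate_fits": len(plate_fits),
                                         "lines": len(per_line)}

        if "variability" in config.stages:
            if per_line is None:
                raise ValueError("variability stage requires fit outputs")
            summary = variability.summarize_all(
                per_line, registry, min_n=thr.min_lines_for_quantiles
            )
            io.write_table(summary, outdir / "variability_summary.tsv",
                           "variability", chash)
            rows = {"chemicals": len(summary)}
            if config.invivo_gsd:
                invivo = pd.read_csv(config.invivo_gsd, sep="\t", comment="#")
                ok = summary["tdvf_shrunk"].notna()
                comp = variability.compare_distributions(
                    summary.loc[ok, "tdvf_shrunk"],
                    variability.gsd_to_factor(invivo["gsd"].to_numpy(float)),
                )
                (outdir / "invivo_comparison.json").write_text(
                    json.dumps({k: (list(v) if isinstance(v, tuple) else v)
                                for k, v in comp.items()}, indent=2)
                )
                rows["invivo_chemicals"] = len(invivo)
            if annot is not None:
                anova = variability.population_anova(per_line, annot)
                io.write_table(anova, outdir / "population_anova.tsv",
                               "variability", chash)
                rows["anova_chemicals"] = len(anova)
            manifest["stages"]["variability"] = rows

        if "gwas" in config.stages:
            if per_line is None or geno is None:
                raise ValueError("gwas stage requires fit outputs and genotypes")
            qc = association.filter_markers(
                geno, call_rate=thr.call_rate, maf=thr.maf, hwe_p=thr.hwe_p,
                min_per_genotype=thr.min_per_genotype,
            )
            X = association.build_covariates(
                annot, genotypes=geno[:, qc["pass_qc"]],
                n_pcs=min(thr.n_pcs, max(1, len(annot) - 2)),
            )
            profiles, _ = doseresponse.normalize_well_table(wells)
            results = _gwas_stage(per_line, profiles, annot, geno, snp_map,
                                  qc, X, thr)
            io.write_table(results, outdir / "association_results.tsv", "gwas", chash)
            manifest["stages"]["gwas"] = {
                "snps_qc": int(qc["pass_qc"].sum()),
                "snps_manova": int(qc["pass_manova"].sum()),
                "results": len(results),
            }
    finally:
        logging.getLogger().removeHandler(fh)
        fh.close()

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir


def _response_matrix(profiles, lines, n_conc=8):
    """Per-line response vectors: replicate plates averaged per concentration."""
    acc = {ln: [] for ln in lines}
    chems = {}
    for p in profiles:
        chems.setdefault(p.chemical_id, []).append(p)
    out = {}
    for chem, plist in chems.items():
        mat = np.full((len(lines), n_conc), np.nan)
        index = {ln: i for i, ln in enumerate(lines)}
        sums = np.zeros((len(lines), n_conc))
        counts = np.zeros((len(lines), n_conc))
        for p in plist:
            i = index.get(p.line_id)
            if i is None:
                continue
            sums[i] += p.y
            counts[i] += 1
        with np.errstate(invalid="ignore"):
            mat = sums / counts
        out[chem] = mat
    return out


def _gwas_stage(per_line, profiles, annot, geno, snp_map, qc, X, thr):
    lines = list(annot["sample_id"])
    responses = _response_matrix(profiles, lines)
    rows = []
    manova_idx = np.flatnonzero(qc["pass_manova"])
    qc_idx = np.flatnonzero(qc["pass_qc"])
    snp_ids = snp_map["snp_id"].to_numpy()
    pos = snp_map.set_index("snp_id")

    for chem, grp in per_line.groupby("chemical_id", sort=True):
        grp = grp.set_index("line_id").reindex(lines)
        Y = responses.get(chem)
        if Y is not None and not np.isnan(Y).any():
            scan = association.magwas_scan(Y, geno[:, manova_idx], X,
                                           snp_ids=snp_ids[manova_idx])
            if not scan.empty:
                scan["q"] = association.per_chemical_fdr(scan["p"].to_numpy())
                for _, r in scan.iterrows():
                    rows.append({"chemical_id": chem, "snp_id": r["snp_id"],
                                 "method": "magwas", "p": r["p"], "q": r["q"],
                                 "partial_r2": r["partial_r2"],
                                 "genotype_counts": r["genotype_counts"]})
        ok = ~grp["censored"].fillna(True).astype(bool)
        y = grp.loc[ok, "log_ec10"].to_numpy(float)
        if ok.sum() >= X.shape[1] + 2:
            Xs = X[ok.to_numpy()]
            recs = []
            for j in qc_idx:
                r = association.ec10_regression(y, geno[ok.to_numpy(), j], Xs)
                if np.isfinite(r["p"]):
                    recs.append((snp_ids[j], r["p"], r["beta"]))
            if recs:
                ps = np.array([r[1] for r in recs])
                qs = association.per_chemical_fdr(ps)
                for (sid, p, beta), qv in zip(recs, qs):
                    rows.append({"chemical_id": chem, "snp_id": sid,
                                 "method": "ec10_lm", "p": p, "q": qv,
                                 "partial_r2": np.nan, "genotype_counts": ""})

    results = pd.DataFrame(rows)
    if not results.empty:
        results["chrom"] = results["snp_id"].map(pos["chromosome"])
        results["pos"] = results["snp_id"].map(pos["position_bp"])
        results = results[["chemical_id", "snp_id", "chrom", "pos", "method",
                           "p", "q", "partial_r2", "genotype_counts"]]
    return results
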