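#!/usr/bin/env python
"""Normalise plates, fit the logistic model with outlier rejection, and
batch-correct/average log EC10 per (chemical, line).

Reads results/study/wells.tsv, writes plate-level fits and the per-line
EC10 table, and scores the estimates against the truth ledger: recovery
error, outlier-flag precision/recall, and replicate agreement.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cytovar import doseresponse as dr
from cytovar import io

STUDY = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    wells = io.read_well_table(STUDY / "wells.tsv")
    truth = pd.read_csv(STUDY / "truth_log_ec10.tsv", sep="\t").set_index("line_id")
    injected = set(pd.read_csv(STUDY / "truth_outliers.tsv", sep="\t")["well_id"])

    plate_fits = dr.fit_well_table(wells)
    per_line, registry = dr.batch_correct_and_aggregate(plate_fits)
    plate_fits.to_csv(STUDY / "plate_fits.tsv", sep="\t", index=False)
    per_line.to_csv(STUDY / "ec10_per_line.tsv", sep="\t", index=False)
    registry.to_csv(STUDY / "ec10_registry.tsv", sep="\t", index=False)

    merged = per_line.merge(
        truth.stack().rename("true").reset_index()
        .rename(columns={"level_1": "chemical_id"}),
        on=["line_id", "chemical_id"],
    )
    ok = ~merged["censored"].astype(bool)
    err = (merged.loc[ok, "log_ec10"] - merged.loc[ok, "true"]).abs()
    print(f"fitted {len(plate_fits)} plate-level profiles -> "
          f"{len(per_line)} (chemical, line) EC10 values "
          f"({(~ok).sum()} censored/no-effect)")
    print(f"recovery: median |log10 EC10 error| = {err.median():.3f} decades "
          f"(90th pct {err.quantile(0.9):.3f})")

    # outlier-flag scoring against the injected truth
    flagged = set()
    for _, r in plate_fits.iterrows():
        if r["outlier_indices"]:
            for j in str(r["outlier_indices"]).split(","):
                flagged.add(f"{r['plate']}:{r['chemical_id']}:{j}")
    tp = len(flagged & injected)
    print(f"outlier wells: {len(injected)} injected, {len(flagged)} flagged, "
          f"recall {tp / max(len(injected), 1):.2f}, "
          f"precision {tp / max(len(flagged), 1):.2f}")

    # replicate agreement (the screen's internal reproducibility)
    reps = registry[~registry["censored"].astype(bool)].groupby(
        ["chemical_id", "line_id"]).filter(lambda g: len(g) == 2)
    if not reps.empty:
        wide = reps.groupby(["chemical_id", "line_id"])["log_ec10_corrected"] \
            .agg(["first", "last"])
        r = np.corrcoef(wide["first"], wide["last"])[0, 1]
        print(f"replicate log EC10 correlation over {len(wide)} pairs: r = {r:.3f}")


if __name__ == "__main__":
    main()
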