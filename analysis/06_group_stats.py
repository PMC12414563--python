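#!/usr/bin/env python
"""Group-level inference on efficiency and directional indices.

Planned two-tailed Student contrasts (low vs high schizotypy) per band with
Bonferroni correction — family of 4 bands for GE/LE, 8 band-by-direction
cells for the combined indices — plus mixed-model omnibus tables with a
subject random intercept.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gcnet.stats import omnibus_model, planned_contrast

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    metrics = pd.read_csv(ROOT / "results" / "04_global_metrics.csv")
    indices = pd.read_csv(ROOT / "results" / "05_directional_indices.csv")

    rows = []
    for band, sub in metrics.groupby("band"):
        for measure in ("GE", "LE"):
            cr = planned_contrast(
                sub.loc[sub["group"] == "low", measure].tolist(),
                sub.loc[sub["group"] == "high", measure].tolist(),
                family_size=4, measure=measure, band=band)
            rows.append(vars(cr))
    for band, sub in indices.groupby("band"):
        for measure in ("CI_fp", "CI_pf"):
            lo = sub.loc[sub["group"] == "low", measure].dropna().tolist()
            hi = sub.loc[sub["group"] == "high", measure].dropna().tolist()
            if len(lo) >= 2 and len(hi) >= 2:
                cr = planned_contrast(lo, hi, family_size=8,
                                      measure=measure, band=band)
                rows.append(vars(cr))
    contrasts = pd.DataFrame(rows)
    contrasts.to_csv(ROOT / "results" / "06_contrasts.csv", index=False,
                     float_format="%.6g")

    for measure in ("GE", "LE"):
        tidy = metrics.rename(columns={measure: "value"})[
            ["subject_id", "group", "band", "value"]]
        tab = omnibus_model(tidy, factors=("group", "band"))
        tab.to_csv(ROOT / "results" / f"06_omnibus_{measure}.csv",
                   index=False, float_format="%.6g")
    tidy = indices.melt(id_vars=["subject_id", "group", "band"],
                        value_vars=["CI_fp", "CI_pf"],
                        var_name="direction", value_name="value")
    tidy["direction"] = tidy["direction"].str.replace("CI_", "", regex=False)
    omnibus_model(tidy, factors=("group", "band", "direction")).to_csv(
        ROOT / "results" / "06_omnibus_CI.csv", index=False,
        float_format="%.6g")

    cols = ["measure", "band", "t", "df", "p_raw", "p_bonferroni",
            "mean_low", "mean_high"]
    print(contrasts[cols].round(4).to_string(index=False))


if __name__ == "__main__":
    main()
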