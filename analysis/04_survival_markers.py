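#!/usr/bin/env python
"""Evaluate prognostic markers on a synthetic survival cohort.

Builds marker indicators from the IHC cohort (RAD54B(N) abnormality and the
FEN1(N)-RAD54B(N) both-abnormal pair), generates exponential survival with
planted hazards (pair-marker HR 2.61, age HR 2.21, stage HR 2.69, null sex),
then reports Kaplan-Meier/log-rank separation of the pair-abnormal group,
univariate Cox fits (the overlapping single marker picks up an attenuated
effect), VIFs for the collinear marker set, and bidirectional stepwise-AIC
multivariate selection.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from slsift.cohort import CohortSpec, generate_survival
from slsift.datasets import ladc_marker_panel
from slsift.survival import (
    cox_multivariate_stepwise,
    cox_univariate,
    km_estimate,
    logrank_p,
    vif,
)
from slsift.synergy import abnormality_table

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 11
STUDY = Path("results/study/ihc_cohort")
OUT = Path("results")

ihc = pd.read_csv(STUDY / "ihc.tsv", sep="\t", index_col=0)
clinical = pd.read_csv(STUDY / "clinical.tsv", sep="\t", index_col=0)
abn = abnormality_table(ihc, ladc_marker_panel())

ind = pd.DataFrame(index=ihc.index)
ind["RAD54B"] = abn["RAD54B(N)"].astype(int)
ind["FEN1_RAD54B"] = (abn["FEN1(N)"] & abn["RAD54B(N)"]).astype(int)
ind["age_gt65"] = (clinical["age"] > 65).astype(int)
ind["stage_34"] = clinical["stage"].isin(["III", "IV"]).astype(int)
ind["sex_male"] = clinical["sex"].eq("male").astype(int)

spec = CohortSpec(
    n_patients=len(ind),
    hazard_effects={
        "FEN1_RAD54B": np.log(2.61),
        "age_gt65": np.log(2.21),
        "stage_34": np.log(2.69),
    },
    seed=SEED + 2,
)
ds = pd.concat([generate_survival(spec, ind), ind], axis=1)

# Kaplan-Meier separation of the pair-abnormal group
curves = km_estimate(ds["time"], ds["event"], ind["FEN1_RAD54B"])
stat, lr_p = logrank_p(ds["time"], ds["event"], ind["FEN1_RAD54B"])
pd.concat(
    {g: c.set_index("time")["survival"] for g, c in curves.items()}, axis=1
).to_csv(OUT / "km_pair_curves.tsv", sep="\t")

planted = {"FEN1_RAD54B": 2.61, "age_gt65": 2.21, "stage_34": 2.69, "sex_male": 1.0}
uni_rows = []
for var in ("RAD54B", "FEN1_RAD54B", "age_gt65", "stage_34", "sex_male"):
    fit = cox_univariate(ds, var)
    uni_rows.append(
        {
            "variable": var,
            "planted_HR": planted.get(var, "induced"),
            "HR": round(fit.hazard_ratios.iloc[0], 2),
            "ci_lower": round(fit.ci_lower.iloc[0], 2),
            "ci_upper": round(fit.ci_upper.iloc[0], 2),
            "p": fit.p_values.iloc[0],
        }
    )
uni = pd.DataFrame(uni_rows)
uni.to_csv(OUT / "cox_univariate.tsv", sep="\t", index=False)

vifs = vif(ind[["RAD54B", "FEN1_RAD54B", "age_gt65", "stage_34", "sex_male"]])
vifs.to_csv(OUT / "marker_vifs.tsv", sep="\t", header=["VIF"])

# the two marker indicators are collinear; enter the pair alone, per the VIFs
step = cox_multivariate_stepwise(ds, ["FEN1_RAD54B", "age_gt65", "stage_34", "sex_male"])
step.summary().round(3).to_csv(OUT / "cox_stepwise.tsv", sep="\t")

n_pair = int(ind["FEN1_RAD54B"].sum())
print(f"pair-abnormal group: {n_pair}/{len(ind)} patients; "
      f"log-rank vs rest: chi2 = {stat:.2f}, p = {lr_p:.3f}")
print("univariate Cox (point estimates are noisy at 131 patients; the planted")
print("effects are recovered to tight bands at larger n in the test suite):")
print(uni.to_string(index=False))
print(f"marker VIFs: RAD54B {vifs['RAD54B']:.2f}, FEN1_RAD54B {vifs['FEN1_RAD54B']:.2f}")
print(f"stepwise-AIC selected: {step.variables} (AIC {step.aic:.1f})")
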