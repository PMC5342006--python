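#!/usr/bin/env python
"""Generate the two synthetic cohorts every downstream analysis consumes.

Writes under results/study/:
  * an 83-patient paired tumor/normal expression cohort with the
    FEN1-RAD54B (up, up) pattern planted at penetrance 0.31 (2-fold), plus
    three unplanted literature pairs as negative controls;
  * a 131-patient IHC + clinical cohort over the full 23-marker panel with
    an interaction-only FEN1(N)-RAD54B(N) x metastasis synergy (OR = 6).
"""

import sys
from pathlib import Path

import pandas as pd

from slsift.cohort import CohortSpec, PlantedPair, SynergyEffect, generate_study
from slsift.datasets import ladc_marker_panel, ladc_marker_rates

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 11
OUT = Path("results/study")

expr_spec = CohortSpec(
    n_patients=83,
    genes=["FEN1", "RAD54B", "BRCA1", "PARP1", "MSH2", "POLB", "TP53", "EGFR"],
    planted_pairs=[PlantedPair("FEN1", "RAD54B", "UU", 0.31, 2.0)],
    noise_sd=1.0,
    seed=SEED,
)
expr_study = generate_study(expr_spec)
expr_study.write(OUT / "expression_cohort")
pd.DataFrame(
    [
        ("FEN1", "RAD54B", "planted"),
        ("BRCA1", "PARP1", "literature"),
        ("MSH2", "POLB", "literature"),
        ("TP53", "EGFR", "literature"),
    ],
    columns=["gene1", "gene2", "source"],
).to_csv(OUT / "expression_cohort" / "pair_list.tsv", sep="\t", index=False)

ihc_spec = CohortSpec(
    n_patients=131,
    markers=ladc_marker_panel(),
    marker_rates=ladc_marker_rates(),
    synergy_effects=[SynergyEffect("FEN1(N)", "RAD54B(N)", "metastasis", 6.0)],
    seed=SEED + 1,
)
ihc_study = generate_study(ihc_spec)
ihc_study.write(OUT / "ihc_cohort")

print(f"expression cohort: {expr_spec.n_patients} patients x {len(expr_spec.genes)} genes")
print(f"ihc cohort: {ihc_spec.n_patients} patients x {len(ihc_spec.markers)} markers")
print(f"written under {OUT}/")
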