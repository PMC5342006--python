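"""End-to-end orchestration of the four screening stages from a config file.

The pipeline reads TSV tables (patients in rows, header row, tab-separated),
runs the expression pattern screen, the IHC synergy screen with 2-hop
expansion, the survival-marker models, and — when a validation cohort is
configured — the predictive-risk transfer, writing one TSV per stage plus a
provenance block.  All randomness flows from the single config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression as xs
from . import synergy as sy
from . import survival as sv
from . import risk as rk
from .synergy import GRADES, MarkerDef

log = logging.getLogger("slsift")

_KNOWN_GRADES = set(GRADES) | {"+-", "+/-"}


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run.

    Any table path may be empty, in which case the stages needing it are
    skipped with a logged notice.
    """

    pair_list: str = ""
    expression: str = ""  # precomputed log2 tumor/normal ratios
    panel: str = ""
    ihc: str = ""
    clinical: str = ""
    survival: str = ""
    out_dir: str = "results"
    fold_cutoff: float = 1.5
    n_perm: int = 10_000
    alpha: float = 0.05
    min_fraction: float = 0.01
    fdr_method: str = "storey"
    fdr_family: str = "feature"
    seed: int = 0

    def __post_init__(self):
        if not 1 < self.fold_cutoff:
            raise ValueError("fold_cutoff must exceed 1")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 <= self.min_fraction < 1:
            raise ValueError("min_fraction must lie in [0, 1)")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def read_panel(path) -> list[MarkerDef]:
    """Marker panel TSV: columns protein, location, criterion."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein", "location", "criterion"}
    if not required <= set(df.columns):
        raise ValueError(f"panel table needs columns {sorted(required)}")
    return [
        MarkerDef.from_criterion(r.protein, r.location, str(r.criterion))
        for r in df.itertuples()
    ]


def validate_inputs(paths: dict) -> list[str]:
    """Schema report over the configured input tables.

    Checks column presence, grade vocabulary in IHC tables, non-negative
    survival times and patient-id joinability; returns a list of violation
    messages (empty = clean).
    """
    problems: list[str] = []
    tables: dict[str, pd.DataFrame] = {}
    for name, path in paths.items():
        if not path:
            continue
        p = Path(path)
        if not p.exists():
            problems.append(f"{name}: file not found: {path}")
            continue
        try:
            tables[name] = pd.read_csv(p, sep="\t", index_col=0)
        except Exception as exc:  # malformed table
            problems.append(f"{name}: unreadable ({exc})")
    ihc = tables.get("ihc")
    if ihc is not None:
        for col in ihc.columns:
            for pid, val in ihc[col].items():
                sval = str(val).strip()
                try:
                    float(sval)
                    continue  # percent observation
                except ValueError:
                    pass
                if sval not in _KNOWN_GRADES:
                    problems.append(
                        f"ihc: unknown grade {sval!r} for patient {pid}, marker {col}"
                    )
    clinical = tables.get("clinical")
    if clinical is not None and "survival_months" in clinical.columns:
        bad = clinical.index[clinical["survival_months"] < 0]
        for pid in bad:
            problems.append(f"clinical: negative survival time for patient {pid}")
    surv = tables.get("survival")
    if surv is not None and "time" in surv.columns:
        bad = surv.index[surv["time"] < 0]
        for pid in bad:
            problems.append(f"survival: negative time for patient {pid}")
    indexed = {k: v for k, v in tables.items() if k in ("expression", "ihc", "clinical", "survival")}
    keys = list(indexed)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a, b = keys[i], keys[j]
            only_a = indexed[a].index.difference(indexed[b].index)
            if 0 < len(only_a) < len(indexed[a].index):
                problems.append(
                    f"join: {len(only_a)} patient(s) in {a} missing from {b} "
                    f"(e.g. {only_a[0]})"
                )
    return problems


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the report dict.

    The report maps stage names to output tables and is also written as
    TSVs under ``config.out_dir`` with a JSON provenance block.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": config.expression,
        "ihc": config.ihc,
        "clinical": config.clinical,
        "survival": config.survival,
    }
    problems = validate_inputs(paths)
    hard = [p for p in problems if "negative" in p or "unknown grade" in p or "unreadable" in p or "not found" in p]
    if hard:
        raise ValueError("input validation failed:\n" + "\n".join(hard))
    for p in problems:
        log.warning("input check: %s", p)

    report: dict = {"violations": problems}

    if config.expression and config.pair_list:
        matrix = pd.read_csv(config.expression, sep="\t", index_col=0)
        pair_df = pd.read_csv(config.pair_list, sep="\t")
        pairs = [(r.gene1, r.gene2) for r in pair_df.itertuples()]
        screen = xs.screen_pairs(
            matrix,
            pairs,
            fold_cutoff=config.fold_cutoff,
            n_perm=config.n_perm,
            seed=config.seed,
            fdr_method=config.fdr_method,
        )
        candidates = xs.select_candidates(screen, min_fraction=config.min_fraction)
        screen.to_csv(out / "expression_screen.tsv", sep="\t", index=False)
        candidates.to_csv(out / "candidate_pairs.tsv", sep="\t", index=False)
        report["expression_screen"] = screen
        report["candidate_pairs"] = candidates
        log.info("expression screen: %d pairs, %d candidates", len(pairs), len(candidates))
    else:
        log.info("expression stage skipped (no expression/pair-list configured)")

    if config.panel and config.ihc and config.clinical:
        panel = read_panel(config.panel)
        ihc = pd.read_csv(config.ihc, sep="\t", index_col=0)
        clinical = pd.read_csv(config.clinical, sep="\t", index_col=0)
        records, predicted = sy.synergy_screen(
            panel,
            ihc,
            clinical,
            alpha=config.alpha,
            fdr_method=config.fdr_method,
            fdr_family=config.fdr_family,
        )
        hits = records[records["label"] != "none"]
        twohop = sy.twohop_candidates(
            [(r.marker1, r.marker2) for r in predicted.itertuples()]
        )
        records.to_csv(out / "synergy_records.tsv", sep="\t", index=False)
        predicted.to_csv(out / "predicted_pairs.tsv", sep="\t", index=False)
        pd.DataFrame(twohop, columns=["marker1", "marker2"]).to_csv(
            out / "twohop_candidates.tsv", sep="\t", index=False
        )
        report["synergy_records"] = records
        report["predicted_pairs"] = predicted
        report["twohop_candidates"] = twohop
        log.info(
            "synergy screen: %d records, %d labelled, %d distinct pairs, %d 2-hop",
            len(records), len(hits), len(predicted), len(twohop),
        )

        if {"survival_months", "event"} <= set(clinical.columns):
            surv_rows = []
            abn = sy.abnormality_table(ihc.loc[clinical.index.intersection(ihc.index)], panel)
            cl = clinical.loc[abn.index]
            ds = pd.DataFrame(
                {"time": cl["survival_months"].astype(float), "event": cl["event"].astype(int)}
            )
            for r in predicted.itertuples():
                ind = (abn[r.marker1] & abn[r.marker2]).astype(int)
                name = f"{r.marker1}&{r.marker2}"
                ds[name] = ind.to_numpy()
                if ds[name].nunique() < 2:
                    continue
                fit = sv.cox_univariate(ds, name)
                surv_rows.append(
                    {
                        "variable": name,
                        "HR": fit.hazard_ratios.iloc[0],
                        "ci_lower": fit.ci_lower.iloc[0],
                        "ci_upper": fit.ci_upper.iloc[0],
                        "p": fit.p_values.iloc[0],
                    }
                )
            surv_table = pd.DataFrame(surv_rows)
            surv_table.to_csv(out / "pair_cox_univariate.tsv", sep="\t", index=False)
            report["pair_cox_univariate"] = surv_table
            log.info("survival stage: %d pair models fitted", len(surv_rows))
        else:
            log.info("survival stage skipped (clinical table has no outcome columns)")
    else:
        log.info("synergy/survival stages skipped (panel/ihc/clinical not all configured)")

    prov = {
        "config": {f.name: getattr(config, f.name) for f in fields(config)},
        "seed": config.seed,
        "stages": sorted(k for k in report if k != "violations"),
    }
    (out / "provenance.json").write_text(json.dumps(prov, indent=2))
    report["provenance"] = prov
    return report
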