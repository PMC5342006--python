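"""Synthetic study generator with the structure the screening pipeline assumes.

Three coupled tables make a study: per-patient log2 tumor/normal expression
ratios with planted co-differential patterns, an IHC cohort of ordinal
staining grades with planted interaction-only pair×feature associations, and
clinical records with survival times driven by marker-dependent hazards.

Planting is explicit: a :class:`PlantedPair` puts a signed log2 fold change
on both genes of a pair in a Bernoulli(penetrance) subset of patients; a
:class:`SynergyEffect` plants a centered (pure-epistasis) interaction on an
adverse clinical feature's log-odds — the both-abnormal cell's odds are
multiplied by the stated odds ratio while single-marker margins stay null;
hazard effects act multiplicatively on an exponential baseline hazard with
independent uniform censoring.

All randomness flows from one seed; each component draws from its own child
stream keyed by a fixed label, so adding markers never perturbs the
expression draws.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .synergy import FEATURES, MarkerDef

_PATTERN_SIGNS = {"UU": (1, 1), "UD": (1, -1), "DU": (-1, 1), "DD": (-1, -1)}

# realistic marginal rates for the five dichotomized clinical features in a
# resected lung-adenocarcinoma cohort (death before 3 years, poorly
# differentiated grade, distant metastasis, N1-2 nodal disease, stage III-IV)
DEFAULT_FEATURE_RATES = {
    "survival3y": 0.45,
    "grade": 0.35,
    "metastasis": 0.20,
    "nodal": 0.45,
    "stage": 0.35,
}


@dataclass(frozen=True)
class PlantedPair:
    """A co-differential-expression pattern planted on one gene pair."""

    gene1: str
    gene2: str
    pattern: str  # UU, UD, DU or DD
    penetrance: float
    fold_magnitude: float

    def __post_init__(self):
        if self.gene1 == self.gene2:
            raise ValueError("planted pair genes must differ")
        if self.pattern not in _PATTERN_SIGNS:
            raise ValueError(f"pattern must be one of {tuple(_PATTERN_SIGNS)}")
        if not 0 <= self.penetrance <= 1:
            raise ValueError("penetrance must lie in [0, 1]")
        if self.fold_magnitude <= 1:
            raise ValueError("fold_magnitude must exceed 1")


@dataclass(frozen=True)
class SynergyEffect:
    """Interaction-only association between a marker pair and a feature.

    The odds of the adverse feature are multiplied by ``odds_ratio`` only
    for patients with both markers abnormal.
    """

    marker1: str
    marker2: str
    feature: str
    odds_ratio: float

    def __post_init__(self):
        if self.feature not in FEATURES:
            raise ValueError(f"unknown feature {self.feature!r}")
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")


@dataclass
class CohortSpec:
    """Design of one synthetic study.

    Defaults mirror the study setting: 83 expression-profiled patients,
    a baseline log2-ratio noise of 1.0 (typical spread of microarray
    tumor/normal log-ratios), a baseline hazard giving ~4-year median
    survival and a 10-year censoring window.
    """

    n_patients: int = 83
    genes: list[str] = field(default_factory=list)
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    noise_sd: float = 1.0
    markers: list[MarkerDef] = field(default_factory=list)
    marker_rates: dict = field(default_factory=dict)  # marker name -> marginal P(abnormal)
    synergy_effects: list[SynergyEffect] = field(default_factory=list)
    feature_rates: dict = field(default_factory=lambda: dict(DEFAULT_FEATURE_RATES))
    hazard_effects: dict = field(default_factory=dict)  # indicator name -> log HR
    baseline_hazard: float = np.log(2) / 48.0  # per month; 48-month median survival
    censor_window: float = 120.0  # months
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censor_window < 0:
            raise ValueError("censor_window must be non-negative")
        names = {m.name for m in self.markers}
        for eff in self.synergy_effects:
            if self.markers and not {eff.marker1, eff.marker2} <= names:
                raise ValueError(
                    f"synergy effect references unknown marker(s): {eff.marker1}, {eff.marker2}"
                )
        for pp in self.planted_pairs:
            if self.genes and not {pp.gene1, pp.gene2} <= set(self.genes):
                raise ValueError(
                    f"planted pair ({pp.gene1}, {pp.gene2}) not in gene panel"
                )

    def patient_ids(self) -> list[str]:
        return [f"P{i:04d}" for i in range(1, self.n_patients + 1)]

    def _component_rng(self, label: str) -> np.random.Generator:
        # fixed per-component labels keep the streams independent of one
        # another and of panel size; crc32 is stable across processes
        ss = np.random.SeedSequence([self.seed, zlib.crc32(label.encode())])
        return np.random.default_rng(ss)

    def to_json(self) -> str:
        d = {
            "n_patients": self.n_patients,
            "genes": list(self.genes),
            "planted_pairs": [vars(p) | {} for p in self.planted_pairs],
            "noise_sd": self.noise_sd,
            "markers": [
                {
                    "protein": m.protein,
                    "location": m.location,
                    "criterion_kind": m.criterion_kind,
                    "direction": m.direction,
                    "threshold": m.threshold,
                }
                for m in self.markers
            ],
            "marker_rates": dict(self.marker_rates),
            "synergy_effects": [vars(e) | {} for e in self.synergy_effects],
            "feature_rates": dict(self.feature_rates),
            "hazard_effects": dict(self.hazard_effects),
            "baseline_hazard": self.baseline_hazard,
            "censor_window": self.censor_window,
            "seed": self.seed,
        }
        return json.dumps(d, indent=2, ensure_ascii=False)


@dataclass
class SyntheticStudy:
    """Expression, IHC and clinical tables over one shared patient index."""

    expression: pd.DataFrame
    ihc: pd.DataFrame
    clinical: pd.DataFrame
    spec: CohortSpec

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.expression.to_csv(out / "expression.tsv", sep="\t", index_label="patient")
        self.ihc.to_csv(out / "ihc.tsv", sep="\t", index_label="patient")
        self.clinical.to_csv(out / "clinical.tsv", sep="\t", index_label="patient")
        (out / "cohort_spec.json").write_text(self.spec.to_json())


def generate_expression(spec: CohortSpec) -> pd.DataFrame:
    """Patient × gene table of log2 tumor/normal ratios with planted patterns.

    Every entry is Normal(0, noise_sd) baseline noise; for each planted
    pair, a Bernoulli(penetrance) subset of patients instead receives
    ±log2(fold_magnitude) on both genes with the pattern's signs.
    Deterministic given the spec (including its seed).
    """
    rng = spec._component_rng("expression")
    patients = spec.patient_ids()
    genes = list(spec.genes)
    X = rng.normal(0.0, spec.noise_sd, size=(spec.n_patients, len(genes)))
    df = pd.DataFrame(X, index=patients, columns=genes)
    for pp in spec.planted_pairs:
        for g in (pp.gene1, pp.gene2):
            if g not in df.columns:
                raise ValueError(f"planted gene {g!r} not in gene panel")
        carriers = rng.random(spec.n_patients) < pp.penetrance
        s1, s2 = _PATTERN_SIGNS[pp.pattern]
        mag = np.log2(pp.fold_magnitude)
        df.loc[carriers, pp.gene1] = s1 * mag
        df.loc[carriers, pp.gene2] = s2 * mag
    return df


def _logit(p: float) -> float:
    return float(np.log(p) - np.log1p(-p))


def generate_ihc_clinical(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """IHC grades plus clinical records with interaction-only synergy.

    Per-marker abnormality is drawn at its marginal rate and mapped back to
    an ordinal grade drawn uniformly from the grades consistent with that
    call (a percent for percent-criterion markers).  Every synergy effect
    enters the adverse-feature log-odds as a *centered* interaction term
    (pure epistasis): the both-abnormal cell has its odds multiplied by
    exactly the effect's odds ratio, while the centering removes the
    marginal main effect of each single marker, so single-marker
    association tests stay null.  Feature flags are rendered as categorical
    clinical fields; the survival-time field is drawn to agree with the
    death-before-36-months flag.
    """
    if not spec.markers:
        raise ValueError("spec defines no IHC markers")
    rng = spec._component_rng("ihc")
    patients = spec.patient_ids()
    n = spec.n_patients

    abnormal: dict[str, np.ndarray] = {}
    obs: dict[str, np.ndarray] = {}
    for m in spec.markers:
        rate = float(spec.marker_rates.get(m.name, 0.5))
        flags = rng.random(n) < rate
        abnormal[m.name] = flags
        if m.criterion_kind == "intensity":
            grades = np.empty(n, dtype=object)
            for status in (True, False):
                pool = m.grades_satisfying(status)
                idx = np.flatnonzero(flags == status)
                if len(idx) and not pool:
                    raise ValueError(
                        f"marker {m.name} criterion leaves no grade for "
                        f"{'abnormal' if status else 'normal'} status"
                    )
                if len(idx):
                    grades[idx] = rng.choice(pool, size=len(idx))
            obs[m.name] = grades
        else:
            cut = float(m.threshold)
            if m.direction == ">=":
                abn_draw = rng.uniform(cut, 100.0, size=n)
                norm_draw = rng.uniform(0.0, cut, size=n)
            else:
                abn_draw = rng.uniform(0.0, cut, size=n)
                norm_draw = rng.uniform(cut, 100.0, size=n)
            obs[m.name] = np.where(flags, abn_draw, norm_draw)
    ihc = pd.DataFrame(obs, index=patients)

    rng_cl = spec._component_rng("clinical")
    adverse: dict[str, np.ndarray] = {}
    for feat in FEATURES:
        p0 = float(spec.feature_rates.get(feat, 0.5))
        if not 0 < p0 < 1:
            adverse[feat] = np.full(n, bool(round(p0)))
            continue
        # centered interaction on the log-odds: pure epistasis with no
        # marginal main effect, so single-marker tests stay null while the
        # both-abnormal cell gets its odds multiplied by exactly the OR
        eta = np.full(n, _logit(p0))
        for eff in spec.synergy_effects:
            if eff.feature != feat:
                continue
            qa = min(float(spec.marker_rates.get(eff.marker1, 0.5)), 0.999)
            qb = min(float(spec.marker_rates.get(eff.marker2, 0.5)), 0.999)
            a = abnormal[eff.marker1].astype(float)
            b = abnormal[eff.marker2].astype(float)
            eta += np.log(eff.odds_ratio) * (a - qa) * (b - qb) / ((1 - qa) * (1 - qb))
        adverse[feat] = rng_cl.random(n) < expit(eta)

    clinical = pd.DataFrame(index=patients)
    died3y = adverse["survival3y"]
    # times consistent with the 3-year dichotomy: deaths spread over the
    # first 35 months, survivors followed (and possibly censored) later
    t_death = rng_cl.uniform(1.0, 35.0, size=n)
    t_late = rng_cl.uniform(36.0, spec.censor_window if spec.censor_window > 36 else 37.0, size=n)
    late_event = rng_cl.random(n) < 0.5
    clinical["survival_months"] = np.where(died3y, t_death, t_late).round(1)
    clinical["event"] = np.where(died3y, 1, late_event.astype(int))
    clinical["grade"] = np.where(
        adverse["grade"], "poor", rng_cl.choice(["well", "moderate"], size=n)
    )
    clinical["metastasis"] = np.where(adverse["metastasis"], "yes", "no")
    clinical["nodal"] = np.where(
        adverse["nodal"], rng_cl.choice(["N1", "N2"], size=n), "N0"
    )
    clinical["stage"] = np.where(
        adverse["stage"],
        rng_cl.choice(["III", "IV"], size=n),
        rng_cl.choice(["I", "II"], size=n),
    )
    clinical["age"] = rng_cl.integers(35, 86, size=n)
    clinical["sex"] = rng_cl.choice(["male", "female"], size=n)
    return ihc, clinical


def generate_survival(
    spec: CohortSpec, indicators: pd.DataFrame
) -> pd.DataFrame:
    """Exponential survival with proportional marker effects and censoring.

    The hazard for subject i is ``baseline_hazard * exp(sum beta_k x_ik)``
    over the spec's hazard effects; censoring is independent Uniform(0,
    censor_window).  Returns ``time`` (months) and ``event`` columns on the
    indicator table's index.
    """
    unknown = [k for k in spec.hazard_effects if k not in indicators.columns]
    if unknown:
        raise ValueError(f"hazard effects reference unknown indicator(s): {unknown}")
    rng = spec._component_rng("survival")
    n = len(indicators)
    lp = np.zeros(n)
    for name, beta in spec.hazard_effects.items():
        lp += float(beta) * indicators[name].to_numpy(dtype=float)
    hazard = spec.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(0.0, spec.censor_window, size=n) if spec.censor_window > 0 else np.zeros(n)
    event = t_event <= t_cens
    return pd.DataFrame(
        {"time": np.minimum(t_event, t_cens), "event": event.astype(int)},
        index=indicators.index,
    )


def generate_study(spec: CohortSpec) -> SyntheticStudy:
    """Generate all three coupled tables of one synthetic study."""
    expression = (
        generate_expression(spec) if spec.genes else pd.DataFrame(index=spec.patient_ids())
    )
    if spec.markers:
        ihc, clinical = generate_ihc_clinical(spec)
    else:
        ihc = pd.DataFrame(index=spec.patient_ids())
        clinical = pd.DataFrame(index=spec.patient_ids())
    return SyntheticStudy(expression=expression, ihc=ihc, clinical=clinical, spec=spec)
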