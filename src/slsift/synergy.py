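"""Marker-pair synergy screen against dichotomized clinical features.

Immunohistochemistry (IHC) observations are dichotomized per marker by its
criterion of abnormality on the ordinal staining scale 0 < ± < 1+ < 2+ < 3+
(or a percent-stained cutoff).  Each unordered marker pair — excluding pairs
of the same protein stained at different cellular locations — is tested by
Fisher's exact test against each of five dichotomized clinical features:
death within three years, poor tumor grade, distant metastasis, nodal
involvement (N1–2 vs N0) and advanced stage (III–IV vs I–II).

A pair shows a *synergistic* correlation when the both-abnormal indicator is
significantly associated with the adverse feature while neither single
marker is; a *putative* synergistic correlation relaxes this to "the pair's
p-value is significant and strictly smaller than both single-marker
p-values".  Either label nominates the pair as a candidate synthetic-lethal
interaction; candidates are optionally expanded through the 2-hop rule
(A–B and B–C known ⇒ propose A–C).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import fdr_qvalues
from .survival import logrank_p

GRADES = ("0", "±", "1+", "2+", "3+")
_GRADE_RANK = {g: i for i, g in enumerate(GRADES)}
# tolerated spellings for the indeterminate grade in input tables
_GRADE_ALIASES = {"+-": "±", "+/-": "±", "0.5": "±"}

FEATURES = ("survival3y", "grade", "metastasis", "nodal", "stage")


def grade_rank(grade: str) -> int:
    """Position of an ordinal IHC grade on the scale 0 < ± < 1+ < 2+ < 3+."""
    g = _GRADE_ALIASES.get(str(grade).strip(), str(grade).strip())
    if g not in _GRADE_RANK:
        raise ValueError(f"unknown IHC grade {grade!r}; expected one of {GRADES}")
    return _GRADE_RANK[g]


@dataclass(frozen=True)
class MarkerDef:
    """One IHC marker: protein, cellular location and abnormality criterion.

    ``criterion_kind`` is ``"intensity"`` (threshold is an ordinal grade) or
    ``"percent"`` (threshold in [0, 100]); ``direction`` is ``">="`` or
    ``"<"``.
    """

    protein: str
    location: str  # C (cytoplasm), N (nucleus) or M (membrane)
    criterion_kind: str
    direction: str
    threshold: str | float

    def __post_init__(self):
        if self.location not in ("C", "N", "M"):
            raise ValueError(f"location must be C, N or M, got {self.location!r}")
        if self.criterion_kind not in ("intensity", "percent"):
            raise ValueError("criterion_kind must be 'intensity' or 'percent'")
        if self.direction not in (">=", "<"):
            raise ValueError("direction must be '>=' or '<'")
        if self.criterion_kind == "intensity":
            grade_rank(self.threshold)  # validates

    @property
    def name(self) -> str:
        return f"{self.protein}({self.location})"

    @classmethod
    def from_criterion(cls, protein: str, location: str, criterion: str) -> "MarkerDef":
        """Parse criteria like ``">=1+"``, ``"<2+"`` or ``">=70%"``."""
        c = criterion.replace("≥", ">=").replace("≧", ">=").strip()
        direction = ">=" if c.startswith(">=") else "<"
        rest = c[2:].strip() if c.startswith(">=") else c[1:].strip()
        if rest.endswith("%"):
            return cls(protein, location, "percent", direction, float(rest[:-1]))
        return cls(protein, location, "intensity", direction, rest)

    def is_abnormal(self, observation) -> bool:
        """Dichotomize one observation by this marker's criterion."""
        if self.criterion_kind == "percent":
            value = float(observation)
            cut = float(self.threshold)
        else:
            value = grade_rank(observation)
            cut = grade_rank(self.threshold)
        return value >= cut if self.direction == ">=" else value < cut

    def grades_satisfying(self, abnormal: bool) -> list[str]:
        """Ordinal grades consistent with abnormal (or normal) status."""
        if self.criterion_kind != "intensity":
            raise ValueError("only intensity criteria map to ordinal grades")
        return [g for g in GRADES if self.is_abnormal(g) == abnormal]


def dichotomize_marker(observation, marker: MarkerDef) -> bool:
    """Abnormal/normal call for one observation under a marker's criterion."""
    return marker.is_abnormal(observation)


def dichotomize_feature(record: pd.Series | dict, feature: str) -> bool | None:
    """Adverse/non-adverse call for one clinical feature; None = not evaluable.

    Rules: death before 36 months vs. surviving 36+ (patients censored alive
    before 36 months are not evaluable); poorly differentiated grade vs. well
    or moderate; metastasis yes vs. no; nodal N1–2 vs. N0; stage III–IV vs.
    I–II.  A missing field makes the record not evaluable.
    """
    if feature not in FEATURES:
        raise ValueError(f"unknown feature {feature!r}; expected one of {FEATURES}")
    get = record.get if hasattr(record, "get") else record.__getitem__

    def _missing(v) -> bool:
        return v is None or (isinstance(v, float) and np.isnan(v))

    if feature == "survival3y":
        t, e = get("survival_months"), get("event")
        if _missing(t) or _missing(e):
            return None
        if float(t) < 36.0:
            return None if not bool(int(e)) else True
        return False
    raw = get(
        {"grade": "grade", "metastasis": "metastasis", "nodal": "nodal", "stage": "stage"}[
            feature
        ]
    )
    if _missing(raw):
        return None
    v = str(raw).strip().lower()
    if feature == "grade":
        return v in ("poor", "poorly", "poorly-differentiated")
    if feature == "metastasis":
        return v in ("yes", "y", "1", "true")
    if feature == "nodal":
        return v in ("n1", "n2", "n1-2")
    return v in ("iii", "iv", "3", "4")


def enumerate_pairs(panel: list[MarkerDef]) -> list[tuple[str, str]]:
    """All unordered marker pairs whose proteins differ.

    Pairs of the same protein stained at different cellular locations are
    excluded; the default 23-marker panel therefore yields 250 pairs.
    """
    names = [m.name for m in panel]
    if len(set(names)) != len(names):
        raise ValueError("duplicate marker identities in panel")
    out = []
    for i in range(len(panel)):
        for j in range(i + 1, len(panel)):
            if panel[i].protein != panel[j].protein:
                out.append((names[i], names[j]))
    return out


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2×2 count table.

    Uses the probability-ordering convention (sum of hypergeometric
    probabilities of all tables, at fixed margins, no more probable than the
    observed one).  A zero margin returns p = 1.0: no association is
    testable.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(t.astype(int), alternative="two-sided")[1])


def classify_synergy(
    p_pair: float, p_single1: float, p_single2: float, alpha: float = 0.05
) -> str:
    """Label a (pair, feature) test as synergistic, putative or none.

    Synergistic: the pair is significant while neither single marker is.
    Putative: the pair is significant and strictly more significant than both
    single markers.  Otherwise none.
    """
    for p in (p_pair, p_single1, p_single2):
        if not (0 < p <= 1):
            raise ValueError("p-values must lie in (0, 1]")
    if p_pair < alpha and p_single1 >= alpha and p_single2 >= alpha:
        return "synergistic"
    if p_pair < alpha and p_pair < p_single1 and p_pair < p_single2:
        return "putative"
    return "none"


def _crosstab(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.array(
        [
            [np.sum(x & y), np.sum(x & ~y)],
            [np.sum(~x & y), np.sum(~x & ~y)],
        ]
    )


def abnormality_table(ihc: pd.DataFrame, panel: list[MarkerDef]) -> pd.DataFrame:
    """Patient × marker boolean table of abnormality calls.

    ``ihc`` holds raw observations (ordinal grades or percents) with one
    column per marker name.
    """
    calls = {}
    for m in panel:
        if m.name not in ihc.columns:
            raise KeyError(f"marker {m.name!r} missing from IHC table")
        calls[m.name] = ihc[m.name].map(m.is_abnormal)
    return pd.DataFrame(calls, index=ihc.index).astype(bool)


def synergy_screen(
    panel: list[MarkerDef],
    ihc: pd.DataFrame,
    clinical: pd.DataFrame,
    alpha: float = 0.05,
    fdr_method: str = "storey",
    fdr_family: str = "feature",
    with_logrank: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full pair × feature synergy screen.

    For every enumerated marker pair and clinical feature, builds the pair
    2×2 (both abnormal vs. otherwise × adverse vs. not, over patients
    evaluable for the feature) and the two single-marker 2×2s, computes the
    Fisher p-values, classifies the synergy label, attaches q-values within
    each feature family (or globally with ``fdr_family="global"``) and the
    log-rank p-value of the both-abnormal group against the rest.

    Returns ``(records, predicted)``: the full record table, and the
    deduplicated list of pairs labelled synergistic or putative under any
    feature.
    """
    common = ihc.index.intersection(clinical.index)
    if len(common) == 0:
        raise ValueError("IHC and clinical tables share no patients")
    ihc = ihc.loc[common]
    clinical = clinical.loc[common]
    abn = abnormality_table(ihc, panel)
    pairs = enumerate_pairs(panel)

    adverse: dict[str, pd.Series] = {}
    for feat in FEATURES:
        adverse[feat] = clinical.apply(lambda r: dichotomize_feature(r, feat), axis=1)

    rows = []
    for feat in FEATURES:
        adv = adverse[feat]
        ok = adv.notna()
        y = adv[ok].astype(bool).to_numpy()
        if ok.sum() and (y.all() or not y.any()):
            warnings.warn(
                f"feature {feat!r} is constant over evaluable patients; "
                "all its tests report p = 1",
                stacklevel=2,
            )
        for m1, m2 in pairs:
            a1 = abn.loc[ok, m1].to_numpy()
            a2 = abn.loc[ok, m2].to_numpy()
            both = a1 & a2
            p1 = fisher_exact_2x2(_crosstab(a1, y))
            p2 = fisher_exact_2x2(_crosstab(a2, y))
            pp = fisher_exact_2x2(_crosstab(both, y))
            label = classify_synergy(pp, p1, p2, alpha)
            row = {
                "feature": feat,
                "marker1": m1,
                "marker2": m2,
                "p_single1": p1,
                "p_single2": p2,
                "p_pair": pp,
                "label": label,
            }
            rows.append(row)
    records = pd.DataFrame(rows)

    if fdr_family == "feature":
        records["q_pair"] = np.nan
        for feat in FEATURES:
            mask = records["feature"] == feat
            records.loc[mask, "q_pair"] = fdr_qvalues(
                records.loc[mask, "p_pair"].to_numpy(), method=fdr_method
            )
    elif fdr_family == "global":
        records["q_pair"] = fdr_qvalues(records["p_pair"].to_numpy(), method=fdr_method)
    else:
        raise ValueError("fdr_family must be 'feature' or 'global'")

    if with_logrank and {"survival_months", "event"} <= set(clinical.columns):
        lr_cache: dict[tuple[str, str], float] = {}
        times = clinical["survival_months"].to_numpy(dtype=float)
        events = clinical["event"].to_numpy(dtype=int)
        for m1, m2 in pairs:
            both = (abn[m1] & abn[m2]).to_numpy()
            if both.all() or not both.any():
                lr_cache[(m1, m2)] = 1.0
            else:
                lr_cache[(m1, m2)] = logrank_p(times, events, both.astype(int))[1]
        records["logrank_pair"] = [
            lr_cache[(r.marker1, r.marker2)] for r in records.itertuples()
        ]
    else:
        records["logrank_pair"] = np.nan

    hits = records[records["label"] != "none"]
    predicted = (
        hits[["marker1", "marker2"]]
        .drop_duplicates()
        .sort_values(["marker1", "marker2"])
        .reset_index(drop=True)
    )
    return records, predicted


def dedupe_pairs(records: pd.DataFrame) -> pd.DataFrame:
    """Distinct marker pairs in a record table (order-normalized)."""
    pairs = {
        tuple(sorted((r.marker1, r.marker2))) for r in records.itertuples()
    }
    out = pd.DataFrame(sorted(pairs), columns=["marker1", "marker2"])
    return out


def twohop_candidates(known_pairs) -> list[tuple[str, str]]:
    """Expand a set of known SL pairs by the 2-hop rule.

    If A–B and B–C are known, A–C is proposed, unless already known.  Input
    pairs are unordered; output is sorted and deduplicated.
    """
    known = {frozenset(p) for p in known_pairs}
    neighbors: dict[str, set[str]] = {}
    for p in known:
        a, b = tuple(p)
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)
    out = set()
    for b, nbrs in neighbors.items():
        for a in nbrs:
            for c in nbrs:
                if a != c and frozenset((a, c)) not in known:
                    out.add(frozenset((a, c)))
    return sorted(tuple(sorted(p)) for p in out)
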