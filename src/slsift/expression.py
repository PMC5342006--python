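"""Co-differential-expression screen for tumor-dependent gene pairs.

Candidate synthetic-lethal pairs are sifted from paired tumor/normal
expression by counting, for each pair, the fraction of patients in which both
genes are simultaneously differentially expressed.  A patient is "up" for a
gene when the log2 tumor/normal ratio reaches ``log2(fold_cutoff)`` and
"down" when it falls below ``-log2(fold_cutoff)``; ratios inside the open
band contribute to no pattern, so the four pattern fractions — (up, up),
(up, down), (down, up), (down, down) — need not sum to one.

Significance of an observed fraction is assessed by a label-exchange
permutation test: exchanging one patient's tumor and normal labels negates
that patient's log-ratios for both genes jointly.  False discovery rates over
the family of tested (pair, pattern) hypotheses are estimated by q-values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

PATTERNS = ("uu", "ud", "du", "dd")

# a label exchange negates both log-ratios, so each pattern maps to its
# sign-mirrored partner
_FLIPPED = {"uu": "dd", "dd": "uu", "ud": "du", "du": "ud"}


def compute_log_ratios(tumor: pd.DataFrame, normal: pd.DataFrame) -> pd.DataFrame:
    """Per-patient log2(tumor/normal) expression ratios.

    Both inputs are patient × gene tables of strictly positive expression
    values on a common index.  Returns a patient × gene table of log2 ratios.
    """
    if not tumor.index.equals(normal.index) or not tumor.columns.equals(normal.columns):
        raise ValueError("tumor and normal tables must share patient and gene indexes")
    for name, df in (("tumor", tumor), ("normal", normal)):
        bad = (df.to_numpy() <= 0) | ~np.isfinite(df.to_numpy())
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-positive {name} expression for patient "
                f"{df.index[i]!r}, gene {df.columns[j]!r}"
            )
    return np.log2(tumor) - np.log2(normal)


@dataclass(frozen=True)
class PatternFractions:
    """Fractions of the four co-differential-expression patterns for one pair."""

    pair: tuple[str, str]
    f_uu: float
    f_ud: float
    f_du: float
    f_dd: float
    fold_cutoff: float = 1.5
    n_patients: int = 0

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.f_uu, self.f_ud, self.f_du, self.f_dd)


def _pair_values(
    matrix: pd.DataFrame, pair: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    g1, g2 = pair
    x1 = matrix[g1].to_numpy(dtype=float)
    x2 = matrix[g2].to_numpy(dtype=float)
    # patients with a missing value in either gene drop out of this pair
    keep = np.isfinite(x1) & np.isfinite(x2)
    return x1[keep], x2[keep]


def _pattern_counts(
    x1: np.ndarray, x2: np.ndarray, fold_cutoff: float
) -> dict[str, int]:
    t = np.log2(fold_cutoff)
    up1, dn1 = x1 >= t, x1 <= -t
    up2, dn2 = x2 >= t, x2 <= -t
    return {
        "uu": int((up1 & up2).sum()),
        "ud": int((up1 & dn2).sum()),
        "du": int((dn1 & up2).sum()),
        "dd": int((dn1 & dn2).sum()),
    }


def pattern_fractions(
    matrix: pd.DataFrame, pair: tuple[str, str], fold_cutoff: float = 1.5
) -> PatternFractions:
    """Fractions of patients showing each co-differential pattern for a pair.

    ``matrix`` is a patient × gene table of log2 tumor/normal ratios.  A
    patient whose ratio for either gene sits inside ``(-log2 c, log2 c)``
    belongs to no pattern.
    """
    if fold_cutoff <= 1:
        raise ValueError("fold_cutoff must exceed 1")
    for g in pair:
        if g not in matrix.columns:
            raise KeyError(f"gene {g!r} not in expression matrix")
    x1, x2 = _pair_values(matrix, pair)
    n = len(x1)
    counts = _pattern_counts(x1, x2, fold_cutoff)
    if n == 0:
        return PatternFractions(tuple(pair), 0.0, 0.0, 0.0, 0.0, fold_cutoff, 0)
    return PatternFractions(
        tuple(pair),
        counts["uu"] / n,
        counts["ud"] / n,
        counts["du"] / n,
        counts["dd"] / n,
        fold_cutoff,
        n,
    )


def _perm_counts(
    x1: np.ndarray,
    x2: np.ndarray,
    pattern: str,
    fold_cutoff: float,
    flips: np.ndarray,
) -> np.ndarray:
    """Pattern counts under a matrix of per-patient label exchanges.

    ``flips`` is (n_perm, n_patients) boolean; a flipped patient contributes
    through the sign-mirrored pattern because the exchange negates both of the
    patient's log-ratios.
    """
    c = _membership(x1, x2, pattern, fold_cutoff)
    c_flip = _membership(x1, x2, _FLIPPED[pattern], fold_cutoff)
    return (~flips) @ c + flips @ c_flip


def _membership(
    x1: np.ndarray, x2: np.ndarray, pattern: str, fold_cutoff: float
) -> np.ndarray:
    t = np.log2(fold_cutoff)
    a = {"u": x1 >= t, "d": x1 <= -t}[pattern[0]]
    b = {"u": x2 >= t, "d": x2 <= -t}[pattern[1]]
    return (a & b).astype(np.int64)


def permutation_pvalue(
    matrix: pd.DataFrame,
    pair: tuple[str, str],
    pattern: str,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    fold_cutoff: float = 1.5,
    add_one: bool = True,
) -> float:
    """Label-exchange permutation p-value for one pattern fraction.

    Each permutation exchanges, independently per patient with probability
    1/2, the tumor/normal labels; an exchange negates that patient's
    log-ratios for both genes jointly.  The statistic is the pattern
    fraction; p = (1 + #{permuted ≥ observed}) / (1 + n_perm).  When
    ``2**n_patients <= n_perm`` the full set of label assignments is
    enumerated instead and p is exact over that set (with the same add-one
    convention, applied to the enumeration size).

    ``add_one=False`` reports the raw proportion ``#{≥ observed}/N`` instead.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"pattern must be one of {PATTERNS}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if matrix.shape[0] == 0:
        raise ValueError("empty expression matrix")
    x1, x2 = _pair_values(matrix, pair)
    n = len(x1)
    if n == 0:
        raise ValueError("no patients with complete data for this pair")
    observed = _membership(x1, x2, pattern, fold_cutoff).sum()

    if 2**n <= n_perm:
        ints = np.arange(2**n, dtype=np.uint64)
        flips = (ints[:, None] >> np.arange(n, dtype=np.uint64)) & 1
        flips = flips.astype(bool)
    else:
        rng = np.random.default_rng(seed)
        flips = rng.random((n_perm, n)) < 0.5
    counts = _perm_counts(x1, x2, pattern, fold_cutoff, flips)
    n_ge = int((counts >= observed).sum())
    if add_one and 2**n > n_perm:
        return (1 + n_ge) / (1 + n_perm)
    return n_ge / len(flips)


def exhaustive_permutation_pvalue(
    matrix: pd.DataFrame,
    pair: tuple[str, str],
    pattern: str,
    fold_cutoff: float = 1.5,
) -> float:
    """Exact label-exchange p-value by enumerating all 2**n assignments."""
    x1, x2 = _pair_values(matrix, pair)
    n = len(x1)
    if n == 0:
        raise ValueError("no patients with complete data for this pair")
    observed = _membership(x1, x2, pattern, fold_cutoff).sum()
    n_ge = 0
    for bits in itertools.product((False, True), repeat=n):
        flips = np.array(bits, dtype=bool)[None, :]
        if _perm_counts(x1, x2, pattern, fold_cutoff, flips)[0] >= observed:
            n_ge += 1
    return n_ge / 2**n


def storey_pi0(pvalues: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's null-proportion estimate with cubic-smoother extrapolation.

    π0(λ) = #{p > λ} / (m (1 − λ)) is computed on a λ-grid, a cubic
    polynomial is fit through the points, and its value at the largest λ is
    the estimate, clipped to (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    m = p.size
    pi0_grid = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
    coef = np.polynomial.polynomial.polyfit(lambdas, pi0_grid, 3)
    pi0 = float(np.polynomial.polynomial.polyval(lambdas.max(), coef))
    return min(max(pi0, 1.0 / m), 1.0)


def fdr_qvalues(pvalues, method: str = "storey") -> np.ndarray:
    """q-values for a family of p-values.

    ``storey`` estimates the null proportion π0 by :func:`storey_pi0`;
    ``bh`` fixes π0 = 1 (Benjamini–Hochberg).  q_i = π0 · min over p_j ≥ p_i
    of (m p_j / rank_j), clipped to [0, 1], order-preserving in p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "storey":
        pi0 = storey_pi0(p)
    elif method == "bh":
        pi0 = 1.0
    else:
        raise ValueError(f"unknown FDR method {method!r}")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1] * pi0
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def screen_pairs(
    matrix: pd.DataFrame,
    pairs: list[tuple[str, str]],
    fold_cutoff: float = 1.5,
    n_perm: int = 10_000,
    seed: int | None = None,
    fdr_method: str = "storey",
) -> pd.DataFrame:
    """Full pattern screen over a candidate pair list.

    Returns one row per (pair, pattern) with the observed fraction, the
    permutation p-value and the q-value over the whole tested family; the
    per-pair fraction columns are repeated for convenience.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for pair, child in zip(pairs, ss.spawn(len(pairs))):
        missing = [g for g in pair if g not in matrix.columns]
        if missing:
            raise KeyError(f"gene(s) {missing} not in expression matrix")
        frac = pattern_fractions(matrix, pair, fold_cutoff)
        rngs = [np.random.default_rng(s) for s in child.spawn(len(PATTERNS))]
        for pattern, rng in zip(PATTERNS, rngs):
            obs = getattr(frac, f"f_{pattern}")
            pval = permutation_pvalue(
                matrix, pair, pattern, n_perm=n_perm, seed=rng, fold_cutoff=fold_cutoff
            )
            rows.append(
                {
                    "gene1": pair[0],
                    "gene2": pair[1],
                    "pattern": pattern,
                    "fraction": obs,
                    "f_uu": frac.f_uu,
                    "f_ud": frac.f_ud,
                    "f_du": frac.f_du,
                    "f_dd": frac.f_dd,
                    "p_value": pval,
                }
            )
    out = pd.DataFrame(rows)
    out["q_value"] = fdr_qvalues(out["p_value"].to_numpy(), method=fdr_method)
    return out


def select_candidates(results: pd.DataFrame, min_fraction: float = 0.01) -> pd.DataFrame:
    """Rank screened pairs and keep those with any pattern above threshold.

    Keeps pairs whose largest pattern fraction strictly exceeds
    ``min_fraction`` and sorts descending lexicographically by
    (f_uu, f_ud, f_du, f_dd), breaking residual ties by gene symbols.
    Accepts the per-(pair, pattern) table from :func:`screen_pairs` or any
    table with one row per pair and the four fraction columns.
    """
    if results.empty:
        raise ValueError("empty screen-result table")
    per_pair = results.drop_duplicates(subset=["gene1", "gene2"]).copy()
    fracs = per_pair[["f_uu", "f_ud", "f_du", "f_dd"]]
    kept = per_pair[fracs.max(axis=1) > min_fraction].copy()
    kept = kept.sort_values(
        by=["f_uu", "f_ud", "f_du", "f_dd", "gene1", "gene2"],
        ascending=[False, False, False, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    kept["rank"] = np.arange(1, len(kept) + 1)
    return kept
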