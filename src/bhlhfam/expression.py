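"""Expression filtering, divergence calling and homeolog bias calling.

Two duplicated genes are considered to have retained a similar expression
pattern when the Pearson correlation of their expression profiles reaches
r >= 0.575, the critical value of a two-tailed correlation t-test at P <= 0.05
with about 12 conditions (see :func:`critical_r`); below it they are called
diverged.  Genes are treated as expressed when FPKM > 1 in at least one
condition.

Per-tissue homeolog bias between the A- and D-subgenome copies is tested with
Fisher's exact test on homeolog-specific read counts against the library
totals, corrected across all pairs x conditions with Benjamini-Hochberg FDR,
and called biased only when the library-size-normalised fold change also
reaches 1.5 toward one homeolog (At > Dt: A-biased, "Ahigh"; Dt > At:
"Dhigh").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DIVERGENCE_R_THRESHOLD = 0.575
FPKM_EXPRESSED = 1.0
DEFAULT_FOLD_MIN = 1.5
DEFAULT_Q_MAX = 0.05
#: alternate preset used for the stricter two-fold / P<0.01 convention
STRICT_PRESET = {"fold_min": 2.0, "q_max": 0.01}

#: exact integer enumeration below this table total; scipy above
_EXACT_FISHER_MAX_N = 2000

BIAS_CATEGORIES = ("Ahigh", "equal", "Dhigh", "mixed", "not_tested")


@dataclass
class ExpressionMatrix:
    """FPKM matrix (genes x conditions) with optional raw counts.

    Raw counts and per-condition library sizes are required for bias calling;
    FPKM alone suffices for expression filtering and divergence calling.
    """

    fpkm: pd.DataFrame
    counts: pd.DataFrame | None = None
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.fpkm.values < 0).any():
            raise ValueError("negative FPKM values")
        if self.counts is not None:
            if (self.counts.values < 0).any():
                raise ValueError("negative counts")
            if self.library_sizes is None:
                raise ValueError("library sizes required with counts")
            if (self.library_sizes <= 0).any():
                raise ValueError("library sizes must be positive")

    @property
    def conditions(self) -> list[str]:
        return list(self.fpkm.columns)


@dataclass(frozen=True)
class DivergenceCall:
    id1: str
    id2: str
    r: float
    call: str  # conserved | diverged | not_testable
    negative: bool = False


@dataclass(frozen=True)
class BiasCall:
    id_a: str
    id_d: str
    per_condition: dict = field(hash=False)
    p_values: dict = field(hash=False)
    q_values: dict = field(hash=False)
    overall: str


def is_expressed(fpkm_profile) -> bool:
    """True when FPKM strictly exceeds 1 in at least one condition."""
    profile = np.asarray(fpkm_profile, dtype=float)
    if profile.size == 0:
        raise ValueError("empty FPKM profile")
    return bool((profile > FPKM_EXPRESSED).any())


def pearson_r(x, y) -> float:
    """Product-moment correlation; NaN signals a zero-variance profile."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("profiles must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def critical_r(n_conditions: int, alpha: float = 0.05) -> float:
    """Smallest |r| significant at two-tailed level ``alpha``.

    Inverts the correlation t-test t = r sqrt(df) / sqrt(1 - r^2) at
    df = n_conditions - 2.  At 12 conditions and alpha 0.05 this gives 0.576,
    the provenance of the conventional 0.575 divergence threshold.
    """
    df = n_conditions - 2
    if df <= 0:
        raise ValueError("need at least 3 conditions")
    t = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t / math.sqrt(df + t * t))


def call_divergence(
    pair: tuple[str, str],
    matrix: ExpressionMatrix,
    threshold: float = DIVERGENCE_R_THRESHOLD,
) -> DivergenceCall:
    """Conserved/diverged call for one duplicated or homeolog pair.

    A pair is testable only when both genes are expressed (FPKM > 1 somewhere)
    and both profiles have nonzero variance; the call is conserved iff
    r >= threshold (inclusive).  Pairs with negative correlation are flagged.
    """
    g1, g2 = pair
    for g in pair:
        if g not in matrix.fpkm.index:
            raise KeyError(f"gene {g} missing from expression matrix")
    x = matrix.fpkm.loc[g1].to_numpy(dtype=float)
    y = matrix.fpkm.loc[g2].to_numpy(dtype=float)
    if not (is_expressed(x) and is_expressed(y)):
        return DivergenceCall(g1, g2, float("nan"), "not_testable")
    r = pearson_r(x, y)
    if math.isnan(r):
        return DivergenceCall(g1, g2, r, "not_testable")
    call = "conserved" if r >= threshold else "diverged"
    return DivergenceCall(g1, g2, r, call, negative=r < 0)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Two-sided by the point-probability method: the sum of hypergeometric
    probabilities of all tables (with the observed margins) no more probable
    than the observed one.  Small tables are enumerated in exact integer
    arithmetic; larger ones delegate to scipy.  Any zero margin gives p = 1.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    n = r1 + r2
    if n > _EXACT_FISHER_MAX_N:
        return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    obs = weights[a - lo]
    total = math.comb(n, c1)
    return sum(w for w in weights if w <= obs) / total


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def bias_table(
    pairs: list[tuple[str, str]],
    counts: pd.DataFrame,
    library_sizes: pd.Series,
    fold_min: float = DEFAULT_FOLD_MIN,
    q_max: float = DEFAULT_Q_MAX,
) -> list[BiasCall]:
    """Per-condition and overall homeolog bias for a set of pairs.

    For each pair and condition the 2x2 table (countA, libA - countA;
    countD, libD - countD) is tested with Fisher's exact test; BH correction
    runs across all pairs x conditions jointly.  A condition is Ahigh when the
    library-size-normalised fold change (pseudo-count 0.5) reaches
    ``fold_min`` toward the A copy and q < ``q_max``; Dhigh symmetrically;
    otherwise equal.  The overall category is Ahigh/Dhigh when at least one
    condition is biased that way and none the opposite way, mixed when both
    directions occur, equal when no condition is biased.
    """
    conditions = list(counts.columns)
    libs = library_sizes.reindex(conditions)
    if libs.isna().any():
        raise ValueError("library size missing for some condition")
    records = []  # (pair_idx, condition, p, fold_log)
    for k, (ga, gd) in enumerate(pairs):
        for g in (ga, gd):
            if g not in counts.index:
                raise KeyError(f"gene {g} missing from count matrix")
        for cond in conditions:
            ca = counts.at[ga, cond]
            cd = counts.at[gd, cond]
            if pd.isna(ca) or pd.isna(cd):
                records.append((k, cond, None, None))
                continue
            ca, cd = int(ca), int(cd)
            la, ld = int(libs[cond]), int(libs[cond])
            p = fisher_exact_2x2(ca, la - ca, cd, ld - cd)
            fold = ((ca + 0.5) / la) / ((cd + 0.5) / ld)
            records.append((k, cond, p, fold))
    tested = [r for r in records if r[2] is not None]
    qs = bh_fdr([r[2] for r in tested]) if tested else np.array([])
    qmap = {(r[0], r[1]): q for r, q in zip(tested, qs)}

    calls = []
    for k, (ga, gd) in enumerate(pairs):
        per_cond: dict[str, str] = {}
        pvals: dict[str, float] = {}
        qvals: dict[str, float] = {}
        for r in records:
            if r[0] != k:
                continue
            _, cond, p, fold = r
            if p is None:
                per_cond[cond] = "not_tested"
                continue
            q = float(qmap[(k, cond)])
            pvals[cond], qvals[cond] = float(p), q
            if q < q_max and fold >= fold_min:
                per_cond[cond] = "Ahigh"
            elif q < q_max and fold <= 1.0 / fold_min:
                per_cond[cond] = "Dhigh"
            else:
                per_cond[cond] = "equal"
        cats = set(per_cond.values())
        if cats <= {"not_tested"}:
            overall = "not_tested"
        elif "Ahigh" in cats and "Dhigh" in cats:
            overall = "mixed"
        elif "Ahigh" in cats:
            overall = "Ahigh"
        elif "Dhigh" in cats:
            overall = "Dhigh"
        else:
            overall = "equal"
        calls.append(BiasCall(ga, gd, per_cond, pvals, qvals, overall))
    return calls


def homeolog_bias(
    pair: tuple[str, str],
    counts: pd.DataFrame,
    library_sizes: pd.Series,
    fold_min: float = DEFAULT_FOLD_MIN,
    q_max: float = DEFAULT_Q_MAX,
) -> BiasCall:
    """Bias call for a single homeolog pair (FDR across its own conditions).

    When many pairs are analysed together use :func:`bias_table`, which
    corrects across all pairs x conditions jointly.
    """
    return bias_table([pair], counts, library_sizes, fold_min, q_max)[0]


def divergence_table(
    pairs: list[tuple[str, str]],
    matrix: ExpressionMatrix,
    threshold: float = DIVERGENCE_R_THRESHOLD,
) -> pd.DataFrame:
    calls = [call_divergence(p, matrix, threshold) for p in pairs]
    return pd.DataFrame(
        {
            "gene1": [c.id1 for c in calls],
            "gene2": [c.id2 for c in calls],
            "r": [round(c.r, 6) if not math.isnan(c.r) else float("nan") for c in calls],
            "call": [c.call for c in calls],
            "negative_r": [c.negative for c in calls],
        }
    )
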