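"""mRNA-protein correlation readout and auxiliary statistics.

The readout that picks the final normalizer: Spearman/Pearson correlation
between log10 normalized transcript copies and logit-transformed qIHC
proportion scores, computed per candidate normalizer; the candidate
maximizing Spearman's rho wins.  Cohorts here are small (7-13 samples), so
Spearman p-values are exact up to n = 12 — computed from the exact null
distribution of T = sum_i i*sigma(i) over permutations via a bitmask
dynamic program, which is identical to full enumeration without touching
all n! orders — and t-approximated above.

Also provided: two-sided Grubbs outlier test (flagging only, never
auto-removal), Lilliefors-corrected Kolmogorov-Smirnov normality,
exact paired Wilcoxon signed-rank, pairwise variant co-expression, and the
post-hoc choice between alternative section scores of a single sample.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .qihc import logit_transform

EXACT_SPEARMAN_MAX_N = 12


@lru_cache(maxsize=None)
def _spearman_t_counts(n: int) -> tuple:
    """Exact null counts of T = sum_i i*sigma(i) over all permutations.

    Bitmask DP: masks encode which ranks are already assigned; the next
    list position is popcount(mask) + 1.  Equivalent to enumerating n!
    permutations but O(2^n * n * T) instead.
    """
    max_t = sum(i * i for i in range(1, n + 1))
    dp: list = [None] * (1 << n)
    dp[0] = np.zeros(max_t + 1, dtype=np.int64)
    dp[0][0] = 1
    full = (1 << n) - 1
    for mask in range(full):
        cur = dp[mask]
        if cur is None:
            continue
        i = bin(mask).count("1") + 1
        for j in range(1, n + 1):
            bit = 1 << (j - 1)
            if mask & bit:
                continue
            nxt = mask | bit
            if dp[nxt] is None:
                dp[nxt] = np.zeros(max_t + 1, dtype=np.int64)
            shift = i * j
            dp[nxt][shift:] += cur[: max_t + 1 - shift]
        dp[mask] = None  # free
    return tuple(dp[full].tolist())


def exact_spearman_pvalue(rho: float, n: int) -> float:
    """Two-sided exact P(|rho_null| >= |rho|) for untied data, n <= 12."""
    if n > EXACT_SPEARMAN_MAX_N:
        raise ValueError(f"exact p limited to n <= {EXACT_SPEARMAN_MAX_N}")
    counts = np.asarray(_spearman_t_counts(n), dtype=float)
    s2 = n * (n + 1) * (2 * n + 1) / 6.0
    t_vals = np.arange(counts.size, dtype=float)
    # sum d^2 = 2*S2 - 2*T ;  rho = 1 - 6*sum(d^2) / (n(n^2-1))
    rho_null = 1.0 - 6.0 * (2.0 * s2 - 2.0 * t_vals) / (n * (n * n - 1.0))
    hit = np.abs(rho_null) >= abs(rho) - 1e-12
    return float(counts[hit].sum() / counts.sum())


def spearman_with_p(x, y) -> tuple[float, float]:
    """Spearman rho with exact p for small untied samples, else t-approx."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho, p_approx = stats.spearmanr(x, y)
    n = len(x)
    tied = len(np.unique(x)) < n or len(np.unique(y)) < n
    if n <= EXACT_SPEARMAN_MAX_N and not tied:
        return float(rho), exact_spearman_pvalue(float(rho), n)
    return float(rho), float(p_approx)


# --------------------------------------------------------------------------
# the correlation readout
# --------------------------------------------------------------------------

@dataclass
class ReadoutResult:
    normalizer: str
    n: int
    spearman_rho: float
    spearman_p: float
    pearson_r: float
    pearson_p: float
    pairs: pd.DataFrame  # columns log10_copies, logit_qihc


def correlate_mrna_protein(
    copies: pd.Series,
    proportions: pd.Series,
    normalizer: str = "",
) -> ReadoutResult:
    """Correlate log10 copies against logit qIHC proportions, paired by sample."""
    copies = pd.Series(copies)
    proportions = pd.Series(proportions)
    unpaired = sorted(set(copies.index) ^ set(proportions.index))
    if unpaired:
        raise ValueError(f"unpaired samples: {unpaired}")
    if len(copies) < 5:
        raise ValueError(f"need at least 5 paired samples, got {len(copies)}")
    if (copies <= 0).any():
        raise ValueError("copies must be positive")
    proportions = proportions.reindex(copies.index)
    x = np.log10(copies.to_numpy(dtype=float))
    y = np.array([logit_transform(p, policy="raise") for p in proportions])
    rho, p_s = spearman_with_p(x, y)
    r, p_r = stats.pearsonr(x, y)
    pairs = pd.DataFrame(
        {"log10_copies": x, "logit_qihc": y}, index=copies.index
    )
    return ReadoutResult(normalizer, len(x), rho, p_s, float(r), float(p_r), pairs)


@dataclass
class NormalizerEvaluation:
    table: pd.DataFrame          # candidate, n, rho, p_rho, r, p_r
    best: str
    tied: bool
    results: dict


def evaluate_normalizers(
    target_copies: pd.Series,
    candidates: dict[str, pd.Series],
    proportions: pd.Series,
    include_input_mass: bool = True,
) -> NormalizerEvaluation:
    """Rank candidate normalizers by the mRNA-protein correlation readout.

    Each candidate's per-sample value divides the target copies
    (input-mass mode passes the raw copies through); the winner maximizes
    Spearman's rho, ties resolved by higher Pearson r then lexicographic id.
    """
    if not candidates and not include_input_mass:
        raise ValueError("need at least one candidate")
    results: dict[str, ReadoutResult] = {}
    if include_input_mass:
        results["input_mass"] = correlate_mrna_protein(
            target_copies, proportions, "input_mass"
        )
    for name in sorted(candidates):
        values = pd.Series(candidates[name]).reindex(target_copies.index)
        if values.isna().any() or (values <= 0).any():
            raise ValueError(f"candidate {name!r} has missing or nonpositive values")
        results[name] = correlate_mrna_protein(
            target_copies / values, proportions, name
        )
    table = pd.DataFrame(
        {
            "candidate": list(results),
            "n": [r.n for r in results.values()],
            "spearman_rho": [r.spearman_rho for r in results.values()],
            "spearman_p": [r.spearman_p for r in results.values()],
            "pearson_r": [r.pearson_r for r in results.values()],
            "pearson_p": [r.pearson_p for r in results.values()],
        }
    ).sort_values(
        ["spearman_rho", "pearson_r", "candidate"], ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    best = table.iloc[0]["candidate"]
    tied = bool(
        (table["spearman_rho"] == table.iloc[0]["spearman_rho"]).sum() > 1
    )
    return NormalizerEvaluation(table, str(best), tied, results)


# --------------------------------------------------------------------------
# auxiliary statistics
# --------------------------------------------------------------------------

@dataclass
class GrubbsResult:
    statistic: float
    p_value: float
    candidate_index: object     # label of the most extreme value
    flagged: bool


def grubbs_test(values, alpha: float = 0.05) -> GrubbsResult:
    """Two-sided Grubbs test; flags (never removes) the extreme value.

    G = max|x - mean| / SD; the p-value follows from the t-distribution
    mapping t^2 = n(n-2)G^2 / ((n-1)^2 - nG^2), p = min(1, 2n * sf(t)).
    """
    s = pd.Series(values, dtype=float)
    n = len(s)
    if n < 3:
        raise ValueError("Grubbs test needs at least 3 values")
    sd = s.std(ddof=1)
    if sd == 0:
        return GrubbsResult(0.0, 1.0, None, False)
    dev = (s - s.mean()).abs()
    idx = dev.idxmax()
    g = float(dev[idx] / sd)
    denom = (n - 1) ** 2 - n * g * g
    if denom <= 0:
        p = 0.0
    else:
        t = math.sqrt(n * (n - 2) * g * g / denom)
        p = min(1.0, 2 * n * stats.t.sf(t, n - 2))
    return GrubbsResult(g, float(p), idx, p < alpha)


def ks_normality(values) -> tuple[float, float]:
    """Kolmogorov-Smirnov normality with Lilliefors small-sample correction
    (mean and SD estimated from the data)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 5:
        raise ValueError("normality test needs at least 5 values")
    if np.std(v) == 0:
        raise ValueError("degenerate input: all values identical")
    stat, p = lilliefors(v, dist="norm")
    return float(stat), float(p)


def wilcoxon_paired(a, b) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank; exact p for n <= 25, zeros dropped.

    All-zero differences return (0, 1) by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    method = "exact" if d.size <= 25 else "approx"
    try:
        res = stats.wilcoxon(d, method=method)
    except ValueError:
        res = stats.wilcoxon(d, method="approx")
    return float(res.statistic), float(res.pvalue)


def pairwise_coexpression(copies: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All pairwise Spearman rho and Pearson r on log10 copies.

    ``copies`` is samples x variants; returns (rho matrix, r matrix).
    """
    if copies.shape[1] < 2:
        raise ValueError("need at least 2 variants")
    if (copies.to_numpy() <= 0).any():
        raise ValueError("copies must be positive")
    x = np.log10(copies.to_numpy(dtype=float))
    cols = list(copies.columns)
    k = len(cols)
    rho = np.eye(k)
    r = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            rho[i, j] = rho[j, i] = stats.spearmanr(x[:, i], x[:, j])[0]
            r[i, j] = r[j, i] = stats.pearsonr(x[:, i], x[:, j])[0]
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(r, index=cols, columns=cols),
    )


@dataclass
class SectionChoice:
    sample: object
    selected_section: object
    r_squared: dict            # section label -> r^2 of the full regression
    proportions: pd.Series     # final one-score-per-sample proportions


def choose_section_score(
    section_scores: pd.DataFrame,
    copies: pd.Series,
) -> SectionChoice:
    """Pick between alternative qIHC scores of the single multi-score sample.

    ``section_scores`` has columns sample, section, proportion; exactly one
    sample may carry several alternatives.  For each alternative the full
    Pearson regression of logit(p) on log10(copies) is fitted with every
    other sample fixed, and the alternative maximizing r^2 is kept.  The
    choice is post hoc; a selection-bias warning is always emitted.
    """
    counts = section_scores.groupby("sample").size()
    multi = counts[counts > 1].index.tolist()
    if len(multi) == 0:
        prop = section_scores.set_index("sample")["proportion"]
        only = section_scores.iloc[0]
        return SectionChoice(None, only["section"], {}, prop)
    if len(multi) > 1:
        raise ValueError(
            f"procedure defined for exactly one multi-score sample, got {multi}"
        )
    sample = multi[0]
    fixed = section_scores[section_scores["sample"] != sample]
    alts = section_scores[section_scores["sample"] == sample]
    r2: dict = {}
    best_label, best_r2, best_prop = None, -np.inf, None
    for _, row in alts.iterrows():
        prop = pd.concat(
            [
                fixed.set_index("sample")["proportion"],
                pd.Series({sample: row["proportion"]}),
            ]
        ).reindex(copies.index)
        res = correlate_mrna_protein(copies, prop)
        r2[row["section"]] = res.pearson_r**2
        if r2[row["section"]] > best_r2:
            best_label, best_r2, best_prop = row["section"], r2[row["section"]], prop
    warnings.warn(
        f"section score for sample {sample!r} chosen post hoc by best regression "
        "fit; this selection is data-dependent and should be reported",
        stacklevel=2,
    )
    return SectionChoice(sample, best_label, r2, best_prop)
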