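"""Reference-gene stability statistics on a samples x genes quantity matrix.

The four classical algorithms are implemented from their published models:

* geNorm — stability M = mean SD of pairwise log2 expression ratios, with
  stepwise exclusion of the least stable gene and the pairwise-variation
  series V_n/V_n+1 that fixes the optimal number of reference genes
  (V < 0.15 by convention).
* NormFinder — model-based variance of log quantities; the group-free
  variant is the residual SD of a gene against the per-sample mean profile.
* BestKeeper — descriptive SD / CV of Cq plus Pearson correlation against
  the BestKeeper index (per-sample geometric mean Cq).
* comparative dCq — mean SD of pairwise Cq differences.

geNorm and NormFinder consume linear relative quantities (log2 internally);
BestKeeper and the comparative dCq method consume efficiency-adjusted Cq
directly, matching each tool's own convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def cq_to_quantity(cq_summaries: pd.DataFrame) -> pd.DataFrame:
    """Relative quantities q_sg = 2^(min_s' Cq_s'g - Cq_sg).

    Expects the CqSummary table (columns sample, assay, consensus_cq) with a
    complete sample x assay grid; the per-gene maximum quantity is 1 by
    construction.
    """
    pivot = cq_summaries.pivot(index="sample", columns="assay", values="consensus_cq")
    if pivot.isna().any().any():
        cells = [
            f"({s}, {a})"
            for s in pivot.index
            for a in pivot.columns
            if pd.isna(pivot.loc[s, a])
        ]
        raise ValueError(f"incomplete sample x assay grid, missing: {', '.join(cells)}")
    q = np.power(2.0, pivot.min(axis=0) - pivot)
    q.columns.name = "gene"
    return q


def _check_matrix(m: pd.DataFrame, min_genes: int, min_samples: int, name: str):
    if m.shape[1] < min_genes:
        raise ValueError(f"{name} needs >= {min_genes} genes, got {m.shape[1]}")
    if m.shape[0] < min_samples:
        raise ValueError(f"{name} needs >= {min_samples} samples, got {m.shape[0]}")


def _rank_table(scores: pd.Series, algorithm: str) -> pd.DataFrame:
    """Ascending-score ranking table (lower = more stable)."""
    out = pd.DataFrame({"gene": scores.index, "score": scores.to_numpy()})
    out["rank"] = out["score"].rank(method="average")
    out = out.sort_values(["score", "gene"], kind="mergesort").reset_index(drop=True)
    out.insert(0, "algorithm", algorithm)
    return out


# --------------------------------------------------------------------------
# geNorm
# --------------------------------------------------------------------------

def genorm_m_values(quantities: pd.DataFrame) -> pd.Series:
    """M_j = mean over partners k of SD_s( log2(q_j / q_k) )."""
    logq = np.log2(quantities.to_numpy(dtype=float))
    genes = list(quantities.columns)
    n = len(genes)
    m = np.zeros(n)
    for j in range(n):
        sds = [
            np.std(logq[:, j] - logq[:, k], ddof=1) for k in range(n) if k != j
        ]
        m[j] = float(np.mean(sds))
    return pd.Series(m, index=genes, name="M")


@dataclass
class GeNormResult:
    m_values: pd.Series          # full-panel M before any exclusion
    exclusion_order: list        # least stable first; final entry = tied pair
    ranking: pd.DataFrame        # algorithm/gene/score/rank, best first
    v_series: pd.Series          # V_n/V_n+1 indexed by n
    optimal_n: int | None        # smallest n with V < cutoff, None if never
    cutoff: float


def genorm(quantities: pd.DataFrame, cutoff: float = 0.15) -> GeNormResult:
    """Full geNorm analysis: stepwise M ranking plus the V_n/V_n+1 series.

    The two final genes cannot be ranked against each other (their M values
    coincide) and are reported as a tie.
    """
    _check_matrix(quantities, 3, 3, "geNorm")
    if (quantities.to_numpy() <= 0).any():
        raise ValueError("quantities must be strictly positive")
    full_m = genorm_m_values(quantities)

    remaining = list(quantities.columns)
    exclusion: list = []
    score_at_exclusion: dict[str, float] = {}
    while len(remaining) > 2:
        m = genorm_m_values(quantities[remaining])
        # deterministic tie-break: highest M, then reverse-lexicographic
        worst_m = m.max()
        ties = sorted(m.index[m == worst_m])
        worst = ties[-1]
        exclusion.append(worst)
        score_at_exclusion[worst] = float(worst_m)
        remaining.remove(worst)
    final_pair = sorted(remaining)
    final_m = genorm_m_values(quantities[remaining])
    for g in final_pair:
        score_at_exclusion[g] = float(final_m[g])
    exclusion.append(tuple(final_pair))

    # ranking best-first: tied pair at fractional rank 1.5, then reversed exclusions
    rows = []
    for g in final_pair:
        rows.append({"gene": g, "score": score_at_exclusion[g], "rank": 1.5})
    for pos, g in enumerate(reversed(exclusion[:-1]), start=3):
        rows.append({"gene": g, "score": score_at_exclusion[g], "rank": float(pos)})
    ranking = pd.DataFrame(rows)
    ranking.insert(0, "algorithm", "geNorm")

    # V series over the stability order (most stable first)
    order = final_pair + list(reversed(exclusion[:-1]))
    logq = np.log2(quantities[order].to_numpy(dtype=float))
    n_genes = len(order)
    v_vals, v_idx = [], []
    log_nf = {n: logq[:, :n].mean(axis=1) for n in range(2, n_genes + 1)}
    for n in range(2, n_genes):
        v_vals.append(float(np.std(log_nf[n] - log_nf[n + 1], ddof=1)))
        v_idx.append(n)
    v_series = pd.Series(v_vals, index=pd.Index(v_idx, name="n"), name="V")
    optimal = next((int(n) for n, v in v_series.items() if v < cutoff), None)
    return GeNormResult(full_m, exclusion, ranking, v_series, optimal, cutoff)


# --------------------------------------------------------------------------
# NormFinder
# --------------------------------------------------------------------------

def normfinder(
    quantities: pd.DataFrame,
    groups: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """NormFinder stability; lower = more stable.

    Without groups (default, single-condition cohorts): the stability of a
    gene is the SD over samples of its log2 quantity after removing the
    per-sample mean across genes — the residual of the two-way
    (sample + gene) additive model.

    With groups: Andersen-style combination of the absolute inter-group
    gene effect and the within-group residual standard error.
    """
    _check_matrix(quantities, 3, 2, "NormFinder")
    x = np.log2(quantities.to_numpy(dtype=float))
    genes = list(quantities.columns)
    if groups is None:
        resid = x - x.mean(axis=1, keepdims=True)
        scores = pd.Series(np.std(resid, axis=0, ddof=1), index=genes)
        return _rank_table(scores, "NormFinder")

    grp = pd.Series(groups) if not isinstance(groups, pd.Series) else groups
    grp = grp.reindex(quantities.index)
    if grp.isna().any():
        raise ValueError("every sample needs a group label")
    counts = grp.value_counts()
    if (counts < 2).any():
        raise ValueError("each group needs at least 2 samples")
    xc = x - x.mean(axis=1, keepdims=True)  # remove sample effects
    gene_mean = xc.mean(axis=0)
    scores = np.zeros(len(genes))
    for gname, idx in grp.groupby(grp).groups.items():
        pos = quantities.index.get_indexer(idx)
        sub = xc[pos]
        d = sub.mean(axis=0) - gene_mean          # inter-group gene effect
        within_sd = sub.std(axis=0, ddof=1)
        scores += np.abs(d) + within_sd / np.sqrt(len(pos))
    scores = pd.Series(scores / counts.size, index=genes)
    return _rank_table(scores, "NormFinder")


# --------------------------------------------------------------------------
# BestKeeper
# --------------------------------------------------------------------------

def bestkeeper(cq_matrix: pd.DataFrame) -> pd.DataFrame:
    """BestKeeper descriptive statistics on adjusted Cq.

    Reports SD(Cq), CV% = 100*SD/mean and Pearson r against the BestKeeper
    index (per-sample geometric mean of Cq across genes); the primary
    ranking key is SD(Cq) ascending, SD > 1 flagged inconsistent.
    """
    _check_matrix(cq_matrix, 2, 3, "BestKeeper")
    cq = cq_matrix.to_numpy(dtype=float)
    index = np.exp(np.log(cq).mean(axis=1))  # geometric mean per sample
    rows = []
    for j, gene in enumerate(cq_matrix.columns):
        sd = float(np.std(cq[:, j], ddof=1))
        mean = float(np.mean(cq[:, j]))
        if np.std(cq[:, j]) == 0 or np.std(index) == 0:
            r, p = (1.0, 0.0) if np.std(cq[:, j]) == 0 and np.std(index) == 0 else (np.nan, np.nan)
        else:
            r, p = stats.pearsonr(cq[:, j], index)
        rows.append(
            {
                "gene": gene,
                "score": sd,
                "cv_pct": 100.0 * sd / mean,
                "r_vs_index": float(r),
                "p_vs_index": float(p),
                "inconsistent": sd > 1.0,
            }
        )
    out = pd.DataFrame(rows)
    out["rank"] = out["score"].rank(method="average")
    out = out.sort_values(["score", "gene"], kind="mergesort").reset_index(drop=True)
    out.insert(0, "algorithm", "BestKeeper")
    return out


# --------------------------------------------------------------------------
# comparative dCq
# --------------------------------------------------------------------------

def comparative_dcq(cq_matrix: pd.DataFrame) -> pd.DataFrame:
    """Mean SD of pairwise Cq differences; invariant to per-gene Cq shifts."""
    _check_matrix(cq_matrix, 3, 3, "comparative dCq")
    cq = cq_matrix.to_numpy(dtype=float)
    genes = list(cq_matrix.columns)
    n = len(genes)
    scores = np.zeros(n)
    for j in range(n):
        sds = [np.std(cq[:, j] - cq[:, k], ddof=1) for k in range(n) if k != j]
        scores[j] = float(np.mean(sds))
    return _rank_table(pd.Series(scores, index=genes), "comparative_dCq")


# --------------------------------------------------------------------------
# normalization factors
# --------------------------------------------------------------------------

def compose_nf(quantities: pd.DataFrame, genes) -> pd.Series:
    """Normalization factor: per-sample geometric mean of member quantities."""
    genes = list(genes)
    if not genes:
        raise ValueError("normalization factor needs at least one gene")
    missing = [g for g in genes if g not in quantities.columns]
    if missing:
        raise ValueError(f"genes not in matrix: {missing}")
    sub = quantities[genes].to_numpy(dtype=float)
    if (sub <= 0).any():
        raise ValueError("quantities must be strictly positive")
    nf = pd.Series(np.exp(np.log(sub).mean(axis=1)), index=quantities.index)
    nf.name = "+".join(str(g) for g in genes)
    return nf
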