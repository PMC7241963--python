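"""Exon-level expression stability from RNA-seq counts.

Candidate reference sequences are single exons and three neighbour
combinations — the direct pair (i, i+1), the skip pair (i, i+2) and the trio
(i, i+1, i+2) — ranked in ascending order of their coefficient of variation
(CV = SD / mean) of TPM expression across samples.  Pairs of consecutive
exons matter because an exon-border-spanning qPCR assay reports their joint
abundance and is robust to single-exon splicing artefacts.

Also houses the two downstream annotation-level analyses: Fisher/BH GO-term
enrichment of the most stable genes, and the hexamer poly(A)-signal scan
used to assess alternative polyadenylation of a target 3' UTR.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

SCHEMES = ("single", "pair_adjacent", "pair_skip", "trio")

#: canonical first, then the three non-canonical hexamers
POLYA_MOTIFS = {
    "AAUAAA": "canonical",
    "AUUAAA": "non-canonical",
    "AGUAAA": "non-canonical",
    "UAUAAA": "non-canonical",
}

META_COLS = ["gene_id", "exon_index", "exon_length"]


def _sample_columns(exon_table: pd.DataFrame) -> list[str]:
    return [c for c in exon_table.columns if c not in META_COLS]


def compute_tpm(exon_table: pd.DataFrame) -> pd.DataFrame:
    """Transcripts-per-kilobase-million per exon per sample.

    TPM_es = (count_es / length_e) / sum_e(count/length)_s * 1e6, so each
    sample column sums to 1e6.

    Parameters
    ----------
    exon_table
        Columns ``gene_id``, ``exon_index``, ``exon_length`` plus one numeric
        column per sample.

    Returns
    -------
    DataFrame indexed by (gene_id, exon_index) with one TPM column per sample.
    """
    samples = _sample_columns(exon_table)
    if not samples:
        raise ValueError("exon table has no sample columns")
    lengths = exon_table["exon_length"].to_numpy(dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("exon lengths must be positive")
    counts = exon_table[samples].to_numpy(dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    rate = counts / lengths[:, None]
    totals = rate.sum(axis=0)
    dead = [s for s, t in zip(samples, totals) if t == 0]
    if dead:
        raise ValueError(f"sample(s) with all-zero counts: {', '.join(dead)}")
    tpm = rate / totals * 1e6
    out = pd.DataFrame(tpm, columns=samples)
    out.index = pd.MultiIndex.from_frame(exon_table[["gene_id", "exon_index"]])
    return out


@dataclass(frozen=True)
class ComboSkeleton:
    gene_id: str
    scheme: str
    members: tuple[int, ...]


def enumerate_combos(exon_table: pd.DataFrame) -> list[ComboSkeleton]:
    """All single/pair/skip/trio combinations permitted by each gene's exons.

    A combination is emitted whenever every exon index it requires exists for
    the gene, so a gene with k consecutively numbered exons yields
    k singles, k-1 adjacent pairs, k-2 skip pairs and k-2 trios.
    """
    combos: list[ComboSkeleton] = []
    for gene, sub in exon_table.groupby("gene_id", sort=True):
        idx = set(int(i) for i in sub["exon_index"])
        for i in sorted(idx):
            combos.append(ComboSkeleton(str(gene), "single", (i,)))
            if i + 1 in idx:
                combos.append(ComboSkeleton(str(gene), "pair_adjacent", (i, i + 1)))
            if i + 2 in idx:
                combos.append(ComboSkeleton(str(gene), "pair_skip", (i, i + 2)))
            if i + 1 in idx and i + 2 in idx:
                combos.append(ComboSkeleton(str(gene), "trio", (i, i + 1, i + 2)))
    return combos


def combo_expression(tpm: pd.DataFrame, combo: ComboSkeleton) -> np.ndarray:
    """Per-sample expression of a combination = sum of member-exon TPM."""
    rows = [tpm.loc[(combo.gene_id, m)] for m in combo.members]
    return np.sum(np.asarray(rows, dtype=float), axis=0)


def rank_by_cv(
    tpm: pd.DataFrame,
    combos: list[ComboSkeleton] | None = None,
    cv_max: float = 1.0,
) -> pd.DataFrame:
    """Rank combinations ascending by expression CV.

    CV uses the sample SD (n-1 denominator) over the summed member-exon TPM.
    Combinations with zero mean are dropped, as are those above ``cv_max``.
    Ties are broken by higher mean abundance, then lexicographic gene id.

    Returns a StabilityTable with columns gene_id, scheme, members,
    mean_tpm, mean_log2_tpm, cv — sorted best (lowest CV) first.
    """
    n_samples = tpm.shape[1]
    if n_samples < 3:
        raise ValueError(f"CV ranking needs >= 3 samples, got {n_samples}")
    if combos is None:
        meta = tpm.index.to_frame(index=False)
        meta["exon_length"] = 1  # lengths irrelevant for enumeration
        combos = enumerate_combos(meta)
    records = []
    for c in combos:
        expr = combo_expression(tpm, c)
        mean = expr.mean()
        if mean == 0:
            continue
        cv = expr.std(ddof=1) / mean
        if cv > cv_max:
            continue
        records.append(
            {
                "gene_id": c.gene_id,
                "scheme": c.scheme,
                "members": "+".join(str(m) for m in c.members),
                "mean_tpm": mean,
                "mean_log2_tpm": float(np.log2(mean)) if mean > 0 else -np.inf,
                "cv": cv,
            }
        )
    table = pd.DataFrame.from_records(
        records, columns=["gene_id", "scheme", "members", "mean_tpm", "mean_log2_tpm", "cv"]
    )
    table = table.sort_values(
        ["cv", "mean_tpm", "gene_id"], ascending=[True, False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table


def top_list_composition(stability_table: pd.DataFrame, n: int) -> dict:
    """Count and fraction of neighbour combinations among the top ``n``."""
    if n <= 0:
        raise ValueError("n must be positive")
    if len(stability_table) < n:
        raise ValueError(f"table has only {len(stability_table)} entries, need {n}")
    top = stability_table.head(n)
    count = int((top["scheme"] != "single").sum())
    return {"n": n, "neighbour_count": count, "neighbour_fraction": count / n}


def select_top_genes(stability_table: pd.DataFrame, n_genes: int = 100) -> pd.DataFrame:
    """Best (lowest-CV) combination per gene, then the ``n_genes`` lowest.

    Emits a warning and returns everything when fewer distinct genes exist.
    """
    if stability_table.empty:
        raise ValueError("empty stability table")
    best = stability_table.drop_duplicates("gene_id", keep="first")
    if len(best) < n_genes:
        warnings.warn(
            f"requested {n_genes} genes but only {len(best)} distinct genes available",
            stacklevel=2,
        )
        return best.reset_index(drop=True)
    return best.head(n_genes).reset_index(drop=True)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Summation of hypergeometric probabilities no larger than the observed
    table's, with the tie comparison done in exact integer arithmetic (no
    floating-point tie guard), so the result is reproducible to full
    precision against any exact oracle.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n_list = a + b
    n_term = a + c
    n = a + b + c + d
    denom = math.comb(n, n_list)
    obs = math.comb(n_term, a) * math.comb(n - n_term, n_list - a)
    total = 0
    for x in range(max(0, n_list + n_term - n), min(n_list, n_term) + 1):
        w = math.comb(n_term, x) * math.comb(n - n_term, n_list - x)
        if w <= obs:
            total += w
    return total / denom


def go_enrichment(
    gene_list: list[str],
    annotation: pd.DataFrame,
    background: set[str] | list[str],
    fdr_cutoff: float = 0.01,
) -> pd.DataFrame:
    """GO-term over-representation by two-sided Fisher's exact test + BH.

    For every term annotating at least one background gene a 2x2 table
    [in-list & in-term, in-list & not, not-in-list & in-term, not & not]
    is tested; p-values are Benjamini-Hochberg adjusted across all tested
    terms and rows with FDR < ``fdr_cutoff`` are returned, ascending FDR.

    ``annotation`` needs columns ``gene_id`` and ``term_id``.
    """
    background = set(background)
    genes = set(gene_list)
    if not genes <= background:
        raise ValueError("gene list must be a subset of the background")
    ann = annotation[annotation["gene_id"].isin(background)]
    if ann.empty:
        return pd.DataFrame(
            columns=["term_id", "gene_number", "term_total", "p", "fdr", "frequency"]
        )
    rows = []
    n_list, n_bg = len(genes), len(background)
    for term, sub in ann.groupby("term_id", sort=True):
        term_genes = set(sub["gene_id"])
        a = len(genes & term_genes)
        b = n_list - a
        c = len(term_genes) - a
        d = (n_bg - n_list) - c
        p = fisher_exact_two_sided(a, b, c, d)
        rows.append(
            {
                "term_id": term,
                "gene_number": a,
                "term_total": len(term_genes),
                "p": p,
                "frequency": a / n_list if n_list else 0.0,
            }
        )
    res = pd.DataFrame(rows)
    res["fdr"] = multipletests(res["p"].to_numpy(), method="fdr_bh")[1]
    res = res[res["fdr"] < fdr_cutoff]
    res = res.sort_values(["fdr", "p", "term_id"], kind="mergesort").reset_index(drop=True)
    return res[["term_id", "gene_number", "term_total", "p", "fdr", "frequency"]]


def scan_polya_signals(sequence: str) -> list[tuple[str, int, str]]:
    """Exact hexamer scan for poly(A) signals on an RNA (or DNA) sequence.

    Returns (motif, 1-based position, label) for every — possibly
    overlapping — occurrence of AAUAAA (canonical) or AUUAAA/AGUAAA/UAUAAA
    (non-canonical).  T is accepted and read as U.
    """
    seq = sequence.upper().replace("T", "U")
    bad = [i + 1 for i, ch in enumerate(seq) if ch not in "ACGU"]
    if bad:
        raise ValueError(f"ambiguous bases at 1-based positions: {bad}")
    hits = []
    for pos in range(len(seq) - 5):
        hexamer = seq[pos : pos + 6]
        if hexamer in POLYA_MOTIFS:
            hits.append((hexamer, pos + 1, POLYA_MOTIFS[hexamer]))
    return hits
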