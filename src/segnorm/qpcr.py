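"""Cq processing: per-well amplification efficiency, efficiency-adjusted Cq,
replicate outlier rules, minus-RT contamination check and dPCR calibration.

The measurement design is 2 cDNA replicates x 2 qPCR replicates per
sample x assay.  Raw Cq values are first rescaled to base-2-equivalent
cycles with the assay's mean efficiency E_fi via

    Cq_adj = Cq * log10(E_fi + 1) / log10(2)

so that adjusted Cq differences read directly as log2 fold changes.  Two
outlier rules then apply: a quadruplicate whose SD exceeds 0.5 cycles loses
the single well whose exclusion minimizes the remaining SD, and cDNA
duplicates whose means differ by more than one cycle lose the replicate
deviating most from the assay's cohort-wide mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import EfficiencyConfig


class NoAmplificationError(ValueError):
    """Raised when a fluorescence curve shows no exponential rise."""


class DpcrSaturationError(ValueError):
    """All partitions positive: concentration above the dynamic range."""


# --------------------------------------------------------------------------
# amplification efficiency from a raw curve
# --------------------------------------------------------------------------

@dataclass
class EfficiencyEstimate:
    efficiency: float          # fractional gain per cycle, 1.0 = doubling
    r_squared: float
    window_start_cycle: int    # 1-based first cycle of the fitted window
    window: int
    low_confidence: bool = False
    clamped: bool = False


def estimate_well_efficiency(
    fluorescence,
    config: EfficiencyConfig | None = None,
) -> EfficiencyEstimate:
    """Estimate E for one well from its raw (not baseline-corrected) curve.

    A window of ``config.window`` consecutive cycles slides over the region
    whose baseline-subtracted fluorescence lies between the configured
    fractional bounds of the plateau; log10(F - baseline) — or, for curves
    that have visibly plateaued, its exact logistic linearization
    log10(F_b / (plateau - F_b)) — is fitted against cycle in each window,
    the window maximizing R-squared wins, and E = 10^slope - 1.

    Raises :class:`NoAmplificationError` for flat curves; estimates whose
    best R-squared falls below the threshold carry ``low_confidence``.
    """
    cfg = config or EfficiencyConfig()
    f = np.asarray(fluorescence, dtype=float)
    if f.ndim != 1 or len(f) < 20:
        raise ValueError("need a 1-D curve of at least 20 cycles")
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite fluorescence values")

    baseline = float(np.median(f[: cfg.n_baseline_cycles]))
    plateau = float(f.max())
    signal = plateau - baseline
    if plateau <= 0 or signal <= cfg.signal_floor_frac * max(abs(plateau), 1e-12):
        raise NoAmplificationError("curve shows no amplification")

    fb = f - baseline
    # a curve still rising at its end has not reached the plateau; only a
    # saturated curve gets the exact logistic linearization below
    tail_rise = float(np.mean(fb[-2:]) - np.mean(fb[-7:-5]))
    saturated = tail_rise < 0.05 * signal
    if saturated:
        # noise-robust plateau: the max alone rides on the noise peak
        signal = float(np.mean(fb[-3:]))
    frac = fb / signal

    in_region = (frac >= cfg.low_frac) & (frac <= cfg.high_frac)
    candidates = np.flatnonzero(in_region)
    if candidates.size == 0:
        raise NoAmplificationError("no cycles inside the exponential-phase bounds")

    # contiguous runs of candidate cycles
    runs: list[np.ndarray] = []
    start = candidates[0]
    prev = candidates[0]
    for c in candidates[1:]:
        if c != prev + 1:
            runs.append(np.arange(start, prev + 1))
            start = c
        prev = c
    runs.append(np.arange(start, prev + 1))

    windows: list[np.ndarray] = []
    for run in runs:
        if len(run) >= cfg.window:
            for i in range(len(run) - cfg.window + 1):
                windows.append(run[i : i + cfg.window])
    short_fallback = False
    if not windows:
        longest = max(runs, key=len)
        if len(longest) < 3:
            raise NoAmplificationError("exponential phase too short to fit")
        windows = [longest]
        short_fallback = True

    if saturated and cfg.saturation_correction:
        # exact linearization of a logistic: F/(P - F) grows as (1+E)^cycle
        y_all = np.log10(
            np.clip(fb, 1e-12, None) / np.clip(1.0 - frac, 1e-12, None)
        )
    else:
        y_all = np.log10(np.clip(fb, 1e-12, None))

    best = None
    for w in windows:
        y = y_all[w]
        x = w.astype(float)
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
        if best is None or r2 > best[0]:
            best = (r2, slope, w)
    r2, slope, w = best
    eff = 10.0**slope - 1.0
    clamped = False
    if not (0.0 < eff <= 1.1):
        eff = min(max(eff, 1e-6), 1.1)
        clamped = True
    return EfficiencyEstimate(
        efficiency=float(eff),
        r_squared=float(r2),
        window_start_cycle=int(w[0]) + 1,
        window=len(w),
        low_confidence=bool(r2 < cfg.r2_threshold or short_fallback),
        clamped=clamped,
    )


def assay_efficiency(well_efficiencies) -> float:
    """E_fi: the mean of the individual per-well efficiencies of an assay."""
    e = np.asarray(list(well_efficiencies), dtype=float)
    if e.size == 0:
        raise ValueError("no per-well efficiencies supplied")
    if np.any((e <= 0) | (e > 1.1)):
        raise ValueError("per-well efficiencies must lie in (0, 1.1]")
    return float(e.mean())


# --------------------------------------------------------------------------
# Cq adjustment and replicate rules
# --------------------------------------------------------------------------

def adjust_cq(raw_cq, e_fi: float):
    """Efficiency-adjusted Cq = Cq * log10(E_fi + 1) / log10(2).

    The identity when E_fi = 1 (perfect doubling); for lower efficiencies the
    raw cycle count is shrunk onto the base-2-equivalent scale.
    """
    if not 0.0 < e_fi <= 1.1:
        raise ValueError(f"E_fi must lie in (0, 1.1], got {e_fi}")
    factor = math.log10(e_fi + 1.0) / math.log10(2.0)
    return np.asarray(raw_cq, dtype=float) * factor if np.ndim(raw_cq) else float(raw_cq) * factor


def filter_technical_replicates(values, sd_limit: float = 0.5):
    """Apply the 0.5-cycle SD rule to one adjusted-Cq quadruplicate.

    Returns ``(keep_mask, flag)`` where flag is None (all kept),
    ``("technical_replicate_removed", index)`` or ``("unresolved_sd", None)``
    when no single removal brings the SD within the limit (the caller then
    falls back on the cDNA-duplicate rule).
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (4,):
        raise ValueError("expected exactly 4 quadruplicate values")
    keep = np.ones(4, dtype=bool)
    if np.std(v, ddof=1) <= sd_limit:
        return keep, None
    loo_sd = np.array([np.std(np.delete(v, i), ddof=1) for i in range(4)])
    i = int(np.argmin(loo_sd))
    if loo_sd[i] <= sd_limit:
        keep[i] = False
        return keep, ("technical_replicate_removed", i)
    return keep, ("unresolved_sd", None)


def reconcile_cdna_duplicates(
    mean1: float,
    mean2: float,
    cohort_mean: float | None,
    diff_limit: float = 1.0,
):
    """Apply the one-cycle cDNA-duplicate rule.

    If the two cDNA-replicate means agree within ``diff_limit`` both are
    kept (consensus = their mean); otherwise the replicate deviating more
    from the assay's cohort-wide mean is dropped, ties dropping replicate 2.

    Returns ``(consensus, kept_replicates, flag)``.
    """
    if abs(mean1 - mean2) <= diff_limit:
        return (mean1 + mean2) / 2.0, (1, 2), None
    if cohort_mean is None:
        raise ValueError(
            "cDNA duplicates disagree by more than the limit but no cohort "
            "mean is available; supply the assay's sample-cohort mean"
        )
    d1, d2 = abs(mean1 - cohort_mean), abs(mean2 - cohort_mean)
    if d1 > d2:
        return mean2, (2,), ("cdna_replicate_removed", 1)
    if d2 > d1:
        return mean1, (1,), ("cdna_replicate_removed", 2)
    return mean1, (1,), ("cdna_replicate_removed_tie", 2)


@dataclass
class CqSummary:
    sample: str
    assay: str
    consensus_cq: float        # efficiency-adjusted, base-2-equivalent cycles
    n_wells_used: int
    flags: list = field(default_factory=list)


def summarize_cq(
    wells: pd.DataFrame,
    efficiencies: dict[str, float],
    sd_limit: float = 0.5,
    cdna_diff_limit: float = 1.0,
) -> pd.DataFrame:
    """Consensus efficiency-adjusted Cq per sample x assay with a flag trail.

    ``wells`` is the long-format table (sample, assay, cdna_rep, qpcr_rep,
    cq); ``efficiencies`` maps assay -> E_fi.  The cohort-wide mean used by
    the cDNA rule is the mean adjusted Cq over all wells of the assay.
    """
    required = {"sample", "assay", "cdna_rep", "qpcr_rep", "cq"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"well table missing columns: {sorted(missing)}")
    df = wells.copy()
    df["adj_cq"] = [
        adjust_cq(cq, efficiencies[assay]) for cq, assay in zip(df["cq"], df["assay"])
    ]
    cohort_means = df.groupby("assay")["adj_cq"].mean().to_dict()

    out = []
    for (sample, assay), grp in df.groupby(["sample", "assay"], sort=True):
        flags: list = []
        vals = grp.sort_values(["cdna_rep", "qpcr_rep"])
        v = vals["adj_cq"].to_numpy()
        reps = vals["cdna_rep"].to_numpy()
        if len(v) == 4:
            keep, flag = filter_technical_replicates(v, sd_limit=sd_limit)
            if flag is not None:
                flags.append(flag)
            if flag is not None and flag[0] == "technical_replicate_removed":
                v, reps = v[keep], reps[keep]
        else:
            flags.append(("missing_wells", int(4 - len(v))))
        means = {r: v[reps == r].mean() for r in np.unique(reps)}
        if len(means) == 2:
            m1, m2 = means[sorted(means)[0]], means[sorted(means)[1]]
            consensus, kept, flag = reconcile_cdna_duplicates(
                m1, m2, cohort_means[assay], diff_limit=cdna_diff_limit
            )
            if flag is not None:
                flags.append(flag)
            n_used = int(np.sum([np.sum(reps == sorted(means)[k - 1]) for k in kept]))
        else:
            consensus = float(np.mean(v))
            n_used = len(v)
        out.append(
            CqSummary(str(sample), str(assay), float(consensus), n_used, flags)
        )
    return pd.DataFrame(
        {
            "sample": [s.sample for s in out],
            "assay": [s.assay for s in out],
            "consensus_cq": [s.consensus_cq for s in out],
            "n_wells_used": [s.n_wells_used for s in out],
            "flags": [s.flags for s in out],
        }
    )


def check_minus_rt(
    cq_plus_rt: float,
    cq_minus_rt: float | None,
    min_dcq: float = 5.0,
) -> bool:
    """Genomic-DNA contamination guard.

    Passes iff the minus-RT control shows no amplification (``None``) or its
    efficiency-adjusted Cq trails the +RT reaction by at least ``min_dcq``
    cycles.
    """
    if cq_minus_rt is None:
        return True
    return (cq_minus_rt - cq_plus_rt) >= min_dcq


# --------------------------------------------------------------------------
# absolute quantification
# --------------------------------------------------------------------------

@dataclass
class DpcrResult:
    total_partitions: int
    positive_partitions: int
    partition_volume_ul: float
    lam: float                  # mean copies per partition
    concentration_per_ul: float
    copies_in_reaction: float


def dpcr_concentration(
    positive: int, total: int, partition_volume_ul: float
) -> DpcrResult:
    """Poisson partition statistics: lambda = -ln(1 - positive/total)."""
    if not 0 <= positive <= total or total <= 0:
        raise ValueError("need 0 <= positive <= total with total > 0")
    if partition_volume_ul <= 0:
        raise ValueError("partition volume must be positive")
    if positive == total:
        raise DpcrSaturationError(
            "all partitions positive: above the dynamic range, dilute and rerun"
        )
    lam = -math.log(1.0 - positive / total)
    return DpcrResult(
        total_partitions=int(total),
        positive_partitions=int(positive),
        partition_volume_ul=float(partition_volume_ul),
        lam=lam,
        concentration_per_ul=lam / partition_volume_ul,
        copies_in_reaction=lam * total,
    )


def cq_to_copies(cq_sample, cq_calibrator: float, calibrator_copies: float):
    """Translate adjusted Cq into copies via a dPCR-counted calibrator.

    copies = calibrator_copies * 2^(Cq_cal - Cq_sample); both Cq values must
    already be efficiency-adjusted (base-2 scale).
    """
    if calibrator_copies <= 0:
        raise ValueError("calibrator copies must be positive")
    return calibrator_copies * np.power(2.0, cq_calibrator - np.asarray(cq_sample, dtype=float))
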