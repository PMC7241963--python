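"""Synthetic study-condition generators with known ground truth.

Every input the pipeline consumes can be generated here: exon count tables
with designed per-gene CV structure and splicing perturbations, replicated
Cq datasets with known per-assay efficiency and injectable outliers,
sigmoid amplification curves, forward-modelled DAB/haematoxylin section
images, and coupled copies-vs-qIHC cohorts with a known logit-linear link.
All generators are deterministic for a given seed and return the generative
truth alongside the data, so noise-free output pushed through the analysis
modules must recover the designed parameters.

The defaults emulate the study conditions this pipeline was built around:
cohorts of 7-15 osteosarcoma samples, 2 cDNA x 2 qPCR replicates, 50-cycle
runs, transcript abundances spanning about two decades, and qIHC scores in
the low-proportion regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .qihc import StainVectors


@dataclass
class SyntheticTruth:
    """Generative parameters realized by a synthetic dataset."""

    seed: int
    cv_targets: dict = field(default_factory=dict)        # gene -> designed CV
    stable_genes: list = field(default_factory=list)
    perturbed_exons: dict = field(default_factory=dict)   # gene -> exon index
    efficiencies: dict = field(default_factory=dict)      # assay -> E_true
    copies: dict = field(default_factory=dict)            # sample -> true copies
    outlier_wells: list = field(default_factory=list)     # (sample, assay, cdna, qpcr)
    outlier_cdna: list = field(default_factory=list)      # (sample, assay, cdna)
    link_alpha: float | None = None
    link_beta: float | None = None
    link_eps_sd: float | None = None
    p_true: float | None = None
    extra: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# exon counts
# --------------------------------------------------------------------------

def gen_exon_counts(
    n_genes: int = 200,
    exons_per_gene_range: tuple[int, int] = (3, 10),
    n_samples: int = 10,
    stable_fraction: float = 0.1,
    cv_low: float = 0.12,
    cv_high: float = 0.8,
    splice_perturb_rate: float = 0.0,
    library_sizes=None,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Exon count table with designed per-gene expression CV.

    Gene abundance across samples is log-normal with sigma set from the
    target CV (CV^2 = exp(sigma^2) - 1); exon counts distribute the gene
    abundance over exons proportionally to length, with Poisson noise.
    With probability ``splice_perturb_rate`` a gene (of >= 3 exons) gets a
    per-sample Beta(2, 2) inclusion factor on one interior exon, emulating
    an alternative-splicing event that destabilizes that single exon while
    constitutive neighbour pairs stay stable.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    if not 0.0 <= stable_fraction <= 1.0:
        raise ValueError("stable_fraction must lie in [0, 1]")
    if not 0.0 < cv_low < cv_high:
        raise ValueError("need 0 < cv_low < cv_high")
    if not 0.0 <= splice_perturb_rate <= 1.0:
        raise ValueError("splice_perturb_rate must lie in [0, 1]")
    lo, hi = exons_per_gene_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid exons_per_gene_range")

    rng = np.random.default_rng(seed)
    samples = [f"S{j + 1:02d}" for j in range(n_samples)]
    if library_sizes is None:
        library_sizes = np.full(n_samples, 20.0)  # depth scale, counts per kb-abundance
    else:
        library_sizes = np.broadcast_to(
            np.asarray(library_sizes, dtype=float), (n_samples,)
        ).copy()

    n_stable = int(round(stable_fraction * n_genes))
    stable_idx = set(rng.choice(n_genes, size=n_stable, replace=False).tolist())

    truth = SyntheticTruth(seed=seed)
    rows = []
    for g in range(n_genes):
        gene = f"G{g + 1:04d}"
        k = int(rng.integers(lo, hi + 1))
        lengths = rng.integers(100, 301, size=k)
        base = 10.0 ** rng.uniform(2.5, 3.5)
        cv = cv_low if g in stable_idx else cv_high
        sigma = np.sqrt(np.log1p(cv * cv))
        abund = base * rng.lognormal(-sigma * sigma / 2.0, sigma, size=n_samples)
        truth.cv_targets[gene] = cv
        if g in stable_idx:
            truth.stable_genes.append(gene)

        inclusion = np.ones((k, n_samples))
        if k >= 3 and rng.random() < splice_perturb_rate:
            e_pert = int(rng.integers(2, k))  # interior exon, 1-based in 2..k-1
            inclusion[e_pert - 1] = rng.beta(2.0, 2.0, size=n_samples)
            truth.perturbed_exons[gene] = e_pert

        for e in range(k):
            expected = abund * (lengths[e] / 1000.0) * library_sizes * inclusion[e]
            counts = rng.poisson(expected)
            rows.append(
                [gene, e + 1, int(lengths[e])] + counts.tolist()
            )
    table = pd.DataFrame(
        rows, columns=["gene_id", "exon_index", "exon_length"] + samples
    )
    return table, truth


# --------------------------------------------------------------------------
# Cq datasets
# --------------------------------------------------------------------------

def gen_cq_dataset(
    true_copies: dict[str, float] | pd.Series,
    assays_with_e: dict[str, float],
    intercepts: dict[str, float],
    noise_sd: float = 0.05,
    cdna_effect_sd: float = 0.1,
    outlier_rate_tech: float = 0.0,
    outlier_rate_cdna: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Long-format CqWell table: 2 cDNA x 2 qPCR replicates per sample x assay.

    Cq = intercept - log_(1+E)(copies) + cDNA effect + well noise.  With the
    stated rates a single well is shifted by 2.5 cycles (trips the 0.5-cycle
    SD rule) or a whole cDNA replicate by 2 cycles (trips the 1-cycle rule);
    the truth records every injected outlier.
    """
    copies = pd.Series(true_copies, dtype=float)
    if (copies <= 0).any():
        raise ValueError("true copies must be positive")
    for assay, e in assays_with_e.items():
        if not 0.0 < e <= 1.1:
            raise ValueError(f"efficiency of {assay} outside (0, 1.1]: {e}")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(
        seed=seed,
        efficiencies=dict(assays_with_e),
        copies=copies.to_dict(),
    )
    rows = []
    for sample, n_copies in copies.items():
        for assay, e in assays_with_e.items():
            base = intercepts[assay] - np.log(n_copies) / np.log(1.0 + e)
            tech_out = rng.random() < outlier_rate_tech
            cdna_out = rng.random() < outlier_rate_cdna
            tech_well = (
                (int(rng.integers(1, 3)), int(rng.integers(1, 3))) if tech_out else None
            )
            bad_cdna = int(rng.integers(1, 3)) if cdna_out else None
            for cdna in (1, 2):
                effect = rng.normal(0.0, cdna_effect_sd)
                for qpcr in (1, 2):
                    cq = base + effect + rng.normal(0.0, noise_sd)
                    if tech_well == (cdna, qpcr):
                        cq += 2.5
                        truth.outlier_wells.append((sample, assay, cdna, qpcr))
                    if bad_cdna == cdna:
                        cq += 2.0
                    rows.append([sample, assay, cdna, qpcr, cq])
            if bad_cdna is not None:
                truth.outlier_cdna.append((sample, assay, bad_cdna))
    wells = pd.DataFrame(
        rows, columns=["sample", "assay", "cdna_rep", "qpcr_rep", "cq"]
    )
    return wells, truth


# --------------------------------------------------------------------------
# amplification curves
# --------------------------------------------------------------------------

def gen_amp_curves(
    e_true,
    cq_true,
    baseline: float = 50.0,
    plateau: float = 30000.0,
    noise_sd: float = 0.0,
    n_cycles: int = 45,
    threshold_frac: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Raw sigmoid amplification curves with known efficiency.

    Signal follows the logistic F(c) = plateau / (1 + B (1+E)^-c) with B
    fixed so the curve crosses ``threshold_frac`` of the plateau at
    ``cq_true``; early-phase successive signal ratios equal 1 + E.  A
    plateau of 0 produces a flat (non-amplifying) baseline trace.
    ``e_true``/``cq_true`` may be arrays to emit a set of wells.
    """
    e_arr, cq_arr = np.broadcast_arrays(
        np.atleast_1d(np.asarray(e_true, dtype=float)),
        np.atleast_1d(np.asarray(cq_true, dtype=float)),
    )
    if np.any((e_arr <= 0) | (e_arr > 1.1)):
        raise ValueError("efficiencies must lie in (0, 1.1]")
    if plateau > 0 and np.any((cq_arr < 1) | (cq_arr >= n_cycles)):
        raise ValueError("cq_true must lie in [1, n_cycles)")
    rng = np.random.default_rng(seed)
    cycles = np.arange(1, n_cycles + 1, dtype=float)
    curves = []
    for e, cq in zip(e_arr.ravel(), cq_arr.ravel()):
        if plateau <= 0:
            signal = np.zeros(n_cycles)
        else:
            b = (1.0 / threshold_frac - 1.0) * (1.0 + e) ** cq
            signal = plateau / (1.0 + b * (1.0 + e) ** (-cycles))
        f = baseline + signal + rng.normal(0.0, noise_sd, size=n_cycles)
        curves.append(f)
    wells = [f"W{i + 1:03d}" for i in range(len(curves))]
    df = pd.DataFrame(
        curves, index=pd.Index(wells, name="well"),
        columns=[f"F_cycle{c}" for c in range(1, n_cycles + 1)],
    )
    truth = SyntheticTruth(
        seed=seed,
        efficiencies={w: float(e) for w, e in zip(wells, e_arr.ravel())},
        extra={"cq_true": {w: float(c) for w, c in zip(wells, cq_arr.ravel())},
               "baseline": baseline, "plateau": plateau},
    )
    return df, truth


# --------------------------------------------------------------------------
# IHC images
# --------------------------------------------------------------------------

def gen_ihc_image(
    shape: tuple[int, int] = (256, 256),
    tissue_mask: np.ndarray | None = None,
    p_true: float = 0.3,
    n_speckles_small: int = 0,
    stain_vectors: StainVectors | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    dab_concentration: float = 0.9,
    hematoxylin_concentration: float = 0.4,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Forward-modelled 8-bit RGB DAB/haematoxylin section image.

    Beer-Lambert synthesis: RGB = od_to_rgb(C_dab V_dab + C_hem V_hem) —
    the exact inverse of the deconvolution used in scoring.  A compact DAB-
    positive region covers fraction ``p_true`` of the tissue; speckles are
    3x3 blocks (9 px, below the 15 um^2 particle threshold at 1 um/px)
    scattered outside it.  Non-tissue pixels are near-white.
    """
    if not 0.0 <= p_true <= 1.0:
        raise ValueError("p_true must lie in [0, 1]")
    stains = stain_vectors or StainVectors.h_dab()
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    if tissue_mask is None:
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        tissue_mask = (
            ((yy - cy) / (0.42 * h)) ** 2 + ((xx - cx) / (0.42 * w)) ** 2
        ) <= 1.0
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    n_tissue = int(tissue_mask.sum())
    if n_tissue == 0:
        raise ValueError("tissue mask is empty")

    # compact positive region: the n_pos tissue pixels closest to the centroid
    n_pos = int(round(p_true * n_tissue))
    positive = np.zeros(shape, dtype=bool)
    if n_pos > 0:
        ty, tx = np.nonzero(tissue_mask)
        d2 = (ty - ty.mean()) ** 2 + (tx - tx.mean()) ** 2
        order = np.argsort(d2, kind="stable")[:n_pos]
        positive[ty[order], tx[order]] = True

    # sub-particle speckles outside the positive region
    speckle = np.zeros(shape, dtype=bool)
    if n_speckles_small > 0:
        forbidden = positive.copy()
        # keep speckles clear of the main region and one another
        margin = 4
        placed = 0
        cand_y, cand_x = np.nonzero(tissue_mask)
        perm = rng.permutation(len(cand_y))
        for idx in perm:
            if placed >= n_speckles_small:
                break
            y, x = int(cand_y[idx]), int(cand_x[idx])
            y0, y1 = max(y - 1, 0), min(y + 2, h)
            x0, x1 = max(x - 1, 0), min(x + 2, w)
            fy0, fy1 = max(y - margin, 0), min(y + margin + 1, h)
            fx0, fx1 = max(x - margin, 0), min(x + margin + 1, w)
            if forbidden[fy0:fy1, fx0:fx1].any():
                continue
            block = np.zeros(shape, dtype=bool)
            block[y0:y1, x0:x1] = tissue_mask[y0:y1, x0:x1]
            if block.sum() == 0 or block.sum() >= 15:
                continue
            speckle |= block
            forbidden[fy0:fy1, fx0:fx1] = True
            placed += 1
        if placed < n_speckles_small:
            raise ValueError(
                f"could only place {placed}/{n_speckles_small} speckles; "
                "use a larger image or fewer speckles"
            )

    c_dab = np.where(positive | speckle, dab_concentration, 0.0)
    c_hem = np.where(tissue_mask, hematoxylin_concentration, 0.0)
    od = (
        c_dab[..., None] * stains.dab[None, None, :]
        + c_hem[..., None] * stains.hematoxylin[None, None, :]
    )
    img = 256.0 * np.power(10.0, -od) - 1.0
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    truth = SyntheticTruth(
        seed=seed,
        p_true=n_pos / n_tissue,
        extra={
            "tissue_mask": tissue_mask,
            "positive_mask": positive,
            "speckle_mask": speckle,
            "requested_p_true": p_true,
        },
    )
    return img, truth


# --------------------------------------------------------------------------
# coupled copies <-> qIHC cohorts
# --------------------------------------------------------------------------

def gen_coupled_dataset(
    n_samples: int = 13,
    alpha: float = -8.0,
    beta: float = 1.5,
    eps_sd: float = 0.4,
    copies_range_log10: tuple[float, float] = (3.0, 5.0),
    seed: int = 0,
) -> tuple[pd.Series, pd.Series, SyntheticTruth]:
    """Copies and qIHC proportions linked by logit(p) = a + b log10(copies) + eps.

    Defaults put the cohort in the study's regime: 13 samples, copies over
    about two decades, proportions mostly below one half.
    """
    if n_samples < 5:
        raise ValueError("need at least 5 samples")
    lo, hi = copies_range_log10
    if not hi > lo:
        raise ValueError("copies range must span more than 0 decades")
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    rng = np.random.default_rng(seed)
    samples = [f"S{j + 1:02d}" for j in range(n_samples)]
    log_copies = rng.uniform(lo, hi, size=n_samples)
    copies = pd.Series(10.0**log_copies, index=samples, name="copies")
    eta = alpha + beta * log_copies + rng.normal(0.0, eps_sd, size=n_samples)
    proportions = pd.Series(expit(eta), index=samples, name="proportion")
    truth = SyntheticTruth(
        seed=seed,
        copies=copies.to_dict(),
        link_alpha=alpha,
        link_beta=beta,
        link_eps_sd=eps_sd,
    )
    return copies, proportions, truth


def gen_normalizer_benchmark(
    n_samples: int = 13,
    nuisance_sd_log2: float = 0.5,
    alpha: float = -9.0,
    beta: float = 2.0,
    eps_sd: float = 0.1,
    copies_range_log10: tuple[float, float] = (3.25, 4.75),
    seed: int = 0,
):
    """Coupled cohort plus candidate normalizers for readout benchmarking.

    Measured target copies are the true copies times a shared log-normal
    technical nuisance (SD ``nuisance_sd_log2`` log2 units, emulating
    input-mass variation).  Candidates: ``norm_true`` tracks the nuisance
    (a well-behaved reference gene, small residual noise) and
    ``noise_gene`` is an equally variable but independent gene.
    Returns (measured copies, candidates dict, proportions, truth).
    """
    rng = np.random.default_rng(seed)
    copies, proportions, truth = gen_coupled_dataset(
        n_samples=n_samples,
        alpha=alpha,
        beta=beta,
        eps_sd=eps_sd,
        copies_range_log10=copies_range_log10,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    n = len(copies)
    nuisance = np.power(2.0, rng.normal(0.0, nuisance_sd_log2, size=n))
    measured = copies * nuisance
    measured.name = "measured_copies"
    candidates = {
        "norm_true": pd.Series(
            nuisance * np.power(2.0, rng.normal(0.0, 0.05, size=n)),
            index=copies.index,
        ),
        "noise_gene": pd.Series(
            np.power(2.0, rng.normal(0.0, nuisance_sd_log2, size=n)),
            index=copies.index,
        ),
    }
    truth.extra.update(
        {"nuisance": pd.Series(nuisance, index=copies.index), "true_copies": copies}
    )
    return measured, candidates, proportions, truth


def gen_variant_copies(
    n_samples: int = 13,
    shares: tuple[float, ...] = (0.95, 0.025, 0.025),
    total_range_log10: tuple[float, float] = (3.0, 5.0),
    share_jitter_log2: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Co-expressed transcript-variant copy numbers with designed shares.

    A common per-sample total (log-uniform) is split across variants by the
    given mean shares with mild log-normal jitter, emulating one major and
    several minor variants transcribed from the same promoter.
    """
    if abs(sum(shares) - 1.0) > 1e-9:
        raise ValueError("shares must sum to 1")
    rng = np.random.default_rng(seed)
    samples = [f"S{j + 1:02d}" for j in range(n_samples)]
    total = 10.0 ** rng.uniform(*total_range_log10, size=n_samples)
    names = [chr(ord("a") + i) for i in range(len(shares))]
    data = {}
    for name, share in zip(names, shares):
        jitter = np.power(2.0, rng.normal(0.0, share_jitter_log2, size=n_samples))
        data[name] = total * share * jitter
    df = pd.DataFrame(data, index=samples)
    truth = SyntheticTruth(seed=seed, extra={"shares": dict(zip(names, shares)),
                                             "total": pd.Series(total, index=samples)})
    return df, truth
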