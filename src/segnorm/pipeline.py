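"""End-to-end workflow: simulate a coherent study bundle and run every stage.

``simulate_bundle`` writes, for one synthetic cohort, everything the real
study measured: an exon count table, raw amplification curves and Cq wells
for four reference assays plus the target assay, a dPCR chip count for the
calibrator sample, and one stained-section image per sample.  Two of the
reference assays (REFA, REFB) are designed to track the shared technical
nuisance that corrupts the target measurement, one tracks it loosely
(REFC) and one is independent noise (REFD) — so the designed best
normalizer is known.

``run_pipeline`` executes the stages in order on such a bundle: exon CV
ranking -> efficiency estimation and Cq consensus -> four stability
algorithms -> consensus rank aggregation -> normalization-factor
composition -> dPCR-calibrated copy counting -> qIHC scoring -> the
mRNA-protein correlation readout that picks the final normalizer.  Every
intermediate table is written with a provenance header and every removal
is audited.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import exons, qihc, qpcr, rankaggr, readout, stability, synthetic
from .config import PipelineConfig
from .io import (
    AuditLog,
    read_cq_table,
    read_curves,
    read_exon_counts,
    read_image,
    read_table,
    write_image,
    write_table,
)

REFERENCE_ASSAYS = ("REFA", "REFB", "REFC", "REFD")
TARGET_ASSAY = "S100A4"


def simulate_bundle(
    out_dir: str | Path,
    n_samples: int = 13,
    seed: int = 0,
    config: PipelineConfig | None = None,
    image_shape: tuple[int, int] = (192, 192),
) -> dict:
    """Write a complete synthetic study bundle; returns the ground truth."""
    cfg = config or PipelineConfig(seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    h = cfg.config_hash()

    # --- exon-level RNA-seq arm ---------------------------------------
    exon_table, exon_truth = synthetic.gen_exon_counts(
        n_genes=150, n_samples=10, stable_fraction=0.1,
        splice_perturb_rate=0.2, seed=int(rng.integers(2**31 - 1)),
    )
    write_table(exon_table, out / "exon_counts.tsv", h, seed)

    # --- cohort: true copies, nuisance, reference genes ----------------
    # strong shared technical nuisance: in this regime input-mass
    # normalization visibly degrades the mRNA-protein correlation
    measured, candidates, proportions, bench_truth = synthetic.gen_normalizer_benchmark(
        n_samples=n_samples, nuisance_sd_log2=1.2, eps_sd=0.2,
        seed=int(rng.integers(2**31 - 1)),
    )
    samples = list(measured.index)
    nuisance = bench_truth.extra["nuisance"]
    ref_abundance = {
        "REFA": candidates["norm_true"],
        "REFB": nuisance * np.power(2.0, rng.normal(0.0, 0.08, n_samples)),
        "REFC": nuisance * np.power(2.0, rng.normal(0.0, 0.35, n_samples)),
        "REFD": candidates["noise_gene"],
    }

    efficiencies = {a: float(e) for a, e in zip(
        REFERENCE_ASSAYS + (TARGET_ASSAY,), (0.95, 0.90, 1.0, 0.85, 0.92)
    )}
    intercepts = {a: 35.0 for a in efficiencies}

    # reference-assay Cq wells (relative quantities scaled to copy-like units)
    ref_frames = []
    for assay in REFERENCE_ASSAYS:
        wells, _ = synthetic.gen_cq_dataset(
            ref_abundance[assay] * 1e4,
            {assay: efficiencies[assay]},
            intercepts,
            noise_sd=0.05,
            cdna_effect_sd=0.05,
            seed=int(rng.integers(2**31 - 1)),
        )
        ref_frames.append(wells)
    write_table(pd.concat(ref_frames, ignore_index=True), out / "cq_reference.csv", h, seed)

    target_wells, _ = synthetic.gen_cq_dataset(
        measured,
        {TARGET_ASSAY: efficiencies[TARGET_ASSAY]},
        intercepts,
        noise_sd=0.05,
        cdna_effect_sd=0.05,
        seed=int(rng.integers(2**31 - 1)),
    )
    write_table(target_wells, out / "cq_target.csv", h, seed)

    # amplification curves: 4 wells per assay at the assay's true efficiency
    curve_frames = []
    for assay, e in efficiencies.items():
        curves, _ = synthetic.gen_amp_curves(
            [e] * 4, rng.uniform(22, 28, 4), noise_sd=30.0,
            seed=int(rng.integers(2**31 - 1)),
        )
        curves.index = [f"{assay}:{i + 1}" for i in range(len(curves))]
        curve_frames.append(curves)
    curves_df = pd.concat(curve_frames)
    curves_df.index.name = "well"
    write_table(curves_df.reset_index(), out / "curves.csv", h, seed)

    # dPCR chip for the calibrator (the cohort's highest expressor)
    calibrator = measured.idxmax()
    total_partitions = 20000
    # dilute onto the chip so the mean occupancy sits in the Poisson sweet spot
    dilution = float(measured[calibrator]) / (0.8 * total_partitions)
    lam = float(measured[calibrator]) / dilution / total_partitions
    positives = int(rng.binomial(total_partitions, 1.0 - np.exp(-lam)))
    dpcr = pd.DataFrame(
        {
            "chip": ["chip1"],
            "sample": [calibrator],
            "positive": [positives],
            "total": [total_partitions],
            "partition_volume_ul": [0.000809],
            "dilution_factor": [dilution],
        }
    )
    write_table(dpcr, out / "dpcr.csv", h, seed)

    # qIHC sections, one per sample
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    realized_p = {}
    for sample in samples:
        img, t = synthetic.gen_ihc_image(
            shape=image_shape, p_true=float(proportions[sample]),
            noise_sd=2.0, seed=int(rng.integers(2**31 - 1)),
        )
        write_image(img, img_dir / f"{sample}.tiff")
        realized_p[sample] = t.p_true

    truth = {
        "seed": seed,
        "designed_normalizers": ["REFA", "REFB"],
        "efficiencies": efficiencies,
        "true_copies": {s: float(v) for s, v in bench_truth.extra["true_copies"].items()},
        "measured_copies": {s: float(v) for s, v in measured.items()},
        "proportions": {s: float(v) for s, v in proportions.items()},
        "realized_p": realized_p,
        "calibrator": str(calibrator),
        "stable_genes": exon_truth.stable_genes,
        "perturbed_exons": exon_truth.perturbed_exons,
    }
    (out / "truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=True))
    cfg.to_yaml(out / "config.yaml")
    return truth


def run_pipeline(
    in_dir: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Run every stage on a bundle directory; returns the result summary."""
    cfg = config or PipelineConfig()
    src = Path(in_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    audit = AuditLog()
    h = cfg.config_hash()
    results: dict = {}

    def need(name: str) -> Path:
        p = src / name
        if not p.exists():
            raise FileNotFoundError(f"stage input missing: {p}")
        return p

    # 1. exon CV ranking
    exon_table = read_exon_counts(need("exon_counts.tsv"))
    tpm = exons.compute_tpm(exon_table)
    ranked = exons.rank_by_cv(tpm, cv_max=cfg.cv_max)
    write_table(ranked, out / "ranked_combos.tsv", h, cfg.seed)
    results["n_ranked_combos"] = len(ranked)
    results["top_composition"] = exons.top_list_composition(
        ranked, min(100, len(ranked))
    )

    # 2. efficiencies from raw curves, Cq consensus
    curves = read_curves(need("curves.csv"))
    per_assay: dict[str, list[float]] = {}
    for well, row in curves.iterrows():
        assay = str(well).split(":")[0]
        try:
            est = qpcr.estimate_well_efficiency(row.to_numpy(), cfg.efficiency)
        except qpcr.NoAmplificationError:
            audit.add("efficiency", "no_amplification", well=str(well))
            continue
        per_assay.setdefault(assay, []).append(est.efficiency)
    e_fi = {a: qpcr.assay_efficiency(v) for a, v in per_assay.items()}
    results["assay_efficiencies"] = e_fi

    ref_wells = read_cq_table(need("cq_reference.csv"))
    summary = qpcr.summarize_cq(
        ref_wells, e_fi, sd_limit=cfg.replicate_sd_cycles,
        cdna_diff_limit=cfg.cdna_diff_cycles,
    )
    for _, r in summary.iterrows():
        audit.extend_flags("cq_consensus", r["sample"], r["assay"], r["flags"])
    write_table(summary.drop(columns="flags"), out / "cq_summary_reference.tsv", h, cfg.seed)

    # 3. stability algorithms
    quantities = stability.cq_to_quantity(summary)
    cq_matrix = summary.pivot(index="sample", columns="assay", values="consensus_cq")
    gres = stability.genorm(quantities, cutoff=cfg.genorm_cutoff)
    nf_res = stability.normfinder(quantities)
    bk_res = stability.bestkeeper(cq_matrix)
    dcq_res = stability.comparative_dcq(cq_matrix)
    rankings = pd.concat(
        [gres.ranking, nf_res, bk_res[["algorithm", "gene", "score", "rank"]], dcq_res],
        ignore_index=True,
    )
    write_table(rankings, out / "stability_rankings.tsv", h, cfg.seed)
    v_tab = gres.v_series.reset_index()
    write_table(v_tab, out / "genorm_v_series.tsv", h, cfg.seed)
    results["genorm_optimal_n"] = gres.optimal_n
    results["genorm_v_series"] = {int(n): float(v) for n, v in gres.v_series.items()}

    # 4. consensus rank aggregation
    lists = []
    for _, grp in rankings.groupby("algorithm"):
        lists.append({g: float(r) for g, r in zip(grp["gene"], grp["rank"])})
    agg = rankaggr.aggregate_ce_mc(lists, seed=cfg.seed)
    results["consensus_order"] = list(agg.order)
    results["consensus_objective"] = agg.objective
    (out / "consensus.yaml").write_text(yaml.safe_dump(agg.as_dict()))

    # 5. normalization factor from the top consensus genes
    n_nf = gres.optimal_n or 2
    nf_genes = list(agg.order[:n_nf])
    nf = stability.compose_nf(quantities, nf_genes)
    results["nf_genes"] = nf_genes

    # 6. dPCR-calibrated copies for the target
    target_wells = read_cq_table(need("cq_target.csv"))
    tsum = qpcr.summarize_cq(
        target_wells, e_fi, sd_limit=cfg.replicate_sd_cycles,
        cdna_diff_limit=cfg.cdna_diff_cycles,
    )
    for _, r in tsum.iterrows():
        audit.extend_flags("cq_consensus_target", r["sample"], r["assay"], r["flags"])
    dpcr = read_table(need("dpcr.csv"))
    d0 = dpcr.iloc[0]
    dres = qpcr.dpcr_concentration(
        int(d0["positive"]), int(d0["total"]), float(d0["partition_volume_ul"])
    )
    dilution = float(d0.get("dilution_factor", 1.0))
    calibrator_copies = dres.copies_in_reaction * dilution
    calibrator = str(d0["sample"])
    tcq = tsum.set_index("sample")["consensus_cq"]
    copies = pd.Series(
        qpcr.cq_to_copies(tcq.to_numpy(), float(tcq[calibrator]), calibrator_copies),
        index=tcq.index, name="copies",
    )
    write_table(copies.reset_index(), out / "target_copies.tsv", h, cfg.seed)
    results["calibrator_copies"] = calibrator_copies

    # 7. qIHC scoring
    img_dir = need("images")
    rows = []
    for img_path in sorted(Path(img_dir).glob("*.tif*")):
        res = qihc.score_section(read_image(img_path), config=cfg.qihc)
        if res.removed_particles:
            audit.add("qihc", "particles_removed", image=img_path.name,
                      count=res.removed_particles)
        rows.append({"sample": img_path.stem, "proportion": res.proportion,
                     "logit": res.logit, "tissue_px": res.tissue_area_px,
                     "positive_px": res.positive_area_px})
    qtab = pd.DataFrame(rows)
    write_table(qtab, out / "qihc_scores.csv", h, cfg.seed)
    proportions = qtab.set_index("sample")["proportion"]

    # 8. correlation readout over candidate normalizers
    genes = list(quantities.columns)
    candidates: dict[str, pd.Series] = {g: quantities[g] for g in genes}
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            pair = [genes[i], genes[j]]
            candidates["+".join(pair)] = stability.compose_nf(quantities, pair)
    # guard against zero/one proportions (logit needs the open interval)
    tissue_px = qtab.set_index("sample")["tissue_px"]
    eps = 1.0 / (2.0 * tissue_px.astype(float))
    proportions = proportions.clip(lower=eps, upper=1.0 - eps)
    evaluation = readout.evaluate_normalizers(copies, candidates, proportions)
    write_table(evaluation.table, out / "normalizer_evaluation.tsv", h, cfg.seed)
    results["best_normalizer"] = evaluation.best
    results["best_rho"] = float(evaluation.table.iloc[0]["spearman_rho"])
    results["nf_value_head"] = float(nf.iloc[0])

    audit.write(out / "audit.jsonl")
    return results
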