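"""Pipeline configuration.

Every threshold the workflow applies lives here with the study's published
value as default, so that no stage hard-codes a constant and a full run is
reproducible from the serialized config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class EfficiencyConfig:
    """Windowed log-linear fit on the exponential phase of a raw curve.

    window: number of consecutive cycles fitted per window.
    low_frac / high_frac: fractional-fluorescence bounds (relative to the
        baseline-subtracted plateau) delimiting the candidate region.
    r2_threshold: minimum R-squared of the best window before the estimate is
        flagged low-confidence.
    signal_floor_frac: minimum (plateau - baseline) relative to the plateau
        for the well to count as amplifying at all.
    n_baseline_cycles: early cycles used to estimate the baseline.
    saturation_correction: when the curve has visibly plateaued, fit
        log10(F / (P - F)) instead of log10(F) — the exact linearization of
        a logistic — so the upper exponential phase carries no
        saturation bias.
    """

    window: int = 5
    low_frac: float = 0.02
    high_frac: float = 0.90
    r2_threshold: float = 0.99
    signal_floor_frac: float = 0.05
    n_baseline_cycles: int = 5
    saturation_correction: bool = True


@dataclass
class QihcConfig:
    """Quantitative-IHC scoring knobs (defaults: the published protocol)."""

    background_threshold: float = 200.0   # 8-bit; whiter pixels = non-tissue
    dab_positive_threshold: float = 200.0  # 8-bit on the deconvolved DAB display channel
    min_particle_area_um2: float = 15.0
    resolution_um_per_px: float = 1.0
    bilateral_sigma_spatial: float = 3.0   # px
    bilateral_sigma_range: float = 25.0    # 8-bit intensity units


@dataclass
class PipelineConfig:
    """All thresholds of the workflow, defaults as published."""

    cv_max: float = 1.0                 # exon-stability CV ceiling
    top_n_genes: int = 100              # GO-enrichment input list size
    go_fdr_cutoff: float = 0.01
    replicate_sd_cycles: float = 0.5    # technical-replicate SD trigger
    cdna_diff_cycles: float = 1.0       # cDNA-duplicate difference trigger
    minus_rt_min_dcq: float = 5.0       # genomic-DNA contamination guard
    genorm_cutoff: float = 0.15         # pairwise-variation V cutoff
    efficiency: EfficiencyConfig = field(default_factory=EfficiencyConfig)
    qihc: QihcConfig = field(default_factory=QihcConfig)
    seed: int = 0

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "efficiency" in d and isinstance(d["efficiency"], dict):
            d["efficiency"] = EfficiencyConfig(**d["efficiency"])
        if "qihc" in d and isinstance(d["qihc"], dict):
            d["qihc"] = QihcConfig(**d["qihc"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Stable short hash identifying this configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
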