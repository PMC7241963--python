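"""File dialects and the audit trail.

Tables travel as TSV/CSV with a single ``#``-prefixed provenance header
(config hash + seed) so that reruns with identical configuration produce
byte-identical files; images as 8-bit RGB TIFF/PNG; configuration as YAML;
the audit log as JSON lines, one record per data-altering decision.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from PIL import Image

EXON_META = ["gene_id", "exon_index", "exon_length"]
CQ_COLUMNS = ["sample", "assay", "cdna_rep", "qpcr_rep", "cq"]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    config_hash: str | None = None,
    seed: int | None = None,
    index: bool = False,
) -> Path:
    """Write a table with a provenance comment header."""
    path = Path(path)
    header = f"# segnorm config_hash={config_hash or 'none'} seed={seed if seed is not None else 'none'}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep=_sep_for(path), index=index)
    return path


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path), comment="#", **kwargs)


def read_exon_counts(path: str | Path) -> pd.DataFrame:
    """Validated exon count table (gene_id, exon_index, exon_length, samples)."""
    df = read_table(path)
    missing = [c for c in EXON_META if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: malformed header, missing columns {missing}")
    samples = [c for c in df.columns if c not in EXON_META]
    if not samples:
        raise ValueError(f"{path}: no sample columns")
    dup = df.duplicated(subset=["gene_id", "exon_index"])
    if dup.any():
        # +2: one for the header line, one for 0- vs 1-based
        lines = (df.index[dup] + 2).tolist()
        raise ValueError(f"{path}: duplicated (gene, exon) rows at data line(s) {lines}")
    neg = df[samples].lt(0)
    if neg.any().any():
        row = int(np.argwhere(neg.to_numpy())[0][0])
        raise ValueError(f"{path}: negative count at data line {row + 2}")
    if (df["exon_length"] <= 0).any():
        raise ValueError(f"{path}: non-positive exon length")
    return df


def read_cq_table(path: str | Path, cycle_limit: float = 50.0) -> pd.DataFrame:
    """Validated long-format Cq well table; warns about incomplete grids."""
    import warnings

    df = read_table(path)
    missing = [c for c in CQ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = ~((df["cq"] > 0) & (df["cq"] <= cycle_limit))
    if bad.any():
        raise ValueError(
            f"{path}: Cq outside (0, {cycle_limit}] at data line(s) "
            f"{(df.index[bad] + 2).tolist()}"
        )
    sizes = df.groupby(["sample", "assay"]).size()
    for (sample, assay), n in sizes.items():
        if n != 4:
            warnings.warn(
                f"{path}: sample {sample!r} assay {assay!r} has {n}/4 wells",
                stacklevel=2,
            )
    return df


def read_curves(path: str | Path) -> pd.DataFrame:
    """Wide fluorescence table: index well, columns F_cycle1..F_cycleN."""
    df = read_table(path)
    if "well" not in df.columns:
        raise ValueError(f"{path}: curve table needs a 'well' column")
    df = df.set_index("well")
    cyc = [c for c in df.columns if c.startswith("F_cycle")]
    if len(cyc) < 20:
        raise ValueError(f"{path}: need >= 20 cycle columns, found {len(cyc)}")
    return df[cyc]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Gene-to-GO-term table with columns gene_id, term_id."""
    df = read_table(path)
    for col in ("gene_id", "term_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: annotation needs column {col!r}")
    return df


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        img = tifffile.imread(str(path))
    else:
        img = np.asarray(Image.open(path).convert("RGB"))
    if img.dtype != np.uint8:
        raise ValueError(f"{path}: expected an 8-bit image")
    return img


def write_image(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(str(path), image)
    else:
        Image.fromarray(image).save(path)
    return path


@dataclass
class AuditLog:
    """Machine-readable trail of every data-altering decision."""

    records: list = field(default_factory=list)

    def add(self, stage: str, rule: str, **detail) -> None:
        self.records.append(
            {
                "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
                "stage": stage,
                "rule": rule,
                **detail,
            }
        )

    def extend_flags(self, stage: str, sample: str, assay: str, flags) -> None:
        for flag in flags:
            rule, detail = flag if isinstance(flag, tuple) else (flag, None)
            self.add(stage, str(rule), sample=sample, assay=assay, detail=detail)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec, default=str) + "\n")
        return path
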