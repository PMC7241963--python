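"""Quantitative immunohistochemistry: DAB proportion scoring.

A brightfield RGB section image is unmixed into stain concentrations by
colour deconvolution in optical-density space (Beer-Lambert), the DAB
channel is denoised with a bilateral filter, background is removed with an
8-bit intensity threshold, sub-particle components are dropped, and the
score is the fraction p of tissue area positive for DAB, reported together
with logit(p) = ln(p / (1 - p)) — the variance-stabilizing transform that
lets proportions near 0 or 1 enter linear models on an equal footing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.measure import label
from skimage.restoration import denoise_bilateral

from .config import QihcConfig

#: Ruifrok-Johnston optical-density unit vectors (R, G, B)
HEMATOXYLIN_OD = np.array([0.650, 0.704, 0.286])
DAB_OD = np.array([0.268, 0.570, 0.776])


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


@dataclass
class StainVectors:
    """Three OD unit vectors (rows): DAB, haematoxylin, residual."""

    dab: np.ndarray
    hematoxylin: np.ndarray
    residual: np.ndarray

    @classmethod
    def h_dab(cls) -> "StainVectors":
        """Standard H-DAB pair with an orthogonal residual third vector."""
        d, h = _unit(DAB_OD), _unit(HEMATOXYLIN_OD)
        return cls(dab=d, hematoxylin=h, residual=_unit(np.cross(d, h)))

    @property
    def matrix(self) -> np.ndarray:
        return np.stack([self.dab, self.hematoxylin, self.residual])

    def inverse(self) -> np.ndarray:
        m = self.matrix
        cond = np.linalg.cond(m)
        if not np.isfinite(cond) or cond > 1e8:
            raise ValueError(f"stain matrix is singular (condition number {cond:.3g})")
        return np.linalg.inv(m)


def rgb_to_od(image: np.ndarray) -> np.ndarray:
    """Optical density per channel: OD = -log10((I + 1) / 256).

    The +1 offset keeps OD finite at I = 0; pure white maps to OD ~ 0.
    """
    img = np.asarray(image)
    if img.dtype != np.uint8:
        raise ValueError("expected an 8-bit (uint8) RGB image")
    return -np.log10((img.astype(float) + 1.0) / 256.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`rgb_to_od` (before uint8 rounding)."""
    intensity = 256.0 * np.power(10.0, -np.asarray(od, dtype=float)) - 1.0
    return np.clip(np.round(intensity), 0, 255).astype(np.uint8)


def color_deconvolve(od_image: np.ndarray, stains: StainVectors) -> np.ndarray:
    """Unmix an OD image into per-stain concentration maps.

    Returns an array (..., 3) ordered (DAB, haematoxylin, residual);
    physically impossible negative concentrations are clipped to zero.
    """
    inv = stains.inverse()
    conc = np.asarray(od_image, dtype=float) @ inv
    return np.clip(conc, 0.0, None)


def dab_display_channel(concentration: np.ndarray) -> np.ndarray:
    """Render a DAB concentration map as the usual 8-bit display channel
    (255 = no stain, darker = more DAB)."""
    return od_to_rgb(np.clip(concentration, 0.0, None)).astype(float)


def logit_transform(p: float, n_tissue_px: int | None = None, policy: str = "clamp") -> float:
    """logit(p) = ln(p / (1 - p)) with a configurable boundary policy.

    At p = 0 or 1, ``clamp`` (default) pulls p to eps / 1 - eps with
    eps = 1 / (2 * n_tissue_px) — half a pixel of positive area — while
    ``raise`` refuses the degenerate score.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion must lie in [0, 1], got {p}")
    if p in (0.0, 1.0):
        if policy == "raise":
            raise ValueError(f"logit undefined at p = {p}")
        if n_tissue_px is None or n_tissue_px <= 0:
            raise ValueError("clamp policy needs the tissue pixel count")
        eps = 1.0 / (2.0 * n_tissue_px)
        p = eps if p == 0.0 else 1.0 - eps
    return math.log(p / (1.0 - p))


@dataclass
class QihcResult:
    tissue_area_px: int
    positive_area_px: int
    tissue_area_um2: float
    positive_area_um2: float
    proportion: float
    logit: float
    removed_particles: int


def score_section(
    image: np.ndarray,
    stains: StainVectors | None = None,
    config: QihcConfig | None = None,
) -> QihcResult:
    """Score one section: fraction of tissue area positive for DAB.

    Pipeline: tissue mask (mean 8-bit intensity at or below the background
    threshold — whiter pixels are slide background), colour deconvolution,
    bilateral filtering of the DAB display channel, DAB positivity (display
    intensity at or below the DAB threshold, i.e. darker than background),
    8-connected particle filter at ceil(min_area / resolution^2) pixels,
    then p = positive / tissue with the logit attached.
    """
    cfg = config or QihcConfig()
    stains = stains or StainVectors.h_dab()
    img = np.asarray(image)
    if img.dtype != np.uint8 or img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an 8-bit RGB image (H, W, 3)")

    tissue = img.mean(axis=2) <= cfg.background_threshold
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError("no tissue detected (every pixel whiter than background)")

    conc = color_deconvolve(rgb_to_od(img), stains)
    dab_display = dab_display_channel(conc[..., 0])
    if cfg.bilateral_sigma_spatial > 0:
        dab_display = 255.0 * denoise_bilateral(
            dab_display / 255.0,
            sigma_color=cfg.bilateral_sigma_range / 255.0,
            sigma_spatial=cfg.bilateral_sigma_spatial,
        )
    positive = (dab_display <= cfg.dab_positive_threshold) & tissue

    min_px = math.ceil(cfg.min_particle_area_um2 / cfg.resolution_um_per_px**2)
    labels, n_comp = label(positive, connectivity=2, return_num=True)
    removed = 0
    if n_comp:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_px)
        small = small[small != 0]
        if small.size:
            positive &= ~np.isin(labels, small)
            removed = int(small.size)

    n_pos = int(positive.sum())
    p = n_pos / n_tissue
    res2 = cfg.resolution_um_per_px**2
    return QihcResult(
        tissue_area_px=n_tissue,
        positive_area_px=n_pos,
        tissue_area_um2=n_tissue * res2,
        positive_area_um2=n_pos * res2,
        proportion=p,
        logit=logit_transform(p, n_tissue_px=n_tissue),
        removed_particles=removed,
    )
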