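"""Synthetic H-DAB histology generator with exact ground truth.

Emulates the structure of an immunostained tissue-microarray core: a
roughly circular tissue disc on white glass, blue-purple hematoxylin
nuclei, and diffuse brown stromal DAB with a controllable area fraction
and optical density.  A high DAB fraction emulates normal stroma, a low
fraction tumor stroma, so a synthetic cohort reproduces the
normal-versus-tumor contrast that the quantification pipeline measures.

The forward model is Beer-Lambert in base-10 OD: per-stain concentration
maps are mixed through a stain matrix and exponentiated to transmitted
8-bit intensities, which makes the generator an exact inverse of the
unmixing stage (up to quantization and noise).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .stains import StainMatrix, default_hdab_matrix, od_to_rgb

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "render_od_to_rgb",
    "generate_sample",
    "generate_cohort",
    "CohortSample",
]


class BlobPlacementError(RuntimeError):
    """Requested DAB fraction unreachable with the given blob count/geometry."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic H-DAB sample.

    Attributes
    ----------
    image_height, image_width : int
        Frame size in pixels.
    tissue_radius_fraction : float
        Tissue disc radius as a fraction of half the smaller frame side,
        in (0, 1].
    nucleus_count : int
        Number of elliptical hematoxylin-stained nuclei.
    nucleus_radius_px : float
        Mean nucleus semi-axis in pixels.
    hematoxylin_od : float
        Hematoxylin concentration inside nuclei (OD units, >= 0).
    tissue_background_od : float
        Faint uniform hematoxylin wash across the tissue disc; makes
        tissue visible against the glass, as eosin-free stroma is in
        real brightfield images.
    dab_target_fraction : float
        Fraction of tissue area carrying DAB, in [0, 1].
    dab_od : float
        DAB concentration inside positive regions (OD units).
    dab_blob_count : int
        Number of discs whose union forms the DAB-positive region.
    dab_disjoint : bool
        Place blob centers far enough apart that blobs stay disjoint
        (used when an exact particle count is the ground truth).
    noise_sd : float
        Gaussian noise standard deviation in 8-bit intensity units,
        added after rendering and clipped to [0, 255].
    background_intensity : int
        Glass/illumination white point (8-bit).
    seed : int
        Seed for all randomness in the sample.
    """

    image_height: int = 512
    image_width: int = 512
    tissue_radius_fraction: float = 0.9
    nucleus_count: int = 80
    nucleus_radius_px: float = 5.0
    hematoxylin_od: float = 0.8
    tissue_background_od: float = 0.12
    dab_target_fraction: float = 0.2
    dab_od: float = 1.0
    dab_blob_count: int = 6
    dab_disjoint: bool = False
    noise_sd: float = 0.0
    background_intensity: int = 255
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dab_target_fraction <= 1.0):
            raise ValueError("dab_target_fraction must be in [0, 1]")
        if min(self.hematoxylin_od, self.dab_od, self.tissue_background_od) < 0:
            raise ValueError("optical densities must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 < self.tissue_radius_fraction <= 1.0):
            raise ValueError("tissue_radius_fraction must be in (0, 1]")
        if self.dab_blob_count < 1:
            raise ValueError("dab_blob_count must be positive")
        if self.nucleus_count < 0:
            raise ValueError("nucleus_count must be >= 0")
        if self.image_height < 8 or self.image_width < 8:
            raise ValueError("image must be at least 8x8")


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-sample truth emitted alongside the rendered image."""

    dab_mask: np.ndarray
    tissue_mask: np.ndarray
    true_dab_fraction: float
    true_blob_count: int
    concentration_maps: np.ndarray  # (H, W, 3): hematoxylin, dab, residual


def render_od_to_rgb(
    concentrations: np.ndarray,
    stains: StainMatrix | None = None,
    background_intensity: float = 255.0,
) -> np.ndarray:
    """Render per-stain concentration maps to an 8-bit RGB image.

    Per pixel and channel, ``I_c = round(bg * 10^(-sum_s conc_s * stain_s,c))``
    clipped to [0, 255] — the forward Beer-Lambert mixing model.
    """
    if stains is None:
        stains = default_hdab_matrix()
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be nonnegative")
    od = conc @ stains.vectors
    return od_to_rgb(od, background_intensity=background_intensity)


def _disc_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _place_blob_centers(rng, center, tissue_radius, count, min_separation, attempts=200):
    """Rejection-sample blob centers inside the tissue disc."""
    centers: list[tuple[float, float]] = []
    margin = 0.92 * tissue_radius
    for _ in range(count):
        for _ in range(attempts):
            ang = rng.uniform(0, 2 * np.pi)
            rad = margin * np.sqrt(rng.uniform())
            cand = (center[0] + rad * np.sin(ang), center[1] + rad * np.cos(ang))
            if min_separation <= 0 or all(
                np.hypot(cand[0] - c[0], cand[1] - c[1]) >= min_separation
                for c in centers
            ):
                centers.append(cand)
                break
        else:
            raise BlobPlacementError(
                f"could not place {count} blob centers with separation "
                f"{min_separation:.1f}px inside a radius-{tissue_radius:.1f}px disc"
            )
    return centers


def _dab_mask_for_fraction(shape, tissue_mask, centers, target_fraction, tol=0.005):
    """Union of equal-radius discs covering ``target_fraction`` of the tissue.

    The common radius is found by bisection; the union area within the tissue
    is monotone in the radius, so the search converges for any reachable
    fraction.
    """
    tissue_area = int(tissue_mask.sum())
    target_px = target_fraction * tissue_area
    if target_px < 1:
        return np.zeros(shape, dtype=bool)
    # pixel tolerance: tight for tiny targets, bounded for large ones
    tol_px = max(1.0, min(tol * tissue_area, 0.05 * target_px))

    def union_area(radius):
        m = np.zeros(shape, dtype=bool)
        for c in centers:
            m |= _disc_mask(shape, c, radius)
        m &= tissue_mask
        return m, int(m.sum())

    lo, hi = 0.0, float(max(shape))
    mask, area = union_area(hi)
    if area < target_px * (1 - tol) - 1:
        raise BlobPlacementError(
            f"target fraction {target_fraction} unreachable: blobs cover at most "
            f"{area / tissue_area:.3f} of tissue"
        )
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        mask, area = union_area(mid)
        if abs(area - target_px) <= tol_px:
            return mask
        if area < target_px:
            lo = mid
        else:
            hi = mid
    return mask


def generate_sample(config: SyntheticConfig) -> tuple[np.ndarray, GroundTruth]:
    """Generate one synthetic H-DAB sample and its exact ground truth.

    Deterministic: identical configs (including seed) give bit-identical
    images.  The rendered image is the Beer-Lambert projection of the returned
    ``GroundTruth.concentration_maps`` plus optional clipped Gaussian noise.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_height, config.image_width
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    tissue_radius = config.tissue_radius_fraction * min(h, w) / 2.0
    tissue_mask = _disc_mask((h, w), center, tissue_radius)

    conc = np.zeros((h, w, 3), dtype=float)
    conc[..., 0] += config.tissue_background_od * tissue_mask

    # nuclei: random ellipses fully inside the disc; overlapping stain adds
    rr, cc = np.mgrid[:h, :w]
    for _ in range(config.nucleus_count):
        ang = rng.uniform(0, 2 * np.pi)
        rad = 0.9 * tissue_radius * np.sqrt(rng.uniform())
        cy = center[0] + rad * np.sin(ang)
        cx = center[1] + rad * np.cos(ang)
        a = config.nucleus_radius_px * rng.uniform(0.7, 1.3)
        b = config.nucleus_radius_px * rng.uniform(0.7, 1.3)
        theta = rng.uniform(0, np.pi)
        dy, dx = rr - cy, cc - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        ellipse = (u / max(a, 1e-6)) ** 2 + (v / max(b, 1e-6)) ** 2 <= 1.0
        conc[..., 0] += config.hematoxylin_od * (ellipse & tissue_mask)

    # DAB blobs: union of discs hitting the target tissue-area fraction
    if config.dab_target_fraction > 0:
        if config.dab_disjoint:
            # radius for k disjoint discs of total area f * tissue_area
            r_expect = np.sqrt(
                config.dab_target_fraction * tissue_mask.sum() / (config.dab_blob_count * np.pi)
            )
            separation = 2.6 * r_expect
        else:
            separation = 0.0
        centers = _place_blob_centers(
            rng, center, tissue_radius, config.dab_blob_count, separation
        )
        dab_mask = _dab_mask_for_fraction(
            (h, w), tissue_mask, centers, config.dab_target_fraction
        )
    else:
        dab_mask = np.zeros((h, w), dtype=bool)
    conc[..., 1] += config.dab_od * dab_mask

    image = render_od_to_rgb(
        conc, background_intensity=config.background_intensity
    ).astype(float)
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=image.shape)
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)

    n_blobs = int(ndimage.label(dab_mask)[1])
    tissue_area = int(tissue_mask.sum())
    truth = GroundTruth(
        dab_mask=dab_mask,
        tissue_mask=tissue_mask,
        true_dab_fraction=float((dab_mask & tissue_mask).sum() / tissue_area),
        true_blob_count=n_blobs,
        concentration_maps=conc,
    )
    return image, truth


@dataclass(frozen=True)
class CohortSample:
    """One generated cohort member: image, truth, and manifest annotations."""

    sample_id: str
    tissue: str
    group: str
    seed: int
    image: np.ndarray
    truth: GroundTruth


def generate_cohort(
    normal_config: SyntheticConfig,
    tumor_config: SyntheticConfig,
    n_normal: int,
    n_tumor: int,
    tissues: list[str],
    seed: int,
) -> list[CohortSample]:
    """Generate a normal-versus-tumor cohort, one row per (tissue, replicate).

    Emulates a tissue-microarray montage: for each tissue, ``n_normal``
    normal samples (high DAB fraction) followed by ``n_tumor`` tumor samples
    (low fraction).  Per-sample seeds are drawn deterministically from
    ``seed`` so the cohort is reproducible as a whole.
    """
    if n_normal < 1 or n_tumor < 1:
        raise ValueError("n_normal and n_tumor must each be >= 1")
    if not tissues:
        raise ValueError("at least one tissue label is required")
    rng = np.random.default_rng(seed)
    samples: list[CohortSample] = []
    for tissue in tissues:
        for group, cfg, n in (
            ("normal", normal_config, n_normal),
            ("tumor", tumor_config, n_tumor),
        ):
            for rep in range(n):
                sample_seed = int(rng.integers(0, 2**31 - 1))
                sample_cfg = replace(cfg, seed=sample_seed)
                image, truth = generate_sample(sample_cfg)
                samples.append(
                    CohortSample(
                        sample_id=f"{tissue}_{group}_{rep + 1}",
                        tissue=tissue,
                        group=group,
                        seed=sample_seed,
                        image=image,
                        truth=truth,
                    )
                )
    return samples
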