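"""Optical-density conversion and stain unmixing for brightfield IHC.

Brightfield immunohistochemistry images mix two chromogens: hematoxylin
(blue-purple nuclear counterstain) and DAB (brown chromogen deposited at
antibody binding sites).  Under the Beer-Lambert law the optical density
of each RGB channel is linear in the amount of each stain, so the
per-pixel stain amounts are recovered by inverting a 3x3 matrix of
stain OD vectors (color deconvolution).  The DAB plane of the resulting
concentration image is the quantified protein signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StainMatrix",
    "default_hdab_matrix",
    "rgb_to_od",
    "od_to_rgb",
    "deconvolve",
]

#: Condition number above which a stain matrix is rejected as unusable.
MAX_CONDITION = 1e6


class SingularStainMatrixError(ValueError):
    """Raised when a stain basis is singular or numerically non-invertible."""


@dataclass(frozen=True)
class StainMatrix:
    """A 3x3 stain basis: rows (hematoxylin, DAB, residual) x columns (R, G, B).

    Each row is a unit-length optical-density vector.  The residual row
    completes the basis so the matrix is invertible; it absorbs color not
    explained by the two real stains.
    """

    vectors: np.ndarray
    names: tuple[str, str, str] = ("hematoxylin", "dab", "residual")

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (3, 3):
            raise ValueError(f"stain matrix must be 3x3, got {v.shape}")
        norms = np.linalg.norm(v, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError(f"stain rows must have unit norm, got norms {norms}")
        cond = np.linalg.cond(v)
        if not np.isfinite(cond) or cond > MAX_CONDITION:
            raise SingularStainMatrixError(
                f"stain matrix is near-singular (condition number {cond:.3g}): {v}"
            )
        object.__setattr__(self, "vectors", v)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.vectors)

    @classmethod
    def from_rows(cls, hematoxylin, dab, residual=None) -> "StainMatrix":
        """Build a basis from stain OD vectors, normalizing each to unit length.

        When ``residual`` is None it is taken as the normalized cross product
        of the two stain vectors, i.e. orthogonal to both.
        """
        h = np.asarray(hematoxylin, dtype=float)
        d = np.asarray(dab, dtype=float)
        h = h / np.linalg.norm(h)
        d = d / np.linalg.norm(d)
        if residual is None:
            r = np.cross(h, d)
            nr = np.linalg.norm(r)
            if nr < 1e-12:
                raise SingularStainMatrixError(
                    "hematoxylin and DAB vectors are collinear; no residual axis"
                )
            r = r / nr
        else:
            r = np.asarray(residual, dtype=float)
            r = r / np.linalg.norm(r)
        return cls(np.vstack([h, d, r]))

    @classmethod
    def from_csv(cls, path) -> "StainMatrix":
        """Load a 3x3 stain matrix from CSV (rows = stains, columns = RGB)."""
        raw = np.loadtxt(path, delimiter=",", dtype=float)
        if raw.shape != (3, 3):
            raise ValueError(f"stain CSV must contain a 3x3 matrix, got {raw.shape}")
        norms = np.linalg.norm(raw, axis=1)
        if np.any(norms < 1e-12):
            raise SingularStainMatrixError(f"zero-length stain row in {path}")
        return cls(raw / norms[:, None])


def default_hdab_matrix() -> StainMatrix:
    """The standard published H-DAB unmixing basis.

    Hematoxylin ~ (0.65, 0.70, 0.29), DAB ~ (0.27, 0.57, 0.78) in OD units,
    with the residual axis as their normalized cross product.  These are the
    widely used brightfield calibration vectors for hematoxylin-counterstained
    DAB immunostains.
    """
    return StainMatrix.from_rows((0.65, 0.70, 0.29), (0.27, 0.57, 0.78))


def rgb_to_od(image: np.ndarray, illumination_reference: float = 255.0) -> np.ndarray:
    """Convert an 8-bit RGB image to optical density.

    ``od_c = log10(reference / max(I_c, 1))`` per pixel and channel, clipped
    below at 0 where the intensity exceeds the reference.  Clamping intensities
    to >= 1 bounds the OD without special-casing black pixels.

    Parameters
    ----------
    image
        ``(H, W, 3)`` array of intensities in [0, 255].
    illumination_reference
        White-point intensity (>= 1); defaults to 255 for white-background
        brightfield images.
    """
    if illumination_reference < 1:
        raise ValueError("illumination_reference must be >= 1")
    intensity = np.maximum(np.asarray(image, dtype=float), 1.0)
    od = np.log10(illumination_reference / intensity)
    return np.maximum(od, 0.0)


def od_to_rgb(od: np.ndarray, background_intensity: float = 255.0) -> np.ndarray:
    """Forward Beer-Lambert model: OD image -> 8-bit transmitted intensities.

    ``I_c = round(background * 10^(-od_c))`` clipped to [0, 255].
    """
    intensity = background_intensity * np.power(10.0, -np.asarray(od, dtype=float))
    return np.clip(np.round(intensity), 0, 255).astype(np.uint8)


def deconvolve(od: np.ndarray, stains: StainMatrix) -> np.ndarray:
    """Unmix an optical-density image into per-stain concentrations.

    Solves ``od = conc @ stains.vectors`` per pixel, so the returned array has
    planes in the basis row order (hematoxylin, DAB, residual).  Small negative
    concentrations arising from noise are retained here (linearity is exact);
    they are clipped to zero only at quantification time.

    Raises
    ------
    SingularStainMatrixError
        If the basis condition number exceeds ``MAX_CONDITION`` (checked at
        ``StainMatrix`` construction).
    """
    od = np.asarray(od, dtype=float)
    if od.shape[-1] != 3:
        raise ValueError(f"OD image must have 3 channels, got shape {od.shape}")
    return od @ stains.inverse
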