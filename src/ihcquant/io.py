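"""Image and table I/O for the pipeline."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from PIL import Image

logger = logging.getLogger("ihcquant")

__all__ = ["read_image", "write_image", "write_mask", "write_metrics_csv"]


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image as an 8-bit (H, W, 3) RGB array.

    Grayscale input is promoted to 3 channels, alpha is dropped, and 16-bit
    input is rescaled to 8 bits (with a logged warning).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    try:
        with Image.open(path) as img:
            if img.mode in ("I", "I;16", "I;16B", "I;16L"):
                logger.warning("16-bit image %s rescaled to 8-bit", path)
                arr = np.asarray(img, dtype=np.float64)
                arr = np.clip(np.round(arr / 257.0), 0, 255).astype(np.uint8)
                img = Image.fromarray(arr, mode="L")
            rgb = img.convert("RGB")
            return np.asarray(rgb, dtype=np.uint8)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ValueError(f"cannot decode image {path}: {exc}") from exc


def write_image(path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def write_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit PNG (255 = positive)."""
    Image.fromarray((np.asarray(mask, dtype=bool) * np.uint8(255))).save(path)


def write_metrics_csv(path, frame, header_lines: list[str] | None = None) -> None:
    """Write a metrics/contrasts table with ``#``-prefixed header comments."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False, lineterminator="\n")
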