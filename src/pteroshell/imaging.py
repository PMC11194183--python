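"""Shell transparency scoring from greyscale micrographs.

Bleached, dried pteropod shells are photographed on a pure-white
(greyscale 255) background; the shell is segmented by intensity
thresholding, apertures and holes are cropped out via exclusion polygons,
and transparency is the mean greyscale of the remaining shell pixels
divided by 255 — a 0 (opaque black) to 1 (fully transparent) scale.

Raster convention: origin top-left, row-major; connected components use
8-connectivity. Exclusion polygons are (row, col) vertex arrays rasterized
with :func:`skimage.draw.polygon`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import draw as skdraw
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "ShellImage",
    "ShellMask",
    "NoShellDetectedError",
    "segment_shell",
    "transparency_score",
    "load_shell_image",
    "score_images",
]

#: default intensity cutoff separating shell from the white background;
#: slightly below 255 to tolerate vignetting near the frame edges
DEFAULT_BACKGROUND_CUTOFF = 250


class NoShellDetectedError(ValueError):
    """No pixels below the background cutoff — nothing to score."""


@dataclass
class ShellImage:
    """A greyscale micrograph with 8-bit intensities."""

    pixels: np.ndarray
    scale_tag: str = "25x"
    image_id: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D greyscale raster, got ndim={px.ndim}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        self.pixels = px


@dataclass
class ShellMask:
    """Boolean shell mask plus the polygons cropped out of it."""

    mask: np.ndarray
    excluded_regions: list = field(default_factory=list)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def _rasterize_polygons(
    polygons: Iterable[Sequence], shape: tuple[int, int]
) -> np.ndarray:
    excluded = np.zeros(shape, dtype=bool)
    for poly in polygons:
        poly = np.asarray(poly, dtype=float)
        rr, cc = skdraw.polygon(poly[:, 0], poly[:, 1], shape=shape)
        excluded[rr, cc] = True
    return excluded


def segment_shell(
    image: ShellImage | np.ndarray,
    background_cutoff: float | None = DEFAULT_BACKGROUND_CUTOFF,
    exclusions: Iterable[Sequence] = (),
    method: str = "fixed",
) -> ShellMask:
    """Threshold the micrograph and return the shell pixel mask.

    Pixels with intensity below ``background_cutoff`` are shell candidates;
    exclusion polygons (apertures, holes) are removed, and only the largest
    8-connected component is kept, rejecting detached debris.

    Parameters
    ----------
    background_cutoff : intensity below which a pixel counts as shell
        (ignored when ``method="otsu"``).
    exclusions : iterable of (N, 2) arrays of (row, col) polygon vertices.
    method : ``"fixed"`` (default) or ``"otsu"`` for an automatic
        threshold on the intensity histogram.

    Raises
    ------
    NoShellDetectedError
        If no shell pixels survive thresholding and exclusion.
    """
    if not isinstance(image, ShellImage):
        image = ShellImage(np.asarray(image))
    px = image.pixels
    if method == "otsu":
        # Otsu returns the highest intensity of the dark class, so the
        # shell criterion is inclusive there and strict for a fixed cutoff
        background_cutoff = threshold_otsu(px)
        candidate = px <= background_cutoff
    elif method == "fixed":
        candidate = px < background_cutoff
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    polys = list(exclusions)
    if polys:
        candidate &= ~_rasterize_polygons(polys, px.shape)
    if not candidate.any():
        raise NoShellDetectedError(
            f"no shell detected in {image.image_id or 'image'}: "
            f"no pixels below cutoff {background_cutoff}"
        )
    labels = measure.label(candidate, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background label
    mask = labels == counts.argmax()
    return ShellMask(mask=mask, excluded_regions=polys)


def transparency_score(image: ShellImage | np.ndarray, mask: ShellMask) -> float:
    """Mean greyscale over shell pixels divided by 255 (0 black .. 1 white)."""
    if not isinstance(image, ShellImage):
        image = ShellImage(np.asarray(image))
    if mask.n_pixels == 0:
        raise NoShellDetectedError("empty mask: cannot score transparency")
    return float(image.pixels[mask.mask].mean() / 255.0)


def load_shell_image(path: str | Path) -> ShellImage:
    """Read a PNG/TIFF micrograph, collapsing RGB to greyscale if needed."""
    px = iio.imread(path)
    if px.ndim == 3:  # RGB(A) saved greyscale — channels are identical
        px = px[..., 0]
    return ShellImage(px.astype(np.uint8), image_id=Path(path).stem)


def load_exclusions(path: str | Path) -> dict[str, list]:
    """Read an exclusion-polygon JSON: {image_id: [[[row, col], ...], ...]}."""
    with open(path) as fh:
        return json.load(fh)


def score_images(
    image_paths: Sequence[str | Path],
    exclusions: dict[str, list] | None = None,
    background_cutoff: float = DEFAULT_BACKGROUND_CUTOFF,
    method: str = "fixed",
    mask_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Score a batch of micrographs.

    Returns a DataFrame with columns ``image_id``, ``n_shell_pixels``,
    ``transparency``; optionally writes each mask as a PNG to ``mask_dir``.
    """
    exclusions = exclusions or {}
    rows = []
    for path in image_paths:
        img = load_shell_image(path)
        mask = segment_shell(
            img,
            background_cutoff=background_cutoff,
            exclusions=exclusions.get(img.image_id, ()),
            method=method,
        )
        rows.append(
            {
                "image_id": img.image_id,
                "n_shell_pixels": mask.n_pixels,
                "transparency": transparency_score(img, mask),
            }
        )
        if mask_dir is not None:
            out = Path(mask_dir) / f"{img.image_id}_mask.png"
            out.parent.mkdir(parents=True, exist_ok=True)
            iio.imwrite(out, (mask.mask * 255).astype(np.uint8))
    return pd.DataFrame(rows, columns=["image_id", "n_shell_pixels", "transparency"])
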