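"""Body-outline templates.

A template fixes the raster geometry shared by every drawing in a cohort and
the boolean *inside-body* mask that restricts all computation to anatomically
meaningful pixels.  The number of true pixels in the mask, ``m``, is the
feature count of every downstream vector (drawings, profiles).

Coordinate convention: row-major, origin top-left, 0-based ``(row, col)``.
All rasters in one cohort must share the exact same width and height; no
resampling or registration is attempted — the workflow assumes a single fixed
printed template.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "BodyTemplate",
    "DegenerateTemplateError",
    "load_template",
    "make_synthetic_template",
    "read_template",
    "write_template",
]


class DegenerateTemplateError(ValueError):
    """Raised when a template's inside mask contains no pixels."""


@dataclass(frozen=True)
class BodyTemplate:
    """Raster geometry plus the inside-body pixel mask.

    Parameters
    ----------
    template_id
        Identifier stored alongside drawings and profiles so mismatched
        artifacts can be detected.
    inside_mask
        Boolean array of shape ``(height, width)``; ``True`` where the pixel
        lies inside the body outlines.
    regions
        Optional named sub-masks of ``inside_mask`` used by the synthetic
        cohort generator.  Every region must be pixel-wise implied by the
        inside mask.
    """

    template_id: str
    inside_mask: np.ndarray
    regions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        mask = np.asarray(self.inside_mask, dtype=bool)
        object.__setattr__(self, "inside_mask", mask)
        if mask.ndim != 2:
            raise ValueError("inside_mask must be a 2-D raster")
        if not mask.any():
            raise DegenerateTemplateError(
                f"template {self.template_id!r}: inside mask has no pixels"
            )
        regions = {k: np.asarray(v, dtype=bool) for k, v in self.regions.items()}
        for name, reg in regions.items():
            if reg.shape != mask.shape:
                raise ValueError(f"region {name!r} shape differs from template")
            if (reg & ~mask).any():
                raise ValueError(f"region {name!r} extends outside the body mask")
        object.__setattr__(self, "regions", regions)

    @property
    def height(self) -> int:
        return self.inside_mask.shape[0]

    @property
    def width(self) -> int:
        return self.inside_mask.shape[1]

    @property
    def m(self) -> int:
        """Feature count: number of inside-body pixels."""
        return int(self.inside_mask.sum())

    def vectorize(self, raster: np.ndarray) -> np.ndarray:
        """Extract the inside-mask pixels of ``raster`` in row-major order."""
        raster = np.asarray(raster)
        if raster.shape != self.inside_mask.shape:
            raise ValueError(
                f"raster shape {raster.shape} does not match template "
                f"{self.inside_mask.shape}"
            )
        return raster[self.inside_mask]

    def rasterize(self, values: np.ndarray, fill=0) -> np.ndarray:
        """Scatter a length-``m`` vector back onto the full raster."""
        values = np.asarray(values)
        if values.shape != (self.m,):
            raise ValueError(f"expected vector of length {self.m}, got {values.shape}")
        out = np.full(self.inside_mask.shape, fill, dtype=values.dtype)
        out[self.inside_mask] = values
        return out

    def region_vector(self, name: str) -> np.ndarray:
        """Boolean length-``m`` indicator of a named region."""
        return self.regions[name][self.inside_mask]


def load_template(
    raster: np.ndarray, inside_threshold: int = 128, template_id: str = "template"
) -> BodyTemplate:
    """Build a template from a grayscale raster.

    A pixel is inside the body iff its intensity is strictly below
    ``inside_threshold`` (dark = inside; outline interiors must already be
    filled by the caller — no flood fill is attempted here).
    """
    raster = np.asarray(raster)
    if raster.ndim != 2:
        raise ValueError("template raster must be single-channel")
    mask = raster < inside_threshold
    return BodyTemplate(template_id=template_id, inside_mask=mask)


def make_synthetic_template(
    width: int = 64,
    height: int = 128,
    n_regions: int = 12,
    seed: int = 0,
    template_id: str | None = None,
) -> BodyTemplate:
    """Construct a simple synthetic body template.

    The silhouette is a rectangle with a one-eighth margin on every side —
    a stand-in for body artwork, not an anatomical drawing.  It is
    partitioned into ``n_regions`` contiguous horizontal bands of (nearly)
    equal pixel count, named ``band_00`` (top) through ``band_{n-1}``
    (bottom).  For a 12-band template the bands correspond roughly to head,
    neck, shoulders, chest/upper arms, elbows, lower back, pelvis, hands,
    thighs, knees, lower legs and feet.

    The construction is deterministic for fixed arguments; ``seed`` is
    accepted for interface uniformity and recorded in the template id.
    """
    if width < 16 or height < 16:
        raise ValueError("template must be at least 16x16 pixels")
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    margin_r = max(1, height // 8)
    margin_c = max(1, width // 8)
    mask = np.zeros((height, width), dtype=bool)
    mask[margin_r : height - margin_r, margin_c : width - margin_c] = True
    body_rows = np.flatnonzero(mask.any(axis=1))
    if n_regions > body_rows.size:
        raise ValueError(
            f"cannot cut {n_regions} bands from a silhouette of "
            f"{body_rows.size} rows"
        )
    # Equal-height row bands over the silhouette; every band is non-empty.
    edges = np.linspace(0, body_rows.size, n_regions + 1).round().astype(int)
    ndigits = max(2, len(str(n_regions - 1)))
    regions: dict[str, np.ndarray] = {}
    for i in range(n_regions):
        band = np.zeros_like(mask)
        rows = body_rows[edges[i] : edges[i + 1]]
        band[rows, :] = mask[rows, :]
        regions[f"band_{i:0{ndigits}d}"] = band
    if template_id is None:
        template_id = f"synthetic-{width}x{height}-r{n_regions}-s{seed}"
    return BodyTemplate(template_id=template_id, inside_mask=mask, regions=regions)


# ---------------------------------------------------------------------------
# Persistence: 8-bit PNG mask (0 = inside, 255 = outside) + JSON sidecar with
# the template id and regions as row-major run-length encodings.


def _rle_encode(mask: np.ndarray) -> list[int]:
    flat = mask.ravel().astype(np.int8)
    change = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate(([0], change, [flat.size]))
    runs = np.diff(bounds).tolist()
    if flat[0] == 1:  # runs alternate starting with a zero-run
        runs = [0] + runs
    return [int(r) for r in runs]


def _rle_decode(runs: list[int], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos = 0
    val = False
    for run in runs:
        if val:
            flat[pos : pos + run] = True
        pos += run
        val = not val
    return flat.reshape(shape)


def write_template(template: BodyTemplate, png_path: str | Path) -> Path:
    """Write the mask PNG and its JSON sidecar; return the sidecar path."""
    png_path = Path(png_path)
    img = np.where(template.inside_mask, 0, 255).astype(np.uint8)
    Image.fromarray(img, mode="L").save(png_path)
    sidecar = png_path.with_suffix(".json")
    meta = {
        "template_id": template.template_id,
        "width": template.width,
        "height": template.height,
        "regions": {k: _rle_encode(v) for k, v in template.regions.items()},
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def read_template(png_path: str | Path, inside_threshold: int = 128) -> BodyTemplate:
    """Read a template written by :func:`write_template`."""
    png_path = Path(png_path)
    raster = np.asarray(Image.open(png_path).convert("L"))
    sidecar = png_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    shape = raster.shape
    regions = {
        k: _rle_decode(v, shape) for k, v in meta.get("regions", {}).items()
    }
    return BodyTemplate(
        template_id=meta.get("template_id", png_path.stem),
        inside_mask=raster < inside_threshold,
        regions=regions,
    )
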