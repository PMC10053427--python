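"""Pain profiles: per-diagnosis pixel-frequency maps.

The profile of a diagnostic group overlaps all of its drawings and records,
for each inside-body pixel, the relative frequency of drawings that marked
it.  Profiles are the reference objects of the similarity classifiers and
are rendered as blue-to-red heatmaps (white = never marked, yellow = 50 %).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

from .drawing_io import Cohort, PainDrawing
from .template import BodyTemplate

__all__ = [
    "PainProfile",
    "build_profile",
    "pool_classes",
    "render_heatmap",
    "write_profile",
    "read_profile",
]


@dataclass(frozen=True)
class PainProfile:
    """Relative marking frequency per inside-body pixel for one group."""

    label: str
    n_drawings: int
    x: np.ndarray  # float vector in [0, 1], length m
    template_id: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "x", x)
        if self.n_drawings < 1:
            raise ValueError("profile needs at least one drawing")
        if x.min() < 0 or x.max() > 1:
            raise ValueError("profile frequencies must lie in [0, 1]")


def build_profile(drawings: Sequence[PainDrawing], label: str) -> PainProfile:
    """Overlap drawings of one group: ``x_i`` = fraction of drawings marking pixel i."""
    drawings = list(drawings)
    if not drawings:
        raise ValueError(f"cannot build profile {label!r} from zero drawings")
    template_ids = {d.template_id for d in drawings}
    if len(template_ids) > 1:
        raise ValueError(f"drawings mix templates: {sorted(template_ids)}")
    if any(d.is_empty for d in drawings):
        raise ValueError("empty drawings must be excluded before profile building")
    counts = np.zeros(drawings[0].y.size, dtype=np.int64)
    for d in drawings:
        counts += d.y
    return PainProfile(
        label=label,
        n_drawings=len(drawings),
        x=counts / len(drawings),
        template_id=template_ids.pop(),
    )


def pool_classes(
    cohort: Cohort, members: Iterable[str], pooled_label: str
) -> PainProfile:
    """Pool several classes into one profile (e.g. all rare diseases).

    Pooling is drawing-weighted, not class-averaged: the union of the member
    classes' drawings is overlapped directly, so a class with more drawings
    informs the pooled profile more.
    """
    members = list(members)
    if not members:
        raise ValueError("members must be non-empty")
    unknown = set(members) - set(cohort.classes)
    if unknown:
        raise ValueError(f"unknown class label(s): {sorted(unknown)}")
    drawings = [d for d in cohort.drawings if d.label in members]
    return build_profile(drawings, pooled_label)


# ---------------------------------------------------------------------------
# Heatmap rendering: piecewise-linear RGB ramp anchored at
# 0+ -> blue (0,0,255), 0.5 -> yellow (255,255,0), 1.0 -> red (255,0,0);
# exactly-zero frequencies and outside-body pixels render white.

_ANCHORS = np.array([0.0, 0.5, 1.0])
_ANCHOR_RGB = np.array([[0, 0, 255], [255, 255, 0], [255, 0, 0]], dtype=float)


def frequency_to_rgb(x: np.ndarray) -> np.ndarray:
    """Map frequencies in [0,1] to the blue-yellow-red ramp (n x 3 uint8)."""
    x = np.asarray(x, dtype=float)
    rgb = np.stack(
        [np.interp(x, _ANCHORS, _ANCHOR_RGB[:, c]) for c in range(3)], axis=-1
    )
    rgb[x == 0] = 255.0  # never-marked pixels are white, not blue
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def render_heatmap(profile: PainProfile, template: BodyTemplate) -> np.ndarray:
    """Render a profile as an RGB raster (height x width x 3, uint8)."""
    if profile.x.shape != (template.m,):
        raise ValueError(
            f"profile has {profile.x.size} pixels, template has {template.m}"
        )
    out = np.full((template.height, template.width, 3), 255, dtype=np.uint8)
    out[template.inside_mask] = frequency_to_rgb(profile.x)
    return out


# ---------------------------------------------------------------------------
# Persistence: JSON metadata + 16-bit grayscale PNG of round(x * 65535).


def write_profile(
    profile: PainProfile, template: BodyTemplate, png_path: str | Path
) -> Path:
    png_path = Path(png_path)
    scaled = np.rint(profile.x * 65535).astype(np.uint16)
    raster = template.rasterize(scaled, fill=0)
    Image.fromarray(raster.astype(np.int32), mode="I").convert("I;16").save(png_path)
    sidecar = png_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "label": profile.label,
                "n_drawings": profile.n_drawings,
                "template_id": profile.template_id or template.template_id,
            },
            indent=1,
        )
    )
    return sidecar


def read_profile(png_path: str | Path, template: BodyTemplate) -> PainProfile:
    png_path = Path(png_path)
    raster = np.asarray(Image.open(png_path), dtype=np.float64)
    meta = json.loads(png_path.with_suffix(".json").read_text())
    x = template.vectorize(raster) / 65535.0
    return PainProfile(
        label=meta["label"],
        n_drawings=int(meta["n_drawings"]),
        x=x,
        template_id=meta.get("template_id", template.template_id),
    )
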