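"""Reading, validating, binarizing and writing pain drawings and cohorts.

A pain drawing is a patient's shading of painful body regions on the shared
template, digitized to a binary vector ``y`` over the template's inside-body
pixels (1 = marked).  Marks falling outside the body outline are clipped
silently.  A drawing with no marked pixel is *empty*: it carries no
information and, following standard practice for such scans, is excluded
from profile building and classification by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .template import BodyTemplate

__all__ = [
    "PainDrawing",
    "Cohort",
    "EmptyDrawingError",
    "read_drawing",
    "write_drawing",
    "load_cohort",
    "write_cohort_manifest",
]

DEFAULT_MARK_THRESHOLD = 128  # dark ink on white paper


class EmptyDrawingError(ValueError):
    """Raised when an empty drawing reaches an operation that forbids it."""


@dataclass(frozen=True)
class PainDrawing:
    """One subject's binary marking vector over the template's inside pixels."""

    subject_id: str
    label: str | None
    y: np.ndarray  # uint8 vector of length template.m, values in {0, 1}
    template_id: str

    def __post_init__(self) -> None:
        y = np.asarray(self.y)
        if y.ndim != 1:
            raise ValueError("y must be a flat vector over inside-mask pixels")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("y components must be 0 or 1")
        object.__setattr__(self, "y", y.astype(np.uint8))

    @property
    def n_marked(self) -> int:
        return int(self.y.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_marked == 0


@dataclass(frozen=True)
class Cohort:
    """Labeled drawings sharing one template; the unit of cross-validation.

    ``classes`` keeps the canonical label order (first appearance), which
    fixes tie-breaking and the row/column order of every confusion matrix.
    """

    template: BodyTemplate
    drawings: tuple[PainDrawing, ...]
    classes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        drawings = tuple(self.drawings)
        object.__setattr__(self, "drawings", drawings)
        if not drawings:
            raise ValueError("cohort must contain at least one drawing")
        m = self.template.m
        seen: list[str] = []
        for d in drawings:
            if d.y.shape != (m,):
                raise ValueError(
                    f"drawing {d.subject_id!r} has {d.y.size} features, "
                    f"template has {m}"
                )
            if d.template_id != self.template.template_id:
                raise ValueError(
                    f"drawing {d.subject_id!r} was digitized on template "
                    f"{d.template_id!r}, not {self.template.template_id!r}"
                )
            if d.label is None:
                raise ValueError(
                    f"drawing {d.subject_id!r} is unlabeled; cohorts require labels"
                )
            if d.label not in seen:
                seen.append(d.label)
        classes = tuple(self.classes) if self.classes else tuple(seen)
        if set(seen) - set(classes):
            raise ValueError("drawing labels outside the declared class list")
        object.__setattr__(self, "classes", classes)

    def __len__(self) -> int:
        return len(self.drawings)

    def by_class(self, label: str) -> list[PainDrawing]:
        return [d for d in self.drawings if d.label == label]

    def class_sizes(self) -> dict[str, int]:
        return {c: len(self.by_class(c)) for c in self.classes}

    def subset(self, labels) -> "Cohort":
        """Cohort restricted to the given labels (canonical order kept)."""
        labels = tuple(labels)
        drawings = tuple(d for d in self.drawings if d.label in labels)
        classes = tuple(c for c in self.classes if c in labels)
        return Cohort(template=self.template, drawings=drawings, classes=classes)


def read_drawing(
    raster: np.ndarray,
    template: BodyTemplate,
    mark_threshold: int = DEFAULT_MARK_THRESHOLD,
    subject_id: str = "",
    label: str | None = None,
) -> PainDrawing:
    """Binarize a grayscale scan into a drawing on ``template``.

    A pixel counts as marked iff its intensity is strictly below
    ``mark_threshold`` *and* it lies inside the body mask; ink outside the
    outline is clipped.  The vector is assembled in row-major order over the
    inside-mask pixels so all drawings on one template are aligned.
    """
    raster = np.asarray(raster)
    if raster.shape != (template.height, template.width):
        raise ValueError(
            f"scan is {raster.shape}, template is "
            f"{(template.height, template.width)}; rasters must match exactly"
        )
    y = template.vectorize(raster < mark_threshold).astype(np.uint8)
    return PainDrawing(
        subject_id=subject_id, label=label, y=y, template_id=template.template_id
    )


def write_drawing(
    drawing: PainDrawing, template: BodyTemplate, path: str | Path
) -> None:
    """Write a drawing as an 8-bit grayscale PNG (marked = 0, blank = 255)."""
    raster = template.rasterize(
        np.where(drawing.y == 1, 0, 255).astype(np.uint8), fill=255
    )
    Image.fromarray(raster, mode="L").save(Path(path))


def load_cohort(
    manifest: str | Path | pd.DataFrame,
    template: BodyTemplate,
    mark_threshold: int = DEFAULT_MARK_THRESHOLD,
    exclude_empty: bool = True,
    strict: bool = False,
    root: str | Path | None = None,
) -> tuple[Cohort, list[str]]:
    """Load a cohort from a CSV manifest with columns ``path,subject_id,label``.

    Returns the cohort and a load log (lines ``subject_id,reason``) recording
    excluded drawings.  ``exclude_empty`` drops drawings with no inside-mask
    mark, mirroring the usual exclusion of blank forms; with ``strict`` an
    empty drawing is an error instead.  Relative raster paths are resolved
    against ``root`` (default: the manifest's directory).
    """
    if isinstance(manifest, pd.DataFrame):
        table = manifest
        base = Path(root) if root is not None else Path(".")
    else:
        manifest = Path(manifest)
        table = pd.read_csv(manifest, dtype=str)
        base = Path(root) if root is not None else manifest.parent
    required = {"path", "subject_id", "label"}
    if not required.issubset(table.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    if len(table) == 0:
        raise ValueError("manifest is empty")
    dup = table["subject_id"][table["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject_id(s) in manifest: {sorted(set(dup))}")

    drawings: list[PainDrawing] = []
    log: list[str] = []
    for row in table.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        raster = np.asarray(Image.open(p).convert("L"))
        d = read_drawing(
            raster,
            template,
            mark_threshold=mark_threshold,
            subject_id=str(row.subject_id),
            label=str(row.label),
        )
        if d.is_empty:
            if strict:
                raise EmptyDrawingError(f"drawing {d.subject_id!r} is empty")
            if exclude_empty:
                log.append(f"{d.subject_id},empty")
                continue
        drawings.append(d)
    if not drawings:
        raise ValueError("no drawings survived loading")
    return Cohort(template=template, drawings=tuple(drawings)), log


def write_cohort_manifest(
    cohort: Cohort, out_dir: str | Path, prefix: str = "pd"
) -> Path:
    """Write every drawing as a PNG plus a ``manifest.csv``; return its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, d in enumerate(cohort.drawings):
        name = f"{prefix}_{i:04d}.png"
        write_drawing(d, cohort.template, out_dir / name)
        rows.append({"path": name, "subject_id": d.subject_id, "label": d.label})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
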