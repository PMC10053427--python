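"""Synthetic pain-drawing cohorts.

The generator emulates the statistical structure the similarity classifiers
assume: each diagnostic class marks a set of named template regions with
class-specific probabilities, all subjects additionally mark any region
with a small shared background-noise probability, and a class may consist
of latent subgroups with different marking maps (mixture weights summing
to 1).  Sampling is region-level Bernoulli — a marked region sets every one
of its pixels — so drawings have the spatial coherence of real pain
markings rather than independent pixel noise.

Reproducibility: one master seed; each subject gets its own random stream
derived from (seed, class label, subject index), so cohorts are bit-stable
under subsetting or reordering of classes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .drawing_io import Cohort, PainDrawing
from .template import BodyTemplate, make_synthetic_template

__all__ = [
    "ClassSpec",
    "SynthSpec",
    "generate_cohort",
    "five_group_spec",
    "analytic_marking_probability",
]


def _check_probs(probs: Mapping[str, float], where: str) -> None:
    for region, p in probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{where}: probability {p} for {region!r} outside [0, 1]")


@dataclass(frozen=True)
class ClassSpec:
    """One diagnostic class: size and region marking probabilities.

    ``subgroups`` optionally replaces ``region_probs`` with a mixture of
    alternative maps, e.g. a disease whose patients split into thighs-marked
    and thighs-unmarked presentations.
    """

    label: str
    n_drawings: int
    region_probs: dict[str, float] = field(default_factory=dict)
    subgroups: tuple[tuple[float, dict[str, float]], ...] = ()  # (weight, map)

    def __post_init__(self) -> None:
        if self.n_drawings < 1:
            raise ValueError(f"class {self.label!r}: n_drawings must be >= 1")
        _check_probs(self.region_probs, f"class {self.label!r}")
        if self.subgroups:
            weights = [w for w, _ in self.subgroups]
            if abs(sum(weights) - 1.0) > 1e-9 or min(weights) < 0:
                raise ValueError(
                    f"class {self.label!r}: subgroup weights must be >= 0 and sum to 1"
                )
            for _, probs in self.subgroups:
                _check_probs(probs, f"class {self.label!r} subgroup")

    def marking_maps(self) -> tuple[tuple[float, dict[str, float]], ...]:
        return self.subgroups if self.subgroups else ((1.0, self.region_probs),)


@dataclass(frozen=True)
class SynthSpec:
    template: BodyTemplate
    classes: tuple[ClassSpec, ...]
    background_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", tuple(self.classes))
        if not 0.0 <= self.background_noise <= 1.0:
            raise ValueError("background_noise must lie in [0, 1]")
        regions = set(self.template.regions)
        for cs in self.classes:
            for _, probs in cs.marking_maps():
                unknown = set(probs) - regions
                if unknown:
                    raise ValueError(
                        f"class {cs.label!r} references unknown regions {sorted(unknown)}"
                    )


def generate_cohort(spec: SynthSpec, ensure_nonempty: bool = True) -> Cohort:
    """Sample a cohort: subgroup draw, then per-region Bernoulli marks + noise.

    With ``ensure_nonempty`` (the default) a subject whose draw marks no
    region is redrawn within its own random stream — the cohort emulates a
    study whose inclusion criterion is the presence of pain, so every
    enrolled subject marks at least one region and class sizes are exact.
    With ``ensure_nonempty=False`` sampling is unconditional and the
    empirical class profile matches :func:`analytic_marking_probability`
    exactly in expectation (the conditional version matches it only up to
    the probability of an all-empty draw, negligible for realistic maps).

    Deterministic for a fixed spec and seed either way.
    """
    template = spec.template
    region_names = list(template.regions)
    region_vectors = {r: template.region_vector(r) for r in region_names}
    drawings: list[PainDrawing] = []
    for cs in spec.classes:
        maps = cs.marking_maps()
        weights = np.array([w for w, _ in maps])
        label_key = zlib.crc32(cs.label.encode())
        for si in range(cs.n_drawings):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=(spec.seed, label_key, si))
            )
            for _attempt in range(1000):
                g = int(rng.choice(len(maps), p=weights))
                probs = maps[g][1]
                y = np.zeros(template.m, dtype=np.uint8)
                for r in region_names:
                    p_class = probs.get(r, 0.0)
                    marked = rng.random() < p_class
                    noisy = rng.random() < spec.background_noise
                    if marked or noisy:
                        y[region_vectors[r]] = 1
                if y.any() or not ensure_nonempty:
                    break
            else:
                raise RuntimeError(
                    f"class {cs.label!r}: could not draw a non-empty subject; "
                    "marking probabilities are (near-)zero everywhere"
                )
            drawings.append(
                PainDrawing(
                    subject_id=f"{cs.label}_{si:04d}",
                    label=cs.label,
                    y=y,
                    template_id=template.template_id,
                )
            )
    return Cohort(
        template=template,
        drawings=tuple(drawings),
        classes=tuple(cs.label for cs in spec.classes),
    )


def analytic_marking_probability(
    spec: SynthSpec, class_spec: ClassSpec
) -> np.ndarray:
    """Expected profile of a class: p_i = 1 - (1 - p_class,i)(1 - noise).

    ``p_class,i`` is the mixture-weighted probability that the region holding
    pixel i is marked by the class map; regions never referenced keep only
    the background-noise probability.  This closed form is what the
    empirical profile of a generated class converges to.
    """
    template = spec.template
    p = np.zeros(template.m)
    for r in template.regions:
        p_class = sum(
            w * probs.get(r, 0.0) for w, probs in class_spec.marking_maps()
        )
        p_marked = 1.0 - (1.0 - p_class) * (1.0 - spec.background_noise)
        vec = template.region_vector(r)
        p[vec] = p_marked
    return p


# ---------------------------------------------------------------------------
# Bundled five-group study spec


#: Cohort sizes of the five diagnostic groups emulated by
#: :func:`five_group_spec`: four rare diseases plus a chronic-pain outgroup.
FIVE_GROUP_SIZES = {"EDS": 59, "GBS": 29, "FSHD": 35, "PROMM": 89, "CP": 50}


def five_group_spec(
    template: BodyTemplate | None = None,
    seed: int = 0,
    background_noise: float = 0.05,
) -> SynthSpec:
    """Five-class spec emulating a rare-disease pain-drawing study cohort.

    Classes: EDS, GBS, FSHD, PROMM and an unspecific chronic-pain (CP)
    outgroup, with sizes 59/29/35/89/50.  Each disease marks one or two
    signature regions with probability ~0.7, partially shared regions with
    ~0.5; PROMM is a two-subgroup mixture (thighs marked vs. not), and CP is
    diffuse with every probability <= 0.4 (lower back highest at 0.4).

    The template needs at least 8 named regions.  The default template is a
    12-band silhouette whose bands stand in, top to bottom, for head, neck,
    shoulders, chest/upper arms, elbows, lower back, pelvis/tailbone, hands,
    thighs, knees, lower legs and feet.
    """
    if template is None:
        template = make_synthetic_template(64, 128, n_regions=12, seed=seed)
    bands = list(template.regions)
    if len(bands) < 8:
        raise ValueError("five_group_spec needs a template with >= 8 regions")

    def b(i: int) -> str:  # band by relative position, robust to region count
        return bands[min(i, len(bands) - 1)]

    neck, shoulders, arms, elbows = b(1), b(2), b(3), b(4)
    lower_back, tailbone, hands = b(5), b(6), b(7)
    thighs, knees, lower_legs, feet = b(8), b(9), b(10), b(11)

    classes = (
        # joint/spine pain: neck, tailbone and knees ~70%, shoulders/elbows ~50%
        ClassSpec("EDS", FIVE_GROUP_SIZES["EDS"], {
            neck: 0.7, tailbone: 0.7, knees: 0.7, shoulders: 0.5, elbows: 0.5,
        }),
        # distal neuropathic pain: feet ~70%, hands and tailbone ~50%
        ClassSpec("GBS", FIVE_GROUP_SIZES["GBS"], {
            feet: 0.7, hands: 0.5, tailbone: 0.5,
        }),
        # shoulder girdle and lower back ~55%, upper arms ~40%
        ClassSpec("FSHD", FIVE_GROUP_SIZES["FSHD"], {
            shoulders: 0.55, lower_back: 0.55, arms: 0.4,
        }),
        # proximal myopathy, heterogeneous: thighs-marked vs thighs-unmarked
        ClassSpec("PROMM", FIVE_GROUP_SIZES["PROMM"], subgroups=(
            (0.6, {thighs: 0.85, shoulders: 0.35, lower_back: 0.35, lower_legs: 0.3}),
            (0.4, {thighs: 0.10, shoulders: 0.35, lower_back: 0.35, lower_legs: 0.3}),
        )),
        # unspecific chronic pain: diffuse, everything well below 50%
        ClassSpec("CP", FIVE_GROUP_SIZES["CP"], {
            lower_back: 0.4, neck: 0.2, shoulders: 0.25, arms: 0.15,
            knees: 0.15, feet: 0.1,
        }),
    )
    return SynthSpec(
        template=template,
        classes=classes,
        background_noise=background_noise,
        seed=seed,
    )
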