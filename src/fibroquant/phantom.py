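"""Synthetic two-tissue muscle-slice phantoms and whole study cohorts.

Real muscle MRI shows fibrous tissue as bright, spatially coherent regions
embedded in darker muscle.  The generator emulates exactly that contrast
structure on 2-D slices: fibrous regions are smoothed random blobs
(thresholded low-pass Gaussian noise) planted so that the fibrous-to-muscle
pixel ratio hits a prescribed target exactly up to one boundary-pixel
quantum, then additive Gaussian grey noise is applied and clipped to
[0, 255].

A cohort consists of four groups (lean/obese x youth/aged) measured in three
muscle compartments bilaterally.  Per-subject ratios are drawn from a normal
law whose mean is the group mean and whose standard deviation is
``SEM * sqrt(n)`` (the per-subject s.d. that a reported standard error of the
mean implies), truncated at zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

from .images import (
    GreyImage,
    LABEL_BACKGROUND,
    LABEL_FIBROUS,
    LABEL_MUSCLE,
    TissueMask,
)

GROUPS = ("lean_youth", "lean_aged", "obese_youth", "obese_aged")
COMPARTMENTS = ("anterolateral_calf", "posterior_calf", "plantar")
SIDES = ("left", "right")


class PhantomGeometryError(ValueError):
    """Raised when a requested fibrous-to-muscle ratio cannot be placed."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and contrast parameters for one synthetic slice.

    ``target_ratio`` is the fibrous/muscle pixel-count ratio to plant inside
    the ROI; grey means are 8-bit grey levels with fibrous brighter than
    muscle; ``blob_scale`` is the Gaussian smoothing length (pixels) that
    sets the spatial granularity of fibrous regions; ``roi_margin`` is the
    width of the background border around the ROI.
    """

    target_ratio: float
    image_height: int = 128
    image_width: int = 128
    muscle_grey_mean: float = 80.0
    fibrous_grey_mean: float = 180.0
    grey_noise_sd: float = 5.0
    blob_scale: float = 4.0
    roi_margin: int = 8
    background_grey: float = 10.0

    def __post_init__(self) -> None:
        if self.target_ratio < 0:
            raise ValueError("target_ratio must be >= 0")
        if self.fibrous_grey_mean <= self.muscle_grey_mean:
            raise ValueError("fibrous tissue must be brighter than muscle")
        if min(self.image_height, self.image_width) < 32:
            raise ValueError("image dimensions must be at least 32 pixels")
        if self.grey_noise_sd < 0 or self.blob_scale <= 0:
            raise ValueError("grey_noise_sd must be >= 0 and blob_scale > 0")
        if self.roi_margin < 0 or 2 * self.roi_margin >= min(
            self.image_height, self.image_width
        ):
            raise ValueError("roi_margin leaves no ROI pixels")

    def roi_mask(self) -> np.ndarray:
        """Boolean ROI: the image minus the background border."""
        roi = np.zeros((self.image_height, self.image_width), dtype=bool)
        m = self.roi_margin
        roi[m : self.image_height - m, m : self.image_width - m] = True
        return roi


@dataclass(frozen=True)
class PhantomOutput:
    """A generated slice together with its ground truth."""

    image: GreyImage
    truth_mask: TissueMask
    true_ratio: float

    @property
    def roi(self) -> np.ndarray:
        return self.truth_mask.foreground


def generate_phantom(spec: PhantomSpec, seed: int) -> PhantomOutput:
    """Generate one two-tissue slice with an exactly planted ratio.

    Fibrous pixels are the top-k values of a low-pass-filtered Gaussian
    random field restricted to the ROI, with k chosen so the fibrous/muscle
    count ratio matches ``spec.target_ratio`` up to integer rounding.  The
    same (spec, seed) always yields bit-identical output.
    """
    rng = np.random.default_rng(seed)
    H, W = spec.image_height, spec.image_width
    roi = spec.roi_mask()
    n_roi = int(roi.sum())

    # fibrous fraction f of the ROI satisfies r = f / (1 - f)
    k = int(round(n_roi * spec.target_ratio / (1.0 + spec.target_ratio)))
    if n_roi - k < 1:
        raise PhantomGeometryError(
            f"target_ratio={spec.target_ratio} leaves no muscle pixels "
            f"in a {n_roi}-pixel ROI"
        )

    field_ = ndimage.gaussian_filter(rng.standard_normal((H, W)), spec.blob_scale)
    labels = np.full((H, W), LABEL_BACKGROUND, dtype=np.uint8)
    labels[roi] = LABEL_MUSCLE
    if k > 0:
        roi_idx = np.flatnonzero(roi.ravel())
        order = np.argsort(field_.ravel()[roi_idx], kind="stable")
        fib_idx = roi_idx[order[-k:]]
        flat = labels.ravel()
        flat[fib_idx] = LABEL_FIBROUS
        labels = flat.reshape(H, W)

    grey = np.full((H, W), spec.background_grey, dtype=np.float64)
    grey[labels == LABEL_MUSCLE] = spec.muscle_grey_mean
    grey[labels == LABEL_FIBROUS] = spec.fibrous_grey_mean
    if spec.grey_noise_sd > 0:
        grey = grey + rng.normal(0.0, spec.grey_noise_sd, size=(H, W))
    grey = np.clip(np.round(grey), 0, 255).astype(np.int64)

    mask = TissueMask(labels=labels)
    true_ratio = mask.fibrous_count / mask.muscle_count
    return PhantomOutput(
        image=GreyImage(pixels=grey, levels=256),
        truth_mask=mask,
        true_ratio=float(true_ratio),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Per-group, per-compartment ratio distributions for a study cohort.

    ``ratio_mean`` and ``ratio_sem`` are nested mappings
    ``{compartment: {group: value}}``.  The shipped default configuration
    carries the reported group means +/- SEM of the fibrous-to-muscle ratio
    for all three compartments.
    """

    ratio_mean: dict[str, dict[str, float]]
    ratio_sem: dict[str, dict[str, float]]
    n_per_group: int = 24
    bilateral_asymmetry_sd: float = 0.01
    seed: int | None = None
    phantom: PhantomSpec = field(
        default_factory=lambda: PhantomSpec(target_ratio=0.0)
    )

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.bilateral_asymmetry_sd < 0:
            raise ValueError("bilateral_asymmetry_sd must be >= 0")
        for comp, means in self.ratio_mean.items():
            sems = self.ratio_sem.get(comp)
            if sems is None or set(sems) != set(means):
                raise ValueError(f"mean/SEM group sets differ for {comp!r}")
            for g, m in means.items():
                if m < 0:
                    raise ValueError(f"ratio_mean[{comp!r}][{g!r}] must be >= 0")
                if sems[g] <= 0:
                    raise ValueError(f"ratio_sem[{comp!r}][{g!r}] must be > 0")

    @property
    def compartments(self) -> tuple[str, ...]:
        return tuple(self.ratio_mean)

    @property
    def groups(self) -> tuple[str, ...]:
        first = next(iter(self.ratio_mean.values()))
        return tuple(first)

    def subject_sd(self, compartment: str, group: str) -> float:
        """Per-subject s.d. implied by the group SEM: ``SEM * sqrt(n)``."""
        return self.ratio_sem[compartment][group] * np.sqrt(self.n_per_group)

    @classmethod
    def from_dict(cls, cfg: dict) -> "CohortSpec":
        phantom = PhantomSpec(target_ratio=0.0, **cfg.get("phantom", {}))
        return cls(
            ratio_mean=cfg["ratio_mean"],
            ratio_sem=cfg["ratio_sem"],
            n_per_group=int(cfg.get("n_per_group", 24)),
            bilateral_asymmetry_sd=float(cfg.get("bilateral_asymmetry_sd", 0.01)),
            seed=cfg.get("seed"),
            phantom=phantom,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        ph = self.phantom
        return {
            "ratio_mean": self.ratio_mean,
            "ratio_sem": self.ratio_sem,
            "n_per_group": self.n_per_group,
            "bilateral_asymmetry_sd": self.bilateral_asymmetry_sd,
            "seed": self.seed,
            "phantom": {
                "image_height": ph.image_height,
                "image_width": ph.image_width,
                "muscle_grey_mean": ph.muscle_grey_mean,
                "fibrous_grey_mean": ph.fibrous_grey_mean,
                "grey_noise_sd": ph.grey_noise_sd,
                "blob_scale": ph.blob_scale,
                "roi_margin": ph.roi_margin,
                "background_grey": ph.background_grey,
            },
        }


def default_cohort_spec() -> CohortSpec:
    """The shipped cohort configuration (reported group means +/- SEM)."""
    text = resources.files("fibroquant.data").joinpath("default_cohort.json").read_text()
    return CohortSpec.from_dict(json.loads(text))


@dataclass(frozen=True)
class SubjectPhantoms:
    """Bilateral phantoms for one subject in one muscle compartment."""

    subject_id: str
    group: str
    compartment: str
    left: PhantomOutput
    right: PhantomOutput
    planted_left: float
    planted_right: float

    @property
    def planted_bilateral(self) -> float:
        return 0.5 * (self.planted_left + self.planted_right)


def _stable_ordinal(name: str) -> int:
    # deterministic, platform-independent small integer from a name
    return sum((i + 1) * b for i, b in enumerate(name.encode())) % 100003


def subject_seed_sequence(
    master_seed: int, group: str, compartment: str, subject_index: int
) -> np.random.SeedSequence:
    """Counter-based seed derivation: stable under cohort-size changes."""
    gi = GROUPS.index(group) if group in GROUPS else _stable_ordinal(group)
    ci = (
        COMPARTMENTS.index(compartment)
        if compartment in COMPARTMENTS
        else _stable_ordinal(compartment)
    )
    return np.random.SeedSequence((int(master_seed), gi, ci, int(subject_index)))


def draw_planted_ratios(
    spec: CohortSpec,
    group: str,
    compartment: str,
    n: int,
    master_seed: int,
) -> np.ndarray:
    """Draw ``n`` per-subject ratios for one group/compartment cell.

    Ratios follow ``Normal(mean, SEM * sqrt(n_per_group))`` truncated at
    zero (negative draws are clipped to 0, so no planted ratio is negative).
    Subject ``i`` always receives the same draw regardless of ``n``.
    """
    mean = spec.ratio_mean[compartment][group]
    sd = spec.subject_sd(compartment, group)
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        rng = np.random.default_rng(
            subject_seed_sequence(master_seed, group, compartment, i)
        )
        out[i] = max(rng.normal(mean, sd), 0.0)
    return out


def iter_cohort(
    spec: CohortSpec,
    seed: int | None = None,
    groups: Sequence[str] | None = None,
    compartments: Sequence[str] | None = None,
) -> Iterator[SubjectPhantoms]:
    """Lazily generate bilateral phantoms for every subject/compartment.

    The left/right planted ratios are the subject ratio plus/minus half a
    zero-mean asymmetry perturbation of s.d. ``bilateral_asymmetry_sd``, so
    their bilateral average equals the subject ratio (before truncation).
    """
    master = spec.seed if seed is None else seed
    if master is None:
        raise ValueError("a master seed is required (CohortSpec.seed or argument)")
    groups = tuple(groups) if groups is not None else spec.groups
    compartments = (
        tuple(compartments) if compartments is not None else spec.compartments
    )
    for comp in compartments:
        for group in groups:
            mean = spec.ratio_mean[comp][group]
            sd = spec.subject_sd(comp, group)
            for i in range(spec.n_per_group):
                ss = subject_seed_sequence(master, group, comp, i)
                rng = np.random.default_rng(ss)
                base = max(rng.normal(mean, sd), 0.0)
                asym = rng.normal(0.0, spec.bilateral_asymmetry_sd)
                planted = {
                    "left": max(base + 0.5 * asym, 0.0),
                    "right": max(base - 0.5 * asym, 0.0),
                }
                children = ss.spawn(len(SIDES))
                sides = {}
                for side, child in zip(SIDES, children):
                    side_seed = int(child.generate_state(1)[0]) & 0x7FFFFFFF
                    ph_spec = replace(spec.phantom, target_ratio=planted[side])
                    sides[side] = generate_phantom(ph_spec, side_seed)
                yield SubjectPhantoms(
                    subject_id=f"{group}_{i + 1:03d}",
                    group=group,
                    compartment=comp,
                    left=sides["left"],
                    right=sides["right"],
                    planted_left=planted["left"],
                    planted_right=planted["right"],
                )


def generate_cohort(
    spec: CohortSpec,
    seed: int | None = None,
    groups: Sequence[str] | None = None,
    compartments: Sequence[str] | None = None,
) -> list[SubjectPhantoms]:
    """Materialize the full cohort (see :func:`iter_cohort`)."""
    return list(iter_cohort(spec, seed=seed, groups=groups, compartments=compartments))
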