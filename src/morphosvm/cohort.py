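"""Seeded case-control cohort simulation and hierarchical control matching.

The generator emulates a population-based first-episode affective-psychosis
study: two patient groups (first-episode psychotic mania, BD-I, and psychotic
major depression, MDD) plus a pool of healthy neighborhood controls (HC),
each subject carrying demographics drawn from the published group marginals
and a set of 3D tissue-density maps on a common template grid.  Group
differences are planted as localized additive mean shifts (a spherical
morphometric abnormality) before smoothing; everything downstream of the
generator treats the maps exactly as it would real data.

Control selection follows the study's hierarchical individual matching:
gender first, then age within a 2-year window, then handedness, taking as
many eligible controls as the pool allows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ravens import DensityMap, TissueMapSet, normalize_tbv, smooth

__all__ = [
    "GROUPS",
    "DEMOGRAPHICS",
    "SubjectRecord",
    "EffectSpec",
    "CohortSpec",
    "Cohort",
    "generate_cohort",
    "match_controls",
    "subjects_to_frame",
    "save_subject_table",
    "load_subject_table",
]

GROUPS = ("BD", "MDD", "HC")

#: Published demographic marginals per group: age mean/SD in years (sampling
#: truncated to the study's 18-50 inclusion window), proportion of males,
#: proportion right-handed.  The HC pool is not tabulated directly — only the
#: two matched control subsamples are — so its marginals sit between them.
DEMOGRAPHICS: dict[str, dict[str, float]] = {
    "BD": {"age_mean": 27.09, "age_sd": 8.87, "male": 0.391, "right_handed": 1.0},
    "MDD": {"age_mean": 29.05, "age_sd": 8.34, "male": 0.211, "right_handed": 0.842},
    "HC": {"age_mean": 28.7, "age_sd": 7.3, "male": 0.30, "right_handed": 0.945},
}

AGE_RANGE = (18.0, 50.0)

#: fraction of subjects acquired on the first of the two identical scanners
SCANNER1_FRACTION = 0.55


@dataclass(frozen=True)
class SubjectRecord:
    """Demographics, diagnostic group, and scanner for one participant."""

    id: str
    group: str
    age: float
    gender: str  # "M" | "F"
    handedness: str  # "right" | "left"
    scanner: str  # "S1" | "S2"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not (AGE_RANGE[0] <= self.age <= AGE_RANGE[1]):
            raise ValueError(f"age {self.age} outside inclusion window {AGE_RANGE}")
        if self.gender not in ("M", "F"):
            raise ValueError(f"gender must be 'M' or 'F', got {self.gender!r}")
        if self.handedness not in ("right", "left"):
            raise ValueError(f"bad handedness {self.handedness!r}")
        if self.scanner not in ("S1", "S2"):
            raise ValueError(f"bad scanner {self.scanner!r}")


@dataclass(frozen=True)
class EffectSpec:
    """A planted localized group difference.

    The effect is an additive mean shift of ``effect_size * noise_sd``
    (a standardized difference, Cohen's d) applied to every voxel inside a
    sphere, for subjects of the *case* group, before smoothing.
    """

    region_center: tuple[int, int, int]
    region_radius: float
    effect_size: float
    compartment: str = "GM"

    def __post_init__(self) -> None:
        if self.region_radius < 1:
            raise ValueError("region radius must be >= 1 voxel")
        if self.compartment not in ("GM", "WM", "VENT"):
            raise ValueError(f"bad compartment {self.compartment!r}")

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        center = np.asarray(self.region_center, dtype=float)
        if np.any(center < 0) or np.any(center >= np.asarray(shape)):
            raise ValueError("effect region center outside volume bounds")
        if np.any(center - self.region_radius < -0.5) or np.any(
            center + self.region_radius > np.asarray(shape) - 0.5
        ):
            raise ValueError("effect region does not fit within volume bounds")
        grids = np.indices(shape, dtype=float)
        dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        return dist2 <= self.region_radius**2


@dataclass
class CohortSpec:
    """Full recipe for one synthetic cohort; identical specs give
    bit-identical cohorts."""

    n_per_group: dict[str, int] = field(default_factory=lambda: {"BD": 23, "HC": 33})
    volume_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    effects: list[EffectSpec] = field(default_factory=list)
    noise_sd: float = 1.0
    smoothing_fwhm: float = 8.0
    scanner1_fraction: float = SCANNER1_FRACTION
    normalize: bool = True
    # the source pipeline does not state whether TBV correction preceded
    # smoothing; default normalizes first, flag flips the order
    normalize_after_smoothing: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 2:
                raise ValueError(f"need at least 2 subjects per group, got {g}={n}")
        if any(s < 8 for s in self.volume_shape):
            raise ValueError("degenerate volume shape: need >= 8 voxels per axis")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.scanner1_fraction <= 1.0:
            raise ValueError("scanner1_fraction must be in [0, 1]")

    @property
    def case_group(self) -> str:
        """Group receiving planted effects: the first non-HC group listed,
        falling back to the first group."""
        for g in self.n_per_group:
            if g != "HC":
                return g
        return next(iter(self.n_per_group))


@dataclass
class Cohort:
    """A generated cohort: subject records plus per-subject tissue maps."""

    subjects: list[SubjectRecord]
    maps: dict[str, TissueMapSet]
    spec: CohortSpec

    def labels(self, positive_group: str, negative_group: str) -> np.ndarray:
        """0/1 label vector over subjects belonging to the two groups,
        1 for the positive group, in subject order."""
        return np.array(
            [1 if s.group == positive_group else 0
             for s in self.subjects
             if s.group in (positive_group, negative_group)]
        )

    def subset_ids(self, *groups: str) -> list[str]:
        return [s.id for s in self.subjects if s.group in groups]


# baseline mean densities inside the synthetic brain mask, per compartment;
# roughly GM-dominated cortex with a small ventricular CSF core
_BASELINE = {"GM": 4.0, "WM": 3.0, "VENT": 1.0}


def _brain_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoid inscribed in the grid — a minimal head-shaped support."""
    grids = np.indices(shape, dtype=float)
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    semi = np.asarray(shape, dtype=float) / 2.0
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return r2 <= 1.0


def _sample_demographics(
    group: str, index: int, rng: np.random.Generator, scanner1_fraction: float
) -> SubjectRecord:
    d = DEMOGRAPHICS[group]
    while True:  # truncated normal via rejection; acceptance is high
        age = rng.normal(d["age_mean"], d["age_sd"])
        if AGE_RANGE[0] <= age <= AGE_RANGE[1]:
            break
    return SubjectRecord(
        id=f"{group}{index:03d}",
        group=group,
        age=round(float(age), 1),
        gender="M" if rng.random() < d["male"] else "F",
        handedness="right" if rng.random() < d["right_handed"] else "left",
        scanner="S1" if rng.random() < scanner1_fraction else "S2",
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a seeded cohort of subject records and tissue-map sets.

    Each subject's compartment maps are baseline density plus i.i.d. Gaussian
    voxel noise (SD ``spec.noise_sd``) inside an ellipsoidal brain mask.
    Case-group subjects additionally receive each planted effect's mean shift
    of ``effect_size * noise_sd`` inside its sphere, *before* the 8 mm-default
    Gaussian smoothing and total-brain-volume normalization — so the planted
    standardized difference is exactly Cohen's d at the voxel level.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.volume_shape)
    mask = _brain_mask(shape)
    effect_masks = [(e, e.mask(shape)) for e in spec.effects]
    case = spec.case_group

    subjects: list[SubjectRecord] = []
    maps: dict[str, TissueMapSet] = {}
    for group, n in spec.n_per_group.items():
        for i in range(n):
            rec = _sample_demographics(group, i, rng, spec.scanner1_fraction)
            subjects.append(rec)
            comp: dict[str, DensityMap] = {}
            for name in ("GM", "WM", "VENT"):
                data = np.zeros(shape)
                noise = rng.normal(0.0, spec.noise_sd, size=shape)
                data[mask] = _BASELINE[name] + noise[mask]
                if group == case:
                    for eff, emask in effect_masks:
                        if eff.compartment == name:
                            data[emask] += eff.effect_size * spec.noise_sd
                np.clip(data, 0.0, None, out=data)
                comp[name] = DensityMap(
                    data=data, compartment=name, voxel_size=spec.voxel_size
                )
            mset = TissueMapSet(gm=comp["GM"], wm=comp["WM"], vent=comp["VENT"])
            if spec.normalize and not spec.normalize_after_smoothing:
                mset = normalize_tbv(mset)
            if spec.smoothing_fwhm > 0:
                mset = TissueMapSet(
                    gm=smooth(mset.gm, spec.smoothing_fwhm),
                    wm=smooth(mset.wm, spec.smoothing_fwhm),
                    vent=smooth(mset.vent, spec.smoothing_fwhm),
                )
            if spec.normalize and spec.normalize_after_smoothing:
                mset = normalize_tbv(mset)
            maps[rec.id] = mset
    return Cohort(subjects=subjects, maps=maps, spec=spec)


def _match_tier(case: SubjectRecord, cand: SubjectRecord) -> int:
    """Hierarchical matching rank: gender, then age within 2 years, then
    handedness.  Lower is better."""
    if cand.gender != case.gender:
        return 3
    if abs(cand.age - case.age) > 2.0:
        return 2
    if cand.handedness != case.handedness:
        return 1
    return 0


def match_controls(
    cases: list[SubjectRecord],
    pool: list[SubjectRecord],
    max_controls: int | None = None,
) -> list[SubjectRecord]:
    """Select matched controls from a pool by hierarchical criteria.

    Matching is individual and greedy: cases take turns (round-robin) picking
    their best remaining control, judged by gender match first, then age
    within a 2-year window, then handedness; ties break toward the smallest
    absolute age difference, then the lowest pool index.  Selection continues
    until the pool is exhausted or ``max_controls`` controls are chosen —
    taking as many controls as possible raises power, so the default is no
    cap.  No control is selected twice.
    """
    case_ids = {c.id for c in cases}
    if any(p.id in case_ids for p in pool):
        raise ValueError("control pool overlaps the case list")
    if max_controls is None:
        max_controls = len(pool)
    if max_controls == 0 or not cases:
        return []
    if not pool:
        warnings.warn("empty control pool: no controls matched", stacklevel=2)
        return []

    remaining: list[tuple[int, SubjectRecord]] = list(enumerate(pool))
    chosen: list[SubjectRecord] = []
    while remaining and len(chosen) < max_controls:
        for case in cases:
            if not remaining or len(chosen) >= max_controls:
                break
            best = min(
                remaining,
                key=lambda item: (
                    _match_tier(case, item[1]),
                    abs(item[1].age - case.age),
                    item[0],
                ),
            )
            remaining.remove(best)
            chosen.append(best[1])
    return chosen


# ---------------------------------------------------------------------------
# subject-table I/O

_COLUMNS = ["id", "group", "age", "gender", "handedness", "scanner"]


def subjects_to_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in subjects], columns=_COLUMNS)


def save_subject_table(subjects: list[SubjectRecord], path: str | Path) -> None:
    subjects_to_frame(subjects).to_csv(path, index=False)


def load_subject_table(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    return [
        SubjectRecord(
            id=str(r.id),
            group=str(r.group),
            age=float(r.age),
            gender=str(r.gender),
            handedness=str(r.handedness),
            scanner=str(r.scanner),
        )
        for r in df.itertuples()
    ]
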