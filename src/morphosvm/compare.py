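"""Adaptive regional-element pattern classification (COMPARE-style).

The classifier turns per-subject tissue-density maps into a small set of
regional volumetric features and feeds them to a Gaussian-RBF support vector
machine:

1. voxelwise discrimination — per-voxel Pearson correlation between density
   and 0/1 group membership; |r| is the voxel's discriminative power;
2. watershed partitioning of the discrimination landscape into candidate
   regions, one per local peak of |r|;
3. region growing from each region's peak voxel, greedily adding 26-connected
   neighbors while the summed regional feature's discriminative power does
   not decrease;
4. feature selection by backward elimination on SVM weight magnitude, with
   the retained subset size chosen by internal cross-validation;
5. a nonlinear SVM (Gaussian radial basis function kernel) on the selected
   regional features.

All operations take explicit label vectors so the leave-one-out harness can
guarantee that held-out subjects never touch any training-side computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed as _skimage_watershed
from sklearn.feature_selection import RFE
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "PipelineConfig",
    "DiscriminationMap",
    "RegionalElement",
    "FeatureSet",
    "TrainedModel",
    "voxelwise_discrimination",
    "watershed_partition",
    "spatial_consistency",
    "grow_region",
    "extract_elements",
    "select_features",
    "train_svm",
    "classify",
    "element_feature",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class PipelineConfig:
    """Tunable settings for feature extraction, selection, and the SVM.

    watershed_floor:
        voxels with |r| below this are background, excluded from candidate
        regions (the source method publishes no floor; 0.1 is the default).
    max_candidates:
        cap on the number of grown regional elements passed to selection,
        keeping the strongest seeds.
    svm_c / svm_gamma:
        RBF-SVM misclassification cost and kernel width; defaults C = 1 and
        gamma = 1 / (n_features * feature variance) (sklearn "scale").
        Class weights are always balanced by inverse class frequency: a
        leave-one-out harness trains on folds imbalanced by exactly one
        subject, and unweighted SVMs then drift toward the majority class —
        systematically the opposite of the held-out subject.
    selection_cv_folds:
        internal stratified CV folds used to pick the retained subset size.
    compartments:
        tissue maps pooled into one candidate set.
    """

    watershed_floor: float = 0.1
    max_candidates: int = 32
    svm_c: float = 1.0
    svm_gamma: float | str = "scale"
    selection_cv_folds: int = 5
    compartments: tuple[str, ...] = ("GM", "WM", "VENT")
    smoothing_fwhm: float = 8.0


@dataclass
class DiscriminationMap:
    """Per-voxel correlation of tissue density with group membership."""

    score: np.ndarray
    compartment: str = "GM"

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=np.float64)
        if not np.all(np.isfinite(self.score)):
            raise ValueError("discrimination map contains non-finite scores")
        if np.any(np.abs(self.score) > 1.0 + 1e-12):
            raise ValueError("correlation scores must lie in [-1, 1]")


@dataclass
class RegionalElement:
    """A grown voxel cluster serving as one volumetric classifier feature.

    ``feature_values[i]`` is subject i's total density over the member
    voxels; ``discriminative_power`` is |Pearson r| of that sum with the
    labels; ``consistency`` is the intraclass correlation of the member
    voxels' per-subject values (spatial agreement in the element's
    neighborhood), used as a ranking tie-break.
    """

    voxels: np.ndarray  # (k, 3) int coordinates
    seed_voxel: tuple[int, int, int]
    feature_values: np.ndarray  # (n_subjects,)
    discriminative_power: float
    consistency: float
    compartment: str = "GM"

    @property
    def size(self) -> int:
        return len(self.voxels)


@dataclass
class FeatureSet:
    """Candidate elements in selection-rank order with the retained count."""

    elements: list[RegionalElement]
    n_selected: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_selected <= len(self.elements):
            raise ValueError("n_selected exceeds the number of elements")

    @property
    def selected(self) -> list[RegionalElement]:
        return self.elements[: self.n_selected]

    def matrix(self, selected_only: bool = True) -> np.ndarray:
        els = self.selected if selected_only else self.elements
        return np.column_stack([e.feature_values for e in els])


def _check_labels(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if counts.min() < 2:
        raise ValueError("need at least 2 subjects per group")
    return (y == classes.max()).astype(np.float64)


def voxelwise_discrimination(
    stack: np.ndarray, labels: np.ndarray, compartment: str = "GM"
) -> DiscriminationMap:
    """Pearson correlation of each voxel's density with 0/1 group labels.

    ``stack`` has shape (n_subjects, X, Y, Z).  Voxels with zero variance
    across subjects score 0 by convention.
    """
    y = _check_labels(labels)
    stack = np.asarray(stack, dtype=np.float64)
    n = stack.shape[0]
    if len(y) != n:
        raise ValueError("label vector length does not match subject count")
    yc = y - y.mean()
    y_norm = np.sqrt((yc**2).sum())
    flat = stack.reshape(n, -1)
    xc = flat - flat.mean(axis=0)
    num = yc @ xc
    x_norm = np.sqrt((xc**2).sum(axis=0))
    r = np.zeros(flat.shape[1])
    ok = x_norm > 0
    r[ok] = num[ok] / (x_norm[ok] * y_norm)
    np.clip(r, -1.0, 1.0, out=r)
    return DiscriminationMap(
        score=r.reshape(stack.shape[1:]), compartment=compartment
    )


def watershed_partition(
    dmap: DiscriminationMap, floor: float = 0.1
) -> np.ndarray:
    """Partition above-floor voxels into catchment basins of |score| peaks.

    Watershed runs on -|score| with one marker per local maximum of |score|
    (26-connectivity), so each region contains exactly one discriminative
    peak.  Voxels with |score| < floor are background (label 0).
    """
    a = np.abs(dmap.score)
    mask = a >= floor
    if not mask.any():
        warnings.warn("all scores below floor: empty partition", stacklevel=2)
        return np.zeros(a.shape, dtype=np.int32)
    peaks = (ndimage.maximum_filter(a, footprint=_CONN26, mode="constant") == a) & mask
    markers, n_mark = ndimage.label(peaks, structure=_CONN26)
    labels = _skimage_watershed(-a, markers=markers, mask=mask, connectivity=_CONN26)
    return labels.astype(np.int32)


def spatial_consistency(values: np.ndarray) -> float:
    """One-way random-effects intraclass correlation, ICC(1,1).

    ``values`` is an (n_subjects, k_features) matrix of per-subject values
    for adjacent candidate features.  Rows are the random targets, columns
    the measurements; ICC(1,1) = (MSB - MSW) / (MSB + (k-1) MSW), bounded in
    [-1/(k-1), 1].  Degenerate zero-variance input returns 0 with a warning.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 features")
    n, k = x.shape
    row_means = x.mean(axis=1)
    grand = x.mean()
    ss_between = k * ((row_means - grand) ** 2).sum()
    ss_within = ((x - row_means[:, None]) ** 2).sum()
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom <= 0:
        warnings.warn("zero-variance input: ICC defined as 0", stacklevel=2)
        return 0.0
    return float((msb - msw) / denom)


def _power_stats(labels: np.ndarray):
    y = _check_labels(labels)
    yc = y - y.mean()
    return yc, float(np.sqrt((yc**2).sum()))


def _feature_power(feature: np.ndarray, yc: np.ndarray, y_norm: float) -> float:
    fc = feature - feature.mean()
    f_norm = np.sqrt((fc**2).sum())
    if f_norm == 0:
        return 0.0
    return float(abs(yc @ fc) / (f_norm * y_norm))


def grow_region(
    seed: tuple[int, int, int],
    dmap: DiscriminationMap,
    stack: np.ndarray,
    labels: np.ndarray,
    region_mask: np.ndarray | None = None,
) -> RegionalElement:
    """Grow a regional element from a watershed peak.

    Starting from the seed voxel, 26-connected neighbors (restricted to
    ``region_mask``, normally the seed's watershed region) are added
    greedily: at each step the neighbor that maximizes the summed feature's
    |Pearson r| with the labels joins, and growth stops as soon as no
    candidate keeps the power from decreasing.  The result is connected and
    never less discriminative than the seed alone.
    """
    shape = dmap.score.shape
    seed = tuple(int(c) for c in seed)
    if any(c < 0 or c >= s for c, s in zip(seed, shape)):
        raise ValueError(f"seed {seed} outside grid {shape}")
    if region_mask is None:
        region_mask = np.ones(shape, dtype=bool)
    stack = np.asarray(stack, dtype=np.float64)
    n = stack.shape[0]
    flat = stack.reshape(n, -1)
    yc, y_norm = _power_stats(labels)

    strides = np.array([shape[1] * shape[2], shape[2], 1], dtype=np.intp)
    offsets = np.array(
        [
            dx * strides[0] + dy * strides[1] + dz
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
        ],
        dtype=np.intp,
    )
    allowed = region_mask.ravel()
    coords = np.indices(shape).reshape(3, -1)

    def in_bounds_neighbors(flat_idx: int) -> np.ndarray:
        c = coords[:, flat_idx]
        nb = []
        for off, (dx, dy, dz) in zip(
            offsets,
            (
                (dx, dy, dz)
                for dx in (-1, 0, 1)
                for dy in (-1, 0, 1)
                for dz in (-1, 0, 1)
                if (dx, dy, dz) != (0, 0, 0)
            ),
        ):
            x, y_, z = c[0] + dx, c[1] + dy, c[2] + dz
            if 0 <= x < shape[0] and 0 <= y_ < shape[1] and 0 <= z < shape[2]:
                nb.append(flat_idx + off)
        return np.array(nb, dtype=np.intp)

    seed_flat = int(seed[0] * strides[0] + seed[1] * strides[1] + seed[2])
    member = {seed_flat}
    feature = flat[:, seed_flat].copy()
    power = _feature_power(feature, yc, y_norm)

    frontier = set()
    for nb in in_bounds_neighbors(seed_flat):
        if allowed[nb] and nb not in member:
            frontier.add(int(nb))

    while frontier:
        cand = np.fromiter(frontier, dtype=np.intp)
        cand.sort()  # deterministic tie-break: lowest flat index wins argmax
        trial = feature[:, None] + flat[:, cand]
        tc = trial - trial.mean(axis=0)
        norms = np.sqrt((tc**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            powers = np.abs(yc @ tc) / (norms * y_norm)
        powers = np.where(norms > 0, powers, 0.0)
        best = int(np.argmax(powers))
        # non-decreasing rule with a round-off guard: exact ties (e.g. a
        # noiseless plateau) must keep growing, genuine drops must stop
        if powers[best] < power - 1e-9:
            break
        power = float(powers[best])
        chosen = int(cand[best])
        member.add(chosen)
        feature = feature + flat[:, chosen]
        frontier.discard(chosen)
        for nb in in_bounds_neighbors(chosen):
            if allowed[nb] and nb not in member:
                frontier.add(int(nb))

    idx = np.array(sorted(member), dtype=np.intp)
    vox = coords[:, idx].T.copy()
    if len(idx) >= 2 and n >= 2:
        consistency = spatial_consistency(flat[:, idx])
    else:
        consistency = 1.0
    return RegionalElement(
        voxels=vox,
        seed_voxel=seed,
        feature_values=feature,
        discriminative_power=power,
        consistency=consistency,
        compartment=dmap.compartment,
    )


def element_feature(element: RegionalElement, volume: np.ndarray) -> float:
    """Summed density of one subject's volume over the element's voxels."""
    v = element.voxels
    return float(volume[v[:, 0], v[:, 1], v[:, 2]].sum())


def extract_elements(
    stack: np.ndarray,
    labels: np.ndarray,
    config: PipelineConfig | None = None,
    compartment: str = "GM",
) -> list[RegionalElement]:
    """Full adaptive regional feature extraction for one tissue compartment.

    Computes the discrimination map, partitions it by watershed, grows one
    element from each region's peak (strongest seeds first, capped at
    ``config.max_candidates``), and returns elements sorted by discriminative
    power, with spatial consistency then seed order breaking ties.
    """
    cfg = config or PipelineConfig()
    dmap = voxelwise_discrimination(stack, labels, compartment)
    regions = watershed_partition(dmap, floor=cfg.watershed_floor)
    n_regions = int(regions.max())
    if n_regions == 0:
        return []
    a = np.abs(dmap.score)
    # one seed per region: its |score| peak (lowest flat index on plateaus)
    flat_labels = regions.ravel()
    flat_a = a.ravel()
    order = np.lexsort((np.arange(flat_a.size), -flat_a))  # by score desc, then index
    seed_of: dict[int, int] = {}
    for i in order:
        lab = int(flat_labels[i])
        if lab > 0 and lab not in seed_of:
            seed_of[lab] = int(i)
            if len(seed_of) == n_regions:
                break
    seeds = sorted(
        seed_of.items(), key=lambda kv: (-flat_a[kv[1]], kv[1])
    )[: cfg.max_candidates]

    shape = dmap.score.shape
    elements = []
    for lab, flat_idx in seeds:
        coord = np.unravel_index(flat_idx, shape)
        elements.append(
            grow_region(coord, dmap, stack, labels, region_mask=regions == lab)
        )
    elements.sort(
        key=lambda e: (
            -e.discriminative_power,
            -e.consistency,
            e.seed_voxel,
        )
    )
    return elements


def _svc_rbf(cfg: PipelineConfig) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svm",
                SVC(
                    kernel="rbf",
                    C=cfg.svm_c,
                    gamma=cfg.svm_gamma,
                    class_weight="balanced",
                ),
            ),
        ]
    )


def select_features(
    candidates: list[RegionalElement],
    labels: np.ndarray,
    config: PipelineConfig | None = None,
) -> FeatureSet:
    """Rank candidate elements by SVM criteria and pick the retained count.

    Ranking is recursive backward elimination on linear-SVM weight magnitude
    (half the surviving features dropped per round).  The number retained is
    the size, over a doubling ladder 1, 2, 4, ..., k of top-ranked subsets,
    that maximizes internal stratified cross-validated accuracy of the RBF
    SVM on the training data alone; ties go to the smaller subset.
    Deterministic given data and configuration.
    """
    if not candidates:
        raise ValueError("no candidate elements to select from")
    cfg = config or PipelineConfig()
    y = _check_labels(np.asarray(labels))
    X = np.column_stack([e.feature_values for e in candidates])
    k = X.shape[1]

    if k == 1:
        order = [0]
    else:
        rfe = RFE(
            estimator=SVC(kernel="linear", C=cfg.svm_c, class_weight="balanced"),
            n_features_to_select=1,
            step=0.5,
        )
        Xs = StandardScaler().fit_transform(X)
        rfe.fit(Xs, y)
        # rank asc; ties (features dropped in the same round) break by the
        # candidates' own order, which is discriminative-power rank
        order = sorted(range(k), key=lambda j: (rfe.ranking_[j], j))

    _, counts = np.unique(y, return_counts=True)
    n_splits = int(min(cfg.selection_cv_folds, counts.min()))
    sizes: list[int] = []
    m = 1
    while m < k:
        sizes.append(m)
        m *= 2
    sizes.append(k)

    best_size, best_acc = sizes[0], -1.0
    if n_splits >= 2:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=False)
        for m in sizes:
            acc = cross_val_score(
                _svc_rbf(cfg), X[:, order[:m]], y, cv=skf, scoring="accuracy"
            ).mean()
            if acc > best_acc + 1e-12:
                best_acc, best_size = float(acc), m
    else:  # too few subjects for internal CV: keep everything
        best_size = k

    return FeatureSet(elements=[candidates[j] for j in order], n_selected=best_size)


@dataclass
class TrainedModel:
    """A fitted RBF-SVM on standardized regional features.

    Standardization statistics come from the training subjects only; the
    decision function is positive on the patient-like side.
    """

    pipeline: Pipeline
    n_features: int
    gamma: float | str
    c: float
    n_support: int = 0
    decision_offset: float = 0.0

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature count {X.shape[1]} does not match model "
                f"({self.n_features})"
            )
        return self.pipeline.decision_function(X)


def train_svm(
    X: np.ndarray,
    labels: np.ndarray,
    config: PipelineConfig | None = None,
) -> TrainedModel:
    """Fit the Gaussian-RBF SVM on a (subjects x features) matrix."""
    cfg = config or PipelineConfig()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2D (subjects x features)")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    y = _check_labels(np.asarray(labels))
    pipe = _svc_rbf(cfg)
    pipe.fit(X, y)
    svm: SVC = pipe.named_steps["svm"]
    return TrainedModel(
        pipeline=pipe,
        n_features=X.shape[1],
        gamma=cfg.svm_gamma,
        c=cfg.svm_c,
        n_support=int(svm.n_support_.sum()),
        decision_offset=float(svm.intercept_[0]),
    )


def classify(model: TrainedModel, features: np.ndarray) -> float:
    """Signed decision value for one subject; positive means patient-like."""
    x = np.asarray(features, dtype=np.float64).reshape(1, -1)
    if not np.all(np.isfinite(x)):
        raise ValueError("features contain non-finite values")
    return float(model.decision(x)[0])


def save_discrimination_map(
    dmap: DiscriminationMap,
    path,
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> None:
    """Write the signed correlation map as a NIfTI-1 volume."""
    import nibabel as nib

    aff = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(dmap.score.astype(np.float32), aff), str(path))


def features_to_csv(fset: FeatureSet, subject_ids, path) -> None:
    """Export the subjects x features matrix of a feature set as CSV."""
    import pandas as pd

    cols = {
        f"{e.compartment}_{'_'.join(map(str, e.seed_voxel))}": e.feature_values
        for e in fset.elements
    }
    pd.DataFrame(cols, index=list(subject_ids)).to_csv(path, index_label="id")
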