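"""Lesion/behaviour data structures and elementary operations.

This module holds the containers shared by the whole package:

* :class:`RegionSet` — the ordered catalogue of regions of interest (ROIs),
  each with an atlas label and a voxel count, plus one designated
  "rest of the brain" (RoB) element that absorbs everything not modelled
  individually.
* :class:`LesionDataset` — the patients × ROIs matrix of graded lesion
  loads (percentage of each region's voxels overlapped by the lesion),
  together with the raw limb motor score and its binarised form.
* :class:`CorrelationMatrix` — pairwise Pearson correlations of the
  regional lesion-load columns, used to audit vascular-territory
  covariance between regions.

It also implements the elementary operations on these containers: motor
score derivation and binarisation, lesion-load extraction from labelled
volumes, lesion-pattern correlation, and the voxel-conserving merge of
discarded regions into the RoB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Region",
    "RegionSet",
    "LesionDataset",
    "CorrelationMatrix",
    "derive_motor_score",
    "binarize_performance",
    "extract_lesion_loads",
    "compute_lesion_correlations",
    "merge_into_rob",
    "filter_patients",
]

#: Motor score value meaning "no limb impairment".
NO_IMPAIRMENT_SCORE = 10
#: Worst possible motor score (both limb items maximal).
WORST_SCORE = 2


@dataclass(frozen=True)
class Region:
    """One catalogue entry: an ROI or the rest-of-brain element.

    Parameters
    ----------
    region_id:
        Unique string identifier (e.g. ``"Internal_Capsule_R"``).
    atlas_label:
        Integer label of the region in the atlas volume; ``None`` for the
        RoB, whose voxels are defined by exclusion.
    voxel_count:
        Number of voxels the region occupies in the atlas (> 0).
    """

    region_id: str
    atlas_label: Optional[int]
    voxel_count: int

    def __post_init__(self) -> None:
        if self.voxel_count <= 0:
            raise ValueError(
                f"region {self.region_id!r}: voxel_count must be positive, "
                f"got {self.voxel_count}"
            )


@dataclass(frozen=True)
class RegionSet:
    """Ordered ROI catalogue with exactly one rest-of-brain element."""

    regions: tuple[Region, ...]
    rob_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("region_ids must be unique")
        if self.rob_id not in ids:
            raise ValueError(f"rob_id {self.rob_id!r} not among region_ids")
        labels = [
            r.atlas_label
            for r in self.regions
            if r.region_id != self.rob_id and r.atlas_label is not None
        ]
        if len(set(labels)) != len(labels):
            raise ValueError("atlas_labels must be unique among non-RoB regions")

    # -- convenience accessors -------------------------------------------
    @property
    def ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    @property
    def voxel_counts(self) -> np.ndarray:
        return np.array([r.voxel_count for r in self.regions], dtype=np.int64)

    @property
    def rob_index(self) -> int:
        return self.ids.index(self.rob_id)

    @property
    def non_rob_ids(self) -> list[str]:
        return [r.region_id for r in self.regions if r.region_id != self.rob_id]

    def __len__(self) -> int:
        return len(self.regions)

    def index(self, region_id: str) -> int:
        return self.ids.index(region_id)

    def __getitem__(self, region_id: str) -> Region:
        return self.regions[self.index(region_id)]


@dataclass
class LesionDataset:
    """Graded lesion loads plus behavioural outcome for a patient cohort.

    ``loads`` is an ``(n_patients, n_regions)`` float matrix in percent
    (0–100), column order bound to ``region_set``.  ``performance`` is the
    binarised behavioural ability (1 = intact, i.e. motor score of 10;
    0 = any deficit).  ``metadata`` optionally carries per-patient flags
    (e.g. bilateral or recurrent stroke) used for leave-out analyses.
    """

    patient_ids: list[str]
    loads: np.ndarray
    raw_motor_score: np.ndarray
    performance: np.ndarray
    region_set: RegionSet
    metadata: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.loads = np.asarray(self.loads, dtype=float)
        self.raw_motor_score = np.asarray(self.raw_motor_score, dtype=int)
        self.performance = np.asarray(self.performance, dtype=int)
        n, p = self.loads.shape
        if len(self.patient_ids) != n:
            raise ValueError("patient_ids length does not match loads rows")
        if p != len(self.region_set):
            raise ValueError(
                f"loads has {p} columns but region_set has "
                f"{len(self.region_set)} regions"
            )
        if np.any(self.loads < 0) or np.any(self.loads > 100):
            raise ValueError("lesion loads must lie in [0, 100]")
        if np.any((self.raw_motor_score < WORST_SCORE) | (self.raw_motor_score > NO_IMPAIRMENT_SCORE)):
            raise ValueError("raw motor scores must lie in [2, 10]")
        expected = (self.raw_motor_score == NO_IMPAIRMENT_SCORE).astype(int)
        if not np.array_equal(self.performance, expected):
            raise ValueError(
                "performance must be 1 exactly when raw_motor_score == 10"
            )
        if self.metadata is not None and len(self.metadata) != n:
            raise ValueError("metadata rows do not match number of patients")

    @property
    def n_patients(self) -> int:
        return self.loads.shape[0]

    @property
    def n_regions(self) -> int:
        return self.loads.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Lesion loads as a DataFrame indexed by patient, columns = ROIs."""
        return pd.DataFrame(
            self.loads, index=self.patient_ids, columns=self.region_set.ids
        )

    def subset(self, mask: np.ndarray) -> "LesionDataset":
        """Restrict to patients where ``mask`` is True (order preserved)."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_patients,):
            raise ValueError("mask length must equal number of patients")
        return LesionDataset(
            patient_ids=[p for p, m in zip(self.patient_ids, mask) if m],
            loads=self.loads[mask],
            raw_motor_score=self.raw_motor_score[mask],
            performance=self.performance[mask],
            region_set=self.region_set,
            metadata=None if self.metadata is None else self.metadata.loc[mask].reset_index(drop=True),
        )


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations of regional lesion-load columns.

    ``r`` is symmetric with unit diagonal; ``p`` holds two-sided p-values
    from the t-distribution with n−2 degrees of freedom.  Columns with zero
    variance have undefined correlations: their off-diagonal cells are NaN
    (missing, not zero) and their ids are listed in ``undefined_ids``.
    """

    r: np.ndarray
    p: np.ndarray
    region_ids: list[str]
    undefined_ids: list[str] = field(default_factory=list)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (region_i, region_j, r, p) table, upper triangle."""
        rows = []
        k = len(self.region_ids)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(
                    (self.region_ids[i], self.region_ids[j], self.r[i, j], self.p[i, j])
                )
        return pd.DataFrame(rows, columns=["region_i", "region_j", "r", "p"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.region_ids, columns=self.region_ids)


# ---------------------------------------------------------------------------
# Score handling
# ---------------------------------------------------------------------------

def derive_motor_score(upper_limb_item: int, lower_limb_item: int) -> int:
    """Global limb motor score from the two NIHSS limb items.

    Each item grades one limb from 0 (no drift) to 4 (no movement).  The
    combined score is ``10 − (upper + lower)``: 10 means no impairment,
    2 means major impairment of both limbs.
    """
    upper = np.asarray(upper_limb_item)
    lower = np.asarray(lower_limb_item)
    if np.any((upper < 0) | (upper > 4)) or np.any((lower < 0) | (lower > 4)):
        raise ValueError("NIHSS limb items must lie in [0, 4]")
    score = NO_IMPAIRMENT_SCORE - (upper + lower)
    return int(score) if score.ndim == 0 else score.astype(int)


def binarize_performance(motor_score: int) -> int:
    """Binary behavioural ability from the motor score.

    Returns 1 (intact ability) exactly when the score equals the
    no-impairment ceiling of 10, else 0 (deficit).  The output encodes
    ability directly, the orientation a performance-based contribution
    analysis requires: higher = better function.
    """
    score = np.asarray(motor_score)
    if np.any((score < WORST_SCORE) | (score > NO_IMPAIRMENT_SCORE)):
        raise ValueError("motor score must lie in [2, 10]")
    out = (score == NO_IMPAIRMENT_SCORE).astype(int)
    return int(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Lesion-load extraction
# ---------------------------------------------------------------------------

def _as_array(volume) -> np.ndarray:
    """Accept a numpy array or a nibabel spatial image."""
    if hasattr(volume, "dataobj"):
        return np.asanyarray(volume.dataobj)
    return np.asarray(volume)


def extract_lesion_loads(
    lesion_mask,
    atlas,
    region_set: RegionSet,
) -> tuple[np.ndarray, np.ndarray]:
    """Absolute and relative lesion load per region from labelled volumes.

    ``lesion_mask`` is a binary volume (1 = lesioned voxel) on the same
    grid as ``atlas``, an integer-labelled volume.  Both may be numpy
    arrays or nibabel images; no resampling is performed — registration to
    a common template is an upstream step.

    For each listed region ``r``: ``absolute[r]`` counts voxels where the
    mask is 1 and the atlas carries the region's label; ``relative[r]`` is
    ``100 * absolute[r] / voxel_count(r)``.  The RoB row is computed over
    all atlas voxels (label > 0) not claimed by any listed region, so the
    per-patient total of absolute counts equals the number of lesioned
    voxels falling inside the atlas.

    Returns
    -------
    (absolute_counts, relative_loads):
        Arrays aligned with ``region_set`` order.
    """
    mask = _as_array(lesion_mask)
    atlas_arr = _as_array(atlas).astype(np.int64)
    if mask.shape != atlas_arr.shape:
        raise ValueError(
            f"grid mismatch: mask {mask.shape} vs atlas {atlas_arr.shape}"
        )
    uniq = np.unique(mask)
    if not np.all(np.isin(uniq, [0, 1])):
        raise ValueError("lesion mask must be binary (values in {0, 1})")
    mask = mask.astype(bool)

    n = len(region_set)
    absolute = np.zeros(n, dtype=np.int64)
    claimed = np.zeros_like(atlas_arr, dtype=bool)
    for i, region in enumerate(region_set.regions):
        if region.region_id == region_set.rob_id:
            continue
        in_region = atlas_arr == region.atlas_label
        if not in_region.any():
            warnings.warn(
                f"atlas label {region.atlas_label} "
                f"({region.region_id!r}) absent from atlas volume; count 0",
                stacklevel=2,
            )
        claimed |= in_region
        absolute[i] = int(np.count_nonzero(mask & in_region))

    rob_i = region_set.rob_index
    rob_domain = (atlas_arr > 0) & ~claimed
    absolute[rob_i] = int(np.count_nonzero(mask & rob_domain))

    relative = 100.0 * absolute / region_set.voxel_counts
    return absolute, relative


# ---------------------------------------------------------------------------
# Lesion-pattern correlation
# ---------------------------------------------------------------------------

def compute_lesion_correlations(
    dataset: LesionDataset,
    region_subset: Optional[Sequence[str]] = None,
) -> CorrelationMatrix:
    """Pairwise Pearson correlation of relative lesion-load columns.

    Correlations are computed across patients for every pair of selected
    regions; two-sided p-values come from the t-distribution with n−2
    degrees of freedom.  Constant columns yield undefined correlations,
    reported as NaN and flagged in ``undefined_ids`` (a missing value,
    deliberately not coerced to 0).
    """
    ids = list(region_subset) if region_subset is not None else dataset.region_set.ids
    cols = [dataset.region_set.index(rid) for rid in ids]
    x = dataset.loads[:, cols]
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 patients for correlation p-values")

    sd = x.std(axis=0)
    defined = sd > 0
    undefined_ids = [rid for rid, d in zip(ids, defined) if not d]

    k = len(ids)
    r = np.full((k, k), np.nan)
    if defined.any():
        sub = np.corrcoef(x[:, defined], rowvar=False)
        sub = np.atleast_2d(sub)
        idx = np.flatnonzero(defined)
        r[np.ix_(idx, idx)] = sub
    np.fill_diagonal(r, 1.0)
    # guard against tiny numerical excursions outside [-1, 1]
    r = np.clip(r, -1.0, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    p[np.isnan(r)] = np.nan
    np.fill_diagonal(p, 0.0)

    return CorrelationMatrix(r=r, p=p, region_ids=ids, undefined_ids=undefined_ids)


# ---------------------------------------------------------------------------
# Rest-of-brain bookkeeping
# ---------------------------------------------------------------------------

def merge_into_rob(dataset: LesionDataset, discard_ids: Sequence[str]) -> LesionDataset:
    """Fold discarded regions into the rest-of-brain element.

    The new RoB lesion load is the voxel-count-weighted pool of the old
    RoB column and every discarded column — equivalently, pooled lesioned
    voxels divided by pooled voxel count, times 100.  This makes merging
    associative and conserves each patient's pooled lesioned-voxel count
    exactly.  Discarded columns are removed; patients, scores and the
    remaining column order are untouched.
    """
    discard_ids = list(discard_ids)
    rs = dataset.region_set
    if rs.rob_id in discard_ids:
        raise ValueError("cannot discard the rest-of-brain element itself")
    missing = [d for d in discard_ids if d not in rs.ids]
    if missing:
        raise ValueError(f"discard ids not in region set: {missing}")
    if not discard_ids:
        return dataset

    vox = rs.voxel_counts.astype(float)
    # absolute lesioned voxels per patient per region
    lesioned = dataset.loads * vox[None, :] / 100.0

    discard_idx = [rs.index(d) for d in discard_ids]
    rob_i = rs.rob_index
    pool_idx = [rob_i] + discard_idx
    pooled_lesioned = lesioned[:, pool_idx].sum(axis=1)
    pooled_vox = vox[pool_idx].sum()
    new_rob_load = 100.0 * pooled_lesioned / pooled_vox

    keep = [i for i in range(len(rs)) if i not in set(discard_idx)]
    new_regions = []
    for i in keep:
        region = rs.regions[i]
        if i == rob_i:
            region = replace(region, voxel_count=int(pooled_vox))
        new_regions.append(region)
    new_rs = RegionSet(regions=tuple(new_regions), rob_id=rs.rob_id)

    new_loads = dataset.loads[:, keep].copy()
    new_loads[:, new_rs.rob_index] = new_rob_load
    # pooling of values in [0, 100] stays in [0, 100]; clip rounding dust
    new_loads = np.clip(new_loads, 0.0, 100.0)

    return LesionDataset(
        patient_ids=list(dataset.patient_ids),
        loads=new_loads,
        raw_motor_score=dataset.raw_motor_score.copy(),
        performance=dataset.performance.copy(),
        region_set=new_rs,
        metadata=dataset.metadata,
    )


def filter_patients(
    dataset: LesionDataset,
    exclude_bilateral: bool = False,
    exclude_recurrent: bool = False,
    bilateral_column: str = "bilateral",
    recurrent_column: str = "recurrent",
) -> LesionDataset:
    """Leave-out subsetting by patient metadata flags.

    Drops patients flagged bilateral and/or recurrent stroke, reproducing
    sensitivity analyses that re-run the pipeline on restricted cohorts.
    Requires ``dataset.metadata`` with boolean-like columns.
    """
    if not (exclude_bilateral or exclude_recurrent):
        return dataset
    if dataset.metadata is None:
        raise ValueError("patient metadata required for leave-out filtering")
    keep = np.ones(dataset.n_patients, dtype=bool)
    if exclude_bilateral:
        keep &= ~dataset.metadata[bilateral_column].to_numpy(dtype=bool)
    if exclude_recurrent:
        keep &= ~dataset.metadata[recurrent_column].to_numpy(dtype=bool)
    return dataset.subset(keep)
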