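"""Shared fixtures: small hand-built datasets and region catalogues."""

import numpy as np
import pytest
from hypothesis import settings

from lesionmsa import LesionDataset, Region, RegionSet

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


def make_region_set(n_regions: int, voxel_counts=None, rob_voxels: int = 10000) -> RegionSet:
    """n_regions ordinary ROIs plus a trailing RoB element."""
    if voxel_counts is None:
        voxel_counts = [1000] * n_regions
    regions = tuple(
        Region(region_id=f"R{i:02d}", atlas_label=i + 1, voxel_count=int(voxel_counts[i]))
        for i in range(n_regions)
    ) + (Region(region_id="RoB", atlas_label=None, voxel_count=rob_voxels),)
    return RegionSet(regions=regions, rob_id="RoB")


def make_dataset(loads: np.ndarray, performance: np.ndarray, region_set=None, voxel_counts=None) -> LesionDataset:
    """Dataset from a loads matrix and binary outcomes (raw score implied)."""
    loads = np.asarray(loads, dtype=float)
    performance = np.asarray(performance, dtype=int)
    n, p = loads.shape
    if region_set is None:
        region_set = make_region_set(p - 1, voxel_counts=voxel_counts)
    raw = np.where(performance == 1, 10, 5)
    return LesionDataset(
        patient_ids=[f"P{i:03d}" for i in range(n)],
        loads=loads,
        raw_motor_score=raw,
        performance=performance,
        region_set=region_set,
    )


def threshold_dataset(n: int = 60, n_regions: int = 4, causal: int = 0,
                      threshold: float = 50.0, seed: int = 0) -> LesionDataset:
    """Outcome is a deterministic threshold on one region's load.

    Half the patients have heavy damage of the causal region; other
    regions carry independent nuisance loads.
    """
    rng = np.random.default_rng(seed)
    loads = np.zeros((n, n_regions + 1))
    loads[:, :n_regions] = rng.uniform(0, 100, size=(n, n_regions))
    performance = (loads[:, causal] < threshold).astype(int)
    loads[:, n_regions] = rng.uniform(0, 3, size=n)  # faint RoB load
    return make_dataset(loads, performance)


@pytest.fixture
def small_threshold_dataset() -> LesionDataset:
    return threshold_dataset(n=60, seed=11)


@pytest.fixture
def tiny_grid() -> dict:
    """One-point forest grid used to keep unit tests fast."""
    return {
        "n_estimators": [30],
        "max_depth": [None],
        "max_features": ["sqrt"],
        "bootstrap": [True],
        "min_samples_leaf": [2],
        "min_samples_split": [2],
    }
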