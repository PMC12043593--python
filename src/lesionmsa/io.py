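"""Readers and writers for the package's on-disk formats.

Tables are CSV/TSV (pandas), volumes NIfTI-1 (nibabel), configuration and
results JSON.  The lesion-load table has a header row of region ids and a
``patient_id`` first column; scores come either as raw NIHSS limb items
(``patient_id, upper_item, lower_item``) or precomputed
(``patient_id, motor_score``).  A JSON sidecar maps region_id to atlas
label and voxel count.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import (
    LesionDataset,
    Region,
    RegionSet,
    binarize_performance,
    derive_motor_score,
)
from .pipeline import IterationTrace, RunConfig
from .shapley import ShapleyResult

__all__ = [
    "read_region_set",
    "write_region_set",
    "read_lesion_dataset",
    "write_lesion_dataset",
    "read_run_config",
    "write_trace",
    "write_shapley_result",
    "load_volume",
]

_METADATA_COLUMNS = ("bilateral", "recurrent")


def read_region_set(path) -> RegionSet:
    """Region catalogue from a JSON sidecar.

    Schema: ``{"rob_id": str, "regions": [{"region_id", "atlas_label",
    "voxel_count"}, ...]}``; the RoB entry may omit ``atlas_label``.
    """
    with open(path) as fh:
        doc = json.load(fh)
    regions = tuple(
        Region(
            region_id=r["region_id"],
            atlas_label=r.get("atlas_label"),
            voxel_count=int(r["voxel_count"]),
        )
        for r in doc["regions"]
    )
    return RegionSet(regions=regions, rob_id=doc["rob_id"])


def write_region_set(region_set: RegionSet, path) -> None:
    doc = {
        "rob_id": region_set.rob_id,
        "regions": [
            {
                "region_id": r.region_id,
                "atlas_label": r.atlas_label,
                "voxel_count": r.voxel_count,
            }
            for r in region_set.regions
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def read_lesion_dataset(
    loads_path,
    scores_path,
    region_set: Optional[RegionSet] = None,
    regions_path=None,
    default_voxel_count: int = 1000,
) -> LesionDataset:
    """Assemble a dataset from a loads table and a scores table.

    If no region catalogue is given, one is synthesised from the loads
    header with uniform voxel counts (adequate for analyses that never
    merge regions by voxel weight); the last column is then taken as the
    RoB if named ``RoB``, otherwise a zero-load RoB column is appended.
    """
    loads_df = _read_table(loads_path)
    patient_col = loads_df.columns[0]
    patient_ids = loads_df[patient_col].astype(str).tolist()
    loads_df = loads_df.drop(columns=[patient_col])

    scores_df = _read_table(scores_path)
    scores_df = scores_df.set_index(scores_df.columns[0])
    scores_df.index = scores_df.index.astype(str)
    scores_df = scores_df.loc[patient_ids]
    if "motor_score" in scores_df.columns:
        raw = scores_df["motor_score"].to_numpy(dtype=int)
    else:
        raw = derive_motor_score(
            scores_df["upper_item"].to_numpy(dtype=int),
            scores_df["lower_item"].to_numpy(dtype=int),
        )
    performance = binarize_performance(raw)

    metadata = None
    meta_cols = [c for c in _METADATA_COLUMNS if c in scores_df.columns]
    if meta_cols:
        metadata = scores_df[meta_cols].reset_index(drop=True)

    if region_set is None and regions_path is not None:
        region_set = read_region_set(regions_path)

    if region_set is None:
        ids = list(loads_df.columns)
        rob_id = "RoB"
        if ids[-1] != rob_id:
            ids = ids + [rob_id]
            loads_df[rob_id] = 0.0
        regions = tuple(
            Region(
                region_id=rid,
                atlas_label=None if rid == rob_id else i + 1,
                voxel_count=default_voxel_count,
            )
            for i, rid in enumerate(ids)
        )
        region_set = RegionSet(regions=regions, rob_id=rob_id)

    loads = loads_df[region_set.ids].to_numpy(dtype=float)
    return LesionDataset(
        patient_ids=patient_ids,
        loads=loads,
        raw_motor_score=raw,
        performance=performance,
        region_set=region_set,
        metadata=metadata,
    )


def write_lesion_dataset(dataset: LesionDataset, loads_path, scores_path) -> None:
    """Write the loads table and the (patient_id, motor_score) table."""
    frame = dataset.to_frame()
    frame.insert(0, "patient_id", dataset.patient_ids)
    frame.to_csv(loads_path, index=False)
    scores = pd.DataFrame(
        {"patient_id": dataset.patient_ids, "motor_score": dataset.raw_motor_score}
    )
    if dataset.metadata is not None:
        for col in dataset.metadata.columns:
            scores[col] = dataset.metadata[col].to_numpy()
    scores.to_csv(scores_path, index=False)


def read_run_config(path) -> RunConfig:
    """Run configuration from JSON (unknown keys rejected)."""
    with open(path) as fh:
        doc = json.load(fh)
    doc.pop("subset", None)  # handled by the caller (patient filtering)
    predictor = doc.pop("predictor", {})
    if "grid" in predictor:
        doc["grid"] = predictor["grid"]
    if "output_mode" in predictor:
        doc["output_mode"] = predictor["output_mode"]
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(doc) - valid
    if unknown:
        raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
    return RunConfig(**doc)


def write_shapley_result(result: ShapleyResult, csv_path=None, json_path=None) -> None:
    if csv_path is not None:
        result.to_frame().to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(result.to_json_dict(), indent=2))


def write_trace(trace: IterationTrace, path) -> None:
    """Serialise an iteration trace to JSON."""
    doc = {
        "stopping_reason": trace.stopping_reason,
        "degenerate": trace.degenerate,
        "final_region_ids": trace.final_region_ids,
        "final_significant_ids": trace.final_significant_ids,
        "config": {
            k: v for k, v in asdict(trace.config).items() if not callable(v)
        },
        "iterations": [
            {
                "region_ids": rec.region_ids,
                "discarded_ids": rec.discarded_ids,
                "rob_significant": rec.rob_significant,
                "reverted": rec.reverted,
                "predictor_chosen": rec.predictor.chosen,
                "result": rec.result.to_json_dict(),
            }
            for rec in trace.iterations
        ],
        "final_result": trace.final_result.to_json_dict(),
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_volume(path) -> np.ndarray:
    """NIfTI volume as a numpy array (no resampling, grid taken as-is)."""
    import nibabel as nib

    return np.asanyarray(nib.load(str(path)).dataobj)
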