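"""HDF5 / JSON / CSV serialization.

An acquisition "run" file holds one group per push
(``/push0/displacement, /push0/beam_distances, /push0/time_axis``) plus
optional target/reference RF groups (``/rf_target/rf, /rf_target/depth_axis``)
and the sequence configuration as a JSON root attribute.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .fusion_eval import COHORT_COLUMNS, validate_cohort
from .models import DisplacementField, RFFrame, SequenceConfig


def write_displacement_field(group: h5py.Group, field: DisplacementField) -> None:
    group.create_dataset("displacement", data=field.displacement)
    group.create_dataset("beam_distances", data=field.beam_distances)
    group.create_dataset("time_axis", data=field.time_axis)
    group.attrs["push_index"] = field.push_index


def read_displacement_field(group: h5py.Group) -> DisplacementField:
    return DisplacementField(
        displacement=np.asarray(group["displacement"]),
        beam_distances=np.asarray(group["beam_distances"]),
        time_axis=np.asarray(group["time_axis"]),
        push_index=int(group.attrs["push_index"]),
    )


def write_rf_frame(group: h5py.Group, frame: RFFrame) -> None:
    group.create_dataset("rf", data=frame.samples)
    group.create_dataset("depth_axis", data=frame.depth_axis)
    group.attrs["center_frequency"] = frame.center_frequency
    group.attrs["sampling_rate"] = frame.sampling_rate


def read_rf_frame(group: h5py.Group) -> RFFrame:
    return RFFrame(
        samples=np.asarray(group["rf"]),
        depth_axis=np.asarray(group["depth_axis"]),
        center_frequency=float(group.attrs["center_frequency"]),
        sampling_rate=float(group.attrs["sampling_rate"]),
    )


def save_run(
    path: str | Path,
    seq: SequenceConfig,
    fields: list[DisplacementField],
    rf_target: RFFrame | None = None,
    rf_reference: RFFrame | None = None,
    ref_props: tuple[float, float, float] | None = None,
) -> None:
    """Write a full acquisition run (all pushes + optional RF pair)."""
    with h5py.File(path, "w") as f:
        f.attrs["sequence_config"] = json.dumps(seq.to_dict())
        for field in fields:
            write_displacement_field(f.create_group(f"push{field.push_index}"), field)
        if rf_target is not None:
            write_rf_frame(f.create_group("rf_target"), rf_target)
        if rf_reference is not None:
            write_rf_frame(f.create_group("rf_reference"), rf_reference)
        if ref_props is not None:
            f.attrs["ref_props"] = json.dumps(list(ref_props))


def load_run(path: str | Path) -> dict:
    """Read a run file; returns a dict with seq, fields, rf frames, ref_props."""
    out: dict = {"fields": [], "rf_target": None, "rf_reference": None, "ref_props": None}
    with h5py.File(path, "r") as f:
        out["seq"] = SequenceConfig.from_dict(json.loads(f.attrs["sequence_config"]))
        push_names = sorted(k for k in f.keys() if k.startswith("push"))
        out["fields"] = [read_displacement_field(f[k]) for k in push_names]
        if "rf_target" in f:
            out["rf_target"] = read_rf_frame(f["rf_target"])
        if "rf_reference" in f:
            out["rf_reference"] = read_rf_frame(f["rf_reference"])
        if "ref_props" in f.attrs:
            out["ref_props"] = tuple(json.loads(f.attrs["ref_props"]))
    return out


def save_cohort(path: str | Path, cohort: pd.DataFrame) -> None:
    validate_cohort(cohort)
    cohort[list(COHORT_COLUMNS)].to_csv(path, index=False)


def load_cohort(path: str | Path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path))
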