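"""HDF5 containers for palpation records and run manifests.

One file per palpation record, layout version 1:

- ``/volumes/data``  float32 [T, h, w, d], attr ``timestamps`` [T] (s)
- ``/reference/data`` float32 [h, w, d], attr ``timestamp``
- ``/force/t``, ``/force/f``  float64 [N] (s, Newton)
- ``/swei/data``  complex64 [h, w, T] (optional), attrs ``bscan_rate_hz``,
  ``lateral_extent_mm``, ``surface_depth_px``, excitation attrs
- root attrs: ``sample_id``, ``location_id``, ``material_json``,
  ``geometry_json``, ``trajectory_json``, ``seed``, ``layout_version``,
  optional ``phase_velocity``

Trajectories are stored as metadata (kind and parameters); the sampled
insertion-depth profile itself is not persisted, so a re-read record keeps
its volumes, forces and timestamps but carries a metadata-only trajectory.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .simkit import (ComplexBScanSequence, ExcitationSpec, MaterialSpec,
                     PalpationRecord, ScanGeometry, ToolTrajectory)

__all__ = ["SchemaError", "LAYOUT_VERSION", "write_record", "read_record",
           "save_dataset", "load_dataset",
           "write_manifest", "read_manifest", "validate_manifest"]

LAYOUT_VERSION = 1


class SchemaError(RuntimeError):
    """A container file violates the expected HDF5 layout."""


def _json_attr(obj) -> str:
    def clean(d):
        return {k: (None if v is None else v) for k, v in d.items()}
    return json.dumps(clean(dataclasses.asdict(obj)), default=float)


def write_record(path: str | Path, record: PalpationRecord) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["layout_version"] = LAYOUT_VERSION
        f.attrs["sample_id"] = record.sample_id
        f.attrs["location_id"] = record.location_id
        f.attrs["material_json"] = _json_attr(record.material)
        f.attrs["geometry_json"] = _json_attr(record.geometry)
        traj = dataclasses.asdict(record.trajectory)
        traj.pop("depth_profile")
        f.attrs["trajectory_json"] = json.dumps(traj, default=float)
        f.attrs["seed"] = record.rng_seed
        if record.phase_velocity is not None:
            f.attrs["phase_velocity"] = record.phase_velocity

        g = f.create_group("volumes")
        g.create_dataset("data", data=record.volumes.astype(np.float32))
        g.attrs["timestamps"] = record.volume_timestamps.astype(np.float64)
        g = f.create_group("reference")
        g.create_dataset("data", data=record.reference_volume.astype(np.float32))
        g.attrs["timestamp"] = float(record.reference_timestamp)
        g = f.create_group("force")
        g.create_dataset("t", data=record.force_timestamps.astype(np.float64))
        g.create_dataset("f", data=record.forces.astype(np.float64))
        if record.swei_sequence is not None:
            seq = record.swei_sequence
            g = f.create_group("swei")
            g.create_dataset("data", data=seq.data.astype(np.complex64))
            g.attrs["bscan_rate_hz"] = seq.geometry.bscan_rate_hz
            g.attrs["lateral_extent_mm"] = seq.geometry.lateral_extent_w_mm
            g.attrs["depth_extent_mm"] = seq.geometry.depth_extent_mm
            if seq.surface_depth_px is not None:
                g.attrs["surface_depth_px"] = np.asarray(seq.surface_depth_px)
            g.attrs["excitation_json"] = _json_attr(seq.excitation)


def _require(f, name: str, kind) -> object:
    if name not in f:
        raise SchemaError(f"missing {kind} '{name}'")
    return f[name]


def read_record(path: str | Path) -> PalpationRecord:
    with h5py.File(path, "r") as f:
        for attr in ("sample_id", "location_id", "material_json",
                     "geometry_json", "trajectory_json", "seed"):
            if attr not in f.attrs:
                raise SchemaError(f"missing root attr '{attr}'")
        material = MaterialSpec(**json.loads(f.attrs["material_json"]))
        geometry = ScanGeometry(**json.loads(f.attrs["geometry_json"]))
        traj_meta = json.loads(f.attrs["trajectory_json"])
        for key in ("velocity_range_mm_s",):
            if traj_meta.get(key) is not None:
                traj_meta[key] = tuple(traj_meta[key])
        trajectory = ToolTrajectory(depth_profile=None, **traj_meta)

        vols = _require(f, "volumes", "group")
        vdata = _require(vols, "data", "dataset")
        if vdata.ndim != 4:
            raise SchemaError(f"'/volumes/data' must be 4D [T,h,w,d], got {vdata.shape}")
        if "timestamps" not in vols.attrs:
            raise SchemaError("missing attr '/volumes@timestamps'")
        vol_t = np.asarray(vols.attrs["timestamps"], dtype=np.float64)
        if vol_t.shape[0] != vdata.shape[0]:
            raise SchemaError("'/volumes/data' length disagrees with timestamps")
        if np.any(np.diff(vol_t) <= 0):
            raise SchemaError("non-monotone timestamps in '/volumes'")

        ref = _require(_require(f, "reference", "group"), "data", "dataset")
        force = _require(f, "force", "group")
        ft = np.asarray(_require(force, "t", "dataset"), dtype=np.float64)
        fv = np.asarray(_require(force, "f", "dataset"), dtype=np.float64)
        if ft.shape != fv.shape:
            raise SchemaError("'/force/t' and '/force/f' lengths differ")
        if np.any(np.diff(ft) <= 0):
            raise SchemaError("non-monotone timestamps in '/force'")

        swei_seq = None
        if "swei" in f:
            g = f["swei"]
            sdata = _require(g, "data", "dataset")
            if sdata.ndim != 3:
                raise SchemaError(f"'/swei/data' must be 3D [h,w,T], got {sdata.shape}")
            exc = ExcitationSpec(**json.loads(g.attrs["excitation_json"]))
            sgeom = ScanGeometry(
                depth_px=sdata.shape[0], lateral_w_px=sdata.shape[1],
                lateral_d_px=None,
                depth_extent_mm=float(g.attrs["depth_extent_mm"]),
                lateral_extent_w_mm=float(g.attrs["lateral_extent_mm"]),
                lateral_extent_d_mm=None,
                bscan_rate_hz=float(g.attrs["bscan_rate_hz"]),
                volume_rate_hz=geometry.volume_rate_hz,
            )
            surf = (np.asarray(g.attrs["surface_depth_px"])
                    if "surface_depth_px" in g.attrs else None)
            swei_seq = ComplexBScanSequence(
                data=np.asarray(sdata), geometry=sgeom, excitation=exc,
                surface_depth_px=surf)

        return PalpationRecord(
            sample_id=str(f.attrs["sample_id"]),
            location_id=str(f.attrs["location_id"]),
            material=material, geometry=geometry,
            volume_timestamps=vol_t, volumes=np.asarray(vdata),
            reference_timestamp=float(f["reference"].attrs["timestamp"]),
            reference_volume=np.asarray(ref),
            force_timestamps=ft, forces=fv, trajectory=trajectory,
            rng_seed=int(f.attrs["seed"]), swei_sequence=swei_seq,
            phase_velocity=(float(f.attrs["phase_velocity"])
                            if "phase_velocity" in f.attrs else None),
        )


# ---------------------------------------------------------------------------
# Dataset shards
# ---------------------------------------------------------------------------

def save_dataset(path: str | Path, dataset) -> None:
    """Write a model-ready dataset shard: /x, /x_ref, /v_swei, /y, /meta."""
    with h5py.File(path, "w") as f:
        f.attrs["layout_version"] = LAYOUT_VERSION
        f.attrs["representation"] = dataset.representation
        f.attrs["with_swei"] = dataset.with_swei
        f.attrs["depth_scale_px"] = dataset.depth_scale_px
        f.create_dataset("x", data=dataset.x.astype(np.float32))
        f.create_dataset("x_ref", data=dataset.x_ref.astype(np.float32))
        f.create_dataset("v_swei", data=dataset.velocity.astype(np.float64))
        f.create_dataset("y", data=dataset.y.astype(np.float64))
        f.create_dataset("t", data=dataset.timestamps.astype(np.float64))
        meta = dataset.meta.to_json(orient="records").encode()
        f.create_dataset("meta", data=np.frombuffer(meta, dtype=np.uint8))


def load_dataset(path: str | Path):
    from .preprocess import Dataset
    with h5py.File(path, "r") as f:
        for name in ("x", "x_ref", "v_swei", "y", "meta"):
            if name not in f:
                raise SchemaError(f"missing dataset '{name}'")
        meta = pd.read_json(
            __import__("io").StringIO(bytes(f["meta"][...]).decode()),
            orient="records")
        return Dataset(
            representation=str(f.attrs["representation"]),
            with_swei=bool(f.attrs["with_swei"]),
            x=np.asarray(f["x"]), x_ref=np.asarray(f["x_ref"]),
            velocity=np.asarray(f["v_swei"]), y=np.asarray(f["y"]),
            timestamps=np.asarray(f["t"]), meta=meta,
            depth_scale_px=float(f.attrs["depth_scale_px"]),
        )


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def write_manifest(path: str | Path, manifest: pd.DataFrame,
                   splits: dict[str, list[str]] | None = None,
                   seeds: dict[str, int] | None = None) -> None:
    payload = {
        "layout_version": LAYOUT_VERSION,
        "records": manifest.to_dict(orient="records"),
        "splits": splits or {},
        "seeds": seeds or {},
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=str))


def read_manifest(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    payload["records"] = pd.DataFrame(payload["records"])
    return payload


def validate_manifest(manifest: dict, base_dir: str | Path | None = None) -> list[str]:
    """Return a list of violations (empty = clean).

    Checks: referenced files exist and parse, split disjointness, trajectory
    hygiene (no evaluation-only random trajectories in a training split),
    and seed completeness.
    """
    violations = []
    records: pd.DataFrame = manifest["records"]
    if "path" in records.columns and base_dir is not None:
        for p in records.path:
            full = Path(base_dir) / p
            if not full.exists():
                violations.append(f"missing file: {p}")
            else:
                try:
                    read_record(full)
                except SchemaError as e:
                    violations.append(f"invalid record {p}: {e}")
    by_id = records.set_index("record_id")
    splits: dict = manifest.get("splits", {})
    for name, ids in splits.items():
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            violations.append(f"duplicate ids in split '{name}': {sorted(dupes)}")
        unknown = set(ids) - set(by_id.index)
        if unknown:
            violations.append(f"unknown ids in split '{name}': {sorted(unknown)}")
        if name.startswith("train"):
            for i in set(ids) & set(by_id.index):
                if by_id.loc[i, "trajectory_kind"] != "sinusoidal":
                    violations.append(
                        f"test-only trajectory in train split: {i}")
    names = list(splits)
    for a, b in ((a, b) for i, a in enumerate(names) for b in names[i + 1:]):
        both = set(splits[a]) & set(splits[b])
        if both and {a, b} != {a}:
            violations.append(f"records in both '{a}' and '{b}': {sorted(both)}")
    if "seed" in records.columns:
        missing = records[records.seed.isna()]
        for i in missing.record_id:
            violations.append(f"record without seed: {i}")
    return violations
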