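"""Raw palpation records to model-ready tensors.

Three standard steps sit between the scanner (or simulator) output and the
regression models:

1. volumes are cropped along depth (200 px by default) and resampled to a
   cubic grid (32^3 at full scale), normalised per volume to [0, 1];
2. a surface deformation map is extracted per volume as the depth index of
   the maximum-intensity voxel along the depth axis, masked where the
   maximum is weak (below half the volume mean) and hole-filled by 2D
   interpolation;
3. each volume receives a force label by linear interpolation of the
   asynchronous force stream at the volume timestamp.

The deformation map stores *depth in pixels* (a surface height map), which
is what the 2D representation feeds to the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import griddata
from scipy.ndimage import zoom

from .simkit import PalpationRecord
from .swei import SweiParams, estimate_phase_velocity

__all__ = [
    "PreprocessError",
    "Dataset",
    "crop_and_downsample",
    "surface_map",
    "fill_holes",
    "align_force_labels",
    "build_dataset",
    "concat_datasets",
]


class PreprocessError(RuntimeError):
    pass


def crop_and_downsample(
    volume: np.ndarray,
    crop_len: int = 200,
    crop_offset: int = 0,
    out_shape: tuple[int, int, int] = (32, 32, 32),
    normalize: bool = True,
) -> np.ndarray:
    """Crop the depth axis and resample to ``out_shape`` (linear interpolation).

    Resampling uses a block-consistent coordinate mapping (output pixel i
    covers input span ``[i/s, (i+1)/s)``), so constants are preserved and a
    feature at input depth z lands near ``z * out/in``.
    """
    h = volume.shape[0]
    if h < crop_offset + crop_len:
        raise PreprocessError(
            f"volume depth {h} shallower than crop {crop_offset}+{crop_len}"
        )
    sub = np.asarray(volume[crop_offset:crop_offset + crop_len], dtype=np.float32)
    factors = [o / s for o, s in zip(out_shape, sub.shape)]
    out = zoom(sub, factors, order=1, mode="nearest", grid_mode=True)
    if out.shape != tuple(out_shape):  # guard against rounding in zoom
        raise PreprocessError(f"resampled shape {out.shape} != {out_shape}")
    if normalize:
        lo, hi = float(out.min()), float(out.max())
        if hi > lo:
            out = (out - lo) / (hi - lo)
        else:
            out = np.zeros_like(out)
    return out.astype(np.float32)


def surface_map(volume: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Depth index of the maximum-intensity voxel along depth, plus validity.

    Entries are valid where the column maximum exceeds 50 % of the mean
    intensity of the whole volume; invalid entries are left to
    :func:`fill_holes`.
    """
    vol = np.asarray(volume)
    if not np.all(np.isfinite(vol)):
        raise PreprocessError("volume contains non-finite values")
    depth_map = np.argmax(vol, axis=0).astype(np.float64)
    col_max = vol.max(axis=0)
    mask = col_max > 0.5 * float(vol.mean())
    if not mask.any():
        raise PreprocessError("no surface anywhere (all columns invalid)")
    return depth_map, mask


def fill_holes(depth_map: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace invalid entries by Delaunay-based linear 2D interpolation.

    Valid entries are returned unchanged; points outside the convex hull of
    the valid set fall back to nearest-neighbour values.
    """
    mask = np.asarray(mask, dtype=bool)
    if int(mask.sum()) < 4:
        raise PreprocessError(f"only {int(mask.sum())} valid points (< 4)")
    out = np.array(depth_map, dtype=np.float64, copy=True)
    if mask.all():
        return out
    pts = np.argwhere(mask)
    vals = out[mask]
    holes = np.argwhere(~mask)
    filled = griddata(pts, vals, holes, method="linear")
    nn = np.isnan(filled)
    if nn.any():
        filled[nn] = griddata(pts, vals, holes[nn], method="nearest")
    out[~mask] = filled
    return out


def align_force_labels(
    force_timestamps: np.ndarray,
    forces: np.ndarray,
    volume_timestamps: np.ndarray,
) -> np.ndarray:
    """Linear interpolation of the force stream at each volume timestamp."""
    ft = np.asarray(force_timestamps, dtype=float)
    fv = np.asarray(forces, dtype=float)
    vt = np.asarray(volume_timestamps, dtype=float)
    if len(ft) != len(fv):
        raise PreprocessError("force stream lengths differ")
    if vt.min() < ft[0] or vt.max() > ft[-1]:
        raise PreprocessError(
            f"volume timestamps [{vt.min():.4f}, {vt.max():.4f}] outside "
            f"force span [{ft[0]:.4f}, {ft[-1]:.4f}] (no extrapolation)"
        )
    return np.interp(vt, ft, fv)


@dataclass
class Dataset:
    """Model-ready samples from one or more palpation records.

    ``x``/``x_ref`` are either volumes (N, h, w, d) in [0, 1] or deformation
    maps (N, w, d) in depth pixels; ``y`` are force labels in Newton;
    ``velocity`` is the per-record shear-wave phase velocity [m/s] (NaN when
    built without SWEI).  ``meta`` has one row per sample.
    """

    representation: str  # "2d" | "3d"
    with_swei: bool
    x: np.ndarray
    x_ref: np.ndarray
    velocity: np.ndarray
    y: np.ndarray
    timestamps: np.ndarray
    meta: pd.DataFrame
    depth_scale_px: float = 200.0  # scale used to normalise 2D maps for models

    def __len__(self) -> int:
        return self.x.shape[0]

    def subset(self, idx: np.ndarray | list[int]) -> "Dataset":
        idx = np.asarray(idx)
        return Dataset(
            representation=self.representation, with_swei=self.with_swei,
            x=self.x[idx], x_ref=self.x_ref[idx], velocity=self.velocity[idx],
            y=self.y[idx], timestamps=self.timestamps[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
            depth_scale_px=self.depth_scale_px,
        )

    def select(self, record_ids: set[str] | list[str]) -> "Dataset":
        wanted = set(record_ids)
        idx = np.where(self.meta["record_id"].isin(wanted).to_numpy())[0]
        return self.subset(idx)


def _record_velocity(record: PalpationRecord, swei_params: SweiParams,
                     seed: int) -> float:
    if record.phase_velocity is not None:
        return float(record.phase_velocity)
    if record.swei_sequence is None:
        raise PreprocessError(
            f"record {record.record_id} has no SWEI sequence or cached velocity"
        )
    return estimate_phase_velocity(record.swei_sequence, swei_params,
                                   seed=seed).velocity


def build_dataset(
    records: list[PalpationRecord],
    representation: str = "3d",
    with_swei: bool = False,
    crop_len: int = 200,
    crop_offset: int = 0,
    out_size: int = 32,
    swei_params: SweiParams | None = None,
    swei_seed: int = 0,
) -> Dataset:
    """One model sample per palpation volume, reference processed identically."""
    if representation not in ("2d", "3d"):
        raise ValueError(f"unknown representation {representation!r}")
    swei_params = swei_params or SweiParams()
    xs, refs, vels, ys, ts, rows = [], [], [], [], [], []
    for rec in records:
        if rec.reference_volume is None:
            raise PreprocessError(f"record {rec.record_id} lacks a reference volume")
        vel = _record_velocity(rec, swei_params, swei_seed) if with_swei else np.nan
        labels = align_force_labels(rec.force_timestamps, rec.forces,
                                    rec.volume_timestamps)

        def process(volume: np.ndarray) -> np.ndarray:
            if representation == "3d":
                return crop_and_downsample(volume, crop_len, crop_offset,
                                           (out_size,) * 3)
            cropped = volume[crop_offset:crop_offset + crop_len]
            dm, mask = surface_map(cropped)
            return fill_holes(dm, mask).astype(np.float32)

        ref = process(rec.reference_volume)
        for t_i, vol, label in zip(rec.volume_timestamps, rec.volumes, labels):
            xs.append(process(vol))
            refs.append(ref)
            vels.append(vel)
            ys.append(label)
            ts.append(t_i)
            rows.append({
                "record_id": rec.record_id,
                "sample_id": rec.sample_id,
                "location_id": rec.location_id,
                "material_id": rec.material.material_id,
                "material_class": rec.material.material_class,
                "concentration": rec.material.concentration,
                "youngs_modulus": rec.material.youngs_modulus,
                "trajectory_kind": rec.trajectory.kind,
                "record_seed": rec.rng_seed,
            })
    return Dataset(
        representation=representation, with_swei=with_swei,
        x=np.stack(xs), x_ref=np.stack(refs),
        velocity=np.asarray(vels, dtype=np.float64),
        y=np.asarray(ys, dtype=np.float64),
        timestamps=np.asarray(ts, dtype=np.float64),
        meta=pd.DataFrame(rows),
        depth_scale_px=float(crop_len),
    )


def concat_datasets(datasets: list[Dataset]) -> Dataset:
    first = datasets[0]
    for ds in datasets[1:]:
        if (ds.representation, ds.with_swei) != (first.representation, first.with_swei):
            raise ValueError("datasets differ in representation or SWEI flag")
    return Dataset(
        representation=first.representation, with_swei=first.with_swei,
        x=np.concatenate([d.x for d in datasets]),
        x_ref=np.concatenate([d.x_ref for d in datasets]),
        velocity=np.concatenate([d.velocity for d in datasets]),
        y=np.concatenate([d.y for d in datasets]),
        timestamps=np.concatenate([d.timestamps for d in datasets]),
        meta=pd.concat([d.meta for d in datasets], ignore_index=True),
        depth_scale_px=first.depth_scale_px,
    )
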