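"""Training, metrics, cross-validation and the three study experiments.

The study design mirrors the phantom experiments the pipeline was built
for: models are trained on sinusoidal palpation trajectories only and
evaluated exclusively on random-step palpation; evaluation metrics are
root-mean-square error (rMSE, reported in mN), normalised mean absolute
error (nMAE = MAE / observed force range) and the Pearson correlation
coefficient (pCC).

Experiments:

1. *Transfer matrix* — one non-fusion model per gelatin stiffness,
   evaluated on every stiffness: accuracy concentrates on the diagonal and
   the signed error flips with the stiffness ordering (stiff-trained models
   overestimate forces on softer gels and vice versa).
2. *Generalisation* — leave-one-stiffness-out cross-validation comparing
   2D/3D inputs with and without phase-velocity fusion.
3. *Tissue transfer* — cross-validation ensembles from (2) evaluated on
   heterogeneous tissue-like samples never seen in training.

The desk profile scales the study to a single CPU: 16^3 volumes, two
phantoms x three locations per material, eight volumes per palpation
record, twenty epochs, with compact model variants of the same
architecture.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .model import ForceNet, ModelConfig, build_model
from .nn import Adam, one_cycle_lr
from .preprocess import Dataset, build_dataset
from .simkit import (GELATIN_CONCENTRATIONS, ExcitationSpec, PalpationRecord,
                     ScanGeometry, make_material, random_steps_trajectory,
                     simulate_palpation, simulate_swei_sequence,
                     sinusoidal_trajectory)
from .swei import SweiParams, estimate_phase_velocity

__all__ = [
    "TrainConfig", "Metrics", "FoldSplit", "StudyProfile",
    "compute_metrics", "make_folds", "train", "predict_dataset",
    "ensemble_predict", "build_study_records", "records_manifest",
    "experiment_transfer_matrix", "experiment_generalization",
    "experiment_tissue_transfer", "run_study",
]


@dataclass(frozen=True)
class TrainConfig:
    """MSE training with Adam and a one-cycle learning-rate policy."""

    epochs: int = 150
    batch_size: int = 128
    lr_min: float = 1e-4
    lr_max: float = 1e-3
    seed: int = 0

    @classmethod
    def desk(cls, seed: int = 0) -> "TrainConfig":
        """Compact-model profile: fewer, larger steps (see StudyProfile)."""
        return cls(epochs=20, batch_size=32, lr_max=3e-3, seed=seed)


@dataclass(frozen=True)
class Metrics:
    """Regression metrics in the units of the supplied arrays."""

    rmse: float
    mae: float
    nmae: float
    pcc: float
    force_range: float


def compute_metrics(predictions: np.ndarray, targets: np.ndarray) -> Metrics:
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(targets, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.size < 2:
        raise ValueError("need at least 2 samples")
    force_range = float(t.max() - t.min())
    if force_range == 0:
        raise ValueError("constant targets: pCC undefined")
    err = p - t
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    pcc = float(np.corrcoef(p, t)[0, 1])
    return Metrics(rmse=rmse, mae=mae, nmae=mae / force_range, pcc=pcc,
                   force_range=force_range)


# ---------------------------------------------------------------------------
# Fold construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldSplit:
    scheme: str  # "by_gel" | "by_phantom"
    fold_id: str
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


def records_manifest(records: Iterable[PalpationRecord]) -> pd.DataFrame:
    rows = [{
        "record_id": r.record_id,
        "sample_id": r.sample_id,
        "location_id": r.location_id,
        "material_id": r.material.material_id,
        "material_class": r.material.material_class,
        "trajectory_kind": r.trajectory.kind,
        "seed": r.rng_seed,
    } for r in records]
    return pd.DataFrame(rows)


def _split_val_test(groups: list[str]) -> tuple[list[str], list[str]]:
    """First third (at least one) of the sorted groups validates, rest tests."""
    groups = sorted(groups)
    n_val = max(1, len(groups) // 3)
    if len(groups) < 2:
        raise ValueError("need at least 2 replicates in the held-out subset")
    return groups[:n_val], groups[n_val:]


def make_folds(manifest: pd.DataFrame, scheme: str) -> list[FoldSplit]:
    """Cross-validation folds with sinusoidal-only training splits.

    ``by_gel``: one fold per material, all its phantoms held out; the
    held-out phantoms are split into validation and test.  ``by_phantom``:
    within each material, one fold per held-out phantom whose locations are
    split into validation and test.  Evaluation splits contain only
    random-trajectory records; training splits only sinusoidal ones.
    """
    sin = manifest[manifest.trajectory_kind == "sinusoidal"]
    rnd = manifest[manifest.trajectory_kind == "random_steps"]
    folds = []
    if scheme == "by_gel":
        for mat in sorted(manifest.material_id.unique()):
            held = rnd[rnd.material_id == mat]
            val_ph, test_ph = _split_val_test(list(held.sample_id.unique()))
            train = sin[sin.material_id != mat]
            folds.append(FoldSplit(
                scheme=scheme, fold_id=mat,
                train_ids=tuple(train.record_id),
                val_ids=tuple(held[held.sample_id.isin(val_ph)].record_id),
                test_ids=tuple(held[held.sample_id.isin(test_ph)].record_id),
            ))
    elif scheme == "by_phantom":
        for mat in sorted(manifest.material_id.unique()):
            mat_sin = sin[sin.material_id == mat]
            mat_rnd = rnd[rnd.material_id == mat]
            for phantom in sorted(mat_rnd.sample_id.unique()):
                held = mat_rnd[mat_rnd.sample_id == phantom]
                val_loc, test_loc = _split_val_test(list(held.location_id.unique()))
                folds.append(FoldSplit(
                    scheme=scheme, fold_id=f"{mat}:{phantom}",
                    train_ids=tuple(mat_sin[mat_sin.sample_id != phantom].record_id),
                    val_ids=tuple(held[held.location_id.isin(val_loc)].record_id),
                    test_ids=tuple(held[held.location_id.isin(test_loc)].record_id),
                ))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    for f in folds:
        overlap = (set(f.train_ids) & set(f.val_ids)) | \
                  (set(f.train_ids) & set(f.test_ids)) | \
                  (set(f.val_ids) & set(f.test_ids))
        if overlap:
            raise AssertionError(f"overlapping splits in fold {f.fold_id}: {overlap}")
    return folds


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _model_tensors(ds: Dataset, model: ForceNet):
    if model.config.representation == "3d":
        x = ds.x[..., None].astype(np.float32)
        ref = ds.x_ref[..., None].astype(np.float32)
    else:
        scale = np.float32(ds.depth_scale_px)
        x = (ds.x / scale)[..., None].astype(np.float32)
        ref = (ds.x_ref / scale)[..., None].astype(np.float32)
    v = ds.velocity.astype(np.float32) if model.config.with_swei else None
    return x, ref, v


def train(model: ForceNet, train_ds: Dataset, val_ds: Dataset,
          config: TrainConfig) -> dict:
    """MSE training on standardised force labels; returns the history and
    leaves the best-validation-rMSE checkpoint loaded in ``model``."""
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise ValueError("empty training or validation split")
    kinds = set(train_ds.meta.trajectory_kind)
    if kinds != {"sinusoidal"}:
        raise ValueError(f"training split must be sinusoidal-only, got {kinds}")
    if model.config.with_swei and not train_ds.with_swei:
        raise ValueError("fusion model requires a dataset with phase velocities")
    if not model.config.with_swei and train_ds.with_swei:
        raise ValueError("non-fusion model fed a SWEI dataset")

    model.y_mean = float(train_ds.y.mean())
    model.y_std = float(train_ds.y.std()) or 1.0
    if model.config.with_swei:
        model.v_mean = float(train_ds.velocity.mean())
        model.v_std = float(train_ds.velocity.std()) or 1.0

    x, ref, v = _model_tensors(train_ds, model)
    y_std = ((train_ds.y - model.y_mean) / model.y_std).astype(np.float32)
    xv, refv, vv = _model_tensors(val_ds, model)
    y_val = val_ds.y

    n = len(train_ds)
    bs = config.batch_size
    steps_per_epoch = max(1, math.ceil(n / bs))
    total_steps = config.epochs * steps_per_epoch
    rng = np.random.default_rng(config.seed)
    adam = Adam(model.params())
    history = {"train_loss": [], "val_rmse": [], "lr": []}
    best = (np.inf, model.get_state())
    step = 0
    for _epoch in range(config.epochs):
        perm = rng.permutation(n)
        losses = []
        for i in range(0, n, bs):
            idx = perm[i:i + bs]
            if idx.size < 2:  # batch statistics degenerate
                continue
            lr = one_cycle_lr(step, total_steps, config.lr_min, config.lr_max)
            out, cache = model.forward(
                x[idx], ref[idx], None if v is None else v[idx], train=True)
            resid = out - y_std[idx]
            losses.append(float(np.mean(resid**2)))
            model.zero_grad()
            model.backward(cache, (2.0 / idx.size) * resid)
            adam.step(lr)
            history["lr"].append(lr)
            step += 1
        pred = model.predict(xv, refv, vv)
        val_rmse = float(np.sqrt(np.mean((pred - y_val)**2)))
        history["train_loss"].append(float(np.mean(losses)))
        history["val_rmse"].append(val_rmse)
        if val_rmse < best[0]:
            best = (val_rmse, model.get_state())
    model.set_state(best[1])
    history["best_val_rmse"] = best[0]
    return history


def predict_dataset(model: ForceNet, ds: Dataset) -> np.ndarray:
    x, ref, v = _model_tensors(ds, model)
    return model.predict(x, ref, v)


def ensemble_predict(models: list[ForceNet], ds: Dataset) -> np.ndarray:
    """Mean of the member predictions (cross-validation ensemble voting)."""
    if not models:
        raise ValueError("empty ensemble")
    keys = {(m.config.representation, m.config.with_swei) for m in models}
    if len(keys) > 1:
        raise ValueError(f"heterogeneous ensemble members: {keys}")
    return np.mean([predict_dataset(m, ds) for m in models], axis=0)


# ---------------------------------------------------------------------------
# Study profile and synthetic data plan
# ---------------------------------------------------------------------------

def _desk_volume_geometry() -> ScanGeometry:
    # 256 px over 4 mm depth keeps the full 3 mm indentation inside the
    # 200 px crop window; 16 x 16 lateral px over 3 x 3 mm
    return ScanGeometry(depth_px=256, lateral_w_px=16, lateral_d_px=16,
                        depth_extent_mm=4.0, lateral_extent_w_mm=3.0,
                        lateral_extent_d_mm=3.0, bscan_rate_hz=14200.0,
                        volume_rate_hz=833.0)


def _desk_swei_geometry() -> ScanGeometry:
    return ScanGeometry.default_swei(depth_px=48, depth_extent_mm=0.353)


@dataclass(frozen=True)
class StudyProfile:
    """Problem sizes and component configurations of one study run."""

    concentrations: tuple[float, ...] = GELATIN_CONCENTRATIONS
    n_phantoms: int = 2
    n_locations: int = 3
    n_volumes: int = 8  # volumes kept per palpation record
    phantom_modulus_jitter: float = 0.06  # lognormal sigma of per-phantom E
    geometry: ScanGeometry = field(default_factory=_desk_volume_geometry)
    swei_geometry: ScanGeometry = field(default_factory=_desk_swei_geometry)
    swei_duration_s: float = 0.1
    swei_snr_db: float = 20.0
    swei_params: SweiParams = field(default_factory=lambda: SweiParams(
        n_subsets=10, pad_time=1024, pad_lateral=1024))
    crop_len: int = 200
    out_size: int = 16
    n_tissue_samples: int = 3
    n_tissue_locations: int = 2
    epochs: int = 20
    batch_size: int = 32
    lr_min: float = 1e-4
    lr_max: float = 3e-3  # compact desk models, short schedules
    matrix_epochs: int = 60  # per-gel training sets are ~1 step/epoch
    model_scale: str = "desk"  # "desk" | "full"

    @classmethod
    def desk(cls) -> "StudyProfile":
        return cls()

    @classmethod
    def full(cls) -> "StudyProfile":
        """Full-scale profile: the complete acquisition plan and training
        recipe (6 phantoms x 9 locations per gel, 150 epochs, batch 128)."""
        return cls(n_phantoms=6, n_locations=9, n_volumes=64,
                   geometry=ScanGeometry.default_volume(),
                   swei_geometry=ScanGeometry.default_swei(),
                   swei_duration_s=0.8, crop_len=200, out_size=32,
                   n_tissue_samples=10, n_tissue_locations=2,
                   epochs=150, batch_size=128, lr_max=1e-3,
                   matrix_epochs=150, model_scale="full")

    def model_config(self, representation: str, with_swei: bool,
                     seed: int) -> ModelConfig:
        if self.model_scale == "desk":
            maker = (ModelConfig.desk_3d if representation == "3d"
                     else ModelConfig.desk_2d)
        else:
            maker = (ModelConfig.default_3d if representation == "3d"
                     else ModelConfig.default_2d)
        return maker(with_swei=with_swei, seed=seed)

    def train_config(self, seed: int, epochs: int | None = None) -> TrainConfig:
        return TrainConfig(epochs=epochs or self.epochs,
                           batch_size=self.batch_size,
                           lr_min=self.lr_min, lr_max=self.lr_max, seed=seed)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def build_study_records(
    profile: StudyProfile,
    seed: int,
    tissue: bool = False,
) -> list[PalpationRecord]:
    """Generate all palpation records of one study arm.

    Gelatin: every (concentration, phantom, location) yields one sinusoidal
    (training) and one random-step (evaluation) record.  Tissue-like:
    random-step evaluation records only.  Each location also receives a
    SWEI sequence whose estimated phase velocity is cached on the records.
    """
    rng_master = np.random.default_rng(seed)
    records: list[PalpationRecord] = []
    if tissue:
        mats = []
        for i in range(profile.n_tissue_samples):
            mats.append((f"T{i}", make_material(
                "tissue_like", seed=int(rng_master.integers(2**31)),
                material_id=f"tissue_{i}")))
        phantoms = [None]
        locations = range(profile.n_tissue_locations)
        kinds = ("random_steps",)
    else:
        mats = [(f"G{c*100:g}", make_material("gelatin", concentration=c))
                for c in profile.concentrations]
        phantoms = range(profile.n_phantoms)
        locations = range(profile.n_locations)
        kinds = ("sinusoidal", "random_steps")

    for tag, mat in mats:
        for ph in phantoms:
            sample_id = tag if ph is None else f"{tag}_P{ph}"
            ph_mat = mat
            if ph is not None and profile.phantom_modulus_jitter > 0:
                # per-phantom preparation variability around the gel's
                # calibrated modulus; the material id stays the gel's
                jitter = float(np.exp(rng_master.normal(
                    0.0, profile.phantom_modulus_jitter)))
                ph_mat = make_material(
                    "gelatin", concentration=mat.concentration,
                    youngs_modulus=mat.youngs_modulus * jitter,
                    material_id=mat.material_id)
            for loc in locations:
                loc_id = f"L{loc}"
                loc_seed = int(rng_master.integers(2**31))
                loc_rng = np.random.default_rng(loc_seed)
                swei_seq = simulate_swei_sequence(
                    ph_mat, profile.swei_geometry,
                    ExcitationSpec(duration_s=profile.swei_duration_s),
                    noise_snr_db=profile.swei_snr_db,
                    seed=int(loc_rng.integers(2**31)),
                )
                velocity = estimate_phase_velocity(
                    swei_seq, profile.swei_params,
                    seed=int(loc_rng.integers(2**31))).velocity
                for kind in kinds:
                    traj_seed = int(loc_rng.integers(2**31))
                    if kind == "sinusoidal":
                        traj = sinusoidal_trajectory(seed=traj_seed)
                    else:
                        traj = random_steps_trajectory(seed=traj_seed)
                    # thin the volume clock so each record keeps
                    # profile.n_volumes frames across the full trajectory
                    geom = replace(profile.geometry,
                                   volume_rate_hz=profile.n_volumes / traj.duration_s)
                    rec = simulate_palpation(
                        ph_mat, geom, traj, seed=int(loc_rng.integers(2**31)),
                        sample_id=sample_id, location_id=loc_id,
                    )
                    rec.phase_velocity = velocity
                    records.append(rec)
    return records


def _build_datasets(records: list[PalpationRecord], profile: StudyProfile):
    """2D and 3D datasets (with cached velocities) over the same records."""
    common = dict(crop_len=profile.crop_len, out_size=profile.out_size,
                  with_swei=True)
    ds3 = build_dataset(records, representation="3d", **common)
    ds2 = build_dataset(records, representation="2d", **common)
    return {"2d": ds2, "3d": ds3}


def _as_plain(ds: Dataset) -> Dataset:
    """View of a dataset without the SWEI channel (for non-fusion models)."""
    return Dataset(representation=ds.representation, with_swei=False,
                   x=ds.x, x_ref=ds.x_ref,
                   velocity=np.full_like(ds.velocity, np.nan),
                   y=ds.y, timestamps=ds.timestamps, meta=ds.meta,
                   depth_scale_px=ds.depth_scale_px)


VARIANTS = ("2d", "3d", "2d_swei", "3d_swei")


def _variant_parts(variant: str) -> tuple[str, bool]:
    rep, _, fusion = variant.partition("_")
    return rep, fusion == "swei"


def _fit_variant(variant: str, datasets: dict, fold: FoldSplit,
                 profile: StudyProfile, seed: int) -> ForceNet:
    rep, with_swei = _variant_parts(variant)
    ds = datasets[rep]
    if not with_swei:
        ds = _as_plain(ds)
    model = build_model(profile.model_config(rep, with_swei, seed))
    train(model, ds.select(fold.train_ids), ds.select(fold.val_ids),
          profile.train_config(seed))
    return model


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def experiment_transfer_matrix(profile: StudyProfile, seed: int,
                               records: list[PalpationRecord] | None = None,
                               representation: str = "3d") -> dict:
    """Single-stiffness models applied across all stiffnesses.

    Trains one non-fusion model per gelatin gel on sinusoidal records of the
    first phantom and evaluates on every gel's random-step records of the
    second phantom.  Returns the rMSE grid [mN] and the signed mean error
    grid [mN], rows = evaluation gel, columns = training gel.
    """
    if records is None:
        records = build_study_records(profile, seed)
    datasets = _build_datasets(records, profile)
    ds = _as_plain(datasets[representation])
    manifest = records_manifest(records)
    gels = sorted(manifest.material_id.unique())
    seeds = _child_seeds(seed + 1, len(gels))

    rmse = np.zeros((len(gels), len(gels)))
    bias = np.zeros((len(gels), len(gels)))
    phantoms = sorted(manifest.sample_id.unique())
    for j, gel in enumerate(gels):
        m = manifest[(manifest.material_id == gel)]
        train_ph, eval_ph = sorted(m.sample_id.unique())[0], None
        train_ids = m[(m.trajectory_kind == "sinusoidal")
                      & (m.sample_id == train_ph)].record_id
        val_ids = m[(m.trajectory_kind == "random_steps")
                    & (m.sample_id == train_ph)].record_id
        model = build_model(profile.model_config(representation, False,
                                                 int(seeds[j])))
        train(model, ds.select(train_ids), ds.select(val_ids),
              profile.train_config(int(seeds[j]), epochs=profile.matrix_epochs))
        for i, gel_eval in enumerate(gels):
            me = manifest[(manifest.material_id == gel_eval)
                          & (manifest.trajectory_kind == "random_steps")
                          & (manifest.sample_id != train_ph)]
            test = ds.select(me.record_id)
            pred = predict_dataset(model, test) * 1e3
            targ = test.y * 1e3
            rmse[i, j] = float(np.sqrt(np.mean((pred - targ)**2)))
            bias[i, j] = float(np.mean(pred - targ))
    return {"gels": gels, "rmse_mn": rmse, "bias_mn": bias}


def experiment_generalization(profile: StudyProfile, seed: int,
                              records: list[PalpationRecord] | None = None,
                              return_models: bool = False) -> dict:
    """Leave-one-stiffness-out comparison of the four model variants."""
    if records is None:
        records = build_study_records(profile, seed)
    datasets = _build_datasets(records, profile)
    manifest = records_manifest(records)
    folds = make_folds(manifest, "by_gel")
    seeds = _child_seeds(seed + 2, len(folds) * len(VARIANTS))

    # the softest and stiffest held-out gels are extrapolation problems
    mean_e = datasets["3d"].meta.groupby("material_id").youngs_modulus.mean()
    by_e = mean_e.sort_values().index
    extrapolation = {by_e[0], by_e[-1]}

    rows = []
    models: dict[tuple[str, str], ForceNet] = {}
    for fi, fold in enumerate(folds):
        for vi, variant in enumerate(VARIANTS):
            rep, with_swei = _variant_parts(variant)
            model = _fit_variant(variant, datasets, fold, profile,
                                 int(seeds[fi * len(VARIANTS) + vi]))
            ds = datasets[rep] if with_swei else _as_plain(datasets[rep])
            test = ds.select(fold.test_ids)
            met = compute_metrics(predict_dataset(model, test) * 1e3,
                                  test.y * 1e3)
            rows.append({"fold": fold.fold_id, "variant": variant,
                         "rmse_mn": met.rmse, "nmae": met.nmae,
                         "pcc": met.pcc,
                         "extrapolation": fold.fold_id in extrapolation})
            models[(variant, fold.fold_id)] = model
    results = pd.DataFrame(rows)
    out = {"results": results,
           "mean_rmse_mn": results.groupby("variant").rmse_mn.mean().to_dict()}
    if return_models:
        out["models"] = models
        out["folds"] = folds
    return out


def experiment_tissue_transfer(profile: StudyProfile, seed: int,
                               models: dict[tuple[str, str], ForceNet],
                               tissue_records: list[PalpationRecord] | None = None,
                               ) -> dict:
    """Cross-validation ensembles evaluated on unseen tissue-like samples."""
    if tissue_records is None:
        tissue_records = build_study_records(profile, seed + 3, tissue=True)
    datasets = _build_datasets(tissue_records, profile)
    rows = []
    for variant in VARIANTS:
        rep, with_swei = _variant_parts(variant)
        members = [m for (v, _), m in models.items() if v == variant]
        ds = datasets[rep] if with_swei else _as_plain(datasets[rep])
        pred = ensemble_predict(members, ds) * 1e3
        met = compute_metrics(pred, ds.y * 1e3)
        rows.append({"variant": variant, "rmse_mn": met.rmse,
                     "nmae": met.nmae, "pcc": met.pcc,
                     "n_members": len(members), "n_samples": len(ds)})
    return {"results": pd.DataFrame(rows)}


def run_study(profile: StudyProfile, seeds: list[int],
              with_matrix: bool = True) -> dict:
    """Full study over several seeds; medians are reported across seeds."""
    per_seed = []
    for s in seeds:
        records = build_study_records(profile, s)
        gen = experiment_generalization(profile, s, records=records,
                                        return_models=True)
        tissue = experiment_tissue_transfer(profile, s, gen["models"])
        entry = {"seed": s, "generalization": gen["results"],
                 "tissue": tissue["results"]}
        if with_matrix:
            entry["matrix"] = experiment_transfer_matrix(profile, s,
                                                         records=records)
        per_seed.append(entry)

    gen_all = pd.concat(
        [e["generalization"].assign(seed=e["seed"]) for e in per_seed])
    tissue_all = pd.concat(
        [e["tissue"].assign(seed=e["seed"]) for e in per_seed])
    summary = {
        "median_rmse_mn": gen_all.groupby(["variant", "seed"]).rmse_mn.mean()
                                 .groupby("variant").median().to_dict(),
        "tissue_median_rmse_mn": tissue_all.groupby("variant").rmse_mn
                                           .median().to_dict(),
        "tissue_median_nmae": tissue_all.groupby("variant").nmae
                                        .median().to_dict(),
        "tissue_median_pcc": tissue_all.groupby("variant").pcc
                                       .median().to_dict(),
    }
    return {"per_seed": per_seed, "generalization": gen_all,
            "tissue": tissue_all, "summary": summary}
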