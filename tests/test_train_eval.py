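"""Metrics, folds, training loop and ensembling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octforce import preprocess as pp
from octforce import simkit as sk
from octforce import train_eval as te
from octforce.model import ModelConfig, build_model


class TestMetrics:
    def test_perfect_predictions(self):
        t = np.array([1.0, 2.0, 5.0])
        m = te.compute_metrics(t, t)
        assert (m.rmse, m.nmae, m.pcc) == (0.0, 0.0, pytest.approx(1.0))

    def test_constant_offset(self):
        t = np.array([10.0, 20.0, 40.0])
        m = te.compute_metrics(t + 10.0, t)
        assert m.rmse == pytest.approx(10.0)
        assert m.mae == pytest.approx(10.0)
        assert m.pcc == pytest.approx(1.0)

    def test_hand_computed_example(self):
        m = te.compute_metrics(np.array([0.0, 10.0, 20.0]),
                               np.array([0.0, 20.0, 40.0]))
        assert m.rmse == pytest.approx(np.sqrt(500 / 3))
        assert m.nmae == pytest.approx(0.25)
        assert m.pcc == pytest.approx(1.0)

    def test_constant_targets_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            te.compute_metrics(np.array([1.0, 2.0]), np.array([3.0, 3.0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            te.compute_metrics(np.zeros(3), np.zeros(4))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_agrees_with_closed_forms_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        t = rng.normal(size=n)
        p = rng.normal(size=n)
        if np.ptp(t) == 0:
            return
        m = te.compute_metrics(p, t)
        err = p - t
        assert m.rmse == pytest.approx(np.sqrt((err**2).sum() / n), rel=1e-9)
        assert m.mae == pytest.approx(np.abs(err).sum() / n, rel=1e-9)
        assert m.nmae == pytest.approx(m.mae / (t.max() - t.min()), rel=1e-9)
        # Pearson correlation from first principles
        pc = (((p - p.mean()) * (t - t.mean())).sum()
              / np.sqrt(((p - p.mean())**2).sum() * ((t - t.mean())**2).sum()))
        assert m.pcc == pytest.approx(pc, rel=1e-9, abs=1e-12)
        assert m.rmse >= m.mae >= 0
        assert -1 <= m.pcc <= 1


def synthetic_manifest(n_gels=7, n_phantoms=6, n_locations=2):
    rows = []
    for g in range(n_gels):
        for p in range(n_phantoms):
            for l in range(n_locations):
                for kind in ("sinusoidal", "random_steps"):
                    rows.append({
                        "record_id": f"G{g}_P{p}/L{l}/{kind}",
                        "sample_id": f"G{g}_P{p}",
                        "location_id": f"L{l}",
                        "material_id": f"G{g}",
                        "trajectory_kind": kind,
                        "seed": g * 100 + p * 10 + l,
                    })
    return pd.DataFrame(rows)


class TestFolds:
    def test_by_gel_seven_folds_each_withholding_one_gel(self):
        folds = te.make_folds(synthetic_manifest(), "by_gel")
        assert len(folds) == 7
        for f in folds:
            held = {f.fold_id}
            train_mats = {i.split("_")[0] for i in f.train_ids}
            assert f.fold_id not in train_mats
            assert len(f.val_ids) > 0 and len(f.test_ids) > 0

    def test_train_never_intersects_eval(self):
        for scheme in ("by_gel", "by_phantom"):
            for f in te.make_folds(synthetic_manifest(), scheme):
                assert not set(f.train_ids) & set(f.test_ids)
                assert not set(f.train_ids) & set(f.val_ids)
                assert not set(f.val_ids) & set(f.test_ids)

    def test_union_of_test_sets_covers_each_gel_once(self):
        folds = te.make_folds(synthetic_manifest(), "by_gel")
        covered = [f.fold_id for f in folds]
        assert sorted(covered) == sorted({f"G{g}" for g in range(7)})

    def test_train_splits_sinusoidal_only(self):
        for f in te.make_folds(synthetic_manifest(), "by_gel"):
            assert all(i.endswith("sinusoidal") for i in f.train_ids)
            assert all(i.endswith("random_steps")
                       for i in f.val_ids + f.test_ids)

    def test_by_phantom_six_folds_per_gel(self):
        folds = te.make_folds(synthetic_manifest(), "by_phantom")
        assert len(folds) == 7 * 6

    def test_too_few_replicates_rejected(self):
        m = synthetic_manifest(n_gels=1, n_phantoms=1)
        with pytest.raises(ValueError, match="replicates"):
            te.make_folds(m, "by_gel")


@pytest.fixture(scope="module")
def two_material_datasets():
    """Tiny two-stiffness corpus: soft (5 %) and stiff (15 %) gels."""
    records = []
    for ci, conc in enumerate((0.05, 0.15)):
        mat = sk.make_material("gelatin", concentration=conc)
        for ph in range(2):
            for kind in ("sinusoidal", "random_steps"):
                traj = (sk.sinusoidal_trajectory(seed=ci * 10 + ph)
                        if kind == "sinusoidal"
                        else sk.random_steps_trajectory(seed=ci * 10 + ph))
                geom = sk.ScanGeometry(
                    depth_px=256, lateral_w_px=16, lateral_d_px=16,
                    depth_extent_mm=4.0, lateral_extent_w_mm=3.0,
                    lateral_extent_d_mm=3.0, bscan_rate_hz=14200.0,
                    volume_rate_hz=10 / traj.duration_s)
                rec = sk.simulate_palpation(
                    mat, geom, traj, seed=ci * 100 + ph * 7 + len(records),
                    sample_id=f"C{ci}_P{ph}", location_id="L0")
                rec.phase_velocity = mat.shear_wave_speed
                records.append(rec)
    return pp.build_dataset(records, "2d", with_swei=True, out_size=16)


class TestTraining:
    def split(self, ds):
        meta = ds.meta
        train = ds.select(meta[meta.trajectory_kind == "sinusoidal"].record_id)
        ev = ds.select(meta[meta.trajectory_kind == "random_steps"].record_id)
        return train, ev

    def test_loss_decreases(self, two_material_datasets):
        train_ds, val_ds = self.split(two_material_datasets)
        model = build_model(ModelConfig.desk_2d(with_swei=True, seed=1))
        hist = te.train(model, train_ds, val_ds,
                        te.TrainConfig(epochs=15, batch_size=16,
                                       lr_max=3e-3, seed=1))
        assert hist["train_loss"][-1] < hist["train_loss"][0]

    def test_single_material_fit_within_ten_percent_of_range(
            self, two_material_datasets):
        """On one clean material the model fits the held-out palpation to
        within 10 % of that material's force range."""
        ds = two_material_datasets
        meta = ds.meta
        soft = meta[meta.sample_id.str.startswith("C0")]
        train_ds = te._as_plain(ds.select(
            soft[soft.trajectory_kind == "sinusoidal"].record_id))
        val_ds = te._as_plain(ds.select(
            soft[soft.trajectory_kind == "random_steps"].record_id))
        model = build_model(ModelConfig.desk_2d(seed=1))
        hist = te.train(model, train_ds, val_ds,
                        te.TrainConfig(epochs=40, batch_size=16,
                                       lr_max=3e-3, seed=1))
        assert hist["best_val_rmse"] <= 0.10 * np.ptp(val_ds.y)

    def test_same_seed_reproducible(self, two_material_datasets):
        train_ds, val_ds = self.split(two_material_datasets)
        results = []
        for _ in range(2):
            model = build_model(ModelConfig.desk_2d(seed=2))
            hist = te.train(model, te._as_plain(train_ds), te._as_plain(val_ds),
                            te.TrainConfig(epochs=3, batch_size=16, seed=4))
            results.append(hist["val_rmse"])
        assert results[0] == results[1]

    def test_random_trajectories_in_train_rejected(self, two_material_datasets):
        train_ds, val_ds = self.split(two_material_datasets)
        model = build_model(ModelConfig.desk_2d(seed=0))
        with pytest.raises(ValueError, match="sinusoidal"):
            te.train(model, te._as_plain(val_ds), te._as_plain(val_ds),
                     te.TrainConfig(epochs=1, seed=0))

    def test_swei_dataset_flag_enforced(self, two_material_datasets):
        train_ds, val_ds = self.split(two_material_datasets)
        model = build_model(ModelConfig.desk_2d(with_swei=False, seed=0))
        with pytest.raises(ValueError, match="SWEI"):
            te.train(model, train_ds, val_ds, te.TrainConfig(epochs=1, seed=0))

    def test_trained_fusion_model_responds_to_velocity(self, two_material_datasets):
        """After training on two stiffnesses, changing only the fused
        velocity changes the predicted force."""
        train_ds, val_ds = self.split(two_material_datasets)
        model = build_model(ModelConfig.desk_2d(with_swei=True, seed=5))
        te.train(model, train_ds, val_ds,
                 te.TrainConfig(epochs=30, batch_size=16, lr_max=3e-3, seed=5))
        x, ref, v = te._model_tensors(val_ds, model)
        soft_c = sk.make_material("gelatin", 0.05).shear_wave_speed
        stiff_c = sk.make_material("gelatin", 0.15).shear_wave_speed
        lo = model.predict(x, ref, np.full_like(v, soft_c))
        hi = model.predict(x, ref, np.full_like(v, stiff_c))
        assert not np.allclose(lo, hi, atol=1e-4)


class TestEnsemble:
    def make_members(self, preds):
        class Stub:
            def __init__(self, value):
                self.config = ModelConfig.desk_2d()
                self._value = value
        return preds

    def test_mean_voting(self, two_material_datasets):
        ds = two_material_datasets
        models = [build_model(ModelConfig.desk_2d(with_swei=True, seed=s))
                  for s in (1, 2, 3)]
        for m in models:
            m.y_std, m.y_mean = 1.0, 0.0
        single = [te.predict_dataset(m, ds) for m in models]
        ens = te.ensemble_predict(models, ds)
        assert np.allclose(ens, np.mean(single, axis=0), atol=1e-9)

    def test_single_member_identity(self, two_material_datasets):
        ds = two_material_datasets
        m = build_model(ModelConfig.desk_2d(with_swei=True, seed=1))
        assert np.array_equal(te.ensemble_predict([m], ds),
                              te.predict_dataset(m, ds))

    def test_heterogeneous_members_rejected(self, two_material_datasets):
        a = build_model(ModelConfig.desk_2d(with_swei=True))
        b = build_model(ModelConfig.desk_2d(with_swei=False))
        with pytest.raises(ValueError, match="heterogeneous"):
            te.ensemble_predict([a, b], two_material_datasets)
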