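"""Training orchestration: batching, variants, logging, reproducibility."""

import numpy as np
import pytest

from irmkd import (
    DistillationConfig,
    LossWeights,
    SyntheticLeafSpec,
    ToyCNN,
    distill,
    generate_dataset,
    train_supervised,
    train_teacher,
)
from irmkd.engine import stratified_split
from irmkd.nn import ConfigurationError, parameter_checksum


@pytest.fixture(scope="module")
def small_data():
    spec = SyntheticLeafSpec(n_classes=3, images_per_class=10, image_size=32, seed=5)
    return generate_dataset(spec)[0]


def quick_config(**kw):
    base = dict(
        n_classes=3,
        epochs=2,
        batch_size=12,
        image_size=32,
        seed=2,
        teacher_widths=(8, 16),
        student_widths=(3, 6),
    )
    base.update(kw)
    return DistillationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(lr=0.0),
            dict(lr=-1.0),
            dict(momentum=1.0),
            dict(epochs=0),
            dict(batch_size=1),
            dict(variant="magic"),
            dict(kd_alpha=2.0),
            dict(lr_schedule="cosine"),
            dict(val_fraction=0.0),
        ],
    )
    def test_invalid_fields_rejected(self, kw):
        with pytest.raises(ValueError):
            quick_config(**kw)

    def test_yaml_roundtrip_with_overrides(self, tmp_path):
        cfg_file = tmp_path / "config.yaml"
        cfg_file.write_text(
            "epochs: 5\nbatch_size: 16\nimage_size: 32\nn_classes: 3\n"
            "teacher_widths: [8, 16]\nstudent_widths: [3, 6]\n"
            "loss:\n  alpha: 0.7\n  beta: 0.2\n  gamma: 0.9\n  temperature: 3\n  variant: irm\n"
            "kd:\n  alpha: 0.6\n"
        )
        cfg = DistillationConfig.from_yaml(cfg_file, epochs=2)
        assert cfg.epochs == 2  # override wins
        assert cfg.batch_size == 16
        assert cfg.variant == "irm"
        assert cfg.weights == LossWeights(alpha=0.7, beta=0.2, gamma=0.9, temperature=3)
        assert cfg.kd_alpha == 0.6


class TestSplit:
    def test_stratified_split_is_disjoint_and_per_class(self):
        labels = np.repeat([0, 1, 2], 20)
        train, val = stratified_split(labels, 0.2, seed=1)
        assert len(np.intersect1d(train, val)) == 0
        assert len(train) + len(val) == 60
        for k in range(3):
            assert np.sum(labels[val] == k) == 4

    def test_split_depends_only_on_seed(self):
        labels = np.repeat([0, 1], 10)
        a = stratified_split(labels, 0.2, seed=3)
        b = stratified_split(labels, 0.2, seed=3)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestTrainTeacher:
    def test_single_epoch_yields_single_record(self, small_data):
        _, log = train_teacher(quick_config(epochs=1), dataset=small_data)
        assert len(log.records) == 1
        assert log.records[0].epoch == 1

    def test_checkpoint_written(self, small_data, tmp_path):
        path = tmp_path / "teacher.ckpt"
        train_teacher(quick_config(), dataset=small_data, out_path=path)
        assert path.exists()

    def test_batch_size_clamps_with_warning(self, small_data):
        with pytest.warns(UserWarning, match="clamping"):
            train_teacher(quick_config(batch_size=512, epochs=1), dataset=small_data)

    def test_missing_data_dir_is_io_error(self):
        with pytest.raises(IOError):
            train_teacher(quick_config(data_dir=None))


@pytest.fixture(scope="module")
def teacher(small_data):
    model, _ = train_teacher(quick_config(epochs=5), dataset=small_data)
    return model


class TestDistill:
    @pytest.mark.parametrize("variant", ["baseline", "kd", "irm", "mtk"])
    def test_all_variants_run_and_log_components(self, small_data, teacher, variant):
        cfg = quick_config(variant=variant, epochs=2)
        student, log = distill(cfg, teacher=teacher, dataset=small_data)
        assert len(log.records) == 2
        df = log.to_dataframe()
        assert list(df.columns) == [
            "epoch", "total", "irm_t", "irm", "logits", "gt", "train_acc", "val_acc", "seconds",
        ]
        if variant == "mtk":
            assert (df[["irm_t", "irm", "logits", "gt"]].to_numpy() != 0).all()

    @pytest.mark.parametrize("variant", ["baseline", "kd", "irm", "mtk"])
    def test_logged_total_decomposes_exactly(self, small_data, teacher, variant):
        cfg = quick_config(variant=variant, epochs=3)
        _, log = distill(cfg, teacher=teacher, dataset=small_data)
        for i, rec in enumerate(log.records):
            assert abs(rec.total - log.total_recomposed(i)) < 1e-6

    def test_seed_reproducibility(self, small_data, teacher):
        cfg = quick_config(variant="mtk", epochs=2)
        _, log_a = distill(cfg, teacher=teacher, dataset=small_data)
        _, log_b = distill(cfg, teacher=teacher, dataset=small_data)
        for ra, rb in zip(log_a.records, log_b.records):
            assert abs(ra.total - rb.total) < 1e-4
            assert ra.val_acc == rb.val_acc

    def test_baseline_is_bit_identical_to_plain_supervised_training(self, small_data):
        cfg = quick_config(variant="baseline", epochs=3)
        student, log_b = distill(cfg, teacher=None, dataset=small_data)
        plain = ToyCNN(list(cfg.student_widths), cfg.n_classes, seed=cfg.seed)
        log_p = train_supervised(plain, cfg, dataset=small_data)
        assert parameter_checksum(student) == parameter_checksum(plain)
        for rb, rp in zip(log_b.records, log_p.records):
            assert rb.total == rp.total and rb.val_acc == rp.val_acc

    def test_teacher_parameters_unchanged(self, small_data, teacher):
        before = parameter_checksum(teacher)
        distill(quick_config(variant="mtk", epochs=2), teacher=teacher, dataset=small_data)
        assert parameter_checksum(teacher) == before

    def test_tap_count_mismatch_is_configuration_error(self, small_data, teacher):
        cfg = quick_config(variant="mtk", student_widths=(3, 6, 12))  # m=3 vs teacher m=2
        with pytest.raises(ConfigurationError, match="taps"):
            distill(cfg, teacher=teacher, dataset=small_data)

    def test_missing_teacher_for_relational_variant_is_io_error(self, small_data):
        with pytest.raises(IOError):
            distill(quick_config(variant="mtk"), teacher=None, dataset=small_data)

    def test_teacher_checkpoint_path_loading(self, small_data, teacher, tmp_path):
        from irmkd import save_checkpoint

        path = tmp_path / "t.ckpt"
        save_checkpoint(teacher, path)
        cfg = quick_config(variant="kd", teacher_ckpt=str(path), epochs=1)
        _, log = distill(cfg, dataset=small_data)
        assert len(log.records) == 1

    def test_augmented_training_runs_and_is_deterministic(self, small_data, teacher):
        from irmkd import AugmentationPlan, HorizontalFlip, Shift

        plan = AugmentationPlan(ops=(HorizontalFlip(), Shift(0.1)), seed=1)
        cfg = quick_config(variant="baseline", epochs=2, augmentation=plan)
        _, log_a = distill(cfg, teacher=None, dataset=small_data)
        _, log_b = distill(cfg, teacher=None, dataset=small_data)
        assert [r.total for r in log_a.records] == [r.total for r in log_b.records]
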