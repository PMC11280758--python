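"""Training loop, augmentation, checkpointing and cross-validation."""

import numpy as np
import pytest

from coatseg.metrics import MetricReport
from coatseg.model import CoatSegNet, ModelConfig, normalize_image
from coatseg.synthetic import LabeledImage, SyntheticSpec, generate_sample
from coatseg.train import (
    AugmentConfig,
    OptimConfig,
    Trainer,
    augment_sample,
    crossvalidate,
    evaluate,
    load_checkpoint,
    load_network,
    save_checkpoint,
)


@pytest.fixture(scope="module")
def small_data():
    spec = SyntheticSpec(image_size=32, seed=5)
    return [generate_sample(spec, i) for i in range(6)]


def make_trainer(seed=0, size=32):
    net = CoatSegNet(ModelConfig.tiny(size, seed=seed))
    return Trainer(net, seed=seed)


class TestAugmentation:
    def test_mask_stays_binary_and_aligned(self, small_data, rng):
        cfg = AugmentConfig(rotation_deg=25.0)
        for s in small_data:
            out = augment_sample(s, cfg, rng)
            assert out.image.shape == s.image.shape
            assert set(np.unique(out.mask)) <= {0, 1}

    def test_flip_only_is_involutive(self, small_data):
        cfg = AugmentConfig(rotation_deg=0.0, hflip=True)
        rng_always = np.random.default_rng(0)
        # find a draw that flips, flip twice -> original
        s = small_data[0]
        flipped = LabeledImage(s.image[:, ::-1].copy(),
                               s.mask[:, ::-1].copy(), s.id)
        again = LabeledImage(flipped.image[:, ::-1].copy(),
                             flipped.mask[:, ::-1].copy(), s.id)
        np.testing.assert_array_equal(again.image, s.image)


class TestTrainer:
    def test_few_steps_record_components_and_weights(self, small_data):
        tr = make_trainer()
        tr.fit(small_data, steps=2, batch_size=2,
               augment=AugmentConfig(enabled=False))
        assert len(tr.log) == 2
        for col in ("loss", "ce", "dice", "focal", "w1", "w2", "w3"):
            assert col in tr.log[0]
        assert tr.log[-1]["step"] == 2

    def test_same_seed_reproduces_training_exactly(self, small_data):
        logs = []
        for _ in range(2):
            tr = make_trainer(seed=3)
            tr.fit(small_data, steps=2, batch_size=2,
                   augment=AugmentConfig(enabled=False))
            logs.append([row["loss"] for row in tr.log])
        assert logs[0] == logs[1]

    def test_checkpoint_roundtrip_and_resumed_step_numbering(
        self, small_data, tmp_path
    ):
        tr = make_trainer(seed=1)
        tr.fit(small_data, steps=2, batch_size=2,
               augment=AugmentConfig(enabled=False))
        save_checkpoint(tmp_path / "ck.npz", tr)

        tr2 = make_trainer(seed=99)
        load_checkpoint(tmp_path / "ck.npz", tr2)
        assert tr2.step_idx == 2
        for (n1, p1), (n2, p2) in zip(
            tr.net.named_parameters(), tr2.net.named_parameters()
        ):
            assert n1 == n2
            np.testing.assert_array_equal(p1.data, p2.data)
        tr2.fit(small_data, steps=1, batch_size=2,
                augment=AugmentConfig(enabled=False))
        assert tr2.log[-1]["step"] == 3

    def test_load_network_restores_predictions(self, small_data, tmp_path):
        tr = make_trainer(seed=2)
        tr.fit(small_data, steps=1, batch_size=2,
               augment=AugmentConfig(enabled=False))
        save_checkpoint(tmp_path / "ck.npz", tr)
        net = load_network(tmp_path / "ck.npz", ModelConfig.tiny(32, seed=7))
        x = normalize_image(small_data[0].image)
        np.testing.assert_array_equal(
            net.predict(x).logits, tr.net.predict(x).logits
        )

    def test_write_log_csv(self, small_data, tmp_path):
        import csv

        tr = make_trainer()
        tr.fit(small_data, steps=1, batch_size=2,
               augment=AugmentConfig(enabled=False))
        tr.write_log(tmp_path / "log.csv")
        with open(tmp_path / "log.csv", newline="") as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == 1
        assert set(rows[0]) == {"step", "loss", "ce", "dice", "focal",
                                "w1", "w2", "w3"}


class _OracleNet:
    """Duck-typed 'model' that answers with the ground truth."""

    def __init__(self, samples):
        self._by_key = {
            normalize_image(s.image).tobytes(): s.mask for s in samples
        }

    def predict(self, x):
        from coatseg.model import SegmentationOutput

        mask = self._by_key[x.tobytes()]
        logits = np.stack([1.0 - mask, mask.astype(np.float64)])
        return SegmentationOutput(logits=logits, prob=logits, mask=mask)


class TestEvaluation:
    def test_oracle_model_scores_all_ones(self, small_data):
        report = evaluate(_OracleNet(small_data), small_data)
        assert all(v == 1.0 for v in report.as_dict().values())

    def test_untrained_network_returns_valid_report(self, small_data):
        net = CoatSegNet(ModelConfig.tiny(32, seed=0))
        report = evaluate(net, small_data)
        assert isinstance(report, MetricReport)
        assert 0.0 <= report.dice <= 1.0


class TestCrossValidation:
    def test_folds_cover_dataset_and_reports_are_complete(self, small_data):
        result = crossvalidate(
            small_data, ModelConfig.tiny(32, seed=0), k=3, seed=0, steps=1,
            optim_cfg=OptimConfig(batch_size=2),
            augment=AugmentConfig(enabled=False),
        )
        assert len(result.fold_reports) == 3
        covered = [
            i for f in range(3) for i in result.split.fold_ids(f)
        ]
        assert sorted(covered) == sorted(s.id for s in small_data)
        assert set(result.mean) == {"accuracy", "precision", "dice",
                                    "recall", "iou"}
        assert all(v >= 0.0 for v in result.std.values())

    def test_dataset_smaller_than_k_rejected(self, small_data):
        with pytest.raises(ValueError):
            crossvalidate(small_data[:2], ModelConfig.tiny(32), k=5, steps=1)
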