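"""Training protocol contracts on deliberately tiny networks and data."""

import numpy as np
import pytest

from hccseg.augment import AugmentParams
from hccseg.nn import DcnnNet, FusionNet
from hccseg.preprocess import SlicePair
from hccseg.training import (TrainConfig, run_loocv, split_training_subsets,
                             train_dcnn_staged, train_dfn)


def make_pairs(rng, n=6, size=16, n_cases=3):
    """Synthetic slice pairs with a bright-square 'lesion' on both phases."""
    pairs = []
    for i in range(n):
        img1 = rng.random((size, size)).astype(np.float32) * 0.3
        img2 = rng.random((size, size)).astype(np.float32) * 0.3
        mask = np.zeros((size, size), dtype=np.uint8)
        x0, y0 = rng.integers(2, size - 8, 2)
        mask[x0:x0 + 5, y0:y0 + 5] = 1
        img1[mask > 0] += 0.6
        img2[mask > 0] += 0.6
        pairs.append(SlicePair(phase1_slice=np.clip(img1, 0, 1),
                               phase2_slice=np.clip(img2, 0, 1),
                               mask_slice=mask, case_id=f"c{i % n_cases}",
                               slice_index=i))
    return pairs


TINY = TrainConfig(base_lr=3e-3, dfn_lr=0.2, epochs=(2, 3, 2), epochs_fusion=3,
                   batch_size=4, seed=0)


class TestStagedTraining:
    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_dcnn_staged(DcnnNet(2, seed=0), [], 0, TINY)

    def test_history_length_and_stage_ordering(self, rng):
        pairs = make_pairs(rng)
        net = DcnnNet(2, seed=0)
        _, hist = train_dcnn_staged(net, pairs, 0, TINY,
                                    AugmentParams(multiplicity=1, seed=0))
        stages = hist.stages()
        assert stages == ["encoder"] * 2 + ["full"] * 3 + ["augmented"] * 2
        assert all(np.isfinite(r.mean_loss) for r in hist.records)

    def test_loss_decreases_with_training(self, rng):
        pairs = make_pairs(rng, n=8)
        net = DcnnNet(2, seed=0)
        cfg = TrainConfig(base_lr=3e-3, epochs=(3, 8, 8), batch_size=4, seed=0)
        _, hist = train_dcnn_staged(net, pairs, 0, cfg,
                                    AugmentParams(multiplicity=1, seed=0))
        assert hist.records[-1].mean_loss < hist.records[0].mean_loss

    def test_deterministic_given_seed(self, rng):
        pairs = make_pairs(rng)
        h = []
        for _ in range(2):
            net = DcnnNet(2, seed=1)
            _, hist = train_dcnn_staged(net, pairs, 0, TINY)
            h.append(hist.losses())
        assert h[0] == h[1]


class TestSubsetSplit:
    def test_even_split_disjoint_covering(self):
        ids = [f"c{i}" for i in range(10)]
        a, b = split_training_subsets(ids, seed=0)
        assert len(a) == 5 and len(b) == 5
        assert set(a) | set(b) == set(ids) and not set(a) & set(b)

    def test_odd_split_extra_to_first(self):
        a, b = split_training_subsets([f"c{i}" for i in range(11)], seed=0)
        assert len(a) == 6 and len(b) == 5

    def test_deterministic(self):
        ids = [f"c{i}" for i in range(9)]
        assert split_training_subsets(ids, 3) == split_training_subsets(ids, 3)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            split_training_subsets(["only"], seed=0)


class TestFusionTraining:
    def test_frozen_subnets_are_untouched(self, rng):
        pairs = make_pairs(rng)
        fnet = FusionNet(2, 2, seed=0)
        # train subnets first on subset A internally, then snapshot before the
        # fusion phase would run again -- easiest check: full train with
        # freeze, then ensure fusion phase didn't alter subnet weights by
        # retraining subnets alone with the same seeds
        train_dfn(fnet, pairs, TINY, freeze_subnets=True)
        from hccseg.training import split_training_subsets as split
        import dataclasses
        a, _ = split(sorted({p.case_id for p in pairs}), TINY.seed)
        pairs_a = [p for p in pairs if p.case_id in a]
        # sub-networks are trained with epochs scaled to match the full-set
        # gradient-step budget; replicate that here
        scale = len(pairs) / len(pairs_a)
        sub_cfg = dataclasses.replace(
            TINY, epochs=tuple(int(np.ceil(e * scale)) for e in TINY.epochs))
        ref = FusionNet(2, 2, seed=0)
        for i, phase in enumerate((0, 1)):
            train_dcnn_staged(ref.subnets[i], pairs_a, phase, sub_cfg)
        for pa, pb in zip(fnet.subnets[0].params() + fnet.subnets[1].params(),
                          ref.subnets[0].params() + ref.subnets[1].params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_history_contains_all_phases(self, rng):
        fnet = FusionNet(2, 2, seed=0)
        _, hist = train_dfn(fnet, make_pairs(rng), TINY, freeze_subnets=True)
        stages = set(hist.stages())
        assert "fusion" in stages
        assert any(s.startswith("subnet1") for s in stages)
        assert any(s.startswith("subnet2") for s in stages)
        assert all(np.isfinite(r.mean_loss) for r in hist.records)

    def test_single_case_dataset_rejected(self, rng):
        pairs = [p for p in make_pairs(rng) if p.case_id == "c0"]
        with pytest.raises(ValueError, match="two cases"):
            train_dfn(FusionNet(2, 2, seed=0), pairs, TINY)


class TestLoocv:
    def test_each_fold_excludes_exactly_its_test_case(self):
        ids = ["a", "b", "c"]
        seen = {}

        def fit(train_ids, fold):
            seen[fold] = list(train_ids)
            return train_ids

        def ev(model, test_id):
            assert test_id not in model
            from hccseg.evaluate import SegMetrics
            return SegMetrics(dsc=0.5, precision=0.5, recall=0.5)

        results = run_loocv(ids, fit, ev)
        assert [r.case_id for r in results] == ids
        for r in results:
            assert r.case_id not in r.train_ids
            assert sorted(r.train_ids + [r.case_id]) == sorted(ids)

    def test_fewer_than_two_cases_rejected(self):
        with pytest.raises(ValueError):
            run_loocv(["solo"], lambda *a: None, lambda *a: None)
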