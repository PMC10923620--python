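"""Metric formulas against brute-force oracles; t-test against closed form."""

import numpy as np
import pytest

from hccseg.evaluate import (ConfusionCounts, MetricSummary, aggregate_metrics,
                             confusion_counts, evaluate_masks, make_report,
                             paired_t_test, render_report_text, seg_metrics)


def brute_force_counts(pred, gt):
    tp = fp = fn = 0
    for p, g in zip(pred.ravel(), gt.ravel()):
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif g and not p:
            fn += 1
    return tp, fp, fn


class TestConfusionCounts:
    def test_perfect_prediction(self, rng):
        gt = (rng.random((8, 8, 4)) > 0.5).astype(np.uint8)
        c = confusion_counts(gt, gt)
        assert (c.tp, c.fp, c.fn) == (int(gt.sum()), 0, 0)

    def test_empty_prediction(self, rng):
        gt = (rng.random((8, 8, 4)) > 0.5).astype(np.uint8)
        c = confusion_counts(np.zeros_like(gt), gt)
        assert (c.tp, c.fp, c.fn) == (0, 0, int(gt.sum()))

    def test_matches_voxel_loop_oracle(self, rng):
        for _ in range(10):
            pred = (rng.random((16, 16, 16)) > 0.5).astype(np.uint8)
            gt = (rng.random((16, 16, 16)) > 0.5).astype(np.uint8)
            c = confusion_counts(pred, gt)
            assert (c.tp, c.fp, c.fn) == brute_force_counts(pred, gt)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))


class TestSegMetrics:
    def test_hand_evaluated_counts(self):
        m = seg_metrics(ConfusionCounts(tp=2, fp=1, fn=2))
        assert m.dsc == pytest.approx(4 / 7)
        assert m.precision == pytest.approx(2 / 3)
        assert m.recall == pytest.approx(0.5)

    def test_conventions_for_degenerate_cases(self):
        assert seg_metrics(ConfusionCounts(0, 0, 0)) == seg_metrics(ConfusionCounts(0, 0, 0))
        perfect = seg_metrics(ConfusionCounts(0, 0, 0))
        assert (perfect.dsc, perfect.precision, perfect.recall) == (1.0, 1.0, 1.0)
        miss = seg_metrics(ConfusionCounts(0, 0, 5))
        assert (miss.dsc, miss.precision, miss.recall) == (0.0, 0.0, 0.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0)

    def test_adding_tp_never_decreases_dsc(self, rng):
        for _ in range(20):
            tp, fp, fn = (int(v) for v in rng.integers(0, 30, 3))
            if fn == 0:
                continue
            before = seg_metrics(ConfusionCounts(tp, fp, fn)).dsc
            after = seg_metrics(ConfusionCounts(tp + 1, fp, fn - 1)).dsc
            assert after >= before

    def test_adding_fp_never_increases_precision(self, rng):
        for _ in range(20):
            tp, fp, fn = (int(v) for v in rng.integers(0, 30, 3))
            if tp + fp == 0:
                continue
            before = seg_metrics(ConfusionCounts(tp, fp, fn)).precision
            after = seg_metrics(ConfusionCounts(tp, fp + 1, fn)).precision
            assert after <= before


class TestAggregate:
    def test_single_case_convention(self):
        m = evaluate_masks(np.ones((2, 2, 2)), np.ones((2, 2, 2)))
        s = aggregate_metrics([m])["dsc"]
        assert (s.mean, s.std, s.median, s.n) == (1.0, 0.0, 1.0, 1)

    def test_known_values(self):
        vals = [seg_metrics(ConfusionCounts(tp, 10 - tp, 10 - tp))
                for tp in (3, 4, 5)]
        s = aggregate_metrics(vals)["dsc"]
        assert s.min <= s.median <= s.max

    def test_matches_sort_based_recomputation(self, rng):
        metrics = [seg_metrics(ConfusionCounts(*map(int, rng.integers(1, 50, 3))))
                   for _ in range(51)]
        s = aggregate_metrics(metrics)["dsc"]
        v = sorted(m.dsc for m in metrics)
        assert s.min == v[0] and s.max == v[-1]
        assert s.median == pytest.approx(v[25])
        assert s.mean == pytest.approx(sum(v) / 51)
        mean = sum(v) / 51
        assert s.std == pytest.approx((sum((x - mean) ** 2 for x in v) / 50) ** 0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_metrics([])


class TestPairedTTest:
    def test_identical_vectors_degenerate(self):
        r = paired_t_test([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert (r.t, r.p, r.degenerate) == (0.0, 1.0, True)

    def test_symmetric_differences_give_t_zero(self):
        r = paired_t_test([1.0, 0.0], [0.0, 1.0])
        assert r.t == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_agrees_with_independent_t_cdf(self, rng):
        # closed-form recomputation with an independent Student-t tail
        # implementation (numerical integration of the density)
        from scipy.integrate import quad
        from math import gamma, sqrt, pi

        def t_two_sided_p(t, df):
            c = gamma((df + 1) / 2) / (gamma(df / 2) * sqrt(df * pi))
            dens = lambda u: c * (1 + u * u / df) ** (-(df + 1) / 2)
            tail, _ = quad(dens, abs(t), np.inf)
            return 2 * tail

        for _ in range(50):
            a = rng.normal(0.7, 0.1, 10)
            b = rng.normal(0.65, 0.1, 10)
            r = paired_t_test(a, b)
            d = a - b
            t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
            assert r.t == pytest.approx(t_ref, abs=1e-12)
            assert r.p == pytest.approx(t_two_sided_p(t_ref, len(d) - 1), abs=1e-9)

    def test_length_mismatch_and_tiny_n_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            paired_t_test([1.0], [1.0])


class TestReport:
    def _summaries(self):
        mk = lambda v: {n: MetricSummary(v, 0.1, v, v - 0.1, v + 0.1, 3)
                        for n in ("dsc", "precision", "recall")}
        return {"DCNN-F": mk(0.69), "DFN-F": mk(0.74), "DFN-R": mk(0.83)}

    def test_three_model_table_structure(self):
        df = make_report(self._summaries())
        assert list(df["model"]) == ["DCNN-F", "DFN-F", "DFN-R"]
        for m in ("dsc", "precision", "recall"):
            for col in ("mean", "std", "median", "min", "max"):
                assert f"{m}_{col}" in df.columns
        assert "p_value" in df.columns

    def test_csv_roundtrip(self, tmp_path):
        import pandas as pd
        df = make_report(self._summaries())
        df.to_csv(tmp_path / "r.csv", index=False)
        back = pd.read_csv(tmp_path / "r.csv")
        assert list(back["model"]) == list(df["model"])
        assert back["dsc_mean"].tolist() == pytest.approx(df["dsc_mean"].tolist())

    def test_p_value_only_for_compared_models(self):
        from hccseg.evaluate import TTestResult
        df = make_report(self._summaries(),
                         tests={"DFN-F": TTestResult(t=1.0, p=0.26, n=3)})
        assert np.isnan(df.loc[df.model == "DCNN-F", "p_value"]).all()
        assert df.loc[df.model == "DFN-F", "p_value"].iloc[0] == pytest.approx(0.26)
        text = render_report_text(df)
        assert "DFN-R" in text
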