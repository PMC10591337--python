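"""AUC scoring, report aggregation, decile profiles and delta-AUC."""

import numpy as np
import pytest

import xasgnn as x
from xasgnn.evaluation import (ExplainReport, auc_roc, delta_auc,
                               evaluate_model, explain_molecule,
                               rse_decile_profile)
from xasgnn.gnn_models import build_model


def brute_force_auc(scores, labels):
    """Enumerate all positive-negative pairs: win 1, tie 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAucRoc:
    @pytest.mark.parametrize("scores,labels,expected", [
        ([0.9, 0.1], [1, 0], 1.0),
        ([0.5, 0.5], [1, 0], 0.5),
        ([3, 1, 2], [1, 0, 1], 1.0),
        ([1, 3, 2], [1, 0, 1], 0.0),
    ])
    def test_examples(self, scores, labels, expected):
        assert auc_roc(np.array(scores, dtype=float),
                       np.array(labels)) == pytest.approx(expected)

    def test_single_class_undefined(self):
        assert auc_roc(np.array([1.0, 2.0]), np.array([1, 1])) is None
        assert auc_roc(np.array([1.0, 2.0]), np.array([0, 0])) is None

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0], labels[-1] = 0, 1
            scores = rng.choice([0.1, 0.25, 0.5, 0.9], size=n)  # force ties
            assert auc_roc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(14)
        scores = rng.normal(size=10)
        labels = np.array([1, 0, 1, 0, 0, 1, 0, 1, 0, 0])
        base = auc_roc(scores, labels)
        assert auc_roc(np.exp(3 * scores), labels) == pytest.approx(base)

    def test_complement_under_score_negation(self):
        rng = np.random.default_rng(15)
        scores = rng.normal(size=9)  # continuous, no ties
        labels = np.array([1, 1, 0, 0, 1, 0, 0, 1, 0])
        assert auc_roc(scores, labels) + auc_roc(-scores, labels) == \
            pytest.approx(1.0)


class TestExplainMolecule:
    def test_explains_peaks_of_reference_spectrum(self, dataset, grid):
        model = build_model(x.ModelConfig(
            architecture="gcn", hidden_sizes=(8,), n_out=100, seed=0))
        rec = dataset[0]
        expl = explain_molecule(model, rec.graph, rec.sticks,
                                rec.transitions, grid)
        assert len(expl) >= 1
        for e in expl:
            assert e.cam_peak_scores.shape == (rec.graph.n_atoms,)
            for auc in (e.auc_core, e.auc_virtual):
                assert auc is None or 0.0 <= auc <= 1.0

    def test_oracle_scores_give_perfect_auc(self, dataset):
        """Scoring atoms by the ground-truth weights themselves ranks every
        contributing atom above every non-contributing one."""
        from xasgnn.ground_truth import labels_for_peak
        n_checked = 0
        for rec in dataset[:20]:
            for p in rec.planted:
                lab = labels_for_peak(rec.sticks, rec.transitions, p.peak,
                                      rec.graph.n_atoms)
                for weights, labels in ((lab.core_weights, lab.core_labels),
                                        (lab.virtual_weights,
                                         lab.virtual_labels)):
                    auc = auc_roc(weights, labels)
                    if auc is not None:
                        assert auc == 1.0
                        n_checked += 1
        assert n_checked >= 20

    def test_random_scores_near_half(self, dataset):
        rng = np.random.default_rng(16)
        aucs = []
        for rec in dataset:
            for p in rec.planted:
                for labels in (p.core_labels, p.virtual_labels):
                    auc = auc_roc(rng.uniform(size=rec.graph.n_atoms), labels)
                    if auc is not None:
                        aucs.append(auc)
        assert len(aucs) >= 100
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)


class TestEvaluateModel:
    def test_report_summary_fields(self, dataset, grid):
        model = build_model(x.ModelConfig(
            architecture="gcn", hidden_sizes=(8,), n_out=100, seed=0))
        report = evaluate_model(model, dataset[:10], grid)
        s = report.summary()
        assert s["n_molecules"] == 10
        assert s["n_peaks"] >= 10
        assert 0.0 <= s["mean_auc_core"] <= 1.0
        assert "mean_rse" in s

    def test_undefined_aucs_counted_not_imputed(self):
        report = ExplainReport()
        report.add_molecule("m", [], mol_rse=0.1)
        assert report.per_molecule[0]["mean_auc_core"] is None
        with pytest.raises(ValueError):
            report.mean_auc("core")


class TestRseDecileProfile:
    def test_constant_auc_constant_bins(self):
        pairs = [(0.01 * i, 0.7) for i in range(20)]
        bins = rse_decile_profile(pairs)
        assert len(bins) == 10
        assert all(auc == pytest.approx(0.7) for _, auc in bins)

    def test_monotone_auc_monotone_bins(self):
        pairs = [(0.01 * i, 1.0 - 0.02 * i) for i in range(30)]
        bins = rse_decile_profile(pairs)
        aucs = [a for _, a in bins]
        assert all(a > b for a, b in zip(aucs, aucs[1:]))
        rses = [r for r, _ in bins]
        assert rses == sorted(rses)

    def test_remainder_spread_over_first_bins(self):
        # 25 molecules -> group sizes 3,3,3,3,3,2,2,2,2,2
        pairs = [(float(i), float(i)) for i in range(25)]
        bins = rse_decile_profile(pairs)
        # group means reconstruct the claimed sizes
        expected_sizes = [3, 3, 3, 3, 3, 2, 2, 2, 2, 2]
        start, expected = 0, []
        for size in expected_sizes:
            expected.append(np.mean(range(start, start + size)))
            start += size
        np.testing.assert_allclose([r for r, _ in bins], expected)

    def test_too_few_molecules_rejected(self):
        with pytest.raises(ValueError):
            rse_decile_profile([(0.1, 0.5)] * 9)


class TestDeltaAuc:
    def _report(self, core, virtual):
        r = ExplainReport()
        r.per_molecule = [{"molecule_id": "m", "n_peaks": 1,
                           "mean_auc_core": core,
                           "mean_auc_virtual": virtual, "rse": None}]
        return r

    def test_identical_reports_zero(self):
        a, b = self._report(0.8, 0.7), self._report(0.8, 0.7)
        d = delta_auc(a, b)
        assert d["core"] == pytest.approx(0.0)
        assert d["virtual"] == pytest.approx(0.0)

    @pytest.mark.parametrize("before,after,expected", [
        (0.8, 0.6, -25.0), (0.7, 0.49, -30.0)])
    def test_percentage_arithmetic(self, before, after, expected):
        d = delta_auc(self._report(before, before),
                      self._report(after, after))
        assert d["core"] == pytest.approx(expected)
        assert d["virtual"] == pytest.approx(expected)
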