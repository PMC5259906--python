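import numpy as np
import pytest
from hypothesis import given, strategies as st

from gtpsite import evaluation
from gtpsite.encoding import WindowFragment, extract_windows
from gtpsite.evaluation import (
    ConfusionCounts,
    auc,
    composition_frequencies,
    confusion,
    metrics,
    protein_kfold,
    roc_curve,
)
from gtpsite.io_formats import ConsistencyError, ParameterError, ProteinRecord


def rank_auc(scores, truth):
    """O(n^2) pairwise comparison oracle."""
    scores = np.asarray(scores)
    truth = np.asarray(truth)
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestConfusion:
    def test_identity(self):
        c = confusion([1, 0], [1, 0])
        assert (c.TP, c.TN, c.FP, c.FN) == (1, 1, 0, 0)

    def test_inverted(self):
        c = confusion([1, 0], [0, 1])
        assert c.TP == 0 and c.TN == 0 and c.FP == 1 and c.FN == 1

    def test_counts_partition_instances(self, rng):
        truth = rng.integers(0, 2, 50)
        pred = rng.integers(0, 2, 50)
        c = confusion(truth, pred)
        tally = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
        for t, p in zip(truth, pred):
            tally["TP" if t and p else "FN" if t else "FP" if p else "TN"] += 1
        assert (c.TP, c.FP, c.TN, c.FN) == (
            tally["TP"], tally["FP"], tally["TN"], tally["FN"],
        )
        assert c.total == 50

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConsistencyError):
            confusion([1, 0], [1])


class TestMetrics:
    def test_perfect_prediction(self):
        r = metrics(ConfusionCounts(10, 0, 40, 0))
        assert r.sensitivity == 100.0 and r.specificity == 100.0
        assert r.accuracy == 100.0 and r.mcc == 1.0

    def test_zero_denominator_reported_as_undefined(self):
        r = metrics(ConfusionCounts(0, 0, 5, 5))
        assert r.sensitivity == 0.0
        assert r.mcc is None  # TP+FP = 0
        r2 = metrics(ConfusionCounts(0, 0, 0, 0))
        assert r2.accuracy is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            ConfusionCounts(-1, 0, 0, 0)

    def test_agrees_with_sklearn_mcc(self, rng):
        import sklearn.metrics

        truth = rng.integers(0, 2, 60)
        pred = rng.integers(0, 2, 60)
        r = metrics(confusion(truth, pred))
        assert r.mcc == pytest.approx(
            sklearn.metrics.matthews_corrcoef(truth, pred), abs=1e-12
        )

    @given(st.tuples(*[st.integers(min_value=1, max_value=500)] * 4))
    def test_mcc_swap_and_inversion_invariances(self, counts):
        tp, fp, tn, fn = counts
        base = metrics(ConfusionCounts(tp, fp, tn, fn)).mcc
        swapped = metrics(ConfusionCounts(tn, fn, tp, fp)).mcc
        inverted = metrics(ConfusionCounts(fn, tn, fp, tp)).mcc
        assert base == pytest.approx(swapped, abs=1e-12)
        assert base == pytest.approx(-inverted, abs=1e-12)


class TestROC:
    def test_perfect_separation_passes_through_corner(self):
        pts = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert [0.0, 1.0] in pts.tolist()
        assert auc(pts) == 1.0

    def test_all_tied_scores_give_diagonal(self):
        pts = roc_curve([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert auc(pts) == pytest.approx(0.5, abs=1e-12)

    def test_matches_exhaustive_threshold_enumeration(self, rng):
        scores = rng.normal(size=10).round(1)  # force some ties
        truth = np.array([1, 1, 1, 0, 0, 0, 0, 0, 1, 0])
        pts = {tuple(p) for p in roc_curve(scores, truth)}
        expected = {(0.0, 0.0), (1.0, 1.0)}
        for t in np.unique(scores):
            pred = (scores >= t).astype(int)
            c = confusion(truth, pred)
            expected.add((c.FP / (c.FP + c.TN), c.TP / (c.TP + c.FN)))
        assert pts == expected

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            roc_curve([0.1, 0.2], [1, 1])

    def test_plot_writes_figure(self, tmp_path):
        pts = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        out = tmp_path / "roc.png"
        evaluation.plot_roc(pts, out)
        assert out.stat().st_size > 0

    def test_auc_equals_rank_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 50))
            truth = rng.integers(0, 2, n)
            if truth.min() == truth.max():
                continue
            scores = rng.normal(size=n).round(1)
            assert auc(roc_curve(scores, truth)) == pytest.approx(
                rank_auc(scores, truth), abs=1e-12
            )


class TestProteinKFold:
    def make_records(self, n, positives):
        recs = []
        for i in range(n):
            npos = positives[i % len(positives)]
            seq = "ACDEFGHIKLMNPQRSTVWY" * 3
            recs.append(
                ProteinRecord(f"P{i}", seq, set(range(1, npos + 1)))
            )
        return recs

    def test_one_protein_per_fold(self):
        recs = self.make_records(5, [3])
        assignment = protein_kfold(recs, k=5, seed=0)
        assert sorted(assignment.values()) == [0, 1, 2, 3, 4]

    def test_same_seed_identical(self):
        recs = self.make_records(12, [1, 5, 9])
        assert protein_kfold(recs, 4, seed=3) == protein_kfold(recs, 4, seed=3)

    def test_positive_balance_on_18_proteins(self):
        recs = self.make_records(18, [2, 4, 6, 8, 10, 12])
        assignment = protein_kfold(recs, k=5, seed=1)
        per_fold = [0] * 5
        for rec in recs:
            per_fold[assignment[rec.id]] += rec.n_positive
        assert max(per_fold) / min(per_fold) <= 2

    def test_every_fold_gets_a_positive(self):
        recs = self.make_records(10, [0, 7])  # half the proteins lack positives
        assignment = protein_kfold(recs, k=5, seed=0)
        per_fold = [0] * 5
        for rec in recs:
            per_fold[assignment[rec.id]] += rec.n_positive
        assert min(per_fold) >= 1

    def test_too_few_proteins_rejected(self):
        with pytest.raises(ParameterError):
            protein_kfold(self.make_records(3, [2]), k=5, seed=0)
        with pytest.raises(ParameterError):
            protein_kfold(self.make_records(6, [0, 0, 3]), k=5, seed=0)


class TestComposition:
    def test_all_positive_single_residue(self):
        rec = ProteinRecord("P1", "GGG", binding_positions={1, 2, 3})
        freqs = composition_frequencies(extract_windows(rec, 3))
        assert freqs[1] == {"G": 1.0}

    def test_class_frequencies_sum_to_one(self, signal_dataset):
        records, _, _ = signal_dataset
        frags = [f for r in records for f in extract_windows(r, 19)]
        freqs = composition_frequencies(frags)
        for label in (0, 1):
            assert sum(freqs[label].values()) == pytest.approx(1.0, abs=1e-12)

    def test_motif_residues_enriched_in_positive_class(self, signal_dataset):
        records, _, _ = signal_dataset
        frags = [f for r in records for f in extract_windows(r, 19)]
        freqs = composition_frequencies(frags)
        # the implanted GK pair makes G and K the dominant binding residues
        top = sorted(freqs[1], key=freqs[1].get, reverse=True)[:4]
        assert {"G", "K"} <= set(top)
        # the motif residues are collectively enriched over the background class
        motif_mass = lambda label: sum(freqs[label].get(aa, 0.0) for aa in "GKSD")
        assert motif_mass(1) > motif_mass(0)

    def test_order_invariance(self):
        rec = ProteinRecord("P1", "GKSDA", binding_positions={2, 4})
        frags = extract_windows(rec, 3)
        assert composition_frequencies(frags) == composition_frequencies(frags[::-1])
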