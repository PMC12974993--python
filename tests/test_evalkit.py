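"""Clustering, fold construction, FDR calibration, metrics, comparisons."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exonppi.evalkit import (
    ClusterSet,
    ThresholdCalibration,
    au_prc,
    au_roc,
    benjamini_hochberg,
    calibrate_thresholds,
    compare_methods,
    compute_metrics,
    confusion_metrics,
    greedy_identity_cluster,
    read_cluster_tsv,
    round_robin_folds,
    training_fdr_at,
    write_cluster_tsv,
)


def mutate(seq: str, rate: float, rng) -> str:
    aa = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(
        str(rng.choice(list(aa))) if rng.random() < rate else c for c in seq
    )


class TestGreedyClustering:
    def test_identical_sequences_co_cluster(self):
        cs = greedy_identity_cluster({"a": "MKTAYIAKQR", "b": "MKTAYIAKQR"})
        assert len(cs.clusters) == 1

    def test_unrelated_sequences_split(self):
        cs = greedy_identity_cluster(
            {"a": "MKTAYIAKQRMKTAYIAKQR", "b": "GGGPWLLSDE" * 2}
        )
        assert len(cs.clusters) == 2

    def test_mutated_families_co_cluster(self):
        rng = np.random.default_rng(0)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        seqs = {}
        family_of = {}
        for fam in range(3):
            seed_seq = "".join(rng.choice(list(aa), size=60))
            for member in range(3):
                sid = f"f{fam}m{member}"
                seqs[sid] = mutate(seed_seq, 0.10, rng)
                family_of[sid] = fam
        cs = greedy_identity_cluster(seqs, threshold=0.30)
        for members in cs.clusters.values():
            assert len({family_of[m] for m in members}) == 1
        assert len(cs.clusters) == 3

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty sequence"):
            greedy_identity_cluster({"a": ""})


class TestClusterTsv:
    def test_read_example(self, tmp_path):
        path = tmp_path / "clu.tsv"
        path.write_text("A\tA\nA\tB\nC\tC\n")
        cs = read_cluster_tsv(path)
        assert cs.clusters == {"A": ["A", "B"], "C": ["C"]}

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_cluster_tsv(path)

    def test_member_with_two_representatives_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("A\tB\nC\tB\n")
        with pytest.raises(ValueError, match="two representatives"):
            read_cluster_tsv(path)

    def test_round_trip(self, tmp_path):
        cs = ClusterSet({"A": ["A", "B"], "C": ["C", "D", "E"]})
        path = tmp_path / "clu.tsv"
        write_cluster_tsv(cs, path)
        assert read_cluster_tsv(path).clusters == cs.clusters

    def test_chain_in_two_clusters_rejected(self):
        with pytest.raises(ValueError, match="two clusters"):
            ClusterSet({"A": ["x"], "B": ["x"]})


def cluster_set_of_sizes(sizes):
    return ClusterSet(
        {
            f"c{i:03d}": [f"c{i:03d}_{j}" for j in range(s)]
            for i, s in enumerate(sizes)
        }
    )


class TestRoundRobinFolds:
    def test_boustrophedon_worked_example(self):
        cs = cluster_set_of_sizes([5, 4, 3, 3, 2, 2, 1, 1, 1, 1])
        fa = round_robin_folds(cs, 5)
        totals = {f: 0 for f in range(1, 6)}
        for cid, fold in fa.cluster_to_fold.items():
            totals[fold] += len(cs.clusters[cid])
        assert [totals[f] for f in range(1, 6)] == [6, 5, 4, 4, 4]

    def test_equal_clusters_one_per_fold(self):
        cs = cluster_set_of_sizes([2] * 5)
        fa = round_robin_folds(cs, 5)
        assert sorted(fa.cluster_to_fold.values()) == [1, 2, 3, 4, 5]

    def test_too_few_clusters_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            round_robin_folds(cluster_set_of_sizes([3, 3]), 5)

    @pytest.mark.parametrize("seed", range(10))
    def test_no_leakage_and_bounded_spread(self, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(1, 12, size=int(rng.integers(6, 40)))
        cs = cluster_set_of_sizes(sizes)
        fa = round_robin_folds(cs, 5)
        totals = {f: 0 for f in range(1, 6)}
        chain_fold = {}
        for cid, fold in fa.cluster_to_fold.items():
            totals[fold] += len(cs.clusters[cid])
            for chain in cs.clusters[cid]:
                assert chain not in chain_fold
                chain_fold[chain] = fold
        spread = max(totals.values()) - min(totals.values())
        assert spread <= max(sizes)

    def test_cross_fold_pairs_dropped(self):
        cs = cluster_set_of_sizes([2] * 5)
        fa = round_robin_folds(cs, 5)
        c2c = cs.chain_to_cluster()
        chains = sorted(c2c)
        pairs = list(itertools.combinations(chains, 2))
        by_fold, dropped = fa.assign_pairs(pairs, c2c)
        for fold, fold_pairs in by_fold.items():
            for a, b in fold_pairs:
                assert fa.fold_of_chain(a, c2c) == fa.fold_of_chain(b, c2c) == fold
        assert len(dropped) + sum(len(v) for v in by_fold.values()) == len(pairs)


class TestCalibrateThresholds:
    def test_separable_scores_threshold_at_lowest_positive(self):
        data = [(v, 0) for v in (0.1, 0.2, 0.3, 0.4)] + [
            (v, 1) for v in np.arange(0.5, 0.951, 0.05)
        ]
        calib = calibrate_thresholds(data)
        assert all(tau == pytest.approx(0.5) for tau in calib.thresholds.values())

    def test_unattainable_level_gives_infinity(self):
        # top score is a negative: FDR can never reach <= 1%
        data = [(0.9, 0), (0.7, 1), (0.5, 0), (0.3, 1)]
        calib = calibrate_thresholds(data, levels=(0.01,))
        assert calib.thresholds[0.01] == np.inf

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            calibrate_thresholds([(0.5, 1), (0.6, 1)])

    @pytest.mark.parametrize("seed", range(10))
    def test_brute_force_oracle_and_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(120), 2)  # ties on purpose
        labels = (rng.random(120) < 0.3).astype(int)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        data = list(zip(scores, labels))
        levels = (0.01, 0.02, 0.03, 0.04, 0.05)
        calib = calibrate_thresholds(data, levels)
        for level in levels:
            # oracle: scan every observed score as a candidate threshold
            feasible = [
                tau
                for tau in sorted(set(scores))
                if training_fdr_at(data, tau) <= level
            ]
            expected = min(feasible) if feasible else np.inf
            assert calib.thresholds[level] == expected
            # training FDR at the chosen threshold respects the level
            if np.isfinite(calib.thresholds[level]):
                assert training_fdr_at(data, calib.thresholds[level]) <= level
        taus = [calib.thresholds[l] for l in levels]
        assert all(a >= b for a, b in zip(taus, taus[1:]))


class TestMetrics:
    def test_auroc_examples(self):
        assert au_roc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0
        # pairwise-comparison oracle counts 3 of 4 concordant pairs
        assert au_roc([1, 1, 0, 0], [0.8, 0.4, 0.6, 0.2]) == 0.75

    @pytest.mark.parametrize("seed", range(10))
    def test_auroc_equals_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        scores = np.round(rng.random(n), 1)  # induce ties
        labels = (rng.random(n) < 0.4).astype(int)
        if len(np.unique(labels)) < 2:
            labels[:2] = [0, 1]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        oracle = np.mean(
            [(1.0 if p > q else 0.5 if p == q else 0.0) for p in pos for q in neg]
        )
        assert au_roc(labels, scores) == pytest.approx(oracle)

    def test_auroc_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        scores = rng.random(200)
        labels = (rng.random(200) < 0.25).astype(int)
        assert au_roc(labels, scores) == pytest.approx(roc_auc_score(labels, scores))

    def test_confusion_closed_form_example(self):
        m = confusion_metrics(tp=8, fp=2, fn=2, tn=88)
        assert m["precision"] == pytest.approx(0.8)
        assert m["recall"] == pytest.approx(0.8)
        assert m["f_score"] == pytest.approx(0.8)
        assert m["mcc"] == pytest.approx(700 / 900)

    def test_mcc_zero_denominator_convention(self):
        assert confusion_metrics(1, 1, 1, 1)["mcc"] == 0.0
        assert confusion_metrics(0, 0, 0, 10)["mcc"] == 0.0
        assert confusion_metrics(0, 0, 0, 10)["precision"] == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_confusion_metrics_agree_with_formula_evaluation(self, seed):
        rng = np.random.default_rng(seed)
        tp, fp, fn, tn = (int(v) for v in rng.integers(0, 50, 4))
        m = confusion_metrics(tp, fp, fn, tn)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        assert m["precision"] == pytest.approx(prec)
        assert m["recall"] == pytest.approx(rec)
        f = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        assert m["f_score"] == pytest.approx(f)
        den = np.sqrt(
            float((tp + fp)) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        mcc = (tp * tn - fp * fn) / den if den else 0.0
        assert m["mcc"] == pytest.approx(mcc)
        assert -1.0 <= m["mcc"] <= 1.0

    def test_report_ranges_and_degenerate_flag(self):
        calib = ThresholdCalibration({0.01: 0.5})
        report = compute_metrics([(0.9, 1), (0.4, 0), (0.7, 1)], calib)
        assert 0 <= report.au_roc <= 1 and 0 <= report.au_prc <= 1
        assert report.au_prc_baseline == pytest.approx(2 / 3)
        assert not report.degenerate
        single = compute_metrics([(0.9, 1), (0.7, 1)], calib)
        assert single.degenerate and np.isnan(single.au_roc)

    def test_au_prc_step_interpolation(self):
        # perfect ranking -> AU-PRC 1; worst ranking -> baseline-ish
        assert au_prc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == pytest.approx(1.0)
        assert au_prc([0, 0, 1], [0.9, 0.8, 0.1]) == pytest.approx(1 / 3)


class TestHeldOutFdr:
    @pytest.mark.parametrize("seed", range(5))
    def test_held_out_fdr_tracks_nominal_level(self, seed):
        """Thresholds calibrated on training data keep the FDR near nominal
        on a large test draw from the same distribution."""
        rng = np.random.default_rng(seed)

        def draw(n):
            n_pos = n // 5  # 1:4 imbalance
            scores = np.concatenate(
                [rng.beta(6, 2, n_pos), rng.beta(2, 6, n - n_pos)]
            )
            labels = np.array([1] * n_pos + [0] * (n - n_pos))
            return list(zip(scores, labels))

        train, test = draw(2000), draw(20000)
        calib = calibrate_thresholds(train)
        for level, tau in calib.thresholds.items():
            assert training_fdr_at(train, tau) <= level
            assert training_fdr_at(test, tau) <= level + 0.02


class TestCompareMethods:
    def test_identical_vectors_p_one_degenerate(self):
        comps = compare_methods({"A": np.ones(6), "B": np.ones(6)})
        assert comps[0].p_value == 1.0 and comps[0].degenerate

    def test_bh_worked_example(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04, 0.05])
        np.testing.assert_allclose(q, 0.05)

    def test_constant_shift_is_significant(self):
        # a uniform improvement over 15 paired tests lands in the
        # 2*(1/2)^15 region (tied ranks push scipy to the normal
        # approximation; exact enumeration on distinct shifts below)
        x = np.arange(15, dtype=float)
        comps = compare_methods({"A": x + 0.5, "B": x})
        assert comps[0].p_value < 1e-3
        rng = np.random.default_rng(0)
        shifts = rng.uniform(0.4, 0.6, 15)
        comps = compare_methods({"A": x + shifts, "B": x})
        assert comps[0].p_value == pytest.approx(2 * 0.5**15)

    def test_q_values_cover_all_pairs(self):
        rng = np.random.default_rng(2)
        data = {m: rng.random(10) for m in "ABCD"}
        comps = compare_methods(data)
        assert len(comps) == 6
        assert all(np.isfinite(c.q_value) for c in comps)
        assert all(c.q_value >= c.p_value - 1e-12 for c in comps)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="same number"):
            compare_methods({"A": np.ones(3), "B": np.ones(4)})


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    scores=st.lists(
        st.floats(min_value=0, max_value=1, allow_nan=False), min_size=4, max_size=60
    ),
    labels_seed=st.integers(min_value=0, max_value=10**6),
)
def test_calibration_never_exceeds_level_property(scores, labels_seed):
    """For any score set with both classes, the training FDR at every
    calibrated finite threshold stays at or below its nominal level."""
    rng = np.random.default_rng(labels_seed)
    labels = (rng.random(len(scores)) < 0.5).astype(int)
    labels[0], labels[1] = 0, 1
    data = list(zip(scores, labels))
    calib = calibrate_thresholds(data)
    for level, tau in calib.thresholds.items():
        if np.isfinite(tau):
            assert training_fdr_at(data, tau) <= level
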