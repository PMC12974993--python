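"""Leakage-controlled evaluation: folds, FDR thresholds, metrics, comparisons.

Evaluation of interface predictors is easy to inflate by sequence
leakage: two chains sharing >30% identity must never be split between
training and testing. Chains are therefore clustered at <30% identity
(MMSeqs2 cluster TSVs are read directly; a greedy alignment-based
fallback is built in) and whole clusters are dealt to five folds by a
round-robin forward-backward order so fold sizes stay as even as
possible.

Decision thresholds for the threshold-dependent metrics (MCC,
precision, recall, F-score) are calibrated on training data so that the
false discovery rate FP/(FP+TP) among predicted positives stays at or
below nominal levels of 1-5%. AU-ROC and AU-PRC complete the six
performance measures. Paired Wilcoxon signed-rank tests with
Benjamini-Hochberg correction compare methods across folds/datasets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata, wilcoxon
from statsmodels.stats.multitest import multipletests

DEFAULT_FDR_LEVELS = (0.01, 0.02, 0.03, 0.04, 0.05)


@dataclass
class ClusterSet:
    """Partition of chain IDs into sequence-identity clusters."""

    clusters: dict[str, list[str]]
    identity_threshold: float = 0.30

    def __post_init__(self):
        seen: set[str] = set()
        for cid, members in self.clusters.items():
            if not members:
                raise ValueError(f"cluster {cid} is empty")
            for m in members:
                if m in seen:
                    raise ValueError(f"chain {m} appears in two clusters")
                seen.add(m)

    def chain_to_cluster(self) -> dict[str, str]:
        return {m: cid for cid, members in self.clusters.items() for m in members}


@dataclass
class FoldAssignment:
    """Cluster-to-fold map; no cluster (hence no chain) spans two folds."""

    cluster_to_fold: dict[str, int]
    n_folds: int

    def fold_of_chain(self, chain_id: str, chain_to_cluster: dict[str, str]) -> int:
        return self.cluster_to_fold[chain_to_cluster[chain_id]]

    def assign_pairs(
        self,
        pairs: list[tuple[str, str]],
        chain_to_cluster: dict[str, str],
    ) -> tuple[dict[int, list[tuple[str, str]]], list[tuple[str, str]]]:
        """Deal protein pairs to folds; both chains must fall in the same
        fold, otherwise the pair is dropped (the conservative,
        leakage-free choice)."""
        by_fold: dict[int, list[tuple[str, str]]] = {
            f: [] for f in range(1, self.n_folds + 1)
        }
        dropped: list[tuple[str, str]] = []
        for a, b in pairs:
            fa = self.fold_of_chain(a, chain_to_cluster)
            fb = self.fold_of_chain(b, chain_to_cluster)
            if fa == fb:
                by_fold[fa].append((a, b))
            else:
                dropped.append((a, b))
        return by_fold, dropped


@dataclass
class ThresholdCalibration:
    """FDR level -> decision threshold (+inf when unattainable)."""

    thresholds: dict[float, float]

    def __post_init__(self):
        levels = sorted(self.thresholds)
        taus = [self.thresholds[t] for t in levels]
        if any(t2 > t1 for t1, t2 in zip(taus, taus[1:])):
            raise ValueError("thresholds must be non-increasing in FDR level")


@dataclass
class MetricReport:
    """Six performance measures for one method on one test fold."""

    au_roc: float
    au_prc: float
    au_prc_baseline: float  # fraction of positives (random-classifier AU-PRC)
    per_level: dict[float, dict[str, float]]  # level -> mcc/precision/recall/f_score
    fold_id: int | None = None
    method: str | None = None
    degenerate: bool = False  # single-class test set: AU-ROC/AU-PRC undefined


# ---------------------------------------------------------------------------
# Clustering


def _global_identity(seq_a: str, seq_b: str, aligner) -> float:
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    return counts.identities / aln.length if aln.length else 0.0


def greedy_identity_cluster(
    sequences: dict[str, str], threshold: float = 0.30
) -> ClusterSet:
    """Greedy representative clustering at a global-identity threshold.

    Sequences are processed longest-first (ties by ID); each joins the
    first existing cluster whose representative aligns with identity
    (matches / alignment length) >= ``threshold``, else founds a new
    cluster. A fallback for when MMSeqs2 output is unavailable.
    """
    if not sequences:
        raise ValueError("no sequences given")
    for sid, seq in sequences.items():
        if not seq:
            raise ValueError(f"empty sequence: {sid}")
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1.0,
        mismatch_score=-1.0,
        open_gap_score=-2.0,
        extend_gap_score=-0.5,
    )
    order = sorted(sequences, key=lambda s: (-len(sequences[s]), s))
    reps: list[str] = []
    clusters: dict[str, list[str]] = {}
    for sid in order:
        placed = False
        for rep in reps:
            if _global_identity(sequences[sid], sequences[rep], aligner) >= threshold:
                clusters[rep].append(sid)
                placed = True
                break
        if not placed:
            reps.append(sid)
            clusters[sid] = [sid]
    return ClusterSet(clusters=clusters, identity_threshold=threshold)


def read_cluster_tsv(path: str | Path, identity_threshold: float = 0.30) -> ClusterSet:
    """MMSeqs2 cluster dialect: two columns (representative, member)."""
    clusters: dict[str, list[str]] = {}
    member_rep: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rep, member = line.rstrip("\n").split("\t")[:2]
            if member in member_rep and member_rep[member] != rep:
                raise ValueError(f"member {member} listed under two representatives")
            if member not in member_rep:
                clusters.setdefault(rep, []).append(member)
                member_rep[member] = rep
    if not clusters:
        raise ValueError("empty cluster TSV")
    return ClusterSet(clusters=clusters, identity_threshold=identity_threshold)


def write_cluster_tsv(cluster_set: ClusterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rep in sorted(cluster_set.clusters):
            for member in cluster_set.clusters[rep]:
                fh.write(f"{rep}\t{member}\n")


# ---------------------------------------------------------------------------
# Fold construction


def round_robin_folds(cluster_set: ClusterSet, k: int = 5) -> FoldAssignment:
    """Deal clusters to ``k`` folds in boustrophedon order.

    Clusters sorted by chain count descending (ties by ID) are assigned
    to folds 1, 2, ..., k, k, ..., 2, 1, 1, 2, ... so chain counts per
    fold end up as similar as possible.
    """
    clusters = cluster_set.clusters
    if len(clusters) < k:
        raise ValueError(f"need at least {k} clusters, got {len(clusters)}")
    order = sorted(clusters, key=lambda c: (-len(clusters[c]), c))
    forward = list(range(1, k + 1))
    cycle = itertools.cycle(forward + forward[::-1])
    return FoldAssignment(
        cluster_to_fold={cid: fold for cid, fold in zip(order, cycle)},
        n_folds=k,
    )


# ---------------------------------------------------------------------------
# FDR-calibrated thresholds


def calibrate_thresholds(
    train_scores: list[tuple[float, int]],
    levels: tuple[float, ...] = DEFAULT_FDR_LEVELS,
) -> ThresholdCalibration:
    """Choose, per FDR level, the smallest observed-score threshold whose
    training FDR (FP / (FP+TP) among scores >= threshold) stays at or
    below the level; +inf (predict nothing) when unattainable.

    Smaller thresholds predict more positives, so this maximizes recall
    subject to the FDR constraint. Candidates are the observed scores
    themselves; equal feasibility resolves toward the higher threshold
    automatically via the minimum over feasible candidates.
    """
    scores = np.array([s for s, _ in train_scores], dtype=float)
    labels = np.array([l for _, l in train_scores], dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("calibration needs both classes")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    tp = np.cumsum(y_sorted == 1)
    fp = np.cumsum(y_sorted == 0)
    # at threshold s_sorted[i], everything with score >= s_sorted[i] is
    # predicted positive; for tied scores only the last index of the tie
    # block reflects the full prediction set
    is_last_of_tie = np.append(s_sorted[1:] != s_sorted[:-1], True)
    fdr = fp / np.maximum(fp + tp, 1)
    thresholds: dict[float, float] = {}
    for level in levels:
        feasible = is_last_of_tie & (fdr <= level)
        if feasible.any():
            # smallest feasible threshold = deepest feasible cut
            thresholds[level] = float(s_sorted[np.nonzero(feasible)[0][-1]])
        else:
            thresholds[level] = float("inf")
    return ThresholdCalibration(thresholds=thresholds)


def training_fdr_at(
    train_scores: list[tuple[float, int]], threshold: float
) -> float:
    """Empirical FDR among training pairs scoring at or above a threshold."""
    scores = np.array([s for s, _ in train_scores], dtype=float)
    labels = np.array([l for _, l in train_scores], dtype=int)
    sel = scores >= threshold
    if not sel.any():
        return 0.0
    fp = int(((labels == 0) & sel).sum())
    tp = int(((labels == 1) & sel).sum())
    return fp / (fp + tp)


# ---------------------------------------------------------------------------
# Metrics


def au_roc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AU-ROC by the rank statistic; tied scores count half."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float(
        (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def au_prc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AU-PRC by step interpolation (average precision)."""
    from sklearn.metrics import average_precision_score

    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        return float("nan")
    return float(average_precision_score(labels, scores))


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Precision, recall, F-score and MCC; zero denominators give 0."""
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f_score = (
        2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    )
    denom = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = ((tp * tn - fp * fn) / denom) if denom else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "f_score": f_score,
        "mcc": float(mcc),
    }


def compute_metrics(
    test_scores: list[tuple[float, int]],
    calibration: ThresholdCalibration,
    fold_id: int | None = None,
    method: str | None = None,
) -> MetricReport:
    """The six performance measures on a test set at calibrated thresholds.

    A single-class test set leaves AU-ROC/AU-PRC undefined (NaN) and is
    flagged degenerate; threshold metrics are still reported.
    """
    scores = np.array([s for s, _ in test_scores], dtype=float)
    labels = np.array([l for _, l in test_scores], dtype=int)
    degenerate = len(np.unique(labels)) < 2
    per_level: dict[float, dict[str, float]] = {}
    for level, tau in calibration.thresholds.items():
        pred = scores >= tau
        tp = int(((labels == 1) & pred).sum())
        fp = int(((labels == 0) & pred).sum())
        fn = int(((labels == 1) & ~pred).sum())
        tn = int(((labels == 0) & ~pred).sum())
        per_level[level] = confusion_metrics(tp, fp, fn, tn)
    return MetricReport(
        au_roc=au_roc(labels, scores),
        au_prc=au_prc(labels, scores),
        au_prc_baseline=float((labels == 1).mean()) if len(labels) else float("nan"),
        per_level=per_level,
        fold_id=fold_id,
        method=method,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Method comparison


@dataclass
class MethodComparison:
    method_a: str
    method_b: str
    p_value: float
    q_value: float = float("nan")
    degenerate: bool = False


def compare_methods(
    per_method_scores: dict[str, np.ndarray],
) -> list[MethodComparison]:
    """Pairwise paired Wilcoxon signed-rank tests, BH-corrected.

    Each method maps to a vector of paired performance values (e.g. one
    per dataset x fold). Zero differences are dropped (the standard
    convention); an all-zero difference vector gives p = 1 and is
    flagged degenerate. Significance is customarily read at q < .05.
    """
    names = sorted(per_method_scores)
    lengths = {len(np.asarray(per_method_scores[n])) for n in names}
    if len(lengths) != 1:
        raise ValueError("all methods need the same number of paired observations")
    if lengths.pop() < 2:
        raise ValueError("need >= 2 paired observations")
    comparisons: list[MethodComparison] = []
    for a, b in itertools.combinations(names, 2):
        x = np.asarray(per_method_scores[a], dtype=float)
        y = np.asarray(per_method_scores[b], dtype=float)
        diffs = x - y
        if np.all(diffs == 0):
            comparisons.append(MethodComparison(a, b, 1.0, degenerate=True))
            continue
        res = wilcoxon(x, y, zero_method="wilcox", alternative="two-sided")
        comparisons.append(MethodComparison(a, b, float(res.pvalue)))
    if comparisons:
        _, q_values, _, _ = multipletests(
            [c.p_value for c in comparisons], method="fdr_bh"
        )
        for c, q in zip(comparisons, q_values):
            c.q_value = float(q)
    return comparisons


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted q-values (convenience wrapper)."""
    _, q, _, _ = multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")
    return q
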