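"""Canonical residue-pair score matrices from upstream predictor outputs.

Interface-prediction methods emit scores at different granularities:
atom-pair interaction scores (reduced to a residue-pair score by taking
the maximum over the atom pairs of the two residues), per-residue
interface probabilities (combined as the product of the two residues'
probabilities), or direct residue-pair likelihoods. All three are
canonicalized into an :class:`RRIScoreMatrix` of shape
(residues of protein 1) x (residues of protein 2).

Missing entries are stored as NaN, never as 0 — an unscored pair is
absence of evidence, not evidence of absence. When an exon-pair block
is sliced for post-processing, missing entries are imputed with the
global matrix minimum so they can never masquerade as strong evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exonmap import ResidueExonMap

PROVENANCE_ATOM = "atom_pair_max"
PROVENANCE_PRODUCT = "residue_product"
PROVENANCE_DIRECT = "direct"


@dataclass
class RRIScoreMatrix:
    """Residue-pair score grid for one protein pair.

    ``scores[i, j]`` is the predicted interaction score of residue ``i``
    of protein 1 with residue ``j`` of protein 2; NaN marks missing.
    """

    scores: np.ndarray
    provenance: str
    resolved_mask1: np.ndarray = field(default=None)  # type: ignore[assignment]
    resolved_mask2: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("score matrix must be 2-D")
        n1, n2 = self.scores.shape
        if self.resolved_mask1 is None:
            self.resolved_mask1 = np.ones(n1, dtype=bool)
        if self.resolved_mask2 is None:
            self.resolved_mask2 = np.ones(n2, dtype=bool)
        self.resolved_mask1 = np.asarray(self.resolved_mask1, dtype=bool)
        self.resolved_mask2 = np.asarray(self.resolved_mask2, dtype=bool)
        if self.resolved_mask1.shape != (n1,) or self.resolved_mask2.shape != (n2,):
            raise ValueError("resolved masks must match matrix shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape

    def global_min(self) -> float:
        """Minimum over non-missing entries (used to impute missing ones)."""
        if np.all(np.isnan(self.scores)):
            raise ValueError("matrix has no scored entries")
        return float(np.nanmin(self.scores))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# provenance={self.provenance}\n")
            for row in self.scores:
                fh.write(
                    "\t".join("NA" if np.isnan(v) else f"{v:.10g}" for v in row) + "\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RRIScoreMatrix":
        provenance = PROVENANCE_DIRECT
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    if "provenance=" in line:
                        provenance = line.split("provenance=")[1].strip()
                    continue
                if not line:
                    continue
                rows.append(
                    [np.nan if v == "NA" else float(v) for v in line.split("\t")]
                )
        if not rows:
            raise ValueError("empty score matrix file")
        return cls(scores=np.array(rows, dtype=float), provenance=provenance)


@dataclass
class ExonPairSubmatrix:
    """The rectangular block of scores for one exon pair.

    Rows are the resolved residues of exon 1, columns those of exon 2,
    in residue order.
    """

    exon1_id: str
    exon2_id: str
    block: np.ndarray

    def __post_init__(self):
        self.block = np.asarray(self.block, dtype=float)
        if self.block.ndim != 2 or self.block.size == 0:
            raise ValueError("block must be a non-empty 2-D array")


def aggregate_atom_scores(
    atom_scores: list[tuple[int, int, float]], n1: int, n2: int
) -> RRIScoreMatrix:
    """Residue-pair scores as the maximum over atom-pair scores.

    ``atom_scores`` holds ``(residue1_index, residue2_index, score)``
    records, one per scored atom pair, already tagged with the residue
    each atom belongs to. Residue pairs with no scored atom pair are
    missing.
    """
    m = np.full((n1, n2), np.nan)
    for i, j, s in atom_scores:
        if not (0 <= i < n1 and 0 <= j < n2):
            raise IndexError(f"atom score references unknown residue ({i},{j})")
        if np.isnan(m[i, j]) or s > m[i, j]:
            m[i, j] = s
    return RRIScoreMatrix(scores=m, provenance=PROVENANCE_ATOM)


def combine_residue_probabilities(
    p1_probs: np.ndarray, p2_probs: np.ndarray
) -> RRIScoreMatrix:
    """Residue-pair scores as the product of per-residue probabilities."""
    p1 = np.asarray(p1_probs, dtype=float)
    p2 = np.asarray(p2_probs, dtype=float)
    for name, p in (("p1", p1), ("p2", p2)):
        if p.ndim != 1:
            raise ValueError(f"{name} must be a vector")
        if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
            raise ValueError(f"{name} probabilities must lie in [0, 1]")
    return RRIScoreMatrix(scores=np.outer(p1, p2), provenance=PROVENANCE_PRODUCT)


def ingest_direct_scores(
    pairs: list[tuple[int, int, float]], n1: int, n2: int
) -> RRIScoreMatrix:
    """Residue-pair scores given directly by the upstream predictor.

    Unlisted pairs are missing; a duplicate listing with a conflicting
    score is an error (identical duplicates are tolerated).
    """
    m = np.full((n1, n2), np.nan)
    for i, j, s in pairs:
        if not (0 <= i < n1 and 0 <= j < n2):
            raise IndexError(f"score references unknown residue ({i},{j})")
        if not np.isnan(m[i, j]) and m[i, j] != s:
            raise ValueError(f"conflicting duplicate score for residue pair ({i},{j})")
        m[i, j] = s
    return RRIScoreMatrix(scores=m, provenance=PROVENANCE_DIRECT)


def slice_exon_pair(
    matrix: RRIScoreMatrix,
    map1: ResidueExonMap,
    map2: ResidueExonMap,
    exon1_id: str,
    exon2_id: str,
) -> ExonPairSubmatrix:
    """Extract the score block of one exon pair, residue order preserved.

    Missing entries inside the block are imputed with the global matrix
    minimum.
    """
    rows = map1.residues_of_exon(exon1_id)
    cols = map2.residues_of_exon(exon2_id)
    if not rows or not cols:
        raise ValueError(f"empty exon: {exon1_id if not rows else exon2_id}")
    block = matrix.scores[np.ix_(rows, cols)].copy()
    if np.any(np.isnan(block)):
        block[np.isnan(block)] = matrix.global_min()
    return ExonPairSubmatrix(exon1_id=exon1_id, exon2_id=exon2_id, block=block)


# --------------------------------------------------------------------------
# TSV ingestion dialects for the three provenance modes

def read_atom_scores_tsv(path: str | Path) -> list[tuple[int, int, float]]:
    """TSV: residue1_index, residue2_index, score (one row per atom pair)."""
    return _read_triples(path, ["residue1_index", "residue2_index", "score"])


def read_direct_scores_tsv(path: str | Path) -> list[tuple[int, int, float]]:
    """TSV: residue1_index, residue2_index, score (one row per residue pair)."""
    return _read_triples(path, ["residue1_index", "residue2_index", "score"])


def read_residue_probs_tsv(path: str | Path) -> np.ndarray:
    """TSV: residue_index, probability — returns the dense probability vector."""
    entries = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["residue_index", "probability"]:
            raise ValueError("unrecognized residue-probability TSV header")
        for line in fh:
            if not line.strip():
                continue
            idx, p = line.split("\t")[:2]
            entries[int(idx)] = float(p)
    if not entries:
        raise ValueError("empty probability TSV")
    n = max(entries) + 1
    probs = np.zeros(n)
    for idx, p in entries.items():
        probs[idx] = p
    return probs


def _read_triples(path: str | Path, expected_header: list[str]):
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(expected_header)] != expected_header:
            raise ValueError(f"unrecognized TSV header (want {expected_header})")
        for line in fh:
            if not line.strip():
                continue
            i, j, s = line.split("\t")[:3]
            out.append((int(i), int(j), float(s)))
    return out
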