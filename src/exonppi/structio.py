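"""Structure I/O and ground-truth interface geometry.

Reads two-chain protein complexes (PDB/mmCIF), extracts heavy atoms,
computes residue-residue interactions (RRIs) by a heavy-atom distance
rule, buried surface area by Shrake-Rupley quadrature, area-based
interface classification, and harmonization of predicted structures
against experimental ones.

An RRI between residue ``r1`` of chain 1 and ``r2`` of chain 2 exists
iff the minimum Euclidean distance between any heavy atom (C, N, O, S)
of ``r1`` and any heavy atom of ``r2`` is at most the cutoff
(default 6 A). Hydrogens never contribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: Heavy-atom elements considered for contacts and surface area.
HEAVY_ELEMENTS = frozenset({"C", "N", "O", "S"})

#: Van der Waals radii (A) used for solvent-accessible surface area.
ELEMENT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

#: Water-probe radius (A) for SASA.
DEFAULT_PROBE = 1.4

#: EPPIC-style buried-area breakpoints (A^2): interfaces burying more
#: than the upper bound are taken as biological, less than the lower
#: bound as crystal-packing artifacts; the band between is left
#: indeterminate (resolving it needs evolutionary evidence).
AREA_LOWER = 400.0
AREA_UPPER = 2200.0


class ChainNotFoundError(KeyError):
    """Requested chain ID absent from the structure file."""


class EmptyChainError(ValueError):
    """Chain has no resolved residues (or no heavy atoms at all)."""


class NotHarmonizableError(ValueError):
    """Predicted chain does not contain the experimental sequence in order."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a chain.

    ``residue_index`` is the 0-based index into the chain's
    resolved-residue list; ``author_number`` is the residue number as
    printed in the source file.
    """

    name: str
    element: str
    coords: tuple[float, float, float]
    residue_index: int
    author_number: int
    is_heavy: bool

    def __post_init__(self):
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.is_heavy != (self.element in HEAVY_ELEMENTS):
            raise ValueError("is_heavy inconsistent with element")


@dataclass
class ChainStructure:
    """One protein chain: resolved residues in structural order.

    ``sequence`` holds one-letter codes of the resolved residues;
    ``author_numbers[i]`` is the author residue number of residue ``i``.
    """

    chain_id: str
    sequence: str
    atoms: list[AtomRecord]
    author_numbers: list[int]

    @property
    def residue_count(self) -> int:
        return len(self.sequence)

    def __post_init__(self):
        n = self.residue_count
        if len(self.author_numbers) != n:
            raise ValueError("author_numbers length mismatch")
        for a in self.atoms:
            if not (0 <= a.residue_index < n):
                raise ValueError(
                    f"atom {a.name} residue_index {a.residue_index} out of range"
                )

    def heavy_atoms(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Heavy-atom coordinates, residue indices and radii as arrays."""
        heavy = [a for a in self.atoms if a.is_heavy]
        if not heavy:
            raise EmptyChainError(f"chain {self.chain_id}: no heavy atoms")
        coords = np.array([a.coords for a in heavy], dtype=float)
        res_idx = np.array([a.residue_index for a in heavy], dtype=int)
        radii = np.array([ELEMENT_RADII.get(a.element, 1.70) for a in heavy])
        return coords, res_idx, radii


@dataclass
class ContactSet:
    """Inter-chain residue contacts.

    ``pairs`` holds ``(i, j)`` with ``i`` a residue index of chain 1 and
    ``j`` of chain 2, never reversed. ``min_distances`` optionally maps
    each pair to its minimum heavy-atom distance.
    """

    pairs: set[tuple[int, int]]
    cutoff: float
    min_distances: dict[tuple[int, int], float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chain1_residue_index\tchain2_residue_index\tmin_distance\n")
            for i, j in sorted(self.pairs):
                d = self.min_distances.get((i, j), float("nan"))
                fh.write(f"{i}\t{j}\t{d:.4f}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, cutoff: float = 6.0) -> "ContactSet":
        pairs: set[tuple[int, int]] = set()
        dists: dict[tuple[int, int], float] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("chain1_residue_index"):
                raise ValueError("unrecognized contact TSV header")
            for line in fh:
                if not line.strip():
                    continue
                i, j, d = line.split("\t")
                pairs.add((int(i), int(j)))
                dists[(int(i), int(j))] = float(d)
        return cls(pairs=pairs, cutoff=cutoff, min_distances=dists)


@dataclass(frozen=True)
class InterfaceClassification:
    buried_area: float
    verdict: str  # biological | crystal_artifact | indeterminate


# ---------------------------------------------------------------------------
# Reading structures


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


def _select_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate locations: highest occupancy wins, ties go to the
    lexicographically first altloc identifier."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
        elif atom.occ > prev.occ or (
            atom.occ == prev.occ and _altloc_key(atom) < _altloc_key(prev)
        ):
            by_name[atom.name] = atom
    return list(by_name.values())


def _altloc_key(atom: gemmi.Atom) -> str:
    return atom.altloc if atom.altloc else "~"


def read_chain(structure: gemmi.Structure, chain_id: str) -> ChainStructure:
    model = structure[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise ChainNotFoundError(f"chain not found: {chain_id!r}")
    sequence: list[str] = []
    author_numbers: list[int] = []
    atoms: list[AtomRecord] = []
    res_index = 0
    for residue in chain:
        if residue.is_water():
            continue
        selected = _select_altlocs(residue)
        records = []
        has_heavy = False
        for atom in selected:
            element = atom.element.name.upper()
            heavy = element in HEAVY_ELEMENTS
            has_heavy = has_heavy or heavy
            records.append(
                AtomRecord(
                    name=atom.name,
                    element=element,
                    coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                    residue_index=res_index,
                    author_number=residue.seqid.num,
                    is_heavy=heavy,
                )
            )
        if not records:
            continue
        if not has_heavy:
            logger.warning(
                "chain %s residue %s %d has no heavy atoms; dropped",
                chain_id, residue.name, residue.seqid.num,
            )
            continue
        sequence.append(_one_letter(residue.name))
        author_numbers.append(residue.seqid.num)
        atoms.extend(records)
        res_index += 1
    if res_index == 0:
        raise EmptyChainError(f"empty chain: {chain_id!r}")
    return ChainStructure(
        chain_id=chain_id,
        sequence="".join(sequence),
        atoms=atoms,
        author_numbers=author_numbers,
    )


def read_structure_pair(
    path: str | Path, chain1_id: str, chain2_id: str
) -> tuple[ChainStructure, ChainStructure]:
    """Read two chains of a PDB or mmCIF file.

    Alternate locations are resolved to the highest-occupancy conformer;
    non-heavy atoms are retained but flagged; residues without any heavy
    atom are dropped with a warning.
    """
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    return read_chain(structure, chain1_id), read_chain(structure, chain2_id)


# ---------------------------------------------------------------------------
# Contacts


def compute_rris(
    c1: ChainStructure, c2: ChainStructure, cutoff: float = 6.0
) -> ContactSet:
    """Residue-residue interactions by the heavy-atom distance rule.

    ``(i, j)`` is a contact iff the minimum distance over heavy-atom
    pairs of residues ``i`` (chain 1) and ``j`` (chain 2) is <= cutoff
    (boundary inclusive). Typical cutoffs: 4, 6 (default) or 8 A.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    xyz1, res1, _ = c1.heavy_atoms()
    xyz2, res2, _ = c2.heavy_atoms()
    tree1, tree2 = cKDTree(xyz1), cKDTree(xyz2)
    neighbors = tree1.query_ball_tree(tree2, r=cutoff)
    min_d: dict[tuple[int, int], float] = {}
    for a1, hits in enumerate(neighbors):
        if not hits:
            continue
        d = np.linalg.norm(xyz2[hits] - xyz1[a1], axis=1)
        i = int(res1[a1])
        for a2, dist in zip(hits, d):
            key = (i, int(res2[a2]))
            if dist <= cutoff and dist < min_d.get(key, np.inf):
                min_d[key] = float(dist)
    return ContactSet(pairs=set(min_d), cutoff=cutoff, min_distances=min_d)


# ---------------------------------------------------------------------------
# Surface area


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = DEFAULT_PROBE,
    n_points: int = 960,
) -> float:
    """Total solvent-accessible surface area (A^2) of an atom set.

    Each atom's probe-expanded sphere is sampled with ``n_points``
    quadrature points; a point is accessible if it lies outside every
    other atom's expanded sphere.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float) + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    total = 0.0
    max_r = radii.max()
    for a in range(len(coords)):
        pts = coords[a] + radii[a] * unit
        # candidate occluders: anything whose expanded sphere could reach
        nearby = tree.query_ball_point(coords[a], r=radii[a] + max_r)
        nearby = [b for b in nearby if b != a]
        accessible = np.ones(n_points, dtype=bool)
        for b in nearby:
            d2 = np.einsum("ij,ij->i", pts - coords[b], pts - coords[b])
            accessible &= d2 > radii[b] ** 2
        total += 4.0 * np.pi * radii[a] ** 2 * accessible.mean()
    return float(total)


def buried_surface_area(
    c1: ChainStructure,
    c2: ChainStructure,
    probe: float = DEFAULT_PROBE,
    n_points: int = 960,
) -> float:
    """Buried surface area: SASA(c1) + SASA(c2) - SASA(complex), >= 0."""
    xyz1, _, r1 = c1.heavy_atoms()
    xyz2, _, r2 = c2.heavy_atoms()
    s1 = shrake_rupley_sasa(xyz1, r1, probe, n_points)
    s2 = shrake_rupley_sasa(xyz2, r2, probe, n_points)
    s12 = shrake_rupley_sasa(
        np.vstack([xyz1, xyz2]), np.concatenate([r1, r2]), probe, n_points
    )
    return max(0.0, s1 + s2 - s12)


def classify_interface_by_area(buried_area: float) -> InterfaceClassification:
    """EPPIC-style hard area classification.

    > 2200 A^2 -> biological; < 400 A^2 -> crystal_artifact; the band in
    between is indeterminate (would need evolutionary scoring).
    """
    if buried_area < 0:
        raise ValueError("buried area must be non-negative")
    if buried_area > AREA_UPPER:
        verdict = "biological"
    elif buried_area < AREA_LOWER:
        verdict = "crystal_artifact"
    else:
        verdict = "indeterminate"
    return InterfaceClassification(buried_area=buried_area, verdict=verdict)


# ---------------------------------------------------------------------------
# Harmonization of predicted vs experimental structures


def harmonize_predicted_structure(
    experimental: ChainStructure, predicted: ChainStructure
) -> ChainStructure:
    """Restrict a predicted chain to the residues of the experimental one.

    The experimental residue sequence must occur in order (not
    necessarily contiguously) within the predicted sequence; the
    returned chain keeps the predicted 3D coordinates of exactly those
    residues. Raises :class:`NotHarmonizableError` otherwise, in which
    case the caller drops the protein pair.
    """
    exp, pred = experimental.sequence, predicted.sequence
    keep: list[int] = []
    p = 0
    for ch in exp:
        while p < len(pred) and pred[p] != ch:
            p += 1
        if p == len(pred):
            raise NotHarmonizableError(
                "experimental sequence not contained in predicted chain"
            )
        keep.append(p)
        p += 1
    keep_set = {old: new for new, old in enumerate(keep)}
    atoms = [
        AtomRecord(
            name=a.name,
            element=a.element,
            coords=a.coords,
            residue_index=keep_set[a.residue_index],
            author_number=a.author_number,
            is_heavy=a.is_heavy,
        )
        for a in predicted.atoms
        if a.residue_index in keep_set
    ]
    return ChainStructure(
        chain_id=predicted.chain_id,
        sequence=exp,
        atoms=atoms,
        author_numbers=[predicted.author_numbers[i] for i in keep],
    )
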