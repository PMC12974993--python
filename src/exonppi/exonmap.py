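"""Exon annotations, transcript checks, and exon-exon interaction labels.

Exons are contiguous segments of the protein sequence, 1-based inclusive
in sequence coordinates (the Ensembl-protein convention). Structure
residues are 0-based; a residue-numbering map (SIFTS-flavoured,
author number -> sequence position) is the single conversion point.

Two exons, one per chain of a co-resolved protein pair, form an
exon-exon interaction (EEI) under the contact definition iff at least
one residue of the first exon forms a residue-residue interaction with
at least one residue of the second. Interface-overlap labels (from
energy- or evolution-based interface callers, ingested from file) mark
an exon pair interacting iff each exon contains at least one interface
residue of its chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .structio import ChainStructure

logger = logging.getLogger(__name__)

VALID_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

LABEL_INTERACTING = "interacting"
LABEL_NON_INTERACTING = "non_interacting"


@dataclass
class ExonTable:
    """Ordered, non-overlapping exon segments over a protein sequence.

    ``exons`` is a list of ``(exon_id, start, end)`` with 1-based
    inclusive coordinates. Unannotated gaps between exons are allowed.
    """

    protein_id: str
    exons: list[tuple[str, int, int]]
    protein_length: int | None = None

    def __post_init__(self):
        prev_end = 0
        for exon_id, start, end in self.exons:
            if start < 1 or end < start:
                raise ValueError(f"exon {exon_id}: bad interval [{start},{end}]")
            if start <= prev_end:
                raise ValueError(f"exon {exon_id}: overlaps or unsorted")
            if self.protein_length is not None and end > self.protein_length:
                raise ValueError(f"exon {exon_id}: end beyond protein length")
            prev_end = end

    def exon_of_position(self, pos: int) -> str | None:
        """Exon ID covering 1-based sequence position ``pos``, or None."""
        for exon_id, start, end in self.exons:
            if start <= pos <= end:
                return exon_id
        return None

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("protein_id\texon_id\tstart\tend\n")
            for exon_id, start, end in self.exons:
                fh.write(f"{self.protein_id}\t{exon_id}\t{start}\t{end}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExonTable":
        exons: list[tuple[str, int, int]] = []
        protein_id = None
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:4] != ["protein_id", "exon_id", "start", "end"]:
                raise ValueError("unrecognized exon TSV header")
            for line in fh:
                if not line.strip():
                    continue
                pid, exon_id, start, end = line.rstrip("\n").split("\t")[:4]
                if protein_id is None:
                    protein_id = pid
                elif pid != protein_id:
                    raise ValueError("exon TSV mixes protein IDs")
                exons.append((exon_id, int(start), int(end)))
        if protein_id is None:
            raise ValueError("empty exon TSV")
        exons.sort(key=lambda e: e[1])
        return cls(protein_id=protein_id, exons=exons)


@dataclass
class ResidueExonMap:
    """Per-residue exon assignment for the resolved residues of a chain."""

    chain_id: str
    exon_ids: list[str | None]

    def residues_of_exon(self, exon_id: str) -> list[int]:
        return [i for i, e in enumerate(self.exon_ids) if e == exon_id]

    def exons_present(self) -> list[str]:
        """Exon IDs with >= 1 resolved residue, in first-residue order."""
        seen: dict[str, None] = {}
        for e in self.exon_ids:
            if e is not None and e not in seen:
                seen[e] = None
        return list(seen)


@dataclass
class EEIRecord:
    """One inter-protein exon pair with its ground-truth label."""

    exon1_id: str
    exon2_id: str
    label: str  # interacting | non_interacting
    label_source: str  # contact | energy | evolution
    n_resolved_pairs: int

    def __post_init__(self):
        if self.label not in (LABEL_INTERACTING, LABEL_NON_INTERACTING):
            raise ValueError(f"bad label {self.label!r}")
        if self.n_resolved_pairs < 1:
            raise ValueError("EEIRecord requires >= 1 resolved residue pair")


def check_transcript_match(protein_seq: str, translated_transcript: str) -> bool:
    """True iff the translated transcript aligns to the protein with no
    gaps and no mismatches — i.e. the sequences are identical.

    Used to select a unique transcript per protein; a full-length
    gapless, mismatch-free global alignment exists exactly when the two
    strings are equal.
    """
    for name, seq in (("protein", protein_seq), ("transcript", translated_transcript)):
        if not seq:
            raise ValueError(f"{name} sequence is empty")
        bad = set(seq.upper()) - VALID_AA
        if bad:
            raise ValueError(f"{name} sequence has invalid characters: {sorted(bad)}")
    return protein_seq.upper() == translated_transcript.upper()


def read_numbering_tsv(path: str | Path) -> dict[str, dict[int, int]]:
    """SIFTS-flavoured numbering map: chain -> {author_number: sequence_index}.

    Sequence indices are 1-based positions in the full protein sequence.
    An author number listed twice for a chain with different sequence
    positions is an error.
    """
    out: dict[str, dict[int, int]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["chain", "author_number", "sequence_index"]:
            raise ValueError("unrecognized numbering TSV header")
        for line in fh:
            if not line.strip():
                continue
            chain, author, seqidx = line.rstrip("\n").split("\t")[:3]
            cmap = out.setdefault(chain, {})
            author_n, seq_n = int(author), int(seqidx)
            if author_n in cmap and cmap[author_n] != seq_n:
                raise ValueError(
                    f"author number {author_n} of chain {chain} mapped to two positions"
                )
            cmap[author_n] = seq_n
    return out


def map_exons_to_residues(
    chain: ChainStructure,
    table: ExonTable,
    numbering: dict[int, int] | None = None,
) -> ResidueExonMap:
    """Assign each resolved residue to the exon covering its sequence position.

    ``numbering`` maps author residue numbers to 1-based sequence
    positions; if omitted, author numbers are taken as sequence
    positions directly. Residues absent from the map, or whose position
    falls in an unannotated gap, map to no exon.
    """
    exon_ids: list[str | None] = []
    seen_positions: dict[int, int] = {}
    for res_idx, author in enumerate(chain.author_numbers):
        if numbering is None:
            pos = author
        else:
            pos = numbering.get(author)
            if pos is None:
                logger.warning(
                    "chain %s: author number %d absent from numbering map",
                    chain.chain_id, author,
                )
                exon_ids.append(None)
                continue
        if pos in seen_positions:
            raise ValueError(
                f"numbering maps residues {seen_positions[pos]} and {res_idx} "
                f"to the same sequence position {pos}"
            )
        seen_positions[pos] = res_idx
        exon_ids.append(table.exon_of_position(pos))
    return ResidueExonMap(chain_id=chain.chain_id, exon_ids=exon_ids)


def label_eeis_contact(
    map1: ResidueExonMap, map2: ResidueExonMap, contacts
) -> list[EEIRecord]:
    """Contact-based EEI labels for every observable exon pair.

    A pair ``(e1, e2)`` is interacting iff some residue contact
    ``(i, j)`` has residue ``i`` mapped to ``e1`` and ``j`` to ``e2``.
    Exon pairs where either exon has no resolved residue are not
    emitted (they are unobservable in the structure, not negative).
    """
    counts1 = {e: len(map1.residues_of_exon(e)) for e in map1.exons_present()}
    counts2 = {e: len(map2.residues_of_exon(e)) for e in map2.exons_present()}
    interacting: set[tuple[str, str]] = set()
    for i, j in contacts.pairs:
        e1 = map1.exon_ids[i] if 0 <= i < len(map1.exon_ids) else None
        e2 = map2.exon_ids[j] if 0 <= j < len(map2.exon_ids) else None
        if e1 is not None and e2 is not None:
            interacting.add((e1, e2))
    records = []
    for e1, n1 in counts1.items():
        for e2, n2 in counts2.items():
            records.append(
                EEIRecord(
                    exon1_id=e1,
                    exon2_id=e2,
                    label=LABEL_INTERACTING
                    if (e1, e2) in interacting
                    else LABEL_NON_INTERACTING,
                    label_source="contact",
                    n_resolved_pairs=n1 * n2,
                )
            )
    return records


def label_eeis_from_interface(
    map1: ResidueExonMap,
    map2: ResidueExonMap,
    interface1: set[int],
    interface2: set[int],
    source: str,
) -> list[EEIRecord]:
    """Interface-overlap EEI labels (energy- or evolution-based callers).

    An exon pair is interacting iff each exon contains at least one
    interface residue of its chain.
    """
    if source not in ("energy", "evolution"):
        raise ValueError("source must be 'energy' or 'evolution'")
    for name, iface, m in (("1", interface1, map1), ("2", interface2, map2)):
        for r in iface:
            if not (0 <= r < len(m.exon_ids)):
                raise ValueError(f"interface residue {r} out of range for chain {name}")
    hit1 = {map1.exon_ids[r] for r in interface1 if map1.exon_ids[r] is not None}
    hit2 = {map2.exon_ids[r] for r in interface2 if map2.exon_ids[r] is not None}
    records = []
    for e1 in map1.exons_present():
        n1 = len(map1.residues_of_exon(e1))
        for e2 in map2.exons_present():
            n2 = len(map2.residues_of_exon(e2))
            records.append(
                EEIRecord(
                    exon1_id=e1,
                    exon2_id=e2,
                    label=LABEL_INTERACTING
                    if (e1 in hit1 and e2 in hit2)
                    else LABEL_NON_INTERACTING,
                    label_source=source,
                    n_resolved_pairs=n1 * n2,
                )
            )
    return records


def write_eei_tsv(records: list[EEIRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("exon1_id\texon2_id\tlabel\tlabel_source\tn_resolved_pairs\n")
        for r in records:
            fh.write(
                f"{r.exon1_id}\t{r.exon2_id}\t{r.label}\t"
                f"{r.label_source}\t{r.n_resolved_pairs}\n"
            )


def read_eei_tsv(path: str | Path) -> list[EEIRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != ["exon1_id", "exon2_id", "label", "label_source",
                          "n_resolved_pairs"]:
            raise ValueError("unrecognized EEI TSV header")
        for line in fh:
            if not line.strip():
                continue
            e1, e2, label, source, n = line.rstrip("\n").split("\t")[:5]
            records.append(
                EEIRecord(
                    exon1_id=e1, exon2_id=e2, label=label,
                    label_source=source, n_resolved_pairs=int(n),
                )
            )
    return records
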