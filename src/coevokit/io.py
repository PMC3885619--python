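"""Readers, writers and coordinate maps for alignments, trees and tables.

All residue/region coordinates are 1-based inclusive on the ungapped
reference sequence; alignment columns are 1-based as well.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA20 = set("ACDEFGHIKLMNPQRSTVWY")
GAP_CHARS = set("-.")
UNKNOWN_CHARS = set("X?")
#: sentinel returned by column_to_reference when the reference is gapped there
GAP = -1

STOP_CODONS = {"TAA", "TAG", "TGA"}


class AlignmentError(ValueError):
    """Raised when an alignment violates its structural invariants."""


class CrossReferenceError(KeyError):
    """Raised when a table references an id absent from its alignment/tree."""


@dataclass(frozen=True)
class FamilyRecord:
    seq_id: str
    organism_id: str
    residues: str


@dataclass
class AlignedFamily:
    """A gapped protein MSA with per-sequence organism labels."""

    family_name: str
    records: list[FamilyRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError(f"{self.family_name}: empty alignment")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentError(
                f"{self.family_name}: unequal sequence lengths {sorted(lengths)}"
            )
        ids = [r.seq_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"{self.family_name}: duplicate seq_ids {dup}")
        allowed = AA20 | GAP_CHARS | UNKNOWN_CHARS
        for r in self.records:
            bad = set(r.residues.upper()) - allowed
            if bad:
                raise AlignmentError(
                    f"{self.family_name}/{r.seq_id}: illegal symbols {sorted(bad)}"
                )
            if not r.organism_id:
                raise AlignmentError(f"{self.family_name}/{r.seq_id}: no organism_id")

    @property
    def n_cols(self) -> int:
        return len(self.records[0].residues)

    @property
    def seq_ids(self) -> list[str]:
        return [r.seq_id for r in self.records]

    def sequence(self, seq_id: str) -> str:
        for r in self.records:
            if r.seq_id == seq_id:
                return r.residues
        raise CrossReferenceError(f"{seq_id} not in family {self.family_name}")

    def organisms(self) -> dict[str, list[str]]:
        """organism_id -> member seq_ids, in record order."""
        out: dict[str, list[str]] = {}
        for r in self.records:
            out.setdefault(r.organism_id, []).append(r.seq_id)
        return out


@dataclass
class CodonFamily:
    """Gapped codon-aligned nucleotide MSA; gaps occur in whole codons."""

    family_name: str
    records: list[FamilyRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError(f"{self.family_name}: empty codon alignment")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"{self.family_name}: unequal lengths")
        if self.n_cols % 3:
            raise AlignmentError(f"{self.family_name}: length not a multiple of 3")
        for r in self.records:
            seq = r.residues.upper()
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3]
                gaps = sum(c in GAP_CHARS for c in codon)
                if gaps not in (0, 3):
                    raise AlignmentError(
                        f"{self.family_name}/{r.seq_id}: partial-codon gap at {i + 1}"
                    )
            ungapped = [seq[i : i + 3] for i in range(0, len(seq), 3)
                        if seq[i] not in GAP_CHARS]
            # the last codon may legitimately be a stop
            if any(c in STOP_CODONS for c in ungapped[:-1]):
                raise AlignmentError(
                    f"{self.family_name}/{r.seq_id}: internal stop codon"
                )

    @property
    def n_cols(self) -> int:
        return len(self.records[0].residues)

    def sequence(self, seq_id: str) -> str:
        for r in self.records:
            if r.seq_id == seq_id:
                return r.residues
        raise CrossReferenceError(f"{seq_id} not in family {self.family_name}")


@dataclass(frozen=True)
class PairingRow:
    organism_id: str
    member_a: str
    member_b: str


@dataclass
class PairingTable:
    """Organism-keyed pairing of family-A and family-B members (paralogs allowed)."""

    rows: list[PairingRow]

    def validate(self, fam_a: AlignedFamily, fam_b: AlignedFamily) -> None:
        a_ids, b_ids = set(fam_a.seq_ids), set(fam_b.seq_ids)
        for row in self.rows:
            if row.member_a not in a_ids:
                raise CrossReferenceError(f"pairing member {row.member_a} not in {fam_a.family_name}")
            if row.member_b not in b_ids:
                raise CrossReferenceError(f"pairing member {row.member_b} not in {fam_b.family_name}")


@dataclass(frozen=True)
class Region:
    region_name: str
    reference_seq_id: str
    start: int  # 1-based inclusive, ungapped reference coordinates
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"{self.region_name}: bad bounds {self.start}-{self.end}")

    def contains(self, residue: int) -> bool:
        return self.start <= residue <= self.end


@dataclass
class RegionSet:
    entries: list[Region]

    def validate(self, fam: AlignedFamily) -> None:
        for reg in self.entries:
            ref_len = ungapped_length(fam, reg.reference_seq_id)
            if reg.end > ref_len:
                raise CrossReferenceError(
                    f"{reg.region_name}: end {reg.end} beyond reference length {ref_len}"
                )


CladePartition = dict  # organism_id -> clade_label


@dataclass
class InteractionMatrix:
    """Bait x prey interaction outcomes; orientation preserved, not symmetrized."""

    bait_ids: list[str]
    prey_ids: list[str]
    outcomes: dict  # (bait, prey) -> 'interacts' | 'no-interaction' | 'untested'

    OUTCOMES = ("interacts", "no-interaction", "untested")

    def __post_init__(self) -> None:
        for b in self.bait_ids:
            for p in self.prey_ids:
                v = self.outcomes.get((b, p))
                if v not in self.OUTCOMES:
                    raise ValueError(f"incomplete/invalid outcome for ({b}, {p}): {v!r}")


SpeciesTree = dendropy.Tree


# ---------------------------------------------------------------------------
# readers / writers


def _read_organism_map(path: str | Path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            out[row[0]] = row[1]
    return out


def read_alignment(
    path: str | Path,
    organism_map: str | Path | Mapping[str, str] | None = None,
    header_regex: str | None = None,
    family_name: str | None = None,
) -> AlignedFamily:
    """Parse an aligned FASTA into an AlignedFamily.

    Organism ids come, in order of precedence, from an explicit map (TSV path or
    dict seq_id -> organism_id), from ``header_regex`` (first capture group
    applied to the record id), else the seq_id itself is used.
    """
    path = Path(path)
    if isinstance(organism_map, (str, Path)):
        organism_map = _read_organism_map(organism_map)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise AlignmentError(f"{rec.id}: empty sequence")
        if organism_map is not None:
            try:
                org = organism_map[rec.id]
            except KeyError:
                raise CrossReferenceError(f"{rec.id} missing from organism map") from None
        elif header_regex is not None:
            m = re.match(header_regex, rec.id)
            if not m:
                raise CrossReferenceError(f"{rec.id}: header_regex did not match")
            org = m.group(1)
        else:
            org = rec.id
        records.append(FamilyRecord(rec.id, org, seq))
    return AlignedFamily(family_name or path.stem, records)


def write_alignment(fam: AlignedFamily | CodonFamily, path: str | Path) -> None:
    recs = [SeqRecord(Seq(r.residues), id=r.seq_id, description="") for r in fam.records]
    SeqIO.write(recs, str(path), "fasta-2line")


def read_codon_alignment(
    path: str | Path,
    organism_map: str | Path | Mapping[str, str] | None = None,
    family_name: str | None = None,
) -> CodonFamily:
    fam = read_alignment(path, organism_map=organism_map, family_name=family_name)
    return CodonFamily(fam.family_name, fam.records)


def read_tree(path: str | Path) -> SpeciesTree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    labels = [t.label for t in tree.taxon_namespace]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels in tree")
    return tree


def write_tree(tree: SpeciesTree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_pairing(path: str | Path) -> PairingTable:
    rows = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 3:
                raise ValueError(f"pairing row needs 3 columns: {row}")
            rows.append(PairingRow(row[0], row[1], row[2]))
    return PairingTable(rows)


def write_pairing(pairing: PairingTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in pairing.rows:
            fh.write(f"{r.organism_id}\t{r.member_a}\t{r.member_b}\n")


def read_regions(path: str | Path) -> RegionSet:
    entries = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            name, ref, start, end = row[:4]
            entries.append(Region(name, ref, int(start), int(end)))
    return RegionSet(entries)


def read_clades(path: str | Path) -> CladePartition:
    out: CladePartition = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            org, clade = row[0], row[1]
            if org in out and out[org] != clade:
                raise ValueError(f"{org} assigned to two clades")
            out[org] = clade
    return out


def read_tip_states(path: str | Path) -> dict[str, int]:
    """organism_id -> 0/1 trait state (0 = no interaction, 1 = interaction)."""
    out = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            state = int(row[1])
            if state not in (0, 1):
                raise ValueError(f"{row[0]}: state must be 0 or 1, got {row[1]}")
            out[row[0]] = state
    return out


def read_interaction_matrix(path: str | Path) -> InteractionMatrix:
    """TSV grid: first row prey ids, first column bait ids."""
    with open(path) as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    prey = rows[0][1:]
    baits, outcomes = [], {}
    for r in rows[1:]:
        baits.append(r[0])
        for p, v in zip(prey, r[1:]):
            outcomes[(r[0], p)] = v
    return InteractionMatrix(baits, prey, outcomes)


# ---------------------------------------------------------------------------
# coordinate maps


def ungapped_length(fam: AlignedFamily, seq_id: str) -> int:
    seq = fam.sequence(seq_id)
    return sum(c not in GAP_CHARS for c in seq)


def column_to_reference(fam: AlignedFamily, reference_seq_id: str, column: int) -> int:
    """Map a 1-based alignment column to the 1-based ungapped reference residue.

    Returns :data:`GAP` when the reference itself is gapped at that column.
    """
    seq = fam.sequence(reference_seq_id)
    if not (1 <= column <= len(seq)):
        raise IndexError(f"column {column} out of range 1..{len(seq)}")
    if seq[column - 1] in GAP_CHARS:
        return GAP
    return sum(c not in GAP_CHARS for c in seq[:column])


def reference_to_column(fam: AlignedFamily, reference_seq_id: str, residue: int) -> int:
    """Inverse of :func:`column_to_reference` for non-gap positions."""
    seq = fam.sequence(reference_seq_id)
    count = 0
    for i, c in enumerate(seq, start=1):
        if c not in GAP_CHARS:
            count += 1
            if count == residue:
                return i
    raise IndexError(f"residue {residue} beyond ungapped length {count}")
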