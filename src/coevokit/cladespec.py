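"""Clade-specific residue detection and overlap with correlated-mutation calls.

A column is clade-specific when at least one pair of clades is mutually
diagnostic there: each clade in the pair is uniform (for a residue under the
strict rule, or for a physicochemical class under the relaxed rule) and the
two clades' residue sets are disjoint.  Gaps or unknowns disqualify a clade
at that column.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from .io import (
    GAP_CHARS,
    UNKNOWN_CHARS,
    AlignedFamily,
    CladePartition,
    column_to_reference,
)

#: five physicochemical classes partitioning the 20 residues
RESIDUE_CLASSES = {
    "small-nonpolar": set("GAST"),
    "hydrophobic": set("CVILPFYMW"),
    "polar": set("NQH"),
    "negatively-charged": set("DE"),
    "positively-charged": set("KR"),
}
_CLASS_OF = {aa: name for name, members in RESIDUE_CLASSES.items() for aa in members}


def residue_class(aa: str) -> str:
    """Physicochemical class of a residue; 'unknown' for non-standard symbols."""
    return _CLASS_OF.get(aa.upper(), "unknown")


@dataclass
class CladeSpecificCall:
    column: int  # 1-based alignment column
    residue: int | None  # reference residue number (None if no reference given)
    composition: dict  # clade -> set of residues observed
    qualifying_pairs: list[tuple[str, str]]
    rule: str


def detect_clade_specific(
    fam: AlignedFamily,
    clades: CladePartition,
    rule: str = "strict",
    min_clade_size: int = 2,
    contrast: str = "pairwise",
    reference_seq_id: str | None = None,
) -> list[CladeSpecificCall]:
    """Find columns diagnostic between clades.

    ``contrast='pairwise'`` calls a column when any pair of clades qualifies;
    ``'all'`` additionally requires every eligible clade to be uniform and all
    their sets mutually disjoint.  Clades below ``min_clade_size`` (counted in
    sequences) never qualify.  Results are independent of sequence order.
    """
    if rule not in ("strict", "class"):
        raise ValueError(f"unknown rule {rule!r}")
    members: dict[str, list[str]] = {}
    for rec in fam.records:
        clade = clades.get(rec.organism_id)
        if clade is not None:
            members.setdefault(clade, []).append(rec.residues.upper())
    eligible = {c for c, seqs in members.items() if len(seqs) >= min_clade_size}
    if len(eligible) < 2:
        raise ValueError("need >= 2 clades meeting min_clade_size")
    skip = GAP_CHARS | UNKNOWN_CHARS

    calls = []
    for col in range(fam.n_cols):
        comp: dict[str, set] = {}
        uniform: dict[str, bool] = {}
        for clade in sorted(eligible):
            chars = {s[col] for s in members[clade]}
            if chars & skip:
                continue  # gap/unknown disqualifies the clade here
            comp[clade] = chars
            if rule == "strict":
                uniform[clade] = len(chars) == 1
            else:
                uniform[clade] = len({residue_class(c) for c in chars}) == 1

        def disjoint(c1: str, c2: str) -> bool:
            # the 'class' rule relaxes within-clade uniformity to the residue
            # class but keeps residue-level disjointness, so its calls are a
            # superset of the strict rule's
            return not (comp[c1] & comp[c2])

        qualifying = [
            (c1, c2)
            for c1, c2 in itertools.combinations(sorted(comp), 2)
            if uniform[c1] and uniform[c2] and disjoint(c1, c2)
        ]
        if not qualifying:
            continue
        if contrast == "all":
            if set(comp) != eligible or not all(uniform.values()):
                continue
            if len(qualifying) != len(list(itertools.combinations(sorted(comp), 2))):
                continue
        residue = None
        if reference_seq_id is not None:
            r = column_to_reference(fam, reference_seq_id, col + 1)
            residue = None if r == -1 else r
        calls.append(CladeSpecificCall(col + 1, residue, comp, qualifying, rule))
    return calls


@dataclass
class CapsOverlap:
    n_calls: int
    n_caps_residues: int
    n_overlap: int
    pct_of_caps: float  # overlap as % of CAPS residues
    covered_groups: list[str]
    pct_groups: float


def overlap_with_caps(
    calls: list[CladeSpecificCall],
    caps_sites: list[int],
    groups=None,
    family: str = "A",
    use_reference: bool = False,
) -> CapsOverlap:
    """Intersect clade-specific calls with correlated-mutation residues.

    Positions compare as alignment columns by default, or as reference residue
    numbers with ``use_reference=True`` (both inputs must then use the same
    numbering).  ``groups`` (CoevolutionGroup list) yields covered-group
    statistics using the member sites of ``family`` ('A' or 'B') only, since
    the two families' position spaces are distinct.
    """
    call_pos = {c.residue if use_reference else c.column for c in calls}
    call_pos.discard(None)
    caps = set(caps_sites)
    overlap = call_pos & caps
    covered = []
    if groups:
        for g in groups:
            gsites = set(g.members_a if family == "A" else g.members_b)
            if gsites & overlap:
                covered.append(g.group_id)
    pct = round(100.0 * len(overlap) / len(caps), 2) if caps else 0.0
    pct_groups = round(100.0 * len(covered) / len(groups), 2) if groups else 0.0
    return CapsOverlap(
        len(call_pos), len(caps), len(overlap), pct, sorted(covered), pct_groups
    )


def calls_to_frame(calls: list[CladeSpecificCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "column": c.column,
                "residue": c.residue,
                "rule": c.rule,
                "qualifying_pairs": ";".join(f"{a}|{b}" for a, b in c.qualifying_pairs),
                "composition": ";".join(
                    f"{k}={''.join(sorted(v))}" for k, v in sorted(c.composition.items())
                ),
            }
        )
    return pd.DataFrame(rows)
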