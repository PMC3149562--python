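"""Ser/Thr conservation calls from a multiple alignment.

A reference S/T residue is *conserved* when every counted ortholog cell in
its alignment column carries the identical residue, *conserved
substituted* when all counted cells stay within the functionally
interchangeable substitution group (S <-> T here: both hydroxyl
acceptors for kinases and OGT) but at least one differs from the
reference, and *not conserved* otherwise.  Gap cells break conservation
under the default strict policy; ``gap_policy="ignore"`` drops them from
the count instead.

``support`` is the fraction of counted non-reference cells that stay
within the substitution group, so conserved and conserved-substituted
columns carry support 1 and (strictly) any support below 1 means not
conserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .sequence_io import GAP, MultipleAlignment, SiteEvidence

ConservationClass = Literal["conserved", "conserved_substituted", "not_conserved"]
GapPolicy = Literal["break", "ignore"]

DEFAULT_GROUP = frozenset("ST")


@dataclass(frozen=True)
class ConservationCall:
    seq_id: str
    position: int  # reported numbering on the reference
    residue: str
    conservation: ConservationClass
    support: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.support <= 1.0:
            raise ValueError(f"support {self.support} outside [0, 1]")


def classify_column(
    column: str,
    ref_residue: str,
    group: Iterable[str] = DEFAULT_GROUP,
    gap_policy: GapPolicy = "break",
    min_support: float = 1.0,
) -> tuple[ConservationClass, float]:
    """Classify one alignment column against the reference residue.

    ``column`` holds the non-reference cells (gaps allowed).  Returns the
    class and the support fraction.  ``min_support`` relaxes the strict
    all-rows rule: a column counts as conserved(-substituted) when at
    least that fraction of counted cells agrees.
    """
    if ref_residue not in group:
        raise ValueError(f"reference residue {ref_residue!r} not in group {sorted(group)}")
    if not column:
        raise ValueError("empty column")
    group = frozenset(group)

    cells = list(column)
    if gap_policy == "ignore":
        cells = [c for c in cells if c != GAP]
        if not cells:  # gaps everywhere: nothing contradicts, nothing supports
            return "not_conserved", 0.0
    elif GAP in cells:
        in_group = sum(1 for c in cells if c in group)
        return "not_conserved", in_group / len(cells)

    support = sum(1 for c in cells if c in group) / len(cells)
    identical = sum(1 for c in cells if c == ref_residue) / len(cells)
    if identical >= min_support:
        return "conserved", support
    if support >= min_support:
        return "conserved_substituted", support
    return "not_conserved", support


def conserved_sites(
    msa: MultipleAlignment,
    ref_id: str,
    group: Iterable[str] = DEFAULT_GROUP,
    gap_policy: GapPolicy = "break",
    min_support: float = 1.0,
    numbering_offset_lookup: int = 0,
) -> list[ConservationCall]:
    """One conservation call per S/T residue of the reference row.

    Reported positions are the reference's ungapped 1-based positions
    (plus ``numbering_offset_lookup`` when the ungapped row is on a
    different scale than the reported one, which is not the case for the
    default workflow where records are renumbered before alignment).
    """
    ref_row = msa.row(ref_id)  # raises KeyError if absent
    pos_to_col = msa.position_to_column(ref_id)
    group = frozenset(group)
    ref_index = msa.ids.index(ref_id)

    calls = []
    for pos, col in sorted(pos_to_col.items()):
        ref_residue = ref_row[col]
        if ref_residue not in group:
            continue
        column = msa.column(col)
        others = column[:ref_index] + column[ref_index + 1 :]
        klass, support = classify_column(
            others, ref_residue, group=group, gap_policy=gap_policy, min_support=min_support
        )
        calls.append(
            ConservationCall(
                seq_id=ref_id,
                position=pos + numbering_offset_lookup,
                residue=ref_residue,
                conservation=klass,
                support=support,
            )
        )
    return calls


def write_conservation_table(calls: Iterable[ConservationCall], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [(c.seq_id, c.position, c.residue, c.conservation, c.support) for c in calls],
        columns=["seq_id", "position", "residue", "class", "support"],
    ).to_csv(path, sep="\t", index=False)


def read_conservation_table(path) -> list[ConservationCall]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"seq_id": str}).rename(columns={"class": "conservation"})
    return [
        ConservationCall(row.seq_id, int(row.position), row.residue,
                         row.conservation, float(row.support))
        for row in df.itertuples(index=False)
    ]


def propagate_by_similarity(
    msa: MultipleAlignment,
    evidence: Iterable[SiteEvidence],
    ref_id: str,
    group: Iterable[str] = DEFAULT_GROUP,
    gap_policy: GapPolicy = "break",
    min_support: float = 1.0,
) -> list[SiteEvidence]:
    """Transfer cross-species experimental sites onto the reference.

    A non-reference site whose alignment column maps onto a reference S/T
    in a conserved or conserved-substituted column yields a
    ``by_similarity`` annotation at the reference position.  Positions
    already covered by reference experimental evidence are not
    duplicated.
    """
    evidence = list(evidence)
    known_ids = set(msa.ids)
    for ev in evidence:
        if ev.seq_id not in known_ids:
            raise ValueError(f"evidence on {ev.seq_id!r}, which is not in the alignment")

    calls = {
        c.position: c
        for c in conserved_sites(msa, ref_id, group=group, gap_policy=gap_policy, min_support=min_support)
    }
    col_to_ref_pos = msa.column_to_position(ref_id)
    existing = {ev.position for ev in evidence if ev.seq_id == ref_id}

    out: list[SiteEvidence] = []
    seen: set[int] = set()
    for ev in sorted(evidence, key=lambda e: (e.seq_id, e.position)):
        if ev.seq_id == ref_id:
            continue
        try:
            col = msa.position_to_column(ev.seq_id)[ev.position]
        except KeyError:
            raise ValueError(f"{ev.seq_id}:{ev.position} beyond the aligned sequence") from None
        ref_pos = col_to_ref_pos.get(col)
        if ref_pos is None:  # reference has a gap here
            continue
        call = calls.get(ref_pos)
        if call is None or call.conservation == "not_conserved":
            continue
        if ref_pos in existing or ref_pos in seen:
            continue
        seen.add(ref_pos)
        out.append(
            SiteEvidence(
                seq_id=ref_id,
                position=ref_pos,
                residue=call.residue,
                source="by_similarity",
                provenance=f"{ev.seq_id}:{ev.position}",
            )
        )
    return out
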