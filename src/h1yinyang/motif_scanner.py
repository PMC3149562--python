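"""Proline-directed kinase consensus motif scanning.

CDK-family kinases phosphorylate Ser/Thr in the consensus (S/T)PXZ or
(S/T)PXK, where X is any residue and Z a basic residue.  These motifs are
concentrated in the lysine-rich C-terminal tails of linker histone H1
subtypes and mark the mitotic phosphosites, so the scanner reports the
position of the S/T residue itself (the motif start), matching how site
maps list single positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .sequence_io import ProteinRecord

MotifClass = Literal["STPXK", "STPXZ"]

#: Default basic set for the Z slot; configurable down to {K, R}.
DEFAULT_BASIC = frozenset("KRH")

MOTIF_CLASSES: tuple[MotifClass, ...] = ("STPXK", "STPXZ")


@dataclass(frozen=True)
class MotifHit:
    """A consensus-motif match anchored at an S/T residue."""

    seq_id: str
    position: int  # reported numbering of the S/T residue
    residue: str
    motif_class: MotifClass
    matched_tetramer: str

    def __post_init__(self) -> None:
        if self.residue not in "ST":
            raise ValueError(f"hit residue must be S or T, got {self.residue!r}")
        if len(self.matched_tetramer) != 4 or self.matched_tetramer[0] != self.residue:
            raise ValueError(f"bad tetramer {self.matched_tetramer!r} for residue {self.residue}")
        if self.matched_tetramer[1] != "P":
            raise ValueError(f"tetramer {self.matched_tetramer!r} lacks P at slot 2")


def scan_motifs(
    record: ProteinRecord,
    classes: Iterable[MotifClass] = MOTIF_CLASSES,
    basic_set: Iterable[str] = DEFAULT_BASIC,
    dedupe: bool = False,
) -> list[MotifHit]:
    """Scan one sequence for (S/T)PXK / (S/T)PXZ motifs.

    Every S/T whose following residue is P and whose +3 residue satisfies
    a requested class constraint is reported once per satisfied class
    (a tetramer ending in K matches both classes when K is in the basic
    set).  With ``dedupe=True`` each position is reported once, keeping
    the more specific STPXK class first.

    Overlapping motifs are all reported; there is no greedy consumption.
    """
    classes = list(dict.fromkeys(classes))
    basic = frozenset(basic_set)
    if not basic <= frozenset("KRH"):
        raise ValueError(f"basic_set must be a subset of K/R/H, got {sorted(basic)}")
    unknown = [c for c in classes if c not in MOTIF_CLASSES]
    if unknown:
        raise ValueError(f"unknown motif classes {unknown}")

    seq = record.sequence
    hits: list[MotifHit] = []
    for i in range(len(seq) - 3):
        if seq[i] not in "ST" or seq[i + 1] != "P":
            continue
        tetra = seq[i : i + 4]
        matched: list[MotifClass] = []
        if "STPXK" in classes and tetra[3] == "K":
            matched.append("STPXK")
        if "STPXZ" in classes and tetra[3] in basic:
            matched.append("STPXZ")
        for mc in sorted(matched, key=MOTIF_CLASSES.index):
            hits.append(
                MotifHit(
                    seq_id=record.id,
                    position=i + 1,
                    residue=tetra[0],
                    motif_class=mc,
                    matched_tetramer=tetra,
                )
            )
    hits.sort(key=lambda h: (h.position, MOTIF_CLASSES.index(h.motif_class)))
    if dedupe:
        seen: set[int] = set()
        deduped = []
        for h in hits:
            if h.position not in seen:
                seen.add(h.position)
                deduped.append(h)
        hits = deduped
    return hits


def write_motif_table(hits: Iterable[MotifHit], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [(h.seq_id, h.position, h.residue, h.motif_class, h.matched_tetramer) for h in hits],
        columns=["seq_id", "position", "residue", "motif_class", "tetramer"],
    ).to_csv(path, sep="\t", index=False)


def read_motif_table(path) -> list[MotifHit]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"seq_id": str})
    return [
        MotifHit(row.seq_id, int(row.position), row.residue, row.motif_class, row.tetramer)
        for row in df.itertuples(index=False)
    ]


def motif_positions_by_residue(hits: Iterable[MotifHit]) -> dict[str, list[int]]:
    """Partition hit positions by S vs T, de-duplicated and sorted."""
    hits = list(hits)
    seq_ids = {h.seq_id for h in hits}
    if len(seq_ids) > 1:
        raise ValueError(f"hits from multiple sequences: {sorted(seq_ids)}")
    out: dict[str, set[int]] = {}
    for h in hits:
        out.setdefault(h.residue, set()).add(h.position)
    return {res: sorted(posns) for res, posns in out.items()}
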