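"""SYNTHETIC stand-in sequences and tables for the nine human H1 subtypes.

The bundled sequences are NOT the SWISS-PROT entries: they are synthetic
H1-like sequences (Lys/Ala/Pro-rich background, no background Ser/Thr)
constructed so that every curated annotation position from
:mod:`h1yinyang.annotations` carries the annotated residue and every
consensus motif is planted — and only planted — at the published
met-cleaved coordinates.  They let the whole pipeline run and be tested
offline; results on them demonstrate the machinery and the numbering
convention, not properties of the real proteins.

A handful of published positions are mutually inconsistent on a single
sequence (for example H1.4 lists a conserved-substituted Ser at 172,
which is the obligatory proline slot of the motif planted at 171).
Conflicts are resolved by priority — motif > experimental > phospho
predictor > glyco predictor > conserved > conserved-substituted >
proposed/FN — and losing rows are dropped from the derived tables.
"""

from __future__ import annotations

import numpy as np

from . import annotations as ann
from .conservation import ConservationCall
from .motif_scanner import MotifHit, scan_motifs
from .sequence_io import ProteinRecord, SiteEvidence, SiteScore, apply_numbering

_BACKGROUND = {  # H1-like, with Ser/Thr (and Pro after planted sites) excluded
    "K": 0.24, "A": 0.24, "P": 0.10, "G": 0.07, "V": 0.06, "E": 0.05,
    "R": 0.04, "L": 0.04, "N": 0.03, "Q": 0.03, "D": 0.02, "I": 0.02,
    "F": 0.02, "Y": 0.01, "H": 0.01, "M": 0.01, "W": 0.005, "C": 0.005,
}

_FIXTURE_SEED = 20110712

#: annotation tables contributing planted S/T residues, in conflict priority
_PRIORITY_TABLES = (
    ann.EXPERIMENTAL_POSITIONS,
    ann.NETPHOS_POSITIONS,
    ann.YINYANG_POSITIONS,
    ann.CONSERVED_POSITIONS,
    ann.CONSERVED_SUB_POSITIONS,
    ann.PROPOSED_YINYANG,
    ann.PROPOSED_FN_YINYANG,
)


def _build_sequence(acc: str, rng: np.random.Generator) -> str:
    """Raw (Met-leading) synthetic sequence for one subtype."""
    length = ann.SEQUENCE_LENGTHS[acc]
    cells: dict[int, str] = {}  # met-cleaved position -> residue
    flexible_x: set[int] = set()

    for residue in "ST":
        for p in ann.MOTIF_POSITIONS[acc][residue]:
            cells[p], cells[p + 1], cells[p + 3] = residue, "P", "K"
            if p + 2 not in cells:
                cells[p + 2] = "A"
                flexible_x.add(p + 2)

    for table in _PRIORITY_TABLES:
        for residue in "ST":
            for p in table[acc][residue]:
                if p in cells:
                    if cells[p] == residue:
                        continue
                    if p in flexible_x:  # motif X slot is free to be S/T
                        cells[p] = residue
                        flexible_x.discard(p)
                    continue  # conflicting printed position: drop
                cells[p] = residue

    aas = sorted(_BACKGROUND)
    probs = np.array([_BACKGROUND[a] for a in aas])
    probs = probs / probs.sum()
    seq = ["M"] + [str(a) for a in rng.choice(aas, size=length - 1, p=probs)]
    for p, aa in cells.items():
        seq[p] = aa  # met-cleaved position p sits at raw 0-based index p
    # planted acceptors must not gain an accidental downstream proline
    for p, aa in cells.items():
        if aa in "ST" and p + 1 not in cells and p + 1 < length and seq[p + 1] == "P":
            seq[p + 1] = "A"
    return "".join(seq)


def synthetic_h1_records(numbering: str = "met_cleaved") -> list[ProteinRecord]:
    """The nine synthetic H1 stand-ins, ids = published accessions."""
    rng = np.random.default_rng(_FIXTURE_SEED)
    records = []
    for acc, subtype in ann.SUBTYPES.items():
        rec = ProteinRecord(
            id=acc,
            sequence=_build_sequence(acc, rng),
            name=f"{subtype} synthetic stand-in (not the SWISS-PROT sequence)",
        )
        records.append(apply_numbering(rec, numbering))  # type: ignore[arg-type]
    return records


def _consistent(records: dict[str, ProteinRecord], acc: str, residue: str, p: int) -> bool:
    rec = records[acc]
    return 1 <= p <= len(rec) and rec.residue_at(p) == residue


def fixture_motif_hits(records: list[ProteinRecord] | None = None) -> list[MotifHit]:
    records = records or synthetic_h1_records()
    hits: list[MotifHit] = []
    for rec in records:
        hits.extend(scan_motifs(rec, dedupe=True))
    return hits


def fixture_evidence(records: list[ProteinRecord] | None = None) -> list[SiteEvidence]:
    records = records or synthetic_h1_records()
    by_id = {r.id: r for r in records}
    out = []
    for acc in ann.SUBTYPES:
        for residue in "ST":
            for p in ann.EXPERIMENTAL_POSITIONS[acc][residue]:
                if _consistent(by_id, acc, residue, p):
                    out.append(SiteEvidence(acc, p, residue, "experimental", "curated"))
    return out


def fixture_score_tables(
    records: list[ProteinRecord] | None = None,
) -> tuple[list[SiteScore], list[SiteScore]]:
    """Imported-style phospho and glyco score tables for the stand-ins.

    Every S/T position of every record is scored: phospho 0.9 at
    phospho-predictor-positive positions (0.2 otherwise); glyco 0.8 at
    O-GlcNAc-positive positions (including the experimentally anchored
    dual sites), 0.45 — just under threshold — at published FN
    positions, 0.2 otherwise.  Thresholds are 0.5 throughout.
    """
    records = records or synthetic_h1_records()
    by_id = {r.id: r for r in records}
    dual = {(a, r, p) for a, r, p in ann.EXPERIMENTAL_DUAL_SITES}
    phospho, glyco = [], []
    for rec in records:
        acc = rec.id
        for pos in rec.positions_of("ST"):
            residue = rec.residue_at(pos)
            p_pos = pos in ann.NETPHOS_POSITIONS[acc][residue]
            g_pos = pos in ann.YINYANG_POSITIONS[acc][residue] or (acc, residue, pos) in dual
            g_fn = pos in ann.PROPOSED_FN_YINYANG[acc][residue]
            phospho.append(SiteScore(acc, pos, residue, "phospho", 0.9 if p_pos else 0.2, 0.5))
            glyco.append(
                SiteScore(acc, pos, residue, "glyco",
                          0.8 if g_pos else (0.45 if g_fn else 0.2), 0.5)
            )
    return phospho, glyco


def fixture_conservation(records: list[ProteinRecord] | None = None) -> list[ConservationCall]:
    """Published conservation classes as fixture annotations.

    The ortholog sets behind the published classes are not available, so
    these calls ship as curated annotations rather than being recomputed
    from an alignment.
    """
    records = records or synthetic_h1_records()
    by_id = {r.id: r for r in records}
    out = []
    for acc in ann.SUBTYPES:
        for residue in "ST":
            for p in ann.CONSERVED_POSITIONS[acc][residue]:
                if _consistent(by_id, acc, residue, p):
                    out.append(ConservationCall(acc, p, residue, "conserved", 1.0))
            for p in ann.CONSERVED_SUB_POSITIONS[acc][residue]:
                if _consistent(by_id, acc, residue, p):
                    out.append(ConservationCall(acc, p, residue, "conserved_substituted", 1.0))
    return out
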