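"""Sequence, alignment and site-table input/output.

This module owns the residue-numbering convention used throughout the
package.  Positions in all tables and reports are 1-based and *reported*
coordinates: for a record in ``met_cleaved`` numbering (the default for
linker histone work, where the initiator methionine is removed by
methionine aminopeptidase) reported position 1 is the residue following
the initiator Met, i.e. one less than the database canonical position.

File formats are delegated to Biopython (FASTA, Clustal / aligned FASTA)
and pandas (TSV site and score tables).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: 20 amino acids plus X for unknown residues / terminal padding.
ALPHABET = AMINO_ACIDS + "X"
GAP = "-"

NumberingConvention = Literal["raw", "met_cleaved"]

SITE_TABLE_COLUMNS = ["seq_id", "position", "residue", "source", "provenance"]
SCORE_TABLE_COLUMNS = ["seq_id", "position", "residue", "predictor", "score", "threshold"]


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence plus its numbering convention.

    ``numbering_offset`` is added to the 1-based index in the *canonical*
    (database) sequence to yield the reported position: 0 for raw
    numbering, -1 after initiator-Met removal.  Because Met removal also
    drops the leading residue, looking a reported position up in
    ``sequence`` is always ``sequence[position - 1]`` regardless of the
    convention.
    """

    id: str
    sequence: str
    name: str = ""
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        for i, aa in enumerate(self.sequence):
            if aa not in ALPHABET:
                raise ValueError(
                    f"{self.id}: illegal residue {aa!r} at position {i + 1}"
                )
        if 1 + self.numbering_offset < 0:
            raise ValueError(f"{self.id}: numbering_offset {self.numbering_offset} too negative")

    def __len__(self) -> int:
        return len(self.sequence)

    def residue_at(self, position: int) -> str:
        """Residue at a reported (1-based, post-offset) position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(
                f"{self.id}: position {position} outside 1..{len(self.sequence)}"
            )
        return self.sequence[position - 1]

    def positions_of(self, residues: str) -> list[int]:
        """Sorted reported positions holding any of the given residues."""
        wanted = set(residues)
        return [i + 1 for i, aa in enumerate(self.sequence) if aa in wanted]


@dataclass(frozen=True)
class MultipleAlignment:
    """A multiple sequence alignment as (id, gapped sequence) rows."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        for rid, s in self.rows:
            bad = set(s) - set(ALPHABET) - {GAP}
            if bad:
                raise ValueError(f"{rid}: illegal alignment characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, seq_id: str) -> str:
        for rid, s in self.rows:
            if rid == seq_id:
                return s
        raise KeyError(f"{seq_id!r} not in alignment (rows: {self.ids})")

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def column(self, index: int) -> str:
        """Alignment column (0-based) across all rows, top to bottom."""
        return "".join(s[index] for _, s in self.rows)

    def position_to_column(self, seq_id: str) -> dict[int, int]:
        """Map 1-based ungapped residue positions of a row to 0-based columns."""
        mapping: dict[int, int] = {}
        pos = 0
        for col, aa in enumerate(self.row(seq_id)):
            if aa != GAP:
                pos += 1
                mapping[pos] = col
        return mapping

    def column_to_position(self, seq_id: str) -> dict[int, int]:
        """Inverse of :meth:`position_to_column` (non-gap cells only)."""
        return {col: pos for pos, col in self.position_to_column(seq_id).items()}


@dataclass(frozen=True)
class SiteEvidence:
    """A phospho/glyco site annotation on one sequence."""

    seq_id: str
    position: int
    residue: str
    source: str  # experimental | by_similarity | imported
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.residue not in "STY":
            raise ValueError(f"{self.seq_id}:{self.position}: residue must be S/T/Y, got {self.residue!r}")
        if self.position < 1:
            raise ValueError(f"{self.seq_id}: position must be >= 1")


@dataclass(frozen=True)
class SiteScore:
    """A per-residue predictor potential with its decision threshold.

    A score is *positive* when ``score >= threshold`` (the >= rule; scores
    landing exactly on the threshold count as positive).
    """

    seq_id: str
    position: int
    residue: str
    predictor: str  # phospho | glyco | a named kinase
    score: float
    threshold: float

    def __post_init__(self) -> None:
        if self.residue not in "STY":
            raise ValueError(f"{self.seq_id}:{self.position}: residue must be S/T/Y, got {self.residue!r}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"{self.seq_id}:{self.position}: score {self.score} outside [0, 1]")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"{self.seq_id}:{self.position}: threshold {self.threshold} outside (0, 1)")

    @property
    def positive(self) -> bool:
        return self.score >= self.threshold


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into records (uppercased, raw numbering)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        name = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(ProteinRecord(id=rec.id, sequence=seq, name=name, numbering_offset=0))
    if not records:
        raise ValueError(f"{path}: no FASTA entries found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.name) for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def apply_numbering(record: ProteinRecord, convention: NumberingConvention) -> ProteinRecord:
    """Switch a raw record to the requested numbering convention.

    ``met_cleaved`` drops the initiator methionine and shifts reported
    numbering so the first retained residue is position 1 (offset -1
    relative to the canonical database coordinates); ``raw`` is the
    identity.
    """
    if convention == "raw":
        return record
    if convention != "met_cleaved":
        raise ValueError(f"unknown numbering convention {convention!r}")
    if not record.sequence.startswith("M"):
        raise ValueError(f"{record.id}: met_cleaved requires a sequence starting with M")
    return replace(record, sequence=record.sequence[1:], numbering_offset=record.numbering_offset - 1)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path, fmt: str | None = None) -> MultipleAlignment:
    """Read a Clustal or aligned-FASTA alignment.

    The format is sniffed from the first line when not given.
    """
    path = Path(path)
    if fmt is None:
        head = path.read_text().lstrip()[:30].upper()
        fmt = "clustal" if head.startswith(("CLUSTAL", "MUSCLE")) else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return MultipleAlignment(rows=tuple((r.id, str(r.seq).upper()) for r in aln))


def write_alignment(msa: MultipleAlignment, path: str | Path, fmt: str = "fasta") -> None:
    from Bio.Align import MultipleSeqAlignment

    aln = MultipleSeqAlignment(
        [SeqRecord(Seq(s), id=rid, description="") for rid, s in msa.rows]
    )
    AlignIO.write(aln, str(path), fmt)


# ---------------------------------------------------------------------------
# TSV site / score tables
# ---------------------------------------------------------------------------

def _check_residue(seq_id: str, position: int, residue: str,
                   records: dict[str, ProteinRecord] | None) -> None:
    if records is None or seq_id not in records:
        return
    actual = records[seq_id].residue_at(position)
    if actual != residue:
        raise ValueError(
            f"{seq_id}:{position}: table says {residue} but sequence has {actual}"
        )


def read_site_table(path: str | Path,
                    records: Sequence[ProteinRecord] | None = None) -> list[SiteEvidence]:
    """Read a TSV of site evidence; cross-check residues when records given."""
    df = pd.read_csv(path, sep="\t", dtype={"seq_id": str, "residue": str, "source": str})
    missing = set(SITE_TABLE_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    by_id = {r.id: r for r in records} if records is not None else None
    out = []
    for row in df.itertuples(index=False):
        ev = SiteEvidence(
            seq_id=row.seq_id,
            position=int(row.position),
            residue=row.residue,
            source=row.source,
            provenance=str(getattr(row, "provenance", "") or ""),
        )
        _check_residue(ev.seq_id, ev.position, ev.residue, by_id)
        out.append(ev)
    return out


def write_site_table(evidence: Iterable[SiteEvidence], path: str | Path) -> None:
    df = pd.DataFrame(
        [(e.seq_id, e.position, e.residue, e.source, e.provenance) for e in evidence],
        columns=SITE_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_score_table(path: str | Path,
                     records: Sequence[ProteinRecord] | None = None) -> list[SiteScore]:
    """Read a TSV of predictor scores; cross-check residues when records given."""
    df = pd.read_csv(path, sep="\t", dtype={"seq_id": str, "residue": str, "predictor": str})
    missing = set(SCORE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    by_id = {r.id: r for r in records} if records is not None else None
    out = []
    for row in df.itertuples(index=False):
        sc = SiteScore(
            seq_id=row.seq_id,
            position=int(row.position),
            residue=row.residue,
            predictor=row.predictor,
            score=float(row.score),
            threshold=float(row.threshold),
        )
        _check_residue(sc.seq_id, sc.position, sc.residue, by_id)
        out.append(sc)
    return out


def write_score_table(scores: Iterable[SiteScore], path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.seq_id, s.position, s.residue, s.predictor, s.score, s.threshold) for s in scores],
        columns=SCORE_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def fetch_uniprot_fasta(accession: str, timeout: float = 30.0) -> ProteinRecord:
    """Optional helper: fetch one canonical sequence from UniProt.

    Requires network access; no part of the pipeline or test suite depends
    on it.
    """
    from urllib.request import urlopen

    url = f"https://rest.uniprot.org/uniprotkb/{accession}.fasta"
    with urlopen(url, timeout=timeout) as fh:
        text = fh.read().decode()
    rec = next(SeqIO.parse(io.StringIO(text), "fasta"))
    return ProteinRecord(id=accession, sequence=str(rec.seq).upper(), name=rec.description)
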