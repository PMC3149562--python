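"""Synthetic ortholog families with planted motifs and ground truth.

The generator emulates the statistical structure the H1 interplay
analysis relies on — a lysine/alanine/proline-rich reference sequence,
an ortholog family with per-column conservation, planted (S/T)PXK
consensus motifs, and correlated phospho / O-GlcNAc truth labels — so
every pipeline stage can be exercised against known ground truth
without any downloads.

Truth labels are drawn from an explicit logistic model over window
cells (implemented directly on the sequence, independently of the
predictor's one-hot encoding, so it can serve as an oracle for the
scorer).  Dual-modification structure is the simplest competing-site
model: the glyco truth copies the phospho truth with probability
``dual_site_corr`` and is drawn from its own logistic model otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequence_io import (
    GAP,
    MultipleAlignment,
    ProteinRecord,
    SiteEvidence,
    SiteScore,
    write_alignment,
    write_fasta,
    write_score_table,
    write_site_table,
)

#: H1-like residue frequencies: linker histones are strongly enriched in
#: Lys, Ala and Pro, with Ser/Thr supplying the acceptor sites.
H1_COMPOSITION: dict[str, float] = {
    "K": 0.22, "A": 0.22, "P": 0.09, "S": 0.06, "T": 0.04,
    "G": 0.06, "V": 0.06, "E": 0.05, "R": 0.03, "L": 0.03,
    "N": 0.02, "Q": 0.02, "D": 0.02, "I": 0.02, "F": 0.02,
    "Y": 0.01, "H": 0.01, "M": 0.01, "W": 0.005, "C": 0.005,
}


@dataclass(frozen=True)
class LabelModel:
    """Logistic truth model over window cells relative to the acceptor.

    ``weights`` maps (offset, residue) to a logit contribution; the
    default is a proline-directed model (strong weight for P at +1,
    basic residue bonus at +3) matching the CDK-type consensus.
    """

    intercept: float = -4.0
    weights: dict[tuple[int, str], float] = field(
        default_factory=lambda: {(1, "P"): 8.0, (3, "K"): 2.5, (3, "R"): 1.5}
    )

    def probability(self, sequence: str, position: int) -> float:
        """P(label=1) for the acceptor at 1-based ``position``."""
        z = self.intercept
        for (offset, aa), w in self.weights.items():
            i = position - 1 + offset
            if 0 <= i < len(sequence) and sequence[i] == aa:
                z += w
        return float(1.0 / (1.0 + np.exp(-z)))


@dataclass(frozen=True)
class SyntheticFamilyConfig:
    n_orthologs: int = 4
    length: int = 220
    composition: dict[str, float] = field(default_factory=lambda: dict(H1_COMPOSITION))
    #: probability a column is frozen (identical across all orthologs)
    conservation_p: float = 0.5
    #: per-ortholog substitution probability at non-frozen columns
    substitution_p: float = 0.3
    n_motifs: int = 10
    phospho_model: LabelModel = field(default_factory=LabelModel)
    glyco_model: LabelModel = field(
        default_factory=lambda: LabelModel(intercept=-4.0, weights={(1, "P"): 7.5, (3, "K"): 2.0})
    )
    window: int = 9
    #: probability a true phospho site is copied as a true glyco site
    dual_site_corr: float = 1.0
    noise_rate: float = 0.0
    #: fraction of true reference phospho sites emitted as experimental
    evidence_fraction: float = 0.5
    n_cross_species_sites: int = 3
    #: number of 3-column gap blocks planted in random orthologs
    n_indels: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conservation_p", "substitution_p", "dual_site_corr",
                     "noise_rate", "evidence_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} {v} outside [0, 1]")
        if self.length < self.window:
            raise ValueError("length must be >= window")
        if self.n_motifs * 4 > self.length:
            raise ValueError("motifs do not fit the sequence")
        total = sum(self.composition.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"composition sums to {total}, expected 1")


@dataclass(frozen=True)
class SyntheticFamily:
    config: SyntheticFamilyConfig
    records: tuple[ProteinRecord, ...]  # reference first
    alignment: MultipleAlignment
    #: reference position -> (phospho, glyco) truth
    truth: dict[int, tuple[bool, bool]]
    planted_motifs: tuple[int, ...]
    #: (ortholog id, ortholog position, expected reference position)
    planted_cross_species_sites: tuple[tuple[str, int, int], ...]
    frozen_columns: tuple[int, ...]  # 0-based reference positions

    @property
    def reference(self) -> ProteinRecord:
        return self.records[0]

    def dual_truth_positions(self) -> list[int]:
        return sorted(p for p, (ph, gl) in self.truth.items() if ph and gl)


REF_ID = "REF"


def generate_family(config: SyntheticFamilyConfig) -> SyntheticFamily:
    """Generate one synthetic ortholog family (deterministic given seed)."""
    rng = np.random.default_rng(config.seed)
    aas = sorted(config.composition)
    probs = np.array([config.composition[a] for a in aas])
    probs = probs / probs.sum()
    L = config.length

    ref = list(rng.choice(aas, size=L, p=probs))

    # plant non-overlapping consensus motifs
    planted: list[int] = []
    occupied = np.zeros(L, dtype=bool)
    tries = 0
    while len(planted) < config.n_motifs:
        tries += 1
        if tries > 200 * max(1, config.n_motifs):
            raise ValueError("could not place motifs without overlap")
        s = int(rng.integers(0, L - 3))
        if occupied[s : s + 4].any():
            continue
        st = "S" if rng.random() < 0.5 else "T"
        x = str(rng.choice(aas, p=probs))
        ref[s], ref[s + 1], ref[s + 2], ref[s + 3] = st, "P", x, "K"
        occupied[s : s + 4] = True
        planted.append(s + 1)  # 1-based acceptor position
    planted.sort()

    # frozen columns: random mask, plus every planted motif column
    frozen = rng.random(L) < config.conservation_p
    frozen |= occupied

    ref_seq = "".join(ref)
    ortho_ids = [f"ORTH{i + 1}" for i in range(config.n_orthologs)]
    ortho_seqs: dict[str, list[str]] = {}
    for oid in ortho_ids:
        row = list(ref_seq)
        for col in range(L):
            if not frozen[col] and rng.random() < config.substitution_p:
                row[col] = str(rng.choice(aas, p=probs))
        ortho_seqs[oid] = row

    # truth labels on reference S/T
    truth: dict[int, tuple[bool, bool]] = {}
    for pos in range(1, L + 1):
        if ref_seq[pos - 1] not in "ST":
            continue
        p_ph = config.phospho_model.probability(ref_seq, pos)
        phospho = bool(rng.random() < p_ph)
        if rng.random() < config.dual_site_corr:
            glyco = phospho
        else:
            glyco = bool(rng.random() < config.glyco_model.probability(ref_seq, pos))
        if config.noise_rate > 0:
            if rng.random() < config.noise_rate:
                phospho = not phospho
            if rng.random() < config.noise_rate:
                glyco = not glyco
        truth[pos] = (phospho, glyco)

    # planted indels: 3-column gap blocks in random orthologs
    gapped: dict[str, list[str]] = {oid: list(s) for oid, s in ortho_seqs.items()}
    for _ in range(config.n_indels):
        oid = str(rng.choice(ortho_ids))
        start = int(rng.integers(0, L - 3))
        for col in range(start, start + 3):
            gapped[oid][col] = GAP

    rows = [(REF_ID, ref_seq)] + [(oid, "".join(gapped[oid])) for oid in ortho_ids]
    alignment = MultipleAlignment(rows=tuple(rows))

    records = [ProteinRecord(id=REF_ID, sequence=ref_seq, name="synthetic reference")]
    for oid in ortho_ids:
        records.append(
            ProteinRecord(
                id=oid,
                sequence="".join(gapped[oid]).replace(GAP, ""),
                name="synthetic ortholog",
            )
        )

    # cross-species sites: frozen, phospho-true reference S/T mapped onto
    # a random ortholog (skipping positions an indel removed there)
    candidates = [
        p for p, (ph, _) in sorted(truth.items()) if ph and frozen[p - 1]
    ]
    cross: list[tuple[str, int, int]] = []
    col_maps = {oid: alignment.column_to_position(oid) for oid in ortho_ids}
    for p in candidates:
        if len(cross) >= config.n_cross_species_sites:
            break
        oid = str(rng.choice(ortho_ids))
        opos = col_maps[oid].get(p - 1)  # gap-free alignment: column = ref pos - 1
        if opos is None:
            continue
        cross.append((oid, opos, p))

    return SyntheticFamily(
        config=config,
        records=tuple(records),
        alignment=alignment,
        truth=truth,
        planted_motifs=tuple(planted),
        planted_cross_species_sites=tuple(cross),
        frozen_columns=tuple(int(c) for c in np.flatnonzero(frozen)),
    )


def emit_pipeline_inputs(family: SyntheticFamily, outdir: str | Path) -> dict[str, Path]:
    """Write the family as standard pipeline inputs.

    Emits FASTA, aligned FASTA, an evidence TSV (a subsample of the
    reference phospho truth as "experimental", plus the planted
    cross-species sites on their ortholog sequences) and phospho/glyco
    score TSVs carrying the label-model probabilities, which stand in
    for external predictor exports.  Deterministic given the family.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = family.config
    rng = np.random.default_rng(cfg.seed + 1)
    ref = family.reference

    paths = {
        "fasta": outdir / "family.fasta",
        "alignment": outdir / "family_aln.fasta",
        "evidence": outdir / "evidence.tsv",
        "phospho_scores": outdir / "phospho_scores.tsv",
        "glyco_scores": outdir / "glyco_scores.tsv",
    }
    write_fasta(family.records, paths["fasta"])
    write_alignment(family.alignment, paths["alignment"])

    cross_ref_positions = {refpos for _, _, refpos in family.planted_cross_species_sites}
    evidence: list[SiteEvidence] = []
    for pos, (phospho, _) in sorted(family.truth.items()):
        if not phospho or pos in cross_ref_positions:
            continue
        if rng.random() < cfg.evidence_fraction:
            evidence.append(
                SiteEvidence(
                    seq_id=ref.id,
                    position=pos,
                    residue=ref.residue_at(pos),
                    source="experimental",
                    provenance="synthetic-truth",
                )
            )
    by_id = {r.id: r for r in family.records}
    for oid, opos, _ in family.planted_cross_species_sites:
        evidence.append(
            SiteEvidence(
                seq_id=oid,
                position=opos,
                residue=by_id[oid].residue_at(opos),
                source="experimental",
                provenance="synthetic-cross-species",
            )
        )
    write_site_table(evidence, paths["evidence"])

    phospho_scores = []
    glyco_scores = []
    for pos in sorted(family.truth):
        residue = ref.residue_at(pos)
        phospho_scores.append(
            SiteScore(ref.id, pos, residue, "phospho",
                      round(cfg.phospho_model.probability(ref.sequence, pos), 6), 0.5)
        )
        glyco_scores.append(
            SiteScore(ref.id, pos, residue, "glyco",
                      round(cfg.glyco_model.probability(ref.sequence, pos), 6), 0.5)
        )
    write_score_table(phospho_scores, paths["phospho_scores"])
    write_score_table(glyco_scores, paths["glyco_scores"])
    return paths


# ---------------------------------------------------------------------------
# window-example generators for the predictor
# ---------------------------------------------------------------------------

def separable_window_examples(
    n: int, window: int = 9, seed: int = 0,
) -> list[tuple[ProteinRecord, int, int]]:
    """Balanced, linearly separable examples: label = P at center+1."""
    rng = np.random.default_rng(seed)
    aas = sorted(H1_COMPOSITION)
    probs = np.array([H1_COMPOSITION[a] for a in aas])
    probs /= probs.sum()
    out = []
    for i in range(n):
        label = i % 2
        seq = list(rng.choice(aas, size=window, p=probs))
        center = window // 2
        seq[center] = "S" if rng.random() < 0.5 else "T"
        if label:
            seq[center + 1] = "P"
        elif seq[center + 1] == "P":
            seq[center + 1] = "A"
        rec = ProteinRecord(id=f"w{i}", sequence="".join(seq))
        out.append((rec, center + 1, label))
    return out


def logistic_window_examples(
    n: int, window: int = 9, seed: int = 0, model: LabelModel | None = None,
) -> list[tuple[ProteinRecord, int, int]]:
    """Examples whose labels are Bernoulli draws from a logistic model.

    Half the windows get a planted P at center+1 (and a K at +3 half of
    the time) so both label classes are well represented.
    """
    model = model or LabelModel()
    rng = np.random.default_rng(seed)
    aas = sorted(H1_COMPOSITION)
    probs = np.array([H1_COMPOSITION[a] for a in aas])
    probs /= probs.sum()
    out = []
    center = window // 2
    for i in range(n):
        seq = list(rng.choice(aas, size=window, p=probs))
        seq[center] = "S" if rng.random() < 0.5 else "T"
        if i % 2:
            seq[center + 1] = "P"
            if center + 3 < window and rng.random() < 0.5:
                seq[center + 3] = "K"
        elif seq[center + 1] == "P":
            seq[center + 1] = "A"
        rec = ProteinRecord(id=f"w{i}", sequence="".join(seq))
        label = int(rng.random() < model.probability(rec.sequence, center + 1))
        out.append((rec, center + 1, label))
    return out
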