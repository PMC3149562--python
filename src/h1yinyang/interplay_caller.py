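"""Yin-Yang interplay calling.

A Yin-Yang site is a Ser/Thr residue where phosphorylation and O-β-GlcNAc
can alternately occupy the same hydroxyl.  The caller combines, per
residue: the phosphorylation arm (predictor score and/or experimental
evidence), the O-GlcNAc arm (predictor score), a false-negative margin
for glyco scores landing just below threshold, and the conservation /
motif context used to filter the proposed-site report.

Classes over scored S/T sites (mutually exclusive, exhaustive):

================  ==========================================================
yin_yang          phospho arm positive and glyco score >= threshold
fn_yin_yang       phospho arm positive and glyco score in
                  [threshold - fn_margin, threshold)
phospho_only      phospho arm positive, glyco below the FN band
glyco_only        glyco positive, phospho arm negative
negative          everything else
================  ==========================================================

The phospho arm is positive when the phospho score clears its threshold
*or* the site is experimentally known to be phosphorylated — proposed
site maps routinely anchor sites on experimental evidence the de novo
predictor misses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .conservation import ConservationCall
from .motif_scanner import MotifHit
from .sequence_io import SiteEvidence, SiteScore

CallClass = Literal["yin_yang", "fn_yin_yang", "phospho_only", "glyco_only", "negative"]

PROPOSABLE_CONSERVATION = ("conserved", "conserved_substituted")


@dataclass(frozen=True)
class InterplayParams:
    phospho_threshold: float = 0.5
    glyco_threshold: float = 0.5
    #: glyco scores within fn_margin below threshold stay FN-eligible
    fn_margin: float = 0.1
    require_conservation_for_proposed: bool = True

    def __post_init__(self) -> None:
        for name in ("phospho_threshold", "glyco_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} {v} outside (0, 1)")
        if not 0.0 < self.fn_margin < self.glyco_threshold:
            raise ValueError(
                f"fn_margin must lie in (0, glyco_threshold), got {self.fn_margin}"
            )


@dataclass(frozen=True)
class YinYangCall:
    seq_id: str
    position: int
    residue: str
    call: CallClass
    phospho_score: float | None
    glyco_score: float | None
    motif_hit: bool = False
    conservation: str | None = None
    experimental: bool = False
    by_similarity: bool = False


def _index_scores(scores: Iterable[SiteScore], arm: str) -> dict[tuple[str, int], SiteScore]:
    out: dict[tuple[str, int], SiteScore] = {}
    for s in scores:
        key = (s.seq_id, s.position)
        if key in out:
            raise ValueError(f"duplicate {arm} score for {s.seq_id}:{s.position}")
        out[key] = s
    return out


def call_sites(
    scores_phospho: Sequence[SiteScore],
    scores_glyco: Sequence[SiteScore],
    evidence: Sequence[SiteEvidence] = (),
    conservation_calls: Sequence[ConservationCall] = (),
    motif_hits: Sequence[MotifHit] = (),
    params: InterplayParams = InterplayParams(),
) -> list[YinYangCall]:
    """Classify every scored S/T site; attach evidence and context flags.

    Tyr scores are carried through the inputs but excluded from interplay
    classification (interplay is proposed on Ser/Thr only).  Output is
    deterministic and sorted by (seq_id, position).
    """
    phospho = _index_scores(scores_phospho, "phospho")
    glyco = _index_scores(scores_glyco, "glyco")

    residue_claims: dict[tuple[str, int], str] = {}
    for coll in (scores_phospho, scores_glyco, evidence, conservation_calls):
        for item in coll:
            key = (item.seq_id, item.position)
            prev = residue_claims.setdefault(key, item.residue)
            if prev != item.residue:
                raise ValueError(
                    f"conflicting residues at {key[0]}:{key[1]}: {prev} vs {item.residue}"
                )

    exp = {(e.seq_id, e.position) for e in evidence if e.source == "experimental"}
    bysim = {(e.seq_id, e.position) for e in evidence if e.source == "by_similarity"}
    cons = {(c.seq_id, c.position): c.conservation for c in conservation_calls}
    motif = {(h.seq_id, h.position) for h in motif_hits}

    keys = sorted(
        {k for k in phospho if residue_claims[k] in "ST"}
        | {k for k in glyco if residue_claims[k] in "ST"}
    )
    calls = []
    for key in keys:
        p = phospho.get(key)
        g = glyco.get(key)
        p_score = p.score if p else None
        g_score = g.score if g else None
        p_thr = p.threshold if p else params.phospho_threshold
        g_thr = g.threshold if g else params.glyco_threshold

        experimental = key in exp
        phospho_pos = (p_score is not None and p_score >= p_thr) or experimental
        glyco_pos = g_score is not None and g_score >= g_thr
        fn_glyco = (
            g_score is not None and g_thr - params.fn_margin <= g_score < g_thr
        )

        if phospho_pos and glyco_pos:
            klass: CallClass = "yin_yang"
        elif phospho_pos and fn_glyco:
            klass = "fn_yin_yang"
        elif phospho_pos:
            klass = "phospho_only"
        elif glyco_pos:
            klass = "glyco_only"
        else:
            klass = "negative"

        calls.append(
            YinYangCall(
                seq_id=key[0],
                position=key[1],
                residue=residue_claims[key],
                call=klass,
                phospho_score=p_score,
                glyco_score=g_score,
                motif_hit=key in motif,
                conservation=cons.get(key),
                experimental=experimental,
                by_similarity=key in bysim,
            )
        )
    return calls


CALL_TABLE_COLUMNS = [
    "seq_id", "position", "residue", "class", "phospho_score", "glyco_score",
    "motif_hit", "conservation", "experimental", "by_similarity",
]


def calls_to_dataframe(calls: Sequence[YinYangCall]):
    import pandas as pd

    return pd.DataFrame(
        [
            (c.seq_id, c.position, c.residue, c.call, c.phospho_score, c.glyco_score,
             c.motif_hit, c.conservation or "", c.experimental, c.by_similarity)
            for c in calls
        ],
        columns=CALL_TABLE_COLUMNS,
    )


def write_calls_table(calls: Sequence[YinYangCall], path) -> None:
    calls_to_dataframe(calls).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ProposedSites:
    """Table-3-shaped report: proposed Yin-Yang and FN-Yin-Yang sites,
    partitioned by residue."""

    yin_yang: dict[str, list[YinYangCall]] = field(default_factory=dict)
    fn_yin_yang: dict[str, list[YinYangCall]] = field(default_factory=dict)

    def positions(self, which: str, residue: str) -> list[int]:
        return [c.position for c in getattr(self, which).get(residue, [])]


def proposed_site_report(
    calls: Sequence[YinYangCall],
    params: InterplayParams = InterplayParams(),
) -> ProposedSites:
    """Partition calls into the proposed Yin-Yang / FN-Yin-Yang lists.

    With ``require_conservation_for_proposed`` only conserved or
    conserved-substituted sites are proposed, mirroring how interplay
    sites are anchored on cross-species conservation.
    """

    def eligible(c: YinYangCall) -> bool:
        if not params.require_conservation_for_proposed:
            return True
        return c.conservation in PROPOSABLE_CONSERVATION

    report = ProposedSites(yin_yang={}, fn_yin_yang={})
    for c in sorted(calls, key=lambda c: (c.seq_id, c.position)):
        if c.call == "yin_yang" and eligible(c):
            report.yin_yang.setdefault(c.residue, []).append(c)
        elif c.call == "fn_yin_yang" and eligible(c):
            report.fn_yin_yang.setdefault(c.residue, []).append(c)
    return report
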