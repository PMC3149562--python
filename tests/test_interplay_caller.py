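import numpy as np
import pytest

from h1yinyang.annotations import EXPERIMENTAL_DUAL_SITES
from h1yinyang.conservation import ConservationCall
from h1yinyang.interplay_caller import (
    InterplayParams,
    call_sites,
    proposed_site_report,
)
from h1yinyang.sequence_io import SiteEvidence, SiteScore


def score(seq_id, pos, residue, predictor, value, thr=0.5):
    return SiteScore(seq_id, pos, residue, predictor, value, thr)


def single_call(p, g, experimental=False, params=InterplayParams()):
    evidence = [SiteEvidence("x", 1, "S", "experimental", "t")] if experimental else []
    (call,) = call_sites(
        [score("x", 1, "S", "phospho", p)], [score("x", 1, "S", "glyco", g)],
        evidence=evidence, params=params,
    )
    return call


def rule_oracle(p, g, experimental, params):
    """Row-by-row class re-derivation, independent of the caller."""
    p_pos = p >= params.phospho_threshold or experimental
    g_pos = g >= params.glyco_threshold
    g_fn = params.glyco_threshold - params.fn_margin <= g < params.glyco_threshold
    if p_pos and g_pos:
        return "yin_yang"
    if p_pos and g_fn:
        return "fn_yin_yang"
    if p_pos:
        return "phospho_only"
    if g_pos:
        return "glyco_only"
    return "negative"


@pytest.mark.parametrize(
    "p,g,expected",
    [
        (0.8, 0.6, "yin_yang"),
        (0.9, 0.45, "fn_yin_yang"),
        (0.9, 0.2, "phospho_only"),
        (0.2, 0.8, "glyco_only"),
        (0.2, 0.45, "negative"),  # FN band requires a positive phospho arm
        (0.5, 0.5, "yin_yang"),   # >= rule at both thresholds
    ],
)
def test_class_definitions(p, g, expected):
    assert single_call(p, g).call == expected


def test_experimental_site_with_glyco_positive_score_is_yin_yang():
    call = single_call(0.2, 0.8, experimental=True)
    assert call.call == "yin_yang" and call.experimental


def test_published_dual_exemplars_called_yin_yang(fixture_tables):
    """The experimentally phosphorylated residues with positive O-GlcNAc
    potential (H1.3 S188, H1.4 S186/T145, H1.5 S17, H1t S177) come out
    as Yin-Yang calls carrying the experimental flag."""
    calls = call_sites(
        fixture_tables["phospho"], fixture_tables["glyco"],
        evidence=fixture_tables["evidence"],
        conservation_calls=fixture_tables["conservation"],
        motif_hits=fixture_tables["motifs"],
    )
    by_key = {(c.seq_id, c.position): c for c in calls}
    for acc, residue, pos in EXPERIMENTAL_DUAL_SITES:
        call = by_key[(acc, pos)]
        assert call.call == "yin_yang", (acc, pos)
        assert call.experimental and call.residue == residue


@pytest.mark.parametrize("seed", range(5))
def test_random_tables_match_rule_oracle(seed):
    rng = np.random.default_rng(seed)
    params = InterplayParams(fn_margin=0.15)
    phospho, glyco, evidence = [], [], []
    for pos in range(1, 60):
        residue = "ST"[pos % 2]
        p, g = round(rng.random(), 3), round(rng.random(), 3)
        phospho.append(score("x", pos, residue, "phospho", p))
        glyco.append(score("x", pos, residue, "glyco", g))
        if rng.random() < 0.2:
            evidence.append(SiteEvidence("x", pos, residue, "experimental", "t"))
    calls = call_sites(phospho, glyco, evidence=evidence, params=params)
    exp = {e.position for e in evidence}
    assert len(calls) == 59
    for c, p, g in zip(calls, phospho, glyco):
        assert c.position == p.position
        assert c.call == rule_oracle(p.score, g.score, c.position in exp, params)


def test_partition_is_exhaustive_and_exclusive():
    rng = np.random.default_rng(42)
    phospho = [score("x", i, "S", "phospho", round(rng.random(), 3)) for i in range(1, 200)]
    glyco = [score("x", i, "S", "glyco", round(rng.random(), 3)) for i in range(1, 200)]
    calls = call_sites(phospho, glyco)
    assert [c.position for c in calls] == list(range(1, 200))
    assert all(
        c.call in {"yin_yang", "fn_yin_yang", "phospho_only", "glyco_only", "negative"}
        for c in calls
    )


def test_monotonicity_in_fn_margin_and_glyco_threshold():
    rng = np.random.default_rng(1)
    phospho = [score("x", i, "S", "phospho", round(rng.random(), 3)) for i in range(1, 300)]
    gvals = [round(rng.random(), 3) for _ in range(1, 300)]

    def counts(fn_margin, g_thr):
        glyco = [score("x", i, "S", "glyco", v, g_thr) for i, v in enumerate(gvals, 1)]
        params = InterplayParams(glyco_threshold=g_thr, fn_margin=fn_margin)
        calls = call_sites(phospho, glyco, params=params)
        return (
            sum(c.call == "fn_yin_yang" for c in calls),
            sum(c.call == "yin_yang" for c in calls),
        )

    fn_counts = [counts(m, 0.5)[0] for m in (0.05, 0.1, 0.2, 0.4)]
    assert fn_counts == sorted(fn_counts)
    yy_counts = [counts(0.05, t)[1] for t in (0.3, 0.5, 0.7, 0.9)]
    assert yy_counts == sorted(yy_counts, reverse=True)


def test_row_order_invariance(fixture_tables):
    rng = np.random.default_rng(0)
    phospho = list(fixture_tables["phospho"])
    glyco = list(fixture_tables["glyco"])
    calls = call_sites(phospho, glyco, evidence=fixture_tables["evidence"])
    rng.shuffle(phospho)
    rng.shuffle(glyco)
    assert call_sites(phospho, glyco, evidence=fixture_tables["evidence"]) == calls


def test_tyrosine_scores_carried_but_not_classified():
    calls = call_sites(
        [score("x", 1, "Y", "phospho", 0.9)], [score("x", 2, "S", "glyco", 0.9)]
    )
    assert [(c.position, c.residue) for c in calls] == [(2, "S")]


class TestValidation:
    def test_duplicate_scores_rejected(self):
        dup = [score("x", 1, "S", "phospho", 0.5), score("x", 1, "S", "phospho", 0.6)]
        with pytest.raises(ValueError, match="duplicate"):
            call_sites(dup, [])

    def test_conflicting_residues_rejected(self):
        with pytest.raises(ValueError, match="conflicting"):
            call_sites(
                [score("x", 1, "S", "phospho", 0.5)],
                [score("x", 1, "T", "glyco", 0.5)],
            )

    @pytest.mark.parametrize(
        "kwargs", [{"phospho_threshold": 1.0}, {"fn_margin": 0.0}, {"fn_margin": 0.6}]
    )
    def test_bad_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            InterplayParams(**kwargs)


class TestProposedReport:
    def make_calls(self, conservation):
        cons = [ConservationCall("x", 1, "S", conservation, 1.0)] if conservation else []
        return call_sites(
            [score("x", 1, "S", "phospho", 0.9), score("x", 2, "T", "phospho", 0.9)],
            [score("x", 1, "S", "glyco", 0.9), score("x", 2, "T", "glyco", 0.45)],
            conservation_calls=cons,
        )

    def test_no_conserved_sites_and_requirement_on_gives_empty_lists(self):
        report = proposed_site_report(self.make_calls(None))
        assert report.yin_yang == {} and report.fn_yin_yang == {}

    def test_requirement_off_returns_raw_partitions(self):
        params = InterplayParams(require_conservation_for_proposed=False)
        report = proposed_site_report(self.make_calls(None), params)
        assert report.positions("yin_yang", "S") == [1]
        assert report.positions("fn_yin_yang", "T") == [2]

    def test_conserved_yin_yang_site_proposed(self):
        report = proposed_site_report(self.make_calls("conserved"))
        assert report.positions("yin_yang", "S") == [1]
        assert report.fn_yin_yang == {}  # T2 has no conservation call
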