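import numpy as np
import pytest

from h1yinyang.conservation import (
    classify_column,
    conserved_sites,
    propagate_by_similarity,
)
from h1yinyang.sequence_io import MultipleAlignment, SiteEvidence
from h1yinyang.synthetic_data import SyntheticFamilyConfig, generate_family


def recount_oracle(msa, ref_id, gap_policy="break"):
    """Brute-force per-column reclassification, coded independently."""
    ref_row = msa.row(ref_id)
    others = [s for rid, s in msa.rows if rid != ref_id]
    calls = {}
    pos = 0
    for col, aa in enumerate(ref_row):
        if aa == "-":
            continue
        pos += 1
        if aa not in "ST":
            continue
        cells = [row[col] for row in others]
        if gap_policy == "ignore":
            cells = [c for c in cells if c != "-"]
        if not cells or "-" in cells:
            calls[pos] = "not_conserved"
        elif all(c == aa for c in cells):
            calls[pos] = "conserved"
        elif all(c in "ST" for c in cells):
            calls[pos] = "conserved_substituted"
        else:
            calls[pos] = "not_conserved"
    return calls


@pytest.mark.parametrize(
    "column,ref,expected",
    [
        ("SSSS", "S", "conserved"),
        ("SSTT", "S", "conserved_substituted"),
        ("SSKA", "S", "not_conserved"),
        ("TTTT", "T", "conserved"),
        ("S-SS", "S", "not_conserved"),  # gaps break conservation by default
    ],
)
def test_classify_column_definitions(column, ref, expected):
    klass, support = classify_column(column, ref)
    assert klass == expected
    if expected == "conserved":
        assert support == 1.0
    if expected == "not_conserved":
        assert support < 1.0


def test_classify_column_gap_policy_ignore():
    klass, support = classify_column("S-SS", "S", gap_policy="ignore")
    assert (klass, support) == ("conserved", 1.0)


def test_classify_column_rejects_empty():
    with pytest.raises(ValueError, match="empty"):
        classify_column("", "S")


def test_min_support_relaxation():
    klass, _ = classify_column("SSSA", "S", min_support=0.75)
    assert klass == "conserved"
    assert classify_column("SSSA", "S")[0] == "not_conserved"


def test_identical_two_row_alignment_everything_conserved():
    msa = MultipleAlignment(rows=(("a", "ASPTKA"), ("b", "ASPTKA")))
    calls = conserved_sites(msa, "a")
    assert [(c.position, c.residue, c.conservation, c.support) for c in calls] == [
        (2, "S", "conserved", 1.0),
        (4, "T", "conserved", 1.0),
    ]


def test_missing_reference_raises():
    msa = MultipleAlignment(rows=(("a", "AS"), ("b", "AS")))
    with pytest.raises(KeyError):
        conserved_sites(msa, "zzz")


@pytest.mark.parametrize("seed", range(8))
@pytest.mark.parametrize("gap_policy", ["break", "ignore"])
def test_conserved_sites_match_brute_force_recount(seed, gap_policy):
    fam = generate_family(
        SyntheticFamilyConfig(seed=seed, length=150, n_motifs=6, n_indels=2)
    )
    calls = conserved_sites(fam.alignment, "REF", gap_policy=gap_policy)
    got = {c.position: c.conservation for c in calls}
    assert got == recount_oracle(fam.alignment, "REF", gap_policy=gap_policy)


def test_row_permutation_leaves_calls_unchanged(small_family):
    msa = small_family.alignment
    rng = np.random.default_rng(3)
    rows = list(msa.rows)
    rng.shuffle(rows)
    permuted = MultipleAlignment(rows=tuple(rows))
    assert conserved_sites(msa, "REF") == conserved_sites(permuted, "REF")


def test_projection_round_trip_is_bijection(small_family):
    msa = small_family.alignment
    for rid in msa.ids:
        p2c = msa.position_to_column(rid)
        c2p = msa.column_to_position(rid)
        assert len(p2c) == len(msa.ungapped(rid))
        assert all(c2p[col] == pos for pos, col in p2c.items())


class TestPropagateBySimilarity:
    msa = MultipleAlignment(rows=(("human", "ASPKKA"), ("mouse", "ASPKKA"), ("rat", "AAPKKA")))

    def test_identical_column_propagates(self):
        ev = [SiteEvidence("mouse", 2, "S", "experimental", "elm")]
        out = propagate_by_similarity(
            MultipleAlignment(rows=(("human", "ASPKKA"), ("mouse", "ASPKKA"))), ev, "human"
        )
        assert [(e.position, e.residue, e.source) for e in out] == [(2, "S", "by_similarity")]

    def test_non_acceptor_reference_column_blocks_propagation(self):
        msa = MultipleAlignment(rows=(("human", "AAPKKA"), ("mouse", "ASPKKA")))
        ev = [SiteEvidence("mouse", 2, "S", "experimental", "elm")]
        assert propagate_by_similarity(msa, ev, "human") == []

    def test_existing_reference_evidence_not_duplicated(self):
        msa = MultipleAlignment(rows=(("human", "ASPKKA"), ("mouse", "ASPKKA")))
        ev = [
            SiteEvidence("human", 2, "S", "experimental", "elm"),
            SiteEvidence("mouse", 2, "S", "experimental", "elm"),
        ]
        assert propagate_by_similarity(msa, ev, "human") == []

    def test_unknown_sequence_rejected(self):
        ev = [SiteEvidence("chicken", 2, "S", "experimental", "elm")]
        with pytest.raises(ValueError, match="chicken"):
            propagate_by_similarity(self.msa, ev, "human")

    def test_planted_cross_species_sites_recovered(self, small_family):
        fam = small_family
        ev = [
            SiteEvidence(oid, opos, fam.alignment.ungapped(oid)[opos - 1], "experimental", "planted")
            for oid, opos, _ in fam.planted_cross_species_sites
        ]
        out = propagate_by_similarity(fam.alignment, ev, "REF")
        assert {e.position for e in out} == {ref for _, _, ref in fam.planted_cross_species_sites}
        assert all(e.source == "by_similarity" for e in out)
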