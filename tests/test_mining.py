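"""ORF finding, SD scoring, precursor mining, length classes, peptide masses."""

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from ribocycle import (
    TEMPLATES,
    AnchorRegion,
    MinerConfig,
    classify_length,
    find_orfs,
    mine_precursors,
    peptide_mass,
    register_modification,
    score_sd,
    synthesize_neighborhood,
    template_anchor,
)

WATER = 18.0105646863


# ---------------------------------------------------------------------------
# ORF finder


def test_single_orf_in_minimal_sequence():
    orfs = find_orfs("ATGTTTTTCTAA", strand="+", min_aa=2)
    assert [(o.start, o.end, o.peptide) for o in orfs] == [(0, 12, "MFF")]


def test_min_length_filter_excludes_single_residue_orf():
    assert find_orfs("ATGTAA", strand="+", min_aa=2) == []


def test_orf_without_stop_is_not_emitted():
    assert find_orfs("ATGTTTTTC", strand="+", min_aa=2) == []


def test_ambiguous_base_voids_orf():
    assert find_orfs("ATGTNTTTCTAA", strand="+", min_aa=2) == []


def test_reverse_strand_coordinates_map_to_forward():
    fwd = "ATGTTTTTCTAA"
    rc = str(Seq(fwd).reverse_complement())
    orfs = find_orfs(rc, strand="-", min_aa=2)
    assert [(o.start, o.end, o.strand, o.peptide) for o in orfs] == [
        (0, 12, "-", "MFF")
    ]


def test_printed_templates_contain_their_peptides():
    for name, (seq, pep) in TEMPLATES.items():
        if name == "competitor":
            continue
        orfs = find_orfs(seq, strand="both", min_aa=3, max_aa=60)
        matches = [o for o in orfs if o.peptide == pep]
        assert len(matches) == 1, name
        assert matches[0].strand == "+"


def test_start_codon_rendered_as_met():
    orfs = find_orfs("GTGTTTAATTAA", strand="+", min_aa=2)
    assert orfs[0].peptide == "MFN"


# ---------------------------------------------------------------------------
# SD scoring


def test_sd_score_on_printed_template_start():
    for name, (seq, _) in TEMPLATES.items():
        if name == "competitor":
            continue
        sd = score_sd(seq, seq.upper().find("ATGCGTACT" if name == "A7" else "ATGG"))
        assert (sd.score, sd.spacer) == (6, 6), name
        assert not sd.edge


def test_no_purine_rich_upstream_scores_low():
    seq = "C" * 40 + "ATGAAATAA"
    sd = score_sd(seq, 40)
    assert sd.score <= 2


def test_start_at_origin_is_edge_flagged():
    sd = score_sd("ATGAAATAA", 0)
    assert sd.score == 0 and sd.edge


def test_tie_breaks_toward_smaller_spacer():
    # AGGAGG placed so spacers 5 and 9 both see perfect matches
    seq = "T" * 10 + "AGGAGG" + "TAGGAGGTT" + "ATG"
    sd = score_sd(seq, len(seq) - 3)
    assert sd.score == 6
    assert sd.spacer == min(
        s for s in range(4, 14)
        if seq[len(seq) - 3 - s - 6 : len(seq) - 3 - s] == "AGGAGG"
    )


def test_minus_strand_scoring_mirrors_plus():
    fwd = "T" * 20 + "AGGAGG" + "ACGTAC" + "ATGAAAAACTAA" + "T" * 20
    start = fwd.find("ATGAAAAAC")
    plus = score_sd(fwd, start)
    rc = str(Seq(fwd).reverse_complement())
    # on the reverse complement the same ORF is on '-' with its start codon's
    # first (reading-order) base at the mirrored coordinate
    minus = score_sd(rc, len(fwd) - 1 - start, strand="-")
    assert (plus.score, plus.spacer) == (minus.score, minus.spacer) == (6, 6)


# ---------------------------------------------------------------------------
# miner


def test_each_template_yields_single_candidate_with_max_sd():
    for name, (seq, pep) in TEMPLATES.items():
        if name == "competitor":
            continue
        cands = mine_precursors(seq, template_anchor(name))
        assert len(cands) == 1, name
        top = cands[0]
        assert top.peptide == pep
        assert top.sd_score == 6
        assert top.upstream and top.same_strand


def test_competitor_template_yields_no_candidates():
    # MFF lacks the C-terminal Asn required for adenylation
    seq, _ = TEMPLATES["competitor"]
    anchor = AnchorRegion("competitor", len(seq) - 30, len(seq), "+")
    assert mine_precursors(seq, anchor) == []


def test_planted_neighborhood_round_trip_50_seeds():
    for seed in range(50):
        nb = synthesize_neighborhood("MRTGNAN", seed=seed)
        anchor = AnchorRegion("nb", nb.anchor_start, nb.anchor_end, "+")
        cands = mine_precursors(nb.sequence, anchor)
        assert cands, f"seed {seed}: planted ORF not recovered"
        top = cands[0]
        assert (top.start, top.end, top.strand) == nb.planted_orf, f"seed {seed}"
        assert top.peptide == "MRTGNAN"


def test_background_false_positive_rate_is_low():
    """Hard filters leave >=95/100 seeded anchor-only backgrounds empty."""
    clean = sum(
        not mine_precursors(
            (nb := synthesize_neighborhood(None, seed=seed)).sequence,
            AnchorRegion("bg", nb.anchor_start, nb.anchor_end, "+"),
        )
        for seed in range(100)
    )
    assert clean >= 95


def test_upstream_same_strand_candidate_ranks_first():
    up = synthesize_neighborhood("MKTAN", seed=1, upstream=True, distance_to_anchor=40)
    down_cassette = synthesize_neighborhood(
        "MGGFN", seed=2, upstream=False, strand="-", distance_to_anchor=40
    )
    # splice the downstream/opposite-strand cassette after the first fixture's anchor
    tail = down_cassette.sequence[down_cassette.anchor_end :]
    seq = up.sequence[: up.anchor_end] + tail
    anchor = AnchorRegion("two", up.anchor_start, up.anchor_end, "+")
    cands = mine_precursors(seq, anchor)
    peps = [c.peptide for c in cands]
    assert "MKTAN" in peps and "MGGFN" in peps
    assert cands[0].peptide == "MKTAN"
    assert cands[0].upstream and cands[0].same_strand
    below = cands[peps.index("MGGFN")]
    assert not below.same_strand and not below.upstream


def test_non_asn_terminus_is_hard_filtered():
    nb = synthesize_neighborhood("MRTGNAN", seed=7)
    # mutate the planted Asn codon into Gln (AAT/AAC -> CAA)
    s, e, _ = nb.planted_orf
    seq = nb.sequence[: e - 6] + "CAA" + nb.sequence[e - 3 :]
    anchor = AnchorRegion("nb", nb.anchor_start, nb.anchor_end, "+")
    assert all(c.peptide != "MRTGQAN" for c in mine_precursors(seq, anchor))
    assert mine_precursors(nb.sequence, anchor)  # unmutated control recovers


def test_strand_symmetry_of_mining():
    nb = synthesize_neighborhood("MSSTVN", seed=12)
    anchor = AnchorRegion("nb", nb.anchor_start, nb.anchor_end, "+")
    cands = mine_precursors(nb.sequence, anchor)

    L = len(nb.sequence)
    rc = str(Seq(nb.sequence).reverse_complement())
    anchor_rc = AnchorRegion("nb", L - nb.anchor_end, L - nb.anchor_start, "-")
    cands_rc = mine_precursors(rc, anchor_rc)

    def key(c):
        return (c.peptide, c.sd_score, c.sd_spacer_nt, c.distance_nt,
                c.same_strand, c.upstream, c.rank_score)

    assert [key(c) for c in cands] == [key(c) for c in cands_rc]
    mirrored = [(L - c.end, L - c.start) for c in cands_rc]
    assert [(c.start, c.end) for c in cands] == mirrored


def test_emitted_candidates_satisfy_hard_filters():
    cfg = MinerConfig()
    for seed in range(20):
        nb = synthesize_neighborhood("MAGTPLN", seed=100 + seed, distance_to_anchor=seed * 10)
        anchor = AnchorRegion("nb", nb.anchor_start, nb.anchor_end, "+")
        for c in mine_precursors(nb.sequence, anchor, cfg):
            assert c.peptide.endswith("N")
            assert c.sd_score >= cfg.sd_threshold
            assert c.distance_nt <= anchor.window_nt
            assert cfg.min_aa <= c.length_aa <= cfg.max_aa


def test_anchor_outside_sequence_errors():
    with pytest.raises(ValueError, match="beyond"):
        mine_precursors("ACGT" * 10, AnchorRegion("x", 30, 60, "+"))


# ---------------------------------------------------------------------------
# peptide utilities


@pytest.mark.parametrize(
    "length,label",
    [(7, "short"), (8, "short"), (17, "long"), (42, "long"), (56, "long"),
     (11, "other"), (1, "other"), (6, "other"), (9, "other"), (57, "other")],
)
def test_length_classification(length, label):
    assert classify_length(length) == label


def test_length_classification_rejects_nonpositive():
    with pytest.raises(ValueError):
        classify_length(0)


def test_glycine_monoisotopic_mass():
    assert peptide_mass("G") == pytest.approx(75.03203, abs=1e-4)
    assert peptide_mass("GG") == pytest.approx(132.05349, abs=1e-4)


def test_formyl_modification_delta():
    assert peptide_mass("MRTGNAN", ["formyl"]) - peptide_mass("MRTGNAN") == (
        pytest.approx(27.99491, abs=1e-4)
    )


def test_user_registered_modification():
    register_modification("aminopropyl_test", 57.0578)
    assert peptide_mass("GG", ["aminopropyl_test"]) == pytest.approx(
        132.05349 + 57.0578, abs=1e-3
    )


def test_unknown_residue_and_modification_error():
    with pytest.raises(ValueError):
        peptide_mass("GZ1")
    with pytest.raises(ValueError, match="register"):
        peptide_mass("GG", ["no_such_mod"])


@given(
    a=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=12),
    b=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=12),
)
@settings(derandomize=True, max_examples=40)
def test_mass_additivity(a, b):
    assert peptide_mass(a + b) == pytest.approx(
        peptide_mass(a) + peptide_mass(b) - WATER, abs=1e-6
    )
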