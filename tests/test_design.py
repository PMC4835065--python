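"""Nearest-neighbor Tm engine, design rule table and candidate enumeration."""

import dataclasses

import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as mt
from hypothesis import given, settings, strategies as st

import dropquant as dq
from dropquant.design import Buffer, TmTargets
from dropquant.errors import PlacementError, ValidationError

from conftest import FIXTURE_LOCUS, PLANTED_OLIGOS


def _biopython_tm(seq, conc_nM, mono=50.0, div=3.0, dntp=0.0):
    """Independent oracle: Biopython's NN engine with the unified duplex
    table, the entropy salt correction, and the C_T/4 convention
    (C_T for self-complementary duplexes, which Biopython does not
    auto-detect)."""
    selfcomp = seq == dq.reverse_complement(seq)
    return mt.Tm_NN(
        seq,
        nn_table=mt.DNA_NN3,
        Na=mono,
        Mg=div,
        dNTPs=dntp,
        saltcorr=5,
        selfcomp=selfcomp,
        dnac1=conc_nM if selfcomp else conc_nM / 2,
        dnac2=0.0 if selfcomp else conc_nM / 2,
    )


ORACLE_OLIGOS = [
    "CGTTGAAC", "ATATATATAT", "GCGCGCATTA", "TTCCTTCTGCACGCC",
    "TGGGCCCTACTCCAGG", "CCGCGTACGCAGGAGC", "CTCAGCATGTACGCCAGAG",
    "CATGGGCATCGGGCG", "CGTAGTCGTACTCGCTGG", "CTGGGCGTGCTGCTGG",
    "CGCGGCGCTTCTGGC", "AACGTTGCAATTGGCC",
]


@pytest.mark.parametrize("seq", ORACLE_OLIGOS)
@pytest.mark.parametrize("conc", [250.0, 900.0])
def test_tm_matches_independent_nn_summation(seq, conc):
    assert dq.tm_nn(seq, conc) == pytest.approx(_biopython_tm(seq, conc), abs=0.1)


@settings(derandomize=True, max_examples=100)
@given(st.text(alphabet="ACGT", min_size=8, max_size=30))
def test_tm_is_strand_symmetric(seq):
    assert dq.tm_nn(seq, 250.0) == pytest.approx(
        dq.tm_nn(dq.reverse_complement(seq), 250.0), abs=1e-9
    )


def test_tm_monotone_in_concentration_and_salt():
    seq = "TGGGCCCTACTCCAGG"
    concs = [50.0, 250.0, 900.0]
    tms = [dq.tm_nn(seq, c) for c in concs]
    assert tms == sorted(tms) and tms[0] < tms[2]
    salts = [10.0, 50.0, 200.0]
    tms = [dq.tm_nn(seq, 250.0, monovalent_mM=s, divalent_mM=0.0) for s in salts]
    assert tms == sorted(tms) and tms[0] < tms[2]


def test_tm_input_validation():
    with pytest.raises(ValidationError):
        dq.tm_nn("ACGTNACGT", 250.0)  # ambiguous base
    with pytest.raises(ValidationError):
        dq.tm_nn("ACGTA", 250.0)  # too short
    with pytest.raises(ValidationError):
        dq.tm_nn("ACGT" * 12, 250.0)  # too long
    with pytest.raises(ValidationError):
        dq.tm_nn("ACGTACGT", 0.0)


def test_base_composition():
    assert dq.g_content("GGGG") == 100.0
    assert dq.gc_content("ATAT") == 0.0
    # a 20-mer TALE binding site with 11 G: G-richness that favors NN repeats
    assert dq.g_content("G" * 11 + "A" * 9) == pytest.approx(55.0)


def test_compliant_design_passes_every_rule(fixture_locus, fixture_oligos):
    report = dq.check_design(fixture_locus, fixture_oligos)
    assert report.passed, report.failed_rules()
    assert {r.rule_id for r in report.rules} == {f"R{i}" for i in range(1, 8)}


def test_report_is_pure_function_of_inputs(fixture_locus, fixture_oligos):
    a = dq.check_design(fixture_locus, fixture_oligos)
    b = dq.check_design(fixture_locus, fixture_oligos)
    assert a == b


def test_shifted_dropoff_probe_fails_only_cut_site_rule(fixture_locus, fixture_oligos):
    """Moving the drop-off probe 10 bp off the cut site breaks R1 and
    nothing else (the shifted window was chosen to keep its Tm in band)."""
    start = fixture_oligos.dropoff_probe.start + 10
    shifted_seq = FIXTURE_LOCUS[start : start + 15]
    shifted = dataclasses.replace(
        fixture_oligos,
        dropoff_probe=dq.Oligo("dropoff_probe", shifted_seq, "+", start, 250.0),
    )
    report = dq.check_design(fixture_locus, shifted)
    assert report.failed_rules() == ("R1",)


def test_snp_inside_primer_fails_only_snp_rule(fixture_locus, fixture_oligos):
    locus = dataclasses.replace(fixture_locus, snp_positions=(40,))  # inside forward
    report = dq.check_design(locus, fixture_oligos)
    assert report.failed_rules() == ("R6",)
    assert report.rule("R6").measured == ((40, "forward"),)


def test_reference_probe_near_cut_fails_placement_rule(fixture_locus, fixture_oligos):
    near_seq = FIXTURE_LOCUS[160:176]
    moved = dataclasses.replace(
        fixture_oligos, ref_probe=dq.Oligo("ref_probe", near_seq, "+", 160, 250.0)
    )
    report = dq.check_design(fixture_locus, moved)
    assert "R4" in report.failed_rules()


def test_gc_rich_targets_relax_only_high_tm(fixture_locus, fixture_oligos):
    """Above-band Tm is forgiven on amplicons past the GC threshold, but
    below-band Tm never is."""
    # targets set low so every fixture oligo melts above its band
    low = TmTargets(primer=50.0, ref_probe=55.0, dropoff_low=51.0, dropoff_high=52.0,
                    gc_relax_percent=40.0)
    assert dq.check_design(fixture_locus, fixture_oligos, targets=low).rule("R5").passed
    no_relax = dataclasses.replace(low, gc_relax_percent=101.0)
    assert not dq.check_design(fixture_locus, fixture_oligos, targets=no_relax).rule("R5").passed
    # targets set high so oligos melt below band: relaxation must not forgive
    high = TmTargets(primer=60.0, ref_probe=65.0, dropoff_low=61.0, dropoff_high=62.0,
                     gc_relax_percent=40.0)
    assert not dq.check_design(fixture_locus, fixture_oligos, targets=high).rule("R5").passed


def test_talen_design_rules(fixture_oligos):
    """A TALEN version of the fixture locus: spacer covered by the probe."""
    locus = dq.TargetLocus(
        sequence=FIXTURE_LOCUS,
        nuclease=dq.TalenSite(left=(110, 128), right=(166, 184), spacer=(144, 157)),
    )
    report = dq.check_design(locus, fixture_oligos)
    assert report.rule("R1").message.startswith("not applicable")
    assert report.rule("R2").passed
    long_spacer = dq.TargetLocus(
        sequence=FIXTURE_LOCUS,
        nuclease=dq.TalenSite(left=(100, 118), right=(170, 188), spacer=(120, 165)),
    )
    assert not dq.check_design(long_spacer, fixture_oligos).rule("R2").passed


def test_pam_validation():
    with pytest.raises(ValidationError):
        dq.TargetLocus(
            sequence=FIXTURE_LOCUS,
            nuclease=dq.Cas9Site(protospacer=(130, 150), pam=(150, 153), strand="+"),
        )  # locus[150:153] is not NGG


def test_published_oligos_round_trip_on_expected_strands():
    """Embed the published NODAL oligo sequences in a synthetic scaffold
    and confirm the placement parser recovers strand and interval."""
    fwd = "TTCCTTCTGCACGCC"
    ref_probe = "TGGGCCCTACTCCAGG"
    dropoff = "CTCAGCATGTACGCCAGAG"
    rev = "TAGGCTGCGGATGATG"
    filler = "ACGTTACA"
    scaffold = (
        filler + fwd + filler + ref_probe + filler + dropoff + filler
        + dq.reverse_complement(rev) + filler
    )
    placed = [
        dq.place_oligo(scaffold, "forward", fwd, 900.0),
        dq.place_oligo(scaffold, "ref_probe", ref_probe, 250.0),
        dq.place_oligo(scaffold, "dropoff_probe", dropoff, 250.0),
        dq.place_oligo(scaffold, "reverse", rev, 900.0),
    ]
    assert [o.strand for o in placed] == ["+", "+", "+", "-"]
    for o in placed:
        found = scaffold[o.interval[0] : o.interval[1]]
        expect = o.sequence if o.strand == "+" else dq.reverse_complement(o.sequence)
        assert found == expect
    with pytest.raises(PlacementError):
        dq.place_oligo(scaffold, "missing", "AAAAAAAACCCCGGGG", 250.0)


def test_enumeration_recovers_a_compliant_design(fixture_locus):
    result = dq.enumerate_candidates(fixture_locus)
    assert result.candidates and not result.diagnostics
    best = result.candidates[0]
    assert best.report.passed
    planted_score = sum(
        abs(dq.tm_nn(seq, conc) - target)
        for (seq, conc), target in zip(
            PLANTED_OLIGOS.values(), (55.0, 55.0, 60.0, 56.5)
        )
    )
    assert best.score <= planted_score + 1e-9
    scores = [c.score for c in result.candidates]
    assert scores == sorted(scores)


def test_enumeration_short_locus_returns_empty(fixture_locus):
    short = dq.TargetLocus(
        sequence=FIXTURE_LOCUS[100:220],
        nuclease=dq.Cas9Site(protospacer=(33, 53), pam=(53, 56), strand="+"),
    )
    result = dq.enumerate_candidates(short)
    assert result.candidates == ()


def test_enumeration_impossible_tm_window_is_diagnosed(fixture_locus):
    constraints = dq.DesignConstraints(
        targets=TmTargets(primer=95.0, ref_probe=98.0, dropoff_low=96.0, dropoff_high=97.0)
    )
    result = dq.enumerate_candidates(fixture_locus, constraints)
    assert result.candidates == ()
    assert result.diagnostics
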