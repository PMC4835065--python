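"""Shared fixtures: simulated control wells, fitted thresholds, and a
synthetic Cas9 locus with a planted rule-compliant oligo set.

The locus was assembled programmatically: a random background with four
planted oligos whose nearest-neighbor melting temperatures fall in the
guideline bands (primers ~55 C at 900 nM, reference probe ~60 C and
drop-off probe 56-57 C at 250 nM under the 50 mM monovalent / 3 mM
divalent buffer), the drop-off probe centered on the blunt cut site 3 bp
5' of an NGG PAM, and 100 bp flanks from the cut to each primer 3' end.
"""

import pytest

import dropquant as dq

# synthetic fixture locus (320 bp), cut site at position 150
FIXTURE_LOCUS = (
    "AAGCACTTGCAGCGGAAATGATCCTAAGAGAAAATGTCTTTACAAGGTCCATTTGTACCTGTATCCTCCGG"
    "TTTAGCGGTTCGGCACGGCCCAAGCAGTATTGGATCTGAAGGATTCCATCTCGAATCGTTTAGTCATCGTG"
    "CGCCTTTAAGCGGGTGAGTCTTTGCGCTTAGTGCCAGTTAGCTATTAATAGTGCCATCACTATGTTTTATG"
    "GTTGCCCCCAATCTGAAATAGTTAAAAAGTGGATGTTAGATTTCATCTCACGTCAACGGCTCCCAGAGATC"
    "TCATGTCGTGCGGTCCTGTCATAAGTTAATAACGTT"
)

PLANTED_OLIGOS = {
    "forward": ("ATGTCTTTACAAGGTCC", 900.0),        # + strand, [33, 50)
    "reverse": ("GACGTGAGATGAAATCT", 900.0),        # - strand, binds [250, 267)
    "ref_probe": ("GTTTAGCGGTTCGGCA", 250.0),       # + strand, [70, 86)
    "dropoff_probe": ("GCCTTTAAGCGGGTG", 250.0),    # + strand, [143, 158), spans cut
}


@pytest.fixture(scope="session")
def control_wells():
    """Negative (wild-type only) and positive (mutant only) control wells."""
    neg = dq.simulate_well(
        dq.WellSpec(copies_wt=10000, n_droplets=15000, seed=101, well_id="neg")
    )
    pos = dq.simulate_well(
        dq.WellSpec(copies_nhej=10000, n_droplets=15000, seed=102, well_id="pos")
    )
    return neg, pos


@pytest.fixture(scope="session")
def thresholds(control_wells):
    return dq.fit_thresholds(*control_wells)


@pytest.fixture(scope="session")
def fixture_locus():
    return dq.TargetLocus(
        sequence=FIXTURE_LOCUS,
        nuclease=dq.Cas9Site(protospacer=(133, 153), pam=(153, 156), strand="+"),
    )


@pytest.fixture(scope="session")
def fixture_oligos():
    return dq.OligoSet(
        **{
            role: dq.place_oligo(FIXTURE_LOCUS, role, seq, conc)
            for role, (seq, conc) in PLANTED_OLIGOS.items()
        }
    )
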