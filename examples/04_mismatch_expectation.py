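"""Expected vs detected signal in a mismatch-nuclease (T7E1) assay.

A 50:50 mix of a wild-type clone and a clone with two distinct mutant
alleles re-anneals into heteroduplexes that the nuclease cleaves; the
expectation follows from random strand pairing.  Band densitometry from
a gel gives the detected percentage for comparison.
"""

import dropquant as dq

# one wild-type and two distinct mutant alleles at 50 / 25 / 25 %
spectrum = (0.50, 0.25, 0.25)
hom = dq.expected_homoduplex_fraction(spectrum)
het = dq.expected_heteroduplex_fraction(spectrum)
print(f"allele spectrum {spectrum}:")
print(f"  homoduplex (uncleaved) expectation:  {100*hom:.1f}%")
print(f"  heteroduplex (cleavable) expectation: {100*het:.1f}%")

# a gel lane: parent band 120 units, two digested fragments 40 and 30
lane = dq.GelLane(parent_intensity=120.0, digested_intensities=(40.0, 30.0))
print(f"  detected percent digested from the gel: "
      f"{dq.detected_percent_digested(lane):.1f}%")

# stain signal scales with fragment length: a mid-amplicon cut of a
# 400 bp product leaves each 200 bp fragment with half the parent signal
fracs = dq.fragment_signal_fractions([200, 200])
print(f"  stain signal retained by equal fragments: {[f'{f:.0%}' for f in fracs]}")
print("detected < expected is typical: cleavage is incomplete and fragments are dimmer")
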