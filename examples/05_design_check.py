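"""Validate a drop-off assay design and enumerate alternatives.

Checks a Cas9 drop-off design against the rule table (cut-site-centered
drop-off probe, distant reference probe, 75-125 bp flanks, Tm targets,
SNP avoidance) and then searches the locus for rule-compliant designs.
"""

import dropquant as dq

LOCUS = (
    "AAGCACTTGCAGCGGAAATGATCCTAAGAGAAAATGTCTTTACAAGGTCCATTTGTACCTGTATCCTCCGG"
    "TTTAGCGGTTCGGCACGGCCCAAGCAGTATTGGATCTGAAGGATTCCATCTCGAATCGTTTAGTCATCGTG"
    "CGCCTTTAAGCGGGTGAGTCTTTGCGCTTAGTGCCAGTTAGCTATTAATAGTGCCATCACTATGTTTTATG"
    "GTTGCCCCCAATCTGAAATAGTTAAAAAGTGGATGTTAGATTTCATCTCACGTCAACGGCTCCCAGAGATC"
    "TCATGTCGTGCGGTCCTGTCATAAGTTAATAACGTT"
)

locus = dq.TargetLocus(
    sequence=LOCUS,
    nuclease=dq.Cas9Site(protospacer=(133, 153), pam=(153, 156), strand="+"),
)
print(f"blunt Cas9 cut 3 bp 5' of the PAM: position {locus.cut_site}")

oligos = dq.OligoSet(
    forward=dq.place_oligo(LOCUS, "forward", "ATGTCTTTACAAGGTCC", 900.0),
    reverse=dq.place_oligo(LOCUS, "reverse", "GACGTGAGATGAAATCT", 900.0),
    ref_probe=dq.place_oligo(LOCUS, "ref_probe", "GTTTAGCGGTTCGGCA", 250.0),
    dropoff_probe=dq.place_oligo(LOCUS, "dropoff_probe", "GCCTTTAAGCGGGTG", 250.0),
)
report = dq.check_design(locus, oligos)
for rule in report.rules:
    print(f"  {rule.rule_id} {'PASS' if rule.passed else 'FAIL'}: {rule.message}")
print(f"overall: {'PASS' if report.passed else 'FAIL'}")

result = dq.enumerate_candidates(locus)
print(f"\nenumeration found {len(result.candidates)} rule-compliant designs;")
best = result.candidates[0]
print(f"best total Tm deviation {best.score:.2f} C, drop-off probe "
      f"{best.oligos.dropoff_probe.sequence} at {best.oligos.dropoff_probe.interval}")
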