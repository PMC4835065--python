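"""Detect large deletions from reference-signal loss and normalized copy number.

Clones whose deletion removes the reference probe (or a primer site)
amplify nothing: a heterozygous deletion halves the reference-channel
copies, a bi-allelic deletion abolishes them.  Normalizing against a
two-copy reference gene (RPP30-style assay) converts the same signal
into copies per genome.
"""

import dropquant as dq

neg = dq.simulate_well(dq.WellSpec(copies_wt=10000, seed=1, well_id="neg"))
pos = dq.simulate_well(dq.WellSpec(copies_nhej=10000, seed=2, well_id="pos"))
th = dq.fit_thresholds(neg, pos)


def ref_copies(spec):
    return dq.quantify_reference(dq.classify(dq.simulate_well(spec), th))


wt = ref_copies(dq.WellSpec(copies_wt=10000, seed=11, well_id="wt"))
het = ref_copies(dq.WellSpec(copies_wt=5000, copies_del=5000, seed=12, well_id="het-del"))
bi = ref_copies(dq.WellSpec(copies_del=10000, seed=13, well_id="bi-del"))
rpp30 = ref_copies(dq.WellSpec(copies_wt=10000, seed=14, well_id="rpp30"))

for name, clone in (("heterozygous deletion", het), ("bi-allelic deletion", bi)):
    screen = dq.deletion_screen(clone, wt)
    cn = dq.copy_number(clone, rpp30)
    print(f"{name}: reference signal {100*screen.ratio:.1f}% of wild type "
          f"[{100*screen.ci_low:.1f}%, {100*screen.ci_high:.1f}%], "
          f"copy number {cn.cn:.2f} per genome, "
          f"deletion suspected: {screen.large_deletion_suspected}")
print("expected: ~50% / CN ~1 for one deleted allele; 0% / CN 0 for two")
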