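"""Call clone genotypes from 5 ng screens of single-cell-derived clones.

A wild-type, a mono-allelic and a bi-allelic mutant clone are simulated
at a 5 ng input and called from the mutant-fraction confidence interval.
"""

import dropquant as dq

neg = dq.simulate_well(dq.WellSpec(copies_wt=10000, seed=1, well_id="neg"))
pos = dq.simulate_well(dq.WellSpec(copies_nhej=10000, seed=2, well_id="pos"))
th = dq.fit_thresholds(neg, pos)

total = dq.genome_equivalents_to_copies(dq.mass_to_genomes(5000.0))  # 5 ng
for seed, (name, mut_frac) in enumerate(
    (("clone-A", 0.0), ("clone-B", 0.5), ("clone-C", 1.0)), start=10
):
    well = dq.simulate_well(
        dq.WellSpec(
            copies_wt=(1 - mut_frac) * total,
            copies_nhej=mut_frac * total,
            seed=seed,
            well_id=name,
        )
    )
    counts = dq.classify(well, th)
    frac = dq.mutant_fraction(dq.quantify_nhej(counts), dq.quantify_wt(counts))
    call = dq.call_genotype(frac)
    print(f"{name}: true mutant fraction {mut_frac:.1f} -> "
          f"measured {frac.fraction:.3f} [{frac.ci_low:.3f}, {frac.ci_high:.3f}] "
          f"-> {call.call}")
print("calls follow the CI rule: <5% wild_type, contains 0.5 mono_allelic, >95% bi_allelic")
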