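# dropquant

A toolkit for analyzing **droplet digital PCR (ddPCR) drop-off assays**
used to detect and quantify nuclease-induced (CRISPR/Cas9 or TALEN) NHEJ
mutations in genome-editing experiments — and for designing such assays.

It is written for bench scientists and analysts screening edited bulk
populations and single-cell-derived clones: people who need absolute
mutant and wild-type copy counts with confidence intervals, genotype
calls, large-deletion flags, and a sanity check that a planned
primer/probe set will actually behave as a drop-off assay.

## The assay and the statistics

A 20 µL reaction is partitioned into ~0.85 nL droplets. Each amplicon
carries two hydrolysis probes:

* a **reference probe** binding away from the nuclease cut site — lights
  up for every amplifiable template;
* a **drop-off (NHEJ) probe** spanning the cut site, with a deliberately
  depressed melting temperature (56–57 °C vs 60 °C for the reference
  probe) — any indel destabilizes it, so mutant templates lose this
  channel's signal while keeping the reference signal.

Quadrant-gating accepted droplets therefore yields: double-positive
(wild type), reference-only (NHEJ mutant), double-negative (empty).
Copies per reaction follow the exclusion-Poisson estimator

```
copies / 20 µL = −ln(1 − p) × 20,000 / 0.85
```

where 20,000 nL is the reaction volume and 0.85 nL the droplet volume.
For the wild type, *p* = double-positives / all droplets. For the mutant,
**p = NHEJ droplets / (NHEJ + empty droplets)** — wild-type droplets are
excluded from the denominator because an indistinguishable subpopulation
of them also co-encapsulates mutant templates. 95% CIs are Wilson score
intervals on *p* pushed through the monotone copies(*p*) map
(Clopper–Pearson available).

On top of this the package provides: a droplet simulator with known
ground truth (Poisson loading, cluster-structured amplitude noise,
optional "rain"); genotype calling (wild-type / mono-allelic /
bi-allelic / complex) from the mutant-fraction CI; large-deletion
screening via reference-signal loss and reference-gene-normalized copy
number; the random-rehybridization expectation model for the competing
T7E1/Surveyor mismatch-nuclease assay (heteroduplex fraction
= 1 − Σfᵢ²); and a design validator built on a SantaLucia-1998
nearest-neighbor melting-temperature engine.

## Worked example

```
$ python examples/01_simulate_and_quantify.py
thresholds: ref=4128 AU, dropoff=4128 AU
quadrants: wt=9692 nhej=1655 empty=3653 anomalous=0
wild-type copies/reaction: 24443 [23937, 24955]
NHEJ copies/reaction:      8792 [8375, 9227]
mutant allele fraction:    26.5% [25.1%, 27.8%]
(true simulated loads: 24,667 wt / 8,667 mutant copies, 26% mutant)
```

A 100 ng bulk sample (≈33,333 locus copies at 6 pg gDNA per diploid
genome) with 26% of alleles edited is simulated into 15,000 droplets;
thresholds are fitted from a wild-type-only and a mutant-only control
well; both populations are then quantified absolutely, and the recovered
mutant fraction brackets the simulated truth. The other examples cover
clone genotyping (`02`), large-deletion/copy-number screening (`03`),
mismatch-assay expectations (`04`) and design validation plus candidate
enumeration (`05`).

The same workflow is scriptable from the shell:

```
dropquant simulate --wt 24667 --nhej 8667 --seed 1 --out s1.csv
dropquant quantify --well s1.csv --neg-control neg.csv --pos-control pos.csv
dropquant mismatch-expect --freqs 0.5,0.25,0.25
dropquant design-check --locus locus.fa --design design.yaml
```

Droplet files use the instrument-export CSV dialect
(`Ch1 Amplitude,Ch2 Amplitude`, one row per accepted droplet); which dye
(FAM = Ch1, HEX = Ch2) plays the reference vs drop-off role is set with
`--roles ref=HEX,dropoff=FAM`.

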