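# Methods

This note records the models implemented in dropquant, the assumptions
behind them, the defaults that matter, and the places where the design
was genuinely open and a choice had to be made.

## Droplet model and simulator

A reaction of volume `V_rxn` (default 20 µL = 20,000 nL) is partitioned
into droplets of volume `V_drop` (default 0.85 nL). Three template
species are modeled:

* `wt` — intact templates: amplify, bind both probes;
* `nhej` — templates with an indel at the drop-off probe site: amplify,
  bind only the reference probe;
* `del` — templates whose deletion removes the reference probe binding
  site or a primer site: amplify nothing.

Molecules are loaded per droplet as independent Poisson draws with mean
`λ_s = copies_s × V_drop / V_rxn` — the standard infinite-reservoir
approximation to multinomial partitioning of a fixed molecule count. At
≥10⁴ droplets the two are indistinguishable; the test suite checks the
Poisson closed form `P(occupied) = 1 − e^(−λ)` against a brute-force
multinomial assignment oracle.

Accepted droplets are a *subsample* of the reaction: `n_droplets ×
V_drop ≤ V_rxn` is enforced as an invariant (a default well of 15,000
droplets covers 12,750 of 20,000 nL). Consequently all estimators are
phrased per volume, never per droplet count: the 20,000 in the estimator
is nanoliters of reaction, and estimates do not rescale with the
accepted-droplet count except through the positive fraction itself.
Tests that operate million-droplet wells give those wells a
proportionally larger reaction volume to preserve the invariant.

Amplitudes are drawn per channel from truncated normals — negative
cluster N(1000, 150) AU, positive cluster N(8000, 400) AU by default.
These values only emulate the look of a typical 2-D droplet plot; they
carry no scientific weight, are fully configurable, and are deliberately
not tuned to mimic any particular instrument run. "Rain" (droplets with
intermediate fluorescence) is modeled, when enabled, by replacing a
positive droplet's amplitude with a uniform draw between the cluster
means with probability `rain_prob` (default 0). Droplets containing both
mutant and wild-type templates are emitted as double-positive — they are
physically indistinguishable from pure wild-type droplets, which is
exactly why the mutant estimator excludes the wild-type quadrant.

What the simulator does *not* model: PCR efficiency and partial
amplification, droplet volume variation, double encapsulation optics,
dye cross-talk/compensation. Passing tests therefore demonstrate the
statistics of molecular counting under ideal chemistry, not robustness
to instrument artifacts.

## Gating

Thresholds come from two control wells — wild-type-only (negative) and
mutant-only (positive). Per channel, droplets from both controls are
pooled and split into two classes by exact 1-D two-means (sorted-scan
SSE minimization; deterministic, ties at the smallest split index). The
cut is the midpoint between `mean_neg + 3σ_neg` and `mean_pos − 3σ_pos`;
overlapping guard bands raise an "inseparable clusters" error carrying
both spans. The 3σ-midpoint rule was chosen for being deterministic and
auditable; with well-separated clusters the exact placement is
immaterial — the suite verifies that shifting both cuts by ±20% of the
inter-cluster gap moves copy estimates by less than 1%.

Drop-off-positive/reference-negative droplets are chemically implausible
(an intact drop-off site implies an intact reference site), so they are
tallied as `n_anomalous`, reported, and excluded from every estimator.

## Quantification

Point estimates use `copies = −ln(1 − p) × V_rxn / V_drop` with the
population-specific `p` described in the README. Degenerate inputs are
errors, not numbers: `p = 1` (saturated well) and an empty denominator
both raise.

Confidence intervals: the 95% Wilson score interval on the droplet
proportion, transformed through the monotone copies(`p`) map so the
endpoint transform is exact. Wilson was chosen because it is
well-behaved at `k = 0` (lower bound exactly 0) and matches common
digital-PCR practice; Clopper–Pearson is available via
`method="clopper-pearson"` for users who want guaranteed-conservative
coverage. The provenance field of every output records which rule was
used. Measured coverage at the suite's operating point (500 copies,
15,000 droplets, 1,000 simulated wells) is within 95% ± 2%.

The mutant **fraction** CI is propagated conservatively by interval
arithmetic — lower bound pairs the mutant lower bound with the wild-type
upper bound, and vice versa. This overstates the interval slightly but
never understates it, which is the right failure mode for genotype
calling. Ratios (deletion screen, copy number) propagate the same way.

Technical replicates are pooled by summing quadrant counts before
estimation; pooling narrows the interval on rare targets and is how the
suite exercises the estimator at the 10⁶-droplet scale (8 pooled
replicate wells).

## Interpretation rules

**Genotype calls** from the mutant-fraction CI: `wild_type` if the CI
lies entirely below 0.05; `bi_allelic` if entirely above 0.95;
`mono_allelic` if the CI contains 0.5 and fits inside [0.2, 0.8];
anything else is `complex`. These cut-offs are a package choice, set
conservatively for diploid loci so that aneuploid or mixed populations
route to `complex` rather than being mis-called; all four numbers are
configurable. At a 5 ng input (≈1,667 locus copies) the suite verifies
≥99% correct calls for true fractions 0 / 0.5 / 1.0 over 500 replicates
each. There is no principled universal rule for calling, say, a
triploid locus with one edited allele; `complex` plus the reported CI is
the honest output there.

**Large deletions**: the clone/wild-type reference-copy ratio, with a
`large_deletion_suspected` flag raised when the ratio CI excludes 1 and
contains `k/ploidy` for some integer `k < ploidy`. An integer-ratio
consistency test generalizes the diploid 50%/0% picture to aneuploid
lines. Copy number is `ploidy × target/reference` against a
known-ploidy reference locus assay (RPP30-style, 2 copies/genome).

**Dilution series**: expected copies scale linearly from the copies
measured by ddPCR in 100 ng of the mutant stock — not from mass/6 pg
arithmetic — so stocks that have lost a target allele are handled
correctly; an optional load multiplier covers designs that deliberately
load a multiple of the nominal mass. Mass↔genome reasoning (6 pg per
diploid cell) is provided separately for limit-of-detection thinking.

**Efficiency comparisons** between editing strategies use a two-sided
Welch t-test on per-experiment mutant fractions. Two zero-variance
groups make the Welch statistic 0/0; this is defined as p = 1 when the
means are equal and p = 0 otherwise.

## Sensitivity: what the simulation shows

With ~6.7 mutant copies (a 20 pg gDNA equivalent) spiked into 100 ng of
wild-type background (λ_wt ≈ 1.42), only `e^(−λ_wt)` ≈ 24% of droplets
are free of wild-type template, so a mutant molecule produces a
*classifiable* NHEJ-quadrant droplet with probability
0.6375 (accepted-volume fraction) × 0.2425 ≈ 0.155, and at least one
such droplet appears in ≈67% of 15,000-droplet wells — not in ~100%, as
one might expect by counting mutant molecules alone. Co-encapsulation
with wild type is the binding constraint on single-well sensitivity at
high backgrounds, and pooling technical replicates is the remedy. The
converse is clean: with zero mutant copies and rain off, no NHEJ
droplets appear at all, so a single observed NHEJ droplet is meaningful.

## Mismatch-nuclease expectation model

Re-annealing after PCR is modeled as drawing ordered strand pairs with
replacement from the allele spectrum (infinite-molecule limit):
homoduplex fraction `Σ fᵢ²`, expected cleavable heteroduplex fraction
`1 − Σ fᵢ²`. Two idealizations are deliberate: all distinct allele
pairs are assumed mutually cleavable, and cleavage is assumed complete.
The model computes *expectations*; real gels under-detect because
digestion is incomplete and each fragment retains only its
length-proportional share of intercalating-stain signal (an equal
bisection halves the signal per band — `fragment_signal_fractions`
quantifies this). Detected percent digested from densitometry is
`100 × Σ digested / (parent + Σ digested)`.

## Melting temperatures and design rules

`tm_nn` implements the unified SantaLucia-1998 nearest-neighbor
ΔH°/ΔS° sums with initiation terms, the symmetry entropy correction for
self-complementary oligos (auto-detected, with `C_T` replacing `C_T/4`
in the concentration term), the SantaLucia entropy salt correction
`ΔS + 0.368 (N−1) ln[Na⁺_eq]`, and a divalent-to-monovalent conversion
`Na_eq = monovalent + 120·√(divalent − dNTP)` (mM). Defaults are the
assay buffer: 50 mM monovalent, 3 mM divalent, 0 mM dNTPs; oligo
concentrations default to 900 nM (primers) and 250 nM (probes). The
exact divalent pathway of any given design tool is approximate-by-nature,
which is why the rule table's Tm bands are ±2 °C (±1 °C around the
56–57 °C drop-off window). The engine is cross-checked in the tests
against an independent nearest-neighbor summation (Biopython's, with
matched conventions) to <0.1 °C.

A practical caveat the validator makes visible: on high-GC targets,
oligos of workable length cannot reach the generic 55/60/56–57 °C
targets — they melt several degrees higher under this buffer. The rule
table therefore tolerates above-band Tm when the amplicon GC exceeds a
configurable threshold (default 60%), while below-band Tm is never
forgiven (a too-cold drop-off probe defeats the assay's sensitivity
mechanism).

Geometry rules use 0-based half-open coordinates throughout. The Cas9
blunt cut is placed 3 bp 5′ of the NGG PAM (between protospacer
positions 17|18 for a 20-mer); a TALEN cut at the spacer midpoint. The
rule table: cut inside the drop-off probe within 3 bp of its center
(Cas9) or spacer ≤20 bp and covered by the probe (TALEN); 75–125 bp
from the cut to each primer 3′ end; reference probe ≥30 bp from the cut
and no oligo overlapping the drop-off interval; Tm bands as above;
no SNP inside any binding site; drop-off Tm strictly below reference
Tm. Internal quenchers are treated as annotations with no thermodynamic
contribution. Candidate enumeration is an exhaustive window scan per
role (best few per role combined and re-vetted through the full rule
table), ranked by total |Tm − target| deviation with position
tie-breaks, so results are deterministic. TALEN repeat-variable-diresidue
efficiency is not scored — there is no predictive model to implement —
but G-content of binding sites is computable for annotation.

## Problem sizes and determinism

Simulation-based checks run at the assay's native scale: 15,000 accepted
droplets per well, 200–1,000 replicate wells for coverage and recovery
studies, and 8 pooled 10⁶-droplet wells for the estimator-consistency
check — sizes chosen so each study's Monte-Carlo error is several times
smaller than the tolerance it checks. Every random draw flows through
a seeded generator; per-well seeds derive deterministically (SHA-256)
from a run seed and the well id, so identical configurations reproduce
outputs byte-for-byte, and every results file carries a config hash.

## Known limitations

* Amplitude clusters are parametric and idealized; no rain-aware
  gating is attempted (quadrant cuts only), which is adequate when rain
  is rare but not for heavily degraded samples.
* The mutant-fraction and ratio CIs are conservative (interval
  arithmetic), not exact profile intervals.
* The Tm engine targets hydrolysis-probe/primer length oligos (8–40 nt)
  and does not model secondary structure, hairpins, dangling ends or
  mismatch thermodynamics.
* Genotype cut-offs assume a diploid locus; aneuploidy is surfaced as
  `complex` rather than resolved.
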