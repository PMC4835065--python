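"""Biological interpretation of copy estimates.

Turns quantification output into the calls an editing screen needs:

* clone genotype (wild type / mono-allelic / bi-allelic / complex) from
  the mutant allele fraction and its CI;
* large-deletion screening from loss of reference-channel signal, and
  reference-gene-normalized copy number (e.g. target vs RPP30);
* dilution-series bookkeeping (expected copies from a calibrated stock);
* between-condition editing-efficiency comparison (Welch t-test).

The genotype cut-offs are a package design choice, deliberately
conservative for diploid loci: anything ambiguous (aneuploid karyotypes,
partial populations) routes to ``complex`` rather than being mis-called.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import UndefinedEstimateError, ValidationError
from .quantify import CopyEstimate, MutantFraction

__all__ = [
    "GenotypeCutoffs",
    "CloneGenotype",
    "call_genotype",
    "DeletionScreen",
    "deletion_screen",
    "CopyNumberResult",
    "copy_number",
    "expected_dilution_copies",
    "DilutionPoint",
    "make_dilution_point",
    "mass_to_genomes",
    "genome_equivalents_to_copies",
    "percent",
    "EfficiencyComparison",
    "compare_efficiency",
]


@dataclass(frozen=True)
class GenotypeCutoffs:
    """Decision boundaries for diploid genotype calls (all on the fraction scale)."""

    wt_max: float = 0.05
    bi_min: float = 0.95
    mono_low: float = 0.2
    mono_high: float = 0.8


@dataclass(frozen=True)
class CloneGenotype:
    call: str  # wild_type | mono_allelic | bi_allelic | complex
    fraction: MutantFraction
    large_deletion_suspected: bool = False


def call_genotype(
    frac: MutantFraction, cutoffs: GenotypeCutoffs = GenotypeCutoffs()
) -> CloneGenotype:
    """Call a clone's genotype from its mutant-fraction CI.

    wild_type if the CI lies entirely below ``wt_max``; bi_allelic if
    entirely above ``bi_min``; mono_allelic if the CI contains 0.5 and
    fits inside [``mono_low``, ``mono_high``]; otherwise complex.
    """
    if frac.ci_high < cutoffs.wt_max:
        call = "wild_type"
    elif frac.ci_low > cutoffs.bi_min:
        call = "bi_allelic"
    elif (
        frac.ci_low <= 0.5 <= frac.ci_high
        and frac.ci_low >= cutoffs.mono_low
        and frac.ci_high <= cutoffs.mono_high
    ):
        call = "mono_allelic"
    else:
        call = "complex"
    return CloneGenotype(call=call, fraction=frac)


def _ratio_ci(num: CopyEstimate, den: CopyEstimate) -> tuple[float, float, float]:
    if den.copies == 0.0:
        raise UndefinedEstimateError("denominator estimate is zero; ratio undefined")
    ratio = num.copies / den.copies
    low = 0.0 if math.isinf(den.ci_high) else num.ci_low / den.ci_high
    high = math.inf if den.ci_low == 0.0 else num.ci_high / den.ci_low
    return ratio, low, high


@dataclass(frozen=True)
class DeletionScreen:
    """Reference-signal ratio clone/wild-type with a deletion flag.

    A heterozygous deletion removing the reference amplicon halves the
    reference copies; a bi-allelic deletion abolishes them.  The flag is
    raised when the ratio CI excludes 1 and is consistent with k intact of
    ``ploidy`` alleles for some integer k < ploidy, which generalizes the
    50%/0% diploid picture to aneuploid lines.
    """

    ratio: float
    ci_low: float
    ci_high: float
    ploidy: int
    large_deletion_suspected: bool


def deletion_screen(
    clone_ref: CopyEstimate, wt_ref: CopyEstimate, ploidy: int = 2
) -> DeletionScreen:
    if ploidy < 1:
        raise ValidationError("must be >= 1", field="ploidy")
    ratio, low, high = _ratio_ci(clone_ref, wt_ref)
    excludes_one = high < 1.0 or low > 1.0
    integer_consistent = any(
        low <= k / ploidy <= high for k in range(ploidy)
    )
    return DeletionScreen(
        ratio=ratio,
        ci_low=low,
        ci_high=high,
        ploidy=ploidy,
        large_deletion_suspected=excludes_one and integer_consistent,
    )


@dataclass(frozen=True)
class CopyNumberResult:
    cn: float
    ci_low: float
    ci_high: float
    target: CopyEstimate
    reference: CopyEstimate
    reference_ploidy: int


def copy_number(
    target: CopyEstimate, reference: CopyEstimate, reference_ploidy: int = 2
) -> CopyNumberResult:
    """Copies per genome: ``reference_ploidy * target / reference``.

    The reference assay targets a locus of known ploidy (canonically
    RPP30, two copies per diploid genome) run on the same sample.
    """
    if reference_ploidy < 1:
        raise ValidationError("must be >= 1", field="reference_ploidy")
    ratio, low, high = _ratio_ci(target, reference)
    return CopyNumberResult(
        cn=reference_ploidy * ratio,
        ci_low=reference_ploidy * low,
        ci_high=reference_ploidy * high,
        target=target,
        reference=reference,
        reference_ploidy=reference_ploidy,
    )


def expected_dilution_copies(
    mass_loaded_ng: float,
    stock_copies_per_100ng: float,
    load_multiplier: float = 1.0,
) -> float:
    """Expected copies at a dilution point, scaled linearly from a ddPCR-calibrated stock.

    Calibration is against the copies *measured* in 100 ng of the mutant
    stock -- not mass/6 pg arithmetic -- so samples that have lost target
    alleles are handled correctly.  ``load_multiplier`` covers designs
    that deliberately load a multiple of the nominal mass (e.g. doubling
    the mutant input when one target copy is absent from the stock).
    """
    if mass_loaded_ng < 0:
        raise ValidationError("must be >= 0", field="mass_loaded_ng")
    if stock_copies_per_100ng < 0:
        raise ValidationError("must be >= 0", field="stock_copies_per_100ng")
    return stock_copies_per_100ng * mass_loaded_ng * load_multiplier / 100.0


@dataclass(frozen=True)
class DilutionPoint:
    mutant_mass_loaded_pg: float
    expected_copies: float
    measured: CopyEstimate
    covered: bool


def make_dilution_point(
    mass_loaded_pg: float,
    stock_copies_per_100ng: float,
    measured: CopyEstimate,
    load_multiplier: float = 1.0,
) -> DilutionPoint:
    expected = expected_dilution_copies(
        mass_loaded_pg / 1000.0, stock_copies_per_100ng, load_multiplier
    )
    return DilutionPoint(
        mutant_mass_loaded_pg=mass_loaded_pg,
        expected_copies=expected,
        measured=measured,
        covered=measured.ci_low <= expected <= measured.ci_high,
    )


def mass_to_genomes(mass_pg: float, pg_per_diploid_cell: float = 6.0) -> float:
    """Diploid genome equivalents in ``mass_pg`` of gDNA (~6 pg per diploid human cell)."""
    if mass_pg < 0:
        raise ValidationError("must be >= 0", field="mass_pg")
    if pg_per_diploid_cell <= 0:
        raise ValidationError("must be > 0", field="pg_per_diploid_cell")
    return mass_pg / pg_per_diploid_cell


def genome_equivalents_to_copies(genomes: float, copies_per_genome: int = 2) -> float:
    """Copies of a locus present at ``copies_per_genome`` per diploid genome."""
    return genomes * copies_per_genome


def percent(part: float, whole: float) -> float:
    """100 * part / whole, e.g. spike-in mass fractions (units must match)."""
    if whole <= 0:
        raise ValidationError("must be > 0", field="whole")
    return 100.0 * part / whole


@dataclass(frozen=True)
class EfficiencyComparison:
    mean_a: float
    mean_b: float
    t: float
    p_value: float


def compare_efficiency(
    condition_a: list[float], condition_b: list[float]
) -> EfficiencyComparison:
    """Welch two-sided t-test on per-experiment mutant fractions.

    Supporting plumbing for comparing editing strategies (e.g. TALEN
    repeat-variable-diresidue choices) across independent experiments.
    Degenerate zero-variance groups are defined as p=1 when the means are
    equal and p=0 otherwise.
    """
    a = np.asarray(condition_a, dtype=float)
    b = np.asarray(condition_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError(
            "need >= 2 observations per condition for a t-test", field="condition"
        )
    if a.std() == 0.0 and b.std() == 0.0:
        equal = a.mean() == b.mean()
        return EfficiencyComparison(
            mean_a=float(a.mean()),
            mean_b=float(b.mean()),
            t=0.0 if equal else math.inf,
            p_value=1.0 if equal else 0.0,
        )
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return EfficiencyComparison(
        mean_a=float(a.mean()), mean_b=float(b.mean()), t=float(t), p_value=float(p)
    )
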