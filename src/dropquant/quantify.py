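"""Absolute quantification from quadrant counts.

The estimator is the exclusion-Poisson formula

    copies per reaction = -ln(1 - p) * V_reaction / V_droplet

with V_reaction = 20,000 nL and V_droplet = 0.85 nL by default.  The
positive fraction ``p`` depends on the population being quantified:

* wild type: p = double-positive droplets / all accepted droplets (all
  other droplets are treated as negative);
* NHEJ mutant: p = NHEJ droplets / (NHEJ + empty droplets).  Wild-type
  droplets are *excluded* from the denominator because an
  indistinguishable subpopulation of them also contains mutant templates;
  including them would bias the mutant estimate downward as the wild-type
  load grows.

Confidence intervals are Wilson score intervals on ``p`` (Clopper-Pearson
available as an option) pushed through the monotone copies(p) map, which
makes the endpoint transform exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from statsmodels.stats.proportion import proportion_confint

from .core import ReactionGeometry
from .errors import SaturatedWellError, UndefinedEstimateError, ValidationError
from .gating import ClusterCounts

__all__ = [
    "CopyEstimate",
    "MutantFraction",
    "ci_from_counts",
    "quantify_wt",
    "quantify_nhej",
    "quantify_reference",
    "mutant_fraction",
]

_CI_METHODS = {"wilson": "wilson", "clopper-pearson": "beta"}


@dataclass(frozen=True)
class CopyEstimate:
    """Copies per reaction with a 95% CI and the underlying occupancy."""

    copies: float
    ci_low: float
    ci_high: float
    lam: float
    p: float
    k: int
    n: int
    reaction_volume_nl: float = 20000.0
    droplet_volume_nl: float = 0.85

    def __post_init__(self):
        if not 0.0 <= self.ci_low <= self.copies <= self.ci_high:
            raise ValidationError(
                f"CI [{self.ci_low}, {self.ci_high}] must bracket the estimate {self.copies}",
                field="ci",
            )


def ci_from_counts(
    k: int,
    n: int,
    geometry: ReactionGeometry = ReactionGeometry(),
    method: str = "wilson",
) -> tuple[float, float]:
    """95% CI on copies per reaction from ``k`` positives among ``n`` droplets.

    The interval is computed on the binomial proportion and transformed
    through ``copies(p) = -ln(1-p) * V_rxn / V_drop``; monotonicity makes
    the endpoint transform valid.  ``k == n`` yields an infinite upper
    bound (the well is saturated).
    """
    if method not in _CI_METHODS:
        raise ValidationError(f"unknown CI method {method!r}", field="method")
    if k < 0 or n <= 0 or k > n:
        raise ValidationError(f"need 0 <= k <= n, got k={k}, n={n}", field="k")
    p_lo, p_hi = proportion_confint(k, n, alpha=0.05, method=_CI_METHODS[method])
    p_lo = 0.0 if k == 0 else min(max(float(p_lo), 0.0), k / n)  # clamp float noise
    p_hi = max(float(p_hi), k / n)
    low = geometry.copies_from_p(p_lo)
    high = geometry.copies_from_p(p_hi) if p_hi < 1.0 else math.inf
    return low, high


def _estimate(
    k: int, n: int, geometry: ReactionGeometry, method: str
) -> CopyEstimate:
    p = k / n
    if p >= 1.0:
        raise SaturatedWellError(
            f"all {n} denominator droplets are positive; lambda is undefined"
        )
    low, high = ci_from_counts(k, n, geometry, method=method)
    lam = -math.log1p(-p)
    return CopyEstimate(
        copies=geometry.copies_from_p(p),
        ci_low=low,
        ci_high=high,
        lam=lam,
        p=p,
        k=k,
        n=n,
        reaction_volume_nl=geometry.reaction_volume_nl,
        droplet_volume_nl=geometry.droplet_volume_nl,
    )


def quantify_wt(
    counts: ClusterCounts,
    geometry: ReactionGeometry = ReactionGeometry(),
    method: str = "wilson",
) -> CopyEstimate:
    """Wild-type copies: double-positive droplets against all accepted droplets."""
    return _estimate(counts.n_wt, counts.n_accepted, geometry, method)


def quantify_nhej(
    counts: ClusterCounts,
    geometry: ReactionGeometry = ReactionGeometry(),
    method: str = "wilson",
) -> CopyEstimate:
    """Mutant (NHEJ) copies with wild-type droplets excluded from the denominator."""
    denom = counts.n_nhej + counts.n_empty
    if denom == 0:
        raise UndefinedEstimateError(
            "no NHEJ or empty droplets; the mutant estimate is undefined"
        )
    return _estimate(counts.n_nhej, denom, geometry, method)


def quantify_reference(
    counts: ClusterCounts,
    geometry: ReactionGeometry = ReactionGeometry(),
    method: str = "wilson",
) -> CopyEstimate:
    """Total amplifiable copies: every reference-positive droplet counts.

    This is the quantity compared between clones in the large-deletion
    screen: deletions removing the reference probe or a primer site lower
    it in proportion to the number of deleted alleles.
    """
    return _estimate(counts.n_wt + counts.n_nhej, counts.n_accepted, geometry, method)


@dataclass(frozen=True)
class MutantFraction:
    """Mutant allele fraction with a conservative 95% CI."""

    fraction: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not 0.0 <= self.ci_low <= self.fraction <= self.ci_high <= 1.0:
            raise ValidationError(
                f"CI [{self.ci_low}, {self.ci_high}] must bracket {self.fraction} within [0,1]",
                field="ci",
            )


def mutant_fraction(nhej: CopyEstimate, wt: CopyEstimate) -> MutantFraction:
    """Mutant fraction nhej / (nhej + wt) with interval-arithmetic CI.

    The CI propagates the two Wilson intervals conservatively: the lower
    bound pairs the mutant lower bound with the wild-type upper bound and
    vice versa.  Conservative by construction (coverage >= nominal).
    """
    total = nhej.copies + wt.copies
    if total == 0.0:
        raise UndefinedEstimateError("both copy estimates are zero; fraction undefined")
    frac = nhej.copies / total
    lo_den = nhej.ci_low + wt.ci_high
    low = 0.0 if (lo_den == 0.0 or math.isinf(wt.ci_high)) else nhej.ci_low / lo_den
    if math.isinf(nhej.ci_high):
        high = 1.0
    else:
        hi_den = nhej.ci_high + wt.ci_low
        high = 1.0 if hi_den == 0.0 else nhej.ci_high / hi_den
    return MutantFraction(fraction=frac, ci_low=min(low, frac), ci_high=max(high, frac))
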