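"""Expectation model for mismatch-nuclease (T7E1/Surveyor) assays.

After PCR, denatured amplicons re-anneal at random; duplexes formed from
two different alleles carry mismatches and are cleaved by the nuclease,
while homoduplexes are not.  Under random re-hybridization in the
infinite-molecule limit, the homoduplex fraction is the probability that
two independently drawn strands carry the same allele, ``sum(f_i^2)``, so
the expected cleavable fraction is ``1 - sum(f_i^2)``.

The model is the idealization used to compute *expected* percent digested:
heteroduplexes are assumed fully cleaved, homoduplexes untouched, and any
two distinct alleles are assumed mutually cleavable.  Enzyme inefficiency
and gel detection limits are deliberately out of model; the companion
function :func:`detected_percent_digested` scores what a gel actually
shows from band densitometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "AlleleSpectrum",
    "expected_homoduplex_fraction",
    "expected_heteroduplex_fraction",
    "GelLane",
    "detected_percent_digested",
    "fragment_signal_fractions",
]


@dataclass(frozen=True)
class AlleleSpectrum:
    """Allele frequencies at the edited locus; must sum to 1."""

    frequencies: tuple

    def __post_init__(self):
        freqs = tuple(float(f) for f in self.frequencies)
        object.__setattr__(self, "frequencies", freqs)
        if len(freqs) < 1:
            raise ValidationError("need at least one allele", field="frequencies")
        if any(f < 0 for f in freqs):
            raise ValidationError("frequencies must be >= 0", field="frequencies")
        if abs(sum(freqs) - 1.0) > 1e-9:
            raise ValidationError(
                f"frequencies sum to {sum(freqs)}, not 1", field="frequencies"
            )


def _spectrum(spec) -> AlleleSpectrum:
    return spec if isinstance(spec, AlleleSpectrum) else AlleleSpectrum(tuple(spec))


def expected_homoduplex_fraction(spec) -> float:
    """P(two random strands carry the same allele) = sum of squared frequencies."""
    s = _spectrum(spec)
    return float(sum(f * f for f in s.frequencies))


def expected_heteroduplex_fraction(spec) -> float:
    """Expected cleavable (mismatched) duplex fraction: 1 - sum(f_i^2).

    E.g. a clone with one wild-type and two distinct mutant alleles at
    (0.50, 0.25, 0.25) yields homoduplexes at 0.25 + 0.0625 + 0.0625 =
    37.5%, hence 62.5% heteroduplex.
    """
    return 1.0 - expected_homoduplex_fraction(spec)


@dataclass(frozen=True)
class GelLane:
    """Band densitometry for one lane: undigested parent plus digested fragments."""

    parent_intensity: float
    digested_intensities: tuple = ()

    def __post_init__(self):
        dig = tuple(float(x) for x in self.digested_intensities)
        object.__setattr__(self, "digested_intensities", dig)
        if self.parent_intensity < 0 or any(x < 0 for x in dig):
            raise ValidationError("band intensities must be >= 0", field="intensities")


def detected_percent_digested(lane: GelLane) -> float:
    """Percent digested as read off the gel: 100 * sum(digested) / sum(all bands)."""
    total = lane.parent_intensity + sum(lane.digested_intensities)
    if total == 0.0:
        raise ValidationError("all band intensities are zero", field="intensities")
    return 100.0 * sum(lane.digested_intensities) / total


def fragment_signal_fractions(fragment_lengths) -> np.ndarray:
    """Fraction of the parent band's stain signal carried by each fragment.

    Intercalating stains bind in proportion to fragment length, so a
    fragment of length l from a parent of length L retains l/L of the
    parent's signal -- an equal bisection leaves each fragment with only
    50%, the floor on signal loss for any single cut.
    """
    lengths = np.asarray(list(fragment_lengths), dtype=float)
    if lengths.size == 0 or np.any(lengths <= 0):
        raise ValidationError("fragment lengths must be positive", field="fragment_lengths")
    return lengths / lengths.sum()
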