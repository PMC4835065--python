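"""Threshold fitting and quadrant gating.

Thresholds are derived from control wells -- a negative control containing
wild-type template only and a positive control containing mutant template
only -- and then applied unchanged to every sample well, mirroring standard
drop-off assay practice.  Gating is plain quadrant classification; with
well-separated clusters the user's exact threshold choice has a negligible
effect on quantification, so nothing fancier is warranted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DropletWell
from .errors import InseparableClustersError, ValidationError

__all__ = ["Thresholds", "ClusterCounts", "fit_thresholds", "classify", "pool_wells"]


@dataclass(frozen=True)
class Thresholds:
    """Per-channel amplitude cuts (AU) with a provenance note."""

    ref_cut: float
    dropoff_cut: float
    provenance: str = ""

    def __post_init__(self):
        if not self.ref_cut > 0:
            raise ValidationError("must be > 0", field="ref_cut")
        if not self.dropoff_cut > 0:
            raise ValidationError("must be > 0", field="dropoff_cut")


@dataclass(frozen=True)
class ClusterCounts:
    """Droplet tallies in the four quadrants.

    * ``n_wt``: double-positive (wild-type amplicon; may co-encapsulate
      mutant templates);
    * ``n_nhej``: reference-positive / drop-off-negative (mutant amplicon);
    * ``n_empty``: double-negative;
    * ``n_anomalous``: drop-off-positive / reference-negative -- chemically
      implausible, reported but excluded from every estimator.
    """

    n_wt: int
    n_nhej: int
    n_empty: int
    n_anomalous: int = 0

    def __post_init__(self):
        for f in ("n_wt", "n_nhej", "n_empty", "n_anomalous"):
            if getattr(self, f) < 0:
                raise ValidationError("count must be >= 0", field=f)

    @property
    def n_accepted(self) -> int:
        return self.n_wt + self.n_nhej + self.n_empty + self.n_anomalous


def _two_class_split(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact 1-D two-means split: partition sorted values minimizing within-class SSE.

    Deterministic (ties broken at the smallest split index); returns the
    (lower, upper) classes.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 2:
        raise ValidationError("need >= 2 droplets to split clusters", field="amplitudes")
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    k = np.arange(1, n)  # lower class = x[:k]
    sse_lo = csq[k - 1] - csum[k - 1] ** 2 / k
    sum_hi = csum[-1] - csum[k - 1]
    sq_hi = csq[-1] - csq[k - 1]
    sse_hi = sq_hi - sum_hi**2 / (n - k)
    best = int(np.argmin(sse_lo + sse_hi)) + 1
    return x[:best], x[best:]


def _fit_cut(channel: str, values: np.ndarray) -> float:
    lo, hi = _two_class_split(values)
    lo_top = float(lo.mean() + 3.0 * lo.std())
    hi_bot = float(hi.mean() - 3.0 * hi.std())
    if lo_top >= hi_bot:
        raise InseparableClustersError(
            channel,
            neg_span=(float(lo.mean() - 3.0 * lo.std()), lo_top),
            pos_span=(hi_bot, float(hi.mean() + 3.0 * hi.std())),
        )
    return 0.5 * (lo_top + hi_bot)


def fit_thresholds(neg_control: DropletWell, pos_control: DropletWell) -> Thresholds:
    """Derive per-channel cuts from a wild-type-only and a mutant-only well.

    Per channel, droplets from both controls are pooled and split into two
    classes (exact 1-D two-means); the cut is placed midway between the
    negative cluster's mean + 3 SD and the positive cluster's mean - 3 SD.
    Overlapping 3-sigma guard bands raise
    :class:`~dropquant.errors.InseparableClustersError`.
    """
    ref = np.concatenate([neg_control.ref, pos_control.ref])
    do = np.concatenate([neg_control.dropoff, pos_control.dropoff])
    return Thresholds(
        ref_cut=_fit_cut("reference", ref),
        dropoff_cut=_fit_cut("dropoff", do),
        provenance=(
            "midpoint of 3-sigma guard bands; controls: "
            f"neg={neg_control.well_id}, pos={pos_control.well_id}"
        ),
    )


def classify(well: DropletWell, th: Thresholds) -> ClusterCounts:
    """Quadrant-gate a well: each droplet is compared to each channel's cut."""
    ref_pos = well.ref > th.ref_cut
    do_pos = well.dropoff > th.dropoff_cut
    return ClusterCounts(
        n_wt=int(np.sum(ref_pos & do_pos)),
        n_nhej=int(np.sum(ref_pos & ~do_pos)),
        n_empty=int(np.sum(~ref_pos & ~do_pos)),
        n_anomalous=int(np.sum(~ref_pos & do_pos)),
    )


def pool_wells(counts: list[ClusterCounts]) -> ClusterCounts:
    """Element-wise sum of technical replicates for pooled quantification.

    Pooling increases the droplet denominator, narrowing the Poisson
    confidence interval on rare targets.
    """
    if not counts:
        raise ValidationError("no wells to pool", field="counts")
    return ClusterCounts(
        n_wt=sum(c.n_wt for c in counts),
        n_nhej=sum(c.n_nhej for c in counts),
        n_empty=sum(c.n_empty for c in counts),
        n_anomalous=sum(c.n_anomalous for c in counts),
    )
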