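"""Core containers shared across the toolkit.

A droplet digital PCR (ddPCR) reaction is partitioned into ~0.85 nL
droplets; each accepted droplet is read in two fluorescence channels.  In a
drop-off assay one probe (the *reference* probe) binds away from the
nuclease cut site and lights up for every amplifiable template, while the
*drop-off* probe spans the cut site and loses signal when an indel disrupts
its binding site.  The containers here carry per-droplet amplitudes plus
the reaction geometry needed to turn droplet counts into absolute copies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: QX200 convention: FAM is read in channel 1, HEX in channel 2.
DYE_TO_CHANNEL = {"FAM": "Ch1", "HEX": "Ch2"}
DEFAULT_CHANNEL_ROLES = {"ref": "Ch1", "dropoff": "Ch2"}


@dataclass(frozen=True)
class ReactionGeometry:
    """Volumes linking droplet occupancy to copies per reaction.

    The canonical QX200 setup partitions a 20 uL (20,000 nL) reaction into
    0.85 nL droplets; ``copies = -ln(1-p) * reaction_volume_nl /
    droplet_volume_nl``.  Note the 20,000 constant is a volume in nL, not a
    droplet count: accepted droplets usually cover only part of the
    reaction volume, and the estimator is phrased per volume so it does not
    rescale with the accepted-droplet count except through p.
    """

    droplet_volume_nl: float = 0.85
    reaction_volume_nl: float = 20000.0

    def __post_init__(self):
        if not self.droplet_volume_nl > 0:
            raise ValidationError("must be > 0", field="droplet_volume_nl")
        if not self.reaction_volume_nl > 0:
            raise ValidationError("must be > 0", field="reaction_volume_nl")

    @property
    def scale(self) -> float:
        """Copies per reaction per unit of lambda."""
        return self.reaction_volume_nl / self.droplet_volume_nl

    def copies_from_p(self, p: float) -> float:
        """Exclusion-Poisson point estimate: ``-ln(1-p) * V_rxn / V_drop``."""
        if not 0.0 <= p < 1.0:
            raise ValidationError(f"positive fraction p={p} must lie in [0, 1)", field="p")
        return -math.log1p(-p) * self.scale


@dataclass
class WellTruth:
    """Simulator ground truth: molecules of each species per droplet."""

    wt: np.ndarray
    nhej: np.ndarray
    dele: np.ndarray

    def quadrant_counts(self):
        """True quadrant occupancy, independent of amplitude gating.

        Reference channel is positive iff the droplet holds >=1 intact (wt)
        or drop-off-disrupted (nhej) template; the drop-off channel iff it
        holds >=1 intact template.  Deletion templates amplify nothing.
        """
        from .gating import ClusterCounts  # local import avoids a cycle

        ref_pos = (self.wt + self.nhej) > 0
        do_pos = self.wt > 0
        return ClusterCounts(
            n_wt=int(np.sum(ref_pos & do_pos)),
            n_nhej=int(np.sum(ref_pos & ~do_pos)),
            n_empty=int(np.sum(~ref_pos & ~do_pos)),
            n_anomalous=int(np.sum(~ref_pos & do_pos)),
        )


@dataclass
class DropletWell:
    """Two-channel amplitudes for the accepted droplets of one well.

    ``ref`` and ``dropoff`` are role-ordered vectors (arbitrary
    fluorescence units); ``channel_roles`` records which physical channel
    (Ch1 = FAM, Ch2 = HEX) plays each role, because assays are free to swap
    fluorophores between the reference and drop-off probes.
    """

    well_id: str
    ref: np.ndarray
    dropoff: np.ndarray
    channel_roles: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_ROLES))
    truth: WellTruth | None = None

    def __post_init__(self):
        self.ref = np.asarray(self.ref, dtype=float)
        self.dropoff = np.asarray(self.dropoff, dtype=float)
        if self.ref.ndim != 1 or self.dropoff.ndim != 1:
            raise ValidationError("amplitude vectors must be 1-D", field="amplitudes")
        if len(self.ref) != len(self.dropoff):
            raise ValidationError(
                f"channel lengths differ ({len(self.ref)} vs {len(self.dropoff)})",
                field="amplitudes",
            )
        if len(self.ref) == 0:
            raise ValidationError("well contains no droplets", field="amplitudes")
        for name, arr in (("ref", self.ref), ("dropoff", self.dropoff)):
            if not np.all(np.isfinite(arr)):
                raise ValidationError("amplitudes must be finite", field=name)
            if np.any(arr < 0):
                raise ValidationError("amplitudes must be >= 0", field=name)

    @property
    def n_accepted(self) -> int:
        return len(self.ref)
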