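"""Synthetic droplet generator with known ground truth.

Emulates Poisson partitioning of three template species into droplets:

* ``wt``   -- intact templates: positive in both channels;
* ``nhej`` -- templates with an indel disrupting the drop-off probe site
  but an intact reference site: reference-positive only;
* ``del``  -- templates whose deletion removes the reference probe or a
  primer binding site: amplify nothing in either channel.

Each species' molecule count per droplet is an independent Poisson draw
with mean ``lambda_s = copies_s * droplet_volume_nl / reaction_volume_nl``
(infinite-reservoir approximation to multinomial partitioning; the
difference is negligible at >= 10^4 droplets).  Accepted droplets cover
only ``n_droplets * droplet_volume`` of the reaction, i.e. they are a
subsample of the reaction volume.

Droplets containing both mutant and wild-type templates are emitted as
double-positive, matching the chemistry: such "intermediate" droplets are
indistinguishable from pure wild-type droplets and are excluded from the
mutant estimator downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import DropletWell, WellTruth
from .errors import ValidationError

__all__ = ["ChannelAmplitudes", "AmplitudeModel", "WellSpec", "simulate_well"]


@dataclass(frozen=True)
class ChannelAmplitudes:
    """Negative/positive cluster amplitude model for one channel (AU).

    Defaults visually match typical 2-D ddPCR plots; the values carry no
    scientific weight and are freely configurable.
    """

    neg_mean: float = 1000.0
    neg_sd: float = 150.0
    pos_mean: float = 8000.0
    pos_sd: float = 400.0

    def validate(self, name: str) -> None:
        if not self.pos_mean > self.neg_mean:
            raise ValidationError(
                f"positive mean ({self.pos_mean}) must exceed negative mean ({self.neg_mean})",
                field=f"{name}.pos_mean",
            )
        if self.neg_sd < 0 or self.pos_sd < 0:
            raise ValidationError("amplitude SDs must be >= 0", field=f"{name}.sd")


@dataclass(frozen=True)
class AmplitudeModel:
    ref: ChannelAmplitudes = field(default_factory=ChannelAmplitudes)
    dropoff: ChannelAmplitudes = field(default_factory=ChannelAmplitudes)


@dataclass(frozen=True)
class WellSpec:
    """Ground-truth description of a simulated well.

    Copy loads are copies per reaction (the whole ``reaction_volume_ul``),
    not per accepted droplet set.
    """

    copies_wt: float = 0.0
    copies_nhej: float = 0.0
    copies_del: float = 0.0
    n_droplets: int = 15000
    droplet_volume_nl: float = 0.85
    reaction_volume_ul: float = 20.0
    amp_model: AmplitudeModel = field(default_factory=AmplitudeModel)
    rain_prob: float = 0.0
    seed: int | None = None
    well_id: str = "sim"

    def validate(self) -> None:
        for f in ("copies_wt", "copies_nhej", "copies_del"):
            if getattr(self, f) < 0:
                raise ValidationError("copy count must be >= 0", field=f)
        if self.n_droplets <= 0:
            raise ValidationError("must be > 0", field="n_droplets")
        if self.droplet_volume_nl <= 0:
            raise ValidationError("must be > 0", field="droplet_volume_nl")
        droplet_total = self.droplet_volume_nl * self.n_droplets
        if droplet_total > self.reaction_volume_ul * 1000.0:
            raise ValidationError(
                f"accepted droplets span {droplet_total} nL, exceeding the "
                f"{self.reaction_volume_ul * 1000.0} nL reaction",
                field="n_droplets",
            )
        if not 0.0 <= self.rain_prob <= 1.0:
            raise ValidationError("must lie in [0, 1]", field="rain_prob")
        self.amp_model.ref.validate("amp_model.ref")
        self.amp_model.dropoff.validate("amp_model.dropoff")

    def with_(self, **kw) -> "WellSpec":
        return replace(self, **kw)

    @property
    def reaction_volume_nl(self) -> float:
        return self.reaction_volume_ul * 1000.0

    def lam(self, copies: float) -> float:
        """Mean molecules per droplet for a species loaded at ``copies``/reaction."""
        return copies * self.droplet_volume_nl / self.reaction_volume_nl


def _amplitudes(rng, positive, chan: ChannelAmplitudes, rain_prob: float):
    n = len(positive)
    amps = rng.normal(chan.neg_mean, chan.neg_sd, size=n)
    pos_draw = rng.normal(chan.pos_mean, chan.pos_sd, size=n)
    amps[positive] = pos_draw[positive]
    if rain_prob > 0.0:
        rain = rng.random(size=n) < rain_prob
        rain_amp = rng.uniform(chan.neg_mean, chan.pos_mean, size=n)
        sel = positive & rain
        amps[sel] = rain_amp[sel]
    return np.clip(amps, 0.0, None)  # fluorescence cannot go negative


def simulate_well(spec: WellSpec) -> DropletWell:
    """Simulate one well; identical spec (including seed) gives bit-identical output.

    The returned well carries a :class:`~dropquant.core.WellTruth` with the
    per-droplet molecule draws, so tests can compare gated counts against
    the simulator's own occupancy bookkeeping.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_droplets
    wt = rng.poisson(spec.lam(spec.copies_wt), size=n)
    nhej = rng.poisson(spec.lam(spec.copies_nhej), size=n)
    dele = rng.poisson(spec.lam(spec.copies_del), size=n)

    ref_pos = (wt + nhej) > 0
    do_pos = wt > 0
    ref_amp = _amplitudes(rng, ref_pos, spec.amp_model.ref, spec.rain_prob)
    do_amp = _amplitudes(rng, do_pos, spec.amp_model.dropoff, spec.rain_prob)

    return DropletWell(
        well_id=spec.well_id,
        ref=ref_amp,
        dropoff=do_amp,
        truth=WellTruth(wt=wt, nhej=nhej, dele=dele),
    )
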