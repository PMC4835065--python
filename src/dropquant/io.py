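"""File formats and run configuration.

Droplet amplitudes travel as the instrument-export CSV dialect: a header
``Ch1 Amplitude,Ch2 Amplitude`` (extra columns such as ``Cluster`` are
tolerated and ignored) and one row per accepted droplet.  Channel 1 reads
FAM, channel 2 reads HEX; which dye plays the reference vs drop-off role
is assay-specific and supplied via the channel-role mapping.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .core import DEFAULT_CHANNEL_ROLES, DYE_TO_CHANNEL, DropletWell, ReactionGeometry
from .errors import ParseError, ValidationError
from .interpret import GenotypeCutoffs

__all__ = [
    "normalize_roles",
    "parse_roles",
    "read_droplet_csv",
    "write_droplet_csv",
    "read_fasta",
    "RunConfig",
    "load_config",
    "config_hash",
    "provenance_lines",
    "well_seed",
]

_REQUIRED_COLS = ("Ch1 Amplitude", "Ch2 Amplitude")


def normalize_roles(roles: dict) -> dict:
    """Map dye names (FAM/HEX) or channel names (Ch1/Ch2) to channels per role."""
    out = {}
    for role in ("ref", "dropoff"):
        if role not in roles:
            raise ValidationError(f"missing role {role!r}", field="channel_roles")
        v = str(roles[role])
        chan = DYE_TO_CHANNEL.get(v.upper(), v.capitalize() if v.lower().startswith("ch") else None)
        if chan not in ("Ch1", "Ch2"):
            raise ValidationError(f"unknown channel/dye {v!r}", field="channel_roles")
        out[role] = chan
    if out["ref"] == out["dropoff"]:
        raise ValidationError("ref and dropoff cannot share a channel", field="channel_roles")
    return out


def parse_roles(text: str) -> dict:
    """Parse ``ref=HEX,dropoff=FAM`` style role assignments."""
    roles = {}
    for item in text.split(","):
        if "=" not in item:
            raise ValidationError(f"malformed role {item!r}", field="roles")
        k, v = item.split("=", 1)
        roles[k.strip()] = v.strip()
    return normalize_roles(roles)


def read_droplet_csv(path, channel_roles: dict | None = None, well_id: str | None = None) -> DropletWell:
    """Read an amplitude CSV into a role-ordered :class:`DropletWell`."""
    roles = normalize_roles(channel_roles or DEFAULT_CHANNEL_ROLES)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ParseError(f"{path}: no droplet rows")
    cols = {}
    for c in _REQUIRED_COLS:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            raise ParseError(f"{path}: non-numeric value in column {c!r} at line {bad[0] + 2}")
        cols[c] = vals.to_numpy(dtype=float)
    return DropletWell(
        well_id=well_id or str(path),
        ref=cols[f"{roles['ref']} Amplitude"],
        dropoff=cols[f"{roles['dropoff']} Amplitude"],
        channel_roles=roles,
    )


def write_droplet_csv(well: DropletWell, path) -> None:
    """Write a well back to the export dialect (full float precision round-trips)."""
    roles = normalize_roles(well.channel_roles)
    by_channel = {roles["ref"]: well.ref, roles["dropoff"]: well.dropoff}
    df = pd.DataFrame({c: by_channel[c.split()[0]] for c in _REQUIRED_COLS})
    df.to_csv(path, index=False, float_format="%.17g")


def read_fasta(path) -> dict:
    """Read FASTA records into {id: uppercased sequence}; DNA alphabet enforced."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ParseError(f"{path}: record {rec.id!r} has illegal characters {sorted(bad)}")
        records[rec.id] = seq
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    return records


# --------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    channel_roles: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_ROLES))
    geometry: ReactionGeometry = field(default_factory=ReactionGeometry)
    thresholds: dict | None = None  # {'ref_cut': .., 'dropoff_cut': ..} or None -> fit from controls
    genotype_cutoffs: GenotypeCutoffs = field(default_factory=GenotypeCutoffs)
    seed: int | None = None

    def as_dict(self) -> dict:
        d = {
            "channel_roles": dict(self.channel_roles),
            "geometry": asdict(self.geometry),
            "thresholds": dict(self.thresholds) if self.thresholds else None,
            "genotype_cutoffs": asdict(self.genotype_cutoffs),
            "seed": self.seed,
        }
        return d


_ALLOWED = {
    "channel_roles": {"ref", "dropoff"},
    "geometry": {"droplet_volume_nl", "reaction_volume_nl"},
    "thresholds": {"ref_cut", "dropoff_cut"},
    "genotype_cutoffs": {"wt_max", "bi_min", "mono_low", "mono_high"},
    "seed": None,
}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config must be a mapping")
    unknown = set(raw) - set(_ALLOWED)
    if unknown:
        raise ValidationError(f"unknown config keys {sorted(unknown)}", field="config")
    for key, allowed in _ALLOWED.items():
        if allowed is None or key not in raw or raw[key] is None:
            continue
        sub_unknown = set(raw[key]) - allowed
        if sub_unknown:
            raise ValidationError(
                f"unknown keys {sorted(sub_unknown)} under {key!r}", field="config"
            )
    kwargs = {}
    if "channel_roles" in raw and raw["channel_roles"]:
        kwargs["channel_roles"] = normalize_roles(raw["channel_roles"])
    if "geometry" in raw and raw["geometry"]:
        kwargs["geometry"] = ReactionGeometry(**raw["geometry"])
    if raw.get("thresholds"):
        kwargs["thresholds"] = dict(raw["thresholds"])
    if "genotype_cutoffs" in raw and raw["genotype_cutoffs"]:
        kwargs["genotype_cutoffs"] = GenotypeCutoffs(**raw["genotype_cutoffs"])
    if "seed" in raw:
        kwargs["seed"] = raw["seed"]
    return RunConfig(**kwargs)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.as_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def provenance_lines(config: RunConfig) -> list[str]:
    """Comment lines stamped onto every results file."""
    return [
        f"# dropquant {__version__}",
        f"# config_hash={config_hash(config)}",
        f"# config={json.dumps(config.as_dict(), sort_keys=True)}",
    ]


def well_seed(run_seed: int, well_id: str) -> int:
    """Deterministic per-well seed (< 2^31) derived from the run seed and well id."""
    digest = hashlib.sha256(f"{run_seed}:{well_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
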