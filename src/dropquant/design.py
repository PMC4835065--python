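"""Drop-off assay design validation.

Checks a candidate primer/probe set against the geometric and
thermodynamic guidelines that make a drop-off assay sensitive to
nuclease-induced indels:

* the drop-off probe must straddle the predicted cut site (Cas9 cuts
  bluntly ~3 bp 5' of the NGG PAM; a TALEN pair cuts within its spacer);
* the reference probe and both primers must sit away from the cut site so
  indels cannot disturb them;
* the cut site should sit mid-amplicon with 75-125 bp to each primer;
* melting temperatures: primers ~55 C, reference probe ~60 C, drop-off
  probe deliberately depressed to 56-57 C so that even a single-base
  indel destabilizes binding (higher values are tolerated on GC-rich
  targets, where oligos of workable length inevitably melt higher);
* no known SNP may fall inside a primer or probe binding site (it would
  mimic a mutant signal, or a false positive in mismatch assays).

Melting temperatures use the unified SantaLucia-1998 nearest-neighbor
parameters with the SantaLucia entropy salt correction; divalent cations
are folded into an equivalent monovalent concentration via the
von-Ahsen-style ``120 * sqrt(divalent - dNTP)`` rule (mM).  Tm is
``dH / (dS + R ln(C_T/4)) - 273.15`` at the stated oligo concentration
(``C_T`` for self-complementary oligos, which also get the symmetry
entropy term).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

from .errors import PlacementError, ValidationError

__all__ = [
    "tm_nn",
    "gc_content",
    "g_content",
    "reverse_complement",
    "Cas9Site",
    "TalenSite",
    "TargetLocus",
    "Oligo",
    "OligoSet",
    "place_oligo",
    "TmTargets",
    "Buffer",
    "RuleResult",
    "DesignReport",
    "check_design",
    "DesignConstraints",
    "EnumerationResult",
    "enumerate_candidates",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Unified nearest-neighbor duplex parameters (dH kcal/mol, dS cal/mol/K),
# 1 M NaCl reference state.  Keys are 5'->3' dinucleotides of one strand.
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
# Duplex initiation per terminal base pair.
_INIT = {"G": (0.1, -2.8), "C": (0.1, -2.8), "A": (2.3, 4.1), "T": (2.3, 4.1)}
_SYM_DS = -1.4  # self-complementary symmetry entropy
_R = 1.9872  # cal/(mol K)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_seq(seq: str, minlen: int = 1, maxlen: int | None = None) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValidationError(
            f"ambiguous/illegal bases {sorted(bad)} in {seq!r}", field="seq"
        )
    if len(seq) < minlen or (maxlen is not None and len(seq) > maxlen):
        raise ValidationError(
            f"length {len(seq)} outside [{minlen}, {maxlen}]", field="seq"
        )
    return seq


@lru_cache(maxsize=65536)
def tm_nn(
    seq: str,
    oligo_conc_nM: float,
    monovalent_mM: float = 50.0,
    divalent_mM: float = 3.0,
    dntp_mM: float = 0.0,
) -> float:
    """Nearest-neighbor melting temperature (C) of a DNA duplex.

    ``oligo_conc_nM`` is the total strand concentration C_T; for
    non-self-complementary oligos annealing to an excess template the
    usual C_T/4 convention applies.  Defaults reproduce the assay buffer:
    50 mM monovalent, 3 mM divalent, no dNTPs.
    """
    seq = _validate_seq(seq, minlen=8, maxlen=40)
    if oligo_conc_nM <= 0:
        raise ValidationError("must be > 0", field="oligo_conc_nM")
    if monovalent_mM < 0 or divalent_mM < 0 or dntp_mM < 0:
        raise ValidationError("salt concentrations must be >= 0", field="salt")

    dh = _INIT[seq[0]][0] + _INIT[seq[-1]][0]
    ds = _INIT[seq[0]][1] + _INIT[seq[-1]][1]
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s

    selfcomp = seq == reverse_complement(seq)
    if selfcomp:
        ds += _SYM_DS

    na_eq_m = (monovalent_mM + 120.0 * math.sqrt(max(divalent_mM - dntp_mM, 0.0))) / 1000.0
    if na_eq_m <= 0:
        raise ValidationError("effective monovalent concentration is zero", field="salt")
    ds += 0.368 * (len(seq) - 1) * math.log(na_eq_m)

    ct = oligo_conc_nM * 1e-9
    ct_eff = ct if selfcomp else ct / 4.0
    return dh * 1000.0 / (ds + _R * math.log(ct_eff)) - 273.15


def gc_content(seq: str) -> float:
    """G+C percentage."""
    seq = _validate_seq(seq)
    return 100.0 * sum(1 for b in seq if b in "GC") / len(seq)


def g_content(seq: str) -> float:
    """G percentage (of the given strand) -- relevant to TALEN binding-site composition."""
    seq = _validate_seq(seq)
    return 100.0 * seq.count("G") / len(seq)


# --------------------------------------------------------------------------
# loci and oligo placement (0-based, half-open intervals throughout)


@dataclass(frozen=True)
class Cas9Site:
    """Protospacer + NGG PAM; blunt cut 3 bp 5' of the PAM."""

    protospacer: tuple
    pam: tuple
    strand: str = "+"

    def cut_site(self) -> int:
        # gap coordinate: the cut falls between positions cut-1 and cut
        if self.strand == "+":
            return self.pam[0] - 3
        return self.pam[1] + 3


@dataclass(frozen=True)
class TalenSite:
    """Left/right TALE binding sites flanking the spacer where FokI cuts."""

    left: tuple
    right: tuple
    spacer: tuple

    def cut_site(self) -> int:
        return (self.spacer[0] + self.spacer[1]) // 2


@dataclass(frozen=True)
class TargetLocus:
    sequence: str
    nuclease: Cas9Site | TalenSite
    snp_positions: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "sequence", _validate_seq(self.sequence))
        n = len(self.sequence)
        nuc = self.nuclease
        intervals = (
            (nuc.protospacer, nuc.pam)
            if isinstance(nuc, Cas9Site)
            else (nuc.left, nuc.right, nuc.spacer)
        )
        for iv in intervals:
            if not (0 <= iv[0] < iv[1] <= n):
                raise ValidationError(f"interval {iv} outside sequence", field="nuclease")
        if isinstance(nuc, Cas9Site):
            if nuc.strand not in "+-":
                raise ValidationError("strand must be '+' or '-'", field="nuclease.strand")
            pam_seq = self.sequence[nuc.pam[0] : nuc.pam[1]]
            if nuc.strand == "-":
                pam_seq = reverse_complement(pam_seq)
            if len(pam_seq) != 3 or pam_seq[1:] != "GG":
                raise ValidationError(
                    f"PAM {pam_seq!r} does not match NGG on strand {nuc.strand}",
                    field="nuclease.pam",
                )
        for p in self.snp_positions:
            if not 0 <= p < n:
                raise ValidationError(f"SNP position {p} outside sequence", field="snp_positions")

    @property
    def cut_site(self) -> int:
        return self.nuclease.cut_site()


@dataclass(frozen=True)
class Oligo:
    name: str
    sequence: str
    strand: str
    start: int  # binding interval on the + strand: [start, start+len)
    conc_nM: float
    fluorophore: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "sequence", _validate_seq(self.sequence))
        if self.strand not in "+-":
            raise ValidationError("strand must be '+' or '-'", field="strand")

    @property
    def interval(self) -> tuple:
        return (self.start, self.start + len(self.sequence))

    @property
    def center(self) -> float:
        return self.start + len(self.sequence) / 2.0

    @property
    def three_prime_end(self) -> int:
        """3' end as a gap coordinate on the + axis (end for +, start for -)."""
        return self.interval[1] if self.strand == "+" else self.interval[0]


def place_oligo(
    target_seq: str, name: str, oligo_seq: str, conc_nM: float, fluorophore=None
) -> Oligo:
    """Locate an oligo in the target on either strand (first hit wins)."""
    target_seq = _validate_seq(target_seq)
    oligo_seq = _validate_seq(oligo_seq)
    i = target_seq.find(oligo_seq)
    if i >= 0:
        return Oligo(name, oligo_seq, "+", i, conc_nM, fluorophore)
    j = target_seq.find(reverse_complement(oligo_seq))
    if j >= 0:
        return Oligo(name, oligo_seq, "-", j, conc_nM, fluorophore)
    raise PlacementError(f"{name} sequence {oligo_seq!r} not found on either strand")


@dataclass(frozen=True)
class OligoSet:
    forward: Oligo
    reverse: Oligo
    ref_probe: Oligo
    dropoff_probe: Oligo

    def __post_init__(self):
        if self.ref_probe.interval == self.dropoff_probe.interval:
            raise ValidationError(
                "reference and drop-off probes occupy the same interval", field="probes"
            )
        amp = self.amplicon
        for probe in (self.ref_probe, self.dropoff_probe):
            if not (amp[0] <= probe.interval[0] and probe.interval[1] <= amp[1]):
                raise ValidationError(
                    f"{probe.name} interval {probe.interval} outside amplicon {amp}",
                    field="probes",
                )

    @property
    def amplicon(self) -> tuple:
        return (self.forward.interval[0], self.reverse.interval[1])

    def all_oligos(self):
        return (self.forward, self.reverse, self.ref_probe, self.dropoff_probe)


# --------------------------------------------------------------------------
# rule table


@dataclass(frozen=True)
class Buffer:
    monovalent_mM: float = 50.0
    divalent_mM: float = 3.0
    dntp_mM: float = 0.0


@dataclass(frozen=True)
class TmTargets:
    primer: float = 55.0
    ref_probe: float = 60.0
    dropoff_low: float = 56.0
    dropoff_high: float = 57.0
    tol: float = 2.0
    dropoff_tol: float = 1.0
    #: amplicon G+C % above which melting above target is tolerated
    gc_relax_percent: float = 60.0


@dataclass(frozen=True)
class RuleResult:
    rule_id: str
    measured: object
    passed: bool
    message: str


@dataclass(frozen=True)
class DesignReport:
    rules: tuple

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.rules)

    def rule(self, rule_id: str) -> RuleResult:
        for r in self.rules:
            if r.rule_id == rule_id:
                return r
        raise KeyError(rule_id)

    def failed_rules(self) -> tuple:
        return tuple(r.rule_id for r in self.rules if not r.passed)


def _overlaps(a: tuple, b: tuple) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _tm(oligo: Oligo, buf: Buffer) -> float:
    return tm_nn(
        oligo.sequence, oligo.conc_nM, buf.monovalent_mM, buf.divalent_mM, buf.dntp_mM
    )


def check_design(
    locus: TargetLocus,
    oligos: OligoSet,
    targets: TmTargets = TmTargets(),
    buffer: Buffer = Buffer(),
) -> DesignReport:
    """Evaluate the full design rule table; pure function of its inputs."""
    for o in oligos.all_oligos():
        iv = o.interval
        if not (0 <= iv[0] < iv[1] <= len(locus.sequence)):
            raise PlacementError(f"{o.name} interval {iv} outside locus")
        found = locus.sequence[iv[0] : iv[1]]
        expect = o.sequence if o.strand == "+" else reverse_complement(o.sequence)
        if found != expect:
            raise PlacementError(
                f"{o.name} sequence does not match the locus at {iv} on strand {o.strand}"
            )

    cut = locus.cut_site
    do = oligos.dropoff_probe
    rules = []

    # R1: Cas9 cut inside the drop-off probe, close to its center
    if isinstance(locus.nuclease, Cas9Site):
        offset = abs(cut - do.center)
        inside = do.interval[0] < cut < do.interval[1]
        rules.append(
            RuleResult(
                "R1",
                round(offset, 1),
                inside and offset <= 3.0,
                f"cut site {cut} vs drop-off probe {do.interval} (center offset {offset:.1f} bp)",
            )
        )
    else:
        rules.append(RuleResult("R1", None, True, "not applicable (TALEN design)"))

    # R2: TALEN spacer short and fully covered by the drop-off probe
    if isinstance(locus.nuclease, TalenSite):
        sp = locus.nuclease.spacer
        sp_len = sp[1] - sp[0]
        covers = do.interval[0] <= sp[0] and sp[1] <= do.interval[1]
        rules.append(
            RuleResult(
                "R2",
                sp_len,
                sp_len <= 20 and covers,
                f"spacer length {sp_len} bp; covered by drop-off probe: {covers}",
            )
        )
    else:
        rules.append(RuleResult("R2", None, True, "not applicable (Cas9 design)"))

    # R3: 75-125 bp from the cut site to each primer's 3' end
    left = cut - oligos.forward.three_prime_end
    right = oligos.reverse.three_prime_end - cut
    rules.append(
        RuleResult(
            "R3",
            (left, right),
            75 <= left <= 125 and 75 <= right <= 125,
            f"flanks cut->primer-3' = {left}/{right} bp (want 75-125 each)",
        )
    )

    # R4: reference probe and primers clear of the drop-off site and cut
    ref = oligos.ref_probe
    clear = not any(
        _overlaps(o.interval, do.interval) for o in (ref, oligos.forward, oligos.reverse)
    )
    ref_dist = abs(ref.center - cut)
    rules.append(
        RuleResult(
            "R4",
            round(ref_dist, 1),
            clear and ref_dist >= 30.0,
            f"reference-probe center {ref_dist:.1f} bp from cut; overlap-free: {clear}",
        )
    )

    # R5: melting temperatures near targets (relaxed upward on GC-rich amplicons)
    amp = locus.sequence[oligos.amplicon[0] : oligos.amplicon[1]]
    amp_gc = gc_content(amp)
    gc_rich = amp_gc >= targets.gc_relax_percent
    tms = {}
    bands = {
        oligos.forward.name: (targets.primer - targets.tol, targets.primer + targets.tol),
        oligos.reverse.name: (targets.primer - targets.tol, targets.primer + targets.tol),
        ref.name: (targets.ref_probe - targets.tol, targets.ref_probe + targets.tol),
        do.name: (
            targets.dropoff_low - targets.dropoff_tol,
            targets.dropoff_high + targets.dropoff_tol,
        ),
    }
    failures, relaxed = [], []
    for o in oligos.all_oligos():
        t = _tm(o, buffer)
        tms[o.name] = round(t, 2)
        lo, hi = bands[o.name]
        if lo <= t <= hi:
            continue
        if t > hi and gc_rich:
            relaxed.append(o.name)
        else:
            failures.append(f"{o.name}={t:.1f}C not in [{lo:.0f},{hi:.0f}]")
    msg = f"Tm {tms}; amplicon GC {amp_gc:.0f}%"
    if relaxed:
        msg += f"; above-target Tm tolerated on GC-rich amplicon: {relaxed}"
    if failures:
        msg += "; " + "; ".join(failures)
    rules.append(RuleResult("R5", tms, not failures, msg))

    # R6: no SNP inside any primer/probe binding site
    hit = [
        (p, o.name)
        for p in locus.snp_positions
        for o in oligos.all_oligos()
        if o.interval[0] <= p < o.interval[1]
    ]
    rules.append(
        RuleResult(
            "R6",
            tuple(hit),
            not hit,
            "no SNPs in oligo binding sites" if not hit else f"SNPs inside oligos: {hit}",
        )
    )

    # R7: drop-off probe deliberately melts below the reference probe
    t_do, t_ref = _tm(do, buffer), _tm(ref, buffer)
    rules.append(
        RuleResult(
            "R7",
            round(t_do - t_ref, 2),
            t_do < t_ref,
            f"drop-off Tm {t_do:.1f}C vs reference Tm {t_ref:.1f}C",
        )
    )

    return DesignReport(rules=tuple(rules))


# --------------------------------------------------------------------------
# candidate enumeration


@dataclass(frozen=True)
class DesignConstraints:
    primer_len: tuple = (16, 28)
    probe_len: tuple = (14, 22)
    primer_conc_nM: float = 900.0
    probe_conc_nM: float = 250.0
    flank: tuple = (75, 125)
    top_k_per_role: int = 4
    targets: TmTargets = field(default_factory=TmTargets)
    buffer: Buffer = field(default_factory=Buffer)

    def with_(self, **kw) -> "DesignConstraints":
        return replace(self, **kw)


@dataclass(frozen=True)
class ScoredCandidate:
    score: float
    oligos: OligoSet
    report: DesignReport


@dataclass(frozen=True)
class EnumerationResult:
    candidates: tuple
    diagnostics: tuple


def _role_candidates(seq, positions_lengths, conc, target_mid, band, buf):
    """Collect (deviation, start, oligo_seq, strand) tuples passing a Tm band."""
    out = []
    for start, length, strand in positions_lengths:
        if start < 0 or start + length > len(seq):
            continue
        sub = seq[start : start + length]
        oseq = sub if strand == "+" else reverse_complement(sub)
        try:
            t = tm_nn(oseq, conc, buf.monovalent_mM, buf.divalent_mM, buf.dntp_mM)
        except ValidationError:
            continue
        if band[0] <= t <= band[1]:
            out.append((abs(t - target_mid), start, oseq, strand))
    out.sort(key=lambda c: (c[0], c[1]))
    return out


def enumerate_candidates(
    locus: TargetLocus, constraints: DesignConstraints = DesignConstraints()
) -> EnumerationResult:
    """Exhaustive sliding-window search for rule-compliant oligo sets.

    Each role (primers, probes) is scanned over its allowed window; the
    best few per role are combined and every combination is vetted with
    :func:`check_design`.  Candidates are ranked by total |Tm - target|
    deviation, ties broken by position, so the ordering is deterministic.
    """
    seq = locus.sequence
    cut = locus.cut_site
    tg, buf = constraints.targets, constraints.buffer
    pl_lo, pl_hi = constraints.primer_len
    pr_lo, pr_hi = constraints.probe_len
    f_lo, f_hi = constraints.flank
    primer_band = (tg.primer - tg.tol, tg.primer + tg.tol)
    ref_band = (tg.ref_probe - tg.tol, tg.ref_probe + tg.tol)
    do_band = (tg.dropoff_low - tg.dropoff_tol, tg.dropoff_high + tg.dropoff_tol)
    do_mid = 0.5 * (tg.dropoff_low + tg.dropoff_high)

    fwd = _role_candidates(
        seq,
        [
            (end - L, L, "+")
            for end in range(cut - f_hi, cut - f_lo + 1)
            for L in range(pl_lo, pl_hi + 1)
        ],
        constraints.primer_conc_nM, tg.primer, primer_band, buf,
    )
    rev = _role_candidates(
        seq,
        [
            (start, L, "-")
            for start in range(cut + f_lo, cut + f_hi + 1)
            for L in range(pl_lo, pl_hi + 1)
        ],
        constraints.primer_conc_nM, tg.primer, primer_band, buf,
    )
    dop = _role_candidates(
        seq,
        [
            (st, L, "+")
            for L in range(pr_lo, pr_hi + 1)
            for st in range(cut - 3 - L // 2, cut + 4 - L // 2)
        ],
        constraints.probe_conc_nM, do_mid, do_band, buf,
    )
    refp = _role_candidates(
        seq,
        [
            (st, L, "+")
            for L in range(pr_lo, pr_hi + 1)
            for st in range(max(cut - f_hi, 0), cut + f_hi)
            if abs(st + L / 2.0 - cut) >= 30.0
        ],
        constraints.probe_conc_nM, tg.ref_probe, ref_band, buf,
    )

    diagnostics = [
        f"no {role} candidate satisfies its Tm window"
        for role, cands in (
            ("forward-primer", fwd), ("reverse-primer", rev),
            ("drop-off-probe", dop), ("reference-probe", refp),
        )
        if not cands
    ]
    if diagnostics:
        return EnumerationResult(candidates=(), diagnostics=tuple(diagnostics))

    k = constraints.top_k_per_role
    results = []
    for df, sf, qf, stf in fwd[:k]:
        for dr, sr, qr, strr in rev[:k]:
            for dd, sd, qd, std in dop[:k]:
                for dref, sref, qref, stref in refp[:k]:
                    try:
                        oset = OligoSet(
                            forward=Oligo("forward", qf, stf, sf, constraints.primer_conc_nM),
                            reverse=Oligo("reverse", qr, strr, sr, constraints.primer_conc_nM),
                            ref_probe=Oligo("ref_probe", qref, stref, sref, constraints.probe_conc_nM),
                            dropoff_probe=Oligo("dropoff_probe", qd, std, sd, constraints.probe_conc_nM),
                        )
                        report = check_design(locus, oset, tg, buf)
                    except (ValidationError, PlacementError):
                        continue
                    if report.passed:
                        results.append(
                            ScoredCandidate(df + dr + dd + dref, oset, report)
                        )
    results.sort(
        key=lambda c: (
            c.score,
            c.oligos.forward.start,
            c.oligos.reverse.start,
            c.oligos.dropoff_probe.start,
            c.oligos.ref_probe.start,
        )
    )
    if not results:
        diagnostics = ["per-role candidates exist but no combination passes the rule table"]
    return EnumerationResult(candidates=tuple(results), diagnostics=tuple(diagnostics))
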