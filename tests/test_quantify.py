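"""Exclusion-Poisson estimators, Wilson intervals and the mutant fraction."""

import math

import numpy as np
import pytest

import dropquant as dq
from dropquant.errors import SaturatedWellError, UndefinedEstimateError, ValidationError

SCALE = 20000.0 / 0.85  # copies per reaction per unit lambda


def test_wt_point_estimate_at_half_occupancy():
    counts = dq.ClusterCounts(n_wt=7500, n_nhej=0, n_empty=7500)
    est = dq.quantify_wt(counts)
    assert est.copies == pytest.approx(-math.log(0.5) * SCALE)  # 16309.35
    assert est.lam == pytest.approx(math.log(2))
    assert est.ci_low < est.copies < est.ci_high


def test_nhej_estimate_excludes_wt_droplets_from_denominator():
    counts = dq.ClusterCounts(n_wt=5000, n_nhej=100, n_empty=9900)
    est = dq.quantify_nhej(counts)
    assert est.p == pytest.approx(0.01)  # 100 / (100 + 9900); wt droplets ignored
    assert est.copies == pytest.approx(-math.log(0.99) * SCALE)  # 236.48


def test_zero_positives_give_zero_copies_with_zero_lower_bound():
    est = dq.quantify_nhej(dq.ClusterCounts(n_wt=0, n_nhej=0, n_empty=10000))
    assert est.copies == 0.0 and est.ci_low == 0.0 and est.ci_high > 0.0


def test_saturated_wells_raise():
    with pytest.raises(SaturatedWellError):
        dq.quantify_wt(dq.ClusterCounts(n_wt=100, n_nhej=0, n_empty=0))
    with pytest.raises(SaturatedWellError):
        dq.quantify_nhej(dq.ClusterCounts(n_wt=0, n_nhej=100, n_empty=0))


def test_empty_denominator_is_undefined():
    with pytest.raises(UndefinedEstimateError):
        dq.quantify_nhej(dq.ClusterCounts(n_wt=100, n_nhej=0, n_empty=0))


def test_ci_from_counts_validates_and_brackets():
    with pytest.raises(ValidationError):
        dq.ci_from_counts(11, 10)
    low, high = dq.ci_from_counts(0, 1000)
    assert low == 0.0
    low, high = dq.ci_from_counts(50, 10000)
    point = dq.ReactionGeometry().copies_from_p(0.005)
    assert low < point < high


def test_clopper_pearson_option_is_wider_than_wilson():
    w = dq.ci_from_counts(50, 10000, method="wilson")
    cp = dq.ci_from_counts(50, 10000, method="clopper-pearson")
    assert cp[0] <= w[0] and cp[1] >= w[1]


def test_saturated_ci_upper_bound_is_infinite():
    low, high = dq.ci_from_counts(100, 100)
    assert math.isinf(high) and low > 0


def _nhej_estimate(spec, thresholds):
    well = dq.simulate_well(spec)
    return dq.quantify_nhej(dq.classify(well, thresholds))


def test_simulated_load_recovered_within_ci(thresholds):
    """500 true copies, 15k droplets: CI covers truth in most replicates."""
    spec = dq.WellSpec(copies_nhej=500, copies_wt=20000, n_droplets=15000)
    covered = 0
    for seed in range(5):
        est = _nhej_estimate(spec.with_(seed=200 + seed), thresholds)
        covered += est.ci_low <= 500 <= est.ci_high
    assert covered >= 3


def test_wt_exclusion_makes_estimate_invariant_to_wt_load(thresholds):
    """Adding wild-type copies must not shift the mutant estimate by more
    than one single-well CI width (the rationale for excluding wt droplets)."""
    means, width = [], None
    for wt in (0, 10**4, 10**5):
        ests = [
            _nhej_estimate(
                dq.WellSpec(copies_nhej=2000, copies_wt=wt, seed=300 + wt + r),
                thresholds,
            )
            for r in range(8)
        ]
        means.append(np.mean([e.copies for e in ests]))
        width = ests[0].ci_high - ests[0].ci_low
    assert max(means) - min(means) < width


def test_copy_estimates_robust_to_threshold_placement(thresholds):
    """Shifting both cuts by +-20% of the inter-cluster gap barely moves
    the estimates when clusters are well separated."""
    well = dq.simulate_well(dq.WellSpec(copies_wt=8000, copies_nhej=2000, seed=31))
    gap = 7000.0  # positive minus negative cluster mean
    ref = dq.classify(well, thresholds)
    base_wt = dq.quantify_wt(ref).copies
    base_nhej = dq.quantify_nhej(ref).copies
    for shift in (-0.2 * gap, 0.2 * gap):
        th = dq.Thresholds(
            ref_cut=thresholds.ref_cut + shift,
            dropoff_cut=thresholds.dropoff_cut + shift,
        )
        counts = dq.classify(well, th)
        assert dq.quantify_wt(counts).copies == pytest.approx(base_wt, rel=0.01)
        assert dq.quantify_nhej(counts).copies == pytest.approx(base_nhej, rel=0.01)


def test_mutant_fraction_basics():
    wt = dq.quantify_wt(dq.ClusterCounts(n_wt=5000, n_nhej=0, n_empty=10000))
    none = dq.quantify_nhej(dq.ClusterCounts(n_wt=5000, n_nhej=0, n_empty=10000))
    assert dq.mutant_fraction(none, wt).fraction == 0.0

    half = dq.ClusterCounts(n_wt=3000, n_nhej=3000, n_empty=9000)
    # equal copies -> fraction 1/2 by symmetry (denominators differ but p maps equal)
    est_n = dq.quantify_nhej(dq.ClusterCounts(n_wt=0, n_nhej=3000, n_empty=12000))
    est_w = dq.quantify_wt(dq.ClusterCounts(n_wt=3000, n_nhej=0, n_empty=12000))
    frac = dq.mutant_fraction(est_n, est_w)
    assert frac.fraction == pytest.approx(0.5)
    assert frac.ci_low < 0.5 < frac.ci_high

    with pytest.raises(UndefinedEstimateError):
        zero = dq.quantify_nhej(dq.ClusterCounts(n_wt=0, n_nhej=0, n_empty=100))
        zero_wt = dq.quantify_wt(dq.ClusterCounts(n_wt=0, n_nhej=0, n_empty=100))
        dq.mutant_fraction(zero, zero_wt)


def test_estimator_consistency_improves_with_droplet_count(thresholds):
    """Relative error trend across three well sizes at fixed copy load."""
    errs = []
    for i, n in enumerate((10**4, 10**5, 10**6)):
        # hold lambda = 0.2 fixed; the reaction volume grows with the well
        vr_nl = n * 0.85 * 1.25
        geom = dq.ReactionGeometry(reaction_volume_nl=vr_nl)
        copies = 0.2 * geom.scale
        rel = []
        for r in range(3):
            spec = dq.WellSpec(
                copies_nhej=copies, n_droplets=n,
                reaction_volume_ul=vr_nl / 1000.0, seed=40 + 10 * i + r,
            )
            well = dq.simulate_well(spec)
            est = dq.quantify_nhej(dq.classify(well, thresholds), geom)
            rel.append(abs(est.copies - copies) / copies)
        errs.append(np.mean(rel))
    assert errs[2] < errs[0]
    assert errs[2] < 0.01
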