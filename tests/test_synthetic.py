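"""Synthetic cohort generator: reference parameters, structure, calibration."""

import numpy as np
import pytest
from scipy.special import ndtr

from nkdetect.cohort import validate_structure
from nkdetect.registry import COMPLEMENT_PAIRS
from nkdetect.synthetic import (
    GenerationError,
    GeneratorConfig,
    GroupParams,
    default_risk_effect,
    generate_detection_cohort,
    generate_planted_cohort,
    generate_risk_cohort,
    reference_spec,
    _rtruncnorm,
)


def test_reference_spec_matches_published_descriptives(spec):
    f27 = spec.feature(27)
    assert f27.cancer.location == 97.47
    assert f27.cancer.scale == 12.19
    assert (f27.benign.lower, f27.benign.upper) == (94.97, 99.90)
    assert spec.psa.benign.location == 8.26
    assert (spec.psa.benign.lower, spec.psa.benign.upper) == (4.70, 19.00)
    assert spec.feature(5).complement_partner == 10


def test_reference_pair_locations_sum_near_100(spec):
    """Printed group means of each complement pair sum to ~100 (the worst
    printed rounding discrepancy is 1.05 percentage points)."""
    for a, b in spec.pair_map:
        for g in ("benign", "cancer"):
            s = spec.feature(a).group(g).location + spec.feature(b).group(g).location
            assert s == pytest.approx(100.0, abs=1.1)


def test_default_detection_shape_and_reproducibility(spec):
    c1 = generate_detection_cohort(spec, GeneratorConfig(seed=3))
    c2 = generate_detection_cohort(spec, GeneratorConfig(seed=3))
    assert c1.n == 71
    assert (c1.labels == 0).sum() == 30 and (c1.labels == 1).sum() == 41
    np.testing.assert_array_equal(c1.values, c2.values)
    np.testing.assert_array_equal(c1.psa, c2.psa)
    c3 = generate_detection_cohort(spec, GeneratorConfig(seed=4))
    assert not np.array_equal(c1.values, c3.values)


def test_complement_pairs_sum_to_exactly_100(spec):
    c = generate_detection_cohort(spec, GeneratorConfig(seed=9))
    for a, b in COMPLEMENT_PAIRS:
        np.testing.assert_allclose(
            c.values[:, a - 1] + c.values[:, b - 1], 100.0, atol=1e-9
        )
    assert not validate_structure(c, tolerance=1e-6).pair_violations


def test_cd16_blocks_are_compositional(spec):
    c = generate_detection_cohort(spec, GeneratorConfig(seed=9))
    v = c.values
    np.testing.assert_allclose(v[:, 0], v[:, 1] + v[:, 2], atol=1e-9)  # dim CD16+
    np.testing.assert_allclose(v[:, 0] + v[:, 3], v[:, 4], atol=1e-8)  # = dim total
    np.testing.assert_allclose(v[:, 5], v[:, 6] + v[:, 7], atol=1e-9)  # bright CD16+
    np.testing.assert_allclose(v[:, 5] + v[:, 8], v[:, 9], atol=1e-8)


def test_generated_values_respect_bounds(spec):
    """Directly simulated features stay inside their per-group bounds; PSA
    stays inside the detection window."""
    c = generate_detection_cohort(spec, GeneratorConfig(seed=21))
    pair_members = {x for p in COMPLEMENT_PAIRS for x in p}
    direct = (pair_members | {13, 14}) - {10, 12, 16, 18, 20, 22, 24, 26, 28, 30, 32}
    for g, gname in ((0, "benign"), (1, "cancer")):
        rows = c.labels == g
        for fid in direct:
            p = spec.feature(fid).group(gname)
            v = c.values[rows, fid - 1]
            assert v.min() >= p.lower - 1e-9 and v.max() <= p.upper + 1e-9
    assert c.psa.min() >= 4.70 and c.psa.max() <= 19.00
    assert ((c.values >= 0) & (c.values <= 100)).all()


def test_truncated_normal_sampler_matches_analytic_moments():
    """Large-n mean of the inverse-CDF truncated-normal sampler agrees with
    the analytic truncated-normal mean."""
    from scipy import stats as ss

    rng = np.random.default_rng(0)
    p = GroupParams(location=72.88, scale=11.74, lower=24.38, upper=87.46)
    x = _rtruncnorm(rng, p, 200_000)
    a, b = (p.lower - p.location) / p.scale, (p.upper - p.location) / p.scale
    ref = ss.truncnorm(a, b, loc=p.location, scale=p.scale)
    assert x.min() >= p.lower and x.max() <= p.upper
    assert x.mean() == pytest.approx(ref.mean(), abs=3 * ref.std() / np.sqrt(x.size))
    assert x.std() == pytest.approx(ref.std(), rel=0.02)


def test_large_sample_feature_means_match_spec(spec):
    """LLN check: with 5000 per group, simulated means of truncated-normal
    pair primaries agree with the analytic mean implied by the spec."""
    from scipy import stats as ss

    c = generate_detection_cohort(spec, GeneratorConfig(5000, 5000, seed=2))
    for fid in (11, 17, 25, 29):  # truncated-normal primaries
        fs = spec.feature(fid)
        for g, gname in ((0, "benign"), (1, "cancer")):
            p = fs.group(gname)
            partner = spec.feature(fs.complement_partner).group(gname)
            lo = max(p.lower, 100 - partner.upper)
            hi = min(p.upper, 100 - partner.lower)
            a, b = (lo - p.location) / p.scale, (hi - p.location) / p.scale
            ref = ss.truncnorm(a, b, loc=p.location, scale=p.scale)
            got = c.values[c.labels == g, fid - 1].mean()
            assert got == pytest.approx(
                ref.mean(), abs=3 * ref.std() / np.sqrt(5000)
            )


def test_effect_scale_zero_pools_the_groups(spec):
    """At effect_scale=0 both groups share one distribution: a rank test on
    a large cohort must not separate them."""
    from scipy import stats as ss

    c = generate_detection_cohort(spec, GeneratorConfig(2000, 2000, 0, 0.0))
    g0, g1 = c.labels == 0, c.labels == 1
    pvals = [
        ss.mannwhitneyu(c.values[g0, j], c.values[g1, j]).pvalue for j in range(32)
    ]
    assert min(pvals) > 0.05 / 32 / 10  # no astronomically small p under H0


def test_effect_scale_monotone_in_separability(spec):
    """Median CV AUC of a fixed classifier does not decrease with
    effect_scale (checked over {0, 0.5, 1, 2}, 10 seeds)."""
    from nkdetect.ensemble import EnsembleConfig
    from nkdetect.evaluation import CONDITIONS, repeated_cv

    medians = []
    for alpha in (0.0, 0.5, 1.0, 2.0):
        aucs = []
        for seed in range(10):
            c = generate_detection_cohort(
                spec, GeneratorConfig(seed=seed, effect_scale=alpha)
            )
            r = repeated_cv(
                c, CONDITIONS["GA+STAT"], EnsembleConfig(seed=0), runs=1,
                master_seed=seed,
            )
            aucs.append(r.means["auc"])
        medians.append(np.median(aucs))
    assert all(b >= a - 0.02 for a, b in zip(medians, medians[1:]))
    assert medians[-1] > medians[0]


def test_risk_cohort_shape_and_psa_tail(spec):
    c = generate_risk_cohort(spec, seed=5)
    assert c.n == 54
    assert (c.labels == 0).sum() == 38 and (c.labels == 1).sum() == 16
    assert c.task == "risk"
    li_psa = c.psa[c.labels == 0]
    h_psa = c.psa[c.labels == 1]
    assert li_psa.max() < 20.0
    assert h_psa.min() >= 4.3 and h_psa.max() <= 2617.0
    c2 = generate_risk_cohort(spec, seed=5)
    np.testing.assert_array_equal(c.values, c2.values)


def test_default_risk_effect_shifts_signature_panel(spec):
    eff = default_risk_effect(spec)
    # one independent shift per signature pair/feature; directions have room
    assert set(eff) == {2, 14, 15, 17, 19, 27}
    for fid, delta in eff.items():
        p = spec.feature(fid).cancer
        assert p.lower <= p.location + delta <= p.upper
    big = generate_risk_cohort(spec, n_li=2000, n_h=2000, seed=1)
    li, h = big.labels == 0, big.labels == 1
    for fid, delta in eff.items():
        observed = big.values[h, fid - 1].mean() - big.values[li, fid - 1].mean()
        assert np.sign(observed) == np.sign(delta)


def test_infeasible_spec_raises(spec):
    cfg = GeneratorConfig(seed=0)
    bad = reference_spec()
    fs = bad.features[29]
    bad.features[29] = type(fs)(
        id=29, family=fs.family,
        benign=GroupParams(location=500.0, scale=1.0, lower=20.43, upper=77.57),
        cancer=fs.cancer, complement_partner=fs.complement_partner,
    )
    with pytest.raises(GenerationError, match="6 scales"):
        generate_detection_cohort(bad, cfg)


def test_planted_cohort_plants_only_the_requested_features():
    c = generate_planted_cohort(seed=1)
    g0, g1 = c.labels == 0, c.labels == 1
    gaps = c.values[g1].mean(axis=0) - c.values[g0].mean(axis=0)
    planted = np.array([2, 20, 27, 28]) - 1
    assert gaps[planted].min() > 5.0  # ~1 sd of 10
    noise = np.delete(gaps, planted)
    assert np.abs(noise).max() < 5.0
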