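import numpy as np
import pytest

from linescape import cn as C
from linescape.tracks import BinnedTrack


def make_track(values, bin_size=10_000, chrom="c"):
    return BinnedTrack.from_values({chrom: bin_size * len(values)}, bin_size, values)


# ----------------------------------------------------------------- bin_depth
def test_bin_depth_constant_and_partial_terminal_bin():
    depth = {"c": np.full(1_000_000, 60.0)}
    track = C.bin_depth(depth, 10_000)
    assert len(track) == 100
    np.testing.assert_allclose(track.values, 60.0)

    ramp = {"c": np.arange(20_000, dtype=float)}
    t2 = C.bin_depth(ramp, 10_000)
    np.testing.assert_allclose(t2.values, [np.mean(np.arange(10_000)),
                                           np.mean(np.arange(10_000, 20_000))])

    t3 = C.bin_depth({"c": np.ones(15_000)}, 10_000)
    assert t3.df["end"].tolist() == [10_000, 15_000]


def test_bin_depth_rejects_bad_inputs():
    with pytest.raises(ValueError, match="bin_size"):
        C.bin_depth({"c": np.ones(10)}, -1)
    with pytest.raises(ValueError, match="negative"):
        C.bin_depth({"c": np.array([-1.0])}, 10)


# ------------------------------------------------------- mappability_correct
@pytest.mark.parametrize(
    "value,fraction,expected",
    [(30.0, 0.6, 50.0), (30.0, 0.4, np.nan), (30.0, 1.0, 30.0), (30.0, 0.5, 60.0)],
)
def test_mappability_correction_rule(value, fraction, expected):
    cov = make_track([value])
    frac = make_track([fraction])
    out = C.mappability_correct(cov, frac).values[0]
    if np.isnan(expected):
        assert np.isnan(out)
    else:
        assert out == pytest.approx(expected)


def test_mappability_correct_requires_same_grid():
    with pytest.raises(ValueError, match="grid"):
        C.mappability_correct(make_track([1, 2]), make_track([1.0]))


# ------------------------------------------------------------------ gc_adjust
def test_gc_adjust_removes_known_bias_curve():
    """Coverage proportional to a smooth g(gc) must come back flat at the
    target level within 1%: the fit absorbs both the bias shape and the
    overall level, and the chain recovers absolute scale later from the
    CN-2 calibration region."""
    rng = np.random.default_rng(0)
    gc_vals = rng.uniform(0.3, 0.6, 400)
    g = 1.0 - 2.0 * (gc_vals - 0.45) ** 2
    cov = make_track(2 * 60.0 * g)
    gc = make_track(gc_vals)
    adjusted = C.gc_adjust(cov, gc, target_coverage=60.0).values
    np.testing.assert_allclose(adjusted, 60.0, rtol=0.01)


def test_gc_adjust_flat_coverage_is_identity():
    rng = np.random.default_rng(1)
    cov = make_track(np.full(200, 80.0))
    gc = make_track(rng.uniform(0.3, 0.6, 200))
    adjusted = C.gc_adjust(cov, gc, target_coverage=80.0).values
    np.testing.assert_allclose(adjusted, 80.0, rtol=0.01)


def test_gc_adjust_propagates_na_and_checks_size():
    rng = np.random.default_rng(2)
    vals = np.full(100, 50.0)
    vals[7] = np.nan
    cov = make_track(vals)
    gc = make_track(rng.uniform(0.3, 0.6, 100))
    adjusted = C.gc_adjust(cov, gc)
    assert np.isnan(adjusted.values[7])
    with pytest.raises(ValueError, match="non-NA bins"):
        C.gc_adjust(make_track([1.0] * 10), make_track([0.5] * 10))


# ----------------------------------------------------------------- log2_ratio
def test_log2_ratio_calibration_arithmetic():
    vals = np.array([40.0] * 20 + [80.0, 20.0])
    track = make_track(vals)
    out, x0 = C.log2_ratio(track, ("c", 0, 200_000))
    assert x0 == pytest.approx(40.0)
    assert out.values[0] == pytest.approx(0.0)
    assert out.values[20] == pytest.approx(1.0)  # 2*x0 -> CN estimate 4
    assert out.values[21] == pytest.approx(-1.0)  # x0/2 -> CN estimate 1
    assert 2 ** (out.values[20] + 1) == pytest.approx(4.0)


def test_log2_ratio_region_cn_rescaling():
    track = make_track(np.full(20, 60.0))
    _, x0 = C.log2_ratio(track, ("c", 0, 200_000), region_cn=3)
    assert x0 == pytest.approx(40.0)


def test_log2_ratio_needs_enough_calibration_bins():
    with pytest.raises(ValueError, match="calibration"):
        C.log2_ratio(make_track(np.full(30, 60.0)), ("c", 0, 50_000))


# -------------------------------------------------------------- segment_track
def test_segment_track_noiseless_levels_and_estimates():
    vals = np.array([0.0] * 40 + [0.585] * 30 + [-1.0] * 30)
    segs = C.segment_track(make_track(vals), seed=0)
    assert [s.n_bins for s in segs] == [40, 30, 30]
    assert segs[0].cn_estimate == pytest.approx(2.0)
    assert segs[1].cn_estimate == pytest.approx(3.0, rel=1e-3)
    assert segs[2].cn_estimate == pytest.approx(1.0)
    assert segs[0].start == 0 and segs[2].end == 1_000_000


def test_segment_track_skips_all_na_chromosome():
    vals = np.full(30, np.nan)
    segs = C.segment_track(make_track(vals), seed=0)
    assert segs == []


def test_segment_track_single_bin_chromosome():
    segs = C.segment_track(make_track([0.3]), seed=0)
    assert len(segs) == 1 and segs[0].n_bins == 1
    assert segs[0].mean_log2 == pytest.approx(0.3)


# ------------------------------------------------------------- fit_cn_mixture
def test_mixture_recovers_weights_and_sds():
    """2,000 weighted estimates at means 3/2/5 (60/30/10%, sd 0.1)."""
    rng = np.random.default_rng(42)
    comps = rng.choice([3.0, 2.0, 5.0], p=[0.6, 0.3, 0.1], size=2000)
    data = rng.normal(comps, 0.1)
    segs = [
        C.CnSegment("c", i, i + 1, mean_log2=np.log2(v) - 1, n_bins=1)
        for i, v in enumerate(data)
    ]
    model = C.fit_cn_mixture(segs, m=8)
    assert model.weights[2] == pytest.approx(0.6, abs=0.05)
    assert model.weights[1] == pytest.approx(0.3, abs=0.05)
    assert model.weights[4] == pytest.approx(0.1, abs=0.05)
    for k in (1, 2, 4):
        assert model.sds[k] == pytest.approx(0.1, abs=0.03)
    diffs = np.diff(model.loglik_trace)
    assert (diffs >= -1e-6).all()
    assert model.weights.sum() == pytest.approx(1.0, abs=1e-9)


def test_mixture_point_mass_and_insufficient_data():
    segs = [C.CnSegment("c", 0, 10, mean_log2=np.log2(3) - 1, n_bins=50)]
    model = C.fit_cn_mixture(segs, m=8)
    assert model.weights[2] == pytest.approx(1.0, abs=1e-6)
    with pytest.raises(ValueError, match="< m"):
        C.fit_cn_mixture(segs[:1], m=8, weight_by_bins=False)


# --------------------------------------------------------- assign_copy_number
def test_bayes_boundary_cases():
    model = C.CnMixtureModel(
        m=8,
        weights=np.array([0.0, 0.5, 0.5, 0.0, 0.0, 0.0, 0.0, 0.0]),
        sds=np.full(8, 0.2),
        loglik=0.0,
    )
    mid = C.CnSegment("c", 0, 10, mean_log2=np.log2(2.5) - 1, n_bins=5)
    C.assign_copy_number([mid], model)
    assert mid.assigned_cn is None
    assert mid.posterior == pytest.approx(0.5, abs=1e-9)

    clear = C.CnSegment("c", 0, 10, mean_log2=np.log2(3.01) - 1, n_bins=5)
    model2 = C.CnMixtureModel(
        m=8, weights=np.full(8, 1 / 8), sds=np.full(8, 0.1), loglik=0.0
    )
    C.assign_copy_number([clear], model2)
    assert clear.assigned_cn == 3 and clear.posterior > 0.99

    low = C.CnSegment("c", 0, 10, mean_log2=np.log2(0.3) - 1, n_bins=5)
    C.assign_copy_number([low], model2)
    assert low.assigned_cn == 0  # below half of the CN-1 expectation


def test_cn_zero_rule_boundary():
    model = C.CnMixtureModel(
        m=8, weights=np.full(8, 1 / 8), sds=np.full(8, 0.1), loglik=0.0
    )
    at = C.CnSegment("c", 0, 10, mean_log2=np.log2(0.5) - 1, n_bins=5)
    C.assign_copy_number([at], model)
    assert at.assigned_cn != 0  # rule is strict <0.5


# --------------------------------------------------------------- cn_histogram
def test_cn_histogram_fractions():
    segs = [
        C.CnSegment("c", 0, 1_000_000, mean_log2=np.log2(3) - 1, n_bins=100),
        C.CnSegment("c", 1_000_000, 2_000_000, mean_log2=0.0, n_bins=100),
    ]
    segs[0].assigned_cn = 3
    segs[1].assigned_cn = None
    hist = C.cn_histogram(segs)
    assert hist == {3: 0.5, "NA": 0.5}
    assert sum(hist.values()) == pytest.approx(1.0, abs=1e-12)


# -------------------------------------------------------- chain invariants
def test_calibration_equivariance(small_genome, small_config, ones_track):
    """Scaling the whole coverage track leaves assigned CN unchanged."""
    from linescape.simulate import simulate_coverage
    from tests.conftest import find_cn_run

    cov = simulate_coverage(small_genome, small_config)
    gc = small_genome.gc_track()
    region = region_cn = None
    for target in (2, 3, 4):
        region = find_cn_run(small_genome.truth_cn.df, target, min_bins=10)
        if region is not None:
            region_cn = target
            break
    assert region is not None
    segs1, _, _ = C.call_copy_number(
        cov, gc, ones_track, region, calibration_cn=region_cn, seed=0
    )
    scaled = cov.with_values(cov.values * 3.7)
    segs2, _, _ = C.call_copy_number(
        scaled, gc, ones_track, region, calibration_cn=region_cn, seed=0
    )
    assert [s.assigned_cn for s in segs1] == [s.assigned_cn for s in segs2]


def test_na_monotonicity(small_genome, small_config):
    """No stage converts an NA bin into a number."""
    import numpy as np

    from linescape.simulate import simulate_coverage

    cov = simulate_coverage(small_genome, small_config)
    gc = small_genome.gc_track()
    frac = np.ones(len(cov))
    frac[[3, 17, 50]] = 0.2  # force NA bins
    mapp = cov.with_values(frac)
    corrected = C.mappability_correct(cov, mapp)
    assert np.isnan(corrected.values[[3, 17, 50]]).all()
    adjusted = C.gc_adjust(corrected, gc)
    assert np.isnan(adjusted.values[[3, 17, 50]]).all()
    log2t, _ = C.log2_ratio(adjusted, (cov.df["chrom"][0], 0, 1_000_000))
    assert np.isnan(log2t.values[[3, 17, 50]]).all()
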