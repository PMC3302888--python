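"""Estimator correctness: TAC extraction, integrals, ratio methods, MRTM,
MRTM2, k2' pooling and the voxelwise parametric map."""

import numpy as np
import pytest

from pibquant.kinetics import (
    DynamicVolume,
    FrameSchedule,
    TimeActivityCurve,
    cumulative_integral,
    estimate_k2prime,
    fit_mrtm,
    fit_mrtm2,
    ito_ratio_bp,
    parametric_bp_map,
    read_tac_csv,
    static_ratio,
    tac_from_voi,
    write_tac_csv,
)
from pibquant.synthetic_data import (
    NoiseSpec,
    PhantomLayout,
    PlasmaInputParams,
    SRTMParams,
    make_frame_schedule,
    reference_curve,
    simulate_dynamic_volume,
    simulate_tac_pair,
    simulate_target_tac,
)


def _toy_tac(values, durations=None):
    values = np.asarray(values, dtype=float)
    durations = np.full(values.size, 60.0) if durations is None else np.asarray(durations, float)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return TimeActivityCurve(FrameSchedule(starts, durations), values)


# ---------------------------------------------------------------------------
# VOI extraction and integrals
# ---------------------------------------------------------------------------


def test_tac_from_voi_uniform_and_checkerboard(schedule_52f):
    sch = make_frame_schedule([(2, 60.0)])
    data = np.zeros((4, 4, 4, 2))
    data[..., 0] = 3.0
    checker = np.indices((4, 4, 4)).sum(axis=0) % 2
    data[..., 1] = np.where(checker, 5.0, 1.0)
    vol = DynamicVolume(data, (1, 1, 1), sch)
    mask = np.ones((4, 4, 4), dtype=int)
    tac = tac_from_voi(vol, mask, 1)
    assert tac.value[0] == pytest.approx(3.0)
    assert tac.value[1] == pytest.approx(3.0)  # (1+5)/2 over equal coverage
    with pytest.raises(ValueError, match="not present"):
        tac_from_voi(vol, mask, 9)


def test_cumulative_integral_constant_and_zero():
    const = _toy_tac([2.0, 2.0, 2.0])
    assert cumulative_integral(const, 180.0) == pytest.approx(360.0)
    zero = _toy_tac([0.0, 0.0])
    assert cumulative_integral(zero, 100.0) == 0.0
    with pytest.raises(ValueError):
        cumulative_integral(const, 500.0)


def test_cumulative_integral_matches_dense_quadrature(noiseless_pair):
    """Frame-level trapezoid vs a dense-grid quadrature of the same
    continuous curve: agreement within 0.5%."""
    ref, tgt, params = noiseless_pair
    plasma = PlasmaInputParams()
    t_min = np.arange(0.0, 60.0 + 1e-9, 0.05 / 60.0)
    cont = reference_curve(plasma, params, t_min)
    t_s = cont.t_min * 60.0
    dense = np.trapezoid(cont.value[t_s <= 1800.0], t_s[t_s <= 1800.0])
    assert cumulative_integral(ref, 1800.0) == pytest.approx(dense, rel=5e-3)


def test_cumulative_integral_monotone_for_nonnegative(noiseless_pair):
    ref, _, _ = noiseless_pair
    ts = np.linspace(0.0, 3600.0, 25)
    vals = [cumulative_integral(ref, t) for t in ts]
    assert np.all(np.diff(vals) >= 0)


# ---------------------------------------------------------------------------
# ratio methods
# ---------------------------------------------------------------------------


def test_static_ratio_identity_and_hand_value():
    tac = _toy_tac(np.arange(1.0, 31.0), durations=np.full(30, 60.0))
    assert static_ratio(tac, tac) == pytest.approx(1.0)
    # hand-computed: frames 21..30 cover 20-30 min; mean target 25.5
    flat = _toy_tac(np.full(30, 2.0))
    assert static_ratio(tac, flat) == pytest.approx(25.5 / 2.0)
    with pytest.raises(ValueError):
        static_ratio(tac, _toy_tac(np.zeros(30)))


def test_ito_ratio_identity_and_scale_invariance(noiseless_pair):
    ref, tgt, _ = noiseless_pair
    assert ito_ratio_bp(ref, ref) == pytest.approx(0.0, abs=1e-12)
    scaled_t = TimeActivityCurve(tgt.schedule, 2.0 * tgt.value)
    scaled_r = TimeActivityCurve(ref.schedule, 2.0 * ref.value)
    assert ito_ratio_bp(scaled_t, scaled_r) == pytest.approx(ito_ratio_bp(tgt, ref), rel=1e-12)
    assert static_ratio(scaled_t, scaled_r) == pytest.approx(static_ratio(tgt, ref), rel=1e-12)


def test_ito_ratio_approaches_bp_from_below(slow_plasma, schedule_52f):
    """For BP_ND = 0.5 the AUC-ratio estimate sits in (0, 0.5] and grows
    toward 0.5 as the window moves late (transient equilibrium)."""
    params = SRTMParams.consistent(bp_nd=0.5)
    ref, tgt = simulate_tac_pair(slow_plasma, params, schedule_52f)
    estimates = [ito_ratio_bp(tgt, ref, w) for w in [(5, 15), (15, 25), (25, 35)]]
    assert np.all(np.diff(estimates) > 0)
    assert all(0 < e <= 0.5 + 1e-6 for e in estimates)


# ---------------------------------------------------------------------------
# MRTM / MRTM2
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("bp", [-0.1, 0.06, 0.5, 1.0, 2.0])
def test_mrtm_and_mrtm2_recover_bp(plasma, schedule_52f, bp):
    """Noiseless consistent kinetics: both models recover BP_ND within 2%
    (absolute 0.005 near zero) and MRTM recovers k2' within 5%."""
    params = SRTMParams.consistent(bp_nd=bp)
    ref, tgt = simulate_tac_pair(plasma, params, schedule_52f)
    m = fit_mrtm(tgt, ref, t_star_min=5.0)
    m2 = fit_mrtm2(tgt, ref, params.ref_k2prime, t_star_min=5.0)
    tol = max(0.02 * abs(bp), 0.005)
    assert abs(m.bp_nd - bp) <= tol
    assert abs(m2.bp_nd - bp) <= tol
    assert m.k2prime == pytest.approx(params.ref_k2prime, rel=0.05)
    assert m.dvr == m.bp_nd + 1.0
    assert m2.dvr == m2.bp_nd + 1.0


def test_mrtm_target_equals_reference(noiseless_pair):
    ref, _, _ = noiseless_pair
    fit = fit_mrtm(ref, ref, t_star_min=5.0)
    assert fit.ok
    assert fit.bp_nd == pytest.approx(0.0, abs=1e-8)
    fit2 = fit_mrtm2(ref, ref, 0.15, t_star_min=5.0)
    assert fit2.bp_nd == pytest.approx(0.0, abs=1e-8)


def test_mrtm_negative_bp_preserved(plasma, schedule_52f):
    """Control-like kinetics yield a negative BP_ND, never clamped."""
    params = SRTMParams.consistent(bp_nd=-0.06)
    ref, tgt = simulate_tac_pair(plasma, params, schedule_52f)
    assert fit_mrtm(tgt, ref, 5.0).bp_nd < 0


def test_mrtm_degenerate_design_never_raises():
    """A rank-deficient design must not raise (voxelwise safety): an
    exactly proportional pair resolves to BP = c - 1 with k2'
    unidentifiable, flagged in the message."""
    flat = _toy_tac(np.full(30, 1.0))
    fit = fit_mrtm(flat, flat, t_star_min=0.0)
    assert fit.ok
    assert fit.bp_nd == pytest.approx(0.0)
    assert np.isnan(fit.k2prime)
    assert "proportional" in fit.message
    double = _toy_tac(np.full(30, 2.0))
    assert fit_mrtm(double, flat, t_star_min=0.0).bp_nd == pytest.approx(1.0)


def test_mrtm2_noisy_bias_bounded(plasma, schedule_52f):
    """200 noisy replicates: mean BP_ND bias within 10% of truth."""
    params = SRTMParams.consistent(bp_nd=0.5)
    t_min = np.arange(0.0, 60.0 + 1e-9, 0.25 / 60.0)
    ref_cont = reference_curve(plasma, params, t_min)
    ref, _ = simulate_tac_pair(plasma, params, schedule_52f)
    noise = NoiseSpec(scale=0.6)
    bps = []
    for s in range(200):
        tgt = simulate_target_tac(ref_cont, params, schedule_52f, noise, seed=s)
        fit = fit_mrtm2(tgt, ref, params.ref_k2prime, 5.0)
        if fit.ok:
            bps.append(fit.bp_nd)
    assert abs(np.mean(bps) - 0.5) <= 0.05


def test_estimate_k2prime_pooling(plasma, schedule_52f):
    params = SRTMParams.consistent(bp_nd=0.5)
    ref, tgt = simulate_tac_pair(plasma, params, schedule_52f)
    regions = []
    for bp in (0.3, 0.5, 0.8, 1.2):
        _, t = simulate_tac_pair(plasma, SRTMParams.consistent(bp_nd=bp), schedule_52f)
        regions.append(t)
    pooled = estimate_k2prime(ref, regions, 5.0)
    assert pooled == pytest.approx(params.ref_k2prime, rel=0.05)
    # identical TACs pool to the single-region estimate
    single = fit_mrtm(tgt, ref, 5.0).k2prime
    assert estimate_k2prime(ref, [tgt] * 4, 5.0) == pytest.approx(single, rel=1e-12)


def test_estimate_k2prime_survives_one_bad_region(plasma, schedule_52f):
    params = SRTMParams.consistent(bp_nd=0.5)
    ref, tgt = simulate_tac_pair(plasma, params, schedule_52f)
    bad = _toy_tac(np.full(52, 1.0), durations=ref.schedule.frame_duration)
    with pytest.warns(UserWarning, match="excluded"):
        pooled = estimate_k2prime(ref, [tgt, tgt, tgt, bad], 5.0)
    assert pooled == pytest.approx(params.ref_k2prime, rel=0.05)


# ---------------------------------------------------------------------------
# parametric maps
# ---------------------------------------------------------------------------


def test_parametric_map_constant_per_region_and_matches_voi(plasma, schedule_52f):
    layout = PhantomLayout()
    region_params = {1: SRTMParams.consistent(0.5), 2: SRTMParams.consistent(0.0)}
    vol, labels = simulate_dynamic_volume(layout, region_params, schedule_52f, plasma=plasma)
    ref = tac_from_voi(vol, labels, 2)
    tgt = tac_from_voi(vol, labels, 1)
    k2p = fit_mrtm(tgt, ref, 5.0).k2prime
    bp_map, n_failed = parametric_bp_map(vol, ref, k2p, labels > 0, 5.0)
    assert n_failed == 0
    region = bp_map[labels == 1]
    assert np.nanstd(region) < 1e-9  # constant within the noiseless region
    voi_bp = fit_mrtm2(tgt, ref, k2p, 5.0).bp_nd
    assert np.nanmean(region) == pytest.approx(voi_bp, rel=0.03)
    assert np.all(np.isnan(bp_map[labels == 0]))


def test_parametric_map_all_zero_volume_fails_everywhere(schedule_52f, noiseless_pair):
    ref, _, _ = noiseless_pair
    vol = DynamicVolume(np.zeros((6, 6, 6, 52)), (1, 1, 1), schedule_52f)
    bp_map, n_failed = parametric_bp_map(vol, ref, 0.15, None, 5.0)
    assert n_failed == 6**3
    assert np.all(np.isnan(bp_map))


# ---------------------------------------------------------------------------
# interchange
# ---------------------------------------------------------------------------


def test_tac_csv_roundtrip(tmp_path, noiseless_pair):
    ref, _, _ = noiseless_pair
    path = tmp_path / "tac.csv"
    write_tac_csv(ref, path)
    back = read_tac_csv(path)
    np.testing.assert_allclose(back.value, ref.value)
    np.testing.assert_allclose(back.schedule.frame_start, ref.schedule.frame_start)
    assert back.region_label == ref.region_label
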