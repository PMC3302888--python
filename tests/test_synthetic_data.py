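"""Generator correctness: schedules, SRTM forward model, assay plates,
plaque images, dual-label exposures and the multimodal cohort."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from pibquant.autoradiography import C11, H3
from pibquant.histology import relative_plaque_burden
from pibquant.kinetics import FrameSchedule
from pibquant.synthetic_data import (
    AssayDesign,
    ContinuousCurve,
    GroupParams,
    NoiseSpec,
    PhantomLayout,
    PhantomRegion,
    PlasmaInputParams,
    CohortSpec,
    SiteTruth,
    SRTMParams,
    default_cohort_spec,
    make_frame_schedule,
    reference_curve,
    simulate_binding_assay,
    simulate_cohort,
    simulate_dual_label_autoradiograph,
    simulate_dynamic_volume,
    simulate_plaque_image,
    simulate_reference_tac,
    simulate_tac_pair,
    simulate_target_tac,
    target_curve,
)
from pibquant.kinetics import tac_from_voi


# ---------------------------------------------------------------------------
# frame schedules
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "code,n_frames,total_s",
    [("52f", 52, 3600.0), ("162f", 162, 3600.0)],
)
def test_named_schedules(code, n_frames, total_s):
    sch = make_frame_schedule(code)
    assert sch.n_frames == n_frames
    assert sch.total_duration == total_s
    assert sch.frame_start[0] == 0.0
    # contiguity: starts equal cumulative durations
    np.testing.assert_allclose(sch.frame_start[1:], np.cumsum(sch.frame_duration)[:-1])


def test_explicit_schedule_and_errors():
    sch = make_frame_schedule([(1, 60.0)])
    assert sch.n_frames == 1 and sch.total_duration == 60.0
    with pytest.raises(ValueError):
        make_frame_schedule("nope")
    with pytest.raises(ValueError):
        make_frame_schedule([(2, -5.0)])


# ---------------------------------------------------------------------------
# SRTM forward model
# ---------------------------------------------------------------------------


def test_reference_tac_zero_plasma_flagged(schedule_52f):
    dead = PlasmaInputParams(amplitude=0.0)
    with pytest.raises(ValueError, match="degenerate"):
        simulate_reference_tac(dead, SRTMParams(), schedule_52f)


def test_reference_tac_linear_in_delivery(plasma, schedule_52f):
    lo = simulate_reference_tac(plasma, SRTMParams(ref_k1=0.3), schedule_52f)
    hi = simulate_reference_tac(plasma, SRTMParams(ref_k1=0.6), schedule_52f)
    np.testing.assert_allclose(hi.value, 2.0 * lo.value, rtol=1e-12)
    assert np.all(lo.value >= 0)


def test_reference_tac_matches_analytic_monoexponential(schedule_52f):
    """Numerical convolution vs closed form for Cp = A exp(-a t):
    C_R = K1*A*(exp(-a t) - exp(-k2' t))/(k2' - a), frame-averaged."""
    a, k2p, K1, A = 0.08, 0.15, 0.3, 100.0
    plasma = PlasmaInputParams(amplitude=A, shape=0.0, clearance_per_min=a, tail_fraction=0.0)
    tac = simulate_reference_tac(plasma, SRTMParams(ref_k2prime=k2p, ref_k1=K1), schedule_52f)

    t0 = schedule_52f.frame_start / 60.0
    t1 = schedule_52f.frame_end / 60.0

    def antideriv(t):  # integral of the closed-form curve
        return K1 * A * (-np.exp(-a * t) / a + np.exp(-k2p * t) / k2p) / (k2p - a)

    expected = (antideriv(t1) - antideriv(t0)) / (t1 - t0)
    np.testing.assert_allclose(tac.value, expected, rtol=1e-3)


def test_target_identity_kinetics(plasma, schedule_52f):
    """R1=1, BP=0, k2=k2' makes target and reference identical."""
    params = SRTMParams(r1=1.0, k2=0.15, bp_nd=0.0, ref_k2prime=0.15)
    ref_tac, tgt = simulate_tac_pair(plasma, params, schedule_52f)
    np.testing.assert_allclose(tgt.value, ref_tac.value, rtol=1e-10)


def test_target_late_ratio_approaches_dvr(slow_plasma, schedule_52f):
    """With a slowly clearing input, the target/reference ratio rises
    toward DVR = 1 + BP_ND late in the scan."""
    params = SRTMParams.consistent(bp_nd=1.0)
    ref, tgt = simulate_tac_pair(slow_plasma, params, schedule_52f)
    ratio = tgt.value / ref.value
    late = ratio[-3:]
    assert np.all(np.diff(ratio[schedule_52f.midpoint > 300]) > -1e-9)
    assert late[-1] == pytest.approx(2.0, abs=0.05)


def test_control_like_negative_bp_ratio_below_one(plasma, schedule_52f):
    from pibquant.kinetics import static_ratio

    params = SRTMParams.consistent(bp_nd=-0.06)
    ref, tgt = simulate_tac_pair(plasma, params, schedule_52f)
    assert static_ratio(tgt, ref, (20.0, 30.0)) < 1.0


def test_srtm_simulator_matches_ode_oracle(plasma, schedule_52f):
    """Independent Runge-Kutta integration of the two-compartment equations
    agrees with the convolution simulator to <0.2% per frame."""
    params = SRTMParams.consistent(bp_nd=0.5)
    t_min = np.arange(0.0, 60.0 + 1e-9, 1.0 / 60.0)  # 1 s resolution
    ref = reference_curve(plasma, params, t_min)
    tgt = target_curve(ref, params)

    def rhs(t, y):
        cp = plasma(np.array([t]))[0]
        cr, ct = y
        dcr = params.ref_k1 * cp - params.ref_k2prime * cr
        # one-tissue target driven by plasma with K1 = R1*K1', k2a apparent
        dct = params.r1 * params.ref_k1 * cp - params.k2a * ct
        return [dcr, dct]

    sol = solve_ivp(rhs, (0.0, 60.0), [0.0, 0.0], t_eval=t_min, method="RK45",
                    rtol=1e-10, atol=1e-12)
    scale = np.max(sol.y[0])
    assert np.max(np.abs(sol.y[0] - ref.value)) / scale < 2e-3
    assert np.max(np.abs(sol.y[1] - tgt.value)) / scale < 2e-3


def test_target_noise_reproducible_by_seed(plasma, schedule_52f):
    params = SRTMParams.consistent(bp_nd=0.5)
    t_min = np.arange(0.0, 60.0 + 1e-9, 0.25 / 60.0)
    ref = reference_curve(plasma, params, t_min)
    noise = NoiseSpec(scale=1.0)
    a = simulate_target_tac(ref, params, schedule_52f, noise, seed=11)
    b = simulate_target_tac(ref, params, schedule_52f, noise, seed=11)
    c = simulate_target_tac(ref, params, schedule_52f, noise, seed=12)
    np.testing.assert_array_equal(a.value, b.value)
    assert np.any(a.value != c.value)


def test_invalid_kinetics_rejected():
    with pytest.raises(ValueError):
        SRTMParams(bp_nd=-1.5)
    with pytest.raises(ValueError):
        SRTMParams(k2=0.0)
    params = SRTMParams(k2=0.12, bp_nd=0.5)
    assert params.k2a == pytest.approx(0.12 / 1.5, rel=1e-15)


# ---------------------------------------------------------------------------
# dynamic volumes
# ---------------------------------------------------------------------------


def test_phantom_voi_means_match_region_tacs(plasma, schedule_52f):
    layout = PhantomLayout()
    params = {1: SRTMParams.consistent(0.5), 2: SRTMParams.consistent(0.0)}
    vol, labels = simulate_dynamic_volume(layout, params, schedule_52f, plasma=plasma)
    # label map voxel counts match an independent geometric count
    grid = np.indices(layout.shape, dtype=float)
    for region in layout.regions:
        d2 = sum((grid[i] - region.center[i]) ** 2 for i in range(3))
        assert (labels == region.label).sum() == (d2 <= region.radius**2).sum()
    # noiseless: VOI mean equals the region kinetics exactly
    t_min = np.arange(0.0, 60.0 + 1e-9, 0.25 / 60.0)
    ref = reference_curve(plasma, params[1], t_min)
    for label in (1, 2):
        expected = simulate_target_tac(ref, params[label], schedule_52f)
        np.testing.assert_allclose(
            tac_from_voi(vol, labels, label).value, expected.value, rtol=1e-9
        )


def test_phantom_overlap_rejected():
    layout = PhantomLayout(
        regions=(PhantomRegion(1, (16, 16, 16), 8.0), PhantomRegion(2, (20, 16, 16), 8.0))
    )
    with pytest.raises(ValueError, match="overlaps"):
        layout.label_map()


# ---------------------------------------------------------------------------
# binding assay plates
# ---------------------------------------------------------------------------


def test_assay_design_defaults_match_plate_protocol():
    design = AssayDesign()
    assert len(design.concentration_nm) == 12
    assert design.concentration_nm[0] == pytest.approx(0.2)
    assert design.concentration_nm[-1] == pytest.approx(48.0)
    assert design.replicates == 8


def test_assay_noiseless_half_saturation():
    """At L = Kd the specific component of the total well is Bmax/2."""
    truth = SiteTruth(kd=(5.0,), bmax=(120.0,), ns=1.5)
    design = AssayDesign(concentration_nm=(2.5, 5.0, 10.0, 20.0), replicates=2)
    data = simulate_binding_assay(truth, design, noise_cv=0.0)
    specific = data.total[:, 0] - data.nonspecific[:, 0]
    assert specific[1] == pytest.approx(60.0, rel=1e-12)


def test_assay_seed_reproducibility():
    truth = SiteTruth()
    a = simulate_binding_assay(truth, noise_cv=0.05, seed=3)
    b = simulate_binding_assay(truth, noise_cv=0.05, seed=3)
    c = simulate_binding_assay(truth, noise_cv=0.05, seed=4)
    np.testing.assert_array_equal(a.total, b.total)
    assert np.any(a.total != c.total)


def test_two_site_semilog_plateaus():
    """Well-separated sites give a double-sigmoid specific curve on the
    semilog axis: a flat stretch between the two rises."""
    truth = SiteTruth(kd=(0.5, 100.0), bmax=(80.0, 80.0), ns=0.0)
    logl = np.linspace(-3, 5, 800)
    y = truth.specific(10.0**logl)
    dy = np.gradient(y, logl)
    i_mid = np.argmin(np.abs(logl - np.log10(np.sqrt(0.5 * 100.0))))
    left_peak = dy[: i_mid].max()
    right_peak = dy[i_mid:].max()
    # bimodal slope: a dip between the two transition peaks
    assert dy[i_mid] < 0.75 * left_peak
    assert dy[i_mid] < 0.75 * right_peak


# ---------------------------------------------------------------------------
# plaque images
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def neocortex_roi():
    roi = np.zeros((384, 384), dtype=bool)
    roi[30:354, 30:354] = True
    return roi


def test_plaque_image_zero_burden(neocortex_roi):
    imgs, truth, _ = simulate_plaque_image(neocortex_roi, 0.0, seed=0)
    assert truth.n_objects == 0 if truth.areas_um2.size else True
    assert truth.areas_um2.size == 0
    assert imgs["thioS"].dtype == np.uint16


@pytest.mark.parametrize("burden", [4.68, 11.78])
def test_plaque_image_hits_target_burden(neocortex_roi, burden):
    """Rendered union-mask burden lands within 0.1 percentage points."""
    _, truth, _ = simulate_plaque_image(neocortex_roi, burden, seed=1)
    assert relative_plaque_burden(truth) == pytest.approx(burden, abs=0.1)


def test_plaque_image_channels_consistent(neocortex_roi):
    imgs, truth, channels = simulate_plaque_image(neocortex_roi, 6.0, seed=2)
    # thioS truth carries every plaque; antibody channels are subsets
    assert channels["ab40"].areas_um2.sum() <= truth.areas_um2.sum() + 1e-9
    assert channels["ab42"].areas_um2.sum() <= truth.areas_um2.sum() + 1e-9
    assert set(imgs) == {"thioS", "ab40", "ab42"}


def test_plaque_image_unreachable_burden():
    tiny = np.zeros((64, 64), dtype=bool)
    tiny[30:34, 30:34] = True  # 16 px ROI cannot take 40% in 0.1 pp steps
    with pytest.raises(ValueError, match="unreachable"):
        simulate_plaque_image(tiny, 39.0, radius_median_um=200.0, seed=0)


# ---------------------------------------------------------------------------
# dual-label exposures
# ---------------------------------------------------------------------------


def test_dual_label_pure_tritium_constant_rate():
    A = np.full((16, 16), 200.0)
    bins = [(0.0, 10.0), (10.0, 20.0), (20.0, 30.0)]
    stack = simulate_dual_label_autoradiograph(A, np.zeros_like(A), (H3, C11), bins, seed=5)
    rates = stack.sum(axis=(1, 2)) / 10.0
    assert np.ptp(rates) / rates.mean() < 0.02  # Poisson scatter only


def test_dual_label_pure_c11_decay_factor():
    B = np.full((32, 32), 3000.0)
    dt = 10.0
    bins = [(i * dt, (i + 1) * dt) for i in range(4)]
    stack = simulate_dual_label_autoradiograph(np.zeros_like(B), B, (H3, C11), bins, seed=6)
    totals = stack.sum(axis=(1, 2))
    expected = np.exp(-C11.lam_per_min * dt)
    ratios = totals[1:] / totals[:-1]
    np.testing.assert_allclose(ratios, expected, rtol=0.02)


def test_dual_label_bin_validation():
    A = np.zeros((4, 4))
    with pytest.raises(ValueError):
        simulate_dual_label_autoradiograph(A, A, (H3, C11), [(0.0, 0.0)], seed=0)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def test_cohort_zero_sd_gives_group_means():
    g = GroupParams(n=3, means={"pet_bpnd": 1.0, "autoradio_ratio": 2.0},
                    sds={"pet_bpnd": 0.0, "autoradio_ratio": 0.0})
    spec = CohortSpec(groups={"tgtg-old": g}, correlation=0.5, seed=0)
    tab = simulate_cohort(spec)
    assert np.all(tab.pet_bpnd == 1.0)
    assert np.all(tab.autoradio_ratio == 2.0)


def test_cohort_group_means_within_2_sem():
    """Monte-Carlo check: sample means near spec means at the study n."""
    spec = default_cohort_spec(seed=123)
    tab = simulate_cohort(spec)
    for group, params in spec.groups.items():
        sub = tab[tab.group == group]
        for m, mean in params.means.items():
            if mean is None:
                assert sub[m].isna().all()
                continue
            sem = params.sds[m] / np.sqrt(params.n)
            assert abs(sub[m].mean() - mean) <= 2.5 * sem + 1e-12


def test_cohort_autoradio_ordering():
    """Group means preserve the severity ordering of the uptake ratios."""
    means = {}
    for s in range(5):
        tab = simulate_cohort(default_cohort_spec(seed=s))
        for g, v in tab.groupby("group")["autoradio_ratio"].mean().items():
            means.setdefault(g, []).append(v)
    avg = {g: np.mean(v) for g, v in means.items()}
    assert avg["tgtg-old"] > avg["tg-old"] > avg["tgtg-young"] > avg["ctl-old"]


def test_cohort_correlation_converges():
    """Empirical cross-modality correlation approaches the spec value at
    large n."""
    spec = default_cohort_spec(seed=9, n_override={g: 10_000 for g in
                                                   ("tg-old", "tgtg-young", "tgtg-old", "ctl-old")})
    tab = simulate_cohort(spec)
    sub = tab[tab.group == "tgtg-old"]
    r = np.corrcoef(sub.pet_bpnd, sub.thioS_burden_pct)[0, 1]
    assert r == pytest.approx(spec.correlation, abs=0.03)


def test_cohort_seed_reproducibility():
    a = simulate_cohort(default_cohort_spec(seed=5))
    b = simulate_cohort(default_cohort_spec(seed=5))
    c = simulate_cohort(default_cohort_spec(seed=6))
    assert a.equals(b)
    assert not a.equals(c)


def test_cohort_non_psd_correlation_rejected():
    spec = default_cohort_spec(seed=0, correlation=-0.9)
    with pytest.raises(ValueError, match="positive semidefinite"):
        simulate_cohort(spec)
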