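import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from fenestra.trace_analysis import (
    AnalysisError,
    RatioTrace,
    Trace,
    average_controls,
    baseline_subtract,
    control_ratio_min,
    detect_preinhibition_peak,
    fit_decay,
    jump_control_constant,
    lowpass_presentation,
    min_windowed,
    normalized_min,
    point_by_point_ratio,
    qc_evaluate,
    ratio_at_marker,
)

from conftest import synthetic_sweep


def constant_trace(value, n=2000, fs=1000.0, onset_s=0.5):
    return Trace(np.full(n, float(value)), fs, t0_s=0.0,
                 metadata={"onset_s": onset_s})


# --------------------------------------------------------------------------
# elementary operations


def test_average_controls():
    c = synthetic_sweep()
    same = average_controls(c, c)
    n = c.n - c.onset_index()
    assert np.allclose(same.current_pA, c.current_pA[c.onset_index():][:n])
    two, four = constant_trace(2.0), constant_trace(4.0)
    assert np.allclose(average_controls(two, four).current_pA, 3.0)
    bad = Trace(np.zeros(100), 500.0, metadata={"onset_s": 0.1})
    with pytest.raises(AnalysisError):
        average_controls(two, bad)  # mismatched sampling rates


def test_baseline_subtract():
    flat = constant_trace(-35.0)
    assert np.allclose(baseline_subtract(flat).current_pA, 0.0)
    sweep = synthetic_sweep()
    offset = sweep.copy_with(sweep.current_pA - 120.0)
    assert np.allclose(baseline_subtract(offset).current_pA,
                       baseline_subtract(sweep).current_pA)
    with pytest.raises(AnalysisError):
        baseline_subtract(sweep, pre_onset_window_ms=2000.0)  # longer than pre-onset data


def test_point_by_point_ratio():
    a = synthetic_sweep()
    r = point_by_point_ratio(a, a)
    assert np.allclose(r.ratio[r.valid], 1.0)
    half = a.copy_with(0.5 * a.current_pA)
    r2 = point_by_point_ratio(half, a)
    assert np.allclose(r2.ratio[r2.valid], 0.5)
    # mask covers exactly the low-current region
    assert not r.valid[0]
    with pytest.raises(AnalysisError):
        point_by_point_ratio(a, a.copy_with(np.zeros(a.n)))


# --------------------------------------------------------------------------
# windowed minimum: brute-force oracle


def brute_force_windowed_min(ratio: RatioTrace, window_ms, search_from_s=None):
    """Exhaustive scan over every admissible centered window placement."""
    n_w = max(1, int(round(window_ms / 1000.0 * ratio.sampling_rate_Hz)))
    n_w += 1 - n_w % 2
    half = n_w // 2
    sel = ratio.valid.copy()
    if search_from_s is not None:
        sel &= ratio.t_s >= search_from_s
    idx = np.flatnonzero(sel)
    best = np.inf
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in runs:
        if run.size == 0:
            continue
        x = ratio.ratio[run]
        for i in range(x.size):
            lo, hi = max(0, i - half), min(x.size, i + half + 1)
            best = min(best, float(np.mean(x[lo:hi])))
    return best


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    window_ms=st.sampled_from([10.0, 30.0, 75.0]),
    gap=st.booleans(),
)
def test_min_windowed_matches_brute_force(seed, window_ms, gap):
    rng = np.random.default_rng(seed)
    n = 400
    values = 1.0 + 0.2 * rng.standard_normal(n)
    valid = np.ones(n, dtype=bool)
    valid[:10] = False
    if gap:
        lo = rng.integers(50, 300)
        valid[lo:lo + rng.integers(1, 60)] = False
    r = RatioTrace(t_s=np.arange(n) / 1000.0, ratio=values, valid=valid,
                   sampling_rate_Hz=1000.0)
    got = min_windowed(r, window_ms)
    assert got.value == pytest.approx(brute_force_windowed_min(r, window_ms), abs=1e-12)


def test_min_windowed_shapes():
    t = np.arange(1000) / 1000.0
    fs = 1000.0
    # V shape: symmetric minimum, window mean equals brute force
    v = np.abs(t - 0.5) + 0.3
    r = RatioTrace(t, v, np.ones_like(t, dtype=bool), fs)
    got = min_windowed(r, 30.0)
    assert got.value == pytest.approx(brute_force_windowed_min(r, 30.0), abs=1e-12)
    assert got.time_s == pytest.approx(0.5, abs=0.002)
    # constant input returns the constant
    rc = RatioTrace(t, np.full_like(t, 0.5), np.ones_like(t, dtype=bool), fs)
    assert min_windowed(rc, 30.0).value == pytest.approx(0.5)
    # monotone ratio: the window abuts the valid-region edge
    rm = RatioTrace(t, 1.0 - 0.5 * t, np.ones_like(t, dtype=bool), fs)
    got_m = min_windowed(rm, 30.0)
    assert got_m.time_s == pytest.approx(t[-1])
    assert got_m.value == pytest.approx(np.mean(rm.ratio[-16:]), abs=1e-12)
    with pytest.raises(AnalysisError):
        min_windowed(rc, 30.0, search_from_s=2.0)  # nothing in range


# --------------------------------------------------------------------------
# normalization


def test_control_ratio_min_constants():
    c1 = constant_trace(-1000.0)
    c2 = constant_trace(-900.0)
    # minima of the two constant ratios are 0.9 and 1/0.9; their mean
    assert control_ratio_min(c1, c2) == pytest.approx(0.5 * (0.9 + 1 / 0.9), rel=1e-9)
    assert control_ratio_min(c1, c1) == pytest.approx(1.0)


def test_normalized_min():
    # pH 9.0 jump normalization: raw 0.296 over the 0.906 control constant
    assert normalized_min(0.296, 0.906) == pytest.approx(0.327, abs=5e-4)
    assert normalized_min(0.42, 1.0) == 0.42
    with pytest.raises(AnalysisError):
        normalized_min(0.5, 0.0)


def test_jump_control_constant():
    mean, sem = jump_control_constant([1.0, 1.0, 1.0])
    assert mean == 1.0 and sem == 0.0
    mean2, sem2 = jump_control_constant([0.9, 0.92, 0.88])
    assert mean2 == pytest.approx(0.9)
    assert sem2 > 0
    with pytest.raises(AnalysisError):
        jump_control_constant([])


def test_normalization_cancels_selection_bias():
    """Zero-drug runs with noise: picking the minimum biases the raw value
    below 1; dividing by the control-ratio minimum removes most of it."""
    raws, norms = [], []
    for seed in range(120):
        rng = np.random.default_rng(seed)
        c1 = synthetic_sweep(rng, noise_sd_pA=8.0)
        c2 = synthetic_sweep(rng, noise_sd_pA=8.0)
        mci = synthetic_sweep(rng, noise_sd_pA=8.0)
        c1b, c2b = baseline_subtract(c1), baseline_subtract(c2)
        ratio = point_by_point_ratio(baseline_subtract(mci), average_controls(c1b, c2b))
        raw = min_windowed(ratio, 30.0, search_from_s=0.054).value
        norm = control_ratio_min(c1b, c2b, 30.0, search_from_s=0.054)
        raws.append(raw)
        norms.append(raw / norm)
    raws, norms = np.array(raws), np.array(norms)
    sem_raw = raws.std(ddof=1) / np.sqrt(raws.size)
    assert raws.mean() < 1.0 - 3.0 * sem_raw          # selection bias is real
    assert abs(norms.mean() - 1.0) < 0.25 * (1.0 - raws.mean())  # and mostly cancelled


# --------------------------------------------------------------------------
# peak detection and decay fitting


def test_preinhibition_peak_detection():
    sweep = synthetic_sweep()  # rises then sags: has a local maximum
    peak = detect_preinhibition_peak(sweep)
    assert peak.found and 0.0 < peak.time_s < 0.5
    ramp = Trace(-np.linspace(0, 1000, 2000), 1000.0, metadata={"onset_s": 0.5})
    assert not detect_preinhibition_peak(ramp).found


def test_zero_drug_peak_matches_control(zero_drug_sim):
    sweeps = zero_drug_sim.sweeps
    p_mci = detect_preinhibition_peak(baseline_subtract(sweeps["mci"]))
    p_ctl = detect_preinhibition_peak(baseline_subtract(sweeps["control1"]))
    assert p_mci.found and p_ctl.found
    assert p_mci.amplitude_pA == pytest.approx(p_ctl.amplitude_pA, rel=1e-3)


@pytest.mark.parametrize("tau_ms", [20.0, 100.0, 500.0, 2000.0])
def test_fit_decay_recovers_planted_tau(tau_ms):
    fs = 2000.0
    t = np.arange(int(10 * fs)) / fs
    r = 0.4 + 0.6 * np.exp(-t / (tau_ms / 1000.0))
    ratio = RatioTrace(t, r, np.ones_like(t, dtype=bool), fs)
    fit = fit_decay(ratio, start_s=0.0)
    assert fit.converged
    assert fit.tau_ms == pytest.approx(tau_ms, rel=0.01)
    assert fit.r_squared > 0.999


def test_fit_decay_flags_non_decaying():
    fs = 1000.0
    t = np.arange(2000) / fs
    ratio = RatioTrace(t, 0.5 + 0.5 * t / t[-1], np.ones_like(t, dtype=bool), fs)
    fit = fit_decay(ratio, start_s=0.0)
    assert not fit.converged
    with pytest.raises(AnalysisError):
        fit_decay(ratio, start_s=1.99)  # too few points after the start


def test_ratio_at_marker():
    t = np.arange(1000) / 1000.0
    r = RatioTrace(t, np.full_like(t, 0.35), np.ones_like(t, dtype=bool), 1000.0)
    assert ratio_at_marker(r, 0.5) == pytest.approx(0.35)
    with pytest.raises(AnalysisError):
        ratio_at_marker(r, 5.0)


# --------------------------------------------------------------------------
# QC rules


def test_qc_include():
    rec = qc_evaluate(-1000.0, -1100.0, 10.0, [-50.0, -70.0, -30.0])
    assert rec.decision == "include" and rec.reasons == ()


@pytest.mark.parametrize(
    "kwargs, reason",
    [
        (dict(peak_control1_pA=-1000.0, peak_control2_pA=-700.0, Rs_MOhm=10.0,
              holding_segments_pA=[-50.0]), "control_mismatch"),
        (dict(peak_control1_pA=-3000.0, peak_control2_pA=-2900.0, Rs_MOhm=10.0,
              holding_segments_pA=[-50.0]), "peak_current"),
        (dict(peak_control1_pA=-1000.0, peak_control2_pA=-1000.0, Rs_MOhm=25.0,
              holding_segments_pA=[-50.0]), "series_resistance"),
        (dict(peak_control1_pA=-1000.0, peak_control2_pA=-1000.0, Rs_MOhm=10.0,
              holding_segments_pA=[-250.0, -100.0]), "holding_current"),
        (dict(peak_control1_pA=-1000.0, peak_control2_pA=-1000.0, Rs_MOhm=10.0,
              holding_segments_pA=[-50.0, -180.0]), "holding_fluctuation"),
    ],
)
def test_qc_exclusion_rules(kwargs, reason):
    rec = qc_evaluate(**kwargs)
    assert rec.decision == "exclude"
    assert reason in rec.reasons


def test_qc_pure_function():
    args = (-1000.0, -1300.0, 22.0, [-250.0, -50.0])
    assert qc_evaluate(*args) == qc_evaluate(*args)
    assert set(qc_evaluate(*args).reasons) == {
        "control_mismatch", "series_resistance", "holding_current",
        "holding_fluctuation",
    }


# --------------------------------------------------------------------------
# presentation filter


def test_lowpass_dc_and_errors():
    flat = constant_trace(-200.0)
    assert np.allclose(lowpass_presentation(flat).current_pA, -200.0, atol=1e-6)
    with pytest.raises(AnalysisError):
        lowpass_presentation(flat, fc_Hz=600.0)  # at/above Nyquist


def test_lowpass_noise_variance_reduction():
    fs, fc, order = 5000.0, 50.0, 4
    rng = np.random.default_rng(11)
    noise = Trace(rng.standard_normal(200_000), fs, metadata={"onset_s": 1.0})
    out = lowpass_presentation(noise, fc_Hz=fc, order=order)
    # expected white-noise gain: integral of |H|^4 (forward+backward pass)
    sos = signal.bessel(order, fc / (fs / 2), btype="low", output="sos")
    w, h = signal.sosfreqz(sos, worN=20_000)
    expected = np.trapezoid(np.abs(h) ** 4, w) / np.pi
    got = out.current_pA.var() / noise.current_pA.var()
    assert got == pytest.approx(expected, rel=0.1)
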