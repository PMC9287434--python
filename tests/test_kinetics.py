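import numpy as np
import pytest

from fenestra.kinetics import (
    CellParams,
    GatingParams,
    MembraneReservoir,
    gillespie_reference,
    integrate_states,
    reservoir_dynamics,
    simulate_mci_experiment,
    solution_at_cell,
    synthesize_current,
)
from fenestra.protocol import Protocol, Segment, SolutionSpec, build_mci_protocol
from fenestra.protonation import CompoundSpec

MEM = CompoundSpec("memantine", "titratable_amine", pKa=10.4, kon_aq=46.0,
                   koff0=67.0, k_in=1.0, k_out=0.5, kon_mem=200.0)
TMM = CompoundSpec("tmm", "permanent_cation", kon_aq=1.1, koff0=67.0)


def _protocol(segments, fs=2000.0, onsets=()):
    return Protocol(label="test", segments=tuple(segments),
                    sampling_rate_Hz=fs, agonist_onset_markers_s=tuple(onsets))


# --------------------------------------------------------------------------
# solution exchange


def test_exchange_step_response():
    p = _protocol([
        Segment(1.0, SolutionSpec()),
        Segment(2.0, SolutionSpec(drug_name="memantine", drug_uM=100.0)),
        Segment(1.0, SolutionSpec()),
    ])
    d = solution_at_cell(p, MEM)
    # 1 - 1/e of the step at one exchange time constant
    assert d.drug_total(1.0 + 0.027) == pytest.approx(100.0 * (1 - np.e**-1), rel=1e-9)
    # residual after a 1 s wash: >30-fold longer than tau, essentially zero
    assert d.drug_total(4.0 - 1e-9) == pytest.approx(100.0 * np.exp(-1000.0 / 27.0), rel=1e-6)
    assert d.drug_total(4.0 - 1e-9) < 1e-13
    # constant segment stays constant
    assert d.agonist(0.5) == 0.0


def test_exchange_ph_relaxes_as_protons():
    p = _protocol([Segment(1.0, SolutionSpec(pH=7.2)), Segment(1.0, SolutionSpec(pH=9.0))])
    d = solution_at_cell(p, MEM)
    h_mid = 0.5 * (10**-7.2 + 10**-9.0)  # proton concentration, not pH, mixes
    t_half = 1.0 + 0.027 * np.log(2.0)
    assert 10 ** -d.pH(t_half) == pytest.approx(h_mid, rel=1e-6)


# --------------------------------------------------------------------------
# membrane reservoir


def test_reservoir_permanent_cation_empty():
    t = np.linspace(0, 10, 100)
    assert np.all(reservoir_dynamics(TMM, lambda t: 1.0, t) == 0.0)
    with pytest.raises(ValueError):
        MembraneReservoir(m=-1.0)


def test_reservoir_washout_time_constant():
    # k_out = 0.5/s: occupancy falls to 1/e of its start in 2 s
    t = np.linspace(0, 4, 401)
    m = reservoir_dynamics(MEM, lambda t: 0.0, t, m0=1.0)
    assert m[np.argmin(abs(t - 2.0))] == pytest.approx(np.e**-1, rel=1e-4)


def test_reservoir_steady_state():
    c = 0.05
    t = np.linspace(0, 60, 600)
    m = reservoir_dynamics(MEM, lambda t: c, t)
    assert m[-1] == pytest.approx(MEM.k_in * c / MEM.k_out, rel=1e-6)


# --------------------------------------------------------------------------
# state integration


def test_zero_drug_states_and_conservation():
    p = build_mci_protocol(MEM, 0.0, sampling_rate_Hz=1000.0)
    st = integrate_states(p, MEM)
    assert np.max(np.abs(st.B)) < 1e-12
    assert np.max(np.abs(st.occupancy_sum() - 1.0)) < 1e-8


def test_closed_channel_admits_no_block():
    """With no agonist ever applied, a loaded membrane reservoir produces
    zero block: both access paths are gated by the open state."""
    drug = SolutionSpec(drug_name="memantine", drug_uM=1000.0, pH=9.0)
    p = _protocol([Segment(30.0, drug), Segment(10.0, SolutionSpec(pH=9.0))], fs=200.0)
    no_aq = MEM.replace(kon_aq=0.0)
    st = integrate_states(p, no_aq)
    assert np.max(st.m) > 1.0  # the reservoir did load
    assert np.max(np.abs(st.B)) == 0.0
    assert np.max(np.abs(st.O)) == 0.0


def test_blocked_equilibrium_matches_two_state_closed_form():
    """Frozen gating (pure open state) reduces block to a two-state
    exchange: B/(B+O) = r/(r + koff) with r the association rate."""
    frozen = GatingParams(beta_open=500.0, alpha_close=0.0, kd_plus=0.0, kd_minus=1.0)
    sol = SolutionSpec(glutamate_uM=1000.0, drug_name="tmm", drug_uM=30.0)
    p = _protocol([Segment(80.0, sol)], fs=100.0)
    st = integrate_states(p, TMM, frozen)
    koff = TMM.koff0 * np.exp(-65.0 / TMM.v_efold)
    r = TMM.kon_aq * 30.0
    assert st.B[-1] / (st.B[-1] + st.O[-1]) == pytest.approx(r / (r + koff), rel=1e-4)


def test_fast_gating_relaxation_rate():
    """With gating much faster than block and p_open ~ 1, the open-state
    decay after a drug step relaxes at kon*c + koff within 5%."""
    fast = GatingParams(beta_open=2000.0, alpha_close=20.0, kd_plus=0.0, kd_minus=1.0)
    glu = SolutionSpec(glutamate_uM=1000.0)
    sol = SolutionSpec(glutamate_uM=1000.0, drug_name="tmm", drug_uM=5.0)
    p = _protocol([Segment(5.0, glu), Segment(20.0, sol)], fs=500.0)
    st = integrate_states(p, TMM, fast)
    koff = TMM.koff0 * np.exp(-65.0 / TMM.v_efold)
    rate = TMM.kon_aq * 5.0 + koff
    sel = (st.t > 5.5) & (st.t < 5.5 + 3.0 / rate)
    y = st.O[sel] - st.O[-1]
    slope = np.polyfit(st.t[sel], np.log(y), 1)[0]
    assert -slope == pytest.approx(rate, rel=0.05)


# --------------------------------------------------------------------------
# current synthesis


def test_current_trivials():
    p = build_mci_protocol(MEM, 0.0, sampling_rate_Hz=500.0)
    st = integrate_states(p, MEM)
    cell = CellParams(leak_pA=-20.0, noise_sd_pA=0.0)
    tr = synthesize_current(st, cell, p)
    # open channels at -65 mV carry inward current on top of the leak
    assert tr.current_pA.min() < -500.0
    zero = st
    zero.O = np.zeros_like(st.O)
    assert np.allclose(synthesize_current(zero, cell, p).current_pA, -20.0)


def test_current_gain_linearity():
    p = build_mci_protocol(MEM, 0.0, sampling_rate_Hz=500.0)
    st = integrate_states(p, MEM)
    c1 = CellParams(g_total_nS=30.0, leak_pA=-20.0)
    c2 = CellParams(g_total_nS=60.0, leak_pA=-20.0)
    i1 = synthesize_current(st, c1, p).current_pA + 20.0
    i2 = synthesize_current(st, c2, p).current_pA + 20.0
    assert np.allclose(i2, 2.0 * i1)


def test_noise_reproducible_given_seed():
    p = build_mci_protocol(MEM, 0.0, glu1_s=1.0, wash1_s=1.0, drug_s=1.0,
                           glu2_s=1.0, wash3_s=1.0, glu3_s=1.0, sampling_rate_Hz=500.0)
    st = integrate_states(p, MEM)
    cell = CellParams(noise_sd_pA=5.0, rng_seed=42)
    a = synthesize_current(st, cell, p).current_pA
    b = synthesize_current(st, cell, p).current_pA
    assert np.array_equal(a, b)


# --------------------------------------------------------------------------
# end-to-end scenario properties


def test_true_min_monotone_in_concentration_and_ph(memantine_calibrated):
    mins = [
        simulate_mci_experiment(memantine_calibrated, c, 7.2).ground_truth["true_min"]
        for c in (30.0, 100.0, 300.0)
    ]
    assert mins[0] >= mins[1] >= mins[2]
    jump = simulate_mci_experiment(memantine_calibrated, 100.0, 7.2, 9.0)
    assert jump.ground_truth["true_min"] < mins[1]  # more uncharged drug, more MCI


def test_preinhibition_peak_in_slow_blocker_scenario(mk801_scenarios):
    for bundle in mk801_scenarios.values():
        meas = bundle["measurement"]
        assert meas.preinhibition_peak.found
        assert meas.preinhibition_peak.time_s < meas.min_time_s
    # the peak precedes block: smaller than the control peak, but same scale
    b = mk801_scenarios[10.0]
    ctrl_peak = np.max(np.abs(b["sim"].sweeps["control1"].current_pA))
    assert 0.5 * ctrl_peak < b["measurement"].preinhibition_peak.amplitude_pA < ctrl_peak


# --------------------------------------------------------------------------
# stochastic oracle


def _ssa_case():
    gating = GatingParams(beta_open=5.0, alpha_close=5.0, kd_plus=1.0, kd_minus=1.0)
    sol = SolutionSpec(glutamate_uM=1000.0, drug_name="tmm", drug_uM=2.0)
    p = _protocol([Segment(1.0, SolutionSpec(glutamate_uM=1000.0)), Segment(2.0, sol)],
                  fs=200.0)
    return p, gating


def test_gillespie_mean_matches_ode():
    p, gating = _ssa_case()
    checkpoints = np.linspace(0.1, 2.9, 20)
    res = gillespie_reference(p, TMM, gating, n_channels=400, n_reps=60, seed=7,
                              t_checkpoints=checkpoints)
    st = integrate_states(p, TMM, gating, t_eval=checkpoints)
    occ = res["occupancy"][:, :, 1]  # open-state fraction
    mean = occ.mean(axis=0)
    se = occ.std(axis=0, ddof=1) / np.sqrt(occ.shape[0]) + 1e-4
    assert np.all(np.abs(mean - st.O) < 3.0 * se)


def test_gillespie_zero_rates_frozen():
    frozen = GatingParams(beta_open=0.0, alpha_close=0.0, kd_plus=0.0, kd_minus=0.0)
    p = _protocol([Segment(2.0, SolutionSpec())], fs=100.0)
    res = gillespie_reference(p, TMM, frozen, n_channels=50, n_reps=3, seed=1)
    assert np.all(res["occupancy"][:, :, 0] == 1.0)  # all channels stay closed


def test_gillespie_block_exchange_binomial_variance():
    """Independent channels in open/blocked exchange: occupancy at a fixed
    time is binomial, so the across-replicate variance matches n*p*(1-p)."""
    frozen = GatingParams(beta_open=5000.0, alpha_close=0.0, kd_plus=0.0, kd_minus=1.0)
    sol = SolutionSpec(glutamate_uM=1000.0, drug_name="tmm", drug_uM=20.0)
    p = _protocol([Segment(3.0, sol)], fs=100.0)
    n, reps = 200, 200
    checkpoints = np.array([2.5])
    res = gillespie_reference(p, TMM, frozen, n_channels=n, n_reps=reps, seed=3,
                              t_checkpoints=checkpoints)
    st = integrate_states(p, TMM, frozen, t_eval=checkpoints)
    p_open = float(st.O[0])
    counts = res["occupancy"][:, 0, 1] * n
    var_expected = n * p_open * (1 - p_open)
    # sample variance of a binomial: allow 4 standard errors of the variance
    se_var = var_expected * np.sqrt(2.0 / (reps - 1))
    assert abs(counts.var(ddof=1) - var_expected) < 4.0 * se_var
    assert counts.mean() == pytest.approx(n * p_open, abs=4.0 * np.sqrt(var_expected / reps) * n / n)


def test_gillespie_desk_scale_guard():
    p, gating = _ssa_case()
    with pytest.raises(ValueError):
        gillespie_reference(p, TMM, gating, n_channels=100_000)
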