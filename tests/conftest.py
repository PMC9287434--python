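"""Shared fixtures: calibrated scenarios are expensive (each calibration is
a root-find over full simulations), so they are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

import fenestra as fx


@pytest.fixture(scope="session")
def memantine():
    return fx.load_compound("memantine")


@pytest.fixture(scope="session")
def memantine_calibrated(memantine):
    """Memantine with membrane-path rates solved from the measured ratio
    minimum (0.611) and onset constant (46.4 ms) at 100 μM, pH 7.2."""
    return fx.calibrate_min_and_tau(memantine, 100.0, 0.611, 0.0464, bath_pH=7.2)


@pytest.fixture(scope="session")
def memantine_scenario():
    return fx.run_scenario("fig1d_ph72")


@pytest.fixture(scope="session")
def tmm_scenario():
    return fx.run_scenario("fig2g_tmm")


@pytest.fixture(scope="session")
def mk801_scenarios():
    return {
        1.0: fx.run_scenario("fig4_mk801_1uM"),
        10.0: fx.run_scenario("fig4_mk801_10uM"),
    }


@pytest.fixture(scope="session")
def reblock_scenario():
    return fx.run_scenario("fig4e_reblock")


@pytest.fixture(scope="session")
def ph9jump_scenario():
    return fx.run_scenario("fig1_ph9jump")


@pytest.fixture(scope="session")
def zero_drug_sim(memantine_calibrated):
    """Noiseless MCI protocol with zero blocker (end-to-end null case)."""
    return fx.simulate_mci_experiment(memantine_calibrated, 0.0, 7.2)


def synthetic_sweep(rng=None, noise_sd_pA: float = 0.0, fs: float = 1000.0,
                    duration_s: float = 3.0, pre_s: float = 0.5,
                    peak_pA: float = -1000.0):
    """Agonist-sweep-shaped synthetic trace: exponential rise plus sag."""
    t = np.arange(int((duration_s + pre_s) * fs)) / fs - pre_s
    tt = np.clip(t, 0.0, None)
    shape = np.where(
        t >= 0,
        peak_pA * (1 - np.exp(-tt / 0.02)) * (0.4 + 0.6 * np.exp(-tt / 1.0)),
        0.0,
    )
    if rng is not None and noise_sd_pA > 0:
        shape = shape + rng.normal(0.0, noise_sd_pA, shape.size)
    return fx.Trace(shape, fs, t0_s=-pre_s, metadata={"onset_s": 0.0})
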