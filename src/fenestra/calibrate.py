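"""Calibration of membrane-path block rates against measured observables.

The membrane-path association rate (kon_mem) and the deep-site unblock
rate (koff0) are not directly observable.  What an MCI experiment yields
is (a) the normalized minimum of the current ratio and (b) the fitted
single-exponential time constant of the ratio decay after the
preinhibition peak (τ_M).  In the fast-gating quasi-steady-state limit of
the trapping scheme the ratio relaxes with rate

    1/τ_M  ≈  p_o * (kon_mem * m + koff(V_hold))

where m is the reservoir occupancy at the recovery-application onset and
p_o the open probability within each pool, and the minimum approaches
koff / (koff + kon_mem * m).  That algebra seeds the
calibration, but the quantities actually matched are the pipeline's own
outputs: the routines below invert the full generative model by
root-finding on simulate-then-quantify, so the calibrated scenario
reproduces the target observables self-consistently (reservoir drainage,
desensitization transient, solution exchange and all).
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from .kinetics import CellParams, GatingParams, simulate_mci_experiment
from .protonation import CompoundSpec, uncharged_fraction
from .trace_analysis import quantify_mci

__all__ = [
    "additive_rate_decomposition",
    "mci_observables",
    "calibrate_min_and_tau",
    "calibrate_tau_pair",
]

_CACHE: dict = {}


def additive_rate_decomposition(concs_uM, taus_s) -> tuple[float, float]:
    """Fit 1/τ_M = a*[blocker] + b to measured onset time constants.

    Returns (a, b): the concentration-proportional membrane-path term and
    the additive unblock term.  Exact for two concentrations; least
    squares for more.  The additive b term is what makes τ_M scale
    sub-proportionally with concentration (e.g. ~3-fold faster for a
    10-fold concentration increase).
    """
    c = np.asarray(concs_uM, dtype=float)
    rates = 1.0 / np.asarray(taus_s, dtype=float)
    A = np.column_stack([c, np.ones_like(c)])
    (a, b), *_ = np.linalg.lstsq(A, rates, rcond=None)
    return float(a), float(b)


def _reservoir_guess(compound: CompoundSpec, conc_uM: float, drug_pH: float,
                     drug_s: float = 30.0, wash_s: float = 1.0) -> float:
    """Analytic reservoir occupancy at recovery onset (for initial guesses)."""
    c_u = conc_uM * uncharged_fraction(compound, drug_pH)
    m_ss = compound.k_in * c_u / compound.k_out
    return m_ss * (1.0 - np.exp(-compound.k_out * drug_s)) * np.exp(-compound.k_out * wash_s)


def mci_observables(
    compound: CompoundSpec,
    conc_uM: float,
    bath_pH: float = 7.2,
    drug_pH: float | None = None,
    *,
    gating: GatingParams | None = None,
    cell: CellParams | None = None,
    protocol_kind: str = "mci",
    search_to_s: float | None = None,
    **protocol_kwargs,
) -> dict:
    """Noiseless simulate-then-quantify; the forward map the calibration inverts.

    ``protocol_kind='reblock'`` runs the variant with voltage steps (used
    for slow unbinders that need a depolarizing recovery step), with the
    minimum search confined to before the first step via ``search_to_s``.
    """
    protocol = None
    if protocol_kind == "reblock":
        from .protocol import build_reblock_protocol

        kwargs = dict(protocol_kwargs)
        kwargs.setdefault("pre_s", 2.0)
        kwargs.setdefault("sampling_rate_Hz", 2000.0)
        protocol = build_reblock_protocol(compound, conc_uM, bath_pH, drug_pH, **kwargs)
        protocol_kwargs = {}
    elif protocol_kind != "mci":
        raise ValueError(f"unknown protocol kind {protocol_kind!r}")
    sim = simulate_mci_experiment(
        compound, conc_uM, bath_pH, drug_pH, protocol=protocol,
        gating=gating, cell=cell or CellParams(noise_sd_pA=0.0),
        **protocol_kwargs,
    )
    meas = quantify_mci(sim.sweeps["control1"], sim.sweeps["mci"], sim.sweeps["control2"],
                        search_to_s=search_to_s)
    return {
        "true_min": sim.ground_truth["true_min"],
        "min_normalized": meas.min_ratio_normalized,
        "tau_s": meas.tau_decay_ms / 1000.0,
        "measurement": meas,
        "sim": sim,
    }


def _effective_po(gating: GatingParams) -> float:
    peak = gating.beta_open / (gating.beta_open + gating.alpha_close)
    return 0.5 * (peak + gating.steady_open_probability())


def calibrate_min_and_tau(
    compound: CompoundSpec,
    conc_uM: float,
    target_true_min: float,
    target_tau_s: float,
    bath_pH: float = 7.2,
    drug_pH: float | None = None,
    *,
    gating: GatingParams | None = None,
    protocol_kind: str = "mci",
    search_to_s: float | None = None,
    xtol: float = 1e-4,
    **protocol_kwargs,
) -> CompoundSpec:
    """Solve (kon_mem, koff0) so one MCI scenario reproduces two observables:
    the ground-truth ratio minimum and the fitted ratio-decay constant.
    """
    key = ("min_tau", compound.name, conc_uM, target_true_min, target_tau_s,
           bath_pH, drug_pH, repr(gating), protocol_kind, search_to_s,
           repr(sorted(protocol_kwargs.items())))
    if key in _CACHE:
        return _CACHE[key]
    gating = gating or GatingParams()
    v_hold = protocol_kwargs.get("v_hold_mV", -65.0)
    p_eff = _effective_po(gating)
    rate = 1.0 / target_tau_s
    koff_guess = rate * target_true_min / p_eff
    m0 = _reservoir_guess(compound, conc_uM, drug_pH if drug_pH is not None else bath_pH)
    kon_guess = rate * (1.0 - target_true_min) / (p_eff * m0)

    def residuals(x):
        c = compound.replace(
            kon_mem=float(np.exp(x[0])),
            koff0=float(np.exp(x[1]) * np.exp(-v_hold / compound.v_efold)),
        )
        obs = mci_observables(c, conc_uM, bath_pH, drug_pH, gating=gating,
                              protocol_kind=protocol_kind, search_to_s=search_to_s,
                              **protocol_kwargs)
        return [obs["true_min"] - target_true_min,
                obs["tau_s"] / target_tau_s - 1.0]

    sol = optimize.root(residuals, [np.log(kon_guess), np.log(koff_guess)],
                        method="hybr", options={"xtol": xtol})
    if not sol.success or max(abs(sol.fun[0]), abs(sol.fun[1])) > 0.01:
        raise RuntimeError(f"calibration did not converge: {sol.message} (residual {sol.fun})")
    out = compound.replace(
        kon_mem=float(np.exp(sol.x[0])),
        koff0=float(np.exp(sol.x[1]) * np.exp(-v_hold / compound.v_efold)),
    )
    _CACHE[key] = out
    return out


def calibrate_tau_pair(
    compound: CompoundSpec,
    concs_uM: tuple[float, float],
    target_taus_s: tuple[float, float],
    bath_pH: float = 7.2,
    drug_pH: float | None = None,
    *,
    gating: GatingParams | None = None,
    protocol_kind: str = "mci",
    search_to_s: float | None = None,
    xtol: float = 1e-4,
    **protocol_kwargs,
) -> CompoundSpec:
    """Solve (kon_mem, koff0) so the fitted onset constants at two blocker
    concentrations match their measured values (τ_M concentration scaling).
    """
    key = ("tau_pair", compound.name, tuple(concs_uM), tuple(target_taus_s),
           bath_pH, drug_pH, repr(gating), protocol_kind, search_to_s,
           repr(sorted(protocol_kwargs.items())))
    if key in _CACHE:
        return _CACHE[key]
    gating = gating or GatingParams()
    v_hold = protocol_kwargs.get("v_hold_mV", -65.0)
    p_eff = _effective_po(gating)
    a, b = additive_rate_decomposition(concs_uM, target_taus_s)
    m_per_uM = _reservoir_guess(compound, 1.0, drug_pH if drug_pH is not None else bath_pH)
    kon_guess = a / (p_eff * m_per_uM)
    koff_guess = max(b / p_eff, 1e-3)

    def residuals(x):
        c = compound.replace(
            kon_mem=float(np.exp(x[0])),
            koff0=float(np.exp(x[1]) * np.exp(-v_hold / compound.v_efold)),
        )
        return [
            mci_observables(c, conc, bath_pH, drug_pH, gating=gating,
                            protocol_kind=protocol_kind, search_to_s=search_to_s,
                            **protocol_kwargs)["tau_s"] / tau - 1.0
            for conc, tau in zip(concs_uM, target_taus_s)
        ]

    sol = optimize.root(residuals, [np.log(kon_guess), np.log(koff_guess)],
                        method="hybr", options={"xtol": xtol})
    if not sol.success or max(abs(f) for f in sol.fun) > 0.01:
        raise RuntimeError(f"calibration did not converge: {sol.message} (residual {sol.fun})")
    out = compound.replace(
        kon_mem=float(np.exp(sol.x[0])),
        koff0=float(np.exp(sol.x[1]) * np.exp(-v_hold / compound.v_efold)),
    )
    _CACHE[key] = out
    return out
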