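"""Quantification pipeline for whole-cell current traces.

Implements the membrane-to-channel inhibition (MCI) metric and its
supporting operations: baseline subtraction, control averaging,
point-by-point ratios with a validity mask, the windowed-minimum
Min I_MCI/I_Control with both normalization variants, preinhibition-peak
detection, single-exponential onset fits (τ_M), marker readouts, and the
quality-control exclusion rules.

Conventions
-----------
* Traces are uniformly sampled current records (pA); each carries an
  agonist-onset time in its metadata, and all alignment is to the
  commanded agonist-application time, not to measured current onset.
* Ratios are computed only where the control current exceeds a fraction
  (default 5%) of its peak magnitude; everything else is masked.
* The windowed minimum is the minimum of the centered moving average of
  the ratio (window truncated at valid-region edges, odd sample count),
  which makes it identical to an exhaustive scan over window placements.
* Quantitative analysis runs on as-sampled data; the 50 Hz low-pass is
  for presentation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

__all__ = [
    "Trace",
    "RatioTrace",
    "MCIMeasurement",
    "QCRecord",
    "WindowedMin",
    "PreinhibitionPeak",
    "DecayFit",
    "AnalysisError",
    "baseline_subtract",
    "average_controls",
    "point_by_point_ratio",
    "min_windowed",
    "control_ratio_min",
    "normalized_min",
    "jump_control_constant",
    "detect_preinhibition_peak",
    "fit_decay",
    "ratio_at_marker",
    "qc_evaluate",
    "lowpass_presentation",
    "quantify_mci",
]


class AnalysisError(ValueError):
    """The requested analysis is not defined on this input."""


@dataclass
class Trace:
    """Uniformly sampled whole-cell current record.

    ``metadata['onset_s']`` holds the commanded agonist-application time on
    this trace's (absolute) time base; analysis operations align on it.
    """

    current_pA: np.ndarray
    sampling_rate_Hz: float
    t0_s: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        if self.current_pA.ndim != 1:
            raise AnalysisError("trace must be one-dimensional")
        if not np.all(np.isfinite(self.current_pA)):
            raise AnalysisError("trace contains non-finite samples")

    @property
    def n(self) -> int:
        return self.current_pA.size

    @property
    def t(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n) / self.sampling_rate_Hz

    @property
    def onset_s(self) -> float:
        try:
            return float(self.metadata["onset_s"])
        except KeyError:
            raise AnalysisError("trace metadata lacks 'onset_s' agonist marker") from None

    def onset_index(self) -> int:
        i = int(round((self.onset_s - self.t0_s) * self.sampling_rate_Hz))
        if not 0 <= i < self.n:
            raise AnalysisError("agonist onset lies outside the trace")
        return i

    def copy_with(self, current_pA: np.ndarray) -> "Trace":
        return Trace(
            current_pA=np.array(current_pA, dtype=float),
            sampling_rate_Hz=self.sampling_rate_Hz,
            t0_s=self.t0_s,
            metadata=dict(self.metadata),
        )


@dataclass
class RatioTrace:
    """Aligned point-by-point ratio with a validity mask.

    Time is relative to the agonist onset used for alignment; ``ratio``
    values are meaningful only where ``valid`` is True.
    """

    t_s: np.ndarray
    ratio: np.ndarray
    valid: np.ndarray
    sampling_rate_Hz: float
    alignment_marker_s: float = 0.0

    def valid_values(self) -> tuple[np.ndarray, np.ndarray]:
        return self.t_s[self.valid], self.ratio[self.valid]


@dataclass(frozen=True)
class WindowedMin:
    value: float
    time_s: float
    window_ms: float


@dataclass(frozen=True)
class PreinhibitionPeak:
    found: bool
    time_s: float = float("nan")
    amplitude_pA: float = float("nan")


@dataclass(frozen=True)
class DecayFit:
    tau_s: float
    plateau: float
    r0: float
    start_s: float
    r_squared: float
    converged: bool

    @property
    def tau_ms(self) -> float:
        return self.tau_s * 1000.0


@dataclass(frozen=True)
class MCIMeasurement:
    raw_windowed_min: float
    window_ms: float
    normalization_constant: float
    min_ratio_normalized: float
    min_time_s: float
    tau_decay_ms: float
    preinhibition_peak: PreinhibitionPeak
    ratio_at_markers: dict = field(default_factory=dict)
    decay_fit: DecayFit | None = None


@dataclass(frozen=True)
class QCRecord:
    peak_control1_pA: float
    peak_control2_pA: float
    Rs_MOhm: float
    control_mismatch_fraction: float
    holding_current_pA: float
    holding_fluctuation_pA: float
    decision: str  # "include" | "exclude"
    reasons: tuple[str, ...]


# --------------------------------------------------------------------------
# elementary trace operations


def baseline_subtract(trace: Trace, pre_onset_window_ms: float = 500.0) -> Trace:
    """Subtract the mean current over a window ending at agonist onset."""
    i_on = trace.onset_index()
    w = int(round(pre_onset_window_ms / 1000.0 * trace.sampling_rate_Hz))
    if w < 1 or i_on - w < 0:
        raise AnalysisError(
            f"pre-onset window of {pre_onset_window_ms} ms does not fit before onset"
        )
    baseline = float(np.mean(trace.current_pA[i_on - w:i_on]))
    out = trace.copy_with(trace.current_pA - baseline)
    out.metadata["baseline_pA"] = baseline
    return out


def _align_to_onset(a: Trace, b: Trace) -> tuple[np.ndarray, np.ndarray, int]:
    """Post-onset samples of both traces, trimmed to their common length."""
    if a.sampling_rate_Hz != b.sampling_rate_Hz:
        raise AnalysisError("sampling rates differ")
    xa = a.current_pA[a.onset_index():]
    xb = b.current_pA[b.onset_index():]
    n = min(xa.size, xb.size)
    if n == 0:
        raise AnalysisError("no overlap after alignment")
    return xa[:n], xb[:n], n


def average_controls(c1: Trace, c2: Trace) -> Trace:
    """Point-by-point mean of the two bracketing control responses."""
    x1, x2, n = _align_to_onset(c1, c2)
    out = Trace(
        current_pA=0.5 * (x1 + x2),
        sampling_rate_Hz=c1.sampling_rate_Hz,
        t0_s=0.0,
        metadata={**c1.metadata, "onset_s": 0.0, "averaged": True},
    )
    return out


def point_by_point_ratio(
    i_mci: Trace,
    i_control: Trace,
    validity_fraction: float = 0.05,
) -> RatioTrace:
    """Point-by-point I_MCI / I_Control, aligned at the agonist onsets.

    Both traces must already be baseline-subtracted.  The ratio is defined
    only where |I_Control| is at least ``validity_fraction`` of its peak
    magnitude; remaining points are masked.
    """
    num, den, n = _align_to_onset(i_mci, i_control)
    peak = float(np.max(np.abs(den)))
    if peak == 0:
        raise AnalysisError("control trace is identically zero")
    valid = np.abs(den) >= validity_fraction * peak
    if not valid.any():
        raise AnalysisError("no valid points in ratio")
    ratio = np.full(n, np.nan)
    np.divide(num, den, out=ratio, where=valid)
    fs = i_mci.sampling_rate_Hz
    return RatioTrace(
        t_s=np.arange(n) / fs,
        ratio=ratio,
        valid=valid,
        sampling_rate_Hz=fs,
        alignment_marker_s=i_mci.onset_s,
    )


def _window_samples(window_ms: float, fs: float) -> int:
    n_w = max(1, int(round(window_ms / 1000.0 * fs)))
    return n_w if n_w % 2 == 1 else n_w + 1


def min_windowed(
    ratio: RatioTrace,
    window_ms: float = 30.0,
    search_from_s: float | None = None,
    search_to_s: float | None = None,
) -> WindowedMin:
    """Minimum of the centered moving-average of the ratio.

    The window (odd sample count) is truncated at the edges of each
    contiguous valid run; the reported value is the smallest window mean
    over all admissible placements, with the search optionally restricted
    to ``[search_from_s, search_to_s]``.
    """
    n_w = _window_samples(window_ms, ratio.sampling_rate_Hz)
    half = n_w // 2
    sel = ratio.valid.copy()
    if search_from_s is not None:
        sel &= ratio.t_s >= search_from_s
    if search_to_s is not None:
        sel &= ratio.t_s <= search_to_s
    idx = np.flatnonzero(sel)
    if idx.size < 1:
        raise AnalysisError("no valid points in the search range")

    best_val, best_t = np.inf, np.nan
    # contiguous runs of selected samples
    splits = np.flatnonzero(np.diff(idx) > 1)
    for run in np.split(idx, splits + 1):
        x = ratio.ratio[run]
        csum = np.concatenate([[0.0], np.cumsum(x)])
        m = x.size
        centers = np.arange(m)
        lo = np.maximum(0, centers - half)
        hi = np.minimum(m, centers + half + 1)
        means = (csum[hi] - csum[lo]) / (hi - lo)
        k = int(np.argmin(means))
        if means[k] < best_val:
            best_val = float(means[k])
            best_t = float(ratio.t_s[run[k]])
    return WindowedMin(value=best_val, time_s=best_t, window_ms=window_ms)


def control_ratio_min(
    c1: Trace,
    c2: Trace,
    window_ms: float = 30.0,
    validity_fraction: float = 0.05,
    search_from_s: float | None = None,
) -> float:
    """Normalization constant from the two control responses.

    Mean of the windowed minima of the point-by-point ratios c2/c1 and
    c1/c2; exactly 1 for identical controls, and slightly below 1 for
    noisy identical controls (the selection bias the normalization exists
    to cancel).
    """
    m21 = min_windowed(
        point_by_point_ratio(c2, c1, validity_fraction), window_ms, search_from_s
    )
    m12 = min_windowed(
        point_by_point_ratio(c1, c2, validity_fraction), window_ms, search_from_s
    )
    return 0.5 * (m21.value + m12.value)


def normalized_min(raw_min: float, normalization_constant: float) -> float:
    """Min I_MCI/I_Control: raw windowed minimum over the control constant."""
    if not normalization_constant > 0:
        raise AnalysisError("normalization constant must be > 0")
    return raw_min / normalization_constant


def jump_control_constant(zero_drug_minima) -> tuple[float, float]:
    """Normalization constant for pH-jump experiments.

    ``zero_drug_minima`` are raw windowed minima from runs of the identical
    pH-jump protocol with zero blocker.  Returns (mean, SEM).
    """
    x = np.asarray(list(zero_drug_minima), dtype=float)
    if x.size == 0:
        raise AnalysisError("no zero-drug measurements supplied")
    sem = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    return float(np.mean(x)), sem


def detect_preinhibition_peak(
    trace: Trace,
    search_to_s: float | None = None,
    smooth_ms: float = 5.0,
    prominence_fraction: float = 0.005,
) -> PreinhibitionPeak:
    """First local maximum of the smoothed current magnitude after onset.

    The initial current peak that precedes blocker transit from the
    membrane to the open channel.  Returns ``found=False`` for traces that
    are monotone over the search window.
    """
    i_on = trace.onset_index()
    x = np.abs(trace.current_pA[i_on:])
    if search_to_s is not None:
        x = x[: int(round(search_to_s * trace.sampling_rate_Hz))]
    k = max(1, int(round(smooth_ms / 1000.0 * trace.sampling_rate_Hz)))
    kernel = np.ones(k) / k
    s = np.convolve(x, kernel, mode="same")
    # the boxcar's zero-padded edges fabricate maxima; keep them out of reach
    interior = s[k:-k] if s.size > 2 * k else s
    peaks, _ = signal.find_peaks(interior, prominence=prominence_fraction * np.max(s))
    if peaks.size == 0:
        return PreinhibitionPeak(found=False)
    p = int(peaks[0]) + (k if s.size > 2 * k else 0)
    return PreinhibitionPeak(
        found=True,
        time_s=p / trace.sampling_rate_Hz,
        amplitude_pA=float(s[p]),
    )


def fit_decay(
    ratio: RatioTrace,
    start_s: float,
    end_s: float | None = None,
    min_points: int = 50,
) -> DecayFit:
    """Single-exponential fit to the ratio decay after the preinhibition peak.

    Model: r(t) = plateau + (r0 - plateau) * exp(-(t - start)/tau).
    Non-decaying input is reported with ``converged=False``.
    """
    sel = ratio.valid & (ratio.t_s >= start_s)
    if end_s is not None:
        sel &= ratio.t_s <= end_s
    t = ratio.t_s[sel] - start_s
    r = ratio.ratio[sel]
    if t.size < min_points:
        raise AnalysisError(f"only {t.size} valid points after the peak; need {min_points}")

    r0_guess, r_inf_guess = float(r[0]), float(r[-1])
    span = float(t[-1] - t[0])
    tau_guess = max(span / 5.0, 2.0 / ratio.sampling_rate_Hz)

    def model(tt, plateau, r0, tau):
        return plateau + (r0 - plateau) * np.exp(-tt / tau)

    try:
        popt, _ = optimize.curve_fit(
            model,
            t,
            r,
            p0=[r_inf_guess, r0_guess, tau_guess],
            bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, 100 * max(span, 1e-3)]),
            maxfev=20_000,
        )
        plateau, r0, tau = (float(v) for v in popt)
        resid = r - model(t, *popt)
        sst = float(np.sum((r - np.mean(r)) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
        converged = r0 > plateau and tau > 0
    except RuntimeError:
        plateau, r0, tau, r2, converged = np.nan, np.nan, np.nan, np.nan, False
    return DecayFit(
        tau_s=tau, plateau=plateau, r0=r0, start_s=start_s, r_squared=r2,
        converged=converged,
    )


def ratio_at_marker(ratio: RatioTrace, marker_s: float, window_ms: float = 10.0) -> float:
    """Mean ratio over a short window centered on a measurement marker.

    ``marker_s`` is on the ratio's time base (relative to agonist onset).
    """
    half = window_ms / 2000.0
    sel = ratio.valid & (ratio.t_s >= marker_s - half) & (ratio.t_s <= marker_s + half)
    if not sel.any():
        raise AnalysisError(f"marker at {marker_s} s lies outside the valid ratio region")
    return float(np.mean(ratio.ratio[sel]))


# --------------------------------------------------------------------------
# quality control

QC_PEAK_LIMIT_PA = 2500.0
QC_RS_LIMIT_MOHM = 20.0
QC_MISMATCH_LIMIT = 0.20
QC_HOLDING_LIMIT_PA = -200.0
QC_FLUCTUATION_LIMIT_PA = 100.0


def qc_evaluate(
    peak_control1_pA: float,
    peak_control2_pA: float,
    Rs_MOhm: float,
    holding_segments_pA,
) -> QCRecord:
    """Apply the exclusion rules to one cell's summary measurements.

    ``holding_segments_pA`` are mean holding currents of the pre-onset
    baseline segments across the experiment; the "fluctuation" is their
    max-minus-min range.  The decision is a pure function of the inputs.
    """
    holding = np.asarray(list(holding_segments_pA), dtype=float)
    if holding.size == 0:
        raise AnalysisError("at least one holding-current segment is required")
    p1, p2 = abs(peak_control1_pA), abs(peak_control2_pA)
    mismatch = abs(p2 - p1) / max(p1, p2) if max(p1, p2) > 0 else 0.0
    fluctuation = float(holding.max() - holding.min())
    most_negative = float(holding.min())

    reasons: list[str] = []
    if mismatch > QC_MISMATCH_LIMIT:
        reasons.append("control_mismatch")
    if max(p1, p2) > QC_PEAK_LIMIT_PA:
        reasons.append("peak_current")
    if Rs_MOhm > QC_RS_LIMIT_MOHM:
        reasons.append("series_resistance")
    if most_negative < QC_HOLDING_LIMIT_PA:
        reasons.append("holding_current")
    if fluctuation > QC_FLUCTUATION_LIMIT_PA:
        reasons.append("holding_fluctuation")

    return QCRecord(
        peak_control1_pA=peak_control1_pA,
        peak_control2_pA=peak_control2_pA,
        Rs_MOhm=Rs_MOhm,
        control_mismatch_fraction=mismatch,
        holding_current_pA=most_negative,
        holding_fluctuation_pA=fluctuation,
        decision="exclude" if reasons else "include",
        reasons=tuple(reasons),
    )


def lowpass_presentation(trace: Trace, fc_Hz: float = 50.0, order: int = 4) -> Trace:
    """Zero-phase Bessel low-pass for figure presentation.

    Never used in the quantitative path; quantification runs on
    as-sampled data.
    """
    nyq = trace.sampling_rate_Hz / 2.0
    if fc_Hz >= nyq:
        raise AnalysisError(f"corner {fc_Hz} Hz is at or above Nyquist ({nyq} Hz)")
    sos = signal.bessel(order, fc_Hz / nyq, btype="low", output="sos")
    out = trace.copy_with(signal.sosfiltfilt(sos, trace.current_pA))
    out.metadata["presentation_filter_Hz"] = fc_Hz
    return out


# --------------------------------------------------------------------------
# end-to-end quantification


def quantify_mci(
    control1: Trace,
    mci: Trace,
    control2: Trace,
    *,
    window_ms: float = 30.0,
    validity_fraction: float = 0.05,
    exclude_initial_ms: float = 54.0,
    search_to_s: float | None = None,
    baseline_window_ms: float = 500.0,
    normalization: float | None = None,
    markers_s: dict | None = None,
    fit_onset: bool = True,
) -> MCIMeasurement:
    """Full MCI quantification of one experiment.

    Baseline-subtracts the three sweeps, averages the controls, forms the
    point-by-point ratio, takes the windowed minimum (excluding the first
    ``exclude_initial_ms`` after onset, twice the solution-exchange time
    constant, to avoid exchange artifacts), normalizes by the control-ratio
    constant (or by a supplied pH-jump constant), detects the preinhibition
    peak and fits the subsequent single-exponential decay (τ_M).

    ``search_to_s`` bounds the minimum search from above (relative to
    onset); in protocols with voltage steps the ratio is meaningless while
    the two sweeps are at different command voltages, so the search should
    end before the first step.
    """
    c1 = baseline_subtract(control1, baseline_window_ms)
    c2 = baseline_subtract(control2, baseline_window_ms)
    m = baseline_subtract(mci, baseline_window_ms)
    ctrl = average_controls(c1, c2)
    ratio = point_by_point_ratio(m, ctrl, validity_fraction)

    t_excl = exclude_initial_ms / 1000.0
    wmin = min_windowed(ratio, window_ms, search_from_s=t_excl, search_to_s=search_to_s)
    if normalization is None:
        norm = control_ratio_min(
            c1, c2, window_ms, validity_fraction, search_from_s=t_excl
        )
    else:
        norm = float(normalization)
    min_norm = normalized_min(wmin.value, norm)

    peak = detect_preinhibition_peak(m)
    decay = None
    tau_ms = float("nan")
    if fit_onset and peak.found and wmin.time_s > peak.time_s:
        try:
            decay = fit_decay(ratio, start_s=peak.time_s, end_s=wmin.time_s)
            if decay.converged:
                tau_ms = decay.tau_ms
        except AnalysisError:
            decay = None

    at_markers = {}
    for name, t_m in (markers_s or {}).items():
        at_markers[name] = ratio_at_marker(ratio, t_m)

    return MCIMeasurement(
        raw_windowed_min=wmin.value,
        window_ms=window_ms,
        normalization_constant=norm,
        min_ratio_normalized=min_norm,
        min_time_s=wmin.time_s,
        tau_decay_ms=tau_ms,
        preinhibition_peak=peak,
        ratio_at_markers=at_markers,
        decay_fit=decay,
    )
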