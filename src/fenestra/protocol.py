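"""Declarative perfusion/voltage protocols for whole-cell recordings.

A protocol is an ordered list of contiguous segments, each pairing a
solution composition with a (piecewise-constant) holding voltage.  The
builders below produce the three protocol families used throughout the
package:

* the MCI protocol — agonist / wash / blocker-without-agonist / brief wash /
  agonist / wash / agonist, which isolates membrane-to-channel inhibition
  from traditional open-channel block;
* the traditional protocol — blocker co-applied with agonist, stepped
  through a concentration ladder with bracketing controls;
* the reblock protocol — the MCI protocol with depolarizing voltage steps
  imposed during recovery, plus a readout marker 200 ms after the final
  step ends.

Voltage steps are realized by splitting segments so downstream integrators
see a single piecewise-constant driver.  Builders are pure functions:
identical arguments yield identical protocols.  Voltages are taken as
already corrected for liquid-junction potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SolutionSpec",
    "Segment",
    "Protocol",
    "ProtocolError",
    "build_mci_protocol",
    "build_traditional_protocol",
    "build_reblock_protocol",
    "validate",
]


class ProtocolError(ValueError):
    """Invalid protocol construction arguments."""


@dataclass(frozen=True)
class SolutionSpec:
    """Composition of an extracellular solution.

    Glycine, amiloride and the competitive antagonist are carried as
    metadata only: they document the recording conditions (suppression of
    off-target currents) and have no kinetic effect in the simulator.
    """

    glutamate_uM: float = 0.0
    glycine_uM: float = 100.0
    agonist_alt_uM: float = 0.0  # NMDA, for neuron-style scenarios
    drug_name: str | None = None
    drug_uM: float = 0.0
    pH: float = 7.2
    amiloride: bool = False
    antagonist_uM: float = 0.0  # APV guard

    @property
    def agonist_uM(self) -> float:
        return self.glutamate_uM + self.agonist_alt_uM


@dataclass(frozen=True)
class Segment:
    duration_s: float
    solution: SolutionSpec
    voltage_mV: float = -65.0


@dataclass(frozen=True)
class Protocol:
    label: str
    segments: tuple[Segment, ...]
    sampling_rate_Hz: float = 20_000.0
    agonist_onset_markers_s: tuple[float, ...] = ()
    measurement_markers_s: dict = field(default_factory=dict)

    @property
    def boundaries_s(self) -> np.ndarray:
        """Cumulative segment end times, prefixed with 0."""
        return np.concatenate(
            [[0.0], np.cumsum([s.duration_s for s in self.segments])]
        )

    @property
    def duration_s(self) -> float:
        return float(sum(s.duration_s for s in self.segments))

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration_s * self.sampling_rate_Hz))
        return np.arange(n) / self.sampling_rate_Hz

    def segment_index(self, t) -> np.ndarray:
        """Index of the segment containing each time (end-exclusive)."""
        edges = self.boundaries_s
        idx = np.searchsorted(edges, np.asarray(t, dtype=float), side="right") - 1
        return np.clip(idx, 0, len(self.segments) - 1)

    def voltage_at(self, t) -> np.ndarray:
        v = np.array([s.voltage_mV for s in self.segments])
        return v[self.segment_index(t)]

    def agonist_windows(self) -> list[tuple[float, float]]:
        """(start, end) of each maximal run of agonist-containing segments."""
        windows: list[tuple[float, float]] = []
        edges = self.boundaries_s
        open_start = None
        for i, seg in enumerate(self.segments):
            has = seg.solution.agonist_uM > 0
            if has and open_start is None:
                open_start = edges[i]
            if not has and open_start is not None:
                windows.append((open_start, edges[i]))
                open_start = None
        if open_start is not None:
            windows.append((open_start, edges[-1]))
        return windows

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "sampling_rate_Hz": self.sampling_rate_Hz,
            "agonist_onset_markers_s": list(self.agonist_onset_markers_s),
            "measurement_markers_s": dict(self.measurement_markers_s),
            "segments": [
                {
                    "duration_s": s.duration_s,
                    "voltage_mV": s.voltage_mV,
                    "solution": {
                        k: v
                        for k, v in vars(s.solution).items()
                    },
                }
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        segments = tuple(
            Segment(
                duration_s=s["duration_s"],
                voltage_mV=s.get("voltage_mV", -65.0),
                solution=SolutionSpec(**s.get("solution", {})),
            )
            for s in d["segments"]
        )
        return cls(
            label=d.get("label", "protocol"),
            segments=segments,
            sampling_rate_Hz=d.get("sampling_rate_Hz", 20_000.0),
            agonist_onset_markers_s=tuple(d.get("agonist_onset_markers_s", ())),
            measurement_markers_s=dict(d.get("measurement_markers_s", {})),
        )


def validate(protocol: Protocol) -> list[str]:
    """Check protocol invariants; returns a list of violations (never raises)."""
    violations: list[str] = []
    for i, seg in enumerate(protocol.segments):
        if not seg.duration_s > 0:
            violations.append(f"segment {i}: duration {seg.duration_s} s is not > 0")
        sol = seg.solution
        for name in ("glutamate_uM", "glycine_uM", "agonist_alt_uM", "drug_uM", "antagonist_uM"):
            if getattr(sol, name) < 0:
                violations.append(f"segment {i}: {name} < 0")
        if not 0.0 < sol.pH < 14.0:
            violations.append(f"segment {i}: pH {sol.pH} outside (0, 14)")
    total = protocol.duration_s
    for t in protocol.agonist_onset_markers_s:
        if not 0.0 <= t <= total:
            violations.append(f"agonist onset marker {t} s outside protocol [0, {total}]")
    for name, t in protocol.measurement_markers_s.items():
        if not 0.0 <= t <= total:
            violations.append(f"marker {name!r} at {t} s outside protocol [0, {total}]")
    return violations


def _drug_label(compound) -> str:
    return compound if isinstance(compound, str) else compound.name


def build_mci_protocol(
    compound,
    drug_uM: float,
    bath_pH: float = 7.2,
    drug_pH: float | None = None,
    *,
    glu1_s: float = 20.0,
    wash1_s: float = 10.0,
    drug_s: float = 30.0,
    wash2_s: float = 1.0,
    glu2_s: float = 25.0,
    wash3_s: float = 41.0,
    glu3_s: float = 20.0,
    pre_s: float = 0.0,
    v_hold_mV: float = -65.0,
    glutamate_uM: float = 1000.0,
    sampling_rate_Hz: float = 20_000.0,
    label: str | None = None,
) -> Protocol:
    """The MCI protocol: blocker applied only in the absence of agonist.

    The drug segment carries ``drug_pH`` (pH-jump support); all other
    segments use ``bath_pH``.  Three agonist-onset markers are emitted, one
    per glutamate application.  When the drug pH differs from the bath pH
    the amiloride flag is set on every segment, mirroring the recording
    conditions used for pH-jump experiments.
    """
    for name, dur in [
        ("glu1_s", glu1_s), ("wash1_s", wash1_s), ("drug_s", drug_s),
        ("wash2_s", wash2_s), ("glu2_s", glu2_s), ("wash3_s", wash3_s),
        ("glu3_s", glu3_s),
    ]:
        if not dur > 0:
            raise ProtocolError(f"{name} must be > 0, got {dur}")
    if pre_s < 0:
        raise ProtocolError("pre_s must be >= 0")
    drug_pH = bath_pH if drug_pH is None else drug_pH
    amiloride = drug_pH != bath_pH
    drug_name = _drug_label(compound)

    ctrl = SolutionSpec(pH=bath_pH, amiloride=amiloride)
    glu = SolutionSpec(glutamate_uM=glutamate_uM, pH=bath_pH, amiloride=amiloride)
    drug = SolutionSpec(
        drug_name=drug_name, drug_uM=drug_uM, pH=drug_pH, amiloride=amiloride
    )
    if drug.agonist_uM > 0:
        raise ProtocolError("MCI drug segment must not contain agonist")

    segs: list[Segment] = []
    if pre_s > 0:
        segs.append(Segment(pre_s, ctrl, v_hold_mV))
    segs += [
        Segment(glu1_s, glu, v_hold_mV),
        Segment(wash1_s, ctrl, v_hold_mV),
        Segment(drug_s, drug, v_hold_mV),
        Segment(wash2_s, ctrl, v_hold_mV),
        Segment(glu2_s, glu, v_hold_mV),
        Segment(wash3_s, ctrl, v_hold_mV),
        Segment(glu3_s, glu, v_hold_mV),
    ]
    t0 = pre_s
    onsets = (
        t0,
        t0 + glu1_s + wash1_s + drug_s + wash2_s,
        t0 + glu1_s + wash1_s + drug_s + wash2_s + glu2_s + wash3_s,
    )
    return Protocol(
        label=label or f"mci_{drug_name}_{drug_uM:g}uM_pH{drug_pH:g}",
        segments=tuple(segs),
        sampling_rate_Hz=sampling_rate_Hz,
        agonist_onset_markers_s=onsets,
    )


def build_traditional_protocol(
    compound,
    conc_list_uM: Sequence[float],
    *,
    v_hold_mV: float = -65.0,
    application_s: float = 10.0,
    control_s: float = 10.0,
    pH: float = 7.2,
    glutamate_uM: float = 1000.0,
    sampling_rate_Hz: float = 20_000.0,
    label: str | None = None,
) -> Protocol:
    """Traditional block protocol: drug co-applied with agonist.

    The agonist is continuously present; the drug steps through
    ``conc_list_uM`` (must be ascending) with a bracketing control
    application before the first and after every drug application.
    Measurement markers are placed 1 s before the end of each application,
    where the response has reached steady state.
    """
    concs = list(conc_list_uM)
    if not concs:
        raise ProtocolError("conc_list_uM must not be empty")
    if any(c < 0 for c in concs):
        raise ProtocolError("concentrations must be >= 0")
    if sorted(concs) != concs:
        raise ProtocolError("concentrations must be ascending")
    drug_name = _drug_label(compound)

    segs: list[Segment] = []
    markers: dict[str, float] = {}
    t = 0.0

    def add(duration: float, sol: SolutionSpec, name: str):
        nonlocal t
        segs.append(Segment(duration, sol, v_hold_mV))
        markers[name] = t + duration - min(1.0, duration / 2)
        t += duration

    glu = SolutionSpec(glutamate_uM=glutamate_uM, pH=pH)
    add(control_s, glu, "control_0")
    for i, c in enumerate(concs):
        sol = SolutionSpec(
            glutamate_uM=glutamate_uM, drug_name=drug_name, drug_uM=c, pH=pH
        )
        add(application_s, sol, f"conc_{c:g}uM")
        add(control_s, glu, f"control_{i + 1}")

    return Protocol(
        label=label or f"traditional_{drug_name}",
        segments=tuple(segs),
        sampling_rate_Hz=sampling_rate_Hz,
        agonist_onset_markers_s=(0.0,),
        measurement_markers_s=markers,
    )


def build_reblock_protocol(
    compound,
    drug_uM: float,
    bath_pH: float = 7.2,
    drug_pH: float | None = None,
    *,
    n_steps: int = 2,
    step_mV: float = 50.0,
    step_ms: float = 500.0,
    step_start_s: float = 3.0,
    inter_step_s: float = 1.0,
    readout_delay_s: float = 0.2,
    **mci_kwargs,
) -> Protocol:
    """MCI protocol with depolarizing V_m steps during recovery.

    ``n_steps`` voltage steps of ``step_ms`` to ``step_mV`` are imposed
    within the recovery (second) agonist application, starting
    ``step_start_s`` after its onset and separated by ``inter_step_s`` at
    the holding potential.  A ``"post_step"`` measurement marker is placed
    ``readout_delay_s`` after the end of the final step.  ``n_steps=0``
    reduces to :func:`build_mci_protocol`.
    """
    base = build_mci_protocol(compound, drug_uM, bath_pH, drug_pH, **mci_kwargs)
    if n_steps == 0:
        return base
    if n_steps < 0:
        raise ProtocolError("n_steps must be >= 0")
    step_s = step_ms / 1000.0
    glu2_onset = base.agonist_onset_markers_s[1]
    glu2_end = base.agonist_onset_markers_s[2] - _wash3(base)
    span = step_start_s + n_steps * step_s + (n_steps - 1) * inter_step_s
    if glu2_onset + span >= glu2_end:
        raise ProtocolError(
            f"{n_steps} step(s) of {step_ms} ms starting {step_start_s} s into the "
            "recovery application do not fit within it"
        )

    # split the glu2 segment at every step edge
    edges = base.boundaries_s
    glu2_idx = int(np.searchsorted(edges, glu2_onset, side="right")) - 1
    glu2 = base.segments[glu2_idx]
    v_hold = glu2.voltage_mV
    cuts: list[tuple[float, float]] = []  # (duration, voltage), relative pieces
    t_rel = 0.0
    for k in range(n_steps):
        start = step_start_s + k * (step_s + inter_step_s)
        cuts.append((start - t_rel, v_hold))
        cuts.append((step_s, step_mV))
        t_rel = start + step_s
    cuts.append((glu2.duration_s - t_rel, v_hold))

    new_segments = (
        base.segments[:glu2_idx]
        + tuple(Segment(d, glu2.solution, v) for d, v in cuts if d > 0)
        + base.segments[glu2_idx + 1:]
    )
    last_step_end = glu2_onset + step_start_s + n_steps * step_s + (n_steps - 1) * inter_step_s
    markers = dict(base.measurement_markers_s)
    markers["steps_start"] = glu2_onset + step_start_s
    markers["post_step"] = last_step_end + readout_delay_s
    return replace(
        base,
        label=base.label + f"_reblock{n_steps}x{step_ms:g}ms",
        segments=new_segments,
        measurement_markers_s=markers,
    )


def _wash3(protocol: Protocol) -> float:
    """Duration of the wash between the second and third agonist applications."""
    onsets = protocol.agonist_onset_markers_s
    windows = protocol.agonist_windows()
    glu2_end = next(end for start, end in windows if start == onsets[1])
    return onsets[2] - glu2_end
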