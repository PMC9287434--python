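"""Charged/uncharged speciation of titratable channel blockers.

Amine channel blockers such as memantine exist in a pH-dependent
equilibrium between a protonated (charged) and a deprotonated (uncharged)
form.  Only the uncharged form is lipophilic enough to partition into the
plasma membrane, so the uncharged fraction gates the membrane-to-channel
inhibition (MCI) pathway.  Speciation follows the dilute-solution
Henderson–Hasselbalch relation

    f_uncharged(pH) = 1 / (1 + 10**(pKa - pH))

Quaternary-ammonium derivatives (e.g. trimethyl-memantine, TMM) carry a
permanent positive charge and have uncharged fraction identically zero.

Activity-coefficient and ionic-strength corrections are deliberately
ignored: the analysis reasons only with nominal pKa values, which are user
inputs (memantine 10.4, dimethyl-memantine 10.7), never predicted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

__all__ = [
    "CompoundSpec",
    "ConfigurationError",
    "uncharged_fraction",
    "uncharged_concentration",
    "fold_change_uncharged",
]

ChargeType = Literal["titratable_amine", "permanent_cation"]


class ConfigurationError(ValueError):
    """A compound definition is internally inconsistent."""


@dataclass(frozen=True)
class CompoundSpec:
    """A channel blocker's protonation chemistry and kinetic parameters.

    Parameters
    ----------
    name
        Compound label (e.g. ``"memantine"``).
    charge_type
        ``"titratable_amine"`` for compounds with a protonatable nitrogen,
        ``"permanent_cation"`` for quaternary ammoniums.
    pKa
        Acid dissociation constant of the ammonium group.  Required for
        titratable amines; meaningless (``None``) for permanent cations.
    kon_aq
        Aqueous-path association rate to the deep blocking site,
        per μM per s (charged form, open channel only).
    koff0
        Deep-site dissociation rate at 0 mV, per s.
    v_efold
        e-fold depolarization of the unblock rate, mV.  ``koff(V) =
        koff0 * exp(V / v_efold)`` so depolarization relieves block.
    k_in
        Membrane-entry rate of the uncharged form, per μM per s.
    k_out
        Membrane-exit rate, per s (sets the reservoir drain time
        constant ``1/k_out``).
    kon_mem
        Membrane-path association rate to the deep site, per reservoir
        unit per s (open channel only).
    """

    name: str
    charge_type: ChargeType
    pKa: float | None = None
    kon_aq: float = 0.0
    koff0: float = 1.0
    v_efold: float = 40.0
    k_in: float = 1.0
    k_out: float = 0.5
    kon_mem: float = 0.0

    def __post_init__(self) -> None:
        if self.charge_type not in ("titratable_amine", "permanent_cation"):
            raise ConfigurationError(
                f"{self.name}: unknown charge_type {self.charge_type!r}"
            )
        if self.charge_type == "titratable_amine":
            if self.pKa is None:
                raise ConfigurationError(
                    f"{self.name}: titratable amine requires a pKa"
                )
            if not 0.0 <= self.pKa <= 14.0:
                raise ConfigurationError(
                    f"{self.name}: pKa {self.pKa} outside [0, 14]"
                )
        for attr in ("kon_aq", "koff0", "v_efold", "k_in", "k_out", "kon_mem"):
            if getattr(self, attr) < 0:
                raise ConfigurationError(f"{self.name}: {attr} must be >= 0")

    @property
    def is_permanent_cation(self) -> bool:
        return self.charge_type == "permanent_cation"

    def replace(self, **kwargs) -> "CompoundSpec":
        """Return a copy with the given fields overridden."""
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


def _check_pH(pH: float) -> None:
    if not 0.0 < pH < 14.0:
        raise ValueError(f"pH {pH} outside (0, 14)")


def uncharged_fraction(compound: CompoundSpec, pH: float) -> float:
    """Fraction of the compound in the uncharged (deprotonated) form.

    Returns exactly 0 for permanent cations.  Strictly increasing in pH
    for titratable amines; equals 0.5 at pH = pKa.
    """
    _check_pH(pH)
    if compound.is_permanent_cation:
        return 0.0
    assert compound.pKa is not None  # enforced by __post_init__
    return 1.0 / (1.0 + 10.0 ** (compound.pKa - pH))


def uncharged_concentration(total_uM: float, compound: CompoundSpec, pH: float) -> float:
    """Concentration (μM) of the uncharged form at the given total and pH."""
    if total_uM < 0:
        raise ValueError("total concentration must be >= 0")
    return total_uM * uncharged_fraction(compound, pH)


def fold_change_uncharged(compound: CompoundSpec, pH_a: float, pH_b: float) -> float:
    """Ratio of uncharged fractions at pH_a vs pH_b.

    For pKa well above both pH values this approaches ``10**(pH_a - pH_b)``
    (e.g. ~60-fold between pH 9.0 and 7.2 at pKa 10.4).  Undefined (0/0)
    for permanent cations.
    """
    if compound.is_permanent_cation:
        raise ConfigurationError(
            f"{compound.name}: uncharged fold-change undefined for a permanent cation"
        )
    return uncharged_fraction(compound, pH_a) / uncharged_fraction(compound, pH_b)
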