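"""Thermodynamic conventions shared by the whole package.

All free energies are in kcal/mol with the convention that favorable
interactions are *negative*. A bound state with interaction energy ``eps``
at free-ligand concentration ``C`` carries the statistical weight
``(C / c0) * exp(-eps / rt)``, so the dissociation constant associated with
``eps`` is ``Kd = c0 * exp(eps / rt)``. This single sign convention is used
identically by every other module.

The defaults ``rt = 0.593 kcal/mol`` (T ~ 298 K) and ``c0 = 1 M`` place the
measured wildtype Yan SAM-SAM dissociation constant (~7 uM) at about
-7 kcal/mol, in the middle of the 0 to -14 kcal/mol affinity axis the model
is scanned over.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ThermoContext",
    "BindingEnergies",
    "DEFAULT_CONTEXT",
    "deltaG_to_kd",
    "kd_to_deltaG",
]


@dataclass(frozen=True)
class ThermoContext:
    """Thermal energy scale and reference concentration.

    Parameters
    ----------
    rt : float
        Thermal energy RT in kcal/mol. Default 0.593 (approx. 298 K).
    c0 : float
        Reference (standard-state) concentration in molar. Default 1.0.
    """

    rt: float = 0.593
    c0: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.rt) and self.rt > 0):
            raise ValueError(f"rt must be finite and > 0, got {self.rt!r}")
        if not (math.isfinite(self.c0) and self.c0 > 0):
            raise ValueError(f"c0 must be finite and > 0, got {self.c0!r}")


DEFAULT_CONTEXT = ThermoContext()


@dataclass(frozen=True)
class BindingEnergies:
    """The three interaction free energies of the occupancy model (kcal/mol).

    Parameters
    ----------
    alpha : float
        Sequence-specific (ETS site) protein-DNA binding free energy.
    beta : float
        Non-specific protein-DNA binding free energy, assigned to every
        non-ETS lattice position.
    gamma_sam : float
        SAM-SAM self-association free energy. Drives both the
        nearest-neighbor cooperativity on DNA and, by default, the off-DNA
        polymer dissociation constant.
    """

    alpha: float = -9.955
    beta: float = -5.837
    gamma_sam: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma_sam"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be a finite number, got {v!r}")


def deltaG_to_kd(dg: float, ctx: ThermoContext = DEFAULT_CONTEXT) -> float:
    """Convert a binding free energy (kcal/mol) to a dissociation constant (M).

    ``Kd = c0 * exp(dg / rt)``; more favorable (more negative) energies give
    smaller dissociation constants.
    """
    if not math.isfinite(dg):
        raise ValueError(f"free energy must be finite, got {dg!r}")
    return ctx.c0 * math.exp(dg / ctx.rt)


def kd_to_deltaG(kd: float, ctx: ThermoContext = DEFAULT_CONTEXT) -> float:
    """Convert a dissociation constant (M) to a binding free energy (kcal/mol).

    Inverse of :func:`deltaG_to_kd`: ``dG = rt * ln(kd / c0)``.
    """
    if not (math.isfinite(kd) and kd > 0):
        raise ValueError(f"kd must be finite and > 0, got {kd!r}")
    return ctx.rt * math.log(kd / ctx.c0)
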