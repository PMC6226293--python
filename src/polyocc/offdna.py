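"""Off-DNA polymer pool: the binding-competent fraction of total TF.

Self-association off DNA follows an isodesmic-style truncated geometric
series in ``x = [TF]_total / Kd``: the mass-fraction of term j is
``x^j / sum_{k=0}^{n} x^k``. The fraction of the pool competent to nucleate
on DNA keeps the first ``m`` terms of that series in the numerator
(m = 1 monomers only; 2 adds dimers; 3 adds trimers):

    f_competent(x) = (sum_{k=0}^{m-1} x^k) / (sum_{k=0}^{n} x^k)

The effective concentration available to bind DNA is then
``c_eff = c_total * f_competent``, which rises to a maximum near Kd and then
collapses as the pool is sequestered into long polymers. The series uses the
*total* concentration directly; no mass balance with DNA-bound material is
applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .thermo import DEFAULT_CONTEXT, BindingEnergies, ThermoContext, deltaG_to_kd

__all__ = [
    "OffDnaParams",
    "SpeciesDistribution",
    "competent_fraction",
    "effective_concentration",
    "species_distribution",
]


@dataclass(frozen=True)
class OffDnaParams:
    """Parameters of the off-DNA polymer pool.

    Parameters
    ----------
    kd_sam : float
        SAM-SAM dissociation constant in molar.
    n_max : int
        Maximum polymer index of the series (default 50; the curves are
        asymptotically insensitive to raising it further below saturation).
    m_species : int
        Number of numerator terms = nucleating species sizes allowed to
        bind DNA; 1, 2 or 3.
    """

    kd_sam: float
    n_max: int = 50
    m_species: int = 1

    def __post_init__(self) -> None:
        if not (math.isfinite(self.kd_sam) and self.kd_sam > 0):
            raise ValueError(f"kd_sam must be finite and > 0, got {self.kd_sam!r}")
        if int(self.n_max) != self.n_max or self.n_max < 1:
            raise ValueError(f"n_max must be an integer >= 1, got {self.n_max!r}")
        if self.m_species not in (1, 2, 3):
            raise ValueError(f"m_species must be 1, 2 or 3, got {self.m_species!r}")
        if self.m_species > self.n_max:
            raise ValueError("m_species cannot exceed n_max")
        object.__setattr__(self, "n_max", int(self.n_max))

    @classmethod
    def from_energies(
        cls,
        energies: BindingEnergies,
        ctx: ThermoContext = DEFAULT_CONTEXT,
        *,
        n_max: int = 50,
        m_species: int = 1,
    ) -> "OffDnaParams":
        """Derive ``kd_sam`` from the SAM-SAM free energy: Kd = c0*exp(gamma/rt)."""
        return cls(
            kd_sam=deltaG_to_kd(energies.gamma_sam, ctx),
            n_max=n_max,
            m_species=m_species,
        )


@dataclass(frozen=True)
class SpeciesDistribution:
    """Mass fractions of the polymer series terms j = 0..n_max."""

    fractions: np.ndarray
    c_total: float


def _log_geom_sum(logx: float, n_terms: int) -> float:
    """log of sum_{j=0}^{n_terms-1} x^j, evaluated stably for any x > 0."""
    return float(logsumexp(np.arange(n_terms) * logx))


def competent_fraction(c_total: float, p: OffDnaParams) -> float:
    """Fraction of total TF present as binding-competent (nucleating) species.

    Equals 1 at zero concentration and decreases strictly with concentration
    (for m_species < n_max). ``x = 1`` is handled by exact term count; very
    large ``x`` is evaluated in the log domain.
    """
    if not (math.isfinite(c_total) and c_total >= 0):
        raise ValueError(f"c_total must be finite and >= 0, got {c_total!r}")
    if c_total == 0.0:
        return 1.0
    x = c_total / p.kd_sam
    if x == 1.0:
        return p.m_species / (p.n_max + 1)
    # closed-form geometric ratio while x^(n+1) stays in floating range
    if (p.n_max + 1) * math.log(x) < 700.0:
        return (x**p.m_species - 1.0) / (x ** (p.n_max + 1) - 1.0)
    logx = math.log(x)
    return math.exp(
        _log_geom_sum(logx, p.m_species) - _log_geom_sum(logx, p.n_max + 1)
    )


def effective_concentration(c_total: float, p: OffDnaParams) -> float:
    """Binding-competent concentration ``c_total * competent_fraction`` (M).

    Evaluated through logarithms so that extreme sequestration underflows
    cleanly to 0.0 instead of producing 0 * inf artifacts.
    """
    if not (math.isfinite(c_total) and c_total >= 0):
        raise ValueError(f"c_total must be finite and >= 0, got {c_total!r}")
    if c_total == 0.0:
        return 0.0
    x = c_total / p.kd_sam
    if x == 1.0:
        return c_total * p.m_species / (p.n_max + 1)
    logx = math.log(x)
    log_frac = _log_geom_sum(logx, p.m_species) - _log_geom_sum(logx, p.n_max + 1)
    try:
        return math.exp(math.log(c_total) + log_frac)
    except OverflowError:  # pragma: no cover - frac <= 1 keeps this unreachable
        raise

def species_distribution(c_total: float, p: OffDnaParams) -> SpeciesDistribution:
    """Mass fractions ``x^j / sum_k x^k`` of the series terms j = 0..n_max.

    The mode sits at j = 0 for x < 1 and at j = n_max for x > 1; at x = 1 the
    distribution is uniform.
    """
    if not (math.isfinite(c_total) and c_total >= 0):
        raise ValueError(f"c_total must be finite and >= 0, got {c_total!r}")
    j = np.arange(p.n_max + 1)
    if c_total == 0.0:
        fractions = np.zeros(p.n_max + 1)
        fractions[0] = 1.0
        return SpeciesDistribution(fractions=fractions, c_total=c_total)
    logx = math.log(c_total / p.kd_sam)
    log_terms = j * logx
    fractions = np.exp(log_terms - logsumexp(log_terms))
    fractions /= fractions.sum()
    return SpeciesDistribution(fractions=fractions, c_total=c_total)
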