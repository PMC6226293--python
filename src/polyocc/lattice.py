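"""Equilibrium occupancy of a 1-D DNA lattice with nearest-neighbor cooperativity.

The DNA element is a row of N binding sites, each either an ETS (sequence
specific) site or a non-specific site. A microstate is a binary occupancy
pattern sigma over the sites; its statistical weight is

    W(sigma) = prod_{occupied i} w_i  *  prod_{adjacent occupied pairs} g

where ``w_i = (C_eff / c0) * exp(-eps_i / rt)`` is the per-site binding weight
and ``g = exp(-gamma_sam / rt)`` the SAM-SAM bond factor between occupied
neighbors. Bonds form only between occupied sites at adjacent lattice
positions (a linear head-to-tail polymer tracking the DNA); ends are free
(non-periodic). Fractional occupancy of site j is the Boltzmann average
``theta_j = sum_{sigma: sigma_j=1} W(sigma) / sum_sigma W(sigma)``.

Two evaluators are provided: :func:`occupancy_bruteforce` enumerates all 2^N
microstates (the oracle, guarded to small N by default) and
:func:`occupancy_fast` computes the same averages by a renormalized
forward/backward transfer recursion in O(N) time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .thermo import DEFAULT_CONTEXT, BindingEnergies, ThermoContext

__all__ = [
    "ETS",
    "NONSPECIFIC",
    "ElementLayout",
    "LatticeWeights",
    "OccupancyResult",
    "build_weights",
    "occupancy_bruteforce",
    "occupancy_fast",
]

ETS = "ETS"
NONSPECIFIC = "NONSPECIFIC"

# w = 0 sites must not poison the log-domain dot product with 0 * (-inf);
# this stands in for log(0) and underflows any occupied weight to zero.
_LOG_ZERO = -1e12


@dataclass(frozen=True)
class ElementLayout:
    """Ordered site classes of the DNA element (positions are 1-based in I/O)."""

    site_classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.site_classes) < 1:
            raise ValueError("element must have at least one site")
        bad = [c for c in self.site_classes if c not in (ETS, NONSPECIFIC)]
        if bad:
            raise ValueError(f"unknown site class(es): {bad}")

    @classmethod
    def default(cls) -> "ElementLayout":
        """The 24-site element: one ETS site first, then 23 non-specific sites."""
        return cls.from_positions(24, (1,))

    @classmethod
    def from_positions(cls, n_sites: int, ets_positions: Sequence[int]) -> "ElementLayout":
        """Build a layout from the element length and 1-based ETS positions."""
        n_sites = int(n_sites)
        if n_sites < 1:
            raise ValueError(f"n_sites must be >= 1, got {n_sites}")
        pos = sorted(int(p) for p in ets_positions)
        for p in pos:
            if not 1 <= p <= n_sites:
                raise ValueError(f"ETS position {p} outside 1..{n_sites}")
        classes = tuple(ETS if i + 1 in pos else NONSPECIFIC for i in range(n_sites))
        return cls(classes)

    @property
    def n_sites(self) -> int:
        return len(self.site_classes)

    @property
    def ets_positions(self) -> tuple[int, ...]:
        return tuple(i + 1 for i, c in enumerate(self.site_classes) if c == ETS)

    def site_energies(self, energies: BindingEnergies) -> np.ndarray:
        """Per-site binding free energies (kcal/mol): alpha at ETS, beta elsewhere."""
        return np.array(
            [energies.alpha if c == ETS else energies.beta for c in self.site_classes]
        )


@dataclass(frozen=True)
class LatticeWeights:
    """Dimensionless microstate weight components.

    ``w[i]`` is the binding weight of site i, ``g`` the nearest-neighbor
    SAM-SAM bond factor (g = 1 means no cooperativity). ``c_eff`` records the
    effective concentration the weights were built from, if known.
    """

    w: np.ndarray
    g: float
    c_eff: float | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if w.ndim != 1 or w.size < 1:
            raise ValueError("w must be a 1-D vector with at least one site")
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValueError("site weights must be finite and non-negative")
        if not (math.isfinite(self.g) and self.g > 0):
            raise ValueError(f"bond factor g must be finite and > 0, got {self.g!r}")


@dataclass(frozen=True)
class OccupancyResult:
    """Per-site fractional occupancy, with the effective concentration used."""

    theta: np.ndarray
    c_eff: float | None = None


def build_weights(
    layout: ElementLayout,
    energies: BindingEnergies,
    c_eff: float,
    ctx: ThermoContext = DEFAULT_CONTEXT,
) -> LatticeWeights:
    """Statistical weights for a layout at effective concentration ``c_eff`` (M).

    ``w_i = (c_eff / c0) * exp(-eps_i / rt)`` with eps_i = alpha (ETS) or beta
    (non-specific); ``g = exp(-gamma_sam / rt)``.
    """
    if not (math.isfinite(c_eff) and c_eff >= 0):
        raise ValueError(f"c_eff must be finite and >= 0, got {c_eff!r}")
    eps = layout.site_energies(energies)
    w = (c_eff / ctx.c0) * np.exp(-eps / ctx.rt)
    g = math.exp(-energies.gamma_sam / ctx.rt)
    return LatticeWeights(w=w, g=g, c_eff=c_eff)


def _check(layout: ElementLayout, weights: LatticeWeights) -> tuple[np.ndarray, float, int]:
    w = np.asarray(weights.w, dtype=float)
    if w.size != layout.n_sites:
        raise ValueError(
            f"weights have {w.size} sites but layout has {layout.n_sites}"
        )
    return w, float(weights.g), layout.n_sites


def occupancy_bruteforce(
    layout: ElementLayout,
    weights: LatticeWeights,
    *,
    max_sites: int = 20,
    chunk_bits: int = 18,
) -> OccupancyResult:
    """Exact occupancy by full enumeration of all 2^N microstates.

    Log-sum-exp accumulation over chunks of microstates keeps the partition
    function in range for arbitrarily large weights. Refuses N > ``max_sites``
    unless the guard is raised explicitly (enumeration is exponential in N).
    """
    w, g, n = _check(layout, weights)
    if n > max_sites:
        raise ValueError(
            f"brute-force enumeration limited to {max_sites} sites, got {n}; "
            "raise max_sites explicitly if you really want 2^N states"
        )
    with np.errstate(divide="ignore"):
        logw = np.log(w)
    logw = np.where(np.isneginf(logw), _LOG_ZERO, logw)
    logg = math.log(g)

    total = 1 << n
    chunk = 1 << min(chunk_bits, n)
    shifts = np.arange(n, dtype=np.uint64)
    z_parts: list[float] = []
    num_parts: list[np.ndarray] = []
    for start in range(0, total, chunk):
        cfg = np.arange(start, min(start + chunk, total), dtype=np.uint64)
        bits = ((cfg[:, None] >> shifts[None, :]) & np.uint64(1)).astype(np.float64)
        pairs = np.bitwise_count(cfg & (cfg >> np.uint64(1))).astype(np.float64)
        log_w_states = bits @ logw + pairs * logg
        z_parts.append(float(logsumexp(log_w_states)))
        occ = np.empty(n)
        for j in range(n):
            mask = bits[:, j] > 0
            occ[j] = logsumexp(log_w_states[mask]) if mask.any() else -np.inf
        num_parts.append(occ)
    log_z = logsumexp(z_parts)
    log_num = logsumexp(np.vstack(num_parts), axis=0)
    theta = np.exp(log_num - log_z)
    return OccupancyResult(theta=theta, c_eff=weights.c_eff)


def occupancy_fast(layout: ElementLayout, weights: LatticeWeights) -> OccupancyResult:
    """Occupancy by forward/backward transfer recursion, O(N) time.

    Mathematically identical to :func:`occupancy_bruteforce`. Each step the
    partial partition vectors are renormalized so no intermediate over- or
    underflows for weights anywhere in double range.
    """
    w, g, n = _check(layout, weights)

    # f[i, s]: partition sum of sites 0..i with site i empty (s=0) / occupied (s=1)
    f = np.empty((n, 2))
    f[0, 0] = 1.0
    f[0, 1] = w[0]
    f[0] /= f[0].sum()
    for i in range(1, n):
        e_prev, o_prev = f[i - 1]
        f[i, 0] = e_prev + o_prev
        # ordered to keep every intermediate product inside double range
        f[i, 1] = w[i] * e_prev + g * (w[i] * o_prev)
        f[i] /= f[i].sum()

    # b[i, s]: partition sum of sites i+1..N-1 conditioned on the state of site i
    b = np.empty((n, 2))
    b[n - 1] = 1.0
    b[n - 1] /= b[n - 1].sum()
    for i in range(n - 2, -1, -1):
        e_next, o_next = b[i + 1]
        b[i, 0] = e_next + w[i + 1] * o_next
        b[i, 1] = e_next + g * (w[i + 1] * o_next)
        b[i] /= b[i].sum()

    occ = f[:, 1] * b[:, 1]
    emp = f[:, 0] * b[:, 0]
    theta = occ / (occ + emp)
    return OccupancyResult(theta=theta, c_eff=weights.c_eff)
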