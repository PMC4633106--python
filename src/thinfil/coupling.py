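"""Local-coupling rate law for myosin binding to regulated actin.

On a thin filament, tropomyosin sterically blocks myosin binding sites.
A bound myosin head displaces tropomyosin locally, which lowers the
energetic cost for *nearby* heads to bind while leaving distant heads
unaffected.  The model reduces this to two dimensionless parameters:

* ``C`` — the critical coupling range in binding-site units.  Two bound
  heads closer than ``C`` sites fully activate the actin between them.
* ``epsilon`` — the factor by which troponin/tropomyosin reduces the
  attachment rate of an *isolated* head (calcium dependent, in (0, 1]).

The attachment rate of an empty site whose nearest bound neighbours sit
``i`` sites to the left and ``j`` sites to the right is piecewise::

    k(i, j) = eps * k0                      if i >= C and j >= C
            = eps**(i/C) * k0               if i <  C and j >= C
            = eps**(j/C) * k0               if i >= C and j <  C
            = eps**((i+j-C)/C) * k0         if i, j < C and i + j > C
            = k0                            if i + j <= C

where ``k0`` is the attachment rate to unregulated (bare) actin.  The
rate always lies in ``[eps*k0, k0]``.  Equivalently, binding against a
single neighbour a distance ``L`` away costs a free energy
``deltaE(L) = (min(L, C)/C) * (-ln eps)`` in units of kT, a linear ramp
that saturates at ``-ln(eps)`` once the heads are uncoupled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NO_NEIGHBOR",
    "CouplingParams",
    "NeighborDistances",
    "EnergyPenalty",
    "attachment_rate",
    "attachment_rates",
    "energy_penalty",
    "neighbor_distances",
]

#: Sentinel distance meaning "no bound myosin on that side (out to the
#: filament end)".  ``math.inf`` compares >= C for every admissible C,
#: so a side with no neighbour is always in the uncoupled regime.
NO_NEIGHBOR: float = math.inf


@dataclass(frozen=True)
class CouplingParams:
    """Parameters of the local-coupling rate law.

    Parameters
    ----------
    C : int
        Critical coupling length in units of the binding-site spacing
        (``C = L_C / dL``); must be >= 1.
    epsilon : float
        Attachment-rate reduction for an isolated head, in (0, 1].
    k0 : float
        Attachment rate to unregulated actin, s^-1 (for solution
        experiments ``k0 = k_b0 * [Myo]``).
    """

    C: int
    epsilon: float
    k0: float

    def __post_init__(self) -> None:
        if not (isinstance(self.C, (int, np.integer)) and self.C >= 1):
            raise ValueError(f"C must be a positive integer, got {self.C!r}")
        if not (0.0 < self.epsilon <= 1.0):
            raise ValueError(f"epsilon must lie in (0, 1], got {self.epsilon!r}")
        if self.k0 < 0:
            raise ValueError(f"k0 must be non-negative, got {self.k0!r}")


@dataclass(frozen=True)
class NeighborDistances:
    """Distances (site counts) to the nearest bound myosin on each side.

    ``i`` is the distance to the left, ``j`` to the right; both are >= 1
    when finite and :data:`NO_NEIGHBOR` when that side is empty out to
    the filament end.
    """

    i: float
    j: float

    def __post_init__(self) -> None:
        for d in (self.i, self.j):
            if d != NO_NEIGHBOR and (d < 1 or d != int(d)):
                raise ValueError(f"neighbor distances must be integers >= 1, got {d!r}")


@dataclass(frozen=True)
class EnergyPenalty:
    """Free-energy cost of binding (kT units); zero when epsilon == 1."""

    deltaE: float


def attachment_rate(i: float, j: float, params: CouplingParams) -> float:
    """Attachment rate (s^-1) for an empty site with neighbour distances i, j.

    Implements the piecewise local-coupling law (see module docstring).
    ``i``/``j`` may be :data:`NO_NEIGHBOR` when no head is bound on that
    side; the result then reduces to the single-neighbour / isolated
    branches.
    """
    for d in (i, j):
        if d != NO_NEIGHBOR and (d < 1 or d != int(d)):
            raise ValueError(f"neighbor distances must be integers >= 1 or NO_NEIGHBOR, got {d!r}")
    C, eps, k0 = params.C, params.epsilon, params.k0
    if i >= C and j >= C:
        return eps * k0
    if i < C and j >= C:
        return eps ** (i / C) * k0
    if i >= C and j < C:
        return eps ** (j / C) * k0
    # both neighbours inside the coupling range
    if i + j > C:
        return eps ** ((i + j - C) / C) * k0
    return k0


def attachment_rates(occupied: np.ndarray, params: CouplingParams) -> np.ndarray:
    """Vectorised attachment rates for every site of a lattice.

    Parameters
    ----------
    occupied : boolean array
        True where a myosin is bound.  Sites beyond either filament end
        count as unoccupied (no activation from outside the lattice).

    Returns
    -------
    rates : float array, same length
        Attachment rate for each *empty* site; 0 for occupied sites.

    Notes
    -----
    Uses the closed form ``k = k0 * eps**(max(min(i,C)+min(j,C)-C, 0)/C)``
    which is algebraically identical to the piecewise law for all
    branches (checked against :func:`attachment_rate` in the test suite).
    """
    occ = np.asarray(occupied, dtype=bool)
    n = occ.size
    C, eps, k0 = params.C, params.epsilon, params.k0
    idx = np.arange(n)
    # distance to nearest occupied site on the left
    last_left = np.where(occ, idx, -1)
    np.maximum.accumulate(last_left, out=last_left)
    di = np.where(last_left >= 0, idx - last_left, C).astype(float)
    # and on the right: same scan on the reversed lattice
    last_rev = np.where(occ[::-1], idx, -1)
    np.maximum.accumulate(last_rev, out=last_rev)
    dj = np.where(last_rev >= 0, idx - last_rev, C).astype(float)[::-1]
    di = np.minimum(di, C)
    dj = np.minimum(dj, C)
    expo = np.maximum(di + dj - C, 0.0) / C
    rates = k0 * np.power(eps, expo)
    rates[occ] = 0.0
    return rates


def energy_penalty(L: float, params: CouplingParams) -> EnergyPenalty:
    """Free-energy cost (kT) of binding at distance ``L`` from one bound head.

    ``deltaE = (min(L, C)/C) * (-ln eps)``: a linear ramp for ``L < C``
    that saturates at ``-ln(eps)`` once the heads deform tropomyosin
    independently.  ``exp(-deltaE)`` equals the single-neighbour rate
    factor of :func:`attachment_rate` with the other side empty.
    """
    if L < 0:
        raise ValueError(f"distance L must be non-negative, got {L!r}")
    ramp = min(L, params.C) / params.C
    return EnergyPenalty(deltaE=-ramp * math.log(params.epsilon))


def neighbor_distances(lattice, site_index: int) -> NeighborDistances:
    """Distances from an empty site to the nearest bound myosin on each side.

    ``lattice`` is any sequence that is truthy at occupied sites (a
    boolean occupancy array, or lattice states where nonzero == bound).
    Returns :data:`NO_NEIGHBOR` for a side with no bound head, including
    past the filament end.
    """
    occ = np.asarray(lattice) != 0
    n = occ.size
    if not 0 <= site_index < n:
        raise IndexError(f"site_index {site_index} outside lattice of {n} sites")
    if occ[site_index]:
        raise ValueError(f"site {site_index} is occupied; attachment rate undefined")
    left = occ[:site_index][::-1]
    right = occ[site_index + 1:]
    i = float(np.argmax(left) + 1) if left.any() else NO_NEIGHBOR
    j = float(np.argmax(right) + 1) if right.any() else NO_NEIGHBOR
    return NeighborDistances(i=i, j=j)
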