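"""Exact master-equation oracle for the coupled-lattice kinetics.

For a small lattice (N sites, 3^N joint states) the binding/release/
detachment dynamics form a finite continuous-time Markov chain whose
stationary distribution can be computed exactly from the generator
matrix (``pi Q = 0``, ``sum pi = 1``).  This module enumerates that
chain and solves it, providing an independent correctness oracle for
the Gillespie engine: empirical time-weighted joint-state frequencies
from long simulations must converge to the exact stationary law.

The transition rates here are written out from the model definition
(piecewise local-coupling attachment, ADP release at k_D, detachment at
k_T[ATP]) independently of :mod:`thinfil.coupling` /
:mod:`thinfil.simulate`, so agreement between the two is evidence, not
tautology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .simulate import AM, AMD, EMPTY, Condition, EventTrace, KineticParams

__all__ = ["StateSpace", "build_generator", "exact_steady_state",
           "site_marginal_occupancy", "empirical_state_distribution",
           "total_variation"]

_MAX_SITES = 10  # 3^10 joint states; dense solves are practical well below this


@dataclass
class StateSpace:
    """Enumerated joint state space of an N-site lattice with its generator."""

    n_sites: int
    Q: np.ndarray  # (3^N, 3^N) generator; rows sum to zero

    @property
    def n_states(self) -> int:
        return 3 ** self.n_sites

    def decode(self, index: int) -> tuple[int, ...]:
        """Joint state as a tuple of per-site states (site 0 first)."""
        digits = []
        for _ in range(self.n_sites):
            digits.append(index % 3)
            index //= 3
        return tuple(digits)

    def encode(self, sites: tuple[int, ...]) -> int:
        code = 0
        for k, s in enumerate(sites):
            code += s * 3 ** k
        return code


def _attach_rate(sites: tuple[int, ...], s: int, C: int, eps: float, k0: float) -> float:
    # Independent re-statement of the piecewise coupling law, with the
    # nearest-neighbour scan done by explicit loops.
    n = len(sites)
    i = None
    for d in range(1, n):
        if s - d >= 0 and sites[s - d] != EMPTY:
            i = d
            break
    j = None
    for d in range(1, n):
        if s + d < n and sites[s + d] != EMPTY:
            j = d
            break
    far = C  # no neighbour on a side behaves as distance >= C
    i = far if i is None else min(i, far)
    j = far if j is None else min(j, far)
    if i >= C and j >= C:
        return eps * k0
    if i < C <= j:
        return eps ** (i / C) * k0
    if j < C <= i:
        return eps ** (j / C) * k0
    if i + j > C:
        return eps ** ((i + j - C) / C) * k0
    return k0


def build_generator(N: int, condition: Condition, kinetics: KineticParams) -> StateSpace:
    """Generator matrix of the joint chain on an N-site lattice (N <= 10)."""
    if not 1 <= N <= _MAX_SITES:
        raise ValueError(f"N must be in [1, {_MAX_SITES}], got {N}")
    k0 = kinetics.k_b0 * condition.myo_nM
    k_detach = kinetics.k_T * condition.atp_uM
    C, eps = condition.C, condition.epsilon
    n_states = 3 ** N
    Q = np.zeros((n_states, n_states))
    space = StateSpace(n_sites=N, Q=Q)
    for a in range(n_states):
        sites = space.decode(a)
        for s in range(N):
            st = sites[s]
            if st == EMPTY:
                rate = _attach_rate(sites, s, C, eps, k0)
                new = AMD
            elif st == AMD:
                rate = kinetics.k_D
                new = AM
            else:
                rate = k_detach
                new = EMPTY
            if rate <= 0.0:
                continue
            b = space.encode(sites[:s] + (new,) + sites[s + 1:])
            Q[a, b] += rate
            Q[a, a] -= rate
    return space


def exact_steady_state(space: StateSpace) -> np.ndarray:
    """Stationary distribution: solve ``pi Q = 0`` with ``sum pi = 1``."""
    ns = scipy.linalg.null_space(space.Q.T)
    if ns.shape[1] != 1:
        raise ValueError(
            f"generator has a {ns.shape[1]}-dimensional null space; chain is "
            "reducible or degenerate"
        )
    pi = ns[:, 0].real
    pi = pi / pi.sum()
    if pi.min() < -1e-9:
        raise ValueError("negative stationary probabilities; generator is invalid")
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def site_marginal_occupancy(space: StateSpace, pi: np.ndarray) -> np.ndarray:
    """Per-site probability of being bound (AMD or AM) under ``pi``."""
    marg = np.zeros(space.n_sites)
    for a, p in enumerate(pi):
        for s, st in enumerate(space.decode(a)):
            if st != EMPTY:
                marg[s] += p
    return marg


def empirical_state_distribution(trace: EventTrace, t_start: float = 0.0) -> np.ndarray:
    """Time-weighted joint-state frequencies observed in a trajectory.

    Replays the event trace from the all-empty state and accumulates the
    time spent in each joint state after ``t_start`` (use the
    equilibration time to discard the transient).
    """
    N = trace.n_sites
    space = StateSpace(n_sites=N, Q=np.zeros((0, 0)))
    occ_time = np.zeros(3 ** N)
    sites = [EMPTY] * N
    next_state = {EMPTY: AMD, AMD: AM, AM: EMPTY}
    t_prev = 0.0
    code = 0
    for t, s, _e in zip(trace.times, trace.sites, trace.events):
        if t > t_start:
            occ_time[code] += t - max(t_prev, t_start)
        old = sites[s]
        new = next_state[old]
        code += (new - old) * 3 ** int(s)
        sites[s] = new
        t_prev = t
    if trace.duration > max(t_prev, t_start):
        occ_time[code] += trace.duration - max(t_prev, t_start)
    total = occ_time.sum()
    if total <= 0:
        raise ValueError("trace has no observation time after t_start")
    return occ_time / total


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """Total-variation distance between two distributions."""
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())
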