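"""Gillespie simulation of GFP-S1 binding to a regulated thin filament.

One side of a thin filament is a 1D lattice of actin monomers (binding
sites, 5.5 nm apart; 546 sites for a 3 um filament).  Each site cycles

    EMPTY --k_b(i,j)--> AMD --k_D--> AM --k_T[ATP]--> EMPTY

where ``AMD`` is the strongly-bound ADP state entered directly from
solution (weak-to-strong transitions faster than the camera are lumped
in), ``AM`` is nucleotide-free rigor, and detachment follows ATP binding.
Only the attachment rate is regulated: it is the local-coupling law of
:mod:`thinfil.coupling` with base rate ``k0 = k_b0 * [Myo]``.  ADP
release and ATP-induced detachment are coupling independent.

A filament has two independently regulated sides; heads from solution
bind either one, and both sides are rendered onto the same pixel line.
The simulator is the exact direct-method Gillespie algorithm: an
exponential waiting time from the total propensity, the event chosen
proportionally to its rate, and all propensities recomputed after every
event.  A run equilibrates for ``t_equil_s`` (default 35 s) before the
camera starts, then records ``n_frames`` at ``frame_rate_hz``; frame
weights are the fraction of each frame a site spent occupied (both AMD
and AM fluoresce — the GFP sits on the myosin, not the nucleotide).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .coupling import CouplingParams, attachment_rates

__all__ = [
    "EMPTY", "AMD", "AM", "BIND", "ADP_RELEASE", "DETACH",
    "KineticParams", "Condition", "LatticeState", "EventTrace", "FrameStack",
    "init_lattice", "per_site_attachment_k0", "propensities",
    "gillespie_run", "sample_frames", "simulate_filament",
]

# site states
EMPTY, AMD, AM = 0, 1, 2
# event codes
BIND, ADP_RELEASE, DETACH = 0, 1, 2

_EVENT_NAMES = {BIND: "BIND", ADP_RELEASE: "ADP_RELEASE", DETACH: "DETACH"}


@dataclass(frozen=True)
class KineticParams:
    """Actomyosin cycle rate constants.

    k_b0 : per-site attachment rate constant, nM^-1 s^-1
        (0.2 nM^-1 um^-1 s^-1 per um of actin, i.e. 0.00055 per site at
        5.5 nm spacing with two sites per repeat — see
        :func:`per_site_k_b0_from_per_um`).
    k_D : ADP release rate, s^-1.
    k_T : ATP-induced detachment rate constant, uM^-1 s^-1.
    """

    k_b0: float = 0.00055
    k_D: float = 350.0
    k_T: float = 2.0

    def __post_init__(self) -> None:
        for name in ("k_b0", "k_D", "k_T"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class Condition:
    """One experimental condition (concentrations, optics-facing settings).

    Concentrations follow the experimental units: myosin in nM, ATP in
    uM.  ``epsilon`` is the coupling factor for the condition's pCa
    (calcium maps to epsilon via configuration, not code) and ``sigma_N``
    the background-noise SD in scaled-intensity units.
    """

    myo_nM: float
    atp_uM: float
    epsilon: float
    frame_rate_hz: float
    n_frames: int
    sigma_N: float = 0.0
    C: int = 70
    t_equil_s: float = 35.0
    length_um: float = 3.0
    spacing_nm: float = 5.5

    def __post_init__(self) -> None:
        if self.myo_nM < 0 or self.atp_uM < 0:
            raise ValueError("concentrations must be non-negative")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (0.0 < self.epsilon <= 1.0):
            raise ValueError("epsilon must lie in (0, 1]")
        if self.sigma_N < 0:
            raise ValueError("sigma_N must be non-negative")
        if self.t_equil_s < 0:
            raise ValueError("t_equil_s must be non-negative")

    @property
    def duration_s(self) -> float:
        """Total simulated time: equilibration plus the recording window."""
        return self.t_equil_s + self.n_frames / self.frame_rate_hz

    def coupling(self, kinetics: KineticParams) -> CouplingParams:
        return CouplingParams(C=self.C, epsilon=self.epsilon,
                              k0=per_site_attachment_k0(kinetics, self.myo_nM))


@dataclass
class LatticeState:
    """Per-site occupancy of one filament side at an instant."""

    states: np.ndarray  # int8 per site: EMPTY/AMD/AM
    time: float = 0.0

    @property
    def n_sites(self) -> int:
        return self.states.size

    def occupied(self) -> np.ndarray:
        return self.states != EMPTY


@dataclass
class EventTrace:
    """Time-ordered record of one side's stochastic trajectory."""

    times: np.ndarray   # float64, strictly increasing
    sites: np.ndarray   # int32
    events: np.ndarray  # int8 (BIND / ADP_RELEASE / DETACH)
    n_sites: int
    duration: float
    side: str = "A"

    def __len__(self) -> int:
        return self.times.size

    def event_names(self) -> list[str]:
        return [_EVENT_NAMES[e] for e in self.events]


@dataclass
class FrameStack:
    """Per-frame, per-site fractional occupancy (camera-sampled trajectory)."""

    weights: np.ndarray  # (n_frames, n_sites), each in [0, 1]
    frame_rate_hz: float

    @property
    def n_frames(self) -> int:
        return self.weights.shape[0]

    @property
    def n_sites(self) -> int:
        return self.weights.shape[1]


def init_lattice(length_um: float, spacing_nm: float = 5.5) -> LatticeState:
    """All-empty lattice with ``ceil(length / spacing)`` sites at time 0.

    3 um at 5.5 nm spacing gives the 546 sites of one thin
    filament side.
    """
    if length_um <= 0 or spacing_nm <= 0:
        raise ValueError("length_um and spacing_nm must be positive")
    n = math.ceil(length_um * 1000.0 / spacing_nm)
    return LatticeState(states=np.zeros(n, dtype=np.int8), time=0.0)


def per_site_k_b0_from_per_um(kappa_b0_per_um: float, spacing_nm: float = 5.5,
                              sides_per_filament: int = 2) -> float:
    """Convert a per-um-of-actin attachment constant to per binding site.

    A filament has two regulated sides, so 1 um of actin carries
    ``1000 / spacing_nm * sides`` sites; 0.2 nM^-1 um^-1 s^-1 becomes
    0.00055 nM^-1 s^-1 per site.
    """
    return kappa_b0_per_um * (spacing_nm / 1000.0) / sides_per_filament


def per_site_attachment_k0(kinetics: KineticParams, myo_nM: float) -> float:
    """Base (unregulated) per-site attachment rate ``k0 = k_b0 * [Myo]``, s^-1."""
    if myo_nM < 0:
        raise ValueError("myo_nM must be non-negative")
    return kinetics.k_b0 * myo_nM


def _rate_vector(states: np.ndarray, coupling: CouplingParams,
                 k_D: float, k_detach: float) -> np.ndarray:
    """Per-site propensity: BIND for EMPTY, ADP release for AMD, detach for AM."""
    rates = attachment_rates(states != EMPTY, coupling)
    rates[states == AMD] = k_D
    rates[states == AM] = k_detach
    return rates


def propensities(lattice: LatticeState, condition: Condition,
                 kinetics: KineticParams) -> list[tuple[int, int, float]]:
    """All possible next events as ``(event, site, rate)`` triples.

    EMPTY sites bind at the local-coupling rate, AMD sites release ADP at
    ``k_D``, AM sites detach at ``k_T * [ATP]`` (s^-1 with ATP in uM).
    """
    coupling = condition.coupling(kinetics)
    k_detach = kinetics.k_T * condition.atp_uM
    rates = _rate_vector(lattice.states, coupling, kinetics.k_D, k_detach)
    event_for_state = {EMPTY: BIND, AMD: ADP_RELEASE, AM: DETACH}
    return [
        (event_for_state[int(lattice.states[s])], s, float(rates[s]))
        for s in range(lattice.n_sites)
        if rates[s] > 0.0
    ]


def gillespie_run(condition: Condition, kinetics: KineticParams,
                  seed, side: str = "A") -> EventTrace:
    """Exact stochastic trajectory of one filament side.

    Direct-method Gillespie: after every event all propensities are
    recomputed, the waiting time is exponential in the total, and the
    event is drawn proportionally to its rate.  The trajectory covers
    ``condition.duration_s`` (equilibration + recording window) and is
    bit-reproducible for a fixed seed (``seed`` may be an int or a
    ``numpy.random.SeedSequence``/``Generator``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lattice = init_lattice(condition.length_um, condition.spacing_nm)
    states = lattice.states
    coupling = condition.coupling(kinetics)
    k_detach = kinetics.k_T * condition.atp_uM
    duration = condition.duration_s

    times: list[float] = []
    sites: list[int] = []
    events: list[int] = []
    t = 0.0
    next_state = {EMPTY: AMD, AMD: AM, AM: EMPTY}
    event_for_state = {EMPTY: BIND, AMD: ADP_RELEASE, AM: DETACH}
    while True:
        rates = _rate_vector(states, coupling, kinetics.k_D, k_detach)
        total = rates.sum()
        if total <= 0.0:  # e.g. [Myo] = 0 with an empty lattice
            break
        t += rng.exponential(1.0 / total)
        if t >= duration:
            break
        cum = np.cumsum(rates)
        s = int(np.searchsorted(cum, rng.random() * total, side="right"))
        state = int(states[s])
        times.append(t)
        sites.append(s)
        events.append(event_for_state[state])
        states[s] = next_state[state]

    return EventTrace(
        times=np.asarray(times, dtype=np.float64),
        sites=np.asarray(sites, dtype=np.int32),
        events=np.asarray(events, dtype=np.int8),
        n_sites=lattice.n_sites,
        duration=duration,
        side=side,
    )


def bound_intervals(trace: EventTrace) -> list[tuple[int, float, float]]:
    """(site, t_bind, t_detach) intervals during which a site fluoresced.

    A site fluoresces from BIND until DETACH (AMD and AM both carry the
    GFP); an interval still open at the end of the trajectory is closed
    at ``trace.duration``.
    """
    open_at: dict[int, float] = {}
    out: list[tuple[int, float, float]] = []
    for t, s, e in zip(trace.times, trace.sites, trace.events):
        if e == BIND:
            open_at[int(s)] = float(t)
        elif e == DETACH:
            out.append((int(s), open_at.pop(int(s)), float(t)))
    for s, t0 in open_at.items():
        out.append((s, t0, trace.duration))
    return out


def sample_frames(trace: EventTrace, condition: Condition) -> FrameStack:
    """Camera-sample a trajectory into per-frame fractional occupancies.

    Frame ``k`` spans ``[t_equil + k/f, t_equil + (k+1)/f)``; the weight
    of a site in a frame is the fraction of the frame it spent bound, so
    a head bound for a tenth of the exposure is a tenth as bright.
    """
    f = condition.frame_rate_hz
    t0 = condition.t_equil_s
    n_frames = condition.n_frames
    window_end = t0 + n_frames / f
    if trace.duration < window_end - 1e-9:
        raise ValueError(
            f"trace covers {trace.duration} s but the recording window ends at {window_end} s"
        )
    dt = 1.0 / f
    weights = np.zeros((n_frames, trace.n_sites))
    for site, a, b in bound_intervals(trace):
        a = max(a, t0)
        b = min(b, window_end)
        if b <= a:
            continue
        k0 = int((a - t0) / dt)
        k1 = min(int((b - t0) / dt), n_frames - 1)
        for k in range(k0, k1 + 1):
            lo = t0 + k * dt
            overlap = min(b, lo + dt) - max(a, lo)
            if overlap > 0:
                weights[k, site] += overlap / dt
    np.clip(weights, 0.0, 1.0, out=weights)
    return FrameStack(weights=weights, frame_rate_hz=f)


def simulate_filament(condition: Condition, kinetics: KineticParams,
                      seed) -> tuple[FrameStack, FrameStack]:
    """Simulate both independently regulated sides of one thin filament.

    The two sides use independent random streams spawned deterministically
    from the master seed, so a run is reproducible while the sides differ
    almost surely.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_a, child_b = ss.spawn(2)
    stacks = []
    for side, child in (("A", child_a), ("B", child_b)):
        trace = gillespie_run(condition, kinetics, np.random.default_rng(child), side=side)
        stacks.append(sample_frames(trace, condition))
    return stacks[0], stacks[1]
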