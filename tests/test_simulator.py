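"""Tests of the Gillespie thin-filament simulator."""

import numpy as np
import pytest

from thinfil import (AM, AMD, BIND, ADP_RELEASE, DETACH, EMPTY,
                     KineticParams, LatticeState, gillespie_run, init_lattice,
                     per_site_attachment_k0, per_site_k_b0_from_per_um,
                     propensities, sample_frames, simulate_filament, EventTrace,
                     FrameStack)

from conftest import make_condition


@pytest.mark.parametrize("length_um,spacing_nm,expected", [
    (3.0, 5.5, 546),       # one side of a 3 um thin filament
    (0.0055, 5.5, 1),
    (1.0, 5.5, 182),
])
def test_init_lattice_site_count(length_um, spacing_nm, expected):
    lat = init_lattice(length_um, spacing_nm)
    assert lat.n_sites == expected
    assert np.all(lat.states == EMPTY)
    assert lat.time == 0.0


def test_init_lattice_rejects_nonpositive():
    with pytest.raises(ValueError):
        init_lattice(0.0, 5.5)
    with pytest.raises(ValueError):
        init_lattice(3.0, -1.0)


def test_per_site_attachment_rate(kinetics):
    assert per_site_attachment_k0(kinetics, 15.0) == pytest.approx(0.00825)
    assert per_site_attachment_k0(kinetics, 0.0) == 0.0
    # per-um constant of 0.2 nM^-1 um^-1 s^-1, two sides, 5.5 nm sites
    assert per_site_k_b0_from_per_um(0.2) == pytest.approx(0.00055)


def test_propensities_on_empty_lattice(kinetics):
    cond = make_condition(myo_nM=15.0, epsilon=0.06)
    lat = init_lattice(3.0, 5.5)
    props = propensities(lat, cond, kinetics)
    assert len(props) == 546
    rates = np.array([r for _, _, r in props])
    assert np.allclose(rates, 0.06 * 0.00825)
    assert rates.sum() == pytest.approx(546 * 0.06 * 0.00825)
    assert all(ev == BIND for ev, _, _ in props)


def test_propensities_of_bound_states(kinetics):
    cond = make_condition(atp_uM=0.5)
    lat = LatticeState(states=np.array([AM, AMD, EMPTY], dtype=np.int8))
    props = {(ev, s): r for ev, s, r in propensities(lat, cond, kinetics)}
    assert props[(DETACH, 0)] == pytest.approx(1.0)      # 2 uM^-1 s^-1 * 0.5 uM
    assert props[(ADP_RELEASE, 1)] == pytest.approx(350.0)


def test_no_myosin_means_no_events(kinetics):
    cond = make_condition(myo_nM=0.0, n_frames=5)
    trace = gillespie_run(cond, kinetics, 0)
    assert len(trace) == 0
    assert trace.duration == pytest.approx(cond.duration_s)
    stacks = simulate_filament(cond, kinetics, 0)
    assert all(np.all(s.weights == 0.0) for s in stacks)


def test_event_sequence_is_bind_adp_detach_cycles(kinetics):
    """Every site's history is a repetition of BIND -> ADP_RELEASE -> DETACH."""
    cond = make_condition(myo_nM=200.0, atp_uM=2.0, epsilon=0.4, n_frames=100,
                          length_um=0.1)
    trace = gillespie_run(cond, kinetics, 3)
    assert len(trace) > 50
    assert np.all(np.diff(trace.times) > 0)
    expected_next = {None: BIND, BIND: ADP_RELEASE, ADP_RELEASE: DETACH, DETACH: BIND}
    last = {}
    for s, e in zip(trace.sites, trace.events):
        assert e == expected_next[last.get(int(s))]
        last[int(s)] = int(e)


def test_determinism_and_side_independence(kinetics):
    cond = make_condition(myo_nM=100.0, epsilon=0.4, n_frames=20, length_um=0.5)
    a1 = simulate_filament(cond, kinetics, 11)
    a2 = simulate_filament(cond, kinetics, 11)
    assert np.array_equal(a1[0].weights, a2[0].weights)
    assert np.array_equal(a1[1].weights, a2[1].weights)
    # the two sides use distinct streams
    assert not np.array_equal(a1[0].weights, a1[1].weights)


def _trace(times_sites_events, n_sites, duration):
    t, s, e = zip(*times_sites_events)
    return EventTrace(times=np.array(t, float), sites=np.array(s, np.int32),
                      events=np.array(e, np.int8), n_sites=n_sites,
                      duration=duration)


def test_sample_frames_full_and_partial_occupancy():
    cond = make_condition(frame_rate_hz=10.0, n_frames=3, t_equil_s=0.0)
    # bound through all of frame 1 -> weight 1
    tr = _trace([(0.10, 0, BIND), (0.05 + 0.2, 0, ADP_RELEASE), (0.30, 0, DETACH)],
                n_sites=2, duration=0.3)
    w = sample_frames(tr, cond).weights
    assert w[1, 0] == pytest.approx(1.0)
    # bound 0.01 s within one frame at 10 Hz -> a tenth as bright
    tr = _trace([(0.02, 1, BIND), (0.025, 1, ADP_RELEASE), (0.03, 1, DETACH)],
                n_sites=2, duration=0.3)
    w = sample_frames(tr, cond).weights
    assert w[0, 1] == pytest.approx(0.1)
    # an interval straddling a frame boundary splits 30%/70%
    tr = _trace([(0.07, 0, BIND), (0.08, 0, ADP_RELEASE), (0.17, 0, DETACH)],
                n_sites=2, duration=0.3)
    w = sample_frames(tr, cond).weights
    assert w[0, 0] == pytest.approx(0.3)
    assert w[1, 0] == pytest.approx(0.7)


def test_sample_frames_rejects_short_trace():
    cond = make_condition(frame_rate_hz=10.0, n_frames=100, t_equil_s=35.0)
    tr = _trace([(0.1, 0, BIND)], n_sites=1, duration=1.0)
    with pytest.raises(ValueError):
        sample_frames(tr, cond)


def test_unregulated_occupancy_matches_three_state_closed_form(kinetics):
    """At eps=1 sites are independent and mean occupancy follows
    p = k_on*tau/(1 + k_on*tau), tau = 1/k_D + 1/(k_T[ATP])."""
    cond = make_condition(myo_nM=15.0, atp_uM=0.5, epsilon=1.0,
                          frame_rate_hz=10.0, n_frames=800, sigma_N=0.0)
    trace = gillespie_run(cond, kinetics, 2024)
    stack = sample_frames(trace, cond)
    k_on = 0.00055 * 15.0
    tau = 1 / 350.0 + 1 / (2.0 * 0.5)
    p = k_on * tau / (1 + k_on * tau)
    assert p == pytest.approx(0.00820, abs=1e-5)  # sanity on the closed form
    site_means = stack.weights.mean(axis=0)
    se = site_means.std(ddof=1) / np.sqrt(site_means.size)
    assert abs(site_means.mean() - p) < 3 * se


def test_occupancy_is_stationary_after_equilibration(kinetics):
    """Mean occupancy in the two halves of the recording window agrees
    within Monte-Carlo error: the 35 s equilibration removes transients.
    Frames are autocorrelated, so the error scale comes from the
    replicate-to-replicate scatter of the half-difference itself."""
    cond = make_condition(myo_nM=300.0, atp_uM=1.0, epsilon=0.4,
                          frame_rate_hz=10.0, n_frames=200, length_um=1.0)
    diffs = []
    for ss in np.random.SeedSequence(5).spawn(8):
        stack = sample_frames(gillespie_run(cond, kinetics, ss), cond)
        half = stack.n_frames // 2
        diffs.append(stack.weights[:half].mean() - stack.weights[half:].mean())
    diffs = np.asarray(diffs)
    se = diffs.std(ddof=1) / np.sqrt(diffs.size)
    assert abs(diffs.mean()) < 4 * se


def test_mean_occupancy_superlinear_in_myosin_with_coupling(kinetics):
    """With eps<1 and C>1 occupancy rises faster than linearly in [Myo]
    (local coupling); raw lattice occupancy, no optics involved."""
    means = []
    for myo in (1.0, 5.0, 10.0, 15.0):
        cond = make_condition(myo_nM=myo, atp_uM=0.1, epsilon=0.06,
                              frame_rate_hz=10.0, n_frames=300)
        reps = [sample_frames(gillespie_run(cond, kinetics, s), cond).weights.mean()
                for s in np.random.SeedSequence(60 + int(myo)).spawn(5)]
        means.append(np.mean(reps))
    x = np.array([1.0, 5.0, 10.0, 15.0])
    y = np.array(means)
    # second differences on the non-uniform grid
    d2 = [2 * ((y[k + 1] - y[k]) / (x[k + 1] - x[k]) - (y[k] - y[k - 1]) / (x[k] - x[k - 1]))
          / (x[k + 1] - x[k - 1]) for k in (1, 2)]
    assert all(v > 0 for v in d2)
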