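"""Order parameters, landscapes, state maps and first-passage events."""

import numpy as np
import pytest

from dualsbm.landscape import (Event, OrderParameterSeries, StateWindow,
                               contact_probability_map, detect_events,
                               first_passage_histogram, landscape_histogram,
                               order_parameters, q_fraction)
from dualsbm.langevin import SimulationParams, Trajectory, run_langevin


def _frozen_traj(coords, n_frames=3):
    frames = np.repeat(coords[None], n_frames, axis=0)
    return Trajectory(frames=frames, times=2.0 * np.arange(n_frames),
                      potential_energy=np.zeros(n_frames),
                      kinetic_energy=np.zeros(n_frames),
                      termination="max_steps")


def test_q_fraction_native_is_one(toy):
    idx, r0 = toy.defs.kow_alpha_contacts
    assert q_fraction(toy.start, idx, r0) == 1.0


def test_q_fraction_blown_apart_is_zero(toy):
    idx, r0 = toy.defs.kow_alpha_contacts
    assert q_fraction(toy.start * 10.0, idx, r0) == 0.0


def test_q_fraction_counts_exactly():
    """Four contacts with three constructed formed gives 0.75."""
    idx = np.array([[0, 1], [0, 2], [0, 3], [0, 4]])
    r0 = np.full(4, 0.5)
    frame = np.array([
        [0.0, 0, 0], [0.5, 0, 0], [0.55, 0, 0], [0.59, 0, 0],
        [0.61, 0, 0],  # 0.61 >= 1.2 * 0.5: broken
    ])
    assert q_fraction(frame, idx, r0) == 0.75


def test_q_fraction_empty_contacts_raise():
    with pytest.raises(ValueError, match="empty"):
        q_fraction(np.zeros((3, 3)), np.zeros((0, 2), dtype=int), np.zeros(0))


def test_q_monotone_under_isotropic_expansion(toy):
    idx, r0 = toy.defs.kow_alpha_contacts
    qs = [q_fraction(toy.start * s, idx, r0)
          for s in (1.0, 1.1, 1.25, 1.5, 2.0)]
    assert all(a >= b for a, b in zip(qs, qs[1:]))
    assert qs[0] == 1.0 and qs[-1] < qs[0]


def test_order_parameters_frozen_alpha_trajectory(toy):
    """A trajectory frozen at the alpha-native structure has Q_KOWalpha = 1,
    Q_ID = 1 for every frame, and a constant non-positive Q_diff."""
    series = order_parameters(_frozen_traj(toy.start), toy.defs)
    np.testing.assert_array_equal(series.q_kow_alpha, 1.0)
    np.testing.assert_array_equal(series.q_id, 1.0)
    assert np.ptp(series.q_diff) == 0.0
    assert np.all(series.q_diff <= 0.0)
    assert series.delta_d.shape == (3,)


def test_order_parameters_match_direct_counting(toy):
    """Two-frame trajectory with known formed-contact lists equals direct
    per-contact counting."""
    frames = np.stack([toy.start, toy.target])
    traj = Trajectory(frames=frames, times=np.array([0.0, 2.0]),
                      potential_energy=np.zeros(2), kinetic_energy=np.zeros(2),
                      termination="max_steps")
    series = order_parameters(traj, toy.defs)
    lam = toy.defs.formed_factor
    for k, frame in enumerate(frames):
        for (idx, r0), got in (
            (toy.defs.id_contacts, series.q_id[k]),
            (toy.defs.kow_alpha_contacts, series.q_kow_alpha[k]),
            (toy.defs.kow_beta_contacts, series.q_kow_beta[k]),
        ):
            formed = sum(
                np.linalg.norm(frame[j] - frame[i]) < lam * r
                for (i, j), r in zip(idx, r0))
            assert got == pytest.approx(formed / len(idx))


def test_order_parameters_topology_mismatch_raises(toy):
    small = _frozen_traj(toy.start[:5])
    with pytest.raises(ValueError, match="topology"):
        order_parameters(small, toy.defs)


def test_landscape_single_frame_single_bin(toy):
    series = order_parameters(_frozen_traj(toy.start, n_frames=1), toy.defs)
    counts, _, _ = landscape_histogram([series], "q_kow_alpha", "q_kow_beta",
                                       bins=20)
    assert counts.sum() == 1
    assert (counts == 1).sum() == 1


def test_landscape_conserves_frames(refolding_batch):
    series = refolding_batch["series"]
    total = sum(len(s.times) for s in series)
    counts, _, _ = landscape_histogram(series, "q_kow_alpha", "q_kow_beta",
                                       bins=40)
    assert counts.sum() == total
    # the delta_d axis is available for the dissociated (Q_ID = 0) frames
    counts2, _, _ = landscape_histogram(series, "delta_d", "q_diff", bins=40)
    assert counts2.sum() == total


def test_landscape_invariant_to_concatenation_order(refolding_batch):
    series = refolding_batch["series"]
    a, _, _ = landscape_histogram(series, "q_id", "q_diff", bins=30)
    b, _, _ = landscape_histogram(series[::-1], "q_id", "q_diff", bins=30)
    np.testing.assert_array_equal(a, b)


def test_landscape_empty_input_raises():
    with pytest.raises(ValueError):
        landscape_histogram([], "q_id", "q_diff")


def test_symmetric_toy_occupancy_balanced(sym_toy):
    """On the mirror-symmetric two-basin system at its hopping temperature,
    occupancies of the Q_diff > 0 and Q_diff < 0 regions agree within three
    standard errors over seeds (half the replicas start in each basin)."""
    from dualsbm.landscape import contact_formed_matrix

    merged = sym_toy["merged"]
    ia, ra = sym_toy["dock_a"]
    ib, rb = sym_toy["dock_b"]
    occ = []
    for seed in range(20):
        start = (sym_toy["model_a"] if seed % 2 == 0
                 else sym_toy["model_b"]).coords / 10.0
        params = SimulationParams(temperature=0.6, max_steps=150_000,
                                  sample_stride=500, stop_rmsd=None,
                                  seed=seed)
        traj = run_langevin(merged, start, params)
        qd = (contact_formed_matrix(traj.frames, ib, rb).mean(axis=1)
              - contact_formed_matrix(traj.frames, ia, ra).mean(axis=1))
        pos, neg = int((qd > 0).sum()), int((qd < 0).sum())
        occ.append(pos / max(pos + neg, 1))
    occ = np.array(occ)
    sem = occ.std(ddof=1) / np.sqrt(len(occ))
    assert abs(occ.mean() - 0.5) < 3 * sem


def test_contact_probability_alpha_window_is_one(toy):
    """A state window holding only alpha-native frames gives probability 1
    for every alpha-layer residue pair (and everything stays in [0, 1])."""
    traj = _frozen_traj(toy.start, n_frames=4)
    series = order_parameters(traj, toy.defs)
    window = StateWindow("KOWalpha", "q_kow_alpha", "q_kow_beta",
                         (0.9, 1.0), (0.0, 1.0))
    residue_of_atom = toy.model_a.residue_number.copy()
    layers = {"KOWalpha": toy.defs.kow_alpha_contacts,
              "ID": toy.defs.id_contacts}
    maps = contact_probability_map([traj], [series], window, layers,
                                   residue_of_atom)
    assert np.all(maps["KOWalpha"]["p"].to_numpy() == 1.0)
    for df in maps.values():
        assert df["p"].between(0, 1).all()


def test_contact_probability_empty_window_raises(toy):
    traj = _frozen_traj(toy.start, n_frames=2)
    series = order_parameters(traj, toy.defs)
    window = StateWindow("I9", "q_kow_alpha", "q_kow_beta",
                         (-1.0, -0.5), (0.0, 1.0))
    with pytest.raises(ValueError, match="I9"):
        contact_probability_map([traj], [series], window,
                                {"ID": toy.defs.id_contacts},
                                toy.model_a.residue_number)


def _monotone_series(values, times=None):
    values = np.asarray(values, dtype=float)
    n = len(values)
    if times is None:
        times = 2.0 * np.arange(n)
    ones = np.ones(n)
    return OrderParameterSeries(times=np.asarray(times, float), q_id=values,
                                q_kow_alpha=ones, q_kow_beta=ones,
                                delta_d=np.zeros(n))


def test_detect_events_threshold_crossing_at_kth_frame():
    """A monotone Q_ID series crossing the dissociation threshold at frame k
    yields exactly one event at the k-th sampled time."""
    series = _monotone_series([1.0, 0.8, 0.6, 0.25, 0.1])
    events = detect_events(series)
    assert [e.kind for e in events] == ["dissociation"]
    assert events[0].frame == 3
    assert events[0].time == 6.0


def test_detect_events_never_crossing_yields_none():
    series = _monotone_series([1.0, 0.9, 0.8])
    assert detect_events(series) == []


def test_detect_events_association_and_strand_formation(toy):
    series = order_parameters(_frozen_traj(toy.target, 3), toy.defs)
    beta = {"hairpin": toy.defs.kow_beta_contacts}
    frames = np.repeat(toy.target[None], 3, axis=0)
    assoc = np.array([0.1, 0.5, 0.9])
    events = detect_events(series, strand_contacts=beta, frames=frames,
                           association_series=assoc)
    kinds = {e.kind: e for e in events}
    assert "dissociation" in kinds        # beta state has Q_ID = 0
    assert kinds["formation:hairpin"].frame == 0
    assert kinds["association"].frame == 2


def test_detect_events_bad_threshold_raises():
    series = _monotone_series([1.0, 0.5])
    with pytest.raises(ValueError):
        detect_events(series, dissociation_threshold=0.0)


def test_first_passage_histogram_conserves_counts():
    rng = np.random.default_rng(0)
    times = rng.uniform(0, 100, size=37)
    events = [Event("formation:x", t, k) for k, t in enumerate(times)]
    counts, edges = first_passage_histogram(events, bins=np.linspace(0, 80, 9))
    assert counts.sum() == len(events)   # out-of-range events still counted
    counts2, _ = first_passage_histogram([events[0]] * 3,
                                         bins=np.linspace(0, 100, 5))
    assert counts2.sum() == 3 and counts2.max() == 3


def test_first_passage_histogram_empty_events():
    counts, _ = first_passage_histogram([], bins=np.linspace(0, 10, 6))
    assert counts.sum() == 0


def test_refolding_traverses_q_diff_and_dissociates_first(refolding_batch):
    """Runs seeded in the alpha basin that complete the switch traverse
    Q_diff from <= -0.5 to >= +0.5, and interface breakage at the
    dissociation threshold precedes fold completion in >= 90% of
    transitions (fold completion marked by Q_diff >= 0.5: at bead
    resolution Q_KOWbeta alone also reads out a compact bent-helix
    intermediate; see the methods note)."""
    series = refolding_batch["series"]
    n_switch = 0
    n_ordered = 0
    for s in series:
        reach = np.flatnonzero(s.q_diff >= 0.5)
        if not len(reach):
            continue
        n_switch += 1
        assert s.q_diff.min() <= -0.5
        k_dis = np.flatnonzero(s.q_id <= 0.30)
        if len(k_dis) and k_dis[0] <= reach[0]:
            n_ordered += 1
    assert n_switch >= 10   # switching temperature: most replicas convert
    assert n_ordered / n_switch >= 0.9
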