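"""Kinetic network assembly: counting, rates, free energies, Eyring-inverted
barriers, and the PATHSAMPLE-dialect database files."""

import numpy as np
import pytest

from dridscape.clustering import StateTrajectory
from dridscape.constants import log_eyring_prefactor
from dridscape.drid import DRIDTrajectory
from dridscape.clustering import regular_space_cluster
from dridscape.network import (TransitionCounts, barrier, build_network,
                               count_transitions, estimate_rates,
                               free_energies, project_reference_states,
                               read_pathsample_db, write_pathsample_db)

from conftest import random_db_network


def st_of(labels, n_states=None, dt=20.0):
    labels = np.asarray(labels)
    return StateTrajectory(labels, n_states or labels.max() + 1, dt)


# ---------------------------------------------------------------------------
# counting & rates
# ---------------------------------------------------------------------------

def test_count_transitions_hand_example():
    tc = count_transitions(st_of([0, 0, 1, 1, 0]))
    assert tc.counts[0, 1] == 1 and tc.counts[1, 0] == 1
    assert list(tc.occupancy) == [3, 2]
    assert tc.counts.sum() == 2


def test_constant_labels_count_nothing():
    tc = count_transitions(st_of([2, 2, 2], n_states=3))
    assert tc.counts.sum() == 0


def test_no_counting_across_trajectory_boundaries():
    tc = count_transitions([st_of([0, 1], 2), st_of([1, 0], 2)])
    assert tc.counts[0, 1] == 1 and tc.counts[1, 0] == 1
    assert tc.counts.sum() == 2  # the boundary pair (1 -> 1 -> 0 join) is not counted


def test_rate_estimator_and_scaling():
    counts = np.array([[0, 5], [0, 0]])
    tc = TransitionCounts(counts, np.array([100, 50]), 20.0)
    k = estimate_rates(tc)
    assert k[0, 1] == pytest.approx(0.0025)
    assert k[1, 0] == 0.0
    tc2 = TransitionCounts(counts, np.array([100, 50]), 40.0)
    assert estimate_rates(tc2)[0, 1] == pytest.approx(0.00125)


def test_counts_recoverable_from_rates():
    rng = np.random.default_rng(7)
    occ = rng.integers(50, 500, 4)
    counts = rng.integers(0, 40, (4, 4))
    np.fill_diagonal(counts, 0)
    tc = TransitionCounts(counts, occ, 20.0)
    k = estimate_rates(tc)
    assert np.allclose(k * occ[:, None] * 20.0, counts)


# ---------------------------------------------------------------------------
# free energies & barriers
# ---------------------------------------------------------------------------

def test_free_energies_hand_example():
    tc = TransitionCounts(np.zeros((3, 3), int), np.array([600, 300, 100]), 20.0)
    f = free_energies(tc)
    assert np.allclose(f, [0.0, np.log(2.0), np.log(6.0)], atol=1e-12)


def test_free_energies_degenerate_cases():
    single = TransitionCounts(np.zeros((1, 1), int), np.array([10]), 20.0)
    assert free_energies(single) == pytest.approx(0.0)
    equal = TransitionCounts(np.zeros((2, 2), int), np.array([5, 5]), 20.0)
    assert np.allclose(free_energies(equal), 0.0)


def test_barrier_hand_value_at_310K():
    """p = (2/3, 1/3), k = (0.01, 0.02) ps^-1: both one-sided barriers and
    their average equal ~6.876 k_B T with ln(kBT/h * 1 ps) ~ 1.8655."""
    assert log_eyring_prefactor(310.0) == pytest.approx(1.8655, abs=2e-4)
    f_hat = barrier(-np.log(2 / 3), -np.log(1 / 3), 0.01, 0.02, 310.0)
    assert f_hat == pytest.approx(6.876, abs=2e-3)


def test_barrier_rejects_nonpositive_rates():
    with pytest.raises(ValueError, match="positive"):
        barrier(0.0, 1.0, 0.0, 0.1, 310.0)


def test_barrier_symmetry_and_anchoring_invariance():
    """Under detailed balance the one-sided values agree to 1e-10, and the
    averaged barrier is identical whether the one-sided formula anchors on
    the reactant or on the product state."""
    rng = np.random.default_rng(42)
    c = log_eyring_prefactor(310.0)
    for _ in range(50):
        f_j, f_k = rng.uniform(0, 4, 2)
        f_hat_true = max(f_j, f_k) + rng.uniform(0.5, 4)
        k_jk = np.exp(c - (f_hat_true - f_j))
        k_kj = np.exp(c - (f_hat_true - f_k))
        one_sided_fwd = f_j - np.log(k_jk) + c
        one_sided_bwd = f_k - np.log(k_kj) + c
        assert one_sided_fwd == pytest.approx(one_sided_bwd, abs=1e-10)
        avg_reactant = barrier(f_j, f_k, k_jk, k_kj, 310.0)
        avg_product = 0.5 * ((f_k - np.log(k_jk) + c) + (f_j - np.log(k_kj) + c))
        assert avg_reactant == pytest.approx(avg_product, abs=1e-12)
        assert avg_reactant == pytest.approx(f_hat_true, abs=1e-10)


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

def test_build_network_three_state_chain():
    labels = np.array([0, 0, 1, 1, 2, 1, 0, 1, 2, 2, 1, 0] * 20)
    net, stats = build_network(st_of(labels), 310.0)
    assert net.n_states == 3
    assert set(net.barriers) == {(0, 1), (1, 2)}       # 0<->2 never observed
    assert stats.probability.sum() == pytest.approx(1.0)
    out = stats.branching.sum(axis=1)
    assert np.allclose(out[out > 0], 1.0)
    for (j, k), fh in net.barriers.items():
        assert fh == net.barriers[(j, k)]  # stored undirected once


def test_single_state_trajectory():
    net, _ = build_network(st_of([0, 0, 0], n_states=1), 310.0)
    assert net.n_states == 1
    assert net.barriers == {}
    assert net.free_energy[0] == 0.0


def test_one_directional_pair_completed_by_detailed_balance():
    labels = np.array([0] * 10 + [1] * 10)  # single 0->1 transition, none back
    net, _ = build_network(st_of(labels), 310.0)
    assert (0, 1) in net.completed_pairs
    p = net.probability
    assert net.rates[1, 0] == pytest.approx(net.rates[0, 1] * p[0] / p[1])
    strict_net, _ = build_network(st_of(labels), 310.0, strict=True)
    assert strict_net.barriers == {}


def test_network_restricted_to_largest_component():
    # two blocks: {0,1} exchanging (many frames), {2,3} exchanging (few)
    labels = np.array([0, 1] * 30 + [2, 3] * 5)
    st = StateTrajectory(np.array(labels), 4, 20.0)
    # break the join between the blocks: treat as two trajectories
    net, _ = build_network([StateTrajectory(labels[:60], 4, 20.0),
                            StateTrajectory(labels[60:], 4, 20.0)], 310.0)
    assert net.n_states == 2
    assert list(net.original_ids) == [0, 1]


# ---------------------------------------------------------------------------
# PATHSAMPLE dialect
# ---------------------------------------------------------------------------

def test_pathsample_roundtrip(tmp_path):
    net = random_db_network(5, seed=3)
    write_pathsample_db(net, tmp_path)
    lines = (tmp_path / "min.data").read_text().splitlines()
    assert len(lines) == 5
    back = read_pathsample_db(tmp_path, net.temperature)
    assert np.array_equal(back.free_energy, net.free_energy)  # %.17g round-trips
    assert set(back.barriers) == set(net.barriers)
    for pair, fh in net.barriers.items():
        assert back.barriers[pair] == fh
    # Eyring reconstruction inverts the barrier computation exactly under DB
    assert np.allclose(back.rates, net.rates, rtol=1e-12)


def test_ts_data_ids_are_one_based(tmp_path):
    net = random_db_network(4, seed=11)
    write_pathsample_db(net, tmp_path)
    for line in (tmp_path / "ts.data").read_text().splitlines():
        parts = line.split()
        j, k = int(parts[3]), int(parts[4])
        assert 1 <= j <= 4 and 1 <= k <= 4
        assert (j - 1, k - 1) in net.barriers or (k - 1, j - 1) in net.barriers


def test_malformed_line_reports_line_number(tmp_path):
    net = random_db_network(3, seed=1)
    write_pathsample_db(net, tmp_path)
    bad = (tmp_path / "min.data").read_text().splitlines()
    bad[1] = "not-a-number 1 1 1 1 1"
    (tmp_path / "min.data").write_text("\n".join(bad) + "\n")
    with pytest.raises(ValueError, match="line 2"):
        read_pathsample_db(tmp_path)


# ---------------------------------------------------------------------------
# reference-state projection
# ---------------------------------------------------------------------------

def test_project_reference_states(rng):
    centers = np.eye(3, 6) * 0.4
    labels = rng.integers(0, 3, 600)
    fp = centers[labels] + rng.normal(0, 0.002, (600, 6))
    drid = DRIDTrajectory(fp, 20.0)
    model = regular_space_cluster(drid, cutoff=0.05)
    assert model.n_states == 3
    # a center fingerprint projects onto its own state
    ids = project_reference_states(model.centers, model)
    assert list(ids) == list(range(3))
    # a jittered copy within the cutoff keeps the id
    noisy = model.centers[1] + rng.normal(0, 0.002, 6)
    assert project_reference_states(noisy[None], model)[0] == 1
    # incompatible m is rejected
    with pytest.raises(ValueError, match="centroid count"):
        project_reference_states(np.zeros((1, 9)), model)
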