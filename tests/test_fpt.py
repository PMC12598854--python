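"""First-passage-time kinetics: operator assembly, spectral solution against
analytic and ODE oracles, log-time densities and endpoint-file plumbing."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from dridscape.fpt import (EndpointSets, FPTDistribution,
                           build_master_operator, default_y_grid,
                           fpt_distribution, log_time_density, mfpt,
                           peak_times, read_min_file, run_endpoint_analysis,
                           write_min_file)
from dridscape.network import KineticNetwork

from conftest import random_db_network


def simple_net(rates):
    rates = np.asarray(rates, dtype=float)
    n = rates.shape[0]
    return KineticNetwork(free_energy=np.zeros(n), rates=rates, barriers={},
                          temperature=310.0, probability=np.full(n, 1.0 / n))


def chain_net():
    # b(0) -> i(1) -> a(2), rates 0.1 and 0.2 ps^-1
    return simple_net([[0, 0.1, 0], [0, 0, 0.2], [0, 0, 0]])


# ---------------------------------------------------------------------------
# operator assembly
# ---------------------------------------------------------------------------

def test_two_state_operator():
    net = simple_net([[0, 0.1], [0, 0]])
    op = build_master_operator(net, EndpointSets(frozenset({1}), frozenset({0})))
    assert op.matrix.shape == (1, 1)
    assert op.matrix[0, 0] == pytest.approx(-0.1)


def test_chain_operator_blocks():
    op = build_master_operator(chain_net(),
                               EndpointSets(frozenset({2}), frozenset({0})))
    assert sorted(np.diag(op.matrix)) == pytest.approx([-0.2, -0.1])
    i_row = list(op.states).index(1)
    b_col = list(op.states).index(0)
    assert op.matrix[i_row, b_col] == pytest.approx(0.1)  # flux b -> i


def test_unreachable_target_is_an_error():
    net = simple_net([[0, 0.1, 0], [0.1, 0, 0], [0, 0, 0]])  # 2 disconnected
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        build_master_operator(net, EndpointSets(frozenset({2}), frozenset({0})))


def test_endpoint_sets_validate():
    with pytest.raises(ValueError, match="overlap"):
        EndpointSets(frozenset({1}), frozenset({1}))
    with pytest.raises(ValueError, match="non-empty"):
        EndpointSets(frozenset(), frozenset({1}))


# ---------------------------------------------------------------------------
# spectral solution vs analytic results
# ---------------------------------------------------------------------------

def test_two_state_exponential():
    net = simple_net([[0, 0.1], [0, 0]])
    d = fpt_distribution(build_master_operator(
        net, EndpointSets(frozenset({1}), frozenset({0}))))
    assert d.eigenvalues == pytest.approx([0.1])
    assert d.amplitudes == pytest.approx([1.0])
    t = np.linspace(0, 50, 11)
    assert np.allclose(d.pdf(t), 0.1 * np.exp(-0.1 * t), atol=1e-12)
    assert mfpt(d) == pytest.approx(10.0)


def test_chain_modes_and_mfpt():
    """Sequential 0.1, 0.2 ps^-1 chain: modes {0.1, 0.2} with amplitudes
    {2, -1}; MFPT = 1/0.1 + 1/0.2 = 15 ps."""
    d = fpt_distribution(build_master_operator(
        chain_net(), EndpointSets(frozenset({2}), frozenset({0}))))
    assert d.eigenvalues == pytest.approx([0.1, 0.2])
    assert d.amplitudes == pytest.approx([2.0, -1.0])
    assert mfpt(d) == pytest.approx(15.0, abs=1e-10)


def test_mfpt_matches_linear_solve_oracle():
    """sum_l A_l / nu_l equals 1^T (-M)^-1 p0 on random DB networks."""
    for seed in range(10):
        net = random_db_network(6, seed=seed, extra_edges=2)
        ep = EndpointSets(frozenset({0}), frozenset({net.n_states - 1}))
        op = build_master_operator(net, ep)
        d = fpt_distribution(op)
        p0 = np.zeros(op.n)
        p0[list(op.states).index(net.n_states - 1)] = 1.0
        d1 = fpt_distribution(op, net.n_states - 1)
        oracle = float(np.ones(op.n) @ np.linalg.solve(-op.matrix, p0))
        assert mfpt(d1) == pytest.approx(oracle, rel=1e-10)
        assert np.sum(d.amplitudes) == pytest.approx(1.0, abs=1e-8)
        assert mfpt(d) >= 1.0 / d.eigenvalues.max() - 1e-12


def test_spectral_pdf_matches_ode_integration():
    """p(t) from the eigen-expansion equals direct integration of the
    master equation (flux into the absorbing set) to 1e-8."""
    for seed in range(8):
        net = random_db_network(6, seed=100 + seed, extra_edges=2,
                                barrier_offset=(0.5, 2.0))
        ep = EndpointSets(frozenset({0}), frozenset({net.n_states - 1}))
        op = build_master_operator(net, ep)
        d = fpt_distribution(op, "local_equilibrium")
        p0 = np.zeros(op.n)
        mask = np.array([s in ep.B for s in op.states])
        p0[mask] = op.eq_weights[mask] / op.eq_weights[mask].sum()
        flux_out = -op.matrix.sum(axis=0)  # per-state rate into A
        t_grid = np.geomspace(0.05 / d.eigenvalues.max(),
                              3.0 / d.eigenvalues.min(), 20)
        sol = solve_ivp(lambda t, p: op.matrix @ p, (0, t_grid[-1]), p0,
                        t_eval=t_grid, method="LSODA", rtol=1e-11, atol=1e-14,
                        jac=lambda t, p: op.matrix)
        p_ode = flux_out @ sol.y
        assert np.allclose(d.pdf(t_grid), p_ode, atol=1e-8)


def test_detailed_balance_solver_path_is_symmetric():
    net = random_db_network(7, seed=5, extra_edges=3)
    op = build_master_operator(net, EndpointSets(frozenset({0}), frozenset({6})))
    assert op.detailed_balance
    sqrt_pi = np.sqrt(op.eq_weights)
    sym = -op.matrix * (sqrt_pi[None, :] / sqrt_pi[:, None])
    assert np.abs(sym - sym.T).max() < 1e-10
    nu = np.linalg.eigvals(-op.matrix)
    assert np.abs(nu.imag).max() < 1e-10


# ---------------------------------------------------------------------------
# log-time density and peaks
# ---------------------------------------------------------------------------

def test_single_mode_log_density_peak_and_norm():
    d = FPTDistribution(np.array([0.1]), np.array([1.0]))
    # the left tail of P(y) decays like e^y, so a 1e-6 normalization check
    # needs a margin beyond ln(1e6) ~ 14 around -ln(nu)
    y = default_y_grid(d, margin=16.0, n=8001)
    p = log_time_density(d, y)
    assert np.trapezoid(p, y) == pytest.approx(1.0, abs=1e-6)
    peaks = peak_times(d)
    assert len(peaks) == 1
    y_star, p_star = peaks[0]
    assert y_star == pytest.approx(-np.log(0.1), abs=1e-9)
    assert p_star == pytest.approx(np.exp(-1.0), abs=1e-9)


def test_two_separated_modes_two_peaks_merged_modes_one():
    separated = FPTDistribution(np.array([1e-4, 1.0]), np.array([0.5, 0.5]))
    assert len(peak_times(separated)) == 2
    merged = FPTDistribution(np.array([0.5, 1.0]), np.array([0.5, 0.5]))
    assert len(peak_times(merged)) == 1


def test_log_density_normalizes_on_multimode(rng):
    net = random_db_network(5, seed=9)
    d = fpt_distribution(build_master_operator(
        net, EndpointSets(frozenset({0}), frozenset({4}))))
    y = default_y_grid(d, margin=16.0, n=16001)
    assert np.trapezoid(log_time_density(d, y), y) == pytest.approx(1.0, abs=1e-6)


# ---------------------------------------------------------------------------
# endpoint files and the PATHSAMPLE-style driver
# ---------------------------------------------------------------------------

def test_min_file_roundtrip_and_errors(tmp_path):
    p = tmp_path / "min.A"
    write_min_file([0, 4], p)
    assert p.read_text().splitlines()[0] == "2"
    assert read_min_file(p) == [0, 4]
    p.write_text("2\n1\n99\n")
    with pytest.raises(ValueError, match="line 3"):
        read_min_file(p, n_states=5)
    p.write_text("3\n1\n2\n")
    with pytest.raises(ValueError, match="header says 3"):
        read_min_file(p)


def test_run_endpoint_analysis(tmp_path):
    net = random_db_network(5, seed=21, extra_edges=2)
    write_min_file([0], tmp_path / "min.A")
    write_min_file([4], tmp_path / "min.B")
    res = run_endpoint_analysis(net, tmp_path / "min.A", tmp_path / "min.B",
                                tmp_path, waitpdfprint=True)
    for name in ("waitlnpdfAB", "waitlnpdfBA"):
        data = np.loadtxt(tmp_path / name)
        assert np.trapezoid(data[:, 1], data[:, 0]) == pytest.approx(1.0, abs=1e-4)
    # one per-start-state file per non-target minimum
    assert sorted(p.name for p in tmp_path.glob("waitlnpdfA.*")) == \
        [f"waitlnpdfA.{i}" for i in (2, 3, 4, 5)]
    assert sorted(p.name for p in tmp_path.glob("peaksB.*")) == \
        [f"peaksB.{i}" for i in (1, 2, 3, 4)]
    # exponentiating the peak ordinate gives the time scale in ps
    peaks = np.loadtxt(tmp_path / "peaksA.5", ndmin=2)
    assert np.allclose(np.exp(peaks[:, 0]), peaks[:, 2], rtol=1e-8)
    assert res["AB"]["mfpt_ps"] > 0 and res["BA"]["mfpt_ps"] > 0
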