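"""Sequential POVM probabilities, collapse, schedules and interference."""

from itertools import product as iter_product

import numpy as np
import pytest

import hsmodels as h
from hsmodels.errors import (
    ImpossibleOutcomeError,
    IncompletePartitionError,
    UnresolvedObservableError,
    UnsupportedStructureError,
)
from .conftest import random_state, random_unitary


@pytest.fixture
def setup(small_grid, rng):
    ux, uy = random_unitary(small_grid, rng), random_unitary(small_grid, rng)
    observables = {
        "X": h.ObservableSpec("X", ux),
        "Y": h.ObservableSpec("Y", uy),
        "C": h.ObservableSpec("C"),  # identity basis
    }
    psi = random_state(small_grid, rng)
    bins = h.BinScheme.equal_width(small_grid, 2)
    return small_grid, observables, psi, bins


def test_cdf_projector_properties(setup):
    grid, obs, psi, _ = setup
    p = h.observable_cdf_projector(obs["X"], 0.5, grid)
    m = p.entries
    assert np.max(np.abs(m @ m - m)) < 1e-10
    assert np.max(np.abs(m - m.conj().T)) < 1e-10
    # identity basis reduces to the plain interval projector
    pc = h.observable_cdf_projector(obs["C"], 0.5, grid)
    assert np.allclose(pc.entries, h.interval_projector(grid, 0.5).entries)
    # full interval -> identity for any unitary
    pu = h.observable_cdf_projector(obs["X"], grid.upper, grid)
    assert np.allclose(pu.entries, np.eye(grid.n_cells), atol=1e-12)


def test_sequential_operator_order_dependence(setup):
    grid, obs, _, bins = setup
    q_xy = h.sequential_operator(h.Context(("X", "Y")), obs, [(bins, 0), (bins, 1)], grid)
    q_yx = h.sequential_operator(h.Context(("Y", "X")), obs, [(bins, 1), (bins, 0)], grid)
    assert np.max(np.abs(q_xy.entries - q_yx.entries)) > 1e-6
    # one shared basis: the product is itself a projector
    shared = {"X": obs["X"], "Y": h.ObservableSpec("Y", obs["X"].basis_unitary)}
    q = h.sequential_operator(h.Context(("X", "Y")), shared, [(bins, 0), (bins, 1)], grid).entries
    assert np.max(np.abs(q @ q - q)) < 1e-10
    with pytest.raises(UnresolvedObservableError):
        h.sequential_operator(h.Context(("X", "W")), obs, [(bins, 0), (bins, 0)], grid)


def test_sequential_distribution_matches_dense_trace_oracle(setup):
    grid, obs, psi, bins = setup
    ctx = h.Context(("X", "Y"))
    dist = h.sequential_distribution(psi, ctx, obs, [bins, bins])
    assert dist.total == pytest.approx(1.0, abs=1e-8)
    rho = np.outer(psi.amplitudes, psi.amplitudes.conj()) * grid.spacing
    for i, j in iter_product(range(2), range(2)):
        q = h.sequential_operator(ctx, obs, [(bins, i), (bins, j)], grid).entries
        oracle = np.trace(q @ rho @ q.conj().T).real
        assert dist.probabilities[i, j] == pytest.approx(oracle, abs=1e-12)


def test_shared_basis_contexts_are_order_free(setup):
    grid, obs, psi, bins = setup
    shared = {"X": obs["X"], "Y": h.ObservableSpec("Y", obs["X"].basis_unitary)}
    d_xy = h.sequential_distribution(psi, h.Context(("X", "Y")), shared, [bins, bins])
    d_yx = h.sequential_distribution(psi, h.Context(("Y", "X")), shared, [bins, bins])
    assert np.max(np.abs(d_xy.probabilities - d_yx.probabilities.T)) < 1e-10


def test_distinct_bases_produce_order_effects(setup):
    grid, obs, psi, bins = setup
    d_xy = h.sequential_distribution(psi, h.Context(("X", "Y")), obs, [bins, bins])
    d_yx = h.sequential_distribution(psi, h.Context(("Y", "X")), obs, [bins, bins])
    assert np.max(np.abs(d_xy.probabilities - d_yx.probabilities.T)) > 1e-6


def test_single_step_distribution_is_rotated_magnitudes(setup):
    grid, obs, psi, _ = setup
    bins = h.BinScheme.equal_width(grid, 4)
    dist = h.sequential_distribution(psi, h.Context(("X",)), obs, [bins])
    u = obs["X"].basis_unitary.entries
    rotated = np.abs(u.conj().T @ psi.amplitudes) ** 2 * grid.spacing
    oracle = rotated.reshape(4, -1).sum(axis=1)
    assert np.allclose(dist.probabilities, oracle, atol=1e-12)


def test_incomplete_partition_refused(setup):
    grid, obs, psi, _ = setup
    partial = h.BinScheme((0.0, 0.5))  # does not reach the upper bound
    with pytest.raises(IncompletePartitionError):
        h.sequential_distribution(psi, h.Context(("X",)), obs, [partial])


def test_collapse_chain_rule_and_idempotence(setup):
    grid, obs, psi, bins = setup
    p_i = h.observable_cdf_projector(obs["C"], 0.5, grid)
    ident = h.OperatorMatrix(grid, np.eye(grid.n_cells), "projector")
    assert np.allclose(h.collapse(psi, ident).amplitudes, psi.amplitudes)
    once = h.collapse(psi, p_i)
    twice = h.collapse(once, p_i)
    assert np.allclose(once.amplitudes, twice.amplitudes, atol=1e-12)
    # chain rule: P(i then j) = P(i) * P(j | collapse on i)
    ctx = h.Context(("C", "Y"))
    dist = h.sequential_distribution(psi, ctx, obs, [bins, bins])
    masks = bins.bin_masks(grid)
    for i in range(2):
        pi_op = h.OperatorMatrix(grid, np.diag(masks[i].astype(complex)), "projector")
        p_first = h.event_probability(pi_op, psi)
        collapsed = h.collapse(psi, pi_op)
        after = h.sequential_distribution(collapsed, h.Context(("Y",)), obs, [bins])
        for j in range(2):
            assert dist.probabilities[i, j] == pytest.approx(
                p_first * after.probabilities[j], abs=1e-10
            )
    zero = h.OperatorMatrix(grid, np.zeros((grid.n_cells,) * 2))
    with pytest.raises(ImpossibleOutcomeError):
        h.collapse(psi, zero)


def test_run_schedule_matches_path_enumeration_oracle(setup, rng):
    grid, obs, psi, bins = setup
    ham = h.hamiltonian(grid, h.HamiltonianParams(0.02))
    sched = h.MeasurementSchedule(
        (
            h.EvolveEvent(0.3),
            h.MeasureEvent("X", bins),
            h.EvolveEvent(0.4),
            h.MeasureEvent("C", bins),
        )
    )
    joint = h.run_schedule(psi, sched, ham, obs)
    assert joint.total == pytest.approx(1.0, abs=1e-8)
    # oracle: exhaustive paths via explicit matrices
    u1 = h.evolution_unitary(ham, 0.3).entries
    u2 = h.evolution_unitary(ham, 0.4).entries
    masks = bins.bin_masks(grid)
    ux = obs["X"].basis_unitary.entries
    for i, j in iter_product(range(2), range(2)):
        px = ux @ np.diag(masks[i].astype(complex)) @ ux.conj().T
        pc = np.diag(masks[j].astype(complex))
        vec = pc @ (u2 @ (px @ (u1 @ psi.amplitudes)))
        oracle = grid.spacing * np.sum(np.abs(vec) ** 2)
        assert joint.probabilities[i, j] == pytest.approx(oracle, abs=1e-10)


def test_zero_duration_schedule_equals_sequential_distribution(setup):
    grid, obs, psi, bins = setup
    ham = h.hamiltonian(grid, h.HamiltonianParams(1.0))
    sched = h.MeasurementSchedule(
        (
            h.EvolveEvent(0.0),
            h.MeasureEvent("X", bins),
            h.MeasureEvent("Y", bins),
        )
    )
    joint = h.run_schedule(psi, sched, ham, obs)
    direct = h.sequential_distribution(psi, h.Context(("X", "Y")), obs, [bins, bins])
    assert np.allclose(joint.probabilities, direct.probabilities, atol=1e-12)


def test_interference_zero_for_identity_first_measurement():
    g = h.make_grid(0, 100, 64)
    psi0 = h.uniform_state(g, 30, 70)
    ham = h.hamiltonian(g, h.HamiltonianParams(50.0))
    one_bin = h.BinScheme((0.0, 100.0))
    res = h.interference_effect(
        psi0, ham, 0.5, 1.0, h.ObservableSpec("C"), h.BinScheme.equal_width(g, 5), one_bin
    )
    assert res.total_variation < 1e-10


def test_interference_zero_for_commuting_dynamics():
    g = h.make_grid(0, 100, 64)
    psi0 = h.uniform_state(g, 30, 70)
    diag_h = h.OperatorMatrix(g, np.diag(g.midpoints).astype(complex), "hermitian")
    res = h.interference_effect(
        psi0, diag_h, 0.5, 1.0, h.ObservableSpec("C"),
        h.BinScheme.equal_width(g, 5), h.BinScheme.equal_width(g, 2),
    )
    assert res.total_variation < 1e-10


def test_interference_positive_for_generic_dynamics():
    g = h.make_grid(0, 100, 64)
    psi0 = h.uniform_state(g, 30, 70)
    ham = h.hamiltonian(g, h.HamiltonianParams(50.0))
    res = h.interference_effect(
        psi0, ham, 0.5, 1.0, h.ObservableSpec("C"),
        h.BinScheme.equal_width(g, 5), h.BinScheme.equal_width(g, 2),
    )
    assert res.total_variation > 1e-3
    assert res.measured_marginal.sum() == pytest.approx(1.0, abs=1e-8)
    assert np.allclose(res.differences, res.measured_marginal - res.unmeasured_marginal)


class TestTwoFactorSpace:
    @pytest.fixture
    def h2_setup(self, rng):
        g = h.make_grid(0, 1, 6)
        ux, uy, uz = (random_unitary(g, rng) for _ in range(3))
        observables = {
            "X": h.ObservableSpec("X", ux, "left"),
            "Y": h.ObservableSpec("Y", uy, "left"),
            "Z": h.ObservableSpec("Z", uz, "right"),
        }
        left = random_state(g, rng)
        right = random_state(g, rng)
        return g, observables, h.tensor_state(left, right), h.BinScheme.equal_width(g, 3)

    def test_matches_dense_product_space_oracle(self, h2_setup):
        g, obs, ps, bins = h2_setup
        ctx = h.Context(("X", "Y", "Z"), "H2")
        dist = h.h2_sequential_distribution(ps, ctx, obs, [bins] * 3)
        assert dist.total == pytest.approx(1.0, abs=1e-8)
        eye = np.eye(6)
        masks = bins.bin_masks(g)

        def proj(label, j):
            u = obs[label].basis_unitary.entries
            return u @ np.diag(masks[j].astype(complex)) @ u.conj().T

        amp = ps.flatten()
        rho = np.outer(amp, amp.conj()) * g.spacing**2
        for i, j, k in iter_product(range(3), repeat=3):
            q = (
                np.kron(proj("Y", j), eye)
                @ np.kron(proj("X", i), eye)
                @ np.kron(eye, proj("Z", k))
            )
            oracle = np.trace(q @ rho @ q.conj().T).real
            assert dist.probabilities[i, j, k] == pytest.approx(oracle, abs=1e-10)

    def test_commuting_factor_position_is_irrelevant(self, h2_setup):
        g, obs, ps, bins = h2_setup
        d_xyz = h.h2_sequential_distribution(
            ps, h.Context(("X", "Y", "Z"), "H2"), obs, [bins] * 3
        )
        d_zxy = h.h2_sequential_distribution(
            ps, h.Context(("Z", "X", "Y"), "H2"), obs, [bins] * 3
        )
        moved = np.moveaxis(d_zxy.probabilities, 0, 2)
        assert np.max(np.abs(d_xyz.probabilities - moved)) < 1e-10

    def test_factorized_commuting_projector_identity(self, h2_setup):
        # (R_X (x) I) (I (x) R_Z) == (U_X (x) U_Z)(M (x) M)(U_X (x) U_Z)^dagger
        g, obs, ps, bins = h2_setup
        eye = np.eye(6)
        masks = bins.bin_masks(g)
        ux = obs["X"].basis_unitary.entries
        uz = obs["Z"].basis_unitary.entries
        rx = ux @ np.diag(masks[0].astype(complex)) @ ux.conj().T
        rz = uz @ np.diag(masks[1].astype(complex)) @ uz.conj().T
        lhs = np.kron(rx, eye) @ np.kron(eye, rz)
        u_joint = np.kron(ux, uz)
        m_joint = np.kron(np.diag(masks[0].astype(complex)), np.diag(masks[1].astype(complex)))
        rhs = u_joint @ m_joint @ u_joint.conj().T
        assert np.max(np.abs(lhs - rhs)) < 1e-10

    def test_unsupported_structure_rejected(self, h2_setup, rng):
        g, obs, ps, bins = h2_setup
        obs = dict(obs)
        obs["W"] = h.ObservableSpec("W", random_unitary(g, rng), "left")
        with pytest.raises(UnsupportedStructureError):
            h.h2_sequential_distribution(
                ps, h.Context(("X", "Y", "W"), "H2"), obs, [bins] * 3
            )
        with pytest.raises(UnsupportedStructureError):
            h.h2_sequential_distribution(
                ps, h.Context(("X", "Y"), "H"), obs, [bins] * 2
            )
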