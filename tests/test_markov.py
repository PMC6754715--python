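"""Drift-diffusion comparator: generator structure, accuracy, invariance."""

import numpy as np
import pytest

import hsmodels as h
from hsmodels.errors import ImpossibleOutcomeError, InvalidArgumentError
from hsmodels.markov import crank_nicolson_evolve


def _gaussian_masses(grid, center, sd):
    m = np.exp(-((grid.midpoints - center) ** 2) / (2 * sd**2))
    return m / m.sum()


def test_generator_conserves_mass_and_is_symmetric_without_drift(small_grid):
    a0 = h.forward_generator(small_grid, h.MarkovParams(0.0, 1.0)).entries.real
    assert np.allclose(a0, a0.T)
    a1 = h.forward_generator(small_grid, h.MarkovParams(2.0, 1.0)).entries.real
    assert np.max(np.abs(a1.sum(axis=0))) < 1e-12
    # off-diagonal rates non-negative (positivity-preserving upwind scheme)
    assert np.min(a1 - np.diag(np.diag(a1))) >= 0


def test_generator_matches_finite_volume_stencil_oracle():
    g = h.make_grid(0, 1, 8)
    mu, sig = 1.5, 0.8
    a = h.forward_generator(g, h.MarkovParams(mu, sig)).entries.real
    # independently coded stencil: flux J_{i+1/2} = mu*m_i/h - D*(m_{i+1}-m_i)/h^2
    d = 0.5 * sig**2
    hh = g.spacing
    oracle = np.zeros((8, 8))
    for i in range(8):
        for j in range(8):
            e = np.zeros(8)
            e[j] = 1.0
            flux = np.zeros(9)  # faces 0..8; 0 and 8 reflecting
            for f in range(1, 8):
                up = e[f - 1] if mu >= 0 else e[f]
                flux[f] = mu * up / hh - d * (e[f] - e[f - 1]) / hh**2
            oracle[i, j] = flux[i] - flux[i + 1]
    assert np.max(np.abs(a - oracle)) < 1e-12


def test_evolution_identity_at_zero_time(small_grid):
    p0 = h.ProbabilityDensity(small_grid, np.ones(8) / 8)
    pt = h.evolve_density(p0, h.MarkovParams(1.0, 1.0), 0.0)
    assert np.allclose(pt.masses, p0.masses)


def test_evolution_matches_analytic_gaussian_solution():
    g = h.make_grid(0, 60, 512)
    mu, sig, t = 1.0, 0.5, 1.0
    s0, x0 = 3.0, 20.0
    p0 = h.ProbabilityDensity(g, _gaussian_masses(g, x0, s0))
    pt = h.evolve_density(p0, h.MarkovParams(mu, sig), t)
    var_t = s0**2 + sig**2 * t
    exact = np.exp(-((g.midpoints - (x0 + mu * t)) ** 2) / (2 * var_t))
    exact /= np.sqrt(2 * np.pi * var_t)
    assert np.max(np.abs(pt.density - exact)) < 1e-3
    assert pt.total == pytest.approx(1.0, abs=1e-10)
    assert np.min(pt.masses) >= 0


def test_uniform_is_stationary_under_pure_diffusion(small_grid):
    p0 = h.ProbabilityDensity(small_grid, np.ones(8) / 8)
    pt = h.evolve_density(p0, h.MarkovParams(0.0, 1.3), 2.0)
    assert np.max(np.abs(pt.masses - p0.masses)) < 1e-8


def test_crank_nicolson_cross_check():
    g = h.make_grid(0, 10, 64)
    p0 = h.ProbabilityDensity(g, _gaussian_masses(g, 4.0, 0.8))
    params = h.MarkovParams(0.7, 0.9)
    a = h.evolve_density(p0, params, 0.8)
    b = crank_nicolson_evolve(p0, params, 0.8, n_steps=400)
    assert np.max(np.abs(a.masses - b.masses)) < 1e-6


def test_diffusion_convergence_is_second_order():
    # halving the spacing reduces the sup-norm error ~4x (pure diffusion)
    errs = []
    for n in (128, 256):
        g = h.make_grid(0, 60, n)
        p0 = h.ProbabilityDensity(g, _gaussian_masses(g, 30.0, 2.0))
        pt = h.evolve_density(p0, h.MarkovParams(0.0, 1.0), 1.0)
        var_t = 4.0 + 1.0
        exact = np.exp(-((g.midpoints - 30.0) ** 2) / (2 * var_t)) / np.sqrt(
            2 * np.pi * var_t
        )
        errs.append(np.max(np.abs(pt.density - exact)))
    ratio = errs[0] / errs[1]
    assert 2.5 < ratio < 6.0


def test_classical_conditioning(small_grid):
    p = h.ProbabilityDensity(small_grid, np.arange(1.0, 9.0) / 36.0)
    mass, cond = h.classical_condition(p, (small_grid.lower, small_grid.upper))
    assert mass == pytest.approx(1.0)
    assert np.allclose(cond.masses, p.masses)
    mass2, cond2 = h.classical_condition(p, (0.0, 0.5))
    _, cond3 = h.classical_condition(cond2, (0.0, 0.5))
    assert np.allclose(cond2.masses, cond3.masses)
    assert mass2 == pytest.approx(p.masses[:4].sum())
    with pytest.raises(ImpossibleOutcomeError):
        h.classical_condition(cond2, (0.75, 1.0))


def test_law_of_total_probability_under_evolution(small_grid):
    p = h.ProbabilityDensity(small_grid, np.arange(1.0, 9.0) / 36.0)
    params = h.MarkovParams(0.4, 0.8)
    edges = [0.0, 0.25, 0.75, 1.0]
    pooled = np.zeros(8)
    for a, b in zip(edges, edges[1:]):
        mass, cond = h.classical_condition(p, (a, b))
        pooled += mass * h.evolve_density(cond, params, 0.6).masses
    direct = h.evolve_density(p, params, 0.6).masses
    assert np.max(np.abs(pooled - direct)) < 1e-10


def test_markov_schedule_marginal_invariance():
    g = h.make_grid(0, 100, 50)
    p0 = h.ProbabilityDensity(g, _gaussian_masses(g, 50, 10))
    params = h.MarkovParams(8.0, 12.0)
    bins2 = h.BinScheme.equal_width(g, 2)
    bins5 = h.BinScheme.equal_width(g, 5)
    with_meas = h.markov_schedule(
        p0,
        params,
        h.MeasurementSchedule(
            (
                h.EvolveEvent(0.5),
                h.MeasureEvent("choice", bins2),
                h.EvolveEvent(1.0),
                h.MeasureEvent("rating", bins5),
            )
        ),
    )
    without = h.markov_schedule(
        p0,
        params,
        h.MeasurementSchedule((h.EvolveEvent(1.5), h.MeasureEvent("rating", bins5))),
    )
    pooled = with_meas.probabilities.sum(axis=0)
    assert np.max(np.abs(pooled - without.probabilities)) < 1e-10
    assert with_meas.total == pytest.approx(1.0, abs=1e-8)


def test_markov_schedule_matches_two_stage_enumeration_oracle():
    g = h.make_grid(0, 1, 16)
    masses = np.exp(-((g.midpoints - 0.4) ** 2) / 0.02)
    p0 = h.ProbabilityDensity(g, masses / masses.sum())
    params = h.MarkovParams(0.2, 0.3)
    bins = h.BinScheme.equal_width(g, 4)
    sched = h.MeasurementSchedule(
        (
            h.EvolveEvent(0.3),
            h.MeasureEvent("a", bins),
            h.EvolveEvent(0.2),
            h.MeasureEvent("b", bins),
        )
    )
    joint = h.markov_schedule(p0, params, sched)
    edges = bins.snapped(g).edges
    p1 = h.evolve_density(p0, params, 0.3)
    for i in range(4):
        try:
            mass_i, cond = h.classical_condition(p1, (edges[i], edges[i + 1]))
        except ImpossibleOutcomeError:
            assert np.allclose(joint.probabilities[i], 0.0)
            continue
        p2 = h.evolve_density(cond, params, 0.2)
        for j in range(4):
            mass_j, _ = (
                h.classical_condition(p2, (edges[j], edges[j + 1]))
                if p2.masses[bins.bin_masks(g)[j]].sum() > 0
                else (0.0, None)
            )
            assert joint.probabilities[i, j] == pytest.approx(mass_i * mass_j, abs=1e-10)


def test_invalid_params_rejected():
    with pytest.raises(InvalidArgumentError):
        h.MarkovParams(0.0, 0.0)
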