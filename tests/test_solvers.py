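"""Solver behavior: exactness, conservation, accessors, determinism, RK4."""

import numpy as np
import pytest
from scipy import stats

from conftest import decay_chain_moments
from rdvox.engine import NA
from rdvox.geometry import (Tetmesh, WellMixedCompartment, WellMixedGeometry,
                            generate_box_tetmesh)
from rdvox.model import Model, apply_systems
from rdvox.solvers import (TetexactSolver, WmdirectSolver, tetexact_run,
                           wmdirect_run, wmrk4_run)


def decay_bound(k=1.0, volume=1e-18):
    model = Model()
    model.add_species("A")
    model.add_reaction("deg", ["A"], [], k, "vsys")
    geom = WellMixedGeometry()
    geom.add_compartment(WellMixedCompartment("comp", volume, ("vsys",)))
    return apply_systems(model, geom)


def jittered_box_mesh(divisions=3, side=1e-6, amplitude=0.25, seed=0):
    """Box mesh with interior vertices displaced, so tet volumes differ."""
    base = generate_box_tetmesh(side, divisions)
    rng = np.random.default_rng(seed)
    v = base.vertices.copy()
    h = side / divisions
    interior = np.all((v > 1e-12) & (v < side - 1e-12), axis=1)
    v[interior] += rng.uniform(-amplitude * h, amplitude * h,
                               size=(interior.sum(), 3))
    return Tetmesh(v, base.tets)


class TestWmdirect:
    def test_decay_moments_match_master_equation_oracle(self):
        n0, k = 30, 1.0
        bound = decay_bound(k)
        times = [0.4, 1.2]
        reps = 400
        counts = np.empty((reps, len(times)))
        for rep, s in enumerate(np.random.SeedSequence(77).spawn(reps)):
            tr = wmdirect_run(bound, {("comp", "A"): n0}, times, seed=s)
            counts[rep] = tr.counts[:, 0, 0]
        for i, t in enumerate(times):
            mean, sd = decay_chain_moments(n0, k, t)
            se = sd / np.sqrt(reps)
            assert abs(counts[:, i].mean() - mean) < 4 * se
            # sample sd agrees with the master equation sd
            assert counts[:, i].std(ddof=1) == pytest.approx(sd, rel=0.2)

    def test_interevent_times_exponential(self):
        # single first-order channel with the count clamped: the propensity
        # stays k*n, so successive event times are iid Exp(k*n)
        n0, k = 1000, 1.0
        bound = decay_bound(k)
        solver = WmdirectSolver(bound, seed=5)
        solver.set_count("comp", "A", n0)
        solver.set_clamped("comp", "A")
        waits = []
        t_prev = 0.0
        for _ in range(3000):
            solver.core.step()
            waits.append(solver.core.t - t_prev)
            t_prev = solver.core.t
        stat = stats.kstest(waits, "expon", args=(0, 1.0 / (k * n0)))
        assert stat.pvalue > 0.01

    def test_no_reactions_means_constant_state(self):
        model = Model()
        model.add_species("A")
        geom = WellMixedGeometry()
        geom.add_compartment(WellMixedCompartment("comp", 1e-18))
        bound = apply_systems(model, geom)
        tr = wmdirect_run(bound, {("comp", "A"): 42}, [0.0, 5.0, 50.0], seed=1)
        assert (tr.counts[:, 0, 0] == 42).all()

    def test_reproducible_with_same_seed(self):
        bound = decay_bound()
        a = wmdirect_run(bound, {("comp", "A"): 500}, [0.5, 1.0], seed=123)
        b = wmdirect_run(bound, {("comp", "A"): 500}, [0.5, 1.0], seed=123)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_conc_count_round_trip(self):
        bound = decay_bound(volume=1e-18)
        solver = WmdirectSolver(bound, seed=0)
        solver.set_conc("comp", "A", 1e-6)
        n = solver.get_count("comp", "A")
        assert n == int(round(1e-6 * NA * 1e-18 * 1e3))
        assert solver.get_conc("comp", "A") == pytest.approx(1e-6, rel=1e-3)

    def test_clamped_species_drives_but_does_not_change(self):
        model = Model()
        model.add_species("A")
        model.add_species("B")
        model.add_reaction("conv", ["A"], ["A", "B"], 5.0, "vsys")
        geom = WellMixedGeometry()
        geom.add_compartment(WellMixedCompartment("comp", 1e-18, ("vsys",)))
        bound = apply_systems(model, geom)
        solver = WmdirectSolver(bound, seed=9)
        solver.set_count("comp", "A", 10)
        solver.set_clamped("comp", "A")
        solver.run(2.0)
        assert solver.get_count("comp", "A") == 10
        assert solver.get_count("comp", "B") > 0


class TestTetexact:
    def diffusion_bound(self, mesh, D=1e-11):
        model = Model()
        model.add_species("A")
        model.add_diffusion("dA", "A", D, "vsys")
        mesh.add_compartment("cyt", range(mesh.n_tets), ("vsys",))
        return apply_systems(model, mesh)

    def test_pure_diffusion_conserves_total(self):
        mesh = generate_box_tetmesh(1e-6, 3)
        bound = self.diffusion_bound(mesh)
        solver = TetexactSolver(bound, seed=4)
        solver.set_comp_count("cyt", "A", 1234)
        tr = solver.sample([1e-4, 1e-3, 5e-3])
        assert (tr.species_total("A") == 1234).all()

    def test_long_run_occupancy_proportional_to_volume(self):
        mesh = jittered_box_mesh(divisions=2, seed=3)
        bound = self.diffusion_bound(mesh, D=1e-10)
        solver = TetexactSolver(bound, seed=8)
        solver.set_tet_count(0, "A", 400)
        # sample well-separated snapshots after mixing
        times = 0.01 + 0.002 * np.arange(40)
        tr = solver.sample(times)
        mean_counts = tr.counts[:, 0, : mesh.n_tets].mean(axis=0)
        expected = 400 * mesh.tet_volumes / mesh.total_volume
        # detailed-balance oracle: stationary occupancy ~ volume fraction
        corr = np.corrcoef(mean_counts, expected)[0, 1]
        assert corr > 0.9
        assert abs(mean_counts.sum() - 400) < 1e-9

    def test_multinomial_injection_weights(self):
        mesh = jittered_box_mesh(divisions=2, seed=1)
        bound = self.diffusion_bound(mesh)
        solver = TetexactSolver(bound, seed=2)
        n = 20000
        solver.set_comp_count("cyt", "A", n)
        counts = solver.tet_counts("A")
        p = mesh.tet_volumes / mesh.total_volume
        chi2 = ((counts - n * p) ** 2 / (n * p)).sum()
        assert stats.chi2.sf(chi2, df=mesh.n_tets - 1) > 0.001
        assert counts.sum() == n

    def test_clamped_boundary_tet_constant_under_diffusion(self):
        mesh = generate_box_tetmesh(1e-6, 2)
        bound = self.diffusion_bound(mesh, D=1e-10)
        solver = TetexactSolver(bound, seed=6)
        solver.set_tet_count(0, "A", 50)
        solver.set_tet_clamped(0, "A")
        tr = solver.sample([1e-4, 1e-3, 2e-3])
        assert (tr.counts[:, 0, 0] == 50).all()
        # molecules flowed out of the clamped source into the rest
        assert tr.counts[-1, 0, 1:].sum() > 0

    def test_set_then_get_identity(self):
        mesh = generate_box_tetmesh(1e-6, 1)
        bound = self.diffusion_bound(mesh)
        solver = TetexactSolver(bound, seed=0)
        solver.set_tet_count(3, "A", 7)
        assert solver.get_tet_count(3, "A") == 7
        with pytest.raises(ValueError):
            solver.set_tet_count(3, "A", -1)
        with pytest.raises(KeyError):
            solver.get_tet_count(3, "missing")

    def test_requires_mesh_geometry(self):
        bound = decay_bound()
        with pytest.raises(TypeError):
            TetexactSolver(bound, seed=0)


class TestWmrk4:
    def test_global_error_scales_as_dt4(self):
        bound = decay_bound(k=1.0)
        times = [1.0]
        errs = []
        for dt in (0.1, 0.05):
            tr = wmrk4_run(bound, {("comp", "A"): 1e-6}, dt, times)
            c = tr.counts[0, 0, 0] / (NA * 1e-18 * 1e3)
            errs.append(abs(c - 1e-6 * np.exp(-1.0)))
        ratio = errs[0] / errs[1]
        assert 12.0 < ratio < 20.0

    def test_reversible_equilibrium_ratio(self):
        model = Model()
        model.add_species("A")
        model.add_species("B")
        model.add_reversible_reaction("iso", ["A"], ["B"], 3.0, 1.0, "vsys")
        geom = WellMixedGeometry()
        geom.add_compartment(WellMixedCompartment("comp", 1e-18, ("vsys",)))
        bound = apply_systems(model, geom)
        tr = wmrk4_run(bound, {("comp", "A"): 1e-6}, 1e-3, [50.0])
        a, b = tr.counts[0, 0, 0], tr.counts[0, 1, 0]
        assert b / a == pytest.approx(3.0, rel=1e-6)

    def test_stochastic_mean_converges_to_rk4(self):
        # law of large numbers at N0 = 1e5: one SSA run tracks the ODE
        n0 = 100_000
        bound = decay_bound(k=1.0)
        tr = wmdirect_run(bound, {("comp", "A"): n0}, [1.0], seed=3)
        ode = wmrk4_run(bound, {("comp", "A"): n0 / (NA * 1e-18 * 1e3)},
                        1e-3, [1.0])
        assert tr.counts[0, 0, 0] == pytest.approx(ode.counts[0, 0, 0], rel=0.02)

    def test_nonpositive_dt_rejected(self):
        bound = decay_bound()
        with pytest.raises(ValueError):
            wmrk4_run(bound, {}, 0.0, [1.0])
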