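"""SSA engine: propensities, diffusion channels, CR selection, dependencies."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rdvox.engine import (NA, CRStructure, DiffusionChannel, NoEventError,
                          build_diffusion_channels, build_dependency_graph,
                          build_reaction_channel, next_event_time,
                          select_direction)
from rdvox.geometry import Tetmesh, generate_box_tetmesh
from rdvox.model import Model, Reaction, apply_systems

#: compartment volume for which N_A * V (in liters) is exactly 1000 /M
V_NAV1000 = 1000.0 / (NA * 1e3)


def make_channel(lhs, k, n_species=3):
    r = Reaction("r", lhs, {}, k)
    index = {s: i for i, s in enumerate(["A", "B", "C"])}
    return build_reaction_channel(r, "c", V_NAV1000, index, 0, 1)


class TestPropensity:
    def test_first_order(self):
        ch = make_channel({"A": 1}, k=2.0)
        assert ch.propensity([5, 0, 0]) == pytest.approx(10.0)

    def test_second_order_distinct(self):
        # k = 1e6 /M.s, N_A V = 1000 /M, nA = nB = 10 -> a = 1e5 /s
        ch = make_channel({"A": 1, "B": 1}, k=1e6)
        assert ch.propensity([10, 10, 0]) == pytest.approx(1e5)

    def test_second_order_identical_vs_pair_count(self):
        ch = make_channel({"A": 2}, k=1e6)
        # exhaustive oracle: ordered reactive pairs among n indistinct
        # molecules number n*(n-1)
        n = 10
        pairs = sum(1 for i in range(n) for j in range(n) if i != j)
        assert pairs == 90
        assert ch.propensity([n, 0, 0]) == pytest.approx(1e6 * pairs / 1000.0)

    def test_zero_order(self):
        ch = make_channel({}, k=1e-3)  # M/s
        assert ch.propensity([0, 0, 0]) == pytest.approx(1e-3 * 1000.0)

    def test_exhausted_reactant_gives_zero(self):
        ch = make_channel({"A": 2}, k=1.0)
        assert ch.propensity([1, 0, 0]) == 0.0
        assert ch.propensity([0, 0, 0]) == 0.0


class TestDiffusionChannels:
    def two_regular_tets(self, a=1.0):
        h = math.sqrt(2.0 / 3.0) * a  # height of a regular tet
        base = [[0, 0, 0], [a, 0, 0], [a / 2, math.sqrt(3) / 2 * a, 0]]
        apex_up = [a / 2, math.sqrt(3) / 6 * a, h]
        apex_dn = [a / 2, math.sqrt(3) / 6 * a, -h]
        return Tetmesh(base + [apex_up, apex_dn],
                       [[0, 1, 2, 3], [0, 1, 2, 4]])

    def test_two_regular_tets_rate_9D_over_a2(self):
        a = 2.5e-7
        D = 1e-10
        mesh = self.two_regular_tets(a)
        mesh.add_compartment("c", [0, 1], ("v",))
        model = Model()
        model.add_species("A")
        model.add_diffusion("dA", "A", D, "v")
        bound = apply_systems(model, mesh)
        channels = build_diffusion_channels(mesh, bound)
        assert len(channels) == 2
        for ch in channels:
            assert len(ch.rates) == 1
            assert ch.rates[0] == pytest.approx(9.0 * D / a ** 2, rel=1e-9)

    def test_grouped_total_is_sum_of_directions(self):
        mesh = generate_box_tetmesh(1e-6, 2)
        mesh.add_compartment("c", range(mesh.n_tets), ("v",))
        model = Model()
        model.add_species("A")
        model.add_diffusion("dA", "A", 1e-11, "v")
        channels = build_diffusion_channels(mesh, apply_systems(model, mesh))
        for ch in channels:
            assert ch.total_rate == pytest.approx(sum(ch.rates))

    def test_isolated_tet_has_no_directions(self):
        mesh = self.two_regular_tets()
        mesh.add_compartment("left", [0], ("v",))  # neighbor in other comp
        mesh.add_compartment("right", [1], ("v",))
        model = Model()
        model.add_species("A")
        model.add_diffusion("dA", "A", 1e-11, "v")
        channels = build_diffusion_channels(mesh, apply_systems(model, mesh))
        for ch in channels:
            assert ch.targets == () and ch.propensity([99, 99]) == 0.0

    def test_channel_count_bound(self):
        # M_diff < 4 * N * N_tet and M_reac = N_tet * M
        mesh = generate_box_tetmesh(1e-6, 2)
        mesh.add_compartment("c", range(mesh.n_tets), ("v",))
        model = Model()
        for s in ("A", "B"):
            model.add_species(s)
            model.add_diffusion(f"d{s}", s, 1e-11, "v")
        model.add_reaction("r", ["A"], ["B"], 1.0, "v")
        bound = apply_systems(model, mesh)
        channels = build_diffusion_channels(mesh, bound)
        n_dirs = sum(len(ch.targets) for ch in channels)
        assert len(channels) == 2 * mesh.n_tets
        assert n_dirs < 4 * 2 * mesh.n_tets


class TestSelectDirection:
    def test_equal_rates_uniform(self):
        ch = DiffusionChannel("d", 0, "A", 0, [1, 2, 3, 4], [1.0] * 4)
        rng = np.random.default_rng(0)
        draws = [select_direction(ch.cum_rates, rng.random()) for _ in range(10000)]
        freqs = np.bincount(draws, minlength=4) / 10000
        assert np.abs(freqs - 0.25).max() < 0.02

    def test_asymmetric_rates_binomial(self):
        ch = DiffusionChannel("d", 0, "A", 0, [1, 2], [3.0, 1.0])
        rng = np.random.default_rng(1)
        n = 20000
        hits = sum(select_direction(ch.cum_rates, rng.random()) == 0
                   for _ in range(n))
        # binomial check at p = 0.75
        assert abs(hits / n - 0.75) < 3 * math.sqrt(0.75 * 0.25 / n)

    def test_single_direction_and_zero_rate(self):
        ch = DiffusionChannel("d", 0, "A", 0, [7], [2.0])
        assert select_direction(ch.cum_rates, 0.99) == 0
        empty = DiffusionChannel("d", 0, "A", 0, [], [])
        with pytest.raises(NoEventError):
            select_direction(empty.cum_rates or (0.0,), 0.5)


class TestDependencyGraph:
    def build(self):
        index = {s: i for i, s in enumerate(["A", "B", "C"])}
        bind = build_reaction_channel(Reaction("bind", {"A": 1, "B": 1}, {"C": 1},
                                               1e6), "c", V_NAV1000, index, 0, 2)
        degC = build_reaction_channel(Reaction("degC", {"C": 1}, {}, 1.0),
                                      "c", V_NAV1000, index, 0, 2)
        # diffusion of A from location 0 to 1 (flat ix: A0=0, A1=1)
        diffA = DiffusionChannel("dA", 0, "A", 0, [1], [1.0])
        other = build_reaction_channel(Reaction("other", {"B": 1}, {}, 1.0),
                                       "c", V_NAV1000, index, 1, 2)
        channels = [bind, degC, diffA, other]
        build_dependency_graph(channels, 6)
        return channels

    def test_reaction_dependents_cover_consumers_of_changed_species(self):
        bind, degC, diffA, other = self.build()
        # bind changes A, B, C in location 0 -> bind itself, degC, diffusion of A
        assert set(bind.dependents) == {0, 1, 2}

    def test_diffusion_affects_both_locations(self):
        bind, degC, diffA, other = self.build()
        # moving A from loc 0 to loc 1 affects bind (A in 0) and itself;
        # nothing consumes A in location 1
        assert set(diffA.dependents_by_dir[0]) == {0, 2}

    def test_disjoint_channels_independent(self):
        bind, degC, diffA, other = self.build()
        assert other.index not in bind.dependents
        assert bind.index not in other.dependents


class TestCRStructure:
    def test_single_channel_always_selected(self):
        cr = CRStructure([4.0])
        rng = np.random.default_rng(0)
        assert all(cr.select(rng) == 0 for _ in range(100))

    def test_selection_matches_linear_scan_oracle(self):
        props = [1.0, 2.0, 4.0, 8.0]
        cr = CRStructure(props)
        rng = np.random.default_rng(42)
        n = 100_000
        counts = np.bincount([cr.select(rng) for _ in range(n)], minlength=4)

        # independent oracle: linear-scan direct method on the same vector
        rng2 = np.random.default_rng(99)
        cum = np.cumsum(props)
        oracle = np.bincount(np.searchsorted(cum, rng2.random(n) * cum[-1]),
                             minlength=4)
        expected = np.asarray(props) / sum(props) * n
        for observed in (counts, oracle):
            chi2 = ((observed - expected) ** 2 / expected).sum()
            assert stats.chi2.sf(chi2, df=3) > 0.01

    def test_zero_propensity_never_selected(self):
        cr = CRStructure([0.0, 5.0, 0.0])
        rng = np.random.default_rng(3)
        assert all(cr.select(rng) == 1 for _ in range(200))

    def test_update_moves_groups(self):
        cr = CRStructure([3.0])
        assert cr.pos[0][0] == 2  # [2, 4)
        cr.update(0, 5.0)
        assert cr.pos[0][0] == 3  # [4, 8)
        cr.update(0, 3.5)
        assert cr.pos[0][0] == 2
        cr.update(0, 0.0)
        assert cr.pos[0] is None

    def test_negative_propensity_rejected(self):
        cr = CRStructure([1.0])
        with pytest.raises(ValueError):
            cr.update(0, -0.5)

    @given(st.lists(st.tuples(st.integers(0, 19),
                              st.floats(0, 1e6, allow_nan=False)),
                    min_size=1, max_size=300))
    @settings(deadline=None, max_examples=50)
    def test_total_matches_recomputation_after_any_updates(self, updates):
        cr = CRStructure([float(i) for i in range(20)])
        for cid, a in updates:
            cr.update(cid, a)
        exact = math.fsum(cr.a)
        assert cr.a_total == pytest.approx(exact, rel=1e-9, abs=1e-12)

    def test_empty_total_raises(self):
        cr = CRStructure([0.0])
        with pytest.raises(NoEventError):
            cr.select(np.random.default_rng(0))


class TestNextEventTime:
    def test_exponential_mean(self):
        rng = np.random.default_rng(5)
        n = 100_000
        dts = [next_event_time(2.0, rng.random()) for _ in range(n)]
        se = 0.5 / math.sqrt(n)
        assert abs(np.mean(dts) - 0.5) < 3 * se

    def test_zero_total_gives_infinity(self):
        assert next_event_time(0.0, 0.5) == math.inf

    def test_negative_total_rejected(self):
        with pytest.raises(ValueError):
            next_event_time(-1.0, 0.5)
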