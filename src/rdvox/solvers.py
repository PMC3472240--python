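"""Simulation solvers: stochastic well-mixed, stochastic spatial, deterministic.

Three solvers share one control/measurement surface:

* :class:`WmdirectSolver` -- exact SSA in well-mixed compartments/patches;
* :class:`TetexactSolver` -- exact spatial SSA over a tetrahedral mesh, with
  grouped diffusion channels, composition-rejection selection and
  dependency-graph updates;
* :func:`wmrk4_run` -- deterministic classical fixed-step 4th-order
  Runge-Kutta on the mass-action ODEs implied by the reactions.

Run-to-time semantics for the stochastic solvers: events are applied while
the next event time is at or before the target time, then the clock is set
to the target (state between events is constant).  Molecule injection into
a mesh compartment distributes multinomially with tet-volume weights.
Clamped (species, location) pairs keep a fixed count while still driving
propensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine
from .engine import NA, SSACore, ReactionChannel, build_reaction_channel, \
    build_diffusion_channels
from .geometry import Tetmesh, WellMixedGeometry
from .model import BoundModel, SurfaceReaction

__all__ = [
    "Trajectory", "WmdirectSolver", "TetexactSolver",
    "wmdirect_run", "tetexact_run", "wmrk4_run", "mass_action_rhs",
]


def _rng(seed) -> np.random.Generator:
    """Mersenne-Twister generator, seedable per run."""
    return np.random.Generator(np.random.MT19937(seed))


@dataclass
class Trajectory:
    """Time-stamped counts per (species x location) for one replicate.

    ``counts`` has shape (n_times, n_species, n_locations); ``volumes`` (m^3)
    is NaN for surface (triangle/patch) locations, where a concentration is
    not defined.
    """

    times: np.ndarray
    species: list[str]
    locations: list
    counts: np.ndarray
    volumes: np.ndarray
    replicate: int = 0
    seed: int | None = None

    def concentrations(self) -> np.ndarray:
        """Molar concentrations, count / (N_A * V * 1e3)."""
        return self.counts / (NA * self.volumes[None, None, :] * 1e3)

    def species_total(self, species: str) -> np.ndarray:
        """Summed count of one species over all locations, per sample time."""
        return self.counts[:, self.species.index(species), :].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (time, replicate, location, species, count,
        concentration)."""
        rows = []
        conc = self.concentrations()
        integer = np.issubdtype(self.counts.dtype, np.integer)
        for it, t in enumerate(self.times):
            for isp, sp in enumerate(self.species):
                for il, loc in enumerate(self.locations):
                    n = self.counts[it, isp, il]
                    rows.append((float(t), self.replicate, str(loc), sp,
                                 int(n) if integer else float(n),
                                 float(conc[it, isp, il])))
        return pd.DataFrame(rows, columns=["time", "replicate", "location",
                                           "species", "count", "concentration"])


class _StochasticSolver:
    """Shared state accessors over an :class:`~rdvox.engine.SSACore`."""

    def __init__(self, bound: BoundModel, seed):
        issues = bound.model.validate()
        if issues:
            raise ValueError("invalid model: " + "; ".join(issues))
        self.bound = bound
        self.seed = seed
        self.rng = _rng(seed)
        self.species = sorted(bound.model.species)
        self.species_index = {s: i for i, s in enumerate(self.species)}
        # subclasses fill these
        self.locations: list = []
        self.loc_volumes: np.ndarray | None = None
        self.core: SSACore | None = None

    # -- indexing -----------------------------------------------------------

    @property
    def n_locations(self) -> int:
        return len(self.locations)

    def _flat(self, species: str, loc_ix: int) -> int:
        if species not in self.species_index:
            raise KeyError(f"unknown species {species!r}")
        if not 0 <= loc_ix < self.n_locations:
            raise KeyError(f"location index {loc_ix} out of range")
        return self.species_index[species] * self.n_locations + loc_ix

    # -- generic accessors --------------------------------------------------

    def run(self, t_end: float) -> None:
        """Advance the simulation clock to ``t_end`` (absolute time)."""
        if t_end < self.core.t:
            raise ValueError("cannot run backwards in time")
        self.core.advance_to(t_end)

    @property
    def t(self) -> float:
        return self.core.t

    @property
    def events_fired(self) -> int:
        return self.core.events_fired

    def counts_array(self) -> np.ndarray:
        return np.asarray(self.core.x, dtype=np.int64).reshape(
            len(self.species), self.n_locations)

    def sample(self, times, replicate: int = 0) -> Trajectory:
        """Run through ``times`` (nondecreasing), recording state at each."""
        times = np.asarray(times, dtype=float)
        if np.any(np.diff(times) < 0):
            raise ValueError("sample times must be nondecreasing")
        out = np.empty((len(times), len(self.species), self.n_locations),
                       dtype=np.int64)
        for i, t in enumerate(times):
            self.run(float(t))
            out[i] = self.counts_array()
        return Trajectory(times, list(self.species), list(self.locations), out,
                          self.loc_volumes.copy(), replicate, self.seed)


# ---------------------------------------------------------------------------
# well-mixed stochastic solver
# ---------------------------------------------------------------------------

class WmdirectSolver(_StochasticSolver):
    """Gillespie SSA in well-mixed compartments and patches."""

    def __init__(self, bound: BoundModel, seed=None, surface_scale=None):
        super().__init__(bound, seed)
        geom = bound.geometry
        if not isinstance(geom, WellMixedGeometry):
            raise TypeError("WmdirectSolver requires a well-mixed geometry")
        self.geometry = geom
        self.locations = list(geom.compartments) + list(geom.patches)
        self._loc_ix = {loc: i for i, loc in enumerate(self.locations)}
        vols = [geom.compartments[c].volume for c in geom.compartments]
        vols += [float("nan")] * len(geom.patches)
        self.loc_volumes = np.asarray(vols)

        channels = []
        n_loc = self.n_locations
        for cid, comp in geom.compartments.items():
            li = self._loc_ix[cid]
            for r in bound.comp_reactions.get(cid, []):
                channels.append(build_reaction_channel(
                    r, cid, comp.volume, self.species_index, li, n_loc))
        for pid, patch in geom.patches.items():
            li = self._loc_ix[pid]
            inner = self._loc_ix[patch.inner]
            outer = self._loc_ix[patch.outer] if patch.outer else None
            v_inner = geom.compartments[patch.inner].volume
            v_outer = geom.compartments[patch.outer].volume if patch.outer else None
            for r in bound.patch_reactions.get(pid, []):
                channels.append(_surface_channel(
                    r, pid, li, inner, outer, v_inner, v_outer, n_loc,
                    self.species_index, surface_scale))
        self.core = SSACore(channels, len(self.species) * n_loc, self.rng)
        self.core.initialize()
        self.m_reac = len(channels)
        self.m_diff = 0

    # -- accessors ----------------------------------------------------------

    def set_count(self, loc: str, species: str, n: int) -> None:
        self.core.set_count(self._flat(species, self._loc_ix[loc]), int(n))

    def get_count(self, loc: str, species: str) -> int:
        return self.core.x[self._flat(species, self._loc_ix[loc])]

    def set_conc(self, comp: str, species: str, molar: float) -> None:
        v = self.geometry.compartments[comp].volume
        self.set_count(comp, species, int(round(molar * NA * v * 1e3)))

    def get_conc(self, comp: str, species: str) -> float:
        v = self.geometry.compartments[comp].volume
        return self.get_count(comp, species) / (NA * v * 1e3)

    def set_clamped(self, loc: str, species: str, flag: bool = True) -> None:
        self.core.clamped[self._flat(species, self._loc_ix[loc])] = bool(flag)


def _surface_channel(r: SurfaceReaction, pid, tri_loc, inner_loc, outer_loc,
                     v_inner, v_outer, n_loc, species_index, surface_scale):
    """Instantiate a surface reaction at one patch element.

    Propensity convention: volume-located reactants are scaled by their own
    compartment element's volume (k*n_A*n_B/(N_A*V_inner) for inner-volume A
    with surface B); pure surface-surface second-order reactions have no
    natural volume and require an explicit per-reaction scale factor
    (events/s per reactant pair) via ``surface_scale``.
    """
    parts = [(r.lhs_inner, inner_loc), (r.lhs_surface, tri_loc),
             (r.lhs_outer, outer_loc)]
    reactants = []
    for ms, loc in parts:
        if ms and loc is None:
            raise ValueError(f"surface reaction {r.id!r} needs an outer compartment")
        for s, st in sorted(ms.items()):
            reactants.append((species_index[s] * n_loc + loc, st))
    order = r.order
    n_vol = sum(r.lhs_inner.values()) + sum(r.lhs_outer.values())
    if order <= 1:
        scale = r.k
    elif n_vol >= 1:
        # scale against the coupled volume element; prefer the inner side
        v = v_inner if r.lhs_inner else v_outer
        scale = r.k * (NA * v * 1e3) ** (1 - order)
    else:
        if not surface_scale or r.id not in surface_scale:
            raise ValueError(
                f"surface-surface second-order reaction {r.id!r}: no default "
                "rate scaling; pass surface_scale={id: events/s per pair}")
        scale = surface_scale[r.id]
    net: dict[int, int] = {}
    for ms, loc, sign in [(r.lhs_inner, inner_loc, -1), (r.lhs_surface, tri_loc, -1),
                          (r.lhs_outer, outer_loc, -1), (r.rhs_inner, inner_loc, 1),
                          (r.rhs_surface, tri_loc, 1), (r.rhs_outer, outer_loc, 1)]:
        if ms and loc is None:
            raise ValueError(f"surface reaction {r.id!r} needs an outer compartment")
        for s, st in ms.items():
            ix = species_index[s] * n_loc + loc
            net[ix] = net.get(ix, 0) + sign * st
    deltas = [(ix, d) for ix, d in sorted(net.items()) if d != 0]
    return ReactionChannel(r.id, "surface-reaction", pid, scale, reactants, deltas)


# ---------------------------------------------------------------------------
# spatial stochastic solver
# ---------------------------------------------------------------------------

class TetexactSolver(_StochasticSolver):
    """Spatial SSA: reactions per tet, surface reactions per patch triangle,
    grouped diffusion channels between face-sharing tets of one compartment."""

    def __init__(self, bound: BoundModel, seed=None, surface_scale=None):
        super().__init__(bound, seed)
        mesh = bound.geometry
        if not isinstance(mesh, Tetmesh):
            raise TypeError("TetexactSolver requires a Tetmesh geometry")
        self.mesh = mesh
        # locations: all tets first, then the patch triangles actually used
        patch_tris = sorted({int(fi) for p in mesh.patches.values() for fi in p.tris})
        self._tri_loc = {fi: mesh.n_tets + i for i, fi in enumerate(patch_tris)}
        self.locations = [("tet", k) for k in range(mesh.n_tets)] + \
                         [("tri", fi) for fi in patch_tris]
        vols = np.concatenate([mesh.tet_volumes,
                               np.full(len(patch_tris), np.nan)])
        self.loc_volumes = vols
        n_loc = self.n_locations

        channels: list = []
        for cid, comp in mesh.compartments.items():
            for r in bound.comp_reactions.get(cid, []):
                for k in comp.tets:
                    k = int(k)
                    channels.append(build_reaction_channel(
                        r, ("tet", k), mesh.tet_volumes[k],
                        self.species_index, k, n_loc))
        self.m_reac = len(channels)
        for pid, patch in mesh.patches.items():
            inner_tets, outer_tets = mesh.patch_tri_tets(pid)
            for r in bound.patch_reactions.get(pid, []):
                for i, fi in enumerate(patch.tris):
                    ti, to = int(inner_tets[i]), int(outer_tets[i])
                    channels.append(_surface_channel(
                        r, ("tri", int(fi)), self._tri_loc[int(fi)], ti,
                        to if to >= 0 else None, mesh.tet_volumes[ti],
                        mesh.tet_volumes[to] if to >= 0 else None,
                        n_loc, self.species_index, surface_scale))
        self.m_reac = len(channels)
        diff = build_diffusion_channels(mesh, bound)
        # build_diffusion_channels lays state out as tets + all mesh tris; we
        # only keep the patch triangles, so remap flat indices
        if len(mesh.tris) != len(patch_tris):
            diff = self._remap_diffusion(diff, mesh, n_loc)
        channels.extend(diff)
        self.m_diff = len(diff)
        self.core = SSACore(channels, len(self.species) * n_loc, self.rng)
        self.core.initialize()

    def _remap_diffusion(self, diff, mesh, n_loc):
        full_loc = mesh.n_tets + len(mesh.tris)
        out = []
        for ch in diff:
            si = ch.source // full_loc
            out.append(engine.DiffusionChannel(
                ch.rule_id, ch.location, ch.species,
                si * n_loc + ch.source % full_loc,
                [si * n_loc + t % full_loc for t in ch.targets], ch.rates))
        return out

    # -- accessors ----------------------------------------------------------

    def set_tet_count(self, k: int, species: str, n: int) -> None:
        self.core.set_count(self._flat(species, int(k)), int(n))

    def get_tet_count(self, k: int, species: str) -> int:
        return self.core.x[self._flat(species, int(k))]

    def set_tet_conc(self, k: int, species: str, molar: float) -> None:
        v = self.mesh.tet_volumes[int(k)]
        self.set_tet_count(k, species, int(round(molar * NA * v * 1e3)))

    def get_tet_conc(self, k: int, species: str) -> float:
        v = self.mesh.tet_volumes[int(k)]
        return self.get_tet_count(k, species) / (NA * v * 1e3)

    def set_tri_count(self, fi: int, species: str, n: int) -> None:
        self.core.set_count(self._flat(species, self._tri_loc[int(fi)]), int(n))

    def get_tri_count(self, fi: int, species: str) -> int:
        return self.core.x[self._flat(species, self._tri_loc[int(fi)])]

    def set_comp_count(self, cid: str, species: str, n: int) -> None:
        """Inject ``n`` molecules, multinomially distributed over tet volumes."""
        comp = self.mesh.compartments[cid]
        vols = self.mesh.tet_volumes[comp.tets]
        alloc = self.rng.multinomial(int(n), vols / vols.sum())
        for k, nk in zip(comp.tets, alloc):
            self.set_tet_count(int(k), species, int(nk))

    def get_comp_count(self, cid: str, species: str) -> int:
        comp = self.mesh.compartments[cid]
        return int(sum(self.get_tet_count(int(k), species) for k in comp.tets))

    def set_comp_conc(self, cid: str, species: str, molar: float) -> None:
        comp = self.mesh.compartments[cid]
        v = float(self.mesh.tet_volumes[comp.tets].sum())
        self.set_comp_count(cid, species, int(round(molar * NA * v * 1e3)))

    def set_tet_clamped(self, k: int, species: str, flag: bool = True) -> None:
        self.core.clamped[self._flat(species, int(k))] = bool(flag)

    def tet_counts(self, species: str) -> np.ndarray:
        """Per-tet counts of one species (over all mesh tets)."""
        arr = self.counts_array()[self.species_index[species]]
        return arr[: self.mesh.n_tets]


# ---------------------------------------------------------------------------
# functional front-ends
# ---------------------------------------------------------------------------

def _apply_initial(solver, initial_counts):
    for (loc, species), n in (initial_counts or {}).items():
        if isinstance(solver, TetexactSolver):
            if isinstance(loc, tuple) and loc[0] == "tet":
                solver.set_tet_count(loc[1], species, n)
            elif isinstance(loc, tuple) and loc[0] == "tri":
                solver.set_tri_count(loc[1], species, n)
            else:
                solver.set_comp_count(loc, species, n)
        else:
            solver.set_count(loc, species, n)


def wmdirect_run(bound: BoundModel, initial_counts, sample_times, seed,
                 replicate: int = 0, surface_scale=None) -> Trajectory:
    """Run the well-mixed SSA once, sampling counts at ``sample_times``.

    ``initial_counts`` maps (compartment-or-patch id, species) to a count.
    """
    solver = WmdirectSolver(bound, seed, surface_scale)
    _apply_initial(solver, initial_counts)
    return solver.sample(sample_times, replicate)


def tetexact_run(bound: BoundModel, initial_counts, sample_times, seed,
                 replicate: int = 0, surface_scale=None) -> Trajectory:
    """Run the spatial SSA once over a tetmesh geometry.

    ``initial_counts`` keys may be compartment ids (multinomial injection by
    tet volume), ``("tet", k)`` or ``("tri", fi)``.
    """
    solver = TetexactSolver(bound, seed, surface_scale)
    _apply_initial(solver, initial_counts)
    return solver.sample(sample_times, replicate)


# ---------------------------------------------------------------------------
# deterministic solver
# ---------------------------------------------------------------------------

def mass_action_rhs(bound: BoundModel, cid: str, species: list[str]):
    """Right-hand side dc/dt (molar/s) of the mass-action ODEs in one
    compartment.  Rate of a reaction = k * prod c_i^nu_i; a reactant pair
    A+A therefore consumes at 2*k*c^2, matching the stochastic
    k*n*(n-1)/(N_A*V) propensity convention in the large-number limit.
    """
    reactions = bound.comp_reactions.get(cid, [])
    sp_ix = {s: i for i, s in enumerate(species)}
    terms = []
    for r in reactions:
        powers = [(sp_ix[s], st) for s, st in r.lhs.items()]
        net = {}
        for s, st in r.lhs.items():
            net[sp_ix[s]] = net.get(sp_ix[s], 0) - st
        for s, st in r.rhs.items():
            net[sp_ix[s]] = net.get(sp_ix[s], 0) + st
        terms.append((r.k, powers, [(i, d) for i, d in net.items() if d != 0]))

    def rhs(c):
        dc = np.zeros_like(c)
        for k, powers, net in terms:
            rate = k
            for i, st in powers:
                rate *= c[i] ** st
            for i, d in net:
                dc[i] += d * rate
        return dc

    return rhs


def wmrk4_run(bound: BoundModel, initial_conc, dt: float, sample_times) -> Trajectory:
    """Classical fixed-step RK4 on the mass-action ODEs (concentrations, molar).

    ``initial_conc`` maps (compartment id, species) to a molar concentration.
    The returned trajectory carries continuous (float) molecule numbers,
    concentration times N_A*V; only the stochastic solvers yield integers.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    geom = bound.geometry
    if not isinstance(geom, WellMixedGeometry):
        raise TypeError("wmrk4_run requires a well-mixed geometry")
    if any(bound.patch_reactions.values()):
        raise NotImplementedError("deterministic solver supports volume reactions only")
    issues = bound.model.validate()
    if issues:
        raise ValueError("invalid model: " + "; ".join(issues))
    species = sorted(bound.model.species)
    comps = list(geom.compartments)
    times = np.asarray(sample_times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("sample times must be nondecreasing")
    conc = np.zeros((len(comps), len(species)))
    for (cid, sp), c0 in (initial_conc or {}).items():
        conc[comps.index(cid), species.index(sp)] = c0
    rhss = [mass_action_rhs(bound, cid, species) for cid in comps]

    out = np.empty((len(times), len(species), len(comps)))
    t = 0.0
    for i, t_target in enumerate(times):
        while t < t_target - 1e-15 * max(1.0, t_target):
            h = min(dt, t_target - t)
            for j, rhs in enumerate(rhss):
                y = conc[j]
                k1 = rhs(y)
                k2 = rhs(y + 0.5 * h * k1)
                k3 = rhs(y + 0.5 * h * k2)
                k4 = rhs(y + h * k3)
                conc[j] = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        out[i] = conc.T
    vols = np.array([geom.compartments[c].volume for c in comps])
    counts = out * (NA * vols[None, None, :] * 1e3)
    traj = Trajectory(times, species, comps, counts, vols)
    return traj
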