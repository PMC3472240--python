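"""Kinetics core shared by the stochastic solvers.

The engine turns a bound model + geometry into a flat list of *channels*
(reaction, surface-reaction and grouped-diffusion processes, each carrying a
propensity), a dependency graph saying which propensities must be recomputed
after each firing, and a composition-rejection (CR) structure that selects
the next channel in O(1) time independent of the number of channels.

Diffusion between neighboring tetrahedra k and l is a reversible first-order
channel pair with rates

    d_{k,l} = D * S / (V_k * dx_{k,l})

where S is the area of the shared face, V_k the source tet volume and dx the
barycenter-to-barycenter distance (symmetric, dx_{k,l} == dx_{l,k}).  All
outgoing directions of one species from one tet are grouped into a single
channel whose propensity is the molecule count times the summed rate; the
direction is picked (proportionally to the per-direction rates) only after
the channel fires.  This is statistically equivalent to up to four separate
channels per tet but needs about a quarter of the memory.

State is a flat list of integer molecule counts indexed by
``species_index * n_locations + location_index``.
"""

from __future__ import annotations

import math
from bisect import bisect_right

import numpy as np
from scipy.constants import Avogadro as NA

__all__ = [
    "NA", "ReactionChannel", "DiffusionChannel", "CRStructure",
    "build_reaction_channel", "build_diffusion_channels",
    "build_dependency_graph", "next_event_time", "select_direction",
    "SSACore", "NoEventError", "CRConsistencyError",
]


class NoEventError(RuntimeError):
    """Selection requested with zero total propensity."""


class CRConsistencyError(RuntimeError):
    """The CR rejection loop failed to terminate (corrupt group brackets)."""


def next_event_time(a_total: float, u: float) -> float:
    """Exponential waiting time -ln(u)/a_total; infinite when a_total == 0.

    ``u`` must lie in the open interval (0, 1); u == 0 is rejected by the
    caller (open-interval uniforms) so the log never sees zero.
    """
    if a_total < 0:
        raise ValueError("total propensity must be >= 0")
    if a_total == 0.0:
        return math.inf
    return -math.log(u) / a_total


def select_direction(cum_rates, u: float) -> int:
    """Pick a direction index with probability rate/total from cumulative rates."""
    total = cum_rates[-1]
    if total <= 0.0:
        raise NoEventError("diffusion channel has zero total rate")
    return bisect_right(cum_rates, u * total)


# ---------------------------------------------------------------------------
# channels
# ---------------------------------------------------------------------------

class ReactionChannel:
    """A reaction instantiated at one location (tet, triangle, or compartment).

    ``scale`` folds the macroscopic rate constant and the N_A*V conversion:
    for a volume reaction of order n, scale = k * (N_A * V * 1e3)^(1-n) with
    V in m^3 (the 1e3 converts m^3 to liters so k stays in molar units).
    The propensity is scale times the product of falling factorials of the
    reactant counts -- k*n for first order, k*nA*nB/(N_A*V) for A+B, and
    k*nA*(nA-1)/(N_A*V) for A+A.
    """

    __slots__ = ("index", "rule_id", "kind", "location", "scale",
                 "reactants", "deltas", "dependents")

    def __init__(self, rule_id, kind, location, scale, reactants, deltas):
        self.index = -1
        self.rule_id = rule_id
        self.kind = kind  # "reaction" | "surface-reaction"
        self.location = location
        self.scale = float(scale)
        #: ((flat state index, stoichiometry), ...)
        self.reactants = tuple(reactants)
        #: ((flat state index, net change), ...)
        self.deltas = tuple(deltas)
        self.dependents: tuple[int, ...] = ()

    def propensity(self, x) -> float:
        a = self.scale
        for ix, st in self.reactants:
            n = x[ix]
            if n < st:
                return 0.0
            if st == 1:
                a *= n
            elif st == 2:
                a *= n * (n - 1)
            else:
                a *= n * (n - 1) * (n - 2)
        return a


class DiffusionChannel:
    """Grouped diffusion of one species out of one tet.

    Propensity = (count in source tet) * sum of per-direction rates; the
    direction is selected after the channel fires.  A channel with no
    directions (isolated tet or reflective compartment boundary on all
    sides) always has zero propensity.
    """

    __slots__ = ("index", "rule_id", "kind", "location", "species", "source",
                 "targets", "rates", "cum_rates", "total_rate",
                 "dependents_by_dir")

    def __init__(self, rule_id, location, species, source, targets, rates):
        self.index = -1
        self.rule_id = rule_id
        self.kind = "diffusion"
        self.location = location  # source tet index
        self.species = species
        self.source = source      # flat state index of species in source tet
        self.targets = tuple(targets)  # flat state indices per direction
        self.rates = tuple(float(r) for r in rates)
        cum = []
        s = 0.0
        for r in self.rates:
            s += r
            cum.append(s)
        self.cum_rates = tuple(cum)
        self.total_rate = s
        self.dependents_by_dir: tuple[tuple[int, ...], ...] = ()

    def propensity(self, x) -> float:
        return x[self.source] * self.total_rate


def build_reaction_channel(reaction, location, volume, species_index, loc_index,
                           n_loc) -> ReactionChannel:
    """Instantiate a volume reaction in one location of known volume (m^3)."""
    order = reaction.order
    scale = reaction.k * (NA * volume * 1e3) ** (1 - order)
    reactants = [(species_index[s] * n_loc + loc_index, st)
                 for s, st in sorted(reaction.lhs.items())]
    net: dict[int, int] = {}
    for s, st in reaction.lhs.items():
        ix = species_index[s] * n_loc + loc_index
        net[ix] = net.get(ix, 0) - st
    for s, st in reaction.rhs.items():
        ix = species_index[s] * n_loc + loc_index
        net[ix] = net.get(ix, 0) + st
    deltas = [(ix, d) for ix, d in sorted(net.items()) if d != 0]
    return ReactionChannel(reaction.id, "reaction", location, scale, reactants, deltas)


def build_diffusion_channels(mesh, bound) -> list[DiffusionChannel]:
    """One grouped channel per (diffusing species, tet) over a bound tetmesh.

    Directions exist only toward face-sharing neighbor tets *in the same
    compartment*: compartment boundaries are reflective.  Species index /
    flat-state layout follows the sorted species ids of the bound model.
    """
    species_index = {s: i for i, s in enumerate(sorted(bound.model.species))}
    n_loc = mesh.n_tets + len(mesh.tris)  # triangles appended after tets
    channels: list[DiffusionChannel] = []
    for cid, comp in mesh.compartments.items():
        rules = bound.comp_diffusions.get(cid, [])
        comp_set = set(int(t) for t in comp.tets)
        for rule in rules:
            if rule.D <= 0.0:
                continue
            si = species_index[rule.species]
            for k in comp.tets:
                k = int(k)
                targets, rates = [], []
                vk = mesh.tet_volumes[k]
                for j in range(4):
                    l = int(mesh.tet_neighbors[k, j])
                    if l < 0 or l not in comp_set:
                        continue
                    s_face = mesh.tet_face_areas[k, j]
                    dx = mesh.barycenter_distance(k, l)
                    targets.append(si * n_loc + l)
                    rates.append(rule.D * s_face / (vk * dx))
                channels.append(DiffusionChannel(
                    rule.id, k, rule.species, si * n_loc + k, targets, rates))
    return channels


def build_dependency_graph(channels, n_flat: int):
    """Attach dependent-channel lists to every channel.

    A channel depends on a firing if one of its reactant (or diffusion
    source) state entries is changed by it.  For reactions the changed set
    is the net stoichiometry; for diffusion it is the source and the chosen
    destination, so dependents are stored per direction.
    """
    consumers: list[list[int]] = [[] for _ in range(n_flat)]
    for i, ch in enumerate(channels):
        ch.index = i
        if ch.kind == "diffusion":
            consumers[ch.source].append(i)
        else:
            for ix, _ in ch.reactants:
                consumers[ix].append(i)

    def deps_for(ixs):
        seen = sorted({d for ix in ixs for d in consumers[ix]})
        return tuple(seen)

    for ch in channels:
        if ch.kind == "diffusion":
            ch.dependents_by_dir = tuple(
                deps_for((ch.source, tgt)) for tgt in ch.targets)
        else:
            ch.dependents = deps_for(tuple(ix for ix, _ in ch.deltas))
    return consumers


# ---------------------------------------------------------------------------
# composition-rejection structure
# ---------------------------------------------------------------------------

#: propensities below this are treated as zero (far below any biological rate)
MIN_PROPENSITY = 2.0 ** -32
#: exact group/sum rebuild interval (events) to cancel floating-point drift
REBUILD_INTERVAL = 1_000_000
#: rejection-loop guard; impossible to hit with correct brackets
MAX_REJECTIONS = 1000


class CRStructure:
    """Power-of-two propensity groups with O(1) selection and update.

    Group g holds channels with propensity in [2^(g-1), 2^g).  Selection is
    a composition step over the (few) group sums followed by rejection
    sampling inside the chosen group with acceptance probability a / 2^g.
    Zero-propensity channels live outside all groups.  Group sums and the
    total are maintained incrementally and rebuilt exactly every
    ``REBUILD_INTERVAL`` updates.
    """

    __slots__ = ("a", "groups", "sums", "pos", "a_total", "_ops", "rebuild_interval")

    def __init__(self, propensities, rebuild_interval: int = REBUILD_INTERVAL):
        self.rebuild_interval = rebuild_interval
        self.a = [0.0] * len(propensities)
        self.groups: dict[int, list[int]] = {}
        self.sums: dict[int, float] = {}
        self.pos: list[tuple[int, int] | None] = [None] * len(propensities)
        self.a_total = 0.0
        self._ops = 0
        for i, a in enumerate(propensities):
            self.update(i, a)
        self.rebuild()

    @staticmethod
    def group_of(a: float) -> int:
        # frexp(a) = (m, e) with m in [0.5, 1): a in [2^(e-1), 2^e) -> group e
        return math.frexp(a)[1]

    def update(self, cid: int, a_new: float) -> None:
        """Move channel ``cid`` to the bracket of ``a_new``; adjust sums."""
        if a_new < 0.0:
            raise ValueError("propensity must be >= 0")
        if a_new < MIN_PROPENSITY:
            a_new = 0.0
        a_old = self.a[cid]
        if a_new == a_old:
            return
        self.a[cid] = a_new
        self.a_total += a_new - a_old
        old_pos = self.pos[cid]
        g_new = self.group_of(a_new) if a_new > 0.0 else None
        if old_pos is not None:
            g_old, idx = old_pos
            if g_old == g_new:
                self.sums[g_old] += a_new - a_old
                self._maybe_rebuild()
                return
            members = self.groups[g_old]
            last = members[-1]
            members[idx] = last
            self.pos[last] = (g_old, idx)
            members.pop()
            self.sums[g_old] -= a_old
            self.pos[cid] = None
        if g_new is not None:
            members = self.groups.setdefault(g_new, [])
            self.pos[cid] = (g_new, len(members))
            members.append(cid)
            self.sums[g_new] = self.sums.get(g_new, 0.0) + a_new
        self._maybe_rebuild()

    def _maybe_rebuild(self) -> None:
        self._ops += 1
        if self._ops >= self.rebuild_interval:
            self.rebuild()

    def rebuild(self) -> None:
        """Exact recomputation of group sums and the total from scratch."""
        self._ops = 0
        self.sums = {g: math.fsum(self.a[c] for c in members)
                     for g, members in self.groups.items() if members}
        self.groups = {g: m for g, m in self.groups.items() if m}
        self.a_total = math.fsum(self.sums.values())

    def select(self, rng) -> int:
        """Draw a channel index with probability proportional to its propensity."""
        if self.a_total <= 0.0:
            raise NoEventError("no channel can fire (total propensity is zero)")
        r = rng.random() * self.a_total
        chosen = None
        acc = 0.0
        for g, s in self.sums.items():
            acc += s
            if r < acc:
                chosen = g
                break
        if chosen is None:  # fp residue: take the last non-empty group
            chosen = g
        members = self.groups[chosen]
        cap = 2.0 ** chosen
        n = len(members)
        a = self.a
        rnd = rng.random
        for _ in range(MAX_REJECTIONS):
            u = rnd() * n
            idx = int(u)
            cid = members[idx]
            if (u - idx) * cap < a[cid]:
                return cid
        raise CRConsistencyError("rejection loop exceeded the guard limit")


# ---------------------------------------------------------------------------
# event loop
# ---------------------------------------------------------------------------

class SSACore:
    """Exact SSA event loop over a fixed channel list.

    Owns the integer state vector, the CR structure and the clamp mask.
    ``advance_to`` applies events while the next event time is at or before
    the target, then sets the clock to the target (the state between events
    is constant).  Randomness comes from a NumPy ``Generator`` seeded per
    run (MT19937).
    """

    def __init__(self, channels, n_flat: int, rng,
                 rebuild_interval: int = REBUILD_INTERVAL):
        self.channels = list(channels)
        self._consumers = build_dependency_graph(self.channels, n_flat)
        self.x = [0] * n_flat
        self.clamped = [False] * n_flat
        self.rng = rng
        self.t = 0.0
        self.events_fired = 0
        self._rebuild_interval = rebuild_interval
        self.cr: CRStructure | None = None

    def initialize(self) -> None:
        """(Re)compute all propensities and build the CR structure."""
        x = self.x
        self.cr = CRStructure([ch.propensity(x) for ch in self.channels],
                              self._rebuild_interval)

    def set_count(self, flat_ix: int, n: int) -> None:
        if n < 0:
            raise ValueError("molecule counts must be >= 0")
        self.x[flat_ix] = n
        if self.cr is not None:
            self._refresh(flat_ix)

    def _refresh(self, flat_ix: int) -> None:
        for cid in self._consumers[flat_ix]:
            self.cr.update(cid, self.channels[cid].propensity(self.x))

    def step(self):
        """Fire exactly one event; returns the channel fired, or None when no
        channel can fire.  The clock advances to the event time."""
        if self.cr is None:
            self.initialize()
        if self.cr.a_total <= 0.0:
            return None
        u = self.rng.random()
        while u <= 0.0:
            u = self.rng.random()
        self.t += -math.log(u) / self.cr.a_total
        ch = self.channels[self.cr.select(self.rng)]
        if ch.kind == "diffusion":
            d = 0
            if len(ch.cum_rates) > 1:
                d = min(bisect_right(ch.cum_rates,
                                     self.rng.random() * ch.total_rate),
                        len(ch.cum_rates) - 1)
            src, tgt = ch.source, ch.targets[d]
            if not self.clamped[src]:
                self.x[src] -= 1
            if not self.clamped[tgt]:
                self.x[tgt] += 1
            deps = ch.dependents_by_dir[d]
        else:
            for ix, delta in ch.deltas:
                if not self.clamped[ix]:
                    self.x[ix] += delta
            deps = ch.dependents
        for dep in deps:
            self.cr.update(dep, self.channels[dep].propensity(self.x))
        self.events_fired += 1
        return ch

    def advance_to(self, t_target: float) -> None:
        if self.cr is None:
            self.initialize()
        x = self.x
        clamped = self.clamped
        cr = self.cr
        channels = self.channels
        rng = self.rng
        rnd = rng.random
        log = math.log
        t = self.t
        fired = 0
        while True:
            a_total = cr.a_total
            if a_total <= 0.0:
                t = t_target
                break
            u = rnd()
            while u <= 0.0:  # open-interval uniform
                u = rnd()
            t_next = t - log(u) / a_total
            if t_next > t_target:
                t = t_target
                break
            t = t_next
            ch = channels[cr.select(rng)]
            if ch.kind == "diffusion":
                src = ch.source
                cum = ch.cum_rates
                if len(cum) == 1:
                    d = 0
                else:
                    d = bisect_right(cum, rnd() * ch.total_rate)
                    if d >= len(cum):
                        d = len(cum) - 1
                tgt = ch.targets[d]
                if not clamped[src]:
                    x[src] -= 1
                if not clamped[tgt]:
                    x[tgt] += 1
                deps = ch.dependents_by_dir[d]
            else:
                for ix, delta in ch.deltas:
                    if not clamped[ix]:
                        x[ix] += delta
                deps = ch.dependents
            for dep in deps:
                cr.update(dep, channels[dep].propensity(x))
            fired += 1
        self.t = t
        self.events_fired += fired
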