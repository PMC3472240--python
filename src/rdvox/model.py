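"""Chemical model description: species, reactions, diffusion rules, systems.

The chemical model is described completely separately from any geometry.
Reaction and diffusion rules are grouped into *volume systems*, and surface
reactions into *surface systems*; geometry compartments and patches attach
these system ids, and :func:`apply_systems` resolves which rules are active
at each location.

Units are SI internally: rate constants of a volume reaction of order ``n``
are in (M^(1-n))/s (so 1/s for first order, 1/(M.s) for second order),
diffusion coefficients in m^2/s.  Reversible reactions are expressed as two
irreversible records (:meth:`Model.add_reversible_reaction`).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "Species", "Reaction", "SurfaceReaction", "DiffusionRule",
    "VolumeSystem", "SurfaceSystem", "Model", "BoundModel",
    "validate_model", "reaction_order", "apply_systems", "BindingError",
]

MAX_VOLUME_ORDER = 3
MAX_SURFACE_ORDER = 2


class BindingError(ValueError):
    """A geometry references a system id not defined in the model."""


def _as_multiset(spec) -> dict[str, int]:
    """Accept a list with repeats or a mapping species->stoichiometry."""
    if spec is None:
        return {}
    if isinstance(spec, Mapping):
        out = {str(k): int(v) for k, v in spec.items() if int(v) != 0}
    else:
        out = dict(Counter(str(s) for s in spec))
    if any(v < 0 for v in out.values()):
        raise ValueError("stoichiometries must be non-negative")
    return out


@dataclass(frozen=True)
class Species:
    id: str
    notes: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("species id must be non-empty")


@dataclass
class Reaction:
    """An irreversible volume reaction with mass-action kinetics.

    ``lhs``/``rhs`` are multisets (species id -> stoichiometry); ``k`` is the
    macroscopic rate constant in (M^(1-order))/s.
    """

    id: str
    lhs: dict[str, int]
    rhs: dict[str, int]
    k: float

    def __post_init__(self):
        self.lhs = _as_multiset(self.lhs)
        self.rhs = _as_multiset(self.rhs)
        if self.k < 0:
            raise ValueError(f"reaction {self.id!r}: k must be >= 0")

    @property
    def order(self) -> int:
        return sum(self.lhs.values())


@dataclass
class SurfaceReaction:
    """A reaction on a patch, possibly coupling inner and outer volumes.

    Reactants and products are each partitioned into inner-volume, surface
    and outer-volume multisets.  At most second order; must either involve a
    surface-located participant or couple the inner and outer volumes.
    """

    id: str
    k: float
    lhs_inner: dict[str, int] = field(default_factory=dict)
    lhs_surface: dict[str, int] = field(default_factory=dict)
    lhs_outer: dict[str, int] = field(default_factory=dict)
    rhs_inner: dict[str, int] = field(default_factory=dict)
    rhs_surface: dict[str, int] = field(default_factory=dict)
    rhs_outer: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("lhs_inner", "lhs_surface", "lhs_outer",
                     "rhs_inner", "rhs_surface", "rhs_outer"):
            setattr(self, name, _as_multiset(getattr(self, name)))
        if self.k < 0:
            raise ValueError(f"surface reaction {self.id!r}: k must be >= 0")

    @property
    def order(self) -> int:
        return (sum(self.lhs_inner.values()) + sum(self.lhs_surface.values())
                + sum(self.lhs_outer.values()))

    def touches_surface(self) -> bool:
        return bool(self.lhs_surface or self.rhs_surface)

    def couples_volumes(self) -> bool:
        return bool((self.lhs_inner or self.rhs_inner)
                    and (self.lhs_outer or self.rhs_outer))


@dataclass
class DiffusionRule:
    """Free diffusion of one species with coefficient ``D`` (m^2/s)."""

    id: str
    species: str
    D: float

    def __post_init__(self):
        if self.D < 0:
            raise ValueError(f"diffusion rule {self.id!r}: D must be >= 0")


@dataclass
class VolumeSystem:
    id: str
    reactions: set[str] = field(default_factory=set)
    diffusions: set[str] = field(default_factory=set)


@dataclass
class SurfaceSystem:
    id: str
    reactions: set[str] = field(default_factory=set)


class Model:
    """Registry of species, rules and the systems that group them."""

    def __init__(self) -> None:
        self.species: dict[str, Species] = {}
        self.reactions: dict[str, Reaction] = {}
        self.surface_reactions: dict[str, SurfaceReaction] = {}
        self.diffusion_rules: dict[str, DiffusionRule] = {}
        self.volume_systems: dict[str, VolumeSystem] = {}
        self.surface_systems: dict[str, SurfaceSystem] = {}

    # -- construction -------------------------------------------------------

    def add_species(self, sid: str, notes: str = "") -> Species:
        if sid in self.species:
            raise ValueError(f"duplicate species id {sid!r}")
        sp = Species(sid, notes)
        self.species[sid] = sp
        return sp

    def add_volume_system(self, vid: str) -> VolumeSystem:
        if vid in self.volume_systems:
            raise ValueError(f"duplicate volume system id {vid!r}")
        vsys = VolumeSystem(vid)
        self.volume_systems[vid] = vsys
        return vsys

    def add_surface_system(self, sid: str) -> SurfaceSystem:
        if sid in self.surface_systems:
            raise ValueError(f"duplicate surface system id {sid!r}")
        ssys = SurfaceSystem(sid)
        self.surface_systems[sid] = ssys
        return ssys

    def add_reaction(self, rid: str, lhs, rhs, k: float, vsys: str) -> Reaction:
        if rid in self.reactions or rid in self.surface_reactions:
            raise ValueError(f"duplicate reaction id {rid!r}")
        r = Reaction(rid, _as_multiset(lhs), _as_multiset(rhs), k)
        self.reactions[rid] = r
        self._vsys(vsys).reactions.add(rid)
        return r

    def add_reversible_reaction(self, rid: str, lhs, rhs, kf: float, kb: float,
                                vsys: str) -> tuple[Reaction, Reaction]:
        """A reversible pair, stored as two irreversible reactions."""
        fwd = self.add_reaction(rid + "_fwd", lhs, rhs, kf, vsys)
        bwd = self.add_reaction(rid + "_bwd", rhs, lhs, kb, vsys)
        return fwd, bwd

    def add_surface_reaction(self, rid: str, k: float, ssys: str, **parts) -> SurfaceReaction:
        if rid in self.reactions or rid in self.surface_reactions:
            raise ValueError(f"duplicate reaction id {rid!r}")
        r = SurfaceReaction(rid, k, **parts)
        self.surface_reactions[rid] = r
        self._ssys(ssys).reactions.add(rid)
        return r

    def add_diffusion(self, did: str, species: str, D: float, vsys: str) -> DiffusionRule:
        if did in self.diffusion_rules:
            raise ValueError(f"duplicate diffusion rule id {did!r}")
        d = DiffusionRule(did, species, D)
        self.diffusion_rules[did] = d
        self._vsys(vsys).diffusions.add(did)
        return d

    def _vsys(self, vid: str) -> VolumeSystem:
        if vid not in self.volume_systems:
            self.add_volume_system(vid)
        return self.volume_systems[vid]

    def _ssys(self, sid: str) -> SurfaceSystem:
        if sid not in self.surface_systems:
            self.add_surface_system(sid)
        return self.surface_systems[sid]

    def validate(self) -> list[str]:
        return validate_model(self)


def reaction_order(reaction: Reaction | SurfaceReaction) -> int:
    """Total reactant stoichiometry (invariant under reactant permutation)."""
    return reaction.order


def validate_model(model: Model) -> list[str]:
    """Collect model violations; an empty list means the model is usable.

    Solvers refuse to build on a non-empty report.  A model needs at least
    one declared species; every species referenced by a rule must be
    declared; reaction orders must be within the supported range (volume
    reactions up to order 3, surface reactions up to order 2).
    """
    issues: list[str] = []
    if not model.species:
        issues.append("no species declared (at least one chemical species is required)")

    def check_refs(rid: str, multiset: dict[str, int]):
        for sid in multiset:
            if sid not in model.species:
                issues.append(f"reaction {rid!r}: undeclared species {sid!r}")

    for rid, r in model.reactions.items():
        check_refs(rid, r.lhs)
        check_refs(rid, r.rhs)
        if r.order > MAX_VOLUME_ORDER:
            issues.append(f"reaction {rid!r}: order {r.order} exceeds supported maximum "
                          f"{MAX_VOLUME_ORDER}")
    for rid, r in model.surface_reactions.items():
        for part in (r.lhs_inner, r.lhs_surface, r.lhs_outer,
                     r.rhs_inner, r.rhs_surface, r.rhs_outer):
            check_refs(rid, part)
        if r.order > MAX_SURFACE_ORDER:
            issues.append(f"surface reaction {rid!r}: order {r.order} exceeds supported "
                          f"maximum {MAX_SURFACE_ORDER}")
        if not (r.touches_surface() or r.couples_volumes()):
            issues.append(f"surface reaction {rid!r}: must involve a surface species or "
                          "couple inner and outer volumes")
    for did, d in model.diffusion_rules.items():
        if d.species not in model.species:
            issues.append(f"diffusion rule {did!r}: undeclared species {d.species!r}")
    for vid, vsys in model.volume_systems.items():
        for rid in vsys.reactions:
            if rid not in model.reactions:
                issues.append(f"volume system {vid!r}: unknown reaction {rid!r}")
        for did in vsys.diffusions:
            if did not in model.diffusion_rules:
                issues.append(f"volume system {vid!r}: unknown diffusion rule {did!r}")
    for sid, ssys in model.surface_systems.items():
        for rid in ssys.reactions:
            if rid not in model.surface_reactions:
                issues.append(f"surface system {sid!r}: unknown surface reaction {rid!r}")
    return issues


@dataclass
class BoundModel:
    """A model resolved against a geometry: active rules per location.

    ``comp_reactions``/``comp_diffusions`` map compartment id -> rule list;
    ``patch_reactions`` maps patch id -> surface-reaction list.  Locations
    with no attached systems have empty lists.
    """

    model: Model
    geometry: object
    comp_reactions: dict[str, list[Reaction]]
    comp_diffusions: dict[str, list[DiffusionRule]]
    patch_reactions: dict[str, list[SurfaceReaction]]


def apply_systems(model: Model, geometry) -> BoundModel:
    """Resolve which rules are active in each compartment and patch.

    ``geometry`` may be a :class:`~rdvox.geometry.WellMixedGeometry` or a
    :class:`~rdvox.geometry.Tetmesh`; both expose ``compartments`` and
    ``patches`` dicts whose members carry attached system ids.  Attaching a
    system only where it is needed lets channels be instantiated only in the
    compartments where its reactions can actually occur.
    """
    issues = validate_model(model)
    if issues:
        raise ValueError("invalid model: " + "; ".join(issues))
    comp_reactions: dict[str, list[Reaction]] = {}
    comp_diffusions: dict[str, list[DiffusionRule]] = {}
    patch_reactions: dict[str, list[SurfaceReaction]] = {}
    for cid, comp in geometry.compartments.items():
        reactions: list[Reaction] = []
        diffusions: list[DiffusionRule] = []
        for vid in comp.volume_systems:
            if vid not in model.volume_systems:
                raise BindingError(f"compartment {cid!r}: unknown volume system {vid!r}")
            vsys = model.volume_systems[vid]
            reactions.extend(model.reactions[r] for r in sorted(vsys.reactions))
            diffusions.extend(model.diffusion_rules[d] for d in sorted(vsys.diffusions))
        comp_reactions[cid] = reactions
        comp_diffusions[cid] = diffusions
    for pid, patch in geometry.patches.items():
        sreactions: list[SurfaceReaction] = []
        for sid in patch.surface_systems:
            if sid not in model.surface_systems:
                raise BindingError(f"patch {pid!r}: unknown surface system {sid!r}")
            ssys = model.surface_systems[sid]
            sreactions.extend(model.surface_reactions[r] for r in sorted(ssys.reactions))
        patch_reactions[pid] = sreactions
    return BoundModel(model, geometry, comp_reactions, comp_diffusions, patch_reactions)
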