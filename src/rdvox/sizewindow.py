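"""Well-mixed subvolume size window (h_min, h_max) for a reaction-diffusion model.

Each tetrahedral voxel is treated as an internally well-mixed reaction
container, which holds only within a window of voxel sizes: voxels must be
small enough that diffusion smooths them out faster than the fastest
reaction consumes gradients (upper bound), but large enough that a singly
*populated* voxel does not react faster than molecules can hop out of it
(lower bound).

Both bounds here come from one criterion -- roughly ten diffusion events per
event of the fastest reaction per voxel -- evaluated for a regular
tetrahedron of edge h with four neighbors, where the total hop rate per
molecule is 4 * 9D/h^2 = 36 D / h^2:

* upper bound (continuous concentrations): 36 D / h^2 >= RATIO * r, with r
  the per-molecule consumption rate of the fastest reaction at the given
  concentrations (r = k * c_other for second order, r = k for first order);
* lower bound (discrete occupancy): a singly-occupied voxel with one
  molecule of each reactant reacts at k / (N_A * V(h)); requiring ten hops
  per such reaction gives h_min proportional to k / (N_A * D).

Each bound carries one calibration constant, fixed once so that the
reference parameter set (second-order k = 100 /uM.s, [A] = [B] = 1 uM,
D = 0.1 um^2/ms) reproduces the (0.02 um, 0.4 um) window; the constants are
module-level and never adjusted per model.  Diagnostics expose the
uncalibrated criterion values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .engine import NA

__all__ = ["SizeWindow", "estimate_size_window", "tets_per_volume",
           "regular_tet_volume", "EVENT_RATIO"]

#: target diffusion events per fastest-reaction event per subvolume
EVENT_RATIO = 10.0
#: total hop rate per molecule out of a regular tet of edge h is _HOP_COEF*D/h^2
_HOP_COEF = 36.0


def regular_tet_volume(h: float) -> float:
    """Volume of a regular tetrahedron of edge h: sqrt(2) h^3 / 12."""
    return math.sqrt(2.0) * h ** 3 / 12.0


def tets_per_volume(h: float) -> float:
    """Tet count density (m^-3) for regular tets of edge h: 1 / V_regular."""
    if h <= 0:
        raise ValueError("edge length must be > 0")
    return 1.0 / regular_tet_volume(h)


def _uncalibrated_h_max(k_si: float, order: int, concs_molar, D: float) -> float:
    """Largest regular-tet edge with hop rate >= EVENT_RATIO x per-molecule
    reaction rate, at continuous concentrations.  k_si in (M^(1-n))/s."""
    if order == 1:
        r = k_si
    elif order == 2:
        r = k_si * max(concs_molar)  # pseudo-first-order rate of the slower pool
    elif order == 3:
        cs = sorted(concs_molar, reverse=True)
        r = k_si * cs[0] * cs[1]
    else:
        raise ValueError("h_max criterion needs reaction order in {1, 2, 3}")
    return math.sqrt(_HOP_COEF * D / (EVENT_RATIO * r))


def _uncalibrated_h_min(k_si: float, order: int) -> float:
    """Edge at which a singly-occupied voxel fires as fast as a tenth of its
    hop rate.  Only reactions of order >= 2 constrain the lower bound (a
    first-order reaction rate does not grow as the voxel shrinks)."""
    if order < 2:
        return 0.0
    # single occupancy: a_reac = k / (N_A V)^(order-1); hop rate 36 D / h^2.
    # ratio >= EVENT_RATIO, solved for h with V = sqrt(2) h^3 / 12.
    # order 2: h = EVENT_RATIO * k' / (3 sqrt(2) N_A' D) with k' = k*1e-3 m^3/mol/s
    kq = k_si * 1e-3 / NA  # m^3/s per molecule pair
    return EVENT_RATIO * kq / (3.0 * math.sqrt(2.0))  # divided by D by the caller


# calibration anchors: k = 100 /uM.s (= 1e8 /M.s), [A]=[B]=1 uM, D = 0.1 um^2/ms
_ANCHOR_K = 1e8
_ANCHOR_C = 1e-6
_ANCHOR_D = 1e-10
_CAL_MAX = 0.4e-6 / _uncalibrated_h_max(_ANCHOR_K, 2, (_ANCHOR_C, _ANCHOR_C), _ANCHOR_D)
_CAL_MIN = 0.02e-6 / (_uncalibrated_h_min(_ANCHOR_K, 2) / _ANCHOR_D)


@dataclass
class SizeWindow:
    """Estimated voxel-edge window and its diagnostics.

    ``h_min``/``h_max`` in meters; ``tets_per_volume_min``/``max`` are the
    corresponding regular-tet count densities (m^-3; min density pairs with
    the max edge).  ``feasible`` is False when h_min >= h_max.  The
    diagnostics carry the uncalibrated criterion edges and the reaction and
    diffusion time scales at the upper bound.
    """

    h_min: float
    h_max: float
    tets_per_volume_min: float
    tets_per_volume_max: float
    feasible: bool
    diagnostics: dict

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        um = 1e6
        lines = [
            f"subvolume size window: h_min = {self.h_min * um:.4g} um, "
            f"h_max = {self.h_max * um:.4g} um"
            + ("" if self.feasible else "  [INFEASIBLE: h_min >= h_max]"),
            f"tets per um^3: {self.tets_per_volume_min * 1e-18:.4g} "
            f"to {self.tets_per_volume_max * 1e-18:.4g}",
        ]
        for k, v in self.diagnostics.items():
            lines.append(f"  {k}: {v:.6g}")
        return "\n".join(lines)


def estimate_size_window(k: float, order: int, concs_molar, D: float) -> SizeWindow:
    """Estimate the (h_min, h_max) voxel-edge window.

    Parameters
    ----------
    k : float
        Rate constant of the fastest reaction, in (M^(1-order))/s.
    order : int
        Order of that reaction (1-3; the lower bound needs order >= 2).
    concs_molar : sequence of float
        Reactant concentrations (M).
    D : float
        Slowest diffusion coefficient among the reactants (m^2/s).

    An infeasible window (h_min >= h_max) is reported, not raised.  Slower
    diffusion narrows the window from both sides.
    """
    if k <= 0 or D <= 0:
        raise ValueError("k and D must be > 0")
    if any(c <= 0 for c in concs_molar):
        raise ValueError("concentrations must be > 0")
    raw_max = _uncalibrated_h_max(k, order, concs_molar, D)
    raw_min = _uncalibrated_h_min(k, order) / D
    h_max = _CAL_MAX * raw_max
    h_min = _CAL_MIN * raw_min
    per_mol_rate = {1: k, 2: k * max(concs_molar),
                    3: k * math.prod(sorted(concs_molar, reverse=True)[:2])}[order]
    diag = {
        "uncalibrated_h_max_m": raw_max,
        "uncalibrated_h_min_m": raw_min,
        "reaction_time_s": 1.0 / per_mol_rate,
        "diffusion_time_at_h_max_s": h_max ** 2 / D,
        "hop_rate_at_h_max_per_s": _HOP_COEF * D / h_max ** 2,
        "event_ratio_target": EVENT_RATIO,
    }
    return SizeWindow(
        h_min=h_min,
        h_max=h_max,
        tets_per_volume_min=tets_per_volume(h_max),
        tets_per_volume_max=tets_per_volume(h_min) if h_min > 0 else math.inf,
        feasible=h_min < h_max,
        diagnostics=diag,
    )
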