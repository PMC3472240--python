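"""Executable validation standard: analytic solutions and coverage harness.

The solvers are validated against a representative set of isolated reaction,
diffusion and reaction-diffusion systems with known closed-form solutions:

* five well-mixed reaction systems (first-order irreversible, first-order
  reversible, second-order with equal and with unequal reactant
  concentrations, and production-degradation), scored by 95%-CI coverage of
  the analytic mean at 110 measurement points in total (20+14+40+20+16);
* diffusion cases on tetrahedral meshes (3D spread from a point source, 1D
  plane source / clamped boundary / constant influx in a tube, and a
  degradation-diffusion front), scored by profile deviation from the closed
  forms since binned concentrations at finite voxel volumes do not admit the
  same point-wise statistical comparison;
* reaction-diffusion controls (diffusion added to a uniform first-order
  decay must not change the mean; a zero-order + second-order birth-death
  system keeps its master-equation stationary distribution when voxels
  exceed the minimum well-mixed size).

All model parameters are frozen module-level constants so the suite is a
fixed, reproducible standard; randomness enters only through the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .engine import NA
from .geometry import Tetmesh, WellMixedCompartment, WellMixedGeometry, \
    generate_box_tetmesh
from .model import Model, apply_systems
from .solvers import TetexactSolver, WmdirectSolver, wmdirect_run

__all__ = [
    "first_order_decay", "first_order_reversible", "second_order_equal",
    "second_order_unequal", "production_degradation_pmf",
    "point_source_3d", "plane_source_tube", "clamped_semi_infinite",
    "constant_influx_tube", "degradation_interface",
    "spatial_binning", "CoverageReport", "run_validation_suite",
    "run_decay_diffusion_control", "run_stationary_rd_case",
    "run_plane_source_case", "run_clamped_case", "run_influx_case",
    "run_degradation_case", "run_point_source_case", "tube_mesh",
]


# ---------------------------------------------------------------------------
# closed-form reaction solutions
# ---------------------------------------------------------------------------

def first_order_decay(n0: float, k: float, t):
    """Mean and sd of the count under A -> 0 (binomial survival).

    mean = n0 e^{-kt}; sd = sqrt(n0 e^{-kt} (1 - e^{-kt})).
    """
    t = np.asarray(t, dtype=float)
    p = np.exp(-k * t)
    return n0 * p, np.sqrt(n0 * p * (1.0 - p))


def first_order_reversible(a0: float, b0: float, kf: float, kb: float, t):
    """Mean counts of A and B under A <-> B (exponential relaxation to the
    k_b/(k_f+k_b) split of the conserved total)."""
    t = np.asarray(t, dtype=float)
    total = a0 + b0
    a_eq = total * kb / (kf + kb)
    a = a_eq + (a0 - a_eq) * np.exp(-(kf + kb) * t)
    return a, total - a


def second_order_equal(c0: float, k: float, t):
    """Concentration under A + B -> C with equal concentrations:
    1/c(t) = 1/c0 + k t."""
    t = np.asarray(t, dtype=float)
    return 1.0 / (1.0 / c0 + k * t)


def second_order_unequal(ca0: float, cb0: float, k: float, t):
    """Concentrations under A + B -> C with unequal concentrations.

    The difference Delta = cA - cB is conserved and
    ln(cA/cB) = ln(cA0/cB0) + k*Delta*t.
    """
    t = np.asarray(t, dtype=float)
    delta = ca0 - cb0
    if delta == 0.0:
        c = second_order_equal(ca0, k, t)
        return c, c
    ratio = (ca0 / cb0) * np.exp(k * delta * t)  # cA/cB
    cb = delta / (ratio - 1.0)
    return cb * ratio, cb


def production_degradation_pmf(lam: float, n):
    """Stationary distribution of 0 -> A (propensity a_p), A -> 0 (rate k):
    Poisson with lambda = a_p / k."""
    return stats.poisson.pmf(np.asarray(n), lam)


# ---------------------------------------------------------------------------
# closed-form diffusion solutions (all return molar concentrations)
# ---------------------------------------------------------------------------

def _to_molar(number_density_m3):
    return number_density_m3 / (NA * 1e3)


def point_source_3d(n0: float, D: float, r, t: float):
    """3D diffusion from an instantaneous point source in an infinite volume:
    C(r,t) = n0 (4 pi D t)^{-3/2} exp(-r^2 / 4Dt)."""
    if D <= 0 or t <= 0:
        raise ValueError("D and t must be > 0")
    r = np.asarray(r, dtype=float)
    dens = n0 * (4.0 * np.pi * D * t) ** -1.5 * np.exp(-(r ** 2) / (4.0 * D * t))
    return _to_molar(dens)


def plane_source_tube(n0: float, area: float, L: float, D: float, x, t: float,
                      n_images: int = 12):
    """1D diffusion in a finite tube [0, L] (reflective ends), all molecules
    initially at the x = 0 end: image-source series of the half-Gaussian."""
    if D <= 0 or t <= 0:
        raise ValueError("D and t must be > 0")
    x = np.asarray(x, dtype=float)
    s = np.zeros_like(x)
    norm = 1.0 / math.sqrt(4.0 * math.pi * D * t)
    for nimg in range(-n_images, n_images + 1):
        s += np.exp(-((x - 2 * nimg * L) ** 2) / (4 * D * t))
        s += np.exp(-((x + 2 * nimg * L) ** 2) / (4 * D * t))
    return _to_molar(n0 / area * norm * s)


def clamped_semi_infinite(c0: float, D: float, x, t: float):
    """Semi-infinite tube with the concentration clamped to c0 at x = 0:
    C(x,t) = c0 erfc(x / (2 sqrt(Dt)))."""
    if D <= 0 or t <= 0:
        raise ValueError("D and t must be > 0")
    x = np.asarray(x, dtype=float)
    return c0 * special.erfc(x / (2.0 * math.sqrt(D * t)))


def _ierfc(z):
    return np.exp(-z ** 2) / math.sqrt(math.pi) - z * special.erfc(z)


def constant_influx_tube(j_end: float, area: float, L: float, D: float, x,
                         t: float, n_images: int = 6):
    """Finite tube [0, L] with constant, equal influx of ``j_end``
    molecules/s at both ends: superposed constant-flux solutions with
    mirror images (source images land on every integer multiple of L)."""
    if D <= 0 or t <= 0:
        raise ValueError("D and t must be > 0")
    x = np.asarray(x, dtype=float)
    sig = 2.0 * math.sqrt(D * t)
    s = np.zeros_like(x)
    for m in range(-n_images, n_images + 1):
        s += _ierfc(np.abs(x - m * L) / sig)
    # 2 F sqrt(t/D) ierfc(..) per image, with boundary flux F = j_end / area
    dens = 2.0 * (j_end / area) * math.sqrt(t / D) * s
    return _to_molar(dens)


def degradation_interface(c0: float, D: float, xi, t: float):
    """Degradation-diffusion front: two reactants that annihilate on contact
    diffuse from opposite halves of a tube; on the initially occupied side
    the concentration is C = c0 erf(xi / (2 sqrt(Dt))) with xi the distance
    from the (zero-clamped) center, while the simulation remains far from
    the tube ends."""
    if D <= 0 or t <= 0:
        raise ValueError("D and t must be > 0")
    xi = np.asarray(xi, dtype=float)
    return c0 * special.erf(xi / (2.0 * math.sqrt(D * t)))


# ---------------------------------------------------------------------------
# spatial binning
# ---------------------------------------------------------------------------

def spatial_binning(mesh: Tetmesh, counts, *, axis: int | None = 0,
                    n_bins: int = 10, center=None, extent=None) -> pd.DataFrame:
    """Bin per-tet counts into axial slabs (or radial shells) and return the
    mean concentration per bin.

    Concentration per bin = (sum of counts) / (N_A * sum of tet volumes) of
    the tets whose *barycenter* falls in the bin, reported at the bin-center
    coordinate.  Empty bins are flagged with NaN concentration.

    Parameters
    ----------
    axis : 0, 1 or 2 for axial binning; None for radial binning around
        ``center``.
    extent : (lo, hi), optional
        Coordinate range covered by the bins; defaults to the barycenter
        range.  Pass the mesh extent to align bins with structured-mesh
        slabs.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (mesh.n_tets,):
        raise ValueError("counts must be per-tet")
    if axis is None:
        if center is None:
            raise ValueError("radial binning needs a center")
        coord = np.linalg.norm(mesh.tet_barycenters - np.asarray(center), axis=1)
        lo = 0.0
    else:
        coord = mesh.tet_barycenters[:, axis]
        lo = coord.min()
    hi = coord.max()
    if extent is not None:
        lo, hi = extent
    edges = np.linspace(lo, hi * (1 + 1e-12), n_bins + 1)
    which = np.clip(np.digitize(coord, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        vol = mesh.tet_volumes[sel].sum()
        cnt = counts[sel].sum()
        conc = cnt / (NA * vol * 1e3) if vol > 0 else np.nan
        rows.append((0.5 * (edges[b] + edges[b + 1]), cnt, vol, conc, not sel.any()))
    return pd.DataFrame(rows, columns=["coord", "count", "volume",
                                       "concentration", "empty"])


# ---------------------------------------------------------------------------
# well-mixed validation suite
# ---------------------------------------------------------------------------

#: compartment volume of every well-mixed validation model (m^3); 1 um^3
WM_VOLUME = 1e-18

#: frozen parameters of the five well-mixed validation models
WM_MODELS = {
    "first_order_irreversible": dict(
        n0=1000, k=1.0, times=np.linspace(0.25, 5.0, 20), replicates=1000),
    "first_order_reversible": dict(
        a0=600, b0=0, kf=0.4, kb=0.2, times=np.linspace(0.5, 7.0, 14),
        replicates=100),
    "second_order_equal": dict(
        n0=1000, k=1e6, times=np.linspace(0.025, 1.0, 40), replicates=100),
    "second_order_unequal": dict(
        na0=1200, nb0=800, k=1e6, times=np.linspace(0.1, 1.0, 10),
        replicates=100),
    "production_degradation": dict(
        lam=20.0, kdeg=1.0, burn_in=10.0, n_samples=30, sample_dt=1.0,
        bins=np.arange(12, 28), replicates=100),
}


@dataclass
class CoverageReport:
    """95%-CI coverage of analytic means across the validation models."""

    models: dict[str, dict] = field(default_factory=dict)
    seed: int | None = None

    def add(self, name: str, covered: int, total: int, detail=None) -> None:
        self.models[name] = {"covered": int(covered), "total": int(total),
                             "detail": detail}

    @property
    def covered(self) -> int:
        return sum(m["covered"] for m in self.models.values())

    @property
    def total(self) -> int:
        return sum(m["total"] for m in self.models.values())

    @property
    def fraction(self) -> float:
        return self.covered / self.total if self.total else float("nan")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "models": {k: {"covered": v["covered"], "total": v["total"]}
                       for k, v in self.models.items()},
            "covered": self.covered,
            "total": self.total,
            "fraction": self.fraction,
        }


def _ci_covers(values: np.ndarray, target: float, alpha: float = 0.05) -> bool:
    """Does the t-distribution CI of the mean of ``values`` contain target?"""
    n = len(values)
    m = values.mean()
    se = values.std(ddof=1) / math.sqrt(n)
    half = stats.t.ppf(1.0 - alpha / 2.0, n - 1) * se
    return abs(m - target) <= half


def _wm_bound(build):
    model, geom, init = build()
    return apply_systems(model, geom), init


def _build_decay(k):
    model = Model()
    model.add_species("A")
    model.add_reaction("deg", ["A"], [], k, "vsys")
    geom = WellMixedGeometry()
    geom.add_compartment(WellMixedCompartment("comp", WM_VOLUME, ("vsys",)))
    return model, geom


def run_validation_suite(seed: int, rate_scale: float = 1.0,
                         replicate_scale: float = 1.0) -> CoverageReport:
    """Run the five well-mixed models and score 95%-CI coverage.

    ``rate_scale`` multiplies every rate constant while leaving the analytic
    references untouched -- a deliberate-fault control (1.5 collapses the
    coverage).  ``replicate_scale`` scales the replicate counts (default
    uses the standard 1000/100).
    """
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(5)
    report = CoverageReport(seed=seed)

    # -- 1. first-order irreversible ----------------------------------------
    p = WM_MODELS["first_order_irreversible"]
    reps = max(2, int(p["replicates"] * replicate_scale))
    model, geom = _build_decay(p["k"] * rate_scale)
    bound = apply_systems(model, geom)
    counts = np.empty((reps, len(p["times"])))
    for rep, s in enumerate(kids[0].spawn(reps)):
        tr = wmdirect_run(bound, {("comp", "A"): p["n0"]}, p["times"], seed=s,
                          replicate=rep)
        counts[rep] = tr.counts[:, 0, 0]
    mean_ref, _ = first_order_decay(p["n0"], p["k"], p["times"])
    cov = sum(_ci_covers(counts[:, i], mean_ref[i]) for i in range(len(p["times"])))
    report.add("first_order_irreversible", cov, len(p["times"]))

    # -- 2. first-order reversible ------------------------------------------
    p = WM_MODELS["first_order_reversible"]
    reps = max(2, int(p["replicates"] * replicate_scale))
    model = Model()
    model.add_species("A")
    model.add_species("B")
    model.add_reversible_reaction("iso", ["A"], ["B"], p["kf"] * rate_scale,
                                  p["kb"] * rate_scale, "vsys")
    geom = WellMixedGeometry()
    geom.add_compartment(WellMixedCompartment("comp", WM_VOLUME, ("vsys",)))
    bound = apply_systems(model, geom)
    counts = np.empty((reps, len(p["times"])))
    for rep, s in enumerate(kids[1].spawn(reps)):
        tr = wmdirect_run(bound, {("comp", "A"): p["a0"], ("comp", "B"): p["b0"]},
                          p["times"], seed=s, replicate=rep)
        counts[rep] = tr.counts[:, 0, 0]  # species A
    a_ref, _ = first_order_reversible(p["a0"], p["b0"], p["kf"], p["kb"], p["times"])
    cov = sum(_ci_covers(counts[:, i], a_ref[i]) for i in range(len(p["times"])))
    report.add("first_order_reversible", cov, len(p["times"]))

    # -- 3. second-order, equal concentrations -------------------------------
    p = WM_MODELS["second_order_equal"]
    reps = max(2, int(p["replicates"] * replicate_scale))
    model = Model()
    for s_ in ("A", "B", "C"):
        model.add_species(s_)
    model.add_reaction("bind", ["A", "B"], ["C"], p["k"] * rate_scale, "vsys")
    geom = WellMixedGeometry()
    geom.add_compartment(WellMixedCompartment("comp", WM_VOLUME, ("vsys",)))
    bound = apply_systems(model, geom)
    counts = np.empty((reps, len(p["times"])))
    for rep, s in enumerate(kids[2].spawn(reps)):
        tr = wmdirect_run(bound, {("comp", "A"): p["n0"], ("comp", "B"): p["n0"]},
                          p["times"], seed=s, replicate=rep)
        counts[rep] = tr.counts[:, 0, 0]
    c0 = p["n0"] / (NA * WM_VOLUME * 1e3)
    ref = second_order_equal(c0, p["k"], p["times"]) * NA * WM_VOLUME * 1e3
    cov = sum(_ci_covers(counts[:, i], ref[i]) for i in range(len(p["times"])))
    report.add("second_order_equal", cov, len(p["times"]))

    # -- 4. second-order, unequal concentrations -----------------------------
    p = WM_MODELS["second_order_unequal"]
    reps = max(2, int(p["replicates"] * replicate_scale))
    model = Model()
    for s_ in ("A", "B", "C"):
        model.add_species(s_)
    model.add_reaction("bind", ["A", "B"], ["C"], p["k"] * rate_scale, "vsys")
    geom = WellMixedGeometry()
    geom.add_compartment(WellMixedCompartment("comp", WM_VOLUME, ("vsys",)))
    bound = apply_systems(model, geom)
    # both source species tracked at each time: mean counts are linear
    # statistics, so their t-CIs are unbiased for the analytic means
    counts = np.empty((reps, 2, len(p["times"])))
    for rep, s in enumerate(kids[3].spawn(reps)):
        tr = wmdirect_run(bound, {("comp", "A"): p["na0"], ("comp", "B"): p["nb0"]},
                          p["times"], seed=s, replicate=rep)
        counts[rep, 0] = tr.counts[:, 0, 0]
        counts[rep, 1] = tr.counts[:, 1, 0]
    ca0 = p["na0"] / (NA * WM_VOLUME * 1e3)
    cb0 = p["nb0"] / (NA * WM_VOLUME * 1e3)
    ca, cb = second_order_unequal(ca0, cb0, p["k"], p["times"])
    refs = np.stack([ca, cb]) * NA * WM_VOLUME * 1e3
    cov = sum(_ci_covers(counts[:, j, i], refs[j, i])
              for j in range(2) for i in range(len(p["times"])))
    report.add("second_order_unequal", cov, 2 * len(p["times"]))

    # -- 5. production-degradation stationary distribution -------------------
    p = WM_MODELS["production_degradation"]
    reps = max(2, int(p["replicates"] * replicate_scale))
    a_prod = p["lam"] * p["kdeg"]  # molecules/s
    k0 = a_prod / (NA * WM_VOLUME * 1e3)  # zero-order k in M/s
    model = Model()
    model.add_species("A")
    model.add_reaction("prod", [], ["A"], k0 * rate_scale, "vsys")
    model.add_reaction("deg", ["A"], [], p["kdeg"] * rate_scale, "vsys")
    geom = WellMixedGeometry()
    geom.add_compartment(WellMixedCompartment("comp", WM_VOLUME, ("vsys",)))
    bound = apply_systems(model, geom)
    times = p["burn_in"] + p["sample_dt"] * np.arange(p["n_samples"])
    bins = p["bins"]
    freqs = np.empty((reps, len(bins)))
    for rep, s in enumerate(kids[4].spawn(reps)):
        tr = wmdirect_run(bound, {("comp", "A"): int(round(p["lam"]))}, times,
                          seed=s, replicate=rep)
        samples = tr.counts[:, 0, 0]
        freqs[rep] = [(samples == b).mean() for b in bins]
    pmf = production_degradation_pmf(p["lam"], bins)
    cov = sum(_ci_covers(freqs[:, i], pmf[i]) for i in range(len(bins)))
    report.add("production_degradation", cov, len(bins))
    return report


# ---------------------------------------------------------------------------
# spatial validation cases
# ---------------------------------------------------------------------------

def tube_mesh(n_slabs: int = 16, slab: float = 0.25e-6, width: float = 0.25e-6,
              vsys=("vsys",)) -> Tetmesh:
    """A long box mesh (aspect >= 10:1 by default) standing in for a tube;
    the radial symmetry of the 1D solutions is exploited by axial binning."""
    mesh = generate_box_tetmesh((n_slabs * slab, width, width), (n_slabs, 1, 1))
    mesh.add_compartment("cyt", range(mesh.n_tets), vsys)
    return mesh


def _diffusion_model(D: float, extra=None) -> Model:
    model = Model()
    model.add_species("A")
    model.add_diffusion("diff_A", "A", D, "vsys")
    if extra:
        extra(model)
    return model


#: frozen spatial-case parameters: D = 10 um^2/s, 0.25 um voxels
SPATIAL = dict(
    D=1e-11, n_slabs=16, slab=0.25e-6, width=0.25e-6,
    times=(6e-3, 18e-3, 40e-3), n_iter=10,
)


def _slab_tets(mesh: Tetmesh, slab_ix: int, slab: float):
    xs = mesh.tet_barycenters[:, 0]
    return np.flatnonzero((xs >= slab_ix * slab) & (xs < (slab_ix + 1) * slab))


def _mean_profiles(run_one, mesh, times, n_iter, seed, n_bins):
    ss = np.random.SeedSequence(seed)
    acc = np.zeros((len(times), n_bins))
    coords = None
    extent = (0.0, float(mesh.vertices[:, 0].max()))
    for s in ss.spawn(n_iter):
        tr = run_one(s)
        for it in range(len(times)):
            binned = spatial_binning(mesh, tr.counts[it, 0, : mesh.n_tets],
                                     axis=0, n_bins=n_bins, extent=extent)
            acc[it] += binned["concentration"].to_numpy()
            coords = binned["coord"].to_numpy()
    return coords, acc / n_iter


def run_plane_source_case(seed: int, n_iter: int | None = None, n0: int = 1000):
    """All molecules start in the first slab of a finite tube; the axial
    profile is compared with the image-series plane-source solution."""
    p = SPATIAL
    n_iter = n_iter or p["n_iter"]
    mesh = tube_mesh(p["n_slabs"], p["slab"], p["width"])
    model = _diffusion_model(p["D"])
    bound = apply_systems(model, mesh)
    first = _slab_tets(mesh, 0, p["slab"])
    L = p["n_slabs"] * p["slab"]
    area = p["width"] ** 2

    def run_one(s):
        solver = TetexactSolver(bound, seed=s)
        vols = mesh.tet_volumes[first]
        alloc = solver.rng.multinomial(n0, vols / vols.sum())
        for k, nk in zip(first, alloc):
            solver.set_tet_count(int(k), "A", int(nk))
        return solver.sample(p["times"])

    coords, prof = _mean_profiles(run_one, mesh, p["times"], n_iter, seed,
                                  p["n_slabs"])
    analytic = np.stack([plane_source_tube(n0, area, L, p["D"], coords, t)
                         for t in p["times"]])
    return {"coords": coords, "profiles": prof, "analytic": analytic,
            "times": p["times"]}


def run_clamped_case(seed: int, n_iter: int | None = None,
                     clamp_per_tet: int = 40):
    """Concentration clamped at the x=0 border of a tube; profiles compared
    with c0 * erfc(x / 2 sqrt(Dt)) while the far end is still empty."""
    p = SPATIAL
    n_iter = n_iter or p["n_iter"]
    mesh = tube_mesh(p["n_slabs"], p["slab"], p["width"])
    model = _diffusion_model(p["D"])
    bound = apply_systems(model, mesh)
    first = _slab_tets(mesh, 0, p["slab"])
    slab_vol = float(mesh.tet_volumes[first].sum())
    c0 = clamp_per_tet * len(first) / (NA * slab_vol * 1e3)

    def run_one(s):
        solver = TetexactSolver(bound, seed=s)
        for k in first:
            solver.set_tet_count(int(k), "A", clamp_per_tet)
            solver.set_tet_clamped(int(k), "A", True)
        return solver.sample(p["times"])

    coords, prof = _mean_profiles(run_one, mesh, p["times"], n_iter, seed,
                                  p["n_slabs"])
    # clamp is applied over the first slab; measure x from its center
    x0 = coords[0]
    analytic = np.stack([clamped_semi_infinite(c0, p["D"],
                                               np.maximum(coords - x0, 0.0), t)
                         for t in p["times"]])
    return {"coords": coords, "profiles": prof, "analytic": analytic,
            "times": p["times"], "c0": c0}


def run_influx_case(seed: int, n_iter: int | None = None,
                    influx_per_end: float = 5000.0):
    """Constant and equal influx of molecules at both tube ends, realised as
    a clamped precursor P (count 1, only in the end slabs) with a P -> P + A
    reaction; profiles compared with the constant-flux image solution."""
    p = SPATIAL
    n_iter = n_iter or p["n_iter"]
    mesh = tube_mesh(p["n_slabs"], p["slab"], p["width"])
    first = _slab_tets(mesh, 0, p["slab"])
    last = _slab_tets(mesh, p["n_slabs"] - 1, p["slab"])
    k_tet = influx_per_end / len(first)  # first-order in clamped P: a = k * 1

    def extra(model):
        model.add_species("P")
        model.add_reaction("influx", ["P"], ["P", "A"], k_tet, "vsys")

    model = _diffusion_model(p["D"], extra)
    bound = apply_systems(model, mesh)
    L = p["n_slabs"] * p["slab"]
    area = p["width"] ** 2

    def run_one(s):
        solver = TetexactSolver(bound, seed=s)
        for k in np.concatenate([first, last]):
            solver.set_tet_count(int(k), "P", 1)
            solver.set_tet_clamped(int(k), "P", True)
        return solver.sample(p["times"])

    coords, prof = _mean_profiles(run_one, mesh, p["times"], n_iter, seed,
                                  p["n_slabs"])
    analytic = np.stack([constant_influx_tube(influx_per_end, area, L, p["D"],
                                              coords, t)
                         for t in p["times"]])
    return {"coords": coords, "profiles": prof, "analytic": analytic,
            "times": p["times"]}


def run_degradation_case(seed: int, n_iter: int | None = None,
                         n_half: int = 1500, k2: float | None = None):
    """Two reactants diffusing from opposite halves of a tube and
    annihilating on contact (A + B -> 0 with a near-diffusion-limited rate);
    the A profile matches diffusion with a zero clamp at the center,
    C = c0 erf(xi / 2 sqrt(Dt))."""
    p = SPATIAL
    n_iter = n_iter or p["n_iter"]
    mesh = tube_mesh(p["n_slabs"], p["slab"], p["width"])
    half = p["n_slabs"] // 2
    left = np.flatnonzero(mesh.tet_barycenters[:, 0] < half * p["slab"])
    right = np.flatnonzero(mesh.tet_barycenters[:, 0] >= half * p["slab"])
    half_vol = float(mesh.tet_volumes[left].sum())
    c0 = n_half / (NA * half_vol * 1e3)
    if k2 is None:
        # annihilation much faster than hopping: k*c0 >> 36 D / slab^2
        hop = 36.0 * p["D"] / p["slab"] ** 2
        k2 = 50.0 * hop / c0

    def extra(model):
        model.add_species("B")
        model.add_diffusion("diff_B", "B", p["D"], "vsys")
        model.add_reaction("annihilate", ["A", "B"], [], k2, "vsys")

    model = _diffusion_model(p["D"], extra)
    bound = apply_systems(model, mesh)

    def run_one(s):
        solver = TetexactSolver(bound, seed=s)
        for tets, sp in ((left, "A"), (right, "B")):
            vols = mesh.tet_volumes[tets]
            alloc = solver.rng.multinomial(n_half, vols / vols.sum())
            for k, nk in zip(tets, alloc):
                solver.set_tet_count(int(k), sp, int(nk))
        return solver.sample(p["times"])

    coords, prof = _mean_profiles(run_one, mesh, p["times"], n_iter, seed,
                                  p["n_slabs"])
    center = half * p["slab"]
    analytic = np.stack([degradation_interface(c0, p["D"],
                                               np.abs(coords - center), t)
                         for t in p["times"]])
    # analytic profile applies on the A side only; zero on the B side
    analytic = np.where(coords[None, :] < center, analytic, 0.0)
    return {"coords": coords, "profiles": prof, "analytic": analytic,
            "times": p["times"], "c0": c0, "center": center}


def run_point_source_case(seed: int, n_iter: int | None = None,
                          n0: int = 2000):
    """3D spread from molecules injected into the center tet of a cube; the
    radial profile is compared with the infinite-volume Gaussian outside an
    exclusion radius of two voxel edge lengths (the source has finite
    volume, so early/near-source bins are excluded)."""
    p = SPATIAL
    n_iter = n_iter or p["n_iter"]
    ndiv = 8
    edge = ndiv * p["slab"]  # 2 um cube
    mesh = generate_box_tetmesh(edge, ndiv)
    mesh.add_compartment("cyt", range(mesh.n_tets), ("vsys",))
    model = _diffusion_model(p["D"])
    bound = apply_systems(model, mesh)
    center = np.full(3, edge / 2.0)
    center_tet = mesh.find_tet(center + 1e-9 * p["slab"])
    times = (3e-3, 6e-3)
    n_bins = 10

    ss = np.random.SeedSequence(seed)
    acc = np.zeros((len(times), n_bins))
    coords = None
    for s in ss.spawn(n_iter):
        solver = TetexactSolver(bound, seed=s)
        solver.set_tet_count(center_tet, "A", n0)
        tr = solver.sample(times)
        for it in range(len(times)):
            binned = spatial_binning(mesh, tr.counts[it, 0, : mesh.n_tets],
                                     axis=None, n_bins=n_bins, center=center)
            coords = binned["coord"].to_numpy()
            acc[it] += np.nan_to_num(binned["concentration"].to_numpy())
    prof = acc / n_iter
    analytic = np.stack([point_source_3d(n0, p["D"], coords, t) for t in times])
    exclusion = 2.0 * p["slab"]
    return {"coords": coords, "profiles": prof, "analytic": analytic,
            "times": times, "exclusion": exclusion}


def profile_deviation(result: dict, mask=None, floor_frac: float = 0.05) -> float:
    """Maximum normalised deviation |sim - analytic| / max(analytic) over the
    region where the analytic profile is non-negligible (>= floor_frac of
    its peak), optionally restricted by ``mask`` over coordinates."""
    dev = 0.0
    for prof, ana in zip(result["profiles"], result["analytic"]):
        peak = np.nanmax(ana)
        sel = ana >= floor_frac * peak
        if mask is not None:
            sel &= mask
        if not sel.any():
            continue
        dev = max(dev, float(np.nanmax(np.abs(prof[sel] - ana[sel])) / peak))
    return dev


def run_mesh_resolution_case(seed: int, divisions=(3, 5), n_iter: int = 10,
                             t_end: float = 5e-3, n_points: int = 10):
    """Second-order reaction-diffusion (k = 100 /uM.s, D = 0.1 um^2/ms,
    [A] = [B] = 1 uM in a 1 um^3 box) simulated on box meshes of different
    resolution, all inside the well-mixed voxel-size window: the mean total
    trajectories must be indistinguishable across resolutions.

    Returns per-resolution mean and standard-error trajectories of the A
    count and the mean squared z-score between the two resolutions.
    """
    k = 1e8       # /M.s  (100 per uM.s)
    D = 1e-10     # m^2/s (0.1 um^2/ms)
    conc = 1e-6   # M
    times = np.linspace(t_end / n_points, t_end, n_points)
    results = {}
    ss = np.random.SeedSequence(seed)
    for ndiv, kid in zip(divisions, ss.spawn(len(divisions))):
        mesh = generate_box_tetmesh(1e-6, ndiv)
        mesh.add_compartment("cyt", range(mesh.n_tets), ("vsys",))
        model = Model()
        for s_ in ("A", "B", "C"):
            model.add_species(s_)
        model.add_reaction("bind", ["A", "B"], ["C"], k, "vsys")
        model.add_diffusion("diff_A", "A", D, "vsys")
        model.add_diffusion("diff_B", "B", D, "vsys")
        model.add_diffusion("diff_C", "C", D, "vsys")
        bound = apply_systems(model, mesh)
        n0 = int(round(conc * NA * mesh.total_volume * 1e3))
        tot = np.empty((n_iter, n_points))
        for it, s in enumerate(kid.spawn(n_iter)):
            solver = TetexactSolver(bound, seed=s)
            solver.set_comp_count("cyt", "A", n0)
            solver.set_comp_count("cyt", "B", n0)
            tr = solver.sample(times)
            tot[it] = tr.species_total("A")
        results[ndiv] = {
            "mean": tot.mean(axis=0),
            "se": tot.std(axis=0, ddof=1) / math.sqrt(n_iter),
            "n0": n0,
            "n_tets": mesh.n_tets,
        }
    d1, d2 = divisions[0], divisions[-1]
    z = (results[d1]["mean"] - results[d2]["mean"]) / np.sqrt(
        results[d1]["se"] ** 2 + results[d2]["se"] ** 2)
    return {"times": times, "results": results,
            "mean_sq_z": float(np.mean(z ** 2)), "max_abs_z": float(np.max(np.abs(z)))}


# ---------------------------------------------------------------------------
# reaction-diffusion controls
# ---------------------------------------------------------------------------

def run_decay_diffusion_control(seed: int, D: float = 2e-13,
                                n_replicates: int = 30, n0: int = 1000,
                                k: float = 0.5, n_points: int = 30):
    """First-order decay with an initially uniform concentration, plus
    diffusion: the mean trajectory must stay on the well-mixed analytic
    curve (diffusion cannot affect a spatially uniform linear process).

    Returns (times, per-replicate totals, analytic mean), with the covered
    point count under 95% t-CIs.
    """
    mesh = generate_box_tetmesh(1e-6, 3)
    mesh.add_compartment("cyt", range(mesh.n_tets), ("vsys",))
    model = Model()
    model.add_species("A")
    model.add_reaction("deg", ["A"], [], k, "vsys")
    if D > 0:
        model.add_diffusion("diff_A", "A", D, "vsys")
    bound = apply_systems(model, mesh)
    times = np.linspace(0.2, 6.0, n_points)
    totals = np.empty((n_replicates, n_points))
    for rep, s in enumerate(np.random.SeedSequence(seed).spawn(n_replicates)):
        solver = TetexactSolver(bound, seed=s)
        solver.set_comp_count("cyt", "A", n0)
        tr = solver.sample(times)
        totals[rep] = tr.species_total("A")
    ref, _ = first_order_decay(n0, k, times)
    covered = sum(_ci_covers(totals[:, i], ref[i]) for i in range(n_points))
    return {"times": times, "totals": totals, "analytic": ref,
            "covered": int(covered), "total": n_points}


def run_stationary_rd_case(seed: int, lam: float = 10.0, mu: float = 2.0,
                           D: float = 1e-11, t_burn: float = 10.0,
                           n_samples: int = 300, sample_dt: float = 1.0):
    """Zero-order production + second-order removal with a clamped partner,
    with diffusion, in a box mesh: the stationary distribution of the total
    count stays on the master-equation solution (Poisson with mean
    lambda_tot/mu) when voxels exceed the minimum well-mixed size.

    Returns the sampled histogram, the analytic pmf and their chi-square
    distance sum((p_obs - p_ref)^2 / p_ref) over bins with p_ref >= 1e-4.
    """
    mesh = generate_box_tetmesh(1e-6, 2)
    mesh.add_compartment("cyt", range(mesh.n_tets), ("vsys",))
    v_tot = mesh.total_volume
    k0 = lam * mu / (NA * v_tot * 1e3)  # zero-order, molar/s, uniform in space
    model = Model()
    model.add_species("A")
    model.add_species("B")
    model.add_diffusion("diff_A", "A", D, "vsys")
    model.add_reaction("prod", [], ["A"], k0, "vsys")
    # per-tet removal: B clamped at 1 per (equal-volume) tet makes the decay
    # rate per A molecule uniform: mu = k2 / (N_A * V_tet)
    v_tet = float(mesh.tet_volumes[0])
    k2 = mu * NA * v_tet * 1e3
    model.add_reaction("removal", ["A", "B"], ["B"], k2, "vsys")
    bound = apply_systems(model, mesh)
    solver = TetexactSolver(bound, seed=np.random.SeedSequence(seed))
    for kt in range(mesh.n_tets):
        solver.set_tet_count(kt, "B", 1)
        solver.set_tet_clamped(kt, "B", True)
    times = t_burn + sample_dt * np.arange(n_samples)
    tr = solver.sample(times)
    totals = tr.species_total("A")
    nmax = int(totals.max()) + 1
    hist = np.bincount(totals.astype(int), minlength=nmax) / len(totals)
    pmf = stats.poisson.pmf(np.arange(nmax), lam)
    sel = pmf >= 1e-4
    chi2 = float(np.sum((hist[sel] - pmf[sel]) ** 2 / pmf[sel]))
    return {"totals": totals, "hist": hist, "pmf": pmf, "chi2": chi2,
            "voxel_edge": v_tet ** (1 / 3)}
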