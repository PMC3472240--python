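"""Declarative run configuration: YAML/JSON schema, unit handling, output.

A run document has five sections -- ``model``, ``geometry``, ``solver``,
``initial`` and ``output``.  The model and the geometry are described
completely separately and are brought together by the requested solver.
Physical quantities may be plain numbers (SI units, molar-based rate
constants) or carry explicit unit strings, e.g. ``"100 /uM.s"``,
``{value: 0.1, units: um^2/ms}``; they are converted at parse time.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import Tetmesh, WellMixedCompartment, WellMixedGeometry, \
    WellMixedPatch, generate_box_tetmesh
from .meshio import import_mesh
from .model import Model, apply_systems
from .solvers import Trajectory, tetexact_run, wmdirect_run, wmrk4_run

__all__ = ["ConfigError", "parse_quantity", "load_config", "run_from_config",
           "write_timeseries", "read_timeseries"]


class ConfigError(ValueError):
    """The run document violates the schema."""


#: multiplicative factors to the internal convention (SI lengths/times,
#: molar-based rate constants)
UNIT_FACTORS = {
    "s": 1.0, "ms": 1e-3, "us": 1e-6,
    "m": 1.0, "um": 1e-6, "nm": 1e-9,
    "m^3": 1.0, "um^3": 1e-18, "L": 1e-3,
    "m^2": 1.0, "um^2": 1e-12,
    "m^2/s": 1.0, "um^2/s": 1e-12, "um^2/ms": 1e-9,
    "/s": 1.0, "1/s": 1.0,
    "/M.s": 1.0, "1/M.s": 1.0, "/mM.s": 1e3, "/uM.s": 1e6,
    "/M^2.s": 1.0, "/uM^2.s": 1e12,
    "M/s": 1.0, "mM/s": 1e-3, "uM/s": 1e-6,
    "M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9,
}


def parse_quantity(value, context: str = "") -> float:
    """A number (already in internal units), ``"<number> <unit>"`` or
    ``{value: x, units: u}``."""
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        parts = value.split()
        if len(parts) == 2:
            num, unit = parts
        else:
            raise ConfigError(f"{context}: cannot parse quantity {value!r}")
        try:
            num = float(num)
        except ValueError:
            raise ConfigError(f"{context}: cannot parse number in {value!r}") from None
    elif isinstance(value, dict) and "value" in value:
        num = float(value["value"])
        unit = value.get("units")
        if unit is None:
            return num
    else:
        raise ConfigError(f"{context}: cannot parse quantity {value!r}")
    if unit not in UNIT_FACTORS:
        raise ConfigError(f"{context}: unknown unit {unit!r}")
    return num * UNIT_FACTORS[unit]


# ---------------------------------------------------------------------------
# section parsers
# ---------------------------------------------------------------------------

def _build_model(doc: dict) -> Model:
    model = Model()
    for sid in doc.get("species", []):
        model.add_species(str(sid))
    for r in doc.get("reactions", []):
        rid = r.get("id")
        if rid is None:
            raise ConfigError("reaction without id")
        vsys = r.get("vsys", "vsys")
        if r.get("reversible"):
            model.add_reversible_reaction(
                rid, r.get("lhs", []), r.get("rhs", []),
                parse_quantity(r["kf"], f"reaction {rid} kf"),
                parse_quantity(r["kb"], f"reaction {rid} kb"), vsys)
        else:
            model.add_reaction(rid, r.get("lhs", []), r.get("rhs", []),
                               parse_quantity(r["k"], f"reaction {rid} k"), vsys)
    for r in doc.get("surface_reactions", []):
        rid = r.get("id")
        parts = {key: r.get(key, []) for key in
                 ("lhs_inner", "lhs_surface", "lhs_outer",
                  "rhs_inner", "rhs_surface", "rhs_outer")}
        model.add_surface_reaction(rid, parse_quantity(r["k"], f"surface {rid} k"),
                                   r.get("ssys", "ssys"), **parts)
    for d in doc.get("diffusion", []):
        model.add_diffusion(d.get("id", f"diff_{d['species']}"), d["species"],
                            parse_quantity(d["D"], f"diffusion {d['species']} D"),
                            d.get("vsys", "vsys"))
    return model


def _mesh_compartments(mesh: Tetmesh, doc: dict, proxies) -> None:
    for c in doc.get("compartments", []):
        cid = c["id"]
        sel = c.get("tets", "all")
        if sel == "all":
            idx = range(mesh.n_tets)
        elif isinstance(sel, dict) and "group" in sel:
            idx = proxies["tet"].internal_of_group(sel["group"])
        else:
            idx = [int(i) for i in sel]
        mesh.add_compartment(cid, idx, tuple(c.get("vsys", [])))
    for p in doc.get("patches", []):
        sel = p.get("tris")
        if isinstance(sel, dict) and "group" in sel:
            idx = proxies["tri"].internal_of_group(sel["group"])
            idx = [mesh._face_index[tuple(sorted(
                proxies["node"].to_internal(v) for v in proxies["tri"].data[i]))]
                for i in idx]
        else:
            idx = [int(i) for i in sel]
        mesh.add_patch(p["id"], idx, p["inner"], p.get("outer"),
                       tuple(p.get("ssys", [])))


def _build_geometry(doc: dict):
    kind = doc.get("kind")
    if kind == "well_mixed":
        geom = WellMixedGeometry()
        for c in doc.get("compartments", []):
            geom.add_compartment(WellMixedCompartment(
                c["id"], parse_quantity(c["volume"], f"compartment {c['id']}"),
                tuple(c.get("vsys", []))))
        for p in doc.get("patches", []):
            geom.add_patch(WellMixedPatch(
                p["id"], parse_quantity(p["area"], f"patch {p['id']}"),
                p["inner"], p.get("outer"), tuple(p.get("ssys", []))))
        return geom
    if kind == "mesh":
        msec = doc.get("mesh", {})
        if "box" in msec:
            box = msec["box"]
            mesh = generate_box_tetmesh(
                [parse_quantity(v, "box lengths") for v in box["lengths"]],
                box["divisions"])
            proxies = {"tet": None, "tri": None, "node": None}
        else:
            mesh, proxies = import_mesh(msec["path"], msec.get("format", "tetgen"),
                                        scale=float(msec.get("scale", 1.0)))
        _mesh_compartments(mesh, doc, proxies)
        return mesh
    raise ConfigError(f"geometry kind must be well_mixed or mesh, got {kind!r}")


def _sample_times(doc) -> np.ndarray:
    if isinstance(doc, dict):
        return np.linspace(parse_quantity(doc.get("start", 0.0), "sample start"),
                           parse_quantity(doc["stop"], "sample stop"),
                           int(doc.get("num", 10)))
    return np.asarray([parse_quantity(t, "sample time") for t in doc])


def load_config(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: run document must be a mapping")
    for section in ("model", "geometry", "solver"):
        if section not in doc:
            raise ConfigError(f"{path}: missing {section!r} section")
    return doc


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------

def write_timeseries(trajectories, path, fmt: str = "csv",
                     provenance: dict | None = None) -> Path:
    """Write one or more trajectories as a tidy long-format table.

    CSV files carry a provenance header in ``#``-comment lines (seed, config
    hash, package version); HDF5 stores the same as root attributes.  The
    table round-trips through :func:`read_timeseries`.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    if not trajectories or all(len(t.times) == 0 for t in trajectories):
        raise ValueError("refusing to write an empty trajectory")
    frame = pd.concat([t.to_frame() for t in trajectories], ignore_index=True)
    path = Path(path)
    meta = {"version": __version__}
    meta.update(provenance or {})
    if fmt == "csv":
        with open(path, "w") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}: {v}\n")
            frame.to_csv(fh, index=False)
    elif fmt == "hdf5":
        frame.to_hdf(path, key="timeseries", mode="w", format="table")
        import h5py
        with h5py.File(path, "a") as fh:
            for k, v in meta.items():
                fh.attrs[k] = str(v)
    else:
        raise ValueError(f"unknown output format {fmt!r}")
    return path


def read_timeseries(path, fmt: str = "csv") -> pd.DataFrame:
    if fmt == "csv":
        return pd.read_csv(path, comment="#")
    if fmt == "hdf5":
        return pd.read_hdf(path, key="timeseries")
    raise ValueError(f"unknown output format {fmt!r}")


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_from_config(path, out: str | None = None) -> Path:
    """Execute the run described by a config document; returns the output path.

    The requested solver runs over the requested replicates; the trajectory
    table is written with a provenance header (seed, config hash, version).
    """
    path = Path(path)
    doc = load_config(path)
    model = _build_model(doc["model"])
    geometry = _build_geometry(doc["geometry"])
    bound = apply_systems(model, geometry)

    sv = doc["solver"]
    name = sv.get("name")
    seed = sv.get("seed", 0)
    replicates = int(sv.get("replicates", 1))
    times = _sample_times(sv.get("sample_times", {"stop": 1.0, "num": 10}))

    init = doc.get("initial", {})
    counts = {}
    for c in init.get("counts", []):
        counts[(_loc(c["location"]), c["species"])] = int(c["count"])
    is_mesh = isinstance(geometry, Tetmesh)
    if name == "tetexact" and not is_mesh:
        raise ConfigError("tetexact requires a mesh geometry")
    if name in ("wmdirect", "wmrk4") and is_mesh:
        raise ConfigError(f"{name} requires a well-mixed geometry")

    trajectories = []
    ss = np.random.SeedSequence(seed)
    if name == "wmrk4":
        conc = {(c["location"], c["species"]):
                parse_quantity(c["conc"], "initial conc")
                for c in init.get("concentrations", [])}
        trajectories.append(wmrk4_run(bound, conc,
                                      parse_quantity(sv.get("dt", 1e-4), "dt"),
                                      times))
    elif name == "wmdirect":
        for rep, s in enumerate(ss.spawn(replicates)):
            trajectories.append(wmdirect_run(bound, counts, times, seed=s,
                                             replicate=rep))
    elif name == "tetexact":
        for rep, s in enumerate(ss.spawn(replicates)):
            trajectories.append(tetexact_run(bound, counts, times, seed=s,
                                             replicate=rep))
    else:
        raise ConfigError(f"unknown solver {name!r}")

    out_doc = doc.get("output", {})
    fmt = out_doc.get("format", "csv")
    out_path = Path(out or out_doc.get("path", path.with_suffix(".out.csv")))
    cfg_hash = hashlib.sha256(json.dumps(doc, sort_keys=True, default=str)
                              .encode()).hexdigest()[:16]
    write_timeseries(trajectories, out_path, fmt,
                     provenance={"seed": seed, "config": str(path),
                                 "config_sha256": cfg_hash})
    return out_path


def _loc(raw):
    """Location spec: a compartment/patch id, or 'tet:<k>' / 'tri:<k>'."""
    if isinstance(raw, str) and ":" in raw:
        kind, _, ix = raw.partition(":")
        if kind in ("tet", "tri"):
            return (kind, int(ix))
    return raw
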