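"""Readers/writers and the reproducible study runner.

Meshes travel as VTK legacy ASCII (``STRUCTURED_POINTS`` would lose the
element data layout, so an ``UNSTRUCTURED_GRID`` of hexahedra is written)
with LGE intensity, segment labels and any other per-element arrays as
``CELL_DATA``.  Activation records are tabular text
(``vertex_id  activation_index  time_ms``).  A study run is driven by one
YAML config and is resumable: completed run ids are skipped.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, IOFormatError
from .mesh import TissueMesh
from .records import ActivationRecord

# ---------------------------------------------------------------------------
# VTK legacy ASCII mesh I/O

def write_mesh(path, mesh: TissueMesh, cell_data: dict | None = None):
    """Write the lattice as a VTK legacy unstructured grid of hexahedra.

    ``cell_data`` maps array names to per-element float/int arrays (the
    LGE map, segment labels, conductivities, ...).
    """
    path = Path(path)
    nx, ny, nz = mesh.shape
    h = mesh.spacing_mm
    # lattice points: (nx+1) x (ny+1) x (nz+1)
    px, py, pz = nx + 1, ny + 1, nz + 1
    ii, jj, kk = np.meshgrid(np.arange(px), np.arange(py), np.arange(pz),
                             indexing="ij")
    pts = np.column_stack([ii.ravel() * h, jj.ravel() * h, kk.ravel() * h])

    def pid(i, j, k):
        return (i * py + j) * pz + k

    cells = np.empty((mesh.n_elements, 8), dtype=np.int64)
    e = 0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                cells[e] = (pid(i, j, k), pid(i + 1, j, k),
                            pid(i + 1, j + 1, k), pid(i, j + 1, k),
                            pid(i, j, k + 1), pid(i + 1, j, k + 1),
                            pid(i + 1, j + 1, k + 1), pid(i, j + 1, k + 1))
                e += 1

    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"scarwave lattice shape={nx},{ny},{nz} "
                f"spacing_um={mesh.spacing_um}\n")
        f.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(pts)} double\n")
        np.savetxt(f, pts, fmt="%.9g")
        f.write(f"CELLS {len(cells)} {len(cells) * 9}\n")
        np.savetxt(f, np.column_stack(
            [np.full(len(cells), 8, dtype=np.int64), cells]), fmt="%d")
        f.write(f"CELL_TYPES {len(cells)}\n")
        np.savetxt(f, np.full(len(cells), 12, dtype=np.int64), fmt="%d")

        data = {"fiber_x": mesh.fibers[:, 0], "fiber_y": mesh.fibers[:, 1],
                "fiber_z": mesh.fibers[:, 2]}
        if mesh.segments is not None:
            data["segments"] = mesh.segments
        if cell_data:
            data.update(cell_data)
        f.write(f"CELL_DATA {len(cells)}\n")
        for name, arr in data.items():
            arr = np.asarray(arr)
            if arr.shape != (mesh.n_elements,):
                raise ConfigError(f"cell array {name!r} has wrong length")
            if np.issubdtype(arr.dtype, np.integer):
                f.write(f"SCALARS {name} long 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, arr, fmt="%d")
            else:
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, arr, fmt="%.17g")


def read_mesh(path):
    """Read a mesh written by :func:`write_mesh`.

    Returns ``(mesh, cell_data)``; fiber components and segments are folded
    back into the mesh, everything else lands in ``cell_data``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 5 or not lines[0].startswith("# vtk"):
        raise IOFormatError(f"{path}: not a VTK legacy file (line 1)")
    try:
        header = dict(tok.split("=") for tok in lines[1].split()
                      if "=" in tok)
        shape = tuple(int(s) for s in header["shape"].split(","))
        spacing = float(header["spacing_um"])
    except Exception as exc:
        raise IOFormatError(f"{path}: malformed header (line 2)") from exc
    n_elem = int(np.prod(shape))

    idx = 0

    def seek(prefix):
        nonlocal idx
        while idx < len(lines) and not lines[idx].startswith(prefix):
            idx += 1
        if idx == len(lines):
            raise IOFormatError(f"{path}: missing {prefix} section "
                                f"(file truncated?)")
        return lines[idx].split()

    def read_block(n, offset):
        if offset + n > len(lines):
            raise IOFormatError(
                f"{path}: truncated at line {len(lines)} while reading "
                f"{n} rows from line {offset + 1}")
        return lines[offset:offset + n]

    seek("POINTS")
    seek("CELL_DATA")
    idx += 1
    cell_data = {}
    while idx < len(lines):
        if not lines[idx].startswith("SCALARS"):
            idx += 1
            continue
        _, name, vtype = lines[idx].split()[:3]
        idx += 2  # skip LOOKUP_TABLE line
        block = read_block(n_elem, idx)
        try:
            if vtype == "long":
                arr = np.array([int(x) for x in block], dtype=np.int64)
            else:
                arr = np.array([float(x) for x in block])
        except ValueError as exc:
            raise IOFormatError(
                f"{path}: bad value near line {idx + 1}") from exc
        cell_data[name] = arr
        idx += n_elem

    for comp in ("fiber_x", "fiber_y", "fiber_z"):
        if comp not in cell_data:
            raise IOFormatError(f"{path}: missing {comp} cell array")
    fibers = np.column_stack([cell_data.pop("fiber_x"),
                              cell_data.pop("fiber_y"),
                              cell_data.pop("fiber_z")])
    mesh = TissueMesh(shape=shape, spacing_um=spacing, fibers=fibers,
                      segments=cell_data.pop("segments", None))
    return mesh, cell_data


# ---------------------------------------------------------------------------
# activation tables

def write_activation(path, record: ActivationRecord):
    df = record.to_frame()
    with open(path, "w") as f:
        f.write("# vertex_id\tactivation_index\ttime_ms\n")
        df.to_csv(f, sep="\t", header=False, index=False,
                  float_format="%.6f")


def read_activation(path, n_vertices=None) -> ActivationRecord:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#",
                         names=["vertex_id", "activation_index", "time_ms"],
                         dtype={"vertex_id": np.int64,
                                "activation_index": np.int64,
                                "time_ms": float})
    except Exception as exc:
        raise IOFormatError(f"{path}: cannot parse activation table "
                            f"({exc})") from exc
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax())
        raise IOFormatError(f"{path}: missing value at data row {bad}")
    sorted_df = df.sort_values(["vertex_id", "time_ms"], kind="stable")
    if not sorted_df.reset_index(drop=True).equals(df.reset_index(drop=True)):
        warnings.warn(f"{path}: rows were not sorted; sorted on read",
                      stacklevel=2)
    return ActivationRecord.from_frame(sorted_df, n_vertices)


# ---------------------------------------------------------------------------
# study configuration and runner

@dataclass
class StudyConfig:
    """One reproducible study: geometries x populations x sites."""

    geometries: list                  # list of SyntheticSpec kwargs dicts
    populations: dict                 # variant -> list of levels
    n_segments: int = 17
    seed: int = 0
    out_dir: str = "study_out"
    protocol: dict = field(default_factory=dict)     # ProtocolSpec overrides
    simulation: dict = field(default_factory=dict)   # SimulationConfig overrides
    analysis: dict = field(default_factory=dict)     # merge window, radius, ...

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise IOFormatError(f"{path}: invalid YAML ({exc})") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "geometries" not in raw or "populations" not in raw:
            raise ConfigError("config needs 'geometries' and 'populations'")
        return cls(**raw)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def run_study(config: StudyConfig) -> pd.DataFrame:
    """Execute a study end to end; resumable and failure-isolated.

    Returns the outcome table (one row per run) and writes, under
    ``config.out_dir``: the manifest, per-run outcome rows (appended as
    completed), initiation-site CSVs and the segment table.
    """
    from .features import local_lge_features
    from .models import build_model
    from .monodomain import SimulationConfig
    from .pacing import (ProtocolSpec, enumerate_experiments, run_protocol,
                         select_pacing_sites)
    from .reentry import (classify_morphology, default_min_cluster,
                          label_reentrant_activations,
                          merge_rapid_activations, trace_initiation)
    from .synth import (SyntheticSpec, generate_lge, generate_mesh,
                        generate_segments)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    protocol = ProtocolSpec(**config.protocol)
    simcfg = SimulationConfig(**config.simulation)
    radius = config.analysis.get("feature_radius_mm", 5.0)
    merge_win = config.analysis.get("merge_window_ms", 50.0)
    type2_cut = config.analysis.get("type2_cutoff_pct", 10.0)

    geoms = {}
    for gi, gkw in enumerate(config.geometries):
        gkw = dict(gkw)
        gkw.setdefault("seed", config.seed + gi)
        spec = SyntheticSpec(**gkw)
        mesh = generate_mesh(spec)
        lge = generate_lge(spec, mesh)
        segs = generate_segments(mesh, config.n_segments)
        mesh.segments = segs
        geoms[f"g{gi}"] = (mesh, lge, segs)

    manifest = enumerate_experiments(config.populations, list(geoms),
                                     config.n_segments)
    manifest.to_csv(out / "manifest.csv", index=False)

    outcome_path = out / "outcomes.csv"
    done = set()
    if outcome_path.exists():
        done = set(pd.read_csv(outcome_path)["run_id"])

    site_rows = []
    outcome_cols = ["run_id", "geometry", "variant", "level", "site",
                    "status", "reentry", "sustained", "n_captured",
                    "extrastimuli", "n_initiation_sites", "seed"]
    for _, row in manifest.iterrows():
        if row.run_id in done:
            continue
        mesh, lge, segs = geoms[row.geometry]
        # crc32, not hash(): string hashing is salted per process and
        # would break the byte-identical-rerun contract
        seed = int(np.random.SeedSequence(
            (config.seed, zlib.crc32(row.run_id.encode()))
        ).generate_state(1)[0] & 0x7FFFFFFF)
        rec_row = dict(run_id=row.run_id, geometry=row.geometry,
                       variant=row.variant, level=row.level, site=row.site,
                       status="ok", reentry=False, sustained=False,
                       n_captured=0, extrastimuli=0, n_initiation_sites=0,
                       seed=seed)
        try:
            model = build_model(mesh, lge, row.variant, row.level,
                                seed=seed, config=simcfg)
            sites = select_pacing_sites(mesh, segs,
                                        protocol.electrode_volume_mm3)
            outcome = run_protocol(model, sites[row.site], protocol,
                                   site_id=row.site)
            rec_row.update(reentry=outcome.reentry,
                           sustained=outcome.sustained,
                           n_captured=outcome.n_captured,
                           extrastimuli=outcome.extrastimuli_delivered)
            if outcome.reentry:
                series = merge_rapid_activations(
                    label_reentrant_activations(
                        outcome.record, outcome.n_captured), merge_win)
                clusters = trace_initiation(
                    series, mesh,
                    min_cluster=config.analysis.get(
                        "min_cluster", default_min_cluster(mesh.n_elements)))
                rec_row["n_initiation_sites"] = len(clusters)
                for ci, cl in enumerate(clusters):
                    feats = local_lge_features(cl.center_mm, mesh, lge,
                                               radius)
                    morph = classify_morphology(feats.mean_lge_pct,
                                                type2_cut)
                    site_rows.append(dict(
                        run_id=row.run_id, cluster=ci,
                        x_mm=cl.center_mm[0], y_mm=cl.center_mm[1],
                        z_mm=cl.center_mm[2], t_ms=cl.step_ms,
                        cluster_size=cl.size, morphology=morph.label,
                        heuristic=morph.heuristic,
                        mean_lge_pct=feats.mean_lge_pct,
                        max_lge_pct=feats.max_lge_pct,
                        lge_volume_ml=feats.lge_volume_ml))
        except Exception as exc:  # isolate failures, keep going
            rec_row["status"] = f"failed: {type(exc).__name__}: {exc}"
        pd.DataFrame([rec_row], columns=outcome_cols).to_csv(
            outcome_path, mode="a", header=not outcome_path.exists(),
            index=False)

    outcomes = pd.read_csv(outcome_path)
    if site_rows:
        sites_df = pd.DataFrame(site_rows)
        sites_path = out / "initiation_sites.csv"
        sites_df.to_csv(sites_path, mode="a",
                        header=not sites_path.exists(), index=False)
    with open(out / "provenance.json", "w") as f:
        json.dump({"seed": config.seed, "n_runs": len(manifest),
                   "package": "scarwave"}, f, indent=1)
    return outcomes
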