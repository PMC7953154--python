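"""File I/O: surface frames (STL/PLY via trimesh), legacy-ASCII VTK output for
grid fields and skeleton polylines, CSV tables, and case manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh


# ---------------------------------------------------------------------------
# Surface frames
# ---------------------------------------------------------------------------

def write_case_frames(case, outdir, fmt: str = "ply") -> list[Path]:
    """Write each phase of a synthetic case as STL or PLY plus a manifest.

    The manifest (``case.json``) records the phase times, region tags,
    inlet-plane geometry, prescribed waveform parameters and ground-truth
    index targets, so the frames can be re-read as a corresponded sequence.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, verts in enumerate(case.frames):
        mesh = trimesh.Trimesh(vertices=verts, faces=case.template.faces,
                               process=False)
        p = outdir / f"frame_{i:03d}.{fmt}"
        mesh.export(p)
        paths.append(p)
    manifest = {
        "n_phases": len(case.frames),
        "period_s": case.params.period,
        "frame_files": [p.name for p in paths],
        "face_tags": case.face_tags.tolist(),
        "index_targets": case.index_targets,
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(case.params).items()},
        "inlets": [
            {"center_cm": inlet.center.tolist(),
             "normal": inlet.normal.tolist(),
             "area_cm2": inlet.area,
             "radius_cm": inlet.radius}
            for inlet in case.waveforms.inlets
        ],
    }
    (outdir / "case.json").write_text(json.dumps(manifest, indent=2))
    return paths


def read_frames(outdir):
    """Read a frame sequence written by :func:`write_case_frames`.

    Returns ``(frames_vertices, faces, face_tags, period)`` ready for
    :func:`atriflow.kinematics.fit_fourier_model`.
    """
    outdir = Path(outdir)
    manifest = json.loads((outdir / "case.json").read_text())
    meshes = [trimesh.load(outdir / f, process=False)
              for f in manifest["frame_files"]]
    faces = np.asarray(meshes[0].faces)
    for m in meshes[1:]:
        if not np.array_equal(np.asarray(m.faces), faces):
            raise ValueError("frame files have mismatched connectivity")
    verts = np.stack([np.asarray(m.vertices, dtype=float) for m in meshes])
    tags = np.asarray(manifest["face_tags"], dtype=np.int32)
    return verts, faces, tags, float(manifest["period_s"])


# ---------------------------------------------------------------------------
# VTK legacy writers (structured points / polylines)
# ---------------------------------------------------------------------------

def write_vtk_fields(path, grid, cell_fields: dict) -> Path:
    """Write cell-centered scalar/vector fields as a legacy-ASCII VTK
    STRUCTURED_POINTS dataset (readable by ParaView/VisIt).

    ``cell_fields`` maps names to ``(n,n,n)`` scalars or ``(n,n,n,3)``
    vectors; staggered velocity triples should be cell-averaged first (see
    :func:`atriflow.solver.cell_velocity`).
    """
    path = Path(path)
    n = grid.n
    dx = grid.dx
    org = grid.origin + 0.5 * dx
    lines = [
        "# vtk DataFile Version 3.0",
        "atriflow fields",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {n} {n} {n}",
        f"ORIGIN {org[0]:.6g} {org[1]:.6g} {org[2]:.6g}",
        f"SPACING {dx:.6g} {dx:.6g} {dx:.6g}",
        f"POINT_DATA {n**3}",
    ]
    for name, arr in cell_fields.items():
        arr = np.asarray(arr)
        if arr.ndim == 3:
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            # VTK expects x fastest -> transpose to (z, y, x) then ravel
            lines.extend(f"{v:.6g}" for v in arr.transpose(2, 1, 0).ravel())
        elif arr.ndim == 4 and arr.shape[-1] == 3:
            lines.append(f"VECTORS {name} double")
            flat = arr.transpose(2, 1, 0, 3).reshape(-1, 3)
            lines.extend(f"{a:.6g} {b:.6g} {c:.6g}" for a, b, c in flat)
        else:
            raise ValueError(f"field {name} has unsupported shape {arr.shape}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_vtk_polylines(path, points: np.ndarray, lines_idx: list) -> Path:
    """Write polylines (e.g. a skeleton branch graph) as legacy-ASCII VTK."""
    path = Path(path)
    out = [
        "# vtk DataFile Version 3.0",
        "atriflow polylines",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(points)} double",
    ]
    out.extend(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}" for p in points)
    total = sum(len(l) + 1 for l in lines_idx)
    out.append(f"LINES {len(lines_idx)} {total}")
    for l in lines_idx:
        out.append(" ".join(str(i) for i in (len(l), *l)))
    path.write_text("\n".join(out) + "\n")
    return path


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def indices_to_csv(path, indices, vols=None) -> Path:
    """Write atrial-function indices (and volume scalars) with units in headers."""
    row = indices.as_dict()
    if vols is not None:
        row.update({
            "v_min_ml": vols.v_min, "v_max_ml": vols.v_max,
            "v_mean_ml": vols.v_mean, "v_pre_a_ml": vols.v_pre_a,
        })
        laa = vols.laa_stats()
        if laa:
            row.update({"v_laa_min_ml": laa[0], "v_laa_mean_ml": laa[1],
                        "v_laa_max_ml": laa[2]})
    df = pd.DataFrame([row])
    df.to_csv(path, index=False)
    return Path(path)


def waveforms_to_csv(path, waveforms, nt: int = 200) -> Path:
    waveforms.sample(nt).to_csv(path, index=False)
    return Path(path)
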