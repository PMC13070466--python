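"""File formats: habit/prior YAML, configuration JSON, keypoint CSV,
mesh export (OBJ / face-cycle JSON), SVG wireframe overlays, heatmap PNG."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .habit import CrystalConfiguration, CrystalHabit, PolyhedronMesh, normals_from_miller
from .projector import Wireframe2D
from .sampler import MorphologyPrior


# -- habit ------------------------------------------------------------------

def load_habit(path) -> CrystalHabit:
    """Load a habit definition from YAML (see the bundled data files)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return habit_from_dict(doc)


def habit_from_dict(doc: dict) -> CrystalHabit:
    name = doc.get("name", "unnamed")
    if "normals" in doc:
        normals = np.asarray(doc["normals"], dtype=float)
    else:
        normals = normals_from_miller(doc["unit_cell"], doc["miller_faces"])
    ops = tuple(
        (np.asarray(op["rotation"], dtype=float), np.asarray(op["permutation"], dtype=int))
        for op in doc["symmetry_ops"]
    )
    return CrystalHabit(
        name=name,
        normals=normals,
        face_groups=tuple(tuple(g) for g in doc["face_groups"]),
        symmetry_ops=ops,
        unit_cell=tuple(doc["unit_cell"]) if "unit_cell" in doc else None,
        miller_faces=tuple(tuple(f) for f in doc["miller_faces"]) if "miller_faces" in doc else None,
    )


def load_prior(path) -> MorphologyPrior:
    """Load the morphology prior block from a habit/prior YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    block = doc.get("prior", doc)
    kwargs = dict(
        mu=np.asarray(block["mu"], dtype=float),
        sigma=np.asarray(block["sigma"], dtype=float),
        ordering=tuple(tuple(p) for p in block.get("ordering", [])),
    )
    for key in (
        "zingg_bounds",
        "intra_group_spread",
        "area_range",
        "eta_range",
        "roughness_range",
        "light_range",
        "rejection_budget",
    ):
        if key in block:
            val = block[key]
            if isinstance(val, list):
                val = tuple(tuple(v) if isinstance(v, list) else v for v in val)
            kwargs[key] = val
    return MorphologyPrior(**kwargs)


def bundled_habit_path(name: str) -> Path:
    return Path(__file__).parent / "data" / f"{name}.yaml"


def load_bundled_habit(name: str) -> CrystalHabit:
    return load_habit(bundled_habit_path(name))


# -- configuration ----------------------------------------------------------

def config_to_dict(config: CrystalConfiguration) -> dict:
    return {
        "habit": config.habit.name,
        "distances": config.distances.tolist(),
        "origin": config.origin.tolist(),
        "rotation_axis_angle": config.rotation.tolist(),
        "refractive_index": config.refractive_index,
        "roughness": config.roughness,
        "light": config.light.tolist(),
    }


def save_config(config: CrystalConfiguration, path) -> None:
    Path(path).write_text(json.dumps(config_to_dict(config), indent=2))


def load_config(path, habit: CrystalHabit) -> CrystalConfiguration:
    doc = json.loads(Path(path).read_text())
    if doc.get("habit") not in (None, habit.name):
        raise ValueError(f"config is for habit {doc['habit']!r}, not {habit.name!r}")
    return CrystalConfiguration(
        habit=habit,
        distances=np.asarray(doc["distances"], dtype=float),
        origin=np.asarray(doc["origin"], dtype=float),
        rotation=np.asarray(doc["rotation_axis_angle"], dtype=float),
        refractive_index=float(doc.get("refractive_index", 1.0)),
        roughness=float(doc.get("roughness", 0.0)),
        light=np.asarray(doc.get("light", [1.0, 1.0, 1.0]), dtype=float),
    )


# -- keypoints --------------------------------------------------------------

def save_keypoints(path, keypoints: np.ndarray, tags=None) -> None:
    K = np.asarray(keypoints, dtype=float).reshape(-1, 2)
    df = pd.DataFrame({"x_px": K[:, 0], "y_px": K[:, 1]})
    df["source_tag"] = tags if tags is not None else ""
    df.to_csv(path, index=False)


def load_keypoints(path):
    df = pd.read_csv(path)
    K = df[["x_px", "y_px"]].to_numpy(dtype=float)
    tags = df["source_tag"].fillna("").tolist() if "source_tag" in df else None
    return K, tags


# -- meshes -----------------------------------------------------------------

def mesh_to_trimesh(mesh: PolyhedronMesh):
    """Triangulated trimesh (fan around each face centroid, posed coords)."""
    import trimesh

    verts = list(mesh.vertices)
    tris = []
    for fid, cyc in enumerate(mesh.faces):
        if len(set(cyc)) < 3:
            continue
        pts = mesh.vertices[list(cyc)]
        c_idx = len(verts)
        verts.append(pts.mean(axis=0))
        for a, b in zip(cyc, cyc[1:] + cyc[:1]):
            tris.append([c_idx, a, b])
    return trimesh.Trimesh(vertices=np.asarray(verts), faces=np.asarray(tris), process=False)


def save_mesh_obj(mesh: PolyhedronMesh, path) -> None:
    mesh_to_trimesh(mesh).export(str(path))


def save_face_cycles_json(mesh: PolyhedronMesh, path) -> None:
    doc = {
        "vertices": mesh.vertices.tolist(),
        "faces": [list(map(int, c)) for c in mesh.faces],
        "face_areas": mesh.face_areas.tolist(),
        "volume": mesh.volume,
        "zero_area_faces": sorted(int(i) for i in mesh.zero_area_faces),
    }
    Path(path).write_text(json.dumps(doc, indent=2))


# -- overlays / heatmaps ----------------------------------------------------

_STROKE = {"front": "#1f77b4", "refracted": "#d62728"}


def save_wireframe_svg(wf: Wireframe2D, geometry, path) -> None:
    """Provenance-coded wireframe overlay (front blue, refracted red)."""
    lines = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{geometry.width}" '
        f'height="{geometry.height}" viewBox="0 0 {geometry.width} {geometry.height}">'
    ]
    for seg in wf.segments:
        kind = seg.provenance[0]
        lines.append(
            f'<line x1="{seg.p0[0]:.2f}" y1="{seg.p0[1]:.2f}" x2="{seg.p1[0]:.2f}" '
            f'y2="{seg.p1[1]:.2f}" stroke="{_STROKE.get(kind, "#333")}" stroke-width="1"/>'
        )
    for (x, y), tag in zip(wf.keypoints, wf.keypoint_tags):
        color = "#2ca02c" if tag == "vertex" else "#ff7f0e"
        lines.append(f'<circle cx="{x:.2f}" cy="{y:.2f}" r="2.5" fill="{color}"/>')
    lines.append("</svg>")
    Path(path).write_text("\n".join(lines))


def save_heatmap_png(heatmap: np.ndarray, path) -> None:
    import imageio.v3 as iio

    img = np.clip(heatmap * 255.0, 0, 255).astype(np.uint8)
    iio.imwrite(str(path), img)


def save_heatmap_npy(heatmap: np.ndarray, path) -> None:
    np.save(str(path), heatmap)
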