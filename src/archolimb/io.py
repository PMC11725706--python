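"""File formats and fixtures: YAML model configs, hoop-stack CSV, muscle
tables, moment-arm sweep CSV, and synthetic-model bundles.

Units in every file: lengths metres, angles degrees, masses kilograms;
meshes are OBJ (triangulated on load).  Fixture files shipping with the
package transcribe the published *Riojasuchus tenuisceps* joint limits,
hindlimb muscle attachment table, and whole-body summary measurements.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .loft import Hoop, SegmentShape
from .meshmass import load_obj, mass_properties, save_obj
from .model import ACS, BodyModel, Joint, Landmark, Pose, Segment
from .muscles import MomentArmCurve, MusclePath, WrapSurface
from .posture import FeatureRecord

__all__ = [
    "load_model",
    "save_model",
    "write_bundle",
    "load_rom_fixture",
    "load_muscle_table",
    "load_summary_fixture",
    "load_feature_fixture",
    "load_hoop_stacks_csv",
    "save_hoop_stacks_csv",
    "sweeps_to_csv",
    "sweeps_from_csv",
    "SchemaError",
]


def _fixture_path(name: str):
    return resources.files("archolimb.data").joinpath(name)


class SchemaError(ValueError):
    """Config validation error carrying the offending field path."""


def _require(mapping, key, path):
    if key not in mapping:
        raise SchemaError(f"{path}: missing required field {key!r}")
    return mapping[key]


# ---------------------------------------------------------------------------
# model config
# ---------------------------------------------------------------------------

def load_model(path) -> BodyModel:
    """Load a YAML model config into a fully linked BodyModel.

    Mesh paths are resolved relative to the config file; a reference to a
    missing mesh raises an error naming the path.  Schema violations raise
    :class:`SchemaError` with the offending field path.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: top level must be a mapping")
    model = BodyModel()
    for i, seg in enumerate(cfg.get("segments", [])):
        spath = f"segments[{i}]"
        name = _require(seg, "name", spath)
        mesh = None
        if seg.get("mesh"):
            mesh_path = path.parent / seg["mesh"]
            if not mesh_path.exists():
                raise SchemaError(f"{spath}.mesh: mesh file not found: {mesh_path}")
            mesh = load_obj(mesh_path)
        placement = np.asarray(seg["placement"], dtype=float) if "placement" in seg \
            else None
        density = float(seg.get("density", 1000.0))
        model.add_segment(
            Segment(name=name, mesh=mesh, density=density,
                    mass_props=mass_properties(mesh, density) if mesh is not None
                    else None,
                    articular_patches={k: list(v) for k, v in
                                       seg.get("articular_patches", {}).items()}),
            placement,
        )
    if "root" in cfg:
        if cfg["root"] not in model.segments:
            raise SchemaError(f"root: unknown segment {cfg['root']!r}")
        model.root = cfg["root"]
    for i, jn in enumerate(cfg.get("joints", [])):
        jpath = f"joints[{i}]"
        try:
            jcs = ACS(origin=_require(jn, "origin", jpath),
                      axes=np.column_stack([np.asarray(_require(jn, ax, jpath), dtype=float)
                                            for ax in ("axis_x", "axis_y", "axis_z")]))
        except ValueError as exc:
            raise SchemaError(f"{jpath}: {exc}") from exc
        joint = Joint(
            name=_require(jn, "name", jpath),
            parent=_require(jn, "parent", jpath),
            child=_require(jn, "child", jpath),
            jcs=jcs,
            dofs=tuple(jn.get("dofs", ["z"])),
            rom={k: tuple(v) for k, v in jn.get("rom", {}).items()},
            cartilage_offset=np.asarray(jn.get("cartilage_offset", [0, 0, 0]),
                                        dtype=float),
        )
        try:
            model.add_joint(joint)
        except ValueError as exc:
            raise SchemaError(f"{jpath}: {exc}") from exc
    for i, mn in enumerate(cfg.get("muscles", [])):
        mpath = f"muscles[{i}]"
        points = [(
            _require(p, "segment", f"{mpath}.points[{k}]"),
            _require(p, "xyz", f"{mpath}.points[{k}]"),
        ) for k, p in enumerate(_require(mn, "points", mpath))]
        wraps = [
            WrapSurface(
                kind=_require(w, "kind", f"{mpath}.wraps[{k}]"),
                segment=_require(w, "segment", f"{mpath}.wraps[{k}]"),
                frame=_frame_from(w, f"{mpath}.wraps[{k}]"),
                radius=float(_require(w, "radius", f"{mpath}.wraps[{k}]")),
                side=int(w.get("side", 0)),
            )
            for k, w in enumerate(mn.get("wraps", []))
        ]
        acr = _require(mn, "acronym", mpath)
        model.muscles[acr] = MusclePath(
            acronym=acr, points=points, wraps=wraps,
            inference=tuple(mn.get("inference", ("", ""))),
            name=mn.get("name", ""),
        )
    for name, lm in (cfg.get("landmarks") or {}).items():
        model.landmarks[name] = Landmark(
            segment=_require(lm, "segment", f"landmarks.{name}"),
            point=_require(lm, "xyz", f"landmarks.{name}"),
        )
    model.chains = {k: list(v) for k, v in (cfg.get("chains") or {}).items()}
    model.preset_poses = {k: Pose(v or {}) for k, v in (cfg.get("poses") or {}).items()}
    if cfg.get("foot_support") is not None:
        model.foot_support = tuple(float(x) for x in cfg["foot_support"])
    try:
        model.validate()
    except ValueError as exc:
        raise SchemaError(str(exc)) from exc
    return model


def _frame_from(w, path):
    origin = np.asarray(_require(w, "origin", path), dtype=float)
    T = np.eye(4)
    T[:3, :3] = np.column_stack([np.asarray(w.get(ax, d), dtype=float)
                                 for ax, d in (("axis_x", (1, 0, 0)),
                                               ("axis_y", (0, 1, 0)),
                                               ("axis_z", (0, 0, 1)))])
    T[:3, 3] = origin
    return T


def save_model(model: BodyModel, path, mesh_dir: str | None = "meshes") -> None:
    """Write *model* as YAML; segment meshes go to *mesh_dir* as OBJ."""
    path = Path(path)
    cfg = {"units": {"length": "m", "angle": "deg", "mass": "kg"},
           "root": model.root, "segments": [], "joints": [], "muscles": []}
    for name, seg in model.segments.items():
        entry = {"name": name, "density": seg.density}
        if seg.mesh is not None and mesh_dir is not None:
            mdir = path.parent / mesh_dir
            mdir.mkdir(parents=True, exist_ok=True)
            save_obj(seg.mesh, mdir / f"{name}.obj")
            entry["mesh"] = f"{mesh_dir}/{name}.obj"
        if seg.articular_patches:
            entry["articular_patches"] = {k: [int(i) for i in v]
                                          for k, v in seg.articular_patches.items()}
        placement = model.reference_placements.get(name)
        if placement is not None and not np.allclose(placement, np.eye(4)):
            entry["placement"] = placement.tolist()
        cfg["segments"].append(entry)
    for j in model.joints.values():
        cfg["joints"].append({
            "name": j.name, "parent": j.parent, "child": j.child,
            "origin": j.jcs.origin.tolist(),
            "axis_x": j.jcs.axes[:, 0].tolist(),
            "axis_y": j.jcs.axes[:, 1].tolist(),
            "axis_z": j.jcs.axes[:, 2].tolist(),
            "dofs": list(j.dofs),
            "rom": {k: [float(a) for a in v] for k, v in j.rom.items()},
            "cartilage_offset": j.cartilage_offset.tolist(),
        })
    for m in model.muscles.values():
        entry = {
            "acronym": m.acronym,
            "points": [{"segment": s, "xyz": p.tolist()} for s, p in m.points],
        }
        if m.name:
            entry["name"] = m.name
        if any(m.inference):
            entry["inference"] = list(m.inference)
        if m.wraps:
            entry["wraps"] = [{
                "kind": w.kind, "segment": w.segment,
                "origin": w.frame[:3, 3].tolist(),
                "axis_x": w.frame[:3, 0].tolist(),
                "axis_y": w.frame[:3, 1].tolist(),
                "axis_z": w.frame[:3, 2].tolist(),
                "radius": w.radius, "side": w.side,
            } for w in m.wraps]
        cfg["muscles"].append(entry)
    if model.landmarks:
        cfg["landmarks"] = {k: {"segment": lm.segment, "xyz": lm.point.tolist()}
                            for k, lm in model.landmarks.items()}
    if model.chains:
        cfg["chains"] = {k: list(v) for k, v in model.chains.items()}
    if model.preset_poses:
        cfg["poses"] = {k: {j: dict(d) for j, d in v.items()}
                        for k, v in model.preset_poses.items()}
    if model.foot_support is not None:
        cfg["foot_support"] = [float(x) for x in model.foot_support]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def write_bundle(skeleton, outdir) -> Path:
    """Write a synthetic skeleton as a directory bundle.

    Layout: ``model.yaml`` + ``meshes/*.obj`` + ``ground_truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_model(skeleton.model, outdir / "model.yaml")
    truth = dict(skeleton.truth)
    truth["seed"] = skeleton.seed
    truth["config_hash"] = skeleton.config_hash()

    def jsonable(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if hasattr(obj, "to_dict"):
            return obj.to_dict()
        if isinstance(obj, dict):
            return {k: jsonable(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [jsonable(v) for v in obj]
        return obj

    with open(outdir / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(jsonable(truth), fh, indent=2, sort_keys=True)
    return outdir


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def load_rom_fixture() -> dict:
    """Published joint ROM limits (degrees), keyed joint → dof → (lo, hi)."""
    with _fixture_path("riojasuchus_rom.yaml").open(encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return {
        jname: {
            "dofs": tuple(j["dofs"]),
            "rom": {dof: tuple(float(v) for v in pair)
                    for dof, pair in j["rom"].items()},
        }
        for jname, j in cfg["joints"].items()
    }


def load_muscle_table() -> pd.DataFrame:
    """The hindlimb muscle origin/insertion table as a DataFrame."""
    with _fixture_path("riojasuchus_muscles.csv").open(encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_summary_fixture() -> dict:
    """Printed whole-body summary (masses kg, lengths m)."""
    with _fixture_path("riojasuchus_summary.yaml").open(encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_feature_fixture() -> list:
    """Posture-classification features for the study taxon (both estimates)."""
    with _fixture_path("riojasuchus_features.yaml").open(encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    out = []
    for rec in cfg["records"]:
        out.append(
            FeatureRecord(
                taxon=rec["taxon"],
                body_mass_kg=float(rec["body_mass_kg"]),
                com_dimensionless=float(rec["com_craniad_offset_m"])
                / float(rec["ga_distance_m"]),
                forelimb_m=float(rec["forelimb_m"]),
                hindlimb_m=float(rec["hindlimb_m"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# hoop stacks and sweeps
# ---------------------------------------------------------------------------

_HOOP_COLS = ["segment", "station"] + [f"v{i}{ax}" for i in range(8) for ax in "xyz"]


def load_hoop_stacks_csv(path) -> dict:
    """Hoop stacks from CSV (segment, station, v0x..v7z), metres."""
    df = pd.read_csv(path)
    missing = [c for c in _HOOP_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"hoop CSV missing columns: {missing}")
    stacks: dict = {}
    for _, row in df.sort_values(["segment", "station"]).iterrows():
        verts = np.array([[row[f"v{i}{ax}"] for ax in "xyz"] for i in range(8)],
                         dtype=float)
        stacks.setdefault(row["segment"], []).append(
            Hoop(station=float(row["station"]), vertices=verts)
        )
    return stacks


def save_hoop_stacks_csv(stacks: dict, path) -> None:
    rows = []
    for name, hoops in stacks.items():
        for h in hoops:
            row = {"segment": name, "station": h.station}
            for i, (x, y, z) in enumerate(h.vertices):
                row.update({f"v{i}x": x, f"v{i}y": y, f"v{i}z": z})
            rows.append(row)
    pd.DataFrame(rows, columns=_HOOP_COLS).to_csv(path, index=False)


def sweeps_to_csv(curves: list, path) -> None:
    """Tidy CSV of moment-arm sweeps: muscle, joint, dof, angle_deg, moment_arm_m."""
    rows = []
    for c in curves:
        for ang, r in zip(c.angles_deg, c.moment_arm_m):
            rows.append({"muscle": c.muscle, "joint": c.joint, "dof": c.dof,
                         "angle_deg": ang, "moment_arm_m": r, "h_deg": c.h_deg})
    pd.DataFrame(rows).to_csv(path, index=False)


def sweeps_from_csv(path) -> list:
    df = pd.read_csv(path)
    curves = []
    for (muscle, joint, dof), grp in df.groupby(["muscle", "joint", "dof"], sort=False):
        grp = grp.sort_values("angle_deg")
        curves.append(MomentArmCurve(
            muscle=muscle, joint=joint, dof=dof,
            angles_deg=grp["angle_deg"].to_numpy(),
            moment_arm_m=grp["moment_arm_m"].to_numpy(),
            h_deg=float(grp["h_deg"].iloc[0]),
        ))
    return curves
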