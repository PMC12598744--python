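"""File formats: eye-model JSON, run configuration, CSV exports and manifests.

The eye-model JSON schema (``model_version`` 1) stores per-structure point
lists at full float precision (Python ``repr`` round-trip, bit-exact), the
rotation point, globe radius/centre and laterality, all in the gaze-centered
frame described in :mod:`ocugaze.eye_model`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import SchemaError
from .eye_model import STRUCTURE_LABELS, EyeModel, StructureCloud

MODEL_VERSION = 1


def write_eye_model(model: EyeModel, path) -> None:
    """Serialize a model to JSON (gaze-centered frame, full precision)."""
    base = model.to_base()
    doc = {
        "model_version": MODEL_VERSION,
        "laterality": base.laterality,
        "globe_radius": base.globe_radius,
        "globe_centre": base.globe_centre.tolist(),
        "rotation_point": base.rotation_point.tolist(),
        "structures": {name: cloud.points.tolist()
                       for name, cloud in base.structures.items()},
    }
    if base.tumor_spec is not None:
        doc["tumor_spec"] = asdict(base.tumor_spec)
    Path(path).write_text(json.dumps(doc, indent=1))


def read_eye_model(path) -> EyeModel:
    """Read and validate an eye-model JSON file."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed JSON in {path}: {exc}") from exc
    if doc.get("model_version") != MODEL_VERSION:
        raise SchemaError(f"unsupported model_version {doc.get('model_version')!r}")
    for key in ("laterality", "globe_radius", "rotation_point", "structures"):
        if key not in doc:
            raise SchemaError(f"eye-model file missing field '{key}'")
    structs = doc["structures"]
    missing = [s for s in STRUCTURE_LABELS if s not in structs]
    if missing:
        raise SchemaError(f"eye-model file missing structures: {missing}")
    structures = {}
    for name, pts in structs.items():
        arr = np.asarray(pts, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3 or not np.all(np.isfinite(arr)):
            raise SchemaError(f"malformed coordinates for structure '{name}'")
        structures[name] = StructureCloud(name, arr)
    spec = None
    if "tumor_spec" in doc:
        from .eye_model import TumorSpec
        spec = TumorSpec(**doc["tumor_spec"])
    model = EyeModel(
        structures=structures,
        rotation_point=np.asarray(doc["rotation_point"], dtype=float),
        globe_radius=float(doc["globe_radius"]),
        globe_centre=np.asarray(doc.get("globe_centre", [0.0, 0.0, 0.0]), dtype=float),
        laterality=doc["laterality"],
        tumor_spec=spec,
    )
    model.validate()
    return model


@dataclass
class RunConfig:
    """Resolved configuration of one run; round-trips through YAML unchanged."""

    seed: int = 0
    prescription: float = 60.0
    n_fractions: int = 4
    distal_margin: float = 2.5
    proximal_margin: float = 2.5
    lateral_margin: float = 2.5
    distal_falloff_80_20: float = 1.0
    lateral_penumbra_80_20: float = 2.0
    grid_shape: tuple = (60, 60, 60)
    grid_spacing: float = 0.59
    weights: dict = field(default_factory=lambda: {
        "macula": 3.0, "optic_disc": 3.0, "cornea": 1.0,
        "retina": 1.0, "ciliary_body": 1.0, "lens": 1.0})
    dense_radius: float = 50.0
    dense_spacing: float = 9.0
    sparse_spacing: float = 25.0
    dense_attempts: int = 200
    sparse_attempts: int = 150
    polar_max: float = 25.0
    plane_distance: float = 132.5

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["grid_shape"] = list(doc["grid_shape"])
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise SchemaError(f"config file {path} is not a mapping")
        if "grid_shape" in doc:
            doc["grid_shape"] = tuple(doc["grid_shape"])
        try:
            return cls(**doc)
        except TypeError as exc:
            raise SchemaError(f"unknown config field: {exc}") from exc


def write_manifest(path, **entries) -> None:
    """Flat key-value run manifest (YAML)."""
    flat = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in entries.items()}
    Path(path).write_text(yaml.safe_dump(flat, sort_keys=True))


def records_to_frame(records) -> "pd.DataFrame":
    """Scattered evaluation records as a flat table (one row per candidate)."""
    import pandas as pd

    rows = []
    for r in records:
        row = {"index": r.index, "x_mm": r.fixation.x, "y_mm": r.fixation.y,
               "polar_deg": r.fixation.polar, "azimuth_deg": r.fixation.azimuth,
               "treatable": r.treatable, "cost": r.cost, "reason": r.reason}
        if r.ntcp:
            row.update({f"ntcp_{k}": v for k, v in r.ntcp.items()})
        if r.metrics is not None:
            row.update(r.metrics.as_row())
        rows.append(row)
    return pd.DataFrame(rows)


def export_dose_grid(grid, path) -> None:
    """Chunked HDF5 export of a dose grid and its structure masks, with the
    grid geometry (spacing, origin, prescription) stored as attributes."""
    import h5py

    with h5py.File(path, "w") as fh:
        d = fh.create_dataset("dose", data=grid.dose, chunks=True,
                              compression="gzip")
        d.attrs["units"] = "GyRBE"
        fh.attrs["spacing_mm"] = grid.spacing
        fh.attrs["origin_mm"] = grid.origin
        fh.attrs["prescription_gyrbe"] = grid.prescription
        g = fh.create_group("masks")
        for name, mask in grid.masks.items():
            g.create_dataset(name, data=mask, chunks=True, compression="gzip")


def read_dose_grid(path):
    """Read back a dose grid written by :func:`export_dose_grid`."""
    import h5py

    from .dose import DoseGrid

    with h5py.File(path, "r") as fh:
        dose = fh["dose"][...]
        grid = DoseGrid(shape=dose.shape, spacing=float(fh.attrs["spacing_mm"]),
                        origin=np.asarray(fh.attrs["origin_mm"]), dose=dose,
                        prescription=float(fh.attrs["prescription_gyrbe"]))
        grid.masks = {name: ds[...].astype(bool)
                      for name, ds in fh["masks"].items()}
    return grid


ENSEMBLE_FORMAT_VERSION = 1


def save_ensemble(ensemble, path) -> None:
    """Versioned model file (pickle payload + feature-name manifest)."""
    import pickle

    with open(path, "wb") as fh:
        pickle.dump({"format_version": ENSEMBLE_FORMAT_VERSION,
                     "feature_names": list(ensemble.feature_names),
                     "ensemble": ensemble}, fh)


def load_ensemble(path):
    import pickle

    with open(path, "rb") as fh:
        doc = pickle.load(fh)
    if doc.get("format_version") != ENSEMBLE_FORMAT_VERSION:
        raise SchemaError(f"unsupported model file version "
                          f"{doc.get('format_version')!r}")
    return doc["ensemble"]


def export_map_csv(gaze_map, path, spacing: float = 2.0) -> None:
    """Regular-raster CSV (x mm, y mm, value) of a continuous gaze map."""
    import csv

    raster = gaze_map.raster(spacing=spacing)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x_mm", "y_mm", gaze_map.quantity])
        for x, y, v in raster:
            w.writerow([f"{x:.6g}", f"{y:.6g}", f"{v:.8g}"])
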