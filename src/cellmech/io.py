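"""Readers and writers for the plain-text dialects used across the package.

Force curves: CSV with a position column (``z_m``/``z_um``/``z_nm``, or
``separation_*``) and a force column (``force_N``/``force_nN``/``force_pN``),
optional ``segment`` column (approach/retract), plus a JSON metadata sidecar
carrying probe geometry, spring constant and trigger force.  Unit suffixes
on the column names are honored, so the same curve expressed in nm/nN or
m/N parses to identical SI arrays.

Localization tables: CSV ``nucleus_id, x_nm, y_nm``.  Track tables: CSV
``track_id, frame, t_h, x_um, y_um``.  Vector fields: CSV ``x_m, y_m,
ux_m, uy_m`` (or ``tx_Pa, ty_Pa``) on a regular grid.  Bead images: TIFF.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .afm import ForceCurve, ProbeGeometry
from .chromatin import LocalizationSet
from .tfm import DisplacementField, TractionField
from .tracks import TrackTable

_LENGTH_UNITS = {"m": 1.0, "um": 1e-6, "nm": 1e-9}
_FORCE_UNITS = {"N": 1.0, "nN": 1e-9, "pN": 1e-12}


def _find_column(columns, stems, units):
    for col in columns:
        for stem in stems:
            prefix = stem + "_"
            if col.startswith(prefix) and col[len(prefix):] in units:
                return col, units[col[len(prefix):]]
    raise ValueError(f"no column matching {stems} with units {sorted(units)}")


def read_force_curve(csv_path, meta_path=None) -> ForceCurve:
    """Read a force-curve CSV plus its JSON metadata sidecar."""
    csv_path = Path(csv_path)
    if meta_path is None:
        meta_path = csv_path.with_suffix(".json")
    meta = json.loads(Path(meta_path).read_text())
    df = pd.read_csv(csv_path)
    zcol, zscale = _find_column(df.columns, ("z", "separation"), _LENGTH_UNITS)
    fcol, fscale = _find_column(df.columns, ("force",), _FORCE_UNITS)
    if "segment" in df.columns:
        df = df[df["segment"].str.lower() == "approach"]
    probe = ProbeGeometry(
        kind=meta["probe_kind"],
        spring_constant=meta["spring_constant_N_per_m"],
        R=meta.get("R_m"),
        theta=math.radians(meta["theta_deg"]) if "theta_deg" in meta else None,
    )
    order = np.argsort(df[zcol].to_numpy())
    return ForceCurve(
        z=df[zcol].to_numpy(dtype=float)[order] * zscale,
        force=df[fcol].to_numpy(dtype=float)[order] * fscale,
        probe=probe,
        trigger_force=meta["trigger_force_N"],
        sample_thickness=meta.get("sample_thickness_m"),
        site_label=meta.get("site_label", ""),
    )


def write_force_curve(curve: ForceCurve, csv_path, meta_path=None) -> None:
    csv_path = Path(csv_path)
    pd.DataFrame({"z_m": curve.z, "force_N": curve.force}).to_csv(
        csv_path, index=False)
    meta = {
        "probe_kind": curve.probe.kind,
        "spring_constant_N_per_m": curve.probe.spring_constant,
        "trigger_force_N": curve.trigger_force,
        "site_label": curve.site_label,
    }
    if curve.probe.R is not None:
        meta["R_m"] = curve.probe.R
    if curve.probe.theta is not None:
        meta["theta_deg"] = math.degrees(curve.probe.theta)
    if curve.sample_thickness is not None:
        meta["sample_thickness_m"] = curve.sample_thickness
    Path(meta_path or csv_path.with_suffix(".json")).write_text(
        json.dumps(meta, indent=1))


def read_localizations(csv_path, nucleus_id: Optional[str] = None) -> list[LocalizationSet]:
    """Read a localization CSV into one LocalizationSet per nucleus."""
    df = pd.read_csv(csv_path)
    if "nucleus_id" not in df.columns:
        df = df.assign(nucleus_id=nucleus_id or "nucleus0")
    out = []
    for nid, g in df.groupby("nucleus_id"):
        out.append(LocalizationSet(
            points=g[["x_nm", "y_nm"]].to_numpy(dtype=float),
            nucleus_id=str(nid)))
    return out


def write_localizations(locs: LocalizationSet, csv_path) -> None:
    pd.DataFrame({
        "nucleus_id": locs.nucleus_id or "nucleus0",
        "x_nm": locs.points[:, 0],
        "y_nm": locs.points[:, 1],
    }).to_csv(csv_path, index=False)


def read_tracks(csv_path, gradient_axis=None) -> TrackTable:
    df = pd.read_csv(csv_path)
    return TrackTable(df, gradient_axis=gradient_axis)


def write_tracks(table: TrackTable, csv_path) -> None:
    cols = ["track_id", "frame", "t_h", "x_um", "y_um"]
    table.data[cols].to_csv(csv_path, index=False)


def read_displacement_field(csv_path) -> DisplacementField:
    df = pd.read_csv(csv_path)
    xs = np.sort(df["x_m"].unique())
    ys = np.sort(df["y_m"].unique())
    spacing = float(xs[1] - xs[0])
    u = np.zeros((len(ys), len(xs), 2))
    ix = np.searchsorted(xs, df["x_m"].to_numpy())
    iy = np.searchsorted(ys, df["y_m"].to_numpy())
    u[iy, ix, 0] = df["ux_m"].to_numpy()
    u[iy, ix, 1] = df["uy_m"].to_numpy()
    return DisplacementField(u=u, spacing=spacing)


def write_displacement_field(field: DisplacementField, csv_path) -> None:
    ny, nx = field.shape
    X, Y = np.meshgrid(np.arange(nx) * field.spacing, np.arange(ny) * field.spacing)
    pd.DataFrame({
        "x_m": X.ravel(), "y_m": Y.ravel(),
        "ux_m": field.u[:, :, 0].ravel(), "uy_m": field.u[:, :, 1].ravel(),
    }).to_csv(csv_path, index=False)


def write_traction_field(field: TractionField, csv_path) -> None:
    ny, nx = field.shape
    X, Y = np.meshgrid(np.arange(nx) * field.spacing, np.arange(ny) * field.spacing)
    pd.DataFrame({
        "x_m": X.ravel(), "y_m": Y.ravel(),
        "tx_Pa": field.T[:, :, 0].ravel(), "ty_Pa": field.T[:, :, 1].ravel(),
    }).to_csv(csv_path, index=False)


def read_image_stack(path) -> np.ndarray:
    arr = tifffile.imread(path)
    return arr[None, ...] if arr.ndim == 2 else arr


def write_image_stack(stack: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))
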