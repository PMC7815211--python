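"""Table/image I/O, schema validation and provenance records.

All on-disk tables are CSV with unit-suffixed column names; every writer
prepends comment lines (``#``) carrying the package version and a hash of
the generating configuration, and analysis runs drop a JSON provenance
record (config + seed + version) next to their outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .quant import CellTrack
from .synthetic import AspirationTrace, DoubletGeometry, NucleiFrames, QuantImage

__all__ = [
    "read_table",
    "write_table",
    "write_provenance",
    "write_doublet_csv",
    "read_doublet_csv",
    "write_trace_csv",
    "read_trace_csv",
    "write_nuclei_csv",
    "read_nuclei_csv",
    "write_image",
    "read_image",
    "read_tracks_csv",
    "read_angles_csv",
]

#: column name -> numpy dtype kind string ("f" float, "i" int, "O"/"U" text)
Schema = Mapping[str, str]

DOUBLET_SCHEMA: Schema = {
    "cell_id": "O",
    "arc_id": "O",
    "point_index": "i",
    "x_um": "f",
    "y_um": "f",
}
TRACE_SCHEMA: Schema = {"t_s": "f", "l_um": "f", "pressure_pa": "f"}
NUCLEI_SCHEMA: Schema = {
    "frame": "i",
    "t_min": "f",
    "nucleus_id": "i",
    "x_um": "f",
    "y_um": "f",
    "layer": "O",
}
TRACK_SCHEMA: Schema = {"cell_id": "O", "frame": "i", "t_min": "f", "x_um": "f", "y_um": "f"}
ANGLES_SCHEMA: Schema = {
    "doublet_id": "O",
    "vertex_id": "O",
    "theta_a_deg": "f",
    "theta_b_deg": "f",
    "bleb_adjacent": "b",
}


def config_hash(config: Mapping[str, Any]) -> str:
    """Short stable hash of a JSON-serialisable configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def read_table(path: str | Path, schema: Schema) -> pd.DataFrame:
    """Read a CSV and validate its columns against a schema.

    Comment lines (``#``) are skipped.  Missing or extra required columns and
    non-numeric cells in numeric columns raise ``ValueError`` naming the
    offending column (and row).
    """
    df = pd.read_csv(path, comment="#")
    missing = set(schema) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns: {sorted(missing)}")
    for col, kind in schema.items():
        if kind in ("f", "i"):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(np.where(bad)[0][0])
                raise ValueError(f"{path}: non-numeric value in column {col!r}, row {row}")
            df[col] = coerced.astype(float if kind == "f" else int)
        elif kind == "b":
            df[col] = df[col].astype(bool)
    return df


def write_table(
    df: pd.DataFrame, path: str | Path, config: Mapping[str, Any] | None = None
) -> None:
    """Write a CSV with a version/config-hash header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# tissuemech {__version__}"
    if config is not None:
        header += f" config_hash={config_hash(config)}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False)


def write_provenance(
    outdir: str | Path, config: Mapping[str, Any], seed: int | None = None
) -> Path:
    """Write a machine-readable provenance record next to run outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record = {
        "software": "tissuemech",
        "version": __version__,
        "seed": seed,
        "config": dict(config),
        "config_hash": config_hash(config),
    }
    path = outdir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True, default=str) + "\n")
    return path


# ---------------------------------------------------------------------------
# doublets


def write_doublet_csv(
    geometry: DoubletGeometry, path: str | Path, doublet_id: str = "d0"
) -> None:
    """Outline CSV (cell_id, arc_id, point_index, x_um, y_um) + ground-truth JSON."""
    rows = []
    for arc_id, pts in geometry.arcs.items():
        cell = {"freeA": "A", "freeB": "B", "contact": "AB"}.get(arc_id, "?")
        for i, (x, y) in enumerate(np.asarray(pts)):
            rows.append(
                {"cell_id": cell, "arc_id": arc_id, "point_index": i, "x_um": x, "y_um": y}
            )
    write_table(pd.DataFrame(rows), path, config={"doublet_id": doublet_id})
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "doublet_id": doublet_id,
                "vertices_um": np.asarray(geometry.vertices).tolist(),
                "ground_truth": geometry.ground_truth,
            },
            indent=2,
        )
        + "\n"
    )


def read_doublet_csv(path: str | Path) -> DoubletGeometry:
    df = read_table(path, DOUBLET_SCHEMA)
    arcs: dict[str, np.ndarray] = {}
    for arc_id, grp in df.groupby("arc_id"):
        grp = grp.sort_values("point_index")
        arcs[str(arc_id)] = grp[["x_um", "y_um"]].to_numpy(dtype=float)
    for required in ("freeA", "freeB", "contact"):
        if required not in arcs:
            raise ValueError(f"{path}: missing arc {required!r}")
    sidecar = Path(path).with_suffix(".json")
    gt: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        gt = meta.get("ground_truth", {})
        vertices = np.asarray(meta["vertices_um"], dtype=float)
    else:
        vertices = np.stack([arcs["contact"][0], arcs["contact"][-1]])
    return DoubletGeometry(arcs=arcs, vertices=vertices, ground_truth=gt)


# ---------------------------------------------------------------------------
# aspiration traces


def write_trace_csv(trace: AspirationTrace, path: str | Path) -> None:
    """Trace CSV (t_s, l_um, pressure_pa) + sidecar JSON with geometry."""
    df = pd.DataFrame(
        {"t_s": trace.t_s, "l_um": trace.l_um, "pressure_pa": trace.pressure_pa}
    )
    write_table(df, path)
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "r_p_um": trace.r_p,
                "r_0_um": trace.r_0,
                "delta_p_pa": trace.delta_p,
                "t_release_s": trace.t_release,
                "clipped": trace.clipped,
                "ground_truth": trace.ground_truth,
            },
            indent=2,
        )
        + "\n"
    )


def read_trace_csv(path: str | Path) -> AspirationTrace:
    df = read_table(path, TRACE_SCHEMA)
    t = df["t_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: t_s must be strictly increasing")
    sidecar = Path(path).with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"sidecar JSON not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    return AspirationTrace(
        t_s=t,
        l_um=df["l_um"].to_numpy(),
        delta_p=float(meta["delta_p_pa"]),
        t_release=float(meta["t_release_s"]),
        r_p=float(meta["r_p_um"]),
        r_0=float(meta["r_0_um"]),
        clipped=bool(meta.get("clipped", False)),
        ground_truth=meta.get("ground_truth", {}),
    )


# ---------------------------------------------------------------------------
# nuclei, tracks, angles


def write_nuclei_csv(frames: NucleiFrames, path: str | Path) -> None:
    write_table(frames.table, path, config=frames.ground_truth)


def read_nuclei_csv(path: str | Path) -> NucleiFrames:
    return NucleiFrames(table=read_table(path, NUCLEI_SCHEMA))


def read_tracks_csv(path: str | Path) -> list[CellTrack]:
    """Tracks CSV (cell_id, frame, t_min, x_um, y_um[, morphology])."""
    df = read_table(path, TRACK_SCHEMA)
    tracks = []
    for cell_id, grp in df.groupby("cell_id"):
        grp = grp.sort_values("frame")
        tracks.append(
            CellTrack(
                cell_id=str(cell_id),
                frames=grp["frame"].to_numpy(),
                t_min=grp["t_min"].to_numpy(),
                x_um=grp["x_um"].to_numpy(),
                y_um=grp["y_um"].to_numpy(),
                morphology=grp["morphology"].tolist() if "morphology" in grp else None,
            )
        )
    return tracks


def read_angles_csv(path: str | Path) -> pd.DataFrame:
    """Per-vertex angle table for manually measured doublets."""
    return read_table(path, ANGLES_SCHEMA)


# ---------------------------------------------------------------------------
# images


def write_image(img: QuantImage, path: str | Path) -> None:
    """Multi-channel TIFF + JSON sidecar (pixel size, channel names) + mask TIFFs."""
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    names = sorted(img.channels)
    stack = np.stack([img.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(path, stack)
    for mask_name, mask in img.masks.items():
        tifffile.imwrite(
            path.with_name(f"{path.stem}_mask_{mask_name}.tif"), mask.astype(np.uint8)
        )
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "pixel_size_um": img.pixel_size_um,
                "channels": names,
                "masks": sorted(img.masks),
            },
            indent=2,
        )
        + "\n"
    )


def read_image(path: str | Path) -> QuantImage:
    import tifffile

    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"sidecar JSON not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    channels = {n: stack[i].astype(float) for i, n in enumerate(meta["channels"])}
    masks = {}
    for mask_name in meta.get("masks", []):
        mpath = path.with_name(f"{path.stem}_mask_{mask_name}.tif")
        if mpath.exists():
            masks[mask_name] = tifffile.imread(mpath).astype(bool)
    return QuantImage(
        channels=channels, pixel_size_um=float(meta["pixel_size_um"]), masks=masks
    )
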