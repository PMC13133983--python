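"""Particle metadata tables and STAR-format I/O.

A :class:`ParticleTable` wraps a :class:`pandas.DataFrame` with one row per
picked filament segment.  Canonical columns (internal names):

========================  =====================================================
column                    meaning
========================  =====================================================
``micrograph_id``         source micrograph (string)
``filament_id``           filament/tube id, unique within a micrograph
``particle_id``           unique integer id within the table
``x``, ``y``              pick coordinates, 0-based pixels in the micrograph
``pixel_size``            Å per pixel
``rot``, ``tilt``,        ZYZ Euler angles in degrees (see :mod:`mtseam.lattice`)
``psi``
``dx``, ``dy``            origin shifts in Å (image-plane, applied to re-center)
``class_id``              3D class label (nullable integer)
``register``              monomer register label: ``A``, ``B`` or ``unassigned``
``pf_index``              protofilament index 0..N-1, set only after expansion
``parent_id``             particle_id of the pre-expansion parent (nullable)
========================  =====================================================

On disk the table is a RELION-style STAR file with a ``data_particles``
block; the column map below translates between internal and STAR tags.
Columns not in the map are preserved verbatim (as text) through a
read/write round-trip.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from gemmi import cif

__all__ = ["ParticleTable", "read_star", "write_star", "StarFormatError"]

REGISTER_A = "A"
REGISTER_B = "B"
REGISTER_UNASSIGNED = "unassigned"

# internal name -> (STAR tag, dtype)
STAR_COLUMN_MAP: dict[str, tuple[str, str]] = {
    "micrograph_id": ("_rlnMicrographName", "str"),
    "filament_id": ("_rlnHelicalTubeID", "int"),
    "particle_id": ("_mtsParticleId", "int"),
    "x": ("_rlnCoordinateX", "float"),
    "y": ("_rlnCoordinateY", "float"),
    "pixel_size": ("_rlnImagePixelSize", "float"),
    "rot": ("_rlnAngleRot", "float"),
    "tilt": ("_rlnAngleTilt", "float"),
    "psi": ("_rlnAnglePsi", "float"),
    "dx": ("_rlnOriginXAngst", "float"),
    "dy": ("_rlnOriginYAngst", "float"),
    "class_id": ("_rlnClassNumber", "nullable_int"),
    "register": ("_mtsRegister", "str"),
    "pf_index": ("_mtsProtofilamentIndex", "nullable_int"),
    "parent_id": ("_mtsParentParticleId", "nullable_int"),
}
_TAG_TO_COLUMN = {tag: (col, kind) for col, (tag, kind) in STAR_COLUMN_MAP.items()}

REQUIRED_COLUMNS = ("micrograph_id", "filament_id", "x", "y", "rot", "tilt", "psi")


class StarFormatError(ValueError):
    """A STAR file does not satisfy the particle-table contract."""


class ParticleTable:
    """Ordered collection of particle records backed by a DataFrame."""

    def __init__(self, df: pd.DataFrame, provenance: str = ""):
        self.df = _normalize(df)
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "ParticleTable":
        return ParticleTable(self.df.copy(), self.provenance)

    def filament_groups(self):
        """Iterate (micrograph_id, filament_id) -> sub-frame, in sorted key order."""
        return self.df.groupby(["micrograph_id", "filament_id"], sort=True)

    def order_along_filaments(self) -> "ParticleTable":
        """Sort each filament's records by arc position along the filament.

        Arc position is the projection of the pick coordinates onto the
        filament's principal axis; idempotent on an already-ordered table.
        The sign of the axis is fixed so the first pick (in current order)
        projects lower than the last, keeping the operation stable.
        """
        parts = []
        for _, grp in self.filament_groups():
            parts.append(grp.iloc[_arc_order(grp)])
        out = pd.concat(parts, axis=0) if parts else self.df
        return ParticleTable(out.reset_index(drop=True), self.provenance)


def _arc_order(grp: pd.DataFrame) -> np.ndarray:
    xy = grp[["x", "y"]].to_numpy(dtype=float)
    if len(xy) < 2:
        return np.arange(len(xy))
    centered = xy - xy.mean(axis=0)
    # principal axis via SVD; stable sign: end minus start
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if axis @ (xy[-1] - xy[0]) < 0:
        axis = -axis
    t = centered @ axis
    return np.argsort(t, kind="stable")


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise StarFormatError(f"missing required column(s): {', '.join(missing)}")
    if "particle_id" not in df.columns:
        df["particle_id"] = np.arange(len(df), dtype=np.int64)
    if "pixel_size" not in df.columns:
        df["pixel_size"] = np.nan
    for col, default in (("dx", 0.0), ("dy", 0.0)):
        if col not in df.columns:
            df[col] = default
    if "register" not in df.columns:
        df["register"] = REGISTER_UNASSIGNED
    for col in ("class_id", "pf_index", "parent_id"):
        if col not in df.columns:
            df[col] = pd.array([pd.NA] * len(df), dtype="Int64")
        else:
            df[col] = df[col].astype("Int64")
    df["filament_id"] = df["filament_id"].astype(np.int64)
    df["particle_id"] = df["particle_id"].astype(np.int64)
    for col in ("x", "y", "pixel_size", "rot", "tilt", "psi", "dx", "dy"):
        df[col] = df[col].astype(float)
    if len(df) and df["particle_id"].duplicated().any():
        raise StarFormatError("particle_id values are not unique")
    ps = df["pixel_size"].dropna()
    if len(ps) and not (ps > 0).all():
        raise StarFormatError("pixel_size must be positive")
    pf_set = df["pf_index"].notna()
    parent_set = df["parent_id"].notna()
    if not (pf_set == parent_set).all():
        raise StarFormatError("pf_index and parent_id must be set together")
    return df


def _format_value(value, kind: str) -> str:
    if kind in ("nullable_int",) and pd.isna(value):
        return "-1"
    if kind == "float":
        if pd.isna(value):
            return "nan"
        return repr(float(value))  # shortest exact round-trip representation
    if kind in ("int", "nullable_int"):
        return str(int(value))
    text = str(value)
    return text if text and " " not in text else cif.quote(text)


def _parse_column(values: list[str], kind: str, tag: str):
    try:
        if kind == "float":
            return np.array([float(v) for v in values], dtype=float)
        if kind == "int":
            return np.array([int(float(v)) for v in values], dtype=np.int64)
        if kind == "nullable_int":
            parsed = [int(float(v)) for v in values]
            return pd.array([pd.NA if p < 0 else p for p in parsed], dtype="Int64")
    except ValueError:
        for row, v in enumerate(values):
            try:
                float(v)
            except ValueError:
                raise StarFormatError(
                    f"malformed numeric cell {v!r} in column {tag} at row {row}"
                ) from None
        raise
    return [cif.as_string(v) for v in values]


def read_star(path) -> ParticleTable:
    """Read a particle table from a RELION-style STAR file.

    Requires the coordinate, Euler-angle and tube-id columns; all other
    mapped columns are optional and unknown columns are carried through as
    text so they survive a round-trip.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = cif.read_file(str(path))
    block = doc.find_block("particles") or doc.sole_block()
    tags: list[str] = []
    for item in block:
        if item.loop is not None:
            tags = list(item.loop.tags)
            break
    if not tags:
        raise StarFormatError(f"no loop found in {path}")
    data: dict[str, object] = {}
    extra: dict[str, list[str]] = {}
    for tag in tags:
        values = list(block.find_loop(tag))
        if tag in _TAG_TO_COLUMN:
            col, kind = _TAG_TO_COLUMN[tag]
            data[col] = _parse_column(values, kind, tag)
        else:
            extra[tag] = [cif.as_string(v) for v in values]
    present = set(data)
    missing = [
        STAR_COLUMN_MAP[c][0] for c in REQUIRED_COLUMNS if c not in present
    ]
    if missing:
        raise StarFormatError(
            f"{path} is missing required column(s): {', '.join(missing)}"
        )
    df = pd.DataFrame(data)
    for tag, values in extra.items():
        df[tag] = values
    return ParticleTable(df, provenance=str(path))


def write_star(table: ParticleTable, path) -> None:
    """Write a particle table as a STAR file with a data_particles block."""
    df = table.df
    doc = cif.Document()
    block = doc.add_new_block("particles")
    known = [c for c in STAR_COLUMN_MAP if c in df.columns]
    extra = [c for c in df.columns if c not in STAR_COLUMN_MAP]
    tags = [STAR_COLUMN_MAP[c][0] for c in known] + list(extra)
    loop = block.init_loop("", tags)
    text_columns = [
        [_format_value(v, STAR_COLUMN_MAP[c][1]) for v in df[c]] for c in known
    ] + [[str(v) for v in df[c]] for c in extra]
    for cells in zip(*text_columns) if text_columns else ():
        loop.add_row(list(cells))
    doc.write_file(str(path))


def concat_tables(tables: Iterable[ParticleTable]) -> ParticleTable:
    """Concatenate tables, offsetting particle ids (and parent links) to
    keep them unique when the inputs collide."""
    frames = [t.df.copy() for t in tables]
    ids = pd.concat([f["particle_id"] for f in frames]) if frames else pd.Series(dtype=np.int64)
    if ids.duplicated().any():
        offset = 0
        for f in frames:
            f["particle_id"] = f["particle_id"] + offset
            if f["parent_id"].notna().any():
                f["parent_id"] = f["parent_id"] + offset
            offset = int(f["particle_id"].max()) + 1 if len(f) else offset
    return ParticleTable(pd.concat(frames, ignore_index=True))
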