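"""Pseudo-helical symmetry expansion, register shifts and metadata recentering.

A microtubule is only pseudo-helical (the seam breaks true symmetry), but
each particle can still be replicated N times under the helical operator so
that every protofilament is treated as an independent particle centered in
the box.  Copy k composes the particle's orientation with a rotation of
k*twist about the helix axis and picks up the image-plane projection of the
k*rise axial translation in its origin shifts.

The same projection machinery serves two further metadata operations: a 3D
recentering offset applied to all particles (focusing the box on one
protofilament and, later, reverting that), and the register-correction
shift, which translates one register class by a tubulin monomer (41 Å)
along the axis so both classes average in the same monomer register.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .lattice import HelicalSymmetry, wrap_angle
from .particles import REGISTER_A, REGISTER_B, REGISTER_UNASSIGNED, ParticleTable

__all__ = [
    "symmetry_expand",
    "shift_register",
    "recenter_metadata",
    "unexpand_at_seam",
    "project_offset",
]

logger = logging.getLogger(__name__)

MONOMER_SHIFT_A = 41.0


class ExpansionError(ValueError):
    """The table is not in the expected expansion state."""


def _rotations(df: pd.DataFrame) -> Rotation:
    """Reference-to-image rotations of every record (vectorized)."""
    angles = np.stack(
        [df["psi"].to_numpy(float), df["tilt"].to_numpy(float), df["rot"].to_numpy(float)],
        axis=1,
    )
    return Rotation.from_euler("ZYZ", angles, degrees=True)


def project_offset(df: pd.DataFrame, offset_3d_A: np.ndarray) -> np.ndarray:
    """Image-plane projection of a reference-frame 3D offset, per record.

    Returns an (n, 2) array of (dx, dy) increments in Å: the first two
    components of R(euler) @ offset.  A positive increment records that the
    feature sits at that displacement from the pick and extraction should
    re-center there.
    """
    offset = np.asarray(offset_3d_A, dtype=float)
    if offset.shape != (3,):
        raise ValueError("offset must be a 3-vector in Å")
    rotated = _rotations(df).apply(offset)
    return rotated[:, :2]


def symmetry_expand(table: ParticleTable, sym: HelicalSymmetry, n_pf: int) -> ParticleTable:
    """Replicate each particle N-fold under the helical operator.

    Copy k (k = 0..N-1) keeps the parent's tilt/psi, adds k*twist to rot,
    and adds the image-plane projection of a k*rise axial translation to
    its origin shifts.  pf_index/parent_id mark the copies; particle ids
    are renumbered to stay unique.
    """
    df = table.df
    if df["pf_index"].notna().any():
        raise ExpansionError("table already expanded (pf_index set)")
    copies = []
    rots = _rotations(df)
    next_id = 0
    for k in range(n_pf):
        copy = df.copy()
        copy["rot"] = wrap_angle(df["rot"].to_numpy(float) + k * sym.twist)
        shift = rots.apply(np.array([0.0, 0.0, k * sym.rise]))
        copy["dx"] = df["dx"].to_numpy(float) + shift[:, 0]
        copy["dy"] = df["dy"].to_numpy(float) + shift[:, 1]
        copy["pf_index"] = pd.array([k] * len(df), dtype="Int64")
        copy["parent_id"] = df["particle_id"].astype("Int64")
        copy["particle_id"] = np.arange(next_id, next_id + len(df), dtype=np.int64)
        next_id += len(df)
        copies.append(copy)
    out = pd.concat(copies, ignore_index=True)
    return ParticleTable(out, provenance="symmetry_expand")


def shift_register(
    table: ParticleTable,
    which: str,
    shift_A: float = MONOMER_SHIFT_A,
) -> ParticleTable:
    """Translate one register class by a monomer along the helix axis.

    Records labeled ``which`` get the image-plane projection of an axial
    ``shift_A`` translation (signed) added to their origin shifts and are
    relabeled to the other class, merging the two register populations.
    Unassigned records are skipped with a warning.  A zero shift leaves the
    table unchanged (relabeling suppressed).
    """
    if which not in (REGISTER_A, REGISTER_B):
        raise ValueError(f"register class must be A or B, got {which!r}")
    df = table.df.copy()
    unassigned = df["register"] == REGISTER_UNASSIGNED
    if unassigned.any():
        logger.warning("%d records with unassigned register skipped", unassigned.sum())
    if shift_A == 0.0:
        return ParticleTable(df, provenance="shift_register(noop)")
    sel = (df["register"] == which).to_numpy()
    shift = project_offset(df.loc[sel], np.array([0.0, 0.0, shift_A]))
    df.loc[sel, "dx"] = df.loc[sel, "dx"].to_numpy(float) + shift[:, 0]
    df.loc[sel, "dy"] = df.loc[sel, "dy"].to_numpy(float) + shift[:, 1]
    other = REGISTER_B if which == REGISTER_A else REGISTER_A
    df.loc[sel, "register"] = other
    return ParticleTable(df, provenance="shift_register")


def recenter_metadata(table: ParticleTable, offset_3d_A) -> ParticleTable:
    """Apply a reference-frame 3D recentering offset to all origin shifts.

    Exactly inverted by recentering with the negated offset.
    """
    df = table.df.copy()
    if len(df):
        shift = project_offset(df, np.asarray(offset_3d_A, dtype=float))
        df["dx"] = df["dx"].to_numpy(float) + shift[:, 0]
        df["dy"] = df["dy"].to_numpy(float) + shift[:, 1]
    return ParticleTable(df, provenance="recenter_metadata")


def unexpand_at_seam(table: ParticleTable, seams: dict) -> ParticleTable:
    """Keep only the seam-position copy of each parent; undo the expansion.

    ``seams`` maps (micrograph_id, filament_id) to the consensus seam index.
    Microtubules without a seam entry are dropped with a warning.  Retained
    records recover their parent's particle_id and have pf_index/parent_id
    cleared, so the result is a valid un-expanded table.
    """
    df = table.df
    if df["pf_index"].isna().any():
        raise ExpansionError("table contains unexpanded records")
    kept = []
    n_dropped_mt = 0
    for (mic, fil), grp in df.groupby(["micrograph_id", "filament_id"], sort=True):
        key = (mic, int(fil))
        if key not in seams:
            n_dropped_mt += 1
            logger.warning("no seam index for %s; %d records dropped", key, len(grp))
            continue
        kept.append(grp[grp["pf_index"] == int(seams[key])])
    if not kept:
        out = df.iloc[0:0].copy()
    else:
        out = pd.concat(kept, ignore_index=True)
    out["particle_id"] = out["parent_id"].astype(np.int64)
    out["pf_index"] = pd.array([pd.NA] * len(out), dtype="Int64")
    out["parent_id"] = pd.array([pd.NA] * len(out), dtype="Int64")
    if n_dropped_mt:
        logger.warning("%d microtubules lacked a seam index", n_dropped_mt)
    return ParticleTable(out, provenance="unexpand_at_seam")
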