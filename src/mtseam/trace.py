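"""Completing and regrouping filament-tracer picks.

Automated filament tracers miss stretches of microtubules (micrograph
edges, crowded fields) and merge picks from crossing filaments under one
id.  This module repairs their output in four steps:

1. ``split_filaments`` — break a filament wherever the in-plane angle jumps
   by more than a threshold between consecutive picks, since a rigid
   microtubule cannot kink.
2. ``fit_centerline`` — model each filament group as a straight line
   (microtubules in vitreous ice are nearly straight); when more than a
   configured fraction of picks deviates beyond a tolerance, fall back to a
   quadratic, which captures gentle bends without overfitting.
3. ``reassign_proximal`` — iteratively move every pick to the filament
   whose centerline model passes closest (within a radius), refitting after
   each round, which undoes tracer id misassignments.
4. ``extrapolate_picks`` — resample the fitted centerline at the segment
   spacing (82 Å, the tubulin dimer repeat) across the whole field, filling
   gaps and extending to the micrograph edges; original picks within half a
   spacing of a grid position adopt it.

Centerlines are parametrized by t, the cumulative chord length of the
ordered picks in pixels; x(t) and y(t) are polynomials of degree 1 or 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .lattice import circular_difference, wrap_angle
from .particles import ParticleTable

__all__ = [
    "FilamentGroup",
    "split_filaments",
    "fit_centerline",
    "extrapolate_picks",
    "reassign_proximal",
    "trace_extend",
]

logger = logging.getLogger(__name__)

DEFAULT_SPACING_A = 82.0
DEFAULT_DIAMETER_A = 360.0  # decorated microtubule; 280 Å undecorated
DEFAULT_MAX_PSI_JUMP = 10.0
DEFAULT_QUAD_FRAC = 0.10


@dataclass
class FilamentGroup:
    """One traced filament: member picks in arc order plus a centerline model."""

    micrograph_id: str
    filament_id: int
    particle_ids: np.ndarray
    t: np.ndarray  # chord-length arc parameter, px
    xy: np.ndarray  # (n, 2) pick coordinates, px
    model_kind: str = "none"  # none | linear | quadratic
    coeffs_x: np.ndarray = field(default_factory=lambda: np.zeros(0))
    coeffs_y: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def fittable(self) -> bool:
        return self.model_kind in ("linear", "quadratic")

    def evaluate(self, t) -> np.ndarray:
        """Model point(s) at arc parameter t, shape (n, 2)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return np.stack(
            [np.polyval(self.coeffs_x, t), np.polyval(self.coeffs_y, t)], axis=1
        )

    def tangent_angle(self, t) -> np.ndarray:
        """In-plane angle of the model tangent at t, degrees."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        dx = np.polyval(np.polyder(self.coeffs_x), t)
        dy = np.polyval(np.polyder(self.coeffs_y), t)
        return wrap_angle(np.rad2deg(np.arctan2(dy, dx)))

    def sample(self, margin: float = 0.0, step: float = 1.0) -> np.ndarray:
        """Densely sampled model points over [t_min - margin, t_max + margin]."""
        lo, hi = self.t.min() - margin, self.t.max() + margin
        ts = np.arange(lo, hi + step, step)
        return self.evaluate(ts)


def _chord_t(xy: np.ndarray) -> np.ndarray:
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])


def split_filaments(table: ParticleTable, max_psi_jump_deg: float = DEFAULT_MAX_PSI_JUMP
                    ) -> ParticleTable:
    """Split filaments at in-plane angle jumps larger than the threshold.

    Differences are circular, so a track crossing the ±180° wrap is not
    split.  Particle count is conserved; the first segment keeps the
    original filament id, later segments get fresh ids per micrograph.
    """
    out = table.order_along_filaments()
    df = out.df
    for mic, mic_grp in df.groupby("micrograph_id", sort=True):
        next_fid = int(mic_grp["filament_id"].max()) + 1
        for _, grp in mic_grp.groupby("filament_id", sort=True):
            psi = grp["psi"].to_numpy(dtype=float)
            if len(psi) < 2:
                continue
            jumps = np.abs(circular_difference(psi[1:], psi[:-1]))
            breaks = np.flatnonzero(jumps > max_psi_jump_deg) + 1
            for start, stop in zip(breaks, np.append(breaks[1:], len(psi))):
                df.loc[grp.index[start:stop], "filament_id"] = next_fid
                next_fid += 1
    return ParticleTable(df, provenance="split_filaments")


def _perpendicular_distance_to_line(xy: np.ndarray, cx, cy) -> np.ndarray:
    """Exact point-to-infinite-line distance for a linear model."""
    p0 = np.array([np.polyval(cx, 0.0), np.polyval(cy, 0.0)])
    d = np.array([cx[0], cy[0]])
    norm = np.linalg.norm(d)
    if norm == 0:
        return np.linalg.norm(xy - p0, axis=1)
    n = np.array([-d[1], d[0]]) / norm
    return np.abs((xy - p0) @ n)


def fit_centerline(
    group: FilamentGroup,
    deviation_tol_px: float,
    quad_fallback_frac: float = DEFAULT_QUAD_FRAC,
) -> FilamentGroup:
    """Fit a linear centerline, falling back to quadratic on poor fits.

    The linear least-squares fit of x(t), y(t) is kept unless the fraction
    of picks whose perpendicular distance to the fitted line exceeds
    ``deviation_tol_px`` is greater than ``quad_fallback_frac``.  Groups
    with fewer than two members are flagged unfittable and passed through.
    """
    n = len(group.xy)
    if n < 2:
        group.model_kind = "none"
        return group
    cx1 = np.polyfit(group.t, group.xy[:, 0], 1)
    cy1 = np.polyfit(group.t, group.xy[:, 1], 1)
    dist = _perpendicular_distance_to_line(group.xy, cx1, cy1)
    frac_off = float(np.mean(dist > deviation_tol_px))
    if frac_off > quad_fallback_frac and n >= 3:
        group.coeffs_x = np.polyfit(group.t, group.xy[:, 0], 2)
        group.coeffs_y = np.polyfit(group.t, group.xy[:, 1], 2)
        group.model_kind = "quadratic"
    else:
        group.coeffs_x, group.coeffs_y = cx1, cy1
        group.model_kind = "linear"
    return group


def make_groups(table: ParticleTable) -> list[FilamentGroup]:
    """Build arc-ordered filament groups from a table (no models fitted)."""
    ordered = table.order_along_filaments()
    groups = []
    for (mic, fil), grp in ordered.filament_groups():
        xy = grp[["x", "y"]].to_numpy(dtype=float)
        groups.append(
            FilamentGroup(
                micrograph_id=mic,
                filament_id=int(fil),
                particle_ids=grp["particle_id"].to_numpy(dtype=np.int64),
                t=_chord_t(xy),
                xy=xy,
            )
        )
    return groups


def _merge_collinear(
    df: pd.DataFrame,
    mic_grp: pd.DataFrame,
    merge_tol_px: float,
    deviation_tol_px: float,
    quad_fallback_frac: float,
    min_members: int,
) -> bool:
    """Merge filament groups that trace the same centerline.

    Two groups are merged (into the lower id) when the picks of each lie,
    on average, within ``merge_tol_px`` of the other group's model — true
    for fragments of one filament, false for crossing filaments, whose
    picks only approach the other model near the crossing point.
    """
    groups = [g for g in make_groups(ParticleTable(mic_grp.copy())) if len(g.xy) >= 2]
    for g in groups:
        fit_centerline(g, deviation_tol_px, quad_fallback_frac)
    groups = [g for g in groups if g.fittable]
    # models are compared over the whole populated field, so fragments of
    # one filament see each other even when their arc ranges do not overlap
    xy_all = mic_grp[["x", "y"]].to_numpy(dtype=float)
    extent = float(np.ptp(xy_all, axis=0).sum()) if len(xy_all) else 0.0
    merged_into: dict[int, int] = {}
    changed = False
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            if len(a.xy) < min_members and len(b.xy) < min_members:
                continue
            tree_a = cKDTree(a.sample(margin=extent, step=2.0))
            tree_b = cKDTree(b.sample(margin=extent, step=2.0))
            mean_ab = float(np.mean(tree_b.query(a.xy)[0]))
            mean_ba = float(np.mean(tree_a.query(b.xy)[0]))
            if mean_ab <= merge_tol_px and mean_ba <= merge_tol_px:
                src, dst = max(a.filament_id, b.filament_id), min(a.filament_id, b.filament_id)
                while dst in merged_into:
                    dst = merged_into[dst]
                merged_into[src] = dst
                changed = True
    for src, dst in merged_into.items():
        sel = (df["micrograph_id"] == mic_grp["micrograph_id"].iloc[0]) & (
            df["filament_id"] == src
        )
        df.loc[sel, "filament_id"] = dst
    return changed


def reassign_proximal(
    table: ParticleTable,
    reassign_radius_px: float,
    deviation_tol_px: float,
    quad_fallback_frac: float = DEFAULT_QUAD_FRAC,
    n_iter: int = 5,
    min_members: int = 3,
) -> ParticleTable:
    """Iteratively reassign picks to the nearest filament centerline.

    Each round refits the centerline model of every filament with at least
    ``min_members`` picks (smaller fragments propose no model, so their
    members are absorbed by real filaments) and moves each pick to the
    filament whose model passes closest, provided that distance is at most
    ``reassign_radius_px``; exact ties go to the lower filament id.  After
    the rounds converge or ``n_iter`` is reached, groups tracing the same
    centerline are merged.  Count is conserved throughout.
    """
    result = table.copy()
    for _ in range(n_iter):
        df = result.df
        changed = False
        for mic, mic_grp in df.groupby("micrograph_id", sort=True):
            groups = [
                g
                for g in make_groups(ParticleTable(mic_grp.copy()))
                if len(g.xy) >= max(2, min_members)
            ]
            if not groups:
                continue
            trees = []
            for g in groups:
                fit_centerline(g, deviation_tol_px, quad_fallback_frac)
                trees.append(cKDTree(g.sample(margin=reassign_radius_px, step=1.0)))
            xy = mic_grp[["x", "y"]].to_numpy(dtype=float)
            dists = np.stack([t.query(xy)[0] for t in trees], axis=1)
            fids = np.array([g.filament_id for g in groups])
            order = np.argsort(fids)  # tie-break: lower filament_id wins
            dists = dists[:, order]
            fids = fids[order]
            best = np.argmin(dists, axis=1)  # argmin takes first on ties
            new_fid = mic_grp["filament_id"].to_numpy(dtype=np.int64).copy()
            in_range = dists[np.arange(len(xy)), best] <= reassign_radius_px
            new_fid[in_range] = fids[best[in_range]]
            if not np.array_equal(new_fid, mic_grp["filament_id"].to_numpy()):
                df.loc[mic_grp.index, "filament_id"] = new_fid
                changed = True
        result = ParticleTable(df, provenance="reassign_proximal")
        if not changed:
            break
    # merging larger fragments improves their fitted models, which can in
    # turn qualify further merges, so iterate to a fixed point
    df = result.df
    for _ in range(n_iter + 5):
        changed = False
        for mic, mic_grp in df.groupby("micrograph_id", sort=True):
            changed |= _merge_collinear(
                df, mic_grp, reassign_radius_px, deviation_tol_px,
                quad_fallback_frac, min_members,
            )
        if not changed:
            break
    return ParticleTable(df, provenance="reassign_proximal")


def extrapolate_picks(
    group: FilamentGroup,
    field_px: float,
    spacing_A: float = DEFAULT_SPACING_A,
    pixel_size: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample a fitted centerline at the segment spacing across the field.

    Returns ``(positions, t_grid, snapped_particle_idx)``: grid positions
    (n, 2) in pixels clipped to the field, their arc parameters, and for
    each grid position the index into ``group.particle_ids`` of the
    original pick that adopts it (-1 for newly created picks).  The grid is
    anchored at the first original pick and marches in both directions by
    one spacing until leaving the field, so a gap-free filament maps onto
    its own (snapped) picks.
    """
    if not group.fittable:
        logger.warning(
            "filament %s/%s has no model; extrapolation skipped",
            group.micrograph_id, group.filament_id,
        )
        return group.xy.copy(), group.t.copy(), np.arange(len(group.xy))
    spacing_px = spacing_A / pixel_size

    def inside(pt):
        return bool((pt >= 0).all() and (pt < field_px).all())

    t_grid = [group.t[0]]
    # march forward then backward from the anchor until out of bounds
    t = group.t[0] + spacing_px
    while inside(group.evaluate(t)[0]) and t < group.t[-1] + 4 * field_px:
        t_grid.append(t)
        t += spacing_px
    t = group.t[0] - spacing_px
    while inside(group.evaluate(t)[0]) and t > group.t[0] - 4 * field_px:
        t_grid.insert(0, t)
        t -= spacing_px
    t_grid = np.array(t_grid)
    positions = group.evaluate(t_grid)
    keep = np.array([inside(p) for p in positions])
    t_grid, positions = t_grid[keep], positions[keep]
    # snap: nearest original pick within spacing/2 adopts the grid position
    snapped = np.full(len(t_grid), -1, dtype=np.int64)
    if len(group.t):
        order = np.argsort(np.abs(group.t[:, None] - t_grid[None, :]).min(axis=1))
        taken = set()
        for i in order:  # nearest-original-wins
            gi = int(np.argmin(np.abs(t_grid - group.t[i])))
            if gi in taken:
                continue
            if abs(t_grid[gi] - group.t[i]) <= spacing_px / 2.0:
                snapped[gi] = i
                taken.add(gi)
    return positions, t_grid, snapped


def apply_extrapolation(
    table: ParticleTable,
    field_px: float,
    spacing_A: float = DEFAULT_SPACING_A,
    deviation_tol_px: float | None = None,
    diameter_A: float = DEFAULT_DIAMETER_A,
    quad_fallback_frac: float = DEFAULT_QUAD_FRAC,
    min_members: int = 3,
) -> ParticleTable:
    """Extrapolate every filament of a table; returns the completed table.

    Grid positions adopted by an original pick keep that pick's record
    (coordinates updated); new positions get fresh records with the model
    tangent as psi.  Original picks that lose a snap contest are kept
    unchanged, so extrapolation only ever adds picks.  Groups smaller than
    ``min_members`` are passed through untouched — a two-pick fragment has
    a formally perfect line fit but no evidential support for sampling new
    positions across the whole field.
    """
    df = table.order_along_filaments().df
    if deviation_tol_px is None:
        ps = float(df["pixel_size"].dropna().iloc[0]) if len(df) else 1.0
        deviation_tol_px = diameter_A / 4.0 / ps
    next_pid = int(df["particle_id"].max()) + 1 if len(df) else 0
    new_rows = []
    for group in make_groups(ParticleTable(df.copy())):
        sub = df[
            (df["micrograph_id"] == group.micrograph_id)
            & (df["filament_id"] == group.filament_id)
        ]
        ps = float(sub["pixel_size"].dropna().iloc[0])
        if len(group.xy) < min_members:
            continue
        fit_centerline(group, deviation_tol_px, quad_fallback_frac)
        if not group.fittable:
            continue
        positions, t_grid, snapped = extrapolate_picks(
            group, field_px, spacing_A, ps
        )
        pid_index = {pid: idx for idx, pid in enumerate(group.particle_ids)}
        row_by_member = {pid_index[p]: i for p, i in zip(sub["particle_id"], sub.index)}
        for gi in range(len(t_grid)):
            if snapped[gi] >= 0:
                row = row_by_member[int(snapped[gi])]
                df.loc[row, ["x", "y"]] = positions[gi]
            else:
                template = sub.iloc[0].to_dict()
                template.update(
                    particle_id=next_pid,
                    x=positions[gi][0],
                    y=positions[gi][1],
                    psi=float(group.tangent_angle(t_grid[gi])[0]),
                    dx=0.0,
                    dy=0.0,
                    class_id=pd.NA,
                    register="unassigned",
                    pf_index=pd.NA,
                    parent_id=pd.NA,
                )
                new_rows.append(template)
                next_pid += 1
    if new_rows:
        df = pd.concat([df, pd.DataFrame(new_rows)], ignore_index=True)
    return ParticleTable(df, provenance="extrapolate_picks").order_along_filaments()


def trace_extend(
    table: ParticleTable,
    field_px: float,
    spacing_A: float = DEFAULT_SPACING_A,
    diameter_A: float = DEFAULT_DIAMETER_A,
    max_psi_jump_deg: float = DEFAULT_MAX_PSI_JUMP,
    quad_fallback_frac: float = DEFAULT_QUAD_FRAC,
    reassign_radius_px: float | None = None,
    n_iter: int = 5,
) -> ParticleTable:
    """Full pick-repair pass: split, fit, reassign (iterated), extrapolate.

    ``reassign_radius_px`` defaults to half the filament radius in pixels;
    ``deviation_tol_px`` (the quadratic-fallback trigger) likewise, both
    derived from the configured filament diameter.
    """
    df = table.df
    ps = float(df["pixel_size"].dropna().iloc[0]) if len(df) else 1.0
    deviation_tol_px = diameter_A / 4.0 / ps
    if reassign_radius_px is None:
        reassign_radius_px = deviation_tol_px
    out = split_filaments(table, max_psi_jump_deg)
    out = reassign_proximal(
        out, reassign_radius_px, deviation_tol_px, quad_fallback_frac, n_iter
    )
    return apply_extrapolation(
        out, field_px, spacing_A, deviation_tol_px, diameter_A, quad_fallback_frac
    )
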