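"""Per-filament smoothing of 3D-class (architecture) assignments.

Heterogeneous refinement classifies each segment independently, but lattice
architecture is a property of the whole filament: protofilament number does
not change along a microtubule except at rare lattice defects.  Smoothing
therefore replaces each particle's class with the modal class of a short
window around it, and stretches that still disagree confidently with the
rest of the filament are split off into their own filament groups while
low-confidence disagreements are unified to the filament's majority class.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .particles import ParticleTable

__all__ = ["smooth_classes", "regroup_stretches", "assign_filament_architecture"]

logger = logging.getLogger(__name__)


def _window_mode(labels: np.ndarray, i: int, window: int):
    """Mode of the centered window at i (truncated at the ends).

    Ties keep the particle's own label if it is among the tied modes,
    otherwise take the smallest tied label; deterministic.
    """
    half = window // 2
    lo, hi = max(0, i - half), min(len(labels), i + half + 1)
    vals, counts = np.unique(labels[lo:hi], return_counts=True)
    top = vals[counts == counts.max()]
    if labels[i] in top:
        return labels[i]
    return top.min()


def smooth_classes(table: ParticleTable, window: int = 7) -> ParticleTable:
    """Replace each particle's class by the modal class of its neighborhood.

    The window is centered (self plus ``window//2`` particles on each side)
    and truncated at filament ends.  Filament membership and particle count
    are unchanged.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    out = table.order_along_filaments()
    df = out.df
    if df["class_id"].isna().any():
        raise ValueError("class_id must be set on every particle before smoothing")
    smoothed = df["class_id"].to_numpy(dtype=np.int64).copy()
    for _, grp in df.groupby(["micrograph_id", "filament_id"], sort=False):
        idx = grp.index.to_numpy()
        labels = df.loc[idx, "class_id"].to_numpy(dtype=np.int64)
        smoothed[idx] = [_window_mode(labels, i, window) for i in range(len(labels))]
    df["class_id"] = pd.array(smoothed, dtype="Int64")
    return ParticleTable(df, provenance="smooth_classes")


def regroup_stretches(
    table: ParticleTable, stretch_frac: float = 0.70, min_run: int = 7
) -> ParticleTable:
    """Split confident off-class stretches into new filaments; unify the rest.

    Within each filament (smoothed classes assumed), maximal contiguous runs
    of particles whose class differs from the filament's modal class are
    examined: if the run spans at least ``min_run`` particles and its
    dominant class accounts for more than ``stretch_frac`` of the run it
    becomes a new filament group with that class; otherwise the whole run is
    reassigned to the filament's modal class.  Every output filament is
    class-uniform.

    ``min_run`` defaults to the smoothing window: an off-class run shorter
    than the window cannot be distinguished from surviving classifier noise,
    while a genuine architecture transition produces an extended stretch.
    """
    out = table.order_along_filaments()
    df = out.df
    next_fid = int(df["filament_id"].max()) + 1 if len(df) else 0
    for (_, _), grp in df.groupby(["micrograph_id", "filament_id"], sort=True):
        idx = grp.index.to_numpy()
        labels = df.loc[idx, "class_id"].to_numpy(dtype=np.int64)
        modal = _majority_class(labels)
        off = labels != modal
        # maximal contiguous runs of off-modal particles
        i = 0
        while i < len(labels):
            if not off[i]:
                i += 1
                continue
            j = i
            while j < len(labels) and off[j]:
                j += 1
            run = labels[i:j]
            vals, counts = np.unique(run, return_counts=True)
            dominant = vals[np.argmax(counts)]
            if len(run) >= min_run and counts.max() / len(run) > stretch_frac:
                df.loc[idx[i:j], "filament_id"] = next_fid
                df.loc[idx[i:j], "class_id"] = int(dominant)
                next_fid += 1
            else:
                df.loc[idx[i:j], "class_id"] = int(modal)
            i = j
    return ParticleTable(df, provenance="regroup_stretches")


def _majority_class(labels: np.ndarray) -> int:
    """Majority label; 50/50 ties go to the class of the longest contiguous run."""
    vals, counts = np.unique(labels, return_counts=True)
    top = vals[counts == counts.max()]
    if len(top) == 1:
        return int(top[0])
    best_label, best_run = None, -1
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        if labels[i] in top and (j - i) > best_run:
            best_label, best_run = int(labels[i]), j - i
        i = j
    logger.warning("majority-class tie %s; chose %d (longest run)", top.tolist(), best_label)
    return best_label


def assign_filament_architecture(table: ParticleTable) -> tuple[dict, pd.DataFrame]:
    """Majority class per filament, plus the dataset class-fraction report.

    Returns ``(mapping, report)`` where mapping is
    {(micrograph_id, filament_id): class_id} and report is a DataFrame of
    per-class particle fractions over the whole dataset (sums to 1).
    """
    df = table.df
    if df["class_id"].isna().any():
        raise ValueError("class_id must be set on every particle")
    mapping = {}
    for (mic, fil), grp in df.groupby(["micrograph_id", "filament_id"], sort=True):
        labels = grp["class_id"].to_numpy(dtype=np.int64)
        mapping[(mic, int(fil))] = _majority_class(labels)
    counts = df["class_id"].value_counts().sort_index()
    report = pd.DataFrame(
        dict(class_id=counts.index.astype(int), n_particles=counts.to_numpy())
    )
    report["fraction"] = report["n_particles"] / report["n_particles"].sum()
    return mapping, report
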