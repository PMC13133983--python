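"""Consensus seam finding from binary register labels.

After pseudo-helical symmetry expansion and register classification, every
original particle contributes one 'layer': the N protofilament records that
share a parent.  In a B-lattice microtubule all lateral contacts are
homotypic except at the seam, so along the protofilament index k the
register labels of a clean layer form a single transition — one register
left of the seam, the other from the seam onward (the circular wrap is
absorbed by the 1.5-dimer stagger of the expansion operator, so indices are
scored in linear order).

Each candidate position p is scored by the fraction of labels consistent
with a seam at p:

    score(p; u, v) = (#{k < p : r_k = u} + #{k >= p : r_k = v}) / n_assigned

which is the maximum-likelihood changepoint statistic when labels are
flipped independently by classification error.  Scores are averaged over
all layers of a microtubule under a single majority orientation (u, v),
and the argmax of the mean profile is the consensus seam.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .particles import REGISTER_A, REGISTER_B, ParticleTable

__all__ = ["SeamProfile", "group_layers", "score_layer", "consensus_seam", "find_seams"]

logger = logging.getLogger(__name__)

_ORIENTATIONS = ((REGISTER_A, REGISTER_B), (REGISTER_B, REGISTER_A))


class SeamError(ValueError):
    """The expanded table cannot be scored for a seam."""


@dataclass
class SeamProfile:
    """Per-microtubule seam scores and consensus."""

    micrograph_id: str
    filament_id: int
    mean_scores: np.ndarray  # length N, mean score per candidate position
    seam_index: int  # argmax of mean_scores
    confidence: float  # mean score at the consensus position, in [0, 1]
    orientation: tuple[str, str]  # (register left of seam, register right)
    n_layers: int


def group_layers(table: ParticleTable, n_pf: int) -> dict:
    """Group an expanded table into per-parent register label vectors.

    Returns {(micrograph_id, filament_id): list of length-N label arrays},
    one array per parent particle, entries ``None`` where the pf_index slot
    has no record.  Raises on duplicate (parent, pf_index) pairs.
    """
    df = table.df
    if df["parent_id"].isna().any():
        raise SeamError("table contains unexpanded records (parent_id unset)")
    dup = df.duplicated(subset=["micrograph_id", "filament_id", "parent_id", "pf_index"])
    if dup.any():
        raise SeamError("duplicate (parent, pf_index) records: corrupt expansion")
    layers: dict = {}
    for (mic, fil), grp in df.groupby(["micrograph_id", "filament_id"], sort=True):
        vectors = []
        for _, sub in grp.groupby("parent_id", sort=True):
            r = np.full(n_pf, None, dtype=object)
            for k, reg in zip(sub["pf_index"], sub["register"]):
                r[int(k)] = reg if reg in (REGISTER_A, REGISTER_B) else None
            vectors.append(r)
        layers[(mic, fil)] = vectors
    return layers


def score_layer(r: np.ndarray, p: int, orientation: tuple[str, str]) -> float:
    """Fraction of assigned labels consistent with a seam at position p.

    ``orientation = (u, v)`` means register u is expected at k < p and v at
    k >= p.  Unassigned (None) labels count toward neither side.
    """
    u, v = orientation
    n = len(r)
    if not 0 <= p < n:
        raise ValueError(f"candidate index {p} out of range 0..{n - 1}")
    assigned = np.array([lab is not None for lab in r])
    n_assigned = int(assigned.sum())
    if n_assigned == 0:
        return 0.0
    k = np.arange(n)
    hits = sum(
        1
        for i in k
        if r[i] is not None and (r[i] == u if i < p else r[i] == v)
    )
    return hits / n_assigned


def _score_matrix(r: np.ndarray, orientation: tuple[str, str]) -> np.ndarray:
    """score_layer over all candidate positions, vectorized."""
    u, v = orientation
    n = len(r)
    is_u = np.array([lab == u for lab in r], dtype=float)
    is_v = np.array([lab == v for lab in r], dtype=float)
    n_assigned = sum(lab is not None for lab in r)
    if n_assigned == 0:
        return np.zeros(n)
    # hits(p) = sum_{k<p} is_u + sum_{k>=p} is_v
    cum_u = np.concatenate([[0.0], np.cumsum(is_u)])[:n]
    tail_v = np.cumsum(is_v[::-1])[::-1]
    return (cum_u + tail_v) / n_assigned


def consensus_seam(
    layer_vectors: list[np.ndarray],
    micrograph_id: str = "",
    filament_id: int = 0,
) -> SeamProfile:
    """Average per-layer seam scores into a consensus seam position.

    A single global orientation is fixed per microtubule by majority vote
    over each layer's best orientation, preventing sign-flip cancellation;
    the per-layer score vectors under that orientation are then averaged and
    the argmax taken (ties broken toward the smaller index, with a warning).
    """
    if not layer_vectors:
        raise SeamError("no layers to score")
    if all(all(lab is None for lab in r) for r in layer_vectors):
        raise SeamError("no assigned register labels in any layer")
    votes = {o: 0 for o in _ORIENTATIONS}
    per_layer = {o: [] for o in _ORIENTATIONS}
    for r in layer_vectors:
        best = {o: _score_matrix(r, o) for o in _ORIENTATIONS}
        for o in _ORIENTATIONS:
            per_layer[o].append(best[o])
        votes[max(_ORIENTATIONS, key=lambda o: best[o].max())] += 1
    orientation = max(_ORIENTATIONS, key=lambda o: votes[o])
    mean_scores = np.mean(per_layer[orientation], axis=0)
    top = np.flatnonzero(mean_scores == mean_scores.max())
    if len(top) > 1:
        logger.warning(
            "seam tie between positions %s for %s/%s; choosing %d",
            top.tolist(), micrograph_id, filament_id, top[0],
        )
    seam = int(top[0])
    return SeamProfile(
        micrograph_id=micrograph_id,
        filament_id=int(filament_id),
        mean_scores=mean_scores,
        seam_index=seam,
        confidence=float(mean_scores[seam]),
        orientation=orientation,
        n_layers=len(layer_vectors),
    )


def find_seams(table: ParticleTable, n_pf: int) -> list[SeamProfile]:
    """Consensus seam for every microtubule in an expanded table."""
    layers = group_layers(table, n_pf)
    return [
        consensus_seam(vectors, micrograph_id=mic, filament_id=fil)
        for (mic, fil), vectors in layers.items()
    ]


def seam_table(profiles: list[SeamProfile]) -> pd.DataFrame:
    """Flatten seam profiles to a DataFrame (CSV-ready)."""
    return pd.DataFrame(
        dict(
            micrograph_id=[p.micrograph_id for p in profiles],
            filament_id=[p.filament_id for p in profiles],
            seam_index=[p.seam_index for p in profiles],
            confidence=[p.confidence for p in profiles],
            n_layers=[p.n_layers for p in profiles],
            orientation=["".join(p.orientation) for p in profiles],
            mean_scores=[
                ";".join(f"{s:.6f}" for s in p.mean_scores) for p in profiles
            ],
        )
    )
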