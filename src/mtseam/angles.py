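"""Per-microtubule unification of in-plane (psi) and around-axis (phi) angles.

Global refinements assign each segment's Euler angles independently, so two
failure modes accumulate along a filament: scattered in-plane angles (bad
alignments, polarity flips) and around-axis angles that land on any of the
N symmetry-equivalent protofilament registers.  Both are corrected per
microtubule:

* ``unify_psi`` — the in-plane angle of a near-straight filament varies
  smoothly with arc length, so a quadratic psi(t) is fitted through the
  particles within a window of the modal psi and every particle's psi is
  replaced by the fitted value.

* ``unify_phi`` — the around-axis angle of a microtubule segment is only
  determined up to the lattice symmetry: the true values lie on one of N
  parallel lines phi_j(t) = phi0 + s*t + j*360/N, where s is the supertwist
  rotation per Å of axial travel.  The line family is fitted (grid search
  over s, circular mean for phi0, then a linear refinement), each particle
  is snapped to its nearest line, and all particles are moved onto the
  modal line so every protofilament averages in the same position as its
  neighbors.

All arithmetic is circular; arc length t is the cumulative chord length of
the ordered picks in Å.
"""

from __future__ import annotations

import logging

import numpy as np

from .lattice import circular_difference, wrap_angle
from .particles import ParticleTable

__all__ = ["unify_psi", "unify_phi", "arc_length"]

logger = logging.getLogger(__name__)


def arc_length(grp) -> np.ndarray:
    """Cumulative chord length (Å) along a filament's ordered picks."""
    xy = grp[["x", "y"]].to_numpy(dtype=float)
    ps = grp["pixel_size"].to_numpy(dtype=float)
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1) * ps[1:]
    return np.concatenate([[0.0], np.cumsum(steps)])


def circular_mode(angles: np.ndarray, bin_deg: float = 4.0) -> float:
    """Modal angle on the circle via histogram, refined by circular mean.

    The densest ``bin_deg`` bin is found on the wrapped circle and the mode
    refined as the circular mean of the values within one bin of its center.
    """
    a = np.mod(np.asarray(angles, dtype=float), 360.0)
    nbins = max(1, int(round(360.0 / bin_deg)))
    edges = np.linspace(0.0, 360.0, nbins + 1)
    counts, _ = np.histogram(a, bins=edges)
    center = (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1]) / 2.0
    near = np.abs(circular_difference(a, center)) <= bin_deg
    rad = np.deg2rad(a[near])
    return wrap_angle(np.rad2deg(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())))


def _fit_psi_track(t: np.ndarray, psi: np.ndarray, window_deg: float):
    """Fit psi(t) through inliers around the circular mode; return fitted values."""
    mode = circular_mode(psi)
    dev = circular_difference(psi, mode)
    inlier = np.abs(dev) <= window_deg
    n_in = int(inlier.sum())
    # unwrap relative to the mode so fits cross the +-180 boundary cleanly
    unwrapped = mode + dev
    if n_in >= 3 and len(np.unique(t[inlier])) >= 3:
        coeffs = np.polyfit(t[inlier], unwrapped[inlier], 2)
    elif n_in >= 2 and len(np.unique(t[inlier])) >= 2:
        coeffs = np.polyfit(t[inlier], unwrapped[inlier], 1)
        logger.warning("psi fit: only %d inliers, falling back to linear", n_in)
    elif n_in >= 1:
        coeffs = np.array([np.mean(unwrapped[inlier])])
        logger.warning("psi fit: only %d inliers, using constant", n_in)
    else:  # cannot happen: the mode always has at least one inlier
        coeffs = np.array([mode])
    fitted = np.polyval(coeffs, t)
    return wrap_angle(fitted), n_in


def unify_psi(table: ParticleTable, inlier_window_deg: float = 10.0) -> ParticleTable:
    """Replace every particle's psi with a per-filament smooth fit.

    Per filament: the modal psi is found on the circle, a quadratic psi(t)
    is fitted through particles within ``inlier_window_deg`` of the mode
    (falling back to linear/constant when inliers are scarce) and ALL
    particles — inliers and outliers alike — take the fitted value at their
    arc position.
    """
    out = table.order_along_filaments()
    df = out.df
    for (mic, fil), grp in df.groupby(["micrograph_id", "filament_id"], sort=False):
        t = arc_length(grp)
        psi = grp["psi"].to_numpy(dtype=float)
        if len(psi) < 2:
            continue
        fitted, n_in = _fit_psi_track(t, psi, inlier_window_deg)
        if n_in < len(psi):
            logger.info(
                "unify_psi %s/%s: %d outliers replaced", mic, fil, len(psi) - n_in
            )
        df.loc[grp.index, "psi"] = fitted
    return ParticleTable(df, provenance="unify_psi")


def _fit_line_family(
    t: np.ndarray,
    phi: np.ndarray,
    period: float,
    slope_grid: np.ndarray,
):
    """Fit phi_j(t) = phi0 + s*t + j*period to angles on the circle.

    For each candidate slope the offset phi0 is the circular mean (period
    ``period``) of phi - s*t, and the cost is the summed squared folded
    residual to the nearest line.  The best grid point is then refined by
    one linear regression on the folded residuals, giving sub-grid accuracy.
    Returns (phi0 in [0, period), slope).
    """
    two_pi = 2.0 * np.pi

    def offset_and_cost(s):
        d = phi - s * t
        theta = d * (two_pi / period)
        phi0 = (period / two_pi) * np.arctan2(
            np.sin(theta).mean(), np.cos(theta).mean()
        )
        resid = d - phi0
        folded = resid - period * np.round(resid / period)
        return phi0 % period, float(np.sum(folded**2))

    costs = [offset_and_cost(s) for s in slope_grid]
    best = int(np.argmin([c for _, c in costs]))
    phi0, _ = costs[best]
    s = float(slope_grid[best])
    # refinement: regress folded residuals on t
    resid = phi - s * t - phi0
    folded = resid - period * np.round(resid / period)
    if len(np.unique(t)) >= 2:
        b, a = np.polyfit(t, folded, 1)
        phi0 = (phi0 + a) % period
        s = s + b
    else:
        phi0 = (phi0 + folded.mean()) % period
    return phi0, s


def unify_phi(
    table: ParticleTable,
    n_pf: int,
    slope_range_deg_per_A: tuple[float, float] = (-0.05, 0.05),
    slope_step: float = 0.001,
    n_rounds: int = 2,
    fixed_slope: float | None = None,
) -> ParticleTable:
    """Snap every particle's phi onto the modal protofilament line.

    Per filament the N-line family is fitted (see module docstring), each
    particle is assigned to its nearest line, and all phi are replaced by
    the modal line's value at their arc position.  ``fixed_slope`` bypasses
    the supertwist grid search (e.g. to impose the theoretical value).
    Applied for ``n_rounds`` rounds; the operation is idempotent, so extra
    rounds are cheap insurance against marginal assignments.
    """
    if n_pf < 2:
        raise ValueError("n_pf must be >= 2")
    period = 360.0 / n_pf
    if fixed_slope is not None:
        slope_grid = np.array([fixed_slope])
    else:
        lo, hi = slope_range_deg_per_A
        slope_grid = np.arange(lo, hi + slope_step / 2, slope_step)
    out = table.order_along_filaments()
    df = out.df
    for _ in range(n_rounds):
        for (mic, fil), grp in df.groupby(["micrograph_id", "filament_id"], sort=False):
            phi = df.loc[grp.index, "rot"].to_numpy(dtype=float)
            if len(phi) < 2:
                logger.warning("unify_phi %s/%s: single particle, skipped", mic, fil)
                continue
            t = arc_length(grp)
            # unwrap phi against a rough linear trend is unnecessary: all
            # arithmetic below is modular with period 360/N
            phi0, s = _fit_line_family(t, phi, period, slope_grid)
            if fixed_slope is not None:
                s = fixed_slope
            d = phi - s * t - phi0
            j = np.round(d / period).astype(int) % n_pf
            vals, counts = np.unique(j, return_counts=True)
            top = vals[counts == counts.max()]
            if len(top) == len(vals) and len(vals) > 1:
                logger.warning(
                    "unify_phi %s/%s: all lines equally populated, using j=0",
                    mic, fil,
                )
                j_star = 0
            else:
                j_star = int(top[0])
            df.loc[grp.index, "rot"] = wrap_angle(phi0 + s * t + j_star * period)
    return ParticleTable(df, provenance="unify_phi")
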