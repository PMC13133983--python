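"""Ground-truthed synthetic inputs for every pipeline stage.

Real inputs to this pipeline come out of a cryo-EM filament tracer and 3D
refinement/classification jobs.  The generators here emulate the statistical
structure of those outputs — polynomial filament centerlines picked every
~82 Å with jitter, dropouts and filament-ID misassignment; smooth in-plane
angle tracks with circular outliers; around-axis angles scattered over the
N symmetry-equivalent lines; binary register labels with a planted seam and
classification error; and toy protofilament densities built from Gaussian
blobs.  Every generator is a pure function of its seed and parameters, and
each returns a truth table alongside the particle table so that recovery
can be measured without leaking the answer into the pipeline input.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lattice import wrap_angle
from .particles import (
    REGISTER_A,
    REGISTER_B,
    ParticleTable,
)
from .volumes import VolumeGrid

__all__ = [
    "make_micrograph_picks",
    "make_angle_tracks",
    "make_register_layers",
    "make_pf_volume",
]

DEFAULT_SPACING_A = 82.0  # alpha/beta-tubulin dimer repeat along the filament


def _filament_curve(rng, field_px: float, curvature: float):
    """Random line or parabola through the field.

    Returns (point, direction, quad_coeff): the centerline is
    p(t) = point + t * direction + 0.5 * quad * t^2 * normal, with t the arc
    parameter in pixels.  ``curvature`` is the magnitude scale of ``quad``
    (px^-1); 0 gives straight lines.
    """
    point = rng.uniform(0.25 * field_px, 0.75 * field_px, size=2)
    angle = rng.uniform(0, np.pi)
    direction = np.array([np.cos(angle), np.sin(angle)])
    quad = rng.uniform(-curvature, curvature) if curvature > 0 else 0.0
    return point, direction, quad


def _eval_curve(point, direction, quad, t):
    normal = np.array([-direction[1], direction[0]])
    t = np.asarray(t, dtype=float)[:, None]
    return point + t * direction + 0.5 * quad * t**2 * normal


def make_micrograph_picks(
    n_filaments: int = 4,
    field_px: int = 4096,
    spacing_A: float = DEFAULT_SPACING_A,
    pixel_size: float = 1.0,
    jitter_px: float = 1.0,
    dropout_frac: float = 0.15,
    id_swap_frac: float = 0.10,
    curvature: float = 0.0,
    seed: int = 0,
    micrograph_id: str = "synthetic_000001.mrc",
):
    """Simulate filament-tracer picks on one micrograph.

    Filaments are random lines (or gentle parabolas for ``curvature > 0``)
    clipped to the field, picked every ``spacing_A`` of arc with Gaussian
    positional jitter.  ``dropout_frac`` of picks are removed and
    ``id_swap_frac`` are relabeled with another filament's id, emulating
    tracer misassignment.  Returns ``(table, truth)`` where ``truth`` holds
    the true filament membership and noise-free position of every surviving
    pick plus rows for the dropped positions (``dropped`` flag).
    """
    if not (0 <= dropout_frac < 1 and 0 <= id_swap_frac < 1):
        raise ValueError("fractions must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    spacing_px = spacing_A / pixel_size
    rows = []
    truth_rows = []
    pid = 0
    for fil in range(n_filaments):
        point, direction, quad = _filament_curve(rng, field_px, curvature)
        # march symmetrically out from the anchor until leaving the field
        t = np.arange(-int(2 * field_px / spacing_px), int(2 * field_px / spacing_px) + 1)
        t = t * spacing_px
        xy = _eval_curve(point, direction, quad, t)
        inside = ((xy >= 0) & (xy < field_px)).all(axis=1)
        xy = xy[inside]
        tt = t[inside]
        # local tangent angle = in-plane rotation psi
        tangent = direction[None, :] + quad * tt[:, None] * np.array(
            [-direction[1], direction[0]]
        )
        psi = np.rad2deg(np.arctan2(tangent[:, 1], tangent[:, 0]))
        for i in range(len(xy)):
            dropped = rng.uniform() < dropout_frac
            jitter = rng.normal(0.0, jitter_px, size=2) if jitter_px > 0 else np.zeros(2)
            obs_fil = fil
            if n_filaments > 1 and rng.uniform() < id_swap_frac:
                others = [f for f in range(n_filaments) if f != fil]
                obs_fil = others[rng.integers(len(others))]
            truth_rows.append(
                dict(
                    particle_id=pid if not dropped else -1,
                    true_filament=fil,
                    true_x=xy[i, 0],
                    true_y=xy[i, 1],
                    true_psi=wrap_angle(psi[i]),
                    dropped=dropped,
                    swapped=(obs_fil != fil) and not dropped,
                )
            )
            if dropped:
                continue
            rows.append(
                dict(
                    micrograph_id=micrograph_id,
                    filament_id=obs_fil,
                    particle_id=pid,
                    x=float(np.clip(xy[i, 0] + jitter[0], 0, field_px - 1)),
                    y=float(np.clip(xy[i, 1] + jitter[1], 0, field_px - 1)),
                    pixel_size=pixel_size,
                    rot=0.0,
                    tilt=90.0,
                    psi=wrap_angle(psi[i]),
                )
            )
            pid += 1
    table = ParticleTable(pd.DataFrame(rows), provenance="simulate.picks")
    truth = pd.DataFrame(truth_rows)
    return table, truth


def make_angle_tracks(
    n_particles: int = 60,
    psi_poly_coeffs=(30.0, 0.002, -2e-7),
    psi_noise_deg: float = 2.0,
    psi_outlier_frac: float = 0.05,
    N: int = 14,
    phi0: float = 10.0,
    supertwist_slope: float = 0.0,
    phi_line_noise_deg: float = 3.0,
    spacing_A: float = DEFAULT_SPACING_A,
    pixel_size: float = 1.0,
    seed: int = 0,
    micrograph_id: str = "synthetic_000001.mrc",
    filament_id: int = 0,
):
    """Simulate one filament's Euler-angle tracks after rough refinement.

    psi follows a low-order polynomial of arc length (constant, slope and
    curvature terms in deg, deg/Å, deg/Å^2) with Gaussian noise plus a
    fraction of circular-uniform outliers.  phi is drawn per particle from
    one of the N symmetry-equivalent lines ``phi0 + slope*t + j*360/N``
    with Gaussian noise, emulating the arbitrary protofilament register a
    global refinement converges into.  Truth records the polynomial, the
    line-family parameters and each particle's true line index j.
    """
    if N < 8:
        raise ValueError("N must be >= 8")
    rng = np.random.default_rng(seed)
    t_A = np.arange(n_particles) * spacing_A  # arc length in Å
    poly = np.zeros(3)
    poly[: len(psi_poly_coeffs)] = psi_poly_coeffs
    psi_true = poly[0] + poly[1] * t_A + poly[2] * t_A**2
    psi = psi_true + rng.normal(0, psi_noise_deg, n_particles)
    outlier = rng.uniform(size=n_particles) < psi_outlier_frac
    psi[outlier] = rng.uniform(-180, 180, outlier.sum())
    j = rng.integers(0, N, n_particles)
    phi = phi0 + supertwist_slope * t_A + j * (360.0 / N)
    phi = phi + rng.normal(0, phi_line_noise_deg, n_particles)
    df = pd.DataFrame(
        dict(
            micrograph_id=micrograph_id,
            filament_id=filament_id,
            particle_id=np.arange(n_particles),
            x=t_A / pixel_size,
            y=100.0,
            pixel_size=pixel_size,
            rot=wrap_angle(phi),
            tilt=90.0,
            psi=wrap_angle(psi),
        )
    )
    truth = pd.DataFrame(
        dict(
            particle_id=np.arange(n_particles),
            t_A=t_A,
            psi_true=wrap_angle(psi_true),
            psi_outlier=outlier,
            phi_line=j,
        )
    )
    truth.attrs.update(
        psi_poly=tuple(poly), phi0=phi0, supertwist_slope=supertwist_slope, N=N
    )
    table = ParticleTable(df, provenance="simulate.angles")
    return table, truth


def make_register_layers(
    n_layers: int = 50,
    N: int = 14,
    seam_index: int = 6,
    flip_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    micrograph_id: str = "synthetic_000001.mrc",
    filament_id: int = 0,
    pixel_size: float = 1.0,
    spacing_A: float = DEFAULT_SPACING_A,
):
    """Simulate a symmetry-expanded table with a planted seam.

    Each layer is one parent particle expanded into N protofilament records;
    register is A for pf_index < seam_index and B otherwise, each label
    independently flipped with ``flip_rate`` and the record dropped with
    ``missing_rate``.  Returns ``(expanded_table, truth)``.
    """
    if not 0 <= seam_index < N:
        raise ValueError(f"seam_index must lie in 0..{N - 1}")
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for layer in range(n_layers):
        parent = layer
        for k in range(N):
            if rng.uniform() < missing_rate:
                continue
            reg = REGISTER_A if k < seam_index else REGISTER_B
            if rng.uniform() < flip_rate:
                reg = REGISTER_B if reg == REGISTER_A else REGISTER_A
            rows.append(
                dict(
                    micrograph_id=micrograph_id,
                    filament_id=filament_id,
                    particle_id=pid,
                    x=layer * spacing_A / pixel_size,
                    y=100.0,
                    pixel_size=pixel_size,
                    rot=wrap_angle(k * (-360.0 / N)),
                    tilt=90.0,
                    psi=0.0,
                    register=reg,
                    pf_index=k,
                    parent_id=parent,
                )
            )
            pid += 1
    columns = [
        "micrograph_id", "filament_id", "particle_id", "x", "y", "pixel_size",
        "rot", "tilt", "psi", "register", "pf_index", "parent_id",
    ]
    table = ParticleTable(
        pd.DataFrame(rows, columns=columns), provenance="simulate.registers"
    )
    truth = pd.DataFrame(
        dict(layer=np.arange(n_layers), seam_index=seam_index, n_pf=N)
    )
    return table, truth


def make_pf_volume(
    box: int = 64,
    voxel_size: float = 2.0,
    blob_centers_A=((0.0, 0.0, 0.0),),
    blob_sigma_A: float = 8.0,
):
    """Toy protofilament density: a sum of isotropic Gaussian blobs.

    ``blob_centers_A`` are (x, y, z) offsets in Å from the box center.
    Returns ``(VolumeGrid, centers_vox)`` where ``centers_vox`` are the
    analytic blob centers in (z, y, x) voxel coordinates, for use as
    oracles by the reference builder tests.
    """
    centers = np.atleast_2d(np.asarray(blob_centers_A, dtype=float))
    half_A = box * voxel_size / 2.0
    if np.any(np.abs(centers) >= half_A):
        raise ValueError("blob center outside the box")
    c0 = (box - 1) / 2.0
    zz, yy, xx = np.meshgrid(
        np.arange(box), np.arange(box), np.arange(box), indexing="ij"
    )
    data = np.zeros((box, box, box), dtype=np.float64)
    sigma_vox = blob_sigma_A / voxel_size
    centers_vox = []
    for cx, cy, cz in centers:
        vx, vy, vz = c0 + cx / voxel_size, c0 + cy / voxel_size, c0 + cz / voxel_size
        centers_vox.append((vz, vy, vx))
        d2 = (xx - vx) ** 2 + (yy - vy) ** 2 + (zz - vz) ** 2
        data += np.exp(-d2 / (2.0 * sigma_vox**2))
    return VolumeGrid(data, voxel_size, label="synthetic protofilament"), np.array(
        centers_vox
    )
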