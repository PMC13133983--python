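import numpy as np
import pytest
from scipy import ndimage

from mtseam import (
    HelicalArchitecture,
    HelicalSymmetry,
    VolumeGrid,
    build_reference_set,
    derive_symmetry,
    estimate_radius_A,
    replicate_protofilament,
    shift_volume_axial,
)
from mtseam.simulate import make_pf_volume

SYM14 = derive_symmetry(HelicalArchitecture(14, 3, 41.0))


def _blob(box=96, voxel=2.0, sigma=8.0):
    vol, centers = make_pf_volume(box=box, voxel_size=voxel, blob_sigma_A=sigma)
    return vol, centers[0]


def test_single_copy_reproduces_input_at_radius_zero():
    vol, _ = _blob(box=48)
    out = replicate_protofilament(vol, SYM14, radius_A=0.0, n_copies=1)
    assert np.abs(out.data - vol.data).max() < 1e-6 * vol.data.max()


def test_copy_centroids_match_analytic_positions():
    # an exaggerated 30 A rise keeps the copies separable for labeling;
    # the placement code is identical for any rise
    vol, c0 = _blob()
    radius = 40.0
    sym = HelicalSymmetry(30.0, -360.0 / 14)
    out = replicate_protofilament(vol, sym, radius_A=radius, n_copies=3)
    v = vol.voxel_size
    lbl, n = ndimage.label(out.data > 0.5 * out.data.max())
    assert n == 3
    coms = np.array(ndimage.center_of_mass(out.data, lbl, range(1, n + 1)))
    expected = []
    for k in range(3):
        ang = np.deg2rad(k * sym.twist)
        x = radius * np.cos(ang) / v
        y = radius * np.sin(ang) / v
        z = k * sym.rise / v
        expected.append(c0 + np.array([z, y, x]))
    expected = np.array(sorted(expected, key=lambda p: p[0]))
    coms = coms[np.argsort(coms[:, 0])]
    assert np.abs(coms - expected).max() < 0.5


def test_mass_conserved_per_copy():
    vol, _ = _blob()
    out = replicate_protofilament(vol, SYM14, radius_A=40.0, n_copies=3)
    assert out.data.sum() == pytest.approx(3 * vol.data.sum(), rel=0.01)


def test_ring_cn_symmetry_on_rod():
    # a z-uniform rod is the fixture for which C_N symmetry holds exactly
    box, v = 96, 4.0
    zz, yy, xx = np.meshgrid(*([np.arange(box)] * 3), indexing="ij")
    c = (box - 1) / 2.0
    sigma_vox = 16.0 / v
    rod = np.exp(-(((xx - c) ** 2 + (yy - c) ** 2) / (2 * sigma_vox**2)))
    vol = VolumeGrid(rod.astype(np.float64), v)
    sym = derive_symmetry(HelicalArchitecture(14, 3, 41.0))
    ring = replicate_protofilament(vol, sym, radius_A=112.0, n_copies=14)
    rotated = ndimage.rotate(
        ring.data, 360.0 / 14, axes=(2, 1), reshape=False, order=3
    )
    # each copy k is z-shifted by k*rise, truncating the rod at the box
    # bottom; the completed ring is exactly C_N only in the z band above
    # the largest shift (plus a spline margin)
    zmin = int(np.ceil(13 * sym.rise / v)) + 4
    slab = slice(zmin, box - 1)
    rel = np.abs(rotated[slab] - ring.data[slab]).max() / ring.data[slab].max()
    assert rel < 1e-3


def test_reference_set_one_per_architecture():
    vol, _ = _blob(box=64, voxel=2.0)
    archs = [HelicalArchitecture.from_string(s) for s in
             ("11-3", "12-3", "13-3", "14-3", "15-4", "16-4")]
    refs = build_reference_set(vol, archs, radius_ref_A=40.0, n_ref=14)
    assert len(refs) == 6
    sums = [r.data.sum() for r in refs]
    assert len(set(np.round(sums, 3))) == 6  # distinct volumes
    for arch, ref in zip(archs, refs):
        assert str(arch) in ref.label


def test_reference_set_validation():
    vol, _ = _blob(box=48)
    with pytest.raises(ValueError):
        build_reference_set(vol, [], radius_ref_A=40.0)
    arch = HelicalArchitecture(14, 3, 41.0)
    with pytest.raises(ValueError):
        build_reference_set(vol, [arch, arch], radius_ref_A=40.0)


def test_radius_must_fit_box():
    vol, _ = _blob(box=48, voxel=2.0)  # 96 A box
    with pytest.raises(ValueError):
        replicate_protofilament(vol, SYM14, radius_A=60.0)


def test_estimate_radius():
    vol, _ = make_pf_volume(box=64, voxel_size=2.0, blob_centers_A=((30.0, 0.0, 0.0),))
    assert estimate_radius_A(vol) == pytest.approx(30.0, abs=0.1)


def test_shift_volume_axial_round_trip():
    vol, _ = _blob()
    fwd = shift_volume_axial(vol, 41.0)
    back = shift_volume_axial(fwd, -41.0)
    assert np.abs(back.data - vol.data).max() / vol.data.max() < 1e-3
    com0 = ndimage.center_of_mass(vol.data)[0]
    com1 = ndimage.center_of_mass(fwd.data)[0]
    assert (com1 - com0) * vol.voxel_size == pytest.approx(41.0, abs=0.2)


def test_shift_exceeding_box_rejected():
    vol, _ = _blob(box=32, voxel=1.0)
    with pytest.raises(ValueError):
        shift_volume_axial(vol, 40.0)
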