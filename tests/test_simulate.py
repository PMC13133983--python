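import numpy as np
import pandas as pd
import pytest

from mtseam.simulate import (
    make_angle_tracks,
    make_micrograph_picks,
    make_pf_volume,
    make_register_layers,
)


def test_picks_deterministic_and_in_field():
    t1, truth1 = make_micrograph_picks(seed=7)
    t2, truth2 = make_micrograph_picks(seed=7)
    pd.testing.assert_frame_equal(t1.df, t2.df)
    pd.testing.assert_frame_equal(truth1, truth2)
    xy = t1.df[["x", "y"]].to_numpy()
    assert np.all(xy >= -5) and np.all(xy < 4096 + 5)  # jitter can cross the edge


def test_picks_noise_bookkeeping():
    table, truth = make_micrograph_picks(
        n_filaments=4, dropout_frac=0.2, id_swap_frac=0.1, seed=1
    )
    surviving = truth[~truth["dropped"]]
    assert len(surviving) == len(table)
    n = len(truth)
    # binomial expectations with generous slack
    assert truth["dropped"].sum() == pytest.approx(0.2 * n, abs=4 * np.sqrt(n))
    assert surviving["swapped"].sum() > 0
    # swapped picks carry a wrong filament label
    sw = surviving[surviving["swapped"]]
    obs = table.df.set_index("particle_id").loc[sw["particle_id"], "filament_id"]
    assert (obs.to_numpy() != sw["true_filament"].to_numpy()).all()


def test_picks_reject_bad_fractions():
    with pytest.raises(ValueError):
        make_micrograph_picks(dropout_frac=1.0)


def test_angle_tracks_truth_structure():
    table, truth = make_angle_tracks(n_particles=40, seed=2)
    assert len(table) == 40
    assert truth.attrs["N"] == 14
    assert set(truth.columns) >= {"psi_true", "psi_outlier", "phi_line", "t_A"}
    # noiseless track equals the polynomial exactly
    clean, ctruth = make_angle_tracks(
        n_particles=10, psi_noise_deg=0.0, psi_outlier_frac=0.0, seed=0
    )
    assert np.allclose(clean.df["psi"].to_numpy(), ctruth["psi_true"].to_numpy())


def test_register_layers_noise_free_structure():
    table, truth = make_register_layers(n_layers=5, N=14, seam_index=6, seed=0)
    assert len(table) == 5 * 14
    df = table.df
    k = df["pf_index"].to_numpy(dtype=int)
    reg = df["register"].to_numpy()
    assert ((k < 6) == (reg == "A")).all()
    assert (truth["seam_index"] == 6).all()


def test_register_layers_all_missing_is_empty_but_valid():
    table, _ = make_register_layers(n_layers=3, missing_rate=1.0, seed=0)
    assert len(table) == 0


def test_register_layers_seam_bounds():
    with pytest.raises(ValueError):
        make_register_layers(N=14, seam_index=14)


def test_pf_volume_centroid_oracle():
    vol, centers_vox = make_pf_volume(box=48, voxel_size=2.0, blob_centers_A=((10.0, -6.0, 14.0),))
    from scipy import ndimage

    com = np.array(ndimage.center_of_mass(vol.data))
    assert np.allclose(com, centers_vox[0], atol=0.05)


def test_pf_volume_rejects_outside_blob():
    with pytest.raises(ValueError):
        make_pf_volume(box=32, voxel_size=1.0, blob_centers_A=((100.0, 0.0, 0.0),))
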