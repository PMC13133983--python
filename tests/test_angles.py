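import numpy as np
import pandas as pd
import pytest

from mtseam import circular_mode, unify_phi, unify_psi, wrap_angle
from mtseam.simulate import make_angle_tracks


def test_circular_mode_wraps():
    rng = np.random.default_rng(0)
    angles = wrap_angle(179.0 + rng.normal(0, 3.0, 500))
    mode = circular_mode(angles)
    assert abs(wrap_angle(mode - 179.0)) < 2.0


def test_unify_psi_recovers_polynomial():
    table, truth = make_angle_tracks(n_particles=60, seed=3)
    out = unify_psi(table)
    err = wrap_angle(out.df["psi"].to_numpy() - truth["psi_true"].to_numpy())
    assert np.sqrt(np.mean(err**2)) < 1.0
    # outliers were replaced by the track, not kept
    outliers = truth["psi_outlier"].to_numpy()
    assert np.abs(err[outliers]).max() < 3.0


def test_unify_psi_idempotent():
    table, _ = make_angle_tracks(n_particles=60, seed=5)
    once = unify_psi(table)
    twice = unify_psi(once)
    assert np.allclose(once.df["psi"].to_numpy(), twice.df["psi"].to_numpy(), atol=1e-9)


def test_unify_phi_collapses_line_family():
    table, truth = make_angle_tracks(
        n_particles=60, seed=7, phi0=13.0, phi_line_noise_deg=3.0
    )
    out = unify_phi(table, n_pf=14)
    phi = out.df["rot"].to_numpy()
    period = 360.0 / 14
    # all particles now sit on a single line: folded residuals to phi0 small
    resid = (phi - 13.0 + period / 2) % period - period / 2
    assert np.abs(resid).max() < 1.5
    assert np.std(resid) < 0.5


def test_unify_phi_idempotent_and_fixed_slope():
    table, _ = make_angle_tracks(n_particles=50, seed=9, supertwist_slope=0.0)
    once = unify_phi(table, n_pf=14)
    twice = unify_phi(once, n_pf=14)
    assert np.allclose(
        wrap_angle(once.df["rot"].to_numpy() - twice.df["rot"].to_numpy()), 0.0, atol=1e-9
    )
    fixed = unify_phi(table, n_pf=14, fixed_slope=0.0)
    assert len(fixed) == len(table)


def test_unify_phi_recovers_supertwist_slope():
    table, truth = make_angle_tracks(
        n_particles=60, seed=11, supertwist_slope=0.004, phi_line_noise_deg=2.0
    )
    out = unify_phi(table, n_pf=14)
    t = truth["t_A"].to_numpy()
    phi = out.df["rot"].to_numpy()
    period = 360.0 / 14
    # the unified phi follows phi0 + slope*t on one line (mod the period)
    resid = (phi - (truth.attrs["phi0"] + 0.004 * t) + period / 2) % period - period / 2
    assert np.abs(resid - resid.mean()).max() < 1.0


def test_unify_phi_validates_n_pf():
    table, _ = make_angle_tracks(n_particles=20, seed=0)
    with pytest.raises(ValueError):
        unify_phi(table, n_pf=1)
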