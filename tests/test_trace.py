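import numpy as np
import pandas as pd
import pytest

from mtseam import ParticleTable, split_filaments, trace_extend
from mtseam.simulate import make_micrograph_picks
from mtseam.trace import fit_centerline, make_groups


def _purity(table, truth):
    """Fraction of surviving true picks whose output grouping matches the
    majority mapping between output groups and true filaments."""
    df = table.df.set_index("particle_id")
    surv = truth[~truth["dropped"]]
    obs = df.loc[df.index.intersection(surv["particle_id"]), "filament_id"]
    tru = surv.set_index("particle_id").loc[obs.index, "true_filament"]
    joint = pd.crosstab(obs, tru)
    return joint.max(axis=1).sum() / joint.to_numpy().sum()


def test_split_filaments_on_psi_jump():
    n = 12
    df = pd.DataFrame(
        dict(
            micrograph_id="m.mrc",
            filament_id=0,
            particle_id=np.arange(n),
            x=np.arange(n) * 80.0,
            y=np.concatenate([np.zeros(6), np.arange(6) * 80.0]),
            pixel_size=1.0,
            rot=0.0,
            tilt=90.0,
            psi=np.concatenate([np.zeros(6), np.full(6, 45.0)]),
        )
    )
    out = split_filaments(ParticleTable(df), max_psi_jump_deg=10.0)
    assert out.df["filament_id"].nunique() == 2
    # first segment keeps the original id
    assert out.df.loc[out.df["particle_id"] < 6, "filament_id"].eq(0).all()


def test_fit_centerline_linear_and_quadratic():
    xy = np.column_stack([np.arange(20) * 50.0, 3.0 + 0.5 * np.arange(20) * 50.0])
    df = pd.DataFrame(
        dict(
            micrograph_id="m.mrc",
            filament_id=0,
            particle_id=np.arange(20),
            x=xy[:, 0],
            y=xy[:, 1],
            pixel_size=1.0,
            rot=0.0,
            tilt=90.0,
            psi=0.0,
        )
    )
    group = make_groups(ParticleTable(df))[0]
    model = fit_centerline(group, deviation_tol_px=90.0)
    pred = model.evaluate(model.t)
    assert np.allclose(pred, xy, atol=1e-6)


def test_noise_free_input_is_fixed_point_up_to_extension():
    table, truth = make_micrograph_picks(
        n_filaments=3, dropout_frac=0.0, id_swap_frac=0.0, jitter_px=0.0, seed=4
    )
    out = trace_extend(table, field_px=4096)
    assert _purity(out, truth) == 1.0
    # nothing was dropped, so no picks should be invented along the filaments
    assert len(out) == len(table)


def test_trace_recovery_under_noise():
    for seed in range(3):
        table, truth = make_micrograph_picks(
            n_filaments=4, dropout_frac=0.15, id_swap_frac=0.10, seed=seed
        )
        out = trace_extend(table, field_px=4096)
        assert _purity(out, truth) >= 0.99
        assert out.df["filament_id"].nunique() == 4


def test_dropped_positions_recovered():
    table, truth = make_micrograph_picks(
        n_filaments=4, dropout_frac=0.15, id_swap_frac=0.10, seed=5
    )
    out = trace_extend(table, field_px=4096)
    dropped = truth[truth["dropped"]]
    xy = out.df[["x", "y"]].to_numpy()
    recovered = 0
    for _, row in dropped.iterrows():
        d = np.hypot(xy[:, 0] - row["true_x"], xy[:, 1] - row["true_y"])
        recovered += d.min() < 41.0  # within half a pick spacing
    assert recovered / max(1, len(dropped)) >= 0.99
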