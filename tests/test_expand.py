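import numpy as np
import pandas as pd
import pytest

from mtseam import (
    ExpansionError,
    HelicalArchitecture,
    ParticleTable,
    derive_symmetry,
    project_offset,
    recenter_metadata,
    shift_register,
    symmetry_expand,
    unexpand_at_seam,
    wrap_angle,
)
from mtseam.particles import REGISTER_B
from tests.conftest import make_table

SYM = derive_symmetry(HelicalArchitecture(14, 3, 41.0))


def test_expand_counts_and_metadata(small_table):
    out = symmetry_expand(small_table, SYM, 14)
    assert len(out) == 14 * len(small_table)
    assert out.df["particle_id"].is_unique
    assert sorted(out.df["pf_index"].unique()) == list(range(14))
    # copy k's rot differs from the parent's by k*twist
    base = small_table.df.set_index("particle_id")
    for k in (0, 1, 13):
        sub = out.df[out.df["pf_index"] == k]
        parent_rot = base.loc[sub["parent_id"], "rot"].to_numpy()
        assert np.allclose(
            wrap_angle(sub["rot"].to_numpy() - parent_rot - k * SYM.twist), 0.0, atol=1e-9
        )


def test_expand_shift_projection_analytic():
    # tilt 90, psi 0, rot 0: R = Ry(90), so an axial (z) offset projects to +x
    t = make_table(n=1)
    t.df["psi"] = 0.0
    t.df["rot"] = 0.0
    table = ParticleTable(t.df)
    out = symmetry_expand(table, SYM, 14)
    k1 = out.df[out.df["pf_index"] == 1].iloc[0]
    assert k1["dx"] == pytest.approx(SYM.rise, abs=1e-9)
    assert k1["dy"] == pytest.approx(0.0, abs=1e-9)


def test_expand_rejects_expanded_table(small_table):
    once = symmetry_expand(small_table, SYM, 14)
    with pytest.raises(ExpansionError):
        symmetry_expand(once, SYM, 14)


def test_expand_unexpand_lossless(small_table):
    expanded = symmetry_expand(small_table, SYM, 14)
    seams = {("mic_0.mrc", 0): 0}
    back = unexpand_at_seam(expanded, seams)
    orig = small_table.df.sort_values("particle_id").reset_index(drop=True)
    rec = back.df.sort_values("particle_id").reset_index(drop=True)
    for col in ("micrograph_id", "filament_id", "particle_id", "x", "y", "rot", "tilt", "psi", "dx", "dy"):
        assert (orig[col] == rec[col]).all() or np.allclose(
            orig[col].to_numpy(float), rec[col].to_numpy(float), atol=1e-12
        ), col
    assert rec["pf_index"].isna().all() and rec["parent_id"].isna().all()


def test_unexpand_requires_expanded(small_table):
    with pytest.raises(ExpansionError):
        unexpand_at_seam(small_table, {("mic_0.mrc", 0): 0})


def test_unexpand_drops_microtubules_without_seam(small_table):
    expanded = symmetry_expand(small_table, SYM, 14)
    out = unexpand_at_seam(expanded, {})
    assert len(out) == 0


def test_shift_register_round_trip():
    t = make_table(n=6, seed=2)
    t.df["register"] = REGISTER_B
    t.df["tilt"] = 85.0  # general orientation
    table = ParticleTable(t.df)
    fwd = shift_register(table, which="B", shift_A=41.0)
    assert (fwd.df["register"] == "A").all()
    back = shift_register(fwd, which="A", shift_A=-41.0)
    for col in ("dx", "dy"):
        assert np.abs(back.df[col].to_numpy() - table.df[col].to_numpy()).max() < 1e-9


def test_shift_register_zero_is_noop():
    t = make_table(n=3)
    t.df["register"] = REGISTER_B
    table = ParticleTable(t.df)
    out = shift_register(table, which="B", shift_A=0.0)
    pd.testing.assert_frame_equal(out.df, table.df)


def test_shift_register_validates_class(small_table):
    with pytest.raises(ValueError):
        shift_register(small_table, which="C")


def test_recenter_metadata_inverse(small_table):
    offset = np.array([3.0, -5.0, 11.0])
    fwd = recenter_metadata(small_table, offset)
    back = recenter_metadata(fwd, -offset)
    for col in ("dx", "dy"):
        assert np.allclose(back.df[col].to_numpy(), small_table.df[col].to_numpy(), atol=1e-12)


def test_project_offset_shape_validation(small_table):
    with pytest.raises(ValueError):
        project_offset(small_table.df, np.array([1.0, 2.0]))
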