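import numpy as np
import pandas as pd
import pytest

from mtseam import (
    ParticleTable,
    StarFormatError,
    concat_tables,
    read_star,
    write_star,
)
from tests.conftest import make_table


def test_normalize_defaults(small_table):
    df = small_table.df
    assert (df["dx"] == 0.0).all() and (df["dy"] == 0.0).all()
    assert (df["register"] == "unassigned").all()
    assert df["pf_index"].isna().all() and df["parent_id"].isna().all()
    assert df["particle_id"].is_unique


def test_duplicate_particle_id_rejected(small_table):
    df = small_table.df.copy()
    df.loc[1, "particle_id"] = df.loc[0, "particle_id"]
    with pytest.raises(StarFormatError):
        ParticleTable(df)


def test_missing_required_column_rejected(small_table):
    with pytest.raises(StarFormatError):
        ParticleTable(small_table.df.drop(columns=["psi"]))


def test_nonpositive_pixel_size_rejected(small_table):
    df = small_table.df.copy()
    df["pixel_size"] = 0.0
    with pytest.raises(StarFormatError):
        ParticleTable(df)


def test_star_round_trip_exact(tmp_path, small_table):
    # plant awkward float values and an extra passthrough column
    t = small_table
    t.df.loc[0, "x"] = 1.0 / 3.0
    t.df.loc[1, "psi"] = -179.99999999999997
    t.df["_customScore"] = np.linspace(0.0, 1.0, len(t.df))
    path = tmp_path / "t.star"
    write_star(t, path)
    back = read_star(path)
    for col in t.df.columns:
        a, b = t.df[col], back.df[col]
        if col == "_customScore":
            # unknown tags are preserved verbatim as text
            assert [repr(v) for v in a] == b.tolist(), col
        elif a.dtype.kind == "f":
            assert np.array_equal(a.to_numpy(), b.to_numpy()), col
        else:
            assert a.astype(str).tolist() == b.astype(str).tolist(), col


def test_star_round_trip_of_round_trip_is_stable(tmp_path, small_table):
    p1, p2 = tmp_path / "a.star", tmp_path / "b.star"
    write_star(small_table, p1)
    write_star(read_star(p1), p2)
    assert p1.read_text() == p2.read_text()


def test_read_star_missing_tag(tmp_path, small_table):
    path = tmp_path / "t.star"
    write_star(small_table, path)
    text = path.read_text().replace("_rlnAnglePsi", "_rlnSomethingElse")
    bad = tmp_path / "bad.star"
    bad.write_text(text)
    with pytest.raises(StarFormatError):
        read_star(bad)


def test_order_along_filaments_sorts_and_is_idempotent():
    t = make_table(n=8)
    shuffled = ParticleTable(t.df.sample(frac=1.0, random_state=3).reset_index(drop=True))
    ordered = shuffled.order_along_filaments()
    x = ordered.df["x"].to_numpy()
    assert np.all(np.diff(x) > 0) or np.all(np.diff(x) < 0)
    again = ordered.order_along_filaments()
    pd.testing.assert_frame_equal(ordered.df, again.df)


def test_concat_tables_unique_ids():
    a = make_table(n=5, micrograph_id="m1.mrc")
    b = make_table(n=5, micrograph_id="m2.mrc")
    merged = concat_tables([a, b])
    assert len(merged) == 10
    assert merged.df["particle_id"].is_unique
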