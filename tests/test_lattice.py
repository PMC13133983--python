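import numpy as np
import pytest

from mtseam import (
    EulerTriplet,
    HelicalArchitecture,
    HelicalSymmetry,
    LatticeValidationError,
    circular_difference,
    derive_symmetry,
    euler_to_matrix,
    helical_operator,
    matrix_to_euler,
    wrap_angle,
)


def test_derive_symmetry_canonical_lattice():
    sym = derive_symmetry(HelicalArchitecture(14, 3, 41.0))
    assert sym.rise == pytest.approx(3 * 41.0 / 14)
    assert sym.twist == pytest.approx(-360.0 / 14)


@pytest.mark.parametrize(
    "n,s,rise,twist",
    [
        (11, 3, 3 * 41.0 / 11, -360.0 / 11),
        (12, 3, 3 * 41.0 / 12, -30.0),
        (13, 3, 3 * 41.0 / 13, -360.0 / 13),
        (14, 3, 8.785714285714286, -25.714285714285715),
        (15, 4, 4 * 41.0 / 15, -24.0),
        (16, 4, 10.25, -22.5),
    ],
)
def test_derive_symmetry_candidate_list(n, s, rise, twist):
    sym = derive_symmetry(HelicalArchitecture(n, s, 41.0))
    assert sym.rise == pytest.approx(rise)
    assert sym.twist == pytest.approx(twist)


def test_architecture_from_string_variants():
    for text in ("14-3", " 14-3 ", "14–3"):  # hyphen, whitespace, en dash
        arch = HelicalArchitecture.from_string(text)
        assert (arch.n_protofilaments, arch.n_starts) == (14, 3)
    with pytest.raises(LatticeValidationError):
        HelicalArchitecture.from_string("fourteen-three")


@pytest.mark.parametrize("n,s", [(7, 3), (19, 3), (14, 1), (14, 5), (14, 0)])
def test_architecture_validation(n, s):
    with pytest.raises(LatticeValidationError):
        HelicalArchitecture(n, s, 41.0)


@pytest.mark.parametrize("rise,twist", [(0.0, -25.7), (-1.0, -25.7), (8.79, 0.0), (8.79, -360.0), (8.79, 10.0)])
def test_symmetry_validation(rise, twist):
    with pytest.raises(LatticeValidationError):
        HelicalSymmetry(rise, twist)


def test_wrap_angle_range_and_fixed_points():
    a = np.array([-540.0, -180.0, -179.9, 0.0, 179.9, 180.0, 360.0, 725.0])
    w = wrap_angle(a)
    assert np.all(w > -180.0) and np.all(w <= 180.0)
    assert w[1] == 180.0  # -180 wraps to the closed end +180
    assert w[3] == 0.0 and w[4] == 179.9
    assert wrap_angle(725.0) == pytest.approx(5.0)


def test_circular_difference_symmetry_and_wrap():
    assert circular_difference(179.0, -179.0) == pytest.approx(-2.0)
    assert circular_difference(-179.0, 179.0) == pytest.approx(2.0)
    assert abs(circular_difference(10.0, 250.0)) <= 180.0


def test_helical_operator_composition():
    sym = derive_symmetry(HelicalArchitecture(14, 3, 41.0))
    op1, op2, op3 = (helical_operator(sym, k) for k in (1, 2, 3))
    combined = op1.compose(op2)
    assert np.allclose(combined.rotation, op3.rotation)
    assert np.allclose(combined.translation, op3.translation)
    assert op1.translation[2] == pytest.approx(sym.rise)
    # full turn of N operators: rotation closes, translation = N * rise
    full = helical_operator(sym, 14)
    assert np.allclose(full.rotation, np.eye(3), atol=1e-12)
    assert full.translation[2] == pytest.approx(3 * 41.0)


def test_rigid_transform_inverse():
    sym = derive_symmetry(HelicalArchitecture(13, 3, 41.0))
    op = helical_operator(sym, 5)
    ident = op.compose(op.inverse())
    assert np.allclose(ident.rotation, np.eye(3), atol=1e-12)
    assert np.allclose(ident.translation, 0.0, atol=1e-12)
    pt = np.array([3.0, -7.0, 11.0])
    assert np.allclose(op.inverse().apply(op.apply(pt)), pt)


def test_euler_matrix_round_trip():
    rng = np.random.default_rng(42)
    for _ in range(50):
        e = EulerTriplet(
            rot=rng.uniform(-180, 180),
            tilt=rng.uniform(1.0, 179.0),  # away from gimbal lock
            psi=rng.uniform(-180, 180),
        )
        back = matrix_to_euler(euler_to_matrix(e))
        assert np.allclose(euler_to_matrix(back), euler_to_matrix(e), atol=1e-10)


def test_euler_gimbal_equivalence():
    # at tilt 0 only rot+psi is determined: (90,0,0) and (0,0,90) coincide
    a = euler_to_matrix(EulerTriplet(rot=90.0, tilt=0.0, psi=0.0))
    b = euler_to_matrix(EulerTriplet(rot=0.0, tilt=0.0, psi=90.0))
    assert np.allclose(a, b, atol=1e-12)
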