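"""Superposition, swivel angles, helix-axis fits and hybrid diameters."""

import numpy as np
import pytest

from dualsbm import (SelectionSpec, fit_helix_axis, hybrid_diameter,
                     interaxial_angle, make_bent_duplex_pair,
                     make_ideal_duplex, superpose, swivel_angle)
from dualsbm.geometry import kabsch, rotation_angle_axis


def _rotation(axis, degrees):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(degrees)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * K @ K


def _pairing(truth):
    return [((a[0], a[1]), (b[0], b[1])) for a, b in truth["pairing"]]


def test_superpose_identity(toy):
    spec = SelectionSpec(groups={"all": [("A", 1, 12), ("B", 1, 14)]})
    t = superpose(toy.model_a, toy.model_a, spec, "all")
    np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
    np.testing.assert_allclose(t.translation, 0.0, atol=1e-9)
    assert t.rmsd == pytest.approx(0.0, abs=1e-9)


def test_superpose_recovers_constructed_rotation(toy):
    spec = SelectionSpec(groups={"all": [("A", 1, 12), ("B", 1, 14)]})
    R = _rotation([0, 0, 1], 90.0)
    moved = toy.model_a.with_coords(toy.model_a.coords @ R.T + [4.0, -2.0, 9.0])
    t = superpose(moved, toy.model_a, spec, "all")
    np.testing.assert_allclose(t.rotation @ R, np.eye(3), atol=1e-6)
    assert t.rmsd == pytest.approx(0.0, abs=1e-6)


def test_superpose_rejects_reflection(toy):
    """Mirrored coordinates still yield a proper rotation (det +1) with a
    non-zero residual."""
    spec = SelectionSpec(groups={"all": [("A", 1, 12), ("B", 1, 14)]})
    mirrored = toy.model_a.with_coords(toy.model_a.coords * [1.0, 1.0, -1.0])
    t = superpose(mirrored, toy.model_a, spec, "all")
    assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)
    assert t.rmsd > 0.1


def test_superpose_collinear_selection_raises():
    from dualsbm.model_io import AtomRecord, MolecularModel

    records = [
        AtomRecord(serial=i + 1, name="CA", element="C", residue_name="GLY",
                   residue_number=i + 1, chain_id="A",
                   position=np.array([3.8 * i, 0.0, 0.0]),
                   molecule_class="protein")
        for i in range(5)
    ]
    m = MolecularModel.from_atoms(records)
    spec = SelectionSpec(groups={"line": [("A", 1, 5)]})
    with pytest.raises(ValueError, match="collinear"):
        superpose(m, m, spec, "line")


def _swivel_spec(groups):
    return SelectionSpec(groups={"core": groups.groups["NGN"],
                                 "swivel": groups.groups["KOW"]})


def test_swivel_self_is_zero(toy):
    spec = _swivel_spec(toy.groups)
    res = swivel_angle(toy.model_a, toy.model_a, spec, "core", "swivel")
    assert res.angle == pytest.approx(0.0, abs=1e-6)
    assert res.core_rmsd == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("degrees", [3.0, 10.0, 57.0])
def test_swivel_recovers_constructed_domain_rotation(toy, degrees):
    """Rotating the swivel module about a known axis through its centroid is
    recovered as angle and axis, independent of an extra global motion."""
    spec = _swivel_spec(toy.groups)
    axis = np.array([0.3, 0.5, 0.8])
    axis /= np.linalg.norm(axis)
    R = _rotation(axis, degrees)
    coords = toy.model_a.coords.copy()
    sw = np.flatnonzero(toy.groups.mask(toy.model_a, "KOW"))
    centroid = coords[sw].mean(axis=0)
    coords[sw] = (coords[sw] - centroid) @ R.T + centroid
    # bury the signal under a global rigid motion of the whole complex
    G = _rotation([1, 1, 0], 33.0)
    moved = toy.model_a.with_coords(coords @ G.T + [10.0, 0.0, -5.0])
    res = swivel_angle(toy.model_a, moved, spec, "core", "swivel")
    assert res.angle == pytest.approx(degrees, abs=1e-4)
    assert abs(np.dot(res.axis, axis)) == pytest.approx(1.0, abs=1e-6)


def test_swivel_symmetric_in_arguments(toy):
    spec = _swivel_spec(toy.groups)
    res_ab = swivel_angle(toy.model_a, toy.model_b, spec, "core", "swivel")
    res_ba = swivel_angle(toy.model_b, toy.model_a, spec, "core", "swivel")
    assert res_ab.angle == pytest.approx(res_ba.angle, abs=1e-6)


def test_helix_axis_recovered_within_one_degree():
    model, truth = make_ideal_duplex(10)
    fit = fit_helix_axis(model, _pairing(truth))
    cosang = abs(np.dot(fit.axis, truth["axis"]))
    assert np.degrees(np.arccos(min(cosang, 1.0))) < 1.0
    assert fit.n_bp == 10


def test_helix_axis_oriented_and_translation_invariant():
    model, truth = make_ideal_duplex(12, axis=[0.0, 1.0, 0.0])
    fit = fit_helix_axis(model, _pairing(truth))
    assert np.dot(fit.axis, truth["axis"]) > 0.99  # 5'->3' orientation
    moved = model.with_coords(model.coords + np.array([100.0, -50.0, 3.0]))
    fit2 = fit_helix_axis(moved, _pairing(truth))
    np.testing.assert_allclose(fit2.axis, fit.axis, atol=1e-9)
    assert fit2.radius == pytest.approx(fit.radius, abs=1e-9)


def test_p_radius_recovered():
    model, truth = make_ideal_duplex(10, p_radius=9.4)
    fit = fit_helix_axis(model, _pairing(truth))
    assert fit.radius == pytest.approx(9.4, abs=0.1)


def test_helix_axis_needs_four_pairs():
    model, truth = make_ideal_duplex(10)
    with pytest.raises(ValueError, match="4 base pairs"):
        fit_helix_axis(model, _pairing(truth)[:3])


def test_helix_axis_missing_atom_raises():
    model, truth = make_ideal_duplex(6)
    bad = _pairing(truth)
    bad[0] = (("U", 99), bad[0][1])
    with pytest.raises(ValueError, match="C1'"):
        fit_helix_axis(model, bad)


def test_interaxial_identical_axes_zero():
    model, truth = make_ideal_duplex(8)
    fit = fit_helix_axis(model, _pairing(truth))
    assert interaxial_angle(fit, fit) == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("angle", [0.0, 102.0, 129.0])
def test_interaxial_angle_of_constructed_pair(angle):
    """Bent duplex pairs built at 0, 102 and 129 degrees are recovered
    within half a degree (the upstream/downstream duplex geometry)."""
    model, truth = make_bent_duplex_pair(angle)
    f1 = fit_helix_axis(model, _pairing(truth["duplex1"]))
    f2 = fit_helix_axis(model, _pairing(truth["duplex2"]))
    assert interaxial_angle(f1, f2) == pytest.approx(angle, abs=0.5)


def test_hybrid_diameter_is_twice_p_radius():
    model, truth = make_ideal_duplex(10, p_radius=9.4)
    diameter, fit = hybrid_diameter(model, _pairing(truth))
    assert diameter == pytest.approx(18.8, abs=0.2)


def test_hybrid_diameter_scales_homogeneously():
    model, truth = make_ideal_duplex(10)
    pairing = _pairing(truth)
    d1, _ = hybrid_diameter(model, pairing)
    scaled = model.with_coords(model.coords * 1.1)
    d2, _ = hybrid_diameter(scaled, pairing)
    assert d2 == pytest.approx(1.1 * d1, rel=1e-9)


def test_angles_invariant_under_rigid_motion_of_either_input(toy):
    spec = _swivel_spec(toy.groups)
    ref = swivel_angle(toy.model_a, toy.model_b, spec, "core", "swivel")
    G = _rotation([0.2, -0.7, 0.4], 71.0)
    moved_b = toy.model_b.with_coords(
        toy.model_b.coords @ G.T + [5.0, 5.0, 5.0])
    res = swivel_angle(toy.model_a, moved_b, spec, "core", "swivel")
    assert res.angle == pytest.approx(ref.angle, abs=1e-6)


def test_rotation_angle_axis_near_identity_and_half_turn():
    angle, _ = rotation_angle_axis(np.eye(3))
    assert angle == pytest.approx(0.0, abs=1e-6)
    R = _rotation([0, 1, 0], 180.0)
    angle, axis = rotation_angle_axis(R)
    assert angle == pytest.approx(180.0, abs=1e-6)
    assert abs(axis[1]) == pytest.approx(1.0, abs=1e-6)


def test_kabsch_matches_scipy_reference():
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(21)
    P = rng.standard_normal((25, 3))
    Q = P @ _rotation([1, 2, 3], 40.0).T + 7.0 \
        + 0.05 * rng.standard_normal((25, 3))
    R, t, rmsd = kabsch(P, Q)
    rot, rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
    np.testing.assert_allclose(R, rot.as_matrix(), atol=1e-8)
    assert rmsd == pytest.approx(rssd / np.sqrt(len(P)), abs=1e-9)
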