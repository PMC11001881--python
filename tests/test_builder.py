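"""Single-basin construction, dual-basin merge and the potential."""

import numpy as np
import pytest

from dualsbm import (MolecularModel, build_single_basin, merge_dual_basin,
                     potential_energy, shadow_contact_map)
from dualsbm.model_io import AtomRecord
from dualsbm.shadow import Contact, ContactMap
from dualsbm.topology import DEFAULTS, DualBasinTopology


def _chain_model(n, spacing=3.8):
    """Non-collinear n-bead chain (slight zigzag keeps dihedrals defined)."""
    pts = np.column_stack([
        spacing * 0.9 * np.arange(n),
        1.5 * (np.arange(n) % 2),
        0.3 * (np.arange(n) % 3),
    ])
    records = [
        AtomRecord(serial=i + 1, name="CA", element="C", residue_name="GLY",
                   residue_number=i + 1, chain_id="A", position=pts[i],
                   molecule_class="protein")
        for i in range(n)
    ]
    bonds = [(i, i + 1) for i in range(n - 1)]
    return MolecularModel.from_atoms(records, bonds=bonds)


def _empty_map():
    return ContactMap([])


@pytest.mark.parametrize("n,nb,na,nd", [(3, 2, 1, 0), (4, 3, 2, 1)])
def test_bonded_term_counts(n, nb, na, nd):
    """3-atom chain: 2 bonds, 1 angle, no dihedral; 4-atom chain adds
    exactly one proper dihedral."""
    topo = build_single_basin(_chain_model(n), _empty_map())
    assert len(topo.bond_idx) == nb
    assert len(topo.angle_idx) == na
    assert len(topo.dihedral_idx) == nd
    assert len(topo.contact_idx) == 0


def test_contact_referencing_missing_atom_raises():
    model = _chain_model(3)
    bad = ContactMap([Contact(0, 7, 0.5, "protein-protein")])
    with pytest.raises(ValueError, match="absent"):
        build_single_basin(model, bad)


def test_native_state_is_global_among_perturbations(toy):
    """The source coordinates minimise the single-basin potential against
    100 randomly jittered (0.05 nm) coordinate sets."""
    topo = toy.topo_a
    x0 = toy.model_a.coords / 10.0
    e0 = topo.energy(x0).total
    rng = np.random.default_rng(42)
    for _ in range(100):
        x = x0 + 0.05 * rng.standard_normal(x0.shape)
        assert topo.energy(x).total >= e0


def test_merge_identity_has_no_dual_terms(toy):
    merged, report = merge_dual_basin(toy.topo_a, toy.topo_a)
    assert report.n_dual_contacts == 0
    assert report.n_dual_dihedrals == 0
    assert merged.n_dual_contacts == 0


def test_merge_distance_threshold_arithmetic():
    """Shared contact at 0.30 vs 0.35 nm (15.4% of the mean) becomes
    dual-basin; 0.30 vs 0.31 nm (3.3%) stays single at the state-B value."""
    model = _chain_model(6)

    def topo_with(r0):
        cmap = ContactMap([Contact(0, 5, r0, "protein-protein")])
        return build_single_basin(model, cmap)

    merged, rep = merge_dual_basin(topo_with(0.30), topo_with(0.35))
    assert rep.n_dual_contacts == 1
    assert merged.n_dual_contacts == 1
    merged, rep = merge_dual_basin(topo_with(0.30), topo_with(0.31))
    assert rep.n_dual_contacts == 0
    np.testing.assert_allclose(merged.contact_r0, [0.31])  # state-B value


def test_merge_dual_classification_symmetric(toy):
    """Swapping the states changes retained single-basin values but not
    which terms are classified dual."""
    m_ab, rep_ab = merge_dual_basin(toy.topo_a, toy.topo_b)
    m_ba, rep_ba = merge_dual_basin(toy.topo_b, toy.topo_a)
    assert rep_ab.n_dual_contacts == rep_ba.n_dual_contacts
    assert rep_ab.n_dual_dihedrals == rep_ba.n_dual_dihedrals
    dual_ab = np.isfinite(m_ab.dihedral_p0_b)
    dual_ba = np.isfinite(m_ba.dihedral_p0_b)
    np.testing.assert_array_equal(dual_ab, dual_ba)
    assert rep_ab.n_dual_contacts <= rep_ab.n_shared_contacts


def test_merge_reports_reproducible(toy):
    r1 = merge_dual_basin(toy.topo_a, toy.topo_b)[1]
    r2 = merge_dual_basin(toy.topo_a, toy.topo_b)[1]
    assert r1.as_dict() == r2.as_dict()


def test_merge_atom_mismatch_raises(toy):
    small = build_single_basin(_chain_model(5), _empty_map())
    with pytest.raises(ValueError, match="mismatch"):
        merge_dual_basin(toy.topo_a, small)


def test_endpoints_are_minima_of_merged_potential(toy):
    """Steepest descent from either native structure stays put
    (< 0.05 nm best-fit RMSD)."""
    from dualsbm.geometry import kabsch
    from dualsbm.langevin import steepest_descent

    for model in (toy.model_a, toy.model_b):
        x0 = model.coords / 10.0
        x = steepest_descent(toy.merged, x0, n_steps=2000)
        _, _, rmsd = kabsch(x, x0)
        assert rmsd < 0.05


def test_dual_contact_scan_has_minima_at_both_distances():
    """A 1-D scan of a dual-basin contact term shows local minima within
    1e-3 nm of both native distances."""
    r0a, r0b = 0.40, 0.80
    topo = DualBasinTopology(
        n_atoms=2,
        bond_idx=np.zeros((0, 2)), bond_r0=np.zeros(0),
        angle_idx=np.zeros((0, 3)), angle_t0=np.zeros(0),
        dihedral_idx=np.zeros((0, 4)), dihedral_p0=np.zeros(0),
        dihedral_p0_b=np.zeros(0),
        contact_idx=np.array([[0, 1]]), contact_r0=np.array([r0a]),
        contact_r0_b=np.array([r0b]),
        params={"eps_nn": 0.0},
    )
    rs = np.arange(0.2, 1.2, 1e-4)
    es = np.array([
        topo.energy(np.array([[0., 0., 0.], [r, 0., 0.]])).contact
        for r in rs
    ])
    interior = (es[1:-1] < es[:-2]) & (es[1:-1] < es[2:])
    minima = rs[1:-1][interior]
    assert np.min(np.abs(minima - r0a)) < 1e-3
    assert np.min(np.abs(minima - r0b)) < 1e-3


def test_basin_b_contacts_contribute_minus_epsilon(toy):
    """At the state-B native coordinates every contact carrying a B basin
    sits within 2% of the full well depth."""
    topo = toy.merged
    coords = toy.model_b.coords / 10.0
    pairs_b = {(c.i, c.j) for c in toy.cmap_b.contacts}
    idx = topo.contact_idx
    d = np.linalg.norm(coords[idx[:, 1]] - coords[idx[:, 0]], axis=1)
    v, _ = topo._contact_v_dv(d)
    eps = topo.params["epsilon"]
    for k, (i, j) in enumerate(idx):
        if (int(i), int(j)) in pairs_b:
            assert v[k] == pytest.approx(-eps, rel=0.02)


def test_forces_match_finite_differences(toy):
    """Analytic forces agree with central differences to 1e-4 relative on
    a jittered toy configuration (all term classes populated)."""
    topo = toy.merged
    rng = np.random.default_rng(11)
    x = toy.model_a.coords / 10.0 + 0.01 * rng.standard_normal(
        (topo.n_atoms, 3))
    _, f = topo.energy_forces(x)
    h = 1e-5
    num = np.zeros_like(f)
    for i in range(topo.n_atoms):
        for k in range(3):
            xp = x.copy()
            xp[i, k] += h
            xm = x.copy()
            xm[i, k] -= h
            num[i, k] = -(topo.energy(xp).total
                          - topo.energy(xm).total) / (2 * h)
    assert np.abs(num - f).max() / np.abs(f).max() < 1e-4


def test_compiled_kernel_matches_vectorised_path(toy):
    """The numba kernel and the numpy reference implement the same
    potential (energies and forces to near machine precision)."""
    from dualsbm._kernels import HAVE_NUMBA, energy_forces

    if not HAVE_NUMBA:
        pytest.fail("numba expected in the target environment")
    topo = toy.merged
    rng = np.random.default_rng(7)
    for _ in range(5):
        x = toy.model_a.coords / 10.0 + 0.05 * rng.standard_normal(
            (topo.n_atoms, 3))
        f = np.zeros_like(x)
        parts = energy_forces(x, *topo.kernel_args(), f)
        ref, f_ref = topo.energy_forces(x)
        assert sum(parts) == pytest.approx(ref.total, abs=1e-10)
        assert np.abs(f - f_ref).max() < 1e-9


def test_potential_energy_breakdown(toy):
    out = potential_energy(toy.merged, toy.model_b.coords / 10.0)
    assert set(out) == {"bond", "angle", "dihedral", "contact",
                        "excluded_volume", "total"}
    assert out["total"] == pytest.approx(
        sum(v for k, v in out.items() if k != "total"))


def test_topology_text_round_trip(toy):
    text = toy.merged.to_text()
    again = DualBasinTopology.from_text(text)
    x = toy.model_a.coords / 10.0
    assert again.energy(x).total == pytest.approx(
        toy.merged.energy(x).total, abs=1e-8)
    assert again.n_dual_contacts == toy.merged.n_dual_contacts
    assert again.n_dual_dihedrals == toy.merged.n_dual_dihedrals
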