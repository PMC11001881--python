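"""Download-free synthetic systems with known ground truth.

Three generators cover every pipeline stage at desk scale:

* :func:`make_two_state_toy` — a bead-per-residue fold-switcher: a rigid
  helical "anchor" chain (NGN stand-in) and a "switch" chain (KOW stand-in)
  that packs against the anchor as a helix in state A (many interdomain
  contacts) and self-packs as a beta-hairpin away from the anchor in state B
  (no interdomain contacts).  Both states share identical covalent bond
  lengths, so a dual-basin model built from them has both as explicit
  minima.
* :func:`make_symmetric_toy` — a mirror-symmetric two-basin system (an arm
  tethered to a C-shaped cradle, docked at +y in state A and at -y in
  state B) whose merged landscape is exactly symmetric under swapping the
  basins; used for occupancy-symmetry checks.
* :func:`make_ideal_duplex` / :func:`make_bent_duplex_pair` — ideal B-form
  DNA pseudo-duplexes (C1' and P pseudo-atoms on exact helices) with the
  true axis, radius and inter-axis angle recorded as ground truth.

Beads are one-atom residues (name CA, residue GLY) so the all-atom code
path is exercised unchanged.  Coordinates are Angstrom, as at the file
interface.  All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .model_io import AtomRecord, MolecularModel, SelectionSpec

# CA-trace helix geometry: 100 deg twist, 2.3 A radius, 1.5 A rise gives the
# canonical ~3.8 A consecutive-bead distance.
_HELIX_TWIST = np.radians(100.0)
_HELIX_RADIUS = 2.3

# Temperature (reduced) at which the default two-state toy switches basins
# on the 10^5-step scale; chosen at design time, recorded in the docs.
TOY_SWITCHING_TEMPERATURE = 0.85
TOY_LOW_TEMPERATURE = 0.3


@dataclass
class ToySwitcherSpec:
    n_anchor_residues: int = 12
    n_switch_residues: int = 14
    bead_spacing: float = 3.8        # Angstrom
    pack_offset: float = 5.0         # Angstrom, switch-to-anchor distance (A)
    unpack_offset: float = 18.0      # Angstrom, hairpin displacement (B)
    seed: int = 0

    def __post_init__(self):
        if self.n_switch_residues < 8:
            raise ValueError("need >= 8 switch residues")


def _bead_model(chains_points: list[tuple[str, np.ndarray]],
                title: str, extra_bonds=()) -> MolecularModel:
    """One CA bead per residue, consecutive beads bonded within a chain."""
    records = []
    bonds = list(extra_bonds)
    serial = 1
    offset = 0
    for chain_id, pts in chains_points:
        for k, p in enumerate(np.asarray(pts, dtype=float)):
            records.append(AtomRecord(
                serial=serial, name="CA", element="C", residue_name="GLY",
                residue_number=k + 1, chain_id=chain_id, position=p,
                molecule_class="protein"))
            if k > 0:
                bonds.append((offset + k - 1, offset + k))
            serial += 1
        offset += len(pts)
    return MolecularModel.from_atoms(records, bonds=bonds, title=title)


def _chain_from_internal(n: int, spacing: float, theta: float,
                         phis: np.ndarray) -> np.ndarray:
    """Polyline from internal coordinates: constant bond length and bead
    angle, per-bead dihedrals ``phis`` (length n - 3).

    Both toy conformations are built this way with the SAME (spacing,
    theta), so their bond lengths and angles agree to machine precision and
    all conformational difference lives in dihedrals and contacts.
    """
    pts = np.zeros((n, 3))
    pts[1] = [spacing, 0.0, 0.0]
    pts[2] = pts[1] + spacing * np.array(
        [-np.cos(theta), np.sin(theta), 0.0])
    for k in range(3, n):
        a, b, c = pts[k - 3], pts[k - 2], pts[k - 1]
        phi = phis[k - 3]
        bc = c - b
        bc /= np.linalg.norm(bc)
        ab = b - a
        nrm = np.cross(ab, bc)
        nrm /= np.linalg.norm(nrm)
        m = np.cross(nrm, bc)
        # place d at bond length `spacing`, angle theta, dihedral phi
        d2 = np.array([
            -spacing * np.cos(theta),
            spacing * np.sin(theta) * np.cos(phi),
            spacing * np.sin(theta) * np.sin(phi),
        ])
        pts[k] = c + d2[0] * bc + d2[1] * m + d2[2] * nrm
    return pts


def _toy_theta(spacing: float) -> float:
    """Bead angle shared by every toy conformation (the CA-helix value)."""
    pts = _helix_points(3, spacing)
    v1 = pts[0] - pts[1]
    v2 = pts[2] - pts[1]
    return float(np.arccos(v1 @ v2 / (np.linalg.norm(v1)
                                      * np.linalg.norm(v2))))


def _helix_points(n: int, spacing: float, radius: float = _HELIX_RADIUS,
                  twist: float = _HELIX_TWIST) -> np.ndarray:
    """Helical polyline along +z with consecutive points exactly ``spacing``
    apart (rise solved from the chord condition)."""
    chord_xy = 2.0 * radius * np.sin(twist / 2.0)
    if chord_xy >= spacing:
        raise ValueError("helix radius too large for the bead spacing")
    rise = np.sqrt(spacing**2 - chord_xy**2)
    k = np.arange(n)
    return np.column_stack([
        radius * np.cos(k * twist),
        radius * np.sin(k * twist),
        k * rise,
    ])


def _check_equal_bonds(a: np.ndarray, b: np.ndarray, tol: float = 1e-6):
    da = np.linalg.norm(np.diff(a, axis=0), axis=1)
    db = np.linalg.norm(np.diff(b, axis=0), axis=1)
    if np.max(np.abs(da - db)) > tol:
        raise AssertionError("conformations have unequal bond lengths")


def _bead_angles(pts: np.ndarray) -> np.ndarray:
    v1 = pts[:-2] - pts[1:-1]
    v2 = pts[2:] - pts[1:-1]
    cos_t = np.einsum("ij,ij->i", v1, v2) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
    return np.arccos(np.clip(cos_t, -1, 1))


def _check_equal_angles(a: np.ndarray, b: np.ndarray, tol: float = 1e-6):
    if np.max(np.abs(_bead_angles(a) - _bead_angles(b))) > tol:
        raise AssertionError("conformations have unequal bead angles")


_HAIRPIN_CACHE: dict = {}


def _hairpin_score(n, spacing, theta, k_turn, turn, n_phi):
    phis = np.full(n_phi, np.pi)
    phis[k_turn:k_turn + 3] = turn
    pts = _chain_from_internal(n, spacing, theta, phis)
    d = np.linalg.norm(pts[None] - pts[:, None], axis=2)
    iu = np.triu_indices(n, k=2)
    if d[iu].min() < 3.6:  # clash
        return -1, phis
    sep = np.abs(np.arange(n)[None] - np.arange(n)[:, None])
    cross = (d < 6.0) & (sep >= 3)
    return int(np.triu(cross, k=1).sum()), phis


def _hairpin_phis(n: int, spacing: float, theta: float) -> np.ndarray:
    """Dihedral sequence for a hairpin: extended (phi = 180 deg) strands
    joined by a three-dihedral turn found by a deterministic grid search
    (coarse 30 deg pass, then 5 deg refinement) that maximises the number
    of clash-free cross-strand bead pairs within the contact cutoff."""
    key = (n, round(spacing, 6))
    if key in _HAIRPIN_CACHE:
        return _HAIRPIN_CACHE[key].copy()
    n_phi = n - 3
    mid = (n - 2) // 2
    best = (-2, None, None)
    coarse = np.radians(np.arange(-150.0, 181.0, 30.0))
    for k_turn in range(max(0, mid - 2), min(n_phi - 2, mid + 2)):
        for pa in coarse:
            for pb in coarse:
                for pc in coarse:
                    score, phis = _hairpin_score(
                        n, spacing, theta, k_turn, (pa, pb, pc), n_phi)
                    if score > best[0]:
                        best = (score, k_turn, (pa, pb, pc))
    if best[1] is None:
        raise ValueError("infeasible hairpin turn geometry")
    k_turn, centre = best[1], np.array(best[2])
    fine = np.radians(np.arange(-15.0, 15.1, 5.0))
    for da in fine:
        for db in fine:
            for dc in fine:
                turn = centre + np.array([da, db, dc])
                score, phis = _hairpin_score(
                    n, spacing, theta, k_turn, turn, n_phi)
                if score > best[0]:
                    best = (score, k_turn, tuple(turn))
    phis = np.full(n_phi, np.pi)
    phis[best[1]:best[1] + 3] = best[2]
    _HAIRPIN_CACHE[key] = phis.copy()
    return phis


def make_two_state_toy(spec: ToySwitcherSpec | None = None
                       ) -> tuple[MolecularModel, MolecularModel,
                                  SelectionSpec]:
    """Two conformations of the anchor/switch toy plus {NGN, KOW} groups.

    State A: the switch helix runs antiparallel alongside the anchor helix
    at ``pack_offset``, giving many interdomain contacts.  State B: the
    switch forms a hairpin displaced by ``unpack_offset`` from the anchor,
    giving none.  The anchor is identical in both states.
    """
    spec = spec or ToySwitcherSpec()
    s = spec.bead_spacing
    theta = _toy_theta(s)
    anchor = _helix_points(spec.n_anchor_residues, s)

    # state A: switch helix alongside the anchor (offset in +x).  Both the
    # helix and the hairpin share bond length and bead angle exactly; only
    # dihedrals (and hence contacts) distinguish the conformations.
    switch_a = _helix_points(spec.n_switch_residues, s)
    switch_a[:, 0] += 2.0 * _HELIX_RADIUS + spec.pack_offset - 2.0
    switch_a[:, 2] += 0.5 * s  # stagger against anchor beads

    # state B: hairpin, displaced sideways from the anchor
    phis = _hairpin_phis(spec.n_switch_residues, s, theta)
    switch_b = _chain_from_internal(spec.n_switch_residues, s, theta, phis)
    switch_b -= switch_b.mean(axis=0)
    switch_b[:, 0] += spec.unpack_offset
    switch_b[:, 1] += spec.unpack_offset

    _check_equal_bonds(switch_a, switch_b)
    _check_equal_angles(switch_a, switch_b)
    model_a = _bead_model([("A", anchor), ("B", switch_a)],
                          title="two_state_toy:A")
    model_b = _bead_model([("A", anchor), ("B", switch_b)],
                          title="two_state_toy:B")
    groups = SelectionSpec(groups={
        "NGN": [("A", 1, spec.n_anchor_residues)],
        "KOW": [("B", 1, spec.n_switch_residues)],
    })
    # self-clash check: no non-bonded pair closer than 2.5 A
    for m in (model_a, model_b):
        d = np.linalg.norm(
            m.coords[None, :, :] - m.coords[:, None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        bonded = {(i, j) for i, j in m.bonds} | {
            (j, i) for i, j in m.bonds}
        for i, j in zip(*np.where(d < 2.5)):
            if (int(i), int(j)) not in bonded:
                raise ValueError(
                    f"infeasible toy geometry: atoms {i},{j} clash "
                    f"({d[i, j]:.2f} A) in {m.title}")
    return model_a, model_b, groups


def make_symmetric_toy(n_base: int = 7, n_arm: int = 4,
                       spacing: float = 3.8, dock_distance: float = 5.0
                       ) -> tuple[MolecularModel, MolecularModel,
                                  SelectionSpec]:
    """Mirror-symmetric two-basin toy: an arm docks against the +y half
    (state A) or the -y half (state B) of a straight base rail.

    The base lies along y in the plane y-mirror maps onto itself (with bead
    order reversed); the arm is tethered to the base midpoint and state B is
    the exact mirror image of state A through the xz-plane.  Mirroring is an
    isometry, so bonds and angles agree exactly between the states; the two
    basins differ only in dihedrals and in which (disjoint) arm-base contact
    set is formed, making the merged dual-basin landscape exactly symmetric
    under exchanging the basins.
    """
    if n_base % 2 == 0:
        raise ValueError("base bead count must be odd (midpoint tether)")
    half = (n_base - 1) // 2
    base = np.zeros((n_base, 3))
    base[:, 0] = dock_distance
    base[:, 1] = spacing * (np.arange(n_base) - half)
    # z zigzag, palindromic so the mirror (order reversal) is exact
    amp = 0.5
    dz = amp * (-1.0) ** np.abs(np.arange(n_base) - half)
    base[:, 2] = dz - dz.mean()

    # arm: runs parallel to the base at x = 0, staggered by half a step,
    # with a small x/z zigzag to avoid collinear (degenerate) dihedrals
    arm = np.zeros((n_arm, 3))
    arm[0] = [0.0, 0.0, 0.0]
    for k in range(1, n_arm):
        d = np.array([0.35 * (-1.0) ** k, 1.0, 0.18 * (-1.0) ** k])
        d /= np.linalg.norm(d)
        arm[k] = arm[k - 1] + spacing * d
    arm_b = arm.copy()
    arm_b[:, 1] *= -1.0  # exact mirror image

    tether = [(half, n_base)]  # base midpoint to arm bead 0
    model_a = _bead_model([("A", base), ("B", arm)],
                          title="symmetric_toy:A", extra_bonds=tether)
    model_b = _bead_model([("A", base), ("B", arm_b)],
                          title="symmetric_toy:B", extra_bonds=tether)
    groups = SelectionSpec(groups={
        "NGN": [("A", 1, n_base)],
        "KOW": [("B", 1, n_arm)],
    })
    return model_a, model_b, groups


# ---------------------------------------------------------------------------
# ideal nucleic-acid duplexes


def make_ideal_duplex(
    n_bp: int,
    twist: float = 36.0,
    rise: float = 3.38,
    p_radius: float = 9.4,
    c1_radius: float = 5.9,
    axis: np.ndarray | None = None,
    origin: np.ndarray | None = None,
    chains: tuple[str, str] = ("U", "V"),
    residue_names: tuple[str, str] = ("DA", "DT"),
) -> tuple[MolecularModel, dict]:
    """Ideal B-form pseudo-duplex: C1' and P pseudo-atoms on exact helices.

    The two strands are antiparallel; paired C1' atoms are antipodal so the
    per-bp C1' midpoints lie exactly on the helix axis.  P atoms sit at
    ``p_radius``.  Returns the model and a ground-truth sidecar (true axis,
    origin, radius, pairing list).
    """
    if n_bp < 4:
        raise ValueError("need >= 4 base pairs")
    if axis is None:
        axis = np.array([0.0, 0.0, 1.0])
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    if origin is None:
        origin = np.zeros(3)
    origin = np.asarray(origin, dtype=float)

    rot = _rotation_from_z(axis)
    tw = np.radians(twist)
    records = []
    serial = 1
    pairing = []
    for strand in (0, 1):
        chain = chains[strand]
        res_name = residue_names[strand]
        for k in range(n_bp):
            # strand 2 numbered from its own 5' end (descending z)
            bp = k if strand == 0 else n_bp - 1 - k
            phase = bp * tw + strand * np.pi
            z = bp * rise
            c1 = np.array([c1_radius * np.cos(phase),
                           c1_radius * np.sin(phase), z])
            p = np.array([p_radius * np.cos(phase - np.radians(25.0)),
                          p_radius * np.sin(phase - np.radians(25.0)),
                          z - 1.0])
            res_id = k + 1
            for name, pos in (("P", p), ("C1'", c1)):
                records.append(AtomRecord(
                    serial=serial, name=name,
                    element="P" if name == "P" else "C",
                    residue_name=res_name, residue_number=res_id,
                    chain_id=chain, position=rot @ pos + origin,
                    molecule_class="dna"))
                serial += 1
    for k in range(n_bp):
        pairing.append(((chains[0], k + 1), (chains[1], n_bp - k)))
    model = MolecularModel.from_atoms(
        records, title=f"ideal_duplex:{n_bp}bp")
    truth = {
        "axis": axis.tolist(),
        "origin": origin.tolist(),
        "p_radius": p_radius,
        "rise": rise,
        "twist_deg": twist,
        "pairing": [[list(a), list(b)] for a, b in pairing],
    }
    return model, truth


def _rotation_from_z(axis: np.ndarray) -> np.ndarray:
    """Proper rotation taking +z onto ``axis``."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(np.dot(z, axis))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def make_bent_duplex_pair(angle: float, n_bp: int = 10,
                          separation: float = 40.0
                          ) -> tuple[MolecularModel, dict]:
    """Two ideal duplexes whose true axes meet at ``angle`` degrees."""
    if not 0.0 <= angle <= 180.0:
        raise ValueError("angle must be in [0, 180] degrees")
    a = np.radians(angle)
    axis1 = np.array([0.0, 0.0, 1.0])
    axis2 = np.array([np.sin(a), 0.0, np.cos(a)])
    m1, t1 = make_ideal_duplex(n_bp, axis=axis1, chains=("U", "V"))
    m2, t2 = make_ideal_duplex(n_bp, axis=axis2,
                               origin=np.array([separation, 0.0, 0.0]),
                               chains=("W", "X"))
    records = m1.atoms + m2.atoms
    for k, r in enumerate(records):
        r.serial = k + 1
    model = MolecularModel.from_atoms(
        records, title=f"bent_duplex_pair:{angle:.1f}deg")
    truth = {
        "angle_deg": angle,
        "duplex1": t1,
        "duplex2": t2,
    }
    return model, truth


def write_ground_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)
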