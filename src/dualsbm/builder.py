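"""Build single-basin structure-based topologies and merge them dual-basin.

A single-basin topology encodes one conformation as the global minimum:
bonds, angles and proper dihedrals are enumerated from covalent connectivity
with equilibrium values measured from the input coordinates, each native
contact gets an attractive Gaussian well at its measured distance, and all
other pairs are purely repulsive.

Two single-basin topologies built on the same covalent topology merge into a
dual-basin model: shared contacts whose native distances differ by more than
a relative threshold (default 10%) become two-well, dihedrals whose periodic
angular difference exceeds a fraction of a turn (default 20% = 72 degrees)
become two-well, and everything else keeps the state-B (active) parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_io import MolecularModel
from .shadow import ANGSTROM_PER_NM, ContactMap
from .topology import DualBasinTopology, wrap_angle


def _adjacency(model: MolecularModel) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {i: [] for i in range(len(model))}
    for i, j in model.bonds:
        adj[i].append(j)
        adj[j].append(i)
    return adj


def enumerate_bonded(model: MolecularModel):
    """Bonds, angles and proper dihedrals from covalent connectivity.

    Angles are all neighbour pairs around a central atom; proper dihedrals
    are all paths i-j-k-l around each central bond (3-rings skipped).
    Tuples are canonicalised so each term appears once.
    """
    adj = _adjacency(model)
    bonds = sorted({(min(i, j), max(i, j)) for i, j in model.bonds})
    angles = []
    for j, nbrs in adj.items():
        nbrs = sorted(nbrs)
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                angles.append((nbrs[a], j, nbrs[b]))
    dihedrals = set()
    for j, k in bonds:
        for i in adj[j]:
            if i == k:
                continue
            for l in adj[k]:
                if l == j or l == i:
                    continue
                t = (i, j, k, l)
                if t[::-1] < t:
                    t = t[::-1]
                dihedrals.add(t)
    return bonds, sorted(angles), sorted(dihedrals)


def _measure(coords_nm: np.ndarray, bonds, angles, dihedrals):
    bonds = np.array(bonds, dtype=np.int64).reshape(-1, 2)
    angles = np.array(angles, dtype=np.int64).reshape(-1, 3)
    dihedrals = np.array(dihedrals, dtype=np.int64).reshape(-1, 4)
    r0 = np.linalg.norm(coords_nm[bonds[:, 1]] - coords_nm[bonds[:, 0]],
                        axis=1) if len(bonds) else np.zeros(0)
    if len(angles):
        u = coords_nm[angles[:, 0]] - coords_nm[angles[:, 1]]
        v = coords_nm[angles[:, 2]] - coords_nm[angles[:, 1]]
        cos_t = np.einsum("ij,ij->i", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
        t0 = np.arccos(np.clip(cos_t, -1, 1))
    else:
        t0 = np.zeros(0)
    if len(dihedrals):
        b1 = coords_nm[dihedrals[:, 1]] - coords_nm[dihedrals[:, 0]]
        b2 = coords_nm[dihedrals[:, 2]] - coords_nm[dihedrals[:, 1]]
        b3 = coords_nm[dihedrals[:, 3]] - coords_nm[dihedrals[:, 2]]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        x = np.einsum("ij,ij->i", n1, n2)
        y = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / np.linalg.norm(
            b2, axis=1)
        p0 = np.arctan2(y, x)
    else:
        p0 = np.zeros(0)
    return bonds, r0, angles, t0, dihedrals, p0


def _graph_exclusions(model: MolecularModel, max_dist: int = 3) -> set:
    adj = _adjacency(model)
    excluded: set[tuple[int, int]] = set()
    for start in range(len(model)):
        frontier = {start}
        seen = {start}
        for _ in range(max_dist):
            nxt = set()
            for a in frontier:
                nxt |= set(adj[a])
            nxt -= seen
            for a in nxt:
                excluded.add((min(start, a), max(start, a)))
            seen |= nxt
            frontier = nxt
    return excluded


def build_single_basin(
    model: MolecularModel,
    cmap: ContactMap,
    params: dict | None = None,
) -> DualBasinTopology:
    """Single-basin all-atom SBM topology for one conformation.

    The model's coordinates (Angstrom) are converted to nm here, exactly
    once; every downstream quantity is in reduced units.
    """
    n = len(model)
    for c in cmap.contacts:
        if not (0 <= c.i < n and 0 <= c.j < n):
            raise ValueError(
                f"contact ({c.i},{c.j}) references atom absent from the "
                f"model ({n} atoms)")
    coords = model.coords / ANGSTROM_PER_NM
    bonds, angles, dihedrals = enumerate_bonded(model)
    b_idx, b_r0, a_idx, a_t0, d_idx, d_p0 = _measure(
        coords, bonds, angles, dihedrals)
    c_idx = np.array([[c.i, c.j] for c in cmap.contacts],
                     dtype=np.int64).reshape(-1, 2)
    c_r0 = np.array([c.r0 for c in cmap.contacts], dtype=float)
    exclusions = _graph_exclusions(model, max_dist=3)
    return DualBasinTopology(
        n_atoms=n,
        bond_idx=b_idx, bond_r0=b_r0,
        angle_idx=a_idx, angle_t0=a_t0,
        dihedral_idx=d_idx, dihedral_p0=d_p0,
        dihedral_p0_b=np.full(len(d_idx), np.nan),
        contact_idx=c_idx, contact_r0=c_r0,
        contact_r0_b=np.full(len(c_idx), np.nan),
        params=params,
        exclusions=exclusions,
        provenance={"source": model.title, "n_contacts": len(cmap)},
    )


@dataclass
class DivergenceReport:
    n_shared_contacts: int
    n_dual_contacts: int
    n_contacts_a_only: int
    n_contacts_b_only: int
    n_dihedrals: int
    n_dual_dihedrals: int
    dist_rel_thresh: float
    dihedral_thresh: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def merge_dual_basin(
    topo_a: DualBasinTopology,
    topo_b: DualBasinTopology,
    dist_rel_thresh: float = 0.10,
    dihedral_thresh: float = 0.20,
) -> tuple[DualBasinTopology, DivergenceReport]:
    """Merge two single-basin topologies into a dual-basin model.

    State B is the target (active) state: bonds, angles and all
    non-divergent terms keep state-B parameters.  The relative distance
    difference is |r0A - r0B| / mean(r0A, r0B); the dihedral criterion is a
    periodic angular difference above ``dihedral_thresh`` of a full turn.
    """
    if topo_a.n_atoms != topo_b.n_atoms:
        raise ValueError(
            f"atom count mismatch: {topo_a.n_atoms} vs {topo_b.n_atoms}")
    for name in ("bond_idx", "angle_idx", "dihedral_idx"):
        ia, ib = getattr(topo_a, name), getattr(topo_b, name)
        if ia.shape != ib.shape or not np.array_equal(ia, ib):
            k = 0
            if ia.shape == ib.shape:
                k = int(np.flatnonzero((ia != ib).any(axis=1))[0])
            raise ValueError(
                f"{name} mismatch between topologies (first differing term "
                f"index {k}); both models must share covalent topology and "
                f"atom ordering")

    # dihedrals: dual where the periodic difference exceeds the threshold
    dphi = np.abs(wrap_angle(topo_a.dihedral_p0 - topo_b.dihedral_p0))
    dual_dih = dphi > dihedral_thresh * 2.0 * np.pi
    p0 = topo_b.dihedral_p0.copy()
    p0_b = np.full(len(p0), np.nan)
    p0[dual_dih] = topo_a.dihedral_p0[dual_dih]
    p0_b[dual_dih] = topo_b.dihedral_p0[dual_dih]

    # contacts: match by atom pair
    pairs_a = {(int(i), int(j)): float(r)
               for (i, j), r in zip(topo_a.contact_idx, topo_a.contact_r0)}
    pairs_b = {(int(i), int(j)): float(r)
               for (i, j), r in zip(topo_b.contact_idx, topo_b.contact_r0)}
    shared = sorted(set(pairs_a) & set(pairs_b))
    a_only = sorted(set(pairs_a) - set(pairs_b))
    b_only = sorted(set(pairs_b) - set(pairs_a))
    c_idx, c_r0, c_r0b = [], [], []
    n_dual = 0
    for pair in shared:
        ra, rb = pairs_a[pair], pairs_b[pair]
        rel = abs(ra - rb) / ((ra + rb) / 2.0)
        c_idx.append(pair)
        if rel > dist_rel_thresh:
            c_r0.append(ra)
            c_r0b.append(rb)
            n_dual += 1
        else:
            c_r0.append(rb)  # state-B value
            c_r0b.append(np.nan)
    for pair in a_only:
        c_idx.append(pair)
        c_r0.append(pairs_a[pair])
        c_r0b.append(np.nan)
    for pair in b_only:
        c_idx.append(pair)
        c_r0.append(pairs_b[pair])
        c_r0b.append(np.nan)

    order = np.lexsort((np.array(c_idx)[:, 1], np.array(c_idx)[:, 0])) \
        if c_idx else np.zeros(0, dtype=int)
    c_idx = np.array(c_idx, dtype=np.int64).reshape(-1, 2)[order]
    c_r0 = np.array(c_r0, dtype=float)[order]
    c_r0b = np.array(c_r0b, dtype=float)[order]

    merged = DualBasinTopology(
        n_atoms=topo_b.n_atoms,
        bond_idx=topo_b.bond_idx, bond_r0=topo_b.bond_r0,
        angle_idx=topo_b.angle_idx, angle_t0=topo_b.angle_t0,
        dihedral_idx=topo_b.dihedral_idx, dihedral_p0=p0,
        dihedral_p0_b=p0_b,
        contact_idx=c_idx, contact_r0=c_r0, contact_r0_b=c_r0b,
        params=dict(topo_b.params),
        exclusions=topo_a.exclusions | topo_b.exclusions,
        provenance={
            "state_a": topo_a.provenance.get("source", ""),
            "state_b": topo_b.provenance.get("source", ""),
            "dist_rel_thresh": dist_rel_thresh,
            "dihedral_thresh": dihedral_thresh,
        },
    )
    report = DivergenceReport(
        n_shared_contacts=len(shared),
        n_dual_contacts=n_dual,
        n_contacts_a_only=len(a_only),
        n_contacts_b_only=len(b_only),
        n_dihedrals=len(p0),
        n_dual_dihedrals=int(dual_dih.sum()),
        dist_rel_thresh=dist_rel_thresh,
        dihedral_thresh=dihedral_thresh,
    )
    return merged, report


def potential_energy(topology: DualBasinTopology, coords: np.ndarray) -> dict:
    """Per-term-class energies plus total, reduced units."""
    return topology.energy(coords).as_dict()
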