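"""Rigid-body and helix geometry of elongation complexes.

Descriptors used to characterise paused elongation complexes:

* swivel angle — after superposing two complexes on a rigid core module, the
  axis-angle magnitude of the best-fit rotation mapping one swivel module
  onto the other;
* duplex helix axis — total-least-squares principal direction of per-base-
  pair reference points (C1' midpoints), with the P-atom radius about it;
* inter-duplex angle — angle between two fitted axes translated to a common
  origin;
* hybrid diameter — twice the mean P radius of the RNA:DNA hybrid about its
  fitted axis.

All coordinates here are Angstrom (file-interface convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_io import MolecularModel, SelectionSpec, select


@dataclass
class RigidTransform:
    rotation: np.ndarray      # 3x3 proper orthonormal
    translation: np.ndarray   # Angstrom
    rmsd: float               # Angstrom

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class SwivelResult:
    angle: float              # degrees, [0, 180]
    axis: np.ndarray          # unit vector
    core_rmsd: float          # Angstrom
    swivel_rmsd: float        # Angstrom


@dataclass
class HelixFit:
    origin: np.ndarray        # Angstrom, centroid of bp reference points
    axis: np.ndarray          # unit vector, oriented 5'->3' of first strand
    radius: float             # Angstrom, mean P distance from axis
    n_bp: int


def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares proper rotation R and translation t with
    ``mobile @ R.T + t ~ reference``; reflections are rejected.

    Returns (R, t, rmsd).  Raises on fewer than 3 effectively non-collinear
    points (the rotation would be underdetermined).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.shape[0] < 3:
        raise ValueError("need >= 3 matched points of equal shape")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # collinearity: a single significant direction leaves rotation free
    scale = np.linalg.norm(P0) * np.linalg.norm(Q0) + 1e-300
    if S[1] / scale < 1e-12:
        raise ValueError("selection is collinear; rotation underdetermined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return R, t, rmsd


def rotation_angle_axis(R: np.ndarray) -> tuple[float, np.ndarray]:
    """Axis-angle decomposition of a proper rotation; angle in degrees."""
    cos_a = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cos_a)))
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    n = np.linalg.norm(w)
    if n < 1e-12:
        # angle ~ 0 or ~ 180; axis from eigenvector of R with eigenvalue 1
        vals, vecs = np.linalg.eig(R)
        k = int(np.argmin(np.abs(vals - 1.0)))
        axis = np.real(vecs[:, k])
        axis /= np.linalg.norm(axis)
    else:
        axis = w / n
    return angle, axis


def _matched_coords(mobile: MolecularModel, reference: MolecularModel,
                    spec: SelectionSpec, group: str):
    """1:1 atom matching by (chain, resnum, inscode, atom name) within the
    selection of both models."""
    sub_m = select(mobile, spec, group)
    sub_r = select(reference, spec, group)
    keys_m = {sub_m.atom_key(i): i for i in range(len(sub_m))}
    keys_r = {sub_r.atom_key(i): i for i in range(len(sub_r))}
    common = [k for k in keys_m if k in keys_r]
    missing = [k for k in keys_m if k not in keys_r]
    missing += [k for k in keys_r if k not in keys_m]
    if not common:
        raise ValueError(f"no matched atoms in selection {group!r}")
    if missing:
        import logging

        logging.getLogger(__name__).info(
            "%d unmatched atoms in selection %r (first 5: %s)",
            len(missing), group, missing[:5])
    idx_m = [keys_m[k] for k in common]
    idx_r = [keys_r[k] for k in common]
    return sub_m.coords[idx_m], sub_r.coords[idx_r]


def superpose(mobile: MolecularModel, reference: MolecularModel,
              spec: SelectionSpec, group: str) -> RigidTransform:
    """Best-fit proper rigid transform of ``mobile`` onto ``reference``
    over the named selection (atoms matched 1:1 by identity)."""
    P, Q = _matched_coords(mobile, reference, spec, group)
    R, t, rmsd = kabsch(P, Q)
    return RigidTransform(rotation=R, translation=t, rmsd=rmsd)


def swivel_angle(model_a: MolecularModel, model_b: MolecularModel,
                 spec: SelectionSpec, core_group: str = "core",
                 swivel_group: str = "swivel") -> SwivelResult:
    """Rotation of the swivel module of B relative to A after core alignment.

    Two-stage: superpose B onto A over the core module, then the axis-angle
    magnitude of the best-fit rotation mapping A's swivel-module atoms onto
    the core-aligned B's.  Symmetric in its arguments to numerical precision.
    """
    core = superpose(model_b, model_a, spec, core_group)
    P, Q = _matched_coords(model_a, model_b, spec, swivel_group)
    Q_aligned = core.apply(Q)
    R, _, sw_rmsd = kabsch(P, Q_aligned)
    angle, axis = rotation_angle_axis(R)
    return SwivelResult(angle=angle, axis=axis, core_rmsd=core.rmsd,
                        swivel_rmsd=sw_rmsd)


def _pair_atoms(duplex: MolecularModel, pairing, atom_name: str):
    """Coordinates of ``atom_name`` for each (chain, resid) in pairing terms."""
    index = {}
    for i in range(len(duplex)):
        index[(str(duplex.chain_id[i]), int(duplex.residue_number[i]),
               str(duplex.name[i]))] = i
    out = []
    for chain, resid in pairing:
        key = (str(chain), int(resid), atom_name)
        if key not in index:
            raise ValueError(
                f"missing {atom_name} atom for residue {chain}/{resid}")
        out.append(duplex.coords[index[key]])
    return np.array(out)


def fit_helix_axis(duplex: MolecularModel, pairing) -> HelixFit:
    """Fit the helix axis of a duplex from base-pair C1' midpoints.

    ``pairing`` is a list of ((chain1, resid1), (chain2, resid2)) base pairs
    ordered 5'->3' along the first strand.  The axis is the total-least-
    squares principal direction of the midpoints, oriented 5'->3' of the
    first strand; the radius is the mean distance of backbone P atoms from
    the axis (5'-terminal residues lacking P are ignored).
    """
    pairing = list(pairing)
    if len(pairing) < 4:
        raise ValueError("need >= 4 base pairs to fit a helix axis")
    c1_1 = _pair_atoms(duplex, [p[0] for p in pairing], "C1'")
    c1_2 = _pair_atoms(duplex, [p[1] for p in pairing], "C1'")
    ref = 0.5 * (c1_1 + c1_2)
    origin = ref.mean(axis=0)
    centered = ref - origin
    _, _, Vt = np.linalg.svd(centered)
    axis = Vt[0]
    # orient 5'->3' of the first strand
    if np.dot(ref[-1] - ref[0], axis) < 0:
        axis = -axis
    axis = axis / np.linalg.norm(axis)

    p_coords = []
    for strand in (0, 1):
        for chain, resid in (p[strand] for p in pairing):
            try:
                p_coords.append(
                    _pair_atoms(duplex, [(chain, resid)], "P")[0])
            except ValueError:
                continue  # 5'-terminal residue without phosphate
    if not p_coords:
        raise ValueError("no P atoms found on paired residues")
    p_coords = np.array(p_coords)
    rel = p_coords - origin
    perp = rel - np.outer(rel @ axis, axis)
    radius = float(np.linalg.norm(perp, axis=1).mean())
    return HelixFit(origin=origin, axis=axis, radius=radius,
                    n_bp=len(pairing))


def interaxial_angle(a: HelixFit, b: HelixFit) -> float:
    """Angle between two fitted helix axes, degrees in [0, 180]."""
    cos_a = np.clip(float(np.dot(a.axis, b.axis)), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos_a)))


def hybrid_diameter(hybrid: MolecularModel, pairing) -> tuple[float, HelixFit]:
    """Diameter of an RNA:DNA hybrid: 2 x mean P radius about its axis."""
    fit = fit_helix_axis(hybrid, pairing)
    return 2.0 * fit.radius, fit
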