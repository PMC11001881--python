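"""Dual-basin structure-based topology: term storage, energies and forces.

All quantities are in reduced units: length nm, mass 1 per atom, energy in
units of the per-contact well depth epsilon, time tau.  Functional forms:

* bond      V = 1/2 k_b (r - r0)^2                         (k_b = 2e4 / nm^2)
* angle     V = 1/2 k_th (theta - theta0)^2                (k_th = 40 / rad^2)
* dihedral  V = K_d [(1 - cos D) + 1/2 (1 - cos 3D)], D = phi - phi0;
            dual-basin dihedrals average the two single-basin forms.
* contact   V = eps [ (1 + (r_ex/r)^12) PROD_b (1 - G_b(r)) - 1 ],
            G_b(r) = exp(-(r - r0_b)^2 / (2 sigma^2)); one Gaussian factor
            for single-basin contacts, two for dual-basin.  The well bottom
            is exactly -eps at r = r0 of either basin (up to the small
            excluded-volume tail).
* non-native pairs  V = eps_nn (r_nn/r)^12, truncated and shifted at r_cut.

Terms are stored as flat numpy arrays; dual-basin terms carry a second
equilibrium value (NaN when single-basin).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

DEFAULTS = {
    "k_bond": 2.0e4,      # eps / nm^2
    "k_angle": 40.0,      # eps / rad^2
    "k_dihedral": 1.0,    # eps
    "epsilon": 1.0,       # contact well depth
    "sigma": 0.05,        # nm, Gaussian well width
    "r_ex": 0.04,         # nm, native-pair excluded volume
    "eps_nn": 1.0,        # eps, non-native repulsion strength
    "r_nn": 0.25,         # nm, non-native excluded-volume radius
    "nn_cutoff": 0.625,   # nm, 2.5 * r_nn truncation (shifted)
}


@dataclass
class BondedTerm:
    """Single bonded term view (bond/angle/dihedral)."""

    kind: str
    atoms: tuple[int, ...]
    equilibrium: tuple[float, ...]  # one value, or two for dual-basin
    force_constant: float


@dataclass
class ContactTerm:
    i: int
    j: int
    basins: tuple[float, ...]  # one or two native distances, nm
    sigma: float
    r_ex: float
    epsilon: float

    @property
    def dual(self) -> bool:
        return len(self.basins) == 2


def wrap_angle(x):
    """Wrap angle(s) into (-pi, pi]."""
    out = np.mod(np.asarray(x, dtype=float) + np.pi, 2 * np.pi) - np.pi
    out = np.where(out == -np.pi, np.pi, out)
    return out if out.ndim else float(out)


@dataclass
class EnergyBreakdown:
    bond: float
    angle: float
    dihedral: float
    contact: float
    excluded_volume: float

    @property
    def total(self) -> float:
        return (self.bond + self.angle + self.dihedral + self.contact
                + self.excluded_volume)

    def as_dict(self) -> dict:
        return {
            "bond": self.bond,
            "angle": self.angle,
            "dihedral": self.dihedral,
            "contact": self.contact,
            "excluded_volume": self.excluded_volume,
            "total": self.total,
        }


class DualBasinTopology:
    """Arrays-of-terms force field with optional dual-basin contacts/dihedrals.

    ``*_b`` companion arrays hold the second basin (NaN = single basin).
    """

    def __init__(
        self,
        n_atoms: int,
        bond_idx: np.ndarray, bond_r0: np.ndarray,
        angle_idx: np.ndarray, angle_t0: np.ndarray,
        dihedral_idx: np.ndarray, dihedral_p0: np.ndarray,
        dihedral_p0_b: np.ndarray,
        contact_idx: np.ndarray, contact_r0: np.ndarray,
        contact_r0_b: np.ndarray,
        params: dict | None = None,
        exclusions: set[tuple[int, int]] | None = None,
        provenance: dict | None = None,
    ):
        self.n_atoms = int(n_atoms)
        self.masses = np.ones(n_atoms)
        self.params = dict(DEFAULTS)
        if params:
            self.params.update(params)
        self.bond_idx = np.asarray(bond_idx, dtype=np.int64).reshape(-1, 2)
        self.bond_r0 = np.asarray(bond_r0, dtype=float)
        self.angle_idx = np.asarray(angle_idx, dtype=np.int64).reshape(-1, 3)
        self.angle_t0 = np.asarray(angle_t0, dtype=float)
        self.dihedral_idx = np.asarray(dihedral_idx, np.int64).reshape(-1, 4)
        self.dihedral_p0 = np.asarray(dihedral_p0, dtype=float)
        self.dihedral_p0_b = np.asarray(dihedral_p0_b, dtype=float)
        self.contact_idx = np.asarray(contact_idx, np.int64).reshape(-1, 2)
        self.contact_r0 = np.asarray(contact_r0, dtype=float)
        self.contact_r0_b = np.asarray(contact_r0_b, dtype=float)
        self.exclusions = set(exclusions) if exclusions else set()
        self.provenance = provenance or {}
        self._nonnative_pairs: np.ndarray | None = None
        self._check()

    # -- construction helpers -------------------------------------------------

    def _check(self) -> None:
        for idx in (self.bond_idx, self.angle_idx, self.dihedral_idx,
                    self.contact_idx):
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_atoms):
                raise ValueError("term atom index out of range")
        if np.any(self.contact_r0 <= 0):
            raise ValueError("non-positive native contact distance")

    @property
    def n_dual_contacts(self) -> int:
        return int(np.isfinite(self.contact_r0_b).sum())

    @property
    def n_dual_dihedrals(self) -> int:
        return int(np.isfinite(self.dihedral_p0_b).sum())

    def bonded_terms(self) -> list[BondedTerm]:
        terms = [
            BondedTerm("bond", tuple(a), (float(r),), self.params["k_bond"])
            for a, r in zip(self.bond_idx, self.bond_r0)
        ]
        terms += [
            BondedTerm("angle", tuple(a), (float(t),), self.params["k_angle"])
            for a, t in zip(self.angle_idx, self.angle_t0)
        ]
        for a, p, pb in zip(self.dihedral_idx, self.dihedral_p0,
                            self.dihedral_p0_b):
            eq = (float(p),) if np.isnan(pb) else (float(p), float(pb))
            terms.append(BondedTerm("dihedral", tuple(a), eq,
                                    self.params["k_dihedral"]))
        return terms

    def contact_terms(self) -> list[ContactTerm]:
        out = []
        for (i, j), r, rb in zip(self.contact_idx, self.contact_r0,
                                 self.contact_r0_b):
            basins = (float(r),) if np.isnan(rb) else (float(r), float(rb))
            out.append(ContactTerm(int(i), int(j), basins,
                                   self.params["sigma"], self.params["r_ex"],
                                   self.params["epsilon"]))
        return out

    def nonnative_pairs(self) -> np.ndarray:
        """Static list of all non-excluded, non-native pairs (i < j).

        Cached; used for systems small enough for all-pairs evaluation.
        """
        if self._nonnative_pairs is None:
            skip = set(self.exclusions)
            skip |= {(int(i), int(j)) for i, j in self.contact_idx}
            n = self.n_atoms
            ii, jj = np.triu_indices(n, k=1)
            keep = np.array(
                [(int(a), int(b)) not in skip for a, b in zip(ii, jj)],
                dtype=bool,
            )
            self._nonnative_pairs = np.column_stack([ii[keep], jj[keep]])
        return self._nonnative_pairs

    def kernel_args(self) -> tuple:
        """Flat argument tuple for the compiled force kernel (same potential
        as the vectorised path; cross-checked in tests)."""
        p = self.params
        return (
            self.bond_idx, self.bond_r0, float(p["k_bond"]),
            self.angle_idx, self.angle_t0, float(p["k_angle"]),
            self.dihedral_idx, self.dihedral_p0, self.dihedral_p0_b,
            float(p["k_dihedral"]),
            self.contact_idx, self.contact_r0, self.contact_r0_b,
            float(p["epsilon"]), float(p["sigma"]), float(p["r_ex"]),
            self.nonnative_pairs(), float(p["eps_nn"]), float(p["r_nn"]),
            float(p["nn_cutoff"]),
        )

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for arr in (self.bond_idx, self.bond_r0, self.angle_idx,
                    self.angle_t0, self.dihedral_idx, self.dihedral_p0,
                    self.dihedral_p0_b, self.contact_idx, self.contact_r0,
                    self.contact_r0_b):
            h.update(np.ascontiguousarray(arr).tobytes())
        h.update(json.dumps(self.params, sort_keys=True).encode())
        return h.hexdigest()[:16]

    # -- energy and forces ----------------------------------------------------

    def energy(self, coords: np.ndarray) -> EnergyBreakdown:
        e, _ = self._energy_forces(coords, want_forces=False)
        return e

    def forces(self, coords: np.ndarray) -> np.ndarray:
        _, f = self._energy_forces(coords, want_forces=True)
        return f

    def energy_forces(self, coords: np.ndarray):
        return self._energy_forces(coords, want_forces=True)

    def _energy_forces(self, coords: np.ndarray, want_forces: bool = True):
        coords = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        f = np.zeros_like(coords) if want_forces else None
        e_bond = self._eval_bonds(coords, f)
        e_angle = self._eval_angles(coords, f)
        e_dih = self._eval_dihedrals(coords, f)
        e_con = self._eval_contacts(coords, f)
        e_ev = self._eval_nonnative(coords, f)
        return EnergyBreakdown(e_bond, e_angle, e_dih, e_con, e_ev), f

    def _eval_bonds(self, coords, f):
        if len(self.bond_idx) == 0:
            return 0.0
        i, j = self.bond_idx[:, 0], self.bond_idx[:, 1]
        d = coords[j] - coords[i]
        r = np.linalg.norm(d, axis=1)
        dr = r - self.bond_r0
        k = self.params["k_bond"]
        if f is not None:
            # dV/dr = k dr; force on j = -dV/dr * d/r
            fij = (-k * dr / r)[:, None] * d
            np.add.at(f, j, fij)
            np.add.at(f, i, -fij)
        return float(0.5 * k * np.sum(dr**2))

    def _eval_angles(self, coords, f):
        if len(self.angle_idx) == 0:
            return 0.0
        ia, ja, ka = (self.angle_idx[:, 0], self.angle_idx[:, 1],
                      self.angle_idx[:, 2])
        u = coords[ia] - coords[ja]
        v = coords[ka] - coords[ja]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cos_t = np.einsum("ij,ij->i", u, v) / (nu * nv)
        cos_t = np.clip(cos_t, -1.0, 1.0)
        theta = np.arccos(cos_t)
        dt = theta - self.angle_t0
        k = self.params["k_angle"]
        if f is not None:
            sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 1e-12))
            uh = u / nu[:, None]
            vh = v / nv[:, None]
            # d theta / d r_i and d theta / d r_k
            dthet_i = (cos_t[:, None] * uh - vh) / (nu * sin_t)[:, None]
            dthet_k = (cos_t[:, None] * vh - uh) / (nv * sin_t)[:, None]
            g = (k * dt)[:, None]
            fi = -g * dthet_i
            fk = -g * dthet_k
            np.add.at(f, ia, fi)
            np.add.at(f, ka, fk)
            np.add.at(f, ja, -(fi + fk))
        return float(0.5 * k * np.sum(dt**2))

    def _dihedral_angles(self, coords):
        idx = self.dihedral_idx
        b1 = coords[idx[:, 1]] - coords[idx[:, 0]]
        b2 = coords[idx[:, 2]] - coords[idx[:, 1]]
        b3 = coords[idx[:, 3]] - coords[idx[:, 2]]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        x = np.einsum("ij,ij->i", n1, n2)
        y = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / nb2
        return np.arctan2(y, x), b1, b2, b3, n1, n2, nb2

    @staticmethod
    def _dihedral_v_dv(delta, k):
        """Cosine dihedral potential and derivative wrt the angle offset."""
        v = k * ((1.0 - np.cos(delta)) + 0.5 * (1.0 - np.cos(3.0 * delta)))
        dv = k * (np.sin(delta) + 1.5 * np.sin(3.0 * delta))
        return v, dv

    def _eval_dihedrals(self, coords, f):
        if len(self.dihedral_idx) == 0:
            return 0.0
        phi, b1, b2, b3, n1, n2, nb2 = self._dihedral_angles(coords)
        k = self.params["k_dihedral"]
        dual = np.isfinite(self.dihedral_p0_b)
        d_a = wrap_angle(phi - self.dihedral_p0)
        v_a, dv_a = self._dihedral_v_dv(d_a, k)
        v = v_a.copy()
        dv = dv_a.copy()
        if dual.any():
            d_b = wrap_angle(phi[dual] - self.dihedral_p0_b[dual])
            v_b, dv_b = self._dihedral_v_dv(d_b, k)
            v[dual] = 0.5 * (v_a[dual] + v_b)
            dv[dual] = 0.5 * (dv_a[dual] + dv_b)
        if f is not None:
            idx = self.dihedral_idx
            n1sq = np.einsum("ij,ij->i", n1, n1)
            n2sq = np.einsum("ij,ij->i", n2, n2)
            # standard dihedral force decomposition
            fi = (dv * nb2 / n1sq)[:, None] * n1
            fl = (-dv * nb2 / n2sq)[:, None] * n2
            s = (np.einsum("ij,ij->i", b1, b2) / nb2**2)[:, None]
            t = (np.einsum("ij,ij->i", b3, b2) / nb2**2)[:, None]
            fj = (-1.0 - s) * fi + t * fl
            fk = s * fi - (1.0 + t) * fl
            np.add.at(f, idx[:, 0], fi)
            np.add.at(f, idx[:, 1], fj)
            np.add.at(f, idx[:, 2], fk)
            np.add.at(f, idx[:, 3], fl)
        return float(np.sum(v))

    def _contact_v_dv(self, r):
        """Gaussian contact energy and dV/dr, handling dual basins."""
        p = self.params
        eps, sig, rex = p["epsilon"], p["sigma"], p["r_ex"]
        ex = (rex / r) ** 12
        dex = -12.0 * ex / r
        g_a = np.exp(-((r - self.contact_r0) ** 2) / (2 * sig**2))
        dg_a = g_a * (-(r - self.contact_r0) / sig**2)
        prod = 1.0 - g_a
        dprod = -dg_a
        dual = np.isfinite(self.contact_r0_b)
        if dual.any():
            rb = self.contact_r0_b[dual]
            g_b = np.exp(-((r[dual] - rb) ** 2) / (2 * sig**2))
            dg_b = g_b * (-(r[dual] - rb) / sig**2)
            p1 = 1.0 - g_a[dual]
            p2 = 1.0 - g_b
            prod[dual] = p1 * p2
            dprod[dual] = -dg_a[dual] * p2 + p1 * (-dg_b)
        v = eps * ((1.0 + ex) * prod - 1.0)
        dv = eps * (dex * prod + (1.0 + ex) * dprod)
        return v, dv

    def _eval_contacts(self, coords, f):
        if len(self.contact_idx) == 0:
            return 0.0
        i, j = self.contact_idx[:, 0], self.contact_idx[:, 1]
        d = coords[j] - coords[i]
        r = np.linalg.norm(d, axis=1)
        v, dv = self._contact_v_dv(r)
        if f is not None:
            fij = (-dv / r)[:, None] * d
            np.add.at(f, j, fij)
            np.add.at(f, i, -fij)
        return float(np.sum(v))

    def _eval_nonnative(self, coords, f):
        p = self.params
        rc = p["nn_cutoff"]
        if self.n_atoms > 2000:
            from scipy.spatial import cKDTree

            tree = cKDTree(coords)
            pairs = tree.query_pairs(rc, output_type="ndarray")
            if pairs.size == 0:
                return 0.0
            skip = self.exclusions | {
                (int(a), int(b)) for a, b in self.contact_idx
            }
            keep = np.array(
                [(min(a, b), max(a, b)) not in skip for a, b in pairs],
                dtype=bool,
            )
            pairs = pairs[keep]
        else:
            pairs = self.nonnative_pairs()
        if len(pairs) == 0:
            return 0.0
        i, j = pairs[:, 0], pairs[:, 1]
        d = coords[j] - coords[i]
        r2 = np.einsum("ij,ij->i", d, d)
        within = r2 < rc * rc
        if not within.any():
            return 0.0
        i, j, d = i[within], j[within], d[within]
        r = np.sqrt(r2[within])
        eps_nn, rnn = p["eps_nn"], p["r_nn"]
        vshift = eps_nn * (rnn / rc) ** 12
        vr = eps_nn * (rnn / r) ** 12
        if f is not None:
            dv = -12.0 * vr / r
            fij = (-dv / r)[:, None] * d
            np.add.at(f, j, fij)
            np.add.at(f, i, -fij)
        return float(np.sum(vr - vshift))

    # -- serialization --------------------------------------------------------

    def to_text(self) -> str:
        """Documented sectioned text format (atoms/bonds/angles/dihedrals/
        contacts/exclusions); round-trips with :meth:`from_text`."""
        lines = ["# dualsbm topology", f"[ params ]"]
        lines.append(json.dumps(self.params, sort_keys=True))
        lines.append("[ atoms ]")
        lines.append(f"{self.n_atoms}")
        lines.append("[ bonds ]  ; i j r0_nm")
        for (i, j), r in zip(self.bond_idx, self.bond_r0):
            lines.append(f"{i} {j} {r:.9f}")
        lines.append("[ angles ]  ; i j k theta0_rad")
        for (i, j, k), t in zip(self.angle_idx, self.angle_t0):
            lines.append(f"{i} {j} {k} {t:.9f}")
        lines.append("[ dihedrals ]  ; i j k l phi0A_rad phi0B_rad|nan")
        for (i, j, k, l), a, b in zip(self.dihedral_idx, self.dihedral_p0,
                                      self.dihedral_p0_b):
            lines.append(f"{i} {j} {k} {l} {a:.9f} {b:.9f}")
        lines.append("[ contacts ]  ; i j r0A_nm r0B_nm|nan")
        for (i, j), a, b in zip(self.contact_idx, self.contact_r0,
                                self.contact_r0_b):
            lines.append(f"{i} {j} {a:.9f} {b:.9f}")
        lines.append("[ exclusions ]  ; i j")
        for i, j in sorted(self.exclusions):
            lines.append(f"{i} {j}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "DualBasinTopology":
        section = None
        params: dict = {}
        n_atoms = 0
        rows: dict[str, list] = {k: [] for k in
                                 ("bonds", "angles", "dihedrals", "contacts",
                                  "exclusions")}
        for raw in text.splitlines():
            line = raw.split(";")[0].strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("["):
                section = line.strip("[] ").split()[0]
                continue
            if section == "params":
                params = json.loads(line)
            elif section == "atoms":
                n_atoms = int(line)
            elif section in rows:
                rows[section].append([float(x) for x in line.split()])

        def arr(name, ncol):
            data = rows[name]
            if not data:
                return np.zeros((0, ncol))
            return np.array(data)

        b = arr("bonds", 3)
        a = arr("angles", 4)
        d = arr("dihedrals", 6)
        c = arr("contacts", 4)
        excl = {(int(i), int(j)) for i, j in rows["exclusions"]}
        return cls(
            n_atoms,
            b[:, :2], b[:, 2] if len(b) else np.zeros(0),
            a[:, :3], a[:, 3] if len(a) else np.zeros(0),
            d[:, :4],
            d[:, 4] if len(d) else np.zeros(0),
            d[:, 5] if len(d) else np.zeros(0),
            c[:, :2],
            c[:, 2] if len(c) else np.zeros(0),
            c[:, 3] if len(c) else np.zeros(0),
            params=params,
            exclusions=excl,
        )
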