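"""Native contact maps with the shadow occlusion criterion.

A pair of heavy atoms is a native contact when it is within the cutoff
(default 6 A = 0.6 nm), satisfies the per-category sequence-separation rule
(>= 3 residues for protein-protein, none for pairs involving nucleic acids)
and its straight line of sight is not occluded by a third atom.  Occlusion
follows the shadow-map concept: a third atom k, modelled as an opaque sphere
of the screening radius (default 1 A), blocks the pair (i, j) when the
distance from k's centre to the segment i-j is below screening radius plus
light radius (equal by default) and k's projection falls strictly between
the endpoints.  Endpoints never occlude their own pair.

Distances in this module are nm (coordinates are converted from the
Angstrom file interface exactly once, on entry).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .model_io import MolecularModel, SelectionSpec

ANGSTROM_PER_NM = 10.0


@dataclass(frozen=True)
class Contact:
    """Native atom pair: indices (i < j), native distance r0 in nm."""

    i: int
    j: int
    r0: float
    category: str  # protein-protein | protein-nucleic | nucleic-nucleic
    groups: tuple[str, str] = ("", "")


@dataclass
class ContactMap:
    contacts: list[Contact]
    cutoff: float = 0.6
    shadow_radius: float = 0.1
    min_seq_sep_protein: int = 3
    min_seq_sep_nucleic: int = 0
    parameters: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.contacts)

    def pairs(self) -> set[tuple[int, int]]:
        return {(c.i, c.j) for c in self.contacts}

    def by_pair(self) -> dict[tuple[int, int], Contact]:
        return {(c.i, c.j): c for c in self.contacts}

    def subset(self, predicate) -> "ContactMap":
        out = ContactMap(
            [c for c in self.contacts if predicate(c)],
            cutoff=self.cutoff,
            shadow_radius=self.shadow_radius,
            min_seq_sep_protein=self.min_seq_sep_protein,
            min_seq_sep_nucleic=self.min_seq_sep_nucleic,
            parameters=dict(self.parameters),
        )
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "parameters": {
                    "cutoff_nm": self.cutoff,
                    "shadow_radius_nm": self.shadow_radius,
                    "min_seq_sep_protein": self.min_seq_sep_protein,
                    "min_seq_sep_nucleic": self.min_seq_sep_nucleic,
                    **self.parameters,
                },
                "contacts": [
                    {
                        "i": c.i,
                        "j": c.j,
                        "r0_nm": c.r0,
                        "category": c.category,
                        "groups": list(c.groups),
                    }
                    for c in self.contacts
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ContactMap":
        d = json.loads(text)
        p = d["parameters"]
        contacts = [
            Contact(c["i"], c["j"], c["r0_nm"], c["category"],
                    tuple(c.get("groups", ("", ""))))
            for c in d["contacts"]
        ]
        return cls(
            contacts,
            cutoff=p["cutoff_nm"],
            shadow_radius=p["shadow_radius_nm"],
            min_seq_sep_protein=p["min_seq_sep_protein"],
            min_seq_sep_nucleic=p["min_seq_sep_nucleic"],
        )

    def to_tsv(self, model: MolecularModel) -> str:
        lines = ["i\tj\tchain_i\tresid_i\tatom_i\tchain_j\tresid_j\tatom_j"
                 "\tr0_nm\tcategory\tgroupA\tgroupB"]
        for c in self.contacts:
            lines.append(
                f"{c.i}\t{c.j}\t{model.chain_id[c.i]}\t"
                f"{model.residue_number[c.i]}\t{model.name[c.i]}\t"
                f"{model.chain_id[c.j]}\t{model.residue_number[c.j]}\t"
                f"{model.name[c.j]}\t{c.r0:.6f}\t{c.category}\t"
                f"{c.groups[0]}\t{c.groups[1]}"
            )
        return "\n".join(lines) + "\n"


def _bond_graph_exclusions(model: MolecularModel, max_dist: int = 2) -> set:
    """Pairs within graph distance <= max_dist in the covalent bond graph
    (bonded pairs and pairs sharing an angle term)."""
    adj: dict[int, set[int]] = {}
    for i, j in model.bonds:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    excluded: set[tuple[int, int]] = set()
    for start, nbrs in adj.items():
        frontier = set(nbrs)
        seen = {start} | frontier
        for a in frontier:
            excluded.add((min(start, a), max(start, a)))
        for _ in range(max_dist - 1):
            nxt = set()
            for a in frontier:
                nxt |= adj.get(a, set())
            nxt -= seen
            for a in nxt:
                excluded.add((min(start, a), max(start, a)))
            seen |= nxt
            frontier = nxt
    return excluded


def _pair_category(class_i: str, class_j: str) -> str:
    nuc = {"dna", "rna"}
    i_nuc, j_nuc = class_i in nuc, class_j in nuc
    if i_nuc and j_nuc:
        return "nucleic-nucleic"
    if i_nuc or j_nuc:
        return "protein-nucleic"
    return "protein-protein"


def _occluded(
    coords: np.ndarray,
    i: int,
    j: int,
    candidates: np.ndarray,
    occlusion_radius: float,
) -> bool:
    """True if any candidate atom's sphere blocks the open segment i-j."""
    a = coords[i]
    d = coords[j] - a
    seg_len2 = float(d @ d)
    if seg_len2 == 0.0:
        raise ValueError(f"atoms {i} and {j} have identical coordinates")
    rel = coords[candidates] - a
    t = rel @ d / seg_len2
    between = (t > 0.0) & (t < 1.0)
    if not between.any():
        return False
    rel = rel[between]
    t = t[between]
    perp = rel - t[:, None] * d
    dist2 = np.einsum("ij,ij->i", perp, perp)
    return bool((dist2 < occlusion_radius**2).any())


def shadow_contact_map(
    model: MolecularModel,
    cutoff: float = 0.6,
    shadow_radius: float = 0.1,
    min_seq_sep_protein: int = 3,
    min_seq_sep_nucleic: int = 0,
    light_radius: float | None = None,
    use_shadow: bool = True,
) -> ContactMap:
    """Compute the shadow contact map of a model.

    Parameters are in nm / residues.  ``use_shadow=False`` gives the
    cutoff-only map (debug aid).  Covalently bonded pairs and pairs sharing
    an angle term are never contacts.
    """
    if len(model) == 0:
        raise ValueError("empty model")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if light_radius is None:
        light_radius = shadow_radius
    occlusion_radius = shadow_radius + light_radius

    coords = model.coords / ANGSTROM_PER_NM
    tree = cKDTree(coords)
    cand = tree.query_pairs(cutoff, output_type="ndarray")
    # degenerate-coordinate check among candidate pairs
    if cand.size:
        d0 = np.linalg.norm(coords[cand[:, 0]] - coords[cand[:, 1]], axis=1)
        zero = d0 == 0.0
        if zero.any():
            i, j = cand[zero][0]
            raise ValueError(
                f"degenerate coordinates: atoms {i} and {j} coincide")

    excluded = _bond_graph_exclusions(model, max_dist=2)
    nuc = np.isin(model.molecule_class, ("dna", "rna"))
    neighbors = tree.query_ball_tree(tree, cutoff) if use_shadow else None
    contacts: list[Contact] = []
    for i, j in cand:
        i, j = int(min(i, j)), int(max(i, j))
        if (i, j) in excluded:
            continue
        category = _pair_category(
            "dna" if nuc[i] else "protein", "dna" if nuc[j] else "protein"
        )
        if model.chain_id[i] == model.chain_id[j]:
            sep = abs(int(model.residue_number[i]) -
                      int(model.residue_number[j]))
            min_sep = (min_seq_sep_protein if category == "protein-protein"
                       else min_seq_sep_nucleic)
            if sep < min_sep:
                continue
        if use_shadow:
            # third atoms near the segment: anything within cutoff of either
            # endpoint can possibly occlude (occ radius << cutoff)
            near = np.array(
                sorted(set(neighbors[i]) | set(neighbors[j])), dtype=int
            )
            near = near[(near != i) & (near != j)]
            if near.size and _occluded(coords, i, j, near, occlusion_radius):
                continue
        r0 = float(np.linalg.norm(coords[i] - coords[j]))
        contacts.append(Contact(i, j, r0, category))
    contacts.sort(key=lambda c: (c.i, c.j))
    return ContactMap(
        contacts,
        cutoff=cutoff,
        shadow_radius=shadow_radius,
        min_seq_sep_protein=min_seq_sep_protein,
        min_seq_sep_nucleic=min_seq_sep_nucleic,
        parameters={"light_radius_nm": light_radius, "use_shadow": use_shadow},
    )


def classify_contacts(cmap: ContactMap, model: MolecularModel,
                      spec: SelectionSpec) -> ContactMap:
    """Label each contact with the selection-group pair of its atoms.

    Every atom may belong to at most one group; the interdomain (ID) subset
    is then the set of contacts whose group pair is {NGN, KOW}.
    """
    n = len(model)
    label = np.full(n, "", dtype="U32")
    for group in spec.groups:
        mask = spec.mask(model, group)
        clash = mask & (label != "")
        if clash.any():
            k = int(np.flatnonzero(clash)[0])
            raise ValueError(
                f"atom {k} ({model.atom_key(k)}) belongs to groups "
                f"{label[k]!r} and {group!r}"
            )
        label[mask] = group
    contacts = [
        Contact(c.i, c.j, c.r0, c.category,
                (str(label[c.i]), str(label[c.j])))
        for c in cmap.contacts
    ]
    out = ContactMap(
        contacts,
        cutoff=cmap.cutoff,
        shadow_radius=cmap.shadow_radius,
        min_seq_sep_protein=cmap.min_seq_sep_protein,
        min_seq_sep_nucleic=cmap.min_seq_sep_nucleic,
        parameters=dict(cmap.parameters),
    )
    return out


def interdomain_subset(cmap: ContactMap, group_a: str = "NGN",
                       group_b: str = "KOW") -> ContactMap:
    """Contacts whose group pair is exactly {group_a, group_b}."""
    want = {group_a, group_b}
    return cmap.subset(lambda c: set(c.groups) == want)
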