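"""Macromolecular structure I/O and named atom selections.

Structures are held in a light :class:`MolecularModel` container (ordered
atoms, covalent bonds, Angstrom coordinates at the file interface).  Parsing,
residue-template bond inference and altloc handling are delegated to biotite;
everything downstream of this module consumes only :class:`MolecularModel`.
"""

from __future__ import annotations

import fnmatch
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# Residue-name sets used to infer the molecule class.  Author numbering and
# names are kept verbatim; unknown residues fall through to "other".
_PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
_DNA_RESIDUES = {"DA", "DC", "DG", "DT", "DI", "DU"}
_RNA_RESIDUES = {"A", "C", "G", "U", "I"}


def classify_residue(res_name: str) -> str:
    """Return the molecule class (protein/dna/rna/other) for a residue name."""
    name = res_name.strip().upper()
    if name in _PROTEIN_RESIDUES:
        return "protein"
    if name in _DNA_RESIDUES:
        return "dna"
    if name in _RNA_RESIDUES:
        return "rna"
    return "other"


@dataclass
class AtomRecord:
    """One atom: identity, author numbering and Angstrom position."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    molecule_class: str = "other"
    insertion_code: str = ""

    def key(self) -> tuple:
        """Identity tuple used for 1:1 atom matching across models."""
        return (self.chain_id, self.residue_number, self.insertion_code,
                self.name)


class MolecularModel:
    """Ordered collection of atoms plus covalent bonds.

    Internally column-major (numpy arrays per field) for speed; the
    :attr:`atoms` property materialises :class:`AtomRecord` views on demand.
    Coordinates are Angstrom at this interface.
    """

    def __init__(
        self,
        serial: np.ndarray,
        name: np.ndarray,
        element: np.ndarray,
        residue_name: np.ndarray,
        residue_number: np.ndarray,
        chain_id: np.ndarray,
        coords: np.ndarray,
        molecule_class: np.ndarray,
        insertion_code: np.ndarray | None = None,
        bonds: Sequence[tuple[int, int]] = (),
        title: str = "",
    ):
        n = len(serial)
        self.serial = np.asarray(serial, dtype=np.int64)
        self.name = np.asarray(name, dtype="U6")
        self.element = np.asarray(element, dtype="U2")
        self.residue_name = np.asarray(residue_name, dtype="U5")
        self.residue_number = np.asarray(residue_number, dtype=np.int64)
        self.chain_id = np.asarray(chain_id, dtype="U4")
        self.coords = np.asarray(coords, dtype=np.float64).reshape(n, 3)
        self.molecule_class = np.asarray(molecule_class, dtype="U7")
        if insertion_code is None:
            insertion_code = np.full(n, "", dtype="U1")
        self.insertion_code = np.asarray(insertion_code, dtype="U1")
        self.bonds = [(int(i), int(j)) for i, j in bonds]
        self.title = title
        self._validate()

    def _validate(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in model")
        n = len(self)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")

    def __len__(self) -> int:
        return len(self.serial)

    @property
    def atoms(self) -> list[AtomRecord]:
        return [
            AtomRecord(
                serial=int(self.serial[i]),
                name=str(self.name[i]),
                element=str(self.element[i]),
                residue_name=str(self.residue_name[i]),
                residue_number=int(self.residue_number[i]),
                chain_id=str(self.chain_id[i]),
                position=self.coords[i].copy(),
                molecule_class=str(self.molecule_class[i]),
                insertion_code=str(self.insertion_code[i]),
            )
            for i in range(len(self))
        ]

    @classmethod
    def from_atoms(
        cls,
        records: Iterable[AtomRecord],
        bonds: Sequence[tuple[int, int]] = (),
        title: str = "",
    ) -> "MolecularModel":
        recs = list(records)
        return cls(
            serial=[r.serial for r in recs],
            name=[r.name for r in recs],
            element=[r.element for r in recs],
            residue_name=[r.residue_name for r in recs],
            residue_number=[r.residue_number for r in recs],
            chain_id=[r.chain_id for r in recs],
            coords=np.array([r.position for r in recs], dtype=float).reshape(
                len(recs), 3),
            molecule_class=[r.molecule_class for r in recs],
            insertion_code=[r.insertion_code for r in recs],
            bonds=bonds,
            title=title,
        )

    def atom_key(self, i: int) -> tuple:
        return (str(self.chain_id[i]), int(self.residue_number[i]),
                str(self.insertion_code[i]), str(self.name[i]))

    def subset(self, indices: np.ndarray, title: str | None = None) -> "MolecularModel":
        """Sub-model of the given atom indices, preserving atom order.

        Bonds with both endpoints inside the subset are remapped; others drop.
        """
        indices = np.asarray(indices, dtype=np.int64)
        order = np.sort(indices)
        remap = {int(old): new for new, old in enumerate(order)}
        bonds = [
            (remap[i], remap[j])
            for i, j in self.bonds
            if i in remap and j in remap
        ]
        return MolecularModel(
            serial=self.serial[order],
            name=self.name[order],
            element=self.element[order],
            residue_name=self.residue_name[order],
            residue_number=self.residue_number[order],
            chain_id=self.chain_id[order],
            coords=self.coords[order],
            molecule_class=self.molecule_class[order],
            insertion_code=self.insertion_code[order],
            bonds=bonds,
            title=self.title if title is None else title,
        )

    def with_coords(self, coords: np.ndarray) -> "MolecularModel":
        out = self.subset(np.arange(len(self)))
        out.coords = np.asarray(coords, dtype=float).reshape(len(self), 3)
        out._validate()
        return out


@dataclass
class SelectionSpec:
    """Named atom groups as (chain, inclusive residue range) terms.

    ``groups[name]`` is a list of ``(chain_id, start, end)`` terms; residue
    numbering is the file's author numbering and ranges are inclusive on both
    ends.  ``atom_names[name]`` optionally restricts a group to atom-name
    globs (e.g. ``["CA", "C1'*"]``).
    """

    groups: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    atom_names: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionSpec":
        groups: dict[str, list[tuple[str, int, int]]] = {}
        atom_names: dict[str, list[str]] = {}
        for name, entry in d.items():
            terms = entry["ranges"] if isinstance(entry, dict) else entry
            groups[name] = [(str(c), int(a), int(b)) for c, a, b in terms]
            if isinstance(entry, dict) and "atom_names" in entry:
                atom_names[name] = list(entry["atom_names"])
        return cls(groups=groups, atom_names=atom_names)

    def to_dict(self) -> dict:
        out: dict = {}
        for name, terms in self.groups.items():
            entry: dict = {"ranges": [list(t) for t in terms]}
            if name in self.atom_names:
                entry["atom_names"] = list(self.atom_names[name])
            out[name] = entry
        return out

    def mask(self, model: MolecularModel, group: str) -> np.ndarray:
        """Boolean membership mask of ``group`` over the model's atoms."""
        if group not in self.groups:
            raise KeyError(f"selection group {group!r} not defined")
        mask = np.zeros(len(model), dtype=bool)
        model_chains = set(np.unique(model.chain_id))
        for chain, start, end in self.groups[group]:
            if chain not in model_chains:
                raise ValueError(
                    f"selection group {group!r} references chain {chain!r} "
                    f"absent from the model (chains: {sorted(model_chains)})"
                )
            term = (
                (model.chain_id == chain)
                & (model.residue_number >= start)
                & (model.residue_number <= end)
                & (model.insertion_code == "")
            )
            mask |= term
        globs = self.atom_names.get(group)
        if globs:
            name_ok = np.zeros(len(model), dtype=bool)
            for g in globs:
                name_ok |= np.array(
                    [fnmatch.fnmatchcase(n, g) for n in model.name]
                )
            mask &= name_ok
        return mask


def _model_from_atom_array(arr, title: str = "") -> MolecularModel:
    import biotite.structure as struc

    n = arr.array_length()
    mol_class = np.array([classify_residue(r) for r in arr.res_name], dtype="U7")
    bonds: list[tuple[int, int]] = []
    if arr.bonds is not None:
        bonds = [(int(i), int(j)) for i, j, _ in arr.bonds.as_array()]
    ins = (
        arr.ins_code
        if "ins_code" in arr.get_annotation_categories()
        else np.full(n, "", dtype="U1")
    )
    return MolecularModel(
        serial=np.arange(1, n + 1),
        name=arr.atom_name,
        element=arr.element,
        residue_name=arr.res_name,
        residue_number=arr.res_id,
        chain_id=arr.chain_id,
        coords=np.asarray(arr.coord, dtype=float),
        molecule_class=mol_class,
        insertion_code=ins,
        bonds=bonds,
        title=title,
    )


def read_structure(path, fmt: str = "auto") -> MolecularModel:
    """Read a PDB or mmCIF file into a :class:`MolecularModel`.

    Heavy-atom model: hydrogens are dropped.  Of alternate locations only the
    first ('A' or blank) is kept; the number of dropped altloc atoms is
    logged.  Covalent bonds come from CONECT records plus residue templates
    and inter-residue backbone linkage; residues with no template are kept
    with ``molecule_class='other'`` and no inferred intra-residue bonds.
    """
    import biotite.structure.io.pdb as pdb
    import biotite.structure.io.pdbx as pdbx

    path = Path(path)
    if fmt == "auto":
        suffix = path.suffix.lower()
        fmt = "mmcif" if suffix in {".cif", ".mmcif"} else "pdb"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # unknown-residue template warnings
        try:
            if fmt == "pdb":
                pf = pdb.PDBFile.read(str(path))
                n_alt = _count_altlocs_pdb(path)
                arr = pf.get_structure(
                    model=1, altloc="first", include_bonds=True
                )
            elif fmt == "mmcif":
                cf = pdbx.CIFFile.read(str(path))
                arr = pdbx.get_structure(
                    cf, model=1, altloc="first", include_bonds=True
                )
                n_alt = 0
            else:
                raise ValueError(f"unknown format {fmt!r}")
        except ValueError:
            raise
        except Exception as exc:  # parse failure -> format error
            raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if n_alt:
        logger.info("dropped %d alternate-location atoms from %s", n_alt, path)
    heavy = (arr.element != "H") & (arr.element != "D")
    arr = arr[heavy]
    return _model_from_atom_array(arr, title=path.stem)


def _count_altlocs_pdb(path: Path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith(("ATOM", "HETATM")) and len(line) > 16:
                if line[16] not in (" ", "", "A"):
                    n += 1
    return n


def _atom_array_from_model(model: MolecularModel):
    import biotite.structure as struc

    n = len(model)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(model.coords, dtype=np.float32)
    arr.chain_id = model.chain_id
    arr.res_id = model.residue_number
    arr.ins_code = model.insertion_code
    arr.res_name = model.residue_name
    arr.atom_name = model.name
    arr.element = model.element
    arr.hetero = model.molecule_class == "other"
    if model.bonds:
        arr.bonds = struc.BondList(
            n, np.array([[i, j] for i, j in model.bonds], dtype=np.uint32)
        )
    else:
        arr.bonds = struc.BondList(n)
    return arr


def write_structure(model: MolecularModel, path, fmt: str = "auto") -> None:
    """Write a model as PDB (fixed-column, with CONECT) or mmCIF."""
    import biotite.structure.io.pdb as pdb
    import biotite.structure.io.pdbx as pdbx

    path = Path(path)
    if fmt == "auto":
        suffix = path.suffix.lower()
        fmt = "mmcif" if suffix in {".cif", ".mmcif"} else "pdb"
    arr = _atom_array_from_model(model)
    if fmt == "pdb":
        pf = pdb.PDBFile()
        pf.set_structure(arr)
        pf.write(str(path))
    elif fmt == "mmcif":
        cf = pdbx.CIFFile()
        pdbx.set_structure(cf, arr)
        cf.write(str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def select(model: MolecularModel, spec: SelectionSpec, group: str) -> MolecularModel:
    """Sub-model of the named selection group, preserving atom order."""
    mask = spec.mask(model, group)
    if not mask.any():
        logger.warning("selection group %r matched no atoms", group)
    return model.subset(np.flatnonzero(mask), title=f"{model.title}:{group}")
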