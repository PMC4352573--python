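"""Reading, writing and pre-processing of molecular structures.

The in-memory unit is :class:`Molecule3D`, a heavy-atom-only record of
elements, coordinates, bonds and formal charges.  Hydrogens present in
input files are folded into a per-atom hydrogen count at parse time:
every fingerprint in this package operates on heavy atoms only and
normalizes by the heavy atom count (HAC).

Pre-processing follows the usual virtual-screening database hygiene:
keep the largest connected fragment (drops counter-ions) and discard
molecules above a heavy-atom-count cutoff (default 50).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.error")

__all__ = [
    "Molecule3D",
    "read_structures",
    "write_sdf",
    "largest_fragment",
    "filter_by_hac",
]


@dataclass
class Molecule3D:
    """A heavy-atom molecular record with optional 3D coordinates.

    Parameters
    ----------
    id : str
        Text identifier (SDF title, MOL2 name, SMILES line id, ...).
    elements : list of str
        Element symbols of the heavy atoms.
    coords : (n, 3) ndarray of float
        Cartesian coordinates in Angstrom.  All zeros when ``has_3d``
        is false.
    bonds : list of (int, int, float)
        Bonds as (atom index, atom index, order); aromatic bonds carry
        order 1.5.
    formal_charges : list of int
        Formal charge per heavy atom.
    has_3d : bool
        Whether ``coords`` carry meaningful 3D information.
    aromatic : list of bool
        Per-atom aromaticity flag, perceived at parse time (synthetic
        fixtures set it explicitly).
    n_hydrogens : list of int
        Total hydrogen count (implicit + explicit) per heavy atom.
    """

    id: str
    elements: list
    coords: np.ndarray
    bonds: list
    formal_charges: list
    has_3d: bool = True
    aromatic: list = field(default_factory=list)
    n_hydrogens: list = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.elements)
        if not self.aromatic:
            self.aromatic = [False] * n
        if not self.n_hydrogens:
            self.n_hydrogens = [0] * n
        if not (len(self.coords) == len(self.formal_charges)
                == len(self.aromatic) == len(self.n_hydrogens) == n):
            raise ValueError(f"{self.id}: per-atom field lengths disagree")
        for i, j, _ in self.bonds:
            if i == j:
                raise ValueError(f"{self.id}: self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"{self.id}: bond ({i},{j}) out of range")
        if self.has_3d and not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.id}: non-finite coordinates")

    @property
    def hac(self) -> int:
        """Heavy atom count (all non-hydrogen atoms)."""
        return len(self.elements)

    def neighbors(self) -> list:
        """Adjacency list over heavy atoms."""
        adj = [[] for _ in range(self.hac)]
        for i, j, _ in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj


_BOND_ORDER = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: 1.5,
}
_ORDER_BOND = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
               3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}


def _from_rdkit(rdmol: Chem.Mol, mol_id: str, has_3d: bool) -> Molecule3D:
    """Convert a sanitized RDKit mol (hydrogens removed) to Molecule3D."""
    conf = rdmol.GetConformer() if (has_3d and rdmol.GetNumConformers()) else None
    elements, charges, aromatic, nh = [], [], [], []
    coords = np.zeros((rdmol.GetNumAtoms(), 3))
    for a in rdmol.GetAtoms():
        elements.append(a.GetSymbol())
        charges.append(a.GetFormalCharge())
        aromatic.append(a.GetIsAromatic())
        nh.append(a.GetTotalNumHs())
        if conf is not None:
            p = conf.GetAtomPosition(a.GetIdx())
            coords[a.GetIdx()] = (p.x, p.y, p.z)
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
              _BOND_ORDER.get(b.GetBondType(), 1.0)) for b in rdmol.GetBonds()]
    return Molecule3D(mol_id, elements, coords, bonds, charges,
                      has_3d=has_3d and conf is not None,
                      aromatic=aromatic, n_hydrogens=nh)


def to_rdkit(mol: Molecule3D) -> Chem.Mol:
    """Build an (unsanitized) RDKit mol from a Molecule3D, for writing."""
    rw = Chem.RWMol()
    for el, q, nh, ar in zip(mol.elements, mol.formal_charges,
                             mol.n_hydrogens, mol.aromatic):
        a = Chem.Atom(el)
        a.SetFormalCharge(int(q))
        a.SetNumExplicitHs(int(nh))
        a.SetNoImplicit(True)
        a.SetIsAromatic(bool(ar))
        rw.AddAtom(a)
    for i, j, order in mol.bonds:
        rw.AddBond(int(i), int(j), _ORDER_BOND.get(float(order), Chem.BondType.SINGLE))
    m = rw.GetMol()
    m.SetProp("_Name", mol.id)
    conf = Chem.Conformer(mol.hac)
    for idx, (x, y, z) in enumerate(mol.coords):
        conf.SetAtomPosition(idx, (float(x), float(y), float(z)))
    conf.Set3D(bool(mol.has_3d))
    m.AddConformer(conf)
    Chem.SanitizeMol(m, Chem.SanitizeFlags.SANITIZE_FINDRADICALS
                     | Chem.SanitizeFlags.SANITIZE_SETCONJUGATION)
    return m


def _iter_mol2_blocks(text: str):
    marker = "@<TRIPOS>MOLECULE"
    parts = text.split(marker)
    for part in parts[1:]:
        yield marker + part


def read_structures(path, format: str) -> list:
    """Read molecules from ``path`` in the given format.

    Supported formats: ``sdf`` (V2000, 3D), ``mol2``, ``smiles`` (one
    record per line, optional whitespace-separated id).  Unparsable
    records are skipped with a logged warning.  Hydrogens are removed
    and counted per heavy atom.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        On an unknown format or when no record parses.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such structure file: {path}")
    fmt = format.lower()
    mols: list = []
    n_skipped = 0

    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        for i, rd in enumerate(supplier):
            if rd is None:
                n_skipped += 1
                logger.warning("%s: record %d unparsable, skipped", path, i)
                continue
            rd = Chem.RemoveHs(rd)
            name = rd.GetProp("_Name") if rd.HasProp("_Name") else ""
            mols.append(_from_rdkit(rd, name or f"{path.stem}_{i}", has_3d=True))
    elif fmt == "mol2":
        for i, block in enumerate(_iter_mol2_blocks(path.read_text())):
            rd = Chem.MolFromMol2Block(block, removeHs=False, sanitize=True)
            if rd is None:
                n_skipped += 1
                logger.warning("%s: mol2 record %d unparsable, skipped", path, i)
                continue
            rd = Chem.RemoveHs(rd)
            name = rd.GetProp("_Name") if rd.HasProp("_Name") else ""
            mols.append(_from_rdkit(rd, name or f"{path.stem}_{i}", has_3d=True))
    elif fmt == "smiles":
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            rd = Chem.MolFromSmiles(fields[0])
            if rd is None:
                n_skipped += 1
                logger.warning("%s: SMILES line %d unparsable, skipped", path, i)
                continue
            mol_id = fields[1] if len(fields) > 1 else f"{path.stem}_{i}"
            mols.append(_from_rdkit(rd, mol_id, has_3d=False))
    else:
        raise ValueError(f"unknown format {format!r}; expected sdf, mol2 or smiles")

    if not mols:
        raise ValueError(f"{path}: no parsable records ({n_skipped} skipped)")
    if n_skipped:
        logger.info("%s: %d records read, %d skipped", path, len(mols), n_skipped)
    return mols


def write_sdf(mols: Iterable[Molecule3D], path) -> None:
    """Write molecules to an SDF (V2000) file."""
    writer = Chem.SDWriter(str(path))
    try:
        for mol in mols:
            writer.write(to_rdkit(mol))
    finally:
        writer.close()


def _components(mol: Molecule3D) -> list:
    """Connected components as lists of atom indices, in first-occurrence order."""
    adj = mol.neighbors()
    seen = [False] * mol.hac
    comps = []
    for start in range(mol.hac):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in adj[v]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(sorted(comp))
    return comps


def extract_atoms(mol: Molecule3D, indices: Sequence[int]) -> Molecule3D:
    """Sub-molecule on the given atom indices, bonds re-indexed."""
    idx = list(indices)
    remap = {old: new for new, old in enumerate(idx)}
    bonds = [(remap[i], remap[j], o) for i, j, o in mol.bonds
             if i in remap and j in remap]
    return Molecule3D(
        mol.id,
        [mol.elements[i] for i in idx],
        mol.coords[idx],
        bonds,
        [mol.formal_charges[i] for i in idx],
        has_3d=mol.has_3d,
        aromatic=[mol.aromatic[i] for i in idx],
        n_hydrogens=[mol.n_hydrogens[i] for i in idx],
    )


def largest_fragment(mol: Molecule3D) -> Molecule3D:
    """Keep the connected component with the most heavy atoms.

    Ties are broken by first occurrence in atom order, so the result is
    deterministic and the operation idempotent.  Coordinates are
    preserved.
    """
    if mol.hac == 0:
        raise ValueError(f"{mol.id}: empty molecule")
    comps = _components(mol)
    if len(comps) == 1:
        return mol
    best = max(comps, key=len)  # max() keeps the earliest of equal sizes
    return extract_atoms(mol, best)


def filter_by_hac(mols: Iterable[Molecule3D], max_hac: int = 50) -> list:
    """Keep molecules with heavy atom count <= ``max_hac``, order preserved."""
    if max_hac < 1:
        raise ValueError("max_hac must be >= 1")
    return [m for m in mols if m.hac <= max_hac]
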