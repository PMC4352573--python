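"""Synthetic point-set molecules with exact coordinates.

Every generator is a pure function of its arguments (and seed), so
all fingerprint, search and benchmarking operations are testable with
no external data.  The geometries are deliberately chemically naive:
the fingerprint formulas consume only elements, category flags, bonds
and coordinates, so exact arithmetic beats realistic valences for
correctness testing.
"""

from __future__ import annotations

import itertools
import math
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .chem_io import Molecule3D

__all__ = [
    "make_pair",
    "make_chain",
    "transform",
    "permute_atoms",
    "enumerate_stereo",
    "random_molecule",
    "make_diastereomer_pair",
]


def make_pair(d: float, elements: Tuple[str, str] = ("C", "C"),
              mol_id: str = "pair") -> Molecule3D:
    """Two bonded atoms at (0,0,0) and (d,0,0) — the minimal 3D fixture."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    return Molecule3D(mol_id, list(elements),
                      np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]),
                      [(0, 1, 1.0)], [0, 0])


def make_chain(n: int, bond_length: float = 1.5, geometry: str = "linear",
               helix_radius: float = 2.0, helix_pitch: float = 0.3,
               element: str = "C", mol_id: str = "chain") -> Molecule3D:
    """A consecutively bonded n-atom chain.

    ``linear`` places atoms on the x-axis at ``bond_length`` spacing,
    so through-space and topological distances are proportional.  A
    ``helix`` coils the chain (consecutive atoms ``bond_length``
    apart along a helix of the given radius and pitch per turn), so
    through-space distances fall far below topological path lengths —
    the geometry of a folded conformer.
    """
    if n < 2:
        raise ValueError("chain needs n >= 2")
    if geometry == "linear":
        coords = np.zeros((n, 3))
        coords[:, 0] = bond_length * np.arange(n)
    elif geometry == "helix":
        if bond_length >= 2.0 * helix_radius:
            raise ValueError("bond_length too long for this helix radius")

        # turn angle whose 3D chord (circle chord + pitch rise) equals
        # the bond length
        def chord_error(dt):
            rise = helix_pitch * dt / (2.0 * math.pi)
            return ((2.0 * helix_radius * math.sin(dt / 2.0))**2
                    + rise**2 - bond_length**2)

        from scipy.optimize import brentq
        dtheta = brentq(chord_error, 1e-9, math.pi)
        theta = dtheta * np.arange(n)
        coords = np.column_stack([
            helix_radius * np.cos(theta),
            helix_radius * np.sin(theta),
            helix_pitch * theta / (2.0 * math.pi),
        ])
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    bonds = [(i, i + 1, 1.0) for i in range(n - 1)]
    return Molecule3D(mol_id, [element] * n, coords, bonds, [0] * n)


def transform(mol: Molecule3D, op: str, axis: Optional[Sequence[float]] = None,
              angle: float = 0.0, vector: Optional[Sequence[float]] = None,
              plane: str = "xy") -> Molecule3D:
    """Rigid motion or reflection of the coordinates; graph unchanged.

    ``op`` is one of ``rotate`` (about ``axis`` through the origin by
    ``angle`` radians), ``translate`` (by ``vector``) or ``mirror``
    (through the coordinate ``plane``: xy, xz or yz).
    """
    coords = mol.coords.copy()
    if op == "rotate":
        ax = np.asarray(axis if axis is not None else (0.0, 0.0, 1.0), float)
        rot = Rotation.from_rotvec(angle * ax / np.linalg.norm(ax))
        coords = rot.apply(coords)
    elif op == "translate":
        coords = coords + np.asarray(vector, dtype=float)
    elif op == "mirror":
        flip_axis = {"xy": 2, "xz": 1, "yz": 0}
        if plane not in flip_axis:
            raise ValueError(f"unknown mirror plane {plane!r}")
        coords[:, flip_axis[plane]] *= -1.0
    else:
        raise ValueError(f"unknown transform {op!r}")
    return Molecule3D(mol.id, list(mol.elements), coords,
                      list(mol.bonds), list(mol.formal_charges),
                      has_3d=mol.has_3d, aromatic=list(mol.aromatic),
                      n_hydrogens=list(mol.n_hydrogens))


def permute_atoms(mol: Molecule3D, order: Sequence[int]) -> Molecule3D:
    """Reorder atoms: atom ``order[k]`` of the input becomes atom k."""
    order = list(order)
    if sorted(order) != list(range(mol.hac)):
        raise ValueError("order must be a permutation of atom indices")
    inverse = {old: new for new, old in enumerate(order)}
    bonds = [(inverse[i], inverse[j], o) for i, j, o in mol.bonds]
    return Molecule3D(mol.id, [mol.elements[i] for i in order],
                      mol.coords[order], bonds,
                      [mol.formal_charges[i] for i in order],
                      has_3d=mol.has_3d,
                      aromatic=[mol.aromatic[i] for i in order],
                      n_hydrogens=[mol.n_hydrogens[i] for i in order])


def enumerate_stereo(n_centers: int, n_double_bonds: int = 0):
    """All 2^(centers + double bonds) stereo configuration strings.

    Each configuration concatenates R/S labels for the stereocenters
    with E/Z labels for the double bonds; with no stereo elements the
    single empty configuration (the molecule itself) is returned.
    A molecule with 5 stereocenters has 32 diastereomeric
    configurations; one with 4 stereogenic double bonds has 16 E/Z
    isomers.
    """
    if n_centers < 0 or n_double_bonds < 0:
        raise ValueError("counts must be >= 0")
    configs = ["".join(rs) + "".join(ez)
               for rs in itertools.product("RS", repeat=n_centers)
               for ez in itertools.product("EZ", repeat=n_double_bonds)]
    return len(configs), configs


def random_molecule(n: int, box: float = 10.0, seed: int = 0,
                    element: str = "C", mol_id: str = "") -> Molecule3D:
    """n atoms uniform in a cube of side ``box``, chained by bonds."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, box, size=(n, 3))
    bonds = [(i, i + 1, 1.0) for i in range(n - 1)]
    return Molecule3D(mol_id or f"rand{seed}", [element] * n, coords,
                      bonds, [0] * n)


def make_diastereomer_pair(mol_id: str = "diastereomer"):
    """Two 3D embeddings of one 4-atom chain with distinct pair geometry.

    Both conformers share bond lengths (1.5 A) and valence angles
    (109.47 deg) on the same 2D graph but differ in the central
    dihedral (anti, 180 deg, vs gauche, 60 deg), so the sorted
    pair-distance multisets differ while every topological property
    is identical — the minimal diastereomer-like test pair.
    """
    b = 1.5
    ang = math.radians(109.47)

    def chain_with_dihedral(dihedral_deg: float, tag: str) -> Molecule3D:
        # place a0-a1-a2 in the xz plane, then a3 by the dihedral
        a0 = np.array([0.0, 0.0, 0.0])
        a1 = np.array([b, 0.0, 0.0])
        a2 = a1 + b * np.array([-math.cos(ang), 0.0, math.sin(ang)])
        # local frame at a2
        u = (a2 - a1) / b
        ref = np.array([0.0, 1.0, 0.0])
        v = np.cross(u, ref)
        v /= np.linalg.norm(v)
        w = np.cross(u, v)
        phi = math.radians(dihedral_deg)
        direction = (-math.cos(ang) * u
                     + math.sin(ang) * (math.cos(phi) * w + math.sin(phi) * v))
        a3 = a2 + b * direction
        coords = np.vstack([a0, a1, a2, a3])
        bonds = [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)]
        return Molecule3D(f"{mol_id}_{tag}", ["C"] * 4, coords, bonds, [0] * 4)

    return chain_with_dihedral(180.0, "anti"), chain_with_dihedral(60.0, "gauche")
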