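"""Pharmacophore atom categories for the category-extended fingerprints.

Four boolean flags per heavy atom:

* ``hyb`` -- hydrophobic: carbon, sulfur or halogen with no bonded
  nitrogen or oxygen neighbor;
* ``hba`` -- hydrogen-bond acceptor: N or O that is not positively
  charged, excluding aromatic N bonded to hydrogen and excluding
  amide/aniline-type nitrogens whose lone pair donates into a pi
  system;
* ``hbd`` -- hydrogen-bond donor: N or O bearing at least one
  hydrogen;
* ``sp2`` -- planar/unsaturated: aromatic atoms and atoms involved in
  a double bond.

An atom may carry several flags (a hydroxyl oxygen is both acceptor
and donor).  The rules are conventional pharmacophore typing; they
depend only on the 2D graph (elements, bonds, charges, hydrogen
counts), never on coordinates, and are invariant under atom
reordering.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chem_io import Molecule3D

__all__ = ["AtomCategories", "assign_categories"]

_HALOGENS = {"F", "Cl", "Br", "I"}
_HYB_ELEMENTS = {"C", "S"} | _HALOGENS


@dataclass
class AtomCategories:
    """Per-atom boolean category flags, each of length HAC."""

    hyb: list
    hba: list
    hbd: list
    sp2: list

    def __len__(self) -> int:
        return len(self.hyb)


def assign_categories(mol: Molecule3D) -> AtomCategories:
    """Assign Hyb/HBA/HBD/sp2 flags to every heavy atom of ``mol``."""
    n = mol.hac
    adj = mol.neighbors()
    elements = mol.elements

    # atoms engaged in a double bond (order exactly 2)
    in_double = set()
    for i, j, order in mol.bonds:
        if order == 2.0:
            in_double.update((i, j))
    # carbons doubly bonded to a heteroatom: their N neighbors are
    # amide/amidine-type and lose acceptor character
    pi_carbons = {i for i, j, order in mol.bonds
                  if order == 2.0 and elements[i] == "C"
                  and elements[j] in ("O", "N", "S")}
    pi_carbons |= {j for i, j, order in mol.bonds
                   if order == 2.0 and elements[j] == "C"
                   and elements[i] in ("O", "N", "S")}

    hyb, hba, hbd, sp2 = [], [], [], []
    for i in range(n):
        el = mol.elements[i]
        charge = mol.formal_charges[i]
        nh = mol.n_hydrogens[i]
        arom = mol.aromatic[i]
        nbr_elems = [mol.elements[j] for j in adj[i]]

        sp2.append(bool(arom or i in in_double))
        hbd.append(el in ("N", "O") and nh >= 1)

        acc = el in ("N", "O") and charge <= 0
        if acc and el == "N":
            if arom and nh >= 1:
                acc = False  # pyrrole-type aromatic NH
            elif not arom:
                # aniline-type (aromatic neighbor) or amide-type
                # (neighbor C doubly bonded to a heteroatom)
                for j in adj[i]:
                    if mol.aromatic[j] or j in pi_carbons:
                        acc = False
                        break
        hba.append(acc)

        hyb.append(el in _HYB_ELEMENTS
                   and not any(e in ("N", "O") for e in nbr_elems))

    return AtomCategories(hyb=hyb, hba=hba, hbd=hbd, sp2=sp2)
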