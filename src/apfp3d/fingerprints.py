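"""Atom-pair and shape fingerprints for ligand-based virtual screening.

Two families of through-space atom-pair fingerprints are the core of
the package:

* gaussian/exponential sampling (3DAPfp, 16 bits; category-extended
  3DXfp, 80 bits): every heavy-atom pair at distance d_AB contributes
  a gaussian of width sigma = 0.18 * d_AB centred at d_AB and sampled
  at 16 geometrically spaced distances (1.45 A, ratio 1.18, up to
  17.36 A); per-bit sums are normalized by HAC^1.5, scaled to percent
  and rounded;
* regular binning (R3DAPfp, 40 bits; R3DXfp, 200 bits): each pair
  increments the 0.5-A bin containing d_AB on [0, 20) A; bin counts
  are normalized by HAC, scaled to percent and rounded.

Their topological parents APfp (20 bits, bond-count distances 1-20)
and Xfp (55 bits, five category blocks over distances 1-11) plus the
comparison shape descriptors PMIfp (normalized principal moments of
inertia), USR and USRCAT complete the scheme set.

The category-extended schemes use the pharmacophore flags from
:mod:`apfp3d.atom_typing` with block order
[Hyb-Hyb, HBA-HBA, HBD-HBD, sp2-sp2, HBA-HBD]; same-category blocks
are normalized by the category atom count (raised to 1.5 for the
gaussian family), the HBA-HBD cross block by the HBA count.

All schemes are invariant to rigid motion, mirror reflection and atom
reordering; the 3D schemes distinguish diastereomeric embeddings of
one topology while the 2D schemes do not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import pdist
from scipy.stats import kurtosis as _kurtosis
from sklearn.base import BaseEstimator, TransformerMixin

from .atom_typing import AtomCategories, assign_categories
from .chem_io import Molecule3D

logger = logging.getLogger(__name__)

__all__ = [
    "SCHEME_LENGTHS",
    "SamplingGrid",
    "Fingerprint",
    "FingerprintEncoder",
    "compute_fingerprint",
    "gaussian_sample",
    "pair_distances_3d",
    "pair_distances_topological",
    "fp_3dapfp",
    "fp_3dxfp",
    "fp_r3dapfp",
    "fp_r3dxfp",
    "fp_apfp",
    "fp_xfp",
    "fp_pmifp",
    "npmi",
    "fp_usr",
    "fp_usrcat",
    "write_fps",
    "read_fps",
]

#: Fixed vector length of every supported scheme.
SCHEME_LENGTHS = {
    "3DAPfp": 16,
    "3DXfp": 80,
    "R3DAPfp": 40,
    "R3DXfp": 200,
    "APfp": 20,
    "Xfp": 55,
    "PMIfp": 3,
    "USR": 12,
    "USRCAT": 60,
}

#: Category blocks of the X-extended schemes, in storage order.
BLOCK_ORDER = ("hyb", "hba", "hbd", "sp2", "cross")


def _geometric_distances() -> np.ndarray:
    return 1.45 * 1.18 ** np.arange(16)


@dataclass(frozen=True)
class SamplingGrid:
    """The 16 geometric sampling distances of the gaussian schemes.

    d1 = 1.45 A, d(n+1) = 1.18 * d(n), so d16 = 17.36 A; the gaussian
    width is ``width_fraction`` (0.18) times the pair distance.
    """

    distances: np.ndarray = field(default_factory=_geometric_distances)
    width_fraction: float = 0.18

    def __post_init__(self):
        d = np.asarray(self.distances, dtype=float)
        if d.ndim != 1 or len(d) != 16 or np.any(np.diff(d) <= 0):
            raise ValueError("grid must hold 16 strictly increasing distances")
        object.__setattr__(self, "distances", d)


DEFAULT_GRID = SamplingGrid()


@dataclass
class Fingerprint:
    """A scheme-tagged fixed-length vector of non-negative values."""

    scheme: str
    values: np.ndarray
    mol_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values)
        expect = SCHEME_LENGTHS.get(self.scheme)
        if expect is None:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.values.shape != (expect,):
            raise ValueError(
                f"{self.scheme} requires length {expect}, got {self.values.shape}")

    def __len__(self) -> int:
        return len(self.values)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    """Round non-negative values half-away-from-zero to integers."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


# ---------------------------------------------------------------------------
# pair distances

def pair_distances_3d(mol: Molecule3D):
    """All unordered heavy-atom pairs (i, j, d) with euclidean d in A.

    Coincident atoms (d = 0) are kept with a warning; count is
    HAC * (HAC - 1) / 2.
    """
    if not mol.has_3d:
        raise ValueError(f"{mol.id}: 3D coordinates required")
    n = mol.hac
    out = []
    if n >= 2:
        d = pdist(mol.coords)
        k = 0
        for i in range(n - 1):
            for j in range(i + 1, n):
                if d[k] == 0.0:
                    logger.warning("%s: coincident atoms %d and %d", mol.id, i, j)
                out.append((i, j, float(d[k])))
                k += 1
    return out


def pair_distances_topological(mol: Molecule3D):
    """All unordered pairs (i, j, t) with t the shortest-path bond count.

    Raises on a disconnected graph; apply ``largest_fragment`` first.
    """
    n = mol.hac
    if n < 2:
        return []
    rows = [i for i, j, _ in mol.bonds] + [j for i, j, _ in mol.bonds]
    cols = [j for i, j, _ in mol.bonds] + [i for i, j, _ in mol.bonds]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    t = shortest_path(adj, method="D", unweighted=True)
    if not np.all(np.isfinite(t)):
        raise ValueError(
            f"{mol.id}: disconnected graph; apply largest_fragment first")
    return [(i, j, int(t[i, j])) for i in range(n - 1) for j in range(i + 1, n)]


# ---------------------------------------------------------------------------
# gaussian sampling family

def gaussian_sample(d_ab: float, grid: SamplingGrid = DEFAULT_GRID) -> np.ndarray:
    """Gaussian of width 0.18*d_ab centred at d_ab, at the 16 grid points.

    Peak amplitude is 1 at the centre.  A zero distance contributes
    the zero vector (the degenerate gaussian is suppressed).
    """
    if d_ab == 0.0:
        return np.zeros(len(grid.distances))
    sigma = grid.width_fraction * d_ab
    return np.exp(-((grid.distances - d_ab) ** 2) / (2.0 * sigma**2))


def _gaussian_bits(distances: Sequence[float], norm_count: int,
                   grid: SamplingGrid) -> np.ndarray:
    total = np.zeros(len(grid.distances))
    for d in distances:
        total += gaussian_sample(d, grid)
    return _round_half_up(100.0 * total / norm_count**1.5)


def fp_3dapfp(mol: Molecule3D, grid: SamplingGrid = DEFAULT_GRID) -> Fingerprint:
    """16-bit gaussian-sampled shape fingerprint, normalized by HAC^1.5."""
    dists = [d for _, _, d in pair_distances_3d(mol)]
    return Fingerprint("3DAPfp", _gaussian_bits(dists, mol.hac, grid), mol.id)


def _category_pair_distances(pairs, flags_a, flags_b=None):
    """Distances of pairs within a category, or across two categories."""
    if flags_b is None:
        return [d for i, j, d in pairs if flags_a[i] and flags_a[j]]
    return [d for i, j, d in pairs
            if (flags_a[i] and flags_b[j]) or (flags_b[i] and flags_a[j])]


def _blockwise(mol, cats, pairs, block_fn, block_len):
    """Assemble the five category blocks common to all X schemes."""
    if cats is None:
        cats = assign_categories(mol)
    flags = {"hyb": cats.hyb, "hba": cats.hba, "hbd": cats.hbd, "sp2": cats.sp2}
    n_hba = sum(cats.hba)
    n_hbd = sum(cats.hbd)
    out = np.zeros(5 * block_len, dtype=np.int64)
    for b, name in enumerate(BLOCK_ORDER):
        if name == "cross":
            if n_hba == 0 or n_hbd == 0:
                continue
            dists = _category_pair_distances(pairs, cats.hba, cats.hbd)
            out[b * block_len:(b + 1) * block_len] = block_fn(dists, n_hba)
        else:
            count = sum(flags[name])
            if count < 2:
                continue
            dists = _category_pair_distances(pairs, flags[name])
            out[b * block_len:(b + 1) * block_len] = block_fn(dists, count)
    return out


def fp_3dxfp(mol: Molecule3D, cats: Optional[AtomCategories] = None,
             grid: SamplingGrid = DEFAULT_GRID) -> Fingerprint:
    """80-bit category-extended gaussian fingerprint (5 x 16 bits)."""
    pairs = pair_distances_3d(mol)
    values = _blockwise(mol, cats, pairs,
                        lambda d, c: _gaussian_bits(d, c, grid), 16)
    return Fingerprint("3DXfp", values, mol.id)


# ---------------------------------------------------------------------------
# regular binning family

_BIN_WIDTH = 0.5
_N_BINS = 40  # [0, 20) A


def _regular_bits(distances: Sequence[float], norm_count: int,
                  mol_id: str = "") -> np.ndarray:
    counts = np.zeros(_N_BINS)
    dropped = 0
    for d in distances:
        k = int(d // _BIN_WIDTH)  # half-open [0.5k, 0.5(k+1))
        if k >= _N_BINS:
            dropped += 1
            continue
        counts[k] += 1
    if dropped:
        logger.info("%s: %d atom pairs beyond 20 A dropped", mol_id, dropped)
    return _round_half_up(100.0 * counts / norm_count)


def fp_r3dapfp(mol: Molecule3D) -> Fingerprint:
    """40-bit regular-binned shape fingerprint (0.5-A bins, /HAC)."""
    dists = [d for _, _, d in pair_distances_3d(mol)]
    return Fingerprint("R3DAPfp", _regular_bits(dists, mol.hac, mol.id), mol.id)


def fp_r3dxfp(mol: Molecule3D,
              cats: Optional[AtomCategories] = None) -> Fingerprint:
    """200-bit category-extended regular-binned fingerprint (5 x 40)."""
    pairs = pair_distances_3d(mol)
    values = _blockwise(mol, cats, pairs,
                        lambda d, c: _regular_bits(d, c, mol.id), _N_BINS)
    return Fingerprint("R3DXfp", values, mol.id)


# ---------------------------------------------------------------------------
# topological parents

def _topo_bits(topo_pairs, norm_count: int, max_t: int) -> np.ndarray:
    counts = np.zeros(max_t)
    for t in topo_pairs:
        if 1 <= t <= max_t:
            counts[t - 1] += 1
    return _round_half_up(100.0 * counts / norm_count)


def fp_apfp(mol: Molecule3D) -> Fingerprint:
    """20-bit topological atom-pair fingerprint (1-20 bonds, /HAC)."""
    topo = [t for _, _, t in pair_distances_topological(mol)]
    return Fingerprint("APfp", _topo_bits(topo, mol.hac, 20), mol.id)


def fp_xfp(mol: Molecule3D, cats: Optional[AtomCategories] = None) -> Fingerprint:
    """55-bit category-extended topological fingerprint (5 x 11 bonds).

    Topological distances are measured on the full molecular graph;
    only the pair selection is restricted to the category.
    """
    pairs = pair_distances_topological(mol)
    values = _blockwise(mol, cats, pairs,
                        lambda t, c: _topo_bits(t, c, 11), 11)
    return Fingerprint("Xfp", values, mol.id)


# ---------------------------------------------------------------------------
# shape descriptors

_MASSES = {
    "H": 1.008, "B": 10.811, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Si": 28.086, "P": 30.974, "S": 32.065, "Cl": 35.453,
    "Br": 79.904, "I": 126.904,
}


def _atom_mass(el: str) -> float:
    if el in _MASSES:
        return _MASSES[el]
    from rdkit.Chem import GetPeriodicTable
    return GetPeriodicTable().GetAtomicWeight(el)


def _principal_moments(mol: Molecule3D):
    masses = np.array([_atom_mass(e) for e in mol.elements])
    xyz = mol.coords - np.average(mol.coords, axis=0, weights=masses)
    x, y, z = xyz[:, 0], xyz[:, 1], xyz[:, 2]
    ixx = np.sum(masses * (y**2 + z**2))
    iyy = np.sum(masses * (x**2 + z**2))
    izz = np.sum(masses * (x**2 + y**2))
    ixy = -np.sum(masses * x * y)
    ixz = -np.sum(masses * x * z)
    iyz = -np.sum(masses * y * z)
    tensor = np.array([[ixx, ixy, ixz], [ixy, iyy, iyz], [ixz, iyz, izz]])
    moments = np.linalg.eigvalsh(tensor)  # ascending I1 <= I2 <= I3
    return np.clip(moments, 0.0, None), masses.sum()


def fp_pmifp(mol: Molecule3D) -> Fingerprint:
    """Principal moments of inertia of the heavy atoms, scaled by mass."""
    if not mol.has_3d:
        raise ValueError(f"{mol.id}: 3D coordinates required")
    moments, mw = _principal_moments(mol)
    return Fingerprint("PMIfp", moments / mw, mol.id)


def npmi(mol: Molecule3D):
    """Normalized principal moments (I1/I3, I2/I3).

    Locates the molecule in the rod-disc-sphere shape triangle with
    corners rod = (0, 1), disc = (0.5, 0.5), sphere = (1, 1).  A fully
    degenerate (point-like) set maps to the sphere corner.
    """
    moments, _ = _principal_moments(mol)
    i1, i2, i3 = moments
    if i3 <= 0.0:
        return (1.0, 1.0)
    return (float(i1 / i3), float(i2 / i3))


_USR_EPS = 1e-12


def _usr_reference_points(coords: np.ndarray) -> np.ndarray:
    """ctd, closest-to-ctd, farthest-from-ctd, farthest-from-that."""
    ctd = coords.mean(axis=0)
    d_ctd = np.linalg.norm(coords - ctd, axis=1)
    cst = coords[int(np.argmin(d_ctd))]
    fct = coords[int(np.argmax(d_ctd))]
    d_fct = np.linalg.norm(coords - fct, axis=1)
    ftf = coords[int(np.argmax(d_fct))]
    return np.vstack([ctd, cst, fct, ftf])


def _usr_moments(coords: np.ndarray, refs: np.ndarray) -> np.ndarray:
    out = np.zeros(12)
    for r, ref in enumerate(refs):
        d = np.linalg.norm(coords - ref, axis=1)
        mean = d.mean()
        std = d.std()
        kurt = 0.0 if std < _USR_EPS else float(_kurtosis(d, fisher=True, bias=True))
        out[3 * r:3 * r + 3] = (mean, std, kurt)
    return out


def fp_usr(mol: Molecule3D) -> Fingerprint:
    """Ultrafast Shape Recognition: 4 reference points x 3 moments.

    The third moment is the excess kurtosis of the distance
    distribution (0 for a degenerate distribution).
    """
    if not mol.has_3d:
        raise ValueError(f"{mol.id}: 3D coordinates required")
    if mol.hac < 2:
        raise ValueError(f"{mol.id}: USR requires at least two atoms")
    refs = _usr_reference_points(mol.coords)
    return Fingerprint("USR", _usr_moments(mol.coords, refs), mol.id)


def fp_usrcat(mol: Molecule3D,
              cats: Optional[AtomCategories] = None) -> Fingerprint:
    """USR over five atom subsets: all, Hyb, aromatic, HBA, HBD.

    Reference points always come from the full molecule; empty subsets
    yield zero blocks.  60 reals (5 x 12).
    """
    if cats is None:
        cats = assign_categories(mol)
    refs = _usr_reference_points(mol.coords)
    subsets = [
        [True] * mol.hac,
        cats.hyb,
        list(mol.aromatic),
        cats.hba,
        cats.hbd,
    ]
    out = np.zeros(60)
    for b, mask in enumerate(subsets):
        idx = [i for i, f in enumerate(mask) if f]
        if idx:
            out[12 * b:12 * (b + 1)] = _usr_moments(mol.coords[idx], refs)
    return Fingerprint("USRCAT", out, mol.id)


# ---------------------------------------------------------------------------
# dispatch + estimator

_SCHEME_3D = {"3DAPfp", "3DXfp", "R3DAPfp", "R3DXfp", "PMIfp", "USR", "USRCAT"}
_NEEDS_CATS = {"3DXfp", "R3DXfp", "Xfp", "USRCAT"}


def compute_fingerprint(mol: Molecule3D, scheme: str,
                        cats: Optional[AtomCategories] = None) -> Fingerprint:
    """Compute any supported scheme for one molecule."""
    if scheme not in SCHEME_LENGTHS:
        raise ValueError(
            f"unknown scheme {scheme!r}; valid: {sorted(SCHEME_LENGTHS)}")
    if scheme in _NEEDS_CATS and cats is None:
        cats = assign_categories(mol)
    dispatch = {
        "3DAPfp": lambda: fp_3dapfp(mol),
        "3DXfp": lambda: fp_3dxfp(mol, cats),
        "R3DAPfp": lambda: fp_r3dapfp(mol),
        "R3DXfp": lambda: fp_r3dxfp(mol, cats),
        "APfp": lambda: fp_apfp(mol),
        "Xfp": lambda: fp_xfp(mol, cats),
        "PMIfp": lambda: fp_pmifp(mol),
        "USR": lambda: fp_usr(mol),
        "USRCAT": lambda: fp_usrcat(mol, cats),
    }
    return dispatch[scheme]()


class FingerprintEncoder(BaseEstimator, TransformerMixin):
    """Transform molecules into fingerprint vectors of one scheme.

    A stateless scikit-learn transformer: ``fit`` only validates the
    scheme; ``transform`` maps a sequence of :class:`Molecule3D` to an
    ``(n, length)`` array whose row order matches the input.

    Parameters
    ----------
    scheme : str, default="3DAPfp"
        One of the keys of :data:`SCHEME_LENGTHS`.

    Attributes
    ----------
    n_features_out_ : int
        Vector length of the fitted scheme.

    Examples
    --------
    >>> from apfp3d.fixtures import make_pair
    >>> enc = FingerprintEncoder(scheme="R3DAPfp").fit([])
    >>> X = enc.transform([make_pair(8.51)])
    >>> int(X[0].argmax()) + 1
    18
    """

    def __init__(self, scheme: str = "3DAPfp"):
        self.scheme = scheme

    def fit(self, X: Iterable[Molecule3D], y=None):
        if self.scheme not in SCHEME_LENGTHS:
            raise ValueError(
                f"unknown scheme {self.scheme!r}; valid: {sorted(SCHEME_LENGTHS)}")
        self.n_features_out_ = SCHEME_LENGTHS[self.scheme]
        return self

    def transform(self, X: Iterable[Molecule3D]) -> np.ndarray:
        if not hasattr(self, "n_features_out_"):
            self.fit(X)
        rows = [compute_fingerprint(m, self.scheme).values for m in X]
        dtype = np.int64 if self.scheme in (
            "3DAPfp", "3DXfp", "R3DAPfp", "R3DXfp", "APfp", "Xfp") else float
        if not rows:
            return np.empty((0, self.n_features_out_), dtype=dtype)
        return np.asarray(rows, dtype=dtype)

    def encode(self, mols: Iterable[Molecule3D]) -> list:
        """Like ``transform`` but returning tagged :class:`Fingerprint`s."""
        self.fit(mols)
        return [compute_fingerprint(m, self.scheme) for m in mols]


# ---------------------------------------------------------------------------
# .fps TSV round-trip: mol_id <TAB> scheme <TAB> comma-separated values

def write_fps(fps: Iterable[Fingerprint], path) -> None:
    """Write fingerprints as a TSV (.fps) file."""
    with open(path, "w") as fh:
        for fp in fps:
            if np.issubdtype(fp.values.dtype, np.integer):
                vals = ",".join(str(int(v)) for v in fp.values)
            else:
                vals = ",".join(f"{v:.6f}" for v in fp.values)
            fh.write(f"{fp.mol_id}\t{fp.scheme}\t{vals}\n")


def read_fps(path) -> list:
    """Read a .fps TSV file back into :class:`Fingerprint` objects."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            mol_id, scheme, vals = line.split("\t")
            if "." in vals:
                values = np.array([float(v) for v in vals.split(",")])
            else:
                values = np.array([int(v) for v in vals.split(",")], dtype=np.int64)
            out.append(Fingerprint(scheme, values, mol_id))
    return out
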