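"""Fingerprint construction checked against literal-formula oracles.

The oracle functions below re-derive every atom-pair scheme from the
written formulas using plain python math (no numpy vectorization, no
shared code paths), so agreement is a genuine cross-check.
"""

import itertools
import math

import numpy as np
import pytest

from apfp3d.atom_typing import assign_categories
from apfp3d.chem_io import Molecule3D
from apfp3d.fingerprints import (SCHEME_LENGTHS, DEFAULT_GRID, Fingerprint,
                                 FingerprintEncoder, compute_fingerprint,
                                 fp_3dapfp, fp_3dxfp, fp_apfp, fp_pmifp,
                                 fp_r3dapfp, fp_r3dxfp, fp_usr, fp_usrcat,
                                 fp_xfp, gaussian_sample, npmi,
                                 pair_distances_3d, pair_distances_topological,
                                 read_fps, write_fps)
from apfp3d.fixtures import (make_chain, make_diastereomer_pair, make_pair,
                             permute_atoms, random_molecule, transform)

GRID = [1.45 * 1.18**k for k in range(16)]


# ---------------------------------------------------------------------------
# oracles: literal re-derivations in plain python

def _round_half_up(x):
    return math.floor(x + 0.5)


def oracle_gaussian_bits(distances, norm):
    bits = [0.0] * 16
    for d in distances:
        if d == 0.0:
            continue
        for n, s in enumerate(GRID):
            bits[n] += math.exp(-((s - d) ** 2) / (2 * (0.18 * d) ** 2))
    return [_round_half_up(100 * b / norm**1.5) for b in bits]


def oracle_regular_bits(distances, norm):
    bits = [0] * 40
    for d in distances:
        k = int(d // 0.5)
        if k < 40:
            bits[k] += 1
    return [_round_half_up(100 * b / norm) for b in bits]


def oracle_topo_bits(topo, norm, max_t):
    bits = [0] * max_t
    for t in topo:
        if 1 <= t <= max_t:
            bits[t - 1] += 1
    return [_round_half_up(100 * b / norm) for b in bits]


def euclid_pairs(mol):
    return [(i, j, math.dist(mol.coords[i], mol.coords[j]))
            for i, j in itertools.combinations(range(mol.hac), 2)]


def bfs_pairs(mol):
    """Topological pair distances by breadth-first search."""
    adj = mol.neighbors()
    out = []
    for i in range(mol.hac):
        dist = {i: 0}
        frontier = [i]
        while frontier:
            nxt = []
            for v in frontier:
                for w in adj[v]:
                    if w not in dist:
                        dist[w] = dist[v] + 1
                        nxt.append(w)
            frontier = nxt
        for j in range(i + 1, mol.hac):
            out.append((i, j, dist[j]))
    return out


def oracle_x_blocks(mol, pairs, block_fn, block_len):
    cats = assign_categories(mol)
    flags = {"hyb": cats.hyb, "hba": cats.hba, "hbd": cats.hbd, "sp2": cats.sp2}
    out = []
    for name in ("hyb", "hba", "hbd", "sp2"):
        count = sum(flags[name])
        if count < 2:
            out += [0] * block_len
        else:
            sel = [d for i, j, d in pairs if flags[name][i] and flags[name][j]]
            out += block_fn(sel, count)
    n_hba, n_hbd = sum(cats.hba), sum(cats.hbd)
    if n_hba == 0 or n_hbd == 0:
        out += [0] * block_len
    else:
        sel = [d for i, j, d in pairs
               if (cats.hba[i] and cats.hbd[j]) or (cats.hbd[i] and cats.hba[j])]
        out += block_fn(sel, n_hba)
    return out


def small_fixtures():
    """<=6-atom fixtures with varied elements and categories."""
    mols = [
        make_pair(8.51, mol_id="p851"),
        make_pair(2.5, ("N", "O"), mol_id="no"),
        make_chain(4, mol_id="c4"),
        make_chain(6, geometry="helix", mol_id="h6"),
        random_molecule(5, seed=11, mol_id="r5"),
        random_molecule(6, seed=12, mol_id="r6"),
    ]
    hetero = random_molecule(6, seed=13, mol_id="het")
    hetero.elements = ["C", "N", "O", "C", "S", "O"]
    hetero.n_hydrogens = [3, 1, 1, 0, 0, 0]
    mols.append(hetero)
    return mols


# ---------------------------------------------------------------------------
# sampling grid + gaussian

def test_grid_matches_printed_series():
    printed = [1.45, 1.71, 2.02, 2.38, 2.81, 3.32, 3.91, 4.62,
               5.45, 6.43, 7.59, 8.96, 10.57, 12.47, 14.71, 17.36]
    np.testing.assert_allclose(DEFAULT_GRID.distances, printed, atol=0.005)
    ratios = DEFAULT_GRID.distances[1:] / DEFAULT_GRID.distances[:-1]
    np.testing.assert_allclose(ratios, 1.18, rtol=1e-12)


def test_gaussian_peak_at_first_grid_point():
    vals = gaussian_sample(1.45)
    assert vals[0] == pytest.approx(1.0)
    assert np.all(np.diff(vals) <= 0)  # monotone decay past the peak


def test_gaussian_matches_hand_formula_at_851():
    vals = gaussian_sample(8.51)
    expected = [math.exp(-((s - 8.51) ** 2) / (2 * (0.18 * 8.51) ** 2))
                for s in GRID]
    np.testing.assert_allclose(vals, expected, rtol=1e-12)


def test_gaussian_far_tail_negligible():
    # width grows with distance, so the far tail asymptotes at
    # exp(-1 / (2 * 0.18^2)) ~ 2e-7 rather than vanishing; it stays
    # far below the percent-scale rounding threshold regardless
    vals = gaussian_sample(1000.0)
    assert np.all(vals < 1e-6)
    assert np.all(np.diff(vals) > 0)  # still rising toward the distant peak


def test_gaussian_zero_distance_suppressed():
    assert np.all(gaussian_sample(0.0) == 0.0)


# ---------------------------------------------------------------------------
# pair distances

def test_pair_distances_3d_contracts():
    mol = make_pair(8.51)
    assert pair_distances_3d(mol) == [(0, 1, pytest.approx(8.51))]
    single = Molecule3D("s", ["C"], np.zeros((1, 3)), [], [0])
    assert pair_distances_3d(single) == []
    tri = Molecule3D("tri", ["C"] * 3,
                     [[0, 0, 0], [2, 0, 0], [1, math.sqrt(3), 0]],
                     [(0, 1, 1.0), (1, 2, 1.0)], [0] * 3)
    assert [d for _, _, d in pair_distances_3d(tri)] == pytest.approx([2.0] * 3)


def test_topological_distances_butane_and_benzene(benzene):
    butane = make_chain(4)
    assert sorted(t for _, _, t in pair_distances_topological(butane)) == \
        [1, 1, 1, 2, 2, 3]
    per_atom = {i: [] for i in range(6)}
    for i, j, t in pair_distances_topological(benzene):
        per_atom[i].append(t)
        per_atom[j].append(t)
    for dists in per_atom.values():
        assert sorted(dists) == [1, 1, 2, 2, 3]


def test_topological_disconnected_raises():
    mol = Molecule3D("dis", ["C"] * 3, np.zeros((3, 3)), [(0, 1, 1.0)], [0] * 3)
    with pytest.raises(ValueError, match="largest_fragment"):
        pair_distances_topological(mol)


def test_apfp_excludes_pairs_beyond_20_bonds():
    chain = make_chain(22)
    fp = fp_apfp(chain)
    # pair (0, 21) at t = 21 contributes nowhere; 21 pairs at t = 1
    assert fp.values[0] == round(100 * 21 / 22)
    topo = dict(((i, j), t) for i, j, t in pair_distances_topological(chain))
    assert topo[(0, 21)] == 21


# ---------------------------------------------------------------------------
# scheme contracts and worked examples

def test_scheme_lengths():
    mol = random_molecule(6, seed=1)
    mol.aromatic = [True, True, False, False, False, False]
    for scheme, length in SCHEME_LENGTHS.items():
        assert len(compute_fingerprint(mol, scheme)) == length


def test_3dapfp_single_atom_zero():
    single = Molecule3D("s", ["C"], np.zeros((1, 3)), [], [0])
    assert np.all(fp_3dapfp(single).values == 0)


def test_3dapfp_two_atom_worked_example():
    fp = fp_3dapfp(make_pair(8.51))
    expected = [_round_half_up(
        100 * math.exp(-((s - 8.51) ** 2) / (2 * (0.18 * 8.51) ** 2)) / 2**1.5)
        for s in GRID]
    assert list(fp.values) == expected


def test_r3dapfp_bin_18_for_851_and_boundary():
    for d in (8.51, 8.50):
        fp = fp_r3dapfp(make_pair(d))
        assert int(np.argmax(fp.values)) + 1 == 18
        assert fp.values[17] == 50  # one pair / HAC 2 * 100
    far = fp_r3dapfp(make_pair(25.0))
    assert np.all(far.values == 0)
    last_bin = fp_r3dapfp(make_pair(19.99))
    assert int(np.argmax(last_bin.values)) + 1 == 40


def test_apfp_butane_hand_count():
    fp = fp_apfp(make_chain(4))
    assert list(fp.values[:3]) == [75, 50, 25]
    assert np.all(fp.values[3:] == 0)


def test_r3dxfp_cross_block_single_pair():
    mol = make_pair(8.51, ("O", "N"), mol_id="cross")
    # make atom 0 a pure acceptor and atom 1 a pure donor
    mol.n_hydrogens = [0, 2]
    cats = assign_categories(mol)
    assert cats.hba == [True, True] and cats.hbd == [False, True]
    cats.hba = [True, False]
    fp = fp_r3dxfp(mol, cats)
    assert fp.values[4 * 40 + 17] == 100  # 1 pair / 1 HBA * 100 in R18
    fp_copy = np.array(fp.values)
    fp_copy[4 * 40 + 17] = 0
    assert np.all(fp_copy == 0)


def test_3dxfp_cross_block_single_pair():
    mol = make_pair(8.51, ("O", "N"), mol_id="cross")
    mol.n_hydrogens = [0, 2]
    cats = assign_categories(mol)
    cats.hba = [True, False]
    fp = fp_3dxfp(mol, cats)
    expected = oracle_gaussian_bits([8.51], 1)
    assert list(fp.values[4 * 16:]) == expected
    assert np.all(fp.values[:4 * 16] == 0)


def test_x_schemes_all_hyb_molecule_equals_parent():
    mol = make_chain(5)  # plain carbons: every atom Hyb, nothing else
    cats = assign_categories(mol)
    assert all(cats.hyb) and not any(cats.hba + cats.hbd + cats.sp2)
    x3d = fp_3dxfp(mol, cats)
    assert list(x3d.values[:16]) == list(fp_3dapfp(mol).values)
    assert np.all(x3d.values[16:] == 0)
    rx = fp_r3dxfp(mol, cats)
    assert list(rx.values[:40]) == list(fp_r3dapfp(mol).values)
    xfp = fp_xfp(mol, cats)
    assert list(xfp.values[:11]) == list(fp_apfp(mol).values[:11])
    assert np.all(xfp.values[11:] == 0)


def test_xfp_pair_beyond_eleven_bonds_contributes_nowhere():
    chain = make_chain(13)  # pair (0, 12) at t = 12
    fp = fp_xfp(chain)
    topo = [t for _, _, t in pair_distances_topological(chain)]
    expected = oracle_topo_bits(topo, 13, 11)
    assert list(fp.values[:11]) == expected


# ---------------------------------------------------------------------------
# oracle equivalence on small fixtures

@pytest.mark.parametrize("mol", small_fixtures(), ids=lambda m: m.id)
def test_atom_pair_schemes_match_literal_oracle(mol):
    dists = [d for _, _, d in euclid_pairs(mol)]
    topo_pairs = bfs_pairs(mol)
    topo = [t for _, _, t in topo_pairs]
    hac = mol.hac
    assert list(fp_3dapfp(mol).values) == oracle_gaussian_bits(dists, hac)
    assert list(fp_r3dapfp(mol).values) == oracle_regular_bits(dists, hac)
    assert list(fp_apfp(mol).values) == oracle_topo_bits(topo, hac, 20)
    assert list(fp_3dxfp(mol).values) == oracle_x_blocks(
        mol, euclid_pairs(mol), oracle_gaussian_bits, 16)
    assert list(fp_r3dxfp(mol).values) == oracle_x_blocks(
        mol, euclid_pairs(mol), oracle_regular_bits, 40)
    assert list(fp_xfp(mol).values) == oracle_x_blocks(
        mol, topo_pairs, lambda t, c: oracle_topo_bits(t, c, 11), 11)


# ---------------------------------------------------------------------------
# shape descriptors

def test_npmi_rod_disc_sphere_corners():
    rod = make_chain(20, mol_id="rod")
    assert npmi(rod) == pytest.approx((0.0, 1.0), abs=1e-9)

    theta = 2 * math.pi * np.arange(12) / 12
    disc_coords = np.column_stack(
        [np.cos(theta), np.sin(theta), np.zeros(12)])
    disc = Molecule3D("disc", ["C"] * 12, disc_coords,
                      [(i, (i + 1) % 12, 1.0) for i in range(12)], [0] * 12)
    assert npmi(disc) == pytest.approx((0.5, 0.5), abs=1e-9)

    octa = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                     [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)
    sphere = Molecule3D("sphere", ["C"] * 6, octa,
                        [(i, i + 1, 1.0) for i in range(5)], [0] * 6)
    assert npmi(sphere) == pytest.approx((1.0, 1.0), abs=1e-9)


def test_pmifp_scales_with_mass(tetrahedron):
    fp = fp_pmifp(tetrahedron)
    assert fp.values.shape == (3,)
    assert fp.values[0] <= fp.values[1] <= fp.values[2]
    # equal point masses at tetrahedron corners: spherical top
    assert fp.values[0] == pytest.approx(fp.values[2])


def test_usr_matches_brute_force_moments(tetrahedron):
    fp = fp_usr(tetrahedron)
    coords = tetrahedron.coords
    ctd = coords.mean(axis=0)
    d_ctd = np.linalg.norm(coords - ctd, axis=1)
    refs = [ctd, coords[np.argmin(d_ctd)], coords[np.argmax(d_ctd)]]
    refs.append(coords[np.argmax(np.linalg.norm(coords - refs[2], axis=1))])
    expected = []
    for ref in refs:
        d = [math.dist(c, ref) for c in coords]
        mean = sum(d) / len(d)
        var = sum((x - mean) ** 2 for x in d) / len(d)
        std = math.sqrt(var)
        kurt = 0.0 if std < 1e-12 else \
            sum((x - mean) ** 4 for x in d) / (len(d) * var**2) - 3.0
        expected += [mean, std, kurt]
    np.testing.assert_allclose(fp.values, expected, atol=1e-12)


def test_usr_zero_spread_on_shell(tetrahedron):
    # all four atoms equidistant from the centroid
    fp = fp_usr(tetrahedron)
    assert fp.values[1] == pytest.approx(0.0, abs=1e-12)  # std of ctd dists
    assert fp.values[2] == 0.0  # kurtosis degenerates to 0


def test_usrcat_block_structure(benzene):
    mol = random_molecule(6, seed=5)
    fp = fp_usrcat(mol)
    assert list(fp.values[:12]) == list(fp_usr(mol).values)
    # plain carbon chain: aromatic, HBA and HBD blocks are zero
    assert np.all(fp.values[24:] == 0)
    # all-aromatic carbocycle: aromatic block equals the all-atom block
    ring = make_chain(6, mol_id="ring")
    ring.aromatic = [True] * 6
    ringfp = fp_usrcat(ring)
    assert list(ringfp.values[24:36]) == list(ringfp.values[:12])


# ---------------------------------------------------------------------------
# invariances

@pytest.mark.parametrize("scheme", sorted(SCHEME_LENGTHS))
def test_rigid_motion_and_mirror_invariance(scheme):
    mol = random_molecule(6, seed=21)
    mol.elements = ["C", "N", "O", "C", "C", "O"]
    mol.n_hydrogens = [2, 1, 1, 0, 0, 0]
    variants = [
        transform(transform(mol, "rotate", axis=(1, 2, 3), angle=0.7),
                  "translate", vector=(5.0, 5.0, 5.0)),
        transform(mol, "mirror", plane="xz"),
    ]
    base = compute_fingerprint(mol, scheme).values
    for var in variants:
        np.testing.assert_allclose(
            compute_fingerprint(var, scheme).values, base, atol=1e-9)


@pytest.mark.parametrize("scheme", sorted(SCHEME_LENGTHS))
def test_permutation_invariance(scheme):
    mol = random_molecule(6, seed=22)
    mol.elements = ["C", "N", "O", "C", "S", "O"]
    mol.n_hydrogens = [2, 1, 1, 0, 0, 0]
    perm = [3, 0, 5, 2, 4, 1]
    base = compute_fingerprint(mol, scheme).values
    permuted = compute_fingerprint(permute_atoms(mol, perm), scheme).values
    np.testing.assert_allclose(permuted, base, atol=1e-9)


def test_diastereomers_share_2d_but_differ_in_3d():
    anti, gauche = make_diastereomer_pair()
    assert list(fp_apfp(anti).values) == list(fp_apfp(gauche).values)
    assert list(fp_xfp(anti).values) == list(fp_xfp(gauche).values)
    assert list(fp_3dapfp(anti).values) != list(fp_3dapfp(gauche).values)
    # sorted pair-distance multisets genuinely differ
    da = sorted(d for _, _, d in euclid_pairs(anti))
    dg = sorted(d for _, _, d in euclid_pairs(gauche))
    assert max(abs(x - y) for x, y in zip(da, dg)) > 0.5


# ---------------------------------------------------------------------------
# encoder + fps round-trip

def test_encoder_transform_shape_and_order():
    mols = [random_molecule(n, seed=n, mol_id=f"r{n}") for n in (3, 5, 7)]
    enc = FingerprintEncoder(scheme="R3DAPfp")
    X = enc.fit(mols).transform(mols)
    assert X.shape == (3, 40)
    assert list(X[1]) == list(fp_r3dapfp(mols[1]).values)
    assert enc.get_params() == {"scheme": "R3DAPfp"}
    assert enc.transform([]).shape == (0, 40)


def test_encoder_rejects_unknown_scheme():
    with pytest.raises(ValueError, match="unknown scheme"):
        FingerprintEncoder(scheme="BOGUS").fit([])


def test_fps_round_trip(tmp_path):
    mols = [random_molecule(n, seed=n, mol_id=f"r{n}") for n in (3, 5)]
    fps = FingerprintEncoder(scheme="3DAPfp").encode(mols)
    fps += FingerprintEncoder(scheme="USR").encode(mols[:1])
    p = tmp_path / "db.fps"
    write_fps(fps, p)
    back = read_fps(p)
    assert [f.mol_id for f in back] == [f.mol_id for f in fps]
    for orig, rt in zip(fps, back):
        assert orig.scheme == rt.scheme
        np.testing.assert_allclose(rt.values, orig.values, atol=1e-6)
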