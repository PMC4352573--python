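# apfp3d — stereoselective 3D atom-pair fingerprints for virtual screening

`apfp3d` is a library and command-line tool for ligand-based virtual
screening (LBVS) with through-space atom-pair fingerprints.  Topological
fingerprints cannot tell diastereomers or conformers of one molecule apart,
because every stereoisomer shares the same bond graph.  Encoding the
*euclidean* distances between heavy-atom pairs instead makes the descriptor
sensitive to 3D shape, conformation and relative stereochemistry, while
staying a fixed-length integer vector that can be searched exactly over
millions of compounds in a sum-sorted index.

## Fingerprint schemes

For a molecule with heavy atom count HAC, each unordered heavy-atom pair
(A, B) at through-space distance d_AB contributes to:

* **3DAPfp** (16 bits, shape): a gaussian g(s) = exp(−(s − d_AB)² / (2σ²))
  with σ = 0.18·d_AB, sampled at 16 geometric distances s_n = 1.45·1.18ⁿ Å
  (1.45 … 17.36 Å).  Per-bit sums are divided by HAC^1.5, scaled by 100 and
  rounded.
* **R3DAPfp** (40 bits, shape): an increment of 1 in the half-open 0.5-Å
  bin [0.5(k−1), 0.5k) containing d_AB, for 0 ≤ d_AB < 20 Å; bin counts
  divided by HAC, scaled by 100 and rounded.
* **3DXfp** (80 bits) and **R3DXfp** (200 bits, pharmacophore): the same
  constructions computed within five pharmacophore category blocks —
  Hyb–Hyb, HBA–HBA, HBD–HBD, sp2–sp2 and the HBA–HBD cross-pair —
  normalized per category count (the cross block to the HBA count).
* **APfp** (20 bits) and **Xfp** (55 bits): the topological parents, with
  bond-count shortest-path distances in place of d_AB.
* **PMIfp / nPMI, USR, USRCAT**: comparison shape descriptors — normalized
  principal moments of inertia (the rod–disc–sphere shape triangle), and
  Ultrafast Shape Recognition moments (mean, standard deviation, excess
  kurtosis of distances to four reference points), plain and
  category-extended.

Similarity is the city-block distance CBD(a, b) = Σ|aᵢ − bᵢ|.  Because
|Σa − Σb| ≤ CBD(a, b), a database sorted by total bit sum supports exact
k-NN and range queries with early termination — the "sum as hash function"
search used by the package's `SumHashNeighbors` estimator.

## Worked example

A single atom pair at 8.51 Å is the canonical construction example:

```python
>>> from apfp3d import fixtures, fp_3dapfp, fp_r3dapfp
>>> pair = fixtures.make_pair(8.51)
>>> list(fp_r3dapfp(pair).values)
[0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 50,
 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]
>>> list(fp_3dapfp(pair).values)
[0, 0, 0, 0, 0, 0, 0, 1, 5, 14, 30, 34, 14, 1, 0, 0]
```

In the regular scheme the pair lands in bin **R18** (8.5–9.0 Å) with value
100·1/HAC = 50.  In the gaussian scheme the same pair spreads over
neighboring sampling points — the peak bits 11 and 12 flank the 7.59 Å and
8.96 Å sampling distances around 8.51 Å, each value being
round(100·g(s_n)/2^1.5).  This fuzziness is what lets the gaussian scheme
tolerate small geometry changes that the hard bins do not.

The same pipeline from the shell:

```sh
apfp3d fixtures --kind pair --d 8.51 --out pair.sdf
apfp3d fp --scheme R3DAPfp --in pair.sdf --out pair.fps
apfp3d search --index db.fps --query-sdf pair.sdf --scheme R3DAPfp \
    --k 100 --out hits.tsv
```

`hits.tsv` lists rank, molecule id and CBD for the exact 100 nearest
neighbors.

## Layout

```
src/apfp3d/
  chem_io.py             SDF/MOL2/SMILES I/O, fragment + HAC filters
  atom_typing.py         Hyb/HBA/HBD/sp2 pharmacophore flags
  fingerprints.py        all schemes + FingerprintEncoder (sklearn transformer)
  similarity_search.py   CBD, Tanimoto, sum-hash index, SumHashNeighbors
  benchmarking.py        ROC AUC, enrichment factors, shape triangle, overlaps
  fixtures.py            exact synthetic point-set molecules
  cli.py                 the `apfp3d` command
docs/methods.md          model description, parameters, design notes
```
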