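"""Evaluation machinery for ligand-based virtual screening.

Recovery of a set of "actives" from a ranked database is scored by
the rank-based ROC AUC (probability that a random active outranks a
random inactive, ties counting one half) and by enrichment factors
EF_f = (fraction of actives recovered in the top f of the ranking)/f.

Shape coverage of a molecule set is summarized as an occupancy
histogram over the normalized-principal-moment-of-inertia triangle
with corners rod = (0, 1), disc = (0.5, 0.5) and sphere = (1, 1).

The stereoselectivity of a fingerprint is quantified by partitioning
the union of three nearest-neighbor hit lists (e.g. two diastereomers
searched with a 3D scheme plus the shared 2D-scheme search) into the
seven regions of their Venn diagram.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, Optional

import numpy as np
from sklearn.metrics import roc_auc_score

from .chem_io import Molecule3D
from .fingerprints import npmi
from .similarity_search import RankedHits

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledRanking",
    "OverlapPartition",
    "roc_auc",
    "enrichment_factor",
    "shape_triangle",
    "nn_overlap",
    "size_constrained_actives",
]


@dataclass
class LabeledRanking:
    """A best-first ranking of mol_ids with a designated active subset.

    ``scores`` (optional, same order, higher = better) carry tie
    information; without them every rank is distinct.
    """

    ranked_ids: list
    active_ids: set
    scores: Optional[list] = None

    def __post_init__(self):
        self.active_ids = set(self.active_ids)
        if len(set(self.ranked_ids)) != len(self.ranked_ids):
            raise ValueError("duplicate ids in ranking")
        if not self.active_ids <= set(self.ranked_ids):
            raise ValueError("active ids must be a subset of ranked ids")
        if self.scores is not None and len(self.scores) != len(self.ranked_ids):
            raise ValueError("scores must parallel ranked_ids")


def roc_auc(r: LabeledRanking) -> float:
    """Rank-based ROC AUC of recovering the actives, ties counting 1/2."""
    labels = np.array([mid in r.active_ids for mid in r.ranked_ids], dtype=int)
    n_act = int(labels.sum())
    if n_act == 0 or n_act == len(labels):
        raise ValueError("AUC needs at least one active and one inactive")
    if r.scores is not None:
        scores = np.asarray(r.scores, dtype=float)
    else:
        scores = -np.arange(len(labels), dtype=float)  # best-first order
    return float(roc_auc_score(labels, scores))


def enrichment_factor(r: LabeledRanking, fraction: float) -> float:
    """Enrichment factor at the given coverage fraction.

    EF_f = (actives within the top ceil(f * N) ranks / total actives) / f.
    Bounded above by 1/f.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n_act = len(r.active_ids)
    if n_act == 0:
        raise ValueError("enrichment needs at least one active")
    top = r.ranked_ids[:math.ceil(fraction * len(r.ranked_ids))]
    found = sum(1 for mid in top if mid in r.active_ids)
    return (found / n_act) / fraction


_TRIANGLE_TOL = 1e-6


def shape_triangle(mols: Iterable[Molecule3D], pixels: int = 50) -> np.ndarray:
    """Occupancy histogram of nPMI values over the shape triangle.

    Returns a (pixels, pixels) count array over I1/I3 in [0, 1] and
    I2/I3 in [0.5, 1]; a molecule whose nPMI falls outside the
    triangle beyond tolerance is counted with a warning.
    """
    hist = np.zeros((pixels, pixels))
    for mol in mols:
        x, y = npmi(mol)
        if (x + y < 1 - _TRIANGLE_TOL or y > 1 + _TRIANGLE_TOL
                or y < x - _TRIANGLE_TOL):
            logger.warning("%s: nPMI (%.4f, %.4f) outside shape triangle",
                           mol.id, x, y)
        ix = min(int(np.clip(x, 0, 1) * pixels), pixels - 1)
        iy = min(int((np.clip(y, 0.5, 1) - 0.5) * 2 * pixels), pixels - 1)
        hist[ix, iy] += 1
    return hist


@dataclass
class OverlapPartition:
    """Seven-way partition of the union of three hit-id sets."""

    only_a: int
    only_b: int
    only_c: int
    ab: int
    ac: int
    bc: int
    abc: int
    shared_fraction_ab: float
    shared_fraction_ac: float
    shared_fraction_bc: float

    @property
    def union_size(self) -> int:
        return (self.only_a + self.only_b + self.only_c
                + self.ab + self.ac + self.bc + self.abc)


def nn_overlap(a: RankedHits, b: RankedHits, c: RankedHits) -> OverlapPartition:
    """Partition three hit lists over one database into Venn regions.

    Also reports pairwise shared fractions, |A ∩ B| divided by the
    longer of the two list lengths.
    """
    sa, sb, sc = set(a.ids()), set(b.ids()), set(c.ids())

    def frac(x: set, y: set) -> float:
        denom = max(len(x), len(y))
        return len(x & y) / denom if denom else 0.0

    return OverlapPartition(
        only_a=len(sa - sb - sc),
        only_b=len(sb - sa - sc),
        only_c=len(sc - sa - sb),
        ab=len((sa & sb) - sc),
        ac=len((sa & sc) - sb),
        bc=len((sb & sc) - sa),
        abc=len(sa & sb & sc),
        shared_fraction_ab=frac(sa, sb),
        shared_fraction_ac=frac(sa, sc),
        shared_fraction_bc=frac(sb, sc),
    )


def size_constrained_actives(hac_by_id: Dict[str, int], query_hac: int,
                             window: int = 2) -> list:
    """Ids whose heavy atom count lies within ``query_hac`` +/- ``window``.

    Reproduces the size-constrained database subset used when
    recovering shape analogs of a query (all molecules of size
    HAC +/- 2 by default).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    return [mid for mid, hac in hac_by_id.items()
            if abs(hac - query_hac) <= window]
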