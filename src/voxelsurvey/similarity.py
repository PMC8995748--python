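"""Pairwise voxel similarities and the survey-size bounds [C_max, C_min].

Each retained voxel is a point p_i = (vm_i, vn_i) in the plane of group
summaries.  The similarity statistic between two voxels is the *squared*
Euclidean distance

    rho(p_i, p_j) = (vm_i - vm_j)^2 + (vn_i - vn_j)^2

(no square root — small rho means near-duplicate voxels).  For tractability
the voxel list is partitioned into g contiguous blocks and the full matrix
is held as the g*(g+1)/2 block-pair matrices (g = 10 gives 55).

The number of distinct voxels participating in ties at the global minimum
of rho is C_min, and at the global maximum is C_max; the survey size l of
the random-survey feature selection is then drawn from [C_max, C_min].
Near-duplicate voxels produce many ties at rho ~ 0, so C_min naturally
exceeds C_max.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .prep import VoxelPairVector

logger = logging.getLogger(__name__)

DEFAULT_EXTREMUM_TOL = 1e-9


def pair_similarity(p_i, p_j) -> float:
    """Squared-distance similarity between two (vm, vn) voxel pairs.

    Symmetric, nonnegative, and zero iff the two pairs coincide.
    """
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    if not (np.all(np.isfinite(p_i)) and np.all(np.isfinite(p_j))):
        raise ValueError("pair_similarity requires finite inputs")
    d = p_i - p_j
    return float(d @ d)


@dataclass
class SimilarityBlockSet:
    """Block-partitioned pairwise similarity matrices.

    ``matrices`` holds one entry per unordered block pair (a <= b), each a
    dense matrix of rho values between the voxels of block a (rows) and
    block b (columns); within-block matrices are symmetric with zero
    diagonal.  ``block_ranges`` are the contiguous [start, stop) index
    ranges of the blocks over the voxel-pair vector.
    """

    g: int
    block_ranges: list[tuple[int, int]]
    matrices: list[tuple[int, int, np.ndarray]]

    @property
    def n_matrices(self) -> int:
        return len(self.matrices)

    def dense(self) -> np.ndarray:
        """Reassemble the full |V'| x |V'| similarity matrix."""
        n = self.block_ranges[-1][1]
        full = np.zeros((n, n))
        for a, b, mat in self.matrices:
            ra, rb = self.block_ranges[a], self.block_ranges[b]
            full[ra[0]:ra[1], rb[0]:rb[1]] = mat
            if a != b:
                full[rb[0]:rb[1], ra[0]:ra[1]] = mat.T
        return full


@dataclass(frozen=True)
class FeatureBounds:
    """Valid survey-size interval: c_max <= l <= c_min."""

    c_max: int
    c_min: int
    extremum_tol: float = DEFAULT_EXTREMUM_TOL

    def __post_init__(self):
        if not (1 <= self.c_max <= self.c_min):
            raise ValueError(
                f"invalid bounds: need 1 <= c_max <= c_min, got "
                f"c_max={self.c_max}, c_min={self.c_min}"
            )


def _points(pairs) -> np.ndarray:
    if isinstance(pairs, VoxelPairVector):
        return np.column_stack([pairs.vm, pairs.vn])
    pts = np.asarray(pairs, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected a VoxelPairVector or an (n, 2) array")
    return pts


def block_ranges(n: int, g: int) -> list[tuple[int, int]]:
    """g contiguous near-equal ranges; sizes differ by at most 1 (the
    remainder is spread over the first blocks)."""
    base, rem = divmod(n, g)
    ranges, start = [], 0
    for i in range(g):
        size = base + (1 if i < rem else 0)
        ranges.append((start, start + size))
        start += size
    return ranges


def block_similarity(pairs, g: int = 10) -> SimilarityBlockSet:
    """Partition the voxel list into g contiguous blocks and compute all
    g*(g+1)/2 block-pair similarity matrices (g = 10 gives the canonical
    55 matrices)."""
    pts = _points(pairs)
    n = len(pts)
    if g < 1:
        raise ValueError(f"g must be >= 1, got {g}")
    if g > n:
        raise ValueError(f"g ({g}) exceeds number of voxel pairs ({n})")
    ranges = block_ranges(n, g)
    matrices = []
    for a in range(g):
        for b in range(a, g):
            ra, rb = ranges[a], ranges[b]
            mat = cdist(pts[ra[0]:ra[1]], pts[rb[0]:rb[1]], metric="sqeuclidean")
            if a == b:
                np.fill_diagonal(mat, 0.0)  # exact zero self-similarity
            matrices.append((a, b, mat))
    return SimilarityBlockSet(g=g, block_ranges=ranges, matrices=matrices)


def feature_count_bounds(
    blocks: SimilarityBlockSet, extremum_tol: float = DEFAULT_EXTREMUM_TOL
) -> FeatureBounds:
    """Count the voxels tied at the global similarity extrema.

    C_min is the number of distinct voxels participating in at least one
    off-diagonal rho within ``extremum_tol`` (relative to the extremum
    scale) of the global minimum; C_max the same for the global maximum.
    Self-similarities (within-block diagonals) are excluded, otherwise the
    minimum would always be 0.  If the computed C_max exceeds C_min the two
    are swapped so the interval [c_max, c_min] stays valid, with a warning.
    """
    n = blocks.block_ranges[-1][1]
    if n < 2:
        raise ValueError("need at least 2 voxels to compute bounds")

    def offdiag(a, b, mat):
        if a != b:
            return mat
        iu = np.triu_indices(mat.shape[0], k=1)
        return mat[iu]

    gmin = min(offdiag(a, b, m).min() for a, b, m in blocks.matrices if offdiag(a, b, m).size)
    gmax = max(offdiag(a, b, m).max() for a, b, m in blocks.matrices if offdiag(a, b, m).size)

    scale = max(abs(gmin), abs(gmax))
    atol = extremum_tol * scale

    def rows_at(target):
        hit = np.zeros(n, dtype=bool)
        for a, b, mat in blocks.matrices:
            close = np.abs(mat - target) <= atol
            if a == b:
                np.fill_diagonal(close, False)
            ra, rb = blocks.block_ranges[a], blocks.block_ranges[b]
            hit[ra[0]:ra[1]] |= close.any(axis=1)
            hit[rb[0]:rb[1]] |= close.any(axis=0)
        return int(hit.sum())

    c_min = rows_at(gmin)  # ties at the minimum (near-duplicates): upper bound
    c_max = rows_at(gmax)  # ties at the maximum: lower bound
    if c_max > c_min:
        logger.warning(
            "computed C_max (%d) > C_min (%d); swapping to keep a valid interval",
            c_max, c_min,
        )
        c_max, c_min = c_min, c_max
    return FeatureBounds(c_max=c_max, c_min=c_min, extremum_tol=extremum_tol)
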