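"""Group matrices, voxel-pair vector and the subjects x voxels feature matrix.

Per-voxel group summaries M (disease) and N (control) are weighted means of
the group's maps.  The voxel-pair vector pairs them as (vm_i, vn_i) per
voxel and drops "equal" voxels — those with |vm - vn| below a tolerance —
as carrying no between-group information.  The feature matrix then gathers
each subject's raw density at every retained voxel.

All flattening is 0-based C order (row-major; last axis fastest), recorded
in outputs as ``flatten_order="C"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CONTROL, DISEASE, GmdCohort

DEFAULT_TOL = 1e-12


@dataclass(frozen=True)
class GroupVoxelVector:
    """Weighted per-voxel group summary (matrix M or N, flattened)."""

    values: np.ndarray
    group: int
    dims: tuple[int, int, int]
    flatten_order: str = "C"

    def __post_init__(self):
        if self.values.shape != (int(np.prod(self.dims)),):
            raise ValueError(
                f"values length {self.values.shape} inconsistent with dims {self.dims}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("group vector contains non-finite values")


@dataclass
class VoxelPairVector:
    """Retained voxels with their (vm, vn) group values and 3D coordinates.

    ``linear_index`` is strictly increasing; ``coords[j]`` is the C-order
    unravelling of ``linear_index[j]`` in ``source_dims``.  ``n_total`` and
    ``n_deleted`` record the filtering bookkeeping
    (``n_total = len(linear_index) + n_deleted``).
    """

    linear_index: np.ndarray
    coords: np.ndarray
    vm: np.ndarray
    vn: np.ndarray
    source_dims: tuple[int, int, int]
    tol: float = DEFAULT_TOL
    flatten_order: str = "C"
    n_total: int = 0
    n_deleted: int = 0

    def __len__(self) -> int:
        return len(self.linear_index)

    @property
    def n_retained(self) -> int:
        return len(self.linear_index)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (linear_index, x, y, z, vm, vn)."""
        return pd.DataFrame(
            {
                "linear_index": self.linear_index,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
                "vm": self.vm,
                "vn": self.vn,
            }
        )


@dataclass
class FeatureMatrix:
    """Subjects x retained-voxels density matrix with labels in {-1, +1}."""

    X: np.ndarray
    y: np.ndarray
    column_index: np.ndarray
    dims: tuple[int, int, int] | None = None
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.X.shape[0] != len(self.y):
            raise ValueError("X rows and y length differ")
        if self.X.shape[1] != len(self.column_index):
            raise ValueError("X columns and column_index length differ")
        bad = set(np.unique(self.y)) - {DISEASE, CONTROL}
        if bad:
            raise ValueError(f"labels must be in {{-1, +1}}, found {sorted(bad)}")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def compute_group_matrices(
    cohort: GmdCohort, weights: np.ndarray | None = None
) -> tuple[GroupVoxelVector, GroupVoxelVector]:
    """Weighted per-voxel mean of each group's maps.

    Parameters
    ----------
    cohort : GmdCohort
    weights : array of float, optional
        Nonnegative per-subject weights in cohort order; uniform if omitted.
        Each group's weights must sum to a positive value.

    Returns
    -------
    (M, N) : tuple of GroupVoxelVector
        Disease summary M and control summary N.
    """
    labels = cohort.labels
    if weights is None:
        weights = np.ones(cohort.n_subjects)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (cohort.n_subjects,):
        raise ValueError(
            f"weights length {weights.shape} != number of subjects {cohort.n_subjects}"
        )
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")

    out = {}
    for group in (DISEASE, CONTROL):
        idx = np.flatnonzero(labels == group)
        if idx.size == 0:
            raise ValueError(f"cohort has no subjects in group {group}")
        w = weights[idx]
        total = w.sum()
        if total <= 0:
            raise ValueError(f"weights for group {group} sum to zero")
        stack = np.stack([cohort.maps[i].data.ravel(order="C") for i in idx])
        out[group] = GroupVoxelVector(
            values=(w @ stack) / total, group=group, dims=cohort.dims
        )
    return out[DISEASE], out[CONTROL]


def build_voxel_pairs(
    M: GroupVoxelVector, N: GroupVoxelVector, tol: float = DEFAULT_TOL
) -> VoxelPairVector:
    """Pair the group summaries per voxel and delete "equal" voxels.

    A voxel is retained iff ``|vm - vn| > tol``; voxels where the two group
    summaries coincide carry no between-group signal.  Order is preserved
    and the retained/deleted counts always sum to the total voxel count.
    """
    if M.dims != N.dims:
        raise ValueError(f"dims mismatch: M {M.dims} vs N {N.dims}")
    if tol < 0:
        raise ValueError(f"tol must be >= 0, got {tol}")
    keep = np.abs(M.values - N.values) > tol
    linear = np.flatnonzero(keep)
    coords = np.column_stack(np.unravel_index(linear, M.dims, order="C"))
    return VoxelPairVector(
        linear_index=linear,
        coords=coords,
        vm=M.values[linear],
        vn=N.values[linear],
        source_dims=M.dims,
        tol=tol,
        n_total=M.values.size,
        n_deleted=int(M.values.size - linear.size),
    )


def assemble_feature_matrix(cohort: GmdCohort, pairs: VoxelPairVector) -> FeatureMatrix:
    """Gather each subject's density at every retained voxel.

    ``X[s, j]`` is subject ``s``'s density at voxel ``pairs.linear_index[j]``;
    ``y`` is -1 for disease and +1 for control.
    """
    if tuple(pairs.source_dims) != tuple(cohort.dims):
        raise ValueError(
            f"pairs built for dims {pairs.source_dims}, cohort has {cohort.dims}"
        )
    n_voxels = int(np.prod(cohort.dims))
    if len(pairs) and (pairs.linear_index.min() < 0 or pairs.linear_index.max() >= n_voxels):
        raise ValueError("pair index out of range for cohort dims")
    X = np.empty((cohort.n_subjects, len(pairs)))
    for s, m in enumerate(cohort.maps):
        X[s] = m.data.ravel(order="C")[pairs.linear_index]
    return FeatureMatrix(
        X=X,
        y=cohort.labels,
        column_index=pairs.linear_index.copy(),
        dims=cohort.dims,
        subject_ids=[m.subject_id for m in cohort.maps],
    )
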